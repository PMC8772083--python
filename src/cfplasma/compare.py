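"""Matched plasma/tumour shared-vs-unique classification and summaries.

Somatic SNV sets from a patient's plasma and tumour samples are intersected
on exact site identity (chromosome, position, ref, alt); shared percentages
are computed relative to each sample's own total. Mutational burden is
SNV count per callable megabase (default 3000 Mb, a whole-genome callable
size). A minimal coding-effect annotator classifies variants against toy
CDS gene models under the standard genetic code.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

from .simulate import GeneModel, revcomp

Site = tuple[str, int, str, str]  # chrom, pos1, ref, alt

DEFAULT_CALLABLE_MB = 3000.0


@dataclass
class PairedVariantSet:
    patient: str
    plasma: set[Site]
    tumour: set[Site]
    shared: set[Site]
    unique_plasma: set[Site]
    unique_tumour: set[Site]

    @property
    def pct_shared_plasma(self) -> float:
        return 100.0 * len(self.shared) / len(self.plasma) if self.plasma else 0.0

    @property
    def pct_shared_tumour(self) -> float:
        return 100.0 * len(self.shared) / len(self.tumour) if self.tumour else 0.0


def classify_shared(plasma_calls, tumour_calls, patient: str = "patient") -> PairedVariantSet:
    """Intersect two somatic call sets on exact (chrom, pos, ref, alt) identity.

    Accepts site tuples or objects with a ``site`` attribute. Duplicate site
    identities within one input are an error.
    """
    def as_sites(calls, label):
        sites = [c if isinstance(c, tuple) else c.site for c in calls]
        if len(sites) != len(set(sites)):
            raise ValueError(f"duplicate site identities in {label} call set")
        return set(sites)

    plasma = as_sites(plasma_calls, "plasma")
    tumour = as_sites(tumour_calls, "tumour")
    shared = plasma & tumour
    return PairedVariantSet(patient, plasma, tumour, shared,
                            plasma - shared, tumour - shared)


def mutation_burden(n_snvs: int, callable_mb: float = DEFAULT_CALLABLE_MB) -> float:
    """Somatic mutations per callable megabase, rounded to 2 decimals."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    return round(n_snvs / callable_mb, 2)


# ---------------------------------------------------------------------------
# minimal functional annotation

_STANDARD_TABLE = None


def _translate(codon: str) -> str:
    global _STANDARD_TABLE
    if _STANDARD_TABLE is None:
        from Bio.Data import CodonTable

        _STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


@dataclass
class AnnotationRecord:
    site: Site
    region: str  # exonic | intronic | intergenic
    effect: str  # synonymous | missense | nonsense | none
    gene: str | None = None
    aa_change: str | None = None


def annotate(site: Site, gene_models: list[GeneModel],
             reference: dict[str, str],
             intron_flank: int = 500) -> AnnotationRecord:
    """Classify one SNV against toy CDS models.

    A variant inside a CDS interval is exonic and gets a codon-level effect
    (substituting the alt base in frame, reverse-complemented on the minus
    strand); a variant within ``intron_flank`` bp of a gene on the same
    chromosome is labelled intronic (stand-in for the rest of the gene
    body); anything else is intergenic.
    """
    chrom, pos1, ref, alt = site
    pos0 = pos1 - 1
    seq = reference[chrom]
    if seq[pos0] != ref:
        raise ValueError(f"reference mismatch at {chrom}:{pos1}: "
                         f"expected {ref}, found {seq[pos0]}")

    for g in gene_models:
        if g.chrom != chrom or not (g.start0 <= pos0 < g.end0):
            continue
        usable = ((g.end0 - g.start0 - g.frame) // 3) * 3
        if g.strand == "+":
            cds_start = g.start0 + g.frame
            cds_pos = pos0 - cds_start
            cds = seq[cds_start:cds_start + usable]
            mut_base = alt
        else:
            cds_end = g.end0 - g.frame  # reading starts at the right edge
            cds_pos = (cds_end - 1) - pos0
            cds = revcomp(seq[cds_end - usable:cds_end])
            mut_base = revcomp(alt)
        if not 0 <= cds_pos < usable:
            # inside the interval but past the last complete codon
            return AnnotationRecord(site, "exonic", "none", g.name)
        codon_idx = cds_pos // 3
        within = cds_pos % 3
        codon = cds[codon_idx * 3:codon_idx * 3 + 3]
        mut = codon[:within] + mut_base + codon[within + 1:]
        aa_ref, aa_alt = _translate(codon), _translate(mut)
        if aa_alt == "*" and aa_ref != "*":
            effect = "nonsense"
        elif aa_alt != aa_ref:
            effect = "missense"
        else:
            effect = "synonymous"
        return AnnotationRecord(site, "exonic", effect, g.name,
                                f"{aa_ref}{codon_idx + 1}{aa_alt}")

    for g in gene_models:
        if g.chrom == chrom and g.start0 - intron_flank <= pos0 < g.end0 + intron_flank:
            return AnnotationRecord(site, "intronic", "none", g.name)
    return AnnotationRecord(site, "intergenic", "none")


# ---------------------------------------------------------------------------
# cohort summary


def summarize_cohort(
    samples: dict[str, list[Site] | set[Site]],
    paired: dict[str, PairedVariantSet],
    annotations: dict[str, list[AnnotationRecord]] | None = None,
    callable_mb: float = DEFAULT_CALLABLE_MB,
) -> pd.DataFrame:
    """One row per sample: SNV count, burden, annotation and sharing columns.

    ``samples`` maps sample name (ending _P0 for plasma, _T0 for tumour) to
    its final somatic call sites; ``paired`` maps patient id to its
    plasma/tumour intersection. Cohort mean rows are appended.
    """
    rows = []
    for name, sites in samples.items():
        n = len(sites)
        ann = (annotations or {}).get(name)
        exonic = sum(a.region == "exonic" for a in ann) if ann else None
        nonsyn = (sum(a.effect in ("missense", "nonsense") for a in ann)
                  if ann else None)
        intronic = sum(a.region == "intronic" for a in ann) if ann else None
        patient = name.rsplit("_", 1)[0]
        pv = paired.get(patient)
        shared = pct = None
        if pv is not None:
            shared = len(pv.shared)
            pct = (round(pv.pct_shared_plasma, 1) if name.endswith("_P0")
                   else round(pv.pct_shared_tumour, 1))
        rows.append({
            "sample": name, "n_snvs": n,
            "mutations_per_mb": mutation_burden(n, callable_mb),
            "exonic": exonic, "nonsynonymous": nonsyn, "intronic": intronic,
            "shared": shared, "pct_shared": pct,
        })
    df = pd.DataFrame(rows)
    plasma = df[df["sample"].str.endswith("_P0")]
    tumour = df[df["sample"].str.endswith("_T0")]
    means = []
    if len(plasma):
        means.append({"sample": "mean_plasma",
                      "n_snvs": round(plasma["n_snvs"].mean()),
                      "mutations_per_mb": round(plasma["mutations_per_mb"].mean(), 2)})
    if len(tumour):
        means.append({"sample": "mean_tumour",
                      "n_snvs": round(tumour["n_snvs"].mean()),
                      "mutations_per_mb": round(tumour["mutations_per_mb"].mean(), 2)})
    if means:
        df = pd.concat([df, pd.DataFrame(means)], ignore_index=True)
    return df


def load_published_cohort() -> pd.DataFrame:
    """Per-sample somatic SNV counts from a published breast-cancer cfDNA
    deep-WGS cohort (four cancer patients with matched tumour, two benign).

    Columns: sample, patient, specimen (plasma/tumour), n_snvs, exonic,
    nonsynonymous, intronic, shared (SNVs found in the matched sample;
    absent for the benign patients, who had no tumour sequenced).
    """
    path = importlib.resources.files("cfplasma") / "data" / "cohort_snv_counts.tsv"
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    return df
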