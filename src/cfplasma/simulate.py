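"""Synthetic matched germline/tumour/plasma cfDNA study generator.

Emulates the statistical structure a plasma-vs-tumour somatic analysis
assumes: a random reference genome with toy CDS gene models, germline
heterozygous variants, clonal tumour mutations drawn from one 96-context
signature, plasma-background mutations drawn from a distinct signature,
per-site binomial read sampling at configurable depth, and plasma fragments
whose lengths follow a mono-/di-nucleosome Gaussian mixture that differs
between tumour-derived and background molecules.

The clonal heterozygous model ties allele fractions to mixture proportions:
a tumour mutation has VAF = purity/2 in the tumour tissue sample and
VAF = tumour_fraction/2 in plasma.

All randomness flows from a single master seed; each stage draws from its own
deterministically derived stream so stages stay reproducible independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

PILEUP_COLUMNS = [
    "chrom", "pos1", "ref", "sample", "depth", "ref_count", "alt_base",
    "alt_count", "mean_baseq_ref", "mean_baseq_alt", "mean_mapq",
    "fwd_alt", "rev_alt", "mean_readpos_alt",
]

FRAGMENT_COLUMNS = [
    "fragment_id", "chrom", "start0", "end0", "length",
    "covered_variant_id", "carried_allele",
]

# stage offsets for per-stage RNG streams derived from the master seed
_STAGES = {
    "reference": 0, "germline": 1, "tumour_mutations": 2,
    "background_mutations": 3, "pileup": 4, "fragments": 5,
    "germline_fragments": 6,
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FragmentLengthModel:
    """Two-component truncated Gaussian mixture of cfDNA fragment lengths.

    Components sit at the mono-nucleosome (~166 bp) and di-nucleosome
    (~332 bp) protection peaks; lengths are truncated to [50, 2000] bp.
    """

    mono_weight: float = 0.85
    di_weight: float = 0.15
    mono_mean: float = 166.0
    mono_sd: float = 10.0
    di_mean: float = 332.0
    di_sd: float = 25.0
    min_length: int = 50
    max_length: int = 2000

    def validate(self) -> None:
        if not np.isclose(self.mono_weight + self.di_weight, 1.0):
            raise ValueError("fragment length mixture weights must sum to 1")
        if min(self.mono_weight, self.di_weight) < 0:
            raise ValueError("mixture weights must be non-negative")
        if self.min_length <= 0 or self.max_length <= self.min_length:
            raise ValueError("invalid truncation bounds")

    @property
    def mean_length(self) -> float:
        return self.mono_weight * self.mono_mean + self.di_weight * self.di_mean

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n integer lengths; out-of-range draws are redrawn."""
        if n == 0:
            return np.zeros(0, dtype=int)
        out = np.empty(n, dtype=int)
        filled = 0
        while filled < n:
            m = n - filled
            comp = rng.random(m) < self.di_weight
            vals = np.where(
                comp,
                rng.normal(self.di_mean, self.di_sd, m),
                rng.normal(self.mono_mean, self.mono_sd, m),
            )
            vals = np.rint(vals).astype(int)
            ok = (vals >= self.min_length) & (vals <= self.max_length)
            k = int(ok.sum())
            out[filled:filled + k] = vals[ok]
            filled += k
        return out


@dataclass
class GeneModel:
    """Toy CDS interval (0-based half-open) with strand and reading frame."""

    chrom: str
    start0: int
    end0: int
    strand: str  # "+" or "-"
    frame: int   # 0/1/2 offset of the first complete codon
    name: str


def default_tumour_signature() -> np.ndarray:
    """Illustrative tumour-like profile: C>T dominant with a C>A component.

    Mimics the C>T-heavy substitution spectrum typical of breast tumour
    genomes without reproducing any catalogued signature.
    """
    from .signatures import CHANNELS

    w = np.full(96, 0.15 / 96)
    for i, ch in enumerate(CHANNELS):
        if ch.substitution == "C>T":
            w[i] += 0.55 / 16
            if ch.context[2] == "G":  # extra weight at CpG sites
                w[i] += 0.10 / 4
        elif ch.substitution == "C>A":
            w[i] += 0.20 / 16
    return w / w.sum()


def default_background_signature() -> np.ndarray:
    """Illustrative plasma-background profile: T>C dominant, flat remainder.

    Mimics the T>C-enriched spectrum reported for non-tumour plasma
    somatic mutations.
    """
    from .signatures import CHANNELS

    w = np.full(96, 0.20 / 96)
    for i, ch in enumerate(CHANNELS):
        if ch.substitution == "T>C":
            w[i] += 0.60 / 16
        elif ch.substitution == "T>G":
            w[i] += 0.20 / 16
    return w / w.sum()


@dataclass
class SimConfig:
    """Parameters of the synthetic matched germline/tumour/plasma study.

    Depth defaults follow the study design the analysis targets: ~30x
    germline, ~60x tumour, ~100x plasma. ``plasma_tumour_fraction`` is the
    proportion of plasma cfDNA molecules of tumour origin; a clonal
    heterozygous tumour mutation therefore appears in plasma at
    VAF = tumour_fraction/2.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.41
    gene_models: list[GeneModel] | None = None
    n_genes: int = 20
    gene_length: int = 300
    n_germline_variants: int = 200
    n_tumour_mutations: int = 250
    n_background_mutations: int = 250
    tumour_signature: np.ndarray = field(default_factory=default_tumour_signature)
    background_signature: np.ndarray = field(default_factory=default_background_signature)
    tumour_purity: float = 0.65
    plasma_tumour_fraction: float = 0.30
    subclonal_fraction: float = 1.0
    depth_germline: float = 30.0
    depth_tumour: float = 60.0
    depth_plasma: float = 100.0
    background_fragment_model: FragmentLengthModel = field(
        default_factory=lambda: FragmentLengthModel(mono_weight=0.85, di_weight=0.15))
    tumour_fragment_model: FragmentLengthModel = field(
        default_factory=lambda: FragmentLengthModel(mono_weight=0.70, di_weight=0.30))
    base_error_rate: float = 1e-3
    background_vaf_range: tuple[float, float] = (0.05, 0.35)
    n_error_sites: int = 200
    n_plasma_fragments: int | None = None  # default: depth * genome / mean length

    def validate(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be at least 10,000 bp")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        for name in ("gc_fraction", "tumour_purity", "plasma_tumour_fraction",
                     "subclonal_fraction", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("tumour_signature", "background_signature"):
            sig = np.asarray(getattr(self, name), dtype=float)
            if sig.shape != (96,):
                raise ValueError(f"{name} must be a 96-vector")
            if (sig < 0).any() or abs(sig.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        self.background_fragment_model.validate()
        self.tumour_fragment_model.validate()
        lo, hi = self.background_vaf_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("background_vaf_range must be ordered and in [0,1]")
        if self.gene_models is not None:
            lengths = self.chromosome_lengths()
            for g in self.gene_models:
                if g.chrom not in lengths or g.end0 > lengths[g.chrom] or g.start0 < 0:
                    raise ValueError(f"gene model {g.name} exceeds chromosome bounds")

    def chromosome_lengths(self) -> dict[str, int]:
        base = self.genome_length // self.n_chromosomes
        lengths = {f"chr{i + 1}": base for i in range(self.n_chromosomes)}
        lengths[f"chr{self.n_chromosomes}"] += self.genome_length - base * self.n_chromosomes
        return lengths

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGES[stage]])


@dataclass
class TruthVariant:
    chrom: str
    pos1: int  # 1-based
    ref: str
    alt: str
    origin: str  # germline | tumour | background
    vaf_germline: float
    vaf_tumour: float
    vaf_plasma: float

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}_{self.pos1}_{self.ref}_{self.alt}"

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos1, self.ref, self.alt)


@dataclass
class TruthSet:
    germline: list[TruthVariant]
    tumour: list[TruthVariant]
    background: list[TruthVariant]

    def all_variants(self) -> list[TruthVariant]:
        return self.germline + self.tumour + self.background

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(v) | {"variant_id": v.variant_id}
                for v in self.all_variants()]
        cols = ["variant_id", "chrom", "pos1", "ref", "alt", "origin",
                "vaf_germline", "vaf_tumour", "vaf_plasma"]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class StudyData:
    """Everything one synthetic patient study produces."""

    config: SimConfig
    reference: dict[str, str]
    gene_models: list[GeneModel]
    truth: TruthSet
    pileups: dict[str, pd.DataFrame]  # keys: germline, tumour, plasma
    plasma_fragments: pd.DataFrame
    germline_fragments: pd.DataFrame


# ---------------------------------------------------------------------------
# reference


def generate_reference(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random reference sequences plus toy CDS gene models.

    Base composition follows ``gc_fraction``; gene models are evenly spaced
    non-overlapping CDS intervals of ``gene_length`` bp (a multiple of 3),
    alternating strand, frame 0.
    """
    config.validate()
    rng = config.rng("reference")
    p = np.array([(1 - config.gc_fraction) / 2, config.gc_fraction / 2,
                  config.gc_fraction / 2, (1 - config.gc_fraction) / 2])
    reference: dict[str, str] = {}
    for chrom, length in config.chromosome_lengths().items():
        idx = rng.choice(4, size=length, p=p)
        reference[chrom] = "".join(np.array(list(BASES))[idx])

    if config.gene_models is not None:
        genes = list(config.gene_models)
    else:
        genes = []
        glen = config.gene_length - config.gene_length % 3
        chroms = list(reference)
        per_chrom = max(1, config.n_genes // len(chroms))
        g = 0
        for chrom in chroms:
            clen = len(reference[chrom])
            spacing = clen // (per_chrom + 1)
            if spacing <= glen:
                raise ValueError("chromosome too short for requested gene models")
            for j in range(per_chrom):
                start = (j + 1) * spacing
                genes.append(GeneModel(chrom, start, start + glen,
                                       "+" if g % 2 == 0 else "-", 0, f"GENE{g + 1}"))
                g += 1
    lengths = config.chromosome_lengths()
    for gene in genes:
        if gene.end0 > lengths[gene.chrom]:
            raise ValueError(f"gene model {gene.name} exceeds chromosome length")
    return reference, genes


# ---------------------------------------------------------------------------
# mutation drawing from a 96-channel signature


def _context_positions(reference: dict[str, str]) -> dict[str, list[tuple[str, int]]]:
    """Map pyrimidine-strand trinucleotide context -> interior genome positions.

    Positions are 0-based sequence indices; purine-centred positions are
    registered under the reverse complement of their local trinucleotide.
    """
    table: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in reference.items():
        for i in range(1, len(seq) - 1):
            tri = seq[i - 1:i + 2]
            if tri[1] in "AG":
                tri = revcomp(tri)
            table.setdefault(tri, []).append((chrom, i))
    return table


def draw_mutations(
    reference: dict[str, str],
    signature: np.ndarray,
    n: int,
    rng: np.random.Generator,
    exclude: set[tuple[str, int]] | None = None,
) -> list[tuple[str, int, str, str]]:
    """Sample n SNVs realising a 96-channel signature on this genome.

    Channels are drawn with probability proportional to signature weight x
    genomic availability of the channel's trinucleotide context; a site is
    then drawn uniformly (without replacement) among positions carrying that
    context on the pyrimidine strand. Returns (chrom, pos1, ref, alt) with
    ref taken from the actual reference base (purine positions yield the
    complemented alt).
    """
    from .signatures import CHANNELS

    signature = np.asarray(signature, dtype=float)
    if signature.shape != (96,) or (signature < 0).any():
        raise ValueError("signature must be a non-negative 96-vector")
    if abs(signature.sum() - 1.0) > 1e-9:
        raise ValueError("signature must sum to 1")
    if n == 0:
        return []

    exclude = exclude or set()
    table = _context_positions(reference)
    avail = {ctx: [p for p in pos if p not in exclude]
             for ctx, pos in table.items()}

    weights = np.array([signature[i] * len(avail.get(ch.context, ()))
                        for i, ch in enumerate(CHANNELS)])
    total = weights.sum()
    if total == 0:
        raise ValueError("no genomic sites available for any weighted context")
    counts = rng.multinomial(n, weights / total)

    # verify availability per context before consuming sites
    per_context: dict[str, int] = {}
    for i, ch in enumerate(CHANNELS):
        per_context[ch.context] = per_context.get(ch.context, 0) + counts[i]
    for ctx, need in per_context.items():
        if need > len(avail.get(ctx, ())):
            raise ValueError(f"context {ctx}: {need} mutations requested but only "
                             f"{len(avail.get(ctx, ()))} sites available")

    shuffled = {}
    for ctx, need in per_context.items():
        if need:
            pos = avail[ctx]
            shuffled[ctx] = [pos[j] for j in rng.permutation(len(pos))[:need]]

    out: list[tuple[str, int, str, str]] = []
    for i, ch in enumerate(CHANNELS):
        for _ in range(counts[i]):
            chrom, idx = shuffled[ch.context].pop()
            ref_base = reference[chrom][idx]
            alt = ch.alt if ref_base in "CT" else ch.alt.translate(_COMPLEMENT)
            out.append((chrom, idx + 1, ref_base, alt))
    return out


# ---------------------------------------------------------------------------
# the full study


def _uniform_snvs(reference: dict[str, str], n: int, rng: np.random.Generator,
                  exclude: set[tuple[str, int]]) -> list[tuple[str, int, str, str]]:
    chroms = list(reference)
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    out = []
    used = set(exclude)
    while len(out) < n:
        ci = rng.choice(len(chroms), p=lengths / lengths.sum())
        chrom = chroms[ci]
        idx = int(rng.integers(1, len(reference[chrom]) - 1))
        if (chrom, idx) in used:
            continue
        used.add((chrom, idx))
        ref_base = reference[chrom][idx]
        alts = [b for b in BASES if b != ref_base]
        out.append((chrom, idx + 1, ref_base, alts[int(rng.integers(3))]))
    return out


def _simulate_pileup_sample(
    sites: pd.DataFrame, sample: str, mean_depth: float, vaf_col: str,
    error_rate: float, rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(sites)
    depth = rng.poisson(mean_depth, n)
    vaf = sites[vaf_col].to_numpy()
    true_alt = rng.binomial(depth, np.clip(vaf, 0, 1))
    # sequencing error: each non-variant read misreads to the tracked alt
    # with rate e/3 and to some other base with rate 2e/3
    err_alt = rng.binomial(depth - true_alt, error_rate / 3)
    alt = true_alt + err_alt
    other_err = rng.binomial(depth - alt, 2 * error_rate / 3)
    ref_count = depth - alt - other_err
    fwd = rng.binomial(alt, 0.5)
    has_alt = alt > 0
    baseq_alt = np.where(has_alt, np.clip(rng.normal(33, 1.5, n), 2, 41), 0.0)
    readpos = np.where(has_alt, np.clip(rng.normal(0.5, 0.08, n), 0.02, 0.98), 0.0)
    df = pd.DataFrame({
        "chrom": sites["chrom"].to_numpy(),
        "pos1": sites["pos1"].to_numpy(),
        "ref": sites["ref"].to_numpy(),
        "sample": sample,
        "depth": depth,
        "ref_count": ref_count,
        "alt_base": sites["alt"].to_numpy(),
        "alt_count": alt,
        "mean_baseq_ref": np.round(np.clip(rng.normal(35, 1.0, n), 2, 41), 2),
        "mean_baseq_alt": np.round(baseq_alt, 2),
        "mean_mapq": np.round(np.clip(rng.normal(58, 2.0, n), 0, 60), 2),
        "fwd_alt": fwd,
        "rev_alt": alt - fwd,
        "mean_readpos_alt": np.round(readpos, 3),
    })
    return df[PILEUP_COLUMNS]


def _place_fragments(
    n: int, lengths: np.ndarray, reference: dict[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    chroms = list(reference)
    clens = np.array([len(reference[c]) for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=n, p=clens / clens.sum())
    max_start = np.maximum(clens[ci].astype(int) - lengths, 1)
    start0 = (rng.random(n) * max_start).astype(int)
    return pd.DataFrame({
        "chrom": np.array(chroms)[ci],
        "start0": start0,
        "end0": start0 + lengths,
        "length": lengths,
    })


def _assign_fragment_alleles(
    frags: pd.DataFrame, origin: np.ndarray, variants: list[TruthVariant],
    tf: float, error_rate: float, rng: np.random.Generator,
) -> pd.DataFrame:
    """Expand a fragment table with one row per covered somatic variant.

    Tumour-origin fragments carry the alt allele of tumour mutations with
    probability 1/2 (heterozygous in tumour cells); background-origin
    fragments carry a background mutation's alt with probability
    vaf/(1 - tf) so that the overall plasma VAF equals the assigned vaf.
    A small error rate flips carried alleles.
    """
    frags = frags.reset_index(drop=True)
    n = len(frags)
    ids = np.array([f"frag{i:07d}" for i in range(n)])
    covered_variant = [""] * n
    carried = [""] * n
    extra_rows = []

    order = np.argsort(frags["start0"].to_numpy(), kind="stable")
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in frags["chrom"].unique():
        mask = frags["chrom"].to_numpy() == chrom
        idx = np.where(mask)[0]
        idx = idx[np.argsort(frags["start0"].to_numpy()[idx])]
        by_chrom[chrom] = idx

    starts = frags["start0"].to_numpy()
    ends = frags["end0"].to_numpy()
    max_len = int(frags["length"].max()) if n else 0

    for v in variants:
        idx = by_chrom.get(v.chrom)
        if idx is None or len(idx) == 0:
            continue
        pos0 = v.pos1 - 1
        s = starts[idx]
        lo = np.searchsorted(s, pos0 - max_len, side="left")
        hi = np.searchsorted(s, pos0, side="right")
        cand = idx[lo:hi]
        cand = cand[ends[cand] > pos0]
        if len(cand) == 0:
            continue
        is_tum = origin[cand] == 1
        if v.origin == "tumour":
            p_alt = np.where(is_tum, 0.5, 0.0)
        else:  # background
            p_bg = min(v.vaf_plasma / (1.0 - tf), 1.0) if tf < 1.0 else 0.0
            p_alt = np.where(is_tum, 0.0, p_bg)
        alt_carry = rng.random(len(cand)) < p_alt
        flip = rng.random(len(cand)) < error_rate
        alt_carry = np.where(flip, ~alt_carry, alt_carry)
        for j, fi in enumerate(cand):
            allele = "alt" if alt_carry[j] else "ref"
            if covered_variant[fi] == "":
                covered_variant[fi] = v.variant_id
                carried[fi] = allele
            else:  # fragment spans >1 variant: one row per covered variant
                extra_rows.append((ids[fi], frags.at[fi, "chrom"],
                                   int(starts[fi]), int(ends[fi]),
                                   int(frags.at[fi, "length"]),
                                   v.variant_id, allele))

    out = pd.DataFrame({
        "fragment_id": ids,
        "chrom": frags["chrom"],
        "start0": frags["start0"],
        "end0": frags["end0"],
        "length": frags["length"],
        "covered_variant_id": covered_variant,
        "carried_allele": carried,
    })
    if extra_rows:
        out = pd.concat([out, pd.DataFrame(extra_rows, columns=FRAGMENT_COLUMNS)],
                        ignore_index=True)
    return out[FRAGMENT_COLUMNS]


def simulate_study(config: SimConfig) -> StudyData:
    """Generate one complete synthetic matched-sample study."""
    config.validate()
    reference, genes = generate_reference(config)

    # --- truth variants
    rng_g = config.rng("germline")
    used: set[tuple[str, int]] = set()
    germ_raw = _uniform_snvs(reference, config.n_germline_variants, rng_g, used)
    used |= {(c, p - 1) for c, p, _, _ in germ_raw}

    tum_raw = draw_mutations(reference, config.tumour_signature,
                             config.n_tumour_mutations,
                             config.rng("tumour_mutations"), exclude=used)
    used |= {(c, p - 1) for c, p, _, _ in tum_raw}

    rng_b = config.rng("background_mutations")
    bg_raw = draw_mutations(reference, config.background_signature,
                            config.n_background_mutations, rng_b, exclude=used)
    used |= {(c, p - 1) for c, p, _, _ in bg_raw}

    sub = config.subclonal_fraction
    lo, hi = config.background_vaf_range
    germline = [TruthVariant(c, p, r, a, "germline", 0.5, 0.5, 0.5)
                for c, p, r, a in germ_raw]
    tumour = [TruthVariant(c, p, r, a, "tumour", 0.0,
                           config.tumour_purity / 2 * sub,
                           config.plasma_tumour_fraction / 2 * sub)
              for c, p, r, a in tum_raw]
    background = [TruthVariant(c, p, r, a, "background", 0.0, 0.0,
                               float(rng_b.uniform(lo, hi)))
                  for c, p, r, a in bg_raw]
    truth = TruthSet(germline, tumour, background)

    # --- pileups at truth sites plus variant-free error sites
    rng_p = config.rng("pileup")
    err_sites = _uniform_snvs(reference, config.n_error_sites, rng_p, used)
    site_rows = [(v.chrom, v.pos1, v.ref, v.alt,
                  v.vaf_germline, v.vaf_tumour, v.vaf_plasma)
                 for v in truth.all_variants()]
    site_rows += [(c, p, r, a, 0.0, 0.0, 0.0) for c, p, r, a in err_sites]
    sites = pd.DataFrame(site_rows, columns=[
        "chrom", "pos1", "ref", "alt", "vaf_germline", "vaf_tumour", "vaf_plasma"])
    sites = sites.sort_values(["chrom", "pos1"]).reset_index(drop=True)

    pileups = {
        "germline": _simulate_pileup_sample(sites, "germline", config.depth_germline,
                                            "vaf_germline", config.base_error_rate, rng_p),
        "tumour": _simulate_pileup_sample(sites, "tumour", config.depth_tumour,
                                          "vaf_tumour", config.base_error_rate, rng_p),
        "plasma": _simulate_pileup_sample(sites, "plasma", config.depth_plasma,
                                          "vaf_plasma", config.base_error_rate, rng_p),
    }

    # --- plasma fragments
    rng_f = config.rng("fragments")
    tf = config.plasma_tumour_fraction
    mean_len = ((1 - tf) * config.background_fragment_model.mean_length
                + tf * config.tumour_fragment_model.mean_length)
    n_frag = config.n_plasma_fragments
    if n_frag is None:
        n_frag = int(round(config.depth_plasma * config.genome_length / mean_len))
    origin = (rng_f.random(n_frag) < tf).astype(int)  # 1 = tumour-derived
    lengths = np.empty(n_frag, dtype=int)
    n_tum = int(origin.sum())
    lengths[origin == 1] = config.tumour_fragment_model.sample(n_tum, rng_f)
    lengths[origin == 0] = config.background_fragment_model.sample(n_frag - n_tum, rng_f)
    placed = _place_fragments(n_frag, lengths, reference, rng_f)
    somatic_truth = truth.tumour + truth.background
    plasma_fragments = _assign_fragment_alleles(
        placed, origin, somatic_truth, tf, config.base_error_rate, rng_f)

    # --- germline fragments (sheared library; for the matched-normal CNA track)
    rng_n = config.rng("germline_fragments")
    n_norm = int(round(config.depth_germline * config.genome_length / 350.0))
    norm_len = np.clip(np.rint(rng_n.normal(350, 50, n_norm)).astype(int), 100, 1000)
    norm = _place_fragments(n_norm, norm_len, reference, rng_n)
    norm.insert(0, "fragment_id", [f"gfrag{i:07d}" for i in range(n_norm)])
    norm["covered_variant_id"] = ""
    norm["carried_allele"] = ""
    germline_fragments = norm[FRAGMENT_COLUMNS]

    return StudyData(config, reference, genes, truth, pileups,
                     plasma_fragments, germline_fragments)


# ---------------------------------------------------------------------------
# writers / readers


def write_fasta(reference: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_gene_models(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tstrand\tframe\tname\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start0}\t{g.end0}\t{g.strand}\t{g.frame}\t{g.name}\n")


def read_gene_models(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "strand", "frame", "name"])
    return [GeneModel(r.chrom, int(r.start), int(r.end), r.strand, int(r.frame), r.name)
            for r in df.itertuples()]


def write_pileup(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pileup(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fragments(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_fragments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df["covered_variant_id"] = df["covered_variant_id"].astype(str)
    df["carried_allele"] = df["carried_allele"].astype(str)
    return df


def write_truth(truth: TruthSet, vcf_path, tsv_path,
                contigs: dict[str, int] | None = None) -> None:
    """Write the truth set as a VCF 4.2 plus a flat TSV."""
    from .vcfio import write_truth_vcf

    write_truth_vcf(truth, vcf_path, contigs or {})
    truth.to_frame().to_csv(tsv_path, sep="\t", index=False)


def read_truth(vcf_path) -> TruthSet:
    from .vcfio import read_truth_vcf

    return read_truth_vcf(vcf_path)
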