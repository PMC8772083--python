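"""Minimal deterministic VCF 4.2 writing, with pysam-based reading.

Writers emit plain sorted text so that identical inputs produce
byte-identical files; readers go through pysam.VariantFile so the files are
exercised against a standard-compliant parser.
"""

from __future__ import annotations

import pandas as pd
import pysam

_CHROM_KEY_CACHE: dict[str, tuple] = {}


def _chrom_key(chrom: str) -> tuple:
    key = _CHROM_KEY_CACHE.get(chrom)
    if key is None:
        tail = chrom[3:] if chrom.startswith("chr") else chrom
        key = (0, int(tail)) if tail.isdigit() else (1, tail)
        _CHROM_KEY_CACHE[chrom] = key
    return key


def _header(contigs: dict[str, int], extra_lines: list[str],
            samples: list[str] | None = None) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=cfplasma"]
    for chrom, length in contigs.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.extend(extra_lines)
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        cols += ["FORMAT"] + samples
    lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def write_truth_vcf(truth, path, contigs: dict[str, int]) -> None:
    from .simulate import TruthSet  # noqa: F401  (type reference only)

    extra = [
        '##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Simulated variant origin">',
        '##INFO=<ID=VAFG,Number=1,Type=Float,Description="Assigned germline VAF">',
        '##INFO=<ID=VAFT,Number=1,Type=Float,Description="Assigned tumour VAF">',
        '##INFO=<ID=VAFP,Number=1,Type=Float,Description="Assigned plasma VAF">',
    ]
    variants = sorted(truth.all_variants(),
                      key=lambda v: (_chrom_key(v.chrom), v.pos1, v.ref, v.alt))
    with open(path, "w") as fh:
        fh.write(_header(contigs, extra))
        for v in variants:
            info = (f"ORIGIN={v.origin};VAFG={v.vaf_germline:.6g};"
                    f"VAFT={v.vaf_tumour:.6g};VAFP={v.vaf_plasma:.6g}")
            fh.write(f"{v.chrom}\t{v.pos1}\t{v.variant_id}\t{v.ref}\t{v.alt}"
                     f"\t.\tPASS\t{info}\n")


def read_truth_vcf(path):
    from .simulate import TruthSet, TruthVariant

    germline, tumour, background = [], [], []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            v = TruthVariant(rec.chrom, rec.pos, rec.ref, rec.alts[0],
                             info["ORIGIN"], float(info["VAFG"]),
                             float(info["VAFT"]), float(info["VAFP"]))
            {"germline": germline, "tumour": tumour,
             "background": background}[v.origin].append(v)
    return TruthSet(germline, tumour, background)


def write_calls_vcf(calls, path, contigs: dict[str, int],
                    normal_name: str = "NORMAL", case_name: str = "CASE") -> None:
    """Write somatic calls with status/p-value INFO and per-sample AD/DP."""
    extra = [
        '##INFO=<ID=SS,Number=1,Type=String,Description="Somatic status">',
        '##INFO=<ID=SPV,Number=1,Type=Float,Description="Somatic p-value (one-tailed Fisher)">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    ordered = sorted(calls, key=lambda c: (_chrom_key(c.chrom), c.pos1, c.ref, c.alt))
    with open(path, "w") as fh:
        fh.write(_header(contigs, extra, [normal_name, case_name]))
        for c in ordered:
            info = f"SS={c.status};SPV={c.somatic_p:.6g}"
            nfmt = f"{c.normal.ref_count},{c.normal.alt_count}:{c.normal.depth}"
            cfmt = f"{c.case.ref_count},{c.case.alt_count}:{c.case.depth}"
            fh.write(f"{c.chrom}\t{c.pos1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}"
                     f"\tAD:DP\t{nfmt}\t{cfmt}\n")


def read_sites(path) -> list[tuple[str, int, str, str]]:
    """Read (chrom, pos1, ref, alt) site identities from any VCF."""
    sites = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                sites.append((rec.chrom, rec.pos, rec.ref, alt))
    return sites


def read_calls(path) -> pd.DataFrame:
    """Read a cfplasma calls VCF into a flat table."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            row = {
                "chrom": rec.chrom, "pos1": rec.pos, "ref": rec.ref,
                "alt": rec.alts[0],
                "status": rec.info.get("SS"),
                "somatic_p": float(rec.info["SPV"]) if "SPV" in rec.info else None,
            }
            for role, name in zip(("normal", "case"), samples):
                ad = rec.samples[name]["AD"]
                row[f"{role}_ref"], row[f"{role}_alt"] = int(ad[0]), int(ad[1])
                row[f"{role}_depth"] = int(rec.samples[name]["DP"])
            rows.append(row)
    return pd.DataFrame(rows)
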