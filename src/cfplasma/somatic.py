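"""Tumour(or plasma)/normal somatic SNV calling with a strict filter cascade.

The caller follows the VarScan2-style procedure: per-site allele counts from
a mate-aware pileup are compared between a case sample and its matched
normal with a one-tailed Fisher's exact test; candidate somatic calls then
pass through, in order,

1. variant calling thresholds (supporting reads, VAF, base quality),
2. somatic classification (normal VAF bound + Fisher p-value),
3. a high-confidence filter (case VAF >= min_tumor_freq, zero alt reads in
   the normal at max_normal_freq = 0),
4. a false-positive filter on read-level metrics (base quality, mapping
   quality, strand balance, position-in-read, VAF),
5. final depth thresholds: >= 10x in both samples, >= 5 alt reads in the
   case, 0 alt reads in the normal.

Each filter is a pure predicate on the call, so the final set does not
depend on the order the read-level filters are applied in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import pandas as pd

SOMATIC = "Somatic"
GERMLINE = "Germline"
LOH = "LOH"
REFERENCE = "Reference"
UNKNOWN = "Unknown"

_BASE_ORDER = {b: i for i, b in enumerate("ACGT")}


@dataclass
class AlleleCounts:
    """Pileup summary for one candidate alt allele at one site in one sample.

    Counts are assumed mate-aware (overlapping read pairs counted once) and
    duplicate-free; the caller does not re-correct them.
    """

    chrom: str
    pos1: int
    ref_base: str
    depth: int
    ref_count: int
    alt_base: str
    alt_count: int
    mean_baseq_alt: float = 30.0
    mean_mapq: float = 60.0
    alt_fwd: int = 0
    alt_rev: int = 0
    mean_readpos_alt: float = 0.5

    def __post_init__(self):
        if min(self.depth, self.ref_count, self.alt_count) < 0:
            raise ValueError("negative read counts")
        if self.ref_count + self.alt_count > self.depth:
            raise ValueError("ref_count + alt_count exceeds depth")
        if self.alt_fwd + self.alt_rev != self.alt_count:
            raise ValueError("strand counts do not sum to alt_count")

    @property
    def vaf(self) -> float:
        used = self.ref_count + self.alt_count
        return self.alt_count / used if used else 0.0


@dataclass
class SomaticParams:
    """All thresholds of the calling and filtering cascade.

    The false-positive filter values follow published VarScan fpfilter
    conventions; the somatic p-value threshold is exposed because the
    upstream pipeline description leaves it at the caller's default.
    """

    min_var_freq: float = 0.01
    min_reads2: int = 2
    min_avg_qual: float = 15.0
    somatic_p_threshold: float = 0.05
    max_normal_freq: float = 0.00
    min_tumor_freq: float = 0.01
    heterozygote_min_vaf: float = 0.10
    # fpfilter
    fp_min_baseq: float = 15.0
    fp_min_mapq: float = 20.0
    fp_min_strand_fraction: float = 0.05
    fp_strand_min_reads: int = 10
    fp_min_readpos: float = 0.10
    fp_max_readpos: float = 0.90
    fp_min_var_freq: float = 0.01
    # final thresholds
    final_min_depth: int = 10
    final_min_alt_reads: int = 5
    final_max_normal_alt: int = 0


@dataclass
class SomaticCall:
    chrom: str
    pos1: int
    ref: str
    alt: str
    normal: AlleleCounts
    case: AlleleCounts
    somatic_p: float
    status: str
    filters_passed: dict[str, bool] = field(default_factory=dict)
    filter_reasons: list[str] = field(default_factory=list)

    @property
    def normal_vaf(self) -> float:
        return self.normal.vaf

    @property
    def case_vaf(self) -> float:
        return self.case.vaf

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos1, self.ref, self.alt)

    @property
    def is_final(self) -> bool:
        keys = ("called", "high_confidence", "fp_filter", "final_thresholds")
        return all(self.filters_passed.get(k, False) for k in keys)


def call_variant(case: AlleleCounts, min_var_freq: float = 0.01,
                 min_reads2: int = 2, min_avg_qual: float = 15.0) -> bool:
    """Does the case sample support the alt allele at calling thresholds?

    Returns False (a not-callable verdict, not an exception) at depth 0.
    """
    if case.depth == 0:
        return False
    return (case.alt_count >= min_reads2
            and case.vaf >= min_var_freq
            and case.mean_baseq_alt >= min_avg_qual)


@lru_cache(maxsize=200_000)
def _hypergeom_upper_tail(case_depth: int, normal_depth: int,
                          total_alt: int, case_alt: int) -> float:
    """P(X >= case_alt) for X hypergeometric; exact integer arithmetic."""
    n_total = case_depth + normal_depth
    hi = min(case_depth, total_alt)
    num = sum(comb(case_depth, k) * comb(normal_depth, total_alt - k)
              for k in range(case_alt, hi + 1)
              if total_alt - k <= normal_depth)
    return num / comb(n_total, total_alt)


def somatic_p_value(normal: AlleleCounts, case: AlleleCounts) -> float:
    """One-tailed Fisher's exact test for excess alt reads in the case.

    The probability of observing at least the case's alt count given the
    pooled 2x2 table of ref/alt reads (hypergeometric upper tail).
    """
    nd = normal.ref_count + normal.alt_count
    cd = case.ref_count + case.alt_count
    if nd <= 0 or cd <= 0:
        raise ValueError("somatic p-value requires positive used depth in both samples")
    total_alt = normal.alt_count + case.alt_count
    return _hypergeom_upper_tail(cd, nd, total_alt, case.alt_count)


def classify_somatic(normal: AlleleCounts, case: AlleleCounts,
                     params: SomaticParams) -> tuple[str, float]:
    """VarScan2-style joint status of a site, with its somatic p-value."""
    p = somatic_p_value(normal, case)
    called_case = call_variant(case, params.min_var_freq, params.min_reads2,
                               params.min_avg_qual)
    normal_het = normal.vaf >= params.heterozygote_min_vaf
    if not called_case and not normal_het:
        return REFERENCE, p
    if normal_het:
        if p <= params.somatic_p_threshold:
            # significant shift from a germline het: toward homozygosity = LOH
            if case.vaf > 0.9 or case.vaf < 0.1:
                return LOH, p
            return UNKNOWN, p
        return GERMLINE, p
    if called_case:
        if normal.vaf <= params.max_normal_freq and p <= params.somatic_p_threshold:
            return SOMATIC, p
        return UNKNOWN, p
    return UNKNOWN, p


def high_confidence_filter(calls: list[SomaticCall],
                           min_tumor_freq: float = 0.01,
                           max_normal_freq: float = 0.00) -> list[SomaticCall]:
    """Keep somatic calls with case VAF >= min_tumor_freq and a clean normal."""
    kept = []
    for c in calls:
        if c.status != SOMATIC:
            continue
        if c.case_vaf >= min_tumor_freq and c.normal_vaf <= max_normal_freq:
            kept.append(c)
    return kept


def fp_filter(call: SomaticCall, params: SomaticParams | None = None) -> tuple[bool, list[str]]:
    """Read-level false-positive filter; every failure reason is recorded."""
    params = params or SomaticParams()
    case = call.case
    reasons = []
    if case.mean_baseq_alt < params.fp_min_baseq:
        reasons.append("low_base_quality")
    if case.mean_mapq < params.fp_min_mapq:
        reasons.append("low_mapping_quality")
    if case.alt_count >= params.fp_strand_min_reads:
        if min(case.alt_fwd, case.alt_rev) / case.alt_count < params.fp_min_strand_fraction:
            reasons.append("strand_bias")
    if not params.fp_min_readpos <= case.mean_readpos_alt <= params.fp_max_readpos:
        reasons.append("read_position")
    if case.vaf < params.fp_min_var_freq:
        reasons.append("low_vaf")
    return (not reasons), reasons


def final_threshold_filter(call: SomaticCall,
                           params: SomaticParams | None = None) -> bool:
    """Final depth/support thresholds: 10x both samples, >=5 alt, clean normal."""
    params = params or SomaticParams()
    return (call.normal.depth >= params.final_min_depth
            and call.case.depth >= params.final_min_depth
            and call.case.alt_count >= params.final_min_alt_reads
            and call.normal.alt_count <= params.final_max_normal_alt)


# ---------------------------------------------------------------------------
# pipeline over pileup tables


def _counts_from_row(row, sample_suffix: str) -> AlleleCounts:
    g = lambda col: row[f"{col}{sample_suffix}"]
    return AlleleCounts(
        chrom=row["chrom"], pos1=int(row["pos1"]), ref_base=row["ref"],
        depth=int(g("depth")), ref_count=int(g("ref_count")),
        alt_base=row["alt_base"], alt_count=int(g("alt_count")),
        mean_baseq_alt=float(g("mean_baseq_alt")),
        mean_mapq=float(g("mean_mapq")),
        alt_fwd=int(g("fwd_alt")), alt_rev=int(g("rev_alt")),
        mean_readpos_alt=float(g("mean_readpos_alt")),
    )


def _select_alt(pileup: pd.DataFrame) -> pd.DataFrame:
    """Single most-supported alt per site, ties broken by A<C<G<T."""
    key = pileup.assign(_order=pileup["alt_base"].map(_BASE_ORDER))
    key = key.sort_values(["chrom", "pos1", "alt_count", "_order"],
                          ascending=[True, True, False, True], kind="stable")
    key = key.drop_duplicates(["chrom", "pos1"], keep="first")
    return key.drop(columns="_order")


def run_somatic_pipeline(
    normal_pileup: pd.DataFrame, case_pileup: pd.DataFrame,
    params: SomaticParams | None = None,
) -> tuple[list[SomaticCall], dict[str, int]]:
    """Run the full calling cascade over matched pileup tables.

    Returns all per-site calls (with per-filter verdicts recorded) plus the
    per-stage surviving counts; the final somatic set is the calls whose
    ``is_final`` flag is true.
    """
    params = params or SomaticParams()
    normal = _select_alt(normal_pileup)
    case = _select_alt(case_pileup)

    merged = normal.merge(case, on=["chrom", "pos1"], suffixes=("_n", "_c"))
    mism = merged[merged["ref_n"] != merged["ref_c"]]
    if len(mism):
        sites = ", ".join(f"{r.chrom}:{r.pos1}" for r in mism.head(20).itertuples())
        raise ValueError(f"reference base mismatch between samples at: {sites}")
    merged = merged.rename(columns={"ref_n": "ref"})
    # evaluate the alt observed in the case sample
    merged = merged.rename(columns={"alt_base_c": "alt_base"})

    calls: list[SomaticCall] = []
    counts = {"sites": len(merged), "called": 0, "somatic": 0,
              "high_confidence": 0, "fp_filter": 0, "final": 0,
              "multiallelic_excluded": (len(normal_pileup) - len(normal))
              + (len(case_pileup) - len(case))}
    for row in merged.to_dict("records"):
        case_counts = _counts_from_row(row | {"alt_base": row["alt_base"]}, "_c")
        # normal counts for the case's alt allele: reuse normal row only if
        # the tracked alt matches, otherwise the normal shows 0 alt reads
        if row["alt_base_n"] == row["alt_base"]:
            normal_counts = _counts_from_row(row | {"alt_base": row["alt_base"]}, "_n")
        else:
            normal_counts = AlleleCounts(
                chrom=row["chrom"], pos1=int(row["pos1"]), ref_base=row["ref"],
                depth=int(row["depth_n"]), ref_count=int(row["ref_count_n"]),
                alt_base=row["alt_base"], alt_count=0)
        if case_counts.depth == 0 or normal_counts.depth == 0:
            continue
        status, p = classify_somatic(normal_counts, case_counts, params)
        called = call_variant(case_counts, params.min_var_freq,
                              params.min_reads2, params.min_avg_qual)
        call = SomaticCall(row["chrom"], int(row["pos1"]), row["ref"],
                           row["alt_base"], normal_counts, case_counts, p, status)
        call.filters_passed["called"] = called
        counts["called"] += called
        if status == SOMATIC:
            counts["somatic"] += 1
        hc = bool(high_confidence_filter([call], params.min_tumor_freq,
                                         params.max_normal_freq))
        call.filters_passed["high_confidence"] = called and hc
        fp_ok, reasons = fp_filter(call, params)
        call.filter_reasons = reasons
        call.filters_passed["fp_filter"] = call.filters_passed["high_confidence"] and fp_ok
        final_ok = final_threshold_filter(call, params)
        call.filters_passed["final_thresholds"] = call.filters_passed["fp_filter"] and final_ok
        counts["high_confidence"] += call.filters_passed["high_confidence"]
        counts["fp_filter"] += call.filters_passed["fp_filter"]
        counts["final"] += call.filters_passed["final_thresholds"]
        calls.append(call)
    return calls, counts


def final_calls(calls: list[SomaticCall]) -> list[SomaticCall]:
    return [c for c in calls if c.is_final]
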