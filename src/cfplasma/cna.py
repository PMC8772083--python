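"""Binned read-depth somatic copy-number screen with tumour-fraction estimate.

Fragment starts are counted in fixed-width genome bins (1 Mb by default,
mapping quality >= 20 when available), median-normalised within each sample,
and expressed as per-bin log2 case/normal ratios. A transparent robust-z
segmenter (median/MAD) merges consecutive deviating bins into gain/loss
segments; it deliberately is not an HMM caller — the screen asks only
whether a copy-number event is detectable at a given tumour fraction.

Under a diploid clonal model a single-copy event at tumour fraction tf
scales depth by (2 +/- tf)/2, so the log2 ratio r inverts to
tf = 2(2^r - 1) for a gain and tf = 2(1 - 2^r) for a loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTH = 1_000_000
DEFAULT_MIN_MAPQ = 20


def bin_counts(positions: pd.DataFrame, chrom_lengths: dict[str, int],
               bin_width: int = DEFAULT_BIN_WIDTH,
               min_mapq: int = DEFAULT_MIN_MAPQ) -> pd.DataFrame:
    """Count fragment starts per half-open genome bin.

    ``positions`` needs columns chrom and start0 (a fragment table works);
    rows with a ``mapq`` column below ``min_mapq`` are dropped. A start at a
    bin boundary belongs to the right-hand bin.
    """
    df = positions
    if "mapq" in df.columns:
        df = df[df["mapq"] >= min_mapq]
    rows = []
    for chrom, length in chrom_lengths.items():
        edges = np.arange(0, length + bin_width, bin_width)
        edges[-1] = max(edges[-1], length)
        starts = df.loc[df["chrom"] == chrom, "start0"].to_numpy()
        hist, _ = np.histogram(starts, bins=edges)
        for i, count in enumerate(hist):
            rows.append({"chrom": chrom, "start0": int(edges[i]),
                         "end0": int(min(edges[i + 1], length)),
                         "count": int(count)})
    return pd.DataFrame(rows)


def log_ratio(case: pd.DataFrame, normal: pd.DataFrame) -> pd.DataFrame:
    """Median-normalised per-bin log2 depth ratio of case over normal.

    Bins where the normal has zero reads are masked (ratio NaN).
    """
    key = ["chrom", "start0", "end0"]
    if not case[key].reset_index(drop=True).equals(normal[key].reset_index(drop=True)):
        raise ValueError("case and normal bin grids differ")
    c = case["count"].to_numpy(dtype=float)
    n = normal["count"].to_numpy(dtype=float)
    med_c = np.median(c[c > 0]) if (c > 0).any() else 1.0
    med_n = np.median(n[n > 0]) if (n > 0).any() else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2((c / med_c) / (n / med_n))
    ratio[n == 0] = np.nan
    out = case[key].copy()
    out["log2_ratio"] = ratio
    return out


@dataclass
class Segment:
    chrom: str
    start0: int
    end0: int
    n_bins: int
    mean_ratio: float
    state: str  # gain | loss


def segment_and_call(ratios: pd.DataFrame, z_threshold: float = 3.0,
                     min_bins: int = 3) -> list[Segment]:
    """Merge runs of consistently deviating bins into called segments.

    A bin deviates when its ratio differs from 0 by at least ``z_threshold``
    robust standard deviations (1.4826 x MAD about the median); runs of at
    least ``min_bins`` same-direction deviating bins become segments.
    """
    usable = ratios.dropna(subset=["log2_ratio"])
    if len(usable) < 10:
        raise ValueError("need at least 10 usable bins to segment")
    r = usable["log2_ratio"].to_numpy()
    med = np.median(r)
    mad = np.median(np.abs(r - med))
    robust_sd = 1.4826 * mad if mad > 0 else np.std(r) or 1e-9
    direction = np.where(r >= z_threshold * robust_sd, 1,
                         np.where(r <= -z_threshold * robust_sd, -1, 0))

    segments: list[Segment] = []
    chroms = usable["chrom"].to_numpy()
    i = 0
    while i < len(usable):
        d = direction[i]
        if d == 0:
            i += 1
            continue
        j = i
        while j < len(usable) and direction[j] == d and chroms[j] == chroms[i]:
            j += 1
        if j - i >= min_bins:
            block = usable.iloc[i:j]
            mean_r = float(block["log2_ratio"].mean())
            segments.append(Segment(
                chrom=str(chroms[i]), start0=int(block["start0"].iloc[0]),
                end0=int(block["end0"].iloc[-1]), n_bins=j - i,
                mean_ratio=mean_r, state="gain" if mean_r > 0 else "loss"))
        i = j
    return segments


def estimate_tumour_fraction(segments: list[Segment]) -> float:
    """Tumour fraction implied by the largest clonal single-copy event.

    tf = 2(2^r - 1) for a gain, 2(1 - 2^r) for a loss, clipped to [0, 1];
    0 when no segment was called.
    """
    if not segments:
        return 0.0
    seg = max(segments, key=lambda s: abs(s.mean_ratio))
    r = seg.mean_ratio
    tf = 2.0 * (2.0 ** r - 1.0) if r > 0 else 2.0 * (1.0 - 2.0 ** r)
    return float(np.clip(tf, 0.0, 1.0))


def segments_frame(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chrom": s.chrom, "start0": s.start0, "end0": s.end0,
          "n_bins": s.n_bins, "mean_log2_ratio": round(s.mean_ratio, 4),
          "state": s.state} for s in segments],
        columns=["chrom", "start0", "end0", "n_bins", "mean_log2_ratio", "state"])


# ---------------------------------------------------------------------------
# synthetic binned-depth studies (for power analyses)


@dataclass
class CnaEvent:
    """A clonal single-copy event spanning ``n_bins`` bins from ``start_bin``."""

    start_bin: int
    n_bins: int
    kind: str = "gain"  # gain | loss


def simulate_bin_counts(n_bins: int, mean_count: float, tf: float,
                        events: list[CnaEvent], seed: int,
                        chrom: str = "chr1",
                        bin_width: int = DEFAULT_BIN_WIDTH,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched normal/case Poisson bin counts with clonal events injected.

    The case's expected count in an event bin is scaled by (2 + tf)/2 for a
    gain and (2 - tf)/2 for a loss, the diploid mixture model the
    tumour-fraction estimator inverts.
    """
    rng = np.random.default_rng(seed)
    scale = np.ones(n_bins)
    for ev in events:
        factor = (2 + tf) / 2 if ev.kind == "gain" else (2 - tf) / 2
        scale[ev.start_bin:ev.start_bin + ev.n_bins] *= factor
    normal_counts = rng.poisson(mean_count, n_bins)
    case_counts = rng.poisson(mean_count * scale)
    grid = pd.DataFrame({
        "chrom": chrom,
        "start0": np.arange(n_bins) * bin_width,
        "end0": (np.arange(n_bins) + 1) * bin_width,
    })
    normal = grid.assign(count=normal_counts)
    case = grid.assign(count=case_counts)
    return case, normal
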