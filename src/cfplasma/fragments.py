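"""cfDNA fragment-length analysis of mutation-supporting fragments.

Plasma cfDNA fragment lengths peak at the mono-nucleosome size (~166 bp)
with a secondary di-nucleosome peak (~332 bp). Fragments that carry the alt
allele of a final somatic plasma variant are "somatic" fragments; they are
split into those supporting variants shared with the matched tumour and
those supporting plasma-unique variants. The module computes per-length
histograms, cumulative densities, shared/unique enrichment ratios at every
length cutoff, and the shared fraction inside the di-nucleosome window
(300-350 bp by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("all", "somatic", "somatic_shared", "somatic_unique")

MAX_LENGTH = 2000


def extract_somatic_fragments(fragments: pd.DataFrame,
                              shared_ids: set[str],
                              unique_ids: set[str],
                              known_ids: set[str] | frozenset = frozenset(),
                              ) -> pd.DataFrame:
    """Label fragments by the somatic variant class they support.

    A fragment is somatic iff it covers a somatic variant's position and
    carries the alt allele; fragments carrying the ref allele at a variant
    site are not somatic. Returns the input with a ``label`` column in
    {none, shared, unique} (one row per fragment-variant pair, as in the
    input). ``known_ids`` lists additional legitimate variant ids that carry
    no shared/unique label (e.g. true variants the caller missed);
    fragments referencing an id outside all three sets are an error.
    """
    frag = fragments.copy()
    covered = frag["covered_variant_id"].astype(str)
    known = (covered.isin(shared_ids) | covered.isin(unique_ids)
             | covered.isin(known_ids) | (covered == ""))
    if not known.all():
        bad = sorted(covered[~known].unique())[:5]
        raise ValueError(f"fragments reference unknown variant ids: {bad}")
    is_alt = frag["carried_allele"].astype(str) == "alt"
    label = np.where(is_alt & covered.isin(shared_ids), "shared",
                     np.where(is_alt & covered.isin(unique_ids), "unique", "none"))
    frag["label"] = label
    return frag


@dataclass
class LengthProfile:
    """Per-length fragment counts and cumulative densities by category."""

    counts: pd.DataFrame  # index: length (bp); columns: CATEGORIES

    @property
    def lengths(self) -> np.ndarray:
        return self.counts.index.to_numpy()

    def cdf(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        cum = self.counts.cumsum(axis=0)
        return cum / totals.replace(0, np.nan)

    def total(self, category: str) -> int:
        return int(self.counts[category].sum())

    def count_le(self, category: str, x: int) -> int:
        return int(self.counts.loc[self.counts.index <= x, category].sum())

    def mode(self, category: str = "all") -> int:
        col = self.counts[category]
        if col.sum() == 0:
            raise ValueError(f"no fragments in category {category!r}")
        return int(col.idxmax())


def length_profile(labelled: pd.DataFrame,
                   multi_variant: str = "per_variant") -> LengthProfile:
    """Exact per-length histogram for each category.

    A fragment spanning several somatic variants appears once per variant in
    the input. With ``multi_variant="per_variant"`` (default) it is counted
    once per variant in the shared/unique categories but only once in the
    ``all`` and ``somatic`` categories; with ``"once"`` it is counted once
    everywhere, classed as shared if it supports any shared variant, so that
    shared + unique = somatic exactly.
    """
    if multi_variant not in ("per_variant", "once"):
        raise ValueError("multi_variant must be 'per_variant' or 'once'")
    if len(labelled) == 0:
        empty = pd.DataFrame(columns=list(CATEGORIES), dtype=int)
        empty.index.name = "length"
        return LengthProfile(empty)
    lengths = labelled["length"].to_numpy()
    if (lengths <= 0).any() or (lengths > MAX_LENGTH).any():
        raise ValueError(f"fragment lengths must be in (0, {MAX_LENGTH}]")

    per_fragment = labelled.drop_duplicates("fragment_id")
    somatic_rows = labelled[labelled["label"] != "none"]
    somatic_frag = somatic_rows.drop_duplicates("fragment_id")
    if multi_variant == "per_variant":
        shared = somatic_rows[somatic_rows["label"] == "shared"]
        unique = somatic_rows[somatic_rows["label"] == "unique"]
    else:  # one count per fragment, shared takes priority
        prioritised = somatic_rows.sort_values(
            "label", kind="stable").drop_duplicates("fragment_id")
        shared = prioritised[prioritised["label"] == "shared"]
        unique = prioritised[prioritised["label"] == "unique"]

    idx = pd.RangeIndex(1, MAX_LENGTH + 1, name="length")
    counts = pd.DataFrame({
        "all": per_fragment["length"].value_counts().reindex(idx, fill_value=0),
        "somatic": somatic_frag["length"].value_counts().reindex(idx, fill_value=0),
        "somatic_shared": shared["length"].value_counts().reindex(idx, fill_value=0),
        "somatic_unique": unique["length"].value_counts().reindex(idx, fill_value=0),
    }).astype(int)
    counts = counts.loc[counts.index <= max(int(lengths.max()), 1)]
    return LengthProfile(counts)


def enrichment_ratio(profile: LengthProfile, x: int) -> tuple[float | None, float | None]:
    """(shared/unique among lengths <= x, unique/shared among lengths > x).

    A ratio with an empty denominator is returned as None rather than
    raising or producing infinity.
    """
    if not 0 < x < MAX_LENGTH:
        raise ValueError("cutoff x must be in (0, 2000)")
    sh_le = profile.count_le("somatic_shared", x)
    un_le = profile.count_le("somatic_unique", x)
    sh_gt = profile.total("somatic_shared") - sh_le
    un_gt = profile.total("somatic_unique") - un_le
    ratio_le = sh_le / un_le if un_le else None
    ratio_gt = un_gt / sh_gt if sh_gt else None
    return ratio_le, ratio_gt


def enrichment_curve(profile: LengthProfile) -> pd.DataFrame:
    """Both enrichment ratios at every observed length cutoff."""
    rows = []
    for x in profile.lengths:
        le, gt = enrichment_ratio(profile, int(x))
        rows.append({"x": int(x), "ratio_shared_unique_le": le,
                     "ratio_unique_shared_gt": gt})
    return pd.DataFrame(rows)


def window_shared_fraction(profile: LengthProfile, lo: int = 300,
                           hi: int = 350) -> tuple[float | None, float | None]:
    """Shared fraction among somatic fragments in [lo, hi] vs over all lengths.

    Returns (window_fraction, overall_fraction); the window fraction is None
    when no somatic fragment falls in the window. Default window is the
    di-nucleosome peak, 300-350 bp inclusive.
    """
    if lo >= hi:
        raise ValueError("window bounds must satisfy lo < hi")
    in_win = (profile.counts.index >= lo) & (profile.counts.index <= hi)
    sh_w = int(profile.counts.loc[in_win, "somatic_shared"].sum())
    un_w = int(profile.counts.loc[in_win, "somatic_unique"].sum())
    sh_t = profile.total("somatic_shared")
    un_t = profile.total("somatic_unique")
    window = sh_w / (sh_w + un_w) if sh_w + un_w else None
    overall = sh_t / (sh_t + un_t) if sh_t + un_t else None
    return window, overall
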