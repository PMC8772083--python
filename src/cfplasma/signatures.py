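"""96-context mutational catalogs, de novo NMF extraction and refitting.

A mutation catalog counts single-base substitutions over the 96 channels
defined by the six pyrimidine-reference substitution types (C>A, C>G, C>T,
T>A, T>C, T>G) and the two flanking bases; substitutions observed on a
purine reference base are mapped to the reverse-complement channel.

De novo extraction factorises a 96 x n catalog V into non-negative S (96 x k
signature profiles, column-stochastic) and H (k x n contributions) by
multiplicative-update NMF under the Frobenius objective, keeping the best of
several seeded random restarts. Refitting expresses a single profile in a
fixed reference basis by non-negative least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Channel:
    substitution: str  # e.g. "C>T"
    context: str       # trinucleotide with the pyrimidine ref centred, e.g. "ACG"

    @property
    def ref(self) -> str:
        return self.substitution[0]

    @property
    def alt(self) -> str:
        return self.substitution[2]

    @property
    def label(self) -> str:
        return f"{self.context[0]}[{self.substitution}]{self.context[2]}"


#: fixed channel order: substitution-major, flanks lexicographic
CHANNELS: list[Channel] = [
    Channel(sub, f"{l}{sub[0]}{r}")
    for sub in _SUBSTITUTIONS for l in _FLANKS for r in _FLANKS
]
CHANNEL_LABELS = [c.label for c in CHANNELS]
_CHANNEL_INDEX = {(c.substitution, c.context): i for i, c in enumerate(CHANNELS)}


def channel_index(ref: str, alt: str, context: str) -> int:
    """96-channel index for a substitution with its trinucleotide context.

    ``context`` is the reference trinucleotide around the variant; purine
    references are flipped to the pyrimidine strand.
    """
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not centre on ref {ref!r}")
    if ref in "AG":
        context = context.translate(_COMPLEMENT)[::-1]
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return _CHANNEL_INDEX[(f"{ref}>{alt}", context)]


def catalog_from_variants(
    variants: dict[str, list[tuple[str, int, str, str]]],
    reference: dict[str, str],
) -> pd.DataFrame:
    """Build a 96 x samples catalog from in-memory SNV lists.

    ``variants`` maps column name -> list of (chrom, pos1, ref, alt).
    Variants at a contig edge (no flanking base) are skipped; the skip count
    is attached as ``df.attrs['skipped']``.
    """
    data = {}
    skipped = 0
    for name, snvs in variants.items():
        col = np.zeros(96, dtype=int)
        for chrom, pos1, ref, alt in snvs:
            seq = reference[chrom]
            i = pos1 - 1
            if i < 1 or i >= len(seq) - 1:
                skipped += 1
                continue
            if seq[i] != ref:
                raise ValueError(f"reference mismatch at {chrom}:{pos1}: "
                                 f"expected {ref}, found {seq[i]}")
            col[channel_index(ref, alt, seq[i - 1:i + 2])] += 1
        data[name] = col
    df = pd.DataFrame(data, index=CHANNEL_LABELS)
    df.attrs["skipped"] = skipped
    return df


def build_catalog(vcf_path, fasta_path, sample_name: str | None = None) -> pd.DataFrame:
    """Catalog a VCF of SNVs against a FASTA reference (one column)."""
    from .simulate import read_fasta
    from .vcfio import read_sites

    reference = read_fasta(fasta_path)
    sites = read_sites(vcf_path)
    name = sample_name or "sample"
    return catalog_from_variants({name: sites}, reference)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# de novo NMF


@dataclass
class SignatureSet:
    signatures: pd.DataFrame     # 96 x k, columns sum to 1
    contributions: pd.DataFrame  # k x n samples (absolute scale)
    reconstruction_error: float  # Frobenius norm of V - S H

    def relative_contributions(self) -> pd.DataFrame:
        h = self.contributions
        total = h.sum(axis=0)
        return h / total.replace(0, np.nan)


def _nmf_mu(V: np.ndarray, k: int, rng: np.random.Generator,
            max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, float]:
    """One multiplicative-update NMF run; objective checked for monotonicity."""
    eps = 1e-12
    m, n = V.shape
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = rng.random((m, k)) * scale + eps
    H = rng.random((k, n)) * scale + eps
    prev = np.linalg.norm(V - W @ H)
    last_checked = prev
    for it in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ H @ H.T + eps)
        if (it + 1) % 10 == 0:
            err = np.linalg.norm(V - W @ H)
            if err > last_checked + 1e-6 * (1 + last_checked):
                raise AssertionError("NMF objective increased")
            if abs(last_checked - err) <= tol * max(last_checked, eps):
                last_checked = err
                break
            last_checked = err
    return W, H, float(np.linalg.norm(V - W @ H))


def extract_denovo(catalog: pd.DataFrame, k: int, n_runs: int = 20,
                   seed: int = 0, max_iter: int = 2000,
                   tol: float = 1e-6) -> SignatureSet:
    """Best-of-``n_runs`` seeded NMF factorisation of a mutation catalog.

    Signature columns are normalised to sum to 1, with the scale absorbed
    into the contribution matrix; columns are ordered by total contribution
    for determinism.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    V = catalog.to_numpy(dtype=float)
    if (V.sum(axis=0) <= 0).any():
        raise ValueError("catalog has an empty sample column")
    if k >= min(96, V.shape[1] * 10):
        raise ValueError("k too large for this catalog")

    best = None
    for run in range(n_runs):
        rng = np.random.default_rng([int(seed), run])
        W, H, err = _nmf_mu(V, k, rng, max_iter, tol)
        if best is None or err < best[2]:
            best = (W, H, err)
    W, H, err = best

    col_sums = W.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    S = W / col_sums
    H = H * col_sums[:, None]
    order = np.argsort(-H.sum(axis=1), kind="stable")
    S, H = S[:, order], H[order]
    labels = [f"Signature {chr(65 + i)}" for i in range(k)]
    return SignatureSet(
        pd.DataFrame(S, index=catalog.index, columns=labels),
        pd.DataFrame(H, index=labels, columns=catalog.columns),
        err,
    )


# ---------------------------------------------------------------------------
# refitting against reference signatures


def refit(profile: np.ndarray | pd.Series, references: pd.DataFrame) -> pd.Series:
    """Non-negative least-squares contributions of reference signatures.

    Returns absolute contributions h minimising ||m - R h||_2; the residual
    norm is attached as ``result.attrs['residual']``.
    """
    from scipy.optimize import nnls

    m = np.asarray(profile, dtype=float).ravel()
    if m.sum() <= 0:
        raise ValueError("cannot refit an all-zero profile")
    R = references.to_numpy(dtype=float)
    if R.shape[0] != m.shape[0]:
        raise ValueError("profile and reference signatures disagree in length")
    h, res = nnls(R, m)
    out = pd.Series(h, index=references.columns)
    out.attrs["residual"] = float(res)
    return out


def relative(h: pd.Series) -> pd.Series:
    total = h.sum()
    if total == 0:
        return h * np.nan
    return h / total


def compare_subsets(shared: pd.Series | np.ndarray, unique: pd.Series | np.ndarray,
                    references: pd.DataFrame) -> pd.DataFrame:
    """Refit two catalog subsets and tabulate contribution differences."""
    rows = {}
    errors = {}
    for name, prof in (("shared", shared), ("unique", unique)):
        try:
            rows[name] = relative(refit(prof, references))
        except ValueError as exc:
            errors[name] = str(exc)
    if not rows:
        raise ValueError(f"both subsets failed to refit: {errors}")
    df = pd.DataFrame(rows)
    if len(rows) == 2:
        df["difference"] = df["unique"] - df["shared"]
    df.attrs["errors"] = errors
    if errors:
        raise ValueError(f"subset refit failed: {errors}; partial result in exc.args[1]",
                         df)
    return df


def default_reference_signatures() -> pd.DataFrame:
    """Bundled synthetic illustrative reference signatures (96 x 5).

    These are stand-ins shaped like well-known mutational processes
    (CpG deamination, APOBEC-like C>T/C>G at TpC, a flat clock-like profile,
    a T>C-heavy profile, a C>A-heavy profile); they are synthetic and carry
    no catalogued aetiology. A user-supplied 96 x r TSV of real reference
    signatures can be used instead anywhere a reference matrix is accepted.
    """
    cols = {}
    deam = np.zeros(96)
    apo = np.zeros(96)
    flat = np.ones(96)
    tc = np.zeros(96)
    ca = np.zeros(96)
    for i, ch in enumerate(CHANNELS):
        if ch.substitution == "C>T" and ch.context[2] == "G":
            deam[i] = 1.0
        if ch.context[0] == "T" and ch.substitution in ("C>T", "C>G"):
            apo[i] = 1.0
        if ch.substitution == "T>C":
            tc[i] = 1.0 + (0.5 if ch.context[0] == "A" else 0.0)
        if ch.substitution == "C>A":
            ca[i] = 1.0
    cols["SYN1_cpg_deamination"] = deam
    cols["SYN2_tpc_editing"] = apo
    cols["SYN3_flat_clock"] = flat
    cols["SYN4_tc_replication"] = tc
    cols["SYN5_ca_oxidative"] = ca
    df = pd.DataFrame(cols, index=CHANNEL_LABELS, dtype=float)
    return df / df.sum(axis=0)


def read_reference_signatures(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise ValueError("reference signature table must have 96 rows")
    return df / df.sum(axis=0)
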