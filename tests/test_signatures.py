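"""96-context catalogs, NMF extraction, NNLS refitting, cosine similarity."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from cfplasma import signatures as sg


def point_mixture(channels):
    v = np.zeros(96)
    for label in channels:
        v[sg.CHANNEL_LABELS.index(label)] = 1.0
    return v / v.sum()


class TestChannels:
    def test_96_unique_substitution_major_channels(self):
        assert len(sg.CHANNELS) == 96
        assert len(set(sg.CHANNEL_LABELS)) == 96
        assert sg.CHANNEL_LABELS[0] == "A[C>A]A"
        assert sg.CHANNEL_LABELS[-1] == "T[T>G]T"

    def test_purine_variant_maps_to_reverse_complement_channel(self):
        # G>A seen in context AGC lies on the purine strand; its
        # pyrimidine-strand channel is C>T in context GCT
        idx = sg.channel_index("G", "A", "AGC")
        assert sg.CHANNEL_LABELS[idx] == "G[C>T]T"

    def test_pyrimidine_variant_kept_as_is(self):
        idx = sg.channel_index("C", "T", "ACA")
        assert sg.CHANNEL_LABELS[idx] == "A[C>T]A"


class TestCatalog:
    reference = {"chr1": "TTACAGCTT"}

    def test_counts_pyrimidine_and_purine_variants(self):
        # C>T at pos 4 (context ACA); G>A at pos 6 (context AGC -> G[C>T]T)
        cat = sg.catalog_from_variants(
            {"s": [("chr1", 4, "C", "T"), ("chr1", 6, "G", "A")]}, self.reference)
        assert cat.loc["A[C>T]A", "s"] == 1
        assert cat.loc["G[C>T]T", "s"] == 1
        assert cat["s"].sum() == 2

    def test_empty_input_gives_zero_catalog(self):
        cat = sg.catalog_from_variants({"s": []}, self.reference)
        assert cat["s"].sum() == 0

    def test_contig_edge_variant_skipped_with_count(self):
        cat = sg.catalog_from_variants(
            {"s": [("chr1", 1, "T", "C"), ("chr1", 4, "C", "T")]}, self.reference)
        assert cat["s"].sum() == 1
        assert cat.attrs["skipped"] == 1

    def test_reference_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            sg.catalog_from_variants({"s": [("chr1", 4, "G", "T")]}, self.reference)

    def test_strand_involution_leaves_catalog_unchanged(self):
        from cfplasma.simulate import revcomp

        seq = "TTACAGCTTGGATCCA"
        variants = [("chr1", 4, "C", "T"), ("chr1", 6, "G", "A"),
                    ("chr1", 11, "G", "C")]
        cat = sg.catalog_from_variants({"s": variants}, {"chr1": seq})
        flipped_seq = revcomp(seq)
        n = len(seq)
        comp = str.maketrans("ACGT", "TGCA")
        flipped_variants = [("chr1", n - pos + 1, ref.translate(comp),
                             alt.translate(comp)) for pos, ref, alt in
                            [(p, r, a) for _, p, r, a in variants]]
        cat_flipped = sg.catalog_from_variants({"s": flipped_variants},
                                               {"chr1": flipped_seq})
        assert cat.equals(cat_flipped)


class TestCosine:
    def test_identical_vectors(self):
        v = np.arange(1, 97, dtype=float)
        assert sg.cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_support(self):
        a, b = np.zeros(96), np.zeros(96)
        a[0], b[1] = 1, 1
        assert sg.cosine_similarity(a, b) == 0.0

    def test_hand_computed_value(self):
        assert sg.cosine_similarity(np.array([1, 1, 0]), np.array([1, 0, 0])) \
            == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            sg.cosine_similarity(np.zeros(3), np.ones(3))


class TestDenovoNMF:
    def rank1_catalog(self):
        s = point_mixture(["A[C>T]G", "C[C>T]G", "T[T>C]A"])
        h = np.array([300.0, 500.0, 200.0])
        return pd.DataFrame(np.outer(s, h), index=sg.CHANNEL_LABELS,
                            columns=["a", "b", "c"]), s

    def test_rank1_catalog_recovered_exactly(self):
        cat, s = self.rank1_catalog()
        res = sg.extract_denovo(cat, k=1, n_runs=5, seed=1)
        assert sg.cosine_similarity(res.signatures.iloc[:, 0], s) >= 0.999

    def test_same_seed_reproduces_factorisation(self):
        cat, _ = self.rank1_catalog()
        a = sg.extract_denovo(cat, k=1, n_runs=3, seed=7)
        b = sg.extract_denovo(cat, k=1, n_runs=3, seed=7)
        assert a.signatures.equals(b.signatures)
        assert a.contributions.equals(b.contributions)

    def test_two_orthogonal_signatures_recovered(self, rng):
        s1 = point_mixture([l for l in sg.CHANNEL_LABELS if "[C>A]" in l])
        s2 = point_mixture([l for l in sg.CHANNEL_LABELS if "[T>C]" in l])
        mixing = [(0.8, 0.2), (0.2, 0.8), (0.5, 0.5), (0.9, 0.1), (0.35, 0.65)]
        V = np.stack([rng.multinomial(5000, a * s1 + b * s2) for a, b in mixing],
                     axis=1)
        cat = pd.DataFrame(V, index=sg.CHANNEL_LABELS,
                           columns=[f"s{i}" for i in range(len(mixing))])
        res = sg.extract_denovo(cat, k=2, n_runs=10, seed=2)
        S = res.signatures.to_numpy()
        cos = np.array([[sg.cosine_similarity(S[:, i], t) for t in (s1, s2)]
                        for i in range(2)])
        rows, cols = linear_sum_assignment(-cos)
        assert (cos[rows, cols] >= 0.95).all()

    def test_matches_sklearn_reconstruction_error(self, rng):
        """Independent cross-check: the multiplicative-update fit reaches the
        reconstruction error sklearn's NMF attains on the same problem."""
        from sklearn.decomposition import NMF

        V = rng.poisson(20, size=(96, 6)).astype(float) + 1
        cat = pd.DataFrame(V, index=sg.CHANNEL_LABELS,
                           columns=[f"s{i}" for i in range(6)])
        res = sg.extract_denovo(cat, k=2, n_runs=10, seed=3)
        sk = NMF(n_components=2, solver="mu", beta_loss="frobenius",
                 init="random", random_state=0, max_iter=2000, tol=1e-6).fit(V)
        sk_err = np.linalg.norm(V - sk.transform(V) @ sk.components_)
        assert res.reconstruction_error <= sk_err * 1.02

    def test_invalid_rank_rejected(self):
        cat, _ = self.rank1_catalog()
        with pytest.raises(ValueError):
            sg.extract_denovo(cat, k=0)

    def test_signature_columns_are_stochastic(self):
        cat, _ = self.rank1_catalog()
        res = sg.extract_denovo(cat, k=1, n_runs=3, seed=1)
        np.testing.assert_allclose(res.signatures.sum(axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            res.relative_contributions().sum(axis=0), 1.0, atol=1e-9)


class TestRefit:
    def test_exact_mixture_recovered(self):
        R = sg.default_reference_signatures()
        h_true = pd.Series([0.2, 0.0, 0.5, 0.3, 0.0], index=R.columns)
        m = R @ h_true
        h = sg.refit(m, R)
        np.testing.assert_allclose(h / h.sum(), h_true, atol=1e-6)
        assert h.attrs["residual"] < 1e-9

    def test_orthogonal_profile_flagged_as_unexplained(self):
        R = pd.DataFrame({"r1": np.eye(96)[:, 0]}, index=sg.CHANNEL_LABELS)
        m = np.zeros(96)
        m[5] = 10.0
        h = sg.refit(m, R)
        assert h.sum() == 0.0

    def test_noisy_mixture_recovered_within_tolerance(self, rng):
        R = sg.default_reference_signatures()
        probs = (0.7 * R["SYN1_cpg_deamination"] + 0.3 * R["SYN4_tc_replication"])
        m = rng.poisson(5000 * probs.to_numpy())
        rel = sg.relative(sg.refit(m, R))
        assert abs(rel["SYN1_cpg_deamination"] - 0.7) < 0.05
        assert abs(rel["SYN4_tc_replication"] - 0.3) < 0.05

    def test_zero_profile_rejected(self):
        R = sg.default_reference_signatures()
        with pytest.raises(ValueError):
            sg.refit(np.zeros(96), R)

    def test_residual_zero_inside_reference_cone(self, rng):
        R = sg.default_reference_signatures()
        h_true = rng.random(R.shape[1])
        m = R.to_numpy() @ h_true
        assert sg.refit(m, R).attrs["residual"] < 1e-9


class TestCompareSubsets:
    def test_identical_subsets_have_zero_difference(self):
        R = sg.default_reference_signatures()
        m = (R @ pd.Series([0.4, 0.1, 0.2, 0.2, 0.1], index=R.columns)) * 1000
        table = sg.compare_subsets(m, m, R)
        np.testing.assert_allclose(table["difference"], 0.0, atol=1e-9)

    def test_background_only_signature_higher_in_unique(self, rng):
        R = sg.default_reference_signatures()
        shared = rng.poisson(3000 * R["SYN1_cpg_deamination"].to_numpy())
        unique = rng.poisson(3000 * R["SYN4_tc_replication"].to_numpy())
        table = sg.compare_subsets(shared + 1, unique + 1, R)
        assert table.loc["SYN4_tc_replication", "unique"] > \
            table.loc["SYN4_tc_replication", "shared"]

    def test_empty_subset_surfaces_error_with_partial_result(self):
        R = sg.default_reference_signatures()
        m = (R @ pd.Series(np.ones(5) / 5, index=R.columns)) * 100
        with pytest.raises(ValueError) as exc:
            sg.compare_subsets(m, np.zeros(96), R)
        partial = exc.value.args[1]
        assert "shared" in partial.columns
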