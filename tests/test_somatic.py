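"""Somatic caller: Fisher statistic, classification and the filter cascade."""

import numpy as np
import pytest
from scipy import stats

from cfplasma import somatic
from cfplasma.simulate import SimConfig, simulate_study
from cfplasma.somatic import (AlleleCounts, SomaticCall, SomaticParams,
                              call_variant, classify_somatic, final_calls,
                              final_threshold_filter, fp_filter,
                              high_confidence_filter, run_somatic_pipeline,
                              somatic_p_value)


def counts(ref, alt, depth=None, baseq=30.0, mapq=60.0, fwd=None,
           readpos=0.5, chrom="chr1", pos=100):
    depth = depth if depth is not None else ref + alt
    fwd = fwd if fwd is not None else alt // 2
    return AlleleCounts(chrom, pos, "A", depth, ref, "C", alt,
                        mean_baseq_alt=baseq, mean_mapq=mapq,
                        alt_fwd=fwd, alt_rev=alt - fwd,
                        mean_readpos_alt=readpos)


class TestCallVariant:
    @pytest.mark.parametrize("ref,alt,baseq,min_vf,min_q,expected", [
        (95, 5, 30, 0.01, 15, True),    # vaf 0.05 over threshold
        (999, 1, 30, 0.01, 15, False),  # vaf 0.001 and 1 read
        (98, 2, 10, 0.01, 15, False),   # base quality too low
        (98, 2, 30, 0.01, 15, True),    # exactly min_reads2
    ])
    def test_threshold_arithmetic(self, ref, alt, baseq, min_vf, min_q, expected):
        assert call_variant(counts(ref, alt, baseq=baseq), min_vf, 2, min_q) is expected

    def test_zero_depth_is_not_callable_not_an_error(self):
        c = AlleleCounts("chr1", 1, "A", 0, 0, "C", 0)
        assert call_variant(c) is False


class TestSomaticPValue:
    def test_known_table(self):
        # normal 50 ref / 0 alt vs case 45 ref / 5 alt
        p = somatic_p_value(counts(50, 0), counts(45, 5))
        assert p == pytest.approx(0.0281, abs=2e-4)

    def test_identical_proportions_not_significant(self):
        p = somatic_p_value(counts(50, 5), counts(50, 5))
        assert p > 0.5

    def test_no_alt_reads_anywhere_gives_p_one(self):
        assert somatic_p_value(counts(10, 0), counts(10, 0)) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            counts(-1, 5)

    def test_matches_hypergeometric_oracle_on_all_small_tables(self):
        """Exhaustive check against scipy's hypergeometric survival function
        for every 2x2 table with total reads <= 60, to 1e-12."""
        worst = 0.0
        for dn in range(1, 60):
            for dc in range(1, 61 - dn):
                n_total = dn + dc
                for total_alt in range(n_total + 1):
                    k_lo = max(0, total_alt - dn)
                    k_hi = min(dc, total_alt)
                    ks = np.arange(k_lo, k_hi + 1)
                    oracle = stats.hypergeom.sf(ks - 1, n_total, total_alt, dc)
                    for k, expected in zip(ks, oracle):
                        got = somatic._hypergeom_upper_tail(dc, dn, total_alt, int(k))
                        worst = max(worst, abs(got - expected))
        assert worst < 1e-12


class TestClassification:
    def test_clean_normal_with_case_variant_is_somatic(self):
        status, p = classify_somatic(counts(100, 0), counts(95, 5), SomaticParams())
        assert status == somatic.SOMATIC and p <= 0.05

    def test_consistent_het_vafs_are_germline(self):
        status, _ = classify_somatic(counts(52, 48), counts(49, 51), SomaticParams())
        assert status == somatic.GERMLINE

    def test_het_normal_shifted_to_homozygous_case_is_loh(self):
        status, p = classify_somatic(counts(50, 50), counts(2, 98), SomaticParams())
        assert status == somatic.LOH and p <= 0.05


class TestFilters:
    def make_call(self, normal, case):
        return SomaticCall(case.chrom, case.pos1, case.ref_base, case.alt_base,
                           normal, case, 0.01, somatic.SOMATIC)

    def test_high_confidence_keeps_clean_normal(self):
        call = self.make_call(counts(100, 0), counts(98, 2))
        assert high_confidence_filter([call]) == [call]

    @pytest.mark.parametrize("normal,case", [
        (counts(29, 1), counts(97, 3)),    # any normal alt read removes
        (counts(100, 0), counts(995, 5)),  # case vaf 0.005 below min_tumor_freq
    ])
    def test_high_confidence_removes(self, normal, case):
        assert high_confidence_filter([self.make_call(normal, case)]) == []

    def test_fp_filter_nominal_metrics_pass(self):
        call = self.make_call(counts(100, 0),
                              counts(95, 5, baseq=30, mapq=60, fwd=3, readpos=0.5))
        ok, reasons = fp_filter(call)
        assert ok and reasons == []

    @pytest.mark.parametrize("kwargs,reason", [
        (dict(fwd=10), "strand_bias"),            # 10 fwd / 0 rev
        (dict(readpos=0.02), "read_position"),
        (dict(baseq=10), "low_base_quality"),
        (dict(mapq=10), "low_mapping_quality"),
    ])
    def test_fp_filter_failure_reasons(self, kwargs, reason):
        call = self.make_call(counts(100, 0), counts(90, 10, **kwargs))
        ok, reasons = fp_filter(call)
        assert not ok and reason in reasons

    def test_final_thresholds_boundary(self):
        # 30x/0 alt normal, 100x/5 alt case: exactly at every bound
        assert final_threshold_filter(
            self.make_call(counts(30, 0), counts(95, 5)))

    @pytest.mark.parametrize("normal,case", [
        (counts(30, 0), counts(96, 4)),   # 4 alt reads
        (counts(29, 1), counts(95, 5)),   # normal alt read
        (counts(9, 0), counts(95, 5)),    # normal depth 9
    ])
    def test_final_thresholds_reject(self, normal, case):
        assert not final_threshold_filter(self.make_call(normal, case))

    def test_read_level_filters_commute(self):
        """fp_filter and final_threshold_filter are pure predicates, so the
        final set is the same whichever is applied first."""
        calls = [self.make_call(counts(30, 0), counts(95, 5)),
                 self.make_call(counts(30, 0), counts(96, 4)),
                 self.make_call(counts(30, 0), counts(90, 10, fwd=10)),
                 self.make_call(counts(9, 0), counts(95, 5))]
        ab = [c for c in calls if fp_filter(c)[0] and final_threshold_filter(c)]
        ba = [c for c in calls if final_threshold_filter(c) and fp_filter(c)[0]]
        assert ab == ba


class TestPipeline:
    def test_recall_and_precision_at_high_tumour_fraction(self, study_uniform100):
        """At tf = 0.30 and 100x depth the cascade recovers >= 90% of clonal
        tumour mutations at >= 90% precision against the somatic truth."""
        study = study_uniform100
        calls, _ = run_somatic_pipeline(study.pileups["germline"],
                                        study.pileups["plasma"])
        called = {c.site for c in final_calls(calls)}
        truth_tum = {v.site for v in study.truth.tumour}
        truth_somatic = truth_tum | {v.site for v in study.truth.background}
        recall = len(called & truth_tum) / len(truth_tum)
        precision = len(called & truth_somatic) / len(called)
        assert recall >= 0.9
        assert precision >= 0.9

    def test_detection_limit_at_sub_percent_tumour_fraction(self, study_lowtf):
        """At tf = 0.005 a clonal mutation sits at VAF 0.0025 — roughly one
        supporting read in 100x — so the cascade recovers almost nothing."""
        study = study_lowtf
        calls, _ = run_somatic_pipeline(study.pileups["germline"],
                                        study.pileups["plasma"])
        called = {c.site for c in final_calls(calls)}
        truth_tum = {v.site for v in study.truth.tumour}
        assert len(called & truth_tum) / len(truth_tum) < 0.2

    def test_null_study_produces_no_final_calls(self):
        cfg = SimConfig(seed=17, genome_length=100_000, n_chromosomes=1,
                        plasma_tumour_fraction=0.0, base_error_rate=0.0,
                        n_background_mutations=0, n_plasma_fragments=500)
        study = simulate_study(cfg)
        calls, _ = run_somatic_pipeline(study.pileups["germline"],
                                        study.pileups["plasma"])
        assert final_calls(calls) == []

    def test_stage_counts_monotonically_non_increasing(self, study_uniform100):
        _, counts_ = run_somatic_pipeline(study_uniform100.pileups["germline"],
                                          study_uniform100.pileups["plasma"])
        chain = [counts_["called"], counts_["high_confidence"],
                 counts_["fp_filter"], counts_["final"]]
        assert chain == sorted(chain, reverse=True)

    def test_reference_mismatch_between_samples_is_an_error(self, small_config):
        study = simulate_study(small_config)
        broken = study.pileups["plasma"].copy()
        broken.loc[broken.index[0], "ref"] = (
            "A" if broken.loc[broken.index[0], "ref"] != "A" else "C")
        with pytest.raises(ValueError, match="mismatch"):
            run_somatic_pipeline(study.pileups["germline"], broken)
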