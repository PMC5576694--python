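"""Filter cascade: boundary behavior, pipeline composition, oracle equivalence."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tkiresist.filtering import (
    FilterConfig,
    apply_quality_filter,
    classify_germline,
    filter_normal_depth,
    filter_tumor_depth,
    run_filter_pipeline,
    select_strategy_a,
    select_strategy_b,
    selected_keys,
    traces_to_dataframe,
)
from tkiresist.simulate import VariantSimSpec, gen_patient_variants
from tkiresist.variants import PatientVariantSet, VariantObservation

from oracle_filter import oracle_outcomes, random_patient_table

CFG = FilterConfig()


def obs(total, mutant, pos=100, mq=60.0, qual=99.0):
    return VariantObservation(
        chrom="1", pos=pos, ref="A", alt="T", gene="G1",
        total_reads=total, mutant_reads=mutant, mq=mq, qual=qual,
    )


def pset_with(n=None, p=None, r=None, pos=100):
    ps = PatientVariantSet(patient_id="T")
    for role, o in (("N", n), ("P", p), ("R", r)):
        if o is not None:
            ps.add(role, o)
    return ps


class TestNormalDepth:
    @pytest.mark.parametrize("depth,removed", [(9, True), (10, False), (0, True)])
    def test_boundary(self, depth, removed):
        ps = pset_with(n=obs(depth, 0), r=obs(50, 5))
        rem, surv = filter_normal_depth(ps, CFG)
        assert (len(rem) == 1) is removed
        assert len(rem) + len(surv) == 1

    def test_missing_normal_treated_as_zero_depth(self):
        ps = pset_with(r=obs(50, 5))
        rem, surv = filter_normal_depth(ps, CFG)
        assert len(rem) == 1 and not surv


class TestGermlineCall:
    @pytest.mark.parametrize(
        "mutant,total,expected",
        [
            (2, 30, "germline"),   # band 1: >=2 mutant at total 10-49
            (1, 30, "somatic"),
            (3, 60, "germline"),   # band 2: >=3 mutant at total >=50
            (2, 60, "somatic"),
            (2, 10, "germline"),   # band-1 lower depth edge
            (2, 49, "germline"),   # band-1 upper depth edge
            (2, 50, "somatic"),    # falls between the bands
            (0, 100, "somatic"),
        ],
    )
    def test_bands(self, mutant, total, expected):
        assert classify_germline(obs(total, mutant), CFG) == expected

    @given(st.integers(10, 500), st.integers(0, 499))
    def test_more_mutant_reads_never_flip_germline_to_somatic(self, total, mutant):
        mutant = min(mutant, total - 1)
        if classify_germline(obs(total, mutant), CFG) == "germline":
            assert classify_germline(obs(total, mutant + 1), CFG) == "germline"


class TestTumorDepth:
    def test_strategy_b_requires_both_biopsies_covered(self):
        ps = pset_with(n=obs(30, 0), p=obs(9, 1), r=obs(50, 10))
        rem, _ = filter_tumor_depth(ps, CFG, "B")
        assert len(rem) == 1

    def test_boundary_depth_10_survives(self):
        ps = pset_with(n=obs(30, 0), p=obs(10, 1), r=obs(10, 3))
        rem, surv = filter_tumor_depth(ps, CFG, "B")
        assert not rem and len(surv) == 1

    def test_strategy_a_checks_resistant_only(self):
        ps = pset_with(n=obs(30, 0), r=obs(12, 3))
        rem, surv = filter_tumor_depth(ps, CFG, "A")
        assert not rem and len(surv) == 1

    def test_strategy_b_without_pre_sample_is_usage_error(self):
        ps = pset_with(n=obs(30, 0), r=obs(50, 10))
        with pytest.raises(ValueError, match="strategy B"):
            filter_tumor_depth(ps, CFG, "B")


class TestQualityGate:
    @pytest.mark.parametrize(
        "mq,qual,kept",
        [(20.0, 50.0, False), (21.0, 21.0, True), (60.0, 19.0, False), (None, 50.0, False)],
    )
    def test_strict_thresholds(self, mq, qual, kept):
        removed, retained = apply_quality_filter([obs(50, 5, mq=mq, qual=qual)], CFG)
        assert (len(retained) == 1) is kept
        assert len(removed) + len(retained) == 1


class TestSelection:
    def test_strategy_a_presence_rule_and_gene_list(self):
        ps = pset_with(n=obs(30, 0), r=obs(40, 4))
        ps.add("R", obs(40, 0, pos=200))
        sel, genes = select_strategy_a(ps, CFG)
        assert [k[1] for k in sel] == [100]
        assert genes == ["G1"]

    def test_strategy_a_gene_listed_once_for_two_variants(self):
        ps = pset_with(n=obs(30, 0), r=obs(40, 4))
        ps.add("R", obs(40, 4, pos=200))
        _, genes = select_strategy_a(ps, CFG)
        assert genes == ["G1"]

    @pytest.mark.parametrize(
        "p_counts,r_counts,selected",
        [
            ((40, 4), (40, 10), True),    # 0.25 > 2 * 0.10
            ((40, 4), (40, 8), False),    # 0.20 not > 0.20 (strict)
            ((40, 0), (40, 2), True),     # resistant-specific: any positive beats 2*0
            ((40, 0), (40, 0), False),
        ],
    )
    def test_strategy_b_doubling_rule(self, p_counts, r_counts, selected):
        ps = pset_with(n=obs(30, 0), p=obs(*p_counts), r=obs(*r_counts))
        sel = select_strategy_b(ps, CFG)
        assert (len(sel) == 1) is selected

    @given(st.integers(1, 20), st.integers(1, 20))
    def test_strategy_b_invariant_under_count_scaling(self, kp, kr):
        base_p, base_r = (40, 4), (40, 9)
        ps1 = pset_with(n=obs(30, 0), p=obs(*base_p), r=obs(*base_r))
        ps2 = pset_with(
            n=obs(30, 0),
            p=obs(base_p[0] * kp, base_p[1] * kp),
            r=obs(base_r[0] * kr, base_r[1] * kr),
        )
        assert bool(select_strategy_b(ps1, CFG)) == bool(select_strategy_b(ps2, CFG))


class TestPipeline:
    def test_noise_free_synthetic_recovers_exactly_planted_resistant(self):
        spec = VariantSimSpec(
            n_patients=1, n_germline=25, n_shared_somatic=12,
            n_resistant_specific=5, depth_mean=100, seed=11, noise=False,
        )
        (pset,), truth = gen_patient_variants(spec)
        traces = run_filter_pipeline(pset, strategy="B")
        planted = truth[truth.label == "resistant_specific"]
        expected = set(zip(planted.chrom, planted.pos, planted.ref, planted.alt))
        assert set(selected_keys(traces)) == expected

    def test_all_variants_failing_step1_go_no_further(self):
        ps = PatientVariantSet(patient_id="T")
        for i in range(4):
            ps.add("N", obs(5, 0, pos=i + 1))
            ps.add("P", obs(50, 5, pos=i + 1))
            ps.add("R", obs(50, 25, pos=i + 1))
        traces = run_filter_pipeline(ps, strategy="B")
        assert {t.outcome for t in traces} == {"removed_step1"}

    def test_empty_set_gives_empty_trace(self):
        assert run_filter_pipeline(PatientVariantSet(patient_id="E"), strategy="A") == []

    def test_outcomes_partition_input(self, rng):
        ps, _ = random_patient_table(rng, 300)
        traces = run_filter_pipeline(ps, strategy="B")
        universe = {k for k in ps.variant_keys() if ps.get(k, "P") or ps.get(k, "R")}
        assert len(traces) == len(universe)
        assert sum(Counter(t.outcome for t in traces).values()) == len(universe)

    @pytest.mark.parametrize("strategy", ["A", "B"])
    def test_matches_brute_force_oracle_on_random_tables(self, strategy):
        rng = np.random.default_rng(404)
        for _ in range(5):
            ps, rows = random_patient_table(rng, 500)
            traces = run_filter_pipeline(ps, strategy=strategy)
            got = {t.key: t.outcome for t in traces}
            assert got == oracle_outcomes(rows, strategy)

    def test_raising_monotone_thresholds_never_grows_selection(self, rng):
        ps, _ = random_patient_table(rng, 400)
        base = set(selected_keys(run_filter_pipeline(ps, CFG, "B")))
        stricter = [
            FilterConfig(normal_min_depth=30),
            FilterConfig(tumor_min_depth=40),
            FilterConfig(mrf_fold=3.5),
            FilterConfig(min_mq=30, min_qual=30),
        ]
        for cfg in stricter:
            assert set(selected_keys(run_filter_pipeline(ps, cfg, "B"))) <= base

    def test_trace_dataframe_carries_thresholds(self):
        ps = pset_with(n=obs(30, 0), p=obs(40, 4), r=obs(40, 10))
        df = traces_to_dataframe(run_filter_pipeline(ps, strategy="B"))
        assert df.loc[0, "outcome"] == "selected"
        assert df.loc[0, "mrf_fold"] == 2.0 and df.loc[0, "min_mq"] == 20.0
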