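import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orabench.genesets import GeneList, append_universe_set
from orabench.ora import (
    ContingencyTable,
    ORAConfig,
    apply_fdr_workaround,
    bh_adjust,
    build_contingency,
    config_for_mode,
    expected_test_count,
    fold_enrichment,
    frame_to_records,
    hypergeom_pvalue,
    records_to_frame,
    run_ora,
    significant_sets,
)

from conftest import bh_stepup_hand, fisher_upper_tail_exact, random_ora_instance


class TestContingencyTable:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ContingencyTable(k=4, n=3, K=5, N=20)
        with pytest.raises(ValueError):
            ContingencyTable(k=1, n=3, K=25, N=20)
        with pytest.raises(ValueError):
            ContingencyTable(k=-1, n=3, K=5, N=20)


class TestHypergeomPvalue:
    @pytest.mark.parametrize(
        "k,n,K,N,expected",
        [
            (0, 3, 5, 20, 1.0),                 # P(X >= 0) is 1
            (3, 3, 5, 20, 10 / 1140),           # enumeration: C(5,3)/C(20,3)
            (4, 4, 5, 10, 5 / 210),             # enumeration: C(5,4)C(5,0)/C(10,4)
        ],
    )
    def test_matches_enumeration(self, k, n, K, N, expected):
        t = ContingencyTable(k=k, n=n, K=K, N=N)
        assert hypergeom_pvalue(t) == pytest.approx(expected, abs=1e-14)
        assert hypergeom_pvalue(t) == pytest.approx(
            float(fisher_upper_tail_exact(k, n, K, N)), abs=1e-14
        )


class TestFoldEnrichment:
    def test_forced_arithmetic(self):
        assert fold_enrichment(ContingencyTable(3, 3, 5, 20)) == pytest.approx(4.0)

    def test_zero_overlap(self):
        assert fold_enrichment(ContingencyTable(0, 3, 5, 20)) == 0.0

    def test_saturated_identity(self):
        assert fold_enrichment(ContingencyTable(5, 5, 20, 20)) == pytest.approx(1.0)

    def test_undefined_reported_as_missing(self):
        assert math.isnan(fold_enrichment(ContingencyTable(0, 0, 5, 20)))
        assert math.isnan(fold_enrichment(ContingencyTable(0, 3, 0, 20)))


class TestBHAdjust:
    def test_hand_stepup_example(self):
        out = bh_adjust([0.01, 0.04, 0.03, 0.005])
        assert np.allclose(out, [0.02, 0.04, 0.04, 0.02])

    def test_single_p_is_itself(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_stay_equal(self):
        out = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [1.2], [-0.1], [float("nan")]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30))
    def test_matches_hand_stepup_and_dominates_raw(self, ps):
        out = bh_adjust(ps)
        assert np.allclose(out, bh_stepup_hand(ps), rtol=1e-12)
        assert (out >= np.asarray(ps) - 1e-15).all()
        order = np.argsort(ps)
        assert (np.diff(out[order]) >= -1e-15).all()


class TestBuildContingency:
    def test_retain_all_vs_annotated_only(self, toy_foreground, toy_background, toy_library):
        from orabench.genesets import annotated_genes

        members = toy_library["S1"].members
        t = build_contingency(toy_foreground, toy_background, members, "retain_all")
        assert (t.k, t.n, t.K, t.N) == (3, 3, 5, 20)
        ann = annotated_genes(toy_library)
        t2 = build_contingency(
            toy_foreground, toy_background, members, "annotated_only", annotated=ann
        )
        assert (t2.k, t2.n, t2.K, t2.N) == (3, 3, 5, 10)

    def test_foreground_outside_background_dropped(self, toy_background, toy_library, caplog):
        fg = GeneList.from_ids("foreground", ["g1", "g99"])
        with caplog.at_level(logging.WARNING, logger="orabench.ora"):
            t = build_contingency(fg, toy_background, toy_library["S1"].members)
        assert t.n == 1
        assert any("dropped 1 foreground" in r.message for r in caplog.records)

    def test_set_disjoint_from_background_gives_zero_K(self, toy_foreground, toy_background, toy_library):
        t = build_contingency(toy_foreground, toy_background, toy_library["S3"].members)
        assert t.K == 0


class TestRunOra:
    def test_correct_mode_toy(self, toy_foreground, toy_background, toy_library):
        records = run_ora(toy_foreground, toy_background, toy_library, config_for_mode("correct"))
        by_id = {r.set_id: r for r in records}
        assert set(by_id) == {"S1", "S2"}  # S3 has no background members
        assert by_id["S1"].p_value == pytest.approx(10 / 1140, abs=1e-12)
        assert by_id["S1"].fdr == pytest.approx(2 * 10 / 1140, abs=1e-12)
        assert by_id["S1"].overlap_members == ("g1", "g2", "g3")
        assert by_id["S2"].k == 0
        assert by_id["S2"].p_value == 1.0 and by_id["S2"].fdr == 1.0

    def test_background_problem_shrinks_universe(self, toy_foreground, toy_background, toy_library):
        records = run_ora(toy_foreground, toy_background, toy_library, config_for_mode("bug-bg"))
        by_id = {r.set_id: r for r in records}
        assert by_id["S1"].N == 10
        assert by_id["S1"].p_value == pytest.approx(10 / 120, abs=1e-12)

    def test_fdr_problem_drops_nonoverlapping_sets(self, toy_foreground, toy_background, toy_library):
        records = run_ora(toy_foreground, toy_background, toy_library, config_for_mode("bug-fdr"))
        assert [r.set_id for r in records] == ["S1"]
        assert records[0].fdr == pytest.approx(10 / 1140, abs=1e-12)  # BH over m=1

    def test_universe_set_never_reported(self, toy_foreground, toy_background, toy_library):
        lib = append_universe_set(toy_library, toy_background)
        records = run_ora(toy_foreground, toy_background, lib, config_for_mode("bug-bg"))
        assert all(r.set_id != "__UNIVERSE__" for r in records)

    def test_no_detected_sets_warns_and_returns_empty(self, toy_foreground, toy_background, caplog):
        from orabench.genesets import GeneSet, GeneSetLibrary

        lib = GeneSetLibrary([GeneSet("S3", "", ("g21", "g22"))])
        with caplog.at_level(logging.WARNING, logger="orabench.ora"):
            records = run_ora(toy_foreground, toy_background, lib,
                              ORAConfig(min_set_size=1))
        assert records == []

    def test_records_sorted_by_p_then_id(self, toy_foreground, toy_background, toy_library):
        records = run_ora(toy_foreground, toy_background, toy_library, config_for_mode("correct"))
        keys = [(r.p_value, r.set_id) for r in records]
        assert keys == sorted(keys)

    def test_fdr_never_below_p(self, toy_foreground, toy_background, toy_library):
        for mode in ("correct", "bug-bg", "bug-fdr", "bug-both"):
            for r in run_ora(toy_foreground, toy_background, toy_library, config_for_mode(mode)):
                assert r.fdr >= r.p_value - 1e-15

    def test_tsv_roundtrip(self, toy_foreground, toy_background, toy_library):
        records = run_ora(toy_foreground, toy_background, toy_library, config_for_mode("correct"))
        assert frame_to_records(records_to_frame(records)) == records


class TestApplyFdrWorkaround:
    def test_padding_with_ones(self, toy_foreground, toy_background, toy_library):
        records = run_ora(toy_foreground, toy_background, toy_library, config_for_mode("bug-fdr"))
        fixed = apply_fdr_workaround(records, expected_set_count=2)
        # BH over {p, 1}: adjusted = min(2p, 1)
        assert fixed[0].fdr == pytest.approx(2 * 10 / 1140, abs=1e-12)

    def test_hand_example_two_observed_four_expected(self, toy_foreground, toy_background, toy_library):
        records = run_ora(toy_foreground, toy_background, toy_library, config_for_mode("correct"))
        from dataclasses import replace

        synthetic = [replace(records[0], p_value=0.01), replace(records[1], p_value=0.02)]
        fixed = apply_fdr_workaround(synthetic, expected_set_count=4)
        assert [r.fdr for r in fixed] == pytest.approx([0.04, 0.04])

    def test_expected_equal_observed_is_identity(self, toy_foreground, toy_background, toy_library):
        records = run_ora(toy_foreground, toy_background, toy_library, config_for_mode("correct"))
        fixed = apply_fdr_workaround(records, expected_set_count=len(records))
        assert [r.fdr for r in fixed] == [r.fdr for r in records]

    def test_expected_below_observed_is_error(self, toy_foreground, toy_background, toy_library):
        records = run_ora(toy_foreground, toy_background, toy_library, config_for_mode("correct"))
        with pytest.raises(ValueError):
            apply_fdr_workaround(records, expected_set_count=1)

    def test_corrected_fdr_elementwise_at_least_original(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            fg, bg, lib = random_ora_instance(rng)
            cfg = config_for_mode("bug-fdr", min_set_size=1, detection_min=1)
            records = run_ora(fg, bg, lib, cfg)
            if not records:
                continue
            expected = expected_test_count(lib, bg, cfg)
            fixed = apply_fdr_workaround(records, expected)
            for before, after in zip(records, fixed):
                assert after.fdr >= before.fdr - 1e-15


class TestSignificantSets:
    def test_threshold(self, toy_foreground, toy_background, toy_library):
        records = run_ora(toy_foreground, toy_background, toy_library, config_for_mode("correct"))
        assert significant_sets(records, 0.05) == {"S1"}

    def test_alpha_one_selects_all(self, toy_foreground, toy_background, toy_library):
        records = run_ora(toy_foreground, toy_background, toy_library, config_for_mode("correct"))
        assert significant_sets(records, 1.0) == {"S1", "S2"}

    def test_empty_records(self):
        assert significant_sets([], 0.05) == set()


class TestWorkaroundEquivalences:
    """The two published fixes recover the correct analysis exactly."""

    def test_universe_append_equals_retain_all(self):
        rng = np.random.default_rng(1)
        cfg_bug = config_for_mode("bug-bg", min_set_size=1, detection_min=1)
        cfg_ok = config_for_mode("correct", min_set_size=1, detection_min=1)
        for _ in range(50):
            fg, bg, lib = random_ora_instance(rng)
            fixed = {
                r.set_id: r
                for r in run_ora(fg, bg, append_universe_set(lib, bg), cfg_bug)
            }
            correct = {r.set_id: r for r in run_ora(fg, bg, lib, cfg_ok)}
            assert set(fixed) == set(correct)
            for sid, r in correct.items():
                f = fixed[sid]
                assert (f.k, f.n, f.K, f.N) == (r.k, r.n, r.K, r.N)
                assert f.p_value == r.p_value
                assert f.fdr == r.fdr

    def test_p1_padding_equals_all_detected_fdr(self):
        rng = np.random.default_rng(2)
        cfg_bug = config_for_mode("bug-fdr", min_set_size=1, detection_min=1)
        cfg_ok = config_for_mode("correct", min_set_size=1, detection_min=1)
        for _ in range(50):
            fg, bg, lib = random_ora_instance(rng)
            bug = run_ora(fg, bg, lib, cfg_bug)
            if not bug:
                continue
            fixed = apply_fdr_workaround(bug, expected_test_count(lib, bg, cfg_bug))
            correct = {r.set_id: r for r in run_ora(fg, bg, lib, cfg_ok)}
            for r in fixed:
                assert r.fdr == correct[r.set_id].fdr


class TestBiasDirections:
    def test_background_problem_deflates_fold_enrichment_by_universe_ratio(self):
        """With a fully annotated foreground, FE_bug = FE_correct * N'/N <= FE_correct."""
        rng = np.random.default_rng(3)
        checked = 0
        cfg_bug = config_for_mode("bug-bg", min_set_size=1, detection_min=1)
        cfg_ok = config_for_mode("correct", min_set_size=1, detection_min=1)
        while checked < 25:
            fg, bg, lib = random_ora_instance(rng)
            from orabench.genesets import annotated_genes, restrict_to_background

            ann = annotated_genes(restrict_to_background(lib, bg))
            fg_ann = GeneList.from_ids("foreground", [g for g in fg if g in ann])
            if not len(fg_ann):
                continue
            bug = {r.set_id: r for r in run_ora(fg_ann, bg, lib, cfg_bug)}
            ok = {r.set_id: r for r in run_ora(fg_ann, bg, lib, cfg_ok)}
            for sid, r in ok.items():
                b = bug[sid]
                if math.isnan(r.fold_enrichment) or math.isnan(b.fold_enrichment):
                    continue
                assert b.fold_enrichment == pytest.approx(
                    r.fold_enrichment * b.N / r.N, rel=1e-12
                )
                assert b.fold_enrichment <= r.fold_enrichment + 1e-12
                checked += 1

    def test_fdr_problem_deflates_fdr_elementwise(self):
        rng = np.random.default_rng(4)
        cfg_bug = config_for_mode("bug-fdr", min_set_size=1, detection_min=1)
        cfg_ok = config_for_mode("correct", min_set_size=1, detection_min=1)
        for _ in range(50):
            fg, bg, lib = random_ora_instance(rng)
            bug = {r.set_id: r for r in run_ora(fg, bg, lib, cfg_bug)}
            ok = {r.set_id: r for r in run_ora(fg, bg, lib, cfg_ok)}
            for sid, r in bug.items():
                assert r.fdr <= ok[sid].fdr + 1e-15
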