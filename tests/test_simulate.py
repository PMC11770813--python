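"""Glucose-insulin kinetics simulator: fixed points, tracer assumptions,
preset orderings, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from deutg import (
    TestMode,
    hfd_params,
    insulin_excursion,
    lfd_params,
    make_cohort,
    simulate_test,
)
from deutg.simulate import SimParams


class TestKinetics:
    def test_undosed_animal_stays_at_fasting_fixed_point(self):
        """Zero glucose and insulin dose: EGP0 = k0*Gb balances uptake, so
        glucose sits at Gb for the whole test."""
        p = replace(lfd_params(), glucose_dose_g_per_kg=0.0, insulin_dose_u_per_kg=0.0)
        out = simulate_test(p, TestMode.ITT, 0, noise=False)
        assert np.allclose(out.true_labeled, 0.0, atol=1e-9)
        assert np.allclose(out.true_unlabeled, p.gb, rtol=1e-7)

    def test_gtt_insulin_stays_basal(self):
        """An IP glucose bolus does not provoke an insulin response."""
        out = simulate_test(lfd_params(), TestMode.GTT, 0, noise=False)
        assert np.allclose(out.true_insulin, lfd_params().insulin_basal)
        assert np.allclose(insulin_excursion(out.times, lfd_params(), TestMode.GTT), 0.0)

    def test_itt_insulin_bolus_rises_and_clears(self):
        p = lfd_params()
        t = np.linspace(0, 50, 200)
        exc = insulin_excursion(t, p, TestMode.ITT)
        assert exc[0] == 0.0
        assert exc.max() > 0.0
        assert exc[-1] < exc.max()

    def test_labeled_trajectory_independent_of_egp_parameters(self):
        """No recirculation: with insulin fixed (GTT mode), the labeled
        species never sees EGP0, sI or sG — EGP makes unlabeled glucose
        only and uptaken tracer never re-enters."""
        base = lfd_params()
        ref = simulate_test(base, TestMode.GTT, 0, noise=False).true_labeled
        for change in (
            {"egp0": 1.0},
            {"si": 10.0},
            {"sg": 0.0},
            {"egp0": 6.0, "si": 0.0, "sg": 0.01},
        ):
            out = simulate_test(replace(base, **change), TestMode.GTT, 0, noise=False)
            assert np.allclose(out.true_labeled, ref, rtol=1e-7)

    def test_true_enrichment_always_physical(self):
        for p in (lfd_params(), hfd_params()):
            for mode in TestMode:
                out = simulate_test(p, mode, 0, noise=False)
                e = out.true_enrichment
                assert np.all((e >= 0.0) & (e <= 1.0))

    def test_more_insulin_action_lowers_exogenous_aoc(self):
        """Exogenous ITT AOC decreases strictly along a kI grid."""
        aocs = []
        for ki in (0.0, 0.05, 0.10, 0.15, 0.20):
            out = simulate_test(replace(lfd_params(), ki=ki), TestMode.ITT, 0, noise=False)
            aocs.append(np.trapezoid(out.true_labeled, out.times))
        assert all(b < a for a, b in zip(aocs, aocs[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(gb=-1.0)
        with pytest.raises(ValueError):
            SimParams(k0=-0.1)


class TestPresets:
    def test_hfd_is_hyperglycemic_in_every_replicate(self):
        """Construction check: high-fat preset has higher fasting glucose."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            lfd = simulate_test(lfd_params(), TestMode.GTT, rng, noise=False)
            hfd = simulate_test(hfd_params(), TestMode.GTT, rng, noise=False)
            assert hfd.true_unlabeled[0] > lfd.true_unlabeled[0]

    def test_hfd_has_blunted_insulin_action(self):
        l, h = lfd_params(), hfd_params()
        assert h.ki < l.ki and h.si < l.si and h.gb > l.gb


class TestCohortGeneration:
    def test_same_seed_byte_identical_csvs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_cohort(seed=42, outdir=d1, n_per_group={"LFD": 3, "HFD": 3})
        make_cohort(seed=42, outdir=d2, n_per_group={"LFD": 3, "HFD": 3})
        for name in ("manifest", "glucometer", "ms_areas", "truth"):
            assert (d1 / f"{name}.csv").read_bytes() == (d2 / f"{name}.csv").read_bytes()

    def test_default_cohort_sizes_match_study(self):
        tables = make_cohort(seed=0)
        counts = tables["manifest"]["group"].value_counts()
        assert counts["LFD"] == 14 and counts["HFD"] == 15

    def test_nonpositive_group_size_rejected(self):
        with pytest.raises(ValueError, match="at least one animal"):
            make_cohort(n_per_group={"LFD": 0, "HFD": 3}, seed=0)

    def test_truth_and_measurement_stored_separately(self):
        tables = make_cohort(seed=1, n_per_group={"LFD": 2, "HFD": 2})
        truth = tables["truth"]
        gluc = tables["glucometer"]
        merged = truth.merge(gluc, on=["animal_id", "test_mode", "time_min"])
        # measurements are noisy versions of the truth, not copies
        assert not np.allclose(merged["true_total"], merged["glucose_mgdl"])
        assert np.all(tables["ms_areas"].filter(like="area_m") >= 0)
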