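"""Factorial diet x insulin statistics and per-timepoint comparisons."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from deutg import factorial_aoc, lfd_params, hfd_params, timepoint_compare
from deutg.stats import compact_letter_display, stats_report
from deutg.studies import simulate_analyzed_cohort


@pytest.fixture(scope="module")
def default_cohort():
    rng = np.random.default_rng(2024)
    return simulate_analyzed_cohort(
        {"LFD": lfd_params(), "HFD": hfd_params()}, {"LFD": 14, "HFD": 15}, rng
    )


class TestFactorial:
    def test_detects_diet_and_insulin_effects(self, default_cohort):
        """At the study's sample sizes the default presets separate
        clearly on the endogenous AOC."""
        aocs, curves, manifest, _ = default_cohort
        res = factorial_aoc(aocs, manifest, outcome="aoc_endogenous")
        assert res.p_diet < 0.05
        assert res.p_insulin < 0.05
        assert set(res.cell_means["letters"]) and len(res.cell_means) == 4
        assert len(res.pairwise) == 6

    def test_cell_means_match_data(self, default_cohort):
        aocs, _, manifest, _ = default_cohort
        res = factorial_aoc(aocs, manifest, outcome="aoc_total")
        df = aocs.merge(manifest[["animal_id", "group"]], on="animal_id")
        for r in res.cell_means.itertuples():
            cell = df[(df["group"] == r.group) & (df["test_mode"] == r.test_mode)]
            assert r.mean == pytest.approx(cell["aoc_total"].mean())
            assert r.n == len(cell)

    def test_single_group_rejected(self, default_cohort):
        aocs, _, manifest, _ = default_cohort
        lfd_only = manifest[manifest["group"] == "LFD"]
        with pytest.raises(ValueError, match="factorial design needs"):
            factorial_aoc(aocs[aocs["animal_id"].str.startswith("LFD")], lfd_only)

    def test_empty_cell_named_in_error(self, default_cohort):
        aocs, _, manifest, _ = default_cohort
        broken = aocs[~((aocs["test_mode"] == "ITT") & aocs["animal_id"].str.startswith("HFD"))]
        with pytest.raises(ValueError, match="HFD.*ITT"):
            factorial_aoc(broken, manifest)

    def test_animal_missing_from_manifest_rejected(self, default_cohort):
        aocs, _, manifest, _ = default_cohort
        with pytest.raises(ValueError, match="missing from manifest"):
            factorial_aoc(aocs, manifest[manifest["animal_id"] != "LFD01"])


class TestCompactLetters:
    def test_cld_from_constructed_pairs(self):
        """A > B = C > D: A and D get sole letters, B and C share one."""
        cells = ["A", "B", "C", "D"]
        means = {"A": 10.0, "B": 5.0, "C": 4.8, "D": 1.0}
        sig = {("A", "B"), ("A", "C"), ("A", "D"), ("B", "D"), ("C", "D")}
        letters = compact_letter_display(cells, sig, means)
        assert letters["B"] == letters["C"]
        assert letters["A"] != letters["B"]
        assert letters["D"] != letters["B"]
        assert len(letters["A"]) == 1

    def test_all_equivalent_share_one_letter(self):
        letters = compact_letter_display(["A", "B"], set(), {"A": 1.0, "B": 2.0})
        assert letters["A"] == letters["B"]


class TestTimepoints:
    def test_early_suppression_difference_flags_early_timepoints(self):
        """Two groups differing only in insulin absorption speed: the
        fast group suppresses EGP sooner, so flags concentrate at the
        10- and 15-min timepoints."""
        fast = replace(lfd_params(), ka_ins=0.45)
        slow = replace(lfd_params(), ka_ins=0.07)
        rng = np.random.default_rng(7)
        _, curves, manifest, _ = simulate_analyzed_cohort(
            {"fast": fast, "slow": slow}, {"fast": 12, "slow": 12}, rng
        )
        tp = timepoint_compare(curves, manifest, value_col="d_endogenous",
                               test_mode="ITT")
        flagged = set(tp.loc[tp["significant"], "time_min"])
        assert {10.0, 15.0} <= flagged
        assert 50.0 not in flagged

    def test_tiny_groups_rejected(self, default_cohort):
        _, curves, manifest, _ = default_cohort
        sub = curves[curves["animal_id"].isin(["LFD01", "HFD01", "HFD02"])]
        with pytest.raises(ValueError, match="n >= 2"):
            timepoint_compare(sub, manifest)

    def test_more_than_two_groups_rejected(self, default_cohort):
        _, curves, manifest, _ = default_cohort
        manifest3 = manifest.copy()
        manifest3.loc[manifest3["animal_id"] == "LFD01", "group"] = "other"
        with pytest.raises(ValueError, match="exactly 2 groups"):
            timepoint_compare(curves, manifest3)


def test_stats_report_shape(default_cohort):
    aocs, curves, manifest, _ = default_cohort
    tidy, text = stats_report(aocs, curves, manifest)
    assert set(tidy["outcome"]) == {"aoc_total", "aoc_exogenous", "aoc_endogenous"}
    assert ((tidy[["p_diet", "p_insulin", "p_interaction"]] >= 0).all().all())
    assert "ME diet" in text and "Per-timepoint" in text
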