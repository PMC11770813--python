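"""Replicate-level simulation studies of the pipeline's statistics.

These functions run many synthetic cohorts through the *measured-data*
analysis path (MS areas -> NNLS correction -> partition -> AOC -> mixed
ANOVA) and summarize operating characteristics: type-I error under a
null where both groups share one generator, power under the default
diet presets, and reproduction of the assay's qualitative patterns
(diet-induced hyperglycemia, augmented EGP under high-fat feeding, and
the ITT total curve tracking its endogenous component).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .aoc import summarize_animal
from .correction import (
    CorrectionOptions,
    EnrichmentPoint,
    EnrichmentSeries,
    IsotopologueSpectrum,
    build_correction_matrix,
    correct_spectrum,
    enrichment_from_fractions,
)
from .isotopes import IonFormula
from .partition import GlucoseSeries, PartitionedCurves, TestMode, baseline_subtract, partition_series
from .simulate import CohortSpec, SimOutput, SimParams, _jitter_params, hfd_params, lfd_params, simulate_test
from .stats import factorial_aoc, timepoint_compare

__all__ = [
    "recover_partition",
    "simulate_analyzed_cohort",
    "type_one_error_study",
    "power_study",
    "pattern_study",
    "monotonicity_curves",
]


def recover_partition(
    out: SimOutput, opts: CorrectionOptions | None = None,
    matrix: np.ndarray | None = None,
) -> PartitionedCurves:
    """Run one simulated animal's *measurements* through the analysis path.

    Corrects the simulated MS spectra by NNLS, extracts enrichment, and
    partitions the glucometer totals — exactly what the pipeline does
    with real data, without the CSV round trip.
    """
    opts = opts if opts is not None else CorrectionOptions()
    if matrix is None:
        matrix = build_correction_matrix(IonFormula(), opts)
    points = []
    for k, t in enumerate(out.times):
        spec = IsotopologueSpectrum(
            sample_id=f"{out.animal_id}_t{int(t)}", time_min=t, areas=out.meas_areas[k]
        )
        fractions, resid, flag = correct_spectrum(spec, matrix, opts.residual_threshold)
        p = enrichment_from_fractions(fractions, t, opts)
        p.residual_norm, p.qc_flag = resid, flag
        points.append(p)
    series = EnrichmentSeries(animal_id=out.animal_id, points=points)
    gluc = GlucoseSeries(
        animal_id=out.animal_id,
        test_mode=out.mode,
        times=out.times,
        total_glucose=out.meas_glucose,
        insulin=out.meas_insulin,
    )
    return partition_series(gluc, series)


def simulate_analyzed_cohort(
    presets: dict[str, SimParams],
    n_per_group: dict[str, int],
    rng: np.random.Generator,
    spec: CohortSpec | None = None,
    noise: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a cohort and analyze every animal's measured data.

    Returns (aoc table, tidy partitioned-curves table, manifest, raw
    partitions keyed by (animal, mode)) with the same schemas the CSV
    pipeline produces.
    """
    spec = spec if spec is not None else CohortSpec()
    opts = CorrectionOptions()
    matrix = build_correction_matrix(IonFormula(), opts)
    aoc_rows, curve_rows, man_rows = [], [], []
    parts: dict[tuple[str, str], PartitionedCurves] = {}
    for group, base in presets.items():
        for i in range(n_per_group[group]):
            animal = f"{group}{i + 1:02d}"
            lean = max(10.0, rng.normal(spec.lean_mass_mean_g, spec.lean_mass_sd_g))
            p = _jitter_params(base, rng, spec, lean)
            man_rows.append(
                {"animal_id": animal, "group": group,
                 "body_mass_g": lean + 10.0, "lean_mass_g": lean}
            )
            for mode in (TestMode.GTT, TestMode.ITT):
                out = simulate_test(p, mode, rng, animal_id=animal, noise=noise)
                part = recover_partition(out, opts, matrix)
                parts[(animal, mode.value)] = part
                s = summarize_animal(part)
                aoc_rows.append(
                    {"animal_id": animal, "test_mode": mode.value,
                     "aoc_total": s.aoc_total, "aoc_exogenous": s.aoc_exogenous,
                     "aoc_endogenous": s.aoc_endogenous}
                )
                d_total = baseline_subtract(part.total)
                d_endo = baseline_subtract(part.endogenous)
                for k, t in enumerate(part.times):
                    curve_rows.append(
                        {"animal_id": animal, "test_mode": mode.value, "time_min": t,
                         "total": part.total[k], "exogenous": part.exogenous[k],
                         "endogenous": part.endogenous[k], "d_total": d_total[k],
                         "d_exogenous": part.exogenous[k], "d_endogenous": d_endo[k]}
                    )
    return (
        pd.DataFrame(aoc_rows),
        pd.DataFrame(curve_rows),
        pd.DataFrame(man_rows),
        parts,
    )


def type_one_error_study(
    n_per_cell: int = 10,
    n_reps: int = 200,
    seed: int = 0,
    outcome: str = "aoc_total",
    alpha: float = 0.05,
    null_insulin: bool = True,
) -> dict[str, float]:
    """Empirical rejection rates when both 'diet' groups share one generator.

    Returns the fraction of replicates in which the diet main effect,
    the insulin (test-mode) main effect, and their interaction reject at
    ``alpha``.  The two groups always share one parameter set, so the
    diet effect and interaction are truly absent.  With ``null_insulin``
    (default) the insulin dose is set to zero as well, making the ITT
    kinetically identical to the GTT — the test-mode factor is then also
    null and all three rates estimate type-I error.  With
    ``null_insulin=False`` the insulin main effect is real and its rate
    is power, not size.
    """
    rng = np.random.default_rng(seed)
    base = lfd_params()
    if null_insulin:
        base = replace(base, insulin_dose_u_per_kg=0.0)
    presets = {"A": base, "B": base}
    n = {"A": n_per_cell, "B": n_per_cell}
    rej = {"diet": 0, "insulin": 0, "interaction": 0}
    for _ in range(n_reps):
        aocs, _, manifest, _ = simulate_analyzed_cohort(presets, n, rng)
        res = factorial_aoc(aocs, manifest, outcome=outcome, alpha=alpha)
        rej["diet"] += res.p_diet < alpha
        rej["insulin"] += res.p_insulin < alpha
        rej["interaction"] += res.p_interaction < alpha
    return {k: v / n_reps for k, v in rej.items()}


def null_timepoint_flag_rate(
    n_per_group: int = 10, n_reps: int = 100, seed: int = 0, alpha: float = 0.05
) -> float:
    """Fraction of per-timepoint comparisons flagged under the null."""
    rng = np.random.default_rng(seed)
    base = lfd_params()
    presets = {"A": base, "B": base}
    n = {"A": n_per_group, "B": n_per_group}
    flagged = total = 0
    for _ in range(n_reps):
        _, curves, manifest, _ = simulate_analyzed_cohort(presets, n, rng)
        tp = timepoint_compare(curves, manifest, value_col="d_endogenous",
                               test_mode="ITT", alpha=alpha)
        flagged += int(tp["significant"].sum())
        total += len(tp)
    return flagged / total


def power_study(
    n_reps: int = 200,
    seed: int = 0,
    n_per_group: dict[str, int] | None = None,
    outcome: str = "aoc_endogenous",
    alpha: float = 0.05,
) -> float:
    """Power for the diet main effect under the default LFD/HFD presets.

    By default mirrors the study cohort sizes (LFD n=14, HFD n=15) and
    asks how often the diet main effect on the endogenous AOC rejects.
    """
    rng = np.random.default_rng(seed)
    presets = {"LFD": lfd_params(), "HFD": hfd_params()}
    n = n_per_group if n_per_group is not None else {"LFD": 14, "HFD": 15}
    hits = 0
    for _ in range(n_reps):
        aocs, _, manifest, _ = simulate_analyzed_cohort(presets, n, rng)
        res = factorial_aoc(aocs, manifest, outcome=outcome, alpha=alpha)
        hits += res.p_diet < alpha
    return hits / n_reps


def pattern_study(
    n_reps: int = 200, seed: int = 0, n_per_group: dict[str, int] | None = None
) -> dict[str, float]:
    """Reproduction rates of the assay's qualitative headline patterns.

    Per replicate cohort (default LFD n=14 / HFD n=15):

    a. mean fasting (t=0) glucometer glucose is higher in the HFD-like
       group (diet-induced hyperglycemia);
    b. mean GTT endogenous AOC is higher (less negative) in the HFD-like
       group (augmented EGP under high-fat feeding);
    c. in the ITT, the group-mean baseline-subtracted total curve
       correlates more strongly with the endogenous than the exogenous
       component, in *both* groups (a conventional ITT primarily reads
       out endogenous glucose metabolism).

    Returns the fraction of replicates showing each pattern.
    """
    rng = np.random.default_rng(seed)
    presets = {"LFD": lfd_params(), "HFD": hfd_params()}
    n = n_per_group if n_per_group is not None else {"LFD": 14, "HFD": 15}
    ok = {"fasting_hfd_gt_lfd": 0, "gtt_endo_aoc_hfd_gt_lfd": 0,
          "itt_total_tracks_endogenous": 0}
    for _ in range(n_reps):
        aocs, curves, manifest, parts = simulate_analyzed_cohort(presets, n, rng)
        merged = curves.merge(manifest[["animal_id", "group"]], on="animal_id")
        fasting = (
            merged[(merged["time_min"] == 0) & (merged["test_mode"] == "GTT")]
            .groupby("group")["total"].mean()
        )
        ok["fasting_hfd_gt_lfd"] += fasting["HFD"] > fasting["LFD"]
        gtt = aocs[aocs["test_mode"] == "GTT"].merge(
            manifest[["animal_id", "group"]], on="animal_id"
        )
        endo = gtt.groupby("group")["aoc_endogenous"].mean()
        ok["gtt_endo_aoc_hfd_gt_lfd"] += endo["HFD"] > endo["LFD"]
        itt = merged[merged["test_mode"] == "ITT"]
        tracks = True
        for _, sub in itt.groupby("group"):
            mean = sub.groupby("time_min")[["d_total", "d_endogenous", "d_exogenous"]].mean()
            c_endo = np.corrcoef(mean["d_total"], mean["d_endogenous"])[0, 1]
            c_exo = np.corrcoef(mean["d_total"], mean["d_exogenous"])[0, 1]
            tracks &= c_endo > c_exo
        ok["itt_total_tracks_endogenous"] += tracks
    return {k: v / n_reps for k, v in ok.items()}


def monotonicity_curves(
    ki_grid: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15, 0.20),
    si_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 3.5, 5.0),
) -> dict[str, list[float]]:
    """Exogenous/endogenous ITT AOCs along insulin-action parameter grids.

    Noiseless kinetics: raising insulin-stimulated uptake (kI) must
    strictly lower the exogenous AOC; raising EGP suppressibility (sI)
    must strictly lower the endogenous AOC.
    """
    base = lfd_params()
    exo_aocs, endo_aocs = [], []
    for ki in ki_grid:
        out = simulate_test(replace(base, ki=ki), TestMode.ITT, 0, noise=False)
        s = summarize_animal(recover_partition(out))
        exo_aocs.append(s.aoc_exogenous)
    for si in si_grid:
        out = simulate_test(replace(base, si=si), TestMode.ITT, 0, noise=False)
        s = summarize_animal(recover_partition(out))
        endo_aocs.append(s.aoc_endogenous)
    return {"ki_grid": list(ki_grid), "exo_aoc": exo_aocs,
            "si_grid": list(si_grid), "endo_aoc": endo_aocs}
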