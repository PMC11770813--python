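"""Synthetic DeutG IP GTT/ITT cohorts: dual-species glucose kinetics plus
the full measurement model.

The simulator tracks labeled ([6,6-2H2]) and unlabeled glucose as two
one-compartment pools sharing a single fractional uptake rate:

    dG_L/dt = ka * (dose/Vd) * exp(-ka*t) - (k0 + kI*I(t)) * G_L
    dG_U/dt = EGP0 * exp(-sI*I(t) - sG*(G_L+G_U-Gb)) - (k0 + kI*I(t)) * G_U

with G_L(0) = 0, G_U(0) = Gb.  I(t) is the insulin excursion above basal:
identically 0 in GTT mode (an IP glucose bolus does not provoke an
insulin spike in the mouse), and a first-order absorbed/cleared IP bolus
in ITT mode (insulin and tracer co-injected at t=0).  Endogenous glucose
production (EGP) emits *unlabeled* glucose only, and labeled glucose
never re-enters circulation after uptake — the tracer's defining
assumptions.  EGP suppression is exponential in the insulin excursion and
in the glucose excess over fasting, which keeps EGP positive without
clamping.  At construction EGP0 = k0*Gb, so an undosed animal sits at the
fasting fixed point G = Gb.

The measurement layer reproduces what the bench produces: glucometer
totals with multiplicative normal noise, LC-MS/MS isotopologue areas
obtained by forward-convolving the true label fractions with the
natural-abundance/purity matrix and applying multiplicative area noise,
and (GTT only) noisy plasma insulin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .correction import CorrectionOptions, build_correction_matrix
from .dosing import GLUCOSE_DOSE_G_PER_KG_LEAN, INSULIN_DOSE_U_PER_KG_LEAN
from .isotopes import IonFormula
from .partition import DEFAULT_SCHEDULE, TestMode

__all__ = ["SimParams", "SimOutput", "lfd_params", "hfd_params",
           "insulin_excursion", "simulate_test", "make_cohort", "CohortSpec"]


@dataclass(frozen=True)
class SimParams:
    """Kinetic, dosing and noise parameters of one simulated animal.

    Rates are per minute; concentrations mg/dL; insulin in units of the
    administered dose per kg lean mass (so the ITT bolus has amplitude
    0.75 by protocol).  ``egp0`` defaults to ``k0 * gb`` so the fasted,
    uninjected animal is at steady state.
    """

    ka_depot: float = 0.12      # /min, IP glucose absorption
    vd: float = 2.5             # dL per kg lean mass, distribution volume
    k0: float = 0.025           # /min, basal (insulin-independent) uptake
    ki: float = 0.15            # /min per insulin-unit, insulin-stimulated uptake
    egp0: float | None = None   # mg/dL/min, basal EGP; None -> k0*gb
    si: float = 3.5             # per insulin-unit, EGP suppression by insulin
    sg: float = 0.004           # per mg/dL, EGP suppression by glucose excess
    gb: float = 150.0           # mg/dL, fasting blood glucose
    ka_ins: float = 0.20        # /min, IP insulin absorption
    ke_ins: float = 0.035       # /min, insulin clearance
    insulin_basal: float = 0.4  # ug/L, reported basal plasma insulin
    glucose_dose_g_per_kg: float = GLUCOSE_DOSE_G_PER_KG_LEAN
    insulin_dose_u_per_kg: float = INSULIN_DOSE_U_PER_KG_LEAN
    lean_mass_g: float = 20.0
    cv_glucometer: float = 0.05
    cv_ms: float = 0.05
    cv_insulin: float = 0.10
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE

    def __post_init__(self) -> None:
        for name in ("ka_depot", "vd", "k0", "ki", "si", "sg", "ka_ins", "ke_ins"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gb <= 0:
            raise ValueError("fasting glucose gb must be positive")
        if self.egp0 is not None and self.egp0 < 0:
            raise ValueError("egp0 must be non-negative")

    @property
    def egp_basal(self) -> float:
        return self.k0 * self.gb if self.egp0 is None else self.egp0


@dataclass
class SimOutput:
    """Ground truth and simulated measurements for one animal/test."""

    animal_id: str
    mode: TestMode
    times: np.ndarray
    true_labeled: np.ndarray      # mg/dL
    true_unlabeled: np.ndarray    # mg/dL
    true_insulin: np.ndarray      # ug/L (basal + excursion, reporting scale)
    meas_glucose: np.ndarray      # mg/dL, glucometer
    meas_areas: np.ndarray        # (n_times, K+1) MS peak areas
    meas_insulin: np.ndarray | None
    params: SimParams

    @property
    def true_enrichment(self) -> np.ndarray:
        total = self.true_labeled + self.true_unlabeled
        return self.true_labeled / total


def lfd_params(**overrides) -> SimParams:
    """Low-fat-diet-like preset: normoglycemic, insulin sensitive."""
    return replace(SimParams(), **overrides)


def hfd_params(**overrides) -> SimParams:
    """High-fat-diet-like preset after ~5 weeks of feeding.

    Hyperglycemic (higher Gb, hence higher basal EGP), impaired glucose
    handling (lower k0), blunted insulin-stimulated uptake (lower kI) and
    slower/weaker EGP suppression (lower sI, sG).
    """
    base = SimParams(gb=185.0, k0=0.016, ki=0.07, si=1.6, sg=0.002)
    return replace(base, **overrides)


PRESETS = {"LFD": lfd_params, "HFD": hfd_params}


def insulin_excursion(t: np.ndarray | float, p: SimParams, mode: TestMode) -> np.ndarray:
    """Insulin above basal, in dose units (U/kg lean), at time t.

    GTT: identically zero (no secretion response to an IP glucose bolus).
    ITT: first-order IP absorption (ka_ins) and clearance (ke_ins) of the
    co-injected bolus, the classic Bateman profile.
    """
    t = np.asarray(t, dtype=float)
    if TestMode(mode) is TestMode.GTT:
        return np.zeros_like(t)
    ka, ke, A = p.ka_ins, p.ke_ins, p.insulin_dose_u_per_kg
    if abs(ka - ke) < 1e-12:
        return A * ka * t * np.exp(-ka * t)
    return A * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))


def _integrate(p: SimParams, mode: TestMode) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    times = np.asarray(p.schedule, dtype=float)
    dose_conc = p.glucose_dose_g_per_kg * 1000.0 / p.vd  # mg/dL if absorbed at once
    egp0 = p.egp_basal

    def rhs(t, y):
        gl, gu = y
        ins = float(insulin_excursion(t, p, mode))
        uptake = p.k0 + p.ki * ins
        inflow_l = p.ka_depot * dose_conc * np.exp(-p.ka_depot * t)
        egp = egp0 * np.exp(-p.si * ins - p.sg * (gl + gu - p.gb))
        return [inflow_l - uptake * gl, egp - uptake * gu]

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        [0.0, p.gb],
        method="RK45",
        t_eval=times,
        rtol=1e-8,
        atol=1e-8,
    )
    if not sol.success:
        raise RuntimeError(
            f"glucose kinetics integration failed ({sol.message}); params: {p!r}"
        )
    return times, sol.y[0], sol.y[1]


def simulate_test(
    p: SimParams,
    mode: TestMode,
    seed: int | np.random.Generator,
    animal_id: str = "sim",
    noise: bool = True,
    correction_opts: CorrectionOptions | None = None,
) -> SimOutput:
    """Simulate one animal through one test (GTT or ITT).

    ``noise=False`` turns off every measurement error source while
    keeping the same kinetics, for noiseless round-trip checks.
    """
    mode = TestMode(mode)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    opts = correction_opts if correction_opts is not None else CorrectionOptions()
    times, gl, gu = _integrate(p, mode)
    total = gl + gu
    ins_true = p.insulin_basal * (1.0 + insulin_excursion(times, p, mode))

    matrix = build_correction_matrix(IonFormula(), opts)
    enr = gl / total
    # species fractions by label count: tracer molecules carry the full
    # complement of label positions; purity is handled inside the matrix
    frac = np.zeros((times.size, opts.max_shift + 1))
    frac[:, 0] = 1.0 - enr
    frac[:, opts.n_label_positions] = enr
    scale = 1e6 * total[:, None] / p.gb
    areas = scale * (matrix @ frac.T).T
    if noise:
        areas = areas * (1.0 + p.cv_ms * rng.standard_normal(areas.shape))
        areas = np.clip(areas, 0.0, None)
        glucometer = total * (1.0 + p.cv_glucometer * rng.standard_normal(times.size))
        glucometer = np.clip(glucometer, 1.0, None)
        ins_meas = ins_true * (1.0 + p.cv_insulin * rng.standard_normal(times.size))
        ins_meas = np.clip(ins_meas, 0.0, None)
    else:
        glucometer = total.copy()
        ins_meas = ins_true.copy()
    return SimOutput(
        animal_id=animal_id,
        mode=mode,
        times=times,
        true_labeled=gl,
        true_unlabeled=gu,
        true_insulin=ins_true,
        meas_glucose=glucometer,
        meas_areas=areas,
        meas_insulin=ins_meas if mode is TestMode.GTT else None,
        params=p,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Between-animal variability applied on top of a group preset.

    Rate parameters (k0, kI, sI, sG, ka_depot) get independent lognormal
    multipliers with coefficient of variation ``cv_rates``; fasting
    glucose gets ``cv_gb``.  Lean and body mass are normal with the given
    means/SDs (HFD animals are heavier at similar lean mass).
    """

    cv_rates: float = 0.15
    cv_gb: float = 0.05
    lean_mass_mean_g: float = 20.0
    lean_mass_sd_g: float = 1.5
    body_mass_mean_g: dict = field(
        default_factory=lambda: {"LFD": 27.0, "HFD": 36.0}
    )
    body_mass_sd_g: float = 2.0


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _jitter_params(base: SimParams, rng: np.random.Generator, spec: CohortSpec,
                   lean_mass_g: float) -> SimParams:
    return replace(
        base,
        k0=base.k0 * float(_lognormal_factor(rng, spec.cv_rates)),
        ki=base.ki * float(_lognormal_factor(rng, spec.cv_rates)),
        si=base.si * float(_lognormal_factor(rng, spec.cv_rates)),
        sg=base.sg * float(_lognormal_factor(rng, spec.cv_rates)),
        ka_depot=base.ka_depot * float(_lognormal_factor(rng, spec.cv_rates)),
        gb=base.gb * float(_lognormal_factor(rng, spec.cv_gb)),
        lean_mass_g=lean_mass_g,
    )


# exact binary round-trip so re-reading CSVs reproduces values bit-for-bit
FLOAT_FMT = "%.17g"


def make_cohort(
    presets: dict[str, SimParams] | None = None,
    n_per_group: dict[str, int] | tuple[int, ...] | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    noise: bool = True,
    spec: CohortSpec | None = None,
    modes: tuple[TestMode, ...] = (TestMode.GTT, TestMode.ITT),
) -> dict[str, pd.DataFrame]:
    """Simulate a cohort and (optionally) write the pipeline-input CSVs.

    Defaults reproduce the study conditions: LFD n=14 vs HFD n=15, both
    tests per animal on the 0/10/15/30/40/50-min schedule.  Returns the
    tables ``manifest``, ``glucometer``, ``ms_areas`` and ``truth``
    (per-timepoint true concentrations and enrichment, for recovery
    tests); with ``outdir`` set, each is also written as CSV with a fixed
    float format so identical seeds give byte-identical files.
    """
    if presets is None:
        presets = {"LFD": lfd_params(), "HFD": hfd_params()}
    if n_per_group is None:
        n_per_group = {"LFD": 14, "HFD": 15}
    if not isinstance(n_per_group, dict):
        n_per_group = dict(zip(presets.keys(), n_per_group))
    spec = spec if spec is not None else CohortSpec()
    for g, n in n_per_group.items():
        if n < 1:
            raise ValueError(f"group {g!r}: need at least one animal")
    rng = np.random.default_rng(seed)

    manifest_rows, gluc_rows, ms_rows, truth_rows = [], [], [], []
    for group, base in presets.items():
        n = n_per_group[group]
        for i in range(n):
            animal = f"{group}{i + 1:02d}"
            lean = max(10.0, rng.normal(spec.lean_mass_mean_g, spec.lean_mass_sd_g))
            body = max(
                lean + 2.0,
                rng.normal(spec.body_mass_mean_g.get(group, 30.0), spec.body_mass_sd_g),
            )
            p = _jitter_params(base, rng, spec, lean)
            manifest_rows.append(
                {
                    "animal_id": animal,
                    "group": group,
                    "body_mass_g": body,
                    "lean_mass_g": lean,
                }
            )
            for mode in modes:
                out = simulate_test(p, mode, rng, animal_id=animal, noise=noise)
                for k, t in enumerate(out.times):
                    gluc_rows.append(
                        {
                            "animal_id": animal,
                            "test_mode": mode.value,
                            "time_min": t,
                            "glucose_mgdl": out.meas_glucose[k],
                            "insulin_ugl": (
                                out.meas_insulin[k] if out.meas_insulin is not None else ""
                            ),
                        }
                    )
                    row = {
                        "sample_id": f"{animal}_{mode.value}_t{int(t)}",
                        "animal_id": animal,
                        "test_mode": mode.value,
                        "time_min": t,
                    }
                    for m in range(out.meas_areas.shape[1]):
                        row[f"area_m{m}"] = out.meas_areas[k, m]
                    ms_rows.append(row)
                    truth_rows.append(
                        {
                            "animal_id": animal,
                            "test_mode": mode.value,
                            "time_min": t,
                            "true_labeled": out.true_labeled[k],
                            "true_unlabeled": out.true_unlabeled[k],
                            "true_total": out.true_labeled[k] + out.true_unlabeled[k],
                            "true_enrichment": out.true_enrichment[k],
                            "true_insulin": out.true_insulin[k],
                        }
                    )
    tables = {
        "manifest": pd.DataFrame(manifest_rows),
        "glucometer": pd.DataFrame(gluc_rows),
        "ms_areas": pd.DataFrame(ms_rows),
        "truth": pd.DataFrame(truth_rows),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False, float_format=FLOAT_FMT)
    return tables
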