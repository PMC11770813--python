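"""Partition total blood glucose into exogenous (tracer) and endogenous parts.

Because intraperitoneally administered [6,6-2H2]glucose does not
significantly recirculate after tissue uptake, the labeled share of
circulating glucose is entirely exogenous (the bolus) and the unlabeled
share entirely endogenous (EGP plus the fasting pool).  Given the
glucometer total and the molar tracer enrichment at each timepoint,

    exogenous(t)  = total(t) * enrichment(t)
    endogenous(t) = total(t) * (1 - enrichment(t))

The glucometer is assumed to respond identically to labeled and
unlabeled glucose (2H2 substitution does not measurably alter
glucose-oxidase chemistry).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .correction import EnrichmentSeries

__all__ = ["TestMode", "GlucoseSeries", "PartitionedCurves", "partition_series",
           "baseline_subtract", "partition_table"]


class TestMode(str, Enum):
    __test__ = False  # not a pytest class, despite the name
    GTT = "GTT"
    ITT = "ITT"


#: The sampling schedule of the 50-min protocol, minutes post-injection.
DEFAULT_SCHEDULE = (0.0, 10.0, 15.0, 30.0, 40.0, 50.0)


@dataclass
class GlucoseSeries:
    """Glucometer trajectory for one animal and one test."""

    animal_id: str
    test_mode: TestMode
    times: np.ndarray  # minutes, strictly increasing, starts at 0
    total_glucose: np.ndarray  # mg/dL
    insulin: np.ndarray | None = None  # ug/L, optional (GTT only in practice)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.total_glucose = np.asarray(self.total_glucose, dtype=float)
        if self.times.size < 2:
            raise ValueError("need at least two timepoints")
        if self.times[0] != 0:
            raise ValueError("first timepoint must be 0 (pre-injection baseline)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size != self.total_glucose.size:
            raise ValueError("times and glucose lengths differ")
        if np.any(self.total_glucose <= 0):
            raise ValueError("total glucose must be positive everywhere")
        if self.insulin is not None:
            self.insulin = np.asarray(self.insulin, dtype=float)
            if self.insulin.size != self.times.size:
                raise ValueError("insulin and times lengths differ")


@dataclass
class PartitionedCurves:
    """Total/exogenous/endogenous glucose trajectories for one animal/test."""

    animal_id: str
    test_mode: TestMode
    times: np.ndarray
    total: np.ndarray
    exogenous: np.ndarray
    endogenous: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "total", "exogenous", "endogenous"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.allclose(self.exogenous + self.endogenous, self.total, rtol=1e-9, atol=0):
            raise ValueError("exogenous + endogenous must equal total")
        if np.any(self.exogenous < 0) or np.any(self.endogenous < 0):
            raise ValueError("partitioned concentrations must be non-negative")


def partition_series(g: GlucoseSeries, e: EnrichmentSeries) -> PartitionedCurves:
    """Split a glucometer trajectory using a matched enrichment trajectory.

    The MS and glucometer samples come from the same tail bleed, so the
    two grids must agree exactly; a mismatch indicates a data error and
    raises rather than interpolating.
    """
    et = e.times
    if et.size != g.times.size or not np.array_equal(et, g.times):
        raise ValueError(
            f"animal {g.animal_id}: enrichment grid {et.tolist()} does not match "
            f"glucometer grid {g.times.tolist()} (no interpolation performed)"
        )
    enr = e.enrichment
    if np.any((enr < 0) | (enr > 1)):
        raise ValueError("enrichment must lie in [0, 1]; clip upstream")
    exo = g.total_glucose * enr
    endo = g.total_glucose * (1.0 - enr)
    return PartitionedCurves(
        animal_id=g.animal_id,
        test_mode=g.test_mode,
        times=g.times.copy(),
        total=g.total_glucose.copy(),
        exogenous=exo,
        endogenous=endo,
    )


def baseline_subtract(values: np.ndarray, baseline: float | None = None) -> np.ndarray:
    """Delta curve relative to the t=0 baseline (delta(0) == 0).

    For exogenous curves the baseline is 0 by construction (no tracer in
    circulation before the injection); passing ``baseline`` overrides the
    default of ``values[0]``.
    """
    values = np.asarray(values, dtype=float)
    b = values[0] if baseline is None else float(baseline)
    return values - b


def partition_table(
    glucose: pd.DataFrame, enrichment: pd.DataFrame
) -> pd.DataFrame:
    """Tidy-table front end to :func:`partition_series`.

    ``glucose`` columns: animal_id, test_mode, time_min, glucose_mgdl
    (insulin_ugl optional). ``enrichment`` columns as produced by
    :func:`deutg.correction.enrichment_table` (with test_mode).
    Returns one row per animal/test/timepoint with total, exogenous,
    endogenous and their baseline-subtracted deltas.
    """
    out = []
    for (animal, mode), gg in glucose.groupby(["animal_id", "test_mode"], sort=True):
        ee = enrichment[
            (enrichment["animal_id"] == animal) & (enrichment["test_mode"] == mode)
        ]
        if ee.empty:
            raise ValueError(f"no enrichment data for animal {animal!r} mode {mode!r}")
        gg = gg.sort_values("time_min")
        ee = ee.sort_values("time_min")
        series = GlucoseSeries(
            animal_id=str(animal),
            test_mode=TestMode(mode),
            times=gg["time_min"].to_numpy(),
            total_glucose=gg["glucose_mgdl"].to_numpy(),
        )
        from .correction import EnrichmentPoint  # local to avoid cycle at import

        eseries = EnrichmentSeries(
            animal_id=str(animal),
            points=[
                EnrichmentPoint(
                    time_min=float(t), enrichment=float(v), enrichment_raw=float(v)
                )
                for t, v in zip(ee["time_min"], ee["enrichment"])
            ],
        )
        p = partition_series(series, eseries)
        d_total = baseline_subtract(p.total)
        d_endo = baseline_subtract(p.endogenous)
        d_exo = baseline_subtract(p.exogenous, baseline=0.0)
        for i, t in enumerate(p.times):
            out.append(
                {
                    "animal_id": animal,
                    "test_mode": mode,
                    "time_min": t,
                    "total": p.total[i],
                    "exogenous": p.exogenous[i],
                    "endogenous": p.endogenous[i],
                    "d_total": d_total[i],
                    "d_exogenous": d_exo[i],
                    "d_endogenous": d_endo[i],
                }
            )
    return pd.DataFrame(out)
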