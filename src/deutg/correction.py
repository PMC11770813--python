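"""Natural-abundance correction of glucose isotopologue spectra.

Blood glucose measured by LC-MS/MS after a [6,6-2H2]glucose bolus shows
peaks at mass shifts M+0..M+K.  Natural 13C/2H/17O/18O abundance places
background signal at M+1 and M+2, on top of the tracer's M+2; the tracer
itself is not isotopically pure.  This module builds the forward
convolution matrix mapping true label-count fractions to observed
mass-shift fractions, inverts it by non-negative least squares, and
extracts molar tracer enrichment.

The correction matrix columns are deliberately *not* renormalized after
truncation at M+K: truncation loses a little mass to shifts > K, and that
loss shows up in the NNLS residual, which is reported as a per-sample QC
metric rather than silently folded back into the fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .isotopes import NATURAL_ABUNDANCE, TRACER_LABEL_POSITIONS, IonFormula

__all__ = [
    "CorrectionOptions",
    "IsotopologueSpectrum",
    "EnrichmentPoint",
    "EnrichmentSeries",
    "build_correction_matrix",
    "correct_spectrum",
    "enrichment_from_fractions",
    "enrichment_table",
]


@dataclass(frozen=True)
class CorrectionOptions:
    """Knobs of the natural-abundance / purity correction.

    tracer_purity
        Isotopic enrichment of the tracer at each labeled position
        (fraction of positions actually carrying 2H). 0.99 is a typical
        commercial specification for [6,6-2H2]glucose.
    natural_abundances
        Element -> per-shift isotope fractions; defaults to the pinned
        IUPAC 2013 representative values.
    max_shift
        K, the largest mass shift recorded in the spectra (>= 2).
    n_label_positions
        Number of deuterated positions on the tracer (2 for [6,6-2H2]).
    residual_threshold
        NNLS relative residual above which a sample is QC-flagged.
    """

    tracer_purity: float = 0.99
    natural_abundances: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(NATURAL_ABUNDANCE)
    )
    max_shift: int = 2
    n_label_positions: int = TRACER_LABEL_POSITIONS
    residual_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.tracer_purity <= 1.0):
            raise ValueError("tracer_purity must be in (0, 1]")
        if self.max_shift < 1:
            raise ValueError("max_shift must be >= 1")
        for el, fracs in self.natural_abundances.items():
            total = float(sum(fracs))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"isotope fractions for {el!r} sum to {total!r}, expected 1"
                )
            if any(f < 0 for f in fracs):
                raise ValueError(f"negative isotope fraction for {el!r}")


@dataclass
class IsotopologueSpectrum:
    """Raw integrated MS peak areas for one blood sample."""

    sample_id: str
    time_min: float
    areas: np.ndarray  # ordered M+0 .. M+K

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.ndim != 1 or self.areas.size < 3:
            raise ValueError("spectrum needs areas for at least M+0..M+2")
        if np.any(self.areas < 0):
            raise ValueError("peak areas must be non-negative")


@dataclass
class EnrichmentPoint:
    """Molar tracer enrichment of one sample, with QC metadata."""

    time_min: float
    enrichment: float  # clipped to [0, 1]
    enrichment_raw: float  # pre-clip value, kept for QC
    residual_norm: float = 0.0
    qc_flag: bool = False


@dataclass
class EnrichmentSeries:
    """Per-animal enrichment trajectory over the sampling schedule."""

    animal_id: str
    points: list[EnrichmentPoint]

    def __post_init__(self) -> None:
        times = [p.time_min for p in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("enrichment times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time_min for p in self.points])

    @property
    def enrichment(self) -> np.ndarray:
        return np.array([p.enrichment for p in self.points])


def _element_shift_distribution(fractions: tuple[float, ...], n_atoms: int) -> np.ndarray:
    """Mass-shift distribution of ``n_atoms`` i.i.d. atoms of one element."""
    base = np.asarray(fractions, dtype=float)
    if n_atoms == 0:
        return np.array([1.0])
    # binary exponentiation of the generating polynomial
    out = np.array([1.0])
    power = base
    n = n_atoms
    while n:
        if n & 1:
            out = np.convolve(out, power)
        n >>= 1
        if n:
            power = np.convolve(power, power)
    return out


def natural_shift_distribution(
    formula: IonFormula, opts: CorrectionOptions, exclude_hydrogens: int = 0
) -> np.ndarray:
    """Full natural-abundance mass-shift distribution of the ion.

    ``exclude_hydrogens`` removes that many H atoms from the convolution
    (the tracer-labeled positions, whose isotopic state is set by the
    tracer purity, not by natural abundance).
    """
    dist = np.array([1.0])
    for el, n in formula.element_counts.items():
        if el == "H":
            n = n - exclude_hydrogens
            if n < 0:
                raise ValueError("cannot exclude more hydrogens than present")
        if el not in opts.natural_abundances:
            raise KeyError(f"no natural abundances configured for element {el!r}")
        dist = np.convolve(dist, _element_shift_distribution(opts.natural_abundances[el], n))
    return dist


def _label_shift_distribution(n_labels: int, purity: float) -> np.ndarray:
    """Shift distribution of the labeled positions themselves.

    Each labeled position carries 2H with probability ``purity`` and 1H
    otherwise, so the shift is Binomial(n_labels, purity).
    """
    return np.array(
        [
            math.comb(n_labels, m) * purity**m * (1.0 - purity) ** (n_labels - m)
            for m in range(n_labels + 1)
        ]
    )


def build_correction_matrix(
    formula: IonFormula | None = None, opts: CorrectionOptions | None = None
) -> np.ndarray:
    """Forward convolution matrix from label-count fractions to observed shifts.

    Column ``j`` is the mass-shift distribution of the glucose species
    whose ``j`` tracer positions are (nominally) deuterated: the natural
    abundance convolution of the formula with ``j`` hydrogens removed,
    convolved with the Binomial(j, purity) label distribution, truncated
    at ``K = opts.max_shift``. Columns sum to <= 1 (truncation loses mass;
    no renormalization).
    """
    formula = formula if formula is not None else IonFormula()
    opts = opts if opts is not None else CorrectionOptions()
    K = opts.max_shift
    if opts.n_label_positions > K:
        raise ValueError("tracer shift exceeds spectrum length")
    if opts.n_label_positions > formula.hydrogen_count:
        raise ValueError("formula has fewer hydrogens than tracer-labeled positions")
    M = np.zeros((K + 1, K + 1))
    for j in range(K + 1):
        n_excl = min(j, formula.hydrogen_count)
        natural = natural_shift_distribution(formula, opts, exclude_hydrogens=n_excl)
        labels = _label_shift_distribution(j, opts.tracer_purity)
        col = np.convolve(natural, labels)[: K + 1]
        M[: col.size, j] = col
    return M


def correct_spectrum(
    spec: IsotopologueSpectrum, matrix: np.ndarray, residual_threshold: float = 0.05
) -> tuple[np.ndarray, float, bool]:
    """Invert the forward convolution by non-negative least squares.

    Returns ``(fractions, residual_norm, qc_flag)`` where ``fractions``
    are the true label-count molar fractions normalized to sum 1, and
    ``residual_norm`` is the NNLS residual of the sum-normalized observed
    spectrum (a QC metric capturing noise and truncation loss).
    """
    total = spec.areas.sum()
    if total == 0:
        raise ValueError("empty spectrum")
    if spec.areas.size != matrix.shape[0]:
        raise ValueError(
            f"spectrum length {spec.areas.size} does not match matrix size {matrix.shape[0]}"
        )
    observed = spec.areas / total
    x, resid = nnls(matrix, observed)
    if x.sum() == 0:
        raise ValueError("degenerate spectrum: NNLS returned all-zero fractions")
    fractions = x / x.sum()
    return fractions, float(resid), bool(resid > residual_threshold)


def enrichment_from_fractions(
    fractions: np.ndarray, time_min: float = 0.0, opts: CorrectionOptions | None = None
) -> EnrichmentPoint:
    """Tracer enrichment = corrected fraction at the tracer's mass shift.

    The raw value is retained for QC; the reported enrichment is clipped
    to [0, 1] so downstream partitioning stays physical.
    """
    opts = opts if opts is not None else CorrectionOptions()
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must sum to 1")
    raw = float(fractions[opts.n_label_positions])
    return EnrichmentPoint(
        time_min=time_min,
        enrichment=float(np.clip(raw, 0.0, 1.0)),
        enrichment_raw=raw,
    )


def enrichment_table(
    areas: pd.DataFrame,
    formula: IonFormula | None = None,
    opts: CorrectionOptions | None = None,
    correct: bool = True,
) -> pd.DataFrame:
    """Convert a tidy MS-areas table to per-sample enrichments.

    ``areas`` needs columns ``animal_id, time_min, area_m0, area_m1,
    area_m2`` (further ``area_mK`` columns allowed; ``sample_id`` and
    ``test_mode`` are carried through if present).  With ``correct=False``
    no natural-abundance correction is applied and the enrichment is the
    simple M+2 share of total area.
    """
    opts = opts if opts is not None else CorrectionOptions()
    area_cols = sorted(
        (c for c in areas.columns if c.startswith("area_m")),
        key=lambda c: int(c.removeprefix("area_m")),
    )
    if len(area_cols) < 3:
        raise ValueError("need at least area_m0, area_m1, area_m2 columns")
    K = len(area_cols) - 1
    run_opts = CorrectionOptions(
        tracer_purity=opts.tracer_purity,
        natural_abundances=opts.natural_abundances,
        max_shift=K,
        n_label_positions=opts.n_label_positions,
        residual_threshold=opts.residual_threshold,
    )
    matrix = (
        build_correction_matrix(formula, run_opts) if correct else np.eye(K + 1)
    )
    rows = []
    carry = [c for c in ("sample_id", "test_mode") if c in areas.columns]
    for _, row in areas.iterrows():
        spec = IsotopologueSpectrum(
            sample_id=str(row.get("sample_id", row["animal_id"])),
            time_min=float(row["time_min"]),
            areas=row[area_cols].to_numpy(dtype=float),
        )
        fractions, resid, flagged = correct_spectrum(
            spec, matrix, run_opts.residual_threshold
        )
        point = enrichment_from_fractions(fractions, spec.time_min, run_opts)
        out = {
            "animal_id": row["animal_id"],
            "time_min": spec.time_min,
            "enrichment": point.enrichment,
            "enrichment_raw": point.enrichment_raw,
            "residual_norm": resid,
            "qc_flag": flagged,
        }
        for c in carry:
            out[c] = row[c]
        rows.append(out)
    return pd.DataFrame(rows)
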