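"""Natural isotope abundances and ion formula handling.

Mass-shift bookkeeping is integer-valued: isotope ``i`` of an element is
indexed by its nominal mass excess over the lightest isotope, so the
single-atom abundance vector for oxygen is ``[p(16O), p(17O), p(18O)]``.
Representative terrestrial abundances (IUPAC 2013) are pinned here so that
correction matrices are reproducible; callers may override any element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Representative isotopic composition of the elements (IUPAC 2013),
# indexed by nominal mass shift relative to the lightest isotope.
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

#: Number of deuterium-labeled positions in [6,6-2H2]glucose.
TRACER_LABEL_POSITIONS = 2

#: Deprotonated glucose ion [M-H]-, the default species assumed measured
#: by LC-MS/MS for glucose quantitation.
DEFAULT_GLUCOSE_ION = {"C": 6, "H": 11, "O": 6}


@dataclass(frozen=True)
class IonFormula:
    """Elemental composition of the measured ion.

    Parameters
    ----------
    element_counts
        Map of element symbol to atom count, e.g. ``{"C": 6, "H": 11, "O": 6}``.
    charge
        Signed ion charge. Carried for provenance; the mass-shift algebra
        does not depend on it.
    """

    element_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GLUCOSE_ION)
    )
    charge: int = -1

    def __post_init__(self) -> None:
        if not self.element_counts:
            raise ValueError("formula must contain at least one element")
        for el, n in self.element_counts.items():
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for element {el!r} must be a non-negative integer")
        if sum(self.element_counts.values()) == 0:
            raise ValueError("formula must contain at least one atom")
        n_h = self.element_counts.get("H", 0)
        if n_h < TRACER_LABEL_POSITIONS:
            raise ValueError(
                f"hydrogen count ({n_h}) is smaller than the number of "
                f"tracer-labeled positions ({TRACER_LABEL_POSITIONS})"
            )

    @property
    def hydrogen_count(self) -> int:
        return self.element_counts.get("H", 0)
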