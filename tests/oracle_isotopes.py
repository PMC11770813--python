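"""Independent brute-force oracle for isotopologue distributions.

Enumerates every isotope composition of a molecular formula with
multinomial probabilities in pure Python — no shared code with the
package's polynomial-convolution implementation.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache


def _compositions(n: int, k: int):
    """All ways to place n atoms into k isotope slots."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first, *rest)


@lru_cache(maxsize=None)
def element_distribution(n_atoms: int, fractions: tuple[float, ...]) -> dict[int, float]:
    """Mass-shift distribution of n_atoms of one element, by enumeration."""
    dist: dict[int, float] = {}
    k = len(fractions)
    for counts in _compositions(n_atoms, k):
        prob = math.factorial(n_atoms)
        for c, f in zip(counts, fractions):
            prob = prob / math.factorial(c) * f**c
        shift = sum(i * c for i, c in enumerate(counts))
        dist[shift] = dist.get(shift, 0.0) + prob
    return dist


def molecule_distribution(
    element_counts: dict[str, int], abundances: dict[str, tuple[float, ...]]
) -> dict[int, float]:
    """Mass-shift distribution of a molecule by exhaustive enumeration."""
    dist: dict[int, float] = {0: 1.0}
    for el, n in element_counts.items():
        ed = element_distribution(n, tuple(abundances[el]))
        new: dict[int, float] = {}
        for s1, p1 in dist.items():
            for s2, p2 in ed.items():
                new[s1 + s2] = new.get(s1 + s2, 0.0) + p1 * p2
        dist = new
    return dist


def labeled_species_distribution(
    element_counts: dict[str, int],
    abundances: dict[str, tuple[float, ...]],
    n_labels: int,
    purity: float,
) -> dict[int, float]:
    """Distribution for a species with n_labels nominally deuterated positions.

    Enumerates each labeled position independently as 2H (probability
    ``purity``, shift +1) or 1H (shift 0); the remaining atoms follow
    natural abundance.
    """
    counts = dict(element_counts)
    counts["H"] = counts["H"] - n_labels
    natural = molecule_distribution(counts, abundances)
    dist: dict[int, float] = {}
    for states in itertools.product([0, 1], repeat=n_labels):
        p_state = math.prod(purity if s else (1.0 - purity) for s in states)
        shift_state = sum(states)
        for s, p in natural.items():
            key = s + shift_state
            dist[key] = dist.get(key, 0.0) + p * p_state
    return dist


def hand_trapezoid(times, values) -> float:
    """One-line trapezoid sum, written independently of the package."""
    return sum(
        (times[i + 1] - times[i]) * (values[i] + values[i + 1]) / 2.0
        for i in range(len(times) - 1)
    )
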