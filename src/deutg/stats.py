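"""Factorial statistics on AOC outcomes and per-timepoint comparisons.

The study design is a 2x2 mixed factorial: diet (between animals) by
insulin, i.e. test mode GTT vs ITT (within animals, the two tests run a
week apart on the same mice).  For each AOC outcome we report the diet
and insulin main effects and their interaction from a mixed-design
two-way ANOVA, plus Holm-adjusted pairwise comparisons among the four
diet x mode cells rendered as a compact letter display (cells not
sharing a letter differ at alpha).  Per-timepoint group differences use
Welch t-tests with Holm adjustment across the five post-baseline
timepoints.

The ANOVA flavor and post-hoc procedure are conventions of this package
(a mixed ANOVA with Holm-adjusted t-tests matches the main-effect /
interaction / letters style of presentation); they are not uniquely
dictated by the assay.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["FactorialResult", "factorial_aoc", "timepoint_compare",
           "compact_letter_display", "stats_report"]


@dataclass
class FactorialResult:
    """Mixed-ANOVA readout for one AOC outcome."""

    outcome: str
    p_diet: float
    p_insulin: float
    p_interaction: float
    cell_means: pd.DataFrame  # group, test_mode, n, mean, se, letters
    pairwise: pd.DataFrame    # cell_a, cell_b, p_raw, p_holm, significant
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)


def compact_letter_display(
    cells: list[str], sig_pairs: set[tuple[str, str]], means: dict[str, float]
) -> dict[str, str]:
    """Assign letters so two cells share a letter iff not significantly different.

    Letters are the maximal cliques of the non-significance graph,
    ordered by descending clique mean so 'a' tags the highest cells.
    """
    g = nx.Graph()
    g.add_nodes_from(cells)
    for a, b in itertools.combinations(cells, 2):
        if (a, b) not in sig_pairs and (b, a) not in sig_pairs:
            g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: -np.mean([means[m] for m in c]))
    letters: dict[str, list[str]] = {c: [] for c in cells}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for cell in clique:
            letters[cell].append(letter)
    return {c: "".join(sorted(v)) for c, v in letters.items()}


def _check_cells(df: pd.DataFrame, min_n: int = 2) -> None:
    counts = df.groupby(["group", "test_mode"], sort=True).size()
    groups = df["group"].unique()
    modes = df["test_mode"].unique()
    if len(groups) < 2 or len(modes) < 2:
        raise ValueError(
            f"factorial design needs >=2 diets and both test modes; "
            f"got diets {sorted(groups)} and modes {sorted(modes)}"
        )
    for g in groups:
        for m in modes:
            n = counts.get((g, m), 0)
            if n < min_n:
                raise ValueError(f"cell (group={g!r}, mode={m!r}) has n={n} < {min_n}")


def factorial_aoc(
    aocs: pd.DataFrame,
    manifest: pd.DataFrame,
    outcome: str = "aoc_total",
    alpha: float = 0.05,
) -> FactorialResult:
    """Diet x insulin mixed ANOVA on one AOC outcome.

    ``aocs`` columns: animal_id, test_mode, and the outcome column;
    ``manifest`` maps animal_id to group.  Animals are the within-subject
    pairing unit across the two test modes.
    """
    df = aocs.merge(manifest[["animal_id", "group"]], on="animal_id", how="left")
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "animal_id"].unique().tolist()
        raise ValueError(f"animals missing from manifest: {missing}")
    _check_cells(df)

    anova = pg.mixed_anova(
        data=df, dv=outcome, within="test_mode", subject="animal_id", between="group"
    )
    pcol = "p_unc" if "p_unc" in anova.columns else "p-unc"
    p_diet = float(anova.loc[anova["Source"] == "group", pcol].iloc[0])
    p_ins = float(anova.loc[anova["Source"] == "test_mode", pcol].iloc[0])
    p_int = float(anova.loc[anova["Source"] == "Interaction", pcol].iloc[0])

    # all six pairwise cell contrasts: paired when same animals (same
    # diet across modes), Welch otherwise
    cells = {
        (g, m): sub.set_index("animal_id")[outcome]
        for (g, m), sub in df.groupby(["group", "test_mode"], sort=True)
    }
    pair_rows = []
    for (ca, cb) in itertools.combinations(sorted(cells), 2):
        a, b = cells[ca], cells[cb]
        if ca[0] == cb[0]:  # same diet, different mode: paired by animal
            common = a.index.intersection(b.index)
            stat = sps.ttest_rel(a.loc[common], b.loc[common])
        else:
            stat = sps.ttest_ind(a, b, equal_var=False)
        pair_rows.append(
            {
                "cell_a": f"{ca[0]}:{ca[1]}",
                "cell_b": f"{cb[0]}:{cb[1]}",
                "p_raw": float(stat.pvalue),
            }
        )
    pairwise = pd.DataFrame(pair_rows)
    pairwise["p_holm"] = multipletests(pairwise["p_raw"], method="holm")[1]
    pairwise["significant"] = pairwise["p_holm"] < alpha

    cell_names = [f"{g}:{m}" for (g, m) in sorted(cells)]
    means = {f"{g}:{m}": float(cells[(g, m)].mean()) for (g, m) in cells}
    sig = {
        (r.cell_a, r.cell_b) for r in pairwise.itertuples() if r.significant
    }
    letters = compact_letter_display(cell_names, sig, means)
    cell_means = pd.DataFrame(
        [
            {
                "group": g,
                "test_mode": m,
                "n": int(cells[(g, m)].size),
                "mean": means[f"{g}:{m}"],
                "se": float(cells[(g, m)].std(ddof=1) / np.sqrt(cells[(g, m)].size)),
                "letters": letters[f"{g}:{m}"],
            }
            for (g, m) in sorted(cells)
        ]
    )

    notes = []
    for (g, m), vals in cells.items():
        if vals.size >= 3:
            w = sps.shapiro(vals)
            if w.pvalue < 0.05:
                notes.append(
                    f"Shapiro-Wilk flags non-normality in cell {g}:{m} (p={w.pvalue:.3g})"
                )
    return FactorialResult(
        outcome=outcome,
        p_diet=p_diet,
        p_insulin=p_ins,
        p_interaction=p_int,
        cell_means=cell_means,
        pairwise=pairwise,
        alpha=alpha,
        notes=notes,
    )


def timepoint_compare(
    curves: pd.DataFrame,
    manifest: pd.DataFrame,
    value_col: str = "d_endogenous",
    test_mode: str = "ITT",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group comparison at each post-baseline timepoint.

    Welch t-tests between the two diet groups at each time > 0, Holm
    adjustment across timepoints; returns time_min, group means, p_raw,
    p_holm and a significance flag.
    """
    df = curves[curves["test_mode"] == test_mode].merge(
        manifest[["animal_id", "group"]], on="animal_id", how="left"
    )
    groups = sorted(df["group"].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"timepoint comparison needs exactly 2 groups, got {groups}")
    rows = []
    for t, sub in df[df["time_min"] > 0].groupby("time_min", sort=True):
        a = sub.loc[sub["group"] == groups[0], value_col].to_numpy()
        b = sub.loc[sub["group"] == groups[1], value_col].to_numpy()
        if a.size < 2 or b.size < 2:
            raise ValueError(f"time {t}: need n >= 2 per group for a comparison")
        stat = sps.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "time_min": t,
                f"mean_{groups[0]}": float(a.mean()),
                f"mean_{groups[1]}": float(b.mean()),
                "p_raw": float(stat.pvalue),
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    out["significant"] = out["p_holm"] < alpha
    return out


def stats_report(
    aocs: pd.DataFrame,
    curves: pd.DataFrame,
    manifest: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, str]:
    """Full statistical readout: factorial ANOVA per AOC outcome plus
    per-timepoint endogenous/exogenous comparisons in both modes.

    Returns a tidy results table and a human-readable text report.
    """
    outcomes = ["aoc_total", "aoc_exogenous", "aoc_endogenous"]
    tidy_rows = []
    lines = ["Factorial diet x insulin analysis (mixed two-way ANOVA)", "=" * 56]
    for outcome in outcomes:
        res = factorial_aoc(aocs, manifest, outcome=outcome, alpha=alpha)
        tidy_rows.append(
            {
                "outcome": outcome,
                "p_diet": res.p_diet,
                "p_insulin": res.p_insulin,
                "p_interaction": res.p_interaction,
            }
        )
        lines.append(f"\n{outcome} (mg/dL*min)")
        lines.append(
            f"  ME diet p={res.p_diet:.4g}; ME insulin p={res.p_insulin:.4g}; "
            f"interaction p={res.p_interaction:.4g}"
        )
        for r in res.cell_means.itertuples():
            lines.append(
                f"  {r.group}:{r.test_mode}  n={r.n}  {r.mean:8.1f} +/- {r.se:6.1f}  [{r.letters}]"
            )
        for note in res.notes:
            lines.append(f"  note: {note}")
    lines.append("\nPer-timepoint group comparisons (Welch + Holm)")
    lines.append("=" * 56)
    for mode in sorted(curves["test_mode"].unique()):
        for col in ("d_total", "d_exogenous", "d_endogenous"):
            tp = timepoint_compare(curves, manifest, value_col=col,
                                   test_mode=mode, alpha=alpha)
            flagged = tp.loc[tp["significant"], "time_min"].tolist()
            lines.append(f"  {mode} {col}: significant at t={flagged or 'none'}")
    return pd.DataFrame(tidy_rows), "\n".join(lines) + "\n"
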