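"""End-to-end orchestration: correction -> partition -> AOC -> stats.

Inputs are three tidy CSVs (animal manifest, glucometer readings, MS
isotopologue areas) plus a plain-text ``key = value`` run config.  Each
stage writes its own CSV so stages can be re-run individually; the run
log records the package version, a hash of the effective config, and QC
flag counts.  All randomness (none in the deterministic stages) flows
from the single config seed, so a run is reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .aoc import summarize_table
from .correction import CorrectionOptions, enrichment_table
from .isotopes import DEFAULT_GLUCOSE_ION, IonFormula
from .partition import partition_table
from .simulate import FLOAT_FMT
from .stats import stats_report

__all__ = ["RunConfig", "PipelineError", "ValidationError", "run_pipeline",
           "load_config"]


class PipelineError(RuntimeError):
    """Stage failure at runtime (exit code 2 at the CLI)."""


class ValidationError(PipelineError):
    """Input schema/contract violation (exit code 1 at the CLI)."""


@dataclass
class RunConfig:
    manifest: Path
    glucometer: Path
    ms_areas: Path
    outdir: Path
    ion_formula: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GLUCOSE_ION))
    tracer_purity: float = 0.99
    correction: bool = True
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("manifest", "glucometer", "ms_areas"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise ValidationError(f"{name} file not found: {p}")
        self.outdir = Path(self.outdir)
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")

    def digest(self) -> str:
        payload = {
            "manifest": str(self.manifest),
            "glucometer": str(self.glucometer),
            "ms_areas": str(self.ms_areas),
            "ion_formula": self.ion_formula,
            "tracer_purity": self.tracer_purity,
            "correction": self.correction,
            "alpha": self.alpha,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _parse_formula(text: str) -> dict[str, int]:
    """Parse 'C6H11O6'-style formulas (single-letter or Xx symbols)."""
    import re

    counts: dict[str, int] = {}
    for sym, num in re.findall(r"([A-Z][a-z]?)(\d*)", text):
        if sym:
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if not counts:
        raise ValidationError(f"cannot parse ion formula {text!r}")
    return counts


def load_config(path: str | Path, outdir: str | Path | None = None) -> RunConfig:
    """Read a plain-text ``key = value`` config file.

    Recognized keys: manifest, glucometer, ms_areas, outdir, ion_formula
    (e.g. C6H11O6), tracer_purity, correction (on/off), alpha, seed.
    Lines starting with '#' are comments; relative paths resolve against
    the config file's directory.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    raw: dict[str, str] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{i}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        raw[key.strip()] = value.strip()
    base = path.parent
    missing = [k for k in ("manifest", "glucometer", "ms_areas") if k not in raw]
    if missing:
        raise ValidationError(f"{path}: missing required config keys: {missing}")
    kwargs = {
        "manifest": base / raw["manifest"],
        "glucometer": base / raw["glucometer"],
        "ms_areas": base / raw["ms_areas"],
        "outdir": Path(outdir) if outdir is not None else base / raw.get("outdir", "results"),
    }
    if "ion_formula" in raw:
        kwargs["ion_formula"] = _parse_formula(raw["ion_formula"])
    if "tracer_purity" in raw:
        kwargs["tracer_purity"] = float(raw["tracer_purity"])
    if "correction" in raw:
        kwargs["correction"] = raw["correction"].lower() in ("1", "true", "on", "yes")
    if "alpha" in raw:
        kwargs["alpha"] = float(raw["alpha"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return RunConfig(**kwargs)


def _read_csv(path: Path, required: list[str], name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as validation error
        raise ValidationError(f"{name} ({path}): unreadable CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} ({path}): missing columns {missing}")
    return df


def _validate_animals(manifest: pd.DataFrame, other: pd.DataFrame, name: str,
                      path: Path) -> None:
    known = set(manifest["animal_id"].astype(str))
    seen = set(other["animal_id"].astype(str))
    orphans = sorted(seen - known)
    if orphans:
        raise ValidationError(
            f"{name} ({path}): animals not in manifest: {orphans}"
        )


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run all stages and write per-stage CSVs, the stats report and a log.

    Returns a map of artifact name to written path.  Deterministic given
    inputs and config.
    """
    manifest = _read_csv(
        cfg.manifest, ["animal_id", "group", "body_mass_g", "lean_mass_g"], "manifest"
    )
    glucometer = _read_csv(
        cfg.glucometer, ["animal_id", "test_mode", "time_min", "glucose_mgdl"], "glucometer"
    )
    ms = _read_csv(
        cfg.ms_areas,
        ["animal_id", "test_mode", "time_min", "area_m0", "area_m1", "area_m2"],
        "ms_areas",
    )
    _validate_animals(manifest, glucometer, "glucometer", cfg.glucometer)
    _validate_animals(manifest, ms, "ms_areas", cfg.ms_areas)

    opts = CorrectionOptions(tracer_purity=cfg.tracer_purity)
    formula = IonFormula(element_counts=dict(cfg.ion_formula))

    try:
        enrich = enrichment_table(ms, formula=formula, opts=opts, correct=cfg.correction)
        partitioned = partition_table(glucometer, enrich)
        aocs = summarize_table(partitioned)
        stats_tidy, report_text = stats_report(aocs, partitioned, manifest, alpha=cfg.alpha)
    except ValueError as exc:
        raise PipelineError(str(exc)) from exc

    cfg.outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("enrichment", enrich),
        ("partitioned", partitioned),
        ("aoc", aocs),
        ("stats", stats_tidy),
    ):
        p = cfg.outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format=FLOAT_FMT)
        paths[name] = p
    report_path = cfg.outdir / "report.txt"
    report_path.write_text(report_text)
    paths["report"] = report_path

    n_flagged = int(enrich["qc_flag"].sum())
    log = cfg.outdir / "run_log.txt"
    log.write_text(
        "\n".join(
            [
                f"deutg version: {__version__}",
                f"config sha256: {cfg.digest()}",
                f"animals: {manifest.shape[0]}",
                f"samples corrected: {enrich.shape[0]}",
                f"QC-flagged samples: {n_flagged}",
                f"natural-abundance correction: {'on' if cfg.correction else 'off'}",
                f"alpha: {cfg.alpha}",
                f"seed: {cfg.seed}",
            ]
        )
        + "\n"
    )
    paths["log"] = log
    return paths
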