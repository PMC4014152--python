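"""Readers, writers and unit utilities for the analysis pipeline.

Study tables travel as TSV (columns ``dose_Gy``, ``experiment``,
``replicate``, ``n_cells_class``, ``count``), RCD profiles and reports as
JSON, and run configurations as JSON or YAML.  Every CLI run also writes a
manifest recording inputs, configuration, seed and library versions.
"""

from __future__ import annotations

import json
import sys
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .branching import ColonySizeDistribution, RCDProfile
from .lattice import ColonySimResult, SimulationConfig
from .survival import SurvivalCurve
from .synthetic import CLONOGENIC_CLASS, pool_counts

__all__ = [
    "StudyTableError",
    "fluence_to_dose",
    "write_study_table",
    "read_study_table",
    "read_colony_counts",
    "write_profile",
    "read_profile",
    "write_profiles_map",
    "read_profiles_map",
    "write_sizes_table",
    "read_sizes_table",
    "write_survival_curve",
    "read_survival_curve",
    "write_report",
    "read_run_config",
    "write_manifest",
]

STUDY_COLUMNS = ["dose_Gy", "experiment", "replicate", "n_cells_class", "count"]

#: Gy per (keV/µm) per (particle/cm²)
DOSE_FLUENCE_COEFF = 1.6e-9


class StudyTableError(ValueError):
    """A study table failed validation; the message names the offending line."""


def fluence_to_dose(let: float, fluence: float) -> float:
    """Absorbed dose from particle fluence.

    ``dose (Gy) = 1.6e-9 * LET (keV/µm) * fluence (particles/cm²)``.
    """
    let = float(let)
    fluence = float(fluence)
    if let < 0 or fluence < 0:
        raise ValueError("LET and fluence must be nonnegative")
    return DOSE_FLUENCE_COEFF * let * fluence


def write_study_table(table: pd.DataFrame, path) -> None:
    table[STUDY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_study_table(path) -> pd.DataFrame:
    """Read and validate a study table; errors cite 1-based file lines."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype={"n_cells_class": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty study table", stacklevel=2)
        return pd.DataFrame(columns=STUDY_COLUMNS)
    missing = [c for c in STUDY_COLUMNS if c not in table.columns]
    if missing:
        raise StudyTableError(f"{path}: missing column(s) {missing}")
    if table.empty:
        warnings.warn(f"{path}: study table has no data rows", stacklevel=2)
        return table
    for i, row in table.iterrows():
        line = i + 2  # 1-based, after the header
        cls = str(row["n_cells_class"])
        if cls != CLONOGENIC_CLASS:
            try:
                n = int(cls)
            except ValueError:
                raise StudyTableError(
                    f"{path}:{line}: size class {cls!r} is neither an integer "
                    f"nor {CLONOGENIC_CLASS!r}"
                ) from None
            if n < 1:
                raise StudyTableError(f"{path}:{line}: size class {n} < 1")
        try:
            count = float(row["count"])
        except (TypeError, ValueError):
            raise StudyTableError(
                f"{path}:{line}: non-numeric count {row['count']!r}"
            ) from None
        if not np.isfinite(count) or count < 0:
            raise StudyTableError(f"{path}:{line}: negative or non-finite count {count}")
    keys = table[["dose_Gy", "experiment", "replicate", "n_cells_class"]]
    dup = keys.duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2
        raise StudyTableError(
            f"{path}:{line}: duplicate (dose, experiment, replicate, class) key"
        )
    return table


def read_colony_counts(path) -> dict[float, ColonySizeDistribution]:
    """Pooled counts-mode distributions per dose from a study table."""
    table = read_study_table(path)
    if table.empty:
        return {}
    return {
        float(d): pool_counts(table, float(d))
        for d in sorted(table["dose_Gy"].astype(float).unique())
    }


def write_profile(profile: RCDProfile, path) -> None:
    payload: dict[str, Any] = {"p1": list(profile.p1)}
    if profile.c is not None:
        payload["c"] = profile.c
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_profile(path) -> RCDProfile:
    payload = json.loads(Path(path).read_text())
    return RCDProfile(p1=tuple(payload["p1"]), c=payload.get("c"))


def _profile_payload(profile: RCDProfile) -> dict:
    payload: dict[str, Any] = {"p1": list(profile.p1)}
    if profile.c is not None:
        payload["c"] = profile.c
    return payload


def write_profiles_map(profiles: dict[float, RCDProfile], path) -> None:
    """Dose -> profile mapping as JSON (doses serialized as string keys)."""
    payload = {
        "profiles": {str(float(d)): _profile_payload(p) for d, p in profiles.items()}
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_profiles_map(path) -> dict[float, RCDProfile]:
    payload = json.loads(Path(path).read_text())
    return {
        float(d): RCDProfile(p1=tuple(spec["p1"]), c=spec.get("c"))
        for d, spec in payload["profiles"].items()
    }


def write_sizes_table(results: dict[float, ColonySimResult], path) -> None:
    """Per-dose final-size counts of simulated colonies (TSV)."""
    rows = []
    for dose in sorted(results):
        uniq, counts = np.unique(results[dose].sizes, return_counts=True)
        rows.extend((dose, int(n), int(k)) for n, k in zip(uniq, counts))
    pd.DataFrame(rows, columns=["dose_Gy", "size", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_sizes_table(path, config: SimulationConfig | None = None) -> dict[float, ColonySimResult]:
    """Reconstruct per-dose simulation results from a sizes table.

    The expansion loses the original draw order of the sizes, which is
    irrelevant to every downstream statistic.
    """
    table = pd.read_csv(path, sep="\t")
    out: dict[float, ColonySimResult] = {}
    for dose, sub in table.groupby("dose_Gy"):
        sizes = np.repeat(sub["size"].to_numpy(int), sub["count"].to_numpy(int))
        n = len(sizes)
        cfg = config or SimulationConfig(n_colonies_per_run=max(n, 1), n_runs=1)
        out[float(dose)] = ColonySimResult(sizes=sizes, config=cfg, seed=-1)
    return out


def write_survival_curve(curve: SurvivalCurve, path) -> None:
    df = pd.DataFrame({"dose_Gy": curve.doses, "sf": curve.sf})
    df["sem"] = curve.sem if curve.sem is not None else np.nan
    df["n"] = curve.n_total if curve.n_total is not None else np.nan
    if curve.n_clonogenic is not None:
        df["n_clonogenic"] = curve.n_clonogenic
    df.to_csv(path, sep="\t", index=False)


def read_survival_curve(path, label: str = "") -> SurvivalCurve:
    df = pd.read_csv(path, sep="\t")
    for col in ("dose_Gy", "sf"):
        if col not in df.columns:
            raise StudyTableError(f"{path}: missing column {col!r}")

    def _opt(col):
        if col in df.columns and df[col].notna().all():
            return df[col].to_numpy(float)
        return None

    return SurvivalCurve(
        doses=df["dose_Gy"].to_numpy(float),
        sf=df["sf"].to_numpy(float),
        sem=_opt("sem"),
        label=label or Path(path).stem,
        n_clonogenic=_opt("n_clonogenic"),
        n_total=_opt("n"),
    )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and obj in (float("inf"), float("-inf")):
        return str(obj)
    return obj


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(report), indent=2) + "\n")


def read_run_config(path) -> dict:
    """Run configuration from JSON or YAML, keyed by file extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def write_manifest(path, *, command: str, seed: int, inputs: dict, config: dict) -> None:
    """Provenance record sufficient to re-run a pipeline stage exactly."""
    from . import __version__

    manifest = {
        "command": command,
        "seed": int(seed),
        "inputs": _jsonify(inputs),
        "config": _jsonify(config),
        "versions": {
            "clonobranch": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
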