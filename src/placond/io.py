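"""Tabular/JSON formats, configuration and the reproducible pipeline.

All file outputs are plain comma-separated text ('.' decimal, UTF-8,
mandatory header with units baked into the column names: ``time_h``,
``Mn_Da``, ``Mw_Da``) or JSON.  Every pipeline run emits a provenance
record — config hash, seed, package and library versions — next to its
artifacts, and re-running with the same config and seed reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .condensed import KineticParameters, simulate
from .fitting import FitResult, FitSettings, GPCDataset, fit
from .integrator import IntegratorSettings
from .mass_balance import (
    InitialState,
    MassLedger,
    dry_mass_scenarios,
    initial_concentrations,
    reference_ledger,
)

__all__ = [
    "read_gpc_table",
    "write_gpc_table",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger("placond")


def read_gpc_table(path: str | Path) -> GPCDataset:
    """Read a GPC series from CSV with columns ``time_h, Mn_Da[, Mw_Da]``.

    Malformed rows are rejected with the offending row index in the
    message; dataset-level invariants (monotone times, positive Mn,
    Mw >= Mn) are enforced by :class:`~placond.fitting.GPCDataset`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GPC table not found: {path}")
    df = pd.read_csv(path)
    for col in ("time_h", "Mn_Da"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in ["time_h", "Mn_Da"] + (["Mw_Da"] if "Mw_Da" in df.columns else []):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"{path}: malformed value in column {col!r}, row {bad[0]}")
        df[col] = vals
    if df["time_h"].isna().any() or df["Mn_Da"].isna().any():
        row = int(df.index[df[["time_h", "Mn_Da"]].isna().any(axis=1)][0])
        raise ValueError(f"{path}: missing time or Mn in row {row}")
    mw = df["Mw_Da"].to_numpy() if "Mw_Da" in df.columns else None
    return GPCDataset(time_h=df["time_h"].to_numpy(), mn=df["Mn_Da"].to_numpy(), mw=mw)


def write_gpc_table(data: GPCDataset, path: str | Path) -> None:
    """Write a GPC series as CSV; inverse of :func:`read_gpc_table`."""
    cols = {"time_h": data.time_h, "Mn_Da": data.mn}
    if data.mw is not None:
        cols["Mw_Da"] = data.mw
    pd.DataFrame(cols).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """One reproducible pipeline run.

    ``scenario`` picks which bounded dry-acid mass seeds the initial
    concentrations; ``params`` are used for the forward simulation and as
    the fit start when given; ``data_path`` switches the fit stage on.
    """

    ledger: MassLedger = dataclasses.field(default_factory=reference_ledger)
    scenario: str = "upper"
    xw0: float = 1e-5
    params: KineticParameters | None = None
    integrator: IntegratorSettings = dataclasses.field(
        default_factory=IntegratorSettings
    )
    fit: FitSettings = dataclasses.field(default_factory=FitSettings)
    data_path: str | None = None
    seed: int = 0
    corrected: bool = False
    sim_hours: float = 200.0

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_to_jsonable(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _build(cls, block: dict[str, Any] | None, **extra):
    block = dict(block or {})
    block.update(extra)
    return cls(**block)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON config whose blocks mirror the dataclasses:
    ``ledger``, ``integrator``, ``fit``, ``params`` plus scalar keys."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    raw = raw or {}
    params = raw.get("params")
    return RunConfig(
        ledger=_build(MassLedger, raw.get("ledger"))
        if raw.get("ledger")
        else reference_ledger(),
        scenario=raw.get("scenario", "upper"),
        xw0=float(raw.get("xw0", 1e-5)),
        params=_build(KineticParameters, params) if params else None,
        integrator=_build(IntegratorSettings, raw.get("integrator")),
        fit=_build(FitSettings, raw.get("fit")),
        data_path=raw.get("data_path"),
        seed=int(raw.get("seed", 0)),
        corrected=bool(raw.get("corrected", False)),
        sim_hours=float(raw.get("sim_hours", 200.0)),
    )


# ---------------------------------------------------------------------------
# pipeline


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def build_initial_state(config: RunConfig) -> InitialState:
    masses = dry_mass_scenarios(config.ledger)
    if config.scenario not in masses:
        raise ValueError(
            f"unknown scenario {config.scenario!r}; choose from {sorted(masses)}"
        )
    return initial_concentrations(config.ledger, masses[config.scenario], config.xw0)


def _fit_result_jsonable(result: FitResult, config: RunConfig) -> dict[str, Any]:
    return {
        "params": _to_jsonable(result.params),
        "keq": result.params.keq,
        "F": result.F,
        "iterations": result.iterations,
        "converged": result.converged,
        "error_measures": result.error_measures,
        "start_F": result.start_F,
        "start_points": [_to_jsonable(p) for p in result.start_points],
        "settings": _to_jsonable(config.fit),
    }


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute charge accounting -> simulation [-> fit] and write artifacts.

    Writes ``initial_state.json`` (the three bounded dry-acid masses and
    the chosen initial concentrations), ``trajectory.csv`` (a forward run
    at ``config.params`` or, after fitting, at the fitted constants),
    ``fit.json`` when a data path is configured, and ``provenance.json``.
    Returns the artifact paths.  A missing data file is reported before
    any integration runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if config.data_path is not None and not Path(config.data_path).exists():
        raise FileNotFoundError(f"configured data_path not found: {config.data_path}")

    init = _stage("init-calc")(build_initial_state)(config)
    p = outdir / "initial_state.json"
    p.write_text(
        json.dumps(
            {
                "dry_mass_scenarios_g": dry_mass_scenarios(config.ledger),
                "scenario": config.scenario,
                "initial_state": _to_jsonable(init),
            },
            indent=2,
            sort_keys=True,
        )
    )
    artifacts["initial_state"] = p
    log.info("initial state written to %s", p)

    fit_result: FitResult | None = None
    if config.data_path is not None:
        data = _stage("read-data")(read_gpc_table)(config.data_path)
        fit_result = _stage("fit")(fit)(data, init, config.fit)
        p = outdir / "fit.json"
        p.write_text(json.dumps(_fit_result_jsonable(fit_result, config),
                                indent=2, sort_keys=True))
        artifacts["fit"] = p
        log.info("fit written to %s (F=%.4g)", p, fit_result.F)

    params = fit_result.params if fit_result is not None else config.params
    if params is not None:
        times = np.arange(1.0, config.sim_hours + 1e-9, 1.0) * 3600.0
        traj = _stage("simulate")(simulate)(
            params, init, config.integrator, times, config.corrected
        )
        p = outdir / "trajectory.csv"
        traj.to_frame().to_csv(p, index=False)
        artifacts["trajectory"] = p
        log.info("trajectory written to %s (stable=%s)", p, traj.stable)

    p = outdir / "provenance.json"
    p.write_text(
        json.dumps(
            {
                "config": _to_jsonable(config),
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "versions": {
                    "placond": __version__,
                    "numpy": np.__version__,
                    "pandas": pd.__version__,
                },
            },
            indent=2,
            sort_keys=True,
        )
    )
    artifacts["provenance"] = p
    return artifacts
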