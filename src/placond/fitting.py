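"""Least-squares estimation of the rate constants from GPC Mn(t) series.

The objective is the plain sum of squared residuals between modeled and
measured number-average molecular weights,

    F(p) = sum_i ( Mn_num(t_i; p) - Mn_exp_i )^2,    p = (k1, k_-1, kw),

minimized with the derivative-free Nelder-Mead simplex.  The search runs
in log10-parameter space — the three constants span orders of magnitude
and must stay positive — from one or more log-uniform random starts.
Trajectories that go unstable under a trial parameter set return a large
penalty (a multiplier on the worst finite objective seen so far) instead
of raising, so the simplex simply walks away from them.

Two structural facts about this problem, both probed by
:func:`degeneracy_scan`:

* scaling ``k1`` and ``k_-1`` by a common factor leaves the trajectory —
  hence F — nearly unchanged over orders of magnitude, because the
  reaction stays in quasi-equilibrium and the water-removal term alone
  drives the slow dynamics; only the equilibrium constant
  ``keq = k1/k_-1`` (and ``kw``) is identified, and fitted ``k1``/``k_-1``
  values are upper bounds along that ray;
* *non*-uniform scaling changes keq and wrecks the long-time Mn
  prediction, inflating F sharply — F is dominated by the high-molecular-
  weight points.

Observation times are stored in hours, as chromatography series are
reported, and converted to seconds internally; mixing the two units would
alias a factor 3600 into the rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .condensed import KineticParameters, simulate
from .integrator import IntegratorSettings
from .mass_balance import InitialState

__all__ = [
    "GPCDataset",
    "FitSettings",
    "FitResult",
    "objective",
    "error_measures",
    "fit",
    "degeneracy_scan",
]

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class GPCDataset:
    """Observed (time, Mn[, Mw]) records from chromatography aliquots.

    Times in hours, molecular weights in Da.  ``mw`` entries may be NaN
    where only Mn was read off; where both are present the dispersity
    Mw/Mn must be >= 1 (and match any explicitly provided dispersity to
    within 1%).
    """

    time_h: np.ndarray
    mn: np.ndarray
    mw: np.ndarray | None = None
    dispersity: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        mn = np.asarray(self.mn, dtype=float)
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "mn", mn)
        if t.ndim != 1 or t.size == 0 or mn.shape != t.shape:
            raise ValueError("time_h and mn must be equal-length 1-D arrays")
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            raise ValueError("times must be finite and nonnegative")
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValueError(f"times must be strictly increasing (row {bad[0] + 1})")
        bad = np.flatnonzero(~(mn > 0))
        if bad.size:
            raise ValueError(f"Mn must be strictly positive (row {bad[0]})")
        if self.mw is not None:
            mw = np.asarray(self.mw, dtype=float)
            object.__setattr__(self, "mw", mw)
            if mw.shape != t.shape:
                raise ValueError("mw must match time_h in length")
            have = np.isfinite(mw)
            bad = np.flatnonzero(have & (mw < mn))
            if bad.size:
                raise ValueError(
                    f"Mw < Mn (dispersity below 1) at row {bad[0]}"
                )
            if self.dispersity is not None:
                d = np.asarray(self.dispersity, dtype=float)
                object.__setattr__(self, "dispersity", d)
                both = have & np.isfinite(d)
                if np.any(np.abs(mw[both] / mn[both] - d[both]) > 0.01 * d[both]):
                    raise ValueError("dispersity inconsistent with Mw/Mn beyond 1%")

    def __len__(self) -> int:
        return int(self.time_h.size)

    @property
    def time_s(self) -> np.ndarray:
        return self.time_h * SECONDS_PER_HOUR


@dataclass(frozen=True)
class FitSettings:
    """Knobs of the simplex search.

    Starts are drawn log-uniformly over ``(k1, keq, kw)`` ranges (keq
    rather than ``k_-1`` because keq is the identified combination);
    ``penalty_mult`` scales the instability penalty; convergence uses an
    absolute function tolerance ``fatol_rel * (1 + F_baseline)`` where the
    baseline is ``sum Mn_exp^2``.
    """

    n_starts: int = 5
    seed: int = 0
    maxiter: int = 2000
    fatol_rel: float = 1e-8
    xatol: float = 1e-6
    penalty_mult: float = 1e6
    corrected: bool = False
    k1_range: tuple[float, float] = (1e-2, 1e2)
    keq_range: tuple[float, float] = (10.0, 1e4)
    kw_range: tuple[float, float] = (1e-6, 1e-2)
    bounded: bool = True
    integrator: IntegratorSettings = field(default_factory=IntegratorSettings)
    start_params: KineticParameters | None = None

    def bounds_log10(self) -> list[tuple[float, float]] | None:
        """Log10 box implied by the start ranges (k_-1 from k1/keq), or
        None when ``bounded`` is off.  Keeping the simplex inside the box
        excludes corners where the quasi-equilibrium reading of the model
        breaks down and only the penalty plateau remains."""
        if not self.bounded:
            return None
        import math

        return [
            (math.log10(self.k1_range[0]), math.log10(self.k1_range[1])),
            (
                math.log10(self.k1_range[0] / self.keq_range[1]),
                math.log10(self.k1_range[1] / self.keq_range[0]),
            ),
            (math.log10(self.kw_range[0]), math.log10(self.kw_range[1])),
        ]


@dataclass
class FitResult:
    """Best parameter set found across starts, with diagnostics."""

    params: KineticParameters
    F: float
    iterations: int
    converged: bool
    error_measures: dict[str, float]
    start_points: list[KineticParameters]
    start_F: list[float]
    message: str = ""

    @property
    def keq(self) -> float:
        return self.params.keq


def _model_mn(
    params: KineticParameters,
    data: GPCDataset,
    init: InitialState,
    settings: IntegratorSettings,
    corrected: bool,
):
    traj = simulate(params, init, settings, sample_times=data.time_s,
                    corrected=corrected)
    return traj.mn, traj.stable


def objective(
    params: KineticParameters,
    data: GPCDataset,
    init: InitialState,
    settings: IntegratorSettings | None = None,
    corrected: bool = False,
    penalty: float | None = None,
) -> float:
    """Sum of squared Mn residuals (Da^2); ``penalty`` returned if unstable.

    With the default ``penalty=None`` an unstable trajectory returns
    ``1e6 * sum(Mn_exp^2)``, the same baseline the fitter starts from.
    """
    settings = settings or IntegratorSettings()
    mn, stable = _model_mn(params, data, init, settings, corrected)
    if not stable or not np.all(np.isfinite(mn)):
        if penalty is None:
            penalty = 1e6 * float(np.sum(data.mn**2))
        return float(penalty)
    return float(np.sum((mn - data.mn) ** 2))


def error_measures(
    params: KineticParameters,
    data: GPCDataset,
    init: InitialState,
    settings: IntegratorSettings | None = None,
    corrected: bool = False,
) -> dict[str, float]:
    """The three goodness measures: ``sse`` (= F, Da^2), ``sse_frac``
    (sum of squared fractional residuals) and ``sad_frac`` (sum of absolute
    fractional residuals).  NaN entries signal an unstable trajectory."""
    settings = settings or IntegratorSettings()
    mn, stable = _model_mn(params, data, init, settings, corrected)
    if not stable or not np.all(np.isfinite(mn)):
        return {"sse": float("nan"), "sse_frac": float("nan"),
                "sad_frac": float("nan")}
    res = mn - data.mn
    frac = res / data.mn
    return {
        "sse": float(np.sum(res**2)),
        "sse_frac": float(np.sum(frac**2)),
        "sad_frac": float(np.sum(np.abs(frac))),
    }


def _draw_starts(settings: FitSettings) -> list[KineticParameters]:
    rng = np.random.default_rng(settings.seed)
    starts: list[KineticParameters] = []
    if settings.start_params is not None:
        starts.append(settings.start_params)
    lo = np.log10([settings.k1_range[0], settings.keq_range[0], settings.kw_range[0]])
    hi = np.log10([settings.k1_range[1], settings.keq_range[1], settings.kw_range[1]])
    while len(starts) < settings.n_starts:
        u = rng.uniform(lo, hi)
        k1, keq, kw = 10.0 ** u
        starts.append(KineticParameters(k1=k1, k_neg1=k1 / keq, kw=kw))
    return starts


def fit(
    data: GPCDataset,
    init: InitialState,
    settings: FitSettings | None = None,
) -> FitResult:
    """Estimate ``(k1, k_-1, kw)`` by multi-start Nelder-Mead least squares.

    Each start runs an independent simplex in log10 space; the best final
    vertex wins.  Fully deterministic for a fixed ``settings.seed``.
    Raises ``RuntimeError`` only if every start ends on the instability
    penalty plateau (no finite objective anywhere).
    """
    settings = settings or FitSettings()
    baseline = float(np.sum(data.mn**2))
    worst_finite = baseline

    variant = (settings.start_params is not None
               and settings.start_params.variant_enabled)
    template = settings.start_params or KineticParameters(1.0, 1.0, 0.0)

    def make_params(x: np.ndarray) -> KineticParameters:
        k1, kneg1, kw = 10.0 ** np.asarray(x, dtype=float)
        return replace(template, k1=k1, k_neg1=kneg1, kw=kw)

    def fun(x: np.ndarray) -> float:
        nonlocal worst_finite
        f = objective(
            make_params(x), data, init, settings.integrator,
            corrected=settings.corrected,
            penalty=settings.penalty_mult * worst_finite,
        )
        if f < settings.penalty_mult * baseline and np.isfinite(f):
            worst_finite = max(worst_finite, f)
        return f

    fatol = settings.fatol_rel * (1.0 + baseline)
    starts = _draw_starts(settings)
    bounds = settings.bounds_log10()
    best = None
    start_F: list[float] = []
    for p0 in starts:
        x0 = np.log10([p0.k1, p0.k_neg1, p0.kw if p0.kw > 0 else 1e-12])
        if bounds is not None:
            x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            fun,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "maxiter": settings.maxiter,
                "fatol": fatol,
                "xatol": settings.xatol,
            },
        )
        start_F.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    params = make_params(best.x)
    F = objective(params, data, init, settings.integrator,
                  corrected=settings.corrected)
    if not np.isfinite(F) or F >= settings.penalty_mult * baseline:
        raise RuntimeError(
            "all simplex starts ended on the instability penalty plateau; "
            f"start objectives: {start_F}"
        )
    if variant:
        params = replace(params, variant_enabled=True)
    return FitResult(
        params=params,
        F=F,
        iterations=int(best.nit),
        converged=bool(best.success),
        error_measures=error_measures(
            params, data, init, settings.integrator, corrected=settings.corrected
        ),
        start_points=starts,
        start_F=start_F,
        message=str(best.message),
    )


def degeneracy_scan(
    params: KineticParameters,
    data: GPCDataset,
    init: InitialState,
    factors: list[tuple[float, float]],
    settings: IntegratorSettings | None = None,
    corrected: bool = False,
) -> pd.DataFrame:
    """Error measures at scaled rate constants.

    ``factors`` holds ``(factor_k1, factor_kneg1)`` pairs; equal factors
    probe the uniform-scaling ray along which only keq matters, unequal
    ones change keq and the long-time prediction.  Returns a DataFrame
    with columns factor_k1, factor_kneg1, F, sse_frac, sad_frac.
    """
    rows = []
    for f1, f2 in factors:
        if f1 <= 0 or f2 <= 0:
            raise ValueError("scale factors must be positive")
        scaled = replace(params, k1=params.k1 * f1, k_neg1=params.k_neg1 * f2)
        m = error_measures(scaled, data, init, settings, corrected=corrected)
        rows.append(
            {
                "factor_k1": f1,
                "factor_kneg1": f2,
                "F": m["sse"],
                "sse_frac": m["sse_frac"],
                "sad_frac": m["sad_frac"],
            }
        )
    return pd.DataFrame(rows)
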