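"""Condensed reversible step-growth model in reacting-bond concentrations.

Step-growth polycondensation of a hydroxy acid,

    HO-R_i-COOH + HO-R_j-COOH  <-->  HO-R_{i+j}-COOH + H2O,

is re-read as a reaction between *bonds* rather than molecules: each chain
carries one hydroxyl-side bond pair (concentration ``a``) and one
carboxyl-side pair (identical concentration, ``b = a``), each ester linkage
is a ``c`` bond, and water is the ``w`` "bond".  Because the rate constants
are assumed independent of chain length, the whole population balance
collapses to three ODEs:

    dc/dt = k1 a^2 - k_-1 c w
    da/dt = -dc/dt
    dw/dt = dc/dt - kw * xw,      xw = w / (2a + c + w + S + C)

where ``k1`` and ``k_-1`` are the polymerization and depolymerization rate
constants (L mol^-1 s^-1, moles counting bonds), ``kw`` (mol L^-1 s^-1) the
effective water-removal coefficient of the azeotropic drying loop — the
removal rate is ``kw`` times the liquid water mole fraction — and ``S``,
``C`` the constant solvent and catalyst concentrations.

Since ``c/a`` is the number-average degree of polymerization, the model
yields the number-average molecular weight directly,

    Mn(t) = (c/a) * FW_mono,

at the cost of giving up the molecular-weight distribution and the
weight average (see :mod:`placond.chain` for the resolved model).  As
written the estimator undercounts by one repeat unit — a monomer has one
chain-end pair and zero esters — so a corrected mode returning
``(c/a + 1) * FW_mono`` is available; the default reproduces the plain
``c/a`` form.

An optional stepwise variant emulates entanglement-limited mobility:
whenever the running Mn exceeds ``me_threshold`` (~9000 g/mol for
poly(L-lactic acid)) the polymerization constant is multiplied by
``k1_reduction_factor`` (default 10-fold decrease), evaluated per step with
no hysteresis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import condensed_euler
from .integrator import IntegratorSettings
from .mass_balance import FW_MONO, InitialState

__all__ = [
    "KineticParameters",
    "MixtureState",
    "Trajectory",
    "ZeroChainEndsError",
    "water_mole_fraction",
    "rhs",
    "number_average_mw",
    "analytic_zero_water",
    "equilibrium_dp",
    "simulate",
]


class ZeroChainEndsError(ZeroDivisionError):
    """Raised when Mn is requested for a state with no chain-end bonds."""


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the condensed model.

    ``k1``/``k_neg1`` in L mol^-1 s^-1 (bond-counting moles), ``kw`` in
    mol L^-1 s^-1 (removal rate = ``kw * xw``; the printed optimal values
    carry no units, but dimensional analysis of the water balance fixes
    them).  The stepwise entanglement variant is off by default.
    """

    k1: float
    k_neg1: float
    kw: float
    me_threshold: float = 9000.0
    k1_reduction_factor: float = 0.1
    variant_enabled: bool = False

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k_neg1 <= 0:
            raise ValueError("k1 and k_neg1 must be strictly positive")
        if self.kw < 0:
            raise ValueError("kw must be nonnegative")
        if self.k1_reduction_factor <= 0:
            raise ValueError("k1_reduction_factor must be positive")
        if self.me_threshold <= 0:
            raise ValueError("me_threshold must be positive")

    @property
    def keq(self) -> float:
        """Equilibrium constant k1 / k_-1."""
        return self.k1 / self.k_neg1


@dataclass(frozen=True)
class MixtureState:
    """Condensed bond concentrations (mol/L) at time ``t`` (s)."""

    t: float
    a: float
    c: float
    w: float
    S: float
    C: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.c < 0 or self.w < 0:
            raise ValueError("concentrations must be nonnegative")
        if self.S < 0 or self.C < 0:
            raise ValueError("S and C must be nonnegative")


def _initial_mixture(init: InitialState) -> MixtureState:
    return MixtureState(t=0.0, a=init.a0, c=init.c0, w=init.w0, S=init.S, C=init.C)


def water_mole_fraction(state: MixtureState) -> float:
    """Liquid water mole fraction, ``w / (2a + c + w + S + C)``.

    The denominator counts bonds the way the condensed model does; the
    chain-resolved model counts molecules instead (denominator
    ``S + C + sum(P_i) + W``), and the two conventions differ by the total
    repeat-unit concentration.  Each model uses its own form.
    """
    denom = 2.0 * state.a + state.c + state.w + state.S + state.C
    if denom <= 0:
        raise ValueError("mole-fraction denominator must be positive")
    return state.w / denom


def rhs(
    state: MixtureState, params: KineticParameters, fw_mono: float = FW_MONO
) -> tuple[float, float, float]:
    """Time derivatives ``(dc/dt, da/dt, dw/dt)`` in mol L^-1 s^-1.

    ``da/dt = -dc/dt`` identically (every ester formed consumes one bond
    pair), so ``a + c`` is a conserved quantity of the reaction part;
    ``dw/dt`` additionally loses ``kw * xw`` to the vapor.
    """
    k1 = params.k1
    if (
        params.variant_enabled
        and state.a > 0.0
        and (state.c / state.a) * fw_mono > params.me_threshold
    ):
        k1 = k1 * params.k1_reduction_factor
    r = k1 * state.a * state.a - params.k_neg1 * state.c * state.w
    dw = r - params.kw * water_mole_fraction(state)
    return r, -r, dw


def number_average_mw(
    state: MixtureState, fw_mono: float = FW_MONO, corrected: bool = False
) -> float:
    """Number-average molecular weight ``(c/a) * fw_mono`` (Da).

    With ``corrected=True`` returns ``(c/a + 1) * fw_mono``, which counts
    the end monomer a chain's ester bonds miss.
    """
    if state.a <= 0:
        raise ZeroChainEndsError("Mn undefined: no chain-end bonds (a = 0)")
    dp = state.c / state.a
    if corrected:
        dp += 1.0
    return dp * fw_mono


def analytic_zero_water(
    a_start: float, k1: float, tau: float, fw_mono: float = FW_MONO
) -> tuple[float, float, float]:
    """Closed-form irreversible limit once water is depleted.

    With ``w = 0`` the system reduces to ``da/dt = -k1 a^2``, giving

        a(tau) = a_start / (1 + k1 a_start tau),
        c(tau) = a_start - a(tau),
        Mn(tau) = fw_mono * k1 * a_start * tau,

    i.e. the number-average molecular weight grows *linearly* in time — the
    long-run regime once the drying loop has stripped the water out.
    ``tau`` is measured from the moment water became negligible and
    ``a_start`` is the chain-end concentration at that moment.
    """
    if a_start <= 0:
        raise ValueError("a_start must be positive")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    a = a_start / (1.0 + k1 * a_start * tau)
    c = a_start - a
    mn = fw_mono * k1 * a_start * tau
    return a, c, mn


def equilibrium_dp(params: KineticParameters) -> float:
    """Early quasi-equilibrium degree of polymerization, ``sqrt(k1/k_-1)``.

    Before any appreciable water removal the water produced equals the
    ester bonds formed (``w ~ c``), so the balance ``k1 a^2 = k_-1 c w``
    pins ``c/a`` at ``sqrt(keq)`` — the plateau the mixture jumps to within
    the first moments of reaction.
    """
    return float(np.sqrt(params.keq))


@dataclass
class Trajectory:
    """Condensed-model trajectory sampled at requested times.

    ``t`` holds the requested sample times (s); ``step_times`` the end of
    the Euler step that produced each record; ``mn`` is NaN wherever the
    run went unstable before the sample.
    """

    t: np.ndarray
    a: np.ndarray
    c: np.ndarray
    w: np.ndarray
    xw: np.ndarray
    mn: np.ndarray
    step_times: np.ndarray
    stable: bool
    n_steps: int
    n_clamped: int
    n_floored: int
    S: float
    C: float
    fw_mono: float
    corrected: bool
    a0: float = 0.0
    c0: float = 0.0
    w0: float = 0.0

    @property
    def removed_water(self) -> np.ndarray:
        """Cumulative water stripped to the vapor, ``(c - w) - (c0 - w0)`` (mol/L)."""
        return (self.c - self.w) - (self.c0 - self.w0)

    def to_frame(self):
        """Tabular export (time_s, a, c, w, xw, Mn_Da)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.t,
                "a_mol_L": self.a,
                "c_mol_L": self.c,
                "w_mol_L": self.w,
                "xw": self.xw,
                "Mn_Da": self.mn,
            }
        )


def simulate(
    params: KineticParameters,
    init: InitialState | MixtureState,
    settings: IntegratorSettings | None = None,
    sample_times: np.ndarray | None = None,
    corrected: bool = False,
) -> Trajectory:
    """Integrate the condensed model and sample it.

    ``sample_times`` are in seconds; by default the run spans
    ``settings.t_end`` sampled hourly.  The heavy loop runs compiled
    (see :mod:`placond._kernels`); unstable runs come back flagged with
    NaN tails rather than raising, because the fitting penalty path needs
    them.
    """
    settings = settings or IntegratorSettings()
    if isinstance(init, InitialState):
        state0 = _initial_mixture(init)
        fw = init.fw_mono
    else:
        state0 = init
        fw = FW_MONO
    if sample_times is None:
        sample_times = np.arange(3600.0, settings.t_end + 1.0, 3600.0)
    times = np.ascontiguousarray(np.asarray(sample_times, dtype=float))
    if times.ndim != 1 or times.size == 0:
        raise ValueError("sample_times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample_times must be strictly increasing")
    out, stable, n_steps, n_clamped, n_floored = condensed_euler(
        state0.a,
        state0.c,
        state0.w,
        state0.S,
        state0.C,
        params.k1,
        params.k_neg1,
        params.kw,
        fw,
        params.variant_enabled,
        params.me_threshold,
        params.k1_reduction_factor,
        settings.base_step,
        settings.frac_threshold,
        settings.h_min,
        settings.abs_floor,
        settings.max_steps,
        times,
    )
    a, c, w, step_t = out[:, 0], out[:, 1], out[:, 2], out[:, 3]
    with np.errstate(invalid="ignore", divide="ignore"):
        xw = w / (2.0 * a + c + w + state0.S + state0.C)
        dp = c / a
        if corrected:
            dp = dp + 1.0
        mn = dp * fw
    return Trajectory(
        t=times,
        a=a,
        c=c,
        w=w,
        xw=xw,
        mn=mn,
        step_times=step_t,
        stable=bool(stable),
        n_steps=int(n_steps),
        n_clamped=int(n_clamped),
        n_floored=int(n_floored),
        S=state0.S,
        C=state0.C,
        fw_mono=fw,
        corrected=corrected,
        a0=state0.a,
        c0=state0.c,
        w0=state0.w,
    )
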