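"""Three-state (N <-> I <-> U) chemical denaturation of a beta-barrel.

The observed (normalized) fluorescence of a GdnHCl titration is a
population-weighted average of three linear state baselines:

    Y_obs = (Y_N + Y_I K_NI + Y_U K_NI K_IU) / (1 + K_NI + K_NI K_IU)

with Y_X = I_X + S_X [D].  Each transition free energy is linear in
denaturant (linear extrapolation / m-value model); the equilibrium
constants are unfolding constants

    K = exp(-(dG_unf - m [D]) / RT),   dG_unf = |dG| > 0,

so K = 1 at the midpoint C_m = dG_unf/m and K << 1 at [D] = 0 for a
stable protein.  Transition free energies are reported on the folding
sign convention (negative for a stable protein), with the unfolded
state U as the zero of the free-energy landscape.

Evaluation is overflow-safe (populations via a log-sum-exp softmax), so
exponents of hundreds of RT are fine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.special import softmax

from .errors import DomainError, FitConvergenceError, FitDiagnosticError, InputError
from .thermo import DENATURATION_CONTEXT, ThermoContext

__all__ = [
    "DenaturantTitration",
    "ThreeStateParams",
    "StatePopulations",
    "LandscapeSummary",
    "equilibrium_constants",
    "predict_observable",
    "fit_three_state",
    "landscape_summary",
]

# fixed m values from prior global fitting, kcal/mol/M (DC12PC mode)
DC12PC_FIXED_M = (2.0, 7.2)


@dataclass
class DenaturantTitration:
    """GdnHCl concentration (M) vs normalized fluorescence."""

    denaturant: np.ndarray
    signal: np.ndarray
    direction: str = "pooled"   # "folding", "unfolding" or "pooled"

    def __post_init__(self):
        self.denaturant = np.asarray(self.denaturant, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.denaturant.shape != self.signal.shape:
            raise InputError("denaturant and signal must have equal length")
        if self.denaturant.size < 8:
            raise InputError("a titration needs at least 8 points")
        if np.any(self.denaturant < 0):
            raise InputError("denaturant concentrations must be >= 0")
        if self.direction not in ("folding", "unfolding", "pooled"):
            raise InputError(f"unknown direction {self.direction!r}")


@dataclass
class ThreeStateParams:
    """Two transition free energies, two m-values, three linear baselines.

    ``dg_ni`` and ``dg_iu`` follow the folding convention (negative for
    stable transitions); their magnitudes enter the unfolding equilibrium
    constants.  ``baselines`` maps state -> (intercept I_X, slope S_X).
    """

    dg_ni: float              # kcal/mol
    dg_iu: float              # kcal/mol
    m_ni: float               # kcal/mol/M
    m_iu: float               # kcal/mol/M
    baselines: dict = field(default_factory=lambda: {
        "N": (0.0, 0.0), "I": (0.5, 0.0), "U": (1.0, 0.0)})
    m_fixed: tuple = (False, False)
    standard_errors: dict = field(default_factory=dict)
    sse: float | None = None

    def __post_init__(self):
        if not (self.m_ni > 0 and self.m_iu > 0):
            raise DomainError("m values must be > 0")
        for state in ("N", "I", "U"):
            if state not in self.baselines:
                raise InputError(f"missing baseline for state {state}")

    @property
    def midpoints(self):
        """(C_m(N-I), C_m(I-U)) in M."""
        return abs(self.dg_ni) / self.m_ni, abs(self.dg_iu) / self.m_iu


@dataclass
class StatePopulations:
    """Per-point fractional populations; each row sums to 1."""

    f_n: np.ndarray
    f_i: np.ndarray
    f_u: np.ndarray


@dataclass
class LandscapeSummary:
    """State free-energy levels relative to U, midpoints, total dG."""

    levels: dict              # {"U": 0, "I": dg_iu, "N": dg_ni + dg_iu}
    midpoints: tuple          # M
    total_dg: float           # kcal/mol, N relative to U


def _log_equilibrium_constants(params: ThreeStateParams, d, context):
    d = np.asarray(d, dtype=float)
    rt = context.rt
    ln_k_ni = -(abs(params.dg_ni) - params.m_ni * d) / rt
    ln_k_iu = -(abs(params.dg_iu) - params.m_iu * d) / rt
    return ln_k_ni, ln_k_iu


def equilibrium_constants(params: ThreeStateParams, d,
                          context: ThermoContext = DENATURATION_CONTEXT):
    """(K_NI, K_IU) at denaturant concentration(s) d (monotone increasing)."""
    ln_ni, ln_iu = _log_equilibrium_constants(params, d, context)
    return np.exp(ln_ni), np.exp(ln_iu)


def predict_observable(params: ThreeStateParams, d,
                       context: ThermoContext = DENATURATION_CONTEXT):
    """(Y_obs array, StatePopulations) at denaturant concentrations d.

    Computed via a softmax over the log-populations, so arbitrarily
    large |exponents| cannot overflow.
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    ln_ni, ln_iu = _log_equilibrium_constants(params, d, context)
    # log-weights of N, I, U relative to N
    logw = np.stack([np.zeros_like(d), ln_ni, ln_ni + ln_iu], axis=1)
    pops = softmax(logw, axis=1)
    baselines = np.stack([
        params.baselines[s][0] + params.baselines[s][1] * d
        for s in ("N", "I", "U")
    ], axis=1)
    y = np.sum(pops * baselines, axis=1)
    return y, StatePopulations(f_n=pops[:, 0], f_i=pops[:, 1], f_u=pops[:, 2])


def landscape_summary(params: ThreeStateParams) -> LandscapeSummary:
    """Free-energy landscape with U as the reference state.

    Levels: U = 0, I = dg_iu, N = dg_ni + dg_iu (negative below U for a
    stable protein); total dG is the N level.
    """
    levels = {"U": 0.0, "I": params.dg_iu, "N": params.dg_ni + params.dg_iu}
    return LandscapeSummary(levels=levels, midpoints=params.midpoints,
                            total_dg=levels["N"])


def fit_three_state(
    titration: DenaturantTitration,
    init: dict | None = None,
    fixed_m: tuple | None = None,
    context: ThermoContext = DENATURATION_CONTEXT,
    flat_baselines: bool = False,
) -> ThreeStateParams:
    """Least-squares fit of the three-state model to a titration.

    ``fixed_m`` pins (m_NI, m_IU) (the workflow for a lipid where m
    values were determined by prior global fitting); otherwise both m
    values float.  Folding- and unfolding-direction points are pooled.
    Raises :class:`FitDiagnosticError` when the titration cannot resolve
    the intermediate (suggesting a two-state treatment) instead of
    silently switching models.
    """
    d, y = titration.denaturant, titration.signal
    init = dict(init or {})

    params = lmfit.Parameters()
    params.add("dgu_ni", value=init.get("dgu_ni", 5.0), min=1e-3)
    params.add("dgu_iu", value=init.get("dgu_iu", 25.0), min=1e-3)
    if fixed_m is not None:
        m_ni0, m_iu0 = fixed_m
        params.add("m_ni", value=float(m_ni0), vary=False)
        params.add("m_iu", value=float(m_iu0), vary=False)
    else:
        params.add("m_ni", value=init.get("m_ni", 2.0), min=1e-3)
        params.add("m_iu", value=init.get("m_iu", 7.0), min=1e-3)

    lo = y[np.argmin(d)]
    hi = y[np.argmax(d)]
    defaults = {"i_n": lo, "i_i": 0.5 * (lo + hi), "i_u": hi,
                "s_n": 0.0, "s_i": 0.0, "s_u": 0.0}
    for name in ("i_n", "i_i", "i_u"):
        params.add(name, value=init.get(name, defaults[name]))
    for name in ("s_n", "s_i", "s_u"):
        params.add(name, value=init.get(name, 0.0), vary=not flat_baselines)

    def build(p):
        return ThreeStateParams(
            dg_ni=-p["dgu_ni"].value, dg_iu=-p["dgu_iu"].value,
            m_ni=p["m_ni"].value, m_iu=p["m_iu"].value,
            baselines={
                "N": (p["i_n"].value, p["s_n"].value),
                "I": (p["i_i"].value, p["s_i"].value),
                "U": (p["i_u"].value, p["s_u"].value),
            },
            m_fixed=(fixed_m is not None, fixed_m is not None),
        )

    def residual(p):
        pred, _ = predict_observable(build(p), d, context)
        return pred - y

    n_free = sum(1 for p in params.values() if p.vary)
    if y.size < n_free + 2:
        raise InputError(f"need at least {n_free + 2} points for {n_free} parameters")

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise FitConvergenceError(
            f"three-state fit did not converge: {result.message}",
            best_params={k: v.value for k, v in result.params.items()})

    fitted = build(result.params)
    mid_ni, mid_iu = fitted.midpoints
    if d.min() > max(mid_ni, mid_iu):
        raise FitDiagnosticError(
            "titration covers only denaturant above both fitted midpoints; "
            "the transitions are not sampled -- collect lower [D] or treat "
            "the data as baseline-only",
            best_params=fitted)
    _, pops = predict_observable(fitted, np.linspace(d.min(), d.max(), 201),
                                 context)
    if pops.f_i.max() < 0.05:
        raise FitDiagnosticError(
            "intermediate never exceeds 5% population over the fitted range; "
            "transitions appear merged -- consider a two-state model",
            best_params=fitted)

    def se(name):
        stderr = result.params[name].stderr
        return float(stderr) if stderr is not None else math.nan

    fitted.standard_errors = {
        "dg_ni": se("dgu_ni"), "dg_iu": se("dgu_iu"),
        "m_ni": se("m_ni") if fixed_m is None else 0.0,
        "m_iu": se("m_iu") if fixed_m is None else 0.0,
        "i_n": se("i_n"), "i_i": se("i_i"), "i_u": se("i_u"),
        "s_n": se("s_n"), "s_i": se("s_i"), "s_u": se("s_u"),
    }
    fitted.sse = float(np.sum(np.asarray(result.residual) ** 2))
    return fitted
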