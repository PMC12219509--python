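"""Steric-trapping binding models for membrane-protein stability.

The steric-trapping assay doubly biotinylates a membrane protein at two
residues that are close in the native fold.  A first monovalent
streptavidin (mSA) binds a biotin tag unhindered; the second can bind
only when the tertiary contacts between the tags are transiently lost,
so attenuation of the second binding phase encodes the denaturation
equilibrium constant K_D and hence the folding free energy
dG_ND = -RT ln(1/K_D) = RT ln K_D (negative for a stable protein).

Three isotherm models are implemented:

* first binding  -- quadratic tight-binding of mSA to a biotin tag,
* competition    -- displacement of a labelled mSA by an unlabelled one
  (implemented exactly as published; an exact coupled-equilibria solver
  ships alongside as a diagnostic oracle),
* second binding -- the attenuated second phase whose midpoint shifts by
  the factor (1 + 1/K_D).

A bounded least-squares front end (`fit_binding_model`) fits any of the
three, with positivity-constrained scale parameters handled as natural
logs and asymptotic standard errors mapped back by the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, FitConvergenceError, InputError
from .thermo import ROOM_CONTEXT, ThermoContext

__all__ = [
    "BindingTitration",
    "CompetitionTitration",
    "FirstBindingFit",
    "CompetitionFit",
    "SecondBindingFit",
    "StabilityRecord",
    "eval_first_binding",
    "eval_competition",
    "eval_second_binding",
    "fit_binding_model",
    "dg_from_kd",
    "kd_from_dg",
    "ddg_wt_minus_mut",
    "stability_difference",
    "single_site_bound_fraction",
    "competition_equilibrium_fraction",
    "compare_competition_to_equilibrium",
]


# ---------------------------------------------------------------------------
# domain types

@dataclass
class BindingTitration:
    """A (total mSA, fluorescence) titration at fixed total protein P_T.

    Concentrations in uM, signal in arbitrary units.
    """

    msa_total: np.ndarray
    signal: np.ndarray
    protein_total: float
    label: str = ""

    def __post_init__(self):
        self.msa_total = np.asarray(self.msa_total, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.msa_total.shape != self.signal.shape:
            raise InputError("msa_total and signal must have equal length")
        if self.msa_total.size < 4:
            raise InputError("a titration needs at least 4 points")
        if np.any(self.msa_total < 0):
            raise InputError("concentrations must be >= 0")
        if not self.protein_total > 0:
            raise InputError("protein_total must be > 0")


@dataclass
class CompetitionTitration:
    """Unlabelled-mSA displacement series against a pre-bound labelled mSA."""

    competitor_total: np.ndarray
    labeled_total: float
    protein_total: float
    signal: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.competitor_total = np.asarray(self.competitor_total, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.competitor_total.shape != self.signal.shape:
            raise InputError("competitor_total and signal must have equal length")
        if self.competitor_total.size < 4:
            raise InputError("a titration needs at least 4 points")
        if self.labeled_total < self.protein_total:
            raise InputError("labeled_total (C_T) must be >= protein_total (P_T)")


@dataclass
class FirstBindingFit:
    """Parameters of the quadratic tight-binding isotherm."""

    kd_biotin: float          # uM
    amplitude: float          # A1, total signal change
    offset: float             # A2, signal at zero mSA
    standard_errors: dict = field(default_factory=dict)
    sse: float | None = None

    def __post_init__(self):
        if self.kd_biotin < 0:
            raise DomainError("kd_biotin must be >= 0")


@dataclass
class CompetitionFit:
    """Parameters of the published competition isotherm."""

    k_ratio: float            # K_unlabel / K_label, dimensionless
    amplitude: float
    offset: float
    standard_errors: dict = field(default_factory=dict)
    sse: float | None = None

    def __post_init__(self):
        if not self.k_ratio > 0:
            raise DomainError("k_ratio must be > 0")


@dataclass
class SecondBindingFit:
    """Parameters of the attenuated second-binding phase.

    ``dg_nd`` is the folding free energy RT ln K_D (kcal/mol, negative for
    a stable protein); K_D is the denaturation equilibrium constant.
    """

    k_denat: float            # K_D, dimensionless
    dg_nd: float              # kcal/mol
    f0: float                 # signal plateau at [mSA] -> 0
    f_inf: float              # signal plateau at [mSA] -> inf
    kd_biotin_fixed: float    # uM, held fixed during fitting
    standard_errors: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None
    sse: float | None = None

    def __post_init__(self):
        if not self.k_denat > 0:
            raise DomainError("k_denat (K_D) must be > 0")
        if not (np.isfinite(self.f0) and np.isfinite(self.f_inf)):
            raise InputError("plateaus must be finite")


@dataclass
class StabilityRecord:
    """One fitted folding free energy with its provenance."""

    construct: str            # "N" (95/172 pair) or "C" (172/267 pair)
    mutation: str             # "WT" allowed
    environment: str          # e.g. "micelle", "bicelle q=1.5"
    dg_nd: float              # kcal/mol
    se: float                 # kcal/mol

    def __post_init__(self):
        if self.se < 0:
            raise InputError("standard error must be >= 0")


# ---------------------------------------------------------------------------
# model curves

def _first_binding_curve(msa, p_total, kd, amplitude, offset):
    msa = np.asarray(msa, dtype=float)
    b = p_total + msa + kd
    disc = b * b - 4.0 * p_total * msa
    bound = (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * p_total)
    return amplitude * bound + offset


def eval_first_binding(params: FirstBindingFit, titration: BindingTitration) -> np.ndarray:
    """Quadratic tight-binding isotherm F([mSA]).

    The bound fraction is the exact single-site mass-balance root, so the
    output is bounded between the offset A2 and A2 + A1.
    """
    if params.kd_biotin < 0:
        raise DomainError("kd_biotin must be >= 0")
    if not np.all(np.isfinite(titration.msa_total)):
        raise InputError("titration concentrations must be finite")
    return _first_binding_curve(
        titration.msa_total, titration.protein_total,
        params.kd_biotin, params.amplitude, params.offset,
    )


def _competition_curve(competitor, p_total, c_total, k_ratio, amplitude, offset):
    """The published competition expression, exactly as printed.

    With r = K_unlabel/K_label:
    F = A1 * (-(P_T + [mSA] + r (C_T - P_T))
              + sqrt((P_T + [mSA] + r (C_T - P_T))^2 + 4 P_T [mSA] r))
        / (2 P_T r) + A2
    where [mSA] is the titrated (unlabelled) competitor concentration.
    """
    msa = np.asarray(competitor, dtype=float)
    if p_total == 0:
        raise DomainError("P_T = 0: competition expression undefined")
    b = p_total + msa + k_ratio * (c_total - p_total)
    disc = b * b + 4.0 * p_total * msa * k_ratio
    return amplitude * (-b + np.sqrt(disc)) / (2.0 * p_total * k_ratio) + offset


def eval_competition(
    k_ratio: float,
    titration: CompetitionTitration,
    amplitude: float,
    offset: float,
) -> np.ndarray:
    """Competition isotherm F([competitor]) as published (monotone in competitor)."""
    if not k_ratio > 0:
        raise DomainError("k_ratio must be > 0")
    return _competition_curve(
        titration.competitor_total, titration.protein_total,
        titration.labeled_total, k_ratio, amplitude, offset,
    )


def _second_binding_shifted(msa, shift, f0, f_inf):
    msa = np.asarray(msa, dtype=float)
    out = np.empty_like(msa)
    zero = msa == 0
    # [mSA] -> 0 limit is the F_o plateau; never divide by zero
    out[zero] = f0
    nz = ~zero
    out[nz] = (f_inf - f0) / (1.0 + shift / msa[nz]) + f0
    return out


def _second_binding_curve(msa, kd_biotin, k_denat, f0, f_inf):
    shift = kd_biotin * (1.0 + 1.0 / k_denat)
    return _second_binding_shifted(msa, shift, f0, f_inf)


def eval_second_binding(fit: SecondBindingFit, msa_total) -> np.ndarray:
    """Attenuated second-binding phase.

    Hyperbolic in [mSA] with half-transition at K_d,biotin * (1 + 1/K_D):
    the apparent affinity of the second mSA is weakened by the (small)
    probability of spontaneous denaturation.
    """
    if not fit.k_denat > 0:
        raise DomainError("k_denat must be > 0")
    if not fit.kd_biotin_fixed > 0:
        raise DomainError("kd_biotin_fixed must be > 0")
    return _second_binding_curve(
        msa_total, fit.kd_biotin_fixed, fit.k_denat, fit.f0, fit.f_inf
    )


# ---------------------------------------------------------------------------
# exact equilibrium oracles (diagnostics)

def single_site_bound_fraction(p_total, ligand_total, kd):
    """Exact bound fraction for P + L <-> PL by mass balance (quadratic root)."""
    return _first_binding_curve(ligand_total, p_total, kd, 1.0, 0.0)


def competition_equilibrium_fraction(p_total, labeled_total, competitor_total,
                                     kd_label, kd_unlabel):
    """Exact two-ligand competitive equilibrium, solved numerically.

    P + A <-> PA (Kd = kd_label, total A = labeled_total) competes with
    P + B <-> PB (Kd = kd_unlabel, total B = competitor_total).  Returns
    the fraction of protein bound by the labelled species A.  Serves as
    the independent oracle for the published closed-form competition
    expression; any deviation of that expression is a property of the
    published form and is reported, not corrected.
    """
    competitor_total = np.atleast_1d(np.asarray(competitor_total, dtype=float))

    def free_protein_residual(p_free, b_total):
        a_bound = labeled_total * p_free / (kd_label + p_free)
        b_bound = b_total * p_free / (kd_unlabel + p_free)
        return p_free + a_bound + b_bound - p_total

    out = np.empty_like(competitor_total)
    for i, b_total in enumerate(competitor_total):
        p_free = brentq(free_protein_residual, 0.0, p_total, args=(b_total,),
                        xtol=1e-15, rtol=1e-14)
        out[i] = (labeled_total * p_free / (kd_label + p_free)) / p_total \
            if p_total > 0 else math.nan
    return out


def compare_competition_to_equilibrium(k_ratio, titration: CompetitionTitration,
                                       kd_label=1.0):
    """Diagnostic: published competition curve vs exact equilibrium solver.

    Evaluates the published expression (amplitude 1, offset 0) and the
    exact competitive equilibrium with the same dissociation-constant
    ratio, both on the dequenching scale (fraction of protein *not*
    occupied by the labelled species, which rises 0 -> 1 as the
    competitor displaces it), and returns (published, exact,
    published - exact) arrays.  ``kd_label`` sets the absolute affinity
    scale used by the exact solver.  The published closed form is not an
    exact solution of the coupled equilibria; its systematic deviation
    is what this diagnostic quantifies.
    """
    published = eval_competition(k_ratio, titration, amplitude=1.0, offset=0.0)
    labeled_bound = competition_equilibrium_fraction(
        titration.protein_total, titration.labeled_total,
        titration.competitor_total, kd_label, k_ratio * kd_label,
    )
    exact = 1.0 - labeled_bound
    return published, exact, published - exact


# ---------------------------------------------------------------------------
# free-energy conversions

def dg_from_kd(k_denat: float, context: ThermoContext = ROOM_CONTEXT) -> float:
    """Folding free energy dG_ND = -RT ln(1/K_D) = RT ln K_D (kcal/mol)."""
    if not k_denat > 0:
        raise DomainError("k_denat must be > 0")
    return context.rt * math.log(k_denat)


def kd_from_dg(dg_nd: float, context: ThermoContext = ROOM_CONTEXT) -> float:
    """Inverse of :func:`dg_from_kd`: K_D = exp(dG_ND / RT)."""
    return math.exp(dg_nd / context.rt)


def stability_difference(a: StabilityRecord, b: StabilityRecord):
    """dG_a - dG_b with standard errors combined in quadrature.

    No matching contract: used for cross-environment comparisons such as
    the bicelle-minus-micelle stabilization of one subdomain.
    """
    return a.dg_nd - b.dg_nd, math.hypot(a.se, b.se)


def ddg_wt_minus_mut(wt: StabilityRecord, mut: StabilityRecord):
    """ddG = dG_WT - dG_Mut for one construct in one environment.

    Positive ddG means the mutation destabilized the protein (dG less
    negative).  Records must share construct and environment.
    """
    if wt.construct != mut.construct:
        raise InputError(
            f"construct mismatch: {wt.construct!r} vs {mut.construct!r}")
    if wt.environment != mut.environment:
        raise InputError(
            f"environment mismatch: {wt.environment!r} vs {mut.environment!r}")
    return stability_difference(wt, mut)


# ---------------------------------------------------------------------------
# least-squares front end

def _init_first(data: BindingTitration):
    y = data.signal
    x = data.msa_total
    offset = y[np.argmin(x)]
    amplitude = y[np.argmax(x)] - offset
    # half-transition concentration as a Kd scale guess
    half = offset + 0.5 * amplitude
    idx = int(np.argmin(np.abs(y - half)))
    kd = max(x[idx], 1e-3)
    return {"kd_biotin": kd, "amplitude": amplitude, "offset": offset}


def _init_second(data: BindingTitration, kd_biotin):
    y = data.signal
    x = data.msa_total
    f0 = y[np.argmin(x)]
    f_inf = y[np.argmax(x)]
    half = 0.5 * (f0 + f_inf)
    idx = int(np.argmin(np.abs(y - half)))
    x_half = max(x[idx], kd_biotin * (1 + 1e-6))
    k_denat = 1.0 / max(x_half / kd_biotin - 1.0, 1e-6)
    return {"k_denat": k_denat, "f0": f0, "f_inf": f_inf}


def _init_competition(data: CompetitionTitration):
    y = data.signal
    x = data.competitor_total
    offset = y[np.argmin(x)]
    amplitude = y[np.argmax(x)] - offset
    return {"k_ratio": 1.0, "amplitude": amplitude, "offset": offset}


def fit_binding_model(
    model: str,
    data,
    fixed: dict | None = None,
    init: dict | None = None,
    context: ThermoContext = ROOM_CONTEXT,
):
    """Fit one of the three steric-trapping isotherms by least squares.

    Parameters
    ----------
    model
        ``"first"``, ``"competition"`` or ``"second"``.
    data
        :class:`BindingTitration` (first/second) or
        :class:`CompetitionTitration` (competition).
    fixed
        Parameters held fixed.  The second-binding fit requires
        ``{"kd_biotin": ...}`` -- the unhindered biotin affinity measured
        separately, exactly as in the assay workflow.
    init
        Optional initial guesses overriding the data-driven defaults.

    Returns the matching fit dataclass with asymptotic standard errors
    and the residual sum of squares.  Scale parameters (K_d, K_D,
    k_ratio) are fitted as natural logs so positivity is structural;
    their standard errors are mapped back by the delta method.
    """
    fixed = dict(fixed or {})
    init = dict(init or {})
    if model not in ("first", "competition", "second"):
        raise InputError(f"unknown model {model!r}")

    params = lmfit.Parameters()
    if model == "first":
        if not isinstance(data, BindingTitration):
            raise InputError("model 'first' expects a BindingTitration")
        guesses = {**_init_first(data), **init}
        n_free = 3
        params.add("ln_kd", value=math.log(max(guesses["kd_biotin"], 1e-12)))
        params.add("amplitude", value=guesses["amplitude"])
        params.add("offset", value=guesses["offset"])

        def residual(p):
            return _first_binding_curve(
                data.msa_total, data.protein_total,
                math.exp(p["ln_kd"].value), p["amplitude"].value,
                p["offset"].value) - data.signal

    elif model == "competition":
        if not isinstance(data, CompetitionTitration):
            raise InputError("model 'competition' expects a CompetitionTitration")
        guesses = {**_init_competition(data), **init}
        n_free = 3
        params.add("ln_k_ratio", value=math.log(max(guesses["k_ratio"], 1e-12)))
        params.add("amplitude", value=guesses["amplitude"])
        params.add("offset", value=guesses["offset"])

        def residual(p):
            return _competition_curve(
                data.competitor_total, data.protein_total, data.labeled_total,
                math.exp(p["ln_k_ratio"].value), p["amplitude"].value,
                p["offset"].value) - data.signal

    else:  # second
        if not isinstance(data, BindingTitration):
            raise InputError("model 'second' expects a BindingTitration")
        if "kd_biotin" not in fixed:
            raise InputError(
                "the second-binding fit requires fixed={'kd_biotin': ...} "
                "(the separately measured unhindered biotin affinity)")
        kd_biotin = float(fixed["kd_biotin"])
        if not kd_biotin > 0:
            raise DomainError("fixed kd_biotin must be > 0")
        guesses = {**_init_second(data, kd_biotin), **init}
        n_free = 3
        params.add("ln_k_denat", value=math.log(max(guesses["k_denat"], 1e-300)))
        params.add("f0", value=guesses["f0"])
        params.add("f_inf", value=guesses["f_inf"])

        def residual(p):
            # midpoint shift Kd*(1 + 1/K_D) evaluated from ln K_D directly:
            # immune to exp underflow when the optimizer probes K_D -> 0
            with np.errstate(over="ignore"):
                shift = kd_biotin * (1.0 + np.exp(-p["ln_k_denat"].value))
            return _second_binding_shifted(
                data.msa_total, shift, p["f0"].value,
                p["f_inf"].value) - data.signal

    if data.signal.size < n_free + 2:
        raise InputError(
            f"need at least {n_free + 2} points to fit {n_free} parameters")

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise FitConvergenceError(
            f"binding fit ({model}) did not converge: {result.message}",
            best_params={k: v.value for k, v in result.params.items()})

    sse = float(np.sum(np.asarray(result.residual) ** 2))

    def se(name):
        stderr = result.params[name].stderr
        return float(stderr) if stderr is not None else math.nan

    if model == "first":
        kd = math.exp(result.params["ln_kd"].value)
        return FirstBindingFit(
            kd_biotin=kd,
            amplitude=result.params["amplitude"].value,
            offset=result.params["offset"].value,
            standard_errors={
                "kd_biotin": kd * se("ln_kd"),
                "amplitude": se("amplitude"),
                "offset": se("offset"),
            },
            sse=sse,
        )
    if model == "competition":
        k_ratio = math.exp(result.params["ln_k_ratio"].value)
        return CompetitionFit(
            k_ratio=k_ratio,
            amplitude=result.params["amplitude"].value,
            offset=result.params["offset"].value,
            standard_errors={
                "k_ratio": k_ratio * se("ln_k_ratio"),
                "amplitude": se("amplitude"),
                "offset": se("offset"),
            },
            sse=sse,
        )

    ln_kd_se = se("ln_k_denat")
    ln_kd_val = result.params["ln_k_denat"].value
    # dG straight from ln K_D; clamp K_D itself away from exp underflow
    dg = context.rt * ln_kd_val
    k_denat = math.exp(max(ln_kd_val, -700.0))
    covar = getattr(result, "covar", None)
    return SecondBindingFit(
        k_denat=k_denat,
        dg_nd=dg,
        f0=result.params["f0"].value,
        f_inf=result.params["f_inf"].value,
        kd_biotin_fixed=kd_biotin,
        standard_errors={
            "k_denat": k_denat * ln_kd_se,
            "dg_nd": context.rt * ln_kd_se,
            "f0": se("f0"),
            "f_inf": se("f_inf"),
        },
        covariance=covar,
        sse=sse,
    )
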