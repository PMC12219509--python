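"""Bicelle composition and physical-property estimators.

Bicelles are discoidal bilayer fragments of lipid (e.g. DMPC) rimmed by
detergent (CHAPS or DHPC).  The nominal lipid-to-detergent molar ratio q
overstates the lipid content of the disks because a fixed detergent
concentration -- the critical bicelle concentration (CBC) -- stays in
the aqueous phase:

    q_eff = [lipid]_total / ([detergent]_total - CBC)

Under ideal mixing the CBC itself follows a harmonic mole-fraction
average of the monomer CMCs:

    1/CBC = chi_lipid/CMC_lipid + chi_detergent/CMC_detergent

Physical readouts:

* Laurdan generalized polarization GP = (I440 - I490)/(I440 + I490),
  reporting headgroup packing/hydration;
* the gel-fluid transition temperature Tm, the inflection of a DPH
  anisotropy melting curve fitted to a sigmoid with linearly sloped
  baselines;
* bilayer (headgroup-to-headgroup) thickness L = 2*pi/Q from the second
  maximum of the SAXS profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .errors import DomainError, FitConvergenceError, InputError

__all__ = [
    "AmphiphileMix",
    "MeltingCurve",
    "SigmoidFitResult",
    "EmissionSpectrum",
    "DEFAULT_CBC_MM",
    "DEFAULT_CMC_MM",
    "q_eff_fixed_cbc",
    "cbc_ideal_mixing",
    "gp_laurdan",
    "fit_melting",
    "thickness_from_peak",
]

# experimentally derived detergent CBCs (mM)
DEFAULT_CBC_MM = {"DHPC": 6.5, "CHAPS": 2.5}
# monomer CMCs (mM)
DEFAULT_CMC_MM = {"DMPC": 6e-6, "DHPC": 15.0, "CHAPS": 6.0}


@dataclass
class AmphiphileMix:
    """Total lipid/detergent concentrations (mM) plus critical concentrations."""

    lipid_total: float
    detergent_total: float
    cbc: float | None = None
    cmc_lipid: float | None = None
    cmc_detergent: float | None = None

    def __post_init__(self):
        for name in ("lipid_total", "detergent_total"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        for name in ("cbc", "cmc_lipid", "cmc_detergent"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InputError(f"{name} must be >= 0")


def q_eff_fixed_cbc(mix: AmphiphileMix) -> float:
    """Effective lipid-to-detergent ratio with a fixed aqueous-phase CBC."""
    if mix.cbc is None:
        raise InputError("mix.cbc is required (e.g. DEFAULT_CBC_MM['CHAPS'])")
    denom = mix.detergent_total - mix.cbc
    if denom <= 0:
        raise DomainError(
            "detergent_total must exceed the CBC for a defined q_eff")
    return mix.lipid_total / denom


def cbc_ideal_mixing(mix: AmphiphileMix) -> float:
    """CBC under ideal lipid/detergent mixing (harmonic CMC average)."""
    if mix.cmc_lipid is None or mix.cmc_detergent is None:
        raise InputError("cmc_lipid and cmc_detergent are required")
    if mix.cmc_lipid <= 0 or mix.cmc_detergent <= 0:
        raise DomainError("CMCs must be > 0")
    total = mix.lipid_total + mix.detergent_total
    if total <= 0:
        raise InputError("total amphiphile concentration must be > 0")
    chi_lipid = mix.lipid_total / total
    chi_det = mix.detergent_total / total
    return 1.0 / (chi_lipid / mix.cmc_lipid + chi_det / mix.cmc_detergent)


@dataclass
class EmissionSpectrum:
    """Laurdan emission spectrum (nm, arbitrary intensity units)."""

    wavelength: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength.shape != self.intensity.shape:
            raise InputError("wavelength and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise InputError("intensities must be >= 0")
        lo, hi = self.wavelength.min(), self.wavelength.max()
        if not (lo <= 440.0 <= hi and lo <= 490.0 <= hi):
            raise InputError("spectrum must cover 440 and 490 nm")


def _intensity_at(spectrum: EmissionSpectrum, target_nm: float) -> float:
    # nearest sample within +-1 nm, else linear interpolation
    idx = int(np.argmin(np.abs(spectrum.wavelength - target_nm)))
    if abs(spectrum.wavelength[idx] - target_nm) <= 1.0:
        return float(spectrum.intensity[idx])
    order = np.argsort(spectrum.wavelength)
    return float(np.interp(target_nm, spectrum.wavelength[order],
                           spectrum.intensity[order]))


def gp_laurdan(spectrum: EmissionSpectrum) -> float:
    """Generalized polarization GP = (I440 - I490)/(I440 + I490), in [-1, 1]."""
    i440 = _intensity_at(spectrum, 440.0)
    i490 = _intensity_at(spectrum, 490.0)
    total = i440 + i490
    if total == 0:
        raise DomainError("I440 + I490 = 0: GP undefined")
    return (i440 - i490) / total


@dataclass
class MeltingCurve:
    """Temperature (C, strictly increasing) vs DPH anisotropy r."""

    temperature: np.ndarray
    anisotropy: np.ndarray

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.temperature.shape != self.anisotropy.shape:
            raise InputError("temperature and anisotropy must have equal length")
        if self.temperature.size < 8:
            raise InputError("a melting curve needs at least 8 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise InputError("temperatures must be strictly increasing")


@dataclass
class SigmoidFitResult:
    """Sigmoid melting fit: inflection Tm, steepness B, two linear baselines."""

    tm: float                 # C
    b: float                  # C, > 0
    m1: float                 # transition-amplitude baseline slope (1/C)
    r1_0: float
    m2: float                 # fluid-phase baseline slope (1/C)
    r2_0: float
    standard_errors: dict = field(default_factory=dict)
    sse: float | None = None

    def __post_init__(self):
        if not self.b > 0:
            raise DomainError("steepness B must be > 0")


def _melting_curve_model(t, tm, b, m1, r1_0, m2, r2_0):
    r1 = m1 * t + r1_0
    r2 = m2 * t + r2_0
    return r1 / (1.0 + np.exp(-(t - tm) / b)) + r2


def fit_melting(curve: MeltingCurve, init: dict | None = None,
                flat_baselines: bool = False) -> SigmoidFitResult:
    """Fit the anisotropy melting curve; Tm is the fitted inflection point.

    The model is r(T) = r1(T) * logistic((T - Tm)/B) + r2(T) with
    r1 = m1*T + r1_0 and r2 = m2*T + r2_0; ``flat_baselines`` pins the
    slopes at zero.  Unweighted least squares.
    """
    t, r = curve.temperature, curve.anisotropy
    init = dict(init or {})

    # inflection guess from the smoothed derivative
    dr = np.gradient(r, t)
    tm0 = init.get("tm", float(t[np.argmax(np.abs(dr))]))
    r2_0_guess = init.get("r2_0", float(r[-1]))
    r1_0_guess = init.get("r1_0", float(r[0] - r[-1]))

    params = lmfit.Parameters()
    params.add("tm", value=tm0, min=t.min() - 5.0, max=t.max() + 5.0)
    params.add("b", value=init.get("b", 1.5), min=1e-3)
    params.add("m1", value=init.get("m1", 0.0), vary=not flat_baselines)
    params.add("r1_0", value=r1_0_guess)
    params.add("m2", value=init.get("m2", 0.0), vary=not flat_baselines)
    params.add("r2_0", value=r2_0_guess)

    def residual(p):
        return _melting_curve_model(
            t, p["tm"].value, p["b"].value, p["m1"].value,
            p["r1_0"].value, p["m2"].value, p["r2_0"].value) - r

    result = lmfit.minimize(residual, params, method="leastsq")
    tm_fit = result.params["tm"].value
    if not result.success or not (t.min() <= tm_fit <= t.max()):
        raise FitConvergenceError(
            "melting fit found no inflection inside the temperature range",
            best_params={k: v.value for k, v in result.params.items()})

    def se(name):
        stderr = result.params[name].stderr
        return float(stderr) if stderr is not None else math.nan

    return SigmoidFitResult(
        tm=float(tm_fit),
        b=float(result.params["b"].value),
        m1=float(result.params["m1"].value),
        r1_0=float(result.params["r1_0"].value),
        m2=float(result.params["m2"].value),
        r2_0=float(result.params["r2_0"].value),
        standard_errors={k: se(k) for k in ("tm", "b", "m1", "r1_0", "m2", "r2_0")},
        sse=float(np.sum(np.asarray(result.residual) ** 2)),
    )


def thickness_from_peak(q_second_max: float) -> float:
    """Bilayer thickness L = 2*pi/Q (Angstrom) from the second SAXS maximum."""
    if not q_second_max > 0:
        raise DomainError("Q must be > 0")
    return 2.0 * math.pi / q_second_max
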