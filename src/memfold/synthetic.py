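"""Synthetic-data generators with known ground truth.

The raw measurements this package analyzes (plate-reader fluorescence
isotherms, anisotropy melting curves, MD contact tables) are not
publicly deposited, so seeded generators are the canonical test inputs.
Each generator forward-simulates the corresponding model with stated
parameters, adds independent homoscedastic Gaussian noise (default
sigma = 1% of the signal's dynamic range), and returns the data
object together with a truth/metadata dictionary.  All randomness flows
through ``numpy.random.default_rng(seed)``, so a fixed spec reproduces
identical output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bicelle import MeltingCurve, _melting_curve_model
from .errors import InputError
from .solvation import ContactTrace
from .steric_binding import (
    BindingTitration,
    CompetitionTitration,
    _competition_curve,
    _first_binding_curve,
    _second_binding_curve,
)
from .three_state import DenaturantTitration, ThreeStateParams, predict_observable

__all__ = [
    "SyntheticSpec",
    "gen_binding_titration",
    "gen_denaturation_titration",
    "gen_melting_curve",
    "gen_contact_traces",
    "gen_mutant_panel",
]


@dataclass
class SyntheticSpec:
    """Seed, design and ground truth for one synthetic dataset."""

    seed: int
    n_points: int = 12
    noise_sigma: float = 0.0
    truth: dict = field(default_factory=dict)
    grid: tuple = ("log", 0.01, 60.0)   # (kind, lo, hi)

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise InputError("noise_sigma must be >= 0")
        if self.n_points < 4:
            raise InputError("n_points must be >= 4")
        kind = self.grid[0]
        if kind not in ("log", "linear"):
            raise InputError(f"unknown grid kind {kind!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def make_grid(self) -> np.ndarray:
        kind, lo, hi = self.grid
        if kind == "log":
            if lo <= 0:
                raise InputError("log grid requires lo > 0")
            return np.geomspace(lo, hi, self.n_points)
        return np.linspace(lo, hi, self.n_points)


def _metadata(spec: SyntheticSpec, model: str, truth: dict, **extra) -> dict:
    return {
        "model": model,
        "seed": spec.seed,
        "n_points": spec.n_points,
        "noise_sigma": spec.noise_sigma,
        "noise_model": "additive iid Gaussian",
        "grid": list(spec.grid),
        "truth": dict(truth),
        **extra,
    }


def gen_binding_titration(spec: SyntheticSpec, model: str = "second"):
    """Simulate a steric-trapping binding isotherm.

    ``model`` is ``"first"``, ``"competition"`` or ``"second"``; the
    default [mSA] design is 12 log-spaced points over 0.01-60 uM (the
    experimental titration window).  Returns (titration, metadata).
    Truth defaults per model:

    * first:       kd_biotin 0.5 uM, amplitude 1, offset 0, P_T 1 uM
    * competition: k_ratio 0.5, C_T 2 uM, P_T 1 uM
    * second:      k_denat 1e-4 (dG ~ -5.4 kcal/mol at room T),
                   kd_biotin 2e-3 uM (weak-biotin mSA variant placing the
                   half-transition mid-window), plateaus 1 -> 0.1
    """
    rng = spec.rng()
    conc = spec.make_grid()

    if model == "first":
        truth = {"kd_biotin": 0.5, "amplitude": 1.0, "offset": 0.0,
                 "protein_total": 1.0, **spec.truth}
        if truth["kd_biotin"] < 0 or truth["protein_total"] <= 0:
            raise InputError("invalid truth for first-binding model")
        signal = _first_binding_curve(conc, truth["protein_total"],
                                      truth["kd_biotin"], truth["amplitude"],
                                      truth["offset"])
        signal = signal + rng.normal(0.0, spec.noise_sigma, conc.size)
        tit = BindingTitration(conc, signal, truth["protein_total"],
                               label=f"synthetic-first-seed{spec.seed}")
        return tit, _metadata(spec, model, truth)

    if model == "competition":
        truth = {"k_ratio": 0.5, "amplitude": 1.0, "offset": 0.0,
                 "protein_total": 1.0, "labeled_total": 2.0, **spec.truth}
        if truth["k_ratio"] <= 0 or truth["labeled_total"] < truth["protein_total"]:
            raise InputError("invalid truth for competition model")
        signal = _competition_curve(conc, truth["protein_total"],
                                    truth["labeled_total"], truth["k_ratio"],
                                    truth["amplitude"], truth["offset"])
        signal = signal + rng.normal(0.0, spec.noise_sigma, conc.size)
        tit = CompetitionTitration(conc, truth["labeled_total"],
                                   truth["protein_total"], signal,
                                   label=f"synthetic-competition-seed{spec.seed}")
        return tit, _metadata(spec, model, truth)

    if model == "second":
        # kd_biotin = 2e-3 uM (2 nM): a weak-biotin mSA variant chosen so
        # the attenuated phase's half-point Kd*(1+1/K_D) ~ 20 uM falls
        # mid-window, as the assay screens for
        truth = {"k_denat": 1e-4, "kd_biotin": 2e-3, "f0": 1.0, "f_inf": 0.1,
                 "protein_total": 1.0, **spec.truth}
        if truth["k_denat"] <= 0 or truth["kd_biotin"] <= 0:
            raise InputError("invalid truth for second-binding model")
        signal = _second_binding_curve(conc, truth["kd_biotin"],
                                       truth["k_denat"], truth["f0"],
                                       truth["f_inf"])
        signal = signal + rng.normal(0.0, spec.noise_sigma, conc.size)
        tit = BindingTitration(conc, signal, truth["protein_total"],
                               label=f"synthetic-second-seed{spec.seed}")
        return tit, _metadata(spec, model, truth)

    raise InputError(f"unknown binding model {model!r}")


def gen_denaturation_titration(spec: SyntheticSpec):
    """Simulate a GdnHCl three-state folding titration.

    Default design: linear 1-5 M grid; default truth is the DC12PC-like
    parameter set (dG = -5.4 / -26.4 kcal/mol, m = 2.0 / 7.2) with flat
    0 / 0.55 / 1 baselines.  Metadata flags midpoints outside the range.
    """
    rng = spec.rng()
    if spec.grid[0] != "linear":
        spec = SyntheticSpec(spec.seed, spec.n_points, spec.noise_sigma,
                             spec.truth, ("linear", 1.0, 5.0))
    d = spec.make_grid()
    truth = {"dg_ni": -5.4, "dg_iu": -26.4, "m_ni": 2.0, "m_iu": 7.2,
             "baselines": {"N": (0.0, 0.0), "I": (0.55, 0.0), "U": (1.0, 0.0)},
             **spec.truth}
    params = ThreeStateParams(dg_ni=truth["dg_ni"], dg_iu=truth["dg_iu"],
                              m_ni=truth["m_ni"], m_iu=truth["m_iu"],
                              baselines=truth["baselines"])
    mid_ni, mid_iu = params.midpoints
    warn = not (d.min() <= mid_ni <= d.max() and d.min() <= mid_iu <= d.max())
    y, _ = predict_observable(params, d)
    y = y + rng.normal(0.0, spec.noise_sigma, d.size)
    tit = DenaturantTitration(d, y, direction="pooled")
    meta = _metadata(spec, "three_state", truth,
                     midpoints=[mid_ni, mid_iu],
                     midpoints_outside_range=bool(warn))
    return tit, meta


def gen_melting_curve(spec: SyntheticSpec):
    """Simulate a DPH anisotropy melting curve.

    Default design: evenly spaced temperatures over 3.0-42.5 C; default
    truth Tm = 24.0 C, B = 1.5 C with gently sloped baselines.
    """
    rng = spec.rng()
    if spec.grid[0] != "linear" or spec.grid[1] == 0.01:
        spec = SyntheticSpec(spec.seed, max(spec.n_points, 8), spec.noise_sigma,
                             spec.truth, ("linear", 3.0, 42.5))
    t = spec.make_grid()
    truth = {"tm": 24.0, "b": 1.5, "m1": 0.0, "r1_0": -0.2,
             "m2": 0.0, "r2_0": 0.3, **spec.truth}
    if not (t.min() <= truth["tm"] <= t.max()):
        raise InputError("truth Tm must lie inside the temperature range")
    r = _melting_curve_model(t, truth["tm"], truth["b"], truth["m1"],
                             truth["r1_0"], truth["m2"], truth["r2_0"])
    r = r + rng.normal(0.0, spec.noise_sigma, t.size)
    return MeltingCurve(t, r), _metadata(spec, "melting", truth)


def gen_contact_traces(
    spec: SyntheticSpec,
    k_on: float = 0.01,
    k_off: float = 0.025,
    n_molecules: int = 50,
    duration: float = 2000.0,
    frame_interval: float = 0.5,
    count_mode: str = "constant",
    mean_count: int = 30,
    role: str = "protein_contact",
):
    """Simulate two-state (bound/unbound) contact traces.

    Each molecule alternates exponential unbound (rate ``k_on``) and
    bound (rate ``k_off``) dwells (ns^-1), discretized to the frame
    grid; bound frames carry a constant contact count or, with
    ``count_mode="poisson"``, 1 + Poisson(mean_count - 1) per frame.
    Returns (list of ContactTrace, metadata); the metadata includes the
    realized number of events.  A frame interval at or above the mean
    bound dwell sets an aliasing flag.
    """
    if not (k_on > 0 and k_off > 0):
        raise InputError("rates must be > 0")
    if count_mode not in ("constant", "poisson"):
        raise InputError(f"unknown count_mode {count_mode!r}")
    rng = spec.rng()
    n_frames = int(round(duration / frame_interval))
    aliasing = frame_interval >= 1.0 / k_off

    traces = []
    n_events = 0
    for mol in range(n_molecules):
        bound = np.zeros(n_frames, dtype=bool)
        t, state = 0.0, False    # start unbound
        while t < duration:
            rate = k_off if state else k_on
            dwell = rng.exponential(1.0 / rate)
            if state:
                i0 = int(np.ceil(t / frame_interval))
                i1 = min(int(np.ceil((t + dwell) / frame_interval)), n_frames)
                if i1 > i0:
                    bound[i0:i1] = True
                    n_events += 1
            t += dwell
            state = not state
        if count_mode == "constant":
            q = np.where(bound, mean_count, 0)
        else:
            q = np.where(bound, 1 + rng.poisson(mean_count - 1, n_frames), 0)
        traces.append(ContactTrace(molecule_id=mol, q=q,
                                   frame_interval=frame_interval, role=role))

    truth = {"k_on": k_on, "k_off": k_off, "tau_true": 1.0 / k_off,
             "count_mode": count_mode, "mean_count": mean_count}
    meta = _metadata(spec, "contact_traces", truth,
                     n_molecules=n_molecules, duration_ns=duration,
                     frame_interval_ns=frame_interval,
                     n_events=n_events, aliasing_warning=bool(aliasing))
    return traces, meta


def gen_mutant_panel(
    spec: SyntheticSpec,
    true_slope: float = 1.0,
    n_mutants: int = 37,
    burial_mix: dict | None = None,
):
    """Simulate a mutational ddG panel across two subdomains.

    ddG^N values are drawn uniformly over 0-3 kcal/mol (typical
    large-to-small substitutions); ddG^C = true_slope * ddG^N + noise.
    ``burial_mix`` gives the class composition, default
    {"buried": .4, "partially_buried": .3, "exposed": .3}; f_ASA is
    sampled accordingly (0 exactly for buried).  Returns
    (pandas.DataFrame panel, metadata).
    """
    import pandas as pd

    if n_mutants < 6:
        raise InputError("n_mutants must be >= 6")
    burial_mix = burial_mix or {"buried": 0.4, "partially_buried": 0.3,
                                "exposed": 0.3}
    rng = spec.rng()
    ddg_n = rng.uniform(0.0, 3.0, n_mutants)
    noise = rng.normal(0.0, spec.noise_sigma, n_mutants)
    ddg_c = true_slope * ddg_n + noise

    classes = rng.choice(list(burial_mix), size=n_mutants,
                         p=np.asarray(list(burial_mix.values())) /
                         sum(burial_mix.values()))
    f_asa = np.empty(n_mutants)
    for i, cl in enumerate(classes):
        if cl == "buried":
            f_asa[i] = 0.0
        elif cl == "partially_buried":
            f_asa[i] = rng.uniform(1e-3, 0.1)
        else:
            f_asa[i] = rng.uniform(0.1 + 1e-6, 1.0)

    panel = pd.DataFrame({
        "mutation": [f"M{i + 1:03d}A" for i in range(n_mutants)],
        "ddg_N": ddg_n,
        "se_N": np.full(n_mutants, spec.noise_sigma),
        "ddg_C": ddg_c,
        "se_C": np.full(n_mutants, spec.noise_sigma),
        "f_asa": f_asa,
        "environment": "synthetic",
    })
    truth = {"true_slope": true_slope, "burial_mix": burial_mix}
    return panel, _metadata(spec, "mutant_panel", truth, n_mutants=n_mutants)
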