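"""Amphiphile solvation dynamics from trajectory-derived contact data.

Inputs are per-molecule heavy-atom contact-count time series (an
amphiphile is "in contact" while it has heavy atoms within the contact
shell of the protein) and, for equilibration diagnostics, per-molecule
coordinate tracks.

Workflow:

1. `detect_contact_events` segments a trace into contact events,
   merging non-contact gaps shorter than the amphiphile relaxation time
   (itself measurable with `rmsd_lag` on bulk molecules).
2. `contact_autocorr` computes the contact autocorrelation

       c(tau) = < q(t) q(t+tau) / q(t)^2 >

   over origins t inside events (q(t) > 0, t+tau inside the trace);
   q is event-scoped, i.e. a later rebinding is a new event and does not
   feed the correlation of the event that ended.  Two origin weightings
   are offered: ``"origin"`` (default) pools all valid origins, which
   for exponential dwell times makes c(tau) an unbiased estimate of the
   dwell survival exp(-k_off tau); ``"event"`` averages within each
   event first and then equally across events (the double-average
   notation), which length-biases short events and shifts the 1/e
   crossing well below the mean dwell time -- kept as a diagnostic.
3. `fit_triple_exp` + `residence_time` extract the residence time tau_R
   as the lag where the (fitted) autocorrelation decays to 1/e.
4. `solvation_dg` converts the ratio of protein-contact to bulk
   (amphiphile-amphiphile) residence times into a solvation free energy

       dG_solv = -RT ln(tau_R,protein / tau_R,bulk)

   (negative when amphiphiles linger on the protein).  The ensemble
   (Boltzmann-average over per-site free energies) and mean-residence-
   time forms are algebraically identical and both are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, FitConvergenceError, InputError
from .thermo import SIMULATION_CONTEXT, ThermoContext

__all__ = [
    "ContactTrace",
    "ContactEvent",
    "AutocorrResult",
    "TripleExpFit",
    "ResidenceTime",
    "SolvationResult",
    "CoordinateTrack",
    "detect_contact_events",
    "contact_autocorr",
    "fit_triple_exp",
    "residence_time",
    "solvation_dg",
    "site_solvation_dg",
    "solvation_dg_ensemble",
    "solvation_dg_mean_tau",
    "rmsd_lag",
    "rmsf",
]


# ---------------------------------------------------------------------------
# domain types

@dataclass
class ContactTrace:
    """Per-molecule heavy-atom contact counts, one value per frame."""

    molecule_id: int
    q: np.ndarray             # non-negative integers
    frame_interval: float     # ns
    role: str = "protein_contact"   # or "bulk_pair"
    part: str = "whole"             # or "headgroup" / "tail"

    def __post_init__(self):
        self.q = np.asarray(self.q)
        if not self.frame_interval > 0:
            raise InputError("frame_interval must be > 0")
        if np.any(self.q < 0):
            raise InputError("contact counts must be >= 0")


@dataclass
class ContactEvent:
    """A maximal run of contact frames, possibly spanning short merged gaps."""

    molecule_id: int
    start_frame: int
    end_frame: int            # inclusive
    merged_gaps: int = 0

    def __post_init__(self):
        if self.start_frame > self.end_frame:
            raise InputError("start_frame must be <= end_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class AutocorrResult:
    """Contact autocorrelation c(tau) with the number of contributing events."""

    tau: np.ndarray           # ns, increasing, tau[0] = 0
    c: np.ndarray
    n_events: int


@dataclass
class TripleExpFit:
    """Normalized triple-exponential decay: sum_j a_j exp(-tau/tau_j)."""

    amplitudes: np.ndarray    # >= 0, sum to 1
    time_constants: np.ndarray  # ns, increasing
    residual_norm: float

    def __call__(self, tau):
        tau = np.asarray(tau, dtype=float)
        return np.sum(
            self.amplitudes[:, None]
            * np.exp(-tau[None, :] / self.time_constants[:, None]),
            axis=0,
        ) if tau.ndim else float(
            np.sum(self.amplitudes * np.exp(-tau / self.time_constants)))


@dataclass
class ResidenceTime:
    """The 1/e decay time of a contact autocorrelation; may be censored."""

    tau_r: float              # ns; a lower bound when censored
    censored: bool = False
    method: str = "fit"


@dataclass
class SolvationResult:
    """Solvation free energy from protein vs bulk residence times."""

    tau_r_protein: float      # ns
    tau_r_bulk: float         # ns
    dg_solv: float            # kcal/mol
    context: ThermoContext = SIMULATION_CONTEXT


@dataclass
class CoordinateTrack:
    """Frames x atoms x 3 heavy-atom coordinates (Angstrom) for one molecule."""

    coords: np.ndarray
    frame_interval: float     # ns
    molecule_id: int = 0
    atom_mask: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 2:
            raise InputError("a track needs at least 2 frames")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coordinates must be finite")
        if self.atom_mask is not None:
            self.coords = self.coords[:, np.asarray(self.atom_mask, bool), :]


# ---------------------------------------------------------------------------
# contact events

def detect_contact_events(trace: ContactTrace, gap_threshold: float = 0.0):
    """Segment a contact trace into events.

    Maximal runs of q > 0 become events; zero-gaps no longer than
    ``gap_threshold`` (ns) between consecutive runs are merged into a
    single event (brief losses of contact shorter than the amphiphile
    relaxation time do not end a contact).  Returns disjoint, ordered
    :class:`ContactEvent` objects; an all-zero trace yields [].
    """
    if gap_threshold < 0:
        raise InputError("gap_threshold must be >= 0")
    gap_frames = int(math.floor(gap_threshold / trace.frame_interval + 1e-9))

    q = np.asarray(trace.q)
    nz = q > 0
    if not nz.any():
        return []
    # run boundaries of the q>0 mask
    padded = np.concatenate([[False], nz, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1

    events = []
    cur_start, cur_end, merged = int(starts[0]), int(ends[0]), 0
    for s, e in zip(starts[1:], ends[1:]):
        gap = int(s) - cur_end - 1
        if gap <= gap_frames:
            cur_end = int(e)
            merged += 1
        else:
            events.append(ContactEvent(trace.molecule_id, cur_start, cur_end, merged))
            cur_start, cur_end, merged = int(s), int(e), 0
    events.append(ContactEvent(trace.molecule_id, cur_start, cur_end, merged))
    return events


# ---------------------------------------------------------------------------
# contact autocorrelation

def contact_autocorr(
    traces,
    max_lag: float,
    gap_threshold: float = 0.0,
    events=None,
    weighting: str = "origin",
) -> AutocorrResult:
    """Contact autocorrelation c(tau) over a set of traces.

    Parameters
    ----------
    traces
        Iterable of :class:`ContactTrace` with a common frame interval.
    max_lag
        Largest lag in ns; must be shorter than the trace duration.
    gap_threshold
        Passed to :func:`detect_contact_events` when ``events`` is None.
    events
        Optional pre-computed mapping molecule_id -> list of events.
    weighting
        ``"origin"`` (default) pools all valid origins across events;
        ``"event"`` reproduces the literal double average (within-event
        mean, then equal event weights).

    Origins are frames t inside an event with q(t) > 0 and t+tau inside
    the trace; q is event-scoped, so q(t+tau) reads 0 once the event has
    ended.  c(0) = 1 by construction.
    """
    traces = list(traces)
    if not traces:
        raise InputError("no traces supplied")
    if weighting not in ("origin", "event"):
        raise InputError(f"unknown weighting {weighting!r}")
    dt = traces[0].frame_interval
    for tr in traces:
        if not math.isclose(tr.frame_interval, dt):
            raise InputError("all traces must share one frame interval")
    n_frames_min = min(tr.q.size for tr in traces)
    max_m = int(round(max_lag / dt))
    if max_m >= n_frames_min:
        raise InputError("max_lag must be shorter than the trace duration")

    lags = np.arange(max_m + 1)
    num = np.zeros(max_m + 1)
    den = np.zeros(max_m + 1)
    per_event = []  # for weighting="event"
    n_events = 0

    for tr in traces:
        evs = events.get(tr.molecule_id) if events is not None else \
            detect_contact_events(tr, gap_threshold)
        q = np.asarray(tr.q, dtype=float)
        t_last = q.size - 1
        for ev in evs:
            n_events += 1
            arr = q[ev.start_frame:ev.end_frame + 1]
            L = arr.size
            w = np.zeros(L)
            nz = arr > 0
            w[nz] = 1.0 / arr[nz]
            # event-scoped q: beyond the event end the product is 0, so
            # num[m] = sum_t arr[t+m] * w[t] is a cross-correlation
            ev_num = np.zeros(max_m + 1)
            upto = min(L, max_m + 1)
            ev_num[:upto] = np.correlate(arr, w, mode="full")[L - 1:L - 1 + upto]
            # origins t with q(t) > 0 and start+t+m <= trace end
            nz_idx = np.flatnonzero(nz)
            limits = t_last - ev.start_frame - lags
            ev_den = np.searchsorted(nz_idx, limits, side="right").astype(float)
            num += ev_num
            den += ev_den
            per_event.append((ev_num, ev_den))

    if n_events == 0:
        raise InputError("no contact events found in the supplied traces")

    if weighting == "origin":
        c = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    else:
        acc = np.zeros(max_m + 1)
        cnt = np.zeros(max_m + 1)
        for ev_num, ev_den in per_event:
            ok = ev_den > 0
            acc[ok] += ev_num[ok] / ev_den[ok]
            cnt[ok] += 1
        c = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)

    return AutocorrResult(tau=lags * dt, c=c, n_events=n_events)


# ---------------------------------------------------------------------------
# decay fitting and residence time

def fit_triple_exp(acr: AutocorrResult) -> TripleExpFit:
    """Least-squares fit of c(tau) to a normalized triple exponential.

    Amplitudes are constrained non-negative with a_1 + a_2 + a_3 = 1;
    time constants are fitted as natural logs and reported in increasing
    order.  If the data are effectively mono-exponential the components
    simply collapse (degenerate time constants), which is fine.
    """
    tau, c = np.asarray(acr.tau, float), np.asarray(acr.c, float)
    if tau.size < 12:
        raise InputError("need at least 12 lag points for a triple-exponential fit")
    if c[0] <= c[-1]:
        raise InputError("autocorrelation must decay")

    span = max(tau[-1], tau[1] * 10)
    # centre the timescale guesses on the raw 1/e crossing when there is one
    below = np.flatnonzero(c <= _INV_E)
    tau_scale = float(tau[below[0]]) if below.size and below[0] > 0 else span / 3.0
    # keep time constants inside a generous but finite window so a
    # vanishing-amplitude component cannot drag its tau to infinity
    ln_lo = math.log(max(tau[1] / 10.0, 1e-9))
    ln_hi = math.log(span * 50.0)

    def make_params(scale):
        # free non-negative amplitudes: c(0) = 1 pins their sum, and the
        # reported amplitudes are normalized to sum exactly 1 afterwards
        params = lmfit.Parameters()
        for name in ("a1", "a2", "a3"):
            params.add(name, value=1.0 / 3.0, min=0.0, max=2.0)
        for name, frac in (("ln_t1", tau_scale / 5.0), ("ln_t2", tau_scale),
                           ("ln_t3", tau_scale * 5.0)):
            params.add(name, value=min(max(math.log(frac) + scale, ln_lo), ln_hi),
                       min=ln_lo, max=ln_hi)
        return params

    def model(p, x):
        a = np.array([p["a1"].value, p["a2"].value, p["a3"].value])
        ts = np.exp([p["ln_t1"].value, p["ln_t2"].value, p["ln_t3"].value])
        return a @ np.exp(-x[None, :] / ts[:, None])

    def residual(p):
        return model(p, tau) - c

    # trust-region reflective: robust when components collapse to fewer
    # than three distinguishable exponentials; deterministic restarts
    # from shifted timescale guesses cover awkward initializations
    result = None
    for scale in (0.0, -1.5, 1.5):
        attempt = lmfit.minimize(residual, make_params(scale),
                                 method="least_squares")
        if attempt.success:
            result = attempt
            break
        if result is None or attempt.chisqr < result.chisqr:
            result = attempt
    # the TRF convergence flag can trip on flat degenerate directions
    # even when the curve is reproduced essentially exactly; accept such
    # solutions, reject genuinely bad ones
    rms = math.sqrt(result.chisqr / tau.size)
    if not result.success and rms > 0.05:
        raise FitConvergenceError(
            "triple-exponential fit did not converge "
            "(consider a single/double-exponential fallback)",
            best_params={k: v.value for k, v in result.params.items()})

    a = np.array([result.params[k].value for k in ("a1", "a2", "a3")])
    ts = np.exp([result.params[k].value for k in ("ln_t1", "ln_t2", "ln_t3")])
    order = np.argsort(ts)
    a, ts = a[order], ts[order]
    total = a.sum()
    if total <= 0:
        raise FitConvergenceError("triple-exponential fit collapsed to zero amplitude")
    a = a / total
    resid = model(result.params, tau) - c
    return TripleExpFit(amplitudes=a, time_constants=ts,
                        residual_norm=float(np.linalg.norm(resid)))


_INV_E = 1.0 / math.e


def residence_time(fit_or_curve, method: str | None = None) -> ResidenceTime:
    """Residence time tau_R: the lag where c(tau) first reaches 1/e.

    Accepts a :class:`TripleExpFit` (bracketed root finding on the
    fitted curve; default workflow) or an :class:`AutocorrResult`
    (linear interpolation on the raw curve; diagnostic).  A curve that
    never decays below 1/e in range yields a censored result carrying
    the largest examined lag as a lower bound.
    """
    if isinstance(fit_or_curve, TripleExpFit):
        fit = fit_or_curve
        hi = 10.0 * fit.time_constants[-1]
        if fit(hi) > _INV_E:
            return ResidenceTime(tau_r=hi, censored=True, method="fit")
        tau_r = brentq(lambda x: fit(x) - _INV_E, 0.0, hi, xtol=1e-12)
        return ResidenceTime(tau_r=float(tau_r), censored=False, method="fit")

    if isinstance(fit_or_curve, AutocorrResult):
        tau, c = fit_or_curve.tau, fit_or_curve.c
        below = np.flatnonzero(c <= _INV_E)
        if below.size == 0:
            return ResidenceTime(tau_r=float(tau[-1]), censored=True,
                                 method="interp")
        j = int(below[0])
        if j == 0:
            return ResidenceTime(tau_r=0.0, censored=False, method="interp")
        # linear interpolation between the bracketing lags
        frac = (c[j - 1] - _INV_E) / (c[j - 1] - c[j])
        tau_r = tau[j - 1] + frac * (tau[j] - tau[j - 1])
        return ResidenceTime(tau_r=float(tau_r), censored=False, method="interp")

    raise InputError("expected a TripleExpFit or AutocorrResult")


# ---------------------------------------------------------------------------
# solvation free energy

def solvation_dg(protein_tau: float, bulk_tau: float,
                 context: ThermoContext = SIMULATION_CONTEXT) -> SolvationResult:
    """dG_solv = -RT ln(tau_R,protein / tau_R,bulk), kcal/mol.

    Negative when amphiphiles reside longer on the protein than on each
    other (favourable solvation of the protein surface).
    """
    if not (protein_tau > 0 and bulk_tau > 0):
        raise DomainError("residence times must be > 0")
    dg = -context.rt * math.log(protein_tau / bulk_tau)
    return SolvationResult(tau_r_protein=protein_tau, tau_r_bulk=bulk_tau,
                           dg_solv=dg, context=context)


def site_solvation_dg(site_taus, bulk_tau,
                      context: ThermoContext = SIMULATION_CONTEXT) -> np.ndarray:
    """Per-site dG_solv(i) = -RT ln(tau_i / tau_bulk) for each contact site."""
    site_taus = np.asarray(site_taus, dtype=float)
    if np.any(site_taus <= 0) or not bulk_tau > 0:
        raise DomainError("residence times must be > 0")
    return -context.rt * np.log(site_taus / bulk_tau)


def solvation_dg_ensemble(site_taus, bulk_tau,
                          context: ThermoContext = SIMULATION_CONTEXT) -> float:
    """Ensemble form: -RT ln( (1/N) sum_i exp(-dG_i/RT) ).

    Boltzmann-averages the per-site solvation free energies over all
    contact sites on the protein.
    """
    dgs = site_solvation_dg(site_taus, bulk_tau, context)
    return float(-context.rt * math.log(np.mean(np.exp(-dgs / context.rt))))


def solvation_dg_mean_tau(site_taus, bulk_tau,
                          context: ThermoContext = SIMULATION_CONTEXT) -> float:
    """Mean-residence-time form: -RT ln( mean(tau_i) / tau_bulk ).

    Identical to :func:`solvation_dg_ensemble` (the exponentials cancel
    exactly); kept separate so the identity can be asserted.
    """
    site_taus = np.asarray(site_taus, dtype=float)
    if np.any(site_taus <= 0) or not bulk_tau > 0:
        raise DomainError("residence times must be > 0")
    return float(-context.rt * math.log(np.mean(site_taus) / bulk_tau))


# ---------------------------------------------------------------------------
# coordinate-track diagnostics

def _kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Heavy-atom RMSD after optimal superposition (translation + rotation)."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = yc - xc @ rot.T
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsd_lag(tracks, lags) -> np.ndarray:
    """Time-lagged conformational RMSD(tau), averaged over molecules and t.

    For each lag, each molecule's conformations at t and t+tau are
    optimally superposed (so rigid-body motion contributes nothing) and
    the heavy-atom RMSD is averaged over all valid origins and over
    molecules.  Used on bulk amphiphiles to measure the conformational
    relaxation time that sets the event-merging gap threshold.
    """
    tracks = list(tracks)
    if not tracks:
        raise InputError("no tracks supplied")
    dt = tracks[0].frame_interval
    lags = np.asarray(lags, dtype=float)
    out = np.empty(lags.size)
    for k, lag in enumerate(lags):
        m = int(round(lag / dt))
        per_mol = []
        for tr in tracks:
            coords = tr.coords
            if coords.shape[1] < 3:
                raise DomainError("need >= 3 atoms for superposition")
            n = coords.shape[0]
            if m >= n:
                continue
            if m == 0:
                per_mol.append(0.0)
                continue
            vals = [_kabsch_rmsd(coords[t], coords[t + m]) for t in range(n - m)]
            per_mol.append(float(np.mean(vals)))
        if not per_mol:
            raise InputError(f"lag {lag} ns exceeds every track duration")
        out[k] = float(np.mean(per_mol))
    return out


def rmsf(track: CoordinateTrack) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure.

    Frames are superposed onto their mean structure (two-pass: align to
    frame 0, average, re-align to the average) before computing
    RMSF_i = sqrt(<|x_i(t) - <x_i>|^2>).
    """
    coords = track.coords
    if coords.shape[0] < 2:
        raise DomainError("RMSF undefined for a single frame")

    def align_all(ref, frames):
        aligned = np.empty_like(frames)
        ref_c = ref - ref.mean(axis=0)
        for i, fr in enumerate(frames):
            fc = fr - fr.mean(axis=0)
            h = fc.T @ ref_c
            u, s, vt = np.linalg.svd(h)
            d = np.sign(np.linalg.det(vt.T @ u.T))
            rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
            aligned[i] = fc @ rot.T
        return aligned

    aligned = align_all(coords[0], coords)
    mean = aligned.mean(axis=0)
    aligned = align_all(mean, aligned)
    mean = aligned.mean(axis=0)
    dev = aligned - mean[None, :, :]
    return np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))
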