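"""CSV/TSV dialects shared by the analysis stages.

All tabular files are plain comma- or tab-separated text with an
optional metadata header of ``# key=value`` lines.  Fit results are
written as flat ``param, estimate, se`` tables so they can be collected
into reports without recomputation.  Synthetic generators write a YAML
sidecar carrying the generating spec and ground truth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bicelle import EmissionSpectrum, MeltingCurve
from .errors import InputError
from .solvation import ContactTrace
from .steric_binding import BindingTitration, CompetitionTitration
from .three_state import DenaturantTitration

__all__ = [
    "read_metadata_header",
    "read_binding_titration",
    "write_binding_titration",
    "read_competition_titration",
    "write_competition_titration",
    "read_denaturation_titration",
    "write_denaturation_titration",
    "read_melting_curve",
    "write_melting_curve",
    "read_spectrum",
    "read_panel",
    "write_panel",
    "read_contact_traces",
    "write_contact_traces",
    "write_fit_result",
    "read_fit_result",
    "write_sidecar",
    "read_sidecar",
]


def read_metadata_header(path) -> dict:
    """Parse leading ``# key=value`` lines into a dict (values as str)."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
    return meta


def _read_table(path, sep=","):
    try:
        return pd.read_csv(path, comment="#", sep=sep)
    except Exception as exc:  # surface file context in the error
        raise InputError(f"could not parse {path}: {exc}") from exc


def _write_with_header(path, df: pd.DataFrame, meta: dict, sep=","):
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, sep=sep)


# -- binding titrations ------------------------------------------------------

def read_binding_titration(path) -> BindingTitration:
    """Read `conc_uM, signal` CSV with a `# protein_total_uM=` header."""
    meta = read_metadata_header(path)
    if "protein_total_uM" not in meta:
        raise InputError(f"{path}: missing '# protein_total_uM=' header line")
    df = _read_table(path)
    for col in ("conc_uM", "signal"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return BindingTitration(df["conc_uM"].to_numpy(), df["signal"].to_numpy(),
                            float(meta["protein_total_uM"]),
                            label=meta.get("label", str(path)))


def write_binding_titration(path, titration: BindingTitration, model="", extra=None):
    meta = {"protein_total_uM": titration.protein_total}
    if model:
        meta["model"] = model
    if titration.label:
        meta["label"] = titration.label
    meta.update(extra or {})
    _write_with_header(path, pd.DataFrame(
        {"conc_uM": titration.msa_total, "signal": titration.signal}), meta)


def read_competition_titration(path) -> CompetitionTitration:
    meta = read_metadata_header(path)
    for key in ("protein_total_uM", "labeled_total_uM"):
        if key not in meta:
            raise InputError(f"{path}: missing '# {key}=' header line")
    df = _read_table(path)
    return CompetitionTitration(df["conc_uM"].to_numpy(),
                                float(meta["labeled_total_uM"]),
                                float(meta["protein_total_uM"]),
                                df["signal"].to_numpy(),
                                label=meta.get("label", str(path)))


def write_competition_titration(path, titration: CompetitionTitration, extra=None):
    meta = {"protein_total_uM": titration.protein_total,
            "labeled_total_uM": titration.labeled_total,
            "model": "competition"}
    meta.update(extra or {})
    _write_with_header(path, pd.DataFrame(
        {"conc_uM": titration.competitor_total, "signal": titration.signal}), meta)


# -- denaturation titrations -------------------------------------------------

def read_denaturation_titration(path) -> DenaturantTitration:
    """Read `gdnhcl_M, norm_fluor[, direction]` CSV."""
    df = _read_table(path)
    for col in ("gdnhcl_M", "norm_fluor"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    direction = "pooled"
    if "direction" in df.columns:
        vals = set(df["direction"].unique())
        direction = vals.pop() if len(vals) == 1 else "pooled"
    return DenaturantTitration(df["gdnhcl_M"].to_numpy(),
                               df["norm_fluor"].to_numpy(), direction)


def write_denaturation_titration(path, titration: DenaturantTitration, extra=None):
    _write_with_header(path, pd.DataFrame({
        "gdnhcl_M": titration.denaturant,
        "norm_fluor": titration.signal,
        "direction": titration.direction,
    }), dict(extra or {}))


# -- melting curves and spectra ----------------------------------------------

def read_melting_curve(path) -> MeltingCurve:
    df = _read_table(path)
    for col in ("temp_C", "anisotropy"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return MeltingCurve(df["temp_C"].to_numpy(), df["anisotropy"].to_numpy())


def write_melting_curve(path, curve: MeltingCurve, extra=None):
    _write_with_header(path, pd.DataFrame({
        "temp_C": curve.temperature, "anisotropy": curve.anisotropy}),
        dict(extra or {}))


def read_spectrum(path) -> EmissionSpectrum:
    df = _read_table(path)
    for col in ("wavelength_nm", "intensity"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return EmissionSpectrum(df["wavelength_nm"].to_numpy(),
                            df["intensity"].to_numpy())


# -- mutant panels -----------------------------------------------------------

def read_panel(path) -> pd.DataFrame:
    """Read `mutation, ddg_N, se_N, ddg_C, se_C, f_asa, environment` CSV."""
    df = _read_table(path)
    for col in ("mutation", "ddg_N", "ddg_C"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return df


def write_panel(path, panel: pd.DataFrame, extra=None):
    _write_with_header(path, panel, dict(extra or {}))


# -- contact traces ----------------------------------------------------------

def read_contact_traces(path) -> list[ContactTrace]:
    """Read a `molecule_id, role, part, frame, q` TSV into ContactTraces."""
    meta = read_metadata_header(path)
    if "frame_interval_ns" not in meta:
        raise InputError(f"{path}: missing '# frame_interval_ns=' header line")
    dt = float(meta["frame_interval_ns"])
    df = _read_table(path, sep="\t")
    for col in ("molecule_id", "role", "part", "frame", "q"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    traces = []
    for (mol, role, part), grp in df.groupby(["molecule_id", "role", "part"]):
        grp = grp.sort_values("frame")
        n = int(grp["frame"].max()) + 1
        q = np.zeros(n, dtype=int)
        q[grp["frame"].to_numpy(int)] = grp["q"].to_numpy(int)
        traces.append(ContactTrace(molecule_id=int(mol), q=q,
                                   frame_interval=dt, role=role, part=part))
    return traces


def write_contact_traces(path, traces, extra=None):
    if not traces:
        raise InputError("no traces to write")
    rows = []
    for tr in traces:
        for frame, q in enumerate(tr.q):
            if q > 0:
                rows.append((tr.molecule_id, tr.role, tr.part, frame, int(q)))
    df = pd.DataFrame(rows, columns=["molecule_id", "role", "part", "frame", "q"])
    meta = {"frame_interval_ns": traces[0].frame_interval}
    meta.update(extra or {})
    _write_with_header(path, df, meta, sep="\t")


# -- fit results and sidecars ------------------------------------------------

def write_fit_result(path, result, extra=None):
    """Write any fit dataclass as a flat `param, estimate, se` CSV."""
    if dataclasses.is_dataclass(result):
        fields = dataclasses.asdict(result)
    elif isinstance(result, dict):
        fields = dict(result)
    else:
        raise InputError("expected a dataclass or dict fit result")
    ses = fields.pop("standard_errors", {}) or {}
    rows = []
    for key, value in fields.items():
        if isinstance(value, (int, float, np.floating)) and not isinstance(value, bool):
            rows.append((key, float(value), float(ses.get(key, np.nan))))
    for key, value in (extra or {}).items():
        rows.append((key, float(value), np.nan))
    pd.DataFrame(rows, columns=["param", "estimate", "se"]).to_csv(path, index=False)


def read_fit_result(path) -> pd.DataFrame:
    df = _read_table(path)
    for col in ("param", "estimate"):
        if col not in df.columns:
            raise InputError(f"{path}: not a fit-result CSV (missing {col!r})")
    return df


def write_sidecar(path, metadata: dict):
    """YAML sidecar carrying a synthetic spec and its ground truth."""
    with open(path, "w") as fh:
        yaml.safe_dump(_yaml_ready(metadata), fh, sort_keys=False)


def read_sidecar(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _yaml_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _yaml_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_ready(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
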