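"""File readers and writers: model YAML/JSON, titration CSV, sidecar YAML.

All text output is UTF-8 with LF line endings and plain decimal notation so
that reruns diff deterministically.  Serialization is canonical (fixed key
order), making write-then-read a byte-stable round trip.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError
from .model import Component, EquilibriumModel, FormationSpecies
from .titration import ElectrodeParams, TitrationDataset, TitrationProtocol

MODEL_KEY_ORDER = (
    "label",
    "temperature_K",
    "ionic_strength_M",
    "pKw",
    "components",
    "species",
    "notes",
)


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise SchemaError(f"{context}: missing required field {key!r}")
    return mapping[key]


# ---------------------------------------------------------------------------
# Equilibrium models
# ---------------------------------------------------------------------------


def model_from_dict(data: Mapping[str, Any], context: str = "model") -> EquilibriumModel:
    components = []
    for i, entry in enumerate(_require(data, "components", context)):
        name = _require(entry, "name", f"{context}.components[{i}]")
        kind = _require(entry, "kind", f"{context}.components[{i}]")
        components.append(Component(str(name), str(kind)))
    declared = [c.name for c in components]
    species = []
    for i, entry in enumerate(_require(data, "species", context)):
        where = f"{context}.species[{i}]"
        coeffs_raw = _require(entry, "coeffs", where)
        coeffs = {}
        for comp, nu in coeffs_raw.items():
            if comp not in declared:
                raise SchemaError(f"{where}.coeffs: undeclared component {comp!r}")
            coeffs[str(comp)] = int(nu)
        sigma = entry.get("sigma")
        species.append(
            FormationSpecies(
                coefficients=coeffs,
                log_beta=float(_require(entry, "log_beta", where)),
                sigma_log_beta=None if sigma is None else float(sigma),
                note=entry.get("note"),
            )
        )
    return EquilibriumModel(
        label=str(_require(data, "label", context)),
        components=components,
        species=species,
        pKw=float(data.get("pKw", 13.78)),
        temperature_K=float(data.get("temperature_K", 298.0)),
        ionic_strength_M=float(data.get("ionic_strength_M", 0.1)),
        notes=[str(n) for n in data.get("notes", [])],
    )


def model_to_dict(model: EquilibriumModel) -> dict:
    order = {name: i for i, name in enumerate(model.component_names)}
    species = []
    for sp in model.species:
        coeffs = {
            name: int(sp.coefficients[name])
            for name in sorted(sp.coefficients, key=order.get)
            if sp.coefficients[name] != 0
        }
        entry: dict[str, Any] = {"coeffs": coeffs, "log_beta": float(sp.log_beta)}
        if sp.sigma_log_beta is not None:
            entry["sigma"] = float(sp.sigma_log_beta)
        if sp.note:
            entry["note"] = sp.note
        species.append(entry)
    data: dict[str, Any] = {
        "label": model.label,
        "temperature_K": float(model.temperature_K),
        "ionic_strength_M": float(model.ionic_strength_M),
        "pKw": float(model.pKw),
        "components": [{"name": c.name, "kind": c.kind} for c in model.components],
        "species": species,
    }
    if model.notes:
        data["notes"] = list(model.notes)
    return data


def dump_model(model: EquilibriumModel, path: str | Path | None = None) -> str:
    """Serialize a model to canonical YAML; write to ``path`` when given."""
    text = yaml.safe_dump(
        model_to_dict(model), sort_keys=False, default_flow_style=None, width=100
    )
    if path is not None:
        Path(path).write_text(text, encoding="utf-8", newline="\n")
    return text


def load_model(path: str | Path) -> EquilibriumModel:
    """Read a model from YAML (``.yaml``/``.yml``) or JSON (``.json``)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise SchemaError(f"{path}: cannot parse: {exc}") from exc
    if not isinstance(data, Mapping):
        raise SchemaError(f"{path}: expected a mapping at the top level")
    return model_from_dict(data, context=str(path))


# ---------------------------------------------------------------------------
# Titration datasets (CSV) and protocols (YAML)
# ---------------------------------------------------------------------------

TITRATION_COLUMNS = ("volume_mL", "value", "kind", "sigma")


def write_titration_csv(dataset: TitrationDataset, path: str | Path) -> None:
    sigma = (
        dataset.sigma
        if dataset.sigma is not None
        else np.zeros_like(dataset.values)
    )
    df = pd.DataFrame(
        {
            "volume_mL": dataset.volumes_mL,
            "value": dataset.values,
            "kind": dataset.kind,
            "sigma": sigma,
        }
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_titration_csv(path: str | Path) -> TitrationDataset:
    path = Path(path)
    df = pd.read_csv(path)
    for column in TITRATION_COLUMNS[:3]:
        if column not in df.columns:
            raise SchemaError(f"{path}: missing column {column!r}")
    kinds = set(df["kind"].astype(str))
    if len(kinds) != 1:
        raise SchemaError(f"{path}: column 'kind' must be uniform, found {sorted(kinds)}")
    kind = kinds.pop()
    if kind not in ("pH", "emf_mV"):
        raise SchemaError(f"{path}: column 'kind' must be 'pH' or 'emf_mV', got {kind!r}")
    volumes = df["volume_mL"].to_numpy(dtype=float)
    if volumes.size < 4:
        raise SchemaError(f"{path}: a titration dataset needs at least 4 points")
    if np.any(np.diff(volumes) <= 0):
        raise SchemaError(f"{path}: column 'volume_mL' must be strictly increasing")
    sigma = (
        df["sigma"].to_numpy(dtype=float) if "sigma" in df.columns else None
    )
    return TitrationDataset(
        volumes_mL=volumes,
        values=df["value"].to_numpy(dtype=float),
        kind=kind,
        sigma=sigma,
        metadata={"path": str(path)},
    )


def protocol_to_dict(protocol: TitrationProtocol) -> dict:
    return {
        "initial_volume_mL": float(protocol.initial_volume_mL),
        "initial_totals": {k: float(v) for k, v in protocol.initial_totals.items()},
        "titrant_concentration_M": float(protocol.titrant_concentration_M),
        "volume_points_mL": [float(v) for v in protocol.volume_points_mL],
        "temperature_K": float(protocol.temperature_K),
        "ionic_strength_M": float(protocol.ionic_strength_M),
    }


def dump_protocol(protocol: TitrationProtocol, path: str | Path) -> None:
    text = yaml.safe_dump(protocol_to_dict(protocol), sort_keys=False, width=100)
    Path(path).write_text(text, encoding="utf-8", newline="\n")


def load_protocol(path: str | Path) -> TitrationProtocol:
    path = Path(path)
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(data, Mapping):
        raise SchemaError(f"{path}: expected a mapping at the top level")
    context = str(path)
    return TitrationProtocol(
        initial_volume_mL=float(_require(data, "initial_volume_mL", context)),
        initial_totals={
            str(k): float(v)
            for k, v in _require(data, "initial_totals", context).items()
        },
        titrant_concentration_M=float(
            _require(data, "titrant_concentration_M", context)
        ),
        volume_points_mL=np.asarray(
            _require(data, "volume_points_mL", context), dtype=float
        ),
        temperature_K=float(data.get("temperature_K", 298.0)),
        ionic_strength_M=float(data.get("ionic_strength_M", 0.1)),
    )


def electrode_to_dict(electrode: ElectrodeParams) -> dict:
    out = {"E0_mV": float(electrode.E0_mV), "slope_mV": float(electrode.slope_mV)}
    if electrode.sigma_E0 is not None:
        out["sigma_E0"] = float(electrode.sigma_E0)
    if electrode.sigma_slope is not None:
        out["sigma_slope"] = float(electrode.sigma_slope)
    return out


def electrode_from_dict(data: Mapping, context: str = "electrode") -> ElectrodeParams:
    return ElectrodeParams(
        E0_mV=float(_require(data, "E0_mV", context)),
        slope_mV=float(data.get("slope_mV", 59.16)),
        sigma_E0=data.get("sigma_E0"),
        sigma_slope=data.get("sigma_slope"),
    )


def write_dataframe_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Plain-decimal CSV (no scientific notation, no locale separators)."""

    def fmt(x):
        if isinstance(x, (float, np.floating)):
            return np.format_float_positional(x, precision=12, trim="-")
        return x

    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(fmt)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh, index=False, lineterminator="\n")
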