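"""Serialization of LVC models and results.

The LVC parameter file is structured text (JSON or YAML by extension) with
``modes`` / ``states`` / ``couplings`` sections carrying explicitly labeled
vectors; round trips are lossless to full double precision and unknown keys
are rejected rather than ignored.  The ``meta`` mapping is free-form; the
key ``numerical_differentiation_delta`` is reserved for the displacement
step used upstream when the gradients were obtained by numerical
differentiation (the gradients themselves are plain inputs here).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .model import (DiabaticState, InterStateCoupling, LVCHamiltonian,
                    LVCError, ModeBasis)

__all__ = ["save_hamiltonian", "load_hamiltonian", "gradients_from_csv"]

_MODE_KEYS = {"frequencies", "labels"}
_STATE_KEYS = {"label", "character", "energy0", "gradient", "dipole"}
_COUPLING_KEYS = {"pair", "constant", "linear"}
_TOP_KEYS = {"modes", "states", "couplings", "frequency_matrix", "meta"}


def _check_keys(d: dict, allowed: set, ctx: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise LVCError(f"unknown keys in {ctx}: {sorted(unknown)}")


def _plain(value):
    """Recursively convert numpy scalars/arrays to built-in types."""
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, np.generic):
        return value.item()
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    return value


def hamiltonian_to_dict(H: LVCHamiltonian) -> dict:
    data = {
        "modes": {"frequencies": H.modes.frequencies.tolist()},
        "states": [
            {
                "label": s.label,
                "character": s.character,
                "energy0": float(s.energy0),
                "gradient": s.gradient.tolist(),
                "dipole": s.dipole.tolist(),
            }
            for s in H.states
        ],
        "couplings": [
            {
                "pair": [int(i) for i in c.pair],
                "constant": float(c.constant),
                **({"linear": c.linear.tolist()}
                   if c.linear is not None else {}),
            }
            for c in H.couplings
        ],
        "meta": _plain(dict(H.meta)),
    }
    if H.modes.labels is not None:
        data["modes"]["labels"] = list(H.modes.labels)
    if H.frequency_matrix is not None:
        data["frequency_matrix"] = H.frequency_matrix.tolist()
    return data


def hamiltonian_from_dict(data: dict) -> LVCHamiltonian:
    _check_keys(data, _TOP_KEYS, "parameter file")
    for key in ("modes", "states"):
        if key not in data:
            raise LVCError(f"parameter file missing section {key!r}")
    _check_keys(data["modes"], _MODE_KEYS, "modes")
    labels = data["modes"].get("labels")
    modes = ModeBasis(np.asarray(data["modes"]["frequencies"], float),
                      labels=tuple(labels) if labels else None)
    states = []
    for k, sd in enumerate(data["states"]):
        _check_keys(sd, _STATE_KEYS, f"states[{k}]")
        states.append(DiabaticState(
            label=sd["label"], character=sd["character"],
            energy0=float(sd["energy0"]),
            gradient=np.asarray(sd["gradient"], float),
            dipole=np.asarray(sd.get("dipole", [0, 0, 0]), float)))
    couplings = []
    for k, cd in enumerate(data.get("couplings", [])):
        _check_keys(cd, _COUPLING_KEYS, f"couplings[{k}]")
        lin = cd.get("linear")
        couplings.append(InterStateCoupling(
            pair=tuple(int(i) for i in cd["pair"]),
            constant=float(cd.get("constant", 0.0)),
            linear=np.asarray(lin, float) if lin is not None else None))
    W = data.get("frequency_matrix")
    return LVCHamiltonian(
        modes, tuple(states), tuple(couplings),
        frequency_matrix=np.asarray(W, float) if W is not None else None,
        meta=dict(data.get("meta", {})))


def save_hamiltonian(H: LVCHamiltonian, path) -> None:
    path = Path(path)
    data = hamiltonian_to_dict(H)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=1))


def load_hamiltonian(path) -> LVCHamiltonian:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return hamiltonian_from_dict(data)


def gradients_from_csv(path) -> dict[str, np.ndarray]:
    """Tabular gradient import: CSV with one column per state label and one
    row per mode; returns label -> gradient vector (eV)."""
    import pandas as pd

    df = pd.read_csv(path)
    return {str(col): df[col].to_numpy(dtype=float) for col in df.columns}
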