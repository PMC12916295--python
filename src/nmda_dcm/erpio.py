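"""ERP dataset container and its plain-text exchange format.

Each subject/session is one JSON sidecar ``<subject>_<session>.json`` plus one
TSV matrix per condition ``<subject>_<session>_<condition>.tsv`` (rows = time
samples, columns = sensor modes).  The format is lossless to ~1e-15 relative
(floats are written with ``repr`` precision).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ERPFormatError, StructuralError

FORMAT_VERSION = 1


@dataclass
class ERPDataset:
    """Evoked responses of one subject/session: two conditions, shared axis."""

    subject: str
    session: str
    times: np.ndarray                  # (T,) ms, uniform step from 0
    conditions: dict                   # name -> (T, modes) array
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conditions = {k: np.asarray(v, dtype=float) for k, v in self.conditions.items()}
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        t = self.times
        if t.ndim != 1 or len(t) < 2:
            raise ERPFormatError("time axis must be 1-D with at least 2 samples")
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise ERPFormatError("time axis must have a uniform step")
        if not (abs(t[0]) < 1e-9 and t[-1] >= 300.0 - 1e-9):
            raise ERPFormatError("epoch must cover 0-300 ms")
        if not self.conditions:
            raise ERPFormatError("dataset has no conditions")
        n_modes = None
        for name, arr in self.conditions.items():
            if arr.ndim != 2 or arr.shape[0] != len(t):
                raise ERPFormatError(
                    f"condition {name!r} has shape {arr.shape}, expected "
                    f"({len(t)}, modes); all conditions share one time axis"
                )
            if n_modes is None:
                n_modes = arr.shape[1]
            elif arr.shape[1] != n_modes:
                raise ERPFormatError("all conditions must have the same mode count")
            if not np.all(np.isfinite(arr)):
                raise ERPFormatError(f"condition {name!r} contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_modes(self) -> int:
        return next(iter(self.conditions.values())).shape[1]

    def stack(self, order=("standard", "deviant")) -> np.ndarray:
        """Concatenate conditions into the (T, modes, conditions) array."""
        missing = [c for c in order if c not in self.conditions]
        if missing:
            raise StructuralError(f"dataset lacks conditions {missing}")
        return np.stack([self.conditions[c] for c in order], axis=-1)


def write_erp(dataset: ERPDataset, directory) -> Path:
    """Write the sidecar + per-condition TSVs; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{dataset.subject}_{dataset.session}"
    sidecar = {
        "format_version": FORMAT_VERSION,
        "subject": dataset.subject,
        "session": dataset.session,
        "t0_ms": float(dataset.times[0]),
        "dt_ms": dataset.dt,
        "n_times": len(dataset.times),
        "n_modes": dataset.n_modes,
        "conditions": sorted(dataset.conditions),
        "units": {"time": "ms", "signal": "arbitrary (mode space)"},
        "meta": dataset.meta,
    }
    with open(directory / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    for name, arr in dataset.conditions.items():
        np.savetxt(directory / f"{stem}_{name}.tsv", arr, delimiter="\t", fmt="%.17g")
    return directory / f"{stem}.json"


def read_erp(directory, subject: str, session: str) -> ERPDataset:
    """Read one subject/session back from its sidecar and TSV matrices."""
    directory = Path(directory)
    stem = f"{subject}_{session}"
    sidecar_path = directory / f"{stem}.json"
    if not sidecar_path.exists():
        raise ERPFormatError(f"missing sidecar {sidecar_path}")
    try:
        with open(sidecar_path) as fh:
            sc = json.load(fh)
    except json.JSONDecodeError as err:
        raise ERPFormatError(f"unparseable sidecar {sidecar_path}: {err}") from None
    for key in ("dt_ms", "n_times", "t0_ms", "conditions", "n_modes"):
        if key not in sc:
            raise ERPFormatError(f"sidecar {sidecar_path} lacks required field {key!r}")
    times = sc["t0_ms"] + np.arange(int(sc["n_times"])) * float(sc["dt_ms"])
    conditions = {}
    for name in sc["conditions"]:
        path = directory / f"{stem}_{name}.tsv"
        if not path.exists():
            raise ERPFormatError(f"missing condition matrix {path}")
        arr = np.loadtxt(path, delimiter="\t", ndmin=2)
        if arr.shape != (int(sc["n_times"]), int(sc["n_modes"])):
            raise ERPFormatError(
                f"{path}: shape {arr.shape} does not match sidecar "
                f"({sc['n_times']}, {sc['n_modes']})"
            )
        conditions[name] = arr
    return ERPDataset(subject, session, times, conditions, meta=sc.get("meta", {}))
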