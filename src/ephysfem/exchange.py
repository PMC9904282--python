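"""Plain-text exchange files and run configuration.

Dialects (all whitespace-separated, meters / S/m / A*m unless noted):

* conductivity tensor file — one line per element, 9 values (row-major 3x3);
* dipole file — ``x y z mx my mz``;
* electrode file — ``x y z``;
* coil file — ``channel_id x y z ox oy oz w``, lines grouped by channel id;
* dense matrices — flat row-major float64 ``.bin`` plus a JSON sidecar with
  shape and channel names, or delimited text;
* INI run configuration with fixed sections and defaulted keys.

Writers prepend a self-describing header line ``# ephysfem <format> v1``;
readers also accept headerless files of the same column layout.
"""

from __future__ import annotations

import configparser
import hashlib
import json
from pathlib import Path

import numpy as np

from .fem import Leadfield, TransferMatrix
from .meg import Coil, CoilModel


class ExchangeError(ValueError):
    pass


def _header(kind: str) -> str:
    return f"# ephysfem {kind} v1\n"


def _load_rows(path) -> np.ndarray:
    return np.loadtxt(path, comments="#", ndmin=2)


# ---------------------------------------------------------------------------
# tensors
# ---------------------------------------------------------------------------

def write_tensor_file(tensors: np.ndarray, path) -> None:
    """One line per element: row-major 3x3 conductivity tensor (S/m)."""
    t = np.asarray(tensors, dtype=float)
    if t.ndim != 3 or t.shape[1:] != (3, 3):
        raise ExchangeError("expected (M,3,3) tensors")
    with open(path, "w") as f:
        f.write(_header("tensors"))
        np.savetxt(f, t.reshape(len(t), 9), fmt="%.17g")


def read_tensor_file(path) -> np.ndarray:
    rows = _load_rows(path)
    if rows.shape[1] != 9:
        raise ExchangeError("tensor file must have 9 columns")
    return rows.reshape(-1, 3, 3)


# ---------------------------------------------------------------------------
# dipoles and electrodes
# ---------------------------------------------------------------------------

def write_dipole_file(positions, moments, path) -> None:
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    mom = np.asarray(moments, dtype=float).reshape(-1, 3)
    if len(pos) != len(mom):
        raise ExchangeError("positions and moments must pair up")
    with open(path, "w") as f:
        f.write(_header("dipoles"))
        np.savetxt(f, np.hstack([pos, mom]), fmt="%.17g")


def read_dipole_file(path):
    rows = _load_rows(path)
    if rows.shape[1] != 6:
        raise ExchangeError("dipole file must have 6 columns (x y z mx my mz)")
    return rows[:, :3], rows[:, 3:]


def write_electrode_file(positions, path) -> None:
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    with open(path, "w") as f:
        f.write(_header("electrodes"))
        np.savetxt(f, pos, fmt="%.17g")


def read_electrode_file(path) -> np.ndarray:
    rows = _load_rows(path)
    if rows.shape[1] != 3:
        raise ExchangeError("electrode file must have 3 columns")
    return rows


# ---------------------------------------------------------------------------
# coils
# ---------------------------------------------------------------------------

def write_coil_file(coils: CoilModel, path) -> None:
    with open(path, "w") as f:
        f.write(_header("coils"))
        for ch in coils.channels:
            for p, o, w in zip(ch.points, ch.orientations, ch.weights):
                f.write(f"{ch.name} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g} "
                        f"{o[0]:.17g} {o[1]:.17g} {o[2]:.17g} {w:.17g}\n")


def read_coil_file(path) -> CoilModel:
    groups: dict[str, list[list[float]]] = {}
    order: list[str] = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 8:
                raise ExchangeError("coil file lines need 8 fields")
            cid = parts[0]
            if cid not in groups:
                groups[cid] = []
                order.append(cid)
            groups[cid].append([float(x) for x in parts[1:]])
    chans = []
    for cid in order:
        rows = np.asarray(groups[cid])
        chans.append(Coil(name=cid, points=rows[:, :3],
                          orientations=rows[:, 3:6], weights=rows[:, 6]))
    return CoilModel(channels=chans)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix_binary(matrix: np.ndarray, path, channel_names=None,
                        kind: str = "matrix") -> None:
    """Row-major float64 .bin with a JSON sidecar (shape, channels, kind)."""
    m = np.ascontiguousarray(matrix, dtype=np.float64)
    path = Path(path)
    m.tofile(path)
    sidecar = {
        "kind": kind,
        "shape": list(m.shape),
        "dtype": "float64",
        "order": "C",
        "channel_names": list(channel_names) if channel_names else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix_binary(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    m = np.fromfile(path, dtype=np.float64).reshape(meta["shape"])
    return m, meta


def write_leadfield_text(lf: Leadfield, path) -> None:
    with open(path, "w") as f:
        f.write(_header("leadfield"))
        f.write(f"# modality={lf.modality} channels={lf.matrix.shape[0]} "
                f"columns={lf.matrix.shape[1]}\n")
        np.savetxt(f, lf.matrix, fmt="%.17g")


def read_leadfield_text(path) -> np.ndarray:
    return _load_rows(path)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

CONFIG_DEFAULTS: dict[str, dict[str, str]] = {
    "mesh": {
        "source": "sphere",  # sphere | msh
        "path": "",
        "radii_mm": "92, 86, 80",
        "tissue_ids": "1, 2, 4",
        "edge_length_mm": "8",
        "seed": "0",
    },
    "conductivity": {
        "mode": "default",  # default | tensor-file | simulated
        "tensor_file": "",
        "overrides": "",  # e.g. "1:0.33, 2:0.0042, 4:0.33"
        "simulated_tissue": "2",
        "simulated_ratio": "10",
        "max_conductivity": "2.0",
        "max_ratio": "10.0",
    },
    "solver": {
        "tolerance": "1e-8",
        "max_iterations": "10000",
        "preconditioner": "auto",
    },
    "source_model": {
        "model": "venant",  # venant | partial_integration
        "dipole_file": "",
        "allowed_tissues": "4",
        "moment_order": "2",
        "reference_length_m": "0.02",
        "weighting_exponent": "1",
        "regularization": "1e-6",
    },
    "sensors": {
        "modality": "eeg",  # eeg | meg
        "electrode_file": "",
        "coil_file": "",
    },
    "output": {
        "directory": "out",
        "write_transfer": "false",
    },
}


class PipelineConfig:
    """Flat-keyed INI configuration with documented defaults.

    Unknown sections or keys are rejected (naming the offender); a parsed
    configuration re-serializes to an identical INI body.
    """

    def __init__(self, values: dict[str, dict[str, str]] | None = None):
        self.values = {s: dict(d) for s, d in CONFIG_DEFAULTS.items()}
        for sec, kv in (values or {}).items():
            if sec not in self.values:
                raise ExchangeError(f"unknown config section [{sec}]")
            for key, val in kv.items():
                if key not in self.values[sec]:
                    raise ExchangeError(f"unknown key {key!r} in section [{sec}]")
                self.values[sec][key] = str(val)

    def get(self, section: str, key: str) -> str:
        return self.values[section][key]

    def getfloat(self, section: str, key: str) -> float:
        return float(self.get(section, key))

    def getint(self, section: str, key: str) -> int:
        return int(self.get(section, key))

    def getbool(self, section: str, key: str) -> bool:
        return self.get(section, key).strip().lower() in ("1", "true", "yes", "on")

    def getlist(self, section: str, key: str) -> list[float]:
        raw = self.get(section, key).strip()
        return [float(x) for x in raw.split(",")] if raw else []

    @classmethod
    def from_ini(cls, path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        cp.optionxform = str
        with open(path) as f:
            cp.read_file(f)
        return cls({s: dict(cp[s]) for s in cp.sections()})

    def to_ini(self, path) -> None:
        cp = configparser.ConfigParser()
        cp.optionxform = str
        for sec, kv in self.values.items():
            cp[sec] = kv
        with open(path, "w") as f:
            cp.write(f)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_exchange_bundle(mesh, cond, sources, sensors, config: PipelineConfig,
                          out_dir) -> dict[str, dict[str, str]]:
    """Write the full forward-run file set; returns {name: {path, sha256}}.

    ``sources`` is (positions, moments); ``sensors`` is either an (E,3)
    electrode array or a :class:`CoilModel`.
    """
    from .msh import write_msh

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, str]] = {}

    def record(name, path):
        manifest[name] = {"path": str(path), "sha256": _sha256(path)}

    mesh_path = out / "mesh.msh"
    write_msh(mesh, mesh_path)
    record("mesh", mesh_path)

    tensors = cond.element_tensors(mesh)
    if len(tensors) != mesh.n_elements:
        raise ExchangeError("tensor count inconsistent with mesh")
    tpath = out / "conductivity.tensors"
    write_tensor_file(tensors, tpath)
    record("tensors", tpath)

    pos, mom = sources
    dpath = out / "dipoles.txt"
    write_dipole_file(pos, mom, dpath)
    record("dipoles", dpath)

    if isinstance(sensors, CoilModel):
        spath = out / "coils.txt"
        write_coil_file(sensors, spath)
    else:
        spath = out / "electrodes.txt"
        write_electrode_file(np.asarray(sensors), spath)
    record("sensors", spath)

    cpath = out / "parameters.ini"
    config.to_ini(cpath)
    record("parameters", cpath)
    return manifest
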