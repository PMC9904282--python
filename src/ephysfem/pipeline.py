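"""End-to-end forward pipeline driven by an INI configuration.

Stages: mesh build/load -> conductivity assignment -> stiffness assembly ->
transfer matrix -> source right-hand sides -> leadfield -> export.  Every
stage logs structured key=value records and all randomness flows through
explicit seeds, so identical configurations reproduce identical files.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np

from . import conductivity as ct
from . import exchange as ex
from . import fem, meg, mesh as mm, msh, sources as src


class PipelineError(RuntimeError):
    pass


class RunLog:
    def __init__(self, verbose: bool = False):
        self.records: list[str] = []
        self.verbose = verbose
        self.warnings: dict[str, int] = {}

    def log(self, stage: str, **kv):
        line = f"stage={stage} " + " ".join(f"{k}={v}" for k, v in kv.items())
        self.records.append(line)
        if self.verbose:
            print(line)

    def count(self, key: str, n: int = 1):
        self.warnings[key] = self.warnings.get(key, 0) + n

    def summary(self) -> str:
        lines = list(self.records)
        for k, v in sorted(self.warnings.items()):
            lines.append(f"warning={k} count={v}")
        return "\n".join(lines) + "\n"


def _stage(log: RunLog, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.log(name, seconds=f"{time.perf_counter() - self.t0:.2f}")
    return _Ctx()


def _build_mesh(cfg: ex.PipelineConfig, log: RunLog) -> mm.FEMesh:
    source = cfg.get("mesh", "source")
    if source == "msh":
        path = cfg.get("mesh", "path")
        if not path or not Path(path).exists():
            raise PipelineError(f"mesh file not found: {path!r}")
        m = msh.read_msh(path)
    elif source == "sphere":
        radii = [r / 1000.0 for r in cfg.getlist("mesh", "radii_mm")]
        ids = [int(t) for t in cfg.getlist("mesh", "tissue_ids")]
        m = mm.build_nested_sphere_mesh(
            radii, ids, cfg.getfloat("mesh", "edge_length_mm") / 1000.0,
            seed=cfg.getint("mesh", "seed"),
        )
    else:
        raise PipelineError(f"unknown mesh source {source!r}")
    log.log("mesh", elements=m.n_elements, vertices=m.n_vertices,
            kind=m.element_kind)
    return m


def _parse_overrides(raw: str) -> dict[int, float]:
    out: dict[int, float] = {}
    for part in raw.split(","):
        part = part.strip()
        if not part:
            continue
        tid, val = part.split(":")
        out[int(tid)] = float(val)
    return out


def _build_conductivity(cfg, m, log) -> ct.ConductivityModel:
    mode = cfg.get("conductivity", "mode")
    overrides = _parse_overrides(cfg.get("conductivity", "overrides"))
    base = ct.default_isotropic(m, overrides=overrides or None)
    if mode == "default":
        cond = base
    elif mode == "tensor-file":
        path = cfg.get("conductivity", "tensor_file")
        if not path or not Path(path).exists():
            raise PipelineError(f"conductivity tensor file not found: {path!r}")
        tensors = ex.read_tensor_file(path)
        if len(tensors) != m.n_elements:
            raise PipelineError("tensor file length does not match mesh")
        params = ct.EmaParameters(
            max_conductivity=cfg.getfloat("conductivity", "max_conductivity"),
            max_eigenvalue_ratio=cfg.getfloat("conductivity", "max_ratio"),
        )
        cond = ct.ConductivityModel(
            mode="tensor", per_tissue=base.per_tissue,
            per_element_tensor=ct.constrain_tensors(tensors, params),
            provenance="ema", mesh_fingerprint=m.fingerprint(),
        )
    elif mode == "simulated":
        cond = ct.simulated_tensor(
            m, cfg.getint("conductivity", "simulated_tissue"),
            cfg.getfloat("conductivity", "simulated_ratio"), cond=base,
        )
    else:
        raise PipelineError(f"unknown conductivity mode {mode!r}")
    log.log("conductivity", mode=mode, provenance=cond.provenance)
    return cond


def run_pipeline(cfg: ex.PipelineConfig, verbose: bool = False) -> dict:
    """Execute the configured forward computation; returns a result dict
    with output paths and the structured run log."""
    log = RunLog(verbose=verbose)
    log.log("start", version="1")

    with _stage(log, "mesh"):
        m = _build_mesh(cfg, log)
    with _stage(log, "conductivity"):
        cond = _build_conductivity(cfg, m, log)
    with _stage(log, "assembly"):
        K = fem.assemble_stiffness(m, cond)
    opts = fem.SolverOptions(
        relative_tolerance=cfg.getfloat("solver", "tolerance"),
        max_iterations=cfg.getint("solver", "max_iterations"),
        preconditioner=cfg.get("solver", "preconditioner"),
    )

    with _stage(log, "sources"):
        dfile = cfg.get("source_model", "dipole_file")
        if not dfile or not Path(dfile).exists():
            raise PipelineError(f"dipole file not found: {dfile!r}")
        pos, mom = ex.read_dipole_file(dfile)
        space = src.SourceSpace(positions=pos, moments=mom)
        allowed = {int(t) for t in cfg.getlist("source_model", "allowed_tissues")}
        model = cfg.get("source_model", "model")
        valid, report = src.validate_sources(
            space, m, allowed, check_venant=(model == "venant"))
        space.valid = valid
        if report["n_invalid"]:
            log.count("invalid_sources", report["n_invalid"])
        log.log("sources", **report)
        params = src.VenantParameters(
            moment_order=cfg.getint("source_model", "moment_order"),
            reference_length=cfg.getfloat("source_model", "reference_length_m"),
            weighting_exponent=cfg.getint("source_model", "weighting_exponent"),
            regularization=cfg.getfloat("source_model", "regularization"),
        )
        B = src.build_rhs_matrix(m, space, model=model, params=params)

    modality = cfg.get("sensors", "modality")
    out = Path(cfg.get("output", "directory"))
    out.mkdir(parents=True, exist_ok=True)
    with _stage(log, "leadfield"):
        if modality == "eeg":
            efile = cfg.get("sensors", "electrode_file")
            if not efile or not Path(efile).exists():
                raise PipelineError(f"electrode file not found: {efile!r}")
            elec = ex.read_electrode_file(efile)
            R = fem.attach_electrodes(m, elec)
            T = fem.eeg_transfer(K, R, opts)
            lf = fem.eeg_leadfield(T, B, source_positions=space.positions)
        elif modality == "meg":
            cfile = cfg.get("sensors", "coil_file")
            if not cfile or not Path(cfile).exists():
                raise PipelineError(f"coil file not found: {cfile!r}")
            coils = ex.read_coil_file(cfile)
            integ = meg.build_meg_integration(m, cond, coils)
            T = meg.meg_transfer(K, integ, opts)
            lf = meg.meg_leadfield(m, cond, coils, space, model=model,
                                   params=params, opts=opts, K=K, transfer=T)
        else:
            raise PipelineError(f"unknown modality {modality!r}")
        log.log("leadfield", channels=lf.matrix.shape[0],
                columns=lf.matrix.shape[1],
                finite=bool(np.isfinite(lf.matrix).all()))

    with _stage(log, "export"):
        lf_path = out / f"leadfield_{modality}.txt"
        ex.write_leadfield_text(lf, lf_path)
        results = {"leadfield": str(lf_path)}
        if cfg.getbool("output", "write_transfer"):
            tpath = out / f"transfer_{modality}.bin"
            ex.write_matrix_binary(T.matrix, tpath,
                                   channel_names=T.channel_names,
                                   kind="transfer")
            results["transfer"] = str(tpath)
        (out / "run.log").write_text(log.summary())
        results["log"] = str(out / "run.log")

    results["leadfield_matrix"] = lf.matrix
    results["log_records"] = log.records
    results["warning_counts"] = log.warnings
    return results
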