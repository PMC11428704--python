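"""Config-driven end-to-end runs: geometry → solve → WSS → indices → report.

A run is described by a YAML/JSON config (validated with pydantic),
executed deterministically for a fixed (config, seed) pair, and exported
as a bundle of text artifacts: VTK mesh and field snapshots, CSV probe
waveforms and WSS/index tables, and a machine-readable ``summary.json``
whose schema ships alongside it.  All internal computation is SI;
mmHg/mL conversions happen only at the I/O boundary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import presets
from .geometry import StructuredMesh, VesselSpec, build_vessel
from .indices import (IndexMaps, WSSSeries, compute_index_maps,
                      index_maps_to_csv, wss_series_to_csv, wss_snapshots)
from .rheology import RheologyParams
from .solver import (FlowSeries, SolverConfig, solve_transient,
                     wall_shear_stress)
from .vtk_io import write_vtk_flow_series, write_vtk_mesh, write_vtk_wall_map
from .waveforms import (Waveform, WaveformSpec, synthesize_pulse,
                        systolic_metrics, waveform_from_csv,
                        waveform_percent_difference, waveform_to_csv)

__all__ = [
    "RunConfig",
    "ProbeSet",
    "ConfigError",
    "ProbeError",
    "load_config",
    "run_case",
    "probe_pressure",
    "validate_against_reference",
    "export_bundle",
    "RunSummary",
]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class ProbeError(ValueError):
    """A probe point does not lie inside the fluid domain."""


class VesselModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "straight"
    inlet_diameter: float = 20.0
    outlet_diameter: Optional[float] = None
    length: float = 100.0
    bend_angle: float = 0.0
    true_lumen_diameter: float | Tuple[float, float] = 0.0
    false_lumen_diameter: float | Tuple[float, float] = 0.0
    septum_thickness: float = presets.DEFAULT_SEPTUM_THICKNESS_MM
    tear_positions: List[Tuple[float, float]] = Field(default_factory=list)


class WaveformModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    period: float = presets.CARDIAC_PERIOD
    peak_time: float = presets.SYSTOLIC_PEAK_TIME
    systolic_level: float = presets.SYSTOLIC_PRESSURE_MMHG
    diastolic_level: float = presets.DIASTOLIC_PRESSURE_MMHG
    harmonic_count: int = 8
    unit: str = "mmHg"
    sharpness: float = 8.0


class RheologyModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    density: float = presets.BLOOD_DENSITY
    mu_inf: float = presets.MU_INF
    mu_zero: float = presets.MU_ZERO
    lambda_time: float = presets.LAMBDA_TIME
    power_n: float = presets.POWER_N


class SolverModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    time_step: Optional[float] = None
    cycles: int = 3
    residual_tolerance: float = presets.RESIDUAL_TOLERANCE
    max_inner_iterations: int = 3
    advection_scheme: str = "upwind"
    inlet_profile: str = "auto"
    n_record: int = 100


class RunConfig(BaseModel):
    """Validated run configuration (units: mm for geometry, SI elsewhere;
    waveform levels in the unit each waveform declares)."""

    model_config = ConfigDict(extra="forbid")
    vessel: VesselModel = Field(default_factory=VesselModel)
    resolution: int = 16
    inlet_waveform: WaveformModel = Field(
        default_factory=lambda: WaveformModel(
            systolic_level=0.4, diastolic_level=0.02, unit="m/s"))
    outlet_waveform: WaveformModel = Field(default_factory=WaveformModel)
    rheology: RheologyModel = Field(default_factory=RheologyModel)
    solver: SolverModel = Field(default_factory=SolverModel)
    probes: Dict[str, Tuple[float, float]] = Field(default_factory=dict)
    snapshot_times: List[float] = Field(
        default_factory=lambda: list(presets.WSS_SNAPSHOT_TIMES))
    export_fields: bool = True
    seed: int = 0


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run config file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raise ConfigError(f"{path}: empty config")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


class ProbeSet:
    """Named probe points (mm coordinates) validated against a mesh."""

    def __init__(self, probes: Dict[str, Tuple[float, float]],
                 mesh: StructuredMesh):
        self.points: Dict[str, Tuple[float, float]] = {}
        for name, (x_mm, y_mm) in probes.items():
            x, y = x_mm * 1e-3, y_mm * 1e-3
            i = int(np.searchsorted(mesh.x_faces, x) - 1)
            j = int(np.searchsorted(mesh.y_faces, y) - 1)
            ni, nj = mesh.shape
            if not (0 <= i < ni and 0 <= j < nj and mesh.fluid[i, j]):
                raise ProbeError(
                    f"probe {name!r} at ({x_mm}, {y_mm}) mm is outside the "
                    "fluid domain")
            self.points[name] = (x, y)

    @staticmethod
    def lumen_presets(mesh: StructuredMesh) -> Dict[str, Tuple[float, float]]:
        """Analogue probe points (mm): mid-length centre of each lumen for
        dissected meshes, or proximal/distal centreline points otherwise."""
        x0 = mesh.x_faces[0] * 1e3
        x1 = mesh.x_faces[-1] * 1e3
        if np.any(mesh.septum):
            j_sep = np.nonzero(np.any(mesh.septum, axis=0))[0]
            y_true = 0.5 * (mesh.y_faces[0] + mesh.y_faces[j_sep[0]]) * 1e3
            y_false = 0.5 * (mesh.y_faces[j_sep[-1] + 1]
                             + mesh.y_faces[-1]) * 1e3
            xm = 0.5 * (x0 + x1)
            return {"true_lumen_mid": (xm, y_true),
                    "false_lumen_mid": (xm, y_false)}
        yc = 0.5 * (mesh.y_faces[0] + mesh.y_faces[-1]) * 1e3
        return {"proximal": (x0 + 0.25 * (x1 - x0), yc),
                "distal": (x0 + 0.75 * (x1 - x0), yc)}


def probe_pressure(series: FlowSeries, probes: ProbeSet,
                   mesh: StructuredMesh) -> Dict[str, dict]:
    """Absolute pressure waveform (mmHg) and min/mean/max per probe.

    The gauge field is interpolated bilinearly at the probe point per
    recorded instant; the outlet waveform value is added back, and the
    mmHg conversion is applied on output only.
    """
    xc = 0.5 * (mesh.x_faces[:-1] + mesh.x_faces[1:])
    yc = 0.5 * (mesh.y_faces[:-1] + mesh.y_faces[1:])
    out = {}
    for name, (x, y) in probes.points.items():
        i = int(np.clip(np.searchsorted(xc, x) - 1, 0, xc.size - 2))
        j = int(np.clip(np.searchsorted(yc, y) - 1, 0, yc.size - 2))
        wx = (x - xc[i]) / (xc[i + 1] - xc[i])
        wy = (y - yc[j]) / (yc[j + 1] - yc[j])
        wx, wy = np.clip(wx, 0.0, 1.0), np.clip(wy, 0.0, 1.0)
        trace = ((1 - wx) * (1 - wy) * series.p[:, i, j]
                 + wx * (1 - wy) * series.p[:, i + 1, j]
                 + (1 - wx) * wy * series.p[:, i, j + 1]
                 + wx * wy * series.p[:, i + 1, j + 1])
        absolute = (trace + series.outlet_pressure) / presets.MMHG_TO_PA
        wf = Waveform(values=absolute, period=series.period, unit="mmHg")
        out[name] = {
            "waveform": wf,
            "min": float(np.min(absolute)),
            "mean": float(np.mean(absolute)),
            "max": float(np.max(absolute)),
        }
    return out


def validate_against_reference(case_flow: Waveform, reference_csv) -> dict:
    """Relative-L2 percent difference of a flow-rate waveform (mL/s)
    against a reference CSV, plus per-sample residuals on the common grid."""
    ref = waveform_from_csv(reference_csv)
    if ref.unit != "mL/s":
        raise ValueError(f"reference must be in mL/s, got {ref.unit!r}")
    if case_flow.unit != "mL/s":
        raise ValueError("case flow waveform must be in mL/s")
    pct = waveform_percent_difference(case_flow, ref)
    n = max(case_flow.n_samples, ref.n_samples)
    t = np.arange(n) * case_flow.period / n
    residuals = case_flow.sample_at(t) - ref.sample_at(t)
    return {"percent_difference": pct,
            "times_s": t.tolist(),
            "residuals_mL_s": residuals.tolist()}


class ProbeSummary(BaseModel):
    min_mmHg: float
    mean_mmHg: float
    max_mmHg: float


class IndexExtrema(BaseModel):
    tawss_max_Pa: float
    tawss_min_Pa: float
    osi_max: float
    rrt_max_per_Pa: float
    ecap_max_per_Pa: float


class RunSummary(BaseModel):
    """Stable machine interface of a run; shipped as summary.json with its
    JSON schema next to it."""

    config_seed: int
    n_cells: int
    cycle_drift: float
    probes: Dict[str, ProbeSummary]
    index_extrema: IndexExtrema
    systolic_comparison: Optional[dict] = None
    wss_snapshot_max_Pa: Dict[str, float]


def run_case(config: RunConfig, out_dir,
             log: Optional[Callable[[str], None]] = None) -> dict:
    """Execute a full case and export its artifact bundle.

    Returns the summary dict (also written to ``summary.json``).  Rerun
    with the same config is bitwise-reproducible: all randomness is seeded
    from ``config.seed`` and exports are deterministic.
    """
    log = log or (lambda msg: None)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        spec = VesselSpec(
            kind=config.vessel.kind,
            inlet_diameter=config.vessel.inlet_diameter,
            outlet_diameter=config.vessel.outlet_diameter,
            length=config.vessel.length,
            bend_angle=config.vessel.bend_angle,
            true_lumen_diameter=config.vessel.true_lumen_diameter,
            false_lumen_diameter=config.vessel.false_lumen_diameter,
            septum_thickness=config.vessel.septum_thickness,
            tear_positions=tuple(map(tuple, config.vessel.tear_positions)),
        )
    except ValueError as exc:
        raise ConfigError(f"vessel: {exc}") from exc
    log("building mesh")
    mesh = build_vessel(spec, config.resolution)
    mesh.validate()

    inlet = synthesize_pulse(
        WaveformSpec(**config.inlet_waveform.model_dump()), seed=config.seed)
    outlet = synthesize_pulse(
        WaveformSpec(**config.outlet_waveform.model_dump()), seed=config.seed)
    rheo = RheologyParams(**config.rheology.model_dump())
    solver_cfg = SolverConfig(**config.solver.model_dump())

    log("solving transient flow")
    series = solve_transient(mesh, inlet, outlet, rheo, solver_cfg)
    log("extracting wall shear stress")
    wss = wall_shear_stress(series, mesh, rheo)
    maps = compute_index_maps(wss)
    snap_times = [t for t in config.snapshot_times if t <= series.period]
    snaps = wss_snapshots(wss, snap_times)

    probe_defs = config.probes or ProbeSet.lumen_presets(mesh)
    probe_set = ProbeSet(probe_defs, mesh)
    probe_data = probe_pressure(series, probe_set, mesh)

    systolic = None
    names = list(probe_data)
    if len(names) >= 2:
        systolic = systolic_metrics(probe_data[names[1]]["waveform"],
                                    probe_data[names[0]]["waveform"])
        systolic = {"test_probe": names[1], "reference_probe": names[0],
                    **systolic}

    summary = RunSummary(
        config_seed=config.seed,
        n_cells=mesh.n_cells,
        cycle_drift=float(series.diagnostics.get("cycle_drift", np.nan)),
        probes={k: ProbeSummary(min_mmHg=v["min"], mean_mmHg=v["mean"],
                                max_mmHg=v["max"])
                for k, v in probe_data.items()},
        index_extrema=IndexExtrema(
            tawss_max_Pa=float(np.max(maps.tawss)),
            tawss_min_Pa=float(np.min(maps.tawss)),
            osi_max=float(np.max(maps.osi)),
            rrt_max_per_Pa=float(np.max(maps.rrt)),
            ecap_max_per_Pa=float(np.max(maps.ecap)),
        ),
        systolic_comparison=systolic,
        wss_snapshot_max_Pa={f"{t:g}": float(np.max(m))
                             for t, m in snaps.items()},
    )

    log("exporting bundle")
    export_bundle({
        "mesh": mesh, "series": series, "wss": wss, "maps": maps,
        "probes": probe_data, "summary": summary,
        "export_fields": config.export_fields,
    }, out_dir)
    return summary.model_dump()


def export_bundle(artifacts: dict, directory) -> List[Path]:
    """Write the artifact bundle with stable names; overwrites in place."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    mesh: StructuredMesh = artifacts["mesh"]
    write_vtk_mesh(directory / "mesh.vtk", mesh)
    written.append(directory / "mesh.vtk")

    series: FlowSeries = artifacts["series"]
    if artifacts.get("export_fields", True):
        written += write_vtk_flow_series(directory / "fields", "flow",
                                         mesh, series)

    wss: WSSSeries = artifacts["wss"]
    wss_series_to_csv(wss, directory / "wss_series.csv")
    written.append(directory / "wss_series.csv")

    maps: IndexMaps = artifacts["maps"]
    index_maps_to_csv(maps, directory / "index_maps.csv")
    written.append(directory / "index_maps.csv")
    if wss.positions is not None:
        write_vtk_wall_map(directory / "wall_indices.vtk", maps,
                           wss.positions)
        written.append(directory / "wall_indices.vtk")

    for name, data in artifacts["probes"].items():
        path = directory / f"probe_{name}.csv"
        waveform_to_csv(data["waveform"], path)
        written.append(path)

    summary: RunSummary = artifacts["summary"]
    spath = directory / "summary.json"
    spath.write_text(json.dumps(summary.model_dump(), indent=1,
                                sort_keys=True))
    schema = directory / "summary.schema.json"
    schema.write_text(json.dumps(RunSummary.model_json_schema(), indent=1,
                                 sort_keys=True))
    written += [spath, schema]
    return written
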