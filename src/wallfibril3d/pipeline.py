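"""End-to-end runs: configuration, orchestration, reports.

A run takes either a phantom preset or a volume file, analyses one or
more ROIs, and writes measurement tables, summary statistics, provenance
and (optionally) ground-truth recovery reports to an output directory.
Every run writes its resolved configuration next to its outputs, and is
bit-reproducible from that file plus the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .filtering import DiffusionParams
from .metrology import AnalysisConfig, AnalysisROI, analyze_roi
from .phantom import (GroundTruth, PhantomSpec, apply_imaging_model,
                      generate_wall_phantom, make_preset, write_ground_truth)
from .skeleton import ClassifyParams
from .stats import notch_overlap_test, summarize, threshold_sensitivity
from .volume import DensityVolume, read_volume, write_volume

__all__ = ["RunConfig", "run_pipeline", "recovery_report", "load_config", "save_config"]

log = logging.getLogger(__name__)

MEASUREMENT_TYPES = ("diameter", "edge_gap", "center_dist", "crosslink_len")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    preset: str | None = None          # phantom preset name, or
    input_path: str | None = None      # a volume file on disk
    voxel_size: float | None = None    # nm, required for TIFF input
    group: str = ""
    seed: int = 0
    n_rois: int = 1
    roi_shape: tuple[int, int, int] | None = None  # (nx, ny, nz) phantom override
    snr: float | None = None
    psf_sigma: float | None = None
    missing_wedge_halfangle_deg: float | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "wallfibril3d_out"
    write_volumes: bool = False
    write_truth: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ana = d.get("analysis")
        if isinstance(ana, dict):
            ana = dict(ana)
            if isinstance(ana.get("diffusion"), dict):
                ana["diffusion"] = DiffusionParams(**ana["diffusion"])
            if isinstance(ana.get("classify"), dict):
                cp = dict(ana["classify"])
                if isinstance(cp.get("crosslink_dz_range"), list):
                    cp["crosslink_dz_range"] = tuple(cp["crosslink_dz_range"])
                ana["classify"] = ClassifyParams(**cp)
            d["analysis"] = AnalysisConfig(**ana)
        if isinstance(d.get("roi_shape"), list):
            d["roi_shape"] = tuple(d["roi_shape"])
        return cls(**d)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _phantom_spec(config: RunConfig, seed: int) -> PhantomSpec:
    overrides: dict = {"seed": seed}
    if config.roi_shape is not None:
        overrides["shape_voxels"] = tuple(config.roi_shape)
    if config.snr is not None:
        overrides["snr"] = config.snr
    if config.psf_sigma is not None:
        overrides["psf_sigma"] = config.psf_sigma
    if config.missing_wedge_halfangle_deg is not None:
        overrides["missing_wedge_halfangle_deg"] = config.missing_wedge_halfangle_deg
    return make_preset(config.preset, **overrides)


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run and write its output bundle.

    Returns a summary dict with the per-type statistics and file paths.
    """
    if (config.preset is None) == (config.input_path is None):
        raise ValueError("exactly one of preset / input_path must be set")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")

    tables: list[pd.DataFrame] = []
    provs: list[dict] = []
    truths: list[GroundTruth] = []
    for r in range(config.n_rois):
        roi_seed = (config.seed + 1009 * r) & 0x7FFFFFFF
        if config.preset is not None:
            spec = _phantom_spec(config, roi_seed)
            clean, truth = generate_wall_phantom(spec)
            vol = apply_imaging_model(clean, spec, truth)
            truths.append(truth)
            ana = _analysis_for(config, spec)
            if config.write_truth:
                write_ground_truth(truth, spec, out / f"truth_roi{r}")
            if config.write_volumes:
                write_volume(vol, out / f"roi{r}.mrc")
        else:
            vol = read_volume(config.input_path, voxel_size=config.voxel_size)
            ana = _analysis_for(config, None)
        roi = AnalysisROI(group=config.group or (config.preset or "volume"),
                          roi_id=f"roi{r}", seed=roi_seed)
        table, prov = analyze_roi(vol, roi, ana)
        tables.append(table)
        provs.append(prov)

    nonempty = [t for t in tables if len(t)]
    table = pd.concat(nonempty, ignore_index=True) if nonempty else tables[0]
    table.to_csv(out / "measurements.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(provs, indent=2, default=str))

    stats = {}
    for mtype in MEASUREMENT_TYPES:
        vals = table.loc[table["type"] == mtype, "value_nm"].to_numpy(float)
        if vals.size:
            stats[mtype] = summarize(vals)
    (out / "summary.json").write_text(json.dumps(stats, indent=2))

    result = {"measurements": str(out / "measurements.csv"),
              "summary": stats, "n_rois": config.n_rois}
    if truths and config.write_truth:
        report = recovery_report(table, truths)
        report.to_csv(out / "recovery.csv", index=False)
        result["recovery"] = str(out / "recovery.csv")
    log.info("run_pipeline: wrote %s", out)
    return result


def _analysis_for(config: RunConfig, spec: PhantomSpec | None) -> AnalysisConfig:
    import copy

    ana = copy.deepcopy(config.analysis)
    ana.seed = config.seed
    if spec is not None:
        ana.polarity = "dense_dark" if spec.contrast_mode == "cryo" else "dense_bright"
    return ana


_TRUTH_GETTERS = {
    "diameter": lambda t: t.diameters(),
    "edge_gap": lambda t: t.drawn_gaps,
    "crosslink_len": lambda t: t.crosslink_lengths(),
}


def recovery_report(measurements: pd.DataFrame, truths: list[GroundTruth] | GroundTruth,
                    tolerance_nm: float = 0.87,
                    tolerance_rel: float = 0.15) -> pd.DataFrame:
    """Recovered vs generated statistics per measurement type.

    Passes when |recovered mean - truth mean| <= max(tolerance_nm,
    tolerance_rel * truth mean) — one voxel or 15% by default.
    """
    if isinstance(truths, GroundTruth):
        truths = [truths]
    rows = []
    for mtype, getter in _TRUTH_GETTERS.items():
        tvals = np.concatenate([np.atleast_1d(getter(t)) for t in truths]) \
            if truths else np.empty(0)
        mvals = measurements.loc[measurements["type"] == mtype, "value_nm"].to_numpy(float)
        if tvals.size == 0 and mvals.size == 0:
            continue
        if mvals.size == 0:
            rows.append(dict(type=mtype, status="no data", passed=False))
            continue
        truth_mean = float(tvals.mean()) if tvals.size else np.nan
        bias = float(mvals.mean() - truth_mean) if tvals.size else np.nan
        tol = max(tolerance_nm, tolerance_rel * abs(truth_mean)) if tvals.size else np.nan
        rows.append(dict(
            type=mtype, status="ok",
            truth_mean=truth_mean,
            truth_sd=float(tvals.std(ddof=1)) if tvals.size > 1 else 0.0,
            recovered_mean=float(mvals.mean()),
            recovered_sd=float(mvals.std(ddof=1)) if mvals.size > 1 else 0.0,
            n=int(mvals.size), bias=bias, tolerance=tol,
            passed=bool(abs(bias) <= tol) if tvals.size else False,
        ))
    if not rows:
        rows.append(dict(type="none", status="no data", passed=False))
    return pd.DataFrame(rows)


def compare_groups(table_a: pd.DataFrame, table_b: pd.DataFrame,
                   types: tuple[str, ...] = ("diameter", "edge_gap", "crosslink_len")
                   ) -> pd.DataFrame:
    """Notched-boxplot comparison of two measurement tables per type."""
    rows = []
    for mtype in types:
        a = table_a.loc[table_a["type"] == mtype, "value_nm"].to_numpy(float)
        b = table_b.loc[table_b["type"] == mtype, "value_nm"].to_numpy(float)
        if a.size == 0 or b.size == 0:
            rows.append(dict(type=mtype, verdict="no data"))
            continue
        cmp = notch_overlap_test(a, b)
        rows.append(dict(
            type=mtype, verdict=cmp.verdict,
            median_a=cmp.stats_a.median, median_b=cmp.stats_b.median,
            notch_a=f"({cmp.stats_a.notch_low:.2f}, {cmp.stats_a.notch_high:.2f})",
            notch_b=f"({cmp.stats_b.notch_low:.2f}, {cmp.stats_b.notch_high:.2f})",
            n_a=cmp.stats_a.n, n_b=cmp.stats_b.n))
    return pd.DataFrame(rows)
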