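"""Predefined validation experiments.

Each function runs one self-contained study on synthetic phantoms —
parameter recovery per preparation preset, two-group discrimination,
extraction control, threshold robustness, thinning topology — at problem
sizes chosen for a single workstation CPU (ROIs of 160 x 160 x 48 voxels
at 0.87 nm/voxel rather than the full 500 x 500 x Z study ROIs; the
phantom statistics are size-invariant, only the measurement counts
shrink).  They are used by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .metrology import AnalysisConfig, AnalysisROI, analyze_roi
from .phantom import (PhantomSpec, apply_imaging_model, generate_wall_phantom,
                      make_preset)
from .segmentation import FOREGROUND_STRUCT
from .skeleton import thin3d
from .stats import notch_overlap_test, threshold_sensitivity
from .volume import DensityVolume, bin_volume

RECOVERY_SHAPE = (160, 160, 48)      # (nx, ny, nz) per analysis ROI
# chemically-prepared walls are sparse (17 nm spacings): a wider field is
# needed to pool comparable measurement counts per ROI
RECOVERY_SHAPE_SPARSE = (224, 224, 56)
SPARSE_PRESETS = ("chem", "extracted")
RECOVERY_IMAGING = dict(snr=3.0, psf_sigma=1.0, missing_wedge_halfangle_deg=60.0)
RECOVERY_PRESETS = ("chem", "hpf", "cryo", "wt_hypocotyl", "cob6")
DEFAULT_THRESHOLD = 0.65             # SD units, the package's operating point


def roi_shape_for(preset: str) -> tuple[int, int, int]:
    return RECOVERY_SHAPE_SPARSE if preset in SPARSE_PRESETS else RECOVERY_SHAPE


def _base_seed(seed: int, salt: int) -> int:
    return int((seed * 2654435761 + salt) % (2 ** 31 - 1))


def binning_pixel_size(seed: int = 0) -> float:
    """Bin a 0.43 nm/voxel volume by 2 and report the effective pixel
    size at the acquisition software's printed precision (2 decimals)."""
    rng = np.random.default_rng(seed)
    vol = DensityVolume(rng.normal(size=(16, 16, 16)).astype(np.float32), 0.43)
    return round(bin_volume(vol, 2).voxel_size, 2)


def _analysis_config(spec: PhantomSpec, seed: int, **kw) -> AnalysisConfig:
    cfg = AnalysisConfig(
        polarity="dense_dark" if spec.contrast_mode == "cryo" else "dense_bright",
        threshold=DEFAULT_THRESHOLD, seed=seed)
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


def run_preset_rois(preset: str, seed: int, n_rois: int = 3,
                    shape: tuple[int, int, int] | None = None,
                    n_planes: int = 2, **spec_overrides
                    ) -> tuple[pd.DataFrame, dict]:
    """Generate and analyse ``n_rois`` phantom volumes of one preset
    under the standard degraded-imaging conditions; returns the pooled
    measurement table and the pooled generated truth statistics."""
    if shape is None:
        shape = roi_shape_for(preset)
    overrides = dict(RECOVERY_IMAGING)
    overrides.update(spec_overrides)
    tables = []
    truth_vals: dict[str, list[np.ndarray]] = {
        "diameter": [], "edge_gap": [], "crosslink_len": []}
    for r in range(n_rois):
        spec = make_preset(preset, shape_voxels=shape,
                           seed=_base_seed(seed, 101 + r), **overrides)
        clean, truth = generate_wall_phantom(spec)
        vol = apply_imaging_model(clean, spec, truth)
        cfg = _analysis_config(spec, seed=_base_seed(seed, 7 + r),
                               n_planes=n_planes)
        table, _ = analyze_roi(vol, AnalysisROI(group=preset, roi_id=f"roi{r}",
                                                seed=0), cfg)
        tables.append(table)
        truth_vals["diameter"].append(truth.diameters())
        truth_vals["edge_gap"].append(truth.drawn_gaps)
        truth_vals["crosslink_len"].append(truth.crosslink_lengths())
    nonempty = [t for t in tables if len(t)]
    pooled = pd.concat(nonempty, ignore_index=True) if nonempty else tables[0]
    truth_stats = {k: float(np.concatenate(v).mean()) if sum(x.size for x in v)
                   else float("nan") for k, v in truth_vals.items()}
    return pooled, truth_stats


def preset_recovery(preset: str, seed: int, n_rois: int = 4) -> dict:
    """Recovered vs generated means for one preset; the acceptance
    experiment behind the per-preset parameter-recovery check.

    Four scaled-down ROIs stand in for the study's three full-size
    volumes per condition; the total measured volume sets the counts."""
    table, truth = run_preset_rois(preset, seed, n_rois=n_rois, n_planes=3)
    out = {}
    for mtype in ("diameter", "edge_gap", "crosslink_len"):
        vals = table.loc[table["type"] == mtype, "value_nm"].to_numpy(float)
        out[mtype] = dict(
            recovered=float(vals.mean()) if vals.size else float("nan"),
            truth=truth[mtype], n=int(vals.size))
    return out


def group_discrimination(seed: int, n_seeds: int = 20,
                         shape: tuple[int, int, int] = (128, 128, 40),
                         n_rois: int = 2, n_planes: int = 5) -> dict:
    """Wild-type vs mutant hypocotyl comparison, repeated over phantom
    seeds: counts how often the edge-gap notch test calls the groups
    different and the diameter notch test calls them the same.

    Each group pools two phantom ROIs per repeat (as the study pooled
    several volumes per tomogram): a single small phantom holds too few
    independent fibrils for a stable median."""
    gap_sig = 0
    diam_sig = 0
    used = 0
    for s in range(n_seeds):
        pops = {}
        for preset in ("wt_hypocotyl", "cob6"):
            tables = []
            for r in range(n_rois):
                spec = make_preset(preset, shape_voxels=shape,
                                   seed=_base_seed(seed, 1000 + 17 * s + 7 * r),
                                   **RECOVERY_IMAGING)
                clean, truth = generate_wall_phantom(spec)
                vol = apply_imaging_model(clean, spec, truth)
                cfg = _analysis_config(spec, seed=_base_seed(seed, 31 * s + 5 + r),
                                       n_planes=n_planes)
                table, _ = analyze_roi(vol, AnalysisROI(group=preset,
                                                        roi_id=f"r{r}", seed=0), cfg)
                tables.append(table)
            table = pd.concat([t for t in tables if len(t)], ignore_index=True)
            pops[preset] = {
                t: table.loc[table["type"] == t, "value_nm"].to_numpy(float)
                for t in ("edge_gap", "diameter")}
        a, b = pops["wt_hypocotyl"], pops["cob6"]
        rng = np.random.default_rng(_base_seed(seed, 999 + s))

        def take(v, n=60):
            if v.size == 0:
                return v
            if v.size >= n:
                return rng.choice(v, size=n, replace=False)
            return v

        ga, gb = take(a["edge_gap"]), take(b["edge_gap"])
        da, db = take(a["diameter"]), take(b["diameter"])
        if min(ga.size, gb.size, da.size, db.size) < 20:
            continue
        used += 1
        if notch_overlap_test(ga, gb).verdict == "significant":
            gap_sig += 1
        if notch_overlap_test(da, db).verdict == "significant":
            diam_sig += 1
    return dict(n_seeds=used, gap_significant=gap_sig, diameter_significant=diam_sig)


def extraction_control(seed: int, n_seeds: int = 20,
                       shape: tuple[int, int, int] = (128, 128, 44)) -> dict:
    """Chemically extracted walls carry no hemicellulose/pectin tethers;
    the pipeline should classify zero cross-links."""
    zero = 0
    for s in range(n_seeds):
        spec = make_preset("extracted", shape_voxels=shape,
                           seed=_base_seed(seed, 4000 + 13 * s), **RECOVERY_IMAGING)
        clean, truth = generate_wall_phantom(spec)
        assert len(truth.crosslinks) == 0
        vol = apply_imaging_model(clean, spec, truth)
        cfg = _analysis_config(spec, seed=_base_seed(seed, 11 * s + 3))
        table, prov = analyze_roi(vol, AnalysisROI(group="extracted", roi_id="r",
                                                   seed=0), cfg)
        if prov["n_crosslinks"] == 0:
            zero += 1
    return dict(n_seeds=n_seeds, zero_crosslink_seeds=zero)


def threshold_robustness(seed: int,
                         shape: tuple[int, int, int] = RECOVERY_SHAPE) -> pd.DataFrame:
    """Threshold-sensitivity sweep on one cryo phantom ROI."""
    spec = make_preset("cryo", shape_voxels=shape, seed=_base_seed(seed, 71),
                       **RECOVERY_IMAGING)
    clean, truth = generate_wall_phantom(spec)
    vol = apply_imaging_model(clean, spec, truth)
    cfg = _analysis_config(spec, seed=_base_seed(seed, 72))
    roi = AnalysisROI(group="cryo", roi_id="sweep", seed=0)
    return threshold_sensitivity(vol, roi, cfg,
                                 deltas=(-0.15, -0.05, 0.0, 0.05, 0.15))


def route_equivalence(seed: int,
                      shape: tuple[int, int, int] = RECOVERY_SHAPE) -> dict:
    """Mean diameter from the semi-automated threshold route vs the
    automated route (orientation smoothing + contour-spectrum isovalue)
    on the same cryo phantom."""
    spec = make_preset("cryo", shape_voxels=shape, seed=_base_seed(seed, 81),
                       **RECOVERY_IMAGING)
    clean, truth = generate_wall_phantom(spec)
    vol = apply_imaging_model(clean, spec, truth)
    roi = AnalysisROI(group="cryo", roi_id="route", seed=0)
    out = {}
    for route in ("threshold", "automated"):
        cfg = _analysis_config(spec, seed=_base_seed(seed, 82))
        cfg.route = route
        if route == "automated":
            cfg.threshold = None  # isovalue from the contour spectrum
        table, _ = analyze_roi(vol, roi, cfg)
        vals = table.loc[table["type"] == "diameter", "value_nm"].to_numpy(float)
        out[route] = float(vals.mean()) if vals.size else float("nan")
    out["difference"] = abs(out["threshold"] - out["automated"])
    return out


# ---------------------------------------------------------------------------
# Topology oracle
# ---------------------------------------------------------------------------

def euler_betti(mask: np.ndarray) -> tuple[int, int]:
    """(components, loops) of a voxel set by exact cell counting.

    The Euler characteristic of the union of closed voxels (which matches
    26-connectivity of the foreground) is V - E + F - C over distinct
    vertices, edges, faces and cubes; b0 comes from 26-connected
    labelling, cavities from enclosed 6-connected background components,
    and b1 = b0 + b2 - chi.
    """
    m = np.pad(np.asarray(mask, dtype=bool), 1)
    C = int(m.sum())
    adj = []
    for ax in range(3):
        s1 = [slice(None)] * 3
        s2 = [slice(None)] * 3
        s1[ax] = slice(0, -1)
        s2[ax] = slice(1, None)
        adj.append(int((m[tuple(s1)] & m[tuple(s2)]).sum()))
    F = 6 * C - sum(adj)
    E = 0
    for ax in range(3):
        x = m
        for o in [i for i in range(3) if i != ax]:
            s1 = [slice(None)] * 3
            s2 = [slice(None)] * 3
            s1[o] = slice(0, -1)
            s2[o] = slice(1, None)
            x = x[tuple(s1)] | x[tuple(s2)]
        E += int(x.sum())
    x = m
    for o in range(3):
        s1 = [slice(None)] * 3
        s2 = [slice(None)] * 3
        s1[o] = slice(0, -1)
        s2[o] = slice(1, None)
        x = x[tuple(s1)] | x[tuple(s2)]
    V = int(x.sum())
    chi = V - E + F - C
    b0 = int(ndi.label(mask, structure=FOREGROUND_STRUCT)[0].max()) if mask.any() else 0
    lab, nb = ndi.label(~np.pad(np.asarray(mask, dtype=bool), 1))
    border = set(np.unique(np.concatenate([
        lab[0].ravel(), lab[-1].ravel(), lab[:, 0].ravel(), lab[:, -1].ravel(),
        lab[:, :, 0].ravel(), lab[:, :, -1].ravel()])))
    b2 = len(set(range(1, nb + 1)) - border)
    return b0, b0 + b2 - chi


def topology_preservation(seed: int, n_masks: int = 50,
                          shape: tuple[int, int, int] = (10, 10, 10)) -> dict:
    """Thin ``n_masks`` random small masks and compare (components,
    loops) before and after against the Euler-characteristic oracle."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for i in range(n_masks):
        mask = rng.random(shape) < rng.uniform(0.2, 0.5)
        if i % 2:
            mask = ndi.binary_closing(mask)
        skel = thin3d(mask)
        if euler_betti(mask) != euler_betti(skel):
            mismatches += 1
    return dict(n_masks=n_masks, mismatches=mismatches)
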