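"""Synthetic cell-wall tomogram phantoms with known geometry.

The generator emulates thin-section tomograms of growing (primary) plant
cell walls: layers (lamellae) of near-parallel cellulose microfibrils —
soft-edged cylinders a few nm in diameter — stacked along the beam axis,
tethered by short bridge-like cross-links attributed to hemicellulose.
Every geometric primitive is recorded in a :class:`GroundTruth` ledger so
that the full measurement pipeline can be validated by parameter recovery.

Coordinate conventions
----------------------
Arrays are ordered ``(z, y, x)``; physical coordinates in nm are
``index * voxel_size`` (voxel centres on the integer lattice).  Fibrils run
along the y axis (in the section plane), lamellae stack along z (the beam
axis), and within a lamella fibrils are placed along x.  The missing wedge
of single-axis tomography is applied about the z axis with the tilt axis
along y.

Geometry model
--------------
Within-lamella surface-to-surface gaps follow the edge-gap distribution of
the chosen preset.  Lamella spacing is derived from the cross-link length
distribution, so cross-links — which in walls tether fibrils across the
narrow inter-lamellar clearance — can realise their own printed length
distribution: each bridge's length is drawn from the preset distribution
(truncated below at the local surface clearance) and the bridge is tilted
along the fibril axis until its between-surfaces length matches the draw.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps

from .volume import DensityVolume

__all__ = [
    "PhantomSpec",
    "TrueFibril",
    "TrueCrossLink",
    "GroundTruth",
    "PRESETS",
    "make_preset",
    "generate_wall_phantom",
    "apply_imaging_model",
    "rasterize_truth_mask",
    "compute_pair_table",
    "write_ground_truth",
]

DIAMETER_FLOOR_NM = 2.2  # smallest credible fibril diameter
GAP_FLOOR_NM = 2.0       # smallest credible gap / cross-link length
FEATURE_LEVEL = 1.0      # nominal feature-to-background contrast of the rasterizer


# ---------------------------------------------------------------------------
# Spec and ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of one synthetic wall volume.  All lengths in nm."""

    shape_voxels: tuple[int, int, int] = (500, 500, 75)  # (nx, ny, nz)
    voxel_size: float = 0.87
    fibril_diameter_mean: float = 5.0
    fibril_diameter_sd: float = 1.5
    edge_gap_mean: float = 6.4
    edge_gap_sd: float = 1.2
    layer_spacing_mean: float | None = None  # derived from cross-links if None
    layer_spacing_sd: float = 0.5
    orientation_jitter_deg: float = 1.5
    crosslink_length_mean: float = 5.0
    crosslink_length_sd: float = 1.5
    crosslink_density: float = 1.0   # expected links per fibril per 100 nm
    crosslink_diameter: float = 2.5
    contrast_mode: str = "cryo"      # {"stained", "cryo"}
    artifact_blob_rate: float = 0.0  # blobs per 1000 nm^3 (stained mode)
    middle_lamella: bool = False
    snr: float = 3.0
    psf_sigma: float = 1.0
    missing_wedge_halfangle_deg: float = 60.0
    seed: int = 0

    def resolved_layer_spacing_mean(self) -> float:
        if self.layer_spacing_mean is not None:
            return self.layer_spacing_mean
        if self.crosslink_density == 0:
            # nothing tethers the lamellae together: spacing follows the
            # in-plane packing scale (extracted walls)
            return self.fibril_diameter_mean + self.edge_gap_mean
        # adjacent-lamella clearance hosts the cross-links; see module docstring
        clearance = max(DIAMETER_FLOOR_NM, self.crosslink_length_mean - self.crosslink_length_sd)
        return clearance + self.fibril_diameter_mean

    def validate(self) -> None:
        positive = dict(
            voxel_size=self.voxel_size,
            fibril_diameter_mean=self.fibril_diameter_mean,
            fibril_diameter_sd=self.fibril_diameter_sd,
            edge_gap_mean=self.edge_gap_mean,
            edge_gap_sd=self.edge_gap_sd,
            crosslink_length_mean=self.crosslink_length_mean,
            crosslink_length_sd=self.crosslink_length_sd,
            crosslink_diameter=self.crosslink_diameter,
            snr=self.snr,
        )
        for name, v in positive.items():
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.crosslink_density < 0:
            raise ValueError("crosslink_density must be >= 0")
        if self.artifact_blob_rate < 0:
            raise ValueError("artifact_blob_rate must be >= 0")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if not 0 < self.missing_wedge_halfangle_deg <= 90:
            raise ValueError("missing_wedge_halfangle_deg must be in (0, 90]")
        if self.contrast_mode not in ("stained", "cryo"):
            raise ValueError(f"contrast_mode must be 'stained' or 'cryo', got {self.contrast_mode!r}")
        if not self.fibril_diameter_mean - 2 * self.fibril_diameter_sd + (
            self.fibril_diameter_mean - DIAMETER_FLOOR_NM
        ) > 0 or self.fibril_diameter_mean <= DIAMETER_FLOOR_NM:
            raise ValueError(
                f"fibril diameter distribution incompatible with the {DIAMETER_FLOOR_NM} nm floor"
            )
        if any(int(s) != s or s < 8 for s in self.shape_voxels):
            raise ValueError(f"shape_voxels must be integers >= 8, got {self.shape_voxels}")

    def content_hash(self) -> str:
        import hashlib

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TrueFibril:
    """One generated fibril: a straight soft cylinder, recorded as a polyline."""

    fibril_id: int
    vertices: np.ndarray       # (n, 3) nm, (z, y, x)
    radii: np.ndarray          # (n,) nm
    layer_index: int
    direction: np.ndarray      # unit (z, y, x)

    @property
    def radius(self) -> float:
        return float(np.median(self.radii))

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.vertices[-1] - self.vertices[0]))


@dataclass
class TrueCrossLink:
    fibril_i: int
    fibril_j: int
    point_i: np.ndarray  # surface attachment on fibril_i, nm (z, y, x)
    point_j: np.ndarray
    length: float        # surface-to-surface, nm


@dataclass
class GroundTruth:
    fibrils: list[TrueFibril] = field(default_factory=list)
    crosslinks: list[TrueCrossLink] = field(default_factory=list)
    pair_table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["fibril_i", "fibril_j", "kind", "center_nm", "edge_nm"]
        )
    )
    artifacts: list[dict] = field(default_factory=list)
    # the generator's own draws, anchored at the ROI mid-plane (for moment checks;
    # pair_table's edge_nm is the realized minimum over the whole ROI instead)
    drawn_gaps: np.ndarray = field(default_factory=lambda: np.empty(0))

    def diameters(self) -> np.ndarray:
        return np.array([2.0 * f.radius for f in self.fibrils])

    def within_layer_gaps(self) -> np.ndarray:
        t = self.pair_table
        return t.loc[t["kind"] == "within_layer", "edge_nm"].to_numpy(float)

    def crosslink_lengths(self) -> np.ndarray:
        return np.array([c.length for c in self.crosslinks])


# ---------------------------------------------------------------------------
# Presets: printed study measurements as generator parameters
# ---------------------------------------------------------------------------

# diameter mean/sd, within-layer edge gap mean/sd, cross-link length mean/sd (nm)
PRESETS: dict[str, dict] = {
    "chem": dict(
        fibril_diameter_mean=4.3, fibril_diameter_sd=1.3,
        edge_gap_mean=17.0, edge_gap_sd=4.3,
        crosslink_length_mean=5.6, crosslink_length_sd=2.1,
        contrast_mode="stained", artifact_blob_rate=0.01, snr=6.0,
    ),
    "hpf": dict(
        fibril_diameter_mean=4.9, fibril_diameter_sd=1.4,
        edge_gap_mean=6.9, edge_gap_sd=2.1,
        crosslink_length_mean=4.6, crosslink_length_sd=1.5,
        contrast_mode="stained", artifact_blob_rate=0.01, snr=6.0,
    ),
    "cryo": dict(
        fibril_diameter_mean=5.0, fibril_diameter_sd=1.5,
        edge_gap_mean=6.4, edge_gap_sd=1.2,
        crosslink_length_mean=5.0, crosslink_length_sd=1.5,
        contrast_mode="cryo", artifact_blob_rate=0.0, snr=3.0,
    ),
    "wt_hypocotyl": dict(
        fibril_diameter_mean=4.5, fibril_diameter_sd=0.9,
        edge_gap_mean=5.2, edge_gap_sd=2.0,
        crosslink_length_mean=4.2, crosslink_length_sd=0.8,
        contrast_mode="stained", artifact_blob_rate=0.01, snr=6.0,
    ),
    "cob6": dict(
        fibril_diameter_mean=4.6, fibril_diameter_sd=0.8,
        edge_gap_mean=8.9, edge_gap_sd=3.8,
        crosslink_length_mean=4.7, crosslink_length_sd=0.8,
        contrast_mode="stained", artifact_blob_rate=0.01, snr=6.0,
    ),
}
# extraction control: chemically prepared walls with hemicellulose/pectin
# removed -> the chem geometry with no cross-links at all
PRESETS["extracted"] = dict(PRESETS["chem"], crosslink_density=0.0)


def make_preset(name: str, **overrides) -> PhantomSpec:
    """Build the spec for one of the study conditions.

    Valid names: ``chem``, ``hpf``, ``cryo``, ``wt_hypocotyl``, ``cob6``,
    ``extracted``.  Keyword overrides replace individual fields (shape,
    seed, snr, ...).
    """
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid options: {', '.join(sorted(PRESETS))}"
        )
    params = dict(PRESETS[name])
    params.update(overrides)
    spec = PhantomSpec(**params)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean: float, sd: float, floor: float,
               size: int | None = None) -> np.ndarray | float:
    """Normal draw truncated below at `floor` (no upper truncation)."""
    a = (floor - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _jitter_direction(rng: np.random.Generator, jitter_deg: float) -> np.ndarray:
    """Unit direction near +y with rms angular deviation `jitter_deg`."""
    sigma = math.radians(jitter_deg) / math.sqrt(2.0)
    sz, sx = rng.normal(0.0, sigma, size=2)
    d = np.array([sz, 1.0, sx])
    return d / np.linalg.norm(d)


def _axis_point(f: TrueFibril, y: float) -> np.ndarray:
    """Point on the fibril axis at ordinate y (axes are graphs over y)."""
    p0, d = f.vertices[0], f.direction
    t = (y - p0[1]) / d[1]
    return p0 + t * d


def _common_y_min_separation(fa: TrueFibril, fb: TrueFibril,
                             y_range: tuple[float, float]) -> float:
    """Minimum over y of the distance between same-y axis points.

    For near-parallel fibrils parametrised over y this matches the true
    closest line-line approach to well below rasterisation error.
    """
    y0, y1 = y_range
    a0, b0 = _axis_point(fa, y0), _axis_point(fb, y0)
    a1, b1 = _axis_point(fa, y1), _axis_point(fb, y1)
    w0 = (b0 - a0)[[0, 2]]
    w1 = (b1 - a1)[[0, 2]]
    # separation vector is linear in y: w(s) = w0 + s (w1 - w0), s in [0,1]
    dw = w1 - w0
    denom = float(dw @ dw)
    s = 0.0 if denom < 1e-30 else float(np.clip(-(w0 @ dw) / denom, 0.0, 1.0))
    return float(np.linalg.norm(w0 + s * dw))


def compute_pair_table(fibrils: list[TrueFibril], y_range: tuple[float, float]) -> pd.DataFrame:
    """Neighbor-pair ledger: within-layer adjacent pairs and the nearest
    adjacent-layer partner of every fibril.

    ``center_nm`` is the closest axis-axis approach inside the ROI;
    ``edge_nm = center_nm - r_i - r_j`` with the (constant) radii, so the
    cylinder-pair identity holds exactly by construction.
    """
    rows = []
    by_layer: dict[int, list[TrueFibril]] = {}
    for f in fibrils:
        by_layer.setdefault(f.layer_index, []).append(f)
    y_mid = 0.5 * (y_range[0] + y_range[1])
    for layer, fl in sorted(by_layer.items()):
        fl = sorted(fl, key=lambda f: _axis_point(f, y_mid)[2])
        for fa, fb in zip(fl[:-1], fl[1:]):
            c = _common_y_min_separation(fa, fb, y_range)
            rows.append((fa.fibril_id, fb.fibril_id, "within_layer",
                         c, c - fa.radius - fb.radius))
        if layer + 1 in by_layer:
            for fa in fl:
                xa = _axis_point(fa, y_mid)[2]
                fb = min(by_layer[layer + 1],
                         key=lambda f: abs(_axis_point(f, y_mid)[2] - xa))
                c = _common_y_min_separation(fa, fb, y_range)
                rows.append((fa.fibril_id, fb.fibril_id, "adjacent_layer",
                             c, c - fa.radius - fb.radius))
    return pd.DataFrame(rows, columns=["fibril_i", "fibril_j", "kind", "center_nm", "edge_nm"])


# ---------------------------------------------------------------------------
# Geometry generation
# ---------------------------------------------------------------------------

_MAX_RETRIES = 40


def _place_fibrils(spec: PhantomSpec,
                   rng: np.random.Generator) -> tuple[list[TrueFibril], np.ndarray]:
    nx, ny, nz = spec.shape_voxels
    vs = spec.voxel_size
    x_extent, y_extent, z_extent = nx * vs, ny * vs, nz * vs
    y_mid = 0.5 * y_extent
    spacing_mean = spec.resolved_layer_spacing_mean()

    z_margin = 5.0 + (6.0 if spec.middle_lamella else 0.0)
    min_clearance = 0.8  # nm; fibrils are rigid rods and cannot interpenetrate
    fibrils: list[TrueFibril] = []
    drawn_gaps: list[float] = []
    fid = 0
    layer = 0
    z = 5.0 + rng.uniform(0.0, 2.0)
    prev_layer: list[TrueFibril] = []
    while z < z_extent - z_margin:
        # fibril diameters for this lamella are drawn as we walk along x
        x = rng.uniform(0.0, 4.0)
        prev: TrueFibril | None = None
        this_layer: list[TrueFibril] = []
        layer_max_r = 0.0
        while True:
            d = float(_truncnorm(rng, spec.fibril_diameter_mean,
                                 spec.fibril_diameter_sd, DIAMETER_FLOOR_NM))
            r = 0.5 * d
            if prev is None:
                xc = x + r
                g = None
            else:
                g = float(_truncnorm(rng, spec.edge_gap_mean, spec.edge_gap_sd, GAP_FLOOR_NM))
                xc = _axis_point(prev, y_mid)[2] + prev.radius + g + r
            if xc + r > x_extent:
                break
            zc = z + rng.normal(0.0, 0.3)

            def clearance(cand: TrueFibril) -> float:
                worst = np.inf
                if prev is not None:
                    worst = (_common_y_min_separation(prev, cand, (0.0, y_extent))
                             - prev.radius - cand.radius)
                xc_cand = _axis_point(cand, y_mid)[2]
                for below in prev_layer:
                    if abs(_axis_point(below, y_mid)[2] - xc_cand) > 4 * r + 8:
                        continue
                    sep = _common_y_min_separation(below, cand, (0.0, y_extent))
                    worst = min(worst, sep - below.radius - cand.radius)
                return worst

            best, best_cl = None, -np.inf
            for attempt in range(_MAX_RETRIES):
                direction = _jitter_direction(rng, spec.orientation_jitter_deg)
                anchor = np.array([zc, y_mid, xc])
                cand = _make_fibril(fid, anchor, direction, r, layer, y_extent, vs)
                cl = clearance(cand)
                if cl > best_cl:
                    best, best_cl = cand, cl
                if cl > min_clearance:
                    break
            if best_cl <= min_clearance:
                # lift the anchor until the rod clears its neighbours
                anchor = np.array([zc + (min_clearance - best_cl) + 0.1, y_mid, xc])
                cand = _make_fibril(fid, anchor, best.direction, r, layer, y_extent, vs)
                if clearance(cand) > 0:
                    best = cand
                else:
                    raise RuntimeError("geometry infeasible: could not place non-crossing fibril")
            fibrils.append(best)
            this_layer.append(best)
            if g is not None:
                drawn_gaps.append(g)
            prev = best
            layer_max_r = max(layer_max_r, r)
            fid += 1
        # next lamella: spacing must clear the fattest fibrils on both sides
        for attempt in range(_MAX_RETRIES):
            step = float(_truncnorm(rng, spacing_mean, spec.layer_spacing_sd,
                                    GAP_FLOOR_NM))
            if step > layer_max_r + 0.5 * spec.fibril_diameter_mean + 0.8:
                break
        z += step
        prev_layer = this_layer
        layer += 1
    if not fibrils:
        raise RuntimeError("geometry infeasible: ROI too small for any fibril")
    return fibrils, np.asarray(drawn_gaps)


def _make_fibril(fid: int, anchor: np.ndarray, direction: np.ndarray, radius: float,
                 layer: int, y_extent: float, vs: float) -> TrueFibril:
    p0 = anchor + (0.0 - anchor[1]) / direction[1] * direction
    p1 = anchor + (y_extent - anchor[1]) / direction[1] * direction
    n = max(2, int(np.linalg.norm(p1 - p0) / (5.0 * vs)) + 1)
    t = np.linspace(0.0, 1.0, n)[:, None]
    vertices = p0[None, :] * (1 - t) + p1[None, :] * t
    return TrueFibril(fid, vertices, np.full(n, radius), layer, direction)


_MAX_BRIDGE_OBLIQUITY = 2.0  # chord length at most this multiple of the axis gap


def _place_crosslinks(spec: PhantomSpec, rng: np.random.Generator,
                      fibrils: list[TrueFibril]) -> list[TrueCrossLink]:
    """Bridges between adjacent lamellae.

    For each link the surface-to-surface length is drawn FIRST from the
    preset distribution (truncated only at the physical floor) and an
    attachment site is then sought whose local clearance supports a bridge
    of that length at bounded obliquity; drawing first keeps the realized
    length sample an honest draw from the preset distribution.
    """
    if spec.crosslink_density == 0:
        return []
    _, ny, _ = spec.shape_voxels
    y_extent = ny * spec.voxel_size
    by_layer: dict[int, list[TrueFibril]] = {}
    for f in fibrils:
        by_layer.setdefault(f.layer_index, []).append(f)
    links: list[TrueCrossLink] = []
    used_y: dict[tuple[int, int], list[float]] = {}
    for fa in fibrils:
        if fa.layer_index + 1 not in by_layer:
            continue
        n_links = rng.poisson(spec.crosslink_density * y_extent / 100.0)
        for _ in range(n_links):
            ell = float(_truncnorm(rng, spec.crosslink_length_mean,
                                   spec.crosslink_length_sd, GAP_FLOOR_NM))
            link = None
            for attempt in range(20):
                y_star = rng.uniform(0.08, 0.92) * y_extent
                a = _axis_point(fa, y_star)
                fb = min(by_layer[fa.layer_index + 1],
                         key=lambda f: float(np.linalg.norm((_axis_point(f, y_star) - a)[[0, 2]])))
                b = _axis_point(fb, y_star)
                d0 = float(np.linalg.norm((b - a)[[0, 2]]))
                g_v = d0 - fa.radius - fb.radius
                # clearance must admit a bridge of length ell without
                # stretching (ell >= g_v) or excessive obliquity; gaps
                # below ~1.5 nm cannot host a resolvable tether
                if not (1.5 <= g_v <= ell and ell <= _MAX_BRIDGE_OBLIQUITY * g_v):
                    continue
                key = (fa.fibril_id, fb.fibril_id)
                if any(abs(y_star - yu) < 4.0 for yu in used_y.get(key, [])):
                    continue
                link = _build_bridge(fa, fb, y_star, ell, rng)
                if link is not None:
                    used_y.setdefault(key, []).append(y_star)
                    break
            if link is not None:
                links.append(link)
    return links


def _build_bridge(fa: TrueFibril, fb: TrueFibril, y_star: float, ell: float,
                  rng: np.random.Generator) -> TrueCrossLink | None:
    """Straight bridge between the two cylinder surfaces with
    between-surfaces length `ell`, tilted along y to absorb the slack."""
    a = _axis_point(fa, y_star)
    b0 = _axis_point(fb, y_star)
    d_perp = float(np.linalg.norm((b0 - a)[[0, 2]]))
    g_v = d_perp - fa.radius - fb.radius
    if ell < g_v - 1e-9:
        return None
    # chord length so that the between-surface segment has length ell
    chord = ell * d_perp / g_v
    dy = math.sqrt(max(chord * chord - d_perp * d_perp, 0.0)) * (1 if rng.random() < 0.5 else -1)
    b = _axis_point(fb, y_star + dy)
    seg = b - a
    seg_len = float(np.linalg.norm(seg))
    d_hat = seg / seg_len
    # exact exit points on each cylinder surface along the segment
    t_a = _surface_exit(a, d_hat, fa)
    t_b = _surface_exit(b, -d_hat, fb)
    if t_a is None or t_b is None or t_a + t_b >= seg_len:
        return None
    p_i = a + t_a * d_hat
    p_j = b - t_b * d_hat
    return TrueCrossLink(fa.fibril_id, fb.fibril_id, p_i, p_j,
                         float(np.linalg.norm(p_j - p_i)))


def _surface_exit(origin: np.ndarray, d_hat: np.ndarray, f: TrueFibril) -> float | None:
    """Distance along d_hat from an on-axis origin to the cylinder surface."""
    perp = d_hat - (d_hat @ f.direction) * f.direction
    norm = float(np.linalg.norm(perp))
    if norm < 1e-9:
        return None
    return f.radius / norm


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------

def _paint_cylinder(vol: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float,
                    vs: float, level: float, soft: bool) -> None:
    """Max-combine a (soft-edged) cylinder around segment p0-p1 into vol."""
    lo = np.minimum(p0, p1) - radius - 1.5 * vs
    hi = np.maximum(p0, p1) + radius + 1.5 * vs
    i0 = np.maximum(np.floor(lo / vs).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / vs).astype(int) + 1, np.array(vol.shape))
    if np.any(i0 >= i1):
        return
    zz, yy, xx = np.meshgrid(*[np.arange(a, b) * vs for a, b in zip(i0, i1)],
                             indexing="ij")
    p = np.stack([zz, yy, xx], axis=-1)
    seg = p1 - p0
    seg2 = float(seg @ seg)
    w = p - p0
    t = np.clip((w @ seg) / seg2, 0.0, 1.0) if seg2 > 0 else np.zeros(p.shape[:-1])
    closest = p0 + t[..., None] * seg
    dist = np.linalg.norm(p - closest, axis=-1)
    if soft:
        contrib = level * np.clip((radius + 0.5 * vs - dist) / vs, 0.0, 1.0)
    else:
        contrib = level * (dist <= radius)
    sl = tuple(slice(a, b) for a, b in zip(i0, i1))
    np.maximum(vol[sl], contrib.astype(vol.dtype), out=vol[sl])


def _rasterize(spec: PhantomSpec, truth: GroundTruth, soft: bool) -> np.ndarray:
    nx, ny, nz = spec.shape_voxels
    vs = spec.voxel_size
    vol = np.zeros((nz, ny, nx), dtype=np.float32)
    for f in truth.fibrils:
        _paint_cylinder(vol, f.vertices[0], f.vertices[-1], f.radius, vs,
                        FEATURE_LEVEL, soft)
    for c in truth.crosslinks:
        d_hat = (c.point_j - c.point_i) / max(np.linalg.norm(c.point_j - c.point_i), 1e-9)
        p0 = c.point_i - 1.5 * vs * d_hat  # embed ends into the fibrils
        p1 = c.point_j + 1.5 * vs * d_hat
        _paint_cylinder(vol, p0, p1, 0.5 * spec.crosslink_diameter, vs,
                        FEATURE_LEVEL, soft)
    if spec.middle_lamella:
        z = np.arange(nz)[:, None, None] * vs
        z_extent = nz * vs
        band = 0.85 * FEATURE_LEVEL * np.clip((z - (z_extent - 7.0)) / 2.0, 0.0, 1.0)
        np.maximum(vol, band.astype(np.float32), out=vol)
    return vol


def rasterize_truth_mask(spec: PhantomSpec, truth: GroundTruth) -> np.ndarray:
    """Hard binary mask of the true fibrils and cross-links (no lamella)."""
    ml = spec.middle_lamella
    spec2 = dataclasses.replace(spec, middle_lamella=False)
    mask = _rasterize(spec2, truth, soft=False) > 0.5
    del ml
    return mask


# ---------------------------------------------------------------------------
# Public generator operations
# ---------------------------------------------------------------------------

def generate_wall_phantom(spec: PhantomSpec) -> tuple[DensityVolume, GroundTruth]:
    """Lay out and rasterize the fibril network; noiseless and unblurred.

    Deterministic for a fixed ``spec.seed``.  Imaging corruption (PSF,
    missing wedge, noise, artifact blobs) is applied separately by
    :func:`apply_imaging_model`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fibrils, drawn_gaps = _place_fibrils(spec, rng)
    crosslinks = _place_crosslinks(spec, rng, fibrils)
    _, ny, _ = spec.shape_voxels
    truth = GroundTruth(
        fibrils=fibrils,
        crosslinks=crosslinks,
        pair_table=compute_pair_table(fibrils, (0.0, ny * spec.voxel_size)),
        drawn_gaps=drawn_gaps,
    )
    data = _rasterize(spec, truth, soft=True)
    vol = DensityVolume(data=data, voxel_size=spec.voxel_size,
                        provenance=[f"phantom:{spec.content_hash()}"])
    return vol, truth


def apply_imaging_model(vol: DensityVolume, spec: PhantomSpec,
                        truth: GroundTruth | None = None) -> DensityVolume:
    """Corrupt a noiseless phantom the way the microscope would.

    Isotropic Gaussian PSF, then the single-axis missing wedge (tilt axis y,
    beam axis z: spatial frequencies with ``|k_z| > tan(halfangle) |k_x|``
    are unmeasured and zeroed), then stained-mode artifact blobs, then
    additive Gaussian noise with standard deviation ``contrast / snr``
    (nominal rasterizer contrast is 1).  In cryo mode the contrast is
    inverted at the end: denser material images darker in unstained
    frozen-hydrated sections.
    """
    vol.require_finite()
    vs = vol.voxel_size
    data = vol.data.astype(np.float32, copy=True)
    if spec.psf_sigma > 0:
        data = ndi.gaussian_filter(data, sigma=spec.psf_sigma / vs, mode="reflect")
    if spec.missing_wedge_halfangle_deg < 90.0:
        data = _apply_missing_wedge(data, spec.missing_wedge_halfangle_deg)
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 0x1A])
    if spec.contrast_mode == "stained" and spec.artifact_blob_rate > 0:
        data = _plant_blobs(data, spec, rng, truth)
    if np.isfinite(spec.snr):
        noise_sd = FEATURE_LEVEL / spec.snr
        data = data + rng.normal(0.0, noise_sd, size=data.shape).astype(np.float32)
    if spec.contrast_mode == "cryo":
        data = -data
    return vol.with_data(data, note=f"imaging:psf={spec.psf_sigma},wedge={spec.missing_wedge_halfangle_deg},snr={spec.snr},mode={spec.contrast_mode}")


def _apply_missing_wedge(data: np.ndarray, halfangle_deg: float) -> np.ndarray:
    nz, ny, nx = data.shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    tan_t = math.tan(math.radians(halfangle_deg))
    keep = np.abs(kz) <= tan_t * np.abs(kx)
    keep = np.broadcast_to(keep, (nz, 1, nx)).copy()
    keep[0, 0, 0] = True  # DC always measured
    spectrum = np.fft.fftn(data, axes=(0, 2))
    spectrum *= keep
    return np.real(np.fft.ifftn(spectrum, axes=(0, 2))).astype(np.float32)


def _plant_blobs(data: np.ndarray, spec: PhantomSpec, rng: np.random.Generator,
                 truth: GroundTruth | None) -> np.ndarray:
    vs = spec.voxel_size
    volume_nm3 = data.size * vs ** 3
    n = rng.poisson(spec.artifact_blob_rate * volume_nm3 / 1000.0)
    out = data.copy()
    nz, ny, nx = data.shape
    for _ in range(n):
        c = rng.uniform([0, 0, 0], [nz * vs, ny * vs, nx * vs])
        sigma = rng.uniform(1.0, 2.5)
        amp = rng.uniform(0.6, 1.2) * FEATURE_LEVEL
        _paint_blob(out, c, sigma, amp, vs)
        if truth is not None:
            truth.artifacts.append(dict(center_nm=c.tolist(), sigma_nm=sigma, amplitude=amp))
    return out


def _paint_blob(vol: np.ndarray, center: np.ndarray, sigma: float, amp: float,
                vs: float) -> None:
    r = 3.0 * sigma
    i0 = np.maximum(np.floor((center - r) / vs).astype(int), 0)
    i1 = np.minimum(np.ceil((center + r) / vs).astype(int) + 1, np.array(vol.shape))
    if np.any(i0 >= i1):
        return
    zz, yy, xx = np.meshgrid(*[np.arange(a, b) * vs for a, b in zip(i0, i1)],
                             indexing="ij")
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    sl = tuple(slice(a, b) for a, b in zip(i0, i1))
    vol[sl] += (amp * np.exp(-d2 / (2 * sigma ** 2))).astype(vol.dtype)


# ---------------------------------------------------------------------------
# On-disk truth ledger
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, spec: PhantomSpec, out_dir: str | Path) -> Path:
    """CSV tables (fibrils, crosslinks, pairs) plus a JSON spec echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frows = [
        dict(fibril_id=f.fibril_id, layer=f.layer_index, radius_nm=f.radius,
             length_nm=f.length,
             z0=f.vertices[0][0], y0=f.vertices[0][1], x0=f.vertices[0][2],
             z1=f.vertices[-1][0], y1=f.vertices[-1][1], x1=f.vertices[-1][2])
        for f in truth.fibrils
    ]
    pd.DataFrame(frows).to_csv(out / "fibrils.csv", index=False)
    crows = [
        dict(fibril_i=c.fibril_i, fibril_j=c.fibril_j, length_nm=c.length,
             zi=c.point_i[0], yi=c.point_i[1], xi=c.point_i[2],
             zj=c.point_j[0], yj=c.point_j[1], xj=c.point_j[2])
        for c in truth.crosslinks
    ]
    pd.DataFrame(crows, columns=["fibril_i", "fibril_j", "length_nm",
                                 "zi", "yi", "xi", "zj", "yj", "xj"]).to_csv(
        out / "crosslinks.csv", index=False)
    truth.pair_table.to_csv(out / "pairs.csv", index=False)
    (out / "phantom_spec.json").write_text(
        json.dumps(dataclasses.asdict(spec), indent=2, default=str))
    return out
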