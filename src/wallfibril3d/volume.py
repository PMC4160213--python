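"""Density volumes and standard-format I/O.

A :class:`DensityVolume` is the package's in-memory tomogram: a 3D float32
grid in array order ``(z, y, x)`` with an isotropic physical voxel size in
nanometres.  The z axis is the beam axis of the (real or simulated)
tomographic acquisition.  Volumes round-trip through MRC/CCP4 maps (voxel
size stored in the header in Ångström, the map convention) and through
multi-page TIFF stacks (which carry no calibrated voxel size, so one must be
supplied on read).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import tifffile

__all__ = ["DensityVolume", "read_volume", "write_volume", "bin_volume"]

_MIN_SHAPE = 8  # processing stages assume at least this many voxels per axis


@dataclass
class DensityVolume:
    """3D scalar density grid with physical calibration.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``; stored as float32.
    voxel_size
        Isotropic voxel edge length in nm.
    provenance
        Free-form history entries (source path, phantom spec hash,
        processing steps); appended to by processing stages.
    """

    data: np.ndarray
    voxel_size: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0 nm, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, note: str | None = None) -> "DensityVolume":
        """New volume sharing calibration, with a provenance note appended."""
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return DensityVolume(data=data, voxel_size=self.voxel_size, provenance=prov)

    def require_finite(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    def require_processable(self) -> None:
        self.require_finite()
        if min(self.shape) < _MIN_SHAPE:
            raise ValueError(
                f"volume shape {self.shape} too small; processing stages need "
                f">= {_MIN_SHAPE} voxels per axis"
            )

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.data).tobytes())
        h.update(np.float64(self.voxel_size).tobytes())
        return h.hexdigest()[:16]


def read_volume(path: str | Path, voxel_size: float | None = None) -> DensityVolume:
    """Read an MRC/CCP4 map or a TIFF stack into a :class:`DensityVolume`.

    MRC voxel size is taken from the header (Å → nm); a header with zero
    cell dimensions requires an explicit ``voxel_size`` (nm).  TIFF carries
    no physical calibration, so ``voxel_size`` is mandatory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".map", ".rec", ".ccp4"):
        try:
            m = gemmi.read_ccp4_map(str(path))
        except (RuntimeError, ValueError) as exc:
            raise ValueError(f"could not read MRC map {path}: {exc}") from exc
        grid = m.grid
        arr = np.array(grid, copy=True)  # (x, y, z)
        data = np.ascontiguousarray(arr.T)  # -> (z, y, x)
        spacing_a = grid.unit_cell.a / grid.nu if grid.nu else 0.0
        if spacing_a <= 0:
            if voxel_size is None:
                raise ValueError(
                    f"{path}: MRC header has zero voxel size; pass voxel_size in nm"
                )
            vs = float(voxel_size)
        else:
            vs = spacing_a / 10.0  # Å -> nm
        return DensityVolume(data=data, voxel_size=vs, provenance=[f"read:{path}"])
    if suffix in (".tif", ".tiff"):
        if voxel_size is None:
            raise ValueError("TIFF stacks carry no voxel size; pass voxel_size in nm")
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        return DensityVolume(
            data=np.asarray(data, dtype=np.float32),
            voxel_size=float(voxel_size),
            provenance=[f"read:{path}"],
        )
    raise ValueError(
        f"unsupported volume format {suffix!r}; supported: .mrc/.map/.rec/.ccp4, .tif/.tiff"
    )


def write_volume(vol: DensityVolume, path: str | Path) -> Path:
    """Write as MRC (float32 mode 2, voxel size in Å) or TIFF by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".map", ".rec", ".ccp4"):
        nz, ny, nx = vol.shape
        grid = gemmi.FloatGrid(nx, ny, nz)
        np.array(grid, copy=False)[:] = np.ascontiguousarray(vol.data.T)
        a = vol.voxel_size * 10.0  # nm -> Å
        grid.set_unit_cell(gemmi.UnitCell(a * nx, a * ny, a * nz, 90.0, 90.0, 90.0))
        m = gemmi.Ccp4Map()
        m.grid = grid
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))
        return path
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), vol.data)
        return path
    raise ValueError(f"unsupported output format {suffix!r}")


def bin_volume(vol: DensityVolume, factor: int) -> DensityVolume:
    """Block-mean downsample by an integer factor; voxel size scales up.

    A trailing remainder in any axis is cropped (the standard binning
    behaviour of acquisition software).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return vol.with_data(vol.data, note="bin:1")
    if any(s < factor for s in vol.shape):
        raise ValueError(f"factor {factor} exceeds volume shape {vol.shape}")
    nz, ny, nx = (s // factor for s in vol.shape)
    d = vol.data[: nz * factor, : ny * factor, : nx * factor]
    d = d.reshape(nz, factor, ny, factor, nx, factor).mean(axis=(1, 3, 5))
    out = DensityVolume(
        data=d.astype(np.float32),
        voxel_size=vol.voxel_size * factor,
        provenance=list(vol.provenance) + [f"bin:{factor}"],
    )
    return out
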