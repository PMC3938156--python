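"""Readers/writers for the external formats the pipeline touches, plus run configuration.

Conventions
-----------
Voxel coordinates are 0-based and continuous: voxel ``i`` covers the half-open
interval ``[i, i+1)`` along each axis, so a point ``p`` belongs to voxel
``floor(p)`` and the voxel's center sits at ``i + 0.5``.  A point maps to
scanner millimetres through the NIfTI affine applied to ``p - 0.5`` (nibabel
places voxel centers at integer indices).
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "FormatError",
    "GradientTable",
    "DWIVolume",
    "RunConfig",
    "read_gradient_table",
    "write_gradient_table",
    "read_volume",
    "write_volume",
    "read_tractogram",
    "write_tractogram",
    "read_table",
    "write_table",
    "read_config",
    "log",
]


class FormatError(ValueError):
    """An external file does not conform to its declared format."""


def log(msg: str) -> None:
    """Structured one-line log to stderr."""
    print(f"[stickflow] {msg}", file=sys.stderr)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientTable:
    """Diffusion encoding: b-values (s/mm^2) and unit gradient directions.

    Directions with b > 0 are unit-norm; b = 0 entries may carry the zero
    vector.  At least one b = 0 entry is required to anchor S0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # (N, 3)

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise FormatError(
                f"count mismatch: {len(bvals)} b-values vs {len(bvecs)} directions"
            )
        if not np.any(bvals <= 0):
            raise FormatError("gradient table has no b=0 entry")
        norms = np.linalg.norm(bvecs, axis=1)
        dw = bvals > 0
        if np.any(norms[dw] == 0):
            raise FormatError("zero direction vector at b > 0")
        bvecs = bvecs.copy()
        bvecs[dw] /= norms[dw, None]
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted acquisition: one 3D frame per gradient."""

    data: np.ndarray  # (x, y, z, gradient)
    affine: np.ndarray  # 4x4 voxel-to-mm
    voxel_dims: np.ndarray  # (3,) mm

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.data.ndim != 4:
            raise FormatError(f"expected 3D/4D data, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        self.voxel_dims = np.asarray(self.voxel_dims, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if np.any(self.voxel_dims <= 0):
            raise FormatError("voxel dimensions must be strictly positive")

    @property
    def shape3(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_dims))

    def frame(self, i: int) -> np.ndarray:
        return self.data[..., i]


@dataclass
class RunConfig:
    """Tracking and fitting parameters shared across the pipeline.

    Defaults follow the reference acquisition protocol: 0.2-voxel steps,
    60 deg turning-angle threshold, sticks eligible for tracking only above a
    0.15 volume fraction, pathway voxels require more than 5 streamline
    visits, 2000 seeds, and equal (0.5/0.5) smoothing of previous and
    incoming directions.
    """

    step_size_voxels: float = 0.2
    angle_threshold_deg: float = 60.0
    fraction_threshold: float = 0.15
    visitation_threshold: int = 5
    n_seeds: int = 2000
    smoothing_weight: float = 0.5
    rng_seed: int = 0
    max_steps: int = 2000
    window_layout: str = "inplane11"  # inplane11 | face7 | cube27
    min_stick_fraction: float = 0.05
    reject_threshold: float = 3.0
    bidirectional: bool = True

    def __post_init__(self):
        for name in ("step_size_voxels", "angle_threshold_deg",
                     "fraction_threshold", "smoothing_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_seeds <= 0 or self.max_steps <= 0:
            raise ValueError("n_seeds and max_steps must be positive")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# gradient tables (FSL dialect)
# ---------------------------------------------------------------------------

def _parse_rows(path) -> list:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as e:
            raise FormatError(f"{path}: non-numeric token ({e})") from None
    return rows

def read_gradient_table(bval_path, bvec_path) -> GradientTable:
    """Read FSL-style bvals (one row) and bvecs (three rows: x, y, z)."""
    brows = _parse_rows(bval_path)
    if len(brows) != 1:
        raise FormatError(f"{bval_path}: expected a single row of b-values")
    vrows = _parse_rows(bvec_path)
    if len(vrows) != 3:
        raise FormatError(f"{bvec_path}: expected three rows (x, y, z)")
    if len({len(r) for r in vrows}) != 1:
        raise FormatError(f"{bvec_path}: ragged rows")
    bvals = np.array(brows[0])
    bvecs = np.array(vrows).T
    if len(bvals) != len(bvecs):
        raise FormatError(
            f"{len(bvals)} b-values but {len(bvecs)} directions"
        )
    return GradientTable(bvals, bvecs)

def write_gradient_table(table: GradientTable, bval_path, bvec_path) -> None:
    Path(bval_path).write_text(" ".join(f"{b:g}" for b in table.bvals) + "\n")
    lines = [" ".join(f"{v:.8f}" for v in table.bvecs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volume(path) -> DWIVolume:
    """Read a 3D/4D NIfTI-1 volume; 3D files are promoted to single-frame 4D."""
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
    except Exception as e:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI volume {path}: {e}") from None
    if data.ndim not in (3, 4):
        raise FormatError(f"{path}: expected 3D or 4D, got {data.ndim}D")
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DWIVolume(data=data, affine=np.asarray(img.affine), voxel_dims=zooms)

def write_volume(vol_or_data, path, affine=None, voxel_dims=None) -> None:
    """Write a DWIVolume (or bare array + affine) as NIfTI-1."""
    if isinstance(vol_or_data, DWIVolume):
        data, affine = vol_or_data.data, vol_or_data.affine
        voxel_dims = vol_or_data.voxel_dims
    else:
        data = np.asarray(vol_or_data)
        if affine is None:
            affine = np.eye(4)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    if voxel_dims is not None:
        zooms = tuple(voxel_dims) + (1.0,) * (data.ndim - 3)
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# tractograms (TRK / TCK via nibabel.streamlines)
# ---------------------------------------------------------------------------

def _vox_to_rasmm_affine(affine: np.ndarray) -> np.ndarray:
    # our voxel centers sit at i + 0.5; nibabel's at integer indices
    shift = np.eye(4)
    shift[:3, 3] = -0.5
    return np.asarray(affine, dtype=float) @ shift

def write_tractogram(tractogram, path, format: str = "trk") -> None:
    """Write streamlines as TrackVis TRK or MRtrix TCK.

    ``tractogram`` is a :class:`stickflow.tracking.Tractogram`; point
    coordinates are converted from continuous voxel space to the format's
    native (RAS mm) convention through the reference affine.
    """
    if format not in ("trk", "tck"):
        raise ValueError(f"unknown tractogram format {format!r}")
    affine = _vox_to_rasmm_affine(tractogram.affine)
    streams = [np.asarray(s.points, dtype=np.float32) for s in tractogram.streamlines]
    nt = nib.streamlines.Tractogram(streams, affine_to_rasmm=affine)
    if format == "trk":
        header = {
            "voxel_sizes": np.asarray(tractogram.voxel_dims, dtype=np.float32),
            "dimensions": np.asarray(tractogram.shape3, dtype=np.int16),
            "voxel_to_rasmm": np.asarray(tractogram.affine, dtype=np.float32),
            "voxel_order": "".join(nib.aff2axcodes(tractogram.affine)),
        }
        nib.streamlines.save(nt, str(path), header=header)
    else:
        nib.streamlines.save(nt, str(path))

def read_tractogram(path, affine) -> list:
    """Read a TRK/TCK file back into continuous voxel coordinates.

    Returns a list of (n_points, 3) arrays in this package's voxel convention.
    """
    tf = nib.streamlines.load(str(path))
    inv = np.linalg.inv(_vox_to_rasmm_affine(affine))
    out = []
    for s in tf.tractogram.streamlines:
        pts = np.c_[s, np.ones(len(s))] @ inv.T
        out.append(pts[:, :3])
    return out


# ---------------------------------------------------------------------------
# tables and config files
# ---------------------------------------------------------------------------

def write_table(records: Sequence[dict], path, columns: Sequence[str] | None = None) -> None:
    """Write keyed records as a TSV with a header row."""
    records = list(records)
    if columns is None:
        columns = list(records[0].keys()) if records else []
    lines = ["\t".join(map(str, columns))]
    for rec in records:
        lines.append("\t".join(_fmt(rec.get(c, "")) for c in columns))
    Path(path).write_text("\n".join(lines) + "\n")

def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)

def read_table(path) -> list:
    """Read a TSV written by :func:`write_table` back into dict records."""
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines:
        return []
    cols = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        vals = line.split("\t")
        rec = {}
        for c, v in zip(cols, vals):
            try:
                rec[c] = int(v)
            except ValueError:
                try:
                    rec[c] = float(v)
                except ValueError:
                    rec[c] = v
        out.append(rec)
    return out

def read_config(path, base: RunConfig | None = None, **overrides) -> RunConfig:
    """Load a flat key=value config file; keyword overrides win over the file."""
    cfg = (base or RunConfig()).as_dict()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}: expected key=value, got {line!r}")
        key, val = (t.strip() for t in line.split("=", 1))
        if key not in cfg:
            raise FormatError(f"{path}: unknown config key {key!r}")
        cfg[key] = _coerce(val, type(cfg[key]))
    cfg.update(overrides)
    resolved = RunConfig(**cfg)
    log("config " + " ".join(f"{k}={v}" for k, v in resolved.as_dict().items()))
    return resolved

def _coerce(val: str, typ):
    if typ is bool:
        return val.lower() in ("1", "true", "yes", "on")
    return typ(val)
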