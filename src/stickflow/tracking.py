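"""Deterministic streamline propagation through a stick field.

Propagation rules: start at each seed along the highest-fraction eligible
stick of the seed voxel (and, by default, also along its antipode, with the
two half-tracks concatenated); at each step the incoming direction is the
trilinear combination, over the 8 voxels around the current point, of each
voxel's smallest-turning-angle stick with volume fraction above the tracking
threshold (0.15), sign-resolved toward the previous direction; the new
direction mixes previous and incoming with equal (0.5/0.5) weight; steps are
0.2 voxel widths; propagation stops when the incoming direction turns by
more than 60 degrees, no voxel contributes a direction, the position leaves
the tracking mask, or the step cap is reached.

All geometry lives in continuous voxel coordinates (voxel ``i`` spans
``[i, i+1)``; data values sit at voxel centers ``i + 0.5``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ballstick import StickField
from .io import RunConfig, log

__all__ = [
    "Streamline",
    "Tractogram",
    "interpolate_direction",
    "propagate",
    "seed_and_track",
]

_CORNERS = np.array([(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)])


@dataclass
class Streamline:
    points: np.ndarray  # (n, 3) continuous voxel coords
    seed_index: int
    seed_point_index: int = 0
    termination_reasons: tuple = ("max_steps", "max_steps")  # (backward, forward)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def termination_reason(self) -> str:
        return self.termination_reasons[1]


@dataclass
class Tractogram:
    streamlines: list
    config: RunConfig
    seed_mask_name: str = "seed"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_dims: np.ndarray = field(default_factory=lambda: np.ones(3))
    shape3: tuple = (0, 0, 0)
    n_seeds: int = 0
    n_discarded: int = 0

    def __len__(self) -> int:
        return len(self.streamlines)


# ---------------------------------------------------------------------------
# direction interpolation
# ---------------------------------------------------------------------------

def _batch_incoming(pos, u, fld: StickField, threshold: float):
    """Trilinear smallest-turning-angle direction for a batch of positions.

    Returns (directions, valid); invalid rows mean no surrounding voxel
    contributed an eligible stick.
    """
    shape = np.asarray(fld.shape3)
    t = pos - 0.5
    base = np.floor(t).astype(int)
    frac = t - base
    acc = np.zeros_like(pos)
    for off in _CORNERS:
        ci = base + off
        inb = np.all((ci >= 0) & (ci < shape), axis=1)
        ci_safe = np.clip(ci, 0, shape - 1)
        ix = tuple(ci_safe.T)
        fr = fld.fractions[ix]  # (m, 3)
        orient = fld.orientations[ix]  # (m, 3, 3)
        eligible = (fr > threshold) & inb[:, None]
        dots = np.einsum("mkc,mc->mk", orient, u)
        score = np.where(eligible, np.abs(dots), -1.0)
        best = np.argmax(score, axis=1)
        rows = np.arange(len(pos))
        has = score[rows, best] > 0
        sgn = np.sign(dots[rows, best])
        sgn[sgn == 0] = 1.0
        d_c = orient[rows, best] * sgn[:, None]
        w = np.prod(np.where(off > 0, frac, 1.0 - frac), axis=1)
        acc += (w * has)[:, None] * d_c
    norm = np.linalg.norm(acc, axis=1)
    valid = norm > 1e-12
    out = np.zeros_like(acc)
    out[valid] = acc[valid] / norm[valid, None]
    return out, valid


def interpolate_direction(position, previous_dir, fld: StickField,
                          config: RunConfig | None = None):
    """Incoming direction at one continuous position, or ``None``.

    Reference (single-point) form of the batch rule: each of the 8
    surrounding voxels offers, among its sticks with fraction above the
    tracking threshold, the orientation with the smallest turning angle
    versus ``previous_dir`` (sign-resolved); the offers are combined with
    trilinear weights and normalized.
    """
    config = config or RunConfig()
    pos = np.asarray(position, dtype=float)[None, :]
    u = np.asarray(previous_dir, dtype=float)[None, :]
    d, valid = _batch_incoming(pos, u, fld, config.fraction_threshold)
    return d[0] if valid[0] else None


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def _initial_direction(seed, fld: StickField, threshold: float):
    vox = tuple(np.floor(seed).astype(int))
    if np.any(np.array(vox) < 0) or np.any(np.array(vox) >= fld.shape3):
        return None
    fr = fld.fractions[vox]
    eligible = fr > threshold
    if not eligible.any():
        return None
    k = int(np.argmax(np.where(eligible, fr, -1.0)))
    return fld.orientations[vox][k]


def _half_tracks(seeds, dirs, fld, mask, config):
    """Propagate a batch of half-tracks; returns per-seed point lists + reasons."""
    n = len(seeds)
    cos_thr = np.cos(np.deg2rad(config.angle_threshold_deg))
    shape = np.asarray(fld.shape3)
    pos = seeds.copy()
    u = dirs.copy()
    active = np.ones(n, dtype=bool)
    reasons = np.array(["max_steps"] * n, dtype=object)
    trail = [[] for _ in range(n)]
    for _ in range(config.max_steps):
        if not active.any():
            break
        ai = np.flatnonzero(active)
        w, valid = _batch_incoming(pos[ai], u[ai], fld, config.fraction_threshold)
        dead = ai[~valid]
        reasons[dead] = "no_direction"
        active[dead] = False
        ai = ai[valid]
        if not len(ai):
            continue
        w = w[valid]
        dots = np.einsum("mc,mc->m", u[ai], w)
        turn_ok = dots >= cos_thr
        dead = ai[~turn_ok]
        reasons[dead] = "angle"
        active[dead] = False
        ai = ai[turn_ok]
        if not len(ai):
            continue
        w = w[turn_ok]
        sw = config.smoothing_weight
        new_dir = (1.0 - sw) * u[ai] + sw * w
        new_dir /= np.linalg.norm(new_dir, axis=1, keepdims=True)
        new_pos = pos[ai] + config.step_size_voxels * new_dir
        vox = np.floor(new_pos).astype(int)
        inb = np.all((vox >= 0) & (vox < shape), axis=1)
        in_mask = np.zeros(len(ai), dtype=bool)
        if inb.any():
            vs = np.clip(vox, 0, shape - 1)
            in_mask[inb] = mask[tuple(vs[inb].T)]
        dead = ai[~in_mask]
        reasons[dead] = "out_of_mask"
        active[dead] = False
        ai = ai[in_mask]
        if not len(ai):
            continue
        new_pos = new_pos[in_mask]
        new_dir = new_dir[in_mask]
        for row, p in zip(ai, new_pos):
            trail[row].append(p)
        pos[ai] = new_pos
        u[ai] = new_dir
    return trail, reasons


def propagate(seed, fld: StickField, mask, config: RunConfig | None = None,
              seed_index: int = 0) -> Streamline:
    """Track one seed (bidirectionally by default) into a Streamline."""
    config = config or RunConfig()
    seed = np.asarray(seed, dtype=float)
    v0 = _initial_direction(seed, fld, config.fraction_threshold)
    if v0 is None:
        return Streamline(seed[None, :], seed_index, 0,
                          ("no_direction", "no_direction"))
    fwd_trail, fwd_r = _half_tracks(seed[None, :], v0[None, :], fld,
                                    np.asarray(mask, bool), config)
    if config.bidirectional:
        bwd_trail, bwd_r = _half_tracks(seed[None, :], -v0[None, :], fld,
                                        np.asarray(mask, bool), config)
    else:
        bwd_trail, bwd_r = [[]], np.array(["none"], dtype=object)
    back = bwd_trail[0][::-1]
    pts = np.array(back + [seed] + fwd_trail[0])
    return Streamline(pts, seed_index, len(back), (str(bwd_r[0]), str(fwd_r[0])))


def seed_and_track(seed_mask, fld: StickField, mask,
                   config: RunConfig | None = None,
                   affine=None, voxel_dims=None,
                   seed_mask_name: str = "seed") -> Tractogram:
    """Uniformly seed the seed-mask voxels and track every seed.

    Seed positions are drawn uniformly over the union of seed-voxel volumes
    with the configured rng seed; one (bidirectional) streamline per seed;
    streamlines with fewer than 2 points are dropped from the tractogram but
    counted in ``n_discarded``.
    """
    config = config or RunConfig()
    seed_mask = np.asarray(seed_mask, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    voxels = np.argwhere(seed_mask)
    if not len(voxels):
        raise ValueError("seed mask is empty")
    rng = np.random.default_rng(config.rng_seed)
    pick = rng.integers(0, len(voxels), size=config.n_seeds)
    seeds = voxels[pick] + rng.random((config.n_seeds, 3))

    dirs = np.zeros_like(seeds)
    valid = np.zeros(config.n_seeds, dtype=bool)
    for i, s in enumerate(seeds):
        v0 = _initial_direction(s, fld, config.fraction_threshold)
        if v0 is not None:
            dirs[i] = v0
            valid[i] = True
    idx = np.flatnonzero(valid)
    streamlines = []
    n_discarded = int((~valid).sum())
    if len(idx):
        fwd_trail, fwd_r = _half_tracks(seeds[idx], dirs[idx], fld, mask, config)
        if config.bidirectional:
            bwd_trail, bwd_r = _half_tracks(seeds[idx], -dirs[idx], fld, mask,
                                            config)
        else:
            bwd_trail = [[] for _ in idx]
            bwd_r = np.array(["none"] * len(idx), dtype=object)
        for j, si in enumerate(idx):
            back = bwd_trail[j][::-1]
            pts = np.array(back + [seeds[si]] + fwd_trail[j])
            if len(pts) < 2:
                n_discarded += 1
                continue
            streamlines.append(
                Streamline(pts, int(si), len(back),
                           (str(bwd_r[j]), str(fwd_r[j])))
            )
    if n_discarded:
        log(f"tracking: {n_discarded} seeds produced no retainable streamline")
    return Tractogram(
        streamlines=streamlines,
        config=config,
        seed_mask_name=seed_mask_name,
        affine=np.eye(4) if affine is None else np.asarray(affine, float),
        voxel_dims=np.ones(3) if voxel_dims is None else np.asarray(voxel_dims, float),
        shape3=fld.shape3,
        n_seeds=config.n_seeds,
        n_discarded=n_discarded,
    )
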