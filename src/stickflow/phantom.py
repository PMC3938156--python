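"""Synthetic diffusion-MRI phantoms with known ground truth.

The generators emulate the reference acquisition — a single b=0 frame plus 55
b=1000 s/mm^2 frames on an electrostatically dispersed direction set, voxel
size 1.88 x 1.88 x 3 mm — and inject, in order: a mean-reverting rigid motion
walk on the diffusion-weighted frames, sporadic whole-frame signal dropout,
and Rician noise (magnitude of a complex Gaussian channel pair).

Tissue follows the multi-compartment ball-and-stick model

    S = S0 * [ (1 - sum_j f_j) * exp(-b d) + sum_j f_j * exp(-b d (g.v_j)^2) ]

with a single diffusivity ``d`` shared by the isotropic ball and every stick.
Fiber bundles are tubes around polyline centerlines; the stick fraction is
constant in the tube core and falls linearly to zero over a one-voxel rim,
giving the partial-volume variation that real bundle borders show (and that
local source separation relies on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import DWIVolume, GradientTable
from .motion import transform_volume

__all__ = [
    "DEFAULT_VOXEL_DIMS",
    "DEFAULT_D",
    "DEFAULT_S0",
    "FiberBundleSpec",
    "PhantomTruth",
    "dispersed_directions",
    "default_gradient_table",
    "ball_stick_signal",
    "rasterize_bundles",
    "simulate_subject",
    "make_crossing_phantom",
    "cerebellum_bundles",
    "simulate_cohort",
    "simulate_metric_records",
]

DEFAULT_VOXEL_DIMS = np.array([1.88, 1.88, 3.0])
DEFAULT_D = 1.7e-3  # mm^2/s, typical white-matter diffusivity
DEFAULT_S0 = 1000.0
PATHWAYS = ("L_DDN", "L_VDN", "R_DDN", "R_VDN")

# AR(1) rigid walk: p_{k+1} = RHO p_k + eps.  Step scales are calibrated so
# the expected motion index equals the requested amplitude; rotations (radians)
# contribute ~2% of the index, keeping angular excursions at realistic ~1 deg.
_RHO = 0.7
_ROT_SHARE = 0.02


@dataclass
class FiberBundleSpec:
    """A tube of coherent fibers around a polyline centerline (voxel coords)."""

    centerline: np.ndarray  # (k, 3), k >= 2
    radius: float  # voxels
    stick_fraction: float  # core volume fraction, in [0, 1]
    diffusivity: float = DEFAULT_D  # mm^2/s

    def __post_init__(self):
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if len(self.centerline) < 2:
            raise ValueError("centerline needs at least 2 points")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0 <= self.stick_fraction <= 1:
            raise ValueError("stick_fraction must lie in [0, 1]")


@dataclass
class PhantomTruth:
    """Everything a test needs to score a pipeline stage against ground truth."""

    orientations: np.ndarray  # (x, y, z, 3, 3) unit vectors, zero-padded
    fractions: np.ndarray  # (x, y, z, 3)
    seed_mask: np.ndarray | None = None
    target_masks: dict = field(default_factory=dict)
    analysis_mask: np.ndarray | None = None
    region_mask: np.ndarray | None = None  # cerebellum surrogate (density denominator)
    motion_params: np.ndarray | None = None  # (n_dwi, 6) injected rigid walk
    outlier_frames: np.ndarray | None = None  # indices into the full frame axis
    d: float = DEFAULT_D
    S0: float = DEFAULT_S0
    S0_map: np.ndarray | None = None

    @property
    def n_sticks(self) -> np.ndarray:
        return (self.fractions > 0).sum(axis=-1)


# ---------------------------------------------------------------------------
# acquisition geometry
# ---------------------------------------------------------------------------

def dispersed_directions(n: int, iters: int = 80) -> np.ndarray:
    """``n`` unit vectors spread by antipodally-symmetric electrostatic repulsion.

    Deterministic: starts from a spherical Fibonacci hemisphere layout and
    descends the Coulomb energy of the n points and their antipodes.
    """
    i = np.arange(n)
    z = (i + 0.5) / n  # upper hemisphere
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z * z)
    pts = np.c_[r * np.cos(phi), r * np.sin(phi), z]
    step = 0.05
    for _ in range(iters):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            diff = pts[:, None, :] - sign * pts[None, :, :]  # (n, n, 3)
            dist = np.linalg.norm(diff, axis=-1)
            np.fill_diagonal(dist, np.inf)
            if sign < 0:
                dist[dist < 1e-9] = np.inf  # own antipode
            force += (diff / dist[..., None] ** 3).sum(axis=1)
        # project onto the tangent plane, take a bounded step
        force -= (force * pts).sum(axis=1, keepdims=True) * pts
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        pts = pts + step * force / norm
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def default_gradient_table(n_directions: int = 55, b: float = 1000.0) -> GradientTable:
    """The reference encoding: one b=0 plus ``n_directions`` at b (s/mm^2)."""
    dirs = dispersed_directions(n_directions)
    bvals = np.r_[0.0, np.full(n_directions, b)]
    bvecs = np.r_[np.zeros((1, 3)), dirs]
    return GradientTable(bvals, bvecs)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def ball_stick_signal(S0, b, g, sticks, d) -> float:
    """Noise-free ball-and-stick signal for one gradient.

    ``sticks`` is a sequence of (unit direction, fraction) pairs; the ball
    takes the remaining fraction.  Shared diffusivity ``d`` in mm^2/s.
    """
    g = np.asarray(g, dtype=float)
    fsum = 0.0
    stick_term = 0.0
    for v, f in sticks:
        if f < 0:
            raise ValueError("negative stick fraction")
        fsum += f
        proj = float(np.dot(g, np.asarray(v, dtype=float)))
        stick_term += f * np.exp(-b * d * proj * proj)
    if fsum > 1 + 1e-9:
        raise ValueError(f"stick fractions sum to {fsum} > 1")
    return float(S0 * ((1.0 - fsum) * np.exp(-b * d) + stick_term))


def _attenuation_field(orients, fracs, table, d) -> np.ndarray:
    """Vectorized per-voxel attenuations, shape grid + (n_frames,)."""
    shape = fracs.shape[:3]
    flat_f = fracs.reshape(-1, fracs.shape[-1])  # (N, 3)
    flat_v = orients.reshape(-1, fracs.shape[-1], 3)
    ball = 1.0 - flat_f.sum(axis=1)  # (N,)
    att = np.empty((flat_f.shape[0], len(table)))
    for i, (b, g) in enumerate(zip(table.bvals, table.bvecs)):
        if b <= 0:
            att[:, i] = 1.0
            continue
        proj2 = np.einsum("nsk,k->ns", flat_v, g) ** 2  # (N, 3)
        att[:, i] = ball * np.exp(-b * d) + np.einsum(
            "ns,ns->n", flat_f, np.exp(-b * d * proj2)
        )
    return att.reshape(shape + (len(table),))


# ---------------------------------------------------------------------------
# bundle rasterization
# ---------------------------------------------------------------------------

def _polyline_distance(points: np.ndarray, centerline: np.ndarray):
    """Min distance from each point to the polyline, plus local unit tangent."""
    best_d = np.full(len(points), np.inf)
    best_t = np.zeros((len(points), 3))
    for a, b in zip(centerline[:-1], centerline[1:]):
        ab = b - a
        L2 = float(ab @ ab)
        t = np.clip((points - a) @ ab / L2, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(points - proj, axis=1)
        closer = d < best_d
        best_d[closer] = d[closer]
        best_t[closer] = ab / np.sqrt(L2)
    return best_d, best_t


def rasterize_bundles(bundles, grid_shape):
    """Per-voxel true stick orientations and fractions for a set of bundles.

    Raises if overlapping bundles push a voxel's total stick fraction above 1.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    orients = np.zeros(grid_shape + (3, 3))
    fracs = np.zeros(grid_shape + (3,))
    counts = np.zeros(grid_shape, dtype=int)
    idx = np.indices(grid_shape).reshape(3, -1).T
    centers = idx + 0.5
    for bu in bundles:
        lo = np.maximum(np.floor(bu.centerline.min(axis=0) - bu.radius - 1), 0).astype(int)
        hi = np.minimum(
            np.ceil(bu.centerline.max(axis=0) + bu.radius + 1), grid_shape
        ).astype(int)
        box = np.all((idx >= lo) & (idx < hi), axis=1)
        d, tang = _polyline_distance(centers[box], bu.centerline)
        rim = min(1.0, bu.radius)
        taper = np.clip((bu.radius - d) / rim, 0.0, 1.0)
        inside = taper > 0
        sel = np.flatnonzero(box)[inside]
        for flat_i, fr, tg in zip(sel, taper[inside], tang[inside]):
            vox = tuple(idx[flat_i])
            k = counts[vox]
            if k >= 3:
                continue  # keep the first three compartments
            orients[vox][k] = tg
            fracs[vox][k] = fr * bu.stick_fraction
            counts[vox] = k + 1
    total = fracs.sum(axis=-1)
    if np.any(total > 1 + 1e-9):
        raise ValueError(
            f"overlapping bundles exceed unit fraction (max {total.max():.3f})"
        )
    return orients, fracs


# ---------------------------------------------------------------------------
# subject-level simulation
# ---------------------------------------------------------------------------

def _motion_walk(n_frames: int, amplitude: float, rng) -> np.ndarray:
    """Stationary AR(1) rigid walk whose expected motion index is ``amplitude``."""
    if amplitude <= 0:
        return np.zeros((n_frames, 6))
    # E[index] = 3 * sqrt(2/pi) * sqrt(2/(1+rho)) * (s_t + s_r)
    k = 3.0 * np.sqrt(2.0 / np.pi) * np.sqrt(2.0 / (1.0 + _RHO))
    s_t = amplitude / (k * (1.0 + _ROT_SHARE))
    s_r = _ROT_SHARE * s_t
    s = np.array([s_t] * 3 + [s_r] * 3)
    sigma = s / np.sqrt(1.0 - _RHO**2)
    p = np.empty((n_frames, 6))
    p[0] = rng.normal(0.0, sigma)
    for kf in range(1, n_frames):
        p[kf] = _RHO * p[kf - 1] + rng.normal(0.0, s)
    return p


def simulate_subject(
    bundles,
    grid_shape,
    table: GradientTable,
    snr: float = 30.0,
    motion_amplitude: float = 0.0,
    outlier_rate: float = 0.0,
    rng_seed: int = 0,
    voxel_dims=DEFAULT_VOXEL_DIMS,
    S0: float = DEFAULT_S0,
    d: float = DEFAULT_D,
    seed_mask=None,
    target_masks=None,
):
    """Simulate one 4D acquisition with full ground truth.

    ``snr`` is S0 over the Gaussian channel sigma of the Rician noise; pass
    ``numpy.inf`` for the noise-free limit.  Dropout replaces a b>0 frame,
    with probability ``outlier_rate``, by the same frame scaled by a factor
    drawn uniformly in [0.2, 0.6].
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(rng_seed)
    orients, fracs = rasterize_bundles(bundles, grid_shape)
    total_f = fracs.sum(axis=-1)
    # mild S0 structure tied to the fiber architecture so frames are registrable
    S0_map = S0 * (0.75 + 0.5 * total_f)
    att = _attenuation_field(orients, fracs, table, d)
    clean = S0_map[..., None] * att

    dwi_idx = np.flatnonzero(table.dwi_mask)
    motion = _motion_walk(len(dwi_idx), motion_amplitude, rng)
    data = clean.copy()
    if motion_amplitude > 0:
        for row, fi in enumerate(dwi_idx):
            data[..., fi] = transform_volume(clean[..., fi], motion[row], voxel_dims)

    dropped = rng.random(len(dwi_idx)) < outlier_rate
    scales = rng.uniform(0.2, 0.6, size=len(dwi_idx))
    for row, fi in enumerate(dwi_idx):
        if dropped[row]:
            data[..., fi] *= scales[row]

    if np.isfinite(snr):
        sigma = S0 / snr
        g1 = rng.normal(0.0, sigma, size=data.shape)
        g2 = rng.normal(0.0, sigma, size=data.shape)
        data = np.sqrt((data + g1) ** 2 + g2**2)

    affine = np.diag(list(voxel_dims) + [1.0])
    volume = DWIVolume(data=data, affine=affine, voxel_dims=np.asarray(voxel_dims))
    fiber_mask = total_f > 0
    analysis = ndimage.binary_dilation(fiber_mask, iterations=1)
    for m in (target_masks or {}).values():
        analysis |= m.astype(bool)
    if seed_mask is not None:
        analysis |= seed_mask.astype(bool)
    truth = PhantomTruth(
        orientations=orients,
        fractions=fracs,
        seed_mask=seed_mask,
        target_masks=dict(target_masks or {}),
        analysis_mask=analysis,
        region_mask=analysis.copy(),
        motion_params=motion,
        outlier_frames=dwi_idx[dropped],
        d=d,
        S0=S0,
        S0_map=S0_map,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# named phantoms
# ---------------------------------------------------------------------------

def _blob_mask(grid_shape, center, radius) -> np.ndarray:
    centers = np.indices(grid_shape).reshape(3, -1).T + 0.5
    d = np.linalg.norm(centers - np.asarray(center, dtype=float), axis=1)
    return (d <= radius).reshape(grid_shape)


def make_crossing_phantom(
    angle_deg: float,
    fractions=(0.4, 0.4),
    grid_shape=(20, 20, 9),
    table: GradientTable | None = None,
    snr: float = 30.0,
    rng_seed: int = 0,
    radius: float = 1.6,
    **kw,
):
    """Two straight bundles crossing at ``angle_deg`` in the grid center.

    End-cap masks (``A_start``, ``A_end``, ``B_start``, ``B_end``) suit
    seed/target experiments; bundle A runs along +x, bundle B at the stated
    angle in the axial plane.
    """
    if not 0 < angle_deg <= 90:
        raise ValueError("angle must lie in (0, 90]")
    if table is None:
        table = default_gradient_table()
    grid_shape = tuple(int(s) for s in grid_shape)
    c = np.asarray(grid_shape, dtype=float) / 2.0
    theta = np.deg2rad(angle_deg)
    ua = np.array([1.0, 0.0, 0.0])
    ub = np.array([np.cos(theta), np.sin(theta), 0.0])
    half = min(grid_shape[0], grid_shape[1]) / 2.0 - 1.0
    bundles = [
        FiberBundleSpec(np.array([c - half * ua, c + half * ua]), radius, fractions[0]),
        FiberBundleSpec(np.array([c - half * ub, c + half * ub]), radius, fractions[1]),
    ]
    volume, truth = simulate_subject(
        bundles, grid_shape, table, snr=snr, rng_seed=rng_seed, **kw
    )
    caps = {}
    for name, u, bu in (("A", ua, bundles[0]), ("B", ub, bundles[1])):
        for tag, end in (("start", c - half * u), ("end", c + half * u)):
            cap = _blob_mask(grid_shape, end + 0.5 * u * (1 if tag == "end" else -1),
                             radius + 0.6)
            caps[f"{name}_{tag}"] = cap
    truth.target_masks = caps
    truth.seed_mask = caps["A_start"]
    for m in caps.values():
        truth.analysis_mask |= m
    truth.region_mask = truth.analysis_mask.copy()
    return volume, truth


def cerebellum_bundles(grid_shape=(32, 32, 12), stick_fraction: float = 0.55,
                       degraded: str | None = None, effect: float = 0.0):
    """Cerebellum-like layout: two lateral seed slabs, four curved bundles to
    dorsal/ventral dentate surrogate blobs.

    Returns (bundles-by-pathway dict, seed_mask, target_masks).
    ``degraded`` names the pathway whose core stick fraction is multiplied by
    (1 - effect).
    """
    gx, gy, gz = grid_shape
    zc = gz / 2.0
    z0, z1 = int(max(zc - 2, 0)), int(min(zc + 2, gz))
    seed = np.zeros(grid_shape, dtype=bool)
    # two thin cortical ribbons per side, wrapped around the bundle origins
    for ys in (slice(9, 13), slice(19, 23)):
        seed[2:5, ys, z0:z1] = True
        seed[gx - 5:gx - 2, ys, z0:z1] = True

    def mirror(pts):
        pts = np.array(pts, dtype=float)
        pts[:, 0] = gx - pts[:, 0]
        return pts

    lines = {
        "L_DDN": np.array([[3, 11, zc], [8, 11, zc], [12.5, 9.5, zc], [13.5, 9, zc]]),
        "L_VDN": np.array([[3, 21, zc], [8, 21, zc], [12.5, 22.5, zc], [13.5, 23, zc]]),
    }
    lines["R_DDN"] = mirror(lines["L_DDN"])
    lines["R_VDN"] = mirror(lines["L_VDN"])
    targets = {
        "L_DDN": _blob_mask(grid_shape, (13.8, 9, zc), 1.7),
        "L_VDN": _blob_mask(grid_shape, (13.8, 23, zc), 1.7),
        "R_DDN": _blob_mask(grid_shape, (gx - 13.8, 9, zc), 1.7),
        "R_VDN": _blob_mask(grid_shape, (gx - 13.8, 23, zc), 1.7),
    }
    bundles = {}
    for name, line in lines.items():
        f = stick_fraction
        if name == degraded:
            f = stick_fraction * (1.0 - effect)
        bundles[name] = FiberBundleSpec(line, radius=1.5, stick_fraction=f)
    return bundles, seed, targets


def simulate_cohort(
    n_per_group=(14, 15),
    effect: float = 0.3,
    degraded_pathway: str = "R_VDN",
    age_range=(3.6, 14.0),
    motion_dists=((2.00, 0.67), (1.12, 0.63)),
    outlier_rates=(0.09, 0.07),
    snr: float = 30.0,
    grid_shape=(32, 32, 12),
    table: GradientTable | None = None,
    rng_seed: int = 0,
):
    """Simulate a two-group cohort of cerebellum-like subjects.

    Group A plays the comparison (typically developing) role, group B the
    clinical role: B subjects carry a (1 - effect) reduction of the core stick
    fraction along ``degraded_pathway``, lower injected motion, and a lower
    dropout rate, mirroring the sedated-versus-awake acquisition contrast.

    Returns (subjects, covariates): ``subjects`` is a list of dicts with keys
    subject_id/group/volume/truth/table; ``covariates`` one record per subject.
    """
    if min(n_per_group) < 2:
        raise ValueError("need at least 2 subjects per group")
    if table is None:
        table = default_gradient_table()
    rng = np.random.default_rng(rng_seed)
    subjects, covariates = [], []
    sid = 0
    for gi, (glabel, n) in enumerate(zip("AB", n_per_group)):
        mu, sd = motion_dists[gi]
        for _ in range(n):
            sid += 1
            age = rng.uniform(*age_range)
            amp = max(float(rng.normal(mu, sd)), 0.05)
            bundles, seed_mask, target_masks = cerebellum_bundles(
                grid_shape,
                degraded=degraded_pathway if glabel == "B" else None,
                effect=effect,
            )
            sub_seed = int(rng.integers(0, 2**31 - 1))
            volume, truth = simulate_subject(
                list(bundles.values()),
                grid_shape,
                table,
                snr=snr,
                motion_amplitude=amp,
                outlier_rate=outlier_rates[gi],
                rng_seed=sub_seed,
                seed_mask=seed_mask,
                target_masks=target_masks,
            )
            subjects.append(
                {
                    "subject_id": f"sub-{sid:03d}",
                    "group": glabel,
                    "volume": volume,
                    "truth": truth,
                    "table": table,
                }
            )
            covariates.append(
                {
                    "subject_id": f"sub-{sid:03d}",
                    "group": glabel,
                    "age": float(age),
                    "motion_target": amp,
                    "outlier_rate": outlier_rates[gi],
                }
            )
    return subjects, covariates


# ---------------------------------------------------------------------------
# record-level cohorts (for statistical calibration at scale)
# ---------------------------------------------------------------------------

def simulate_metric_records(
    n_per_group=(14, 15),
    effect_sd: float = 0.0,
    affected=("R_VDN",),
    metric: str = "FA",
    baseline: float = 0.27,
    sd: float = 0.03,
    age_slope: float = 0.0,
    motion_slope: float = 0.0,
    age_range=(3.6, 14.0),
    motion_dists=((2.00, 0.67), (1.12, 0.63)),
    rng=None,
):
    """Draw per-subject pathway metric records without any imaging.

    The metric is Gaussian around ``baseline`` with spread ``sd``; group B is
    shifted down by ``effect_sd`` pooled standard deviations on the
    ``affected`` pathways.  Optional linear age and motion dependencies apply
    to every subject.  Used for large Monte-Carlo calibration of the group
    statistics at the study's sample sizes.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    records = []
    sid = 0
    for gi, (glabel, n) in enumerate(zip("AB", n_per_group)):
        mu, msd = motion_dists[gi]
        for _ in range(n):
            sid += 1
            age = rng.uniform(*age_range)
            motion = max(float(rng.normal(mu, msd)), 0.05)
            rec = {
                "subject_id": f"sub-{sid:03d}",
                "group": glabel,
                "age": float(age),
                "motion": motion,
            }
            for pw in PATHWAYS:
                val = baseline + age_slope * (age - np.mean(age_range)) \
                    + motion_slope * motion + rng.normal(0.0, sd)
                if glabel == "B" and pw in affected:
                    val -= effect_sd * sd
                rec[f"{metric}_{pw}"] = float(val)
            records.append(rec)
    return records
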