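"""Multi-fiber estimation: local independent-component decomposition
alternated with ball-and-stick model fitting.

At every analysis voxel a small spatial window of attenuation profiles
(S/S0 across the diffusion-weighted gradients) forms a data matrix whose
rows are voxels and whose columns are gradients.  Partial-volume variation
across the window makes the single-fiber attenuation profiles separable as
hidden sources; FastICA recovers up to three of them, each source is fitted
with a one-stick attenuation model to extract its orientation, and the
volume fractions of all sticks plus the isotropic ball are then re-estimated
at the center voxel by constrained least squares with the orientations held
fixed.  Pruning low-fraction sticks and re-decomposing closes the loop.

The window defaults to the center voxel, its six face neighbors and its four
in-slice diagonal neighbors (eleven voxels), a layout chosen for strongly
anisotropic voxels where through-slice neighbors are farther away in
millimetres than in-plane ones; face-only (7) and full-cube (27) layouts are
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar, nnls

from .io import DWIVolume, GradientTable, RunConfig, log
from .tensor import fa as _fa_of

__all__ = [
    "WindowDegenerateError",
    "LocalWindow",
    "StickField",
    "window_offsets",
    "build_window",
    "decompose_sources",
    "fit_single_stick",
    "fit_voxel_icabsm",
    "fit_stick_field",
    "BallStickModel",
    "StickFieldResults",
]

_LAYOUTS = {
    "face7": np.array(
        [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    ),
    "inplane11": np.array(
        [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
         (0, 0, -1), (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0)]
    ),
    "cube27": np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    ),
}

_D_BOUNDS = (1e-5, 5e-3)  # mm^2/s search range for the shared diffusivity
_FLATNESS_TOL = 1e-3  # relative modulation below which a profile is isotropic


class WindowDegenerateError(RuntimeError):
    """Too few usable window rows for source separation."""


def window_offsets(layout: str) -> np.ndarray:
    try:
        return _LAYOUTS[layout]
    except KeyError:
        raise ValueError(f"unknown window layout {layout!r}") from None


@dataclass
class LocalWindow:
    """Attenuation data matrix of a spatial neighborhood.

    ``data`` rows are member voxels, columns the b>0 gradients.
    """

    center: tuple
    members: np.ndarray  # (m, 3) voxel indices
    data: np.ndarray  # (m, n_dwi)


@dataclass
class StickField:
    """Per-voxel multi-fiber solution over a grid (up to 3 sticks each)."""

    orientations: np.ndarray  # (x, y, z, 3, 3), unit vectors, zero-padded
    fractions: np.ndarray  # (x, y, z, 3)
    d: np.ndarray  # (x, y, z) shared diffusivity, mm^2/s
    S0: np.ndarray  # (x, y, z)
    mask: np.ndarray  # analysis mask
    fallback: np.ndarray | None = None  # voxels that used the single-tensor fallback

    @property
    def shape3(self) -> tuple:
        return self.fractions.shape[:3]

    @property
    def n_sticks(self) -> np.ndarray:
        return (self.fractions > 0).sum(axis=-1)

    @property
    def ball_fraction(self) -> np.ndarray:
        return 1.0 - self.fractions.sum(axis=-1)

    def save(self, prefix) -> None:
        """Write the field as NIfTI volumes under ``prefix``_*.nii."""
        from pathlib import Path

        from .io import write_volume

        prefix = str(prefix)
        shape = self.shape3
        write_volume(self.orientations.reshape(shape + (9,)),
                     prefix + "_stick_dirs.nii")
        write_volume(self.fractions, prefix + "_stick_fracs.nii")
        write_volume(self.d, prefix + "_d.nii")
        write_volume(self.S0, prefix + "_s0.nii")
        write_volume(self.mask.astype(np.float32), prefix + "_mask.nii")

    @classmethod
    def load(cls, prefix) -> "StickField":
        from .io import read_volume

        prefix = str(prefix)
        dirs = read_volume(prefix + "_stick_dirs.nii").data
        shape = dirs.shape[:3]
        return cls(
            orientations=dirs.reshape(shape + (3, 3)),
            fractions=read_volume(prefix + "_stick_fracs.nii").data,
            d=read_volume(prefix + "_d.nii").data[..., 0],
            S0=read_volume(prefix + "_s0.nii").data[..., 0],
            mask=read_volume(prefix + "_mask.nii").data[..., 0] > 0.5,
        )

    def no_stick_density(self, region_mask=None) -> float:
        """Fraction of region voxels carrying no stick compartment."""
        region = self.mask if region_mask is None else np.asarray(region_mask, bool)
        n = int(region.sum())
        if n == 0:
            return 1.0
        return float((self.n_sticks[region] == 0).sum() / n)


# ---------------------------------------------------------------------------
# window construction
# ---------------------------------------------------------------------------

def precompute_attenuations(volume: DWIVolume, table: GradientTable) -> tuple:
    """One-off (mean b0 volume, S/S0 attenuation 4D array) for window reuse."""
    b0 = volume.data[..., table.b0_mask].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        att = volume.data[..., table.dwi_mask] / b0[..., None]
    att[~np.isfinite(att)] = 0.0
    return b0, att


def build_window(volume: DWIVolume, mask, center, table: GradientTable,
                 layout: str = "inplane11", precomputed=None) -> LocalWindow:
    """Attenuation matrix for the neighborhood of ``center``.

    Members falling outside the mask or the grid are dropped (the window
    shrinks at edges); rows with non-positive S0 are dropped and logged.
    Raises :class:`WindowDegenerateError` below 3 usable rows.
    ``precomputed`` accepts the output of :func:`precompute_attenuations`
    when many windows are built over the same volume.
    """
    mask = np.asarray(mask, dtype=bool)
    center = tuple(int(c) for c in center)
    if not mask[center]:
        raise ValueError(f"window center {center} outside mask")
    offs = window_offsets(layout)
    cand = np.asarray(center)[None, :] + offs
    shape = np.asarray(volume.shape3)
    ok = np.all((cand >= 0) & (cand < shape), axis=1)
    cand = cand[ok]
    ok2 = mask[tuple(cand.T)]
    cand = cand[ok2]
    b0_vol, att_vol = precomputed or precompute_attenuations(volume, table)
    b0 = b0_vol[tuple(cand.T)]
    rows = att_vol[tuple(cand.T)]
    usable = b0 > 0
    if not np.all(usable):
        log(f"window at {center}: dropped {int((~usable).sum())} rows with S0<=0")
    cand, rows = cand[usable], rows[usable]
    if len(cand) < 3:
        raise WindowDegenerateError(
            f"window at {center} has {len(cand)} usable rows (< 3)"
        )
    return LocalWindow(center=center, members=cand, data=rows)


# ---------------------------------------------------------------------------
# hidden-source decomposition
# ---------------------------------------------------------------------------

def decompose_sources(window: LocalWindow, max_components: int = 3,
                      rng_seed: int = 0) -> list:
    """Recover up to ``max_components`` source attenuation profiles by FastICA.

    The number of components is chosen by principal-component analysis
    (eigenvalue share >= 5%, capped at ``min(max_components, rows - 1)``).
    Each returned profile is shifted to be nonnegative and scaled to unit
    maximum; its sign is first resolved so that the deep attenuation dips the
    stick signature produces lie below the bulk of the profile (negative
    skew).  Deterministic under ``rng_seed``; if FastICA does not converge the
    principal components are returned instead.
    """
    from sklearn.decomposition import PCA, FastICA
    from sklearn.exceptions import ConvergenceWarning

    X = window.data.T  # samples = gradients, features = window voxels
    max_components = int(min(max_components, X.shape[1] - 1, 3))
    if max_components < 1:
        return []
    centered = X - X.mean(axis=0, keepdims=True)
    total_var = float(np.var(centered))
    if total_var < 1e-16:  # flat window: no directional structure
        return []
    # eigenvalue shares straight from the SVD of the centered matrix
    svals = np.linalg.svd(centered, compute_uv=False)
    evr = svals**2 / np.sum(svals**2)
    k = int(np.sum(evr >= 0.05))
    k = max(1, min(k, max_components))
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ica = FastICA(
                n_components=k, algorithm="deflation", fun="exp",
                max_iter=500, tol=1e-4, random_state=rng_seed,
                whiten="unit-variance",
            )
            sources = ica.fit_transform(X)  # (n_dwi, k)
            loadings = ica.mixing_  # (window voxels, k)
        except (ConvergenceWarning, ValueError):
            log(f"FastICA did not converge at {window.center}; PCA fallback")
            p = PCA(n_components=k).fit(X)
            sources = p.transform(X)
            loadings = p.components_.T
    profiles = []
    for j in range(sources.shape[1]):
        s = sources[:, j]
        if np.ptp(s) == 0:
            continue
        # physical mixing weights (volume fractions) are nonnegative: pick
        # the sign that makes this source's loading column mostly positive
        lsum = float(loadings[:, j].sum())
        if lsum < 0:
            s = -s
        elif lsum == 0 and np.mean((s - np.median(s)) ** 3) > 0:
            s = -s
        s = s - s.min()
        m = s.max()
        profiles.append(s / m if m > 0 else s)
    return profiles


# ---------------------------------------------------------------------------
# per-source stick fit
# ---------------------------------------------------------------------------

def _angles_of(v: np.ndarray) -> tuple:
    theta = float(np.arccos(np.clip(v[2], -1.0, 1.0)))
    phi = float(np.arctan2(v[1], v[0]))
    return theta, phi

def _vec_of(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])

def canonical(v: np.ndarray) -> np.ndarray:
    """Antipodally-canonical representative: first nonzero coordinate positive."""
    for comp in v:
        if abs(comp) > 1e-12:
            return v if comp > 0 else -v
    return v


def _profile_tensor_direction(profile, table: GradientTable) -> np.ndarray:
    """Principal direction of the log-profile quadratic form (fit initializer)."""
    g = table.bvecs[table.dwi_mask]
    b = table.bvals[table.dwi_mask]
    p = np.clip(profile, 1e-6, None)
    y = -np.log(p) / b  # ~ d * (g.v)^2 up to offset
    q = np.c_[g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
              2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]]
    X = np.c_[np.ones(len(y)), q]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    Dxx, Dyy, Dzz, Dxy, Dxz, Dyz = coef[1:]
    D = np.array([[Dxx, Dxy, Dxz], [Dxy, Dyy, Dyz], [Dxz, Dyz, Dzz]])
    w, V = np.linalg.eigh(D)
    return V[:, np.argmax(w)]


def fit_single_stick(profile, table: GradientTable):
    """Fit one stick attenuation ``c * exp(-b d (g.v)^2) + a`` to a profile.

    The free offset/scale absorb the affine indeterminacy ICA leaves on each
    source.  Returns ``(v, d)`` with ``v`` antipodally canonical, or
    ``(None, None)`` for a flat (isotropic) profile.  Variable projection:
    the nonlinear search runs over (d, theta, phi) with (a, c) solved
    linearly at each step.
    """
    profile = np.asarray(profile, dtype=float)
    rng_rel = np.ptp(profile) / max(np.max(np.abs(profile)), 1e-12)
    if rng_rel < _FLATNESS_TOL:
        return None, None
    g = table.bvecs[table.dwi_mask]
    b = table.bvals[table.dwi_mask]
    v0 = _profile_tensor_direction(profile, table)
    theta0, phi0 = _angles_of(v0)
    n = len(b)
    sum_p = float(profile.sum())

    def _pieces(params):
        log_d, theta, phi = params
        d = np.exp(log_d)
        v = _vec_of(theta, phi)
        u = g @ v
        e = np.exp(-b * d * u * u)
        # closed-form 2x2 normal equations for the linear (scale, offset) pair
        see, se = float(e @ e), float(e.sum())
        sep = float(e @ profile)
        det = see * n - se * se
        if abs(det) < 1e-12:
            return d, v, u, e, 1.0, 0.0
        c = (sep * n - se * sum_p) / det
        a = (see * sum_p - se * sep) / det
        return d, v, u, e, c, a

    def model_and_resid(params):
        _d, _v, _u, e, c, a = _pieces(params)
        return c * e + a - profile

    def jac(params):
        # Kaufman approximation: treat the projected linear pair as fixed
        d, v, u, e, c, a = _pieces(params)
        _log_d, theta, phi = params
        st, ct = np.sin(theta), np.cos(theta)
        sp, cp = np.sin(phi), np.cos(phi)
        dv_dtheta = np.array([ct * cp, ct * sp, -st])
        dv_dphi = np.array([-st * sp, st * cp, 0.0])
        ce = c * e
        J = np.empty((len(e), 3))
        J[:, 0] = ce * (-b * d * u * u)  # d/d(log d)
        J[:, 1] = ce * (-2.0 * b * d * u * (g @ dv_dtheta))
        J[:, 2] = ce * (-2.0 * b * d * u * (g @ dv_dphi))
        return J

    sol = least_squares(
        model_and_resid,
        x0=[np.log(1.5e-3), theta0, phi0],
        jac=jac, method="lm", xtol=1e-8, ftol=1e-8, max_nfev=30,
    )
    d_hat = float(np.clip(np.exp(sol.x[0]), *_D_BOUNDS))
    v = canonical(_vec_of(sol.x[1], sol.x[2]))
    # reject non-modulating solutions (offset ate the whole profile)
    if d_hat * np.max(b) < 0.05 or d_hat <= 2.0 * _D_BOUNDS[0]:
        return None, None
    return v, float(d_hat)


# ---------------------------------------------------------------------------
# center-voxel fraction refit
# ---------------------------------------------------------------------------

def _fraction_fit(att, table: GradientTable, orients, d):
    """Simplex-constrained least squares for (ball, stick) fractions at fixed d."""
    b = table.bvals[table.dwi_mask]
    g = table.bvecs[table.dwi_mask]
    cols = [np.exp(-b * d)]
    for v in orients:
        cols.append(np.exp(-b * d * (g @ v) ** 2))
    A = np.column_stack(cols)
    # sum-to-one enforced through a heavily weighted penalty row, then exact
    # renormalization of the nonnegative solution
    w = 1e3
    A_aug = np.vstack([A, w * np.ones(A.shape[1])])
    y_aug = np.r_[att, w]
    f, rnorm = nnls(A_aug, y_aug)
    total = f.sum()
    if total > 0:
        f = f / total
    resid = A @ f - att
    return f, float(resid @ resid)


def _fit_fractions_shared_d(att, table, orients, d0):
    """Optimize the shared diffusivity and the fraction simplex jointly."""

    def obj(d):
        return _fraction_fit(att, table, orients, d)[1]

    res = minimize_scalar(obj, bounds=_D_BOUNDS, method="bounded",
                          options={"xatol": 1e-5, "maxiter": 40})
    d_opt = float(res.x)
    f, sse = _fraction_fit(att, table, orients, d_opt)
    return f, d_opt, sse


# ---------------------------------------------------------------------------
# per-voxel alternation
# ---------------------------------------------------------------------------

@dataclass
class StickVoxel:
    orientations: np.ndarray  # (k, 3)
    fractions: np.ndarray  # (k,)
    ball_fraction: float
    d: float
    S0: float
    fallback: bool = False


def _ball_only(att, table, S0) -> StickVoxel:
    b = table.bvals[table.dwi_mask]
    mean_att = float(np.clip(np.mean(att), 1e-6, 1.0))
    d = float(np.clip(-np.log(mean_att) / np.mean(b), *_D_BOUNDS))
    return StickVoxel(np.zeros((0, 3)), np.zeros(0), 1.0, d, S0)


def _tensor_fallback(signals, table, S0) -> StickVoxel:
    from .tensor import DegenerateFitError, fit_tensor_robust

    try:
        tv = fit_tensor_robust(signals, table, reject_threshold=np.inf)
    except DegenerateFitError:
        return StickVoxel(np.zeros((0, 3)), np.zeros(0), 1.0, 1.5e-3, S0, True)
    l1, l2, l3 = tv.eigenvalues
    f = float(np.clip(_fa_of(l1, l2, l3), 0.0, 1.0))
    if f <= 0:
        sv = _ball_only(signals[table.dwi_mask] / max(S0, 1e-9), table, S0)
        sv.fallback = True
        return sv
    v = canonical(tv.eigenvectors[:, 0])
    d = float(np.clip((l1 + l2 + l3) / 3.0, *_D_BOUNDS))
    return StickVoxel(v[None, :], np.array([f]), 1.0 - f, d, S0, True)


def fit_voxel_icabsm(volume: DWIVolume, mask, table: GradientTable, center,
                     config: RunConfig | None = None,
                     precomputed=None) -> StickVoxel:
    """Resolve up to 3 stick compartments at one voxel.

    Alternates source decomposition over the local window with ball-and-stick
    fraction refitting at the center voxel until the fraction vector moves by
    less than 1e-3 (at most 10 rounds).  The decomposition is deterministic
    given the window, so it is evaluated once and the alternation reduces to
    iterating the constrained fraction refit over the shrinking candidate
    set: sticks below the minimum retained fraction are pruned and the
    survivors refitted until stable, then renormalized with the ball to sum
    to one.  A degenerate window falls back to a single-tensor stick.
    """
    config = config or RunConfig()
    center = tuple(int(c) for c in center)
    S0 = float(volume.data[center][table.b0_mask].mean())
    signals = volume.data[center]
    if S0 <= 0:
        return StickVoxel(np.zeros((0, 3)), np.zeros(0), 1.0, 1.5e-3, max(S0, 0.0))
    att = signals[table.dwi_mask] / S0
    try:
        window = build_window(volume, mask, center, table, config.window_layout,
                              precomputed)
    except WindowDegenerateError:
        return _tensor_fallback(signals, table, S0)
    if np.ptp(att) / max(np.max(np.abs(att)), 1e-12) < _FLATNESS_TOL:
        return _ball_only(att, table, S0)

    max_k = min(3, len(window.members) - 1)
    profiles = decompose_sources(window, max_k, config.rng_seed)
    cand = []
    for p in profiles:
        v, _dj = fit_single_stick(p, table)
        if v is None:
            continue
        # merge near-collinear candidates (keep the first)
        if any(abs(v @ u) > np.cos(np.deg2rad(5.0)) for u in cand):
            continue
        cand.append(v)
    if not cand:
        return _ball_only(att, table, S0)

    d_hat = 1.5e-3
    ball = 1.0
    fracs = np.zeros(0)
    for _ in range(10):
        f, d_hat, _ = _fit_fractions_shared_d(att, table, cand, d_hat)
        ball, stick_f = f[0], f[1:]
        keep = stick_f >= config.min_stick_fraction
        if not keep.any():
            return _ball_only(att, table, S0)
        cand = [v for v, k in zip(cand, keep) if k]
        fracs = stick_f[keep]
        if keep.all():
            # the refit with a fixed candidate set is deterministic, so an
            # un-pruned solution is already the alternation's fixed point
            break
    # fold any pruned mass back through exact renormalization with the ball
    norm = ball + fracs.sum()
    if norm <= 0 or not len(fracs):
        return _ball_only(att, table, S0)
    ball, fracs = ball / norm, fracs / norm
    order = np.argsort(fracs)[::-1]
    orients = np.array([canonical(cand[i]) for i in order])
    return StickVoxel(orients, fracs[order], float(ball),
                      float(d_hat), S0)


# ---------------------------------------------------------------------------
# whole-field fit, statsmodels-style surface
# ---------------------------------------------------------------------------

class BallStickModel:
    """Whole-volume multi-fiber ball-and-stick model over an analysis mask."""

    def __init__(self, volume: DWIVolume, table: GradientTable, mask,
                 config: RunConfig | None = None):
        if np.asarray(mask).shape != volume.shape3:
            raise ValueError("mask shape does not match volume")
        if volume.n_frames != len(table):
            raise ValueError("frame count does not match gradient table")
        self.volume = volume
        self.table = table
        self.mask = np.asarray(mask, dtype=bool)
        self.config = config or RunConfig()

    def fit(self) -> "StickFieldResults":
        shape = self.volume.shape3
        orients = np.zeros(shape + (3, 3))
        fracs = np.zeros(shape + (3,))
        d_map = np.zeros(shape)
        S0_map = np.zeros(shape)
        fallback = np.zeros(shape, dtype=bool)
        n_fallback = 0
        pre = precompute_attenuations(self.volume, self.table)
        for vox in zip(*np.nonzero(self.mask)):
            sv = fit_voxel_icabsm(self.volume, self.mask, self.table, vox,
                                  self.config, precomputed=pre)
            k = len(sv.fractions)
            if k:
                orients[vox][:k] = sv.orientations
                fracs[vox][:k] = sv.fractions
            d_map[vox] = sv.d
            S0_map[vox] = sv.S0
            fallback[vox] = sv.fallback
            n_fallback += int(sv.fallback)
        if n_fallback:
            log(f"ball-stick fit: {n_fallback} voxels used the tensor fallback")
        field_ = StickField(orients, fracs, d_map, S0_map, self.mask.copy(),
                            fallback)
        return StickFieldResults(self, field_)


@dataclass
class StickFieldResults:
    model: BallStickModel
    field: StickField

    @property
    def no_stick_density(self) -> float:
        return self.field.no_stick_density()

    def track(self, seed_mask, config: RunConfig | None = None):
        from .tracking import seed_and_track

        return seed_and_track(seed_mask, self.field, self.model.mask,
                              config or self.model.config)

    def summary(self) -> str:
        m = self.model.mask
        ns = self.field.n_sticks[m]
        lines = [
            "ICA ball-and-stick multi-fiber fit",
            f"  mask voxels        : {int(m.sum())}",
            f"  window layout      : {self.model.config.window_layout}",
            f"  sticks/voxel (mean): {ns.mean():.2f}",
            f"  voxels with 0/1/2/3 sticks: "
            + "/".join(str(int((ns == k).sum())) for k in range(4)),
            f"  no-stick density   : {self.no_stick_density:.3f}",
            f"  mean ball fraction : {self.field.ball_fraction[m].mean():.3f}",
        ]
        return "\n".join(lines)


def fit_stick_field(volume: DWIVolume, mask, table: GradientTable,
                    config: RunConfig | None = None):
    """Functional facade: fit every mask voxel; returns (StickField, density)."""
    res = BallStickModel(volume, table, mask, config).fit()
    return res.field, res.no_stick_density
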