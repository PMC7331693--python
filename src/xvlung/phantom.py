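"""Synthetic breathing-lung phantom with known ground truth.

The phantom emulates the features of a time-resolved small-animal lung CT
series that the analysis chain consumes, at desk scale: a two-lobed
lung-shaped mask filled with fine speckle texture, per-voxel fractional
expansion drawn from one of three archetype distributions (``healthy``:
narrow unimodal; ``heterogeneous``: wide unimodal; ``clustered``: bimodal
with spatially contiguous low-expansion blobs), a ~0.5 s breath (0.15 s
inspiration, 0.35 s expiration) sampled at 15 phases, a bilaterally
symmetric rib/spine/sternum bone structure for orientation work, and an
optional zero-displacement "heart blur" region in the lower-left lung.

Displacement fields are synthesised as gradients of a smooth potential whose
(central-difference) divergence matches the target local volume change, so
the warps are curl-free and integrable, and the true per-phase fields are
exactly consistent with the stored expansion map. All randomness flows from
``PhantomConfig.seed`` through named child streams (mask jitter, expansion
noise, blob seeds, low-mode noise, texture, per-phase noise), so identical
configurations reproduce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import BoundaryError, ConfigurationError, SizingError, VoxelGrid3D
from .expansion import ExpansionMap, jacobian_expansion
from .global_function import VolumeTimeCurve
from .velocimetry import DisplacementField, _grid_positions

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "make_lung_mask",
    "make_expansion_scene",
    "make_breath_curve",
    "make_speckle_sequence",
    "make_bone_phantom",
    "ground_truth_fields",
    "xv_mask",
]

_PROFILES = ("healthy", "heterogeneous", "clustered")

#: default spread of the principal expansion mode per profile (unitless)
_DEFAULT_SIGMA = {"healthy": 0.010, "heterogeneous": 0.022, "clustered": 0.010}

# named child streams of the master seed, in fixed order
_STREAMS = ("mask", "noise_main", "blobs", "noise_low", "texture", "phase_noise")


@dataclass
class PhantomConfig:
    """Parameters of one synthetic animal.

    Expansion magnitudes are unitless fractional volume changes; the default
    principal mode (``mu_main = 0.10``) is a plausible regional tidal
    expansion for a ventilated mouse, with the narrow/wide/low-mode spreads
    chosen so the three profiles mimic the tall-narrow, low-wide and
    split-peak histogram archetypes.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 0.05  # mm per fine voxel
    profile: str = "healthy"
    mu_main: float = 0.10
    sigma_main: float | None = None  # profile default when None
    mu_low: float = 0.04
    sigma_low: float = 0.008
    weight_low: float = 0.30
    n_blobs: int = 3
    heart_blur: float | None = None  # fraction of the mask forced to zero
    smooth_vox: float = 6.0  # expansion-noise correlation kernel, fine voxels
    speckle_grain: float = 4.0  # band-pass speckle grain, fine voxels
    insp_time: float = 0.15  # s
    exp_time: float = 0.35  # s
    n_phases: int = 15
    tidal_fraction: float = 0.10
    exp_shape: str = "exponential"  # or "linear"
    exp_rate: float | None = None  # 1/s; default expires 95% over exp_time
    noise_std: float = 0.0  # additive image noise per phase
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in _PROFILES:
            raise ConfigurationError(f"profile must be one of {_PROFILES}")
        if self.sigma_main is None:
            self.sigma_main = _DEFAULT_SIGMA[self.profile]
        if self.sigma_main < 0:
            raise ConfigurationError("sigma_main must be >= 0")
        if not (0 <= self.weight_low < 1):
            raise ConfigurationError("weight_low must be in [0, 1)")
        if self.profile == "clustered" and self.mu_low >= self.mu_main:
            raise ConfigurationError("clustered profile requires mu_low < mu_main")
        if self.profile == "clustered" and self.weight_low == 0:
            raise ConfigurationError("clustered profile requires weight_low > 0")
        if self.n_phases < 3:
            raise ConfigurationError("n_phases must be >= 3")
        if self.insp_time <= 0 or self.exp_time <= 0:
            raise ConfigurationError("insp_time and exp_time must be positive")
        if self.exp_shape not in ("exponential", "linear"):
            raise ConfigurationError("exp_shape must be 'exponential' or 'linear'")
        if self.heart_blur is not None and not (0 < self.heart_blur < 1):
            raise ConfigurationError("heart_blur must be a mask fraction in (0, 1)")

    @property
    def period(self) -> float:
        """Breath period (s): inspiration plus expiration."""
        return self.insp_time + self.exp_time

    def rng(self, stream: str) -> np.random.Generator:
        """Named child generator of the master seed (splittable, documented)."""
        idx = _STREAMS.index(stream)
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[idx])


@dataclass
class GroundTruth:
    """Known truth for one phantom animal.

    ``peak_displacement`` is the fine-grid displacement (voxels) from breath
    start to peak inspiration; per-frame fields are ``(s[p+1] - s[p]) *
    peak_displacement`` with ``s`` the per-phase breath scales, so the series
    integrates exactly back to the peak field.
    """

    expansion_map: np.ndarray
    lung_mask: np.ndarray
    blur_region: np.ndarray
    params: dict = field(default_factory=dict)
    peak_displacement: np.ndarray | None = None
    phase_scales: np.ndarray | None = None

    def frame_displacement(self, p: int) -> np.ndarray:
        """True displacement (fine grid, voxels/frame) from phase p to p+1."""
        if self.peak_displacement is None or self.phase_scales is None:
            raise ConfigurationError("ground truth carries no displacement series")
        ds = self.phase_scales[p + 1] - self.phase_scales[p]
        return ds * self.peak_displacement

    @property
    def displacement_series(self) -> list[np.ndarray]:
        if self.phase_scales is None:
            return []
        return [self.frame_displacement(p) for p in range(len(self.phase_scales) - 1)]


def _ellipsoid(shape, center, semi) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    return (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0


def make_lung_mask(config: PhantomConfig) -> VoxelGrid3D:
    """Two ellipsoidal lung-like lobes separated by a midline.

    The lobes are mildly jittered per seed (a few percent in semi-axis) but
    always remain two separate connected components.
    """
    shape = tuple(config.grid_shape)
    if min(shape) < 32:
        raise SizingError(
            f"grid {shape} too small to contain two lung lobes (need >= 32 per axis)"
        )
    Z, Y, X = shape
    cz, cy, cx = (Z - 1) / 2.0, (Y - 1) / 2.0, (X - 1) / 2.0
    rng = config.rng("mask")
    jit = 1.0 + 0.03 * rng.uniform(-1, 1, size=(2, 3))
    mask = np.zeros(shape, dtype=bool)
    for side, sgn in enumerate((-1.0, +1.0)):
        center = (cz, cy, cx + sgn * 0.22 * X)
        semi = (0.38 * Z * jit[side, 0], 0.30 * Y * jit[side, 1], 0.16 * X * jit[side, 2])
        mask |= _ellipsoid(shape, center, semi)
    # enforce a clear midline separation between the lobes
    gap = max(1, int(round(0.02 * X)))
    mask[:, :, int(np.floor(cx)) - gap + 1 : int(np.ceil(cx)) + gap] = False
    n_comp = ndimage.label(mask)[1]
    if n_comp != 2 or mask.sum() == 0:
        raise SizingError("could not fit two separated lung lobes in this grid")
    return VoxelGrid3D(mask, config.voxel_size, meta={"kind": "lung_mask"})


def _smooth_unit_noise(
    rng: np.random.Generator, shape, sigma: float, region: np.ndarray
) -> np.ndarray:
    """Spatially correlated noise, exactly zero-mean and unit-std over region."""
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    vals = noise[region]
    sd = vals.std()
    if sd == 0:
        return np.zeros(shape)
    return (noise - vals.mean()) / sd


def _grow_blobs(
    mask: np.ndarray, n_blobs: int, target_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Grow contiguous blobs from random in-mask seeds by dilation until the
    target volume fraction is reached; the final shell is trimmed at random
    so the achieved fraction matches the target to within rounding."""
    target = int(round(target_frac * mask.sum()))
    interior = ndimage.binary_erosion(mask, iterations=3)
    cand = np.argwhere(interior if interior.any() else mask)
    seeds_idx = cand[rng.choice(len(cand), size=min(n_blobs, len(cand)), replace=False)]
    blobs = np.zeros_like(mask)
    blobs[tuple(seeds_idx.T)] = True
    struct = ndimage.generate_binary_structure(3, 1)
    while blobs.sum() < target:
        grown = ndimage.binary_dilation(blobs, struct) & mask
        if grown.sum() == blobs.sum():
            break  # blobs filled the whole mask region available
        shell = grown & ~blobs
        excess = int(grown.sum()) - target
        if excess > 0:
            shell_idx = np.argwhere(shell)
            drop = shell_idx[rng.choice(len(shell_idx), size=excess, replace=False)]
            grown[tuple(drop.T)] = False
        blobs = grown
    return blobs


def _blur_region(mask: np.ndarray, frac: float) -> np.ndarray:
    """Contiguous near-spherical region of ``frac`` of the mask, placed in the
    lower-left lung (caudal z, left x) where cardiac blur is expected."""
    Z, Y, X = mask.shape
    center = np.array([0.70 * (Z - 1), 0.60 * (Y - 1), 0.28 * (X - 1)])
    idx = np.argwhere(mask)
    d2 = ((idx - center) ** 2).sum(axis=1)
    n_target = max(1, int(round(frac * len(idx))))
    chosen = idx[np.argsort(d2, kind="stable")[:n_target]]
    region = np.zeros_like(mask)
    region[tuple(chosen.T)] = True
    return region


def make_expansion_scene(
    config: PhantomConfig, mask: VoxelGrid3D | np.ndarray
) -> tuple[ExpansionMap, GroundTruth]:
    """Draw the per-voxel fractional-expansion scene for one animal.

    Healthy and heterogeneous profiles are single spatially smoothed unimodal
    distributions (narrow vs wide); the clustered profile additionally paints
    ``n_blobs`` contiguous regions with values from the low mode. A heart-blur
    region, if configured, is forced to exactly zero expansion. The noise is
    re-centred so the achieved sub-population means equal the configured
    ``mu`` values exactly.
    """
    marr = mask.data if isinstance(mask, VoxelGrid3D) else np.asarray(mask)
    marr = marr.astype(bool)
    if not marr.any():
        raise ConfigurationError("mask is empty")
    shape = marr.shape

    blobs = np.zeros(shape, dtype=bool)
    if config.profile == "clustered":
        if config.weight_low == 0:
            raise ConfigurationError("clustered profile requires weight_low > 0")
        blobs = _grow_blobs(marr, config.n_blobs, config.weight_low, config.rng("blobs"))

    # centre each sub-population's noise over its own region, so the
    # achieved means equal the configured mu values exactly
    values = np.zeros(shape)
    main = marr & ~blobs
    noise = _smooth_unit_noise(config.rng("noise_main"), shape, config.smooth_vox, main)
    values[main] = config.mu_main + config.sigma_main * noise[main]
    if blobs.any():
        low_noise = _smooth_unit_noise(config.rng("noise_low"), shape, config.smooth_vox, blobs)
        values[blobs] = config.mu_low + config.sigma_low * low_noise[blobs]

    blur = np.zeros(shape, dtype=bool)
    if config.heart_blur is not None:
        blur = _blur_region(marr, config.heart_blur)
        values[blur] = 0.0

    weight_achieved = blobs.sum() / marr.sum() if config.profile == "clustered" else 0.0
    params = {
        "profile": config.profile,
        "mu_main": config.mu_main,
        "sigma_main": config.sigma_main,
        "mu_low": config.mu_low if config.profile == "clustered" else None,
        "sigma_low": config.sigma_low if config.profile == "clustered" else None,
        "weight_low": weight_achieved,
        "heart_blur": config.heart_blur,
    }
    emap = ExpansionMap(
        values=np.where(marr, values, np.nan),
        mask=marr,
        voxel_volume=config.voxel_size**3,
        meta=dict(params),
    )
    truth = GroundTruth(
        expansion_map=np.where(marr, values, 0.0),
        lung_mask=marr,
        blur_region=blur,
        params=params,
    )
    return emap, truth


def make_breath_curve(config: PhantomConfig) -> VolumeTimeCurve:
    """Fractional inspired volume over one breath, sampled at ``n_phases``.

    Rises linearly from 0 to ``tidal_fraction`` over the inspiration, with
    the peak snapped to the sampled phase nearest ``insp_time``, then decays
    (linearly or exponentially at ``exp_rate``) back toward zero.
    """
    if config.tidal_fraction < 0:
        raise ConfigurationError("tidal_fraction must be >= 0")
    times = np.linspace(0.0, config.period, config.n_phases)
    peak_idx = int(np.argmin(np.abs(times - config.insp_time)))
    peak_idx = max(peak_idx, 1)
    t_peak = times[peak_idx]
    tidal = config.tidal_fraction

    v = np.zeros_like(times)
    v[: peak_idx + 1] = tidal * times[: peak_idx + 1] / t_peak
    te = times[peak_idx + 1 :] - t_peak
    if config.exp_shape == "exponential":
        k = config.exp_rate if config.exp_rate is not None else np.log(20.0) / config.exp_time
        v[peak_idx + 1 :] = tidal * np.exp(-k * te)
    else:
        v[peak_idx + 1 :] = tidal * np.clip(1.0 - te / config.exp_time, 0.0, None)
    return VolumeTimeCurve(
        times=times,
        fractional_volume=v,
        meta={
            "insp_time": config.insp_time,
            "exp_time": config.exp_time,
            "exp_shape": config.exp_shape,
            "exp_rate": config.exp_rate
            if config.exp_rate is not None
            else float(np.log(20.0) / config.exp_time),
            "peak_phase": peak_idx,
        },
    )


def _poisson_gradient(c: np.ndarray) -> np.ndarray:
    """Displacement u = grad(phi) with the central-difference divergence of u
    equal to c minus its mean (periodic spectral inverse Laplacian)."""
    shape = c.shape
    freqs = [np.fft.fftfreq(n) for n in shape]
    sz = np.sin(2 * np.pi * freqs[0])[:, None, None]
    sy = np.sin(2 * np.pi * freqs[1])[None, :, None]
    sx = np.sin(2 * np.pi * freqs[2])[None, None, :]
    denom = -(sz**2 + sy**2 + sx**2)
    denom[0, 0, 0] = 1.0
    chat = np.fft.fftn(c)
    chat[0, 0, 0] = 0.0
    phihat = chat / denom
    u = np.empty(shape + (3,))
    for ax, s in enumerate((sz, sy, sx)):
        u[..., ax] = np.fft.ifftn(1j * s * phihat).real
    return u


def _solve_peak_displacement(
    target: np.ndarray, mask: np.ndarray, n_iter: int = 4, far_margin: int = 8
) -> np.ndarray:
    """Curl-free displacement whose local volume change det(I+grad u)-1
    matches ``target`` inside the mask.

    The compensating contraction (the periodic domain must conserve volume;
    physically, the virtual chest wall) is spread uniformly over the
    exterior at least ``far_margin`` voxels away from the lung, so the
    displacement field in a shell just outside the lung is divergence-free —
    as for real tissue bordering the lung — and surface-flux volume
    estimators see no spurious sink there.
    """
    outside = ndimage.distance_transform_edt(~mask) > far_margin
    if outside.sum() < 0.05 * mask.size:
        outside = ~mask
    c_in = np.where(mask, target, 0.0)
    u = np.zeros(target.shape + (3,))
    for _ in range(n_iter):
        c = c_in.copy()
        if outside.any():
            c[outside] = -c_in[mask].sum() / outside.sum()
        u = _poisson_gradient(c)
        achieved = jacobian_expansion(u, spacing=1.0)
        c_in = np.where(mask, c_in + (target - achieved), 0.0)
    return u


def _speckle_texture(config: PhantomConfig, mask: np.ndarray) -> np.ndarray:
    """CT-like reference texture: dark exterior air, soft-tissue body
    ellipsoid, and band-passed speckle (~``speckle_grain`` voxel grain)
    inside the lung so interrogation windows see ample unique structure."""
    shape = mask.shape
    Z, Y, X = shape
    rng = config.rng("texture")
    body = _ellipsoid(shape, ((Z - 1) / 2, (Y - 1) / 2, (X - 1) / 2), (0.46 * Z, 0.42 * Y, 0.46 * X))
    # guarantee a closed soft-tissue shell around the lungs even where a
    # lobe approaches the body surface
    body |= ndimage.binary_dilation(mask, iterations=3)
    tex = np.full(shape, 0.02)
    tex[body] = 0.55
    white = rng.standard_normal(shape)
    g = config.speckle_grain / 4.0
    band = ndimage.gaussian_filter(white, g) - ndimage.gaussian_filter(white, 2.5 * g)
    band = band / band.std()
    tex[mask] = 0.22 + 0.06 * band[mask]
    tex += 0.01 * ndimage.gaussian_filter(rng.standard_normal(shape), 1.0)
    return tex


def make_speckle_sequence(
    scene: GroundTruth, curve: VolumeTimeCurve, config: PhantomConfig
) -> tuple[list[VoxelGrid3D], GroundTruth]:
    """Warp a reference speckle texture through one breath.

    The scene's expansion map is rescaled so its in-mask mean equals the
    curve's tidal fraction (the global fractional volume *is* the mask
    average of regional expansion, so the two must agree), and the returned
    ground truth carries the rescaled map together with the exact per-frame
    displacement series in voxels/frame.
    """
    if curve.n_phases != config.n_phases:
        raise ConfigurationError("curve and config disagree on the phase count")
    mask = scene.lung_mask
    e = scene.expansion_map
    mean_e = e[mask].mean() if mask.any() else 0.0
    tidal = curve.tidal_fraction
    if mean_e > 0 and tidal > 0:
        scale = tidal / mean_e
    else:
        scale = 0.0
    e_peak = scale * e

    if scale == 0.0 or not np.any(e_peak):
        u_peak = np.zeros(e.shape + (3,), dtype=np.float32)
    else:
        u_peak = _solve_peak_displacement(e_peak, mask)
        if scene.blur_region.any():
            u_peak[scene.blur_region] = 0.0
        u_peak = u_peak.astype(np.float32)

    s = np.zeros(curve.n_phases) if tidal <= 0 else curve.fractional_volume / tidal

    tex = _speckle_texture(config, mask)
    shape = np.array(e.shape)
    base_coords = np.meshgrid(*(np.arange(n, dtype=float) for n in e.shape), indexing="ij")
    noise_rng = config.rng("phase_noise")

    # Render frames by a backward-warp recursion: with per-frame (Eulerian)
    # displacement d_p, frame p+1 satisfies I_{p+1}(x) = I_p(x - d_p(x))
    # exactly, so the apparent inter-frame motion a correlator should report
    # equals the stored truth, and the truth series sums to the peak field.
    # The backward map is tracked as G_p with I_p(x) = T(x + G_p(x)),
    # G_{p+1}(x) = G_p(x - d_p(x)) - d_p(x); the texture is interpolated once
    # per frame (no compounding blur).
    volumes: list[VoxelGrid3D] = []
    G = np.zeros(e.shape + (3,))
    for p in range(curve.n_phases):
        if p > 0:
            ds = s[p] - s[p - 1]
            if ds != 0.0 and np.any(u_peak):
                d = ds * u_peak.astype(float)
                coords = [base_coords[ax] - d[..., ax] for ax in range(3)]
                G = np.stack(
                    [
                        ndimage.map_coordinates(G[..., ax], coords, order=1, mode="nearest")
                        - d[..., ax]
                        for ax in range(3)
                    ],
                    axis=-1,
                )
        if not np.any(G):
            vol = tex.copy()
        else:
            sample = [base_coords[ax] + G[..., ax] for ax in range(3)]
            for ax in range(3):
                if sample[ax].min() < -0.5 or sample[ax].max() > shape[ax] - 0.5:
                    raise BoundaryError(
                        f"phase {p}: warp samples outside the grid along axis {ax}"
                    )
            vol = ndimage.map_coordinates(tex, sample, order=3, mode="nearest")
        if config.noise_std > 0:
            vol = vol + config.noise_std * noise_rng.standard_normal(vol.shape)
        volumes.append(VoxelGrid3D(vol, config.voxel_size, meta={"phase": p}))

    truth = GroundTruth(
        expansion_map=e_peak,
        lung_mask=mask,
        blur_region=scene.blur_region,
        params={**scene.params, "expansion_scale": scale, "tidal_fraction": tidal},
        peak_displacement=u_peak,
        phase_scales=s,
    )
    return volumes, truth


def xv_mask(
    mask: np.ndarray, window_size: int, overlap_fraction: float, min_coverage: float = 0.5
) -> np.ndarray:
    """Binary lung mask on the XV vector grid (window coverage >= threshold)."""
    mask = np.asarray(mask, dtype=bool)
    stride = max(int(round(window_size * (1.0 - overlap_fraction))), 1)
    starts = [_grid_positions(n, window_size, stride) for n in mask.shape]
    out = np.zeros(tuple(len(sv) for sv in starts), dtype=bool)
    for i, z0 in enumerate(starts[0]):
        for j, y0 in enumerate(starts[1]):
            for k, x0 in enumerate(starts[2]):
                win = mask[z0 : z0 + window_size, y0 : y0 + window_size, x0 : x0 + window_size]
                out[i, j, k] = win.mean() >= min_coverage
    return out


def ground_truth_fields(
    truth: GroundTruth, window_size: int, overlap_fraction: float = 0.5
) -> list[DisplacementField]:
    """Sample the true fine-grid displacement series onto the XV vector grid.

    Returns one DisplacementField per consecutive phase pair, in voxels/frame,
    with the same grid geometry the velocimetry estimator would produce.
    """
    if truth.peak_displacement is None or truth.phase_scales is None:
        raise ConfigurationError("ground truth carries no displacement series")
    mask = truth.lung_mask
    stride = max(int(round(window_size * (1.0 - overlap_fraction))), 1)
    starts = [_grid_positions(n, window_size, stride) for n in mask.shape]
    origin = (window_size - 1) / 2.0
    centers = np.meshgrid(*(sv + origin for sv in starts), indexing="ij")
    coords = np.stack([c.ravel() for c in centers])
    grid_shape = tuple(len(sv) for sv in starts)

    u_samp = np.stack(
        [
            ndimage.map_coordinates(
                truth.peak_displacement[..., ax].astype(float), coords, order=3
            ).reshape(grid_shape)
            for ax in range(3)
        ],
        axis=-1,
    )
    valid = xv_mask(mask, window_size, overlap_fraction)
    fields = []
    for p in range(len(truth.phase_scales) - 1):
        ds = truth.phase_scales[p + 1] - truth.phase_scales[p]
        fields.append(
            DisplacementField(
                vectors=ds * u_samp,
                valid=valid.copy(),
                peak_quality=np.full(grid_shape, np.inf),
                grid_origin=(origin, origin, origin),
                grid_stride=stride,
                phase_index=p,
                window_size=window_size,
                filled=np.zeros(grid_shape, dtype=bool),
                meta={"source": "ground_truth"},
            )
        )
    return fields


def make_bone_phantom(
    angle: float,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (48, 160, 160),
    voxel_size: float = 0.05,
) -> VoxelGrid3D:
    """Bilaterally symmetric rib/spine/sternum phantom rotated in the axial plane.

    The spine (at large ``y``, i.e. the bottom of the axial image) is
    distinctly larger than the sternum; rib pairs mirror about the vertical
    midline. ``angle`` (degrees, |angle| <= 90) rotates the sample in the
    (y, x) plane; the true angle is recorded in ``meta['true_angle']``.
    """
    if abs(angle) > 90:
        raise ConfigurationError("|angle| must be <= 90 degrees")
    Z, Y, X = grid_shape
    cy, cx = (Y - 1) / 2.0, (X - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(Y, dtype=float), np.arange(X, dtype=float), indexing="ij")

    def disc(y0, x0, r):
        return (yy - y0) ** 2 + (xx - x0) ** 2 <= r**2

    plane = np.zeros((Y, X))
    body = ((yy - cy) / (0.42 * Y)) ** 2 + ((xx - cx) / (0.45 * X)) ** 2 <= 1.0
    plane[body] = 0.30
    bones = disc(cy + 0.30 * Y, cx, 0.050 * X)  # spine, bottom of image
    bones |= disc(cy - 0.33 * Y, cx, 0.020 * X)  # sternum, smaller
    for fy in (-0.26, -0.14, -0.02, 0.10, 0.22):
        dx = 0.36 * X * np.sqrt(max(0.0, 1.0 - (fy / 0.45) ** 2))
        bones |= disc(cy + fy * Y, cx - dx, 0.016 * X)
        bones |= disc(cy + fy * Y, cx + dx, 0.016 * X)
    plane[bones] = 1.0

    vol = np.repeat(plane[None, :, :], Z, axis=0)
    if angle != 0:
        vol = ndimage.rotate(vol, angle, axes=(1, 2), reshape=False, order=1)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB0]).generate_state(1)[0])
    vol = vol + 0.01 * rng.standard_normal(vol.shape)
    return VoxelGrid3D(vol, voxel_size, meta={"kind": "bone_phantom", "true_angle": float(angle)})


def simulate_animal(config: PhantomConfig, with_images: bool = False):
    """Convenience: mask -> scene -> curve (-> speckle volumes).

    Returns a dict with keys ``mask``, ``scene_map``, ``truth``, ``curve``
    and, when ``with_images``, ``volumes`` (the truth then also carries the
    displacement series).
    """
    mask = make_lung_mask(config)
    emap, truth = make_expansion_scene(config, mask)
    curve = make_breath_curve(config)
    out = {"mask": mask, "scene_map": emap, "truth": truth, "curve": curve}
    if with_images:
        volumes, truth = make_speckle_sequence(truth, curve, config)
        out["volumes"] = volumes
        out["truth"] = truth
    return out
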