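"""Synthetic 3D phantoms with a textured ellipsoidal foreground.

Real studies of this kind work on parahippocampal regions of interest cut out
of T1-weighted MRI scans.  The phantoms generated here stand in for such ROIs
during development and testing: a box-shaped volume containing an ellipsoidal
foreground structure whose local statistics (mean intensity, noise amplitude,
spatial autocorrelation) differ from the background, together with the exact
ground-truth mask.  Nothing about MRI physics (bias fields, Rician noise,
partial-volume effects) is simulated.

Texture is produced as Gaussian white noise convolved with a Gaussian kernel
of the requested smoothing length and rescaled to the requested standard
deviation, which gives directly controllable grey-level cooccurrence contrast
and correlation inside versus outside the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "TextureSpec",
    "PhantomConfig",
    "PhantomJitter",
    "PhantomDataset",
    "generate_phantom",
    "generate_dataset",
    "make_planted_matrix",
]

# Stretch factor applied to the smoothing length along an anisotropy axis.
_ANISO_FACTOR = 2.0


@dataclass(frozen=True)
class TextureSpec:
    """Local texture of one region: mean level, noise sd, correlation length.

    ``smoothing`` is the Gaussian kernel sigma (voxels) applied to the white
    noise before rescaling; 0 means uncorrelated noise.  ``anisotropy``, if
    given, is a unit 3-vector; the smoothing length is stretched along it.
    """

    mean: float
    noise_sd: float = 0.0
    smoothing: float = 0.0
    anisotropy: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.smoothing < 0:
            raise ValueError(f"smoothing must be >= 0, got {self.smoothing}")
        if self.anisotropy is not None:
            v = np.asarray(self.anisotropy, dtype=float)
            if v.shape != (3,) or not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
                raise ValueError("anisotropy must be a unit 3-vector")

    def sigmas(self) -> np.ndarray:
        """Per-axis smoothing sigmas, stretched along the anisotropy axis."""
        s = np.full(3, float(self.smoothing))
        if self.anisotropy is not None:
            s *= 1.0 + (_ANISO_FACTOR - 1.0) * np.abs(np.asarray(self.anisotropy))
        return s


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of one phantom volume.

    The defaults define the study conditions used throughout the test-suite
    and the acceptance experiments: foreground and background overlap in
    intensity (20-unit mean difference against 12 units of noise) and differ
    in spatial autocorrelation, so that neither a grey-level threshold nor any
    single feature separates the classes cleanly.
    """

    seed: int = 0
    shape: tuple[int, int, int] = (28, 26, 24)
    center: tuple[float, float, float] | None = None  # None -> volume center
    semiaxes: tuple[float, float, float] = (7.0, 6.0, 5.0)
    fg_texture: TextureSpec = field(
        default_factory=lambda: TextureSpec(mean=130.0, noise_sd=12.0, smoothing=1.5)
    )
    bg_texture: TextureSpec = field(
        default_factory=lambda: TextureSpec(mean=110.0, noise_sd=12.0, smoothing=0.5)
    )
    intensity_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) != s or s < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if any(a <= 0 for a in self.semiaxes):
            raise ValueError(f"semi-axes must be positive, got {self.semiaxes}")
        lo, hi = self.intensity_range
        if not lo < hi:
            raise ValueError(f"intensity_range must satisfy low < high, got {self.intensity_range}")
        c = self.resolved_center()
        for ci, ai, ni in zip(c, self.semiaxes, self.shape):
            if ci - ai < -0.5 or ci + ai > ni - 0.5:
                raise ValueError(
                    f"ellipsoid (center {tuple(c)}, semi-axes {self.semiaxes}) does not "
                    f"fit inside the volume of shape {self.shape}"
                )

    def resolved_center(self) -> tuple[float, float, float]:
        if self.center is not None:
            return tuple(float(c) for c in self.center)
        return tuple((n - 1) / 2.0 for n in self.shape)


@dataclass(frozen=True)
class PhantomJitter:
    """Per-subject perturbations applied on top of a base configuration.

    Each field is the half-width of a uniform jitter: centers move by up to
    ``center`` voxels per axis, semi-axes are scaled by 1 ± ``semiaxes_frac``,
    region means shift by up to ``mean`` intensity units, and noise sds are
    scaled by 1 ± ``noise_frac``.
    """

    center: float = 1.0
    semiaxes_frac: float = 0.1
    mean: float = 3.0
    noise_frac: float = 0.1

    @classmethod
    def none(cls) -> "PhantomJitter":
        return cls(center=0.0, semiaxes_frac=0.0, mean=0.0, noise_frac=0.0)


@dataclass
class PhantomDataset:
    """A cohort of phantom subjects: volumes, masks and the configs used."""

    volumes: list[np.ndarray]
    masks: list[np.ndarray]
    configs: list[PhantomConfig]

    @property
    def n_subjects(self) -> int:
        return len(self.volumes)

    @property
    def subject_ids(self) -> list[str]:
        return [f"sub-{i:03d}" for i in range(self.n_subjects)]


def ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    """Binary mask of voxels with sum(((v - c) / a)^2) <= 1."""
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return (q <= 1.0).astype(np.uint8)


def _textured_noise(shape, texture: TextureSpec, rng: np.random.Generator) -> np.ndarray:
    if texture.noise_sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    sig = texture.sigmas()
    if np.any(sig > 0):
        white = gaussian_filter(white, sigma=sig, mode="reflect")
        sd = white.std()
        if sd > 0:  # restore the requested marginal sd after smoothing
            white /= sd
    return texture.noise_sd * white


def generate_phantom(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (volume, mask) pair; bit-identical for identical configs.

    The volume is the per-region mean plus smoothed noise, clipped to the
    configured intensity range; the mask is exactly the ellipsoid indicator.
    """
    rng = np.random.default_rng(config.seed)
    mask = ellipsoid_mask(config.shape, config.resolved_center(), config.semiaxes)
    fg = config.fg_texture.mean + _textured_noise(config.shape, config.fg_texture, rng)
    bg = config.bg_texture.mean + _textured_noise(config.shape, config.bg_texture, rng)
    volume = np.where(mask.astype(bool), fg, bg)
    volume = np.clip(volume, *config.intensity_range)
    return volume.astype(np.float64), mask


def subject_seed(master_seed: int, index: int) -> int:
    """Collision-free per-subject seed derived from the master seed."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0] % (2**31))


def generate_dataset(
    n_subjects: int,
    base_config: PhantomConfig | None = None,
    jitter: PhantomJitter | None = None,
) -> PhantomDataset:
    """Generate a cohort of jittered phantom subjects.

    Per-subject seeds are derived from ``base_config.seed`` so the cohort is
    fully reproducible; geometry/texture jitter is drawn from a separate
    stream so that subject 0 with zero jitter equals the base phantom.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    base = base_config if base_config is not None else PhantomConfig()
    jit = jitter if jitter is not None else PhantomJitter()

    volumes, masks, configs = [], [], []
    for i in range(n_subjects):
        seed_i = subject_seed(base.seed, i)
        jrng = np.random.default_rng(subject_seed(base.seed, 10_000 + i))
        center = np.array(base.resolved_center())
        center = center + jrng.uniform(-jit.center, jit.center, size=3)
        axes = np.array(base.semiaxes) * (
            1.0 + jrng.uniform(-jit.semiaxes_frac, jit.semiaxes_frac, size=3)
        )
        fg = replace(
            base.fg_texture,
            mean=base.fg_texture.mean + jrng.uniform(-jit.mean, jit.mean),
            noise_sd=base.fg_texture.noise_sd
            * (1.0 + jrng.uniform(-jit.noise_frac, jit.noise_frac)),
        )
        bg = replace(
            base.bg_texture,
            mean=base.bg_texture.mean + jrng.uniform(-jit.mean, jit.mean),
            noise_sd=base.bg_texture.noise_sd
            * (1.0 + jrng.uniform(-jit.noise_frac, jit.noise_frac)),
        )
        cfg = replace(
            base,
            seed=seed_i,
            center=tuple(center),
            semiaxes=tuple(axes),
            fg_texture=fg,
            bg_texture=bg,
        )
        vol, mask = generate_phantom(cfg)
        volumes.append(vol)
        masks.append(mask)
        configs.append(cfg)
    return PhantomDataset(volumes=volumes, masks=masks, configs=configs)


def make_planted_matrix(
    n_subjects: int = 6,
    voxels_per_subject: int = 120,
    n_informative: int = 3,
    n_noise: int = 17,
    effect: float = 0.8,
    foreground_fraction: float = 0.4,
    seed: int = 0,
):
    """Toy feature matrix with a known informative subset.

    Informative columns carry a class-mean shift of ``effect`` standard
    deviations; noise columns are standard normal in both classes.  Used for
    feature-recovery studies where the ground truth must be known exactly.

    Returns ``(X, y, groups, informative_idx)`` with the informative columns
    placed at seeded random positions among the noise columns.
    """
    rng = np.random.default_rng(seed)
    p = n_informative + n_noise
    n = n_subjects * voxels_per_subject
    y = (rng.random(n) < foreground_fraction).astype(int)
    X = rng.standard_normal((n, p))
    informative_idx = np.sort(rng.choice(p, size=n_informative, replace=False))
    for j in informative_idx:
        X[:, j] += effect * y
    groups = np.repeat([f"sub-{i:03d}" for i in range(n_subjects)], voxels_per_subject)
    return X, y, groups, informative_idx
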