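"""The 315-value per-voxel texture descriptor for 3D volumes.

Layout of the descriptor (one slot per :class:`FeatureSpec`):

======  =====================================================================
count   group
======  =====================================================================
1       position (radial distance from the ROI center, normalized to [0, 1])
1       grey level (normalized intensity at the voxel)
66      Haralick group, cubic mask 3x3x3
66      Haralick group, cubic mask 5x5x5
66      Haralick group, cubic mask 7x7x7
66      Haralick group, cubic mask 9x9x9
49      Haar-like 3D block-difference features
======  =====================================================================

Each Haralick group of 66 contains 13 signed gradients along the 13 distinct
diagonal directions of the 26-neighbourhood (endpoints at distance
r = (m - 1) / 2 from the voxel), 5 principal statistical moments of the m^3
cube, and 3 x 16 grey-level cooccurrence statistics: for each of the three
m x m plane projections through the voxel (slice normal to x, y and z), the
energy, contrast, correlation and inverse difference moment of the normalized
symmetric GLCM at orientations 0, 45, 90 and 135 degrees (pair distance 1).

Diagonal naming.  Directions are labelled by canonical segment names on the
reference cube with vertices A(0,0,0) B(1,0,0) C(1,1,0) D(0,1,0) E(0,0,1)
F(1,0,1) G(1,1,1) H(0,1,1): the four body diagonals are AG, CE, DF, BH; the
three axes run between opposite face midpoints (MN, OP, QR for x, y, z); the
six face-diagonal directions run between opposite edge midpoints (IL, JK, ST,
UV, WX, YZ).  The assignment of midpoint letters to directions is a fixed
documented convention.

All windows are border-clamped (nearest-voxel replication), so every voxel of
an ROI is featurizable.  Grey levels are quantized once over the whole
normalized ROI so all windows share one level map; the number of levels G
defaults to 8.

Two extraction paths are provided: per-voxel reference functions
(:func:`extract_voxel_vector` and the operations it composes) written for
clarity, and a vectorized whole-ROI path (:func:`extract_roi_matrix`) based on
sliding-window cumulative sums and kernel correlation.  The two are verified
against each other in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate

__all__ = [
    "DEFAULT_LEVELS",
    "MASK_SIZES",
    "ORIENTATIONS",
    "PLANES",
    "STAT_NAMES",
    "MOMENT_NAMES",
    "DIRECTIONS",
    "FeatureSpec",
    "GLCMatrix",
    "feature_specs",
    "feature_names",
    "feature_groups",
    "quantize",
    "glcm",
    "haralick_stats",
    "diagonal_gradients",
    "principal_moments",
    "haar_features",
    "haar_feature_names",
    "position_feature",
    "extract_voxel_vector",
    "extract_roi_matrix",
]

DEFAULT_LEVELS = 8
MASK_SIZES = (3, 5, 7, 9)
ORIENTATIONS = (0, 45, 90, 135)
PLANES = ("X", "Y", "Z")
STAT_NAMES = ("energy", "contrast", "corr", "idm")
MOMENT_NAMES = ("mean", "var", "skew", "kurt", "m5")

# In-plane pair offset (row, col) per orientation, pair distance 1.
_ORIENT_OFFSET = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

# Slice normal axis per plane label; the in-plane (row, col) axes are the two
# remaining axes in increasing order: X -> (y, z), Y -> (x, z), Z -> (x, y).
_PLANE_AXIS = {"X": 0, "Y": 1, "Z": 2}

# The 13 distinct directions of the 26-neighbourhood: 3 axes, 6 face
# diagonals, 4 body diagonals, each with a canonical segment label (see
# module docstring).
DIRECTIONS: tuple[tuple[str, tuple[int, int, int]], ...] = (
    ("MN", (1, 0, 0)),
    ("OP", (0, 1, 0)),
    ("QR", (0, 0, 1)),
    ("IL", (1, 1, 0)),
    ("JK", (1, -1, 0)),
    ("ST", (1, 0, 1)),
    ("UV", (1, 0, -1)),
    ("WX", (0, 1, 1)),
    ("YZ", (0, 1, -1)),
    ("AG", (1, 1, 1)),
    ("CE", (1, 1, -1)),
    ("DF", (1, -1, 1)),
    ("BH", (1, -1, -1)),
)

_VAR_TINY = 1e-12  # below this a variance is treated as degenerate (-> 0 convention)


@dataclass(frozen=True)
class FeatureSpec:
    """One slot of the descriptor: its index, name, group and parameters."""

    index: int
    name: str
    group: str  # position | grey | haralick | haar
    subgroup: str | None = None  # gradient | moment | texstat | t1 | t1ax | t2
    params: dict = field(default_factory=dict)


@dataclass
class GLCMatrix:
    """Normalized symmetric grey-level cooccurrence matrix of one subimage."""

    levels: int
    matrix: np.ndarray
    plane: str | None = None
    orientation: int | None = None
    mask_size: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.levels, self.levels):
            raise ValueError("GLCM shape must be (levels, levels)")
        if abs(self.matrix.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM entries must sum to 1")


def _haar_bank() -> list[tuple[str, tuple]]:
    """The default bank of exactly 49 Haar-like templates.

    39 type-1 half-cube contrasts split by the plane normal to each of the 13
    diagonal directions at mask sizes 5, 7 and 9; 6 type-1 axis-aligned
    half-cube contrasts at mask sizes 3 and 5; 4 type-2 center-surround
    contrasts with center cube c in {1, 3, 5, 7} against its (c+2)-shell.
    """
    bank: list[tuple[str, tuple]] = []
    for m in (5, 7, 9):
        for label, d in DIRECTIONS:
            bank.append((f"haar_t1_{label}_m{m}", ("t1", d, m)))
    for m in (3, 5):
        for ax_label, d in (("x", (1, 0, 0)), ("y", (0, 1, 0)), ("z", (0, 0, 1))):
            bank.append((f"haar_t1ax_{ax_label}_m{m}", ("t1", d, m)))
    for c in (1, 3, 5, 7):
        bank.append((f"haar_t2_c{c}", ("t2", c)))
    assert len(bank) == 49
    return bank


_HAAR_BANK = _haar_bank()


def haar_feature_names() -> list[str]:
    return [name for name, _ in _HAAR_BANK]


def feature_specs() -> list[FeatureSpec]:
    """The full ordered list of 315 feature specifications."""
    specs: list[FeatureSpec] = []

    def add(name, group, subgroup=None, **params):
        specs.append(FeatureSpec(len(specs), name, group, subgroup, params))

    add("position", "position")
    add("grey_level", "grey")
    for m in MASK_SIZES:
        for label, d in DIRECTIONS:
            add(f"grad_m{m}_{label}", "haralick", "gradient", mask_size=m, direction=d, label=label)
        for mom in MOMENT_NAMES:
            add(f"moment_m{m}_{mom}", "haralick", "moment", mask_size=m, moment=mom)
        for plane in PLANES:
            for deg in ORIENTATIONS:
                for stat in STAT_NAMES:
                    add(
                        f"haralick_m{m}_{stat}_{plane}_{deg}",
                        "haralick",
                        "texstat",
                        mask_size=m,
                        plane=plane,
                        orientation=deg,
                        statistic=stat,
                    )
    for name, spec in _HAAR_BANK:
        kind = spec[0]
        if kind == "t1":
            add(name, "haar", "t1", direction=spec[1], mask_size=spec[2])
        else:
            add(name, "haar", "t2", center=spec[1])
    assert len(specs) == 315
    return specs


_SPECS = feature_specs()


def feature_names() -> list[str]:
    return [s.name for s in _SPECS]


def feature_groups() -> dict[str, np.ndarray]:
    """Column indices per group (position, grey, haralick, haar)."""
    out: dict[str, list[int]] = {}
    for s in _SPECS:
        out.setdefault(s.group, []).append(s.index)
    return {k: np.asarray(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# quantization and per-patch GLCM (reference path)
# ---------------------------------------------------------------------------


def quantize(values, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Map intensities in [0, 1] to integer grey levels in [0, levels).

    level = floor(intensity * levels), clamped to levels - 1 so that an
    intensity of exactly 1 falls in the top level; monotone in intensity.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    v = np.asarray(values, dtype=float)
    if v.size and (v.min() < 0 or v.max() > 1):
        raise ValueError(
            f"intensities must lie in [0, 1] (got range [{v.min():g}, {v.max():g}]); "
            "normalize the volume first"
        )
    return np.minimum((v * levels).astype(np.int64), levels - 1)


def glcm(patch, orientation: int, levels: int = DEFAULT_LEVELS) -> GLCMatrix:
    """Normalized symmetric cooccurrence matrix of a 2D integer-level patch.

    Ordered voxel pairs at the orientation's unit offset are counted in both
    directions (symmetrization) and normalized to sum to 1.
    """
    patch = np.asarray(patch)
    if patch.ndim != 2:
        raise ValueError("glcm expects a 2D patch")
    if orientation not in _ORIENT_OFFSET:
        raise ValueError(f"orientation must be one of {sorted(_ORIENT_OFFSET)}, got {orientation}")
    if patch.min() < 0 or patch.max() >= levels:
        raise ValueError("patch levels must lie in [0, levels)")
    dr, dc = _ORIENT_OFFSET[orientation]
    h, w = patch.shape
    if h - abs(dr) < 1 or w - abs(dc) < 1:
        raise ValueError(f"patch of shape {patch.shape} too small for offset ({dr}, {dc})")
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    start = patch[r0:r1, c0:c1]
    end = patch[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    counts = np.zeros((levels, levels), dtype=np.int64)
    np.add.at(counts, (start.ravel(), end.ravel()), 1)
    sym = counts + counts.T
    return GLCMatrix(levels=levels, matrix=sym / sym.sum(), orientation=orientation)


def haralick_stats(g) -> tuple[float, float, float, float]:
    """(energy, contrast, correlation, idm) of a normalized GLCM.

    correlation uses the marginal means/sds of the symmetric matrix and is
    defined as 0 when either marginal variance is degenerate.
    """
    p = g.matrix if isinstance(g, GLCMatrix) else np.asarray(g, dtype=float)
    n = p.shape[0]
    k = np.arange(n, dtype=float)
    kk, ll = np.meshgrid(k, k, indexing="ij")
    energy = float((p**2).sum())
    contrast = float(((kk - ll) ** 2 * p).sum())
    idm = float((p / (1.0 + (kk - ll) ** 2)).sum())
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    mu_r = float(k @ pr)
    mu_c = float(k @ pc)
    var_r = float((k**2) @ pr) - mu_r**2
    var_c = float((k**2) @ pc) - mu_c**2
    if var_r <= _VAR_TINY or var_c <= _VAR_TINY:
        corr = 0.0
    else:
        corr = (float((kk * ll * p).sum()) - mu_r * mu_c) / np.sqrt(var_r * var_c)
    return energy, contrast, corr, idm


# ---------------------------------------------------------------------------
# per-voxel reference operations
# ---------------------------------------------------------------------------


def _clamped(volume: np.ndarray, idx) -> float:
    return volume[tuple(np.clip(i, 0, n - 1) for i, n in zip(idx, volume.shape))]


def diagonal_gradients(volume, voxel, m: int) -> np.ndarray:
    """Signed intensity differences along the 13 diagonal directions.

    For direction d and radius r = (m - 1) / 2 the gradient is
    I(v + r d) - I(v - r d), with out-of-bounds endpoints clamped to the
    nearest voxel.  Output follows the canonical :data:`DIRECTIONS` order.
    """
    if m % 2 == 0 or m < 3:
        raise ValueError(f"mask size must be odd and >= 3, got {m}")
    volume = np.asarray(volume, dtype=float)
    v = np.asarray(voxel)
    r = (m - 1) // 2
    out = np.empty(13)
    for i, (_, d) in enumerate(DIRECTIONS):
        d = np.asarray(d)
        out[i] = _clamped(volume, v + r * d) - _clamped(volume, v - r * d)
    return out


def _clamped_cube(volume: np.ndarray, voxel, m: int) -> np.ndarray:
    r = m // 2
    idx = [np.clip(np.arange(c - r, c + r + 1), 0, n - 1) for c, n in zip(voxel, volume.shape)]
    return volume[np.ix_(*idx)]


def principal_moments(volume, voxel, m: int) -> np.ndarray:
    """Mean, variance, skewness, excess kurtosis and 5th standardized moment
    of the m^3 border-clamped cube around the voxel.

    Standardized moments are 0 by convention when the variance is degenerate.
    """
    if m % 2 == 0 or m < 3:
        raise ValueError(f"mask size must be odd and >= 3, got {m}")
    cube = _clamped_cube(np.asarray(volume, dtype=float), voxel, m).ravel()
    mu = cube.mean()
    c = cube - mu
    var = float((c**2).mean())
    if var <= _VAR_TINY:
        return np.array([mu, var, 0.0, 0.0, 0.0])
    sd = np.sqrt(var)
    skew = float((c**3).mean()) / sd**3
    kurt = float((c**4).mean()) / sd**4 - 3.0
    m5 = float((c**5).mean()) / sd**5
    return np.array([mu, var, skew, kurt, m5])


def _haar_kernel(spec: tuple) -> np.ndarray:
    if spec[0] == "t1":
        _, d, m = spec
        r = m // 2
        ax = np.arange(-r, r + 1)
        ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
        dot = ox * d[0] + oy * d[1] + oz * d[2]
        pos = dot > 0
        neg = dot < 0
        return pos / pos.sum() - neg / neg.sum()
    _, c = spec
    m = c + 2
    r = m // 2
    ax = np.arange(-r, r + 1)
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    half = (c - 1) // 2
    center = np.maximum(np.maximum(np.abs(ox), np.abs(oy)), np.abs(oz)) <= half
    shell = ~center
    return center / center.sum() - shell / shell.sum()


def haar_features(volume, voxel) -> np.ndarray:
    """The 49 Haar-like block differences at one voxel (border-clamped).

    Each feature is mean(positive block) - mean(negative block) of its
    template; see :func:`_haar_bank` for the template enumeration.
    """
    volume = np.asarray(volume, dtype=float)
    out = np.empty(49)
    for i, (_, spec) in enumerate(_HAAR_BANK):
        k = _haar_kernel(spec)
        m = k.shape[0]
        cube = _clamped_cube(volume, voxel, m)
        out[i] = float((cube * k).sum())
    return out


def position_feature(voxel, roi_shape, mode: str = "radial"):
    """Normalized position of a voxel within the ROI box.

    ``radial`` (default): Euclidean distance from the ROI center divided by
    the half-diagonal, in [0, 1].  ``coords``: the three coordinates divided
    by (axis length - 1), an optional non-default mode that inflates the
    descriptor to 317 values.
    """
    v = np.asarray(voxel, dtype=float)
    n = np.asarray(roi_shape, dtype=float)
    if mode == "coords":
        return v / np.maximum(n - 1, 1)
    if mode != "radial":
        raise ValueError(f"unknown position mode {mode!r}")
    center = (n - 1) / 2.0
    half_diag = np.linalg.norm(center)
    if half_diag == 0:
        return 0.0
    return float(np.linalg.norm(v - center) / half_diag)


def _plane_patch(levels: np.ndarray, voxel, plane: str, m: int) -> np.ndarray:
    """Border-clamped m x m subimage of the slice through `voxel` normal to `plane`."""
    nrm = _PLANE_AXIS[plane]
    in_plane = [a for a in range(3) if a != nrm]
    r = m // 2
    idx: list = [None, None, None]
    idx[nrm] = np.array([voxel[nrm]])
    for a in in_plane:
        idx[a] = np.clip(np.arange(voxel[a] - r, voxel[a] + r + 1), 0, levels.shape[a] - 1)
    patch = levels[np.ix_(*idx)]
    return patch.reshape(m, m)  # (row, col) = in-plane axes in increasing order


def _check_normalized(volume: np.ndarray) -> None:
    if volume.size and (volume.min() < -1e-9 or volume.max() > 1 + 1e-9):
        raise ValueError(
            "volume must be normalized to [0, 1] before feature extraction "
            "(see volume_io.normalize_intensity)"
        )


def extract_voxel_vector(
    volume, voxel, levels: int = DEFAULT_LEVELS, level_map: np.ndarray | None = None
) -> np.ndarray:
    """The full 315-value descriptor of one voxel (reference implementation).

    ``volume`` must be normalized to [0, 1].  ``level_map`` may carry a
    pre-quantized copy of the volume to avoid re-quantizing per call.
    """
    volume = np.asarray(volume, dtype=float)
    _check_normalized(volume)
    lv = level_map if level_map is not None else quantize(volume, levels)
    vec = np.empty(315)
    vec[0] = position_feature(voxel, volume.shape)
    vec[1] = volume[tuple(voxel)]
    pos = 2
    for m in MASK_SIZES:
        vec[pos : pos + 13] = diagonal_gradients(volume, voxel, m)
        pos += 13
        vec[pos : pos + 5] = principal_moments(volume, voxel, m)
        pos += 5
        for plane in PLANES:
            patch = _plane_patch(lv, voxel, plane, m)
            for deg in ORIENTATIONS:
                vec[pos : pos + 4] = haralick_stats(glcm(patch, deg, levels))
                pos += 4
    vec[pos : pos + 49] = haar_features(volume, voxel)
    return vec


# ---------------------------------------------------------------------------
# vectorized whole-ROI path
# ---------------------------------------------------------------------------


def _sliding_sum(arr: np.ndarray, size: int, axis: int) -> np.ndarray:
    """Sums over all length-`size` windows along `axis` (output shrinks by size-1)."""
    a = np.moveaxis(np.asarray(arr, dtype=np.float64), axis, 0)
    c = np.concatenate([np.zeros((1,) + a.shape[1:]), np.cumsum(a, axis=0)], axis=0)
    return np.moveaxis(c[size:] - c[:-size], 0, axis)


def _box_sum(arr: np.ndarray, sizes, axes) -> np.ndarray:
    out = arr
    for size, axis in zip(sizes, axes):
        out = _sliding_sum(out, size, axis)
    return out


def _shift_clamped(volume: np.ndarray, shift) -> np.ndarray:
    """volume evaluated at index + shift with border clamping."""
    out = volume
    for ax, s in enumerate(shift):
        if s:
            idx = np.clip(np.arange(volume.shape[ax]) + s, 0, volume.shape[ax] - 1)
            out = np.take(out, idx, axis=ax)
    return out


def _gradients_volume(volume: np.ndarray, m: int) -> np.ndarray:
    r = (m - 1) // 2
    out = np.empty((13,) + volume.shape)
    for i, (_, d) in enumerate(DIRECTIONS):
        fwd = _shift_clamped(volume, tuple(r * c for c in d))
        bwd = _shift_clamped(volume, tuple(-r * c for c in d))
        out[i] = fwd - bwd
    return out


def _moments_volume(volume: np.ndarray, m: int) -> np.ndarray:
    """Per-voxel (mean, var, skew, kurt, m5) over m^3 clamped cubes."""
    r = m // 2
    padded = np.pad(volume, r, mode="edge")
    n = float(m**3)
    raw = [
        _box_sum(padded**p, (m, m, m), (0, 1, 2)) / n for p in range(1, 6)
    ]
    mu, e2, e3, e4, e5 = raw
    mu2 = e2 - mu**2
    mu3 = e3 - 3 * mu * e2 + 2 * mu**3
    mu4 = e4 - 4 * mu * e3 + 6 * mu**2 * e2 - 3 * mu**4
    mu5 = e5 - 5 * mu * e4 + 10 * mu**2 * e3 - 10 * mu**3 * e2 + 4 * mu**5
    ok = mu2 > _VAR_TINY
    sd = np.sqrt(np.where(ok, mu2, 1.0))
    skew = np.where(ok, mu3 / sd**3, 0.0)
    kurt = np.where(ok, mu4 / sd**4 - 3.0, 0.0)
    m5s = np.where(ok, mu5 / sd**5, 0.0)
    return np.stack([mu, np.maximum(mu2, 0.0), skew, kurt, m5s])


def _texstats_volume(level_map: np.ndarray, plane: str, m: int, deg: int, levels: int):
    """Per-voxel (energy, contrast, corr, idm) for one plane/mask/orientation.

    Windows are the m x m in-plane neighbourhoods of every voxel with edge
    clamping; pair counting and symmetrization match :func:`glcm` exactly.
    """
    nrm = _PLANE_AXIS[plane]
    a1, a2 = (a for a in range(3) if a != nrm)
    dr, dc = _ORIENT_OFFSET[deg]
    r = m // 2
    pad = [(0, 0)] * 3
    pad[a1] = pad[a2] = (r, r)
    P = np.pad(level_map, pad, mode="edge").astype(np.float64)

    def ip_slice(lo_extra, hi_cut, axis):
        sl = [slice(None)] * 3
        sl[axis] = slice(lo_extra, P.shape[axis] - hi_cut)
        return sl

    p0, p1 = max(0, -dr), max(0, dr)
    q0, q1 = max(0, -dc), max(0, dc)
    s_start = [slice(None)] * 3
    s_end = [slice(None)] * 3
    s_start[a1] = slice(p0, P.shape[a1] - p1)
    s_end[a1] = slice(p0 + dr, P.shape[a1] - p1 + dr)
    s_start[a2] = slice(q0, P.shape[a2] - q1)
    s_end[a2] = slice(q0 + dc, P.shape[a2] - q1 + dc)
    A = P[tuple(s_start)]
    B = P[tuple(s_end)]

    sizes = (m - abs(dr), m - abs(dc))
    axes = (a1, a2)
    n_pairs = float(sizes[0] * sizes[1])

    def wsum(arr):
        return _box_sum(arr, sizes, axes)

    diff2 = (A - B) ** 2
    contrast = wsum(diff2) / n_pairs
    idm = wsum(1.0 / (1.0 + diff2)) / n_pairs
    mu = wsum(A + B) / (2 * n_pairs)
    e2 = wsum(A**2 + B**2) / (2 * n_pairs)
    var = e2 - mu**2
    cov = wsum(A * B) / n_pairs - mu**2
    ok = var > _VAR_TINY
    corr = np.where(ok, cov / np.where(ok, var, 1.0), 0.0)

    Ai = A.astype(np.int64)
    Bi = B.astype(np.int64)
    counts = np.empty((levels, levels) + contrast.shape)
    for k in range(levels):
        ak = Ai == k
        for l in range(levels):
            counts[k, l] = wsum((ak & (Bi == l)).astype(np.float64))
    psym = (counts + counts.transpose(1, 0, *range(2, counts.ndim))) / (2 * n_pairs)
    energy = (psym**2).sum(axis=(0, 1))
    return energy, contrast, corr, idm


def _haar_volume(volume: np.ndarray) -> np.ndarray:
    out = np.empty((49,) + volume.shape)
    for i, (_, spec) in enumerate(_HAAR_BANK):
        out[i] = correlate(volume, _haar_kernel(spec), mode="nearest")
    return out


def _position_volume(shape) -> np.ndarray:
    center = (np.asarray(shape, dtype=float) - 1) / 2.0
    half_diag = np.linalg.norm(center)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    if half_diag == 0:
        return np.zeros(shape)
    return np.sqrt(d2) / half_diag


def extract_roi_matrix(
    sv_or_volume,
    mask=None,
    levels: int = DEFAULT_LEVELS,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Feature matrix of every voxel of a normalized ROI volume.

    Accepts either a ``SubjectVolume`` or a bare (volume, mask) pair.  Returns
    ``(X, y)`` where X has one row per voxel in lexicographic voxel order and
    columns in :func:`feature_specs` order; y is the flattened binary mask
    (1 = foreground class A), or None when no mask is available.
    """
    if hasattr(sv_or_volume, "intensities"):
        volume = sv_or_volume.intensities
        mask = sv_or_volume.mask if mask is None else mask
    else:
        volume = sv_or_volume
    volume = np.asarray(volume, dtype=float)
    _check_normalized(volume)
    lv = quantize(volume, levels)

    n_vox = volume.size
    X = np.empty((n_vox, 315))
    X[:, 0] = _position_volume(volume.shape).ravel()
    X[:, 1] = volume.ravel()
    pos = 2
    for m in MASK_SIZES:
        g = _gradients_volume(volume, m)
        X[:, pos : pos + 13] = g.reshape(13, n_vox).T
        pos += 13
        mom = _moments_volume(volume, m)
        X[:, pos : pos + 5] = mom.reshape(5, n_vox).T
        pos += 5
        for plane in PLANES:
            for deg in ORIENTATIONS:
                stats = _texstats_volume(lv, plane, m, deg, levels)
                for s in stats:
                    X[:, pos] = s.ravel()
                    pos += 1
    h = _haar_volume(volume)
    X[:, pos : pos + 49] = h.reshape(49, n_vox).T

    y = None
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != volume.shape:
            raise ValueError(f"mask shape {mask.shape} does not match volume {volume.shape}")
        y = (mask.ravel() > 0).astype(int)
    return X, y
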