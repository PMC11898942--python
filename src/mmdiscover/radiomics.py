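"""IBSI-style 3D radiomic features from an image / lesion-mask pair.

The panel covers the feature families reported as discriminative for
aggressive prostate disease on bi-parametric MR: first-order intensity
statistics, grey-level co-occurrence (GLCM), size-zone (GLSZM) and
run-length (GLRLM) texture, Laws 3D texture energies, multilevel Haar
wavelet sub-band energies, and shape morphology (minimum-volume enclosing
ellipsoid density, intensity-weighted centre of mass).

Conventions (all configurable or documented):

* Texture features are computed after fixed-bin-number discretization
  (default 32 levels) of in-mask intensities, which makes them invariant
  to affine intensity rescaling.
* Everything except the weighted centre of mass is computed on the mask's
  bounding-box crop ("mask frame"), so features are exactly translation
  invariant; filter responses near the crop edge use edge replication.
* GLCM / GLRLM use the 13 unique 3D direction offsets at distance 1, with
  features averaged across directions (the ``avg`` prefix in the feature
  registry); GLSZM zones are 26-connected.
* Positions are 0-based voxel indices times spacing (mm).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable

import numpy as np
import pywt
from scipy import ndimage
from scipy.spatial import ConvexHull

from .containers import RoiMask, VolumetricImage

# ---------------------------------------------------------------------------
# configuration and registry

LAWS_KERNELS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}
LAWS_NAMES = ["L5", "E5", "S5", "W5", "R5"]

#: 13 unique direction offsets in 3D (half of the 26-neighbourhood; the
#: first non-zero component is positive).
DIRECTIONS_13 = [
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and (d > (0, 0, 0))
]

_OCTANTS_DETAIL = ["aad", "ada", "add", "daa", "dad", "dda", "ddd"]


@dataclasses.dataclass
class DiscretizationConfig:
    """Fixed-bin-number grey-level discretization for texture matrices."""

    n_levels: int = 32
    binning: str = "fixed-bin-number"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.binning != "fixed-bin-number":
            raise ValueError("only fixed-bin-number binning is implemented")


def wavelet_subband_names(levels: int = 2) -> list[str]:
    """Canonical wavelet sub-band names.

    Sub-bands are enumerated level-1 detail octants first (C1..C7), then the
    deepest level's approximation plus detail octants (C8..C15 for two
    levels).  The published feature spelling ``3D_Wavelet_P1_L{level}_C{k}``
    is adopted with ``P1`` a fixed prefix; the external naming scheme is not
    defined anywhere public, so this mapping is this package's convention.
    """
    names = []
    k = 1
    for lev in range(1, levels):
        for _ in _OCTANTS_DETAIL:
            names.append(f"3D_Wavelet_P1_L{lev}_C{k}")
            k += 1
    names.append(f"3D_Wavelet_P1_L{levels}_C{k}")  # deepest approximation
    k += 1
    for _ in _OCTANTS_DETAIL:
        names.append(f"3D_Wavelet_P1_L{levels}_C{k}")
        k += 1
    return names


def feature_registry(levels: int = 2) -> list[str]:
    """Stable ordered names of every feature extract_feature_vector emits."""
    names = [
        "Statistical_Coefficient_of_variance",
        "Maximum_histogram_gradient_grey_level",
        "Volume_at_intensity_fraction_10",
        "Weighted_CoM_x_(mm)",
        "Weighted_CoM_y_(mm)",
        "Weighted_CoM_z_(mm)",
        "Avg_Coocurrence_Joint_MAX",
        "Avg_Coocurrence_Autocorrelation",
        "avgCoocurrence_Difference_entropy",
        "GLSZM_Small_zone_high_grey_level_emphasis",
        "GLSZM_High_grey_level_zone_emphasis",
        "avg_3D_LGRE_(Low_grey_level_run_emphasis)",
        "Volume_density_minimum_volume_enclosing_ellipsoid",
    ]
    names += [
        f"3D_Laws_features_{a}_{b}_{c}"
        for a, b, c in itertools.product(LAWS_NAMES, repeat=3)
    ]
    names += wavelet_subband_names(levels)
    return names


# ---------------------------------------------------------------------------
# discretization

def discretize(
    image: VolumetricImage, mask: RoiMask, cfg: DiscretizationConfig
) -> np.ndarray:
    """Map in-mask intensities to integer levels 1..n_levels.

    Fixed bin number: the in-mask min maps to level 1 and the max to
    ``n_levels``.  A constant image maps to level 1 everywhere (documented
    convention).  Voxels outside the mask are 0.
    """
    m = mask.voxels
    vals = image.voxels[m]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros(image.voxels.shape, dtype=np.int32)
    if hi == lo:
        out[m] = 1
        return out
    n = cfg.n_levels
    lev = np.floor(n * (image.voxels[m] - lo) / (hi - lo)).astype(np.int32) + 1
    out[m] = np.minimum(lev, n)
    return out


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrices(
    disc: np.ndarray, mask: np.ndarray, n_levels: int
) -> list[np.ndarray]:
    """Symmetrized, normalized co-occurrence matrix per direction (distance 1).

    Directions yielding no in-mask voxel pairs are dropped.
    """
    mats = []
    for d in DIRECTIONS_13:
        sl_a = tuple(
            slice(max(0, -o), disc.shape[ax] - max(0, o)) for ax, o in enumerate(d)
        )
        sl_b = tuple(
            slice(max(0, o), disc.shape[ax] + min(0, o)) for ax, o in enumerate(d)
        )
        a, b = disc[sl_a], disc[sl_b]
        ma, mb = mask[sl_a], mask[sl_b]
        valid = ma & mb
        if not valid.any():
            continue
        i, j = a[valid] - 1, b[valid] - 1
        mat = np.zeros((n_levels, n_levels))
        np.add.at(mat, (i, j), 1.0)
        mat = mat + mat.T
        mats.append(mat / mat.sum())
    return mats


def _glcm_features_one(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    idx = np.arange(1, n + 1)
    joint_max = float(p.max())
    autocorr = float((p * np.outer(idx, idx)).sum())
    # difference distribution p_{|i-j|}
    k = np.abs(idx[:, None] - idx[None, :])
    pk = np.array([p[k == kk].sum() for kk in range(n)])
    nz = pk[pk > 0]
    diff_entropy = float(-(nz * np.log2(nz)).sum())
    return {
        "joint_max": joint_max,
        "autocorrelation": autocorr,
        "difference_entropy": diff_entropy,
    }


def glcm_features(
    disc: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    """Joint maximum, autocorrelation and difference entropy averaged over
    the 13 distance-1 directions."""
    if int(mask.sum()) < 2:
        raise ValueError("GLCM needs at least 2 in-mask voxels")
    mats = glcm_matrices(disc, mask, n_levels)
    if not mats:
        raise ValueError("no co-occurring voxel pairs in mask")
    per_dir = [_glcm_features_one(p) for p in mats]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_counts(disc: np.ndarray, mask: np.ndarray) -> dict[tuple[int, int], int]:
    """Zone counts: (grey level, zone size) -> number of 26-connected zones."""
    counts: dict[tuple[int, int], int] = {}
    levels = np.unique(disc[mask])
    for lev in levels:
        lab, nlab = ndimage.label((disc == lev) & mask, structure=_STRUCT_26)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            counts[(int(lev), int(s))] = counts.get((int(lev), int(s)), 0) + 1
    return counts


def glszm_features(disc: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Small-zone high-grey-level emphasis and high-grey-level zone emphasis."""
    counts = glszm_counts(disc, mask)
    ns = sum(counts.values())
    szhge = sum(c * (i**2) / (j**2) for (i, j), c in counts.items()) / ns
    hglze = sum(c * (i**2) for (i, j), c in counts.items()) / ns
    return {
        "small_zone_high_grey_level_emphasis": float(szhge),
        "high_grey_level_zone_emphasis": float(hglze),
    }


# ---------------------------------------------------------------------------
# GLRLM

def glrlm_runs(
    disc: np.ndarray, mask: np.ndarray, direction: tuple[int, int, int]
) -> dict[tuple[int, int], int]:
    """Run counts (level, run length) along one direction.

    A run starts at a voxel whose predecessor along -direction is outside
    the grid, outside the mask, or a different level; out-of-mask voxels
    break runs.
    """
    shape = disc.shape
    runs: dict[tuple[int, int], int] = {}
    dz, dy, dx = direction
    in_mask = mask
    for z, y, x in zip(*np.nonzero(mask)):
        pz, py, px = z - dz, y - dy, x - dx
        if (
            0 <= pz < shape[0]
            and 0 <= py < shape[1]
            and 0 <= px < shape[2]
            and in_mask[pz, py, px]
            and disc[pz, py, px] == disc[z, y, x]
        ):
            continue  # not a run start
        lev = disc[z, y, x]
        length = 1
        nz, ny, nx = z + dz, y + dy, x + dx
        while (
            0 <= nz < shape[0]
            and 0 <= ny < shape[1]
            and 0 <= nx < shape[2]
            and in_mask[nz, ny, nx]
            and disc[nz, ny, nx] == lev
        ):
            length += 1
            nz, ny, nx = nz + dz, ny + dy, nx + dx
        key = (int(lev), length)
        runs[key] = runs.get(key, 0) + 1
    return runs


def glrlm_lglre(disc: np.ndarray, mask: np.ndarray) -> float:
    """Low grey-level run emphasis, averaged over the 13 directions."""
    vals = []
    for d in DIRECTIONS_13:
        runs = glrlm_runs(disc, mask, d)
        total = sum(runs.values())
        vals.append(sum(c / (i**2) for (i, _), c in runs.items()) / total)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Laws texture energy

def laws_energy(
    image: VolumetricImage, mask: RoiMask, kernel_triplet: tuple[str, str, str]
) -> float:
    """Mean absolute response to a separable 3D Laws filter over the ROI.

    The triplet's kernels are applied along axes (0, 1, 2) of the mask's
    bounding-box crop; the crop is implicitly padded by edge replication.
    """
    bbox = mask.bounding_box()
    sub = image.voxels[bbox]
    resp = sub
    for axis, name in enumerate(kernel_triplet):
        resp = ndimage.correlate1d(resp, LAWS_KERNELS[name], axis=axis, mode="nearest")
    return float(np.abs(resp[mask.voxels[bbox]]).mean())


# ---------------------------------------------------------------------------
# wavelet sub-band energies

def _coeff_mask(mask_bbox: np.ndarray, level: int, coeff_shape: tuple[int, ...]) -> np.ndarray:
    """Project the ROI mask onto a coefficient grid: a coefficient is in
    the support if any voxel it covers (a 2^level cube) is in the mask."""
    scale = 2**level
    out = np.zeros(coeff_shape, dtype=bool)
    for idx in np.ndindex(*coeff_shape):
        sl = tuple(
            slice(i * scale, min((i + 1) * scale, mask_bbox.shape[ax]))
            for ax, i in enumerate(idx)
        )
        if all(s.start < s.stop for s in sl) and mask_bbox[sl].any():
            out[idx] = True
    return out


def wavelet_energies(
    image: VolumetricImage, mask: RoiMask, levels: int = 2, wavelet: str = "haar"
) -> dict[str, float]:
    """Per-sub-band mean squared coefficient over the mask-projected support.

    Multilevel separable 3D decomposition (orthonormal Haar, periodization
    mode) of the mask bounding-box crop.  Sub-band names follow
    :func:`wavelet_subband_names`.
    """
    bbox = mask.bounding_box()
    sub = image.voxels[bbox]
    if any(s < 2**levels for s in sub.shape):
        raise ValueError(f"ROI bounding box must be >= {2**levels} per axis")
    mb = mask.voxels[bbox]
    coeffs = pywt.wavedecn(sub, wavelet, mode="periodization", level=levels)
    names = wavelet_subband_names(levels)
    out: dict[str, float] = {}
    # pywt layout: [cA_L, {details level L}, ..., {details level 1}];
    # canonical order: shallow detail levels first, then the deepest level's
    # approximation followed by its detail octants.
    entries: list[tuple[int, np.ndarray]] = []
    for lev in range(1, levels):
        detail_dict = coeffs[levels - lev + 1]
        for band in _OCTANTS_DETAIL:
            entries.append((lev, detail_dict[band]))
    entries.append((levels, coeffs[0]))
    for band in _OCTANTS_DETAIL:
        entries.append((levels, coeffs[1][band]))
    for name, (lev, arr) in zip(names, entries):
        support = _coeff_mask(mb, lev, arr.shape)
        out[name] = float((arr[support] ** 2).mean()) if support.any() else 0.0
    return out


# ---------------------------------------------------------------------------
# first-order intensity statistics

def intensity_stats(
    image: VolumetricImage, mask: RoiMask, cfg: DiscretizationConfig
) -> dict[str, float]:
    """Coefficient of variation, max-histogram-gradient grey level and
    volume at intensity fraction 10%.

    * COV = sample SD / mean of in-mask intensities (mean must be nonzero).
    * Max histogram gradient: the discretized grey level at which the
      central-difference gradient of the level histogram is maximal.
    * Volume at intensity fraction 10: fraction of ROI voxels with
      intensity >= min + 0.10 * (max - min).
    """
    vals = image.voxels[mask.voxels]
    mean = float(vals.mean())
    if mean == 0.0:
        raise ValueError("COV undefined: in-mask mean intensity is zero")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    cov = sd / mean

    disc = discretize(image, mask, cfg)
    h = np.bincount(disc[mask.voxels], minlength=cfg.n_levels + 1)[1:].astype(float)
    n = cfg.n_levels
    grad = np.empty(n)
    grad[0] = h[1] - h[0] if n > 1 else 0.0
    grad[-1] = h[-1] - h[-2] if n > 1 else 0.0
    if n > 2:
        grad[1:-1] = (h[2:] - h[:-2]) / 2.0
    max_grad_level = float(np.argmax(grad) + 1)

    lo, hi = float(vals.min()), float(vals.max())
    thr = lo + 0.10 * (hi - lo)
    vfrac10 = float((vals >= thr).mean())
    return {
        "cov": cov,
        "max_histogram_gradient_grey_level": max_grad_level,
        "volume_at_intensity_fraction_10": vfrac10,
    }


# ---------------------------------------------------------------------------
# morphology: MVEE density and weighted centre of mass

def mvee(points: np.ndarray, tol: float = 1e-6, max_iter: int = 5000):
    """Minimum-volume enclosing ellipsoid by Khachiyan's algorithm.

    Returns ``(center, A)`` with the ellipsoid
    ``{x : (x-c)^T A (x-c) <= 1}``.
    """
    pts = np.asarray(points, dtype=float)
    n, d = pts.shape
    q = np.column_stack([pts, np.ones(n)]).T  # (d+1) x n
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x = (q * u) @ q.T
        m = np.einsum("ij,ij->j", q, np.linalg.solve(x, q))
        j = int(np.argmax(m))
        mx = m[j]
        step = (mx - d - 1.0) / ((d + 1.0) * (mx - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        if np.linalg.norm(new_u - u) < tol:
            u = new_u
            break
        u = new_u
    c = pts.T @ u
    cov = (pts.T * u) @ pts - np.outer(c, c)
    a = np.linalg.inv(cov) / d
    return c, a


def ellipsoid_volume(a: np.ndarray) -> float:
    from math import gamma, pi

    d = a.shape[0]
    unit = pi ** (d / 2) / gamma(d / 2 + 1)
    return float(unit / np.sqrt(np.linalg.det(a)))


def morphology(
    mask: RoiMask, image: VolumetricImage, spacing_mm: tuple[float, float, float]
) -> dict[str, float]:
    """MVEE volume density and intensity-weighted centre of mass (mm).

    The ellipsoid is fitted to the corner points of the mask voxels (in mm),
    so even a single-voxel or coplanar-voxel mask yields a full-rank point
    cloud; the convex hull is taken first to keep Khachiyan's iteration
    small.  Density = voxel volume of the mask / MVEE volume.
    """
    sp = np.asarray(spacing_mm, dtype=float)
    vox = np.argwhere(mask.voxels).astype(float)
    offsets = np.array(list(itertools.product((-0.5, 0.5), repeat=3)))
    corners = (vox[:, None, :] + offsets[None, :, :]).reshape(-1, 3) * sp
    corners = np.unique(corners, axis=0)
    if len(corners) > 8:
        hull = ConvexHull(corners)
        corners = corners[hull.vertices]
    _, a = mvee(corners)
    vol_mask = mask.n_voxels * float(np.prod(sp))
    density = vol_mask / ellipsoid_volume(a)

    w = image.voxels[mask.voxels]
    wsum = float(w.sum())
    if wsum == 0.0:
        com = vox.mean(axis=0) * sp
    else:
        com = (vox * w[:, None]).sum(axis=0) / wsum * sp
    return {
        "mvee_volume_density": float(density),
        "weighted_com_x_mm": float(com[0]),
        "weighted_com_y_mm": float(com[1]),
        "weighted_com_z_mm": float(com[2]),
    }


# ---------------------------------------------------------------------------
# full panel

def extract_feature_vector(
    image: VolumetricImage,
    mask: RoiMask,
    cfg: DiscretizationConfig | None = None,
    wavelet_levels: int = 2,
) -> dict[str, float]:
    """Compute the full named feature panel for one image/mask pair.

    Returns an ordered mapping whose keys equal :func:`feature_registry`.
    Texture features are computed on the bounding-box crop after
    fixed-bin-number discretization; the weighted centre of mass is in the
    full-grid frame (voxel index times spacing, mm).
    """
    cfg = cfg or DiscretizationConfig()
    if image.voxels.shape != mask.voxels.shape:
        raise ValueError("image and mask shapes differ")
    bbox = mask.bounding_box()
    sub_img = VolumetricImage(image.voxels[bbox], image.spacing_mm)
    sub_mask = RoiMask(mask.voxels[bbox])
    disc = discretize(sub_img, sub_mask, cfg)

    stats = intensity_stats(image, mask, cfg)
    morph = morphology(mask, image, image.spacing_mm)
    glcm = glcm_features(disc, sub_mask.voxels, cfg.n_levels)
    glszm = glszm_features(disc, sub_mask.voxels)
    lglre = glrlm_lglre(disc, sub_mask.voxels)

    out: dict[str, float] = {
        "Statistical_Coefficient_of_variance": stats["cov"],
        "Maximum_histogram_gradient_grey_level": stats["max_histogram_gradient_grey_level"],
        "Volume_at_intensity_fraction_10": stats["volume_at_intensity_fraction_10"],
        "Weighted_CoM_x_(mm)": morph["weighted_com_x_mm"],
        "Weighted_CoM_y_(mm)": morph["weighted_com_y_mm"],
        "Weighted_CoM_z_(mm)": morph["weighted_com_z_mm"],
        "Avg_Coocurrence_Joint_MAX": glcm["joint_max"],
        "Avg_Coocurrence_Autocorrelation": glcm["autocorrelation"],
        "avgCoocurrence_Difference_entropy": glcm["difference_entropy"],
        "GLSZM_Small_zone_high_grey_level_emphasis": glszm["small_zone_high_grey_level_emphasis"],
        "GLSZM_High_grey_level_zone_emphasis": glszm["high_grey_level_zone_emphasis"],
        "avg_3D_LGRE_(Low_grey_level_run_emphasis)": lglre,
        "Volume_density_minimum_volume_enclosing_ellipsoid": morph["mvee_volume_density"],
    }
    for a, b, c in itertools.product(LAWS_NAMES, repeat=3):
        out[f"3D_Laws_features_{a}_{b}_{c}"] = laws_energy(image, mask, (a, b, c))
    out.update(wavelet_energies(image, mask, wavelet_levels))
    assert list(out) == feature_registry(wavelet_levels)
    return out
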