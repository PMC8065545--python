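"""The 93-feature radiomic engine.

Computes, for one (image, mask) pair, the fixed 93-feature vector used by
the whole pipeline: 14 morphological, 18 first-order, and 61 textural
features (24 GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM), after

1. resampling to isotropic voxel spacing (upsampling the coarse slice
   axis to the smallest in-plane spacing; tri-linear intensities,
   nearest-neighbour masks),
2. VOI re-segmentation by Collewet normalization (retain intensities
   within mean +/- 3 SD, single pass),
3. fixed-bin-number discretization to 64 gray levels.

Texture matrices are 3D: GLCM and GLRLM use the 13 unique direction
offsets at Chebyshev distance 1 (per-direction feature values averaged);
GLSZM zones and NGTDM neighbourhoods use 26-connectivity. Only in-mask
voxels enter any matrix.

All feature definitions follow the conventional radiomics formulation
(the fixed-bin-number property makes every texture feature invariant to
strictly increasing intensity transforms; everything is invariant to
translation of the grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .preprocessing import ImageVolume, PipelineConfig, logger

# ---------------------------------------------------------------------------
# canonical feature names (the frozen 93-name list, in canonical order)
# ---------------------------------------------------------------------------

SHAPE_NAMES = [
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
]
FOS_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
    "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]
GLCM_NAMES = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MaximumProbability", "MCC", "SumAverage", "SumEntropy", "SumSquares",
]
GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]
GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]
NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

FEATURE_CLASSES = {
    "shape": SHAPE_NAMES, "fos": FOS_NAMES, "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES, "glszm": GLSZM_NAMES, "ngtdm": NGTDM_NAMES,
}
#: All 93 canonical feature names, class-prefixed (e.g. "glszm_SmallAreaHighGrayLevelEmphasis").
FEATURE_NAMES = [f"{cls}_{name}" for cls, names in FEATURE_CLASSES.items()
                 for name in names]
assert len(FEATURE_NAMES) == 93

#: Short aliases used in the literature for specific features.
ALIASES = {
    "SRHGLE": "glrlm_ShortRunHighGrayLevelEmphasis",
    "SAHGLE": "glszm_SmallAreaHighGrayLevelEmphasis",
    "LAHGLE": "glszm_LargeAreaHighGrayLevelEmphasis",
    "ADC_mean": "fos_Mean",
}

#: The 13 unique 3D direction offsets at Chebyshev distance 1.
DIRECTIONS_13 = [
    (dx, dy, dz)
    for dz in (0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]
assert len(DIRECTIONS_13) == 13


@dataclass
class DiscretizedVoi:
    """Gray-level grid of a VOI after resegmentation and FBN discretization.

    ``levels`` holds integers in 1..n_bins on in-mask voxels and 0 (the
    excluded sentinel) elsewhere; ``mask`` is the effective (post-Collewet)
    VOI mask on the isotropic grid.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        inside = self.levels[self.mask]
        if inside.size and not ((inside >= 1).all() and (inside <= self.n_bins).all()):
            raise ValueError("in-mask levels outside [1, n_bins]")


# ---------------------------------------------------------------------------
# resampling / resegmentation / discretization
# ---------------------------------------------------------------------------

def resample_isotropic(volume: ImageVolume,
                       mask: np.ndarray) -> tuple[ImageVolume, np.ndarray]:
    """Resample an (image, mask) pair to isotropic spacing.

    Target spacing is the smallest in-plane spacing, applied to all axes —
    i.e. the coarse slice axis is upsampled. Intensities are tri-linearly
    interpolated and the mask is resampled nearest-neighbour.
    """
    spacing = np.asarray(volume.spacing_mm)
    target = float(min(spacing[0], spacing[1]))
    factors = spacing / target
    if np.allclose(factors, 1.0):
        return volume, np.asarray(mask, dtype=bool).copy()
    data = ndimage.zoom(volume.data, factors, order=1, mode="nearest")
    rmask = ndimage.zoom(np.asarray(mask, dtype=np.uint8), factors, order=0,
                         mode="nearest").astype(bool)
    if rmask.shape != data.shape:  # rounding differences never occur with same factors
        raise RuntimeError("resampled mask/volume shape mismatch")
    if not rmask.any():
        raise ValueError("VOI empty after resampling")
    return ImageVolume(data, (target, target, target), volume.origin_mm), rmask


def collewet_resegment(values: np.ndarray) -> np.ndarray:
    """Boolean retain-flags for Collewet VOI normalization.

    Single pass: compute mean and sample SD of the in-mask intensities and
    retain values within mean +/- 3 SD. With a finite sample SD at least
    one value always survives.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        return np.ones(values.shape, dtype=bool)
    mu = values.mean()
    sd = values.std(ddof=1)
    keep = np.abs(values - mu) <= 3.0 * sd
    assert keep.any(), "Collewet resegmentation removed every voxel"
    return keep


def discretize_fbn(values: np.ndarray, n_bins: int = 64) -> np.ndarray:
    """Fixed-bin-number discretization to integer levels 1..n_bins.

    level(x) = min(n_bins, floor(n_bins * (x - min) / (max - min)) + 1);
    the maximum maps exactly to n_bins and a constant VOI maps to level 1.
    """
    values = np.asarray(values, dtype=np.float64)
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.ones(values.shape, dtype=np.int64)
    lev = np.floor(n_bins * (values - vmin) / (vmax - vmin)).astype(np.int64) + 1
    np.clip(lev, 1, n_bins, out=lev)
    return lev


# ---------------------------------------------------------------------------
# morphology (14 features)
# ---------------------------------------------------------------------------

def shape_features(mask: np.ndarray, spacing_mm) -> dict[str, float]:
    """The 14 morphological features of a binary VOI.

    Surface and mesh volume come from a marching-cubes triangulation of the
    zero-padded mask; axis lengths, elongation and flatness from the
    principal-component eigenvalues of the in-mask voxel physical
    coordinates (lambda1 >= lambda2 >= lambda3):

        Sphericity = (36 pi V^2)^(1/3) / A,
        Elongation = sqrt(lambda2 / lambda1),
        Flatness   = sqrt(lambda3 / lambda1).

    A fully degenerate point cloud (single voxel) gets Elongation =
    Flatness = 1 (an isotropic cloud).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = tuple(float(s) for s in spacing_mm)
    voxel_volume = float(mask.sum()) * float(np.prod(spacing))

    def _mesh(field):
        verts, faces, _, _ = measure.marching_cubes(field, level=0.5,
                                                    spacing=spacing)
        a = float(measure.mesh_surface_area(verts, faces))
        tri = verts[faces]
        v = float(abs(np.einsum("ij,ij->", tri[:, 0],
                                np.cross(tri[:, 1], tri[:, 2]))) / 6.0)
        return verts, faces, a, v

    # a lightly smoothed mask surface removes the voxelization facets that
    # inflate the area of the raw 0/1 mesh (a digitized ball would otherwise
    # read ~8% too much surface); fall back to the raw mesh whenever
    # smoothing degenerates (sparse/spongy masks barely crossing the level)
    padded = np.pad(mask, 2).astype(np.float64)
    smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
    area = mesh_volume = None
    if smoothed.max() > 0.5 > smoothed.min():
        _, _, a, v = _mesh(smoothed)
        if v >= 0.3 * voxel_volume:
            area, mesh_volume = a, v
    if area is None:
        _, _, area, mesh_volume = _mesh(padded)

    coords = np.argwhere(mask) * np.asarray(spacing)
    # pairwise diameters on the convex hull (max distance is attained there)
    surf = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(surf) * np.asarray(spacing)
    pts = _hull_points(pts)
    diam3d = _max_pairwise(pts)
    diam_slice = _max_pairwise(pts[:, :2])    # in-plane (drop slice axis)
    diam_col = _max_pairwise(pts[:, [0, 2]])  # drop axis 1
    diam_row = _max_pairwise(pts[:, 1:])      # drop axis 0

    if coords.shape[0] > 1:
        lam = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        lam = np.clip(lam, 0.0, None)
    else:
        lam = np.zeros(3)
    if lam[0] <= 0:
        elongation = flatness = 1.0
        major = minor = least = 0.0
    else:
        elongation = float(np.sqrt(lam[1] / lam[0]))
        flatness = float(np.sqrt(lam[2] / lam[0]))
        major, minor, least = (4.0 * np.sqrt(lam)).tolist()

    sphericity = ((36.0 * np.pi * mesh_volume ** 2) ** (1.0 / 3.0) / area
                  if area > 0 else np.nan)
    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / mesh_volume if mesh_volume > 0 else np.nan,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": diam3d,
        "Maximum2DDiameterSlice": diam_slice,
        "Maximum2DDiameterColumn": diam_col,
        "Maximum2DDiameterRow": diam_row,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }


def _hull_points(pts: np.ndarray) -> np.ndarray:
    if pts.shape[0] <= 4:
        return pts
    try:
        from scipy.spatial import ConvexHull
        return pts[ConvexHull(pts).vertices]
    except Exception:  # degenerate (coplanar/collinear) clouds
        return pts


def _max_pairwise(pts: np.ndarray) -> float:
    if pts.shape[0] < 2:
        return 0.0
    if pts.shape[0] > 3000:  # stay memory-bounded; hull normally keeps this tiny
        from scipy.spatial import ConvexHull
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pts = np.unique(pts, axis=0)[:3000]
    from scipy.spatial.distance import pdist
    return float(pdist(pts).max())


# ---------------------------------------------------------------------------
# first-order statistics (18 features)
# ---------------------------------------------------------------------------

def first_order_features(values: np.ndarray, levels: np.ndarray, n_bins: int,
                         voxel_volume_mm3: float) -> dict[str, float]:
    """The 18 first-order features of the retained VOI intensities.

    Entropy (bits) and uniformity are computed on the ``n_bins``-bin
    discretized histogram; everything else on the raw retained values.
    Skewness and kurtosis of a constant distribution are defined as 0.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty intensity set")
    p = np.bincount(np.asarray(levels, dtype=np.int64).ravel(),
                    minlength=n_bins + 1)[1:].astype(np.float64)
    p /= p.sum()
    nz = p[p > 0]
    mean = x.mean()
    var = x.var()  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if var > 0:
        m = x - mean
        skew = float((m ** 3).mean() / var ** 1.5)
        kurt = float((m ** 4).mean() / var ** 2)  # not excess kurtosis
    else:
        skew = kurt = 0.0
    return {
        "Energy": float((x ** 2).sum()),
        "TotalEnergy": float(voxel_volume_mm3 * (x ** 2).sum()),
        "Entropy": float(-(nz * np.log2(nz)).sum()),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean())
            if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": float((nz ** 2).sum()),
    }


# ---------------------------------------------------------------------------
# texture matrix construction
# ---------------------------------------------------------------------------

def _shift(a: np.ndarray, off: tuple[int, int, int], fill=0) -> np.ndarray:
    """out[v] = a[v + off], with ``fill`` outside the grid."""
    out = np.full_like(a, fill)
    src = []
    dst = []
    for n, d in zip(a.shape, off):
        src.append(slice(max(d, 0), n + min(d, 0)))
        dst.append(slice(max(-d, 0), n + min(-d, 0)))
    out[tuple(dst)] = a[tuple(src)]
    return out


def glcm_matrices(voi: DiscretizedVoi) -> list[np.ndarray]:
    """Symmetrized gray-level co-occurrence count matrices, one per direction.

    Entry [i, j] counts in-mask voxel pairs at the direction offset with
    levels (i, j), in both orders. Matrices are indexed by raw level
    (0..n_bins; row/column 0 stays empty).
    """
    nb = voi.n_bins
    lev = voi.levels
    inmask = voi.mask
    out = []
    for d in DIRECTIONS_13:
        lev2 = _shift(lev, d)
        valid = inmask & _shift(inmask, d)
        a = lev[valid]
        b = lev2[valid]
        counts = np.bincount(a * (nb + 1) + b,
                             minlength=(nb + 1) ** 2).reshape(nb + 1, nb + 1)
        out.append((counts + counts.T).astype(np.float64))
    return out


def glrlm_matrices(voi: DiscretizedVoi) -> list[np.ndarray]:
    """Gray-level run-length count matrices, one per direction.

    Entry [i, j] counts maximal in-mask runs of level i and length j along
    the direction (each undirected run counted once).
    """
    lev = voi.levels
    inmask = voi.mask
    nb = voi.n_bins
    max_len = max(lev.shape) * 2  # safe bound for diagonal runs
    out = []
    for d in DIRECTIONS_13:
        nxt_same = inmask & _shift(inmask, d) & (lev == _shift(lev, d, fill=-1))
        prev_same = inmask & _shift(inmask, tuple(-x for x in d)) \
            & (lev == _shift(lev, tuple(-x for x in d), fill=-1))
        starts = inmask & ~prev_same
        length = np.ones(lev.shape, dtype=np.int64)
        chain = nxt_same.copy()
        k = 1
        while chain.any():
            length += chain
            chain = chain & _shift(nxt_same, tuple(k * x for x in d), fill=False)
            k += 1
        lv = lev[starts]
        ln = length[starts]
        mat = np.zeros((nb + 1, max_len + 1), dtype=np.float64)
        np.add.at(mat, (lv, ln), 1.0)
        out.append(mat)
    return out


def glszm_matrix(voi: DiscretizedVoi) -> np.ndarray:
    """Gray-level size-zone count matrix (single, direction-free).

    Zones are 26-connected components of equal level within the mask;
    entry [i, j] counts zones of level i and size j voxels.
    """
    lev = voi.levels
    nb = voi.n_bins
    structure = np.ones((3, 3, 3), dtype=int)
    sizes: dict[int, np.ndarray] = {}
    max_size = 1
    for g in np.unique(lev[voi.mask]):
        lab, n = ndimage.label(lev == g, structure=structure)
        if n:
            s = np.bincount(lab.ravel())[1:]
            sizes[int(g)] = s
            max_size = max(max_size, int(s.max()))
    mat = np.zeros((nb + 1, max_size + 1), dtype=np.float64)
    for g, s in sizes.items():
        np.add.at(mat, (g, s), 1.0)
    return mat


def ngtdm_table(voi: DiscretizedVoi) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Neighbourhood gray-tone difference table.

    Returns (levels, n_i, s_i, Nvp): for each occupied level i, n_i in-mask
    voxels of that level that have at least one in-mask 26-neighbour, and
    s_i the summed absolute difference between i and the mean level of the
    in-mask neighbours. Nvp is the total count of such valid voxels.
    """
    lev = voi.levels
    inmask = voi.mask
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nbr_count = ndimage.correlate(inmask.astype(np.float64), kernel, mode="constant")
    nbr_sum = ndimage.correlate((lev * inmask).astype(np.float64), kernel,
                                mode="constant")
    valid = inmask & (nbr_count > 0)
    diffs = np.abs(lev[valid] - nbr_sum[valid] / nbr_count[valid])
    lv = lev[valid]
    levels = np.unique(lv)
    n_i = np.array([(lv == g).sum() for g in levels], dtype=np.float64)
    s_i = np.array([diffs[lv == g].sum() for g in levels], dtype=np.float64)
    return levels.astype(np.float64), n_i, s_i, int(valid.sum())


# ---------------------------------------------------------------------------
# texture features from matrices
# ---------------------------------------------------------------------------

def _glcm_features_single(counts: np.ndarray) -> dict[str, float] | None:
    total = counts.sum()
    if total == 0:
        return None
    occ = np.flatnonzero(counts.sum(axis=0) + counts.sum(axis=1))
    p = counts[np.ix_(occ, occ)] / total
    i = occ.astype(np.float64)[:, None]
    j = occ.astype(np.float64)[None, :]
    ng = occ.size
    px = p.sum(axis=1)
    mu = float((occ * px).sum())          # == mu_x == mu_y (symmetric)
    sigma2 = float(((occ - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    diff = np.abs(i - j)
    k_diff = np.arange(int(diff.max()) + 1)
    p_diff = np.array([p[diff == k].sum() for k in k_diff])
    s = i + j
    k_sum = np.unique(s)
    p_sum = np.array([p[s == k].sum() for k in k_sum])
    da = float((k_diff * p_diff).sum())

    pz = p[p > 0]
    hxy = float(-(pz * np.log2(pz)).sum())
    pxz = px[px > 0]
    hx = float(-(pxz * np.log2(pxz)).sum())
    pp = px[:, None] * px[None, :]
    with np.errstate(divide="ignore"):
        lpp = np.where(pp > 0, np.log2(np.where(pp > 0, pp, 1.0)), 0.0)
    hxy1 = float(-(p * lpp).sum())
    hxy2 = float(-(pp * lpp).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    autoc = float((i * j * p).sum())
    if sigma > 0:
        correlation = (autoc - mu * mu) / sigma2
    else:
        correlation = 1.0
    if ng > 1:
        a_mat = np.divide(p, px[:, None], out=np.zeros_like(p), where=px[:, None] > 0)
        b_mat = np.divide(p, px[None, :], out=np.zeros_like(p), where=px[None, :] > 0)
        eig = np.real(np.linalg.eigvals(a_mat @ b_mat.T))
        mcc = float(np.sqrt(max(0.0, np.sort(eig)[-2])))
    else:
        mcc = 1.0

    off = diff > 0
    cm = i + j - 2.0 * mu
    nbins_ng = float(ng)
    return {
        "Autocorrelation": autoc,
        "ClusterProminence": float((cm ** 4 * p).sum()),
        "ClusterShade": float((cm ** 3 * p).sum()),
        "ClusterTendency": float((cm ** 2 * p).sum()),
        "Contrast": float((diff ** 2 * p).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff[p_diff > 0]
                                     * np.log2(p_diff[p_diff > 0])).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + diff)).sum()),
        "Idm": float((p / (1.0 + diff ** 2)).sum()),
        "Idmn": float((p / (1.0 + diff ** 2 / nbins_ng ** 2)).sum()),
        "Idn": float((p / (1.0 + diff / nbins_ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((p[off] / diff[off] ** 2).sum()),
        "JointAverage": mu,
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "MCC": mcc,
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum[p_sum > 0]
                              * np.log2(p_sum[p_sum > 0])).sum()),
        "SumSquares": sigma2,
    }


def glcm_features(voi: DiscretizedVoi) -> dict[str, float]:
    """The 24 GLCM features, averaged over the 13 directions."""
    per_dir = [f for f in map(_glcm_features_single, glcm_matrices(voi))
               if f is not None]
    if not per_dir:
        logger.warning("glcm_features: no valid voxel pair in any direction; "
                       "returning degenerate fallbacks")
        fb = {name: 0.0 for name in GLCM_NAMES}
        fb.update(Correlation=1.0, MCC=1.0, Id=1.0, Idm=1.0, Idmn=1.0, Idn=1.0,
                  MaximumProbability=1.0, JointEnergy=1.0, Imc2=0.0)
        return fb
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_NAMES}


def _run_zone_features(mat: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared feature formulas of the run-length and size-zone families.

    ``mat[i, j]`` counts runs (zones) of gray level i and length (size) j.
    """
    total = mat.sum()
    if total == 0:
        return {name: 0.0 for name in (GLRLM_NAMES if kind == "glrlm" else GLSZM_NAMES)}
    i = np.arange(mat.shape[0], dtype=np.float64)[:, None]
    j = np.arange(mat.shape[1], dtype=np.float64)[None, :]
    i = np.where(i == 0, np.inf, i)  # level 0 / length 0 rows are empty anyway
    j = np.where(j == 0, np.inf, j)
    p = mat / total
    ri = mat.sum(axis=1)  # per-level counts
    rj = mat.sum(axis=0)  # per-length counts
    mu_i = float((np.arange(mat.shape[0]) * ri).sum() / total)
    mu_j = float((np.arange(mat.shape[1]) * rj).sum() / total)
    pz = p[p > 0]
    feats = {
        "SmallEmphasis": float((mat / j ** 2).sum() / total),
        "LargeEmphasis": float((mat * np.where(np.isinf(j), 0.0, j) ** 2).sum() / total),
        "GrayLevelNonUniformity": float((ri ** 2).sum() / total),
        "GrayLevelNonUniformityNormalized": float((ri ** 2).sum() / total ** 2),
        "SizeNonUniformity": float((rj ** 2).sum() / total),
        "SizeNonUniformityNormalized": float((rj ** 2).sum() / total ** 2),
        "Percentage": float(total / n_voxels),
        "GrayLevelVariance": float(((np.arange(mat.shape[0]) - mu_i) ** 2 * ri).sum() / total),
        "SizeVariance": float(((np.arange(mat.shape[1]) - mu_j) ** 2 * rj).sum() / total),
        "Entropy": float(-(pz * np.log2(pz)).sum()),
        "LowGrayLevelEmphasis": float((mat / i ** 2).sum() / total),
        "HighGrayLevelEmphasis": float((mat * np.where(np.isinf(i), 0.0, i) ** 2).sum() / total),
        "SmallLowGrayLevelEmphasis": float((mat / (i ** 2 * j ** 2)).sum() / total),
        "SmallHighGrayLevelEmphasis": float(
            (mat * np.where(np.isinf(i), 0.0, i) ** 2 / j ** 2).sum() / total),
        "LargeLowGrayLevelEmphasis": float(
            (mat * np.where(np.isinf(j), 0.0, j) ** 2 / i ** 2).sum() / total),
        "LargeHighGrayLevelEmphasis": float(
            (mat * np.where(np.isinf(i), 0.0, i) ** 2
             * np.where(np.isinf(j), 0.0, j) ** 2).sum() / total),
    }
    if kind == "glrlm":
        names = dict(zip(
            ["ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
             "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
             "RunLengthNonUniformityNormalized", "RunPercentage",
             "GrayLevelVariance", "RunVariance", "RunEntropy",
             "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
             "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
             "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis"],
            ["SmallEmphasis", "LargeEmphasis", "GrayLevelNonUniformity",
             "GrayLevelNonUniformityNormalized", "SizeNonUniformity",
             "SizeNonUniformityNormalized", "Percentage", "GrayLevelVariance",
             "SizeVariance", "Entropy", "LowGrayLevelEmphasis",
             "HighGrayLevelEmphasis", "SmallLowGrayLevelEmphasis",
             "SmallHighGrayLevelEmphasis", "LargeLowGrayLevelEmphasis",
             "LargeHighGrayLevelEmphasis"]))
    else:
        names = dict(zip(
            ["SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
             "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
             "SizeZoneNonUniformityNormalized", "ZonePercentage",
             "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
             "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
             "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
             "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis"],
            ["SmallEmphasis", "LargeEmphasis", "GrayLevelNonUniformity",
             "GrayLevelNonUniformityNormalized", "SizeNonUniformity",
             "SizeNonUniformityNormalized", "Percentage", "GrayLevelVariance",
             "SizeVariance", "Entropy", "LowGrayLevelEmphasis",
             "HighGrayLevelEmphasis", "SmallLowGrayLevelEmphasis",
             "SmallHighGrayLevelEmphasis", "LargeLowGrayLevelEmphasis",
             "LargeHighGrayLevelEmphasis"]))
    return {out: feats[src] for out, src in names.items()}


def glrlm_features(voi: DiscretizedVoi) -> dict[str, float]:
    """The 16 GLRLM features, averaged over the 13 directions."""
    n_vox = int(voi.mask.sum())
    per_dir = [_run_zone_features(m, n_vox, "glrlm") for m in glrlm_matrices(voi)
               if m.sum() > 0]
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_NAMES}


def glszm_features(voi: DiscretizedVoi) -> dict[str, float]:
    """The 16 GLSZM features (single direction-free matrix)."""
    return _run_zone_features(glszm_matrix(voi), int(voi.mask.sum()), "glszm")


def ngtdm_features(voi: DiscretizedVoi) -> dict[str, float]:
    """The 5 NGTDM features (coarseness, contrast, busyness, complexity,
    strength), with defined division-by-zero fallbacks."""
    levels, n_i, s_i, nvp = ngtdm_table(voi)
    if nvp == 0:
        return {"Coarseness": 1e6, "Contrast": 0.0, "Busyness": 0.0,
                "Complexity": 0.0, "Strength": 0.0}
    p_i = n_i / nvp
    ngp = levels.size
    il = levels
    denom_coarse = float((p_i * s_i).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else 1e6
    if ngp > 1:
        pij = p_i[:, None] * p_i[None, :]
        dij2 = (il[:, None] - il[None, :]) ** 2
        contrast = float((pij * dij2).sum()) * s_i.sum() / (ngp * (ngp - 1) * nvp)
    else:
        contrast = 0.0
    denom_busy = float(np.abs(il[:, None] * p_i[:, None]
                              - il[None, :] * p_i[None, :]).sum())
    busyness = denom_coarse / denom_busy if denom_busy > 0 else 0.0
    psum = p_i[:, None] + p_i[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        cx = np.abs(il[:, None] - il[None, :]) \
            * (p_i[:, None] * s_i[:, None] + p_i[None, :] * s_i[None, :]) / psum
    complexity = float(np.nansum(cx)) / nvp
    s_total = float(s_i.sum())
    strength = (float((psum * (il[:, None] - il[None, :]) ** 2).sum()) / s_total
                if s_total > 0 else 0.0)
    return {"Coarseness": coarseness, "Contrast": contrast,
            "Busyness": busyness, "Complexity": complexity, "Strength": strength}


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def _crop_to_mask(data: np.ndarray, mask: np.ndarray,
                  margin: int = 2) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return data[sl], mask[sl]


def extract_all(image: ImageVolume, mask: np.ndarray,
                config: PipelineConfig | None = None) -> pd.Series:
    """Run the full chain and return the 93-feature vector.

    resample to isotropic -> morphological features on the resampled mask
    -> Collewet resegmentation -> 64-bin FBN discretization -> first-order
    and texture families on the resegmented VOI. Deterministic; the result
    is a Series indexed by the canonical class-prefixed feature names.
    """
    config = config or PipelineConfig()
    iso, rmask = resample_isotropic(image, mask)
    data, rmask = _crop_to_mask(iso.data, rmask)

    out: dict[str, float] = {}
    for k, v in shape_features(rmask, iso.spacing_mm).items():
        out[f"shape_{k}"] = v

    keep = collewet_resegment(data[rmask])
    eff_mask = np.zeros_like(rmask)
    eff_mask[rmask] = keep
    values = data[eff_mask]
    level_values = discretize_fbn(values, config.n_bins)
    levels = np.zeros(rmask.shape, dtype=np.int64)
    levels[eff_mask] = level_values
    voi = DiscretizedVoi(levels=levels, mask=eff_mask, n_bins=config.n_bins,
                         spacing_mm=iso.spacing_mm)

    for k, v in first_order_features(values, level_values, config.n_bins,
                                     float(np.prod(iso.spacing_mm))).items():
        out[f"fos_{k}"] = v
    for k, v in glcm_features(voi).items():
        out[f"glcm_{k}"] = v
    for k, v in glrlm_features(voi).items():
        out[f"glrlm_{k}"] = v
    for k, v in glszm_features(voi).items():
        out[f"glszm_{k}"] = v
    for k, v in ngtdm_features(voi).items():
        out[f"ngtdm_{k}"] = v

    vec = pd.Series(out).reindex(FEATURE_NAMES)
    if vec.isna().any():
        missing = vec.index[vec.isna()].tolist()
        raise RuntimeError(f"feature extraction produced NaN/missing: {missing}")
    return vec
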