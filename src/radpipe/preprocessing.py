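"""Image preprocessing for the multiparametric prostate MRI pipeline.

Covers the steps between image acquisition and feature extraction:

* apparent diffusion coefficient (ADC) maps from a two-b-value
  monoexponential diffusion model,
* linear standardization of T2-weighted intensities into a fixed range,
* the minimum-lesion-volume inclusion filter applied on the ADC-map VOI.

Bias-field correction is deliberately out of scope: the pipeline expects
already-corrected volumes (the synthetic cohort generator emits bias-free
images).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("radpipe")

#: Modality keys used throughout the pipeline.
MOD_T2W = "t2w"
MOD_ADC = "adc"
MOD_DWI_LOW = "dwi_low"
MOD_DWI_HIGH = "dwi_high"


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid with physical voxel spacing.

    Parameters
    ----------
    data
        3D array of intensities (any float dtype; stored as float64).
    spacing_mm
        Per-axis voxel size in millimetres.
    origin_mm
        Physical position of the first voxel (defaults to the origin).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class AdcParams:
    """b-values (s/mm^2) of the DWI pair used for the monoexponential fit."""

    b_low: float = 50.0
    b_high: float = 800.0

    def __post_init__(self) -> None:
        if not (self.b_high > self.b_low >= 0):
            raise ValueError(f"need b_high > b_low >= 0, got {self.b_low}, {self.b_high}")


@dataclass
class PipelineConfig:
    """Constants of the analysis pipeline, exposed as one config object.

    Defaults are the pipeline's operating point: T2w intensities rescaled
    into 0-600, VOIs retained only above 0.7 cc on the ADC mask, fixed
    64-bin discretization, |r| > 0.8 redundancy threshold, stability at
    Friedman p > 0.05, top-10 stable features feeding the signatures, and
    10 balanced undersampled subsets for classifier evaluation.
    """

    t2w_scale_range: tuple[float, float] = (0.0, 600.0)
    voi_min_cc: float = 0.7
    n_bins: int = 64
    r_threshold: float = 0.8
    stability_alpha: float = 0.05
    top_k_stable: int = 10
    n_subsets: int = 10
    cv_folds: int = 5
    stability_subset_size: int = 20
    linkage: str = "complete"
    skew_threshold: float = 2.0
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    adc: AdcParams = field(default_factory=AdcParams)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.t2w_scale_range
        if not hi > lo:
            raise ValueError("t2w_scale_range must be ordered")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        for name in ("voi_min_cc", "r_threshold", "stability_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# ADC map computation
# ---------------------------------------------------------------------------

def compute_adc(s_low: ImageVolume, s_high: ImageVolume,
                params: AdcParams | None = None) -> ImageVolume:
    """Voxel-wise ADC (mm^2/s) from a two-b-value DWI pair.

    The monoexponential decay ``S(b) = S0 * exp(-b * ADC)`` inverts to

        ADC = ln(S_low / S_high) / (b_high - b_low).

    Voxels where either signal is non-positive (noise floor, background)
    are set to ADC 0 and counted in a warning; the diffusion model is
    undefined there.
    """
    params = params or AdcParams()
    if s_low.shape != s_high.shape:
        raise ValueError(f"DWI grids differ: {s_low.shape} vs {s_high.shape}")
    if s_low.spacing_mm != s_high.spacing_mm:
        raise ValueError(f"DWI spacings differ: {s_low.spacing_mm} vs {s_high.spacing_mm}")
    valid = (s_low.data > 0) & (s_high.data > 0)
    adc = np.zeros_like(s_low.data)
    np.divide(np.log(s_low.data, where=valid, out=np.zeros_like(s_low.data))
              - np.log(s_high.data, where=valid, out=np.zeros_like(s_high.data)),
              params.b_high - params.b_low, out=adc, where=valid)
    n_bad = int(valid.size - valid.sum())
    if n_bad:
        logger.warning("compute_adc: %d voxel(s) with non-positive DWI signal set to ADC=0", n_bad)
    adc[~valid] = 0.0
    return ImageVolume(adc, s_low.spacing_mm, s_low.origin_mm)


def standardize_t2w(volume: ImageVolume,
                    scale_range: tuple[float, float] = (0.0, 600.0)) -> ImageVolume:
    """Affine rescaling of T2w intensities: observed min -> lo, max -> hi.

    A strictly monotone map, so voxel rank order is preserved. The min/max
    are taken over the whole volume (standardization precedes any
    VOI-restricted analysis). A constant volume has no defined map.
    """
    lo, hi = scale_range
    vmin = float(volume.data.min())
    vmax = float(volume.data.max())
    if vmax == vmin:
        raise ValueError("cannot standardize a constant volume")
    scaled = lo + (volume.data - vmin) * ((hi - lo) / (vmax - vmin))
    return ImageVolume(scaled, volume.spacing_mm, volume.origin_mm)


# ---------------------------------------------------------------------------
# VOI volume filter
# ---------------------------------------------------------------------------

def voi_volume_cc(mask: np.ndarray, spacing_mm: Sequence[float]) -> float:
    """Volume of a binary mask in cubic centimetres (voxel count x voxel volume)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return float(mask.sum()) * float(np.prod(spacing_mm)) / 1000.0


def filter_cohort_by_volume(cases: Iterable, min_cc: float = 0.7,
                            reader: int = 1) -> tuple[list, pd.DataFrame]:
    """Split a cohort into included/excluded by the ADC-VOI volume cut-off.

    Inclusion requires the reader-1 ADC mask volume to *strictly exceed*
    ``min_cc`` (a lesion of exactly 0.7 cc is excluded). Returns the
    included cases and a per-case report with volumes and the decision.
    """
    included: list = []
    rows = []
    for case in cases:
        key = (MOD_ADC, reader)
        if key not in case.masks:
            raise ValueError(f"case {case.patient_id}: missing ADC mask for reader {reader}")
        vol_cc = voi_volume_cc(case.masks[key], case.volumes[MOD_ADC].spacing_mm)
        keep = vol_cc > min_cc
        if abs(vol_cc - min_cc) < 1e-9:
            logger.info("volume filter: case %s sits on the %.2f cc boundary (excluded)",
                        case.patient_id, min_cc)
        rows.append({"patient_id": case.patient_id, "volume_cc": vol_cc, "included": keep})
        if keep:
            included.append(case)
    report = pd.DataFrame(rows, columns=["patient_id", "volume_cc", "included"])
    return included, report
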