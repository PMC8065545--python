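"""Synthetic 3D lesion-phantom cohorts for the prostate-MRI radiomic pipeline.

The patient images behind the analysis are not shareable, so this module
generates a fully labelled stand-in cohort with the statistical structure
the downstream stages assume:

* anisotropic voxel grids (fine in-plane, coarse through-plane);
* one ellipsoidal index lesion per patient whose interior carries a
  Gaussian-random-field texture with a class-dependent correlation length,
  embedded in a uniform background;
* a T2w-like volume and a DWI pair (b = 50 / 800 s/mm^2) constructed so
  that the monoexponential relation S(b) = S0 * exp(-b * ADC) holds exactly
  voxel-wise before noise — the generating ADC field is therefore
  recoverable by ``preprocessing.compute_adc``;
* two readers' masks per modality, reader 2 being a bounded random
  boundary perturbation of reader 1;
* clinical labels (high/low Gleason grade group, extracapsular extension,
  nodal stage with a pNx fraction, lesion zone) drawn to match the target
  prevalences, with ECE and pN positively associated with the high-GGG
  class;
* a stated fraction of lesions below the 0.7 cc inclusion cut-off to
  exercise the volume filter.

Lower mean ADC and coarser texture in the "high" class encode the
aggressiveness signal the classifiers are meant to recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocessing import (MOD_ADC, MOD_DWI_HIGH, MOD_DWI_LOW, MOD_T2W,
                            ImageVolume, logger)

PN_N0 = "pN0"
PN_N1 = "pN1"
PN_NX = "pNx"


@dataclass
class PhantomParams:
    """Generator settings; the defaults define the emulated study conditions.

    Geometry mirrors a 1.5 T endorectal-coil protocol: 0.6 mm in-plane
    resolution with 3 mm slices. Class mean ADCs (mm^2/s) sit at typical
    tumour values (high-grade ~0.85e-3, lower-grade ~1.25e-3) against a
    benign-tissue background of 1.6e-3; texture correlation lengths make
    the high class coarser. Label prevalences follow the analyzed cohort
    (high GGG 71%, ECE 61%, pN>=1 21%, pNx 16%, PZ 69%/TZ 26%/both 5%),
    and 40/102 of lesions are drawn below the 0.7 cc cut-off so the volume
    filter removes them, as in the enrolled cohort.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 24)
    spacing_mm: tuple[float, float, float] = (0.6, 0.6, 3.0)
    lesion_radius_range_mm: tuple[float, float] = (6.0, 10.0)
    small_lesion_radius_range_mm: tuple[float, float] = (3.5, 5.0)
    small_lesion_fraction: float = 40.0 / 102.0
    texture_correlation_length_mm: dict = field(
        default_factory=lambda: {"low": 2.0, "high": 5.0})
    class_mean_adc: dict = field(
        default_factory=lambda: {"low": 1.25e-3, "high": 0.85e-3})
    class_mean_t2w: dict = field(
        default_factory=lambda: {"low": 330.0, "high": 250.0})
    texture_amplitude_adc: float = 0.15e-3
    texture_amplitude_t2w: float = 45.0
    background_adc: float = 1.6e-3
    background_t2w: float = 420.0
    s0: float = 1000.0
    noise_sd_t2w: float = 12.0
    noise_sd_dwi: float = 8.0
    reader_perturbation_mm: float = 1.0
    label_prevalences: dict = field(default_factory=lambda: {
        "ggg_high": 44.0 / 62.0, "ece": 0.61, "pn1": 13.0 / 62.0,
        "pnx": 10.0 / 62.0, "pz": 0.69, "tz": 0.26})
    label_association: float = 0.15
    n_patients: int = 102
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacings must be positive")
        if any(r <= 0 for r in self.lesion_radius_range_mm):
            raise ValueError("lesion radii must be positive")
        for k, v in self.label_prevalences.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"prevalence {k}={v} outside [0, 1]")
        if not 0.0 <= self.small_lesion_fraction <= 1.0:
            raise ValueError("small_lesion_fraction outside [0, 1]")


def compact_params(**overrides) -> PhantomParams:
    """A reduced-size phantom preset for fast cohort studies.

    Same statistical structure as the default, on a 48x48x14 grid at
    (0.7, 0.7, 2.8) mm with smaller lesions; an extraction runs in tens of
    milliseconds instead of hundreds.
    """
    base = dict(grid_shape=(48, 48, 14), spacing_mm=(0.7, 0.7, 2.8),
                lesion_radius_range_mm=(6.0, 8.5),
                small_lesion_radius_range_mm=(3.5, 5.0))
    base.update(overrides)
    return PhantomParams(**base)


def null_effect(params: PhantomParams) -> PhantomParams:
    """Copy of ``params`` with the class effect removed (identical class
    means and correlation lengths), for chance-level controls."""
    mid_adc = float(np.mean(list(params.class_mean_adc.values())))
    mid_t2w = float(np.mean(list(params.class_mean_t2w.values())))
    mid_len = float(np.mean(list(params.texture_correlation_length_mm.values())))
    return dataclasses.replace(
        params,
        class_mean_adc={"low": mid_adc, "high": mid_adc},
        class_mean_t2w={"low": mid_t2w, "high": mid_t2w},
        texture_correlation_length_mm={"low": mid_len, "high": mid_len},
    )


@dataclass
class LesionCase:
    """One patient: per-modality volumes, per-(modality, reader) masks, labels."""

    patient_id: str
    volumes: dict  # modality -> ImageVolume
    masks: dict    # (modality, reader:int) -> bool ndarray
    labels: dict   # ggg_high: bool, ece: bool, pn: pN0|pN1|pNx
    zone: str = "PZ"  # PZ | TZ | both

    def __post_init__(self) -> None:
        for (mod, _reader), mask in self.masks.items():
            vol = self.volumes[mod]
            if mask.shape != vol.shape:
                raise ValueError(
                    f"{self.patient_id}: mask grid {mask.shape} != volume grid {vol.shape}")
            if not mask.any():
                raise ValueError(f"{self.patient_id}: empty mask for {mod}")


# ---------------------------------------------------------------------------
# random fields and masks
# ---------------------------------------------------------------------------

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_random_field(shape: tuple[int, int, int], spacing_mm,
                          correlation_length_mm: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field.

    White noise smoothed with a Gaussian kernel whose FWHM (in mm) is the
    requested correlation length, then re-standardized. The simplest
    stationary field with one tunable texture scale — exactly what the
    co-occurrence-family features respond to.
    """
    noise = rng.standard_normal(shape)
    sigma_vox = [max(correlation_length_mm * _FWHM_TO_SIGMA / s, 1e-6)
                 for s in spacing_mm]
    fld = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    sd = fld.std()
    if sd < 1e-12:  # pathological (huge kernel): fall back to the raw noise
        return noise - noise.mean()
    return (fld - fld.mean()) / sd


def _ellipsoid_mask(shape, spacing_mm, center_mm, semi_axes_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing_mm)],
                        indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semi_axes_mm))
    return q <= 1.0


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


def perturb_mask(mask: np.ndarray, spacing_mm, magnitude_mm: float,
                 seed: int, min_dice: float = 0.6,
                 max_tries: int = 20) -> np.ndarray:
    """Second-reader mask: random boundary dilation/erosion of bounded depth.

    The mask boundary is moved by a smooth random field applied to the
    signed Euclidean distance (positive outside), so no boundary point
    moves farther than ``magnitude_mm``. Draws are retried (and, as a last
    resort, the magnitude damped) until the result is nonempty with Dice
    overlap >= ``min_dice`` against the input; ``magnitude_mm = 0`` returns
    the input unchanged.
    """
    if magnitude_mm < 0:
        raise ValueError("perturbation magnitude must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot perturb an empty mask")
    if magnitude_mm == 0:
        return mask.copy()
    d_in = ndimage.distance_transform_edt(mask, sampling=spacing_mm)
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing_mm)
    signed = d_out - d_in  # negative inside, positive outside
    rng = np.random.default_rng(seed)
    mag = magnitude_mm
    for attempt in range(max_tries):
        fld = gaussian_random_field(mask.shape, spacing_mm,
                                    correlation_length_mm=4.0 * max(spacing_mm[:2]),
                                    rng=rng)
        # unit-SD field scaled then saturated at +/- mag: boundary excursions
        # reach the full depth over ~1/3 of the surface but never exceed it
        eta = np.clip(fld * mag, -mag, mag)
        new = signed <= eta
        if new.any() and dice(mask, new) >= min_dice:
            return new
        if attempt >= max_tries // 2:
            mag *= 0.7  # damp toward the identity, which always passes
    logger.warning("perturb_mask: retries exhausted, returning unperturbed mask")
    return mask.copy()


# ---------------------------------------------------------------------------
# single-phantom generation
# ---------------------------------------------------------------------------

def generate_phantom(params: PhantomParams, class_label: str, seed: int,
                     patient_id: str = "case", radius_mm: float | None = None,
                     labels: dict | None = None, zone: str = "PZ") -> LesionCase:
    """One lesion phantom of the given class ("high" or "low").

    The lesion interior is ``class mean + amplitude * GRF``; the DWI pair is
    the exact monoexponential forward model of the ADC field (noise added
    afterwards, if configured). Reader-1 masks are the true ellipsoid on
    both modalities; reader 2 is a perturbation of reader 1.
    """
    if class_label not in ("high", "low"):
        raise ValueError(f"class_label must be 'high' or 'low', got {class_label!r}")
    rng = np.random.default_rng(seed)
    shape = params.grid_shape
    spacing = params.spacing_mm
    extent = np.array([n * s for n, s in zip(shape, spacing)])

    if radius_mm is None:
        radius_mm = float(rng.uniform(*params.lesion_radius_range_mm))
    # random axis ratios at fixed equivalent-sphere radius
    ratios = np.array([1.0, rng.uniform(0.6, 1.0), rng.uniform(0.6, 1.0)])
    semi = radius_mm * ratios / np.prod(ratios) ** (1.0 / 3.0)
    if np.any(2.0 * semi >= extent):
        raise ValueError(f"lesion (semi-axes {semi} mm) does not fit grid extent {extent} mm")
    center = extent / 2.0 + rng.uniform(-1.0, 1.0, size=3) * spacing
    mask = _ellipsoid_mask(shape, spacing, center, semi)
    if not mask.any():
        raise ValueError("lesion mask empty after digitization")

    corr_len = params.texture_correlation_length_mm[class_label]

    adc = np.full(shape, params.background_adc, dtype=np.float64)
    fld = gaussian_random_field(shape, spacing, corr_len, rng)
    adc[mask] = params.class_mean_adc[class_label] + params.texture_amplitude_adc * fld[mask]
    np.clip(adc, 1e-5, None, out=adc)

    t2w = np.full(shape, params.background_t2w, dtype=np.float64)
    fld = gaussian_random_field(shape, spacing, corr_len, rng)
    t2w[mask] = params.class_mean_t2w[class_label] + params.texture_amplitude_t2w * fld[mask]

    b_low, b_high = 50.0, 800.0
    s_low = params.s0 * np.exp(-b_low * adc)
    s_high = params.s0 * np.exp(-b_high * adc)
    if params.noise_sd_dwi > 0:
        s_low = s_low + rng.normal(0.0, params.noise_sd_dwi, size=shape)
        s_high = s_high + rng.normal(0.0, params.noise_sd_dwi, size=shape)
        np.clip(s_low, 1e-3, None, out=s_low)
        np.clip(s_high, 1e-3, None, out=s_high)
    if params.noise_sd_t2w > 0:
        t2w = t2w + rng.normal(0.0, params.noise_sd_t2w, size=shape)

    volumes = {
        MOD_T2W: ImageVolume(t2w, spacing),
        MOD_ADC: ImageVolume(adc, spacing),
        MOD_DWI_LOW: ImageVolume(s_low, spacing),
        MOD_DWI_HIGH: ImageVolume(s_high, spacing),
    }
    masks = {(MOD_T2W, 1): mask.copy(), (MOD_ADC, 1): mask.copy()}
    for mod in (MOD_T2W, MOD_ADC):
        masks[(mod, 2)] = perturb_mask(
            mask, spacing, params.reader_perturbation_mm,
            seed=int(rng.integers(2 ** 31)))

    labels = labels or {"ggg_high": class_label == "high", "ece": False, "pn": PN_N0}
    return LesionCase(patient_id=patient_id, volumes=volumes, masks=masks,
                      labels=labels, zone=zone)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _conditional_prob(p: float, q_high: float, delta: float) -> tuple[float, float]:
    """(P(label|high), P(label|low)) with marginal p and a positive
    association with the high class of strength delta, clipped to stay in
    [0, 1] while preserving the marginal whenever feasible."""
    if q_high in (0.0, 1.0) or p in (0.0, 1.0):
        return p, p
    p_h = min(1.0, p + delta)
    p_l = (p - p_h * q_high) / (1.0 - q_high)
    if p_l < 0.0:
        p_l = 0.0
        p_h = min(1.0, p / q_high)
    return p_h, p_l


def draw_labels(params: PhantomParams, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical label table for ``params.n_patients`` patients.

    ``ggg_high`` (the image-generating class) is Bernoulli at its
    prevalence; ECE and pN>=1 are drawn conditionally on the class so their
    marginals match while being positively associated with high GGG; pNx
    status and zone are independent of the class.
    """
    prev = params.label_prevalences
    n = params.n_patients
    high = rng.random(n) < prev["ggg_high"]
    p_e_h, p_e_l = _conditional_prob(prev["ece"], prev["ggg_high"], params.label_association)
    ece = rng.random(n) < np.where(high, p_e_h, p_e_l)
    pnx = rng.random(n) < prev["pnx"]
    p_n1 = prev["pn1"] / max(1.0 - prev["pnx"], 1e-12)  # marginal among assessable
    p_n_h, p_n_l = _conditional_prob(min(p_n1, 1.0), prev["ggg_high"], params.label_association)
    n1 = rng.random(n) < np.where(high, p_n_h, p_n_l)
    pn = np.where(pnx, PN_NX, np.where(n1, PN_N1, PN_N0))
    u = rng.random(n)
    zone = np.where(u < prev["pz"], "PZ", np.where(u < prev["pz"] + prev["tz"], "TZ", "both"))
    return pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "ggg_high": high, "ece": ece, "pn": pn, "zone": zone,
        "true_class": np.where(high, "high", "low"),
    })


def generate_cohort(params: PhantomParams,
                    out_dir: str | Path | None = None
                    ) -> tuple[list[LesionCase], pd.DataFrame]:
    """Full synthetic cohort: phantoms, two-reader masks and label table.

    A ``small_lesion_fraction`` of patients receives a lesion drawn from
    the sub-threshold radius range (below the 0.7 cc cut-off), so the
    downstream volume filter has work to do. If ``out_dir`` is given the
    volumes/masks are written as NIfTI and the labels as CSV.
    """
    if params.n_patients < 4:
        raise ValueError("need n_patients >= 4")
    rng = np.random.default_rng(params.seed)
    labels = draw_labels(params, rng)
    small = rng.random(params.n_patients) < params.small_lesion_fraction
    seeds = rng.integers(2 ** 31, size=params.n_patients)
    cases = []
    for i, row in labels.iterrows():
        case_rng = np.random.default_rng(int(seeds[i]))
        rng_radius = float(case_rng.uniform(*(params.small_lesion_radius_range_mm
                                              if small[i] else params.lesion_radius_range_mm)))
        case = generate_phantom(
            params, row["true_class"], seed=int(case_rng.integers(2 ** 31)),
            patient_id=row["patient_id"], radius_mm=rng_radius,
            labels={"ggg_high": bool(row["ggg_high"]), "ece": bool(row["ece"]),
                    "pn": row["pn"]},
            zone=row["zone"])
        cases.append(case)
    if out_dir is not None:
        write_cohort(cases, labels, out_dir)
    return cases, labels


def write_cohort(cases: list[LesionCase], labels: pd.DataFrame,
                 out_dir: str | Path) -> None:
    """Write NIfTI volumes/masks (one file per patient/modality[/reader]) and
    the label table CSV."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for case in cases:
        for mod, vol in case.volumes.items():
            affine = np.diag(list(vol.spacing_mm) + [1.0])
            nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine),
                     out / f"{case.patient_id}_{mod}.nii.gz")
        for (mod, reader), mask in case.masks.items():
            affine = np.diag(list(case.volumes[mod].spacing_mm) + [1.0])
            nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine),
                     out / f"{case.patient_id}_{mod}_mask_r{reader}.nii.gz")
    labels.to_csv(out / "labels.csv", index=False)
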