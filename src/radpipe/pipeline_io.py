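"""End-to-end pipeline orchestration, configuration and I/O.

Wires the stages together — synthetic cohort (or NIfTI input directory)
-> ADC/T2w preprocessing -> 0.7 cc volume filter -> per-reader 93-feature
extraction -> stability ranking and redundancy pruning -> two-group
clustering with Fisher association -> signature evaluation — under a
single seed, and records a run manifest (config snapshot, stage outputs
with checksums, consistency counts).

All tabular outputs are CSV; summary results are JSON. Reruns with the
same config and seed are bit-identical for CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster_association as ca
from . import feature_engine as fe
from . import feature_selection as fs
from . import signature_eval as se
from .preprocessing import (MOD_ADC, MOD_DWI_HIGH, MOD_DWI_LOW, MOD_T2W,
                            ImageVolume, PipelineConfig, compute_adc,
                            filter_cohort_by_volume, logger, standardize_t2w)
from .synthetic_cohort import LesionCase, PhantomParams, generate_cohort

MODALITIES = (MOD_T2W, MOD_ADC)

# fixed per-stage seed offsets fanned out from the single config seed
_STAGE_SEED_OFFSET = {"cohort": 0, "stability": 101, "signatures": 202}


@dataclass
class RunManifest:
    """What a pipeline run did: config, seeds, outputs, counts."""

    config: dict
    seed: int
    outputs: dict = field(default_factory=dict)   # name -> {path, sha256}
    counts: dict = field(default_factory=dict)
    timestamp: str = ""

    def add_output(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[name] = {"path": str(path), "sha256": digest}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# per-case preprocessing + extraction
# ---------------------------------------------------------------------------

def preprocess_case(case: LesionCase, config: PipelineConfig) -> LesionCase:
    """Derive the ADC map from the DWI pair (when present) and standardize T2w."""
    vols = dict(case.volumes)
    if MOD_DWI_LOW in vols and MOD_DWI_HIGH in vols:
        vols[MOD_ADC] = compute_adc(vols[MOD_DWI_LOW], vols[MOD_DWI_HIGH], config.adc)
    elif MOD_ADC not in vols:
        raise ValueError(f"case {case.patient_id}: neither ADC nor a DWI pair present")
    vols[MOD_T2W] = standardize_t2w(vols[MOD_T2W], config.t2w_scale_range)
    return LesionCase(patient_id=case.patient_id, volumes=vols, masks=case.masks,
                      labels=case.labels, zone=case.zone)


def case_features(case: LesionCase, modality: str, reader: int,
                  config: PipelineConfig) -> pd.Series:
    """93-feature vector of one case for the given modality and reader mask."""
    return fe.extract_all(case.volumes[modality], case.masks[(modality, reader)],
                          config)


def extract_feature_table(cases: list[LesionCase], modality: str, reader: int,
                          config: PipelineConfig,
                          patient_ids: list[str] | None = None) -> pd.DataFrame:
    """(patients x 93) feature table for one modality and reader."""
    rows = {}
    for case in cases:
        if patient_ids is not None and case.patient_id not in patient_ids:
            continue
        rows[case.patient_id] = case_features(case, modality, reader, config)
    tab = pd.DataFrame(rows).T
    tab.index.name = "patient_id"
    return tab


def combined_table(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Join per-modality tables into one with 'modality:feature' columns."""
    parts = []
    for mod, tab in tables.items():
        t = tab.copy()
        t.columns = [f"{mod}:{c}" for c in t.columns]
        parts.append(t)
    return pd.concat(parts, axis=1)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_cases(cases: list[LesionCase], labels: pd.DataFrame) -> list[dict]:
    """Machine-readable consistency issues of a loaded cohort (never raises)."""
    issues = []
    for case in cases:
        for (mod, reader), mask in case.masks.items():
            vol = case.volumes.get(mod)
            if vol is None:
                issues.append({"patient_id": case.patient_id, "issue": "missing volume",
                               "detail": mod})
                continue
            if mask.shape != vol.shape:
                issues.append({"patient_id": case.patient_id, "issue": "grid mismatch",
                               "detail": f"{mod} r{reader}: mask {mask.shape} vs "
                                         f"volume {vol.shape}"})
            if not mask.any():
                issues.append({"patient_id": case.patient_id, "issue": "empty mask",
                               "detail": f"{mod} r{reader}"})
    required = {"patient_id", "ggg_high", "ece", "pn", "zone"}
    missing_cols = required - set(labels.columns)
    if missing_cols:
        issues.append({"patient_id": "*", "issue": "label schema",
                       "detail": f"missing columns {sorted(missing_cols)}"})
    else:
        known = set(labels["patient_id"])
        for case in cases:
            if case.patient_id not in known:
                issues.append({"patient_id": case.patient_id,
                               "issue": "missing label row", "detail": ""})
    return issues


def load_cohort(in_dir: str | Path) -> tuple[list[LesionCase], pd.DataFrame]:
    """Read a cohort written by ``synthetic_cohort.write_cohort`` (NIfTI + CSV)."""
    import nibabel as nib

    in_dir = Path(in_dir)
    labels = pd.read_csv(in_dir / "labels.csv")
    cases = []
    for _, row in labels.iterrows():
        pid = row["patient_id"]
        vols = {}
        masks = {}
        for mod in (MOD_T2W, MOD_ADC, MOD_DWI_LOW, MOD_DWI_HIGH):
            p = in_dir / f"{pid}_{mod}.nii.gz"
            if not p.exists():
                continue
            try:
                img = nib.load(p)
                data = np.asarray(img.dataobj, dtype=np.float64)
            except Exception as exc:
                raise ValueError(f"cannot read NIfTI file {p}: {exc}") from exc
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
            vols[mod] = ImageVolume(data, spacing)
            for reader in (1, 2):
                mp = in_dir / f"{pid}_{mod}_mask_r{reader}.nii.gz"
                if mp.exists():
                    masks[(mod, reader)] = np.asarray(
                        nib.load(mp).dataobj).astype(bool)
        cases.append(LesionCase(patient_id=pid, volumes=vols, masks=masks,
                                labels={"ggg_high": bool(row["ggg_high"]),
                                        "ece": bool(row["ece"]), "pn": row["pn"]},
                                zone=row["zone"]))
    return cases, labels


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> tuple[PhantomParams, PipelineConfig]:
    """Read a YAML config with optional 'synthetic' and 'pipeline' sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    synth = PhantomParams(**raw.get("synthetic", {}))
    pipe_raw = raw.get("pipeline", {})
    if "adc" in pipe_raw:
        from .preprocessing import AdcParams
        pipe_raw["adc"] = AdcParams(**pipe_raw["adc"])
    if "t2w_scale_range" in pipe_raw:
        pipe_raw["t2w_scale_range"] = tuple(pipe_raw["t2w_scale_range"])
    pipe = PipelineConfig(**pipe_raw)
    return synth, pipe


def run_pipeline(out_dir: str | Path,
                 config: PipelineConfig | None = None,
                 phantom: PhantomParams | None = None,
                 in_dir: str | Path | None = None,
                 seed: int | None = None,
                 write_images: bool = False,
                 plots: bool = False) -> RunManifest:
    """Execute the whole pipeline and write all stage outputs under ``out_dir``.

    Either ``in_dir`` (a NIfTI cohort directory) or a synthetic cohort
    generated from ``phantom`` provides the input. A single seed fans out
    to the stages by fixed offsets.
    """
    config = config or PipelineConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if in_dir is not None:
        cases, labels = load_cohort(in_dir)
    else:
        phantom = phantom or PhantomParams()
        phantom = dataclasses.replace(
            phantom, seed=config.seed + _STAGE_SEED_OFFSET["cohort"])
        cases, labels = generate_cohort(
            phantom, out_dir=out / "cohort" if write_images else None)

    manifest = RunManifest(
        config={"pipeline": _asdict(config),
                "synthetic": _asdict(phantom) if phantom is not None else None},
        seed=config.seed, timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    issues = validate_cases(cases, labels)
    if issues:
        logger.warning("run_pipeline: %d validation issue(s)", len(issues))
    (out / "validation.json").write_text(json.dumps(issues, indent=2))
    manifest.add_output("validation", out / "validation.json")

    cases = [preprocess_case(c, config) for c in cases]
    included, volume_report = filter_cohort_by_volume(cases, config.voi_min_cc)
    volume_report.to_csv(out / "volume_filter.csv", index=False)
    manifest.add_output("volume_filter", out / "volume_filter.csv")
    manifest.counts.update(
        n_input=len(cases), n_included=len(included),
        n_excluded=len(cases) - len(included))
    if len(included) < 4:
        raise ValueError("fewer than 4 patients pass the volume filter")
    included_ids = [c.patient_id for c in included]
    labels = labels[labels["patient_id"].isin(included_ids)].reset_index(drop=True)

    # stability is assessed on a patient subset with both readers' masks
    rng = np.random.default_rng(config.seed + _STAGE_SEED_OFFSET["stability"])
    n_sub = min(config.stability_subset_size, len(included))
    subset_ids = sorted(rng.choice(included_ids, size=n_sub, replace=False).tolist())

    tables: dict[str, pd.DataFrame] = {}
    stability: dict[str, fs.StabilityReport] = {}
    redundancy: dict[str, fs.RedundancyResult] = {}
    for mod in MODALITIES:
        tab1 = extract_feature_table(included, mod, reader=1, config=config)
        tables[mod] = tab1
        tab1.to_csv(out / f"features_{mod}_reader1.csv")
        manifest.add_output(f"features_{mod}_reader1", out / f"features_{mod}_reader1.csv")
        tab2 = extract_feature_table(included, mod, reader=2, config=config,
                                     patient_ids=subset_ids)
        tab2.to_csv(out / f"features_{mod}_reader2.csv")
        manifest.add_output(f"features_{mod}_reader2", out / f"features_{mod}_reader2.csv")
        rep = fs.stability_rank([tab1.loc[subset_ids], tab2.loc[subset_ids]],
                                alpha=config.stability_alpha)
        stability[mod] = rep
        rep.table.to_csv(out / f"stability_{mod}.csv")
        manifest.add_output(f"stability_{mod}", out / f"stability_{mod}.csv")
        red = fs.redundancy_reduce(tab1, rep.stable_features, config.r_threshold)
        redundancy[mod] = red
        red.table.to_csv(out / f"redundancy_{mod}.csv", index=False)
        manifest.add_output(f"redundancy_{mod}", out / f"redundancy_{mod}.csv")
        manifest.counts[f"n_stable_{mod}"] = len(rep.stable_features)
        manifest.counts[f"n_nonredundant_{mod}"] = len(red.representatives)

    # clustering + association, per modality and joint
    associations: dict[str, dict[str, float]] = {}
    cluster_tables = {
        MOD_T2W: tables[MOD_T2W][redundancy[MOD_T2W].representatives],
        MOD_ADC: tables[MOD_ADC][redundancy[MOD_ADC].representatives],
        "joint": combined_table({
            m: tables[m][redundancy[m].representatives] for m in MODALITIES}),
    }
    for name, tab in cluster_tables.items():
        assignment = ca.hierarchical_two_groups(
            tab, linkage=config.linkage, skew_threshold=config.skew_threshold)
        assignment.groups.rename("group").to_csv(out / f"clusters_{name}.csv")
        manifest.add_output(f"clusters_{name}", out / f"clusters_{name}.csv")
        associations[name] = ca.associate(assignment, labels)
        if plots:
            ca.plot_heatmap(tab, assignment, labels, out / f"heatmap_{name}.png")
    (out / "associations.json").write_text(
        json.dumps({"schema": 1, "fisher_p": associations}, indent=2, sort_keys=True))
    manifest.add_output("associations", out / "associations.json")

    # signatures: redundancy is reduced *within* each modality's top-10
    # stable features, so the representatives always lie in the top-10
    top_redundancy = {
        mod: fs.redundancy_reduce(tables[mod],
                                  stability[mod].top_stable(config.top_k_stable),
                                  config.r_threshold)
        for mod in MODALITIES
    }
    specs = [
        se.build_signature(stability, top_redundancy, [MOD_T2W], "S_TOP-T2w",
                           config.top_k_stable),
        se.build_signature(stability, top_redundancy, [MOD_ADC], "S_TOP-ADC",
                           config.top_k_stable),
        se.build_signature(stability, top_redundancy, [MOD_T2W, MOD_ADC], "S_TOP",
                           config.top_k_stable),
        se.adc_mean_signature(),
        se.build_signature(stability, top_redundancy, [MOD_T2W, MOD_ADC],
                           "S_TOP+ADCmean", config.top_k_stable,
                           append_adc_mean=True),
    ]
    joint = combined_table(tables)
    report = se.run_all_signatures(
        joint, labels, specs, n_subsets=config.n_subsets, cv_folds=config.cv_folds,
        seed=config.seed + _STAGE_SEED_OFFSET["signatures"])
    report.to_csv(out / "signature_performance.csv", index=False)
    manifest.add_output("signature_performance", out / "signature_performance.csv")
    manifest.counts["n_signatures"] = len(specs)

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _asdict(obj) -> dict | None:
    if obj is None:
        return None
    d = dataclasses.asdict(obj)

    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    return clean(d)
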