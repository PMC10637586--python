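"""End-to-end orchestration: phantom generation -> preprocessing -> voxel
maps -> consensus k -> habitat maps -> radiomics -> selection -> SVM ->
evaluation, from one configuration mapping.

The configuration is a nested dict (typically loaded from YAML); every
defaulted value is echoed into the run report so a run is auditable and
replayable from (config, seed) alone.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import ConsensusKSelector, segment_patient
from .evaluate import (
    auc_ci_delong,
    calibration_curve,
    decision_curve,
    delong_paired_test,
    threshold_metrics,
    train_svm,
)
from .phantom import CohortSpec, PatientCase, PhantomSpec, generate_cohort
from .preprocess import Volume, load_case, normalize_grayscale, resample
from .radiomics import ExtractionConfig, extract_cohort
from .selection import select_features
from .voxel_maps import EntropyConfig, VoxelScaler, build_voxel_table, entropy_map

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "analyze_cases", "stats_report"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": None,
    "input_dir": None,  # read an existing cohort tree instead of generating
    "synthetic": {
        "cohort": {},  # CohortSpec field overrides
        "phantom": {},  # PhantomSpec field overrides
    },
    "preprocess": {"target_spacing": [1.0, 1.0, 3.0], "normalize_range": [0.0, 255.0]},
    "entropy": {"window_radius": 2, "n_bins": 32, "epsilon": 1e-12},
    "habitat": {
        "k_range": [2, 10],
        "reps": 1000,
        "item_fraction": 0.8,
        "delta_area_threshold": 0.05,
        "max_items": 5000,
        "voxels_per_patient": 2000,
        "k_fixed": None,  # skip consensus selection when set
    },
    "radiomics": {
        "bin_width": 25.0,
        "log_sigmas": [1.0, 2.0, 3.0],
        "wavelet": "coif1",
        "families": ["firstorder", "shape", "glcm", "glrlm", "glszm", "ngtdm", "gldm"],
        "filters": ["original", "log", "wavelet"],
        "min_region_voxels": 10,
    },
    "selection": {
        "use_icc": True,
        "icc_threshold": 0.75,
        "icc_subset": 30,
        "pearson_threshold": 0.9,
        "n_folds": 5,
    },
    "model": {"n_folds": 5},
    "evaluation": {"calibration_bins": 10, "dca_grid": [0.01, 0.99, 0.01]},
}

_REQUIRED = {("habitat", "k_range"), ("seed",)}


def validate_config(user: Mapping) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys.

    Returns the fully-expanded config (every defaulted value made
    explicit). Raises ``KeyError`` naming any unknown or missing required
    key.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    import dataclasses

    spec_fields = {
        "synthetic.cohort": {f.name for f in dataclasses.fields(CohortSpec)},
        "synthetic.phantom": {f.name for f in dataclasses.fields(PhantomSpec)},
    }

    def merge(dst: dict, src: Mapping, path: str) -> None:
        if path in spec_fields:
            # free-form spec overrides, validated against the dataclass fields
            for key in src:
                if key not in spec_fields[path]:
                    raise KeyError(f"unknown config key: {path}.{key}")
            dst.update(src)
            return
        for key, value in src.items():
            where = f"{path}.{key}" if path else str(key)
            if key not in dst:
                raise KeyError(f"unknown config key: {where}")
            if isinstance(dst[key], dict) and isinstance(value, Mapping):
                merge(dst[key], value, where)
            else:
                dst[key] = value

    merge(cfg, user, "")
    for keypath in _REQUIRED:
        node: object = user
        for part in keypath:
            if not isinstance(node, Mapping) or part not in node:
                raise KeyError(f"missing required config key: {'.'.join(keypath)}")
            node = node[part]
    lo, hi = cfg["habitat"]["k_range"]
    if not (2 <= lo <= hi):
        raise ValueError(f"invalid habitat.k_range: {cfg['habitat']['k_range']}")
    return cfg


def _config_hash(cfg: Mapping) -> str:
    # hash the analysis-relevant configuration only: where the artifacts are
    # written must not change the identity of the run
    content = {k: v for k, v in cfg.items() if k not in ("outdir", "input_dir")}
    return hashlib.sha256(
        json.dumps(content, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_cohort_tree(input_dir: Path, target_spacing) -> list[PatientCase]:
    """Read a generated cohort file tree back into PatientCase objects."""
    clinical = pd.read_csv(input_dir / "clinical.csv")
    cases = []
    for _, row in clinical.iterrows():
        pdir = input_dir / str(row["patient_id"])
        img, mask = load_case(pdir / "img.nii.gz", pdir / "mask_r1.nii.gz")
        img, mask = resample(img, mask, target_spacing)
        _, mask_r2 = load_case(pdir / "img.nii.gz", pdir / "mask_r2.nii.gz")
        truth_path = pdir / "truth.nii.gz"
        truth = None
        if truth_path.exists():
            _, truth_vol = load_case(pdir / "img.nii.gz", truth_path)
            truth = truth_vol.data
        cases.append(
            PatientCase(
                patient_id=str(row["patient_id"]),
                cohort=str(row["cohort"]),
                label=int(row["label"]),
                volume=img.data,
                mask=mask.data,
                mask_r2=mask_r2.data,
                truth=truth if truth is not None else np.zeros_like(mask.data),
                spacing=img.spacing,
            )
        )
    return cases


def analyze_cases(cases: Sequence[PatientCase], cfg: Mapping, seed: int) -> dict:
    """Run the analysis stages on in-memory cases; returns the run report.

    Stage order: normalise grayscale -> entropy maps -> voxel tables ->
    cohort consensus k (training voxels only) -> per-patient habitat maps
    -> per-region radiomics -> ICC/Pearson/LASSO funnel -> SVM -> paired
    evaluation against the whole-tumour model.
    """
    rng = np.random.default_rng(seed)
    ecfg = EntropyConfig(
        window_radius=cfg["entropy"]["window_radius"],
        n_bins=cfg["entropy"]["n_bins"],
        epsilon=cfg["entropy"]["epsilon"],
    )
    norm_range = tuple(cfg["preprocess"]["normalize_range"])

    # ---- per-patient voxel features
    volumes: dict[str, Volume] = {}
    masks: dict[str, Volume] = {}
    tables: dict[str, pd.DataFrame] = {}
    for case in cases:
        vol = Volume(case.volume, case.spacing)
        mask = Volume(case.mask, case.spacing)
        vol = normalize_grayscale(vol, mask, norm_range)
        ent = entropy_map(vol, mask, ecfg)
        tables[case.patient_id] = build_voxel_table(vol, ent, mask, case.patient_id)
        volumes[case.patient_id] = vol
        masks[case.patient_id] = mask

    train_ids = [c.patient_id for c in cases if c.cohort == "train"]
    test_ids = [c.patient_id for c in cases if c.cohort == "test"]

    # ---- cohort-level scaler and consensus k on pooled training voxels
    per_patient = int(cfg["habitat"]["voxels_per_patient"])
    pooled_parts = []
    for pid in train_ids:
        t = tables[pid]
        if len(t) > per_patient:
            t = t.iloc[rng.choice(len(t), per_patient, replace=False)]
        pooled_parts.append(t)
    pooled = pd.concat(pooled_parts, ignore_index=True)
    scaler = VoxelScaler().fit(pooled)

    if cfg["habitat"]["k_fixed"] is not None:
        k_star = int(cfg["habitat"]["k_fixed"])
        consensus = None
    else:
        selector = ConsensusKSelector(
            k_range=tuple(cfg["habitat"]["k_range"]),
            n_reps=int(cfg["habitat"]["reps"]),
            item_fraction=float(cfg["habitat"]["item_fraction"]),
            delta_area_threshold=float(cfg["habitat"]["delta_area_threshold"]),
            max_items=int(cfg["habitat"]["max_items"]),
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        selector.fit(scaler.transform(pooled))
        k_star = selector.k_
        consensus = {
            "areas": selector.areas_,
            "delta_areas": selector.delta_areas_,
            "k_star": k_star,
        }

    # ---- per-patient segmentation at k*
    habitat_maps = {}
    excluded = []
    for case in cases:
        try:
            habitat_maps[case.patient_id] = segment_patient(
                tables[case.patient_id],
                masks[case.patient_id],
                k_star,
                scaler,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        except ValueError as exc:
            logger.warning("patient %s excluded from segmentation: %s", case.patient_id, exc)
            excluded.append(case.patient_id)
    cases = [c for c in cases if c.patient_id not in excluded]

    # ---- radiomics per region
    xcfg = ExtractionConfig(
        bin_width=float(cfg["radiomics"]["bin_width"]),
        log_sigmas=tuple(cfg["radiomics"]["log_sigmas"]),
        wavelet=cfg["radiomics"]["wavelet"],
        families=tuple(cfg["radiomics"]["families"]),
        filters=tuple(cfg["radiomics"]["filters"]),
        min_region_voxels=int(cfg["radiomics"]["min_region_voxels"]),
    )
    matrices = extract_cohort(cases, habitat_maps, xcfg, volumes=volumes, masks=masks)

    # ---- optional ICC stage: re-run maps + extraction with reader-2 masks
    icc_matrices = None
    if cfg["selection"]["use_icc"]:
        subset = train_ids[: int(cfg["selection"]["icc_subset"])]
        sub_cases = [c for c in cases if c.patient_id in subset]
        r2_tables, r2_masks, r2_maps = {}, {}, {}
        for case in sub_cases:
            vol = Volume(case.volume, case.spacing)
            m2 = Volume(case.mask_r2, case.spacing)
            vol2 = normalize_grayscale(vol, m2, norm_range)
            ent2 = entropy_map(vol2, m2, ecfg)
            r2_tables[case.patient_id] = build_voxel_table(vol2, ent2, m2, case.patient_id)
            r2_masks[case.patient_id] = m2
        r2_volumes = {}
        for case in sub_cases:
            vol = Volume(case.volume, case.spacing)
            r2_volumes[case.patient_id] = normalize_grayscale(
                vol, r2_masks[case.patient_id], norm_range
            )
        for case in sub_cases:
            r2_maps[case.patient_id] = segment_patient(
                r2_tables[case.patient_id],
                r2_masks[case.patient_id],
                k_star,
                scaler,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        icc_matrices = extract_cohort(
            sub_cases, r2_maps, xcfg, volumes=r2_volumes, masks=r2_masks
        )

    # ---- selection + model + evaluation per region
    labels = {c.patient_id: c.label for c in cases}
    y_train = np.array([labels[p] for p in train_ids if p in labels])
    y_test = np.array([labels[p] for p in test_ids if p in labels])
    regions = list(matrices)
    region_scores: dict[str, dict[str, np.ndarray]] = {}
    report_models: dict[str, dict] = {}
    svm_seed = int(rng.integers(0, 2**31 - 1))
    sel_seed = int(rng.integers(0, 2**31 - 1))

    for region in regions:
        mat = matrices[region].dropna(axis=1)
        train_mat = mat.loc[[p for p in train_ids if p in mat.index]]
        test_mat = mat.loc[[p for p in test_ids if p in mat.index]]
        r2_mat = None
        if icc_matrices is not None and region in icc_matrices:
            r2 = icc_matrices[region].dropna(axis=1)
            shared = [c for c in train_mat.columns if c in r2.columns]
            r2_mat = r2[shared]
            train_mat = train_mat[shared]
            test_mat = test_mat[shared]
        try:
            train_z, test_z, sel_report = select_features(
                train_mat,
                np.array([labels[p] for p in train_mat.index]),
                test=test_mat,
                train_r2=r2_mat,
                icc_threshold=float(cfg["selection"]["icc_threshold"]),
                pearson_threshold=float(cfg["selection"]["pearson_threshold"]),
                n_folds=int(cfg["selection"]["n_folds"]),
                seed=sel_seed,
            )
        except ValueError as exc:
            logger.warning("region %s: selection failed (%s); skipped", region, exc)
            continue
        if train_z.shape[1] == 0:
            # all-zero LASSO support (no signal at the chosen penalty):
            # fall back to the Pearson survivor set so the SVM still trains
            logger.warning("region %s: empty LASSO support; using Pearson survivors", region)
            from .selection import zscore_fit_apply

            train_z, test_z, _ = zscore_fit_apply(
                train_mat[sel_report.survivors_pearson],
                test_mat[sel_report.survivors_pearson] if test_mat is not None else None,
            )
        svm = train_svm(train_z, np.array([labels[p] for p in train_mat.index]), seed=svm_seed)
        s_train = svm.decision_scores(train_z)
        s_test = svm.decision_scores(test_z) if test_z is not None and len(test_z) else None
        region_scores[region] = {"train": s_train, "test": s_test}

        auc_tr, ci_tr = auc_ci_delong(s_train, y_train)
        entry = {
            "n_features": {
                "extracted": int(matrices[region].shape[1]),
                **sel_report.stage_counts(),
            },
            "svm_params": svm.best_params_,
            "threshold": svm.threshold_,
            "train": {
                "auc": auc_tr,
                "ci": ci_tr,
                **threshold_metrics(s_train, y_train, svm.threshold_),
            },
        }
        if s_test is not None and len(np.unique(y_test)) == 2:
            auc_te, ci_te = auc_ci_delong(s_test, y_test)
            entry["test"] = {
                "auc": auc_te,
                "ci": ci_te,
                **threshold_metrics(s_test, y_test, svm.threshold_),
            }
            entry["test"]["calibration"] = calibration_curve(
                s_test, y_test, n_bins=int(cfg["evaluation"]["calibration_bins"])
            )
            lo, hi, step = cfg["evaluation"]["dca_grid"]
            entry["test"]["decision_curve"] = decision_curve(
                s_test, y_test, thresholds=np.arange(lo, hi + 1e-12, step)
            ).to_dict(orient="list")
        report_models[region] = entry

    # paired DeLong comparisons against the whole-tumour reference
    if "whole" in region_scores:
        for region in regions:
            if region == "whole" or region not in region_scores:
                continue
            for split, y in (("train", y_train), ("test", y_test)):
                s_r = region_scores[region][split]
                s_w = region_scores["whole"][split]
                if s_r is None or s_w is None or len(np.unique(y)) < 2:
                    continue
                report_models[region].setdefault("delong_vs_whole", {})[split] = (
                    delong_paired_test(s_r, s_w, y)
                )

    return {
        "seed": seed,
        "k_star": k_star,
        "consensus": consensus,
        "n_patients": {"train": len(train_ids), "test": len(test_ids)},
        "excluded_patients": excluded,
        "models": report_models,
    }


def run_pipeline(user_config: Mapping) -> dict:
    """Validate the config, obtain the cohort, run all stages, emit a report.

    Returns the report dict; writes ``report.json`` (and the generated
    cohort tree) under ``outdir`` when one is configured.
    """
    cfg = validate_config(user_config)
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"]) if cfg["outdir"] else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    if cfg["input_dir"]:
        cases = _load_cohort_tree(
            Path(cfg["input_dir"]), tuple(cfg["preprocess"]["target_spacing"])
        )
    else:
        cohort_spec = CohortSpec(**{"seed": seed, **cfg["synthetic"]["cohort"]})
        phantom_over = dict(cfg["synthetic"]["phantom"])
        for key in ("grid_shape", "voxel_spacing", "tumour_axes", "habitat_fractions",
                    "habitat_intensity_means", "habitat_intensity_sds", "habitat_smoothness"):
            if key in phantom_over:
                phantom_over[key] = tuple(phantom_over[key])
        phantom_spec = PhantomSpec(**phantom_over)
        cases = generate_cohort(
            cohort_spec, phantom_spec, out_dir=outdir / "cohort" if outdir else None
        )

    report = analyze_cases(cases, cfg, seed)
    report["config"] = cfg
    report["config_hash"] = _config_hash(cfg)
    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonify)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return str(obj)


def stats_report(
    categorical: Mapping[str, np.ndarray] | None = None,
    continuous: Mapping[str, tuple] | None = None,
) -> pd.DataFrame:
    """Characteristics-table battery: chi-square (Yates on 2x2) or Fisher
    recommendation for categorical variables, pooled-variance t from
    summaries for continuous ones.

    Defaults to the bundled two-centre cervical-cancer training cohort.
    Returns a tidy table (variable, test, statistic, p).
    """
    from . import clinical, datasets

    if categorical is None and continuous is None:
        categorical = datasets.table1_categorical("train")
        continuous = datasets.table1_continuous("train")
    rows = []
    for name, table in (categorical or {}).items():
        table = np.asarray(table)
        expected = clinical.expected_counts(table)
        fisher_advised = bool((expected < 5).any()) and table.shape == (2, 2)
        if table.shape == (2, 2):
            stat, p = clinical.chisq_2x2(table)
            test = "chi-square (Yates)"
            if fisher_advised:
                p = clinical.fisher_exact_2x2(table)
                test = "Fisher exact"
                stat = np.nan
        else:
            stat, _, p = clinical.chisq_rxc(table)
            test = "chi-square"
        rows.append({"variable": name, "test": test, "statistic": stat, "p": p})
    for name, groups in (continuous or {}).items():
        (m1, s1, n1), (m2, s2, n2) = groups
        t, df, p = clinical.two_sample_t_from_stats(m1, s1, n1, m2, s2, n2)
        rows.append({"variable": name, "test": "t (pooled)", "statistic": t, "p": p})
    return pd.DataFrame(rows)
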