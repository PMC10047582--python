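"""End-to-end orchestration: simulate -> extract -> train -> predict -> evaluate.

All randomness flows from one root seed, expanded deterministically per stage,
so a run is reproducible from its config alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import (aggregate_cohort, sector_metrics, sector_partition,
                         voxel_metrics)
from .features import VoxelFeatureExtractor
from .io import MaskVolume
from .labeling import derive_labels
from .phantom import CaseBundle, PhantomSpec, generate_cohort, load_case, save_case
from .postprocess import (CorrectionConfig, ProbabilityMap, distance_correction,
                          distance_from_cavity, predicted_labels,
                          probability_map_from_scores, write_case_outputs)
from .training import ALGORITHMS, RecurrenceVoxelClassifier, save_model

log = logging.getLogger("perirec")


@dataclass
class RunConfig:
    """Serializable description of one full run."""

    schema_version: int = 1
    n_train: int = 4
    n_test: int = 2
    phantom: dict = field(default_factory=dict)        # PhantomSpec overrides
    features: dict = field(default_factory=dict)       # VoxelFeatureExtractor params
    algorithm: str = "lightgbm"
    algorithms: tuple[str, ...] | None = None          # for evaluate-all
    correction: dict = field(default_factory=dict)     # CorrectionConfig overrides
    activation_fraction: float = 0.05
    score_percentile: float = 95.0
    seed: int = 0
    out_dir: str = "perirec_run"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def make_extractor(self) -> VoxelFeatureExtractor:
        kw = dict(self.features)
        for key in ("filters", "families", "log_sigmas_mm"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return VoxelFeatureExtractor(**kw)

    def make_spec(self, seed: int | None = None) -> PhantomSpec:
        kw = dict(self.phantom)
        for key in ("grid_shape", "spacing_mm"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if seed is not None:
            kw["seed"] = seed
        return PhantomSpec(**kw)

    def make_correction(self) -> CorrectionConfig:
        return CorrectionConfig(**self.correction)


def _stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31.

    Uses a stable digest of the stage name (Python's ``hash`` is salted per
    process and would break cross-invocation reproducibility).
    """
    import zlib

    ss = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_cohort(config: RunConfig) -> tuple[list[CaseBundle], list[CaseBundle]]:
    t0 = time.time()
    train, test = generate_cohort(config.n_train, config.n_test, config.make_spec(),
                                  seed=_stage_seed(config.seed, "simulate"))
    log.info("simulate: %d train + %d test cases in %.1fs",
             len(train), len(test), time.time() - t0)
    return train, test


def extract_features(cases: list[CaseBundle],
                     extractor: VoxelFeatureExtractor) -> pd.DataFrame:
    """Voxel x feature table with labels for a list of cases."""
    t0 = time.time()
    parts = [extractor.transform(case) for case in cases]
    df = pd.concat(parts, axis=0)
    log.info("extract: %d rows x %d features in %.1fs",
             len(df), len(extractor.manifest_), time.time() - t0)
    return df


def extract_balanced_training_features(cases: list[CaseBundle],
                                        extractor: VoxelFeatureExtractor,
                                        seed: int) -> pd.DataFrame:
    """Undersample, then extract: labels come from the masks alone, so the
    majority voxels dropped by pooled undersampling never pay feature cost.

    The retained row set is identical to undersampling a full pooled feature
    table with the same seed (all minority voxels plus a uniform majority
    subset of the same size, pooled over the training cases).
    """
    from .training import undersample

    t0 = time.time()
    labels = []
    for case in cases:
        lab = derive_labels(case.peritumor_mask, case.followup_enhancing_mask)
        labels.append(lab.labels_at(case.peritumor_mask.indices))
    offsets = np.cumsum([0] + [len(y) for y in labels])
    pooled = np.concatenate(labels)
    keep = undersample(pooled, seed=seed)
    parts = []
    for i, case in enumerate(cases):
        local = keep[(keep >= offsets[i]) & (keep < offsets[i + 1])] - offsets[i]
        if local.size == 0:
            continue
        idx = case.peritumor_mask.indices[local]
        parts.append(extractor.transform(case, indices=idx))
    df = pd.concat(parts, axis=0)
    log.info("extract(balanced): %d of %d pooled voxels in %.1fs",
             len(df), len(pooled), time.time() - t0)
    return df


def fit_model(features: pd.DataFrame, config: RunConfig,
              algorithm: str | None = None) -> RecurrenceVoxelClassifier:
    algorithm = algorithm or config.algorithm
    cols = [c for c in features.columns if c not in ("label", "qc_small_kernel")]
    clf = RecurrenceVoxelClassifier(algorithm=algorithm,
                                    random_state=_stage_seed(config.seed, "train"))
    t0 = time.time()
    clf.fit(features[cols], features["label"].to_numpy())
    log.info("train[%s]: %s -> %s rows in %.1fs", algorithm,
             clf.n_before_, clf.n_after_, time.time() - t0)
    return clf


def predict_case(clf: RecurrenceVoxelClassifier, bundle: CaseBundle,
                 extractor: VoxelFeatureExtractor,
                 correction: CorrectionConfig | None = None,
                 features: pd.DataFrame | None = None) -> dict:
    """Raw map, corrected map, Otsu-thresholded labels and threshold for one case."""
    if bundle.peritumor_mask.n_voxels == 0:
        raise ValueError(f"case {bundle.case_id!r}: empty peritumor")
    correction = correction or CorrectionConfig()
    if features is None:
        features = extractor.transform(bundle)
    cols = clf.feature_names_
    scores = clf.recurrence_probability(features[cols])
    raw = probability_map_from_scores(scores, bundle.peritumor_mask, stage="raw")
    dist = distance_from_cavity(bundle.cavity_mask)
    corrected = distance_correction(raw, dist, correction)
    labels, theta = predicted_labels(corrected)
    return {"raw": raw, "corrected": corrected, "labels": labels, "theta": theta}


def evaluate_case(bundle: CaseBundle, prediction: dict,
                  activation_fraction: float = 0.05,
                  score_percentile: float = 95.0) -> dict[str, dict]:
    """Voxel- and sector-mode metrics for one predicted case."""
    truth = derive_labels(bundle.peritumor_mask, bundle.followup_enhancing_mask)
    corrected: ProbabilityMap = prediction["corrected"]
    vm = voxel_metrics(corrected.scores, prediction["labels"], truth)
    partition = sector_partition(bundle.peritumor_mask, bundle.cavity_mask)
    truth_mask = MaskVolume(data=(truth.data == 1).astype(np.uint8),
                            affine=truth.affine.copy())
    sm = sector_metrics(partition, truth_mask, prediction["labels"], corrected,
                        activation_fraction=activation_fraction,
                        score_percentile=score_percentile)
    return {"voxel": vm, "sector": sm}


def evaluate_cohort(train_cases: list[CaseBundle], test_cases: list[CaseBundle],
                    config: RunConfig,
                    algorithms: tuple[str, ...] | None = None) -> dict:
    """Train each requested backend and score it on the held-out cases.

    Returns per-case metrics and a cohort summary table with one
    (algorithm, mode) block per backend and evaluation mode — the structure of
    a mean ± SD results table over voxel- and region-based modes.
    """
    algorithms = algorithms or config.algorithms or (config.algorithm,)
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithms: {sorted(unknown)}")
    if not test_cases:
        raise ValueError("empty test cohort")
    extractor = config.make_extractor().fit()
    correction = config.make_correction()
    train_feats = extract_balanced_training_features(
        train_cases, extractor, seed=_stage_seed(config.seed, "undersample"))
    test_feats = {c.case_id: extractor.transform(c) for c in test_cases}

    summaries, per_case_rows, models = [], [], {}
    for algorithm in algorithms:
        clf = fit_model(train_feats, config, algorithm=algorithm)
        models[algorithm] = clf
        per_mode: dict[str, list] = {"voxel": [], "sector": []}
        for case in test_cases:
            pred = predict_case(clf, case, extractor, correction,
                                features=test_feats[case.case_id])
            metrics = evaluate_case(case, pred,
                                    activation_fraction=config.activation_fraction,
                                    score_percentile=config.score_percentile)
            for mode in ("voxel", "sector"):
                per_mode[mode].append(metrics[mode])
                per_case_rows.append({"algorithm": algorithm, "mode": mode,
                                      "case_id": case.case_id, **metrics[mode]})
        for mode in ("voxel", "sector"):
            summaries.append(aggregate_cohort(per_mode[mode], mode=mode,
                                              algorithm=algorithm))
    return {"summary": pd.concat(summaries, ignore_index=True),
            "per_case": pd.DataFrame(per_case_rows),
            "models": models}


# --------------------------------------------------------------- file-based

def run_simulate(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    train, test = simulate_cohort(config)
    for split, cases in (("train", train), ("test", test)):
        for case in cases:
            save_case(case, out / "cohort" / split)
    config.to_file(out / "run_config.json")
    return out / "cohort"


def _load_split(config: RunConfig, split: str) -> list[CaseBundle]:
    root = Path(config.out_dir) / "cohort" / split
    if not root.exists():
        raise FileNotFoundError(f"no {split} cohort under {root}; run simulate first")
    return [load_case(d) for d in sorted(root.iterdir()) if d.is_dir()]


def run_extract(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    extractor = config.make_extractor().fit()
    for split in ("train", "test"):
        df = extract_features(_load_split(config, split), extractor)
        df.to_parquet(out / f"features_{split}.parquet")
    (out / "feature_manifest.json").write_text(
        json.dumps({"n_features": extractor.n_features_,
                    "columns": extractor.manifest_}, indent=2))
    return out


def run_train(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    path = out / "features_train.parquet"
    if not path.exists():
        run_extract(config)
    feats = pd.read_parquet(path)
    clf = fit_model(feats, config)
    model_dir = save_model(clf, out / f"model_{config.algorithm}")
    report = {"algorithm": config.algorithm, "before_balancing": clf.n_before_,
              "after_balancing": clf.n_after_}
    (out / f"model_{config.algorithm}" / "balancing.json").write_text(
        json.dumps(report, indent=2))
    return model_dir


def run_predict(config: RunConfig) -> Path:
    from .training import load_model

    out = Path(config.out_dir)
    clf = load_model(out / f"model_{config.algorithm}")
    extractor = config.make_extractor().fit()
    correction = config.make_correction()
    pred_dir = out / "predictions" / config.algorithm
    for case in _load_split(config, "test"):
        pred = predict_case(clf, case, extractor, correction)
        write_case_outputs(pred_dir / case.case_id, pred["raw"], pred["corrected"],
                           pred["labels"], pred["theta"], correction)
    return pred_dir


def run_evaluate(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    train = _load_split(config, "train")
    test = _load_split(config, "test")
    result = evaluate_cohort(train, test, config)
    result["per_case"].to_csv(out / "metrics_per_case.csv", index=False)
    result["summary"].to_csv(out / "metrics_summary.csv", index=False)
    cohort = {
        f"{row.algorithm}/{row['mode']}/{row.metric}": row.formatted
        for _, row in result["summary"].iterrows()
    }
    (out / "metrics_summary.json").write_text(json.dumps(cohort, indent=2))
    return out


def run_all(config: RunConfig) -> Path:
    run_simulate(config)
    run_extract(config)
    run_train(config)
    run_predict(config)
    return run_evaluate(config)
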