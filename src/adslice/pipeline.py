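"""Evaluation protocol: split, cross-validate, ensemble, repeat.

For each trial the dataset is split 80/20 per class into development and
test sets; stratified fivefold cross-validation on the development set
yields five trained slice classifiers; a subject's prediction is the mean
over the five fold models of the mean per-slice AD probability; the
ensemble is evaluated on the held-out test split (within-dataset) and,
unchanged, on the entirety of a second dataset (between-dataset).  Trials
repeat with derived seeds and are aggregated as mean and sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import metrics as mx
from .augment import AugmentConfig
from .model import (
    ClassifierConfig,
    FoldModel,
    SubjectSlices,
    TrainConfig,
    prepare_subject,
    train_fold,
)

__all__ = [
    "DatasetSplit",
    "EnsembleModel",
    "TrialResult",
    "ExperimentConfig",
    "split_dev_test",
    "stratified_kfold",
    "predict_subject",
    "run_trial",
    "run_experiment",
    "prepare_phantom_dataset",
    "run_phantom_experiment",
]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    development_ids: dict  # label -> list of subject_ids
    test_ids: dict
    trial_seed: int

    def all_development(self) -> list:
        return [sid for ids in self.development_ids.values() for sid in ids]

    def all_test(self) -> list:
        return [sid for ids in self.test_ids.values() for sid in ids]


def split_dev_test(subjects, dev_fraction: float, seed: int) -> DatasetSplit:
    """Per-class random development/test split (development count floored)."""
    if not 0.0 < dev_fraction < 1.0:
        raise ValueError("dev_fraction must lie strictly between 0 and 1")
    by_label: dict = {}
    for s in subjects:
        by_label.setdefault(int(s.label), []).append(s.subject_id)
    if len(by_label) != 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    dev, test = {}, {}
    for label in sorted(by_label):
        ids = sorted(by_label[label])
        if len(ids) < 2:
            raise ValueError("each class needs at least 2 subjects")
        perm = rng.permutation(len(ids))
        n_dev = int(np.floor(dev_fraction * len(ids)))
        if n_dev == 0 or n_dev == len(ids):
            raise ValueError("split leaves an empty development or test set")
        dev[label] = sorted(ids[i] for i in perm[:n_dev])
        test[label] = sorted(ids[i] for i in perm[n_dev:])
    return DatasetSplit(development_ids=dev, test_ids=test, trial_seed=seed)


def stratified_kfold(development: list, k: int, seed: int) -> list[tuple[list, list]]:
    """Class-balanced k-fold partition of development subjects.

    Returns k (train_ids, val_ids) pairs whose validation sets partition the
    development set with per-class counts differing by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    subjects = sorted(development, key=lambda s: s.subject_id)
    labels = np.array([s.label for s in subjects])
    for label in np.unique(labels):
        if (labels == label).sum() < k:
            raise ValueError("each class needs at least k subjects")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32 - 1))
    folds = []
    ids = np.array([s.subject_id for s in subjects])
    for train_idx, val_idx in skf.split(ids, labels):
        folds.append((sorted(ids[train_idx]), sorted(ids[val_idx])))
    return folds


# ---------------------------------------------------------------------------
# ensembling
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """The k fold models of one trial; predictions are fold-averaged."""

    fold_models: list[FoldModel]

    def __post_init__(self) -> None:
        if any(m is None for m in self.fold_models):
            raise ValueError("missing fold model in ensemble")

    @property
    def k(self) -> int:
        return len(self.fold_models)


def predict_subject(ensemble: EnsembleModel, subject: SubjectSlices) -> float:
    """Mean over fold models of the slice-averaged AD probability."""
    fold_means = [
        m.classifier.predict_subject_prob(subject) for m in ensemble.fold_models
    ]
    return float(np.mean(fold_means))


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    dev_fraction: float = 0.8
    k_folds: int = 5
    n_trials: int = 5
    master_seed: int = 0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    ci_level: float = 0.95


@dataclass
class TrialResult:
    trial_index: int
    trial_seed: int
    within: dict
    between: dict | None
    split: DatasetSplit
    predictions: dict


def _evaluate(ensemble, subjects, ci_level):
    scores = np.array([predict_subject(ensemble, s) for s in subjects])
    labels = np.array([s.label for s in subjects])
    result = mx.evaluate_scores(scores, labels, ci_level)
    preds = [
        {"subject_id": s.subject_id, "label": int(s.label), "probability": float(p)}
        for s, p in zip(subjects, scores)
    ]
    return result, preds


def run_trial(
    dataset_a: list[SubjectSlices],
    dataset_b: list[SubjectSlices] | None,
    config: ExperimentConfig,
    trial_seed: int,
    trial_index: int = 0,
) -> TrialResult:
    """One split + fivefold-ensemble training + within/between evaluation."""
    by_id = {s.subject_id: s for s in dataset_a}
    split = split_dev_test(dataset_a, config.dev_fraction, trial_seed)
    dev_subjects = [by_id[sid] for sid in split.all_development()]
    folds = stratified_kfold(dev_subjects, config.k_folds, trial_seed)

    fold_models = []
    for fold_index, (train_ids, val_ids) in enumerate(folds):
        rng = np.random.default_rng((trial_seed, fold_index))
        fm = train_fold(
            [by_id[sid] for sid in train_ids],
            [by_id[sid] for sid in val_ids],
            config.classifier,
            config.train,
            aug_config=config.augment,
            rng=rng,
        )
        fm.fold_index = fold_index
        fold_models.append(fm)
    ensemble = EnsembleModel(fold_models=fold_models)

    test_subjects = [by_id[sid] for sid in split.all_test()]
    within, within_preds = _evaluate(ensemble, test_subjects, config.ci_level)
    between, between_preds = (None, None)
    if dataset_b is not None:
        between, between_preds = _evaluate(ensemble, dataset_b, config.ci_level)

    return TrialResult(
        trial_index=trial_index,
        trial_seed=trial_seed,
        within=within,
        between=between,
        split=split,
        predictions={"within": within_preds, "between": between_preds},
    )


_METRICS = ("auc", "accuracy", "sensitivity", "specificity")


def _summarize_trials(trials: list[dict]) -> dict:
    out = {}
    for m in _METRICS:
        mean, sd = mx.trial_summary([t[m] for t in trials])
        out[m] = {"mean": mean, "sd": sd}
    return out


def run_experiment(
    dataset_a: list[SubjectSlices],
    dataset_b: list[SubjectSlices] | None,
    config: ExperimentConfig,
    n_trials: int | None = None,
) -> dict:
    """Repeated trials with derived seeds, aggregated Tables-style report.

    Trial seeds are ``master_seed + trial_index`` so the whole five-trial
    table reproduces from one seed.  When a second dataset is given, each
    trial's ensemble is additionally evaluated, unchanged, on all of it, and
    paired t-tests compare within- vs between-dataset metrics across trials.
    """
    n_trials = config.n_trials if n_trials is None else n_trials
    if n_trials < 2:
        raise ValueError("need at least two trials to aggregate")

    trials = [
        run_trial(dataset_a, dataset_b, config, config.master_seed + i, trial_index=i)
        for i in range(n_trials)
    ]

    report: dict = {
        "n_trials": n_trials,
        "master_seed": config.master_seed,
        "trials": [
            {
                "trial": t.trial_index + 1,
                "seed": t.trial_seed,
                "within": t.within,
                "between": t.between,
            }
            for t in trials
        ],
        "summary": {"within": _summarize_trials([t.within for t in trials])},
        "predictions": [t.predictions for t in trials],
    }
    if dataset_b is not None:
        report["summary"]["between"] = _summarize_trials([t.between for t in trials])
        comparisons = {}
        for m in _METRICS:
            within_vals = [t.within[m] for t in trials]
            between_vals = [t.between[m] for t in trials]
            try:
                ts = mx.paired_ttest(within_vals, between_vals)
                comparisons[m] = {"t": ts.statistic, "p": ts.p_value, "df": ts.df}
            except ValueError:
                comparisons[m] = {"t": None, "p": None, "df": len(trials) - 1}
        report["comparisons"] = {"within_vs_between_paired_t": comparisons}
    return report


# ---------------------------------------------------------------------------
# phantom end-to-end driver
# ---------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    n_slices: int = 30
    slice_direction: str = "posterior_to_anterior"
    n_template_subjects: int = 8


def prepare_phantom_dataset(
    spec,
    n_ad: int,
    n_cn: int,
    template,
    pconfig: PreprocessConfig,
    input_px: int,
    seed: int,
) -> list[SubjectSlices]:
    """Generate, align and slice a phantom cohort into classifier-ready form."""
    from .phantom import iter_cohort
    from .preprocess import FAST_STEP1, FAST_STEP2, extract_coronal_slices, two_step_align

    records = []
    for volume, subject in iter_cohort(spec, n_ad, n_cn, seed):
        aligned = two_step_align(
            volume, template, settings_step1=FAST_STEP1, settings_step2=FAST_STEP2
        ).aligned
        stack = extract_coronal_slices(
            aligned,
            template,
            n_slices=pconfig.n_slices,
            direction=pconfig.slice_direction,
            subject_ref=subject.subject_id,
        )
        records.append(prepare_subject(stack, subject, input_px))
    return records


def build_phantom_template(spec, pconfig: PreprocessConfig, seed: int):
    """Template from a dedicated small CN phantom cohort.

    Template subjects are generated without misalignment — the reference
    population stands in for scans that were already co-registered when the
    template was constructed — so the template frame is the canonical one
    and the geometry-derived anchor index applies exactly.
    """
    from dataclasses import replace

    from .phantom import build_template, generate_volume, _subject_plan

    tspec = replace(spec, misalign_rot_deg_max=0.0, misalign_trans_mm_max=0.0)
    n = pconfig.n_template_subjects
    plan, rng = _subject_plan(tspec, 1, n, seed)
    cn_vols = [
        generate_volume(tspec, params, rng)[0]
        for params in plan
        if params["diagnosis"] == "CN"
    ]
    return build_template(cn_vols, geometry=tspec.geometry)


def run_phantom_experiment(
    spec,
    n_ad: int,
    n_cn: int,
    config: ExperimentConfig,
    pconfig: PreprocessConfig | None = None,
    spec_b=None,
    n_ad_b: int | None = None,
    n_cn_b: int | None = None,
) -> dict:
    """Full pipeline on synthetic cohorts: generate, align, train, evaluate.

    A second cohort (``spec_b``) enables the between-dataset arm; it is
    preprocessed with the first cohort's template so slice indices agree.
    """
    pconfig = pconfig or PreprocessConfig()
    seed = config.master_seed
    template = build_phantom_template(spec, pconfig, seed=seed + 10_000)
    dataset_a = prepare_phantom_dataset(
        spec, n_ad, n_cn, template, pconfig, config.classifier.input_px, seed=seed + 20_000
    )
    dataset_b = None
    if spec_b is not None:
        dataset_b = prepare_phantom_dataset(
            spec_b,
            n_ad_b or n_ad,
            n_cn_b or n_cn,
            template,
            pconfig,
            config.classifier.input_px,
            seed=seed + 30_000,
        )
    report = run_experiment(dataset_a, dataset_b, config)
    report["cohort"] = {
        "n_ad": n_ad,
        "n_cn": n_cn,
        "atrophy_effect": spec.atrophy_effect,
        "grid_size": spec.grid_size,
        "voxel_spacing_mm": spec.voxel_spacing_mm,
        "n_slices": pconfig.n_slices,
    }
    return report
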