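"""Personal and leave-one-subject-out evaluation with night-level
aggregation.

The protocol honours the provenance of the comparison observations so that
no information about a test migraine night can reach training:

* personal split — two migraine nights are drawn at random and *all* of
  their comparison observations go to the test set together; 20% of the
  non-migraine comparisons join them; the remainder is partitioned into
  five observation-level folds, four for training and one for validation
  (used by the forward feature search);
* LOSO split — one subject's observations are the test set; everyone
  else's form the five folds.

Because the comparison matrix is stochastic (random signs) and the splits
are random, every experiment is repeated (20 times by default) with a
fresh matrix per repetition, and results are reported as mean ± SD.

Predicted observation labels are folded back to nights by majority vote:
a migraine comparison votes on its migraine (left) night, a non-migraine
comparison votes on both member nights; ties alert (migraine).  Scores are
balanced accuracy — the mean of the two per-class true-positive rates —
plus sensitivity (TPR of non-migraine nights) and specificity (TPR of
migraine nights); that orientation follows the convention that the models
recognise non-migraine nights more reliably.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import (MIGRAINE_COMPARISON, ComparisonObservation,
                      build_comparison_matrix, observations_matrix)
from .errors import FitError, SplitError, ValidationError
from .features import FEATURE_NAMES, NightFeatureVector
from .model import fit_discriminant, inject_noise, predict_labels, sfs_select

log = logging.getLogger(__name__)

PRE_MIGRAINE = "pre_migraine"
NON_MIGRAINE = "non_migraine"


@dataclass(frozen=True)
class SplitPlan:
    """Index-level description of one train/validation/test split.

    Indices refer to the observation list the plan was built from.  The
    last fold is the validation part; the others train.
    """

    mode: str                       # "personal" | "loso"
    test_indices: np.ndarray
    folds: tuple[np.ndarray, ...]   # partition of the non-test indices
    test_migraine_night_ids: tuple[str, ...] = ()
    held_out_subject: str | None = None

    @property
    def train_indices(self) -> np.ndarray:
        return np.concatenate(self.folds[:-1]) if len(self.folds) > 1 else np.empty(0, int)

    @property
    def validation_indices(self) -> np.ndarray:
        return self.folds[-1]


def _partition_folds(indices: np.ndarray, n_folds: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, ...]:
    perm = rng.permutation(indices)
    return tuple(np.sort(part) for part in np.array_split(perm, n_folds))


def make_personal_split(obs: list[ComparisonObservation], seed: int,
                        n_test_migraine_nights: int = 2,
                        test_fraction: float = 0.2,
                        n_folds: int = 5) -> SplitPlan:
    """Personal within-subject split honouring migraine-night provenance.

    All observations derived from the randomly chosen test migraine nights
    enter the test set simultaneously, so no test migraine night is ever
    seen in training.  Raises :class:`SplitError` naming the deficit when
    the subject has fewer than 3 migraine nights or 5 non-migraine
    comparisons.
    """
    rng = np.random.default_rng(seed)
    mig_nights = sorted({o.left_night_id for o in obs if o.label == MIGRAINE_COMPARISON})
    non_idx = np.array([i for i, o in enumerate(obs) if o.label != MIGRAINE_COMPARISON])
    if len(mig_nights) < n_test_migraine_nights + 1:
        raise SplitError(f"need >= {n_test_migraine_nights + 1} migraine nights, "
                         f"have {len(mig_nights)}")
    if len(non_idx) < 5:
        raise SplitError(f"need >= 5 non-migraine comparisons, have {len(non_idx)}")

    test_nights = set(rng.choice(mig_nights, size=n_test_migraine_nights, replace=False))
    test_mig = [i for i, o in enumerate(obs)
                if o.label == MIGRAINE_COMPARISON and o.left_night_id in test_nights]
    n_test_non = max(int(np.floor(test_fraction * len(non_idx) + 0.5)), 1)
    test_non = rng.choice(non_idx, size=n_test_non, replace=False)
    test = np.sort(np.concatenate([test_mig, test_non]).astype(int))
    rest = np.setdiff1d(np.arange(len(obs)), test)
    folds = _partition_folds(rest, n_folds, rng)
    return SplitPlan("personal", test, folds,
                     test_migraine_night_ids=tuple(sorted(test_nights)))


def flatten_by_subject(obs_by_subject: dict[str, list[ComparisonObservation]]) -> list[ComparisonObservation]:
    """Deterministic flattening (sorted subject order) used by LOSO plans."""
    return [o for s in sorted(obs_by_subject) for o in obs_by_subject[s]]


def make_loso_split(obs_by_subject: dict[str, list[ComparisonObservation]],
                    held_out: str, seed: int = 0, n_folds: int = 5) -> SplitPlan:
    """Leave-one-subject-out split over the flattened observation list."""
    if held_out not in obs_by_subject:
        raise ValidationError(f"unknown subject {held_out!r}")
    if len(obs_by_subject) < 2:
        raise SplitError("LOSO needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    flat = flatten_by_subject(obs_by_subject)
    subj = np.array([o.subject_id for o in flat])
    test = np.flatnonzero(subj == held_out)
    rest = np.flatnonzero(subj != held_out)
    folds = _partition_folds(rest, n_folds, rng)
    return SplitPlan("loso", test, folds, held_out_subject=held_out)


def check_leakage(obs: list[ComparisonObservation], plan: SplitPlan) -> None:
    """Machine check of the leakage invariant: no test migraine night's
    comparisons may appear outside the test set."""
    if plan.mode == "personal":
        outside = set(np.concatenate([f for f in plan.folds]) if plan.folds else [])
        for i in outside:
            if obs[i].label == MIGRAINE_COMPARISON and \
                    obs[i].left_night_id in plan.test_migraine_night_ids:
                raise SplitError(f"leakage: test migraine night "
                                 f"{obs[i].left_night_id} found in train/validation")
    else:
        for fold in plan.folds:
            for i in fold:
                if obs[i].subject_id == plan.held_out_subject:
                    raise SplitError("leakage: held-out subject in train/validation")


def aggregate_night_predictions(
        predictions: list[tuple[ComparisonObservation, str]]) -> dict[str, str]:
    """Fold per-observation predictions back to per-night labels.

    A migraine-comparison prediction votes on the left (migraine) night;
    a non-migraine-comparison prediction votes on both member nights.  The
    night's label is the modal vote, ties resolved to migraine (an alert is
    cheaper than a missed attack).  Nights with zero votes are absent.
    """
    votes: dict[str, Counter] = {}
    for o, pred in predictions:
        vote = PRE_MIGRAINE if pred == MIGRAINE_COMPARISON else NON_MIGRAINE
        nights = [o.left_night_id] if o.label == MIGRAINE_COMPARISON \
            else [o.left_night_id, o.right_night_id]
        for nid in nights:
            votes.setdefault(nid, Counter())[vote] += 1
    out = {}
    for nid, ctr in votes.items():
        out[nid] = PRE_MIGRAINE if ctr[PRE_MIGRAINE] >= ctr[NON_MIGRAINE] else NON_MIGRAINE
    return out


def balanced_accuracy(truth: list[str] | np.ndarray,
                      predicted: list[str] | np.ndarray) -> tuple[float, float, float]:
    """Night-level balanced accuracy plus (sensitivity, specificity).

    Balanced accuracy is the mean of the two per-class true-positive
    rates; sensitivity is the TPR of non-migraine nights and specificity
    the TPR of migraine nights.  Both classes must appear in the truth.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) == 0 or len(truth) != len(predicted):
        raise ValidationError("need aligned nonempty label sequences")
    tprs = {}
    for cls in (NON_MIGRAINE, PRE_MIGRAINE):
        mask = truth == cls
        if not mask.any():
            raise ValidationError(f"class {cls!r} absent from truth; TPR undefined")
        tprs[cls] = float(np.mean(predicted[mask] == cls))
    bacc = 0.5 * (tprs[NON_MIGRAINE] + tprs[PRE_MIGRAINE])
    return bacc, tprs[NON_MIGRAINE], tprs[PRE_MIGRAINE]


@dataclass
class ExperimentConfig:
    """Knobs of the repeated-evaluation protocol."""

    mode: str = "personal"          # "personal" | "loso"
    classifier: str = "qda"         # "lda" | "qda"
    n_repetitions: int = 20
    noise_strength: float = 0.1
    sfs_eps: float = 1e-3
    max_features: int = 15
    regularization: float = 1e-6
    n_test_migraine_nights: int = 2
    test_fraction: float = 0.2
    n_folds: int = 5
    refit_with_noise: bool = False
    refit_include_validation: bool = True


@dataclass
class EvaluationReport:
    """Per-repetition records plus mean ± SD aggregation."""

    records: pd.DataFrame
    config: ExperimentConfig

    def aggregate(self) -> pd.DataFrame:
        """Per-subject mean and SD over repetitions, plus an overall row."""
        ok = self.records.dropna(subset=["balanced_accuracy"])
        per = ok.groupby("subject_id")[["balanced_accuracy", "sensitivity",
                                        "specificity"]].agg(["mean", "std"])
        per.columns = ["_".join(c) for c in per.columns]
        overall = per.mean(axis=0).to_frame().T
        overall.index = ["overall"]
        # overall SD is the SD of per-repetition subject means
        rep_means = ok.groupby("repetition")["balanced_accuracy"].mean()
        overall.loc["overall", "balanced_accuracy_std"] = rep_means.std()
        return pd.concat([per, overall])

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(self.records["balanced_accuracy"].mean())


def _evaluate_split(obs: list[ComparisonObservation], plan: SplitPlan,
                    night_truth: dict[str, str], cfg: ExperimentConfig,
                    seed: int) -> dict:
    """SFS + refit + prediction + night aggregation for one split."""
    check_leakage(obs, plan)
    X, y = observations_matrix(obs)
    tr, va, te = plan.train_indices, plan.validation_indices, plan.test_indices
    Xn, yn = inject_noise(X[tr], y[tr], cfg.noise_strength, seed)
    sel = sfs_select(Xn, yn, X[va], y[va], kind=cfg.classifier,
                     lam=cfg.regularization, eps=cfg.sfs_eps,
                     max_features=cfg.max_features)
    fit_idx = np.concatenate([tr, va]) if cfg.refit_include_validation else tr
    Xf, yf = X[fit_idx][:, sel], y[fit_idx]
    if cfg.refit_with_noise:
        Xf, yf = inject_noise(Xf, yf, cfg.noise_strength, seed + 1)
    final = fit_discriminant(Xf, yf, cfg.classifier, cfg.regularization,
                             selected_features=[FEATURE_NAMES[j] for j in sel])
    preds = predict_labels(final, X[te][:, sel])
    night_pred = aggregate_night_predictions(
        [(obs[i], p) for i, p in zip(te, preds)])
    nights = sorted(night_pred)
    bacc, sens, spec = balanced_accuracy([night_truth[n] for n in nights],
                                         [night_pred[n] for n in nights])
    return {"balanced_accuracy": bacc, "sensitivity": sens, "specificity": spec,
            "n_test_nights": len(nights),
            "selected_features": ",".join(final.selected_features)}


def run_repeated_experiment(nights: list[NightFeatureVector],
                            config: ExperimentConfig | None = None,
                            seed: int = 0,
                            seeds: list[int] | None = None) -> EvaluationReport:
    """The full repeated protocol over a cohort of nightly feature vectors.

    Each repetition regenerates the comparison matrices (fresh random
    signs), redraws the split, reruns noise injection and the forward
    feature search, refits, predicts, and aggregates to nights.  A
    repetition whose split or fit is infeasible is recorded as
    not-evaluable (NaN) with a warning, never imputed.
    """
    cfg = config or ExperimentConfig()
    if cfg.n_repetitions < 1:
        raise ValidationError("need at least one repetition")
    if seeds is not None and len(seeds) != cfg.n_repetitions:
        raise ValidationError("len(seeds) must equal n_repetitions")
    master = np.random.default_rng(seed)
    rep_seeds = (np.asarray(seeds, dtype=np.int64) if seeds is not None
                 else master.integers(0, 2**31 - 1, size=cfg.n_repetitions))

    by_subject: dict[str, list[NightFeatureVector]] = {}
    for v in nights:
        by_subject.setdefault(v.subject_id, []).append(v)
    night_truth = {v.night_id: v.label for v in nights}
    subjects = sorted(by_subject)

    rows = []
    for r, rs in enumerate(rep_seeds):
        rng = np.random.default_rng(int(rs))
        obs_by_subject = {
            s: build_comparison_matrix(by_subject[s], int(rng.integers(0, 2**31 - 1)))
            for s in subjects}
        if cfg.mode == "personal":
            for s in subjects:
                row = {"subject_id": s, "repetition": r}
                try:
                    plan = make_personal_split(
                        obs_by_subject[s], int(rng.integers(0, 2**31 - 1)),
                        cfg.n_test_migraine_nights, cfg.test_fraction, cfg.n_folds)
                    row.update(_evaluate_split(obs_by_subject[s], plan, night_truth,
                                               cfg, int(rng.integers(0, 2**31 - 1))))
                except (SplitError, FitError, ValidationError) as exc:
                    log.warning("rep %d subject %s not evaluable: %s", r, s, exc)
                    row.update({"balanced_accuracy": np.nan, "sensitivity": np.nan,
                                "specificity": np.nan, "n_test_nights": 0,
                                "selected_features": ""})
                rows.append(row)
        elif cfg.mode == "loso":
            flat = flatten_by_subject(obs_by_subject)
            for s in subjects:
                row = {"subject_id": s, "repetition": r}
                try:
                    plan = make_loso_split(obs_by_subject, s,
                                           int(rng.integers(0, 2**31 - 1)), cfg.n_folds)
                    row.update(_evaluate_split(flat, plan, night_truth, cfg,
                                               int(rng.integers(0, 2**31 - 1))))
                except (SplitError, FitError, ValidationError) as exc:
                    log.warning("rep %d held-out %s not evaluable: %s", r, s, exc)
                    row.update({"balanced_accuracy": np.nan, "sensitivity": np.nan,
                                "specificity": np.nan, "n_test_nights": 0,
                                "selected_features": ""})
                rows.append(row)
        else:
            raise ValidationError(f"unknown mode {cfg.mode!r}")
    records = pd.DataFrame(rows)
    return EvaluationReport(records, cfg)
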