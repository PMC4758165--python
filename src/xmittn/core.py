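"""The four-stage cross-cohort validation pipeline.

Stage 1 draws many random train/CV partitions of the training cohort
(default 1000 folds of 180 train + 50 CV subjects). Stage 2 fits every
registered algorithm on each fold's training rows — once per feature-set
experiment, on the *same* partitions — and scores the held-out CV rows
with the Gini index (2*AUROC - 1, the Somers' D of the score against the
stage label; 0 at chance, 1 at perfect ranking). Stage 3 turns each
algorithm-by-experiment Gini distribution into an empirical p-value: the
fraction of folds whose Gini is at or below 0, i.e. the mass of the null
"no better than chance" outcome; combinations with p < alpha (0.05,
unadjusted) are selected. Stage 4 refits each selected combination once
on the full training cohort, freezes it, and validates it on an
independent test cohort via bootstrap: 1000 balanced test sets of 50
MCI-AD + 50 AD subjects drawn with replacement, each scored for Gini,
sensitivity, specificity and accuracy, with a test p-value again equal
to the fraction of replicate Ginis at or below 0. Per-subject sampling
and labeling tallies from Stage 4 feed the P(AD) staging module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .classifiers import ALGORITHM_LABELS, ALGORITHM_NAMES, StageClassifier
from .cohort import (
    EXP1_FEATURES,
    Cohort,
    Experiment,
    FeatureMatrix,
    build_feature_matrix,
)
from .exceptions import ConfigurationError, UndefinedGiniError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gini index
# ---------------------------------------------------------------------------

def compute_gini(labels, scores) -> float:
    """Gini index of a continuous score against binary labels.

    Defined as 2*AUROC - 1 with the Mann-Whitney tie convention (a tied
    positive-negative pair counts one half). 0 means chance-level
    ranking, 1 perfect, negative values worse than chance.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if np.unique(labels).size < 2:
        raise UndefinedGiniError("Gini undefined: labels contain a single class")
    return float(2.0 * roc_auc_score(labels, scores) - 1.0)


def stage3_pvalue(gini_values) -> float:
    """Empirical p-value: fraction of Gini values at or below 0.

    Non-finite entries (folds dropped because their CV set was
    single-class) are excluded from both numerator and denominator.
    """
    values = np.asarray(gini_values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("stage3_pvalue: no finite Gini values")
    return float(np.mean(finite <= 0.0))


# ---------------------------------------------------------------------------
# Stage 1: split plan
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Repeated random subsampling plan for Stage-1 cross-validation.

    ``stratified`` (default) preserves the cohort's MCI-AD:AD proportion
    in each fold's train and CV sets to within integer rounding, which
    prevents single-class CV sets; an unstratified mode is available, in
    which single-class CV folds are later dropped from the p-value
    denominator.
    """

    n_folds: int = 1000
    train_size: int = 180
    cv_size: int = 50
    master_seed: int = 0
    stratified: bool = True
    train_indices: list[np.ndarray] = field(default_factory=list, repr=False)
    cv_indices: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def populated(self) -> bool:
        return len(self.train_indices) == self.n_folds > 0


def _largest_remainder(fractions: np.ndarray, total: int, caps: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` across classes by largest remainder."""
    ideal = fractions * total
    counts = np.floor(ideal).astype(int)
    counts = np.minimum(counts, caps)
    remainder = ideal - counts
    order = np.argsort(-remainder, kind="stable")
    i = 0
    while counts.sum() < total:
        c = order[i % len(order)]
        if counts[c] < caps[c]:
            counts[c] += 1
        i += 1
        if i > 10 * len(order) and counts.sum() < total:
            raise ConfigurationError("cannot allocate fold sizes under class caps")
    return counts


def make_splits(labels, plan: SplitPlan) -> SplitPlan:
    """Populate a split plan with ``n_folds`` independent random partitions.

    Each fold samples ``train_size`` training and ``cv_size`` CV subjects
    without replacement (disjoint within the fold); folds are mutually
    independent and fully reproducible from ``master_seed``.
    """
    labels = np.asarray(labels)
    n = labels.size
    if plan.train_size + plan.cv_size > n:
        raise ConfigurationError(
            f"train_size + cv_size = {plan.train_size + plan.cv_size} exceeds "
            f"cohort size {n}"
        )
    classes, class_idx = np.unique(labels, return_inverse=True)
    per_class = [np.flatnonzero(class_idx == k) for k in range(classes.size)]
    n_per_class = np.array([idx.size for idx in per_class])
    fractions = n_per_class / n

    train_lists, cv_lists = [], []
    for fold in range(plan.n_folds):
        rng = np.random.default_rng(
            np.random.SeedSequence((int(plan.master_seed), fold))
        )
        if plan.stratified:
            t_counts = _largest_remainder(fractions, plan.train_size, n_per_class)
            v_counts = _largest_remainder(
                fractions, plan.cv_size, n_per_class - t_counts
            )
            train, cv = [], []
            for idx, t_c, v_c in zip(per_class, t_counts, v_counts):
                perm = rng.permutation(idx)
                train.append(perm[:t_c])
                cv.append(perm[t_c:t_c + v_c])
            train = np.sort(np.concatenate(train))
            cv = np.sort(np.concatenate(cv))
        else:
            perm = rng.permutation(n)
            train = np.sort(perm[:plan.train_size])
            cv = np.sort(perm[plan.train_size:plan.train_size + plan.cv_size])
        train_lists.append(train)
        cv_lists.append(cv)
    plan.train_indices = train_lists
    plan.cv_indices = cv_lists
    return plan


# ---------------------------------------------------------------------------
# Stages 2-3: CV Gini distributions and selection
# ---------------------------------------------------------------------------

@dataclass
class GiniDistribution:
    """CV-fold Gini indices for one algorithm x experiment combination."""

    algorithm: str
    experiment: Experiment
    gini_values: np.ndarray
    n_dropped: int = 0

    @property
    def p_value(self) -> float:
        return stage3_pvalue(self.gini_values)

    @property
    def n_folds(self) -> int:
        return int(self.gini_values.size)


def _fold_seed(master_seed: int, fold: int, algorithm: str) -> int:
    """Deterministic per-(fold, algorithm) seed below 2**31."""
    alg_index = ALGORITHM_NAMES.index(algorithm)
    ss = np.random.SeedSequence((int(master_seed), fold, alg_index))
    return int(ss.generate_state(1)[0] % (2**31))


def _experiment_matrices(cohort: Cohort, experiments) -> dict[Experiment, FeatureMatrix]:
    """Feature matrices sharing one subject set across experiments.

    EXP1's features are the leading columns of EXP2's, so when both are
    requested EXP1 is sliced out of the EXP2 matrix; the complete-case
    subject set is then identical, which keeps the Stage-1 splits valid
    for both experiments.
    """
    experiments = [Experiment(e) for e in experiments]
    out: dict[Experiment, FeatureMatrix] = {}
    if Experiment.EXP2 in experiments:
        full = build_feature_matrix(cohort, Experiment.EXP2)
        out[Experiment.EXP2] = full
        if Experiment.EXP1 in experiments:
            out[Experiment.EXP1] = FeatureMatrix(
                experiment=Experiment.EXP1,
                feature_names=EXP1_FEATURES,
                values=full.values[:, : len(EXP1_FEATURES)],
                labels=full.labels,
                subject_ids=list(full.subject_ids),
            )
    elif Experiment.EXP1 in experiments:
        out[Experiment.EXP1] = build_feature_matrix(cohort, Experiment.EXP1)
    return out


def run_training_stage(
    cohort: Cohort,
    plan: SplitPlan | None = None,
    algorithms=None,
    experiments=(Experiment.EXP1, Experiment.EXP2),
    hyperparams: dict | None = None,
) -> dict[tuple[str, Experiment], GiniDistribution]:
    """Stages 1-2: CV Gini distribution per algorithm x experiment.

    Every algorithm and experiment sees the *same* random partitions.
    Per-fold fit seeds derive deterministically from the plan's master
    seed, the fold index, and the algorithm name. Folds whose CV set is
    single-class (possible only in unstratified mode) are recorded as
    missing and excluded from the p-value denominator, with a logged
    count.

    ``hyperparams`` maps algorithm name to an override dict.
    """
    plan = plan or SplitPlan()
    algorithms = list(algorithms or ALGORITHM_NAMES)
    hyperparams = hyperparams or {}
    matrices = _experiment_matrices(cohort, experiments)
    any_matrix = next(iter(matrices.values()))
    if not plan.populated:
        plan = make_splits(any_matrix.labels, plan)

    results: dict[tuple[str, Experiment], GiniDistribution] = {}
    ginis = {
        (alg, exp): np.full(plan.n_folds, np.nan)
        for alg in algorithms for exp in matrices
    }
    n_dropped = 0
    for fold, (tr, cv) in enumerate(zip(plan.train_indices, plan.cv_indices)):
        cv_labels = any_matrix.labels[cv]
        if np.unique(cv_labels).size < 2:
            n_dropped += 1
            continue
        for exp, matrix in matrices.items():
            X_tr, y_tr = matrix.values[tr], matrix.labels[tr]
            X_cv = matrix.values[cv]
            for alg in algorithms:
                model = StageClassifier(
                    algorithm=alg,
                    hyperparams=hyperparams.get(alg),
                    random_state=_fold_seed(plan.master_seed, fold, alg),
                ).fit(X_tr, y_tr)
                scores = model.predict_score(X_cv)
                ginis[(alg, exp)][fold] = compute_gini(cv_labels, scores)
    if n_dropped:
        logger.info(
            "run_training_stage: %d/%d fold(s) dropped (single-class CV set)",
            n_dropped, plan.n_folds,
        )
    for (alg, exp), values in ginis.items():
        results[(alg, exp)] = GiniDistribution(
            algorithm=alg, experiment=exp, gini_values=values, n_dropped=n_dropped
        )
    return results


def select_models(
    results: dict[tuple[str, Experiment], GiniDistribution],
    alpha: float = 0.05,
) -> list[tuple[str, Experiment]]:
    """Stage 3: combinations with p strictly below alpha, unadjusted.

    p exactly equal to alpha is NOT selected. An empty selection is a
    legitimate outcome (no combination beats chance).
    """
    if not results:
        raise ValueError("select_models: empty results map")
    return [key for key, dist in results.items() if dist.p_value < alpha]


def freeze_final_model(
    cohort: Cohort,
    algorithm: str,
    experiment: Experiment | str,
    hyperparams: dict | None = None,
    random_state: int = 0,
    selection=None,
) -> StageClassifier:
    """Stage 4 prelude: one model refit on ALL eligible training subjects.

    The frozen model — including its internal standardization — is what
    transfers to the test cohort; no refitting happens there. Freezing a
    combination outside the Stage-3 selection is allowed but logged.
    """
    experiment = Experiment(experiment)
    if selection is not None and (algorithm, experiment) not in selection:
        logger.warning(
            "freezing (%s, %s) which is not in the Stage-3 selection",
            algorithm, experiment.value,
        )
    matrix = build_feature_matrix(cohort, experiment)
    return StageClassifier(
        algorithm=algorithm, hyperparams=hyperparams, random_state=random_state
    ).fit(matrix)


# ---------------------------------------------------------------------------
# Stage 4: bootstrap validation
# ---------------------------------------------------------------------------

@dataclass
class BootstrapValidationResult:
    """Frozen-model performance over balanced bootstrap test sets."""

    algorithm: str
    experiment: Experiment
    n_boot: int
    per_class: int
    gini_values: np.ndarray
    sensitivity: float
    specificity: float
    accuracy: float
    subject_ids: list[str]
    times_sampled: np.ndarray
    times_labeled_ad: np.ndarray
    master_seed: int = 0

    @property
    def p_value(self) -> float:
        return stage3_pvalue(self.gini_values)


def bootstrap_validate(
    model,
    test_cohort: Cohort,
    n_boot: int = 1000,
    per_class: int = 50,
    master_seed: int = 0,
    experiment: Experiment | str | None = None,
) -> BootstrapValidationResult:
    """Stage 4: frozen-model validation on an independent test cohort.

    Each replicate draws ``per_class`` MCI-AD and ``per_class`` AD
    subjects with replacement (replacement is forced: real test cohorts
    can be smaller than the replicate size), scores them with the frozen
    model, and records the Gini plus confusion-matrix rates. Sensitivity
    is the fraction of AD subjects labeled AD, specificity the fraction
    of MCI-AD subjects labeled MCI-AD; all three metrics are averaged
    over replicates. A replicate whose scores are all tied has AUROC 1/2
    and hence Gini 0, counted into the p-value mass. Per-subject sampled
    and labeled-AD tallies are accumulated for P(AD) staging.

    The test cohort must already be C3-normalized against its OWN normal
    reference (never the training cohort's).
    """
    if experiment is None:
        names = tuple(getattr(model, "feature_names_", None) or ())
        experiment = Experiment.EXP1 if len(names) == 6 else Experiment.EXP2
    experiment = Experiment(experiment)
    matrix = build_feature_matrix(test_cohort, experiment)
    labels = matrix.labels
    mci_idx = np.flatnonzero(labels == 0)
    ad_idx = np.flatnonzero(labels == 1)
    if mci_idx.size == 0 or ad_idx.size == 0:
        raise ValueError("bootstrap_validate: test cohort must contain both classes")

    # Predictions are pointwise, so score/predict once and index per replicate.
    scores_all = np.asarray(model.predict_score(matrix.values), dtype=float)
    preds_all = np.asarray(model.predict(matrix.values))

    n_subjects = labels.size
    times_sampled = np.zeros(n_subjects, dtype=np.int64)
    times_labeled_ad = np.zeros(n_subjects, dtype=np.int64)
    ginis = np.empty(n_boot)
    sens = np.empty(n_boot)
    spec = np.empty(n_boot)
    acc = np.empty(n_boot)

    for rep in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence((int(master_seed), rep)))
        take_mci = rng.choice(mci_idx, size=per_class, replace=True)
        take_ad = rng.choice(ad_idx, size=per_class, replace=True)
        take = np.concatenate([take_mci, take_ad])
        rep_labels = labels[take]
        rep_scores = scores_all[take]
        rep_preds = preds_all[take]
        if np.all(rep_scores == rep_scores[0]):
            ginis[rep] = 0.0
        else:
            ginis[rep] = compute_gini(rep_labels, rep_scores)
        sens[rep] = np.mean(rep_preds[per_class:] == 1)
        spec[rep] = np.mean(rep_preds[:per_class] == 0)
        acc[rep] = np.mean(rep_preds == rep_labels)
        np.add.at(times_sampled, take, 1)
        np.add.at(times_labeled_ad, take[rep_preds == 1], 1)

    return BootstrapValidationResult(
        algorithm=getattr(model, "algorithm", "unknown"),
        experiment=experiment,
        n_boot=n_boot,
        per_class=per_class,
        gini_values=ginis,
        sensitivity=float(np.mean(sens)),
        specificity=float(np.mean(spec)),
        accuracy=float(np.mean(acc)),
        subject_ids=list(matrix.subject_ids),
        times_sampled=times_sampled,
        times_labeled_ad=times_labeled_ad,
        master_seed=master_seed,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report_table2(
    training_results: dict[tuple[str, Experiment], GiniDistribution],
    test_results: dict[tuple[str, Experiment], BootstrapValidationResult] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-cohort p-value table, one row per algorithm.

    Columns hold the training-cohort CV p-values for each experiment and
    the test-cohort bootstrap p-values, the latter populated only for
    combinations actually validated (unselected cells stay blank). A
    parallel boolean column flags p < alpha.
    """
    test_results = test_results or {}
    rows = []
    for alg in ALGORITHM_NAMES:
        row = {"algorithm": ALGORITHM_LABELS[alg]}
        for exp in (Experiment.EXP1, Experiment.EXP2):
            dist = training_results.get((alg, exp))
            p = dist.p_value if dist is not None else np.nan
            row[f"p_{exp.value.lower()}_train"] = p
            boot = test_results.get((alg, exp))
            row[f"p_{exp.value.lower()}_test"] = (
                boot.p_value if boot is not None else np.nan
            )
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("algorithm")
    for col in list(frame.columns):
        frame[f"sig_{col[2:]}"] = frame[col] < alpha
    return frame
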