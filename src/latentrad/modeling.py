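"""Classifier grid over input configurations and outcomes, with evaluation.

Six classifiers (random forest, XGBoost, Gaussian naive Bayes, extra trees,
elastic-net logistic regression, RBF-kernel SVM) are trained on each of the
seven input configurations for each binary outcome, under stratified 5-fold
cross-validation plus a final refit evaluated on a held-out test cohort.
Every data-dependent transformation (nonnegative shift, NMF) is re-fit
inside each training fold; a leakage guard aborts the run if any fit ever
touches evaluation rows.

Also provides threshold metrics, calibration and decision curves, and a
model-agnostic grouped permutation importance standing in for group-level
attribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FeatureBlock
from .reduction import build_input_configurations, reduce_block

logger = logging.getLogger(__name__)

OUTCOMES = ("poor_outcome", "exp3", "exp6", "exp9")
CLASSIFIER_NAMES = ("RF", "XGBoost", "GaussianNB", "ExtraTrees",
                    "ElasticNet_LogReg", "SVM_RBF")


class PlattSVM:
    """RBF-kernel SVM with decision-function scores and Platt probabilities.

    AUC uses the raw decision-function values (rank-equivalent to any
    monotone link); threshold metrics use a logistic (Platt) fit of the
    training decision values, estimated on the training fold only.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.svm = make_pipeline(StandardScaler(),
                                 SVC(kernel="rbf", random_state=seed))
        self.platt = LogisticRegression()

    def fit(self, X, y):
        self.svm.fit(X, y)
        d = self.svm.decision_function(X)
        self.platt.fit(d[:, None], y)
        return self

    def decision_function(self, X):
        return self.svm.decision_function(X)

    def predict_proba(self, X):
        return self.platt.predict_proba(self.decision_function(X)[:, None])


class LeakageError(RuntimeError):
    """A fit touched rows reserved for evaluation."""


def guard_disjoint(fit_ids, eval_ids, context: str = "") -> None:
    """Abort if any evaluation case participates in a fit."""
    overlap = set(fit_ids) & set(eval_ids)
    if overlap:
        raise LeakageError(
            f"leakage in {context or 'fit'}: {len(overlap)} evaluation case(s) "
            f"in the fit set (e.g. {sorted(overlap)[:3]})")


@dataclass
class ClassifierSpec:
    """One classifier with pinned hyperparameters and seed.

    Reference-scale tree ensembles use 1000 estimators; the elastic-net
    logistic regression uses l1_ratio 0.5 with the saga solver; the SVM uses
    an RBF kernel.  Unstated hyperparameters follow the implementation
    defaults and are captured in ``hyperparams`` for the config snapshot.
    """

    name: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}")

    def build(self):
        hp = dict(self.hyperparams)
        if self.name == "RF":
            return RandomForestClassifier(
                n_estimators=hp.get("n_estimators", 1000),
                random_state=self.seed, n_jobs=1)
        if self.name == "XGBoost":
            return XGBClassifier(
                n_estimators=hp.get("n_estimators", 1000),
                eval_metric="logloss", random_state=self.seed, n_jobs=1,
                verbosity=0)
        if self.name == "GaussianNB":
            return GaussianNB()
        if self.name == "ExtraTrees":
            return ExtraTreesClassifier(
                n_estimators=hp.get("n_estimators", 1000),
                random_state=self.seed, n_jobs=1)
        if self.name == "ElasticNet_LogReg":
            return make_pipeline(
                StandardScaler(),
                LogisticRegression(l1_ratio=0.5, solver="saga",
                                   max_iter=hp.get("max_iter", 3000),
                                   random_state=self.seed))
        if self.name == "SVM_RBF":
            return PlattSVM(seed=self.seed)
        raise AssertionError


def default_classifier_specs(seed: int = 0, n_estimators: int = 1000) -> list:
    """The six classifier specs (reference scale: 1000 trees/rounds)."""
    hp = {"n_estimators": n_estimators}
    return [
        ClassifierSpec("RF", dict(hp), seed),
        ClassifierSpec("XGBoost", dict(hp), seed),
        ClassifierSpec("GaussianNB", {}, seed),
        ClassifierSpec("ExtraTrees", dict(hp), seed),
        ClassifierSpec("ElasticNet_LogReg", {}, seed),
        ClassifierSpec("SVM_RBF", {}, seed),
    ]


def stratified_kfold(labels, k: int = 5, seed: int = 0):
    """Stratified fold assignment; returns a list of (train_idx, val_idx).

    ``labels`` is a 1D binary array; both classes must be present.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("stratification requires both classes present")
    if len(y) < k:
        raise ValueError("need at least k cases")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney rank statistic with ties counted 1/2."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    r = rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def binary_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """AUC plus confusion-table metrics at a probability threshold.

    PPV/NPV with an undefined denominator are reported as NaN (missing),
    never coerced to 0.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    auc = roc_auc(s, y)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    if np.isnan(ppv) or np.isnan(sens) or (ppv + sens) == 0:
        f1 = np.nan if (np.isnan(ppv) or np.isnan(sens)) else 0.0
    else:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    return dict(auc=auc, f1=f1, sensitivity=sens, specificity=spec,
                ppv=ppv, npv=npv)


@dataclass
class ResultGrid:
    """Tidy results over (configuration x classifier x outcome x split)."""

    rows: list = field(default_factory=list)

    def add(self, configuration, classifier, outcome, split, metrics, fold=None):
        row = dict(configuration=configuration, classifier=classifier,
                   outcome=outcome, split=split, fold=fold)
        row.update(metrics)
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def auc_table(self, split: str = "test") -> pd.DataFrame:
        """Pipelines x classifiers AUC matrix per outcome (folds averaged)."""
        df = self.to_frame()
        df = df[(df["split"] == split)]
        return df.pivot_table(index="configuration", columns=["outcome", "classifier"],
                              values="auc", aggfunc="mean")

    def cv_fold_aucs(self, configuration, classifier, outcome) -> np.ndarray:
        df = self.to_frame()
        sel = df[(df.split == "cv") & (df.configuration == configuration)
                 & (df.classifier == classifier) & (df.outcome == outcome)]
        return sel.sort_values("fold")["auc"].to_numpy()

    def summary(self) -> pd.DataFrame:
        """Mean AUC by configuration and outcome on the test split."""
        df = self.to_frame()
        out = (df[df.split == "test"]
               .groupby(["outcome", "configuration"])["auc"]
               .mean().unstack(0))
        return out

    def check_complete(self, n_configs: int = 7, n_classifiers: int = 6,
                       n_outcomes: int = 4) -> None:
        df = self.to_frame()
        test = df[df.split == "test"]
        cells = test.groupby(["configuration", "classifier", "outcome"]).size()
        expected = n_configs * n_classifiers * n_outcomes
        if len(cells) != expected:
            raise ValueError(f"incomplete grid: {len(cells)} of {expected} test cells")
        bad = df[[c for c in ("auc",) if c in df]].apply(
            lambda s: ((s < 0) | (s > 1)).any())
        if bad.any():
            raise ValueError("metrics outside [0, 1]")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _fit_and_score(spec: ClassifierSpec, Xtr, ytr, Xev, yev, threshold=0.5):
    est = spec.build()
    est.fit(Xtr, ytr)
    prob = est.predict_proba(Xev)[:, 1]
    metrics = binary_metrics(prob, yev, threshold)
    if spec.name == "SVM_RBF":
        # AUC from decision-function values (monotone link); threshold
        # metrics keep the Platt-style probabilities
        dec = est.decision_function(Xev)
        metrics["auc"] = roc_auc(dec, yev)
    return est, prob, metrics


def _reduced_configs(raw_blocks: dict, case_ids, train_ids, k: int,
                     nmf_iters: int, seed: int, cache: dict,
                     seg_joint: bool = False):
    """Fit per-family reductions on ``train_ids`` and assemble the 7 configs.

    ``raw_blocks`` must contain 'radiomics', 'shape', 'seg_full', 'seg_half'
    and 'vaegan' blocks covering ``case_ids``.  The two segmentation-encoder
    sources are reduced to k//2 components each and concatenated, so the
    combined segmentation-encoder latent set has width k.
    """
    from .reduction import reduce_seg_latents

    key = (frozenset(case_ids), frozenset(train_ids), k, seg_joint)
    if key not in cache:
        sub = {name: blk.subset(case_ids) for name, blk in raw_blocks.items()}
        rad, _ = reduce_block(sub["radiomics"], k, train_ids, nmf_iters, seed,
                              prefix="radiomics")
        seg = reduce_seg_latents(sub["seg_full"], sub["seg_half"], k, train_ids,
                                 nmf_iters, seed, joint=seg_joint)
        vae, _ = reduce_block(sub["vaegan"], k, train_ids, nmf_iters, seed,
                              prefix="vaegan")
        cache[key] = build_input_configurations(rad, sub["shape"], seg, vae)
    return cache[key]


def run_grid(raw_blocks: dict, labels: pd.DataFrame, train_ids, test_ids,
             specs=None, outcomes=OUTCOMES, k: int = 16, n_folds: int = 5,
             nmf_iters: int = 150, seed: int = 0, threshold: float = 0.5,
             config_names=None, reduction_cache: dict | None = None,
             seg_joint: bool = False) -> ResultGrid:
    """Cross-validate and test every (configuration, classifier, outcome) cell.

    Per cell: stratified ``n_folds``-fold CV on the training cohort (all
    reductions re-fit inside each training fold) and a final refit on the
    full training cohort evaluated on the disjoint test cohort.
    ``config_names`` restricts the configurations (default: all seven).
    Deterministic given seeds.
    """
    specs = specs if specs is not None else default_classifier_specs(seed)
    guard_disjoint(train_ids, test_ids, "train/test split")
    grid = ResultGrid()
    all_ids = list(train_ids) + list(test_ids)
    y_all = labels.loc[all_ids]

    for outcome in outcomes:
        y_train = labels.loc[list(train_ids), outcome].to_numpy().astype(int)
        folds = stratified_kfold(y_train, k=n_folds, seed=seed)
        cache: dict = reduction_cache if reduction_cache is not None else {}
        # cross-validation
        for fold_i, (tr_idx, va_idx) in enumerate(folds):
            ftr_ids = [train_ids[i] for i in tr_idx]
            fva_ids = [train_ids[i] for i in va_idx]
            guard_disjoint(ftr_ids, fva_ids, f"fold {fold_i}")
            configs = _reduced_configs(raw_blocks, list(train_ids), ftr_ids,
                                       k, nmf_iters, seed, cache, seg_joint)
            for config in configs:
                if config_names and config.name not in config_names:
                    continue
                X = config.matrix()
                guard_disjoint(ftr_ids, fva_ids, f"{config.name} fold {fold_i}")
                Xtr = X.subset(ftr_ids).matrix
                Xva = X.subset(fva_ids).matrix
                ytr = labels.loc[ftr_ids, outcome].to_numpy().astype(int)
                yva = labels.loc[fva_ids, outcome].to_numpy().astype(int)
                for spec in specs:
                    _, _, metrics = _fit_and_score(spec, Xtr, ytr, Xva, yva, threshold)
                    grid.add(config.name, spec.name, outcome, "cv", metrics, fold=fold_i)
        # final refit on the full training cohort, evaluated on the test set
        configs = _reduced_configs(raw_blocks, all_ids, list(train_ids),
                                   k, nmf_iters, seed, cache, seg_joint)
        for config in configs:
            if config_names and config.name not in config_names:
                continue
            X = config.matrix()
            guard_disjoint(list(train_ids), list(test_ids), f"{config.name} test")
            Xtr = X.subset(list(train_ids)).matrix
            Xte = X.subset(list(test_ids)).matrix
            ytr = labels.loc[list(train_ids), outcome].to_numpy().astype(int)
            yte = labels.loc[list(test_ids), outcome].to_numpy().astype(int)
            for spec in specs:
                _, _, metrics = _fit_and_score(spec, Xtr, ytr, Xte, yte, threshold)
                grid.add(config.name, spec.name, outcome, "test", metrics)
    return grid


# ---------------------------------------------------------------------------
# calibration, decision curves, attribution


def calibration_curve(scores, labels, bins: int = 10):
    """Quantile-binned predicted vs observed event rates, plus Brier score."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(s) < bins:
        raise ValueError("need at least `bins` cases")
    edges = np.unique(np.quantile(s, np.linspace(0, 1, bins + 1)))
    if len(edges) < 2:  # constant scores: one bin
        idx = np.zeros(len(s), dtype=int)
        edges = np.array([s.min(), s.max()])
    else:
        idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        m = idx == b
        if not m.any():
            continue
        rows.append(dict(bin=b, n=int(m.sum()), mean_predicted=float(s[m].mean()),
                         observed_rate=float(y[m].mean())))
    curve = pd.DataFrame(rows)
    brier = float(np.mean((s - y) ** 2))
    return curve, brier


def decision_curve(scores, labels, thresholds=None) -> pd.DataFrame:
    """Net benefit TP/n - (FP/n) pt/(1-pt) across treatment thresholds.

    Includes treat-all and treat-none reference policies.
    """
    if thresholds is None:
        thresholds = np.arange(0.05, 0.95, 0.05)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in (0, 1)")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n = len(y)
    prev = y.mean()
    rows = []
    for pt in thresholds:
        flag = s >= pt
        tp = int((flag & (y == 1)).sum())
        fp = int((flag & (y == 0)).sum())
        odds = pt / (1.0 - pt)
        nb = tp / n - (fp / n) * odds
        nb_all = prev - (1.0 - prev) * odds
        rows.append(dict(threshold=float(pt), net_benefit=nb,
                         treat_all=nb_all, treat_none=0.0))
    return pd.DataFrame(rows)


def group_attribution(model, X, y, group_map: dict, seed: int = 0,
                      n_repeats: int = 10) -> pd.DataFrame:
    """Grouped permutation importance: mean AUC drop when a feature group's
    columns are jointly permuted (floored at 0).

    ``group_map`` maps group name -> column indices and must partition the
    columns of ``X``.
    """
    X = np.asarray(X, dtype=float)
    cols = sorted(c for idxs in group_map.values() for c in idxs)
    if cols != list(range(X.shape[1])):
        raise ValueError("group map must partition the feature columns")
    base = roc_auc(model.predict_proba(X)[:, 1], y)
    rng = np.random.default_rng(seed)
    rows = []
    for group, idxs in group_map.items():
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            perm = rng.permutation(len(X))
            Xp[:, idxs] = Xp[perm][:, idxs]
            drops.append(base - roc_auc(model.predict_proba(Xp)[:, 1], y))
        rows.append(dict(group=group, importance=max(0.0, float(np.mean(drops))),
                         raw_mean_drop=float(np.mean(drops))))
    return pd.DataFrame(rows).sort_values("importance", ascending=False,
                                          ignore_index=True)


def plot_calibration(curve: pd.DataFrame, brier: float, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="ideal")
    ax.plot(curve["mean_predicted"], curve["observed_rate"], "o-", label="model")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed event rate")
    ax.set_title(f"Calibration (Brier = {brier:.3f})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_decision_curve(table: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(table["threshold"], table["net_benefit"], label="model")
    ax.plot(table["threshold"], table["treat_all"], label="treat all")
    ax.plot(table["threshold"], table["treat_none"], label="treat none")
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=max(-0.1, table[["net_benefit", "treat_all"]].min().min() - 0.02))
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
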