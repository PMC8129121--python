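"""Nested stratified cross-validated pattern classification.

The classifier discriminates high- from low-schizotypy subjects from the
14 alpha features (4 IAF, 4 amplitude, 3 wPLI, 3 TLI).  A tenfold
stratified outer loop estimates unbiased performance; inside each outer
training set a tenfold stratified inner loop jointly selects the feature
combination, the classifier family (linear C-SVM or L2 logistic
regression) and the regularization strength C in {0.1, 0.2, 0.3} by mean
balanced accuracy.  The winner is refit on the full outer training set and
scored once on the untouched outer test fold.  Features are standardized
with statistics of the training rows only, at both levels.  The whole
procedure is repeated (1000 repetitions at full scale) with fresh fold
assignments, recording how often each feature combination is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

try:  # low-level solver entry points (same libraries the estimators wrap)
    from sklearn.svm import _libsvm
    from sklearn.svm._base import _fit_liblinear
except ImportError:  # pragma: no cover - fall back to the estimator API
    _libsvm = None
    _fit_liblinear = None

__all__ = [
    "FEATURE_NAMES",
    "FeatureCombination",
    "SearchGrid",
    "CVReport",
    "enumerate_combinations",
    "default_grid",
    "nested_cv",
    "classification_metrics",
    "aggregate_roc",
    "ranking_report",
]

#: Canonical order of the 14 alpha features.
FEATURE_NAMES: tuple[str, ...] = (
    "iaf_frontal_L", "iaf_frontal_R", "iaf_posterior_L", "iaf_posterior_R",
    "amp_frontal_L", "amp_frontal_R", "amp_posterior_L", "amp_posterior_R",
    "wpli_intra_L", "wpli_intra_R", "wpli_inter",
    "tli_intra_L", "tli_intra_R", "tli_inter",
)

POSITIVE_CLASS = "HSG"

#: family-set catalogue: name -> (include frontal activity, include intra
#: connectivity, include inter-hemispheric connectivity)
_FAMILY_SETS: dict[str, tuple[bool, bool, bool]] = {
    "posterior-activity": (False, False, False),
    "posterior-activity+intra": (False, True, False),
    "all-activity": (True, False, False),
    "all-activity+intra": (True, True, False),
    "all-activity+intra+inter": (True, True, True),
}

_SCOPES = ("L", "R", "L+R")
_FAMILY_ORDER = ("logreg", "svm")  # tie-break order


@dataclass(frozen=True)
class FeatureCombination:
    """A named subset of the 14 features (hemisphere scope x family set)."""

    name: str
    scope: str
    family_set: str
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [f for f in self.features if f not in FEATURE_NAMES]
        if unknown:
            raise ValueError(f"unknown features {unknown}")
        if self.scope in ("L", "R"):
            other = "R" if self.scope == "L" else "L"
            banned = [f for f in self.features if f.endswith(f"_{other}")]
            if banned:
                raise ValueError(
                    f"scope {self.scope} combination contains contralateral "
                    f"features {banned}"
                )


def _combo_features(scope: str, family_set: str) -> tuple[str, ...]:
    frontal, intra, inter = _FAMILY_SETS[family_set]
    hemis = ("L", "R") if scope == "L+R" else (scope,)
    feats: list[str] = []
    for h in hemis:
        feats += [f"iaf_posterior_{h}", f"amp_posterior_{h}"]
        if frontal:
            feats += [f"iaf_frontal_{h}", f"amp_frontal_{h}"]
        if intra:
            feats += [f"wpli_intra_{h}", f"tli_intra_{h}"]
    if inter:
        feats += ["wpli_inter", "tli_inter"]
    return tuple(f for f in FEATURE_NAMES if f in feats)


def enumerate_combinations(
    scopes: tuple[str, ...] = _SCOPES,
    family_sets: tuple[str, ...] | None = None,
) -> list[FeatureCombination]:
    """The default 15-entry catalogue: 3 hemisphere scopes x 5 family sets."""
    family_sets = tuple(_FAMILY_SETS) if family_sets is None else family_sets
    if not scopes or not family_sets:
        raise ValueError("catalogue must contain at least one combination")
    out = []
    for scope in scopes:
        for fam in family_sets:
            out.append(
                FeatureCombination(
                    name=f"{scope}:{fam}",
                    scope=scope,
                    family_set=fam,
                    features=_combo_features(scope, fam),
                )
            )
    return out


@dataclass
class SearchGrid:
    """Joint search space of the inner loop."""

    combinations: list[FeatureCombination]
    families: tuple[str, ...] = _FAMILY_ORDER
    C_values: tuple[float, ...] = (0.1, 0.2, 0.3)

    def __post_init__(self) -> None:
        if not self.combinations or not self.families or not self.C_values:
            raise ValueError("search grid must be non-empty")
        if any(c <= 0 for c in self.C_values):
            raise ValueError("C values must be positive")
        for f in self.families:
            if f not in _FAMILY_ORDER:
                raise ValueError(f"unknown classifier family {f!r}")


def default_grid() -> SearchGrid:
    return SearchGrid(combinations=enumerate_combinations())


def _make_model(family: str, C: float):
    if family == "svm":
        return SVC(kernel="linear", C=C)
    return LogisticRegression(C=C, solver="liblinear")  # L2 penalty (default)


def _fast_linear_fit(family: str, C: float, X: np.ndarray, y: np.ndarray):
    """Linear decision boundary (w, b) via the same C solvers the public
    estimators wrap (libsvm / liblinear), minus the per-call estimator
    overhead.  Used only for inner-loop scoring; oriented so that positive
    decisions mean class 1.  Equivalence with the public estimators is
    asserted in the test suite.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    if _libsvm is None or _fit_liblinear is None:  # pragma: no cover
        model = _make_model(family, C).fit(X, y)
        return model.coef_.ravel(), float(model.intercept_[0])
    if family == "svm":
        out = _libsvm.fit(X, y.astype(np.float64), svm_type=0, kernel="linear", C=C)
        w = (out[3] @ out[1]).ravel()
        b = float(out[4][0])
    else:
        coef, intercept, _ = _fit_liblinear(
            X, y, C=C, fit_intercept=True, intercept_scaling=1.0,
            class_weight=None, penalty="l2", dual=False, verbose=0,
            max_iter=1000, tol=1e-4, random_state=0, loss="logistic_regression",
        )
        w = coef.ravel()
        b = float(intercept[0]) if np.ndim(intercept) else float(intercept)
    dec = X @ w + b
    pos, neg = y == 1, y == 0
    if pos.any() and neg.any() and dec[pos].mean() < dec[neg].mean():
        w, b = -w, -b
    return w, b


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos = y_true == 1
    neg = ~pos
    sens = np.mean(y_pred[pos] == 1) if pos.any() else np.nan
    spec = np.mean(y_pred[neg] == 0) if neg.any() else np.nan
    return np.nanmean([sens, spec])


def _rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney rank AUC; ties contribute 0.5."""
    n_pos = int(np.sum(y_true == 1))
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classification_metrics(
    tp: int,
    fn: int,
    tn: int,
    fp: int,
    y_true: np.ndarray | None = None,
    scores: np.ndarray | None = None,
) -> dict[str, float]:
    """Sensitivity, specificity, balanced accuracy and rank AUC.

    The positive class is the high-schizotypy group.  Metrics that are
    undefined for a fold (single-class test set) come back as NaN.
    """
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    ba = (sens + spec) / 2.0
    auc = float("nan")
    if y_true is not None and scores is not None:
        auc = _rank_auc(np.asarray(y_true), np.asarray(scores))
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": ba,
        "auc": auc,
    }


def _standardize(train: np.ndarray, *others: np.ndarray):
    """Z-score columns with training-set statistics only."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return tuple((arr - mu) / sd for arr in (train, *others))


def _select_best(
    X_train: np.ndarray,
    y_train: np.ndarray,
    grid: SearchGrid,
    feature_index: dict[str, int],
    k_inner: int,
    seed: int,
) -> tuple[FeatureCombination, str, float]:
    """Inner stratified CV over the joint grid; winner by mean balanced accuracy.

    Ties prefer fewer features, then lower C, then logistic regression
    before the SVM, then catalogue order.
    """
    counts = np.bincount(y_train, minlength=2)
    k = min(k_inner, int(counts.min()))
    if k < 2:
        raise ValueError("inner CV needs at least 2 subjects per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    col_idx = {c.name: [feature_index[f] for f in c.features] for c in grid.combinations}
    configs = [
        (ci, fi, Ci)
        for ci in range(len(grid.combinations))
        for fi in range(len(grid.families))
        for Ci in range(len(grid.C_values))
    ]
    ba_sum = np.zeros(len(configs))
    n_folds = 0
    for tr, va in skf.split(X_train, y_train):
        Xtr, Xva = _standardize(X_train[tr], X_train[va])
        ytr, yva = y_train[tr], y_train[va]
        sub_tr = {
            c.name: np.ascontiguousarray(Xtr[:, col_idx[c.name]])
            for c in grid.combinations
        }
        sub_va = {c.name: Xva[:, col_idx[c.name]] for c in grid.combinations}
        for ki, (ci, fi, Ci) in enumerate(configs):
            name = grid.combinations[ci].name
            w, b = _fast_linear_fit(
                grid.families[fi], grid.C_values[Ci], sub_tr[name], ytr
            )
            pred = (sub_va[name] @ w + b > 0).astype(int)
            ba_sum[ki] += _balanced_accuracy(yva, pred)
        n_folds += 1
    mean_ba = ba_sum / n_folds

    def sort_key(ki: int):
        ci, fi, Ci = configs[ki]
        combo = grid.combinations[ci]
        fam_rank = _FAMILY_ORDER.index(grid.families[fi])
        return (-mean_ba[ki], len(combo.features), grid.C_values[Ci], fam_rank, ci)

    best = min(range(len(configs)), key=sort_key)
    ci, fi, Ci = configs[best]
    return grid.combinations[ci], grid.families[fi], grid.C_values[Ci]


def _run_outer_fold(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    grid: SearchGrid,
    feature_index: dict[str, int],
    k_inner: int,
    seed: int,
) -> tuple[tuple[FeatureCombination, str, float], dict[str, float], np.ndarray, np.ndarray]:
    """Select on the outer training set only, then score the held-out fold."""
    Xtr_all, ytr = X[train_idx], y[train_idx]
    combo, family, C = _select_best(Xtr_all, ytr, grid, feature_index, k_inner, seed)
    cols = [feature_index[f] for f in combo.features]
    Xtr, Xte = _standardize(Xtr_all, X[test_idx])
    model = _make_model(family, C)
    model.fit(Xtr[:, cols], ytr)
    yte = y[test_idx]
    pred = model.predict(Xte[:, cols])
    scores = model.decision_function(Xte[:, cols])
    tp = int(np.sum((yte == 1) & (pred == 1)))
    fn = int(np.sum((yte == 1) & (pred == 0)))
    tn = int(np.sum((yte == 0) & (pred == 0)))
    fp = int(np.sum((yte == 0) & (pred == 1)))
    metrics = classification_metrics(tp, fn, tn, fp, yte, scores)
    metrics.update(tp=tp, fn=fn, tn=tn, fp=fp)
    return (combo, family, C), metrics, yte, scores


@dataclass
class CVReport:
    """Everything the nested CV produced."""

    records: pd.DataFrame            # one row per repetition x outer fold
    per_repetition: pd.DataFrame     # fold-averaged metrics per repetition
    summary: dict[str, float]        # mean/sd of the four metrics
    selection_freq: pd.DataFrame     # combination -> selection frequency (%)
    roc: pd.DataFrame                # common-FPR-grid averaged ROC
    fold_scores: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def nested_cv(
    features: pd.DataFrame,
    grid: SearchGrid | None = None,
    k_outer: int = 10,
    k_inner: int = 10,
    n_repeats: int = 50,
    seed: int = 0,
) -> CVReport:
    """Repeated tenfold nested stratified cross-validation.

    ``features`` must carry a ``group`` column (HSG/LSG) plus the feature
    columns used by the grid.  Rows with missing values in any used
    feature are dropped listwise.  Identical seeds give identical reports.
    """
    if grid is None:
        grid = default_grid()
    used = sorted({f for c in grid.combinations for f in c.features},
                  key=FEATURE_NAMES.index)
    frame = features.dropna(subset=list(used)).reset_index(drop=True)
    y = (frame["group"] == POSITIVE_CLASS).to_numpy().astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    if min(y.sum(), y.size - y.sum()) < k_outer:
        raise ValueError("each class must have at least k_outer subjects")
    X = frame[list(used)].to_numpy(dtype=float)
    feature_index = {f: i for i, f in enumerate(used)}

    ss = np.random.SeedSequence([seed])
    rep_seeds = ss.generate_state(2 * n_repeats) % (2**31)
    rows = []
    fold_scores: list[tuple[np.ndarray, np.ndarray]] = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=k_outer, shuffle=True, random_state=int(rep_seeds[2 * rep])
        )
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            (combo, family, C), metrics, yte, scores = _run_outer_fold(
                X, y, tr, te, grid, feature_index, k_inner,
                seed=int(rep_seeds[2 * rep + 1]) + fold,
            )
            fold_scores.append((yte, scores))
            rows.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "combination": combo.name,
                    "family": family,
                    "C": C,
                    **metrics,
                }
            )
    records = pd.DataFrame(rows)
    metric_cols = ["sensitivity", "specificity", "balanced_accuracy", "auc"]
    per_rep = records.groupby("repeat")[metric_cols].mean().reset_index()
    summary = {}
    for m in metric_cols:
        summary[f"{m}_mean"] = float(per_rep[m].mean())
        summary[f"{m}_sd"] = float(per_rep[m].std(ddof=1)) if n_repeats > 1 else 0.0
    counts = records["combination"].value_counts()
    freq = pd.DataFrame(
        {
            "combination": [c.name for c in grid.combinations],
            "selection_freq_pct": [
                100.0 * counts.get(c.name, 0) / len(records) for c in grid.combinations
            ],
        }
    ).sort_values("selection_freq_pct", ascending=False, kind="stable").reset_index(drop=True)
    roc = aggregate_roc(fold_scores)
    return CVReport(
        records=records,
        per_repetition=per_rep,
        summary=summary,
        selection_freq=freq,
        roc=roc,
        fold_scores=fold_scores,
    )


def aggregate_roc(
    fold_scores: list[tuple[np.ndarray, np.ndarray]],
    n_grid: int = 101,
    ci_level: float = 0.999,
) -> pd.DataFrame:
    """Vertical averaging of per-fold ROC curves on a common FPR grid.

    Returns mean TPR, its SD across folds, and the normal-approximation
    confidence interval of the mean at each grid point.  Folds whose test
    set lacks one of the classes are skipped (and counted in the
    ``n_skipped`` attribute of the frame).
    """
    if len(fold_scores) < 2:
        raise ValueError("need at least two folds to average ROC curves")
    fpr_grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    skipped = 0
    for y_true, scores in fold_scores:
        y_true = np.asarray(y_true)
        if len(np.unique(y_true)) < 2:
            skipped += 1
            continue
        fpr, tpr, _ = roc_curve(y_true, scores)
        interp = np.interp(fpr_grid, fpr, tpr)
        interp[0], interp[-1] = 0.0, 1.0
        tprs.append(interp)
    if not tprs:
        raise ValueError("no fold had both classes present")
    T = np.vstack(tprs)
    mean = T.mean(axis=0)
    sd = T.std(axis=0, ddof=1) if T.shape[0] > 1 else np.zeros(n_grid)
    z = norm.ppf(0.5 + ci_level / 2.0)
    half = z * sd / np.sqrt(T.shape[0])
    out = pd.DataFrame(
        {
            "fpr": fpr_grid,
            "tpr_mean": mean,
            "tpr_sd": sd,
            "ci_lo": np.clip(mean - half, 0, 1),
            "ci_hi": np.clip(mean + half, 0, 1),
        }
    )
    out.attrs["n_curves"] = T.shape[0]
    out.attrs["n_skipped"] = skipped
    return out


def ranking_report(report: CVReport) -> pd.DataFrame:
    """Combination selection frequencies (%), ordered, summing to 100."""
    return report.selection_freq.copy()
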