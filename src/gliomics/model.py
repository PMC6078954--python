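"""L1-penalized predictive modeling of molecular subtype from radiomic features.

The workflow mirrors penalized-regression practice with glmnet-style
conventions: an institution-balanced random train/validation split, an
L1-penalized logistic (binomial) or multinomial-logit fit along a descending
lambda path, lambda chosen at the minimum cross-validated deviance
(lambda_min), an unpenalized refit on the selected features, and evaluation
by accuracy / sensitivity / specificity / PPV / NPV (binary) or accuracy plus
the confusion matrix (3-class).  The whole chain can be repeated over fresh
splits, with and without the atlas-occupancy location features, and the two
arms compared with an exact McNemar test on pooled validation predictions.

Feature standardization (zero mean, unit variance) is always computed on the
training portion only and applied to held-out data, including inside each CV
fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.contingency_tables import mcnemar

from .features import feature_columns

__all__ = [
    "SplitSpec",
    "FitResult",
    "Metrics",
    "ComparisonResult",
    "institution_balanced_split",
    "lasso_lambda_max",
    "fit_lasso_cv",
    "refit_and_evaluate",
    "compute_metrics",
    "repeat_and_compare",
    "idh_labels",
    "select_feature_columns",
]

TRAIN_FRACTION_DEFAULT = 111 / 169  # the modeled 111/58 split
_COEF_TOL = 1e-6  # |coefficient| above this counts as selected


@dataclass
class SplitSpec:
    """Institution-balanced random split specification."""

    train_fraction: float = TRAIN_FRACTION_DEFAULT
    seed: int = 0
    balance_key: str = "institution"

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


def institution_balanced_split(manifest: pd.DataFrame, spec: SplitSpec):
    """Split case ids into train/validation, balancing institutions.

    Each institution contributes round(n_i * fraction) training cases via
    largest-remainder rounding, adjusted so the total equals
    round(N * fraction) exactly; the within-institution choice is random
    given ``spec.seed``.  Returns (train_ids, validation_ids).
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    rng = np.random.default_rng(spec.seed)
    key = spec.balance_key
    n_total = len(manifest)
    target = int(round(n_total * spec.train_fraction))

    groups = manifest.groupby(key, sort=True)
    names = list(groups.groups)
    sizes = np.array([len(groups.get_group(g)) for g in names])
    quotas = sizes * spec.train_fraction
    counts = np.floor(quotas).astype(int)
    short = target - counts.sum()
    # ties broken toward larger institutions, then group order, for determinism
    order = sorted(
        range(len(names)),
        key=lambda i: (-(quotas[i] - counts[i]), -sizes[i], i),
    )
    for i in order[:short]:
        counts[i] += 1

    train_ids, val_ids = [], []
    for g, k in zip(names, counts):
        ids = groups.get_group(g)["case_id"].to_numpy()
        perm = rng.permutation(len(ids))
        train_ids += list(ids[perm[:k]])
        val_ids += list(ids[perm[k:]])
    return sorted(train_ids), sorted(val_ids)


class _Standardizer:
    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.sd = sd

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def lasso_lambda_max(X: np.ndarray, y: np.ndarray, family: str) -> float:
    """Smallest penalty that shrinks every coefficient to zero.

    For standardized X this is max_j |x_j . (y - ybar)| / n (binomial) or the
    max over classes of the analogous score with one-hot class indicators
    (multinomial).
    """
    n = X.shape[0]
    Xs = _Standardizer(X)(X)
    if family == "binomial":
        classes = np.unique(y)
        y01 = (y == classes[-1]).astype(float)
        return float(np.abs(Xs.T @ (y01 - y01.mean())).max() / n)
    classes = np.unique(y)
    Y = (y[:, None] == classes[None, :]).astype(float)
    resid = Y - Y.mean(axis=0)
    return float(np.abs(Xs.T @ resid).max() / n)


def _deviance(model, Xs: np.ndarray, y: np.ndarray) -> float:
    proba = model.predict_proba(Xs)
    idx = np.searchsorted(model.classes_, y)
    p = np.clip(proba[np.arange(len(y)), idx], 1e-12, 1.0)
    return float(-2.0 * np.log(p).sum())


def _make_estimator(family: str, lam: float, n: int, tol: float = 1e-4) -> LogisticRegression:
    c = 1.0 / (n * lam)
    solver = "liblinear" if family == "binomial" else "saga"
    return LogisticRegression(
        l1_ratio=1.0, C=c, solver=solver, max_iter=300, tol=tol,
    )


@dataclass
class FitResult:
    """Outcome of a cross-validated LASSO path fit."""

    task: str
    family: str
    classes: np.ndarray
    lambda_path: np.ndarray
    cv_deviance: np.ndarray
    lambda_min: float
    coefficients: pd.DataFrame  # features x classes (one column for binomial)
    selected: list = field(default_factory=list)
    used_location: bool = True

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def fit_lasso_cv(
    X: pd.DataFrame, y, family: str = "binomial", n_folds: int = 10,
    seed: int = 0, n_lambdas: int = 30, lambda_min_ratio: float = 0.01,
    lambda_path: np.ndarray | None = None, task: str = "",
) -> FitResult:
    """L1-penalized logistic / multinomial fit with CV-selected lambda_min.

    The lambda path descends log-linearly from lambda_max (all-zero model) to
    lambda_max * ``lambda_min_ratio``; the CV loss is the held-out deviance.
    Selected features are those with a nonzero coefficient (any class) at
    lambda_min.
    """
    if family not in ("binomial", "multinomial"):
        raise ValueError(f"unknown family {family!r}")
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y contains a single class")
    if family == "binomial" and classes.size != 2:
        raise ValueError("binomial family needs exactly 2 classes")
    if n_folds > len(y):
        raise ValueError("more CV folds than samples")
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    n = Xa.shape[0]

    if lambda_path is None:
        lam_max = lasso_lambda_max(Xa, y, family)
        lambda_path = lam_max * np.logspace(0, np.log10(lambda_min_ratio), n_lambdas)
    lambda_path = np.asarray(lambda_path, dtype=float)

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros(lambda_path.size)
    for tr, te in cv.split(Xa, y):
        std = _Standardizer(Xa[tr])
        Xtr, Xte = std(Xa[tr]), std(Xa[te])
        model = None
        for j, lam in enumerate(lambda_path):
            # a looser tolerance is enough for lambda selection; the final
            # fit below is run at full precision
            est = _make_estimator(family, lam, len(tr), tol=1e-3)
            if model is not None:
                est.warm_start = True
                est.coef_ = model.coef_.copy()
                est.intercept_ = model.intercept_.copy()
            est.fit(Xtr, y[tr])
            model = est
            dev[j] += _deviance(est, Xte, y[te])
    dev /= n
    lambda_min = float(lambda_path[int(np.argmin(dev))])

    std = _Standardizer(Xa)
    final = _make_estimator(family, lambda_min, n)
    final.fit(std(Xa), y)
    coef = final.coef_.T  # features x classes (1 column for binomial)
    cols = [str(c) for c in final.classes_] if coef.shape[1] > 1 else ["coef"]
    coefficients = pd.DataFrame(coef, index=names, columns=cols)
    selected = [f for f, c in zip(names, np.abs(coef).max(axis=1)) if c > _COEF_TOL]
    return FitResult(
        task=task, family=family, classes=classes,
        lambda_path=lambda_path, cv_deviance=dev, lambda_min=lambda_min,
        coefficients=coefficients, selected=selected,
    )


@dataclass
class Metrics:
    """Classification metrics; binary tasks also carry rate metrics."""

    task: str
    n: int
    accuracy: float
    confusion: pd.DataFrame
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None

    def as_dict(self) -> dict:
        d = {"n": self.n, "accuracy": self.accuracy}
        for k in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def compute_metrics(y_true, y_pred, task: str = "subtype_3class",
                    pos_label=None) -> Metrics:
    """Accuracy plus confusion matrix; binary adds sens/spec/PPV/NPV."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(np.concatenate([y_true, y_pred]))
    cm = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    acc = float((y_true == y_pred).mean())
    m = Metrics(task=task, n=len(y_true), accuracy=acc, confusion=cm)
    if task == "idh_binary":
        if pos_label is None:
            pos_label = classes[0]
        tp = int(((y_true == pos_label) & (y_pred == pos_label)).sum())
        tn = int(((y_true != pos_label) & (y_pred != pos_label)).sum())
        fp = int(((y_true != pos_label) & (y_pred == pos_label)).sum())
        fn = int(((y_true == pos_label) & (y_pred != pos_label)).sum())
        m.sensitivity = _safe_div(tp, tp + fn)
        m.specificity = _safe_div(tn, tn + fp)
        m.ppv = _safe_div(tp, tp + fp)
        m.npv = _safe_div(tn, tn + fn)
    return m


class _MajorityModel:
    """Fallback when LASSO selects nothing: predict the majority class."""

    def __init__(self, y: np.ndarray):
        classes, counts = np.unique(y, return_counts=True)
        self.majority = classes[int(np.argmax(counts))]
        self.classes_ = classes

    def predict(self, X) -> np.ndarray:
        return np.full(len(X), self.majority, dtype=object)


def refit_and_evaluate(fit: FitResult, X_train: pd.DataFrame, y_train,
                       X_val: pd.DataFrame, y_val, pos_label=None):
    """Unpenalized refit on the LASSO-selected features, then evaluation.

    Classes are predicted by maximum posterior probability (threshold 0.5 in
    the binary case).  Returns (train_metrics, val_metrics, predictions).
    """
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    unseen = set(y_val) - set(y_train)
    if unseen:
        raise ValueError(f"validation contains class(es) absent at refit: {sorted(unseen)}")
    task = fit.task or ("idh_binary" if fit.family == "binomial" else "subtype_3class")
    if fit.selected:
        cols = fit.selected
        std = _Standardizer(X_train[cols].to_numpy(dtype=float))
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        model.fit(std(X_train[cols].to_numpy(dtype=float)), y_train)
        pred_train = model.predict(std(X_train[cols].to_numpy(dtype=float)))
        pred_val = model.predict(std(X_val[cols].to_numpy(dtype=float)))
    else:
        model = _MajorityModel(y_train)
        pred_train = model.predict(X_train)
        pred_val = model.predict(X_val)
    m_train = compute_metrics(y_train, pred_train, task, pos_label)
    m_val = compute_metrics(y_val, pred_val, task, pos_label)
    preds = {"train": pred_train, "validation": pred_val}
    return m_train, m_val, preds


def idh_labels(subtypes: pd.Series | np.ndarray) -> np.ndarray:
    """Collapse the three molecular subtypes to IDH-mutant vs IDH-wildtype."""
    s = np.asarray(subtypes)
    return np.where(s == "IDHwt", "IDHwt", "IDHmt")


def select_feature_columns(table: pd.DataFrame, task: str, use_location: bool) -> list[str]:
    """Feature columns for a task, with or without location occupancies.

    Texture and shape features are always included.  When location is on, the
    IDH binary task uses the 10-label structural-atlas occupancies (the only
    scheme that covers the deep white matter) and the 3-class task the
    49-label cortical occupancies; the two schemes are never mixed.
    """
    cols = feature_columns(table)
    texture = [c for c in cols if not c.startswith(("MNI_str_loc", "HrvdOxf_loc"))]
    if not use_location:
        return texture
    prefix = "MNI_str_loc" if task == "idh_binary" else "HrvdOxf_loc"
    return texture + [c for c in cols if c.startswith(prefix)]


@dataclass
class ComparisonResult:
    """Repeated-split metrics for location-on vs location-off arms."""

    task: str
    n_rep: int
    metrics: dict          # arm -> list of per-repetition validation Metrics
    train_metrics: dict    # arm -> list of per-repetition training Metrics
    summary: pd.DataFrame  # mean +/- SD per metric and arm
    mcnemar_p: float | None
    wins: int              # repetitions where location-on >= location-off accuracy
    selected: dict         # arm -> list of selected-feature lists


def _summarize(metrics_by_arm: dict) -> pd.DataFrame:
    rows = []
    for arm, ms in metrics_by_arm.items():
        keys = ms[0].as_dict().keys()
        for k in keys:
            if k == "n":
                continue
            vals = np.array([m.as_dict()[k] for m in ms], dtype=float)
            rows.append((arm, k, vals.mean(), vals.std(ddof=1) if len(vals) > 1 else 0.0))
    return pd.DataFrame(rows, columns=["arm", "metric", "mean", "sd"])


def repeat_and_compare(
    table: pd.DataFrame, task: str = "idh_binary", n_rep: int = 5,
    seed: int = 0, train_fraction: float = TRAIN_FRACTION_DEFAULT,
    n_folds: int = 10, n_lambdas: int = 30, arms: tuple = (True, False),
) -> ComparisonResult:
    """Run the split -> LASSO -> refit -> evaluate chain over fresh splits.

    Each repetition draws a new institution-balanced split and fits each arm
    (with / without location features).  Reports per-metric mean and SD per
    arm and, when both arms run, an exact McNemar test on the pooled
    validation predictions.
    """
    if n_rep < 2:
        raise ValueError("need >= 2 repetitions")
    if task not in ("idh_binary", "subtype_3class"):
        raise ValueError(f"unknown task {task!r}")
    family = "binomial" if task == "idh_binary" else "multinomial"
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_rep)

    manifest = table.reset_index()[["case_id", "institution"]]
    y_all = pd.Series(
        idh_labels(table["subtype"]) if task == "idh_binary" else table["subtype"].to_numpy(),
        index=table.index,
    )
    pos_label = "IDHmt" if task == "idh_binary" else None

    arm_names = {True: "location_on", False: "location_off"}
    metrics = {arm_names[a]: [] for a in arms}
    train_metrics = {arm_names[a]: [] for a in arms}
    selected = {arm_names[a]: [] for a in arms}
    pooled_correct = {arm_names[a]: [] for a in arms}

    for r in range(n_rep):
        split = SplitSpec(train_fraction=train_fraction, seed=int(rep_seeds[r]))
        train_ids, val_ids = institution_balanced_split(manifest, split)
        for use_loc in arms:
            arm = arm_names[use_loc]
            cols = select_feature_columns(table, task, use_loc)
            Xtr, Xva = table.loc[train_ids, cols], table.loc[val_ids, cols]
            ytr, yva = y_all.loc[train_ids].to_numpy(), y_all.loc[val_ids].to_numpy()
            fit = fit_lasso_cv(
                Xtr, ytr, family=family, n_folds=n_folds,
                seed=int(rep_seeds[r]), n_lambdas=n_lambdas, task=task,
            )
            fit.used_location = use_loc
            m_tr, m_va, preds = refit_and_evaluate(fit, Xtr, ytr, Xva, yva, pos_label)
            metrics[arm].append(m_va)
            train_metrics[arm].append(m_tr)
            selected[arm].append(fit.selected)
            pooled_correct[arm].append(preds["validation"] == yva)

    summary = _summarize(metrics)
    wins = 0
    mcnemar_p = None
    if len(arms) == 2:
        on = [m.accuracy for m in metrics["location_on"]]
        off = [m.accuracy for m in metrics["location_off"]]
        wins = int(sum(a >= b for a, b in zip(on, off)))
        c_on = np.concatenate(pooled_correct["location_on"])
        c_off = np.concatenate(pooled_correct["location_off"])
        tbl = [
            [int((c_on & c_off).sum()), int((c_on & ~c_off).sum())],
            [int((~c_on & c_off).sum()), int((~c_on & ~c_off).sum())],
        ]
        mcnemar_p = float(mcnemar(tbl, exact=True).pvalue)
    return ComparisonResult(
        task=task, n_rep=n_rep, metrics=metrics, train_metrics=train_metrics,
        summary=summary, mcnemar_p=mcnemar_p, wins=wins, selected=selected,
    )
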