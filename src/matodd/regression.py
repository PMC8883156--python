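"""Regressing discrimination sensitivity on feature distances.

One row per task condition: predictors are per-feature distances among the
condition's stimuli, the response is the condition's d'.  Five feature
conditions are compared: pixel color means (3 predictors) and pixel color
statistics (12) are fit by plain OLS; the grayscale, grayscale+color, and
full-color texture-statistics conditions (32/44/96 predictors) are fit by
lasso with the penalty tuned so that exactly 18 coefficients are nonzero,
selected by 5-fold cross-validation within the training split.  Accuracy is
summarized over stratified 4:1 train/test resamples as distributions of
test MSE and R^2, with per-task bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionDataset",
    "RegressionResult",
    "FEATURE_CONDITIONS",
    "assemble_dataset",
    "split_train_test",
    "fit_ols",
    "fit_lasso_fixed_support",
    "resample_evaluate",
]

#: feature condition -> (variant, penalized?)
FEATURE_CONDITIONS: dict[str, tuple[str, bool]] = {
    "color_means": ("color_means", False),
    "color_stats": ("color_stats", False),
    "ps_gray": ("ps_gray", True),
    "ps_gray_plus_color": ("ps_gray_plus_color", True),
    "ps_color": ("ps_color", True),
}

DEFAULT_SUPPORT = 18


@dataclass(frozen=True)
class RegressionDataset:
    X: pd.DataFrame  # rows = task conditions, columns = per-feature distances
    y: pd.Series  # d' per condition
    task: pd.Series  # stratification label (material dimension) per condition

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.X) != len(self.task):
            raise ValueError("X, y and task must have equal length")
        if self.X.isna().any().any() or self.y.isna().any():
            raise ValueError("dataset contains missing values")

    def subset(self, idx: np.ndarray) -> "RegressionDataset":
        return RegressionDataset(
            self.X.iloc[idx], self.y.iloc[idx], self.task.iloc[idx]
        )

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class RegressionResult:
    condition_name: str
    mse_distribution: np.ndarray
    r2_distribution: np.ndarray
    per_task_mse: pd.DataFrame  # columns: task, mse, ci_lo, ci_hi
    support: list[str] | None  # selected features of the last penalized fit

    @property
    def median_mse(self) -> float:
        return float(np.median(self.mse_distribution))

    @property
    def median_r2(self) -> float:
        return float(np.median(self.r2_distribution))


def assemble_dataset(
    distance_rows: pd.DataFrame,
    sensitivities: pd.Series,
    task_labels: pd.Series,
) -> RegressionDataset:
    """Join per-condition feature distances with per-condition d'.

    All three inputs are indexed by condition label; a condition present in
    one but not the other is an error naming the gap.
    """
    missing_y = set(distance_rows.index) - set(sensitivities.index)
    missing_x = set(sensitivities.index) - set(distance_rows.index)
    if missing_y or missing_x:
        raise ValueError(
            f"unmatched conditions: no d' for {sorted(missing_y)[:5]}, "
            f"no distances for {sorted(missing_x)[:5]}"
        )
    idx = distance_rows.index
    return RegressionDataset(
        X=distance_rows,
        y=sensitivities.loc[idx],
        task=task_labels.loc[idx],
    )


def split_train_test(
    dataset: RegressionDataset, seed: int, test_fraction: float = 0.2
) -> tuple[RegressionDataset, RegressionDataset]:
    """Stratified 4:1 split keeping the task ratio constant.

    Within each task stratum, round(n * test_fraction) rows go to test with
    a largest-remainder rule (strata with the largest fractional remainders
    receive the extra test rows when rounding down would under-fill the test
    set).  Strata smaller than 5 rows are pooled into one stratum with a
    warning.
    """
    rng = np.random.default_rng(seed)
    tasks = dataset.task.to_numpy()
    labels = pd.unique(tasks)
    strata: dict[str, np.ndarray] = {}
    small: list[np.ndarray] = []
    for t in labels:
        idx = np.flatnonzero(tasks == t)
        if len(idx) < 5:
            small.append(idx)
        else:
            strata[t] = idx
    if small:
        logger.warning(
            "%d strata smaller than 5 rows pooled for splitting", len(small)
        )
        strata["__pooled__"] = np.concatenate(small)

    n_total = len(dataset)
    target_test = int(round(n_total * test_fraction))
    floors = {}
    remainders = {}
    for t, idx in strata.items():
        exact = len(idx) * test_fraction
        floors[t] = int(np.floor(exact))
        remainders[t] = exact - floors[t]
    shortfall = target_test - sum(floors.values())
    order = sorted(strata, key=lambda t: -remainders[t])
    extra = set(order[: max(0, shortfall)])

    test_idx: list[np.ndarray] = []
    for t, idx in strata.items():
        k = floors[t] + (1 if t in extra else 0)
        k = min(max(k, 1), len(idx) - 1)  # every stratum in both halves
        perm = rng.permutation(idx)
        test_idx.append(perm[:k])
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(n_total), test)
    return dataset.subset(train), dataset.subset(test)


@dataclass(frozen=True)
class LinearFit:
    intercept: float
    coef: pd.Series
    x_mean: pd.Series
    x_sd: pd.Series

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xs = (X - self.x_mean) / self.x_sd
        return self.intercept + Xs.to_numpy() @ self.coef.to_numpy()

    @property
    def support(self) -> list[str]:
        return list(self.coef.index[self.coef.to_numpy() != 0.0])


def _standardize_train(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    mean = X.mean()
    sd = X.std(ddof=0).replace(0.0, 1.0)
    return (X - mean) / sd, mean, sd


def fit_ols(train: RegressionDataset) -> LinearFit:
    """Ordinary least squares with intercept on standardized predictors."""
    if train.X.shape[1] > len(train):
        raise ValueError("more columns than rows; OLS is underdetermined")
    Xs, mean, sd = _standardize_train(train.X)
    A = np.column_stack([np.ones(len(train)), Xs.to_numpy()])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name the offending columns for the caller
        _, R = np.linalg.qr(A)
        bad = [
            train.X.columns[j - 1]
            for j in range(1, A.shape[1])
            if abs(R[j, j]) < 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(A, train.y.to_numpy(), rcond=None)
    return LinearFit(
        intercept=float(beta[0]),
        coef=pd.Series(beta[1:], index=train.X.columns),
        x_mean=mean,
        x_sd=sd,
    )


def _support_size(coefs: np.ndarray) -> np.ndarray:
    return np.count_nonzero(np.abs(coefs) > 1e-12, axis=0)


def fit_lasso_fixed_support(
    train: RegressionDataset,
    k: int = DEFAULT_SUPPORT,
    cv_folds: int = 5,
    seed: int = 0,
    lambda_mode: str = "cv_min",
) -> LinearFit:
    """Lasso with the penalty tuned to exactly ``k`` nonzero coefficients.

    The regularization path is scanned (log-spaced, refined by bisection
    between the bracketing penalties) for penalties whose fitted support has
    exactly k features; when the path's support size jumps past k, the
    largest support not exceeding k is used instead, with a log message.
    Among the candidate penalties, ``lambda_mode="cv_min"`` picks the one
    minimizing 5-fold cross-validated MSE within the training set;
    ``lambda_mode="first"`` keeps the least-penalized candidate.
    Predictors are standardized on the training split only.
    """
    if k >= train.X.shape[1]:
        raise ValueError("support target must be below the number of columns")
    if lambda_mode not in ("cv_min", "first"):
        raise ValueError("lambda_mode must be 'cv_min' or 'first'")
    Xs, mean, sd = _standardize_train(train.X)
    Xm = Xs.to_numpy()
    ym = train.y.to_numpy()

    alphas, coefs, _ = lasso_path(Xm, ym, alphas=120, eps=1e-4)
    sizes = _support_size(coefs)

    def refine(a_hi: float, a_lo: float) -> list[float]:
        """Bisect (a_lo, a_hi) for alphas achieving support exactly k."""
        found = []
        for _ in range(40):
            a_mid = np.sqrt(a_hi * a_lo)
            s = _support_size(
                Lasso(alpha=a_mid, max_iter=50_000).fit(Xm, ym).coef_[:, None]
            )[0]
            if s == k:
                found.append(a_mid)
                break
            if s < k:
                a_hi = a_mid
            else:
                a_lo = a_mid
        return found

    candidates = list(alphas[sizes == k])
    if not candidates:
        # path jumped past k: bisect each bracketing alpha pair
        below = np.flatnonzero(sizes < k)
        above = np.flatnonzero(sizes > k)
        if len(below) and len(above):
            candidates = refine(alphas[below[-1]], alphas[above[0]])
    if not candidates:
        under = sizes[sizes <= k]
        if len(under) == 0:
            raise ValueError("lasso path never reaches a support <= k")
        best = under.max()
        logger.info(
            "no penalty achieves support %d; using largest support below: %d",
            k,
            best,
        )
        candidates = [float(alphas[sizes == best][0])]

    if lambda_mode == "first" or len(candidates) == 1:
        alpha = float(candidates[0])
    else:
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        cv_mse = []
        for a in candidates:
            errs = []
            for tr, te in kf.split(Xm):
                model = Lasso(alpha=a, max_iter=50_000).fit(Xm[tr], ym[tr])
                errs.append(float(np.mean((model.predict(Xm[te]) - ym[te]) ** 2)))
            cv_mse.append(np.mean(errs))
        alpha = float(candidates[int(np.argmin(cv_mse))])

    model = Lasso(alpha=alpha, max_iter=100_000).fit(Xm, ym)
    coef = model.coef_.copy()
    coef[np.abs(coef) <= 1e-12] = 0.0
    return LinearFit(
        intercept=float(model.intercept_),
        coef=pd.Series(coef, index=train.X.columns),
        x_mean=mean,
        x_sd=sd,
    )


def _test_metrics(fit: LinearFit, test: RegressionDataset) -> tuple[float, float]:
    pred = fit.predict(test.X)
    resid = test.y.to_numpy() - pred
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((test.y.to_numpy() - test.y.to_numpy().mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return mse, r2


def resample_evaluate(
    dataset: RegressionDataset,
    condition_name: str,
    n_resamples: int = 10_000,
    seed: int = 0,
    support: int = DEFAULT_SUPPORT,
    cv_folds: int = 5,
    lambda_mode: str = "cv_min",
) -> RegressionResult:
    """Distribution of out-of-sample error over stratified resamples.

    Each resample draws a fresh 4:1 stratified split, fits the condition's
    model (OLS for the pixel conditions, fixed-support lasso for the
    texture-statistics conditions) on the training split only, and records
    test MSE and R^2.  Per-task MSEs are summarized with percentile
    bootstrap 95% confidence intervals over the resamples.
    """
    if condition_name not in FEATURE_CONDITIONS:
        raise ValueError(f"unknown condition {condition_name!r}")
    _, penalized = FEATURE_CONDITIONS[condition_name]
    rng = np.random.default_rng(seed)
    mses, r2s = [], []
    per_task: dict[str, list[float]] = {t: [] for t in pd.unique(dataset.task)}
    last_support: list[str] | None = None
    for i in range(n_resamples):
        split_seed = int(rng.integers(2**31))
        train, test = split_train_test(dataset, seed=split_seed)
        if penalized:
            fit = fit_lasso_fixed_support(
                train, k=support, cv_folds=cv_folds, seed=split_seed,
                lambda_mode=lambda_mode,
            )
            last_support = fit.support
        else:
            fit = fit_ols(train)
        mse, r2 = _test_metrics(fit, test)
        mses.append(mse)
        r2s.append(r2)
        pred = fit.predict(test.X)
        resid2 = (test.y.to_numpy() - pred) ** 2
        for t in pd.unique(test.task):
            sel = test.task.to_numpy() == t
            per_task[t].append(float(resid2[sel].mean()))

    rows = []
    for t, errs in per_task.items():
        errs = np.asarray(errs)
        if len(errs) == 0:
            continue
        rows.append(
            {
                "task": t,
                "mse": float(errs.mean()),
                "ci_lo": float(np.percentile(errs, 2.5)),
                "ci_hi": float(np.percentile(errs, 97.5)),
            }
        )
    return RegressionResult(
        condition_name=condition_name,
        mse_distribution=np.asarray(mses),
        r2_distribution=np.asarray(r2s),
        per_task_mse=pd.DataFrame(rows),
        support=last_support,
    )
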