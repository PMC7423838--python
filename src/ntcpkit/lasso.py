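"""Bootstrap LASSO logistic stability selection.

Workflow: a stratified 2/3-1/3 train/validation split (balanced on cancer
subtype x outcome), then 1,000 bootstrap resamples of the training set.
Each resample is fit with L1-penalized logistic regression (predictors
standardized with training statistics, penalty weight chosen by seeded
k-fold cross-validation) and scored on the fixed validation set by the
Mann-Whitney AUC.  Feature selection frequencies and pairwise co-selection
frequencies summarize stability; the final model is a single LASSO refit on
the full training data with bootstrap standard errors and percentile CIs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .errors import DataError, DegenerateOutcomeError, ParameterError, UndefinedStatisticError

logger = logging.getLogger(__name__)

#: Coefficients with original-scale magnitude above this count as selected.
SELECTION_TOL = 1e-8

#: Grid of inverse penalty strengths searched by cross-validation.
_CS_GRID = np.logspace(-3.0, 2.0, 16)


@dataclass(frozen=True)
class LambdaRule:
    """How the L1 penalty weight is chosen.

    ``kind="cv"``: per-fit k-fold cross-validated deviance minimum (seeded
    folds).  ``kind="fixed"``: use ``lam`` directly; ``lam=0`` yields the
    unpenalized maximum-likelihood fit.
    """

    kind: str = "cv"
    folds: int = 5
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("cv", "fixed"):
            raise ParameterError(f"unknown lambda rule {self.kind!r}")
        if self.kind == "fixed" and self.lam < 0:
            raise ParameterError("lambda must be >= 0")
        if self.kind == "cv" and self.folds < 2:
            raise ParameterError("cv folds must be >= 2")


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    strata: Mapping[str, str]
    fractions: tuple[float, float] = (2 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.validation_ids):
            raise ParameterError("train and validation sets overlap")


@dataclass(frozen=True)
class LassoFit:
    """One fitted L1 logistic model, coefficients on the original scale."""

    coefficients: dict[str, float]
    intercept: float
    lam: float

    @property
    def selected(self) -> frozenset[str]:
        return frozenset(
            f for f, c in self.coefficients.items() if abs(c) > SELECTION_TOL
        )

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.intercept)
        for f, c in self.coefficients.items():
            eta += c * X[f].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class BootstrapEnsemble:
    """Aggregate of the bootstrap replicates."""

    features: list[str]
    coef_matrix: np.ndarray  # (n_boot, n_features), original scale
    intercepts: np.ndarray  # (n_boot,)
    validation_aucs: np.ndarray  # (n_boot,)
    seed: int
    n_redrawn: int = 0
    run_id: str = ""

    @property
    def n_boot(self) -> int:
        return int(self.coef_matrix.shape[0])

    @property
    def mean_auc(self) -> float:
        return float(self.validation_aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.validation_aucs.std(ddof=1)) if self.n_boot > 1 else 0.0

    @property
    def selection_matrix(self) -> np.ndarray:
        return (np.abs(self.coef_matrix) > SELECTION_TOL).astype(int)

    @property
    def selection_counts(self) -> pd.Series:
        return pd.Series(self.selection_matrix.sum(axis=0), index=self.features, name="count")

    @property
    def pair_counts(self) -> pd.DataFrame:
        s = self.selection_matrix
        return pd.DataFrame(s.T @ s, index=self.features, columns=self.features)


@dataclass(frozen=True)
class FinalModelRow:
    variable: str
    coefficient: float
    std: float
    odds_ratio: float
    ci95: tuple[float, float]


def odds_ratio(coefficient: float, decimals: int = 3) -> float:
    """Odds-ratio scale of a logistic coefficient, rounded for reporting."""
    return float(round(np.exp(coefficient), decimals))


# ---------------------------------------------------------------------------
# Split


def stratified_split(
    ids: Sequence[str],
    subtype: Mapping[str, str],
    outcome: Mapping[str, int],
    fractions: tuple[float, float] = (2 / 3, 1 / 3),
    seed: int = 0,
) -> SplitPlan:
    """Train/validation split balanced within subtype x outcome strata.

    Within each stratum of size n, round(n * train_fraction) patients go to
    training (shuffled, seeded); a stratum of size 1 goes to training with
    a warning.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError("split fractions must sum to 1")
    missing = [i for i in ids if i not in subtype or i not in outcome]
    if missing:
        raise DataError(f"missing subtype/outcome labels for: {missing[:5]}")
    rng = np.random.default_rng(seed)
    strata: dict[tuple[str, int], list[str]] = {}
    for pid in ids:
        strata.setdefault((str(subtype[pid]), int(outcome[pid])), []).append(pid)

    train: list[str] = []
    val: list[str] = []
    for key in sorted(strata):
        members = list(strata[key])
        if len(members) == 1:
            warnings.warn(f"stratum {key} has a single patient; assigned to training")
            train.extend(members)
            continue
        rng.shuffle(members)
        n_train = int(round(len(members) * fractions[0]))
        n_train = min(max(n_train, 1), len(members) - 1)
        train.extend(members[:n_train])
        val.extend(members[n_train:])
    return SplitPlan(
        train_ids=tuple(sorted(train)),
        validation_ids=tuple(sorted(val)),
        strata={pid: f"{subtype[pid]}|{outcome[pid]}" for pid in ids},
        fractions=fractions,
    )


# ---------------------------------------------------------------------------
# Fitting


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def fit_lasso_logistic(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    lambda_rule: LambdaRule = LambdaRule(),
    seed: int = 0,
) -> LassoFit:
    """L1-penalized logistic fit with coefficients on the original scale.

    Predictors are standardized internally (mean 0, unit variance); the
    objective is the negative log-likelihood plus lam * sum |beta_i| with
    an unpenalized intercept.  ``lam`` maps to scikit-learn's ``C`` as
    ``C = 1/lam``.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("outcome vector contains a single class")
    if X.shape[0] != y.shape[0]:
        raise ParameterError("X and y length mismatch")
    cols = list(X.columns)
    Xs, mu, sd = _standardize(X.to_numpy(dtype=float))

    if lambda_rule.kind == "fixed" and lambda_rule.lam == 0.0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=5000, tol=1e-10)
            model.fit(Xs, y)
        lam = 0.0
    elif lambda_rule.kind == "fixed":
        # liblinear penalizes the intercept; a large intercept_scaling makes
        # that penalty negligible
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            warnings.filterwarnings("ignore", message="Inconsistent values: penalty=l1")
            # extreme penalties on the CV grid may stop at max_iter; those
            # fits lose the CV comparison anyway
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = LogisticRegression(
                penalty="l1",
                C=1.0 / lambda_rule.lam,
                solver="liblinear",
                intercept_scaling=1e4,
                max_iter=5000,
                tol=1e-8,
                random_state=seed,
            )
            model.fit(Xs, y)
        lam = lambda_rule.lam
    else:
        folds = min(lambda_rule.folds, int(np.bincount(y).min()))
        if folds < 2:
            # too few minority events for CV: fall back to a moderate penalty
            logger.debug("CV infeasible (minority class too small); using lam=1")
            return fit_lasso_logistic(X, y, LambdaRule(kind="fixed", lam=1.0), seed)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            # scikit-learn 1.8+ emits FutureWarnings for the penalty= API
            warnings.simplefilter("ignore", FutureWarning)
            warnings.filterwarnings("ignore", message="Inconsistent values: penalty=l1")
            # extreme penalties on the CV grid may stop at max_iter; those
            # fits lose the CV comparison anyway
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = LogisticRegressionCV(
                Cs=_CS_GRID,
                cv=cv,
                penalty="l1",
                solver="liblinear",
                intercept_scaling=1e4,
                scoring="neg_log_loss",
                max_iter=5000,
                tol=1e-8,
                refit=True,
                random_state=seed,
            )
            model.fit(Xs, y)
            lam = float(1.0 / model.C_[0])

    beta_std = model.coef_.ravel()
    beta = beta_std / sd
    intercept = float(model.intercept_[0] - (beta_std * mu / sd).sum())
    return LassoFit(
        coefficients={c: float(b) for c, b in zip(cols, beta)},
        intercept=intercept,
        lam=lam,
    )


def evaluate_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of positive-negative pairs correctly
    ordered, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("AUC undefined with a single class")
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Bootstrap ensemble


def bootstrap_ensemble(
    X_train: pd.DataFrame,
    y_train: np.ndarray | pd.Series,
    X_val: pd.DataFrame,
    y_val: np.ndarray | pd.Series,
    n_boot: int = 1000,
    lambda_rule: LambdaRule = LambdaRule(),
    seed: int = 0,
    run_id: str = "",
) -> BootstrapEnsemble:
    """Fit the bootstrap LASSO ensemble and score the fixed validation set.

    Each replicate resamples the training patients with replacement (same
    n); replicates that draw a single outcome class are redrawn (counted in
    ``n_redrawn``).  Fully reproducible given ``seed``.
    """
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    y_tr = np.asarray(y_train, dtype=int)
    y_va = np.asarray(y_val, dtype=int)
    missing = [f for f in X_train.columns if f not in X_val.columns]
    if missing:
        raise DataError(f"candidate features absent from validation data: {missing}")
    X_val = X_val[list(X_train.columns)]
    if len(np.unique(y_tr)) < 2:
        raise DegenerateOutcomeError("training outcome contains a single class")

    rng = np.random.default_rng(seed)
    n = len(X_train)
    feats = list(X_train.columns)
    coefs = np.zeros((n_boot, len(feats)))
    intercepts = np.zeros(n_boot)
    aucs = np.zeros(n_boot)
    n_redrawn = 0

    Xtr = X_train.reset_index(drop=True)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.unique(y_tr[idx]).size > 1:
                break
            n_redrawn += 1
        fit = fit_lasso_logistic(
            Xtr.iloc[idx], y_tr[idx], lambda_rule, seed=int(rng.integers(2**31 - 1))
        )
        coefs[b] = [fit.coefficients[f] for f in feats]
        intercepts[b] = fit.intercept
        aucs[b] = evaluate_auc(fit.predict_proba(X_val), y_va)
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap replicates", n_redrawn)

    return BootstrapEnsemble(
        features=feats,
        coef_matrix=coefs,
        intercepts=intercepts,
        validation_aucs=aucs,
        seed=seed,
        n_redrawn=n_redrawn,
        run_id=run_id,
    )


def final_model(
    X_train: pd.DataFrame,
    y_train: np.ndarray | pd.Series,
    ensemble: BootstrapEnsemble,
    lambda_rule: LambdaRule = LambdaRule(),
    seed: int = 0,
) -> tuple[list[FinalModelRow], LassoFit]:
    """LASSO refit on the full training data with bootstrap uncertainty.

    Per retained variable: coefficient from the refit, standard error as
    the SD of that coefficient over the ensemble (zeros included), odds
    ratio exp(coefficient), and 95% CI as the exponentiated 2.5th/97.5th
    bootstrap coefficient percentiles.
    """
    if list(X_train.columns) != ensemble.features:
        raise DataError("ensemble features do not match the training columns")
    fit = fit_lasso_logistic(X_train, y_train, lambda_rule, seed=seed)
    retained = sorted(fit.selected)
    if not retained:
        warnings.warn("no variables retained; reporting intercept-only model")

    rows: list[FinalModelRow] = []
    for var in retained:
        j = ensemble.features.index(var)
        draws = ensemble.coef_matrix[:, j]
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append(
            FinalModelRow(
                variable=var,
                coefficient=float(fit.coefficients[var]),
                std=float(draws.std(ddof=1)),
                odds_ratio=odds_ratio(fit.coefficients[var]),
                ci95=(float(np.exp(lo)), float(np.exp(hi))),
            )
        )
    lo, hi = np.percentile(ensemble.intercepts, [2.5, 97.5])
    rows.append(
        FinalModelRow(
            variable="Constant",
            coefficient=float(fit.intercept),
            std=float(ensemble.intercepts.std(ddof=1)),
            odds_ratio=odds_ratio(fit.intercept),
            ci95=(float(np.exp(lo)), float(np.exp(hi))),
        )
    )
    return rows, fit


def final_model_frame(rows: Sequence[FinalModelRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "coefficient": [r.coefficient for r in rows],
            "std": [r.std for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "ci95_low": [r.ci95[0] for r in rows],
            "ci95_high": [r.ci95[1] for r in rows],
        }
    )
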