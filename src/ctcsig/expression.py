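"""Expression signature pipeline.

Housekeeping normalization, tumor-vs-normal differential expression, the
repeated-split L1 (LASSO) training harness against the continuous
recurrence score, and subset-resampling robustness of the selected
model.

The regression target throughout is a recurrence score on the 0-100
scale (an Oncotype-DX-like surrogate for outcome); model quality is
summarized by the Pearson correlation between predicted and observed
scores on training and held-out samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .config import HK_GENES
from .simulate import ExpressionCohort

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "SignatureModel",
    "HarnessResult",
    "RobustnessResult",
    "hk_normalize",
    "differential_expression",
    "split_samples",
    "fit_l1_model",
    "run_harness",
    "subset_robustness",
    "pearson_with_p",
]


@dataclass
class NormalizedMatrix:
    """log2 expression after per-sample housekeeping normalization."""

    values: pd.DataFrame          # genes x samples
    hk_genes: list[str]
    excluded_samples: list[str] = field(default_factory=list)


@dataclass
class SignatureModel:
    """A trained linear signature: sparse per-gene coefficients + intercept."""

    coefficients: pd.Series       # nonzero entries only
    intercept: float
    lambda_: float
    training_meta: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.coefficients.index)

    def signs(self) -> pd.Series:
        """+1/-1 per model gene (zero-coefficient genes are not stored)."""
        return np.sign(self.coefficients).astype(int)

    def predict(self, values: pd.DataFrame) -> pd.Series:
        """Score samples of a genes x samples matrix."""
        x = values.loc[self.coefficients.index]
        return pd.Series(self.intercept + self.coefficients.to_numpy() @ x.to_numpy(),
                         index=values.columns)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "intercept": float(self.intercept),
            "lambda": float(self.lambda_),
            "training_meta": self.training_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        return cls(coefficients=pd.Series(d["coefficients"], dtype=float),
                   intercept=float(d["intercept"]), lambda_=float(d["lambda"]),
                   training_meta=d.get("training_meta", {}))


@dataclass
class HarnessResult:
    """All candidate models from the repeated-split harness."""

    candidates: list[SignatureModel]
    performance: pd.DataFrame     # per iteration: r_train, p_train, r_test, p_test
    selected_index: int

    @property
    def selected(self) -> SignatureModel:
        return self.candidates[self.selected_index]


@dataclass
class RobustnessResult:
    """Per-fraction distributions of subset correlations for a fixed model."""

    r_values: dict[float, np.ndarray]
    p_values: dict[float, np.ndarray]

    def median_r(self, fraction: float) -> float:
        return float(np.median(self.r_values[fraction]))

    def median_p(self, fraction: float) -> float:
        return float(np.median(self.p_values[fraction]))

    def summary(self) -> pd.DataFrame:
        rows = [(f, self.median_r(f), self.median_p(f), len(self.r_values[f]))
                for f in sorted(self.r_values)]
        return pd.DataFrame(rows, columns=["fraction", "median_r", "median_p", "n_rep"])


# ---------------------------------------------------------------------------
# normalization and differential expression
# ---------------------------------------------------------------------------

def hk_normalize(cohort: ExpressionCohort | pd.DataFrame,
                 hk_genes: list[str] | None = None) -> NormalizedMatrix:
    """Normalize counts to the geometric mean of the housekeeping genes.

    ``value(g, i) = log2((count(g, i) + 1) / geomean_{k in HK}(count(k, i) + 1))``

    The +1 pseudocount guards the zeros typical of degraded FFPE
    material.  HK genes are retained in the output (their normalized
    values are meaningful QC), but they are excluded from predictor sets
    downstream.  Samples whose HK counts are all zero carry no usable
    scale and are dropped with a logged record.
    """
    counts = cohort.counts if isinstance(cohort, ExpressionCohort) else cohort
    if hk_genes is None:
        hk_genes = list(HK_GENES)
    missing = [g for g in hk_genes if g not in counts.index]
    if missing:
        raise ValueError(f"housekeeping genes missing from counts: {missing}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")

    hk_counts = counts.loc[hk_genes]
    dead = hk_counts.columns[(hk_counts == 0).all(axis=0)]
    if len(dead):
        logger.warning("excluding %d sample(s) with all-zero HK counts: %s",
                       len(dead), list(dead))
        counts = counts.drop(columns=dead)
        hk_counts = hk_counts.drop(columns=dead)

    log_counts = np.log2(counts + 1.0)
    log_geomean = np.log2(hk_counts + 1.0).mean(axis=0)
    values = log_counts.sub(log_geomean, axis=1)
    return NormalizedMatrix(values=values, hk_genes=list(hk_genes),
                            excluded_samples=list(dead))


def differential_expression(norm: NormalizedMatrix, labels: pd.Series,
                            alpha: float = 0.01) -> pd.DataFrame:
    """Per-gene Welch t-test of tumor vs normal on normalized values.

    Returns a table with ``log2_fc`` (mean tumor - mean normal), raw and
    BH-adjusted p-values, direction, a ``significant`` flag at raw
    ``p < alpha`` (0.01 by default, the conventional volcano-plot
    threshold for this panel), and an ``untestable`` flag for genes
    where the test statistic is undefined (a zero-variance group).
    """
    labels = labels.reindex(norm.values.columns)
    tumor = norm.values.loc[:, (labels == "tumor").to_numpy()]
    normal = norm.values.loc[:, (labels == "normal").to_numpy()]
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p_raw = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
    log2_fc = tumor.mean(axis=1) - normal.mean(axis=1)
    untestable = ~np.isfinite(p_raw)
    p_for_adjust = np.where(untestable, 1.0, p_raw)
    _, p_adj, _, _ = multipletests(p_for_adjust, method="fdr_bh")
    p_adj = np.where(untestable, np.nan, p_adj)

    return pd.DataFrame({
        "log2_fc": log2_fc,
        "t_stat": t_stat,
        "p_value": np.where(untestable, np.nan, p_raw),
        "p_adjusted": p_adj,
        "direction": np.where(log2_fc >= 0, "up", "down"),
        "significant": np.where(untestable, False, p_raw < alpha),
        "untestable": untestable,
    }, index=norm.values.index)


# ---------------------------------------------------------------------------
# splitting and model fitting
# ---------------------------------------------------------------------------

def split_samples(n_samples: int, train_frac: float = 0.6,
                  seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Random exhaustive disjoint train/test partition of ``range(n_samples)``.

    Train size is ``floor(train_frac * n_samples)`` — 339 samples at 60%
    give the 203/136 split, 327 give 196/131.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    if n_samples < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    n_train = int(np.floor(train_frac * n_samples))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def fit_l1_model(norm: NormalizedMatrix | pd.DataFrame, y: pd.Series,
                 lambda_: float | None = None, cv: int = 10,
                 seed: int | None = None, hk_genes: list[str] | None = None,
                 ) -> SignatureModel:
    """L1-penalized linear model of the recurrence score.

    Minimizes ``(1/2n) ||y - X b - b0||^2 + lambda ||b||_1`` with the
    penalty chosen by ``cv``-fold cross-validation at the minimum mean
    CV error (pass ``lambda_`` to skip CV).  Housekeeping genes never
    enter the predictor set.  ``y``'s index selects the training
    samples.  A constant response yields the intercept-only null model
    with a warning.
    """
    if isinstance(norm, NormalizedMatrix):
        values, hk = norm.values, norm.hk_genes
    else:
        values, hk = norm, (hk_genes or [])
    predictors = [g for g in values.index if g not in hk]
    X = values.loc[predictors, y.index].to_numpy().T
    if np.isnan(X).any() or y.isna().any():
        raise ValueError("missing values in predictors or response")
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    if n <= 10:
        raise ValueError("need more than 10 training samples")

    if np.ptp(yv) == 0.0:
        logger.warning("constant response: returning intercept-only model")
        return SignatureModel(coefficients=pd.Series(dtype=float),
                              intercept=float(yv.mean()), lambda_=np.inf,
                              training_meta={"degenerate": "constant-response"})

    if lambda_ is None:
        folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
        fit = LassoCV(cv=folds, alphas=100, max_iter=50_000).fit(X, yv)
        lambda_ = float(fit.alpha_)
        coef, intercept = fit.coef_, float(fit.intercept_)
    else:
        fit = Lasso(alpha=lambda_, max_iter=50_000).fit(X, yv)
        coef, intercept = fit.coef_, float(fit.intercept_)

    nz = np.flatnonzero(coef)
    coefficients = pd.Series(coef[nz], index=[predictors[i] for i in nz])
    return SignatureModel(coefficients=coefficients, intercept=intercept,
                          lambda_=float(lambda_),
                          training_meta={"n_train": n, "cv_folds": cv, "seed": seed})


def pearson_with_p(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series,
                   ) -> tuple[float, float]:
    """Sample Pearson R with the two-sided t-test p-value.

    ``t = R sqrt((n - 2) / (1 - R^2))`` on ``n - 2`` degrees of freedom.
    Degenerate input (length < 3 or a zero-variance vector) raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


# ---------------------------------------------------------------------------
# repeated-split harness and robustness
# ---------------------------------------------------------------------------

def run_harness(norm: NormalizedMatrix | pd.DataFrame, y: pd.Series,
                n_iter: int = 10, train_frac: float = 0.6,
                seeds: list[int] | None = None, cv: int = 10,
                hk_genes: list[str] | None = None) -> HarnessResult:
    """Repeated random-split L1 training with best-iteration selection.

    Each iteration draws its own ``train_frac`` split, fits the CV-tuned
    L1 model on the training side, and records the Pearson R (and
    p-value) of predictions against the score on both sides.  The
    selected iteration maximizes ``mean(R_train, R_test)``; iterations
    with a degenerate fit (no genes selected, or undefined correlation)
    are recorded but excluded from selection.
    """
    if seeds is None:
        seeds = list(range(n_iter))
    if len(seeds) != n_iter:
        raise ValueError("seeds must have length n_iter")
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    samples = list(y.index)
    n = len(samples)

    candidates, rows = [], []
    for it, seed in enumerate(seeds):
        train_idx, test_idx = split_samples(n, train_frac=train_frac, seed=seed)
        train_ids = [samples[i] for i in train_idx]
        test_ids = [samples[i] for i in test_idx]
        model = fit_l1_model(norm, y.loc[train_ids], cv=cv, seed=seed,
                             hk_genes=hk_genes)
        model.training_meta.update({"iteration": it, "split_seed": seed})
        candidates.append(model)
        try:
            if not model.genes:
                raise ValueError("empty model")
            r_tr, p_tr = pearson_with_p(model.predict(values[train_ids]), y.loc[train_ids])
            r_te, p_te = pearson_with_p(model.predict(values[test_ids]), y.loc[test_ids])
            rows.append((it, r_tr, p_tr, r_te, p_te, False))
        except ValueError as exc:
            logger.warning("iteration %d degenerate (%s); excluded from selection", it, exc)
            rows.append((it, np.nan, np.nan, np.nan, np.nan, True))

    perf = pd.DataFrame(rows, columns=["iteration", "r_train", "p_train",
                                       "r_test", "p_test", "degenerate"]).set_index("iteration")
    usable = perf[~perf["degenerate"]]
    if usable.empty:
        raise ValueError("every harness iteration was degenerate")
    mean_r = (usable["r_train"] + usable["r_test"]) / 2.0
    selected = int(mean_r.idxmax())
    return HarnessResult(candidates=candidates, performance=perf, selected_index=selected)


def subset_robustness(model: SignatureModel, norm: NormalizedMatrix | pd.DataFrame,
                      y: pd.Series, fractions: np.ndarray | None = None,
                      n_rep: int = 1000, seed: int | None = None) -> RobustnessResult:
    """Correlation of a *fixed* model over random sample subsets.

    For each fraction ``f``, draws ``n_rep`` subsets of size
    ``floor(f * n)`` without replacement and computes the Pearson R (and
    p) between the model's predictions and the score on each subset.
    Fractions whose subset size drops below 3 are skipped with a
    warning.  The default grid is 10% to 100% in 5% steps.
    """
    if fractions is None:
        fractions = np.round(np.arange(0.10, 1.0001, 0.05), 2)
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    preds = model.predict(values[y.index]).to_numpy()
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    rng = np.random.default_rng(seed)

    r_values: dict[float, np.ndarray] = {}
    p_values: dict[float, np.ndarray] = {}
    for f in fractions:
        size = int(np.floor(f * n))
        if size < 3:
            logger.warning("fraction %.2f gives subset size %d < 3; skipped", f, size)
            continue
        rs = np.empty(n_rep)
        ps = np.empty(n_rep)
        for k in range(n_rep):
            idx = rng.choice(n, size=size, replace=False)
            rs[k], ps[k] = pearson_with_p(preds[idx], yv[idx])
        r_values[float(f)] = rs
        p_values[float(f)] = ps
    return RobustnessResult(r_values=r_values, p_values=p_values)
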