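"""External survival validation.

Transfers a trained signature to an external cohort — signs only for
expression (bridging platform-scale differences), annotated genes for
copy number — stratifies by the threshold maximizing the standardized
log-rank statistic, and compares recurrence-free survival with
Kaplan-Meier curves and the two-group log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .expression import NormalizedMatrix, SignatureModel

logger = logging.getLogger(__name__)

__all__ = [
    "RiskScoreVector",
    "CutpointResult",
    "KmCurve",
    "LogRankResult",
    "sign_only_score",
    "cn_gene_score",
    "optimal_cutpoint",
    "km_estimate",
    "logrank_test",
    "rfs_at",
]


@dataclass
class RiskScoreVector:
    scores: pd.Series
    provenance: str                  # 'sign_only' | 'coefficients' | 'cn_gene_level'
    dropped_genes: list[str] = field(default_factory=list)


@dataclass
class CutpointResult:
    threshold: float
    statistic: float                 # standardized log-rank |Z| at the threshold
    n_low: int
    n_high: int
    minprop: float


@dataclass
class KmCurve:
    """Product-limit survival estimate for one group."""

    label: str
    times: np.ndarray                # ordered distinct observed times
    survival: np.ndarray             # S(t) right after each time
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray


@dataclass
class LogRankResult:
    statistic: float                 # chi-square, 1 df
    p_value: float
    z: float                         # signed standardized statistic (group order)
    observed: dict[str, float]
    expected: dict[str, float]


# ---------------------------------------------------------------------------
# score transfer
# ---------------------------------------------------------------------------

def sign_only_score(model: SignatureModel, expr: NormalizedMatrix | pd.DataFrame,
                    ) -> RiskScoreVector:
    """Score an external cohort with the model's coefficient signs only.

    ``score_j = sum_g sign(beta_g) * x_gj`` over the model genes present
    in the cohort; absent genes are dropped with a logged count.  The
    input is expected to be housekeeping-normalized log2 expression on
    the external platform.
    """
    values = expr.values if isinstance(expr, NormalizedMatrix) else expr
    signs = model.signs()
    present = [g for g in signs.index if g in values.index]
    dropped = [g for g in signs.index if g not in values.index]
    if not present:
        raise ValueError("no model genes present in the external cohort")
    if dropped:
        logger.info("sign-only transfer: %d model gene(s) absent from cohort: %s",
                    len(dropped), dropped)
    scores = pd.Series(signs.loc[present].to_numpy(dtype=float)
                       @ values.loc[present].to_numpy(),
                       index=values.columns)
    return RiskScoreVector(scores=scores, provenance="sign_only", dropped_genes=dropped)


def cn_gene_score(model: SignatureModel, gene_map: dict[str, list[str]],
                  cn_by_gene: pd.DataFrame) -> RiskScoreVector:
    """Gene-level transfer of a segment-keyed copy-number model.

    Each model segment maps to its annotated genes; each available gene
    contributes ``sign(beta_segment) * cn_gene`` (summed over genes —
    segments spanning more genes weigh more).  Genes without
    copy-number data are excluded and logged.
    """
    if not gene_map:
        raise ValueError("empty segment-to-gene mapping")
    signs = model.signs()
    total = pd.Series(0.0, index=cn_by_gene.columns)
    used, dropped = [], []
    for segment in signs.index:
        for gene in gene_map.get(segment, []):
            if gene in cn_by_gene.index:
                total = total + float(signs[segment]) * cn_by_gene.loc[gene]
                used.append(gene)
            else:
                dropped.append(gene)
    if not used:
        raise ValueError("no mapped genes available in the copy-number data")
    if dropped:
        logger.info("CN transfer: %d gene(s) lacked copy-number data: %s",
                    len(dropped), dropped)
    return RiskScoreVector(scores=total, provenance="cn_gene_level",
                           dropped_genes=dropped)


# ---------------------------------------------------------------------------
# log-rank and Kaplan-Meier
# ---------------------------------------------------------------------------

def _logrank_z(time: np.ndarray, event: np.ndarray, in_group1: np.ndarray) -> float:
    """Signed standardized two-group log-rank statistic.

    At each distinct event time, accumulates observed minus
    hypergeometric-expected events in group 1; Z = sum(O1 - E1) /
    sqrt(sum V).
    """
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], in_group1[order]
    n = len(t)
    event_times = np.unique(t[e == 1])
    num = 0.0
    var = 0.0
    # at-risk counts via suffix sums over the sorted times
    for et in event_times:
        at_risk = t >= et
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        d = int(((t == et) & (e == 1)).sum())
        d1 = int(((t == et) & (e == 1) & g).sum())
        num += d1 - d * n1 / n_tot
        if n_tot > 1:
            var += d * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d) / (n_tot - 1)
    if var <= 0.0:
        return 0.0
    return num / np.sqrt(var)


def logrank_test(time: pd.Series, event: pd.Series,
                 groups: pd.Series) -> LogRankResult:
    """Standard two-group log-rank test (hypergeometric variance).

    ``groups`` must take exactly two values; the signed Z is oriented
    so that positive means the first group (sorted label order) has
    more events than expected.
    """
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    t = time.to_numpy(dtype=float)
    e = event.to_numpy(dtype=int)
    if (t < 0).any():
        raise ValueError("negative survival time")
    g1 = (groups == labels[0]).to_numpy()
    if g1.sum() == 0 or (~g1).sum() == 0:
        raise ValueError("each group needs at least one subject")

    z = _logrank_z(t, e, g1)
    chi2 = z * z
    p = float(stats.chi2.sf(chi2, df=1))

    observed, expected = {}, {}
    for lab, mask in ((labels[0], g1), (labels[1], ~g1)):
        observed[lab] = float(e[mask].sum())
    # E = O - (O - E); recover per-group expectation from the accumulated sums
    oe1 = _logrank_oe(t, e, g1)
    expected[labels[0]] = observed[labels[0]] - oe1
    expected[labels[1]] = observed[labels[1]] + oe1
    return LogRankResult(statistic=float(chi2), p_value=p, z=float(z),
                         observed=observed, expected=expected)


def _logrank_oe(time: np.ndarray, event: np.ndarray, in_group1: np.ndarray) -> float:
    """sum(O1 - E1) over distinct event times."""
    total = 0.0
    for et in np.unique(time[event == 1]):
        at_risk = time >= et
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & in_group1).sum())
        d = int(((time == et) & (event == 1)).sum())
        d1 = int(((time == et) & (event == 1) & in_group1).sum())
        total += d1 - d * n1 / n_tot
    return total


def km_estimate(time: pd.Series, event: pd.Series,
                groups: pd.Series | None = None) -> list[KmCurve]:
    """Kaplan-Meier product-limit curves with Greenwood 95% CIs per group."""
    if (time < 0).any():
        raise ValueError("negative survival time")
    if groups is None:
        groups = pd.Series("all", index=time.index)
    curves = []
    for label in sorted(pd.unique(groups)):
        mask = groups == label
        if mask.sum() == 0:
            raise ValueError(f"group {label!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask], label=str(label))
        tbl = kmf.event_table
        ci = kmf.confidence_interval_survival_function_
        grid = kmf.survival_function_.index.to_numpy(dtype=float)
        curves.append(KmCurve(
            label=str(label),
            times=grid,
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
            ci_lower=ci.iloc[:, 0].to_numpy(),
            ci_upper=ci.iloc[:, 1].to_numpy(),
            at_risk=tbl["at_risk"].reindex(grid).to_numpy(dtype=float),
        ))
    return curves


def rfs_at(curve: KmCurve, t: float) -> float:
    """Survival probability S(t) from the right-continuous step function.

    Beyond the last observed time, the last estimate is carried
    forward.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


# ---------------------------------------------------------------------------
# optimal cutpoint
# ---------------------------------------------------------------------------

def optimal_cutpoint(scores: RiskScoreVector | pd.Series, time: pd.Series,
                     event: pd.Series, minprop: float = 0.1) -> CutpointResult:
    """Threshold maximizing the absolute standardized log-rank statistic.

    Candidates are the midpoints of consecutive distinct scores;
    admissible candidates leave both groups with at least
    ``minprop * n`` samples.  Ties in |Z| break toward the lower
    threshold.  Requires >= 10 samples and >= 1 event.
    """
    s = scores.scores if isinstance(scores, RiskScoreVector) else scores
    s = s.astype(float)
    time = time.reindex(s.index)
    event = event.reindex(s.index)
    n = len(s)
    if n < 10:
        raise ValueError("need at least 10 samples")
    if event.sum() < 1:
        raise ValueError("need at least one event")
    distinct = np.unique(s.to_numpy())
    if len(distinct) < 2:
        raise ValueError("all scores identical: no cutpoint exists")

    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    t = time.to_numpy(dtype=float)
    e = event.to_numpy(dtype=int)
    sv = s.to_numpy()
    min_n = minprop * n

    best: tuple[float, float, int, int] | None = None
    for c in candidates:
        high = sv > c
        n_high = int(high.sum())
        n_low = n - n_high
        if n_low < min_n or n_high < min_n:
            continue
        z = abs(_logrank_z(t, e, high))
        if best is None or z > best[1] + 1e-12:
            best = (float(c), z, n_low, n_high)
    if best is None:
        raise ValueError("no admissible cutpoint under the minprop constraint")
    return CutpointResult(threshold=best[0], statistic=best[1],
                          n_low=best[2], n_high=best[3], minprop=minprop)
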