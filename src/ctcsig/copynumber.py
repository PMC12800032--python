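"""Copy-number signature pipeline.

QC gating of segment-level samples, intersection of fixed 1-Mb bins
with the CTC signature regions, and a bidirectional stepwise-AIC linear
model of the recurrence score over the retained segments.  The L1
harness from the expression module is reused for the LASSO arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import HarnessResult, SignatureModel, run_harness
from .simulate import GenomicRegion, SegmentMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QcReport",
    "CtcSegmentMatrix",
    "StepwiseTrace",
    "qc_filter_samples",
    "overlap_ctc_segments",
    "stepwise_model",
    "cn_l1_model",
]

TF_MIN = 0.15
MAD_MAX = 0.15


@dataclass
class QcReport:
    """Per-sample QC outcome with failure reasons."""

    table: pd.DataFrame  # tumor_fraction, gc_map_mad, passed, reason

    @property
    def passed(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])

    @property
    def failed(self) -> list[str]:
        return list(self.table.index[~self.table["passed"]])


@dataclass
class CtcSegmentMatrix:
    """Sample x segment log-ratios, restricted to CTC-overlapping bins."""

    segments: pd.DataFrame   # index bin_id; chrom, start, end, region_ids
    log_ratios: pd.DataFrame # samples x bin_id

    @property
    def segment_ids(self) -> list[str]:
        return list(self.segments.index)


@dataclass
class StepwiseTrace:
    """Accepted moves of a stepwise search plus the final model."""

    steps: list[tuple[int, str, str, float]]  # (step, 'add'|'remove', segment, AIC)
    model: SignatureModel
    aic: float


def qc_filter_samples(seg: SegmentMatrix, tf_min: float = TF_MIN,
                      mad_max: float = MAD_MAX) -> tuple[SegmentMatrix, QcReport]:
    """Drop samples with low tumor fraction or high GC-Map MAD.

    A sample fails iff ``tumor_fraction < tf_min`` or
    ``gc_map_mad > mad_max`` (strict inequalities: boundary values are
    retained).  Samples missing either metric fail with reason
    ``missing-qc``.
    """
    rows = []
    for s in seg.samples:
        tf = seg.tumor_fraction.get(s, np.nan)
        mad = seg.gc_map_mad.get(s, np.nan)
        if pd.isna(tf) or pd.isna(mad):
            rows.append((s, tf, mad, False, "missing-qc"))
        elif tf < tf_min and mad > mad_max:
            rows.append((s, tf, mad, False, "low-tumor-fraction;high-gc-map-mad"))
        elif tf < tf_min:
            rows.append((s, tf, mad, False, "low-tumor-fraction"))
        elif mad > mad_max:
            rows.append((s, tf, mad, False, "high-gc-map-mad"))
        else:
            rows.append((s, tf, mad, True, ""))
    table = pd.DataFrame(rows, columns=["sample", "tumor_fraction", "gc_map_mad",
                                        "passed", "reason"]).set_index("sample")
    keep = list(table.index[table["passed"]])
    filtered = SegmentMatrix(
        bins=seg.bins,
        log_ratios=seg.log_ratios.loc[keep],
        tumor_fraction=seg.tumor_fraction.loc[keep],
        gc_map_mad=seg.gc_map_mad.loc[keep],
        cohort_role=seg.cohort_role,
    )
    for s in table.index[~table["passed"]]:
        logger.info("QC excluded %s: %s", s, table.loc[s, "reason"])
    return filtered, QcReport(table=table)


def overlap_ctc_segments(seg: SegmentMatrix,
                         regions: list[GenomicRegion]) -> CtcSegmentMatrix:
    """Keep bins sharing >= 1 bp with any CTC region (half-open, 0-based).

    Each retained bin is annotated with every overlapping region id;
    column order follows the input bin order.  The result is
    independent of the order in which regions are supplied.
    """
    for r in regions:
        if r.start >= r.end:  # GenomicRegion validates, but guard foreign input
            raise ValueError(f"malformed region {r.region_id}: start >= end")
    rows = []
    for b in seg.bins:
        hits = sorted(r.region_id for r in regions
                      if r.chrom == b.chrom and b.start < r.end and r.start < b.end)
        if hits:
            rows.append((b.region_id, b.chrom, b.start, b.end, tuple(hits)))
    segments = pd.DataFrame(rows, columns=["bin_id", "chrom", "start", "end",
                                           "region_ids"]).set_index("bin_id")
    return CtcSegmentMatrix(segments=segments,
                            log_ratios=seg.log_ratios[list(segments.index)])


# ---------------------------------------------------------------------------
# stepwise-AIC model
# ---------------------------------------------------------------------------

def _aic(X: np.ndarray, y: np.ndarray, cols: list[int]) -> tuple[float, np.ndarray]:
    """Gaussian-likelihood AIC (up to a model-independent constant) and
    OLS coefficients (intercept first) for the given column subset."""
    n = len(y)
    design = np.column_stack([np.ones(n)] + [X[:, j] for j in cols])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ beta) ** 2))
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2.0 * (len(cols) + 1), beta


def stepwise_model(X: CtcSegmentMatrix | pd.DataFrame, y: pd.Series,
                   max_steps: int = 200) -> StepwiseTrace:
    """Bidirectional stepwise linear regression under AIC.

    Starts from the intercept-only model; at each step evaluates adding
    any excluded segment and removing any included one, takes the move
    with the lowest AIC, and stops when no move improves it.  Exactly
    duplicated columns are deduplicated first (with a warning).  The
    trace of accepted moves is returned alongside the final model.
    """
    lr = X.log_ratios if isinstance(X, CtcSegmentMatrix) else X
    lr = lr.loc[y.index]
    dup = lr.T.duplicated()
    if dup.any():
        logger.warning("dropping %d duplicate segment column(s): %s",
                       dup.sum(), list(lr.columns[dup]))
        lr = lr.loc[:, ~dup.to_numpy()]
    names = list(lr.columns)
    Xv = lr.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)

    included: list[int] = []
    current_aic, _ = _aic(Xv, yv, included)
    steps: list[tuple[int, str, str, float]] = []
    for step in range(1, max_steps + 1):
        best = (current_aic, None, None)  # (aic, action, column)
        for j in range(len(names)):
            if j in included:
                trial = [c for c in included if c != j]
                action = "remove"
            else:
                trial = included + [j]
                action = "add"
            aic, _ = _aic(Xv, yv, trial)
            if aic < best[0] - 1e-10:
                best = (aic, action, j)
        if best[1] is None:
            break
        current_aic = best[0]
        j = best[2]
        if best[1] == "add":
            included.append(j)
        else:
            included.remove(j)
        steps.append((step, best[1], names[j], current_aic))

    final_aic, beta = _aic(Xv, yv, included)
    coefficients = pd.Series(beta[1:], index=[names[j] for j in included])
    model = SignatureModel(coefficients=coefficients, intercept=float(beta[0]),
                           lambda_=0.0, training_meta={"method": "stepwise-aic",
                                                       "n_steps": len(steps)})
    return StepwiseTrace(steps=steps, model=model, aic=final_aic)


def cn_l1_model(X: CtcSegmentMatrix | pd.DataFrame, y: pd.Series,
                n_iter: int = 1000, train_frac: float = 0.6,
                seeds: list[int] | None = None, cv: int = 10) -> HarnessResult:
    """The repeated-split L1 harness applied to CTC segments.

    Identical to the expression harness but defaulting to 1000
    repetitions (the copy-number arm of the analysis); the top
    iterations are recoverable from ``HarnessResult.performance``.
    """
    lr = X.log_ratios if isinstance(X, CtcSegmentMatrix) else X
    return run_harness(lr.T, y, n_iter=n_iter, train_frac=train_frac,
                       seeds=seeds, cv=cv, hk_genes=[])
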