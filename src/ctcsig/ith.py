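"""Intratumor heterogeneity (ΔH) from Multiplex-FISH spot counts.

Per cell, a probe is called "gained" when its spot count exceeds the
centromeric control count (control-ratio normalization absorbs the
sectioning signal loss of thin tissue sections).  Cells collapse to
5-bit gain signatures; signatures whose frequency exceeds a 99% Wilson
bound around the matched-normal null are "true clones"; the Shannon
index of the true-clone table (plus the residual class) gives the
per-core heterogeneity H, and ΔH is the absolute difference between a
patient's two spatially separate tumor cores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .config import FISH_CONTROL, FISH_PROBES
from .simulate import FishCore

logger = logging.getLogger(__name__)

__all__ = [
    "CloneSignature",
    "NullModel",
    "CoreHeterogeneity",
    "DeltaH",
    "call_gain_status",
    "estimate_null_from_normals",
    "call_true_clones",
    "core_heterogeneity_index",
    "delta_h",
    "compare_groups_wilcoxon",
    "oncotype_risk_group",
    "wilson_upper_bound",
    "ith_pipeline",
]

#: A clone signature is a 5-tuple of 0/1 gain flags in canonical probe order.
CloneSignature = tuple[int, ...]

NO_GAIN: CloneSignature = (0,) * len(FISH_PROBES)


@dataclass
class NullModel:
    """Pooled-normal signature frequencies and the global false-positivity rate."""

    frequencies: dict[CloneSignature, float]
    n_cells: int
    fpr: float                        # fraction of normal cells with any gain call

    def frequency(self, signature: CloneSignature) -> float:
        return self.frequencies.get(signature, 0.0)


@dataclass
class CoreHeterogeneity:
    """True-clone frequency table and Shannon index for one core."""

    core_id: str
    patient_id: str
    table: dict[CloneSignature | str, float]  # true clones + 'residual'
    h: float                                  # Shannon index (nats by default)
    n_cells: int
    evaluable: bool = True


@dataclass
class DeltaH:
    """Between-core heterogeneity difference for one patient."""

    patient_id: str
    h_a: float
    h_b: float
    delta: float
    evaluable: bool = True


def call_gain_status(core: FishCore) -> list[CloneSignature]:
    """Per-cell 5-bit gain signatures against the centromeric control.

    Probe g is gained in a cell iff ``count_g > count_control``.  Cells
    with a zero control count carry no ploidy reference and are dropped
    with a logged count.
    """
    expected = set(FISH_PROBES) | {FISH_CONTROL}
    if set(core.counts.columns) != expected:
        unknown = set(core.counts.columns) - expected
        raise ValueError(f"unknown probe column(s): {sorted(unknown)}")
    counts = core.counts[list(FISH_PROBES)].to_numpy()
    control = core.counts[FISH_CONTROL].to_numpy()
    evaluable = control >= 1
    n_dropped = int((~evaluable).sum())
    if n_dropped:
        logger.info("core %s: dropped %d cell(s) with zero control count",
                    core.core_id, n_dropped)
    gains = counts[evaluable] > control[evaluable][:, None]
    return [tuple(int(v) for v in row) for row in gains]


def estimate_null_from_normals(normal_cores: list[FishCore]) -> NullModel:
    """Pool all normal cells into per-signature null frequencies.

    The global false-positivity rate is the fraction of pooled normal
    cells showing any gain call; it is the empirical operating point of
    the gain rule on diploid tissue.
    """
    signatures: list[CloneSignature] = []
    for core in normal_cores:
        signatures.extend(call_gain_status(core))
    n = len(signatures)
    if n == 0:
        raise ValueError("no evaluable normal cells")
    if n < 50:
        logger.warning("only %d evaluable normal cells; null model is unstable", n)
    freq: dict[CloneSignature, float] = {}
    for s in signatures:
        freq[s] = freq.get(s, 0.0) + 1.0
    freq = {s: c / n for s, c in freq.items()}
    fpr = 1.0 - freq.get(NO_GAIN, 0.0)
    return NullModel(frequencies=freq, n_cells=n, fpr=fpr)


def wilson_upper_bound(p0: float, n: int, conf: float = 0.99) -> float:
    """Upper limit of the two-sided Wilson score interval for a
    proportion ``p0`` observed on ``n`` trials."""
    z = stats.norm.ppf(1.0 - (1.0 - conf) / 2.0)
    z2 = z * z
    center = p0 + z2 / (2 * n)
    half = z * np.sqrt(p0 * (1 - p0) / n + z2 / (4 * n * n))
    return float((center + half) / (1 + z2 / n))


def call_true_clones(core: FishCore, null: NullModel, conf: float = 0.99,
                     min_cells: int = 20) -> CoreHeterogeneity:
    """Identify true gain clones against the normal-derived null and
    compute the core's Shannon heterogeneity.

    A nonzero signature with observed frequency ``f̂`` over the core's
    ``n`` evaluable cells is a true clone iff ``f̂`` exceeds the upper
    Wilson bound at level ``conf`` around its null frequency (evaluated
    at the same ``n``).  Retained clone frequencies plus the residual
    class (all remaining cells) form the table; H = -sum p ln p.  A
    homogeneous core (no true clones) has a single residual class and
    H = 0.
    """
    signatures = call_gain_status(core)
    n = len(signatures)
    if n < min_cells:
        logger.warning("core %s: %d evaluable cells < %d; not evaluable",
                       core.core_id, n, min_cells)
        return CoreHeterogeneity(core_id=core.core_id, patient_id=core.patient_id,
                                 table={}, h=float("nan"), n_cells=n, evaluable=False)
    observed: dict[CloneSignature, int] = {}
    for s in signatures:
        observed[s] = observed.get(s, 0) + 1

    table: dict[CloneSignature | str, float] = {}
    residual = 1.0
    for s, count in sorted(observed.items()):
        if s == NO_GAIN:
            continue
        f_hat = count / n
        if f_hat > wilson_upper_bound(null.frequency(s), n, conf):
            table[s] = f_hat
            residual -= f_hat
    table["residual"] = max(residual, 0.0)
    total = sum(table.values())
    table = {k: v / total for k, v in table.items()}
    h = core_heterogeneity_index(np.array(list(table.values())))
    return CoreHeterogeneity(core_id=core.core_id, patient_id=core.patient_id,
                             table=table, h=h, n_cells=n)


def core_heterogeneity_index(freqs: np.ndarray, units: str = "nats") -> float:
    """Shannon index H = -sum p ln p of a frequency vector.

    ``0 * ln 0`` is taken as 0; frequencies must be nonnegative and sum
    to 1 within 1e-9.  ``units='bits'`` divides by ln 2.
    """
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("frequencies must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1 (got {p.sum()!r})")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if units == "bits":
        h /= np.log(2.0)
    elif units != "nats":
        raise ValueError("units must be 'nats' or 'bits'")
    return h


def delta_h(core_a: CoreHeterogeneity, core_b: CoreHeterogeneity) -> DeltaH:
    """Net (absolute) heterogeneity difference between two cores of one tumor."""
    if core_a.patient_id != core_b.patient_id:
        raise ValueError(
            f"cores from different patients: {core_a.patient_id} vs {core_b.patient_id}")
    if not (core_a.evaluable and core_b.evaluable):
        return DeltaH(patient_id=core_a.patient_id, h_a=core_a.h, h_b=core_b.h,
                      delta=float("nan"), evaluable=False)
    return DeltaH(patient_id=core_a.patient_id, h_a=core_a.h, h_b=core_b.h,
                  delta=abs(core_a.h - core_b.h))


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def oncotype_risk_group(score: float) -> str:
    """Risk bin from a recurrence score: low 0-15, intermediate 16-25, high 26-100."""
    if score < 16:
        return "low"
    if score < 26:
        return "intermediate"
    return "high"


def _ranksum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: exact null distribution when the
    combined sample is small (n <= 20) and tie-free, otherwise the
    normal approximation with midranks, tie-corrected variance, and a
    signed continuity correction (which vanishes when W sits at its
    null mean, so identical groups give p = 1)."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    has_ties = len(np.unique(pooled)) < n
    if not has_ties and n <= 20:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return w, float(res.pvalue)
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0
    diff = w - mean_w
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var_w)
    return w, float(2.0 * stats.norm.sf(abs(z)))


def compare_groups_wilcoxon(values: pd.Series, group_labels: pd.Series,
                            ) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests of ΔH between patient groups.

    Typical groupings: Oncotype risk bins (low / intermediate / high) or
    overall grade (II vs III).  Each compared group needs >= 3 patients.
    Returns one row per unordered pair with the rank-sum statistic W of
    the first group and the p-value.
    """
    group_labels = group_labels.reindex(values.index)
    groups = {g: values[group_labels == g].dropna().to_numpy(dtype=float)
              for g in pd.unique(group_labels.dropna())}
    for g, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 patients")
    rows = []
    for a, b in combinations(sorted(groups), 2):
        w, p = _ranksum_test(groups[a], groups[b])
        rows.append((a, b, len(groups[a]), len(groups[b]), w, p))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b",
                                       "w_statistic", "p_value"])


def ith_pipeline(patients: list[tuple[FishCore, FishCore, FishCore]],
                 conf: float = 0.99, min_cells: int = 20,
                 fpr_threshold: float | None = 0.106) -> tuple[pd.DataFrame, NullModel]:
    """End-to-end ΔH over a cohort of (core_A, core_B, normal) triplets.

    Builds the pooled-normal null, flags the cohort when its empirical
    false-positivity rate exceeds ``fpr_threshold`` (the inclusion gate;
    pass ``None`` to disable), then scores every patient.  Returns a
    per-patient table (h_a, h_b, delta_h, evaluable) and the null model.
    """
    null = estimate_null_from_normals([normal for _, _, normal in patients])
    if fpr_threshold is not None and null.fpr > fpr_threshold:
        logger.warning("pooled-normal FPR %.3f exceeds the inclusion gate %.3f",
                       null.fpr, fpr_threshold)
    rows = []
    for core_a, core_b, _ in patients:
        ha = call_true_clones(core_a, null, conf=conf, min_cells=min_cells)
        hb = call_true_clones(core_b, null, conf=conf, min_cells=min_cells)
        dh = delta_h(ha, hb)
        rows.append((dh.patient_id, dh.h_a, dh.h_b, dh.delta, dh.evaluable))
    table = pd.DataFrame(rows, columns=["patient_id", "h_a", "h_b", "delta_h",
                                        "evaluable"]).set_index("patient_id")
    return table, null
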