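"""Synthetic cohort generators.

Every downstream stage of the pipeline (expression signature training,
copy-number modeling, external survival validation, FISH heterogeneity
scoring) can be exercised on data from this module alone.  Each cohort
carries a ``truth`` dictionary with the latent parameters used to
generate it, so recovery tests can assert against ground truth.

The generators emulate the *outputs* of the wet-lab/upstream tools
(NanoString counts, ichorCNA 1-Mb log-ratio segments, per-cell FISH spot
counts), not the tools themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    FISH_CONTROL,
    FISH_PROBES,
    HK_GENES,
    GeneratorConfig,
    InvalidConfigError,
)

__all__ = [
    "GenomicRegion",
    "GenePanel",
    "ExpressionCohort",
    "SegmentMatrix",
    "SurvivalCohort",
    "FishCore",
    "FishDataset",
    "default_panel",
    "generate_expression_cohort",
    "generate_cn_cohort",
    "generate_survival_cohort",
    "generate_fish_cores",
]

# sub-stream tags: one per generator, so cohorts are independent of each
# other while remaining fully determined by (seed, config)
_TAG_PANEL = 0
_TAG_EXPR = 1
_TAG_CN = 2
_TAG_SURV = 3
_TAG_FISH = 4


def _rng(config: GeneratorConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([tag, config.seed])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicRegion:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    region_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"region {self.region_id}: start ({self.start}) must be < end ({self.end})"
            )

    def overlaps(self, other: "GenomicRegion") -> bool:
        """Share >= 1 bp under half-open semantics."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class GenePanel:
    """The targeted gene panel: gene ids, categories, CTC region links."""

    genes: pd.DataFrame  # index gene_id; columns: category, region_id

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes.index)

    @property
    def hk_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["category"] == "HOUSEKEEPING"])

    def by_category(self, category: str) -> list[str]:
        return list(self.genes.index[self.genes["category"] == category])


@dataclass
class ExpressionCohort:
    """Gene x sample count matrix with labels, scores, and generator truth."""

    counts: pd.DataFrame          # genes x samples, nonnegative integers
    sample_labels: pd.Series      # 'tumor' | 'normal' per sample
    scores: pd.Series             # recurrence score in [0, 100], tumor samples only
    panel: GenePanel
    truth: dict = field(default_factory=dict)

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.sample_labels.index[self.sample_labels == "tumor"])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.sample_labels.index[self.sample_labels == "normal"])


@dataclass
class SegmentMatrix:
    """Sample x 1-Mb-bin copy-number log-ratios with per-sample QC."""

    bins: list[GenomicRegion]
    log_ratios: pd.DataFrame      # samples x bin_id
    tumor_fraction: pd.Series
    gc_map_mad: pd.Series
    cohort_role: str              # 'tumor' | 'panel_of_normals'

    def __post_init__(self) -> None:
        widths = {b.end - b.start for b in self.bins}
        if len(self.bins) and widths != {self.bins[0].end - self.bins[0].start}:
            raise ValueError("bins must share a fixed width")
        if list(self.log_ratios.columns) != [b.region_id for b in self.bins]:
            raise ValueError("log_ratio columns must match bin ids, in order")

    @property
    def samples(self) -> list[str]:
        return list(self.log_ratios.index)


@dataclass
class SurvivalCohort:
    """External validation cohort: expression + per-gene CN + censored RFS."""

    expression: pd.DataFrame      # genes x samples, linear platform scale
    cn_by_gene: pd.DataFrame      # genes x samples, copy-number values
    time: pd.Series               # months, >= 0
    event: pd.Series              # 1 = recurrence event, 0 = censored
    truth: dict = field(default_factory=dict)


@dataclass
class FishCore:
    """Per-cell spot counts for one core: 5 probes + centromeric control."""

    counts: pd.DataFrame          # cells x (probes + control)
    core_id: str
    patient_id: str
    tissue: str                   # 'tumor' | 'normal'

    def __post_init__(self) -> None:
        expected = set(FISH_PROBES) | {FISH_CONTROL}
        if set(self.counts.columns) != expected:
            raise ValueError(f"core {self.core_id}: probe columns must be {sorted(expected)}")


@dataclass
class FishDataset:
    """Two tumor cores + one normal core per patient."""

    patients: list[tuple[FishCore, FishCore, FishCore]]
    divergence: list[float]
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gene panel
# ---------------------------------------------------------------------------

def default_panel(config: GeneratorConfig) -> GenePanel:
    """Build the synthetic gene panel (89 CTC / 24 BC / 14 EMT / 5 HK default).

    CTC genes link to fabricated signature regions; housekeeping genes
    use the real normalization gene names so downstream defaults apply.
    """
    rows = []
    for i in range(config.n_ctc_genes):
        rows.append((f"CTC{i + 1:03d}", "CTC", f"R{i % config.n_ctc_regions + 1:03d}"))
    for i in range(config.n_bc_genes):
        rows.append((f"BC{i + 1:03d}", "BREAST_CANCER", None))
    for i in range(config.n_emt_genes):
        rows.append((f"EMT{i + 1:03d}", "EMT", None))
    for name in HK_GENES:
        rows.append((name, "HOUSEKEEPING", None))
    df = pd.DataFrame(rows, columns=["gene_id", "category", "region_id"]).set_index("gene_id")
    if df.index.duplicated().any():
        raise InvalidConfigError("gene ids must be unique")
    return GenePanel(genes=df)


def _panel_truth(config: GeneratorConfig) -> tuple[GenePanel, pd.Series]:
    """Panel plus the hidden driver-gene weights shared by the expression
    and survival generators (same seed sub-stream, so a model trained on
    the expression cohort transfers to the survival cohort)."""
    rng = _rng(config, _TAG_PANEL)
    panel = default_panel(config)
    non_hk = [g for g in panel.gene_ids if g not in panel.hk_genes]
    drivers = rng.choice(non_hk, size=config.n_driver_genes, replace=False)
    magnitude = rng.uniform(config.driver_effect_low, config.driver_effect_high,
                            size=config.n_driver_genes)
    sign = np.where(rng.random(config.n_driver_genes) < config.driver_positive_frac, 1.0, -1.0)
    weights = pd.Series(magnitude * sign, index=drivers, name="driver_weight")
    return panel, weights


# ---------------------------------------------------------------------------
# expression cohort
# ---------------------------------------------------------------------------

def generate_expression_cohort(config: GeneratorConfig) -> ExpressionCohort:
    """Negative-binomial panel counts plus a driver-determined recurrence score.

    Per-gene latent log2 activity: baseline + tumor shift (for a
    configurable fraction of non-HK genes) + per-sample biological noise
    (larger for drivers).  Counts are NB with mean ``2**(activity +
    library offset)`` and dispersion ``nb_dispersion``.  The tumor
    recurrence score is an affine function of the drivers' centered
    latent activity plus Gaussian noise, clipped to [0, 100].
    """
    rng = _rng(config, _TAG_EXPR)
    panel, weights = _panel_truth(config)
    genes = panel.gene_ids
    hk = set(panel.hk_genes)
    n_genes = len(genes)

    samples = [f"T{i + 1:03d}" for i in range(config.n_tumor)] + \
              [f"N{i + 1:03d}" for i in range(config.n_normal)]
    labels = pd.Series(["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
                       index=samples, name="label")
    n_samples = len(samples)
    is_tumor = (labels == "tumor").to_numpy()

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n_genes)

    # tumor-vs-normal shifts, skewed toward overexpression; HK genes flat
    non_hk_idx = np.array([i for i, g in enumerate(genes) if g not in hk])
    de_effect = np.zeros(n_genes)
    n_de = int(round(config.tumor_de_fraction * len(non_hk_idx)))
    de_idx = rng.choice(non_hk_idx, size=n_de, replace=False)
    de_effect[de_idx] = rng.normal(config.tumor_effect_mean, config.tumor_effect_sd, size=n_de)

    biol_sd = np.full(n_genes, config.biological_sd)
    for i, g in enumerate(genes):
        if g in hk:
            biol_sd[i] = 0.1
        elif g in weights.index:
            biol_sd[i] = config.driver_biological_sd

    activity = (baseline[:, None]
                + np.outer(de_effect, is_tumor.astype(float))
                + rng.normal(0.0, 1.0, size=(n_genes, n_samples)) * biol_sd[:, None])
    library = rng.normal(0.0, config.library_size_sd, size=n_samples)
    mu = np.exp2(activity + library[None, :])

    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)

    # recurrence score from centered driver activity (tumor samples only)
    driver_pos = [genes.index(g) for g in weights.index]
    centered = activity[driver_pos][:, is_tumor] - (baseline + de_effect)[driver_pos][:, None]
    risk = weights.to_numpy() @ centered
    noise = rng.normal(0.0, config.score_noise_sd, size=risk.shape)
    raw_scores = config.score_intercept + config.score_scale * risk + noise
    scores = pd.Series(np.clip(raw_scores, 0.0, 100.0),
                       index=[s for s, t in zip(samples, is_tumor) if t], name="score")

    truth = {
        "driver_weights": weights,
        "de_effect": pd.Series(de_effect, index=genes),
        "baseline_log2": pd.Series(baseline, index=genes),
        "latent_risk": pd.Series(risk, index=scores.index),
        "library_log2": pd.Series(library, index=samples),
    }
    return ExpressionCohort(counts=counts_df, sample_labels=labels, scores=scores,
                            panel=panel, truth=truth)


# ---------------------------------------------------------------------------
# copy-number cohort
# ---------------------------------------------------------------------------

def _make_bins(config: GeneratorConfig) -> list[GenomicRegion]:
    per_chrom = config.n_bins // config.n_chromosomes
    bins = []
    k = 0
    for c in range(config.n_chromosomes):
        n = per_chrom if c < config.n_chromosomes - 1 else config.n_bins - per_chrom * (
            config.n_chromosomes - 1)
        for j in range(n):
            start = j * config.bin_size
            bins.append(GenomicRegion(f"chr{c + 1}", start, start + config.bin_size,
                                      f"bin{k + 1:04d}"))
            k += 1
    return bins


def _fabricate_regions(config: GeneratorConfig, bins: list[GenomicRegion],
                       rng: np.random.Generator) -> list[GenomicRegion]:
    """Non-overlapping CTC signature regions placed on the binned genome.

    Regions are offset by half a bin so that overlaps exercise partial
    (not only identity) bin intersection.
    """
    n_bins = len(bins)
    sizes = rng.integers(config.region_min_bins, config.region_max_bins + 1,
                         size=config.n_ctc_regions)
    # choose non-adjacent anchor bins so regions cannot touch
    stride = max(config.region_max_bins + 2, n_bins // config.n_ctc_regions)
    anchors = (np.arange(config.n_ctc_regions) * stride) % (n_bins - config.region_max_bins - 1)
    anchors = np.sort(np.unique(anchors))[: config.n_ctc_regions]
    regions = []
    for i, (a, s) in enumerate(zip(anchors, sizes)):
        b = bins[int(a)]
        start = b.start + config.bin_size // 2
        end = start + int(s) * config.bin_size
        # clamp within the anchor bin's chromosome span
        chrom_bins = [x for x in bins if x.chrom == b.chrom]
        chrom_end = max(x.end for x in chrom_bins)
        end = min(end, chrom_end)
        if end <= start:
            continue
        regions.append(GenomicRegion(b.chrom, start, end, f"R{i + 1:03d}"))
    return regions


def generate_cn_cohort(
    config: GeneratorConfig,
) -> tuple[SegmentMatrix, SegmentMatrix, list[GenomicRegion]]:
    """Tumor and panel-of-normals segment matrices plus CTC regions.

    Normals are pure noise ``N(0, cn_normal_sd)``.  Tumors add a
    per-sample gain dosage on ``n_cn_driver_bins`` CTC-overlapping bins;
    the dosage drives a recurrence score recorded in ``truth`` (the
    cohort's regression target).  QC metadata is drawn so that
    ``cn_qc_fail_fraction`` of tumors violate the tumor-fraction or
    GC-Map-MAD gates.
    """
    rng = _rng(config, _TAG_CN)
    bins = _make_bins(config)
    regions = _fabricate_regions(config, bins, rng)
    bin_ids = [b.region_id for b in bins]

    overlapping = [i for i, b in enumerate(bins) if any(b.overlaps(r) for r in regions)]
    if len(overlapping) < config.n_cn_driver_bins:
        raise InvalidConfigError("not enough CTC-overlapping bins for the drivers")
    driver_bins = sorted(rng.choice(overlapping, size=config.n_cn_driver_bins, replace=False))

    normals = rng.normal(0.0, config.cn_normal_sd, size=(config.n_cn_normals, len(bins)))
    normal_ids = [f"PN{i + 1:02d}" for i in range(config.n_cn_normals)]
    normal_mat = SegmentMatrix(
        bins=bins,
        log_ratios=pd.DataFrame(normals, index=normal_ids, columns=bin_ids),
        tumor_fraction=pd.Series(0.0, index=normal_ids),
        gc_map_mad=pd.Series(rng.uniform(0.02, 0.10, size=config.n_cn_normals),
                             index=normal_ids),
        cohort_role="panel_of_normals",
    )

    tumor_ids = [f"CT{i + 1:03d}" for i in range(config.n_cn_tumor)]
    lr = rng.normal(0.0, config.cn_tumor_sd, size=(config.n_cn_tumor, len(bins)))
    dosage = rng.beta(2.0, 2.0, size=config.n_cn_tumor)
    for j in driver_bins:
        lr[:, j] += config.cn_gain_log_ratio * dosage

    # QC metadata: a configured fraction fails one gate or the other
    tf = rng.uniform(0.20, 0.80, size=config.n_cn_tumor)
    mad = rng.uniform(0.02, 0.12, size=config.n_cn_tumor)
    n_fail = int(round(config.cn_qc_fail_fraction * config.n_cn_tumor))
    fail_idx = rng.choice(config.n_cn_tumor, size=n_fail, replace=False)
    half = n_fail // 2
    tf[fail_idx[:half]] = rng.uniform(0.02, 0.149, size=half)
    mad[fail_idx[half:]] = rng.uniform(0.151, 0.30, size=n_fail - half)

    z = (dosage - dosage.mean()) / (dosage.std() if dosage.std() > 0 else 1.0)
    scores = np.clip(config.cn_score_intercept + config.cn_score_scale * (z + 1) / 2
                     + rng.normal(0.0, config.cn_score_noise_sd, size=config.n_cn_tumor),
                     0.0, 100.0)

    tumor_mat = SegmentMatrix(
        bins=bins,
        log_ratios=pd.DataFrame(lr, index=tumor_ids, columns=bin_ids),
        tumor_fraction=pd.Series(tf, index=tumor_ids),
        gc_map_mad=pd.Series(mad, index=tumor_ids),
        cohort_role="tumor",
    )
    tumor_mat.truth = {  # type: ignore[attr-defined]
        "driver_bins": [bin_ids[j] for j in driver_bins],
        "dosage": pd.Series(dosage, index=tumor_ids),
        "scores": pd.Series(scores, index=tumor_ids, name="score"),
        "qc_fail_samples": [tumor_ids[i] for i in sorted(fail_idx)],
    }
    return tumor_mat, normal_mat, regions


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def generate_survival_cohort(config: GeneratorConfig,
                             replicate: int = 0) -> SurvivalCohort:
    """External cohort with platform-shifted expression and censored RFS.

    ``replicate`` re-draws the cohort (samples, survival, platform shift)
    while keeping the panel and its hidden driver genes tied to
    ``config.seed``, so replicate external cohorts remain compatible
    with one internally trained signature.

    Latent risk is linear in the same hidden driver genes as the
    expression cohort; event times are exponential with hazard
    ``baseline_hazard * exp(survival_beta * standardized risk)``,
    censored by an independent uniform time and by the follow-up
    horizon.  Observed expression is ``2**(offset + scale * latent)``
    per gene (positive per-gene scale, so sign-only transfer is what is
    being stressed, not coefficient transfer).
    """
    rng = np.random.default_rng([_TAG_SURV, config.seed, replicate])
    panel, weights = _panel_truth(config)
    genes = panel.gene_ids
    n_genes = len(genes)
    samples = [f"EXT{i + 1:04d}" for i in range(config.n_survival)]

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n_genes)
    latent = baseline[:, None] + rng.normal(0.0, 1.0, size=(n_genes, config.n_survival))

    driver_pos = [genes.index(g) for g in weights.index]
    risk = weights.to_numpy() @ (latent[driver_pos] - baseline[driver_pos][:, None])
    risk_std = (risk - risk.mean()) / risk.std()

    hazard = config.baseline_hazard * np.exp(config.survival_beta * risk_std)
    t_event = rng.exponential(1.0 / hazard)
    horizon = config.survival_horizon_months
    if config.censoring_rate > 0:
        t_cens = rng.uniform(0.0, horizon / config.censoring_rate, size=config.n_survival)
        t_cens = np.minimum(t_cens, horizon)
    else:
        t_cens = np.full(config.n_survival, horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    # external platform: positive per-gene rescaling + offset, linear scale
    scale = rng.uniform(config.platform_scale_low, config.platform_scale_high, size=n_genes)
    offset = rng.normal(0.0, config.platform_offset_sd, size=n_genes)
    expression = np.exp2(offset[:, None] + scale[:, None] * latent)

    # gene-level copy number: mostly neutral, coupled to risk for drivers
    cn = rng.normal(0.0, 0.1, size=(n_genes, config.n_survival))
    cn[driver_pos] += 0.2 * np.sign(weights.to_numpy())[:, None] * risk_std[None, :]

    truth = {
        "driver_weights": weights,
        "latent_risk": pd.Series(risk_std, index=samples),
        "platform_scale": pd.Series(scale, index=genes),
        "platform_offset": pd.Series(offset, index=genes),
    }
    return SurvivalCohort(
        expression=pd.DataFrame(expression, index=genes, columns=samples),
        cn_by_gene=pd.DataFrame(cn, index=genes, columns=samples),
        time=pd.Series(time, index=samples, name="time_months"),
        event=pd.Series(event, index=samples, name="event"),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# FISH cohort
# ---------------------------------------------------------------------------

def _clone_library(config: GeneratorConfig) -> pd.DataFrame:
    """Copy-state table: diploid clone + one single-gain clone per probe
    + two double-gain clones.  Control is always diploid."""
    probes = list(FISH_PROBES)
    rows = {"diploid": {p: 2 for p in probes}}
    for p in probes:
        states = {q: 2 for q in probes}
        states[p] = config.fish_gain_copies
        rows[f"gain_{p}"] = states
    for pair in [(probes[0], probes[2]), (probes[1], probes[3])]:
        states = {q: 2 for q in probes}
        for p in pair:
            states[p] = config.fish_gain_copies
        rows[f"gain_{pair[0]}_{pair[1]}"] = states
    df = pd.DataFrame(rows).T[probes]
    df[FISH_CONTROL] = 2
    return df


def _sample_core(rng: np.random.Generator, clone_states: pd.DataFrame,
                 clone_weights: np.ndarray, n_cells: int, loss_prob: float,
                 core_id: str, patient_id: str, tissue: str) -> FishCore:
    clone_idx = rng.choice(len(clone_states), size=n_cells, p=clone_weights)
    copies = clone_states.to_numpy()[clone_idx]            # cells x probes
    observed = rng.binomial(copies, 1.0 - loss_prob)
    counts = pd.DataFrame(observed, columns=clone_states.columns,
                          index=[f"{core_id}_c{i + 1}" for i in range(n_cells)])
    return FishCore(counts=counts, core_id=core_id, patient_id=patient_id, tissue=tissue)


def generate_fish_cores(config: GeneratorConfig) -> FishDataset:
    """Per-patient FISH triplets (2 tumor cores + 1 diploid normal core).

    Each patient carries a clone pool (diploid + ``fish_clones_per_patient``
    gain clones).  Core A uses the pool weights directly; core B
    reallocates them multiplicatively, ``w_B ∝ w_A * exp(d * sd * eps)``
    with per-clone standard normal ``eps`` — at divergence ``d = 0`` the
    cores share one composition, and the between-core composition gap
    (hence the downstream ΔH) grows stochastically with ``d``.
    Observed spot counts lose each copy independently with
    ``fish_loss_prob`` (sectioning truncation).
    """
    rng = _rng(config, _TAG_FISH)
    library = _clone_library(config)
    gain_clones = [c for c in library.index if c != "diploid"]
    d = config.fish_divergence

    def draw_weights() -> np.ndarray:
        w = np.zeros(len(library))
        w0 = rng.uniform(config.fish_diploid_weight_low, config.fish_diploid_weight_high)
        active = rng.choice(len(gain_clones), size=config.fish_clones_per_patient,
                            replace=False)
        part = rng.dirichlet(np.ones(config.fish_clones_per_patient))
        w[0] = w0
        for a, p in zip(active, part):
            w[1 + a] = (1.0 - w0) * p
        return w

    # index 0 is the diploid clone by construction
    assert library.index[0] == "diploid"

    patients = []
    truth_weights = {}
    for i in range(config.n_fish_patients):
        pid = f"P{i + 1:03d}"
        w_a = draw_weights()
        eps = rng.normal(0.0, 1.0, size=len(w_a))
        w_b = w_a * np.exp(d * config.fish_divergence_sd * eps)
        w_b = w_b / w_b.sum()
        core_a = _sample_core(rng, library, w_a, config.cells_per_core,
                              config.fish_loss_prob, f"{pid}_A", pid, "tumor")
        core_b = _sample_core(rng, library, w_b, config.cells_per_core,
                              config.fish_loss_prob, f"{pid}_B", pid, "tumor")
        diploid_only = np.zeros(len(library))
        diploid_only[0] = 1.0
        normal = _sample_core(rng, library, diploid_only, config.cells_per_core,
                              config.fish_loss_prob, f"{pid}_N", pid, "normal")
        patients.append((core_a, core_b, normal))
        truth_weights[pid] = {"core_A": w_a, "core_B": w_b}

    return FishDataset(
        patients=patients,
        divergence=[d] * config.n_fish_patients,
        truth={"clone_library": library, "clone_weights": truth_weights},
    )
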