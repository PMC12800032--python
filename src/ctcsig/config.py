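"""Configuration for the synthetic cohort generators.

A single frozen dataclass holds every tunable of the four generators
(expression, copy number, survival, FISH).  The same ``(seed, config)``
pair always produces byte-identical cohorts; each generator draws from
its own deterministic sub-stream of the seed so that, e.g., changing a
FISH parameter never perturbs the expression cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


class InvalidConfigError(ValueError):
    """Raised when a generator configuration fails validation."""


#: Canonical FISH probe set: five CTC genomic regions plus the
#: chromosome-19 centromere used as the per-cell ploidy control.
FISH_PROBES = ("KLK10", "MUC16", "CCNE1", "TGFB1", "BSG")
FISH_CONTROL = "CEP19"

#: The five housekeeping genes used for geometric-mean normalization.
HK_GENES = ("PUM1", "GUSB", "GAPDH", "POLR2A", "PSMC4")


@dataclass(frozen=True)
class GeneratorConfig:
    """All scalar knobs of the synthetic-data generators.

    Defaults reproduce the study conditions the downstream pipeline
    assumes: a 132-gene panel (89 CTC + 24 breast-cancer + 14 EMT +
    5 housekeeping) measured on 339 tumor and 64 normal samples, a
    55-sample copy-number panel of normals, recurrence scores on the
    0-100 Oncotype DX scale, a 240-month survival horizon, and FISH
    cores whose diploid normals show an ~10.6% any-gain false-positivity
    rate under the count-greater-than-control gain rule.
    """

    seed: int = 0

    # ---- expression cohort -------------------------------------------------
    n_ctc_genes: int = 89
    n_bc_genes: int = 24
    n_emt_genes: int = 14
    n_tumor: int = 339
    n_normal: int = 64
    nb_dispersion: float = 10.0          # NB size parameter r (var = mu + mu^2/r)
    baseline_log2_mean: float = 8.0      # per-gene baseline log2 expression
    baseline_log2_sd: float = 1.5
    library_size_sd: float = 0.30        # per-sample log2 depth offset SD
    tumor_de_fraction: float = 0.60      # fraction of non-HK genes with a tumor shift
    tumor_effect_mean: float = 0.50      # mean tumor log2FC (skewed toward gains)
    tumor_effect_sd: float = 1.00
    biological_sd: float = 0.50          # between-sample log2 variation, non-drivers
    n_driver_genes: int = 20             # hidden genes that drive the recurrence score
    driver_effect_low: float = 0.5       # |weight| range of driver effects
    driver_effect_high: float = 1.5
    driver_positive_frac: float = 0.7    # fraction of drivers with a positive sign
    driver_biological_sd: float = 1.0    # between-tumor log2 SD of driver activity
    score_intercept: float = 20.0        # recurrence-score scale (Oncotype-like)
    score_scale: float = 2.5
    score_noise_sd: float = 6.0

    # ---- copy-number cohort ------------------------------------------------
    genome_length: int = 250_000_000
    bin_size: int = 1_000_000
    n_chromosomes: int = 5
    n_cn_tumor: int = 327
    n_cn_normals: int = 55
    cn_normal_sd: float = 0.08           # log-ratio noise in normals
    cn_tumor_sd: float = 0.10
    n_ctc_regions: int = 20
    region_min_bins: int = 1
    region_max_bins: int = 3
    n_cn_driver_bins: int = 5            # CTC-overlapping bins carrying the signal
    cn_gain_log_ratio: float = 0.5       # full-dosage gain amplitude
    cn_qc_fail_fraction: float = 0.15    # fraction of tumors violating QC gates
    cn_score_intercept: float = 15.0
    cn_score_scale: float = 30.0
    cn_score_noise_sd: float = 16.0

    # ---- survival cohort ---------------------------------------------------
    n_survival: int = 400
    survival_horizon_months: float = 240.0   # 20-year follow-up window
    baseline_hazard: float = 0.004           # events per month at risk = 0
    survival_beta: float = 0.7               # log-hazard per unit standardized risk
    censoring_rate: float = 1.0              # censor ~ U(0, horizon/censoring_rate)
    platform_scale_low: float = 0.5          # external-platform per-gene rescaling
    platform_scale_high: float = 2.0
    platform_offset_sd: float = 1.0

    # ---- FISH cohort -------------------------------------------------------
    n_fish_patients: int = 108
    cells_per_core: int = 100
    fish_loss_prob: float = 0.0562       # per-copy sectioning signal loss; gives
                                         # ~10.6% any-gain FPR in diploid normals
                                         # (a probe beats the shared diploid control
                                         # only when the control drops to 1, so
                                         # FPR ~= 2p(1-p))
    fish_gain_copies: int = 4            # copy state of a gained probe in a clone
    fish_divergence: float = 0.5         # between-core clone reallocation (>= 0)
    fish_divergence_sd: float = 1.5      # log-normal reallocation scale at divergence 1
    fish_clones_per_patient: int = 3     # gain clones in a patient's pool
    fish_diploid_weight_low: float = 0.3
    fish_diploid_weight_high: float = 0.6

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be > 0")
        for name in ("n_ctc_genes", "n_bc_genes", "n_emt_genes", "n_tumor",
                     "n_normal", "n_cn_tumor", "n_cn_normals", "n_survival",
                     "n_fish_patients", "cells_per_core", "bin_size",
                     "genome_length", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.n_driver_genes > self.n_genes - self.n_hk_genes:
            raise InvalidConfigError("more driver genes than non-HK panel genes")
        if self.genome_length % self.bin_size != 0:
            raise InvalidConfigError("genome_length must be a multiple of bin_size")
        if not 0.0 <= self.fish_loss_prob <= 1.0:
            raise InvalidConfigError("fish_loss_prob must lie in [0, 1]")
        if self.censoring_rate < 0:
            raise InvalidConfigError("censoring_rate must be >= 0")
        if self.baseline_hazard <= 0:
            raise InvalidConfigError("baseline_hazard must be > 0")
        if not 0.0 <= self.cn_qc_fail_fraction <= 1.0:
            raise InvalidConfigError("cn_qc_fail_fraction must lie in [0, 1]")
        n_bins = self.genome_length // self.bin_size
        max_region_bins = self.n_ctc_regions * (self.region_max_bins + 1)
        if max_region_bins > n_bins:
            raise InvalidConfigError("CTC regions cannot fit inside the genome")

    # number of HK genes is fixed by the normalization scheme
    @property
    def n_hk_genes(self) -> int:
        return len(HK_GENES)

    @property
    def n_genes(self) -> int:
        return self.n_ctc_genes + self.n_bc_genes + self.n_emt_genes + self.n_hk_genes

    @property
    def n_bins(self) -> int:
        return self.genome_length // self.bin_size

    def replace(self, **changes) -> "GeneratorConfig":
        """Return a copy with ``changes`` applied (and re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        """Stable hash of the full configuration, for fixture manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
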