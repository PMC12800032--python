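"""Plain-text serialization of cohorts and models.

Formats: TSV count/expression matrices (genes x samples, header row of
sample ids), BED for CTC regions (0-based half-open), a SEG-style
segment table (sample, chrom, start, end, log_ratio), a survival TSV
(sample, time_months, event), a long-format FISH TSV (patient, core,
cell_id, probe, spot_count), and JSON for signature models.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FISH_CONTROL, FISH_PROBES, GeneratorConfig
from .expression import SignatureModel
from .simulate import (
    ExpressionCohort,
    FishCore,
    FishDataset,
    GenomicRegion,
    SegmentMatrix,
    SurvivalCohort,
)

__all__ = [
    "write_fixtures",
    "read_counts_tsv",
    "read_bed",
    "read_seg",
    "read_survival_tsv",
    "read_fish_tsv",
    "write_model_json",
    "read_model_json",
]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Gene x sample matrix with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_bed(path: str | Path) -> list[GenomicRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            regions.append(GenomicRegion(chrom, int(start), int(end), name))
    return regions


def read_seg(path: str | Path) -> pd.DataFrame:
    """SEG-style long table: sample, chrom, start, end, log_ratio."""
    return pd.read_csv(path, sep="\t")


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_fish_tsv(path: str | Path) -> list[tuple[FishCore, FishCore, FishCore]]:
    """Reconstruct per-patient core triplets from the long FISH table."""
    long = pd.read_csv(path, sep="\t")
    patients = []
    for pid, pgroup in long.groupby("patient", sort=True):
        cores = {}
        for core_id, cgroup in pgroup.groupby("core", sort=True):
            counts = cgroup.pivot(index="cell_id", columns="probe", values="spot_count")
            counts = counts[list(FISH_PROBES) + [FISH_CONTROL]]
            tissue = "normal" if str(core_id).endswith("_N") else "tumor"
            cores[str(core_id)] = FishCore(counts=counts, core_id=str(core_id),
                                           patient_id=str(pid), tissue=tissue)
        tumor = sorted(c for c in cores if not c.endswith("_N"))
        normal = [c for c in cores if c.endswith("_N")]
        if len(tumor) != 2 or len(normal) != 1:
            raise ValueError(f"patient {pid}: expected 2 tumor + 1 normal core")
        patients.append((cores[tumor[0]], cores[tumor[1]], cores[normal[0]]))
    return patients


def write_model_json(model: SignatureModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, default=str))


def read_model_json(path: str | Path) -> SignatureModel:
    return SignatureModel.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def _write_bed(regions: list[GenomicRegion], path: Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


def _write_seg(seg: SegmentMatrix, path: Path) -> None:
    rows = []
    for sample in seg.samples:
        lr = seg.log_ratios.loc[sample]
        for b in seg.bins:
            rows.append((sample, b.chrom, b.start, b.end, lr[b.region_id]))
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "log_ratio"]) \
        .to_csv(path, sep="\t", index=False)


def _write_fish(dataset: FishDataset, path: Path) -> None:
    rows = []
    for core_a, core_b, normal in dataset.patients:
        for core in (core_a, core_b, normal):
            for cell_id, counts in core.counts.iterrows():
                for probe in list(FISH_PROBES) + [FISH_CONTROL]:
                    rows.append((core.patient_id, core.core_id, cell_id, probe,
                                 int(counts[probe])))
    pd.DataFrame(rows, columns=["patient", "core", "cell_id", "probe", "spot_count"]) \
        .to_csv(path, sep="\t", index=False)


def write_fixtures(dataset, path: str | Path,
                   config: GeneratorConfig | None = None) -> dict:
    """Serialize any generated cohort to plain-text files under ``path``.

    Accepts an ``ExpressionCohort``, the ``(tumor, normals, regions)``
    triple from the copy-number generator, a ``SurvivalCohort``, or a
    ``FishDataset``.  Returns (and writes) a manifest listing the files,
    the seed, and the configuration hash.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def emit(name: str, writer) -> None:
        writer(out / name)
        files.append(name)

    if isinstance(dataset, ExpressionCohort):
        emit("expression_counts.tsv",
             lambda p: dataset.counts.to_csv(p, sep="\t"))
        emit("sample_labels.tsv",
             lambda p: dataset.sample_labels.rename("label").to_csv(p, sep="\t"))
        emit("scores.tsv", lambda p: dataset.scores.rename("score").to_csv(p, sep="\t"))
    elif isinstance(dataset, SurvivalCohort):
        emit("external_expression.tsv",
             lambda p: dataset.expression.to_csv(p, sep="\t"))
        emit("external_cn_by_gene.tsv",
             lambda p: dataset.cn_by_gene.to_csv(p, sep="\t"))
        emit("survival.tsv", lambda p: pd.DataFrame(
            {"time_months": dataset.time, "event": dataset.event}).to_csv(p, sep="\t"))
    elif isinstance(dataset, FishDataset):
        emit("fish_counts.tsv", lambda p: _write_fish(dataset, p))
    elif isinstance(dataset, tuple) and len(dataset) == 3 \
            and isinstance(dataset[0], SegmentMatrix):
        tumor, normals, regions = dataset
        emit("cn_tumor.seg.tsv", lambda p: _write_seg(tumor, p))
        emit("cn_normals.seg.tsv", lambda p: _write_seg(normals, p))
        emit("ctc_regions.bed", lambda p: _write_bed(regions, p))
        emit("cn_qc.tsv", lambda p: pd.DataFrame(
            {"tumor_fraction": tumor.tumor_fraction,
             "gc_map_mad": tumor.gc_map_mad}).to_csv(p, sep="\t"))
        truth = getattr(tumor, "truth", None)
        if truth and "scores" in truth:
            emit("cn_scores.tsv",
                 lambda p: truth["scores"].rename("score").to_csv(p, sep="\t"))
    else:
        raise TypeError(f"cannot serialize object of type {type(dataset).__name__}")

    manifest = {
        "files": files,
        "seed": config.seed if config is not None else None,
        "config_hash": config.content_hash() if config is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
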