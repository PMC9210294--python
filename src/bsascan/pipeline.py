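"""End-to-end orchestration: read -> filter (-> intersect/swap) -> stats ->
thresholds -> windows -> peaks, with a reproducibility manifest.

Two entry modes mirror the two ways BSA-Seq datasets arrive:

* **with parents** — parental calls either share the bulk table (joint
  filtering, heterozygous-parent removal, then AD/GT swapping onto the
  reference parent) or live in a second table (parents filtered separately,
  intersected with the bulk set, parental GQ applied after intersection,
  then swapping);
* **bulks only** — hygiene filtering of the bulk calls alone; the ΔAF method
  is refused in this mode because without a reference parent the per-SNP
  ΔAF signs are arbitrary and trait peaks cancel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association_stats import SmoothingParams, compute_stats
from .errors import ConfigurationError
from .sliding_windows import (
    PeakCall,
    WindowConfig,
    build_windows,
    call_peaks,
    mean_snp_count_per_window,
)
from .snp_filtering import (
    FilterConfig,
    FilterReport,
    filter_parent_gq,
    filter_snps,
    intersect_with_parents,
    swap_to_reference_parent,
)
from .thresholds import NullModel, ThresholdEstimate, genome_wide_ratio_threshold, snp_level_thresholds
from .variant_io import SampleRoleMap, read_variants_table, read_vcf, write_snp_table

logger = logging.getLogger("bsascan")

METHODS = ("ratio", "g", "delta_af")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    input: str | Path | list
    roles: SampleRoleMap
    parents_input: str | Path | list | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    null_model: NullModel = field(default_factory=NullModel)
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    alpha: float = 0.01
    methods: tuple[str, ...] = ("ratio",)
    out_dir: str | Path | None = None
    peak_position: str = "start"

    def __post_init__(self):
        if isinstance(self.methods, str):
            self.methods = (self.methods,) if self.methods != "all" else METHODS
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigurationError(f"unknown method(s): {sorted(unknown)}")
        if "delta_af" in self.methods and not self.roles.has_parents:
            raise ConfigurationError(
                "the delta_af (allele frequency) method requires parental data: "
                "without a reference parent the per-SNP ΔAF signs are arbitrary "
                "and trait-associated windows cancel to zero"
            )


@dataclass
class RunResult:
    stats: pd.DataFrame
    windows: pd.DataFrame
    peaks: dict[str, list[PeakCall]]
    genome_ratio_threshold: ThresholdEstimate | None
    filter_reports: dict[str, FilterReport]
    manifest: dict


def _read_any(source, roles: SampleRoleMap):
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix.lower() in {".vcf", ".bcf"} or str(path).endswith(".vcf.gz"):
            return read_vcf(path, roles)
        return read_variants_table(path, roles)
    return list(source)  # already records


def prepare_records(cfg: RunConfig) -> tuple[list, dict[str, FilterReport]]:
    """Read and filter records, handling the three input layouts."""
    reports: dict[str, FilterReport] = {}
    records = _read_any(cfg.input, cfg.roles)
    use_parents = cfg.roles.has_parents
    if use_parents and cfg.parents_input is not None:
        parent_records = _read_any(cfg.parents_input, cfg.roles)
        bulk_kept, reports["bulks"] = filter_snps(records, cfg.filter, use_parents=False)
        parent_kept, reports["parents"] = filter_snps(
            parent_records, cfg.filter, parent_table=True
        )
        merged = intersect_with_parents(bulk_kept, parent_kept)
        logger.info("common SNPs after parent intersection: %d", len(merged))
        merged, n_gq = filter_parent_gq(merged, cfg.filter)
        logger.info("removed %d SNPs with low parental GQ", n_gq)
        kept = merged
    elif use_parents:
        kept, reports["joint"] = filter_snps(records, cfg.filter, use_parents=True)
    else:
        kept, reports["bulks"] = filter_snps(records, cfg.filter, use_parents=False)
    for name, rep in reports.items():
        logger.info("filter report (%s):\n%s", name, rep.as_text())
    if use_parents:
        ref_parent = cfg.roles.reference_parent or "parent1"
        kept = swap_to_reference_parent(kept, ref_parent)
    return kept, reports


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full scan and (optionally) write the run artifacts."""
    records, reports = prepare_records(cfg)
    stats = compute_stats(records, alpha=cfg.alpha, smoothing=cfg.smoothing)
    logger.info("computing statistics for %d SNPs", len(stats))
    model = cfg.null_model
    need_snp_thresholds = {"g", "delta_af"} & set(cfg.methods)
    if need_snp_thresholds:
        stats = snp_level_thresholds(stats, model, smoothing=cfg.smoothing)
    windows = build_windows(stats, cfg.window)
    peaks: dict[str, list[PeakCall]] = {}
    genome_thr = None
    if "ratio" in cfg.methods:
        mean_count = mean_snp_count_per_window(windows)
        genome_thr = genome_wide_ratio_threshold(stats, mean_count, model)
        logger.info(
            "genome-wide ratio threshold %.4f (mean %.1f SNPs/window)",
            genome_thr.upper,
            mean_count,
        )
        peaks["ratio"] = call_peaks(
            windows,
            "ratio",
            genome_threshold=genome_thr,
            stats=stats,
            model=model,
            position=cfg.peak_position,
        )
    if "g" in cfg.methods:
        peaks["g"] = call_peaks(windows, "g", position=cfg.peak_position)
    if "delta_af" in cfg.methods:
        peaks["delta_af"] = call_peaks(windows, "delta_af", position=cfg.peak_position)
    for method, calls in peaks.items():
        logger.info("%s method: %d peak(s)", method, len(calls))

    manifest = {
        "package_version": __version__,
        "alpha": cfg.alpha,
        "methods": list(cfg.methods),
        "window": {"size": cfg.window.window_size, "step": cfg.window.step},
        "null_model": {
            "alt_freq": model.alt_freq,
            "replicates": model.replicates,
            "alpha_sim": model.alpha_sim,
            "ratio_percentile": model.ratio_percentile,
            "delta_af_ci": model.delta_af_ci,
            "g_percentile": model.g_percentile,
            "seed": model.seed,
        },
        "smoothing": {
            "window_length": cfg.smoothing.window_length,
            "polyorder": cfg.smoothing.polyorder,
        },
        "counts": {
            "snps_analyzed": int(len(stats)),
            "ssnps": int(stats["is_ssnp"].sum()),
            "windows": int(len(windows)),
            "filter_reports": {
                name: {"input": r.input_count, "output": r.output_count, **r.removed}
                for name, r in reports.items()
            },
        },
        "genome_ratio_threshold": genome_thr.upper if genome_thr else None,
        "peaks": {
            m: [
                {
                    "chrom": p.chrom,
                    "position": p.position,
                    "value": p.value,
                    "window_threshold": p.window_threshold,
                    "verified": p.verified,
                }
                for p in calls
            ]
            for m, calls in peaks.items()
        },
    }
    result = RunResult(stats, windows, peaks, genome_thr, reports, manifest)
    if cfg.out_dir is not None:
        _write_artifacts(result, cfg)
    return result


def _write_artifacts(result: RunResult, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_snp_table(result.stats, out / "snp_stats.tsv")
    result.windows.to_csv(out / "windows.tsv", sep="\t", index=False)
    rows = [
        {
            "chrom": p.chrom,
            "position": p.position,
            "statistic": p.statistic,
            "value": p.value,
            "genome_threshold": p.genome_threshold,
            "window_threshold": p.window_threshold,
            "verified": p.verified,
        }
        for calls in result.peaks.values()
        for p in calls
    ]
    pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "position",
            "statistic",
            "value",
            "genome_threshold",
            "window_threshold",
            "verified",
        ],
    ).to_csv(out / "peaks.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
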