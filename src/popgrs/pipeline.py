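"""End-to-end orchestration: curate -> EAF -> enrichment -> cluster -> score.

A run is described by a :class:`RunConfig` (YAML-loadable).  Every
artifact is written under the output directory together with a manifest
recording inputs, parameter values and the seed, sufficient to
reproduce the run.  Reruns with identical config produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

from . import __version__
from .catalog import (
    CurationReport,
    deduplicate,
    harmonize,
    parse_association_table,
    write_association_tsv,
)
from .enrichment import (
    DEFAULT_THRESHOLD,
    build_matrix,
    cluster_populations,
    kruskal_wallis_eaf,
)
from .errors import ConfigurationError, DegenerateInputError, PopgrsError
from .genotypes import SamplePanel, compute_eaf, read_vcf_genotypes
from .scores import (
    correlate_prevalence,
    population_mean_score,
    read_prevalence_table,
    score_samples,
)

FREQ_PRECISION = 6  # decimals for serialized frequencies


@dataclass
class RunConfig:
    association_path: str
    vcf_path: str
    panel_path: str
    out_dir: str
    prevalence_path: str | None = None
    trait: Literal["OAG", "IOP"] = "OAG"
    grouping: Literal["population", "super_population"] = "super_population"
    reference_group: str = "GLOBAL"
    threshold: float = DEFAULT_THRESHOLD
    filter_cutoff: float = 0.10
    sidedness: Literal["two-sided", "enrichment", "depletion"] = "two-sided"
    exclude_focal_group: bool = False
    cluster_metric: Literal["correlation", "euclidean"] = "correlation"
    cluster_linkage: Literal["average", "complete", "ward", "single"] = "average"
    seed: int = 0
    column_map: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.threshold <= 0:
            raise ConfigurationError("threshold must be > 0")
        if not (0.0 <= self.filter_cutoff <= 1.0):
            raise ConfigurationError("filter_cutoff must be in [0, 1]")
        for name in ("association_path", "vcf_path", "panel_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigurationError(f"{name} does not exist: {p}")
        if self.prevalence_path and not Path(self.prevalence_path).exists():
            raise ConfigurationError(
                f"prevalence_path does not exist: {self.prevalence_path}"
            )


def _log(msg: str) -> None:
    print(f"[popgrs] {msg}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the machine-readable run report.

    Stages: curate associations, read genotypes, per-group and pooled
    EAF, enrichment matrix + classification counts, population
    clustering, Kruskal-Wallis frequency comparison, composite risk
    scores, and (when prevalence data are supplied) the
    score-prevalence correlation.  A stage failure halts the run; the
    report written so far is kept under ``failed.marker``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}
    stage = "curate"
    try:
        # --- curate ---------------------------------------------------
        cur_report = CurationReport()
        records = parse_association_table(
            config.association_path, config.trait,
            column_map=config.column_map, report=cur_report,
        )
        records = harmonize(records, cur_report)
        records, cur_report = deduplicate(records, cur_report)
        if not records:
            raise DegenerateInputError("no association records survived curation")
        write_association_tsv(records, out / "curated_associations.tsv")
        (out / "curation_report.json").write_text(cur_report.to_json() + "\n")
        report["stages"]["curate"] = {"n_snps": len(records)}
        _log(f"curate: {cur_report.n_in} -> {cur_report.n_out} records")

        # --- genotypes & EAF -------------------------------------------
        stage = "eaf"
        panel = SamplePanel.from_tsv(config.panel_path)
        genotypes, vcf_report = read_vcf_genotypes(config.vcf_path, records)
        if not genotypes.rsids:
            raise DegenerateInputError("no association SNPs found in the VCF")
        freqs = compute_eaf(genotypes, panel, config.grouping)
        pooled = compute_eaf(genotypes, panel, "pooled", config.reference_group)
        table = freqs.concat(pooled)
        table.to_tsv(out / "eaf.tsv", precision=FREQ_PRECISION)
        report["stages"]["eaf"] = {
            "n_matched": len(vcf_report.matched),
            "n_unmatched": len(vcf_report.unmatched),
            "n_skipped": len(vcf_report.skipped),
            "groups": table.groups,
        }
        _log(f"eaf: {len(vcf_report.matched)} SNPs matched in VCF")

        # --- enrichment -----------------------------------------------
        stage = "enrich"
        groups = [g for g in table.groups if g != config.reference_group]
        matrix = build_matrix(
            table, genotypes.rsids, groups, config.reference_group,
            threshold=config.threshold, alternative=config.sidedness,
            exclude_focal=config.exclude_focal_group,
        )
        matrix.to_cells_frame().to_csv(out / "enrichment.tsv", sep="\t",
                                       index=False, float_format="%.6g")
        matrix.values.to_csv(out / "matrix.tsv", sep="\t", float_format="%.6g")
        matrix.classes.to_csv(out / "classes.tsv", sep="\t")
        counts = matrix.class_counts()
        (out / "class_counts.json").write_text(json.dumps(counts, indent=2) + "\n")
        report["stages"]["enrich"] = {"class_counts": counts,
                                      "n_missing_cells": len(matrix.missing)}
        _log(f"enrich: {len(matrix.cells)} cells tested")

        # --- cluster & frequency comparison ---------------------------
        stage = "cluster"
        if matrix.values.shape[1] >= 2:
            tree = cluster_populations(
                matrix, metric=config.cluster_metric, method=config.cluster_linkage
            )
            (out / "dendrogram.nwk").write_text(tree.newick + "\n")
            top = [sorted(c) for c in tree.cut(2)]
            report["stages"]["cluster"] = {"top_split": top,
                                           "n_imputed": tree.n_imputed}
        h, p = kruskal_wallis_eaf(table, groups)
        report["stages"]["kruskal_wallis"] = {"H": h, "p_value": p}

        # --- scores ----------------------------------------------------
        stage = "score"
        scores = score_samples(genotypes)
        scores.to_csv(out / "scores.tsv", sep="\t", index=False,
                      float_format=f"%.{FREQ_PRECISION}f")
        summaries = population_mean_score(genotypes, panel, grouping=config.grouping)
        pd_summaries = [
            {"group": s.group, "n_samples": s.n_samples,
             "mean_score": round(s.mean_score, FREQ_PRECISION),
             "sd_score": round(s.sd_score, FREQ_PRECISION)}
            for s in summaries
        ]
        with (out / "score_summary.tsv").open("w") as fh:
            fh.write("group\tn_samples\tmean_score\tsd_score\n")
            for s in pd_summaries:
                fh.write(f"{s['group']}\t{s['n_samples']}\t"
                         f"{s['mean_score']:.6f}\t{s['sd_score']:.6f}\n")
        report["stages"]["score"] = {"summaries": pd_summaries}

        # --- correlate --------------------------------------------------
        if config.prevalence_path:
            stage = "correlate"
            prevalences = read_prevalence_table(config.prevalence_path)
            corr = {}
            for outcome in ("oag", "high_iop"):
                try:
                    res = correlate_prevalence(summaries, prevalences, outcome)
                    corr[outcome] = {"r": round(res.r, 6), "n": res.n,
                                     "dropped": list(res.dropped)}
                except DegenerateInputError as exc:
                    corr[outcome] = {"error": str(exc)}
            (out / "correlation.json").write_text(json.dumps(corr, indent=2) + "\n")
            report["stages"]["correlate"] = corr

    except PopgrsError as exc:
        report["failed_stage"] = stage
        report["error"] = {"code": type(exc).__name__, "message": str(exc)}
        (out / "failed.marker").write_text(json.dumps(report["error"]) + "\n")
        (out / "run_report.json").write_text(json.dumps(report, indent=2) + "\n")
        raise

    manifest = {
        "tool": "popgrs",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "run_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
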