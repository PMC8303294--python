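"""End-to-end orchestration: simulate or ingest, score, test, cluster, scan.

A :class:`PipelineConfig` (usually loaded from YAML) drives the stages in
dependency order:

    cohort -> scoring -> differential expression -> signature ->
    sample clustering -> design -> archetypes -> intersection -> seed scan

Each stage writes its outputs as TSV under the configured output directory
and appends a record (parameters, output files, row counts, warnings) to a
machine-readable :class:`RunReport`.  Identical config + seed gives
byte-identical outputs.  A failing stage stops the run but leaves the
completed stages' outputs and a report marking the failure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clustering, de, scoring, synthetic
from . import io as fio
from . import seeds as seedscan

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config"]

logger = logging.getLogger("fibromir")

#: a miR-214-3p-like sequence used for the demonstration seed scan
DEFAULT_MIRNA = ("miR-214-3p", "ACAGCAGGCACAGACAGGCAGU")


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run; defaults follow the study conventions."""

    outdir: str = "fibromir-out"
    seed: int = 0
    # cohort inputs: paths, or None to simulate
    counts_path: str | None = None
    markers_path: str | None = None
    groups_path: str | None = None
    cohort: synthetic.CohortParams = field(default_factory=synthetic.CohortParams)
    # scoring / signature
    threshold: float = 0.25
    r_min: float = 0.5
    k: int = 25
    # DE thresholds defining "modulated"
    padj_max: float = 0.05
    lfc_min: float = 1.0
    # clustering
    cluster_k: int = 2
    # 2x2 design
    design_counts_path: str | None = None
    design_annot_path: str | None = None
    design: synthetic.DesignParams = field(default_factory=synthetic.DesignParams)
    e_min: float = 1.0
    l_min: float = 1.0
    # seed scan
    mirna_fasta: str | None = None
    utr_fasta: str | None = None
    utr_length: int = 500


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (missing keys -> defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort = synthetic.CohortParams(**raw.pop("cohort", {}))
    design = synthetic.DesignParams(**raw.pop("design", {}))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(cohort=cohort, design=design, **raw)


@dataclass
class RunReport:
    """Machine-readable record of a pipeline run."""

    version: str
    seed: int
    stages: list = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None

    def add(self, name: str, params: dict, outputs: dict, warnings: list | None = None):
        self.stages.append(
            {
                "stage": name,
                "params": params,
                "outputs": outputs,
                "warnings": warnings or [],
            }
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_json() + "\n")
        return path


def _out(report: RunReport, stage: str, params: dict, **frames) -> dict[str, pd.DataFrame]:
    """Helper recording written outputs with their row counts."""
    outputs = {}
    for fname, (path, frame) in frames.items():
        outputs[str(path)] = int(len(frame))
    report.add(stage, params, outputs)
    return frames


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage in dependency order; see the module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, seed=config.seed)
    handler_added = False
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("[fibromir:%(stage)s] %(message)s"))
        logger.addHandler(h)
        handler_added = True

    def log(stage: str, msg: str):
        logger.info(msg, extra={"stage": stage})

    stage = "cohort"
    try:
        # ---- cohort data -------------------------------------------------
        if config.counts_path:
            counts = fio.read_counts(config.counts_path)
            markers = fio.read_table(config.markers_path)
            groups = fio.read_table(config.groups_path)["group"]
            truth = None
        else:
            params = dataclasses.replace(config.cohort, seed=config.seed)
            counts, markers, truth = synthetic.generate_cohort(params)
            groups = truth.group
        log(stage, f"{counts.shape[0]} miRNAs x {counts.shape[1]} samples")
        p_counts = fio.write_table(counts, outdir / "cohort_counts.tsv")
        p_markers = fio.write_table(markers, outdir / "cohort_markers.tsv")
        report.add(
            stage,
            {"simulated": config.counts_path is None, "seed": config.seed},
            {str(p_counts): len(counts), str(p_markers): len(markers)},
        )

        # ---- fibrotic scoring -------------------------------------------
        stage = "scoring"
        fs = scoring.fibrotic_score(markers)
        strata = scoring.stratify(fs, config.threshold)
        annotation = pd.DataFrame({"FS": fs, "stratum": strata, "group": groups})
        p = fio.write_table(annotation, outdir / "fibrosis_annotation.tsv")
        report.add(stage, {"threshold": config.threshold}, {str(p): len(annotation)})
        log(stage, f"strata: {strata.value_counts().to_dict()}")

        # ---- differential expression --------------------------------------
        stage = "de"
        de_res = de.DifferentialExpression(counts, groups, reference="control").fit()
        p = fio.write_table(de_res.results, outdir / "de_results.tsv")
        modulated_cohort = de_res.significant(config.padj_max, config.lfc_min).index
        report.add(
            stage,
            {"padj_max": config.padj_max, "lfc_min": config.lfc_min},
            {str(p): len(de_res.results)},
        )
        log(stage, f"{len(modulated_cohort)} modulated miRNAs")

        # ---- fibrosis signature -------------------------------------------
        stage = "signature"
        norm = de.normalize_counts(counts, de_res.size_factors)
        log_expr = np.log2(norm + 1.0)
        sig = scoring.correlate_with_score(log_expr, fs)
        sig = scoring.select_signature(sig, config.r_min, config.k)
        p = fio.write_table(sig, outdir / "signature.tsv")
        report.add(stage, {"r_min": config.r_min, "k": config.k}, {str(p): len(sig)})
        log(stage, f"{int(sig['selected'].sum())} signature miRNAs")

        # ---- sample clustering on the signature ---------------------------
        stage = "clustering"
        selected = sig.index[sig["selected"]]
        basis = log_expr.loc[selected] if len(selected) >= 2 else log_expr
        scaled, dropped = clustering.zscore_rows(basis)
        dend = clustering.hac_complete(scaled, axis="columns")
        labels = dend.cut(config.cluster_k)
        p = fio.write_table(labels.to_frame(), outdir / "sample_clusters.tsv")
        report.add(
            stage,
            {"k": config.cluster_k, "linkage": "complete", "distance": "1 - Pearson r"},
            {str(p): len(labels)},
            warnings=[f"dropped constant miRNAs: {dropped}"] if dropped else [],
        )

        # ---- 2x2 design + archetypes --------------------------------------
        stage = "design"
        if config.design_counts_path:
            dcounts = fio.read_counts(config.design_counts_path)
            condition = fio.read_table(config.design_annot_path)["condition"]
        else:
            dparams = dataclasses.replace(config.design, seed=config.seed + 1)
            dcounts, dtruth = synthetic.generate_design(dparams)
            condition = dtruth.condition
        dnorm = de.normalize_counts(dcounts)
        mean_expr = dnorm.T.groupby(condition).mean().T
        arch = clustering.classify_archetype(mean_expr, config.e_min, config.l_min)
        p = fio.write_table(arch, outdir / "archetypes.tsv")
        report.add(
            stage,
            {"e_min": config.e_min, "l_min": config.l_min},
            {str(p): len(arch)},
        )
        log(stage, f"archetypes: {arch['class'].value_counts().to_dict()}")

        # ---- DMD x differentiation intersection ---------------------------
        stage = "intersection"
        modulated_design = arch.index[arch["class"] != "unclassified"]
        only_a, both, only_b, members = clustering.intersect_modulated(
            modulated_cohort, modulated_design
        )
        p = fio.write_table(members, outdir / "venn_membership.tsv")
        report.add(
            stage,
            {"dmd_only": only_a, "intersection": both, "diff_only": only_b},
            {str(p): len(members)},
        )

        # ---- seed scan -----------------------------------------------------
        stage = "seedscan"
        if config.mirna_fasta and config.utr_fasta:
            mirnas = fio.read_fasta(config.mirna_fasta)
            utrs = fio.read_fasta(config.utr_fasta)
        else:
            name, mseq = DEFAULT_MIRNA
            utr_seq, _ = synthetic.generate_utr_with_sites(
                config.utr_length,
                mseq,
                planted=[(60, "8mer"), (200, "7mer-m8")],
                seed=config.seed + 2,
                utr_id="synthetic-utr",
            )
            mirnas = {name: mseq}
            utrs = {"synthetic-utr": utr_seq}
            fio.write_fasta(utrs, outdir / "utr.fasta")
        rows = []
        for mname, mseq in mirnas.items():
            for uname, useq in utrs.items():
                for site in seedscan.seed_sites(mseq, useq, utr_id=uname):
                    rows.append(
                        {
                            "mirna": mname,
                            "utr": site.utr_id,
                            "start": site.start,
                            "end": site.end,
                            "site_type": site.site_type,
                            "sequence": site.sequence,
                        }
                    )
        sites = pd.DataFrame(
            rows, columns=["mirna", "utr", "start", "end", "site_type", "sequence"]
        )
        p = fio.write_table(sites, outdir / "seed_sites.tsv", index=False)
        report.add(stage, {"n_mirnas": len(mirnas), "n_utrs": len(utrs)}, {str(p): len(sites)})
        log(stage, f"{len(sites)} seed sites")

    except Exception as exc:  # noqa: BLE001 - report the failing stage, re-raise
        report.failed_stage = stage
        report.error = f"{type(exc).__name__}: {exc}"
        report.write(outdir / "report.json")
        raise
    finally:
        if handler_added:
            logger.handlers.clear()

    report.write(outdir / "report.json")
    return report
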