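"""End-to-end orchestration: simulate/load -> FPKM -> presence calls -> DE ->
classification -> concordance, with input validation and a consolidated
JSON report.

All tabular interchange is TSV (tab-separated, header row, first column
``gene_id``, no quoting); summaries are JSON. Logging goes to stderr;
machine-readable output goes to files only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import classify_genes, summarize_classification
from .concord import compare_datasets
from .diffexp import NegativeBinomialDE
from .errors import ConfigurationError, ValidationError
from .expression import call_expressed, compute_fpkm, condition_mean_fpkm, count_detected
from .simdata import SimConfig, SimulatedExperiment, generate_counts, write_experiment

log = logging.getLogger("ganglioseq")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Exactly one of the two input modes must be supplied: either the four
    real-input paths (counts/conditions/annotation plus optional reference
    and comparison), or a ``sim`` block describing a synthetic experiment.
    """

    counts_path: str | None = None
    conditions_path: str | None = None
    annotation_path: str | None = None
    reference_path: str | None = None
    comparison_path: str | None = None
    sim: SimConfig | None = None
    min_fpkm: float = 1.0
    min_replicates: int = 2
    strict_gt: bool = False
    alpha: float = 0.05
    top_k: int | None = None
    fold_threshold: float = 2.0
    outdir: str = "ganglioseq_out"
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_paths = self.counts_path is not None
        has_sim = self.sim is not None
        if has_paths == has_sim:
            raise ConfigurationError(
                "supply exactly one of: real input paths, or a 'sim' block"
            )
        if has_paths and (self.conditions_path is None or self.annotation_path is None):
            raise ConfigurationError(
                "real-input mode needs counts, conditions and annotation paths"
            )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        """Load a flat key-value config file with an optional nested ``sim``
        block; keyword overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must be a mapping")
        sim_block = raw.pop("sim", None)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        seed = raw.get("seed")
        if sim_block is not None:
            if seed is not None:
                sim_block = {**sim_block, "seed": seed}
            if "class_proportions" in sim_block:
                sim_block["class_proportions"] = dict(sim_block["class_proportions"])
            for key in ("baseline_mean_log_range", "library_size_range", "gene_length_range"):
                if key in sim_block:
                    sim_block[key] = tuple(sim_block[key])
            raw["sim"] = SimConfig(**sim_block)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class Finding:
    """A machine-readable validation finding (not an exception)."""

    code: str
    message: str
    items: tuple = ()

    def to_dict(self) -> dict:
        return {"code": self.code, "message": self.message, "items": list(self.items)}


def validate_tables(
    counts: pd.DataFrame,
    conditions: pd.Series,
    annotation: pd.DataFrame,
) -> list[Finding]:
    """Check the core input tables; an empty list means valid."""
    findings: list[Finding] = []
    dup = counts.index[counts.index.duplicated()].unique()
    if len(dup):
        findings.append(Finding("DUP_GENE", "duplicate gene ids in counts", tuple(dup[:10])))
    dup = annotation.index[annotation.index.duplicated()].unique()
    if len(dup):
        findings.append(
            Finding("DUP_GENE", "duplicate gene ids in annotation", tuple(dup[:10]))
        )
    dup = counts.columns[counts.columns.duplicated()].unique()
    if len(dup):
        findings.append(Finding("DUP_SAMPLE", "duplicate sample names", tuple(dup[:10])))
    vals = counts.to_numpy()
    if (vals < 0).any():
        bad = counts.index[(vals < 0).any(axis=1)]
        findings.append(Finding("NEG_COUNT", "negative count entries", tuple(bad[:10])))
    cond = conditions.reindex(counts.columns)
    missing = cond.index[cond.isna()]
    if len(missing):
        findings.append(
            Finding("NO_CONDITION", "samples without a condition label", tuple(missing))
        )
    bad_labels = cond.dropna()[~cond.dropna().isin(["A", "B"])]
    if len(bad_labels):
        findings.append(
            Finding(
                "BAD_CONDITION",
                "condition labels must be 'A' or 'B'",
                tuple(bad_labels.index[:10]),
            )
        )
    unannotated = counts.index.difference(annotation.index)
    if len(unannotated):
        findings.append(
            Finding(
                "MISSING_LENGTH",
                "genes in counts missing from the annotation",
                tuple(unannotated[:10]),
            )
        )
    if "length_bp" in annotation.columns:
        nonpos = annotation.index[pd.to_numeric(annotation["length_bp"]) < 1]
        if len(nonpos):
            findings.append(
                Finding("BAD_LENGTH", "non-positive gene lengths", tuple(nonpos[:10]))
            )
    else:
        findings.append(Finding("MISSING_LENGTH", "annotation lacks a length_bp column"))
    return findings


def _load_inputs(config: PipelineConfig) -> SimulatedExperiment:
    if config.sim is not None:
        sim = config.sim
        if config.seed is not None and config.seed != sim.seed:
            sim = dataclasses.replace(sim, seed=config.seed)
        log.info("simulate: %d genes, %d+%d replicates, seed %d",
                 sim.n_genes, sim.n_reps_a, sim.n_reps_b, sim.seed)
        return generate_counts(sim)
    counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
    cond_table = pd.read_csv(config.conditions_path, sep="\t", index_col=0)
    conditions = cond_table.iloc[:, 0].astype(str)
    annotation = pd.read_csv(config.annotation_path, sep="\t", index_col=0)
    if "family" in annotation.columns:
        annotation["family"] = annotation["family"].fillna("")
    reference: frozenset[str] = frozenset()
    if config.reference_path:
        lines = Path(config.reference_path).read_text().splitlines()
        reference = frozenset(l.strip() for l in lines if l.strip())
    comparison = None
    if config.comparison_path:
        comparison = pd.read_csv(config.comparison_path, sep="\t", index_col=0)
    return SimulatedExperiment(
        counts=counts,
        conditions=conditions,
        annotation=annotation,
        truth=pd.DataFrame(index=counts.index),
        reference_presence=reference,
        comparison=comparison if comparison is not None else pd.DataFrame(
            columns=["fpkm_a", "fpkm_b"]
        ),
        config=None,
    )


def validate_inputs(config: PipelineConfig) -> list[Finding]:
    """Load the configured inputs and return validation findings."""
    exp = _load_inputs(config)
    return validate_tables(exp.counts, exp.conditions, exp.annotation)


@dataclass
class RunReport:
    """Consolidated numbers from one pipeline run."""

    n_genes: int
    n_samples: int
    n_detected: int
    n_significant: int
    classification: dict
    concordance: dict | None
    parameters: dict
    version: str = __version__
    elapsed_seconds: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class PipelineValidationError(ValidationError):
    """Raised when input validation produced findings."""

    def __init__(self, findings: list[Finding]):
        self.findings = findings
        super().__init__(
            "input validation failed: " + "; ".join(f.code for f in findings)
        )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage in order and write all outputs under ``outdir``.

    Deterministic given the seed: rerunning with the same configuration
    produces byte-identical output files.
    """
    t0 = time.perf_counter()
    logging.basicConfig(
        level=getattr(logging, str(config.log_level).upper(), logging.INFO),
        format="[%(name)s] %(message)s",
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    exp = _load_inputs(config)
    findings = validate_tables(exp.counts, exp.conditions, exp.annotation)
    if findings:
        raise PipelineValidationError(findings)

    if config.sim is not None:
        write_experiment(exp, outdir)

    log.info("fpkm: normalizing %d genes x %d samples", *exp.counts.shape)
    fpkm = compute_fpkm(exp.counts, exp.annotation)
    calls = call_expressed(
        fpkm,
        exp.conditions,
        min_fpkm=config.min_fpkm,
        min_replicates=config.min_replicates,
        strict=config.strict_gt,
    )
    n_detected = count_detected(calls)
    log.info("call: %d genes detected", n_detected)

    de_res = NegativeBinomialDE(exp.counts, exp.conditions, alpha=config.alpha).fit()
    log.info("de: %d significant at FDR %g", de_res.n_significant, config.alpha)

    cls = classify_genes(de_res.table, calls, exp.reference_presence)
    summary = summarize_classification(cls)
    log.info("classify: %s", summary.counts)

    concordance = None
    if len(exp.comparison):
        sig_neuronal = cls.index[
            cls["category"].isin(["up_a", "up_b", "exclusive_a", "exclusive_b"])
        ]
        symbols = exp.annotation["symbol"]
        report = None
        if len(sig_neuronal):
            report = compare_datasets(
                condition_mean_fpkm(fpkm, exp.conditions),
                calls,
                symbols,
                exp.comparison,
                de_res.table.loc[sig_neuronal, "log2fc"],
                min_fpkm=config.min_fpkm,
                top_k=config.top_k,
                fold_threshold=config.fold_threshold,
            )
            concordance = report.to_dict()
            log.info("concord: rho=%.3f same-trend=%.3f",
                     report.spearman_rho, report.frac_same_trend)
        else:
            log.info("concord: skipped (no significant neuronal DE genes)")

    fpkm.to_csv(outdir / "fpkm.tsv", sep="\t")
    calls.to_csv(outdir / "presence.tsv", sep="\t")
    de_res.to_tsv(outdir / "de.tsv")
    cls.to_csv(outdir / "classification.tsv", sep="\t")
    if concordance is not None:
        (outdir / "concordance.json").write_text(json.dumps(concordance, indent=2) + "\n")

    report = RunReport(
        n_genes=int(exp.counts.shape[0]),
        n_samples=int(exp.counts.shape[1]),
        n_detected=n_detected,
        n_significant=de_res.n_significant,
        classification=summary.to_dict(),
        concordance=concordance,
        parameters={
            "min_fpkm": config.min_fpkm,
            "min_replicates": config.min_replicates,
            "strict_gt": config.strict_gt,
            "alpha": config.alpha,
            "top_k": config.top_k,
            "fold_threshold": config.fold_threshold,
            "seed": config.seed if config.seed is not None else (
                config.sim.seed if config.sim else None
            ),
        },
        elapsed_seconds=round(time.perf_counter() - t0, 3),
    )
    payload = report.to_dict()
    payload["elapsed_seconds"] = 0.0  # keep report files byte-reproducible
    (outdir / "report.json").write_text(json.dumps(payload, indent=2) + "\n")
    return report
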