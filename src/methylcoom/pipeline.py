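"""File-based pipeline orchestration.

``run_pipeline`` chains the stages — probe filtering, dynamic-CpG
selection, trajectory and linear-model fitting (with the one-round refit),
tumor placement and cross-validation, cell-of-origin methylome inference,
class A-D calling, methylation-expression correlation and region-set
enrichment — writing every intermediate table to the output directory plus
a JSON run manifest.  It is implemented as the composition of the same
file-based stage functions the CLI subcommands expose, so subcommands and
the single ``run`` entry point produce identical outputs.  All randomness
flows from the config seed; a fixed config yields byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aberrations import call_classes, compute_deltas, summarize_classes
from .coo import cross_validate, infer_coo_methylome, place_samples
from .integration import (
    assign_mirna_promoters,
    correlate,
    promoter_windows,
    region_enrichment,
)
from .io import (
    filter_probes,
    load_annotation,
    load_beta_matrix,
    load_expression,
    load_regions,
    load_sample_sheet,
    save_beta_matrix,
)
from .trajectory import Trajectory, refit_with_linear_cpgs
from .metree import MeTree

__all__ = ["RunConfig", "run_pipeline", "fit_stage", "map_stage", "call_stage",
           "correlate_stage", "enrich_stage"]

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Inputs, thresholds and run settings for one pipeline execution.

    Threshold defaults are the method's published operating point: 20%
    methylation change for dynamic CpGs and aberration calls, 75% patient
    fraction, p 0.05 throughout, Pearson |r| 0.7 for genes and Spearman
    |rho| 0.35 for miRNAs, 5000 cross-validation repetitions on a 70/30
    split.
    """

    reference_betas: str = ""
    tumor_betas: str = ""
    sample_sheet: str = ""
    probe_annotation: str = ""
    genes: str | None = None
    expression_tumor: str | None = None
    expression_normal: str | None = None
    mirna_tss: str | None = None
    mirna_expression: str | None = None
    segment_beds: list[str] = field(default_factory=list)
    region_beds: list[str] = field(default_factory=list)

    delta_threshold: float = 0.20
    p_threshold: float = 0.05
    linearity_p: float = 0.05
    lack_of_fit: bool = False
    delta_cut: float = 0.20
    patient_fraction: float = 0.75
    pearson_r: float = 0.7
    spearman_r: float = 0.35
    correlation_p: float = 0.05
    placement_method: str = "phylogenetic"
    cv_reps: int = 5000
    cv_split: float = 0.70
    cv_scheme: str = "subsample"
    cv_placement: str = "taxon_addition"
    seed: int = 0
    outdir: str = "methylcoom_out"

    def __post_init__(self) -> None:
        for name in ("delta_threshold", "p_threshold", "linearity_p", "delta_cut",
                     "patient_fraction", "pearson_r", "spearman_r",
                     "correlation_p", "cv_split"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        required = {
            "reference_betas": self.reference_betas,
            "tumor_betas": self.tumor_betas,
            "sample_sheet": self.sample_sheet,
            "probe_annotation": self.probe_annotation,
        }
        for name, p in required.items():
            if not p:
                raise FileNotFoundError(f"config is missing required input {name!r}")
        optional = [self.genes, self.expression_tumor, self.expression_normal,
                    self.mirna_tss, self.mirna_expression]
        for p in list(required.values()) + [q for q in optional if q] \
                + list(self.segment_beds) + list(self.region_beds):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=index_label,
              index=index_label is not None)


def _save_trajectory(traj: Trajectory, outdir: Path) -> None:
    payload = {
        "backbone": traj.backbone,
        "ds_map": {k: float(v) for k, v in traj.ds_map.items()},
        "branchedness": float(traj.branchedness),
        "start": traj.start,
        "end": traj.end,
        "probes": traj.probes,
    }
    (outdir / "trajectory.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    (outdir / "tree.nwk").write_text(traj.to_newick() + "\n")


def _load_trajectory(outdir: Path) -> Trajectory:
    payload = json.loads((outdir / "trajectory.json").read_text())
    return Trajectory(
        tree=MeTree({}, {}),  # tree geometry is not needed downstream
        backbone=payload["backbone"],
        ds_map=payload["ds_map"],
        branchedness=payload["branchedness"],
        start=payload["start"],
        end=payload["end"],
        probes=payload["probes"],
    )


# ---------------------------------------------------------------------------
# stages (each reads inputs from disk and writes tables to outdir)


def fit_stage(config: RunConfig, outdir: Path) -> None:
    ref = load_beta_matrix(config.reference_betas)
    sheet = load_sample_sheet(config.sample_sheet)
    annotation = load_annotation(config.probe_annotation)
    ref = filter_probes(ref, annotation)
    traj, model, table = refit_with_linear_cpgs(
        ref,
        sheet,
        delta_threshold=config.delta_threshold,
        p_threshold=config.p_threshold,
        linearity_p=config.linearity_p,
        lack_of_fit=config.lack_of_fit,
    )
    _tsv(table, outdir / "dynamic_cpgs.tsv", "probe_id")
    _tsv(model, outdir / "linear_model.tsv", "probe_id")
    _save_trajectory(traj, outdir)


def map_stage(config: RunConfig, outdir: Path) -> None:
    ref = filter_probes(
        load_beta_matrix(config.reference_betas), load_annotation(config.probe_annotation)
    )
    tumors = filter_probes(
        load_beta_matrix(config.tumor_betas), load_annotation(config.probe_annotation)
    )
    sheet = load_sample_sheet(config.sample_sheet)
    traj = _load_trajectory(outdir)
    model = pd.read_csv(outdir / "linear_model.tsv", sep="\t", index_col="probe_id")
    assignments = place_samples(
        tumors, ref, sheet, traj, traj.probes,
        method=config.placement_method, model=model,
    )
    if config.cv_reps >= 2:
        cv = cross_validate(
            tumors, ref, sheet, traj, traj.probes,
            reps=config.cv_reps, split=config.cv_split,
            seed=config.seed, scheme=config.cv_scheme,
            placement=config.cv_placement,
        )
        assignments = assignments.join(cv)
    _tsv(assignments, outdir / "coo_assignments.tsv", "sample_id")
    coo = infer_coo_methylome(model, assignments)
    save_beta_matrix(coo.clip(0.0, 1.0), outdir / "coo_methylomes.tsv")


def call_stage(config: RunConfig, outdir: Path) -> None:
    tumors = filter_probes(
        load_beta_matrix(config.tumor_betas), load_annotation(config.probe_annotation)
    )
    coo = pd.read_csv(outdir / "coo_methylomes.tsv", sep="\t", index_col="probe_id")
    table = pd.read_csv(outdir / "dynamic_cpgs.tsv", sep="\t", index_col="probe_id")
    deltas = compute_deltas(tumors, coo)
    calls = call_classes(
        deltas, table["dynamic"],
        delta_cut=config.delta_cut, patient_fraction=config.patient_fraction,
    )
    summary = summarize_classes(calls, deltas)
    _tsv(deltas, outdir / "delta_matrix.tsv", "probe_id")
    _tsv(calls, outdir / "class_calls.tsv", "probe_id")
    counts = pd.DataFrame(
        sorted(summary["counts"].items()), columns=["category", "count"]
    )
    _tsv(counts.set_index("category"), outdir / "class_summary.tsv", "category")
    if "per_sample" in summary:
        _tsv(summary["per_sample"].set_index("class"), outdir / "class_per_sample.tsv", "class")


def correlate_stage(config: RunConfig, outdir: Path) -> None:
    if not (config.genes and config.expression_tumor):
        return
    annotation = load_annotation(config.probe_annotation)
    tumors = filter_probes(load_beta_matrix(config.tumor_betas), annotation)
    calls = pd.read_csv(outdir / "class_calls.tsv", sep="\t", index_col="probe_id")
    hit_probes = set(calls.index[calls["class"] != "none"])
    genes = pd.read_csv(config.genes, sep="\t")
    expr = load_expression(config.expression_tumor)
    pmap = promoter_windows(genes, annotation)
    pairs = (
        pmap[["gene_id", "probes"]]
        .explode("probes")
        .dropna()
        .rename(columns={"gene_id": "feature_id", "probes": "probe_id"})
    )
    pairs = pairs[pairs["probe_id"].isin(hit_probes)]
    table = correlate(
        tumors, expr, pairs, method="pearson",
        r_threshold=config.pearson_r, p_threshold=config.correlation_p,
    )
    _tsv(table.set_index("feature_id"), outdir / "gene_correlations.tsv", "feature_id")
    if config.expression_normal:
        expr_n = load_expression(config.expression_normal)
        passing = sorted(set(table.loc[table["passes"], "feature_id"]))
        if passing:
            from .integration import compare_target_expression

            cmp = compare_target_expression(
                _merged_expression(expr, expr_n, passing),
                passing, expr.sample_ids, expr_n.sample_ids,
            )
            _tsv(cmp.set_index("gene_id"), outdir / "target_expression.tsv", "gene_id")
    if config.mirna_tss and config.mirna_expression and config.segment_beds:
        mirna_tss = pd.read_csv(config.mirna_tss, sep="\t")
        mirna_expr = load_expression(config.mirna_expression)
        sources = [load_regions(p) for p in config.segment_beds]
        pmap_m = assign_mirna_promoters(sources, mirna_tss, annotation)
        if len(pmap_m):
            pairs_m = (
                pmap_m[["mirna_id", "probes"]]
                .explode("probes")
                .dropna()
                .rename(columns={"mirna_id": "feature_id", "probes": "probe_id"})
                .drop_duplicates()
            )
            pairs_m = pairs_m[pairs_m["probe_id"].isin(hit_probes)]
            table_m = correlate(
                tumors, mirna_expr, pairs_m, method="spearman",
                r_threshold=config.spearman_r, p_threshold=config.correlation_p,
            )
            _tsv(table_m.set_index("feature_id"), outdir / "mirna_correlations.tsv",
                 "feature_id")


def _merged_expression(expr_a, expr_b, features):
    from .io import ExpressionMatrix

    merged = pd.concat([expr_a.data.loc[features], expr_b.data.loc[features]], axis=1)
    return ExpressionMatrix(merged)


def enrich_stage(config: RunConfig, outdir: Path) -> None:
    if not config.region_beds:
        return
    annotation = load_annotation(config.probe_annotation)
    calls = pd.read_csv(outdir / "class_calls.tsv", sep="\t", index_col="probe_id")
    region_sets = [load_regions(p) for p in config.region_beds]
    present = [c for c in ("A", "B", "C", "D") if (calls["class"] == c).any()]
    if not present:
        return
    table = region_enrichment(calls, annotation, region_sets, classes=present)
    _tsv(table.set_index("region_set"), outdir / "region_enrichment.tsv", "region_set")


_STAGES = [
    ("fit", fit_stage),
    ("map", map_stage),
    ("call", call_stage),
    ("correlate", correlate_stage),
    ("enrich", enrich_stage),
]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written as
    ``manifest.json``)."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, stage in _STAGES:
        try:
            stage(config, outdir)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
    manifest = {
        "package": "methylcoom",
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "outputs": {},
    }
    for p in sorted(outdir.glob("*.tsv")):
        with open(p) as fh:
            rows = sum(1 for _ in fh) - 1
        manifest["outputs"][p.name] = rows
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
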