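"""Self-contained synthetic data with the structure the pipeline assumes.

The generator emulates a sorted-cell differentiation series profiled on a
methylation array, plus a tumor cohort derived from intermediate stages of
that series:

* a linear differentiation continuum of ``n_subpopulations`` discrete
  stages (default 6, mirroring the naive -> mature B cell panel) with a few
  donors each;
* per-CpG methylation programs: stable CpGs (bimodal low/high baselines),
  linear dynamic CpGs (``alpha + beta * stage`` with a total change above
  the 20% dynamic threshold), and non-linear contaminants (sigmoid, step or
  non-monotone bump programs) that a linearity filter should remove;
* Gaussian donor noise on the beta scale, clipped to [0, 1] (a logit-normal
  alternative is available);
* tumor samples at planted differentiation stages carrying planted class
  A-D aberrations (loss/gain of a fixed magnitude in a >= 75% carrier
  subset of tumors);
* expression matrices in which planted genes respond affinely (decreasing)
  to their promoter methylation, pri-miRNA tables with promoter segments
  from two sources, and region sets enriched for planted aberrations.

Truth tables record every planted parameter so downstream stages can be
scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    BetaMatrix,
    ExpressionMatrix,
    GenomicRegionSet,
    ProbeAnnotation,
    SampleSheet,
    save_annotation,
    save_beta_matrix,
    save_expression,
    save_regions,
    save_sample_sheet,
)

__all__ = ["SimulationConfig", "Scenario", "simulate_reference", "simulate_tumors",
           "simulate_scenario", "write_scenario"]

SUBPOP_NAMES = ["NBC", "GCF", "loMBC", "intMBC", "sMGZ", "hiMBC"]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic scenario.

    Defaults mirror the reference design the method targets: 6
    subpopulations x 3 donors, 34 tumors, ~16% dynamic CpGs of which one
    fifth behave non-linearly, donor noise sd 0.02 on the beta scale, and
    planted aberration counts in the ratio the four classes occur at
    (A >> B, C >> D, hypomethylation dominant).
    """

    n_probes: int = 20_000
    n_subpopulations: int = 6
    donors_per_subpopulation: int = 3
    fraction_dynamic: float = 0.16          # probes with a dynamic program
    fraction_nonlinear: float = 0.20        # share of dynamic probes that are contaminants
    noise_sd: float = 0.02
    noise_model: str = "gaussian"           # or "logit-normal"
    nonlinear_shape: str = "sigmoid"        # "sigmoid" | "step" | "bump"
    n_tumors: int = 34
    tumor_noise_sd: float | None = None     # defaults to noise_sd
    planted_stages: list[float] | None = None  # defaults to even spacing in [20, 95]
    planted_counts: dict = field(
        default_factory=lambda: {"A": 500, "B": 50, "C": 400, "D": 50}
    )
    aberration_magnitude: float = 0.30
    carrier_fraction: float = 0.85
    n_correlated_genes: int = 50
    n_null_genes: int = 150
    expression_noise_sd: float = 0.1
    n_mirnas: int = 20
    n_planted_mirnas: int = 8
    n_snp_probes: int = 200
    n_sex_probes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_dynamic", "fraction_nonlinear", "carrier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.carrier_fraction < 0.75 and any(self.planted_counts.values()):
            # planted calls target the >=75%-of-patients rule
            raise ValueError("carrier_fraction below 0.75 cannot produce class calls")
        if self.fraction_dynamic == 0 and (
            self.planted_counts.get("A", 0) or self.planted_counts.get("B", 0)
        ):
            raise ValueError("class A/B probes require a non-zero dynamic fraction")

    @property
    def stages(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.n_subpopulations)

    @property
    def tumor_stages(self) -> np.ndarray:
        if self.planted_stages is not None:
            return np.asarray(self.planted_stages, dtype=float)
        return np.linspace(20.0, 95.0, self.n_tumors)


@dataclass
class Scenario:
    """A full synthetic dataset plus its ground truth."""

    config: SimulationConfig
    ref: BetaMatrix
    tumors: BetaMatrix
    sheet: SampleSheet
    annotation: ProbeAnnotation
    ref_truth: pd.DataFrame       # per-probe program and parameters
    tumor_truth: pd.DataFrame     # per-probe planted class
    carriers: pd.DataFrame        # probes x tumor samples bool (planted shift applied)
    planted_stages: pd.Series     # per tumor sample
    genes: pd.DataFrame
    gene_truth: pd.DataFrame      # gene -> planted flag, promoter probe
    expr_tumor: ExpressionMatrix
    expr_normal: ExpressionMatrix
    mirna_tss: pd.DataFrame
    mirna_truth: pd.DataFrame
    mirna_expr: ExpressionMatrix
    segment_sources: list
    region_sets: list


# ---------------------------------------------------------------------------
# reference continuum


def _program_values(truth: pd.DataFrame, stages: np.ndarray) -> np.ndarray:
    """Evaluate each probe's planted program at the given stages."""
    t = np.asarray(stages, dtype=float)[None, :] / 100.0
    a0 = truth["a0"].to_numpy()[:, None]
    delta = truth["delta_true"].to_numpy()[:, None]
    mid = truth["shape_mid"].to_numpy()[:, None] / 100.0
    bump = truth["bump"].to_numpy()[:, None]
    kind = truth["program"].to_numpy()
    out = np.tile(a0, (1, t.shape[1]))
    lin = kind == "linear"
    out[lin] = (a0 + delta * t)[lin]
    sig = kind == "sigmoid"
    if sig.any():
        width = 0.05
        raw = 1.0 / (1.0 + np.exp(-(t - mid) / width))
        lo = 1.0 / (1.0 + np.exp(mid / width))
        hi = 1.0 / (1.0 + np.exp(-(1.0 - mid) / width))
        norm = (raw - lo) / (hi - lo)
        out[sig] = (a0 + delta * norm)[sig]
    step = kind == "step"
    if step.any():
        out[step] = (a0 + delta * (t >= mid))[step]
    bmp = kind == "bump"
    if bmp.any():
        out[bmp] = (a0 + delta * t + bump * np.sin(np.pi * t))[bmp]
    return np.clip(out, 0.0, 1.0)


def _add_noise(values: np.ndarray, sd: float, rng: np.random.Generator, model: str) -> np.ndarray:
    if sd == 0:
        return np.clip(values, 0.0, 1.0)
    if model == "gaussian":
        return np.clip(values + rng.normal(0.0, sd, size=values.shape), 0.0, 1.0)
    if model == "logit-normal":
        eps = 1e-4
        v = np.clip(values, eps, 1 - eps)
        logit = np.log(v / (1 - v))
        # scale chosen so the beta-scale sd near 0.5 matches `sd`
        noisy = logit + rng.normal(0.0, 4.0 * sd, size=values.shape)
        return 1.0 / (1.0 + np.exp(-noisy))
    raise ValueError(f"unknown noise model {model!r}")


def simulate_reference(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Reference continuum: (BetaMatrix, SampleSheet, ProbeAnnotation, truth).

    The beta matrix includes SNP-flagged and sex-chromosome decoy probes so
    the probe filter has work to do; the truth table covers analysis probes
    only.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_probes
    n_dyn = int(round(n * config.fraction_dynamic))
    n_nonlin = int(round(n_dyn * config.fraction_nonlinear))
    n_lin = n_dyn - n_nonlin
    n_stable = n - n_dyn

    programs = np.array(
        ["stable"] * n_stable + ["linear"] * n_lin
        + [config.nonlinear_shape] * n_nonlin
    )
    rng.shuffle(programs)

    a0 = np.empty(n)
    delta = np.zeros(n)
    stable = programs == "stable"
    n_st = int(stable.sum())
    comp = rng.random(n_st)
    base = np.where(
        comp < 0.45,
        rng.beta(5, 45, n_st),
        np.where(comp < 0.9, rng.beta(45, 5, n_st), rng.uniform(0.2, 0.8, n_st)),
    )
    a0[stable] = base
    dyn = ~stable
    n_dy = int(dyn.sum())
    mag = rng.uniform(0.25, 0.60, n_dy)
    sign = rng.choice([-1.0, 1.0], n_dy)
    d = mag * sign
    lo = np.where(d > 0, 0.02, 0.02 - d)
    hi = np.where(d > 0, 0.98 - d, 0.98)
    a0[dyn] = lo + rng.random(n_dy) * (hi - lo)
    delta[dyn] = d
    shape_mid = rng.uniform(25.0, 75.0, n)
    bump = np.zeros(n)
    if config.nonlinear_shape == "bump":
        bmp = programs == "bump"
        nb = int(bmp.sum())
        headroom_up = 1.0 - np.maximum(a0[bmp], a0[bmp] + delta[bmp])
        amp = rng.uniform(0.40, 0.50, nb)
        bump[bmp] = np.where(headroom_up >= amp, amp, -amp)

    probe_ids = np.array([f"cg{i:07d}" for i in range(n)])
    truth = pd.DataFrame(
        {
            "program": programs,
            "a0": a0,
            "delta_true": delta,
            "shape_mid": shape_mid,
            "bump": bump,
        },
        index=probe_ids,
    )
    prog = _program_values(truth, config.stages)
    end_start = prog[:, -1] - prog[:, 0]
    truth["delta_end_start"] = end_start
    truth["dynamic_true"] = np.abs(end_start) > 0.20
    truth["linear_true"] = (programs == "linear") & truth["dynamic_true"]

    sample_ids, subpops, ordinals = [], [], []
    columns = {}
    for o, sub in enumerate(_subpop_names(config.n_subpopulations)):
        stage_vals = prog[:, o]
        for dnr in range(config.donors_per_subpopulation):
            sid = f"{sub}_d{dnr + 1}"
            columns[sid] = _add_noise(stage_vals, config.noise_sd, rng, config.noise_model)
            sample_ids.append(sid)
            subpops.append(sub)
            ordinals.append(o)
    beta = pd.DataFrame(columns, index=probe_ids)

    # decoy probes removed by the filter
    decoys = {}
    ann_rows = []
    pos = 1000 * (np.arange(n) + 1)
    for pid, p in zip(probe_ids, pos):
        ann_rows.append((pid, "chr1", int(p), False, False))
    for k in range(config.n_snp_probes):
        pid = f"cg_snp{k:05d}"
        decoys[pid] = rng.uniform(0, 1, len(sample_ids))
        ann_rows.append((pid, "chr1", 1000 * (n + k + 1), True, False))
    for k in range(config.n_sex_probes):
        pid = f"cg_chrX{k:05d}"
        decoys[pid] = rng.uniform(0, 1, len(sample_ids))
        ann_rows.append((pid, "chrX", 1000 * (k + 1), False, True))
    if decoys:
        beta = pd.concat(
            [beta, pd.DataFrame(decoys, index=sample_ids).T], axis=0
        )
    annotation = ProbeAnnotation(
        pd.DataFrame(
            ann_rows, columns=["probe_id", "chrom", "pos", "snp", "sex_chrom"]
        ).set_index("probe_id")
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {"role": "reference", "subpopulation": subpops, "ordinal": ordinals},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return BetaMatrix(beta), sheet, annotation, truth


def _subpop_names(k: int) -> list[str]:
    if k <= len(SUBPOP_NAMES):
        return SUBPOP_NAMES[:k]
    return SUBPOP_NAMES + [f"SUB{i}" for i in range(len(SUBPOP_NAMES), k)]


# ---------------------------------------------------------------------------
# tumors, expression, regions


def simulate_tumors(
    config: SimulationConfig,
    ref_truth: pd.DataFrame,
    rng: np.random.Generator,
):
    """Tumor cohort with planted class A-D aberrations.

    Tumors sit at planted stages of the continuum; planted class A/C (B/D)
    probes are shifted down (up) by the aberration magnitude in a random
    carrier subset of ``carrier_fraction`` of the tumors.  Probes are drawn
    with enough headroom that the shift survives clipping.  Returns
    ``(BetaMatrix, tumor_truth, carriers, planted_stages)``.
    """
    stages = config.tumor_stages
    if len(stages) != config.n_tumors:
        raise ValueError("planted_stages length must equal n_tumors")
    sd = config.tumor_noise_sd if config.tumor_noise_sd is not None else config.noise_sd
    probes = ref_truth.index
    baseline = _program_values(ref_truth, stages)  # probes x tumors
    mag = config.aberration_magnitude
    margin = 0.05
    base_min = baseline.min(axis=1)
    base_max = baseline.max(axis=1)
    linear_dyn = (ref_truth["program"] == "linear").to_numpy()
    stable = (ref_truth["program"] == "stable").to_numpy()
    eligible = {
        "A": linear_dyn & (base_min >= mag + margin),
        "B": linear_dyn & (base_max <= 1.0 - mag - margin),
        "C": stable & (base_min >= mag + margin),
        "D": stable & (base_max <= 1.0 - mag - margin),
    }
    planted = pd.Series("none", index=probes, dtype=object)
    taken = np.zeros(len(probes), dtype=bool)
    for cls in ("A", "B", "C", "D"):
        want = int(config.planted_counts.get(cls, 0))
        pool = np.flatnonzero(eligible[cls] & ~taken)
        if want > len(pool):
            raise ValueError(
                f"cannot plant {want} class {cls} probes: only {len(pool)} eligible"
            )
        chosen = rng.choice(pool, size=want, replace=False)
        planted.iloc[chosen] = cls
        taken[chosen] = True

    sample_ids = [f"CLL{k + 1:03d}" for k in range(config.n_tumors)]
    n_carr = int(np.ceil(config.carrier_fraction * config.n_tumors))
    carriers = pd.DataFrame(
        False, index=probes, columns=sample_ids, dtype=bool
    )
    shift = np.zeros((len(probes), config.n_tumors))
    direction = {"A": -1.0, "B": +1.0, "C": -1.0, "D": +1.0}
    for cls in ("A", "B", "C", "D"):
        for i in np.flatnonzero(planted.to_numpy() == cls):
            cols = rng.choice(config.n_tumors, size=n_carr, replace=False)
            shift[i, cols] = direction[cls] * mag
            carriers.iloc[i, cols] = True
    values = _add_noise(baseline + shift, sd, rng, config.noise_model)
    tumors = BetaMatrix(pd.DataFrame(values, index=probes, columns=sample_ids))
    tumor_truth = pd.DataFrame({"planted_class": planted})
    planted_stages = pd.Series(stages, index=sample_ids, name="stage")
    return tumors, tumor_truth, carriers, planted_stages


def _expression_from_methylation(
    meth: pd.DataFrame, probe_for_gene: pd.Series, offsets: pd.Series,
    noise_sd: float, rng: np.random.Generator,
) -> pd.DataFrame:
    """Affine-decreasing response: expr = offset + 2 * (1 - beta) + noise."""
    rows = {}
    for gene, probe in probe_for_gene.items():
        base = offsets[gene] + 2.0 * (1.0 - meth.loc[probe].to_numpy())
        rows[gene] = base + rng.normal(0.0, noise_sd, meth.shape[1])
    return pd.DataFrame(rows, index=meth.columns).T


def _simulate_expression(
    config: SimulationConfig,
    annotation: ProbeAnnotation,
    tumor_truth: pd.DataFrame,
    ref_truth: pd.DataFrame,
    tumors: BetaMatrix,
    ref: BetaMatrix,
    rng: np.random.Generator,
):
    """Gene models + expression for tumors and normals; planted genes track
    the methylation of a planted class A promoter probe."""
    class_a = list(tumor_truth.index[tumor_truth["planted_class"] == "A"])
    if len(class_a) < config.n_correlated_genes:
        raise ValueError("not enough planted class A probes for correlated genes")
    planted_probes = [
        class_a[i] for i in
        sorted(rng.choice(len(class_a), config.n_correlated_genes, replace=False))
    ]
    stable_pool = list(
        ref_truth.index[(ref_truth["program"] == "stable")
                        & (tumor_truth["planted_class"] == "none")]
    )
    null_probes = [
        stable_pool[i] for i in
        sorted(rng.choice(len(stable_pool), config.n_null_genes, replace=False))
    ]
    rows = []
    probe_for_gene = {}
    for k, probe in enumerate(planted_probes):
        gid = f"GENEP{k:04d}"
        pos = int(annotation.table.loc[probe, "pos"])
        rows.append((gid, "chr1", pos + 100, "+"))
        probe_for_gene[gid] = probe
    for k, probe in enumerate(null_probes):
        gid = f"GENEN{k:04d}"
        pos = int(annotation.table.loc[probe, "pos"])
        rows.append((gid, "chr1", pos + 100, "+"))
        probe_for_gene[gid] = probe
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    gene_truth = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "planted": genes["gene_id"].str.startswith("GENEP"),
            "promoter_probe": [probe_for_gene[g] for g in genes["gene_id"]],
        }
    ).set_index("gene_id")

    offsets = pd.Series(
        rng.uniform(1.0, 5.0, len(genes)), index=genes["gene_id"]
    )
    planted_ids = list(gene_truth.index[gene_truth["planted"]])
    null_ids = list(gene_truth.index[~gene_truth["planted"]])

    def build(meth_df: pd.DataFrame) -> pd.DataFrame:
        planted_block = _expression_from_methylation(
            meth_df, gene_truth.loc[planted_ids, "promoter_probe"],
            offsets, config.expression_noise_sd, rng,
        )
        null_block = pd.DataFrame(
            offsets[null_ids].to_numpy()[:, None]
            + rng.normal(0.0, 1.0, (len(null_ids), meth_df.shape[1])),
            index=null_ids,
            columns=meth_df.columns,
        )
        return pd.concat([planted_block, null_block]).clip(lower=0.0)

    expr_tumor = ExpressionMatrix(build(tumors.data))
    expr_normal = ExpressionMatrix(build(ref.data))
    return genes, gene_truth, expr_tumor, expr_normal


def _simulate_mirnas(
    config: SimulationConfig,
    annotation: ProbeAnnotation,
    tumor_truth: pd.DataFrame,
    ref_truth: pd.DataFrame,
    tumors: BetaMatrix,
    rng: np.random.Generator,
):
    """pri-miRNA TSS table, two promoter-segment sources, expression."""
    class_c = list(tumor_truth.index[tumor_truth["planted_class"] == "C"])
    if len(class_c) < config.n_planted_mirnas:
        raise ValueError("not enough planted class C probes for miRNA promoters")
    anchors = [
        class_c[i] for i in
        sorted(rng.choice(len(class_c), config.n_planted_mirnas, replace=False))
    ]
    stable_pool = list(
        ref_truth.index[(ref_truth["program"] == "stable")
                        & (tumor_truth["planted_class"] == "none")]
    )
    n_null = config.n_mirnas - config.n_planted_mirnas
    null_anchors = [
        stable_pool[i] for i in
        sorted(rng.choice(len(stable_pool), n_null, replace=False))
    ]
    rows, src1, src2 = [], [], []
    probe_for_mirna = {}
    for k, probe in enumerate(anchors + null_anchors):
        mid = f"MIR{k:03d}"
        pos = int(annotation.table.loc[probe, "pos"])
        # segment around the probe, TSS ~50 kb downstream on the + strand
        rows.append((mid, "chr1", pos + 50_000, "+"))
        src1.append(("chr1", pos - 600, pos + 500))
        src2.append(("chr1", pos - 500, pos + 600))
        probe_for_mirna[mid] = probe
    mirna_tss = pd.DataFrame(rows, columns=["mirna_id", "chrom", "tss", "strand"])
    sources = [
        GenomicRegionSet("segments_src1", pd.DataFrame(src1, columns=["chrom", "start", "end"])),
        GenomicRegionSet("segments_src2", pd.DataFrame(src2, columns=["chrom", "start", "end"])),
    ]
    mirna_truth = pd.DataFrame(
        {
            "mirna_id": mirna_tss["mirna_id"],
            "planted": mirna_tss["mirna_id"].isin([f"MIR{k:03d}" for k in range(len(anchors))]),
            "promoter_probe": [probe_for_mirna[m] for m in mirna_tss["mirna_id"]],
        }
    ).set_index("mirna_id")
    offsets = pd.Series(rng.uniform(1.0, 4.0, len(mirna_tss)), index=mirna_tss["mirna_id"])
    blocks = {}
    for mid in mirna_tss["mirna_id"]:
        if mirna_truth.loc[mid, "planted"]:
            meth = tumors.data.loc[mirna_truth.loc[mid, "promoter_probe"]].to_numpy()
            blocks[mid] = offsets[mid] + 2.0 * (1.0 - meth) + rng.normal(
                0.0, 0.15, tumors.n_samples
            )
        else:
            blocks[mid] = offsets[mid] + rng.normal(0.0, 1.0, tumors.n_samples)
    mirna_expr = ExpressionMatrix(
        pd.DataFrame(blocks, index=tumors.sample_ids).T.clip(lower=0.0)
    )
    return mirna_tss, mirna_truth, mirna_expr, sources


def _simulate_region_sets(
    config: SimulationConfig,
    annotation: ProbeAnnotation,
    tumor_truth: pd.DataFrame,
    rng: np.random.Generator,
):
    """An enriched super-enhancer-like set plus a null set."""
    planted = tumor_truth.index[tumor_truth["planted_class"].isin(["A", "B"])]
    others = tumor_truth.index[tumor_truth["planted_class"] == "none"]
    n_se_planted = int(0.4 * len(planted))
    n_se_bg = int(0.02 * len(others))
    se_probes = list(
        rng.choice(planted, n_se_planted, replace=False)
    ) + list(rng.choice(others, n_se_bg, replace=False))
    null_probes = list(rng.choice(others, int(0.05 * len(others)), replace=False))

    def as_regions(name: str, probes) -> GenomicRegionSet:
        pos = annotation.table.loc[probes, "pos"].to_numpy()
        df = pd.DataFrame(
            {"chrom": "chr1", "start": pos - 250, "end": pos + 250}
        ).sort_values("start", ignore_index=True)
        return GenomicRegionSet(name, df)

    return [as_regions("synthetic_SE", se_probes), as_regions("synthetic_null", null_probes)]


def simulate_scenario(config: SimulationConfig | None = None) -> Scenario:
    """Generate a complete seeded scenario (reference, tumors, expression,
    miRNAs, region sets) with all truth tables."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    ref, sheet, annotation, ref_truth = simulate_reference(config, rng)
    tumors, tumor_truth, carriers, planted_stages = simulate_tumors(
        config, ref_truth, rng
    )
    genes, gene_truth, expr_tumor, expr_normal = _simulate_expression(
        config, annotation, tumor_truth, ref_truth, tumors, ref, rng
    )
    mirna_tss, mirna_truth, mirna_expr, sources = _simulate_mirnas(
        config, annotation, tumor_truth, ref_truth, tumors, rng
    )
    region_sets = _simulate_region_sets(config, annotation, tumor_truth, rng)
    full_sheet = SampleSheet(
        pd.concat(
            [
                sheet.table,
                pd.DataFrame(
                    {"role": "tumor", "subpopulation": pd.NA, "ordinal": np.nan},
                    index=pd.Index(tumors.sample_ids, name="sample_id"),
                ),
            ]
        )
    )
    return Scenario(
        config=config,
        ref=ref,
        tumors=tumors,
        sheet=full_sheet,
        annotation=annotation,
        ref_truth=ref_truth,
        tumor_truth=tumor_truth,
        carriers=carriers,
        planted_stages=planted_stages,
        genes=genes,
        gene_truth=gene_truth,
        expr_tumor=expr_tumor,
        expr_normal=expr_normal,
        mirna_tss=mirna_tss,
        mirna_truth=mirna_truth,
        mirna_expr=mirna_expr,
        segment_sources=sources,
        region_sets=region_sets,
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, str]:
    """Write every scenario table in the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def tsv(name: str, df: pd.DataFrame, **kw) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", float_format="%.12g", **kw)
        paths[name] = str(p)

    save_beta_matrix(scenario.ref, outdir / "reference_betas.tsv")
    save_beta_matrix(scenario.tumors, outdir / "tumor_betas.tsv")
    save_sample_sheet(scenario.sheet, outdir / "sample_sheet.tsv")
    save_annotation(scenario.annotation, outdir / "probe_annotation.tsv")
    save_expression(scenario.expr_tumor, outdir / "expression_tumor.tsv")
    save_expression(scenario.expr_normal, outdir / "expression_normal.tsv")
    save_expression(scenario.mirna_expr, outdir / "mirna_expression_tumor.tsv")
    for name in (
        "reference_betas.tsv", "tumor_betas.tsv", "sample_sheet.tsv",
        "probe_annotation.tsv", "expression_tumor.tsv", "expression_normal.tsv",
        "mirna_expression_tumor.tsv",
    ):
        paths[name] = str(outdir / name)
    tsv("genes.tsv", scenario.genes, index=False)
    tsv("mirna_tss.tsv", scenario.mirna_tss, index=False)
    tsv("truth_reference.tsv", scenario.ref_truth, index_label="probe_id")
    tsv("truth_tumor.tsv", scenario.tumor_truth, index_label="probe_id")
    tsv("truth_stages.tsv", scenario.planted_stages.to_frame(), index_label="sample_id")
    tsv("truth_genes.tsv", scenario.gene_truth, index_label="gene_id")
    tsv("truth_mirnas.tsv", scenario.mirna_truth, index_label="mirna_id")
    for rs in scenario.segment_sources + scenario.region_sets:
        p = outdir / f"{rs.name}.bed"
        save_regions(rs, p)
        paths[f"{rs.name}.bed"] = str(p)
    with open(outdir / "simulation_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(scenario.config), fh, sort_keys=True)
    paths["simulation_config.yaml"] = str(outdir / "simulation_config.yaml")
    return paths
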