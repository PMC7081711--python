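"""Linking disease-specific CpGs to transcripts and region sets.

Disease-specific CpGs are tied to candidate transcripts in three ways:

* gene promoter windows (-2.5 kb, +0.5 kb around the TSS, strand-aware)
  with Pearson correlation between promoter CpG methylation and gene
  expression (|r| >= 0.7, p < 0.05 by default);
* super-enhancer-style region sets assigned to their closest gene, with
  the same correlation rule;
* simplified promoter segments within 100 kb upstream of a pri-miRNA TSS,
  with Spearman correlation against pri-miRNA expression (|rho| >= 0.35).

Region-set enrichment of each aberration class uses a two-sided Fisher
exact test with all retained array probes as the background, and target
gene expression between cohorts is compared with the two-sided Wilcoxon
rank-sum test.
"""

from __future__ import annotations

from functools import reduce

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

from .io import BetaMatrix, ExpressionMatrix, GenomicRegionSet, ProbeAnnotation

__all__ = [
    "promoter_windows",
    "assign_mirna_promoters",
    "correlate",
    "closest_gene",
    "region_enrichment",
    "compare_target_expression",
]


def _probe_points(annotation: ProbeAnnotation, probes=None) -> pr.PyRanges:
    """Probes as single-base half-open intervals [pos-1, pos)."""
    tab = annotation.table if probes is None else annotation.table.loc[list(probes)]
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": tab["chrom"].to_numpy(),
                "Start": tab["pos"].to_numpy() - 1,
                "End": tab["pos"].to_numpy(),
                "probe_id": tab.index.to_numpy(),
            }
        )
    )


def promoter_windows(
    genes: pd.DataFrame,
    annotation: ProbeAnnotation | None = None,
    upstream: int = 2500,
    downstream: int = 500,
) -> pd.DataFrame:
    """Strand-aware promoter windows and the probes falling inside.

    ``genes`` needs columns gene_id, chrom, tss (1-based), strand.  A +
    strand TSS ``t`` yields the half-open window ``[t-upstream-1, t+downstream)``
    (1-based inclusive span ``t-upstream .. t+downstream``); the - strand
    window is mirrored.  Returns one row per gene with window coordinates
    and, when an annotation is given, a ``probes`` column listing assigned
    probe ids.
    """
    bad = set(genes["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"unknown strand values: {sorted(bad)}")
    tss = genes["tss"].to_numpy()
    plus = (genes["strand"] == "+").to_numpy()
    start = np.where(plus, tss - upstream - 1, tss - downstream - 1)
    end = np.where(plus, tss + downstream, tss + upstream)
    out = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "chrom": genes["chrom"].to_numpy(),
            "start": np.maximum(start, 0),
            "end": end,
            "strand": genes["strand"].to_numpy(),
        }
    )
    if annotation is not None:
        windows = pr.PyRanges(
            out.rename(
                columns={"chrom": "Chromosome", "start": "Start", "end": "End"}
            )[["Chromosome", "Start", "End", "gene_id"]]
        )
        hits = windows.join(_probe_points(annotation)).df
        assigned = (
            hits.groupby("gene_id")["probe_id"].apply(sorted).to_dict()
            if len(hits)
            else {}
        )
        out["probes"] = [assigned.get(g, []) for g in out["gene_id"]]
    return out


def _merge(regions: pd.DataFrame) -> pr.PyRanges:
    return pr.PyRanges(
        regions.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"})[
            ["Chromosome", "Start", "End"]
        ]
    ).merge()


def simplify_segments(
    segment_sets: list[GenomicRegionSet], combine: str = "intersection"
) -> pd.DataFrame:
    """Combine promoter segmentations from several sources.

    Default: per-source union-merge, intersection across sources (keeping
    only segment stretches present in every source), then a final merge of
    touching pieces.  ``combine="union"`` merges across sources instead.
    """
    if not segment_sets:
        raise ValueError("no segment sets supplied")
    merged = [_merge(s.table) for s in segment_sets]
    if combine == "intersection":
        combined = reduce(lambda a, b: a.intersect(b), merged)
    elif combine == "union":
        combined = pr.PyRanges(pd.concat([m.df for m in merged], ignore_index=True))
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    df = combined.merge().df
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return df.rename(
        columns={"Chromosome": "chrom", "Start": "start", "End": "end"}
    ).reset_index(drop=True)


def assign_mirna_promoters(
    segment_sets: list[GenomicRegionSet],
    mirna_tss: pd.DataFrame,
    annotation: ProbeAnnotation | None = None,
    max_distance: int = 100_000,
    combine: str = "intersection",
) -> pd.DataFrame:
    """Putative pri-miRNA promoters from simplified promoter segments.

    A merged segment is assigned to a pri-miRNA when it overlaps the TSS or
    its closest edge lies within ``max_distance`` bases upstream of the TSS
    (strand-aware).  ``mirna_tss`` needs columns mirna_id, chrom, tss
    (1-based), strand.  Returns one row per (miRNA, segment) assignment.
    """
    segs = simplify_segments(segment_sets, combine=combine)
    rows = []
    for m in mirna_tss.itertuples(index=False):
        t0 = m.tss - 1  # 0-based TSS point
        sub = segs[segs["chrom"] == m.chrom]
        for seg in sub.itertuples(index=False):
            overlaps = seg.start <= t0 < seg.end
            if m.strand == "+":
                upstream = seg.end <= t0 and t0 - (seg.end - 1) <= max_distance
            elif m.strand == "-":
                upstream = seg.start > t0 and seg.start - t0 <= max_distance
            else:
                raise ValueError(f"unknown strand {m.strand!r} for {m.mirna_id}")
            if overlaps or upstream:
                rows.append((m.mirna_id, seg.chrom, seg.start, seg.end))
    out = pd.DataFrame(rows, columns=["mirna_id", "chrom", "start", "end"])
    if annotation is not None and len(out):
        segments = pr.PyRanges(
            out.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"})
        )
        hits = segments.join(_probe_points(annotation)).df
        if len(hits):
            key = ["mirna_id", "Start", "End"]
            assigned = hits.groupby(key)["probe_id"].apply(sorted).to_dict()
            out["probes"] = [
                assigned.get((r.mirna_id, r.start, r.end), [])
                for r in out.itertuples(index=False)
            ]
        else:
            out["probes"] = [[] for _ in range(len(out))]
    elif annotation is not None:
        out["probes"] = []
    return out


def correlate(
    meth: BetaMatrix,
    expr: ExpressionMatrix,
    pairs: pd.DataFrame,
    method: str = "pearson",
    r_threshold: float = 0.7,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Methylation-expression correlation per (feature, probe) pair.

    ``pairs`` needs columns feature_id and probe_id (e.g. exploded from a
    promoter map).  Correlations run across the shared samples of both
    matrices (>= 4 required).  A pair passes when p < ``p_threshold`` and
    |r| >= ``r_threshold``; pairs with a constant vector on either side are
    excluded (r, p = NaN) but kept in the table with ``excluded=True``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    shared = [s for s in meth.sample_ids if s in set(expr.sample_ids)]
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared samples; need >= 4")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for rec in pairs.itertuples(index=False):
        feature, probe = rec.feature_id, rec.probe_id
        if probe not in meth.data.index or feature not in expr.data.index:
            continue
        x = meth.data.loc[probe, shared].to_numpy(dtype=float)
        y = expr.data.loc[feature, shared].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if len(x) < 4 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((feature, probe, method, np.nan, np.nan, False, True))
            continue
        r, p = corr(x, y)
        rows.append(
            (feature, probe, method, float(r), float(p),
             bool(p < p_threshold and abs(r) >= r_threshold), False)
        )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "probe_id", "method", "r", "p_value", "passes", "excluded"],
    )


def closest_gene(regions: GenomicRegionSet, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each region the gene with the nearest TSS.

    Distance is 0 when the TSS falls inside the region; ties are broken by
    the smaller TSS coordinate, then lexicographic gene id.  Regions on a
    chromosome without genes are returned unassigned and flagged.
    """
    rows = []
    for i, reg in enumerate(regions.table.itertuples(index=False)):
        sub = genes[genes["chrom"] == reg.chrom]
        if len(sub) == 0:
            rows.append((i, reg.chrom, reg.start, reg.end, None, np.nan, True))
            continue
        t0 = sub["tss"].to_numpy() - 1
        dist = np.maximum(0, np.maximum(reg.start - t0, t0 - (reg.end - 1)))
        order = sorted(
            range(len(sub)),
            key=lambda k: (dist[k], t0[k], sub["gene_id"].iloc[k]),
        )
        best = order[0]
        rows.append(
            (i, reg.chrom, reg.start, reg.end,
             sub["gene_id"].iloc[best], int(dist[best]), False)
        )
    return pd.DataFrame(
        rows,
        columns=["region_index", "chrom", "start", "end", "gene_id", "distance", "unassigned"],
    )


def region_enrichment(
    calls: pd.DataFrame,
    annotation: ProbeAnnotation,
    region_sets: list[GenomicRegionSet],
    classes=("A", "B", "C", "D"),
) -> pd.DataFrame:
    """Fisher enrichment of each aberration class in each region set.

    Background = all retained probes (the calls index); foreground = the
    probes of one class.  The 2x2 table crosses set membership with
    foreground vs background-minus-foreground; fold change is the ratio of
    in-set proportions (foreground over full background).
    """
    bg_probes = list(calls.index)
    bg_total = len(bg_probes)
    points = _probe_points(annotation, bg_probes)
    rows = []
    for rs in region_sets:
        merged = _merge(rs.table)
        hits = points.join(merged).df
        in_set = set(hits["probe_id"]) if len(hits) else set()
        bg_hits = len(in_set)
        for cls in classes:
            fg = calls.index[calls["class"] == cls]
            fg_total = len(fg)
            if fg_total == 0:
                raise ValueError(f"empty foreground for class {cls!r}")
            a = sum(1 for p in fg if p in in_set)
            b = fg_total - a
            c = bg_hits - a
            d = (bg_total - fg_total) - c
            _, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            fc = (
                (a / fg_total) / (bg_hits / bg_total) if bg_hits > 0 else np.nan
            )
            rows.append(
                (rs.name, cls, a, fg_total, bg_hits, bg_total, fc,
                 np.log2(fc) if fc and fc > 0 else -np.inf if fc == 0 else np.nan,
                 float(fisher_p))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_set", "class", "fg_hits", "fg_total", "bg_hits", "bg_total",
            "fold_change", "log2_fold_change", "fisher_p",
        ],
    )


def compare_target_expression(
    expr: ExpressionMatrix,
    genes,
    group_a,
    group_b,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparison of expression between cohorts.

    ``group_a`` / ``group_b`` are sample id lists (>= 3 each).  Returns per
    gene the p value, both group medians and the direction of the median
    shift (sign of median(a) - median(b)).  All-tied values yield p = 1.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs >= 3 samples")
    rows = []
    for g in genes:
        x = expr.data.loc[g, group_a].to_numpy(dtype=float)
        y = expr.data.loc[g, group_b].to_numpy(dtype=float)
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0
        else:
            _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        ma, mb = float(np.median(x)), float(np.median(y))
        rows.append((g, float(p), ma, mb, int(np.sign(ma - mb))))
    return pd.DataFrame(
        rows, columns=["gene_id", "p_value", "median_a", "median_b", "direction"]
    )
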