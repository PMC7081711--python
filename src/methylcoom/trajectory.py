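"""Differentiation-axis inference and per-CpG linear methylation models.

The reference cohort is a set of sorted cell subpopulations ordered from a
naive start state to a mature end state.  The stages of the analysis:

1. *Dynamic CpGs* — probes whose mean beta changes by more than a threshold
   (default 20%) between the start and end subpopulations, with a
   two-sample equal-variance t-test p below 0.05.
2. *Trajectory* — Manhattan distances between per-subpopulation mean
   profiles over the dynamic probes feed a balanced minimum-evolution tree;
   the path from the start leaf to the end leaf is the differentiation
   backbone, and each subpopulation's attachment point on it defines its
   differentiation stage d.s., rescaled so the end state sits at 100.
3. *Linear model* — per CpG, ordinary least squares of beta on d.s. across
   all reference samples; the regression F-test classifies CpGs as linear.
4. *Refit* — tree, axis and model are rebuilt once using only linear
   dynamic CpGs, removing probes whose non-linear programs would distort
   the Manhattan geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io import BetaMatrix, SampleSheet
from .metree import MeTree, build_me_tree

__all__ = [
    "Trajectory",
    "identify_dynamic_cpgs",
    "manhattan_distances",
    "build_me_tree",
    "subpopulation_profiles",
    "derive_axis",
    "fit_linear_model",
    "refit_with_linear_cpgs",
]


@dataclass
class Trajectory:
    """A non-branched differentiation axis extracted from an unrooted tree.

    ``ds_map`` assigns each subpopulation its differentiation stage: path
    distance from the start leaf to the subpopulation's attachment point on
    the start->end backbone, rescaled so the end state equals 100 ("% of
    normal differentiation programming achieved").  ``branchedness`` is the
    fraction of total branch length lying off the backbone.
    """

    tree: MeTree
    backbone: list[str]
    ds_map: dict[str, float]
    branchedness: float
    start: str
    end: str
    probes: list[str]

    def to_newick(self) -> str:
        return self.tree.to_newick()


def identify_dynamic_cpgs(
    ref: BetaMatrix,
    sheet: SampleSheet,
    delta_threshold: float = 0.20,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag CpGs with a >|delta_threshold| methylation change start vs end.

    ``delta`` is mean(end) - mean(start); the test is a two-sample
    equal-variance (Student) t-test between start- and end-subpopulation
    samples.  Intermediate subpopulations do not enter the contrast.
    Returns a DataFrame indexed by probe with columns delta, p_value,
    dynamic.
    """
    subs = sheet.subpopulations()
    start_samples = sheet.samples_of(subs[0])
    end_samples = sheet.samples_of(subs[-1])
    if len(start_samples) < 2 or len(end_samples) < 2:
        raise ValueError("start and end subpopulations each need >= 2 samples")
    a = ref.data[start_samples].to_numpy()
    b = ref.data[end_samples].to_numpy()
    delta = np.nanmean(b, axis=1) - np.nanmean(a, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance probes handled below
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True, nan_policy="omit")
    p = np.asarray(p, dtype=float)
    # degenerate: both groups constant
    var_a = np.nanvar(a, axis=1)
    var_b = np.nanvar(b, axis=1)
    both_const = (var_a == 0) & (var_b == 0)
    p[both_const & (delta == 0)] = 1.0
    p[both_const & (delta != 0)] = 0.0
    dynamic = (np.abs(delta) > delta_threshold) & (p < p_threshold)
    return pd.DataFrame(
        {"delta": delta, "p_value": p, "dynamic": dynamic}, index=ref.data.index
    )


def manhattan_distances(matrix: BetaMatrix | pd.DataFrame, probes=None) -> pd.DataFrame:
    """Pairwise Manhattan (L1) distances between sample columns.

    ``d(i, j) = sum_p |beta_pi - beta_pj|`` over the selected probes, which
    must be free of missing values.
    """
    df = matrix.data if isinstance(matrix, BetaMatrix) else matrix
    if probes is not None:
        probes = list(probes)
        if not probes:
            raise ValueError("empty probe subset")
        df = df.loc[probes]
    if df.shape[0] == 0:
        raise ValueError("empty probe subset")
    if df.isna().any().any():
        raise ValueError("missing values among selected probes")
    d = squareform(pdist(df.to_numpy().T, metric="cityblock"))
    return pd.DataFrame(d, index=df.columns, columns=df.columns)


def subpopulation_profiles(ref: BetaMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Mean beta profile per reference subpopulation (probes x subpops)."""
    cols = {}
    for sub in sheet.subpopulations():
        cols[sub] = ref.data[sheet.samples_of(sub)].mean(axis=1)
    return pd.DataFrame(cols)


def _attachment_points(tree: MeTree, backbone_labels: list[str], start: str, end: str):
    """Map each leaf to (distance of its backbone junction from start)."""
    path_nodes = tree.path(start, end)
    node_pos: dict[int, float] = {}
    acc = 0.0
    for k, node in enumerate(path_nodes):
        if k > 0:
            acc += tree.adj[path_nodes[k - 1]][node]
        node_pos[node] = acc
    on_path = set(path_nodes)
    out: dict[str, float] = {}
    for label in tree.leaf_labels:
        leaf = tree.leaf_node(label)
        if leaf in on_path:
            out[label] = node_pos[leaf]
            continue
        # walk from the leaf until the backbone is reached
        nodes = tree.path(label, end)
        junction = next(n for n in nodes if n in on_path)
        out[label] = node_pos[junction]
    return out, node_pos, path_nodes


def derive_axis(
    tree: MeTree,
    sheet: SampleSheet,
    probes=None,
    branchedness_tolerance: float = 0.2,
) -> Trajectory:
    """Extract the differentiation axis from a reference tree.

    The backbone is the path from the start (lowest-ordinal) to the end
    (highest-ordinal) subpopulation leaf; each subpopulation's d.s. is the
    distance from the start leaf to its attachment point, scaled to
    end = 100.  Warns when the off-backbone branch-length fraction exceeds
    ``branchedness_tolerance``.
    """
    subs = sheet.subpopulations()
    start, end = subs[0], subs[-1]
    raw, node_pos, path_nodes = _attachment_points(tree, subs, start, end)
    raw_end = raw[end]
    if raw_end <= 0:
        raise ValueError("start and end subpopulations coincide on the tree")
    ds_map = {s: 100.0 * raw[s] / raw_end for s in subs}
    backbone = sorted(subs, key=lambda s: ds_map[s])
    total = tree.total_length()
    backbone_len = node_pos[path_nodes[-1]]
    branchedness = 1.0 - backbone_len / total if total > 0 else 0.0
    if branchedness > branchedness_tolerance:
        warnings.warn(
            f"trajectory branchedness {branchedness:.3f} exceeds "
            f"tolerance {branchedness_tolerance}",
            stacklevel=2,
        )
    return Trajectory(
        tree=tree,
        backbone=backbone,
        ds_map=ds_map,
        branchedness=branchedness,
        start=start,
        end=end,
        probes=list(probes) if probes is not None else [],
    )


def build_axis(
    ref: BetaMatrix,
    sheet: SampleSheet,
    probes,
    branchedness_tolerance: float = 0.2,
) -> Trajectory:
    """Convenience: profiles -> Manhattan distances -> ME tree -> axis."""
    profiles = subpopulation_profiles(ref, sheet).loc[list(probes)]
    dist = manhattan_distances(profiles)
    tree = build_me_tree(dist.to_numpy(), list(dist.columns))
    return derive_axis(tree, sheet, probes=probes, branchedness_tolerance=branchedness_tolerance)


def fit_linear_model(
    ref: BetaMatrix,
    sheet: SampleSheet,
    trajectory: Trajectory,
    linearity_p: float = 0.05,
    lack_of_fit: bool = False,
) -> pd.DataFrame:
    """Per-CpG OLS of beta on differentiation stage across reference samples.

    Returns a DataFrame indexed by probe with columns alpha (intercept at
    d.s. 0), beta (beta units per d.s. unit), resid_var, linearity_p and
    linear.  The default verdict follows the overall regression F-test
    (equivalent to the slope t-test): p < ``linearity_p`` supports a linear
    methylation program.  With ``lack_of_fit=True`` the verdict instead
    compares the line against the saturated subpopulation-means model and
    calls a CpG linear when lack of fit is NOT significant.

    Probes missing in any reference sample get NaN coefficients and
    ``linear=False``; every other probe receives alpha and beta so the model
    can predict methylomes genome-wide.
    """
    samples = sheet.reference_samples
    ds = np.array(
        [trajectory.ds_map[sheet.table.loc[s, "subpopulation"]] for s in samples]
    )
    if len(np.unique(ds)) < 3:
        raise ValueError("need >= 3 distinct differentiation stages for the F-test")
    y = ref.data[samples].to_numpy()  # probes x samples
    complete = ~np.isnan(y).any(axis=1)
    n = len(samples)
    x = ds - ds.mean()
    sxx = float((x**2).sum())
    yc = y - np.nanmean(y, axis=1, keepdims=True)
    beta = (yc * x).sum(axis=1) / sxx
    alpha = np.nanmean(y, axis=1) - beta * ds.mean()
    fitted = alpha[:, None] + beta[:, None] * ds[None, :]
    sse = ((y - fitted) ** 2).sum(axis=1)
    ssr = beta**2 * sxx
    df_e = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssr / (sse / df_e)
    p = stats.f.sf(f, 1, df_e)
    p = np.where(sse <= 0, np.where(ssr > 0, 0.0, 1.0), p)
    if lack_of_fit:
        # pure-error decomposition over subpopulation groups
        groups = [sheet.table.loc[s, "subpopulation"] for s in samples]
        uniq = sorted(set(groups), key=groups.index)
        k = len(uniq)
        sse_pure = np.zeros(y.shape[0])
        for g in uniq:
            idx = [i for i, gg in enumerate(groups) if gg == g]
            sub = y[:, idx]
            sse_pure += ((sub - np.nanmean(sub, axis=1, keepdims=True)) ** 2).sum(axis=1)
        sse_lof = sse - sse_pure
        df_lof, df_pe = k - 2, n - k
        with np.errstate(divide="ignore", invalid="ignore"):
            f_lof = (sse_lof / df_lof) / (sse_pure / df_pe)
        p_lof = stats.f.sf(f_lof, df_lof, df_pe)
        p_lof = np.where(sse_pure <= 0, np.where(sse_lof > 1e-18, 0.0, 1.0), p_lof)
        linear = p_lof >= linearity_p  # linearity not rejected
        p_report = p_lof
    else:
        linear = p < linearity_p
        p_report = p
    out = pd.DataFrame(
        {
            "alpha": alpha,
            "beta": beta,
            "resid_var": sse / max(df_e, 1),
            "linearity_p": p_report,
            "linear": linear,
        },
        index=ref.data.index,
    )
    out.loc[~complete, ["alpha", "beta", "resid_var", "linearity_p"]] = np.nan
    out.loc[~complete, "linear"] = False
    return out


def refit_with_linear_cpgs(
    ref: BetaMatrix,
    sheet: SampleSheet,
    delta_threshold: float = 0.20,
    p_threshold: float = 0.05,
    linearity_p: float = 0.05,
    lack_of_fit: bool = False,
    branchedness_tolerance: float = 0.2,
):
    """Full two-pass axis construction.

    Pass 1: dynamic CpGs -> tree/axis -> per-CpG linear model.  Pass 2:
    tree/axis and model rebuilt on the linear AND dynamic probe set (exactly
    one refit round).  Returns ``(trajectory, model, dynamic_table)`` where
    ``dynamic_table`` carries delta, p_value, dynamic, linear, linearity_p
    for every probe and the trajectory's ``probes`` attribute holds the
    final linear dynamic set.
    """
    sheet.validate_for_fitting()
    complete = ~ref.data.isna().any(axis=1)
    dyn = identify_dynamic_cpgs(ref, sheet, delta_threshold, p_threshold)
    dyn.loc[~complete, "dynamic"] = False
    dynamic_probes = list(dyn.index[dyn["dynamic"]])
    if not dynamic_probes:
        raise ValueError("no dynamic CpGs at the configured thresholds")
    axis1 = build_axis(ref, sheet, dynamic_probes, branchedness_tolerance)
    model1 = fit_linear_model(ref, sheet, axis1, linearity_p, lack_of_fit)
    linear_dynamic = list(dyn.index[dyn["dynamic"] & model1["linear"]])
    if not linear_dynamic:
        raise ValueError("no linear dynamic CpGs; cannot refit the trajectory")
    axis2 = build_axis(ref, sheet, linear_dynamic, branchedness_tolerance)
    model2 = fit_linear_model(ref, sheet, axis2, linearity_p, lack_of_fit)
    table = dyn.copy()
    # the linear flag reflects the probe set the final axis was built on
    table["linear"] = table.index.isin(linear_dynamic)
    table["linearity_p"] = model1["linearity_p"]
    return axis2, model2, table
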