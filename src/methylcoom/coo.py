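"""Cell-of-origin placement and virtual methylome inference.

Each tumor sample is mapped onto the normal differentiation trajectory to
obtain a continuous differentiation stage d.s. in [0, 100] (extrapolation
up to a cap for the projection method).  Its cell-of-origin methylome is
then predicted per CpG from the linear programming model,
``M = alpha + beta * d.s.``, clipped to the valid beta range.

Two placement methods are provided.  The default "phylogenetic" method adds
one tumor at a time to the reference subpopulation representatives, builds
a joint balanced minimum-evolution tree on the linear dynamic CpGs, and
reads off the attachment point of the tumor branch on the start->end
backbone; placing tumors one at a time keeps an aberrant sample from
distorting another's stage.  The "projection" method instead scans a d.s.
grid and picks the stage whose model-predicted methylome is closest in
Manhattan distance.

Cross-validation re-places resampled tumor cohorts *jointly* (references
plus the sampled tumors in one tree) so that cohort composition genuinely
perturbs the placements, and summarizes each sample's d.s. distribution by
quartiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleSheet
from .metree import MeTree, build_me_tree
from .trajectory import Trajectory, manhattan_distances, subpopulation_profiles

__all__ = [
    "place_samples",
    "cross_validate",
    "infer_coo_methylome",
]

_TUMOR_PREFIX = "tumor::"
DS_CAP = 120.0


def _backbone_positions(tree: MeTree, start: str, end: str):
    """Distance-from-start of every node on the start->end path."""
    path_nodes = tree.path(start, end)
    pos: dict[int, float] = {}
    acc = 0.0
    for k, node in enumerate(path_nodes):
        if k > 0:
            acc += tree.adj[path_nodes[k - 1]][node]
        pos[node] = acc
    return pos, path_nodes


def _attach(tree: MeTree, label: str, backbone_pos: dict[int, float], end: str):
    """(distance from start of the junction, pendant distance to junction)."""
    leaf = tree.leaf_node(label)
    if leaf in backbone_pos:
        return backbone_pos[leaf], 0.0
    nodes = tree.path(label, end)
    pendant = 0.0
    for k, node in enumerate(nodes):
        if node in backbone_pos:
            return backbone_pos[node], pendant
        pendant += tree.adj[node][nodes[k + 1]]
    raise RuntimeError("leaf not connected to backbone")  # pragma: no cover


def _joint_ds(
    profiles: pd.DataFrame, tumor_block: pd.DataFrame, start: str, end: str
) -> pd.DataFrame:
    """Joint ME tree of subpopulation profiles + tumor columns -> d.s. table."""
    tumor_block = tumor_block.rename(columns=lambda s: _TUMOR_PREFIX + s)
    joint = pd.concat([profiles, tumor_block], axis=1)
    complete = ~joint.isna().any(axis=1)
    joint = joint.loc[complete]
    dist = manhattan_distances(joint)
    tree = build_me_tree(dist.to_numpy(), list(dist.columns))
    pos, _ = _backbone_positions(tree, start, end)
    raw_end, _ = _attach(tree, end, pos, end)
    rows = []
    for col in tumor_block.columns:
        raw, pendant = _attach(tree, col, pos, end)
        rows.append((col[len(_TUMOR_PREFIX):], 100.0 * raw / raw_end, pendant))
    return pd.DataFrame(rows, columns=["sample_id", "ds", "placement_distance"]).set_index(
        "sample_id"
    )


def place_samples(
    tumors: BetaMatrix,
    ref: BetaMatrix,
    sheet: SampleSheet,
    trajectory: Trajectory,
    cpgs,
    method: str = "phylogenetic",
    model: pd.DataFrame | None = None,
    grid_step: float = 0.1,
    ds_cap: float = DS_CAP,
) -> pd.DataFrame:
    """Assign each tumor a differentiation stage on the normal trajectory.

    ``cpgs`` is the linear dynamic probe set the trajectory was fitted on.
    Returns a DataFrame indexed by sample with columns ds and
    placement_distance (Manhattan distance from the sample to its
    attachment point; for the phylogenetic method, the tumor's pendant
    branch length).  ``model`` (alpha/beta table) is required for the
    projection method.
    """
    cpgs = list(cpgs)
    missing_frac = tumors.data.loc[cpgs].isna().mean(axis=0)
    bad = missing_frac[missing_frac > 0.20]
    if len(bad):
        raise ValueError(
            f"tumor samples missing > 20% of placement CpGs: {list(bad.index)[:5]}"
        )
    if method == "phylogenetic":
        profiles = subpopulation_profiles(ref, sheet).loc[cpgs]
        rows = []
        for s in tumors.sample_ids:  # one at a time: taxon addition
            block = tumors.data.loc[cpgs, [s]]
            rows.append(_joint_ds(profiles, block, trajectory.start, trajectory.end))
        out = pd.concat(rows).loc[tumors.sample_ids]
    elif method == "projection":
        if model is None:
            raise ValueError("projection placement requires the linear model table")
        sub = model.loc[cpgs]
        alpha = sub["alpha"].to_numpy()[:, None]
        beta = sub["beta"].to_numpy()[:, None]
        grid = np.arange(0.0, ds_cap + grid_step / 2, grid_step)
        pred = np.clip(alpha + beta * grid[None, :], 0.0, 1.0)  # probes x grid
        recs = []
        for s in tumors.sample_ids:
            obs = tumors.data.loc[cpgs, s].to_numpy()[:, None]
            ok = ~np.isnan(obs[:, 0])
            dist = np.abs(obs[ok] - pred[ok]).sum(axis=0)
            k = int(np.argmin(dist))
            recs.append((s, float(grid[k]), float(dist[k])))
        out = pd.DataFrame(
            recs, columns=["sample_id", "ds", "placement_distance"]
        ).set_index("sample_id")
    else:
        raise ValueError(f"unknown placement method {method!r}")
    out["ds"] = out["ds"].clip(upper=ds_cap)
    return out


def cross_validate(
    tumors: BetaMatrix,
    ref: BetaMatrix,
    sheet: SampleSheet,
    trajectory: Trajectory,
    cpgs,
    reps: int = 5000,
    split: float = 0.70,
    seed: int | None = None,
    scheme: str = "subsample",
    placement: str = "taxon_addition",
) -> pd.DataFrame:
    """Placement stability by repeated 70/30 cohort resampling.

    Per repetition a fraction ``split`` of the tumor cohort is drawn
    (without replacement under the default "subsample" scheme, matching a
    resampling design that avoids repeated picks in the large group; with
    replacement under "bootstrap") and re-placed.  Returns per-sample
    Q1/median/Q3 of d.s. across the repetitions in which the sample
    appeared, plus the number of appearances.

    ``placement`` selects the per-repetition mechanism.  The default
    "taxon_addition" re-places every sampled tumor one at a time against
    the fixed reference backbone — the same mechanism as the point
    estimate, so placements are independent of cohort composition and the
    d.s. distributions collapse onto the point estimates (the stability
    the taxon-addition design buys).  "joint" rebuilds one tree per
    repetition from the references plus the whole sampled cohort; this
    exposes genuine cohort-composition variability but carries a
    cohort-density bias (nearby noisy samples make L1 distances
    sub-additive, compressing the backbone), so its quartiles should be
    compared only against a full-cohort joint placement.
    """
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    samples = tumors.sample_ids
    if len(samples) < 4:
        raise ValueError("cross-validation needs >= 4 tumor samples")
    if scheme not in ("subsample", "bootstrap"):
        raise ValueError(f"unknown resampling scheme {scheme!r}")
    if placement not in ("taxon_addition", "joint"):
        raise ValueError(f"unknown placement mechanism {placement!r}")
    rng = np.random.default_rng(seed)
    k = max(2, int(round(split * len(samples))))
    profiles = subpopulation_profiles(ref, sheet).loc[list(cpgs)]
    data = tumors.data.loc[list(cpgs)]
    single: dict[str, float] = {}
    if placement == "taxon_addition":
        for s in samples:
            placed = _joint_ds(
                profiles, data[[s]], trajectory.start, trajectory.end
            )
            single[s] = float(placed.loc[s, "ds"])
    collected: dict[str, list[float]] = {s: [] for s in samples}
    for _ in range(reps):
        if scheme == "subsample":
            chosen = rng.choice(len(samples), size=k, replace=False)
        else:
            chosen = np.unique(rng.choice(len(samples), size=k, replace=True))
        cols = [samples[i] for i in sorted(chosen)]
        if placement == "taxon_addition":
            for s in cols:
                collected[s].append(single[s])
        else:
            placed = _joint_ds(profiles, data[cols], trajectory.start, trajectory.end)
            for s in cols:
                collected[s].append(float(placed.loc[s, "ds"]))
    rows = []
    for s in samples:
        vals = np.array(collected[s])
        if len(vals) == 0:
            rows.append((s, np.nan, np.nan, np.nan, 0))
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append((s, q1, med, q3, len(vals)))
    return pd.DataFrame(
        rows, columns=["sample_id", "q1", "median", "q3", "n_reps"]
    ).set_index("sample_id")


def infer_coo_methylome(
    model: pd.DataFrame, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Predict each sample's cell-of-origin methylome from the linear model.

    ``M_p = clip(alpha_p + beta_p * ds, 0, 1)`` for every modeled probe
    (non-dynamic probes simply carry beta ~ 0).  Returns a probes x samples
    DataFrame aligned with the model's probe index.
    """
    alpha = model["alpha"].to_numpy()[:, None]
    beta = model["beta"].to_numpy()[:, None]
    ds = assignments["ds"].to_numpy()[None, :]
    m = np.clip(alpha + beta * ds, 0.0, 1.0)
    return pd.DataFrame(m, index=model.index, columns=assignments.index)
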