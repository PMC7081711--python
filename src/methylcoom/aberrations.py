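"""Disease-specific CpG calling against per-sample cell-of-origin methylomes.

A CpG is disease-specific when its observed methylation deviates from the
inferred cell-of-origin value M by more than a cut-off (default: strictly
more than 20%) in at least a given fraction of patients (default: at least
75%).  Calls are stratified by whether the CpG is part of the normal
differentiation program:

* class A / B — loss / gain at dynamic CpGs (sites with epigenetic
  programming during normal differentiation);
* class C / D — loss / gain at CpGs stable during normal differentiation.

Patient fractions are computed over non-missing samples per probe; a
(probe, sample) missing value counts toward neither the aberrant nor the
total tally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import BetaMatrix

__all__ = ["compute_deltas", "call_classes", "summarize_classes"]

CLASSES = ["A", "B", "C", "D"]


def compute_deltas(tumors: BetaMatrix, coo: pd.DataFrame) -> pd.DataFrame:
    """Delta methylation: observed tumor beta minus inferred COO beta.

    ``coo`` is the probes x samples matrix of per-sample cell-of-origin
    methylomes; every tumor sample must have one.
    """
    missing = [s for s in tumors.sample_ids if s not in coo.columns]
    if missing:
        raise ValueError(f"samples without a cell-of-origin methylome: {missing[:5]}")
    probes = tumors.data.index
    obs = tumors.data
    exp = coo.loc[probes, obs.columns]
    return obs - exp


def call_classes(
    deltas: pd.DataFrame,
    dynamic: pd.Series,
    delta_cut: float = 0.20,
    patient_fraction: float = 0.75,
) -> pd.DataFrame:
    """Classify each probe into A/B/C/D/none from its per-patient deltas.

    Loss (gain) at a patient means delta strictly below -``delta_cut``
    (strictly above +``delta_cut``); a class is called when the loss or
    gain fraction over non-missing patients is at least
    ``patient_fraction``.  Dynamic probes yield classes A (loss) / B
    (gain); non-dynamic probes yield C / D.  If both directions pass
    (possible only for configured fractions <= 0.5) the probe is labeled
    none and flagged ambiguous.
    """
    if deltas.shape[1] == 0:
        raise ValueError("no tumor samples")
    vals = deltas.to_numpy()
    n_obs = (~np.isnan(vals)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac_loss = np.where(n_obs > 0, np.nansum(vals < -delta_cut, axis=1) / np.maximum(n_obs, 1), 0.0)
        frac_gain = np.where(n_obs > 0, np.nansum(vals > delta_cut, axis=1) / np.maximum(n_obs, 1), 0.0)
    dyn = dynamic.reindex(deltas.index).fillna(False).to_numpy(dtype=bool)
    loss_hit = frac_loss >= patient_fraction
    gain_hit = frac_gain >= patient_fraction
    ambiguous = loss_hit & gain_hit
    label = np.full(len(deltas), "none", dtype=object)
    only_loss = loss_hit & ~ambiguous
    only_gain = gain_hit & ~ambiguous
    label[only_loss & dyn] = "A"
    label[only_gain & dyn] = "B"
    label[only_loss & ~dyn] = "C"
    label[only_gain & ~dyn] = "D"
    return pd.DataFrame(
        {
            "dynamic": dyn,
            "fraction_loss": frac_loss,
            "fraction_gain": frac_gain,
            "class": label,
            "ambiguous": ambiguous,
        },
        index=deltas.index,
    )


def summarize_classes(calls: pd.DataFrame, deltas: pd.DataFrame | None = None) -> dict:
    """Per-class counts plus optional per-sample delta summaries.

    Returns a dict with ``counts`` (per class, plus hypomethylated = A + C
    and hypermethylated = B + D and the total probe count) and, when a
    delta matrix is supplied, ``per_sample`` — mean and SD of delta per
    sample within each called class.
    """
    counts = {c: int((calls["class"] == c).sum()) for c in CLASSES}
    counts["none"] = int((calls["class"] == "none").sum())
    counts["hypomethylated"] = counts["A"] + counts["C"]
    counts["hypermethylated"] = counts["B"] + counts["D"]
    counts["total_probes"] = int(len(calls))
    out = {"counts": counts}
    if deltas is not None:
        rows = []
        for c in CLASSES:
            probes = calls.index[calls["class"] == c]
            if len(probes) == 0:
                continue
            sub = deltas.loc[probes]
            for s in sub.columns:
                rows.append((c, s, float(sub[s].mean()), float(sub[s].std(ddof=1))))
        out["per_sample"] = pd.DataFrame(
            rows, columns=["class", "sample_id", "mean_delta", "sd_delta"]
        )
    return out
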