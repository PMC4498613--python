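"""Peak calling on LOD profiles and power/FDR aggregation over replicates.

A true QTL is scored as detected in a replicate when at least one significant
peak falls inside its support interval (default +/-5 cM around the true
position); significant peaks outside every support interval are false
positives, and FDR is the percentage of false peaks among all peaks pooled
over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linkage import GeneticMap
from .simulate import QTLArchitecture

__all__ = ["call_peaks", "power_fdr", "interval_power", "PowerReport"]


def call_peaks(profile: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """One call per maximal contiguous run of scan positions with LOD >= threshold.

    The call is placed at the run's maximum-LOD position (leftmost on ties);
    runs never merge across chromosomes.  Returns the corresponding profile
    rows.
    """
    if profile.empty:
        return profile.iloc[0:0]
    calls = []
    for chrom, sub in profile.groupby("chromosome", sort=False):
        sig = (sub["LOD"].to_numpy() >= threshold).astype(int)
        if not sig.any():
            continue
        edges = np.diff(np.concatenate([[0], sig, [0]]))
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]
        lod = sub["LOD"].to_numpy()
        for s, t in zip(starts, ends):
            calls.append(sub.index[s + int(np.argmax(lod[s:t]))])
    return profile.loc[calls]


@dataclass
class PowerReport:
    """Per-QTL detection power and estimate summaries, plus pooled FDR."""

    per_qtl: pd.DataFrame
    fdr: float
    n_replicates: int
    n_calls: int
    n_false: int


def _assign_calls(calls: pd.DataFrame, truth: QTLArchitecture,
                  support_halfwidth: float) -> np.ndarray:
    """Index of the nearest in-support true QTL per call, -1 for false positives."""
    assign = np.full(len(calls), -1, dtype=int)
    if truth.n_qtl == 0 or calls.empty:
        return assign
    tchrom = np.array(truth.chromosomes)
    tpos = truth.positions
    for i, (_, row) in enumerate(calls.iterrows()):
        same = tchrom == str(row["chromosome"])
        if not same.any():
            continue
        d = np.abs(tpos - row["position_cM"])
        d[~same] = np.inf
        j = int(np.argmin(d))
        if d[j] <= support_halfwidth:
            assign[i] = j
    return assign


def power_fdr(calls_per_replicate: list[pd.DataFrame], truth: QTLArchitecture,
              support_halfwidth: float = 5.0) -> PowerReport:
    """Detection power, FDR and estimate summaries over simulation replicates.

    A replicate detects QTL j when >= 1 call lies within the support interval;
    multiple same-replicate calls in one interval count as a single detection
    but each remains a true (non-false) call.  Estimated positions/effects are
    averaged over the assigned calls of detecting replicates.
    """
    n_rep = len(calls_per_replicate)
    detected = np.zeros((n_rep, truth.n_qtl), bool)
    per_qtl_calls: list[list[pd.Series]] = [[] for _ in range(truth.n_qtl)]
    n_calls = n_false = 0
    for r, calls in enumerate(calls_per_replicate):
        assign = _assign_calls(calls, truth, support_halfwidth)
        n_calls += len(assign)
        n_false += int((assign == -1).sum())
        for i, j in enumerate(assign):
            if j >= 0:
                detected[r, j] = True
                per_qtl_calls[j].append(calls.iloc[i])
    rows = []
    effect_cols = [c for c in (calls_per_replicate[0].columns if n_rep else [])
                   if c == "avg_effect" or c.startswith(("a_", "ae_"))]
    for j in range(truth.n_qtl):
        got = pd.DataFrame(per_qtl_calls[j])
        row = {
            "chromosome": truth.chromosomes[j],
            "true_position_cM": truth.positions[j],
            "power": 100.0 * detected[:, j].mean() if n_rep else np.nan,
            "n_detections": len(got),
        }
        for col, name in [("position_cM", "position_cM"), *[(c, c) for c in effect_cols]]:
            vals = got[col].to_numpy() if not got.empty else np.empty(0)
            row[f"mean_{name}"] = vals.mean() if vals.size else np.nan
            row[f"se_{name}"] = vals.std(ddof=1) if vals.size > 1 else np.nan
        rows.append(row)
    fdr = 100.0 * n_false / n_calls if n_calls else np.nan
    return PowerReport(per_qtl=pd.DataFrame(rows), fdr=fdr,
                       n_replicates=n_rep, n_calls=n_calls, n_false=n_false)


def interval_power(calls_per_replicate: list[pd.DataFrame],
                   gmap: GeneticMap) -> pd.DataFrame:
    """Share of replicates with >= 1 call in each marker interval.

    A call exactly at a marker position is attributed to the interval on the
    marker's right (except at a chromosome's last marker).
    """
    intervals = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        for k in range(len(pos) - 1):
            intervals.append((chrom, pos[k], pos[k + 1]))
    hits = np.zeros(len(intervals))
    n_rep = len(calls_per_replicate)
    for calls in calls_per_replicate:
        seen = set()
        for _, row in calls.iterrows():
            chrom, p = str(row["chromosome"]), row["position_cM"]
            pos = gmap.positions(chrom)
            k = int(np.searchsorted(pos, p, side="right")) - 1
            k = min(max(k, 0), len(pos) - 2)
            seen.add((chrom, k))
        for chrom, k in seen:
            pos = gmap.positions(chrom)
            idx = intervals.index((chrom, pos[k], pos[k + 1]))
            hits[idx] += 1
    out = pd.DataFrame(intervals, columns=["chromosome", "start_cM", "end_cM"])
    out["frequency"] = 100.0 * hits / n_rep if n_rep else np.nan
    return out
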