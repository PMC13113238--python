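"""Read-depth de novo CNV detection and CNV rate statistics.

Window depths (default 1 kb) are normalized twice: by each subline's
median window depth (library size) and then by the cross-subline median of
the same window (local mappability).  Runs of consecutive windows whose
ratio crosses the gain (>= 1.4) or loss (<= 0.6) threshold, merged across
single-window gaps, are emitted as CNV calls when they span >= 3000 bp and
the event is confined to exactly one subline of the condition (the
de novo definition, paralleling the SNM putation rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CnvParams:
    gain_threshold: float = 1.4
    loss_threshold: float = 0.6
    min_windows: int = 3
    min_length: int = 3000
    merge_gap: int = 1
    unique_to_subline: bool = True


def normalize_depth(
    depths: pd.DataFrame, masked_windows: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Two-stage median normalization of per-window depths.

    depths: long frame with subline_id, scaffold, start, end, depth.
    Masked windows (indel/multimap-heavy; frame with scaffold, start) are
    dropped before normalization.
    """
    df = depths.copy()
    if masked_windows is not None and len(masked_windows):
        key = set(zip(masked_windows["scaffold"], masked_windows["start"]))
        keep = [
            (s, p) not in key for s, p in zip(df["scaffold"], df["start"])
        ]
        df = df[keep]
    med = df.groupby("subline_id")["depth"].transform("median")
    if (med <= 0).any():
        raise ValueError("subline median depth is zero")
    df["rel"] = df["depth"] / med
    win_med = df.groupby(["scaffold", "start"])["rel"].transform("median")
    df["ratio"] = df["rel"] / win_med
    return df.drop(columns=["rel"])


def _runs(mask: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Maximal runs of True, merging runs separated by <= merge_gap False."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev <= merge_gap + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def call_cnvs(
    ratios: pd.DataFrame, params: CnvParams | None = None
) -> pd.DataFrame:
    """Threshold-crossing run caller on the normalized ratio table.

    Returns records with subline_id, scaffold, start, end, copy_state,
    mean_ratio, length.  With unique_to_subline, candidates overlapping a
    same-direction candidate in another subline are dropped (shared events
    predate the MA experiment and are not de novo).
    """
    params = params or CnvParams()
    candidates = []
    for (subline, scaf), grp in ratios.groupby(["subline_id", "scaffold"]):
        grp = grp.sort_values("start")
        ratio = grp["ratio"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for state, mask in (
            ("gain", ratio >= params.gain_threshold),
            ("loss", ratio <= params.loss_threshold),
        ):
            for i0, i1 in _runs(mask, params.merge_gap):
                n_hit = int(mask[i0 : i1 + 1].sum())
                if n_hit < params.min_windows:
                    continue
                start, end = int(starts[i0]), int(ends[i1])
                if end - start < params.min_length:
                    continue
                candidates.append(
                    {
                        "subline_id": subline,
                        "scaffold": scaf,
                        "start": start,
                        "end": end,
                        "copy_state": state,
                        "mean_ratio": float(ratio[i0 : i1 + 1].mean()),
                        "length": end - start,
                    }
                )
    records = pd.DataFrame(
        candidates,
        columns=[
            "subline_id",
            "scaffold",
            "start",
            "end",
            "copy_state",
            "mean_ratio",
            "length",
        ],
    )
    if params.unique_to_subline and len(records) > 1:
        drop = np.zeros(len(records), dtype=bool)
        for i in range(len(records)):
            a = records.iloc[i]
            for j in range(len(records)):
                if i == j:
                    continue
                b = records.iloc[j]
                if (
                    a["subline_id"] != b["subline_id"]
                    and a["scaffold"] == b["scaffold"]
                    and a["copy_state"] == b["copy_state"]
                    and a["start"] < b["end"]
                    and b["start"] < a["end"]
                ):
                    drop[i] = True
                    break
        records = records[~drop].reset_index(drop=True)
    return records.sort_values(["subline_id", "scaffold", "start"]).reset_index(
        drop=True
    )


def mann_whitney_lengths(lengths_a, lengths_b) -> float:
    """Two-sided Mann-Whitney U p-value on CNV length distributions.

    Exact for small samples without ties, normal approximation with tie
    correction otherwise (scipy's 'auto' policy).  Identical inputs give 1.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty length sample")
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)


def cnv_stats(records: pd.DataFrame, meta: pd.DataFrame) -> dict:
    """Per-condition CNV rates, bp burden, and subline concentration.

    Rate = CNV count / sum of subline generations; bp-per-generation =
    summed CNV length / total generations.  The concentration table gives
    each subline's share of the condition's CNVs.  When two conditions are
    present, lengths are compared with a two-sided Mann-Whitney U test.
    """
    if (meta["generations"] <= 0).any():
        raise ValueError("non-positive generations")
    merged = records.merge(
        meta[["subline_id", "condition", "generations"]], on="subline_id", how="left"
    )
    out: dict = {"per_condition": [], "concentration": None}
    conc_rows = []
    for cond, cmeta in meta.groupby("condition"):
        total_T = float(cmeta["generations"].sum())
        sub = merged[merged["condition"] == cond]
        out["per_condition"].append(
            {
                "condition": cond,
                "n_cnvs": int(len(sub)),
                "total_generations": total_T,
                "cnv_rate": len(sub) / total_T,
                "bp_per_generation": float(sub["length"].sum()) / total_T,
                "mean_length": float(sub["length"].mean()) if len(sub) else float("nan"),
            }
        )
        for subline in cmeta["subline_id"]:
            k = int((sub["subline_id"] == subline).sum())
            conc_rows.append(
                {
                    "condition": cond,
                    "subline_id": subline,
                    "n_cnvs": k,
                    "fraction": k / len(sub) if len(sub) else float("nan"),
                }
            )
    out["per_condition"] = pd.DataFrame(out["per_condition"])
    out["concentration"] = pd.DataFrame(conc_rows)
    conds = list(meta["condition"].unique())
    if len(conds) == 2:
        la = merged.loc[merged["condition"] == conds[0], "length"]
        lb = merged.loc[merged["condition"] == conds[1], "length"]
        if len(la) and len(lb):
            out["length_mwu_p"] = mann_whitney_lengths(la, lb)
    return out
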