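"""Mutation-rate and spectrum statistics for MA sublines.

The genome-wide base-substitution rate of subline i is

    mu_bs = m_i / (2 n_i T_i),        SE = sqrt(mu_bs / (2 n_i T_i)),

with m_i the SNM count, n_i the analyzed diploid sites and T_i the
generations propagated.  The condition-level rate is the mean across
sublines with SE = s / sqrt(N) (s the across-subline SD).  Conditional
(class-specific) rates replace n_i with the count of ancestral sites at
which the class can arise, with SE = sqrt(mu_cond / (L * 2 n_b * Tbar)).

Also here: Ts/Tv and the AT-gaining/GC-gaining mutation bias, MNM
clustering (SNMs of one subline within a 50 bp window), genome-wide
heterozygosity pi_t, and the life-table reproductive rate r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AT_GAINING,
    GC_GAINING,
    SNM_CLASSES,
    TRANSITIONS,
    TRANSVERSIONS,
    class_origin_bases,
)


@dataclass(frozen=True)
class RateEstimate:
    """A mutation rate (per site per generation) with its standard error."""

    mu: float
    se: float
    m: float
    n: float
    T: float


def subline_rate(m: float, n: float, T: float) -> RateEstimate:
    """Genome-wide SNM rate of one subline: mu = m / (2 n T)."""
    if n <= 0 or T <= 0:
        raise ValueError("n and T must be positive")
    if m < 0:
        raise ValueError("mutation count must be non-negative")
    mu = m / (2.0 * n * T)
    se = math.sqrt(mu / (2.0 * n * T))
    return RateEstimate(mu=mu, se=se, m=m, n=n, T=T)


def pooled_rate(rates: list[RateEstimate]) -> RateEstimate:
    """Condition-level rate: mean of subline rates, SE = s / sqrt(N)."""
    if not rates:
        raise ValueError("no subline rates to pool")
    if len(rates) < 2:
        raise ValueError("pooling requires at least 2 sublines")
    mus = np.array([r.mu for r in rates])
    se = float(np.std(mus, ddof=1) / math.sqrt(len(mus)))
    return RateEstimate(
        mu=float(mus.mean()),
        se=se,
        m=float(sum(r.m for r in rates)),
        n=float(np.mean([r.n for r in rates])),
        T=float(np.mean([r.T for r in rates])),
    )


def genome_wide_rates(snms: pd.DataFrame, meta: pd.DataFrame) -> tuple[
    pd.DataFrame, RateEstimate
]:
    """Per-subline rate table plus the pooled condition estimate."""
    counts = snms.groupby("subline_id").size() if len(snms) else pd.Series(dtype=int)
    rows = []
    rates = []
    for rec in meta.itertuples(index=False):
        m = int(counts.get(rec.subline_id, 0))
        est = subline_rate(m, rec.n_sites, rec.generations)
        rates.append(est)
        rows.append(
            {
                "subline_id": rec.subline_id,
                "m": m,
                "n_sites": rec.n_sites,
                "generations": rec.generations,
                "mu": est.mu,
                "se": est.se,
            }
        )
    return pd.DataFrame(rows), pooled_rate(rates)


def conditional_rates(snms: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-class conditional rates averaged across sublines.

    For class c with ancestral pair (b, b'), each subline contributes
    mu_i = m_{c,i} / (2 (n_b,i + n_b',i) T_i); the table reports the mean,
    the SE sqrt(mu / (L * 2 nbar_b * Tbar)), and the pooled count.
    """
    L = len(meta)
    if L == 0:
        raise ValueError("no sublines")
    T_bar = float(meta["generations"].mean())
    rows = []
    for cls in SNM_CLASSES:
        b1, b2 = class_origin_bases(cls)
        n_b = meta[f"n_{b1}"].to_numpy(float) + meta[f"n_{b2}"].to_numpy(float)
        if (n_b <= 0).any() and len(snms):
            has = (snms["snm_class"] == cls).any()
            if has:
                raise ValueError(f"class {cls} observed but eligible-site tally is 0")
        mus = []
        m_tot = 0
        for i, rec in enumerate(meta.itertuples(index=False)):
            m = int(
                (
                    (snms["subline_id"] == rec.subline_id)
                    & (snms["snm_class"] == cls)
                ).sum()
            ) if len(snms) else 0
            m_tot += m
            mus.append(
                m / (2.0 * n_b[i] * rec.generations) if n_b[i] > 0 else 0.0
            )
        mu = float(np.mean(mus))
        nbar = float(np.mean(n_b))
        se = math.sqrt(mu / (L * 2.0 * nbar * T_bar)) if nbar > 0 else 0.0
        rows.append({"snm_class": cls, "m": m_tot, "mu": mu, "se": se, "n_b": nbar})
    table = pd.DataFrame(rows)
    table.attrs["total_snms"] = int(len(snms))
    return table


def ts_tv_ratio(snm_classes) -> float:
    """Transitions / transversions; NaN when no transversions observed."""
    classes = pd.Series(list(snm_classes))
    ts = int(classes.isin(TRANSITIONS).sum())
    tv = int(classes.isin(TRANSVERSIONS).sum())
    if ts + tv != len(classes):
        raise ValueError("unrecognized SNM class label")
    if tv == 0:
        return float("nan")
    return ts / tv


def gcat_bias(snm_classes, method: str = "counts", spectrum: pd.DataFrame | None = None) -> float:
    """AT-gaining over GC-gaining mutation bias.

    method='counts' (default): ratio of raw counts of SNMs with ancestral
    G:C gaining A:T/T:A over SNMs with ancestral A:T gaining G:C/C:G.
    method='rates': ratio of the summed conditional rates of the same
    classes (requires a conditional-rate table).  NaN when the denominator
    is empty.
    """
    if method == "rates":
        if spectrum is None:
            raise ValueError("method='rates' needs a conditional-rate table")
        at_gain = spectrum.loc[spectrum["snm_class"].isin(AT_GAINING), "mu"].sum()
        gc_gain = spectrum.loc[spectrum["snm_class"].isin(GC_GAINING), "mu"].sum()
    elif method == "counts":
        classes = pd.Series(list(snm_classes))
        at_gain = int(classes.isin(AT_GAINING).sum())
        gc_gain = int(classes.isin(GC_GAINING).sum())
    else:
        raise ValueError(f"unknown method {method!r}")
    if gc_gain == 0:
        return float("nan")
    return at_gain / gc_gain


def cluster_mnms(snms: pd.DataFrame, window: int = 50, min_size: int = 2) -> pd.DataFrame:
    """Flag multinucleotide mutation (MNM) clusters.

    SNMs of one subline on one scaffold whose consecutive gaps are <=
    window form a cluster by transitive chaining; clusters of >= min_size
    get is_clustered=True and a shared cluster_id.
    """
    snms = snms.copy()
    snms["is_clustered"] = False
    snms["cluster_id"] = -1
    next_id = 0
    for (_subline, _scaf), grp in snms.groupby(["subline_id", "scaffold"]):
        order = grp.sort_values("pos")
        pos = order["pos"].to_numpy()
        if pos.size < 2:
            continue
        new_cluster = np.concatenate([[True], np.diff(pos) > window])
        cluster_lab = np.cumsum(new_cluster)
        for lab in np.unique(cluster_lab):
            members = order.index[cluster_lab == lab]
            if members.size >= min_size:
                snms.loc[members, "is_clustered"] = True
                snms.loc[members, "cluster_id"] = next_id
                next_id += 1
    return snms


def heterozygosity_pi(consensus: pd.DataFrame) -> float:
    """Fraction of analyzable consensus sites called heterozygous (pi_t)."""
    if len(consensus) == 0:
        raise ValueError("no analyzable sites")
    return float(consensus["is_het"].mean())


def reproductive_rate(lifetable: pd.DataFrame, days: int = 30) -> pd.DataFrame:
    """Reproductive rate r: summed daily offspring over the first `days` days.

    Returns per-replicate r; the group mean is in .attrs['mean_r'].
    """
    if (lifetable["offspring"] < 0).any():
        raise ValueError("negative offspring counts")
    sub = lifetable[lifetable["day"] <= days]
    per_rep = (
        sub.groupby("replicate")["offspring"].sum().rename("r").reset_index()
    )
    per_rep.attrs["mean_r"] = float(per_rep["r"].mean()) if len(per_rep) else float("nan")
    return per_rep


def spectrum_summary(snms: pd.DataFrame, meta: pd.DataFrame) -> dict:
    """One-stop condition summary mirroring the supplementary rate tables."""
    per_subline, pooled = genome_wide_rates(snms, meta)
    cond = conditional_rates(snms, meta)
    return {
        "per_subline": per_subline,
        "pooled": pooled,
        "conditional": cond,
        "n_mutations": int(len(snms)),
        "ts_tv": ts_tv_ratio(snms["snm_class"]) if len(snms) else float("nan"),
        "gc_to_at_bias": gcat_bias(snms["snm_class"]) if len(snms) else float("nan"),
    }
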