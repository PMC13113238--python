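"""Regional distribution tests and mutation-context analyses.

Compares the observed placement of de novo SNMs across genomic regions
(intergenic, promoter, exon, intron, splice junction, 3'UTR) with the
expectation under a uniform distribution over analyzable sites, using
two-sided exact binomial tests; compares conditions with two-sided Fisher
exact tests; builds trinucleotide mutation-context tables with per-context
1-df chi-square tests against genome triplet abundance; and computes the
A+T% sliding-window profile around SNMs.

Two-sided binomial p-values use the minimum-likelihood definition (sum of
all outcome probabilities not exceeding the observed outcome's); Fisher
p-values sum hypergeometric tables at most as probable as the observed.
No multiple-testing correction is applied by default; a Benjamini-
Hochberg option is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import BASES, REGION_PRECEDENCE, SNM_CLASSES
from .simulate import ReferenceGenome, RegionAnnotation


def region_expectation(
    ann: RegionAnnotation | None = None,
    site_regions: pd.Series | None = None,
) -> pd.DataFrame:
    """Expected per-region SNM proportions under a uniform distribution.

    Either from the full annotation (every base analyzable) or from the
    region labels of an analyzable-site sample.  Proportions sum to 1.
    """
    if site_regions is not None:
        counts = site_regions.value_counts()
        counts = {r: int(counts.get(r, 0)) for r in REGION_PRECEDENCE}
    elif ann is not None:
        counts = ann.region_base_counts()
    else:
        raise ValueError("need an annotation or an analyzable-site sample")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no analyzable sites")
    return pd.DataFrame(
        {
            "region": list(REGION_PRECEDENCE),
            "analyzable_sites": [counts[r] for r in REGION_PRECEDENCE],
            "expected_p": [counts[r] / total for r in REGION_PRECEDENCE],
        }
    )


def region_enrichment(k: int, N: int, p: float) -> float:
    """Two-sided exact binomial p-value of k successes in N at probability p."""
    if not 0 <= k <= N:
        raise ValueError("need 0 <= k <= N")
    if not 0 < p < 1:
        raise ValueError("degenerate expected proportion")
    return float(stats.binomtest(k, N, p, alternative="two-sided").pvalue)


def region_compare(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 (region x condition) table."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("empty margin in contingency table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def region_tests(
    snm_regions: pd.Series, expectation: pd.DataFrame
) -> pd.DataFrame:
    """Per-region observed vs expected proportions with exact binomial tests."""
    N = int(len(snm_regions))
    if N == 0:
        raise ValueError("no SNMs")
    obs = snm_regions.value_counts()
    rows = []
    for rec in expectation.itertuples(index=False):
        k = int(obs.get(rec.region, 0))
        p = rec.expected_p
        rows.append(
            {
                "region": rec.region,
                "observed": k,
                "observed_p": k / N,
                "expected_p": p,
                "p_value": region_enrichment(k, N, p) if 0 < p < 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def region_condition_tests(
    regions_a: pd.Series, regions_b: pd.Series
) -> pd.DataFrame:
    """Fisher tests comparing each region's SNM share between two conditions."""
    na, nb = len(regions_a), len(regions_b)
    rows = []
    for region in REGION_PRECEDENCE:
        ka = int((regions_a == region).sum())
        kb = int((regions_b == region).sum())
        # a region hit in neither condition carries no signal
        p = 1.0 if ka + kb == 0 else region_compare([[ka, na - ka], [kb, nb - kb]])
        rows.append(
            {"region": region, "observed_a": ka, "observed_b": kb, "p_value": p}
        )
    return pd.DataFrame(rows)


def rates_by_compartment(
    snms: pd.DataFrame,
    meta: pd.DataFrame,
    site_sample: pd.DataFrame,
) -> dict:
    """Conditional rates split into intergenic vs genic compartments.

    site_sample carries one row per analyzable site with columns 'region'
    and 'base' (consensus ancestral base); compartment-specific n_{b,i}
    are the metadata tallies scaled by the sampled compartment shares.
    Returns the two rate tables plus per-class Fisher tests on the counts.
    """
    from .spectrum import conditional_rates

    if len(site_sample) == 0:
        raise ValueError("empty analyzable-site sample")
    site_sample = site_sample.copy()
    site_sample["compartment"] = np.where(
        site_sample["region"] == "intergenic", "intergenic", "genic"
    )
    out: dict = {}
    counts_by_comp = {}
    for comp in ("intergenic", "genic"):
        sub_sites = site_sample[site_sample["compartment"] == comp]
        comp_meta = meta.copy()
        for b in BASES:
            share_num = (sub_sites["base"] == b).sum()
            share_den = (site_sample["base"] == b).sum()
            share = share_num / share_den if share_den else 0.0
            comp_meta[f"n_{b}"] = comp_meta[f"n_{b}"] * share
        if len(snms):
            in_comp = np.where(
                snms["region"] == "intergenic", "intergenic", "genic"
            ) == comp
            comp_snms = snms[in_comp]
        else:
            comp_snms = snms
        out[comp] = conditional_rates(comp_snms, comp_meta)
        counts_by_comp[comp] = comp_snms
    fisher_rows = []
    for cls in SNM_CLASSES:
        ki = int((counts_by_comp["intergenic"]["snm_class"] == cls).sum())
        kg = int((counts_by_comp["genic"]["snm_class"] == cls).sum())
        ni = len(counts_by_comp["intergenic"])
        ng = len(counts_by_comp["genic"])
        if ni + ng == 0 or (ki + kg == 0 and ni - ki + ng - kg == 0):
            p = float("nan")
        else:
            try:
                p = region_compare([[ki, ni - ki], [kg, ng - kg]])
            except ValueError:
                p = float("nan")
        fisher_rows.append({"snm_class": cls, "intergenic": ki, "genic": kg, "p_value": p})
    out["class_tests"] = pd.DataFrame(fisher_rows)
    return out


# ---------------------------------------------------------------------------
# trinucleotide contexts
# ---------------------------------------------------------------------------


def genome_triplet_counts(ref: ReferenceGenome) -> pd.Series:
    """Counts of all overlapping reference-strand triplets ('Tot. Trips')."""
    counts: dict[str, int] = {}
    for seq in ref.scaffolds.values():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        lut = np.zeros(128, dtype=np.int64)
        for b in BASES:
            lut[ord(b)] = BASES.index(b)
        idx = lut[arr]
        trip = idx[:-2] * 16 + idx[1:-1] * 4 + idx[2:]
        binc = np.bincount(trip, minlength=64)
        for t in range(64):
            if binc[t]:
                key = BASES[t // 16] + BASES[(t // 4) % 4] + BASES[t % 4]
                counts[key] = counts.get(key, 0) + int(binc[t])
    all_trips = [a + b + c for a in BASES for b in BASES for c in BASES]
    return pd.Series({t: counts.get(t, 0) for t in all_trips}, name="tot_trips")


def context_table(
    snms: pd.DataFrame,
    ref: ReferenceGenome,
    collapse_strands: bool = False,
    cpg_row: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Observed vs expected mutated-triplet counts with 1-df chi-square tests.

    The context of an SNM is (5' flank, ancestral base, 3' flank) on the
    reference strand.  Expected count per triplet = total context-
    assignable SNMs x genome abundance of that triplet / total triplets.
    Edge SNMs (flank 'N') are excluded.  With collapse_strands=True,
    reverse-complement triplet pairs are pooled.  cpg_row adds the pooled
    row of C/G-origin SNMs flanked by C or G on either or both sides.
    """
    usable = snms[(snms["context_5p"] != "N") & (snms["context_3p"] != "N")]
    contexts = usable["context_5p"] + usable["ancestral"] + usable["context_3p"]
    tot = genome_triplet_counts(ref)
    if collapse_strands:
        comp = str.maketrans("ACGT", "TGCA")
        mapped = {}
        for t in tot.index:
            rc = t.translate(comp)[::-1]
            key = min(t, rc)
            mapped[t] = key
        tot = tot.groupby(tot.index.map(mapped)).sum()
        contexts = contexts.map(mapped)
    n_total = int(len(contexts))
    obs = contexts.value_counts()
    total_trips = int(tot.sum())
    rows = []
    for trip in tot.index:
        o = int(obs.get(trip, 0))
        e = n_total * tot[trip] / total_trips if total_trips else 0.0
        if e > 0:
            chi2 = (o - e) ** 2 / e
            p = float(stats.chi2.sf(chi2, df=1))
            flagged = False
        else:
            chi2, p = float("nan"), float("nan")
            flagged = o > 0  # observed where none expected
        rows.append(
            {
                "context": trip,
                "tot_trips": int(tot[trip]),
                "mut_trips": o,
                "expected": e,
                "chi2": chi2,
                "p_value": p,
                "zero_expected_flag": flagged,
            }
        )
    table = pd.DataFrame(rows)
    if bh_correct:
        ok = table["p_value"].notna()
        table.loc[ok, "p_bh"] = stats.false_discovery_control(
            table.loc[ok, "p_value"].to_numpy()
        )
    if cpg_row:
        is_cpg = table["context"].map(
            lambda t: t[1] in "CG" and (t[0] in "CG" or t[2] in "CG")
        )
        sub = table[is_cpg]
        o = int(sub["mut_trips"].sum())
        e = float(sub["expected"].sum())
        chi2 = (o - e) ** 2 / e if e > 0 else float("nan")
        pooled = {
            "context": "CpG",
            "tot_trips": int(sub["tot_trips"].sum()),
            "mut_trips": o,
            "expected": e,
            "chi2": chi2,
            "p_value": float(stats.chi2.sf(chi2, df=1)) if e > 0 else float("nan"),
            "zero_expected_flag": False,
        }
        table = pd.concat([table, pd.DataFrame([pooled])], ignore_index=True)
    table.attrs["n_assignable"] = n_total
    table.attrs["n_edge_dropped"] = int(len(snms) - len(usable))
    return table


def at_window_profile(
    snms: pd.DataFrame, ref: ReferenceGenome, flank: int = 200, window: int = 4
) -> pd.DataFrame:
    """Mean A+T fraction in a sliding window across stacked SNM neighbourhoods.

    Each SNM contributes its +/-flank window (2*flank+1 nt); SNMs too close
    to a scaffold edge are dropped (count in .attrs['n_dropped']).  A
    window of `window` nt slides in 1-nt steps giving 2*flank+2-window
    offsets; offset is the window's start relative to the SNM.
    """
    rows = []
    n_dropped = 0
    arrays = {k: np.frombuffer(v.encode(), dtype=np.uint8) for k, v in ref.scaffolds.items()}
    at_codes = (ord("A"), ord("T"))
    for rec in snms.itertuples(index=False):
        arr = arrays[rec.scaffold]
        if rec.pos - flank < 0 or rec.pos + flank >= arr.size:
            n_dropped += 1
            continue
        seg = arr[rec.pos - flank : rec.pos + flank + 1]
        rows.append(np.isin(seg, at_codes))
    if not rows:
        raise ValueError("no SNMs with full flanking sequence")
    stack = np.array(rows, dtype=float)
    is_at = stack.mean(axis=0)  # per-offset A+T fraction across SNMs
    kernel = np.ones(window) / window
    profile = np.convolve(is_at, kernel, mode="valid")
    offsets = np.arange(-flank, flank + 2 - window)
    out = pd.DataFrame({"offset": offsets, "at_fraction": profile})
    out.attrs["n_dropped"] = n_dropped
    out.attrs["n_used"] = stack.shape[0]
    return out
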