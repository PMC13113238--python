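"""Consensus-genotype / putation SNM caller.

Works on pileup-derived per-subline, per-site read evidence.  A site is
screened per subline: multimapped reads are removed first, sites within
20 bp of an indel-mask position or outside the 12-45x residual depth band
are excluded, and a genotype is called homozygous when the top allele
carries >= 90% of reads, heterozygous when exactly two alleles each carry
30-70%, with every call allele supported by >= 2 reads in each orientation.

Across the sublines of one condition, a site is analyzable only when every
subline yields a call.  If all calls agree the shared genotype is the
'consensus' (ancestral) genotype; if all but exactly one subline share a
genotype, the odd subline's call is a candidate de novo mutation
('putation').  Any other configuration removes the site from both the
mutation count and the analyzed-site denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BASES, REGION_PRECEDENCE, classify_snm
from .simulate import COUNT_COLUMNS, ReferenceGenome, RegionAnnotation

STATE_EXCLUDED = "excluded"
STATE_NO_CALL = "no_call"
STATE_HOM = "hom"
STATE_HET = "het"

# genotype code = 4*a1 + a2 with a1 <= a2 (base indices); -1 = no call
NO_GENOTYPE = -1


@dataclass(frozen=True)
class CallerParams:
    """Screening thresholds; defaults follow the study's criteria (a)-(e)."""

    depth_min: int = 12
    depth_max: int = 45
    hom_fraction: float = 0.9
    het_low: float = 0.3
    het_high: float = 0.7
    min_orientation_reads: int = 2
    indel_pad: int = 20
    # filter switches, used by the monotonicity property tests
    apply_depth_band: bool = True
    apply_orientation: bool = True
    apply_indel_mask: bool = True


def genotype_code(a1: str, a2: str) -> int:
    i, j = sorted((BASES.index(a1), BASES.index(a2)))
    return 4 * i + j


def genotype_alleles(code: int) -> tuple[str, str]:
    return BASES[code // 4], BASES[code % 4]


def _indel_excluded(
    scaffold: np.ndarray, pos: np.ndarray, mask: pd.DataFrame, pad: int
) -> np.ndarray:
    """True where a site lies within +/-pad (inclusive) of a masked position."""
    out = np.zeros(pos.size, dtype=bool)
    if mask is None or mask.empty:
        return out
    for scaf, grp in mask.groupby("scaffold"):
        mpos = np.sort(grp["pos"].to_numpy())
        sel = scaffold == scaf
        if not sel.any():
            continue
        p = pos[sel]
        idx = np.searchsorted(mpos, p)
        near = np.zeros(p.size, dtype=bool)
        left = np.clip(idx - 1, 0, mpos.size - 1)
        right = np.clip(idx, 0, mpos.size - 1)
        near |= np.abs(p - mpos[left]) <= pad
        near |= np.abs(mpos[right] - p) <= pad
        out[sel] = near
    return out


def screen_and_genotype(
    evidence: pd.DataFrame,
    indel_mask: pd.DataFrame | None = None,
    params: CallerParams | None = None,
) -> pd.DataFrame:
    """Screen evidence rows and assign per-subline genotype calls.

    Returns a frame with subline_id, scaffold, pos, state, genotype
    (code; -1 when not called) and the residual depth after multimap
    removal.  Raises on malformed rows (negative counts or counts
    exceeding depth).
    """
    params = params or CallerParams()
    counts = evidence[COUNT_COLUMNS].to_numpy(dtype=np.int64)
    if (counts < 0).any() or (evidence["multimap_reads"].to_numpy() < 0).any():
        raise ValueError("negative read counts")
    fwd = counts[:, 0::2]
    rev = counts[:, 1::2]
    allele = fwd + rev
    resid = allele.sum(axis=1)
    if (resid + evidence["multimap_reads"].to_numpy() != evidence["depth"].to_numpy()).any():
        raise ValueError("allele counts and multimap reads do not sum to depth")

    scaffold = evidence["scaffold"].to_numpy()
    pos = evidence["pos"].to_numpy()

    excluded = np.zeros(len(evidence), dtype=bool)
    if params.apply_indel_mask:
        excluded |= _indel_excluded(scaffold, pos, indel_mask, params.indel_pad)
    if params.apply_depth_band:
        excluded |= (resid < params.depth_min) | (resid > params.depth_max)
    else:
        excluded |= resid == 0  # fractions undefined

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = allele / np.where(resid > 0, resid, 1)[:, None]

    m = params.min_orientation_reads
    orient_ok = (
        (fwd >= m) & (rev >= m)
        if params.apply_orientation
        else np.ones_like(fwd, dtype=bool)
    )

    order = np.argsort(frac, axis=1)
    top = order[:, -1]
    second = order[:, -2]
    rows = np.arange(len(evidence))
    top_frac = frac[rows, top]

    hom = (top_frac >= params.hom_fraction) & orient_ok[rows, top]

    in_band = (frac >= params.het_low) & (frac <= params.het_high)
    band_count = in_band.sum(axis=1)
    het = (
        (band_count == 2)
        & in_band[rows, top]
        & in_band[rows, second]
        & orient_ok[rows, top]
        & orient_ok[rows, second]
    )

    state = np.full(len(evidence), STATE_NO_CALL, dtype=object)
    code = np.full(len(evidence), NO_GENOTYPE, dtype=np.int64)
    state[hom] = STATE_HOM
    a = top[hom]
    code[hom] = 4 * a + a
    state[het & ~hom] = STATE_HET
    hsel = het & ~hom
    a1 = np.minimum(top[hsel], second[hsel])
    a2 = np.maximum(top[hsel], second[hsel])
    code[hsel] = 4 * a1 + a2
    state[excluded] = STATE_EXCLUDED
    code[excluded] = NO_GENOTYPE

    return pd.DataFrame(
        {
            "subline_id": evidence["subline_id"].to_numpy(),
            "scaffold": scaffold,
            "pos": pos,
            "state": state,
            "genotype": code,
            "depth_used": resid,
        }
    )


def find_consensus_and_putations(
    calls: pd.DataFrame, sublines: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consensus genotypes and putations across the sublines of a condition.

    A site is analyzable only if every subline has a hom/het call there;
    sites absent from a subline's evidence are treated as no_call.  Needs
    at least 3 sublines for the all-but-one rule to be meaningful.
    """
    if sublines is None:
        sublines = sorted(calls["subline_id"].unique())
    if len(sublines) < 3:
        raise ValueError("consensus requires at least 3 sublines")

    wide = calls.pivot_table(
        index=["scaffold", "pos"],
        columns="subline_id",
        values="genotype",
        aggfunc="first",
        fill_value=NO_GENOTYPE,
    )
    for s in sublines:
        if s not in wide.columns:
            wide[s] = NO_GENOTYPE
    wide = wide[sublines]
    G = wide.to_numpy(dtype=np.int64)
    n = len(sublines)

    callable_all = (G >= 0).all(axis=1)
    counts = np.zeros((G.shape[0], 16), dtype=np.int32)
    for c in range(16):
        counts[:, c] = (G == c).sum(axis=1)
    maxcount = counts.max(axis=1)
    mode = counts.argmax(axis=1)

    is_consensus = callable_all & (maxcount == n)
    is_putation = callable_all & (maxcount == n - 1)

    idx = wide.index.to_frame(index=False)
    analyzable = is_consensus | is_putation
    consensus = idx.loc[analyzable].copy()
    consensus["genotype"] = mode[analyzable]
    a1, a2 = zip(*(genotype_alleles(c) for c in consensus["genotype"])) if len(
        consensus
    ) else ((), ())
    consensus["allele1"] = list(a1)
    consensus["allele2"] = list(a2)
    consensus["is_het"] = consensus["allele1"] != consensus["allele2"]
    consensus = consensus.reset_index(drop=True)

    put_rows = []
    sub_arr = np.array(sublines, dtype=object)
    for i in np.flatnonzero(is_putation):
        cons = mode[i]
        odd = int(np.flatnonzero(G[i] != cons)[0])
        put_rows.append(
            {
                "scaffold": idx.iloc[i]["scaffold"],
                "pos": int(idx.iloc[i]["pos"]),
                "subline_id": sub_arr[odd],
                "consensus_genotype": int(cons),
                "derived_genotype": int(G[i, odd]),
            }
        )
    putations = pd.DataFrame(
        put_rows,
        columns=["scaffold", "pos", "subline_id", "consensus_genotype", "derived_genotype"],
    )
    return consensus, putations


def _changed_alleles(cons_code: int, derived_code: int) -> tuple[str, str] | None:
    """(ancestral, derived) allele of a single-allele genotype change, else None."""
    anc = list(genotype_alleles(cons_code))
    der = list(genotype_alleles(derived_code))
    for x in list(anc):
        if x in der:
            anc.remove(x)
            der.remove(x)
    if len(anc) == 1 and len(der) == 1:
        return anc[0], der[0]
    return None


def annotate_snms(
    putations: pd.DataFrame,
    ref: ReferenceGenome,
    ann: RegionAnnotation | None = None,
) -> pd.DataFrame:
    """Annotate putations into SNM records (class, triplet context, region).

    Putations whose derived genotype differs from the consensus by more
    than one allele are dropped (count in .attrs['n_rejected']).  Sites at
    a scaffold edge get context 'N' flanks and are excluded from context
    tables downstream.
    """
    rows = []
    n_rejected = 0
    label_cache: dict[str, np.ndarray] = {}
    for rec in putations.itertuples(index=False):
        change = _changed_alleles(rec.consensus_genotype, rec.derived_genotype)
        if change is None:
            n_rejected += 1
            continue
        anc, der = change
        seq = ref.scaffolds[rec.scaffold]
        five = seq[rec.pos - 1] if rec.pos >= 1 else "N"
        three = seq[rec.pos + 1] if rec.pos + 1 < len(seq) else "N"
        region = ""
        if ann is not None:
            if rec.scaffold not in label_cache:
                label_cache[rec.scaffold] = ann.label_array(rec.scaffold)
            region = REGION_PRECEDENCE[label_cache[rec.scaffold][rec.pos]]
        rows.append(
            {
                "subline_id": rec.subline_id,
                "scaffold": rec.scaffold,
                "pos": rec.pos,
                "ancestral": anc,
                "derived": der,
                "snm_class": classify_snm(anc, der),
                "context_5p": five,
                "context_3p": three,
                "region": region,
                "is_clustered": False,
            }
        )
    snms = pd.DataFrame(
        rows,
        columns=[
            "subline_id",
            "scaffold",
            "pos",
            "ancestral",
            "derived",
            "snm_class",
            "context_5p",
            "context_3p",
            "region",
            "is_clustered",
        ],
    )
    snms.attrs["n_rejected"] = n_rejected
    return snms


def tally_analyzed_sites(
    consensus: pd.DataFrame,
    meta: pd.DataFrame,
    total_sites: float | None = None,
    evaluated_sites: int | None = None,
) -> pd.DataFrame:
    """Fill n_i and n_{b,i} in the subline metadata from the consensus.

    Census mode (total_sites None): counts analyzable sites directly.
    Sampled mode: the evidence covered `evaluated_sites` sampled sites out
    of an analytic total of `total_sites`; n_i = total_sites x analyzable
    fraction, partitioned by the observed consensus base composition.
    Heterozygous consensus sites contribute 0.5 to each allele's tally.
    """
    base_w = dict.fromkeys(BASES, 0.0)
    for rec in consensus.itertuples(index=False):
        if rec.allele1 == rec.allele2:
            base_w[rec.allele1] += 1.0
        else:
            base_w[rec.allele1] += 0.5
            base_w[rec.allele2] += 0.5
    n_analyzable = float(len(consensus))

    if total_sites is not None:
        if not evaluated_sites:
            raise ValueError("sampled mode needs evaluated_sites > 0")
        frac = n_analyzable / evaluated_sites
        n_i = total_sites * frac
        scale = n_i / n_analyzable if n_analyzable else 0.0
    else:
        n_i = n_analyzable
        scale = 1.0

    meta = meta.copy()
    if total_sites is not None and "n_sites" in meta.columns and n_analyzable:
        # sampled composition should be close to the analytic composition
        at_obs = (base_w["A"] + base_w["T"]) / n_analyzable
        at_ana = float((meta["n_A"] + meta["n_T"]).iloc[0] / meta["n_sites"].iloc[0])
        if abs(at_obs - at_ana) > 0.1:
            warnings.warn(
                f"sampled base composition (A+T {at_obs:.3f}) deviates from the "
                f"analytic metadata ({at_ana:.3f})",
                stacklevel=2,
            )
    meta["n_sites"] = n_i
    for b in BASES:
        meta[f"n_{b}"] = base_w[b] * scale
    return meta


@dataclass
class CallResult:
    calls: pd.DataFrame
    consensus: pd.DataFrame
    putations: pd.DataFrame
    snms: pd.DataFrame
    meta: pd.DataFrame
    heterozygosity: float = field(default=float("nan"))


def call_pipeline(
    evidence: pd.DataFrame,
    meta: pd.DataFrame,
    ref: ReferenceGenome,
    ann: RegionAnnotation | None = None,
    indel_mask: pd.DataFrame | None = None,
    params: CallerParams | None = None,
    analytic_total: float | None = None,
) -> CallResult:
    """Evidence -> screened calls -> consensus/putations -> annotated SNMs.

    With analytic_total set (simulator mode), the analyzed-site totals are
    reconciled against the number of distinct evaluated sites.
    """
    sublines = list(meta["subline_id"])
    calls = screen_and_genotype(evidence, indel_mask, params)
    consensus, putations = find_consensus_and_putations(calls, sublines)
    snms = annotate_snms(putations, ref, ann)
    evaluated = int(evidence[["scaffold", "pos"]].drop_duplicates().shape[0])
    meta_out = tally_analyzed_sites(
        consensus,
        meta,
        total_sites=analytic_total,
        evaluated_sites=evaluated if analytic_total is not None else None,
    )
    het = float(consensus["is_het"].mean()) if len(consensus) else float("nan")
    return CallResult(calls, consensus, putations, snms, meta_out, het)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_evidence(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_meta(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_position_bed(path: str | Path) -> pd.DataFrame:
    """Single-position BED (e.g. indel mask) -> scaffold/pos frame."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            rows.append({"scaffold": parts[0], "pos": int(parts[1])})
    return pd.DataFrame(rows, columns=["scaffold", "pos"])


def write_vcf(
    snms: pd.DataFrame, sublines: list[str], ref: ReferenceGenome, path: str | Path
) -> None:
    """SNMs as VCF 4.2 with one sample column per subline.

    REF/ALT are the ancestral/derived alleles of the single changed allele;
    the mutant subline is genotyped 0/1 and all others 0/0.  Positions are
    converted to VCF's 1-based convention.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mutacc\n")
        for scaf, length in ref.lengths.items():
            fh.write(f"##contig=<ID={scaf},length={length}>\n")
        for key, desc in [
            ("SUBLINE", "Subline carrying the de novo mutation"),
            ("CLASS", "Strand-collapsed SNM class"),
            ("CONTEXT", "Reference-strand triplet 5p/site/3p"),
            ("REGION", "Genomic region label"),
            ("CLUSTERED", "1 if part of a multinucleotide mutation cluster"),
        ]:
            typ = "Integer" if key == "CLUSTERED" else "String"
            fh.write(
                f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sublines)
            + "\n"
        )
        ordered = snms.sort_values(["scaffold", "pos"])
        for rec in ordered.itertuples(index=False):
            ctx = f"{rec.context_5p}{rec.ancestral}{rec.context_3p}"
            info = (
                f"SUBLINE={rec.subline_id};CLASS={rec.snm_class};CONTEXT={ctx};"
                f"REGION={rec.region or '.'};CLUSTERED={int(bool(rec.is_clustered))}"
            )
            gts = ["0/1" if s == rec.subline_id else "0/0" for s in sublines]
            fh.write(
                f"{rec.scaffold}\t{rec.pos + 1}\t.\t{rec.ancestral}\t{rec.derived}"
                f"\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )
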