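"""Synthetic mutation-accumulation (MA) data with known ground truth.

Generates every input the downstream pipeline consumes: a reference genome
with a full region annotation, planted de novo SNMs and CNVs, per-subline
per-site pileup-style read evidence at ~25x Poisson depth with sequencing
error and strand balance, indel/multimap masks, windowed depth-of-coverage
tables for CNV detection, one-compartment cadmium biokinetics records, and
daily life-table offspring counts.

Evidence rows are emitted only for truth sites plus a random background
sample of clean sites; the analyzed-site totals n_i and per-base n_{b,i}
are carried analytically in the subline metadata so that rate denominators
remain correct at desk scale.  All randomness flows through one
numpy Generator: a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    BASES,
    COMPLEMENT,
    REGION_INDEX,
    REGION_PRECEDENCE,
    SNM_CLASSES,
    array_to_seq,
    class_origin_bases,
    seq_to_array,
)

# Default spectrum used to split a genome-wide rate across the six classes.
# Chosen to reproduce a Ts/Tv ratio near 1.07 and an AT-gaining/GC-gaining
# bias near 1.8 (control-condition values for the adapted genotype).
DEFAULT_CLASS_WEIGHTS = {
    "A:T->G:C": 0.197,
    "A:T->C:G": 0.080,
    "A:T->T:A": 0.130,
    "G:C->A:T": 0.320,
    "G:C->T:A": 0.170,
    "G:C->C:G": 0.103,
}

# Flat key/value config-file keys for the per-class rates.
CLASS_CONFIG_KEYS = {
    "A:T->G:C": "rate_at_gc",
    "A:T->C:G": "rate_at_cg",
    "A:T->T:A": "rate_at_ta",
    "G:C->A:T": "rate_gc_at",
    "G:C->T:A": "rate_gc_ta",
    "G:C->C:G": "rate_gc_cg",
}


def class_rates_from_total(
    mu_total: float, gc_content: float, weights: dict[str, float] | None = None
) -> dict[str, float]:
    """Split a genome-wide SNM rate into per-class conditional rates.

    The conditional rate of class c is defined per eligible (ancestral-pair)
    diploid site, so weights w_c (class shares of the mutation count) map to
    mu_c = w_c * mu_total / f_c with f_c the genomic fraction of eligible
    bases.  The weighted recombination sum(mu_c * f_c) equals mu_total.
    """
    if weights is None:
        weights = DEFAULT_CLASS_WEIGHTS
    total_w = sum(weights.values())
    at_frac = 1.0 - gc_content
    rates = {}
    for cls in SNM_CLASSES:
        frac = at_frac if cls.startswith("A:T") else gc_content
        if frac == 0.0:
            rates[cls] = 0.0
        else:
            rates[cls] = weights[cls] / total_w * mu_total / frac
    return rates


@dataclass
class SimulationConfig:
    """All knobs of the synthetic MA experiment.

    Rates are per diploid eligible site per generation; n_sites is the
    analytic count of analyzed diploid sites per subline (the real genome
    acts as the spatial substrate only).
    """

    # genome
    n_scaffolds: int = 4
    scaffold_length: int = 250_000
    gc_content: float = 0.41
    genes_per_scaffold: int = 40
    promoter_length: int = 1000
    n_exons: int = 4
    exon_length: int = 200
    intron_length: int = 300
    splice_length: int = 10
    utr3_length: int = 300
    # experiment
    condition: str = "control"
    n_sublines: int = 12
    generations: float = 61.75
    n_sites: float = 1.0e8
    class_rates: dict[str, float] = field(
        default_factory=lambda: class_rates_from_total(2.06e-9, 0.41)
    )
    mnm_fraction: float = 0.05
    # evidence
    depth_mean: float = 25.0
    error_rate: float = 1e-3
    strand_prob: float = 0.5
    multimap_fraction: float = 0.02
    multimap_region_fraction: float = 0.01
    multimap_region_rate: float = 0.45
    indel_density: float = 1e-4
    het_fraction: float = 0.026
    background_sites: int = 20_000
    # CNV
    cnv_rate: float = 0.088
    cnv_length_min: int = 3000
    cnv_length_max: int = 30_000
    cnv_gain_prob: float = 0.5
    depth_window: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.class_rates.values()):
            raise ValueError("class rates must be non-negative")
        if self.depth_mean <= 0:
            raise ValueError("depth mean must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_sublines < 1 or self.generations <= 0:
            raise ValueError("need at least one subline with T > 0")

    @property
    def subline_ids(self) -> list[str]:
        tag = self.condition[:1].upper() or "S"
        return [f"{tag}{i + 1:02d}" for i in range(self.n_sublines)]


@dataclass
class ReferenceGenome:
    """Scaffold-id -> A/C/G/T sequence."""

    scaffolds: dict[str, str]

    def __post_init__(self) -> None:
        if not self.scaffolds or sum(len(s) for s in self.scaffolds.values()) == 0:
            raise ValueError("reference must contain sequence")
        for name, seq in self.scaffolds.items():
            if set(seq) - set(BASES):
                raise ValueError(f"scaffold {name} contains non-ACGT characters")

    @property
    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.scaffolds.items()}

    @property
    def gc_content(self) -> float:
        gc = tot = 0
        for seq in self.scaffolds.values():
            gc += seq.count("G") + seq.count("C")
            tot += len(seq)
        return gc / tot

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: seq_to_array(v) for k, v in self.scaffolds.items()}

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.scaffolds.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        return cls(
            {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        )


@dataclass
class RegionAnnotation:
    """Region intervals (0-based half-open) plus scaffold lengths.

    Only non-intergenic intervals are stored; everything unlabelled is
    intergenic.  Overlaps are resolved by precedence (splice_junction >
    exon > utr3 > intron > promoter > intergenic).
    """

    intervals: list[tuple[str, int, int, str]]
    scaffold_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for scaf, start, end, label in self.intervals:
            if label not in REGION_INDEX:
                raise ValueError(f"unknown region label {label!r}")
            if not 0 <= start < end <= self.scaffold_lengths[scaf]:
                raise ValueError(f"interval out of bounds: {scaf}:{start}-{end}")

    def label_array(self, scaffold: str) -> np.ndarray:
        """Per-base region codes (indices into REGION_PRECEDENCE)."""
        arr = np.zeros(self.scaffold_lengths[scaffold], dtype=np.int8)
        pending = [iv for iv in self.intervals if iv[0] == scaffold]
        # paint in precedence order so more specific labels win
        pending.sort(key=lambda iv: REGION_INDEX[iv[3]])
        for _, start, end, label in pending:
            arr[start:end] = REGION_INDEX[label]
        return arr

    def label_at(self, scaffold: str, pos: int) -> str:
        return REGION_PRECEDENCE[self.label_array(scaffold)[pos]]

    def region_base_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(REGION_PRECEDENCE, 0)
        for scaf in self.scaffold_lengths:
            arr = self.label_array(scaf)
            binc = np.bincount(arr, minlength=len(REGION_PRECEDENCE))
            for i, label in enumerate(REGION_PRECEDENCE):
                counts[label] += int(binc[i])
        return counts

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for scaf, start, end, label in self.intervals:
                fh.write(f"{scaf}\t{start}\t{end}\t{label}\n")

    @classmethod
    def from_bed(
        cls, path: str | Path, scaffold_lengths: dict[str, int]
    ) -> "RegionAnnotation":
        intervals = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                scaf, start, end, label = line.split()[:4]
                intervals.append((scaf, int(start), int(end), label))
        return cls(intervals, scaffold_lengths)


@dataclass
class Masks:
    """Indel positions (site exclusion +/-20 bp) and multimap-heavy regions."""

    indel_positions: pd.DataFrame  # columns: scaffold, pos
    multimap_regions: pd.DataFrame  # columns: scaffold, start, end

    def write(self, indel_path: str | Path, multimap_path: str | Path) -> None:
        with open(indel_path, "w") as fh:
            for rec in self.indel_positions.itertuples(index=False):
                fh.write(f"{rec.scaffold}\t{rec.pos}\t{rec.pos + 1}\n")
        with open(multimap_path, "w") as fh:
            for rec in self.multimap_regions.itertuples(index=False):
                fh.write(f"{rec.scaffold}\t{rec.start}\t{rec.end}\n")


@dataclass
class TruthSet:
    """Planted mutations: the simulator's ground truth."""

    snms: pd.DataFrame  # subline_id, scaffold, pos, ancestral, derived, snm_class
    cnvs: pd.DataFrame  # subline_id, scaffold, start, end, copy_state

    @staticmethod
    def empty() -> "TruthSet":
        return TruthSet(
            pd.DataFrame(
                columns=["subline_id", "scaffold", "pos", "ancestral", "derived", "snm_class"]
            ),
            pd.DataFrame(columns=["subline_id", "scaffold", "start", "end", "copy_state"]),
        )


# ---------------------------------------------------------------------------
# reference genome + annotation
# ---------------------------------------------------------------------------


def generate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ReferenceGenome, RegionAnnotation]:
    """Random genome with gene models partitioning every base into a region."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T

    gene_body = (
        config.n_exons * config.exon_length
        + (config.n_exons - 1) * config.intron_length
        + config.utr3_length
    )
    footprint = config.promoter_length + gene_body
    if config.genes_per_scaffold * footprint > config.scaffold_length:
        raise ValueError("gene models exceed scaffold length")
    if config.n_exons >= 2 and config.intron_length < 2 * config.splice_length:
        raise ValueError("introns shorter than their splice junctions")

    scaffolds: dict[str, str] = {}
    intervals: list[tuple[str, int, int, str]] = []
    for s in range(config.n_scaffolds):
        name = f"scaffold_{s + 1}"
        arr = rng.choice(4, size=config.scaffold_length, p=probs).astype(np.uint8)
        scaffolds[name] = array_to_seq(arr)
        if config.genes_per_scaffold == 0:
            continue
        slack = config.scaffold_length - config.genes_per_scaffold * footprint
        gap = slack // (config.genes_per_scaffold + 1)
        cursor = gap
        for _ in range(config.genes_per_scaffold):
            start = cursor
            intervals.append((name, start, start + config.promoter_length, "promoter"))
            pos = start + config.promoter_length
            for e in range(config.n_exons):
                intervals.append((name, pos, pos + config.exon_length, "exon"))
                pos += config.exon_length
                if e < config.n_exons - 1:
                    intervals.append((name, pos, pos + config.intron_length, "intron"))
                    intervals.append(
                        (name, pos, pos + config.splice_length, "splice_junction")
                    )
                    intervals.append(
                        (
                            name,
                            pos + config.intron_length - config.splice_length,
                            pos + config.intron_length,
                            "splice_junction",
                        )
                    )
                    pos += config.intron_length
            intervals.append((name, pos, pos + config.utr3_length, "utr3"))
            cursor = pos + config.utr3_length + gap
    lengths = {k: len(v) for k, v in scaffolds.items()}
    return ReferenceGenome(scaffolds), RegionAnnotation(intervals, lengths)


def generate_masks(
    ref: ReferenceGenome, config: SimulationConfig, rng: np.random.Generator
) -> Masks:
    """Genotype-vs-reference indel positions and multimap-heavy regions.

    Indels are shared across sublines (they separate the founding genotype
    from the reference assembly, not individual sublines).
    """
    indel_rows = []
    mm_rows = []
    for scaf, seq in ref.scaffolds.items():
        length = len(seq)
        n_indels = rng.binomial(length, config.indel_density)
        if n_indels:
            pos = np.sort(rng.choice(length, size=n_indels, replace=False))
            indel_rows.append(pd.DataFrame({"scaffold": scaf, "pos": pos}))
        region_span = 2000
        n_regions = int(config.multimap_region_fraction * length / region_span)
        for _ in range(n_regions):
            start = int(rng.integers(0, max(1, length - region_span)))
            mm_rows.append({"scaffold": scaf, "start": start, "end": start + region_span})
    indel = (
        pd.concat(indel_rows, ignore_index=True)
        if indel_rows
        else pd.DataFrame(columns=["scaffold", "pos"])
    )
    multimap = pd.DataFrame(mm_rows, columns=["scaffold", "start", "end"])
    return Masks(indel, multimap)


# ---------------------------------------------------------------------------
# planting mutations
# ---------------------------------------------------------------------------


def _eligible_positions(
    ref: ReferenceGenome, masks: Masks | None, pad: int = 20
) -> dict[str, list[tuple[str, np.ndarray]]]:
    """Per ancestral pair, the plantable positions of each scaffold.

    Excludes scaffold edges (flanking bases needed for context) and +/-pad
    around indel-mask positions (those sites would never be analyzable).
    """
    arrays = ref.arrays()
    out: dict[str, list[tuple[str, np.ndarray]]] = {"A:T": [], "G:C": []}
    for scaf, arr in arrays.items():
        ok = np.ones(arr.size, dtype=bool)
        ok[0] = ok[-1] = False
        if masks is not None and not masks.indel_positions.empty:
            here = masks.indel_positions.loc[
                masks.indel_positions["scaffold"] == scaf, "pos"
            ].to_numpy()
            for p in here:
                ok[max(0, p - pad) : p + pad + 1] = False
        is_at = (arr == 0) | (arr == 3)
        out["A:T"].append((scaf, np.flatnonzero(ok & is_at)))
        out["G:C"].append((scaf, np.flatnonzero(ok & ~is_at)))
    return out


def _derived_allele(ancestral: str, snm_class: str) -> str:
    """Derived base implied by an ancestral base and a strand-collapsed class."""
    target = snm_class.split("->")[1][0]  # derived pair's first base (A or G strand)
    if ancestral in "AG":
        return target
    return COMPLEMENT[target]


def plant_snms(
    ref: ReferenceGenome,
    ann: RegionAnnotation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    masks: Masks | None = None,
) -> TruthSet:
    """Plant per-subline SNMs at Poisson counts implied by the class rates.

    The expected count of class c in subline i is 2 * n_c * T_i * mu_c with
    n_c = n_sites * (genomic fraction of c's ancestral pair).  A configured
    fraction of SNMs is rearranged into MNM clusters (2-3 SNMs within 50 bp
    of an anchor SNM of the same subline).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pools = _eligible_positions(ref, masks)
    pair_frac = {"A:T": 1.0 - config.gc_content, "G:C": config.gc_content}
    arrays = ref.arrays()

    flat_pools = {}
    for pair, per_scaf in pools.items():
        scafs = []
        positions = []
        for scaf, pos in per_scaf:
            scafs.extend([scaf] * pos.size)
            positions.append(pos)
        flat_pools[pair] = (
            np.array(scafs, dtype=object),
            np.concatenate(positions) if positions else np.array([], dtype=int),
        )

    rows = []
    for i, subline in enumerate(config.subline_ids):
        T = config.generations
        for pair in ("A:T", "G:C"):
            classes = [c for c in SNM_CLASSES if c.startswith(pair)]
            lams = np.array(
                [
                    2.0 * config.n_sites * pair_frac[pair] * T * config.class_rates[c]
                    for c in classes
                ]
            )
            pool_scafs, pool_pos = flat_pools[pair]
            if pool_pos.size == 0:
                continue  # no eligible bases of this pair in the substrate genome
            counts = rng.poisson(lams)
            total = int(counts.sum())
            if total == 0:
                continue
            if total > pool_pos.size:
                raise ValueError(
                    "expected mutation count exceeds eligible sites; lower the rates"
                )
            idx = rng.choice(pool_pos.size, size=total, replace=False)
            cls_labels = np.repeat(classes, counts)
            for j, k in enumerate(idx):
                scaf = pool_scafs[k]
                pos = int(pool_pos[k])
                anc = BASES[arrays[scaf][pos]]
                cls = cls_labels[j]
                rows.append(
                    {
                        "subline_id": subline,
                        "scaffold": scaf,
                        "pos": pos,
                        "ancestral": anc,
                        "derived": _derived_allele(anc, cls),
                        "snm_class": cls,
                    }
                )
    snms = pd.DataFrame(
        rows, columns=["subline_id", "scaffold", "pos", "ancestral", "derived", "snm_class"]
    )
    if config.mnm_fraction > 0 and len(snms) >= 2:
        snms = _form_mnm_clusters(snms, ref, config, rng, masks)
    snms = snms.sort_values(["subline_id", "scaffold", "pos"]).reset_index(drop=True)
    return TruthSet(snms, TruthSet.empty().cnvs)


def _form_mnm_clusters(
    snms: pd.DataFrame,
    ref: ReferenceGenome,
    config: SimulationConfig,
    rng: np.random.Generator,
    masks: Masks | None,
) -> pd.DataFrame:
    """Relocate a fraction of SNMs to within 50 bp of a same-subline anchor.

    Totals are preserved: mutations are moved, never added, so planted
    counts stay at the Poisson draws.
    """
    arrays = ref.arrays()
    snms = snms.copy()
    for subline, grp in snms.groupby("subline_id"):
        if len(grp) < 2:
            continue
        k = int(round(config.mnm_fraction * len(grp)))
        if k == 0:
            continue
        movers = rng.choice(grp.index.to_numpy(), size=min(k, len(grp) - 1), replace=False)
        for idx in movers:
            others = grp.index[grp.index != idx]
            anchor = snms.loc[rng.choice(others.to_numpy())]
            scaf = anchor["scaffold"]
            arr = arrays[scaf]
            lo = max(1, int(anchor["pos"]) - 50)
            hi = min(arr.size - 1, int(anchor["pos"]) + 51)
            window = np.arange(lo, hi)
            pair = "AT" if snms.loc[idx, "snm_class"].startswith("A:T") else "GC"
            cand = window[np.isin(arr[window], [BASE_IDX[pair[0]], BASE_IDX[pair[1]]])]
            taken = set(
                zip(
                    snms.loc[snms.subline_id == subline, "scaffold"],
                    snms.loc[snms.subline_id == subline, "pos"],
                )
            )
            cand = np.array([p for p in cand if (scaf, int(p)) not in taken], dtype=int)
            if cand.size == 0:
                continue
            new_pos = int(rng.choice(cand))
            anc = BASES[arr[new_pos]]
            snms.loc[idx, ["scaffold", "pos", "ancestral", "derived"]] = [
                scaf,
                new_pos,
                anc,
                _derived_allele(anc, snms.loc[idx, "snm_class"]),
            ]
    return snms


BASE_IDX = {b: i for i, b in enumerate(BASES)}


def plant_cnvs(
    ref: ReferenceGenome,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Plant non-overlapping per-subline CNVs (gain = 3 copies, loss = 1).

    Counts are Poisson(cnv_rate * T) per subline; lengths log-uniform in
    [cnv_length_min, cnv_length_max].
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lengths = ref.lengths
    if config.cnv_length_max > max(lengths.values()):
        raise ValueError("CNV length bound exceeds scaffold length")
    scaf_names = list(lengths)
    scaf_p = np.array([lengths[s] for s in scaf_names], dtype=float)
    scaf_p /= scaf_p.sum()

    rows = []
    for subline in config.subline_ids:
        n = rng.poisson(config.cnv_rate * config.generations)
        placed: list[tuple[str, int, int]] = []
        for _ in range(n):
            length = int(
                np.exp(
                    rng.uniform(
                        np.log(config.cnv_length_min), np.log(config.cnv_length_max)
                    )
                )
            )
            ok = False
            for _attempt in range(100):
                scaf = scaf_names[rng.choice(len(scaf_names), p=scaf_p)]
                if lengths[scaf] <= length:
                    continue
                start = int(rng.integers(0, lengths[scaf] - length))
                end = start + length
                if all(
                    s != scaf or end <= a or start >= b for s, a, b in placed
                ):
                    ok = True
                    break
            if not ok:
                raise ValueError("infeasible CNV packing; lower rate or lengths")
            placed.append((scaf, start, end))
            rows.append(
                {
                    "subline_id": subline,
                    "scaffold": scaf,
                    "start": start,
                    "end": end,
                    "copy_state": "gain" if rng.random() < config.cnv_gain_prob else "loss",
                }
            )
    cnvs = pd.DataFrame(
        rows, columns=["subline_id", "scaffold", "start", "end", "copy_state"]
    )
    return TruthSet(TruthSet.empty().snms, cnvs)


# ---------------------------------------------------------------------------
# read evidence
# ---------------------------------------------------------------------------

COUNT_COLUMNS = [f"count{b}_{o}" for b in BASES for o in ("fwd", "rev")]
EVIDENCE_COLUMNS = ["subline_id", "scaffold", "pos", "depth"] + COUNT_COLUMNS + [
    "multimap_reads"
]


def _copy_ratio(
    cnvs: pd.DataFrame, subline: str, scaffold: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    ratio = np.ones(pos.size)
    if cnvs.empty:
        return ratio
    sub = cnvs[cnvs["subline_id"] == subline]
    for rec in sub.itertuples(index=False):
        hit = (scaffold == rec.scaffold) & (pos >= rec.start) & (pos < rec.end)
        ratio[hit] = 1.5 if rec.copy_state == "gain" else 0.5
    return ratio


def _sample_counts(
    n_reads: np.ndarray, probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Row-wise multinomial via chained conditional binomials (vectorized)."""
    remaining = n_reads.astype(np.int64).copy()
    ptot = np.ones(len(n_reads))
    counts = np.zeros((len(n_reads), 4), dtype=np.int64)
    for b in range(3):
        p = np.divide(probs[:, b], ptot, out=np.zeros_like(ptot), where=ptot > 0)
        p = np.clip(p, 0.0, 1.0)
        counts[:, b] = rng.binomial(remaining, p)
        remaining -= counts[:, b]
        ptot -= probs[:, b]
    counts[:, 3] = remaining
    return counts


def emit_evidence(
    ref: ReferenceGenome,
    truth: TruthSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    masks: Masks | None = None,
) -> pd.DataFrame:
    """Pileup-style evidence at truth sites plus a clean background sample.

    Per site x subline: depth ~ Poisson(depth_mean x CNV copy ratio);
    multimapped reads ~ Binomial(depth, multimap fraction) are excluded
    from the allele counts (depth = sum(counts) + multimap_reads); the
    remaining reads draw alleles from the true genotype with per-read
    error to a uniform other base, and split fwd/rev by the strand-balance
    probability.  A het_fraction of background sites is ancestrally
    heterozygous in every subline.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    arrays = ref.arrays()
    lengths = ref.lengths
    scaf_names = list(lengths)

    # --- assemble the site list -------------------------------------------
    truth_sites = truth.snms[["scaffold", "pos"]].drop_duplicates()
    taken = set(zip(truth_sites["scaffold"], truth_sites["pos"]))

    n_bg = config.background_sites
    scaf_p = np.array([lengths[s] for s in scaf_names], dtype=float)
    scaf_p /= scaf_p.sum()
    bg_scaf_idx = rng.choice(len(scaf_names), size=n_bg, p=scaf_p)
    bg_rows = []
    for si, scaf in enumerate(scaf_names):
        count = int((bg_scaf_idx == si).sum())
        if count == 0:
            continue
        pos = rng.choice(lengths[scaf], size=min(count, lengths[scaf]), replace=False)
        for p in pos:
            if (scaf, int(p)) not in taken:
                bg_rows.append((scaf, int(p)))
    n_het = int(round(len(bg_rows) * config.het_fraction))
    het_flags = np.zeros(len(bg_rows), dtype=bool)
    if n_het:
        het_flags[rng.choice(len(bg_rows), size=n_het, replace=False)] = True

    sites = pd.DataFrame(
        [(s, p, "background") for s, p in bg_rows],
        columns=["scaffold", "pos", "site_type"],
    )
    sites.loc[het_flags, "site_type"] = "het_background"
    if not truth_sites.empty:
        ts = truth_sites.copy()
        ts["site_type"] = "snm_truth"
        sites = pd.concat([ts, sites], ignore_index=True)
    sites = sites.sort_values(["scaffold", "pos"]).reset_index(drop=True)

    ref_base = np.array(
        [BASES[arrays[s][p]] for s, p in zip(sites["scaffold"], sites["pos"])]
    )
    # ancestral het alt allele per het-background site (shared by sublines)
    het_alt = np.array([""] * len(sites), dtype=object)
    is_het_bg = (sites["site_type"] == "het_background").to_numpy()
    for i in np.flatnonzero(is_het_bg):
        alts = [b for b in BASES if b != ref_base[i]]
        het_alt[i] = alts[rng.choice(3)]

    # truth lookup: (scaffold, pos, subline) -> derived allele
    derived_map = {
        (r.scaffold, r.pos, r.subline_id): r.derived
        for r in truth.snms.itertuples(index=False)
    }

    # multimap fraction per site
    mm_frac = np.full(len(sites), config.multimap_fraction)
    if masks is not None and not masks.multimap_regions.empty:
        for rec in masks.multimap_regions.itertuples(index=False):
            hit = (
                (sites["scaffold"] == rec.scaffold)
                & (sites["pos"] >= rec.start)
                & (sites["pos"] < rec.end)
            ).to_numpy()
            mm_frac[hit] = config.multimap_region_rate

    scaf_arr = sites["scaffold"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    truth_site_idx = np.flatnonzero((sites["site_type"] == "snm_truth").to_numpy())
    frames = []
    for subline in config.subline_ids:
        ratio = _copy_ratio(truth.cnvs, subline, scaf_arr, pos_arr)
        depth_total = rng.poisson(config.depth_mean * ratio)
        multimap = rng.binomial(depth_total, mm_frac)
        n_reads = depth_total - multimap

        # genotype allele probabilities per site
        probs = np.zeros((len(sites), 4))
        for b, bi in BASE_IDX.items():
            probs[:, bi] = (ref_base == b).astype(float)
        for i in np.flatnonzero(is_het_bg):
            probs[i] = 0.0
            probs[i, BASE_IDX[ref_base[i]]] = 0.5
            probs[i, BASE_IDX[het_alt[i]]] = 0.5
        if derived_map:
            for i in truth_site_idx:
                key = (scaf_arr[i], int(pos_arr[i]), subline)
                if key in derived_map:
                    probs[i] = 0.0
                    anc = ref_base[i]
                    probs[i, BASE_IDX[anc]] = 0.5
                    probs[i, BASE_IDX[derived_map[key]]] = 0.5
        e = config.error_rate
        probs = probs * (1.0 - e) + (e / 3.0) * (1.0 - probs)

        counts = _sample_counts(n_reads, probs, rng)
        fwd = rng.binomial(counts, config.strand_prob)
        rev = counts - fwd
        frame = {
            "subline_id": subline,
            "scaffold": scaf_arr,
            "pos": pos_arr,
            "depth": n_reads + multimap,
        }
        for bi, b in enumerate(BASES):
            frame[f"count{b}_fwd"] = fwd[:, bi]
            frame[f"count{b}_rev"] = rev[:, bi]
        frame["multimap_reads"] = multimap
        frames.append(pd.DataFrame(frame))
    evidence = pd.concat(frames, ignore_index=True)[EVIDENCE_COLUMNS]
    return evidence


def emit_window_depths(
    ref: ReferenceGenome,
    truth: TruthSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Windowed depth-of-coverage per subline for read-depth CNV calling.

    Window mean depth is Poisson read counts over the window divided by
    window size, scaled by the average CNV copy ratio over the window.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    w = config.depth_window
    frames = []
    for scaf, length in ref.lengths.items():
        starts = np.arange(0, length - w + 1, w)
        ends = starts + w
        for subline in config.subline_ids:
            ratio = np.ones(starts.size)
            sub = truth.cnvs[
                (truth.cnvs["subline_id"] == subline)
                & (truth.cnvs["scaffold"] == scaf)
            ]
            for rec in sub.itertuples(index=False):
                ov = np.clip(np.minimum(ends, rec.end) - np.maximum(starts, rec.start), 0, w)
                r = 1.5 if rec.copy_state == "gain" else 0.5
                ratio += (ov / w) * (r - 1.0)
            reads = rng.poisson(config.depth_mean * ratio * w)
            frames.append(
                pd.DataFrame(
                    {
                        "subline_id": subline,
                        "scaffold": scaf,
                        "start": starts,
                        "end": ends,
                        "depth": reads / w,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# biokinetics + life tables
# ---------------------------------------------------------------------------


def simulate_biokinetics(
    k_u_star: float,
    k_e: float,
    t_exposure: float,
    t_elim: float,
    noise_sd: float = 0.0,
    n_isolates: int = 4,
    beakers_per_isolate: int = 2,
    clade: str = "adapted",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Forward-simulate A/E-daphnid burden records from the one-compartment model."""
    from .biokinetics import elimination_burden, uptake_burden

    if k_u_star < 0 or k_e < 0:
        raise ValueError("rate constants must be non-negative")
    if t_exposure <= 0 or t_elim < 0:
        raise ValueError("durations must be positive")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(0) if rng is None else rng
    cd_a_true = uptake_burden(k_u_star, k_e, t_exposure)
    cd_e_true = elimination_burden(cd_a_true, k_e, t_elim)
    rows = []
    for i in range(n_isolates):
        for b in range(beakers_per_isolate):
            cd_a = cd_a_true + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            cd_e = cd_e_true + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {
                    "isolate": f"{clade[:4]}_{i + 1}",
                    "clade": clade,
                    "beaker": f"b{b + 1}",
                    "cd_a": cd_a,
                    "cd_e": cd_e,
                    "t_exposure": t_exposure,
                    "t_elim": t_elim,
                    "dry_weight": 1.0,
                }
            )
    return pd.DataFrame(rows)


def simulate_lifetable(
    schedule,
    replicates: int,
    noise: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Daily offspring counts per replicate over the observation window.

    With noise=False the schedule is emitted verbatim; otherwise daily
    counts are Poisson around the schedule means.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size < 1:
        raise ValueError("need at least one day")
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    for r in range(replicates):
        if noise:
            counts = rng.poisson(schedule)
        else:
            counts = schedule.astype(int)
        for day, c in enumerate(counts, start=1):
            rows.append({"replicate": r + 1, "day": day, "offspring": int(c)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end driver + I/O
# ---------------------------------------------------------------------------


@dataclass
class SimulationOutputs:
    config: SimulationConfig
    reference: ReferenceGenome
    annotation: RegionAnnotation
    masks: Masks
    truth: TruthSet
    evidence: pd.DataFrame
    window_depths: pd.DataFrame
    meta: pd.DataFrame


def subline_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Analytic per-subline metadata: T, n_i and per-base n_{b,i}."""
    at = (1.0 - config.gc_content) / 2.0
    gc = config.gc_content / 2.0
    return pd.DataFrame(
        {
            "subline_id": config.subline_ids,
            "condition": config.condition,
            "generations": config.generations,
            "n_sites": config.n_sites,
            "n_A": config.n_sites * at,
            "n_C": config.n_sites * gc,
            "n_G": config.n_sites * gc,
            "n_T": config.n_sites * at,
        }
    )


def run_simulation(config: SimulationConfig) -> SimulationOutputs:
    """Run every stage with a single seeded generator (deterministic)."""
    rng = np.random.default_rng(config.seed)
    ref, ann = generate_reference(config, rng)
    masks = generate_masks(ref, config, rng)
    snm_truth = plant_snms(ref, ann, config, rng, masks)
    cnv_truth = plant_cnvs(ref, config, rng)
    truth = TruthSet(snm_truth.snms, cnv_truth.cnvs)
    evidence = emit_evidence(ref, truth, config, rng, masks)
    window_depths = emit_window_depths(ref, truth, config, rng)
    meta = subline_metadata(config)
    return SimulationOutputs(config, ref, ann, masks, truth, evidence, window_depths, meta)


def write_outputs(out: SimulationOutputs, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out.reference.write_fasta(outdir / "reference.fasta")
    out.annotation.write_bed(outdir / "regions.bed")
    out.masks.write(outdir / "indel_mask.bed", outdir / "multimap_mask.bed")
    out.truth.snms.to_csv(outdir / "snm_truth.tsv", sep="\t", index=False)
    with open(outdir / "cnv_truth.bed", "w") as fh:
        for rec in out.truth.cnvs.itertuples(index=False):
            fh.write(
                f"{rec.scaffold}\t{rec.start}\t{rec.end}\t"
                f"{rec.subline_id}:{rec.copy_state}\n"
            )
    out.evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    out.window_depths.to_csv(outdir / "window_depth.tsv", sep="\t", index=False)
    out.meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    save_config(out.config, outdir / "config.yaml")


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Flat key/value YAML; per-class rates under rate_* keys."""
    data = {
        k: v
        for k, v in config.__dict__.items()
        if k != "class_rates"
    }
    for cls, key in CLASS_CONFIG_KEYS.items():
        data[key] = float(config.class_rates[cls])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    rates = {}
    for cls, key in CLASS_CONFIG_KEYS.items():
        if key in data:
            rates[cls] = float(data.pop(key))
    config = SimulationConfig(**data)
    if rates:
        full = dict(config.class_rates)
        full.update(rates)
        config = replace(config, class_rates=full)
    return config
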