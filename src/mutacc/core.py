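"""Shared vocabulary for the mutation-accumulation pipeline.

Nucleotide alphabets, the six strand-collapsed single-nucleotide mutation
(SNM) classes, and the genomic region labels with their precedence order.
Coordinates are 0-based, half-open everywhere; BED files are written in
their native convention.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Six strand-collapsed SNM classes, named ancestral-pair -> derived-pair.
SNM_CLASSES = (
    "A:T->G:C",
    "A:T->C:G",
    "A:T->T:A",
    "G:C->A:T",
    "G:C->T:A",
    "G:C->C:G",
)
TRANSITIONS = frozenset({"A:T->G:C", "G:C->A:T"})
TRANSVERSIONS = frozenset(set(SNM_CLASSES) - TRANSITIONS)
# Directionality for the GC->AT mutation bias: AT-gaining over GC-gaining.
AT_GAINING = frozenset({"G:C->A:T", "G:C->T:A"})
GC_GAINING = frozenset({"A:T->G:C", "A:T->C:G"})

# Region labels; precedence resolves overlapping annotation (most specific
# label wins).  Listed low -> high so painting in order gives the resolution.
REGION_PRECEDENCE = (
    "intergenic",
    "promoter",
    "intron",
    "utr3",
    "exon",
    "splice_junction",
)
REGION_INDEX = {r: i for i, r in enumerate(REGION_PRECEDENCE)}


def base_pair(base: str) -> str:
    """Strand-collapsed ancestral pair ('A:T' or 'G:C') of a base."""
    if base in "AT":
        return "A:T"
    if base in "GC":
        return "G:C"
    raise ValueError(f"not a nucleotide: {base!r}")


def classify_snm(ancestral: str, derived: str) -> str:
    """Assign one of the six SNM classes to an ancestral->derived base change.

    The change is collapsed onto the A or G strand so that e.g. T->C and
    A->G are both 'A:T->G:C'.
    """
    if ancestral not in BASES or derived not in BASES:
        raise ValueError(f"invalid alleles {ancestral!r}->{derived!r}")
    if ancestral == derived:
        raise ValueError("ancestral and derived alleles are identical")
    a, d = ancestral, derived
    if a in "TC":  # collapse to the A/G strand
        a, d = COMPLEMENT[a], COMPLEMENT[d]
    if a == "A":
        return {"G": "A:T->G:C", "C": "A:T->C:G", "T": "A:T->T:A"}[d]
    return {"A": "G:C->A:T", "T": "G:C->T:A", "C": "G:C->C:G"}[d]


def class_origin_bases(snm_class: str) -> tuple[str, str]:
    """The two ancestral bases at which a class can arise."""
    return ("A", "T") if snm_class.startswith("A:T") else ("G", "C")


def seq_to_array(seq: str) -> np.ndarray:
    """Nucleotide string -> uint8 array of indices into BASES."""
    lut = np.full(128, 255, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def array_to_seq(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)
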