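"""Upstream-sequence extraction and cis-element consensus scanning.

Elements are IUPAC consensus strings from an editable catalog (the shipped
defaults approximate commonly cited hormone- and stress-responsive motifs;
any published scan using a proprietary pattern set will differ per element).
Matching is exact IUPAC containment, overlaps allowed, both strands optional.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CATEGORIES = {"hormone", "stress_defense", "enhancer"}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CisElement:
    name: str
    consensus: str
    category: str

    def __post_init__(self):
        if not self.consensus:
            raise ValueError(f"element {self.name!r}: empty consensus")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(
                f"element {self.name!r}: illegal IUPAC letters {sorted(bad)}"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"element {self.name!r}: unknown category")


@dataclass(frozen=True)
class ElementHit:
    gene: Optional[str]
    element: str
    position: int  # 1-based leftmost base of the match, + strand coordinates
    strand: str


def default_elements() -> list[CisElement]:
    path = Path(importlib.resources.files("gstfam") / "data" / "cis_elements.tsv")
    return read_elements(path)


def read_elements(path) -> list[CisElement]:
    df = pd.read_csv(path, sep="\t")
    return [
        CisElement(row["name"], row["consensus"].upper(), row["category"])
        for _, row in df.iterrows()
    ]


def extract_upstream(genome, features, length: int, gene_id: str) -> str:
    """``length`` bases 5' of the CDS start, strand-aware, clipped at edges."""
    if length <= 0:
        raise ValueError("upstream window length must be positive")
    gene = features.gene(gene_id)  # KeyError if absent
    contig = genome.get(gene.seqid)
    if gene.strand == "+":
        start = max(1, gene.start - length)
        window = contig[start - 1: gene.start - 1]
    elif gene.strand == "-":
        end = min(len(contig), gene.end + length)
        window = reverse_complement(contig[gene.end: end])
    else:
        raise ValueError(f"gene {gene_id!r} has no usable strand")
    if len(window) < length:
        logger.warning(
            "gene %s: upstream window clipped to %d bp at contig edge",
            gene_id, len(window),
        )
    return window


def _iupac_match(seq: str, pos: int, consensus: str) -> bool:
    for off, letter in enumerate(consensus):
        if seq[pos + off] not in IUPAC[letter]:
            return False
    return True


def scan_elements(
    seq: str,
    elements: Sequence[CisElement],
    both_strands: bool = True,
    gene: Optional[str] = None,
) -> list[ElementHit]:
    """All (overlapping) IUPAC matches, ordered by position then strand.

    Minus-strand hits are reported at their leftmost + strand coordinate.
    """
    seq = seq.upper()
    hits = []
    for element in elements:
        cons = element.consensus.upper()
        m = len(cons)
        for pos in range(len(seq) - m + 1):
            if _iupac_match(seq, pos, cons):
                hits.append(ElementHit(gene, element.name, pos + 1, "+"))
        if both_strands:
            rc = reverse_complement(seq)
            for pos in range(len(rc) - m + 1):
                if _iupac_match(rc, pos, cons):
                    plus_pos = len(seq) - (pos + m) + 1
                    hits.append(ElementHit(gene, element.name, plus_pos, "-"))
    hits.sort(key=lambda h: (h.position, h.strand, h.element))
    return hits


@dataclass
class ElementCountReport:
    counts: pd.DataFrame  # genes x elements
    row_totals: pd.Series
    col_totals: pd.Series
    category_totals: dict[str, int]


def element_count_matrix(
    upstreams: dict[str, str],
    elements: Sequence[CisElement],
    both_strands: bool = True,
) -> ElementCountReport:
    """Integer hit counts per gene and element, with totals and subtotals."""
    if not upstreams:
        raise ValueError("no upstream sequences supplied")
    names = [e.name for e in elements]
    rows = {}
    for gene, seq in upstreams.items():
        hits = scan_elements(seq, elements, both_strands, gene=gene)
        row = dict.fromkeys(names, 0)
        for h in hits:
            row[h.element] += 1
        rows[gene] = row
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    counts = counts.loc[list(upstreams)]
    by_cat: dict[str, int] = {}
    for e in elements:
        by_cat[e.category] = by_cat.get(e.category, 0) + int(counts[e.name].sum())
    return ElementCountReport(
        counts=counts,
        row_totals=counts.sum(axis=1),
        col_totals=counts.sum(axis=0),
        category_totals=by_cat,
    )
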