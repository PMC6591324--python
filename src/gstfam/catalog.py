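"""Family catalog construction and annotation.

Gene records, candidate screening against labeled references,
physicochemical annotation (molecular weight, isoelectric point), per-family
summaries, and exon/intron structure comparison.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import align

logger = logging.getLogger(__name__)

#: Gene-name prefix -> class label, longest prefixes matched first.
CLASS_PREFIXES = (
    ("CaGSTU", "tau"),
    ("CaGSTF", "phi"),
    ("CaGSTT", "theta"),
    ("CaGSTZ", "zeta"),
    ("CaGSTL", "lambda"),
    ("CaEF1B", "EF1Bgamma"),
    ("CaDHAR", "DHAR"),
    ("CaTCHQD", "TCHQD"),
    ("CaMGST", "MGST"),
    ("CaGHR", "GHR"),
)

CLASS_LABELS = frozenset(label for _, label in CLASS_PREFIXES)

#: Default locus-id pattern; the 2-digit field is the chromosome ("00" -> 0).
LOCUS_PATTERN = r"Capana(\d{2})g\d{6}"

#: Average residue masses (Da) for the 20 standard amino acids.
RESIDUE_MASSES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: pKa values used by the isoelectric-point solver.
PKA_NTERM = 7.5
PKA_CTERM = 3.55
PKA_SIDE_CHAINS = {
    "D": 4.05, "E": 4.45, "H": 5.98,
    "C": 9.0, "Y": 10.0, "K": 10.0, "R": 12.0,
}
# H, K, R titrate as bases; D, E, C, Y as acids.
_POSITIVE = {"H", "K", "R"}
_NEGATIVE = {"D", "E", "C", "Y"}


def class_from_name(name: str) -> str:
    """Infer the family class from a gene-name prefix."""
    for prefix, label in CLASS_PREFIXES:
        if name.startswith(prefix):
            return label
    raise ValueError(f"cannot infer class from gene name {name!r}")


@dataclass
class GeneRecord:
    """One catalog row: a placed gene with its class and annotations."""

    name: str
    locus_id: str
    cds_start: int
    cds_end: int
    strand: str
    class_label: str
    chromosome: Optional[int] = None
    gene_len_bp: Optional[int] = None
    protein_len_aa: Optional[int] = None
    mw_kda: Optional[float] = None
    pi: Optional[float] = None
    localization: Optional[str] = None
    exon_count: Optional[int] = None
    protein_id: Optional[str] = None

    def __post_init__(self):
        if self.cds_end < self.cds_start:
            raise ValueError(
                f"{self.name}: cds_end {self.cds_end} < cds_start {self.cds_start}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.name}: strand must be '+' or '-'")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"{self.name}: unknown class {self.class_label!r}")
        if self.chromosome is None:
            try:
                self.chromosome = chromosome_of(self.locus_id)
            except ValueError:
                pass

    @property
    def span_bp(self) -> int:
        return gene_length(self.cds_start, self.cds_end)


@dataclass
class CatalogTable:
    """Ordered collection of gene records with unique names."""

    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self):
        if not self.records:
            raise ValueError("catalog has no records")
        seen = set()
        for rec in self.records:
            if rec.name in seen:
                raise ValueError(f"duplicate gene name {rec.name!r}")
            seen.add(rec.name)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, name: str) -> GeneRecord:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(name)


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline-wide thresholds; the seed is recorded in every report."""

    evalue_threshold: float = 1e-10
    identity_threshold_pct: float = 80.0
    tandem_window_bp: int = 100_000
    lambda_subst: float = 1.5e-8  # substitutions/site/year
    upstream_len_bp: int = 1000
    bootstrap_reps: int = 1000
    rng_seed: int = 0

    def __post_init__(self):
        for name in (
            "evalue_threshold",
            "identity_threshold_pct",
            "tandem_window_bp",
            "lambda_subst",
            "upstream_len_bp",
            "bootstrap_reps",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def gene_length(cds_start: int, cds_end: int) -> int:
    """Length in bp of a 1-based inclusive span."""
    if cds_end < cds_start:
        raise ValueError(f"reversed coordinates: {cds_start} > {cds_end}")
    return cds_end - cds_start + 1


def chromosome_of(locus_id: str, pattern: str = LOCUS_PATTERN) -> int:
    """Chromosome number parsed from a locus identifier ("00" -> 0)."""
    m = re.fullmatch(pattern, locus_id)
    if m is None:
        raise ValueError(f"locus id {locus_id!r} does not match {pattern!r}")
    return int(m.group(1))


def _check_residues(seq: str) -> str:
    if not seq:
        raise ValueError("empty protein sequence")
    seq = seq.upper()
    for i, res in enumerate(seq):
        if res not in RESIDUE_MASSES:
            raise ValueError(f"unknown residue {res!r} at position {i + 1}")
    return seq


def molecular_weight(seq: str) -> float:
    """Average molecular weight in kDa (residue masses plus one water)."""
    seq = _check_residues(seq)
    return (sum(RESIDUE_MASSES[r] for r in seq) + WATER_MASS) / 1000.0


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at ``ph`` (termini + ionizable sides)."""
    seq = _check_residues(seq)

    def pos(pka):  # protonated fraction carries +1
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def neg(pka):  # deprotonated fraction carries -1
        return -1.0 / (1.0 + 10.0 ** (pka - ph))

    charge = pos(PKA_NTERM) + neg(PKA_CTERM)
    for res in seq:
        if res in _POSITIVE:
            charge += pos(PKA_SIDE_CHAINS[res])
        elif res in _NEGATIVE:
            charge += neg(PKA_SIDE_CHAINS[res])
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    seq = _check_residues(seq)
    lo, hi = 0.0, 14.0
    # bisect the sign change to interval 1e-7: tighter than the charge
    # tolerance so near-flat titration curves still localize the true zero
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    if abs(net_charge(seq, mid)) > tol:
        raise ArithmeticError("net charge did not converge to zero")
    return mid


@dataclass(frozen=True)
class CandidateHit:
    candidate_id: str
    best_query_id: str
    score: float
    evalue: float


def screen_candidates(proteome, queries, cfg: AnalysisConfig) -> list[CandidateHit]:
    """Local-alignment screen of a proteome against family queries.

    Keeps proteins whose best local alignment against any query has
    ``E <= cfg.evalue_threshold``; a stand-in for a database search at the
    same threshold semantics.
    """
    if not len(queries.entries):
        raise ValueError("empty query set")
    if not len(proteome.entries):
        raise ValueError("empty proteome")
    hits = []
    for cand_id, _, cand_seq in proteome.entries:
        best = None
        for query_id, _, query_seq in queries.entries:
            aln = align.local_align(cand_seq, query_seq)
            if aln.score <= 0:
                continue
            params = align.SignificanceParams(
                search_space=float(len(cand_seq) * len(query_seq))
            )
            e = align.evalue(aln.score, params)
            if best is None or e < best.evalue:
                best = CandidateHit(cand_id, query_id, aln.score, e)
        if best is not None and best.evalue <= cfg.evalue_threshold:
            hits.append(best)
    return hits


def classify_member(protein: str, references) -> tuple[str, str, float]:
    """Assign the class of the best-scoring labeled reference.

    ``references`` is a SeqCollection whose descriptions carry class labels.
    Returns ``(class_label, reference_id, identity_pct)``. Ties break by
    higher identity, then lexicographic reference id.
    """
    if not len(references.entries):
        raise ValueError("no references")
    scored = []
    for ref_id, desc, ref_seq in references.entries:
        label = desc.strip().split()[0] if desc.strip() else None
        if label not in CLASS_LABELS:
            raise ValueError(f"reference {ref_id!r} lacks a class label")
        aln = align.global_align(protein, ref_seq)
        ident = align.percent_identity(aln)
        scored.append((-aln.score, -ident, ref_id, label))
    scored.sort()
    if len(scored) > 1 and scored[0][:2] == scored[1][:2]:
        logger.warning(
            "classification tie between %s and %s; keeping %s",
            scored[0][2], scored[1][2], scored[0][2],
        )
    _, neg_ident, ref_id, label = scored[0]
    return label, ref_id, -neg_ident


def _stats(values: Sequence[float], names: Sequence[str]) -> dict:
    pairs = sorted(zip(values, names))
    return {
        "min": pairs[0][0],
        "min_name": pairs[0][1],
        "max": pairs[-1][0],
        "max_name": pairs[-1][1],
        "mean": sum(values) / len(values),
    }


def summarize_family(catalog: CatalogTable) -> dict:
    """Counts per class and chromosome plus min/max/mean of the numeric columns.

    Gene-span statistics are recomputed from the printed coordinates;
    protein length, MW and pI come from the catalog columns as printed.
    """
    recs = list(catalog)
    names = [r.name for r in recs]
    class_counts: dict[str, int] = {}
    chrom_counts: dict[int, int] = {}
    for r in recs:
        class_counts[r.class_label] = class_counts.get(r.class_label, 0) + 1
        chrom_counts[r.chromosome] = chrom_counts.get(r.chromosome, 0) + 1
    n = len(recs)
    summary = {
        "n_records": n,
        "class_counts": dict(sorted(class_counts.items())),
        "chromosome_counts": dict(sorted(chrom_counts.items())),
        "chromosome_pct": {
            c: round(100.0 * k / n, 1) for c, k in sorted(chrom_counts.items())
        },
        "gene_span_bp": _stats([r.span_bp for r in recs], names),
    }
    for attr, key in (
        ("protein_len_aa", "protein_len_aa"),
        ("mw_kda", "mw_kda"),
        ("pi", "pi"),
    ):
        vals = [getattr(r, attr) for r in recs]
        if all(v is not None for v in vals):
            summary[key] = _stats(vals, names)
    return summary


@dataclass(frozen=True)
class GeneStructure:
    """Exon layout of one gene; introns are the gaps between exons."""

    gene_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.gene_id}: empty exon list")
        prev_end = None
        for start, end in self.exons:
            if end < start:
                raise ValueError(f"{self.gene_id}: exon end < start")
            if prev_end is not None and start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (_, end), (start, _) in zip(self.exons, self.exons[1:]):
            out.append((end + 1, start - 1))
        return tuple(out)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1


@dataclass(frozen=True)
class StructureDelta:
    exon_delta: int
    intron_delta: int
    classification: str  # same_count | intron_gain | intron_loss


def compare_structures(a: GeneStructure, b: GeneStructure) -> StructureDelta:
    """Intron gain/loss classification oriented from ``a`` to ``b``."""
    intron_delta = b.intron_count - a.intron_count
    if intron_delta > 0:
        kind = "intron_gain"
    elif intron_delta < 0:
        kind = "intron_loss"
    else:
        kind = "same_count"
    return StructureDelta(b.exon_count - a.exon_count, intron_delta, kind)


def build_catalog(rows: Iterable[dict]) -> CatalogTable:
    """Assemble a CatalogTable from parsed row dicts (class inferred if absent)."""
    records = []
    for row in rows:
        row = dict(row)
        if "class_label" not in row or not row["class_label"]:
            row["class_label"] = class_from_name(row["name"])
        records.append(GeneRecord(**row))
    return CatalogTable(records)
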