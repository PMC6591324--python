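"""Duplicate-pair detection, tandem/segmental classification and dating.

dN/dS follows Nei & Gojobori (1986): per-position synonymous site fractions,
equal-weight averaging over all minimal mutational pathways between differing
codons, Jukes-Cantor correction of the proportions. Mutational paths through
stop codons are excluded. Divergence time is T = dS / (2 * lambda).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Optional

from . import align
from .catalog import AnalysisConfig, CatalogTable, GeneRecord

NUCLEOTIDES = "ACGT"

#: Standard genetic code.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOP_CODONS = {c for c, aa in CODON_TABLE.items() if aa == "*"}
SENSE_CODONS = sorted(set(CODON_TABLE) - STOP_CODONS)


@dataclass
class DuplicatePair:
    """A homologous gene pair with divergence estimates."""

    gene_a: str
    gene_b: str
    identity_pct: float
    mode: Optional[str] = None  # tandem | segmental
    dn: Optional[float] = None
    ds: Optional[float] = None
    omega: Optional[float] = None  # None when ds == 0 (undefined)
    t_mya: Optional[float] = None

    @property
    def selection_call(self) -> Optional[str]:
        if self.omega is None:
            return None
        if self.omega < 1:
            return "purifying"
        if self.omega > 1:
            return "positive"
        return "neutral"


@dataclass(frozen=True)
class GeneCluster:
    chromosome: int
    members: tuple[str, ...]
    span_bp: int

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least 2 members")


def _codons(seq: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    for i, codon in enumerate(codons):
        if codon not in CODON_TABLE:
            raise ValueError(f"invalid codon {codon!r} at codon position {i + 1}")
        if codon in STOP_CODONS and i < len(codons) - 1:
            raise ValueError(f"internal stop codon {codon} at codon position {i + 1}")
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return codons


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Each position contributes 1/3 per possible single-nucleotide change;
    changes producing a stop codon are dropped from both tallies.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = CODON_TABLE[codon]
    syn = nonsyn = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            if CODON_TABLE[mutant] == aa:
                syn += 1.0 / 3.0
            else:
                nonsyn += 1.0 / 3.0
    return syn, nonsyn


def count_sites(seq: str) -> tuple[float, float]:
    """Total (S, N) over a CDS (stop-codon mutational paths excluded)."""
    codons = _codons(seq)
    if not codons:
        raise ValueError("empty CDS")
    s_total = n_total = 0.0
    for codon in codons:
        s, n = codon_sites(codon)
        s_total += s
        n_total += n
    return s_total, n_total


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over stop-free minimal pathways."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        current = codon_a
        syn = nonsyn = 0
        valid = True
        for pos in order:
            mutant = current[:pos] + codon_b[pos] + current[pos + 1:]
            if mutant in STOP_CODONS:
                valid = False
                break
            if CODON_TABLE[mutant] == CODON_TABLE[current]:
                syn += 1
            else:
                nonsyn += 1
            current = mutant
        if valid:
            paths.append((syn, nonsyn))
    if not paths:
        # All minimal pathways pass through a stop; fall back to including them.
        for order in itertools.permutations(diffs):
            current = codon_a
            syn = nonsyn = 0
            for pos in order:
                mutant = current[:pos] + codon_b[pos] + current[pos + 1:]
                if CODON_TABLE[mutant] == CODON_TABLE[current]:
                    syn += 1
                else:
                    nonsyn += 1
                current = mutant
            paths.append((syn, nonsyn))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance from an observed proportion of differences."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise ValueError(f"proportion {p:.4f} >= 3/4: distance saturated")
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class NeiGojoboriResult:
    dn: float
    ds: float
    omega: Optional[float]
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


def nei_gojobori(cds_a: str, cds_b: str) -> NeiGojoboriResult:
    """Nei-Gojobori dN/dS between two codon-aligned CDS.

    Codon pairs containing an alignment gap are stripped. Site counts are
    averaged over the two sequences; proportions are Jukes-Cantor corrected.
    ``omega`` is None when ds == 0.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS must have equal length")
    if len(cds_a) % 3 != 0:
        raise ValueError("aligned CDS length is not a multiple of 3")
    kept_a, kept_b = [], []
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3].upper(), cds_b[i:i + 3].upper()
        if "-" in ca or "-" in cb:
            continue
        kept_a.append(ca)
        kept_b.append(cb)
    if kept_a and kept_a[-1] in STOP_CODONS and kept_b[-1] in STOP_CODONS:
        kept_a.pop()
        kept_b.pop()
    for seq_codons, tag in ((kept_a, "a"), (kept_b, "b")):
        for i, codon in enumerate(seq_codons):
            if codon not in CODON_TABLE:
                raise ValueError(f"sequence {tag}: invalid codon {codon!r}")
            if codon in STOP_CODONS:
                raise ValueError(
                    f"sequence {tag}: internal stop codon at codon {i + 1}"
                )
    codons_a, codons_b = kept_a, kept_b
    if not codons_a:
        raise ValueError("no comparable codons")
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        s_a += sa; n_a += na; s_b += sb; n_b += nb
        d_s, d_n = _pathway_counts(ca, cb)
        sd += d_s
        nd += d_n
    s_sites = 0.5 * (s_a + s_b)
    n_sites = 0.5 * (n_a + n_b)
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    omega = dn / ds if ds > 0 else None
    return NeiGojoboriResult(dn, ds, omega, s_sites, n_sites, sd, nd)


def divergence_time(ds: float, lambda_subst: float = 1.5e-8) -> float:
    """Divergence time in million years: T = dS / (2 * lambda)."""
    if ds < 0:
        raise ValueError("ds must be non-negative")
    if lambda_subst <= 0:
        raise ValueError("lambda must be positive")
    return ds / (2.0 * lambda_subst) / 1e6


def find_duplicate_pairs(
    catalog: CatalogTable,
    proteins,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> list[DuplicatePair]:
    """All unordered catalog pairs passing the E-value and identity screen.

    A gene may appear in more than one pair. Every catalog record must have a
    protein in ``proteins`` (keyed by gene name).
    """
    ids = set(proteins.ids())
    missing = [r.name for r in catalog if r.name not in ids]
    if missing:
        raise ValueError(f"missing protein sequences for {missing}")
    names = [r.name for r in catalog]
    pairs = []
    for i, name_a in enumerate(names):
        seq_a = proteins.get(name_a)
        for name_b in names[i + 1:]:
            seq_b = proteins.get(name_b)
            local = align.local_align(seq_a, seq_b)
            if local.score <= 0:
                continue
            params = align.SignificanceParams(
                search_space=float(len(seq_a) * len(seq_b))
            )
            if align.evalue(local.score, params) > cfg.evalue_threshold:
                continue
            ident = align.percent_identity(align.global_align(seq_a, seq_b))
            if ident >= cfg.identity_threshold_pct:
                pairs.append(DuplicatePair(name_a, name_b, ident))
    return pairs


def classify_pair(
    rec_a: GeneRecord, rec_b: GeneRecord, window: int = 100_000
) -> str:
    """"tandem" iff same chromosome and inter-gene gap <= window (inclusive)."""
    if rec_a.chromosome != rec_b.chromosome:
        return "segmental"
    first, second = sorted((rec_a, rec_b), key=lambda r: r.cds_start)
    distance = max(0, second.cds_start - first.cds_end)
    return "tandem" if distance <= window else "segmental"


def annotate_pairs(
    pairs: list[DuplicatePair],
    catalog: CatalogTable,
    cds,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> list[DuplicatePair]:
    """Fill in mode, dN/dS and divergence time for screened pairs.

    CDS pairs are codon-aligned by globally aligning the proteins and
    threading codons through the protein alignment.
    """
    out = []
    for pair in pairs:
        rec_a, rec_b = catalog.get(pair.gene_a), catalog.get(pair.gene_b)
        mode = classify_pair(rec_a, rec_b, cfg.tandem_window_bp)
        aligned_a, aligned_b = codon_align(cds.get(pair.gene_a), cds.get(pair.gene_b))
        ng = nei_gojobori(aligned_a, aligned_b)
        out.append(
            replace(
                pair,
                mode=mode,
                dn=ng.dn,
                ds=ng.ds,
                omega=ng.omega,
                t_mya=divergence_time(ng.ds, cfg.lambda_subst),
            )
        )
    return out


def codon_align(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Codon-aware alignment of two CDS via their protein translation."""
    prot_a = translate(cds_a)
    prot_b = translate(cds_b)
    aln = align.global_align(prot_a, prot_b)
    return (
        _thread_codons(aln.aligned_a, cds_a),
        _thread_codons(aln.aligned_b, cds_b),
    )


def _thread_codons(aligned_protein: str, cds: str) -> str:
    cds = cds.upper().replace("U", "T")
    out = []
    pos = 0
    for aa in aligned_protein:
        if aa == "-":
            out.append("---")
        else:
            out.append(cds[pos:pos + 3])
            pos += 3
    return "".join(out)


def translate(cds: str) -> str:
    """Translate a CDS (trailing stop allowed, internal stops rejected)."""
    return "".join(CODON_TABLE[c] for c in _codons(cds))


def find_clusters(catalog: CatalogTable, window: int = 100_000) -> list[GeneCluster]:
    """Maximal single-linkage runs of >= 2 genes with gaps <= window."""
    by_chrom: dict[int, list[GeneRecord]] = {}
    for rec in catalog:
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    clusters = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.cds_start, r.cds_end))
        run = [recs[0]]
        for prev, cur in zip(recs, recs[1:]):
            gap = max(0, cur.cds_start - prev.cds_end)
            if gap <= window:
                run.append(cur)
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(chrom, run))
                run = [cur]
        if len(run) >= 2:
            clusters.append(_make_cluster(chrom, run))
    return clusters


def _make_cluster(chrom: int, run: list[GeneRecord]) -> GeneCluster:
    span = max(r.cds_end for r in run) - min(r.cds_start for r in run) + 1
    return GeneCluster(chrom, tuple(r.name for r in run), span)
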