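"""Seeded two-species gene-family simulator with serialized ground truth.

Every pipeline stage has a planted-truth counterpart here: post-split
birth-death gain/loss from a known ancestral count (for reconciliation),
codon evolution at controlled omega and dS (for the substitution estimator),
tandem/segmental placements (for duplicate classification), promoter windows
with planted element counts (for the scanner), and expression tiers plus
stress responses (for the expression layer). Outputs are byte-identical
across runs at a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import expression as expr_mod
from . import io_formats, promoter
from .catalog import CatalogTable, GeneRecord
from .duplication import CODON_TABLE, SENSE_CODONS, STOP_CODONS, translate

NUCLEOTIDES = "ACGT"


# ---------------------------------------------------------------------------
# birth-death family simulation

@dataclass
class FamilyTruth:
    """Per-unit survivor counts and the derived gain/loss tallies."""

    ancestral_count: int
    species: tuple[str, str]
    seed: int
    unit_survivors: list[dict] = field(default_factory=list)

    @property
    def observable_units(self) -> int:
        return sum(1 for u in self.unit_survivors if sum(u.values()) > 0)

    def extant(self, sp: str) -> int:
        return sum(u[sp] for u in self.unit_survivors)

    def gains(self, sp: str) -> int:
        return sum(max(0, u[sp] - 1) for u in self.unit_survivors)

    def losses_observable(self, sp: str) -> int:
        """Losses countable on the emitted tree (units extinct in ``sp`` only)."""
        return sum(
            1 for u in self.unit_survivors if u[sp] == 0 and sum(u.values()) > 0
        )

    def losses_total(self, sp: str) -> int:
        return sum(1 for u in self.unit_survivors if u[sp] == 0)

    def check_identity(self):
        for sp in self.species:
            assert self.extant(sp) == (
                self.ancestral_count - self.losses_total(sp) + self.gains(sp)
            )

    def as_dict(self) -> dict:
        return {
            "ancestral_count": self.ancestral_count,
            "species": list(self.species),
            "seed": self.seed,
            "unit_survivors": self.unit_survivors,
            "observable_units": self.observable_units,
            "per_species": {
                sp: {
                    "extant": self.extant(sp),
                    "gains": self.gains(sp),
                    "losses_observable": self.losses_observable(sp),
                    "losses_total": self.losses_total(sp),
                }
                for sp in self.species
            },
        }


def _bd_subtree(gain_rate, loss_rate, t_total, rng, leaf_namer):
    """Pruned birth-death genealogy of one gene copy over ``t_total``.

    Returns (TreeNode or None, n_survivors); extinct subtrees are pruned and
    unary nodes suppressed.
    """
    total = gain_rate + loss_rate

    def evolve(t_left):
        if total > 0:
            wait = rng.exponential(1.0 / total)
        else:
            wait = math.inf
        if wait >= t_left:
            return TreeNode(name=leaf_namer(), length=t_left), 1
        if rng.random() < gain_rate / total:
            left, n_left = evolve(t_left - wait)
            right, n_right = evolve(t_left - wait)
            n = n_left + n_right
            if n == 0:
                return None, 0
            if left is None or right is None:
                child = left if left is not None else right
                child.length += wait
                return child, n
            node = TreeNode(length=wait)
            node.extend([left, right])
            return node, n
        return None, 0  # death

    return evolve(t_total)


def simulate_family(
    ancestral_count: int,
    gain_rate: float,
    loss_rate: float,
    split_age: float = 1.0,
    seed: int = 0,
    species: tuple[str, str] = ("P", "T"),
    cap: int = 10_000,
) -> tuple[Optional[TreeNode], FamilyTruth]:
    """Evolve ``ancestral_count`` genes post-split in two lineages.

    Each ancestral gene evolves independently by birth-death in each lineage;
    survivors become ``<species>|g<unit>_<k>`` leaves. The emitted tree joins
    unit subtrees under ancestral-duplication backbone nodes (a both-species
    unit, when present, sits deepest so species-overlap reconciliation
    recovers every unit). Returns (tree or None if everything died, truth).
    """
    if ancestral_count < 1:
        raise ValueError("ancestral_count must be >= 1")
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    expected = ancestral_count * math.exp((gain_rate - loss_rate) * split_age)
    if expected > cap:
        raise ValueError(
            f"expected family size {expected:.0f} exceeds cap {cap}; lower the rates"
        )
    rng = np.random.default_rng(seed)
    truth = FamilyTruth(ancestral_count, species, seed)
    unit_trees = []
    for unit in range(1, ancestral_count + 1):
        survivors = {}
        subtrees = {}
        for sp in species:
            counter = [0]

            def namer(sp=sp, counter=counter):
                counter[0] += 1
                return f"{sp}|g{unit}_{counter[0]}"

            subtree, n = _bd_subtree(gain_rate, loss_rate, split_age, rng, namer)
            survivors[sp] = n
            subtrees[sp] = subtree
        truth.unit_survivors.append(survivors)
        alive = [subtrees[sp] for sp in species if subtrees[sp] is not None]
        if len(alive) == 2:
            node = TreeNode(length=0.1)  # speciation node of this unit
            node.extend(alive)
            unit_trees.append((True, node))
        elif len(alive) == 1:
            unit_trees.append((False, alive[0]))
    truth.check_identity()
    if not unit_trees:
        return None, truth
    # put a both-species unit deepest so backbone joins stay "ancestral"
    unit_trees.sort(key=lambda t: not t[0])
    core = unit_trees[0][1]
    for _, subtree in unit_trees[1:]:
        joined = TreeNode(length=0.1)
        joined.extend([core, subtree])
        core = joined
    core.length = None
    return core, truth


# ---------------------------------------------------------------------------
# codon evolution

def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random CDS of sense codons starting with ATG (no stops)."""
    if n_codons < 2:
        raise ValueError("need at least 2 codons")
    body = rng.choice([c for c in SENSE_CODONS if c != "ATG"], size=n_codons - 1)
    return "ATG" + "".join(body)


def evolve_cds(
    ancestor: str,
    omega: float,
    expected_ds: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Descendant CDS after mutation-acceptance codon evolution.

    Proposals arrive at one per site per unit of scaled time ``expected_ds``
    (so accepted synonymous changes accumulate at ~``expected_ds`` per
    synonymous site); synonymous proposals are always accepted, nonsynonymous
    with probability ``omega``, stop-creating proposals never.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if expected_ds < 0 or omega < 0:
        raise ValueError("omega and expected_ds must be non-negative")
    seq = list(ancestor.upper())
    n = len(seq)
    if n % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    if expected_ds == 0:
        return "".join(seq)
    n_events = rng.poisson(n * expected_ds)
    for _ in range(n_events):
        pos = int(rng.integers(n))
        current = seq[pos]
        alt = NUCLEOTIDES[int(rng.integers(4))]
        if alt == current:
            alt = NUCLEOTIDES[(NUCLEOTIDES.index(current) + 1 + int(rng.integers(3))) % 4]
        codon_start = pos - pos % 3
        old_codon = "".join(seq[codon_start:codon_start + 3])
        new_codon = old_codon[: pos - codon_start] + alt + old_codon[pos - codon_start + 1:]
        if new_codon in STOP_CODONS:
            continue
        if CODON_TABLE[new_codon] == CODON_TABLE[old_codon]:
            seq[pos] = alt
        elif rng.random() < omega:
            seq[pos] = alt
    return "".join(seq)


# ---------------------------------------------------------------------------
# full dataset simulation

@dataclass(frozen=True)
class DatasetParams:
    n_tandem_pairs: int = 3
    n_segmental_pairs: int = 3
    n_singletons: int = 6
    n_codons: int = 200
    pair_expected_ds: float = 0.06
    pair_omega: float = 0.3
    tandem_gap_bp: tuple[int, int] = (5_000, 50_000)
    segmental_gap_bp: int = 150_000
    upstream_len_bp: int = 1000
    family_ancestral: int = 8
    family_gain_rate: float = 0.3
    family_loss_rate: float = 0.2
    family_split_age: float = 1.0

    @property
    def n_genes(self) -> int:
        return 2 * (self.n_tandem_pairs + self.n_segmental_pairs) + self.n_singletons


@dataclass
class SyntheticDataset:
    params: DatasetParams
    seed: int
    catalog: CatalogTable
    genome: io_formats.SeqCollection
    features: io_formats.FeatureSet
    proteins: io_formats.SeqCollection
    cds: io_formats.SeqCollection
    promoters: dict[str, str]
    expression_tissue: pd.DataFrame
    expression_stress: pd.DataFrame
    gene_tree: Optional[TreeNode]
    truth: dict


def _clean_background(length, elements, rng, max_iter=200):
    """Random DNA with zero IUPAC hits for any catalog element, both strands."""
    seq = list(rng.choice(list(NUCLEOTIDES), size=length))
    for _ in range(max_iter):
        hits = promoter.scan_elements("".join(seq), elements, both_strands=True)
        if not hits:
            return "".join(seq)
        for h in hits:
            width = len(next(e.consensus for e in elements if e.name == h.element))
            for off in range(width):
                seq[h.position - 1 + off] = rng.choice(list(NUCLEOTIDES))
    raise RuntimeError("could not generate an element-free background")


def _plant_elements(background, elements, planted, rng, max_iter=100):
    """Insert ``planted`` (element name -> count) occurrences; verify exactly."""
    by_name = {e.name: e for e in elements}
    want = {name: k for name, k in planted.items() if k > 0}
    for _ in range(max_iter):
        seq = list(background)
        taken: list[tuple[int, int]] = []
        ok = True
        for name in sorted(want):
            cons = by_name[name].consensus
            for _ in range(want[name]):
                placed = False
                for _ in range(200):
                    pos = int(rng.integers(0, len(seq) - len(cons)))
                    # keep one spacer base so planted motifs cannot overlap
                    if all(pos + len(cons) < s or pos > e for s, e in taken):
                        seq[pos:pos + len(cons)] = list(cons)
                        taken.append((pos, pos + len(cons)))
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        got = {}
        for h in promoter.scan_elements("".join(seq), elements, both_strands=True):
            got[h.element] = got.get(h.element, 0) + 1
        if got == want:
            return "".join(seq)
    raise RuntimeError("could not plant element counts exactly")


def simulate_dataset(
    params: DatasetParams = DatasetParams(), seed: int = 0
) -> SyntheticDataset:
    """Generate a fully consistent synthetic dataset with serialized truth."""
    rng = np.random.default_rng(seed)
    elements = promoter.default_elements()
    p = params

    genes = []  # dicts accumulated, then laid out per chromosome
    pair_truth = []
    idx = 1

    def new_gene(cds_seq, pair_id=None):
        nonlocal idx
        gene = {
            "name": f"CaGSTU{900 + idx}",
            "cds": cds_seq,
            "protein": translate(cds_seq),
            "pair": pair_id,
            "strand": "+",
            "n_exons": 1,
        }
        idx += 1
        genes.append(gene)
        return gene

    for k in range(p.n_tandem_pairs):
        ancestor = random_cds(p.n_codons, rng)
        a = new_gene(evolve_cds(ancestor, p.pair_omega, p.pair_expected_ds, rng=rng),
                     pair_id=f"tp{k}")
        b = new_gene(evolve_cds(ancestor, p.pair_omega, p.pair_expected_ds, rng=rng),
                     pair_id=f"tp{k}")
        pair_truth.append(
            {"gene_a": a["name"], "gene_b": b["name"], "mode": "tandem"}
        )
    for k in range(p.n_segmental_pairs):
        ancestor = random_cds(p.n_codons, rng)
        a = new_gene(evolve_cds(ancestor, p.pair_omega, p.pair_expected_ds, rng=rng),
                     pair_id=f"sp{k}")
        b = new_gene(evolve_cds(ancestor, p.pair_omega, p.pair_expected_ds, rng=rng),
                     pair_id=f"sp{k}")
        pair_truth.append(
            {"gene_a": a["name"], "gene_b": b["name"], "mode": "segmental"}
        )
    for _ in range(p.n_singletons):
        new_gene(random_cds(p.n_codons, rng))

    # strand mix and a planted intron-gain pair among the singletons
    singles = [g for g in genes if g["pair"] is None]
    for g in singles[::2]:
        g["strand"] = "-"
    if len(singles) >= 2:
        singles[0]["strand"] = singles[1]["strand"] = "+"
        singles[0]["n_exons"] = 2
        singles[1]["n_exons"] = 3
        structure_truth = {
            "gene_a": singles[0]["name"],
            "gene_b": singles[1]["name"],
            "classification": "intron_gain",
        }
    else:
        structure_truth = None

    # promoters with planted element counts
    element_truth = {}
    for g in genes:
        n_kinds = int(rng.integers(1, 4))
        chosen = rng.choice([e.name for e in elements], size=n_kinds, replace=False)
        planted = {name: int(rng.integers(1, 3)) for name in sorted(chosen)}
        background = _clean_background(p.upstream_len_bp, elements, rng)
        g["promoter"] = _plant_elements(background, elements, planted, rng)
        element_truth[g["name"]] = planted

    # chromosome layout: tandem pairs together, segmental pairs split
    chrom_genes: dict[int, list[dict]] = {}

    def place(chrom, gene):
        chrom_genes.setdefault(chrom, []).append(gene)

    chrom = 1
    for k in range(p.n_tandem_pairs):
        a, b = [g for g in genes if g["pair"] == f"tp{k}"]
        place(chrom, a)
        place(chrom, b)
        chrom += 1
    seg_chroms = []
    for k in range(p.n_segmental_pairs):
        a, b = [g for g in genes if g["pair"] == f"sp{k}"]
        if k % 2 == 0:
            place(chrom, a)
            place(chrom + 1, b)  # cross-chromosome
            seg_chroms.extend([chrom, chrom + 1])
            chrom += 2
        else:
            a["segmental_same_chrom"] = b["segmental_same_chrom"] = True
            place(chrom, a)
            place(chrom, b)  # same chromosome, gap > window
            chrom += 1
    for g in singles:
        place(chrom, g)
        chrom += 1

    contigs = []
    features = []
    records = []
    for chrom_id in sorted(chrom_genes):
        cursor = 1
        parts = []
        seqid = f"chr{chrom_id}"
        for g in chrom_genes[chrom_id]:
            if g.get("segmental_same_chrom") and parts:
                gap = p.segmental_gap_bp + int(rng.integers(0, 20_000))
            elif parts:
                gap = int(rng.integers(*p.tandem_gap_bp))
            else:
                gap = 200
            spacer = "".join(rng.choice(list(NUCLEOTIDES), size=gap))
            parts.append(spacer)
            cursor += gap
            body, exon_spans = _gene_body(g, rng)
            if g["strand"] == "+":
                parts.append(g["promoter"])
                cursor += len(g["promoter"])
                start = cursor
                parts.append(body)
                cursor += len(body)
                end = cursor - 1
            else:
                start = cursor
                parts.append(promoter.reverse_complement(body))
                cursor += len(body)
                end = cursor - 1
                parts.append(promoter.reverse_complement(g["promoter"]))
                cursor += len(g["promoter"])
            g.update(chrom=chrom_id, start=start, end=end, seqid=seqid)
            features.extend(_gene_features(g, exon_spans))
            records.append(
                GeneRecord(
                    name=g["name"],
                    locus_id=f"SYN{chrom_id:02d}g{900 + genes.index(g):06d}",
                    cds_start=start,
                    cds_end=end,
                    strand=g["strand"],
                    class_label="tau",
                    chromosome=chrom_id,
                    protein_len_aa=len(g["protein"]),
                )
            )
        tail = "".join(rng.choice(list(NUCLEOTIDES), size=200))
        parts.append(tail)
        contigs.append((seqid, "", "".join(parts)))

    genome = io_formats.SeqCollection(contigs, alphabet="dna")
    feature_set = io_formats.FeatureSet(features)
    proteins = io_formats.SeqCollection(
        [(g["name"], "tau", g["protein"]) for g in genes], alphabet="protein"
    )
    cds = io_formats.SeqCollection(
        [(g["name"], "", g["cds"]) for g in genes], alphabet="dna"
    )
    catalog = CatalogTable(records)

    # expression: equal-sized tiers, planted stress responders
    tier_means = {"low": 2.0, "medium": 40.0, "high": 800.0}
    names = [g["name"] for g in genes]
    tiers = {}
    for i, name in enumerate(names):
        tiers[name] = ("low", "medium", "high")[i % 3]
    tissue_cols = [f"tissue_{t}" for t in range(1, 7)]
    tissue_rows = {}
    for name in names:
        mu = tier_means[tiers[name]]
        noise = 2.0 ** rng.normal(0.0, 0.1, size=len(tissue_cols))
        tissue_rows[name] = np.round(mu * noise, 3)
    expression_tissue = pd.DataFrame.from_dict(
        tissue_rows, orient="index", columns=tissue_cols
    ).loc[names]

    stress_cols = ["0h", "1h", "3h", "6h", "12h", "24h"]
    responders = {name: (i % 2 == 0) for i, name in enumerate(names)}
    stress_rows = {}
    for name in names:
        base = 10.0
        fold = np.array([1.0, 2.0, 4.0, 8.0, 8.0, 6.0]) if responders[name] else np.ones(6)
        noise = 2.0 ** rng.normal(0.0, 0.05, size=6)
        stress_rows[name] = np.round(base * fold * noise, 3)
    expression_stress = pd.DataFrame.from_dict(
        stress_rows, orient="index", columns=stress_cols
    ).loc[names]

    tree, family_truth = simulate_family(
        p.family_ancestral,
        p.family_gain_rate,
        p.family_loss_rate,
        p.family_split_age,
        seed=seed,
    )

    truth = {
        "seed": seed,
        "params": {
            "n_tandem_pairs": p.n_tandem_pairs,
            "n_segmental_pairs": p.n_segmental_pairs,
            "n_singletons": p.n_singletons,
            "n_codons": p.n_codons,
            "pair_expected_ds": p.pair_expected_ds,
            "pair_omega": p.pair_omega,
        },
        "pairs": pair_truth,
        "structure_pair": structure_truth,
        "elements": element_truth,
        "tiers": tiers,
        "stress_responders": responders,
        "family": family_truth.as_dict(),
        "genes": {
            g["name"]: {
                "chromosome": g["chrom"],
                "start": g["start"],
                "end": g["end"],
                "strand": g["strand"],
            }
            for g in genes
        },
    }

    return SyntheticDataset(
        params=p,
        seed=seed,
        catalog=catalog,
        genome=genome,
        features=feature_set,
        proteins=proteins,
        cds=cds,
        promoters={g["name"]: g["promoter"] for g in genes},
        expression_tissue=expression_tissue,
        expression_stress=expression_stress,
        gene_tree=tree,
        truth=truth,
    )


def _gene_body(gene, rng) -> tuple[str, list[tuple[int, int]]]:
    """Transcript-orientation gene body and exon spans relative to gene start."""
    cds = gene["cds"]
    n_exons = gene["n_exons"]
    if n_exons == 1 or gene["strand"] == "-":
        gene["n_exons"] = 1
        return cds, [(1, len(cds))]
    cut_points = sorted(
        int(x) * 3 for x in rng.choice(
            range(10, len(cds) // 3 - 10), size=n_exons - 1, replace=False
        )
    )
    exon_seqs = []
    prev = 0
    for cut in cut_points:
        exon_seqs.append(cds[prev:cut])
        prev = cut
    exon_seqs.append(cds[prev:])
    body_parts = []
    spans = []
    offset = 0
    for i, exon in enumerate(exon_seqs):
        spans.append((offset + 1, offset + len(exon)))
        body_parts.append(exon)
        offset += len(exon)
        if i < len(exon_seqs) - 1:
            intron = "GT" + "".join(rng.choice(list(NUCLEOTIDES), size=96)) + "AG"
            body_parts.append(intron)
            offset += len(intron)
    return "".join(body_parts), spans


def _gene_features(gene, exon_spans) -> list[io_formats.Feature]:
    start, end, seqid, strand = gene["start"], gene["end"], gene["seqid"], gene["strand"]
    gid = gene["name"]
    feats = [
        io_formats.Feature(seqid, "gstfam_sim", "gene", start, end, strand, ".", gid, None),
        io_formats.Feature(
            seqid, "gstfam_sim", "mRNA", start, end, strand, ".", f"{gid}.t1", gid
        ),
    ]
    for k, (s, e) in enumerate(exon_spans, start=1):
        feats.append(
            io_formats.Feature(
                seqid, "gstfam_sim", "exon", start + s - 1, start + e - 1, strand,
                ".", f"{gid}.e{k}", f"{gid}.t1",
            )
        )
        feats.append(
            io_formats.Feature(
                seqid, "gstfam_sim", "CDS", start + s - 1, start + e - 1, strand,
                "0", f"{gid}.c{k}", f"{gid}.t1",
            )
        )
    return feats


# ---------------------------------------------------------------------------
# emission

def emit_dataset(dataset: SyntheticDataset, out_dir, force: bool = False) -> dict:
    """Write every dataset artifact; returns {relative path: sha256}."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (pass force=True to overwrite)")
    out.mkdir(parents=True, exist_ok=True)

    io_formats.write_fasta(dataset.genome, out / "genome.fna")
    io_formats.write_gff3(dataset.features, out / "genes.gff3")
    io_formats.write_fasta(dataset.proteins, out / "proteins.faa")
    io_formats.write_fasta(dataset.cds, out / "cds.fna")
    io_formats.write_fasta(
        io_formats.SeqCollection(
            [(name, "promoter", seq) for name, seq in dataset.promoters.items()],
            alphabet="dna",
        ),
        out / "promoters.fna",
    )
    io_formats.write_catalog_table(dataset.catalog, out / "catalog.tsv")
    expr_mod.write_expression_tsv(dataset.expression_tissue, out / "expression_tissue.tsv")
    expr_mod.write_expression_tsv(dataset.expression_stress, out / "expression_stress.tsv")
    if dataset.gene_tree is not None:
        io_formats.write_newick(dataset.gene_tree, out / "gene_tree.nwk")
    with open(out / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    checksums = {}
    for path in sorted(out.iterdir()):
        if path.is_file():
            checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return checksums
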