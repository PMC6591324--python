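"""Readers and writers for the formats the pipeline touches.

Catalog TSV (including the packaged reference fixture), FASTA, GFF3 and
Newick. Every reader/writer pair round-trips its own output. Gene-tree leaf
labels follow the ``<species>|<gene>`` convention because trees mix two
species.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .catalog import CatalogTable, GeneRecord, class_from_name

PathLike = Union[str, Path]

DNA_LETTERS = set("ACGTRYSWKMBDHVN")
PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

CATALOG_COLUMNS = [
    "gene_name", "locus_id", "cds_start", "cds_end", "strand",
    "gene_len_bp", "protein_len_aa", "mw_kda", "pi", "localization",
]


# ---------------------------------------------------------------------------
# catalog TSV

def packaged_catalog_path() -> Path:
    """Path of the packaged reference catalog fixture (85 pepper genes)."""
    return Path(importlib.resources.files("gstfam") / "data" / "table1_catalog.tsv")


def read_catalog_table(path: PathLike) -> CatalogTable:
    """Parse a tab-separated catalog into a validated CatalogTable.

    The class label is inferred from the gene-name prefix. Malformed rows
    raise a parse error naming the offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty catalog file")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in CATALOG_COLUMNS[:5] if c not in header]
    if missing:
        raise ValueError(f"{path}: header missing columns {missing}")
    idx = {c: header.index(c) for c in header}
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        try:
            name = fields[idx["gene_name"]]
            rec = GeneRecord(
                name=name,
                locus_id=fields[idx["locus_id"]],
                cds_start=int(fields[idx["cds_start"]]),
                cds_end=int(fields[idx["cds_end"]]),
                strand=fields[idx["strand"]],
                class_label=class_from_name(name),
                gene_len_bp=_opt_int(fields, idx, "gene_len_bp"),
                protein_len_aa=_opt_int(fields, idx, "protein_len_aa"),
                mw_kda=_opt_float(fields, idx, "mw_kda"),
                pi=_opt_float(fields, idx, "pi"),
                localization=(
                    fields[idx["localization"]] if "localization" in idx else None
                ),
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
        records.append(rec)
    if not records:
        raise ValueError(f"{path}: catalog contains no data rows")
    return CatalogTable(records)


def _opt_int(fields, idx, col):
    return int(fields[idx[col]]) if col in idx and fields[idx[col]] else None


def _opt_float(fields, idx, col):
    return float(fields[idx[col]]) if col in idx and fields[idx[col]] else None


def read_packaged_catalog() -> CatalogTable:
    return read_catalog_table(packaged_catalog_path())


def write_catalog_table(catalog: CatalogTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for r in catalog:
            fh.write(
                "\t".join(
                    "" if v is None else str(v)
                    for v in (
                        r.name, r.locus_id, r.cds_start, r.cds_end, r.strand,
                        r.gene_len_bp, r.protein_len_aa, r.mw_kda, r.pi,
                        r.localization,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA

@dataclass
class SeqCollection:
    """Ordered sequence records with a declared alphabet (dna or protein)."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)
    alphabet: str = "protein"

    def __post_init__(self):
        if self.alphabet not in {"dna", "protein"}:
            raise ValueError("alphabet must be 'dna' or 'protein'")
        letters = DNA_LETTERS if self.alphabet == "dna" else PROTEIN_LETTERS
        seen = set()
        normalized = []
        for seq_id, desc, seq in self.entries:
            if seq_id in seen:
                raise ValueError(f"duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
            seq = seq.upper()
            bad = set(seq) - letters - {"-"}
            if bad:
                raise ValueError(
                    f"record {seq_id!r}: illegal {self.alphabet} residues {sorted(bad)}"
                )
            normalized.append((seq_id, desc, seq))
        self.entries = normalized

    def __len__(self):
        return len(self.entries)

    def get(self, seq_id: str) -> str:
        for sid, _, seq in self.entries:
            if sid == seq_id:
                return seq
        raise KeyError(seq_id)

    def ids(self) -> list[str]:
        return [sid for sid, _, _ in self.entries]


def read_fasta(path: PathLike, alphabet: str = "protein") -> SeqCollection:
    """Read a FASTA file; residues are uppercased, duplicate ids rejected."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        entries.append((rec.id, desc, str(rec.seq)))
    if not entries:
        raise ValueError(f"{path}: no FASTA records found")
    return SeqCollection(entries, alphabet)


def write_fasta(coll: SeqCollection, path: PathLike, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description=desc)
        for sid, desc, seq in coll.entries
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3

FEATURE_TYPES = {"gene", "mRNA", "exon", "CDS"}


@dataclass(frozen=True)
class Feature:
    """One GFF3 row (1-based inclusive coordinates)."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    strand: str
    phase: str
    feature_id: Optional[str]
    parent: Optional[str]

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(
                f"feature {self.feature_id or '?'}: end {self.end} < start {self.start}"
            )


@dataclass
class FeatureSet:
    """GFF3 features with the Parent hierarchy resolved and validated."""

    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        by_id = {f.feature_id: f for f in self.features if f.feature_id}
        for f in self.features:
            if f.parent is not None:
                if f.parent not in by_id:
                    raise ValueError(
                        f"feature {f.feature_id or f.type}: unknown Parent {f.parent!r}"
                    )
                parent = by_id[f.parent]
                if not (parent.start <= f.start and f.end <= parent.end):
                    raise ValueError(
                        f"feature {f.feature_id or f.type} exceeds parent "
                        f"{f.parent} span"
                    )

    def __len__(self):
        return len(self.features)

    def of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.type == ftype]

    def gene(self, gene_id: str) -> Feature:
        for f in self.features:
            if f.type == "gene" and f.feature_id == gene_id:
                return f
        raise KeyError(f"gene {gene_id!r} not in feature set")

    def children(self, feature_id: str) -> list[Feature]:
        return [f for f in self.features if f.parent == feature_id]


def _parse_attributes(text: str) -> dict:
    attrs = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: PathLike) -> FeatureSet:
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            seqid, source, ftype, start, end, _score, strand, phase, attr_text = cols
            attrs = _parse_attributes(attr_text)
            try:
                feat = Feature(
                    seqid=seqid,
                    source=source,
                    type=ftype,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    phase=phase,
                    feature_id=attrs.get("ID"),
                    parent=attrs.get("Parent"),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            features.append(feat)
    return FeatureSet(features)


def write_gff3(fs: FeatureSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in fs.features:
            attrs = []
            if f.feature_id:
                attrs.append(f"ID={f.feature_id}")
            if f.parent:
                attrs.append(f"Parent={f.parent}")
            fh.write(
                "\t".join(
                    [
                        f.seqid, f.source, f.type, str(f.start), str(f.end),
                        ".", f.strand, f.phase, ";".join(attrs) or ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick

def read_newick(path_or_text: PathLike) -> TreeNode:
    """Read a single Newick tree; polytomies are accepted."""
    text = None
    if isinstance(path_or_text, Path) or (
        isinstance(path_or_text, str)
        and "(" not in path_or_text
    ):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    try:
        tree = TreeNode.read(StringIO(text), format="newick", convert_underscores=False)
    except Exception as exc:  # skbio raises several parse-error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    return tree


def write_newick(tree: TreeNode, path: PathLike) -> None:
    with open(path, "w") as fh:
        tree.write(fh, format="newick")


def leaf_species(label: str) -> str:
    """Species tag of a ``<species>|<gene>`` leaf label."""
    if label is None or "|" not in label:
        raise ValueError(f"leaf label {label!r} lacks a '<species>|<gene>' tag")
    return label.split("|", 1)[0]
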