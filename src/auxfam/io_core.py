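"""Readers and writers for the external formats the pipeline touches.

All coordinates exposed by this module are 1-based inclusive, matching
GFF3 and the family-table convention.  Any half-open arithmetic needed by
an algorithm is performed locally and never leaks out of a function.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# Alphabets
# ---------------------------------------------------------------------------

DNA_LETTERS = set("ACGTN")
# 20 standard residues; X tolerated on read for masked positions.
PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
GAP = "-"

_ALPHABETS = {
    "dna": DNA_LETTERS,
    "protein": PROTEIN_LETTERS,
    "aligned-protein": PROTEIN_LETTERS | {GAP},
    "aligned-dna": DNA_LETTERS | {GAP},
}


class IoError(ValueError):
    """Raised for malformed or inconsistent external data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """An ordered collection of named sequences over a declared alphabet.

    ``records`` is a list of ``(id, sequence)`` pairs; descriptions (text
    after the first whitespace on a FASTA header) are kept apart in
    ``descriptions`` so that ids stay clean join keys.
    """

    records: list[tuple[str, str]]
    alphabet: str = "dna"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alphabet not in _ALPHABETS:
            raise IoError(f"unknown alphabet {self.alphabet!r}")
        letters = _ALPHABETS[self.alphabet]
        seen: set[str] = set()
        for rid, seq in self.records:
            if rid in seen:
                raise IoError(f"duplicate sequence id {rid!r}")
            seen.add(rid)
            if not seq:
                raise IoError(f"empty sequence for id {rid!r}")
            bad = set(seq.upper()) - letters
            if bad:
                raise IoError(
                    f"sequence {rid!r} contains letters {sorted(bad)} outside "
                    f"alphabet {self.alphabet!r}"
                )

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)

    def __contains__(self, rid: str) -> bool:
        return any(r == rid for r, _ in self.records)


@dataclass
class GeneModel:
    """One gene: location, exon layout and coding content.

    Spans are 1-based inclusive ``(start, end)`` tuples on the forward
    genomic strand; ``exons`` are sorted by start regardless of gene
    strand.  ``cds`` defaults to the exon spans when the annotation does
    not distinguish UTRs.
    """

    name: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    orf_length_nt: int = 0
    locus_id: str = ""
    cds: list[tuple[int, int]] | None = None
    utrs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise IoError(f"gene {self.name!r}: unknown strand {self.strand!r}")
        if self.start > self.end:
            raise IoError(f"gene {self.name!r}: span start > end")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise IoError(f"gene {self.name!r}: exon start > end ({s}..{e})")
            if s < self.start or e > self.end:
                raise IoError(
                    f"gene {self.name!r}: exon {s}..{e} outside gene span "
                    f"{self.start}..{self.end}"
                )
            if prev_end is not None and s <= prev_end:
                raise IoError(f"gene {self.name!r}: overlapping exons")
            prev_end = e
        if self.cds is not None:
            self.cds = sorted(self.cds)

    @property
    def cds_spans(self) -> list[tuple[int, int]]:
        return self.cds if self.cds is not None else self.exons

    @property
    def atg_position(self) -> int:
        """Genomic coordinate of the first coding base (the A of ATG)."""
        spans = self.cds_spans
        if not spans:
            raise IoError(f"gene {self.name!r} has no CDS")
        return spans[0][0] if self.strand == "+" else spans[-1][1]


@dataclass
class AnnotationSet:
    """A set of gene models plus free-text provenance."""

    genes: list[GeneModel]
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.name in seen:
                raise IoError(f"duplicate gene name {g.name!r}")
            seen.add(g.name)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, name: str) -> GeneModel:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, alphabet: str = "dna") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    The id is the header token up to the first whitespace; the remainder
    is stored in ``descriptions``.  Duplicate ids and empty sequences are
    hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise IoError(f"no such file: {path}")
    records: list[tuple[str, str]] = []
    descriptions: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        records.append((rec.id, seq))
        desc = rec.description[len(rec.id):].strip()
        if desc:
            descriptions[rec.id] = desc
    if not records:
        raise IoError(f"no FASTA records in {path}")
    return SequenceSet(records, alphabet=alphabet, descriptions=descriptions)


def write_fasta(seqs: SequenceSet, path: str | os.PathLike, width: int = 60) -> None:
    """Write a :class:`SequenceSet` as FASTA wrapped at ``width`` columns."""
    recs = []
    for rid, seq in seqs.records:
        recs.append(
            SeqRecord(Seq(seq), id=rid, description=seqs.descriptions.get(rid, ""))
        )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike) -> AnnotationSet:
    """Parse gene/mRNA/exon/CDS features into one :class:`GeneModel` per gene.

    CDS lengths are summed into the ORF length.  An exon outside its
    gene's span, or an unknown strand, is a hard error naming the gene.
    """
    path = Path(path)
    if not path.exists():
        raise IoError(f"no such file: {path}")
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene", order_by="start"):
        name = gf.attributes.get("Name", [gf.id])[0]
        locus = gf.attributes.get("locus_id", [gf.id])[0]
        if gf.strand not in {"+", "-"}:
            raise IoError(f"gene {name!r}: unknown strand {gf.strand!r}")
        exons = [(f.start, f.end)
                 for f in db.children(gf, featuretype="exon", order_by="start")]
        cds = [(f.start, f.end)
               for f in db.children(gf, featuretype="CDS", order_by="start")]
        utrs = [(f.start, f.end)
                for t in ("five_prime_UTR", "three_prime_UTR")
                for f in db.children(gf, featuretype=t, order_by="start")]
        if not exons:
            exons = list(cds)
        for s, e in exons:
            if s < gf.start or e > gf.end:
                raise IoError(
                    f"gene {name!r}: exon {s}..{e} outside gene span "
                    f"{gf.start}..{gf.end}"
                )
        orf = sum(e - s + 1 for s, e in cds)
        genes.append(
            GeneModel(
                name=name, chromosome=gf.seqid, strand=gf.strand,
                start=gf.start, end=gf.end, exons=exons,
                orf_length_nt=orf, locus_id=locus,
                cds=cds or None, utrs=utrs,
            )
        )
    return AnnotationSet(genes, source=str(path))


def write_gff3(annotation: AnnotationSet, path: str | os.PathLike) -> None:
    """Write gene/mRNA/exon/CDS features with ID/Parent links."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            attrs = f"ID={g.name};Name={g.name}"
            if g.locus_id:
                attrs += f";locus_id={g.locus_id}"
            fh.write(
                f"{g.chromosome}\tauxfam\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.name}.1"
            fh.write(
                f"{g.chromosome}\tauxfam\tmRNA\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={mrna};Parent={g.name}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chromosome}\tauxfam\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
            for i, (s, e) in enumerate(g.cds_spans, 1):
                fh.write(
                    f"{g.chromosome}\tauxfam\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# Tables, trees, hit files
# ---------------------------------------------------------------------------

def write_table(rows: Iterable[Sequence], path: str | os.PathLike,
                header: Sequence[str]) -> None:
    """Write rows as TSV with a header line."""
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, header)) + "\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def write_newick(tree, path: str | os.PathLike) -> None:
    """Serialize a dendropy tree; internal-node labels carry supports."""
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            )
        )


BED_HEADER = ("promoter_id", "start", "end", "strand", "motif", "word")


def write_bedlike_hits(hits, path: str | os.PathLike) -> None:
    """Write motif hits as a 6-column BED-like file (header included).

    ``start``/``end`` are the hit's window offsets (negative, ATG-relative,
    1-based inclusive like every other coordinate in the package).
    """
    rows = [
        (h.promoter_id, h.offset, h.offset + len(h.word) - 1,
         h.strand, h.motif, h.word)
        for h in hits
    ]
    write_table(rows, path, header=BED_HEADER)
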