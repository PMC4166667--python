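"""Exon-intron structure and genome-distribution summaries."""

from __future__ import annotations

from .io_core import AnnotationSet, GeneModel, IoError

# GeneModel lives in io_core (readers construct it); re-exported here as
# the structural vocabulary of this module.
__all__ = [
    "GeneModel",
    "intron_count",
    "introns",
    "structure_diagram_table",
    "distribution_map",
    "DIAGRAM_HEADER",
]


def intron_count(gene: GeneModel) -> int:
    """Number of introns: exon count minus one."""
    if not gene.exons:
        raise IoError(f"gene {gene.name!r} has no exons")
    return len(gene.exons) - 1


def introns(gene: GeneModel) -> list[tuple[int, int]]:
    """Intron spans (1-based inclusive) between consecutive exons."""
    if not gene.exons:
        raise IoError(f"gene {gene.name!r} has no exons")
    return [
        (a_end + 1, b_start - 1)
        for (_, a_end), (b_start, _) in zip(gene.exons, gene.exons[1:])
    ]


DIAGRAM_HEADER = ("gene", "feature", "start", "end", "length")


def structure_diagram_table(
    genes: list[GeneModel] | AnnotationSet,
) -> list[tuple[str, str, int, int, int]]:
    """Rows of (gene, feature, start, end, length) for structure diagrams.

    Features are listed 5'->3' in transcription orientation: for a
    minus-strand gene the first row is the feature nearest the highest
    genomic coordinate.  Coordinates themselves stay genomic (1-based
    inclusive) and feature lengths always sum to the span length.
    """
    if isinstance(genes, AnnotationSet):
        genes = genes.genes
    rows: list[tuple[str, str, int, int, int]] = []
    for g in genes:
        feats = [("exon", s, e) for s, e in g.exons]
        feats += [("intron", s, e) for s, e in introns(g)]
        feats += [("UTR", s, e) for s, e in g.utrs]
        feats.sort(key=lambda f: f[1], reverse=(g.strand == "-"))
        for kind, s, e in feats:
            rows.append((g.name, kind, s, e, e - s + 1))
    return rows


def distribution_map(
    genes: list[GeneModel] | AnnotationSet,
    chromosome_lengths: dict[str, int],
) -> dict[str, list[GeneModel]]:
    """Genes per chromosome, ordered by start; empty chromosomes listed.

    Every gene's chromosome must be in the universe and its span must fit
    the chromosome length.  The result is invariant to input order.
    """
    if isinstance(genes, AnnotationSet):
        genes = genes.genes
    out: dict[str, list[GeneModel]] = {c: [] for c in chromosome_lengths}
    for g in genes:
        if g.chromosome not in chromosome_lengths:
            raise IoError(
                f"gene {g.name!r}: chromosome {g.chromosome!r} not in universe"
            )
        if g.end > chromosome_lengths[g.chromosome]:
            raise IoError(
                f"gene {g.name!r} extends beyond chromosome "
                f"{g.chromosome!r} length {chromosome_lengths[g.chromosome]}"
            )
        out[g.chromosome].append(g)
    for c in out:
        out[c].sort(key=lambda g: g.start)
    return out
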