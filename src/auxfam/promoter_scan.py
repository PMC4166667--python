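"""Strand-aware degenerate motif scanning in promoter windows.

Promoters are the 1000 bp (configurable) immediately 5' of the
translation start (ATG), reported in ATG-relative coordinates -1000..-1.
Both strands are scanned with IUPAC-degenerate words; the default
vocabulary is the classical auxin-responsive element AUX1 (TGTCTC), its
relaxed variant AUX2 (TGTVYS), three bZIP response elements (GRE BACGTV,
TGA TGACG, AC ACTCAT) and two Myb response elements (MRE1 AMCWAMC, MRE2
GGWTW).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

from .io_core import GeneModel, IoError, SequenceSet

# ---------------------------------------------------------------------------
# IUPAC machinery
# ---------------------------------------------------------------------------

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(word: str) -> str:
    """Reverse complement of a plain or IUPAC-degenerate DNA word."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(word.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter {exc.args[0]!r}") from None


def expand_iupac(word: str) -> list[str]:
    """All concrete ACGT words compatible with a degenerate word."""
    sets = [sorted(IUPAC[c]) for c in _validated(word)]
    return ["".join(p) for p in product(*sets)]


def _validated(word: str) -> str:
    word = word.upper()
    for c in word:
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {c!r} in {word!r}")
    return word


def iupac_match(word: str, text: str) -> list[int]:
    """All (overlapping) 0-based offsets where ``word`` matches ``text``.

    Each text position must be a concrete base contained in the word
    letter's set; an N in the *text* matches nothing (conservative
    scanning of masked sequence).
    """
    word = _validated(word)
    text = text.upper()
    m, n = len(word), len(text)
    hits = []
    for i in range(n - m + 1):
        ok = True
        for j in range(m):
            c = text[i + j]
            if c not in "ACGT" or c not in IUPAC[word[j]]:
                ok = False
                break
        if ok:
            hits.append(i)
    return hits


# ---------------------------------------------------------------------------
# Motif vocabulary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifDef:
    name: str
    word: str

    def __post_init__(self) -> None:
        w = _validated(self.word)
        if len(w) < 4:
            raise ValueError(f"motif {self.name!r}: word shorter than 4")
        object.__setattr__(self, "word", w)


#: the default promoter vocabulary
DEFAULT_MOTIFS: tuple[MotifDef, ...] = (
    MotifDef("AUX1", "TGTCTC"),
    MotifDef("AUX2", "TGTVYS"),
    MotifDef("GRE", "BACGTV"),
    MotifDef("TGA", "TGACG"),
    MotifDef("AC", "ACTCAT"),
    MotifDef("MRE1", "AMCWAMC"),
    MotifDef("MRE2", "GGWTW"),
)

MOTIFS_BY_NAME = {m.name: m for m in DEFAULT_MOTIFS}


@dataclass(frozen=True)
class MotifHit:
    """One promoter match.

    ``offset`` is the ATG-relative position of the match's 5'-most
    promoter base, in [-window, -len(word)]; ``word`` is the matched
    promoter-forward substring (for a minus-strand hit this is the
    reverse complement of the motif reading).
    """

    promoter_id: str
    motif: str
    strand: str
    offset: int
    word: str


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------

def extract_promoter(
    genome: SequenceSet, gene: GeneModel, window: int = 1000
) -> str:
    """The ``window`` bases immediately 5' of the gene's ATG.

    For a plus-strand gene this is the genomic sequence just upstream of
    the first CDS base; for a minus-strand gene it is the reverse
    complement of the bases just 3' (in genomic coordinates) of the CDS
    end, so the returned string always reads 5'->3' toward the ATG.
    Truncated with a warning at the chromosome edge.
    """
    if not gene.cds_spans:
        raise IoError(f"gene {gene.name!r} has no CDS")
    chrom = genome[gene.chromosome]
    atg = gene.atg_position
    if gene.strand == "+":
        start = max(1, atg - window)
        prom = chrom[start - 1:atg - 1]
    else:
        end = min(len(chrom), atg + window)
        prom = reverse_complement(chrom[atg:end])
    if len(prom) < window:
        warnings.warn(
            f"promoter of {gene.name} truncated to {len(prom)} bp at the "
            "chromosome edge",
            stacklevel=2,
        )
    return prom


def extract_promoters(
    genome: SequenceSet, annotation, window: int = 1000
) -> SequenceSet:
    """Promoter window per gene, keyed by gene name."""
    recs = [
        (g.name, extract_promoter(genome, g, window))
        for g in annotation.genes
    ]
    return SequenceSet(recs, alphabet="dna")


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def scan_promoter_text(
    promoter_id: str,
    text: str,
    motifs: tuple[MotifDef, ...] = DEFAULT_MOTIFS,
    collapse_palindromes: bool = False,
) -> list[MotifHit]:
    """Scan one promoter string (5'->3', ATG at the right edge)."""
    window = len(text)
    hits: dict[tuple[str, str, int], MotifHit] = {}
    for motif in motifs:
        for i in iupac_match(motif.word, text):
            off = i - window
            hits[(motif.name, "+", off)] = MotifHit(
                promoter_id, motif.name, "+", off, text[i:i + len(motif.word)]
            )
        rc = reverse_complement(motif.word)
        for i in iupac_match(rc, text):
            off = i - window
            key = (motif.name, "-", off)
            if collapse_palindromes and (motif.name, "+", off) in hits:
                continue
            hits[key] = MotifHit(
                promoter_id, motif.name, "-", off, text[i:i + len(motif.word)]
            )
    return sorted(hits.values(), key=lambda h: (h.motif, h.offset, h.strand))


def scan_promoters(
    promoters: SequenceSet,
    motifs: tuple[MotifDef, ...] = DEFAULT_MOTIFS,
    collapse_palindromes: bool = False,
) -> list[MotifHit]:
    """Scan every promoter on both strands; see :class:`MotifHit`."""
    out: list[MotifHit] = []
    for pid, text in promoters.records:
        out.extend(
            scan_promoter_text(pid, text, motifs, collapse_palindromes)
        )
    return out


def brute_force_scan(
    promoter_id: str,
    text: str,
    motifs: tuple[MotifDef, ...] = DEFAULT_MOTIFS,
) -> list[MotifHit]:
    """Independent oracle: enumerate every window x strand x motif.

    Checks each window against the explicit IUPAC expansion of the word
    (forward strand) or of its reverse complement (minus strand).  Meant
    for short promoters in tests; quadratic in expansion size.
    """
    text = text.upper()
    window = len(text)
    hits: dict[tuple[str, str, int], MotifHit] = {}
    for motif in motifs:
        for strand, words in (
            ("+", expand_iupac(motif.word)),
            ("-", expand_iupac(reverse_complement(motif.word))),
        ):
            m = len(motif.word)
            for i in range(window - m + 1):
                sub = text[i:i + m]
                if sub in words:
                    hits[(motif.name, strand, i - window)] = MotifHit(
                        promoter_id, motif.name, strand, i - window, sub
                    )
    return sorted(hits.values(), key=lambda h: (h.motif, h.offset, h.strand))


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def _word_matches_motif(hit: MotifHit, motif: MotifDef) -> bool:
    word = hit.word if hit.strand == "+" else reverse_complement(hit.word)
    return len(word) == len(motif.word) and bool(iupac_match(motif.word, word))


def count_table(
    hits: list[MotifHit],
    per: str = "family",
    motifs: tuple[MotifDef, ...] = DEFAULT_MOTIFS,
    exclude_aux1_from_aux2: bool = False,
):
    """Per-motif totals, both strands pooled.

    ``per='family'`` returns one dict motif->count over all promoters;
    ``per='promoter'`` returns ``{promoter_id: {motif: count}}``.  With
    ``exclude_aux1_from_aux2`` any AUX2 hit whose matched word also
    satisfies the AUX1 word is dropped from the AUX2 total (the two
    counting conventions differ only when the stricter core is present).
    """
    if per not in {"family", "promoter"}:
        raise ValueError("per must be 'family' or 'promoter'")
    names = [m.name for m in motifs]
    aux1 = MOTIFS_BY_NAME.get("AUX1")

    def _keep(h: MotifHit) -> bool:
        if exclude_aux1_from_aux2 and h.motif == "AUX2" and aux1 is not None:
            return not _word_matches_motif(h, aux1)
        return True

    if per == "family":
        counts = {n: 0 for n in names}
        for h in hits:
            if h.motif in counts and _keep(h):
                counts[h.motif] += 1
        return counts
    out: dict[str, dict[str, int]] = {}
    for h in hits:
        row = out.setdefault(h.promoter_id, {n: 0 for n in names})
        if h.motif in row and _keep(h):
            row[h.motif] += 1
    return out
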