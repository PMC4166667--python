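"""Family membership and Table-1-style per-gene statistics.

Candidate family members are found by a conserved-pattern scan against
the PB1-like region (domains III/IV), the package's self-contained
stand-in for a profile-HMM search, followed by unique-sequence
deduplication.  Per-gene statistics cover ORF length, deduced protein
length, average molecular weight and isoelectric point.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

from .domain_grammar import (
    DEFAULT_MAX_MISMATCH_FRAC,
    DOMAIN_BLOCKS,
    _best_block_match,
)
from .io_core import SequenceSet

# ---------------------------------------------------------------------------
# Constants: residue masses (average), pKa set
# ---------------------------------------------------------------------------

#: average residue masses in Da (monomer minus water); one water is added
#: per chain.  Standard average-mass table.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: EMBOSS-style pKa values used by the isoelectric-point bisection
PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,       # positive groups
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,  # negative groups
}
_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")

#: default conserved-pattern set for family identification: the PB1-like
#: domain III/IV consensus blocks; a protein matching either is a candidate
DEFAULT_FAMILY_PATTERNS = (DOMAIN_BLOCKS["III"], DOMAIN_BLOCKS["IV"])


class ResidueError(ValueError):
    """A protein sequence contains a non-standard residue."""


def _check_residues(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ResidueError("empty protein sequence")
    for i, c in enumerate(seq, start=1):
        if c not in AVERAGE_RESIDUE_MASS:
            raise ResidueError(
                f"non-standard residue {c!r} at position {i}"
            )
    return seq


# ---------------------------------------------------------------------------
# Identification
# ---------------------------------------------------------------------------

def scan_proteome(
    proteins: SequenceSet,
    patterns: tuple[str, ...] = DEFAULT_FAMILY_PATTERNS,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> list[str]:
    """Ids of proteins matching any conserved-region pattern.

    A pattern matches when its best ungapped sliding-window alignment has
    at most ``max_mismatch_frac`` mismatches.  Proteins with identical
    sequences are collapsed first, keeping the lexicographically smallest
    id, so re-scanning the result is idempotent.  An empty proteome
    yields an empty list.
    """
    by_seq: dict[str, str] = {}
    for rid, seq in proteins.records:
        keep = by_seq.get(seq)
        if keep is None or rid < keep:
            by_seq[seq] = rid
    kept = set(by_seq.values())
    hits = []
    for rid, seq in proteins.records:
        if rid not in kept:
            continue
        for pat in patterns:
            _, frac = _best_block_match(seq, pat)
            if frac <= max_mismatch_frac:
                hits.append(rid)
                break
    return hits


# ---------------------------------------------------------------------------
# Per-protein statistics
# ---------------------------------------------------------------------------

def orf_to_protein_length(orf_nt: int) -> int:
    """Deduced polypeptide length for an ORF that includes the stop codon.

    ``orf_nt/3 - 1``: one codon per residue, stop codon excluded.
    """
    if orf_nt < 6:
        raise ValueError("ORF must be at least 6 nt (one codon plus stop)")
    if orf_nt % 3:
        raise ValueError(
            f"ORF length {orf_nt} not divisible by 3: inconsistent annotation"
        )
    return orf_nt // 3 - 1


def molecular_weight(seq: str) -> float:
    """Average molecular weight in kDa.

    Sum of average residue masses plus one water; family tables round to
    2 decimals on output.
    """
    seq = _check_residues(seq)
    da = sum(AVERAGE_RESIDUE_MASS[c] for c in seq) + WATER_MASS
    return da / 1000.0


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a protein at a given pH."""
    seq = _check_residues(seq)
    pos = 1.0 / (1.0 + 10.0 ** (ph - PKA["Nterm"]))
    neg = 1.0 / (1.0 + 10.0 ** (PKA["Cterm"] - ph))
    for res in _POSITIVE:
        n = seq.count(res)
        if n:
            pos += n / (1.0 + 10.0 ** (ph - PKA[res]))
    for res in _NEGATIVE:
        n = seq.count(res)
        if n:
            neg += n / (1.0 + 10.0 ** (PKA[res] - ph))
    return pos - neg


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection.

    Net charge is monotone decreasing in pH, so bisection on [0, 14]
    converges; iteration stops when |charge| < ``tol``.  Family tables
    round to 2 decimals on output.
    """
    seq = _check_residues(seq)
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid)
        if abs(q) < tol:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


# ---------------------------------------------------------------------------
# Family table
# ---------------------------------------------------------------------------

FAMILY_TABLE_COLUMNS = [
    "gene", "locus_id", "orf_length_nt", "introns", "chromosome",
    "start", "end", "length_aa", "mol_wt_kda", "pi",
]


@dataclass
class FamilyTable:
    """Table-1-style per-gene statistics (column order mirrors the
    published family table)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(FAMILY_TABLE_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"family table missing columns {sorted(missing)}")
        self.df = self.df[FAMILY_TABLE_COLUMNS].reset_index(drop=True)
        bad = self.df[self.df["start"] >= self.df["end"]]
        if len(bad):
            raise ValueError(
                f"span start >= end for {bad['gene'].tolist()}"
            )
        if (self.df["chromosome"].astype(str).str.len() == 0).any():
            raise ValueError("empty chromosome field")

    def __len__(self) -> int:
        return len(self.df)


def build_family_table(annotation, proteins: SequenceSet,
                       members: list[str] | None = None) -> FamilyTable:
    """Assemble the family table from gene models plus protein sequences.

    ``members`` restricts to identified family members (gene names must
    match protein ids); by default every annotated gene is included.
    """
    rows = []
    for g in annotation.genes:
        if members is not None and g.name not in members:
            continue
        seq = proteins[g.name]
        rows.append({
            "gene": g.name,
            "locus_id": g.locus_id,
            "orf_length_nt": g.orf_length_nt,
            "introns": len(g.exons) - 1,
            "chromosome": g.chromosome,
            "start": g.start,
            "end": g.end,
            "length_aa": len(seq),
            "mol_wt_kda": round(molecular_weight(seq), 2),
            "pi": round(isoelectric_point(seq), 2),
        })
    return FamilyTable(pd.DataFrame(rows, columns=FAMILY_TABLE_COLUMNS))


def load_reference_table() -> FamilyTable:
    """The packaged 17-member MtIAA family table (printed values, kept
    verbatim including any internal inconsistencies)."""
    with importlib.resources.files("auxfam.data").joinpath(
        "mtiaa_table1.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["chromosome"] = df["chromosome"].astype(str)
    return FamilyTable(df)


def validate_family_table(table: FamilyTable) -> list[str]:
    """Genes whose printed ORF length and aa length disagree.

    Returns the rows where ``orf/3 - 1 != length_aa`` (or the ORF is not
    a whole number of codons) — a self-consistency check that surfaces
    annotation or typesetting errors instead of silently fixing them.
    """
    bad = []
    for _, row in table.df.iterrows():
        orf = int(row["orf_length_nt"])
        if orf % 3 or orf < 6 or orf_to_protein_length(orf) != int(
            row["length_aa"]
        ):
            bad.append(row["gene"])
    return bad


def chromosome_distribution(
    table: FamilyTable,
    universe: list[str] | None = None,
) -> dict[str, int]:
    """Gene counts per chromosome.

    With a ``universe`` supplied, chromosomes carrying zero members are
    reported explicitly (e.g. the empty chromosome 6 of the reference
    family).
    """
    counts: dict[str, int] = {}
    if universe is not None:
        counts = {str(c): 0 for c in universe}
    for c in table.df["chromosome"].astype(str):
        counts[c] = counts.get(c, 0) + 1
    return counts
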