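"""Domain-grammar annotation of Aux/IAA proteins.

Aux/IAA repressors carry up to four conserved domains.  Domain I holds a
leucine-repeat repression motif (LxLxL core, e.g. TELRLGLPG); domain II
holds the degron word (core GWPPV) that makes the protein auxin-labile;
domains III and IV form the PB1-like interface that dimerises with ARF
transcription factors.  Two nuclear localisation signals are typical: a
bipartite one (a KR dipeptide between domains I and II plus a basic
stretch at the end of domain II) and a "typical" basic cluster just after
domain IV.

Domains are located by matching a consensus block per domain with a
configurable mismatch tolerance; truncated proteins are classified by the
exact set of missing domains.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

# ---------------------------------------------------------------------------
# Canonical domain blocks
#
# These consensus blocks define the family grammar used throughout the
# package: the synthetic generator assembles proteins from them and the
# annotator matches against them.  Residues K/R/W/L appear only where the
# grammar needs them (basic NLS stretches, the degron tryptophan, the
# leucine repeat), so a match is never ambiguous.
# ---------------------------------------------------------------------------

DOMAIN_BLOCKS: dict[str, str] = {
    "I": "NETELRLGLPGFSEVG",
    "II": "AKAQIVGWPPVRSYRKN",
    "III": "GDYVPTYEDADGMSHEQF",
    "IV": "SGQMVHAFDNTCEYVITDPV",
}

DOMAIN_ORDER = ("I", "II", "III", "IV")

#: canonical degron word inside domain II
CANONICAL_DEGRON = "GWPPV"

#: the package-wide default mismatch tolerance for domain block matching
DEFAULT_MAX_MISMATCH_FRAC = 0.2


@dataclass
class DomainAnnotation:
    """Per-protein domain/motif annotation.

    Intervals are 1-based inclusive positions on the protein sequence.
    ``degron_state`` is ``canonical`` (word == GWPPV), ``modified`` (some
    other x-W-P-P-x word) or ``absent``.
    """

    protein_id: str
    domains: dict[str, tuple[int, int] | None] = field(default_factory=dict)
    lxlxlx: tuple[int, int] | None = None
    lxlxlx_word: str = ""
    degron_state: str = "absent"
    degron_word: str = ""
    degron_interval: tuple[int, int] | None = None
    nls_bipartite: bool = False
    nls_bipartite_intervals: tuple[tuple[int, int], tuple[int, int]] | None = None
    nls_typical: bool = False
    nls_typical_interval: tuple[int, int] | None = None

    def has_domain(self, name: str) -> bool:
        return self.domains.get(name) is not None

    def __post_init__(self) -> None:
        if self.degron_state == "canonical" and self.degron_word[1:4] != "WPP":
            raise ValueError("canonical degron must carry the WPP core")


@dataclass(frozen=True)
class Architecture:
    """Result of :func:`classify_architecture`."""

    canonical: bool
    missing: frozenset[str] = frozenset()

    def __str__(self) -> str:
        if self.canonical:
            return "canonical"
        return "truncated{" + ",".join(sorted(self.missing)) + "}"


# ---------------------------------------------------------------------------
# Block matching
# ---------------------------------------------------------------------------

def _best_block_match(seq: str, block: str) -> tuple[int, float]:
    """Return (0-based offset, mismatch fraction) of the best sliding-window
    alignment of ``block`` against ``seq`` (no indels)."""
    n, m = len(seq), len(block)
    if n < m:
        return (-1, 1.0)
    best_off, best_frac = -1, 1.0
    for off in range(n - m + 1):
        mism = sum(1 for a, b in zip(seq[off:off + m], block) if a != b)
        frac = mism / m
        if frac < best_frac:
            best_off, best_frac = off, frac
            if frac == 0.0:
                break
    return best_off, best_frac


def locate_domains(
    seq: str,
    blocks: dict[str, str] = DOMAIN_BLOCKS,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> dict[str, tuple[int, int] | None]:
    """Locate each domain block in ``seq``.

    A domain is present when its best sliding-window match has at most
    ``max_mismatch_frac`` mismatches; the interval is 1-based inclusive.
    """
    if not set(blocks) <= set(DOMAIN_ORDER) and not all(
        isinstance(k, str) for k in blocks
    ):
        raise ValueError("unknown domain name in blocks")
    out: dict[str, tuple[int, int] | None] = {}
    for name, block in blocks.items():
        off, frac = _best_block_match(seq, block)
        if off >= 0 and frac <= max_mismatch_frac:
            out[name] = (off + 1, off + len(block))
        else:
            out[name] = None
    return out


# ---------------------------------------------------------------------------
# Motif rules
# ---------------------------------------------------------------------------

def find_lxlxlx(seq: str, strict: bool = False) -> tuple[int, int, str] | None:
    """Find the leftmost leucine-repeat core: L at alternating positions.

    Default rule: a 5-residue window ``L x L x L`` (three leucines).  With
    ``strict=True`` a fourth alternating leucine is required (7-residue
    window ``L x L x L x L``).  Returns ``(start, end, word)`` 1-based or
    ``None``.
    """
    need = 4 if strict else 3
    span = 2 * need - 1
    for i in range(len(seq) - span + 1):
        if all(seq[i + 2 * k] == "L" for k in range(need)):
            return (i + 1, i + span, seq[i:i + span])
    return None


_DEGRON_RE = re.compile(r"(?=([A-Z]WPP[A-Z]))")


def find_degron(seq: str) -> tuple[str, str, tuple[int, int] | None]:
    """Search for the degron word x-W-P-P-x.

    Returns ``(state, word, interval)`` where state is ``canonical`` iff
    the word equals GWPPV, ``modified`` for any other x-W-P-P-x match
    (e.g. the DWPPV variant), and ``absent`` otherwise.
    """
    for m in _DEGRON_RE.finditer(seq):
        word = m.group(1)
        state = "canonical" if word == CANONICAL_DEGRON else "modified"
        return state, word, (m.start() + 1, m.start() + 5)
    return "absent", "", None


def _basic_count(window: str) -> int:
    return sum(1 for c in window if c in "KR")


def find_nls(
    seq: str,
    domain_intervals: dict[str, tuple[int, int] | None],
) -> tuple[bool, bool,
           tuple[tuple[int, int], tuple[int, int]] | None,
           tuple[int, int] | None]:
    """Detect bipartite and typical nuclear localisation signals.

    Bipartite: a KR dipeptide strictly between domain I's end and domain
    II's start, together with >=3 K/R inside domain II's last 10 residues.
    Typical: a 7-residue window with >=4 K/R within the 15 residues after
    domain IV.  A missing prerequisite domain makes the corresponding flag
    false rather than raising.
    """
    bip, bip_iv = False, None
    d1, d2 = domain_intervals.get("I"), domain_intervals.get("II")
    if d1 is not None and d2 is not None and d2[0] > d1[1] + 1:
        between = seq[d1[1]:d2[0] - 1]        # strictly between, 0-based slice
        kr = between.find("KR")
        if kr >= 0:
            tail_start = max(d2[0], d2[1] - 9)
            tail = seq[tail_start - 1:d2[1]]
            if _basic_count(tail) >= 3:
                bip = True
                bip_iv = ((d1[1] + kr + 1, d1[1] + kr + 2),
                          (tail_start, d2[1]))
    typ, typ_iv = False, None
    d4 = domain_intervals.get("IV")
    if d4 is not None:
        region = seq[d4[1]:d4[1] + 15]
        for i in range(len(region) - 6):
            if _basic_count(region[i:i + 7]) >= 4:
                typ = True
                typ_iv = (d4[1] + i + 1, d4[1] + i + 7)
                break
    return bip, typ, bip_iv, typ_iv


# ---------------------------------------------------------------------------
# Whole-protein annotation and classification
# ---------------------------------------------------------------------------

def annotate(
    protein_id: str,
    seq: str,
    blocks: dict[str, str] = DOMAIN_BLOCKS,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    strict_lxlxlx: bool = False,
) -> DomainAnnotation:
    """Full annotation: domains I-IV, LxLxL motif, degron, NLS signals."""
    domains = locate_domains(seq, blocks, max_mismatch_frac)
    lx = find_lxlxlx(seq, strict=strict_lxlxlx)
    state, word, degron_iv = find_degron(seq)
    bip, typ, bip_iv, typ_iv = find_nls(seq, domains)
    return DomainAnnotation(
        protein_id=protein_id,
        domains=domains,
        lxlxlx=(lx[0], lx[1]) if lx else None,
        lxlxlx_word=lx[2] if lx else "",
        degron_state=state,
        degron_word=word,
        degron_interval=degron_iv,
        nls_bipartite=bip,
        nls_bipartite_intervals=bip_iv,
        nls_typical=typ,
        nls_typical_interval=typ_iv,
    )


def classify_architecture(annotation: DomainAnnotation) -> Architecture:
    """Canonical iff all four domains are present; else the missing set."""
    missing = frozenset(
        d for d in DOMAIN_ORDER if not annotation.has_domain(d)
    )
    return Architecture(canonical=not missing, missing=missing)


ANNOTATION_HEADER = (
    "protein_id",
    "domain_I", "domain_II", "domain_III", "domain_IV",
    "lxlxlx", "lxlxlx_word",
    "degron_state", "degron_word",
    "nls_bipartite", "nls_typical",
    "architecture",
)


def annotation_rows(annotations: list[DomainAnnotation]) -> list[tuple]:
    """Flatten annotations into TSV rows (see ``ANNOTATION_HEADER``)."""

    def _iv(iv):
        return f"{iv[0]}..{iv[1]}" if iv else "."

    rows = []
    for a in annotations:
        rows.append((
            a.protein_id,
            _iv(a.domains.get("I")), _iv(a.domains.get("II")),
            _iv(a.domains.get("III")), _iv(a.domains.get("IV")),
            _iv(a.lxlxlx), a.lxlxlx_word or ".",
            a.degron_state, a.degron_word or ".",
            int(a.nls_bipartite), int(a.nls_typical),
            str(classify_architecture(a)),
        ))
    return rows
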