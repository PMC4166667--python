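"""Synthetic toy data with planted ground truth.

Every downstream stage of the pipeline is exercised against data whose
truth is known exactly: a multi-chromosome genome with planted multi-exon
genes (1500 bp of clear flank around each gene so full promoter windows
always exist), proteins assembled from the canonical domain blocks with
controllable omissions and degron variants, promoters with motif words
planted at known offsets and strands, alignments with planted
near-identical sister pairs, and qPCR Ct tables with planted log2
fold-change effects plus Gaussian noise.

All generators are pure functions of their parameters and an integer
seed; each output artifact draws from its own RNG stream derived from the
master seed, so stages are individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .domain_grammar import (
    CANONICAL_DEGRON,
    DEFAULT_MAX_MISMATCH_FRAC,
    DOMAIN_BLOCKS,
    DOMAIN_ORDER,
)
from .io_core import AnnotationSet, GeneModel, IoError, SequenceSet
from .promoter_scan import (
    DEFAULT_MOTIFS,
    MotifDef,
    expand_iupac,
    extract_promoter,
    reverse_complement,
    scan_promoter_text,
)

# residues used for inter-domain linkers: no K/R/W/L, so linkers can never
# fake a degron, a leucine repeat or a basic NLS stretch
LINKER_ALPHABET = "ADEGNQSTVHPFYIMC"

# basic cluster planted just after domain IV as the typical NLS
TYPICAL_NLS_CLUSTER = "SKKRRGE"

# RNG sub-stream tags, one per output artifact
_STREAM_GENOME = 11
_STREAM_PROTEIN = 13
_STREAM_MOTIF = 17
_STREAM_CT = 19
_STREAM_ALIGN = 23

# experimental design constants: two organs, five biological replicates,
# infection followed to 72 h post inoculation, auxin treatment to 24 h
DEFAULT_ORGANS = ("root", "shoot")
DEFAULT_REPLICATES = 5
INFECTION_TIMEPOINTS = (3, 6, 12, 24, 48, 72)
IAA_TIMEPOINTS = (3, 6, 12, 24)
FOUR_CONDITIONS = ("-Sin/-NOA", "+Sin/-NOA", "-Sin/+NOA", "+Sin/+NOA")
MOCK_CONDITION = "-Sin/-NOA"
REFERENCE_GENE = "ACTIN"


@dataclass
class ProteinArchitecture:
    """Recipe for one synthetic protein.

    ``domains`` lists which of I-IV to include; ``partial`` maps a domain
    to the fraction of its block to keep (a fraction below 0.8 leaves too
    many mismatches for the annotator's default 20% tolerance, emulating
    a partially deleted domain).
    """

    name: str
    domains: tuple[str, ...] = DOMAIN_ORDER
    degron: str = CANONICAL_DEGRON
    nls_bipartite: bool = True
    nls_typical: bool = True
    partial: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in self.domains:
            if d not in DOMAIN_ORDER:
                raise IoError(f"unknown domain name {d!r}")
        for d in self.partial:
            if d not in DOMAIN_ORDER:
                raise IoError(f"unknown domain name {d!r}")

    def expected_missing(
        self, max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC
    ) -> frozenset[str]:
        """Domains the annotator should report missing at a tolerance."""
        missing = set(DOMAIN_ORDER) - set(self.domains)
        for d, frac in self.partial.items():
            if d in self.domains and (1.0 - frac) > max_mismatch_frac:
                missing.add(d)
        return frozenset(missing)


@dataclass
class SyntheticTruth:
    """Planted ground truth, written alongside every synthetic dataset."""

    seed: int
    planted_genes: list[tuple[GeneModel, int]] = field(default_factory=list)
    planted_motifs: list[tuple[str, str, int, str, str]] = field(
        default_factory=list
    )  # (promoter id, motif, offset, strand, concrete word)
    planted_architectures: dict[str, ProteinArchitecture] = field(
        default_factory=dict
    )
    planted_effects: dict[tuple[str, str, str, float], float] = field(
        default_factory=dict
    )  # (gene, organ, condition, timepoint) -> true log2FC
    noise_sd: float = 0.0
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pid, motif, offset, strand, word in self.planted_motifs:
            if not (-10000 <= offset <= -1):
                raise IoError(
                    f"planted offset {offset} for {pid}/{motif} outside window"
                )
        for key, eff in self.planted_effects.items():
            if not np.isfinite(eff):
                raise IoError(f"non-finite planted effect for {key}")


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize planted truth as JSON (seed and parameters included)."""
    doc = {
        "seed": truth.seed,
        "noise_sd": truth.noise_sd,
        "planted_genes": [
            {**asdict(g), "chromosome_index": ci}
            for g, ci in truth.planted_genes
        ],
        "planted_motifs": [
            {"promoter_id": p, "motif": m, "offset": o, "strand": s, "word": w}
            for p, m, o, s, w in truth.planted_motifs
        ],
        "planted_architectures": {
            k: asdict(v) for k, v in truth.planted_architectures.items()
        },
        "planted_effects": [
            {"gene": g, "organ": o, "condition": c, "timepoint": t,
             "log2fc": v}
            for (g, o, c, t), v in truth.planted_effects.items()
        ],
        "planted_pairs": truth.planted_pairs,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def generate_genome(
    n_chrom: int,
    genes_per_chrom: int | Sequence[int],
    seed: int,
    exon_count_range: tuple[int, int] = (2, 8),
    exon_length_range: tuple[int, int] = (90, 240),
    intron_length_range: tuple[int, int] = (60, 300),
    flank: int = 2200,
    chromosome_lengths: Sequence[int] | None = None,
) -> tuple[SequenceSet, AnnotationSet, SyntheticTruth]:
    """A toy genome of ``n_chrom`` chromosomes with planted genes.

    Background sequence is i.i.d. uniform ACGT.  Genes never overlap and
    keep at least 1500 bp of clear flank on both sides, so a full 1000 bp
    promoter window always exists regardless of strand; the default
    flank (2200 bp) exceeds two promoter windows, so the promoters of
    adjacent genes never overlap even when the genes face each other.
    The default exon count range 2..8 makes intron counts 1..7 occur,
    matching the spread seen in real family surveys.  A zero gene count
    leaves a chromosome empty.
    """
    if n_chrom < 1:
        raise IoError("n_chrom must be >= 1")
    if isinstance(genes_per_chrom, int):
        counts = [genes_per_chrom] * n_chrom
    else:
        counts = list(genes_per_chrom)
    if len(counts) != n_chrom:
        raise IoError("genes_per_chrom length must equal n_chrom")
    if any(c < 0 for c in counts):
        raise IoError("gene counts must be >= 0")
    if flank < 1500:
        raise IoError("flank must keep >= 1500 bp upstream of every gene")
    rng = np.random.default_rng([seed, _STREAM_GENOME])

    chrom_records: list[tuple[str, str]] = []
    genes: list[GeneModel] = []
    truth = SyntheticTruth(seed=seed)
    gene_no = 0
    for ci, n_genes in enumerate(counts, start=1):
        chrom = f"chr{ci}"
        cursor = 0  # last occupied base (0 = nothing yet)
        for _ in range(n_genes):
            gene_no += 1
            start = cursor + flank + int(rng.integers(0, 200))
            n_ex = int(rng.integers(exon_count_range[0],
                                    exon_count_range[1] + 1))
            exon_lens = rng.integers(exon_length_range[0],
                                     exon_length_range[1] + 1,
                                     size=n_ex).tolist()
            # keep the summed coding length a whole number of codons
            excess = sum(exon_lens) % 3
            exon_lens[-1] -= excess
            intron_lens = rng.integers(intron_length_range[0],
                                       intron_length_range[1] + 1,
                                       size=max(0, n_ex - 1)).tolist()
            exons = []
            pos = start
            for i, el in enumerate(exon_lens):
                exons.append((pos, pos + el - 1))
                pos += el
                if i < len(intron_lens):
                    pos += intron_lens[i]
            end = exons[-1][1]
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            gm = GeneModel(
                name=f"SynIAA{gene_no}",
                chromosome=chrom,
                strand=strand,
                start=start,
                end=end,
                exons=exons,
                orf_length_nt=sum(exon_lens),
                locus_id=f"syn{ci}g{gene_no:03d}",
                cds=exons,
            )
            genes.append(gm)
            truth.planted_genes.append((gm, ci))
            cursor = end
        needed = cursor + flank
        if chromosome_lengths is not None:
            want = chromosome_lengths[ci - 1]
            if want < needed:
                raise IoError(
                    f"chromosome {chrom} too short ({want} bp) to host "
                    f"{n_genes} genes (needs {needed} bp)"
                )
            length = want
        else:
            length = needed
        chrom_records.append((chrom, _random_dna(rng, length)))
    genome = SequenceSet(chrom_records, alphabet="dna")
    annotation = AnnotationSet(genes, source=f"synthetic(seed={seed})")
    return genome, annotation, truth


# ---------------------------------------------------------------------------
# Proteins
# ---------------------------------------------------------------------------

def _linker(rng: np.random.Generator, lo: int = 6, hi: int = 16) -> str:
    n = int(rng.integers(lo, hi + 1))
    letters = np.array(list(LINKER_ALPHABET))
    return "".join(letters[rng.integers(0, len(letters), size=n)])


def generate_proteins(
    architectures: Iterable[ProteinArchitecture],
    seed: int,
) -> tuple[SequenceSet, SyntheticTruth]:
    """Assemble proteins from randomized linkers and canonical blocks.

    Each protein concatenates an N-terminal linker and the requested
    domain blocks in I..IV order.  The degron word replaces GWPPV inside
    domain II; a KR dipeptide is inserted between domains I and II when
    the bipartite NLS is requested; the basic cluster for the typical NLS
    follows domain IV.  Linker residues exclude K/R/W/L so no motif can
    arise by chance.
    """
    rng = np.random.default_rng([seed, _STREAM_PROTEIN])
    truth = SyntheticTruth(seed=seed)
    records: list[tuple[str, str]] = []
    for arch in architectures:
        parts: list[str] = ["M" + _linker(rng)]
        pos = len(parts[0])
        prev: str | None = None
        for dom in DOMAIN_ORDER:
            if dom not in arch.domains:
                continue
            spacer = _linker(rng)
            if prev == "I" and dom == "II" and arch.nls_bipartite:
                spacer = _linker(rng, 3, 6) + "KR" + _linker(rng, 3, 6)
            parts.append(spacer)
            pos += len(spacer)
            block = DOMAIN_BLOCKS[dom]
            if dom == "II" and arch.degron != CANONICAL_DEGRON:
                block = block.replace(CANONICAL_DEGRON, arch.degron)
            frac = arch.partial.get(dom, 1.0)
            if not 0.0 < frac <= 1.0:
                raise IoError(f"partial fraction for {dom} must be in (0, 1]")
            block = block[: max(1, round(len(block) * frac))]
            parts.append(block)
            pos += len(block)
            if dom == "IV" and arch.nls_typical:
                gap = _linker(rng, 2, 4)
                parts.append(gap + TYPICAL_NLS_CLUSTER)
                pos += len(gap) + len(TYPICAL_NLS_CLUSTER)
            prev = dom
        parts.append(_linker(rng))
        records.append((arch.name, "".join(parts)))
        truth.planted_architectures[arch.name] = arch
    return SequenceSet(records, alphabet="protein"), truth


def canonical_family_architectures(n: int, prefix: str = "SynIAA") -> list[
        ProteinArchitecture]:
    """``n`` fully canonical architectures named ``prefix``1..n."""
    return [ProteinArchitecture(name=f"{prefix}{i}") for i in range(1, n + 1)]


def decoy_architectures(n: int, prefix: str = "decoy") -> list[
        ProteinArchitecture]:
    """Decoys without the PB1-like region (domains III/IV absent)."""
    return [
        ProteinArchitecture(
            name=f"{prefix}{i}", domains=("I", "II"),
            nls_typical=False,
        )
        for i in range(1, n + 1)
    ]


# ---------------------------------------------------------------------------
# Promoter motif planting
# ---------------------------------------------------------------------------

def _promoter_to_genome(gene: GeneModel, window: int):
    """Map promoter text index (0-based) -> (genomic 1-based pos, flipped)."""
    atg = gene.atg_position
    if gene.strand == "+":
        return lambda i: (atg - window + i, False)
    return lambda i: (atg + window - i, True)


def plant_motifs(
    annotation: AnnotationSet,
    genome: SequenceSet,
    plan: Sequence[tuple[str, str | MotifDef, int, str]],
    seed: int,
    window: int = 1000,
    motif_free_background: bool = False,
    vocabulary: tuple[MotifDef, ...] = DEFAULT_MOTIFS,
    max_clean_rounds: int = 500,
) -> tuple[SequenceSet, SyntheticTruth]:
    """Edit the genome so each planned motif occurs at a known place.

    ``plan`` rows are ``(gene name, motif, ATG-relative offset, strand)``;
    the concrete word is drawn uniformly from the IUPAC expansion of the
    motif.  Planting is strand-aware twice over: relative to the promoter
    (a minus-strand hit is written as the word's reverse complement in
    promoter letters) and relative to the gene (a minus-strand gene's
    promoter is itself the reverse complement of genomic sequence).

    With ``motif_free_background`` every promoter's background is
    rejection-resampled until scanning with ``vocabulary`` yields exactly
    the planted occurrences, which makes the planted truth an exact
    oracle.  Note the vocabulary must then be free of nested word pairs
    (e.g. AUX1 inside AUX2): a secondary match lying wholly inside
    planted letters cannot be resampled away and raises.
    """
    motif_by_name = {m.name: m for m in vocabulary}
    texts = {rid: list(seq) for rid, seq in genome.records}
    rng = np.random.default_rng([seed, _STREAM_MOTIF])
    truth = SyntheticTruth(seed=seed)
    # genomic positions occupied by planted letters, across all genes, so
    # cleaning one promoter can never disturb another gene's plant
    occupied: dict[str, set[int]] = {rid: set() for rid, _ in genome.records}

    planned: dict[str, list[tuple[MotifDef, int, str]]] = {}
    for gene_name, motif, offset, strand in plan:
        if isinstance(motif, str):
            if motif not in motif_by_name:
                raise IoError(f"motif {motif!r} not in vocabulary")
            motif = motif_by_name[motif]
        if strand not in {"+", "-"}:
            raise IoError(f"bad strand {strand!r}")
        if not (-window <= offset <= -len(motif.word)):
            raise IoError(
                f"offset {offset} places {motif.name} outside the "
                f"[-{window}, -1] window"
            )
        planned.setdefault(gene_name, []).append((motif, offset, strand))

    touched = set(planned)
    if motif_free_background:
        touched = set(g.name for g in annotation.genes)

    for gene_name in sorted(touched):
        gene = annotation[gene_name]
        cur_genome = SequenceSet(
            [(rid, "".join(t)) for rid, t in texts.items()], alphabet="dna"
        )
        text = list(extract_promoter(cur_genome, gene, window))
        if len(text) < window:
            raise IoError(
                f"gene {gene_name}: promoter shorter than window; cannot plant"
            )
        to_pos = _promoter_to_genome(gene, window)
        gpos = [to_pos(i)[0] for i in range(window)]
        taken = occupied[gene.chromosome]
        planted_mask = [False] * window
        expected: set[tuple[str, str, int]] = set()
        for motif, offset, strand in planned.get(gene_name, []):
            word = expand_iupac(motif.word)[
                int(rng.integers(0, len(expand_iupac(motif.word))))
            ]
            start = window + offset
            span = range(start, start + len(word))
            if any(planted_mask[i] for i in span):
                raise IoError(
                    f"gene {gene_name}: planted motifs overlap at offset "
                    f"{offset}"
                )
            text_word = word if strand == "+" else reverse_complement(word)
            for k, i in enumerate(span):
                text[i] = text_word[k]
                planted_mask[i] = True
                taken.add(gpos[i])
            expected.add((motif.name, strand, offset))
            truth.planted_motifs.append(
                (gene_name, motif.name, offset, strand, word)
            )
        if motif_free_background:
            def _unexpected(h):
                if (h.motif, h.strand, h.offset) in expected:
                    return False
                start = window + h.offset
                # a hit lying wholly inside planted letters (this gene's
                # or, for overlapping promoters, a neighbour's) is a
                # deterministic consequence of the plan, not background
                # chance, and cannot be resampled away
                return not all(
                    gpos[i] in taken
                    for i in range(start, start + len(h.word))
                )

            for _round in range(max_clean_rounds):
                hits = scan_promoter_text(gene_name, "".join(text), vocabulary)
                bad = [h for h in hits if _unexpected(h)]
                if not bad:
                    break
                for h in bad:
                    start = window + h.offset
                    for i in range(start, start + len(h.word)):
                        if gpos[i] not in taken:
                            text[i] = "ACGT"[int(rng.integers(0, 4))]
            else:
                raise IoError(
                    f"gene {gene_name}: could not clean background in "
                    f"{max_clean_rounds} rounds"
                )
        # write the promoter back into genomic coordinates
        to_pos = _promoter_to_genome(gene, window)
        chrom_text = texts[gene.chromosome]
        for i, c in enumerate(text):
            pos, flipped = to_pos(i)
            chrom_text[pos - 1] = reverse_complement(c) if flipped else c
    edited = SequenceSet(
        [(rid, "".join(t)) for rid, t in texts.items()],
        alphabet="dna",
        descriptions=dict(genome.descriptions),
    )
    return edited, truth


# ---------------------------------------------------------------------------
# Alignments with planted sister pairs
# ---------------------------------------------------------------------------

def generate_alignment(
    n_taxa: int = 17,
    length: int = 120,
    n_pairs: int = 3,
    seed: int = 0,
    pair_mutations: int = 1,
    names: Sequence[str] | None = None,
) -> tuple[SequenceSet, SyntheticTruth]:
    """A gap-free protein alignment with planted near-identical pairs.

    Non-pair taxa are i.i.d. random sequences; each planted pair's second
    member copies the first with ``pair_mutations`` substitutions, so the
    pair forms a cherry with essentially certain bootstrap support.
    """
    if 2 * n_pairs > n_taxa:
        raise IoError("n_pairs too large for n_taxa")
    rng = np.random.default_rng([seed, _STREAM_ALIGN])
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    if names is None:
        names = [f"G{i:02d}" for i in range(1, n_taxa + 1)]
    elif len(names) != n_taxa:
        raise IoError("names length must equal n_taxa")
    names = list(names)
    seqs: dict[str, str] = {}
    truth = SyntheticTruth(seed=seed)
    i = 0
    for p in range(n_pairs):
        a, b = names[i], names[i + 1]
        base = aas[rng.integers(0, 20, size=length)]
        other = base.copy()
        for _ in range(pair_mutations):
            j = int(rng.integers(0, length))
            cur = other[j]
            choices = [c for c in aas if c != cur]
            other[j] = choices[int(rng.integers(0, len(choices)))]
        seqs[a] = "".join(base)
        seqs[b] = "".join(other)
        truth.planted_pairs.append((a, b))
        i += 2
    for name in names[i:]:
        seqs[name] = "".join(aas[rng.integers(0, 20, size=length)])
    recs = [(n, seqs[n]) for n in names]
    return SequenceSet(recs, alphabet="aligned-protein"), truth


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

@dataclass
class ExperimentDesign:
    """Organs x conditions x timepoints x replicates of a qPCR experiment."""

    organs: tuple[str, ...] = DEFAULT_ORGANS
    conditions: tuple[str, ...] = (MOCK_CONDITION, "+Sin/-NOA")
    timepoints: tuple[float, ...] = INFECTION_TIMEPOINTS
    replicates: int = DEFAULT_REPLICATES

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise IoError("replicates must be >= 1")


def generate_ct_table(
    genes: Sequence[str],
    design: ExperimentDesign,
    effects: Mapping[tuple[str, str, str, float], float],
    noise_sd: float,
    seed: int,
    reference: str = REFERENCE_GENE,
):
    """Simulate a Ct table with planted log2 fold changes.

    Ct(gene, sample) = baseCt(gene, organ) - log2FC(gene, organ,
    condition, timepoint) + eps with eps ~ Normal(0, noise_sd).  The
    reference gene is appended with log2FC identically zero (its Ct still
    carries measurement noise).  Returns a tidy pandas DataFrame with
    columns gene/organ/condition/timepoint/replicate/ct.
    """
    import pandas as pd

    if noise_sd < 0:
        raise IoError("noise_sd must be >= 0")
    rng = np.random.default_rng([seed, _STREAM_CT])
    all_genes = list(genes)
    if reference not in all_genes:
        all_genes.append(reference)
    base = {
        (g, o): (rng.uniform(17.0, 19.0) if g == reference
                 else rng.uniform(22.0, 28.0))
        for g in all_genes for o in design.organs
    }
    rows = []
    for g in all_genes:
        for o in design.organs:
            for c in design.conditions:
                for t in design.timepoints:
                    eff = 0.0 if g == reference else float(
                        effects.get((g, o, c, t), 0.0)
                    )
                    for r in range(1, design.replicates + 1):
                        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                        rows.append(
                            (g, o, c, t, r, base[(g, o)] - eff + eps)
                        )
    return pd.DataFrame(
        rows,
        columns=["gene", "organ", "condition", "timepoint", "replicate", "ct"],
    )


def random_additive_matrix(
    n_taxa: int,
    seed: int,
    branch_range: tuple[float, float] = (0.1, 1.0),
):
    """An additive distance matrix from a random planted binary tree.

    Builds a random rooted binary tree over taxa T1..Tn with branch
    lengths drawn uniformly from ``branch_range`` and returns its exact
    leaf-to-leaf path-length matrix together with the planted topology's
    non-trivial bipartitions (as unordered pairs of leaf-label sets).
    Because the matrix is perfectly additive with strictly positive
    internal branches, neighbor joining must recover the topology and
    reproduce the matrix.
    """
    from .phylogeny import DistanceMatrix

    if n_taxa < 3:
        raise IoError("need at least 3 taxa")
    rng = np.random.default_rng([seed, 29])
    ids = [f"T{i}" for i in range(1, n_taxa + 1)]
    D = np.zeros((n_taxa, n_taxa))
    comps: list[dict[int, float]] = [{i: 0.0} for i in range(n_taxa)]
    clades: list[frozenset[str]] = []
    while len(comps) > 1:
        a = int(rng.integers(0, len(comps)))
        b = int(rng.integers(0, len(comps) - 1))
        if b >= a:
            b += 1
        ca, cb = comps[a], comps[b]
        la, lb = rng.uniform(*branch_range, size=2)
        for x, dx in ca.items():
            for y, dy in cb.items():
                D[x, y] = D[y, x] = dx + la + dy + lb
        merged = {x: dx + la for x, dx in ca.items()}
        merged.update({y: dy + lb for y, dy in cb.items()})
        clades.append(frozenset(ids[x] for x in merged))
        comps = [c for k, c in enumerate(comps) if k not in (a, b)]
        comps.append(merged)
    everything = frozenset(ids)
    bips = {
        frozenset({c, everything - c})
        for c in clades
        if 2 <= len(c) <= n_taxa - 2
    }
    return DistanceMatrix(ids, D), bips


def plant_infection_effects(
    genes: Sequence[str],
    magnitude: float = 2.0,
    attenuation: float = 0.25,
    organs: tuple[str, ...] = DEFAULT_ORGANS,
    timepoints: tuple[float, ...] = INFECTION_TIMEPOINTS,
) -> dict[tuple[str, str, str, float], float]:
    """Effects for the four-condition infection/inhibitor design.

    Infection (+Sin/-NOA) represses each gene in roots and induces it in
    shoots by ``magnitude`` log2 units; the auxin-influx inhibitor
    (+Sin/+NOA) attenuates the infection effect to ``attenuation`` times
    its size; the inhibitor alone (-Sin/+NOA) has no effect, mirroring a
    design whose mock is the untreated condition.
    """
    effects: dict[tuple[str, str, str, float], float] = {}
    sign = {"root": -1.0, "shoot": +1.0}
    for g in genes:
        for o in organs:
            s = sign.get(o, 1.0)
            for t in timepoints:
                effects[(g, o, "+Sin/-NOA", t)] = s * magnitude
                effects[(g, o, "+Sin/+NOA", t)] = s * magnitude * attenuation
                effects[(g, o, "-Sin/+NOA", t)] = 0.0
    return effects
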