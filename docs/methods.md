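# Methods

This note records the models, conventions and design choices behind
`auxfam`, in the order the pipeline runs.

## Coordinates and formats

All external coordinates are 1-based inclusive (GFF3 convention);
half-open arithmetic is confined to function bodies in `io_core`.
FASTA is wrapped at 60 columns on write; GFF3 gene/mRNA/exon/CDS
features round-trip losslessly for id, coordinates and strand. Gene
name and locus id are separate fields; joins are always on locus id.
`N` is legal in genomic sequence and never matches any motif letter.

## Synthetic data and what it does (not) emulate

The generator plants exact truth for every downstream stage and is a
pure function of its parameters and an integer seed; each artifact
(genome, proteins, motifs, alignment, Ct table) draws from its own RNG
stream derived from the master seed, so stages are individually
reproducible.

* **Genome** — i.i.d. uniform ACGT background; genes non-overlapping
  with ≥1500 bp clear flank (default inter-gene spacing 2200 bp, more
  than two promoter windows, so adjacent promoters never overlap even
  for convergent gene pairs). Exon counts default to 2–8, so intron
  counts 1–7 occur; summed exon length is forced to a whole number of
  codons. The default layout is 17 genes over eight chromosomes as
  3/3/1/4/2/0/1/3, i.e. one chromosome deliberately empty.
* **Proteins** — concatenations of fixed consensus blocks for domains
  I–IV joined by random linkers. Linker residues exclude K, R, W and L,
  so a leucine repeat, a degron or a basic NLS stretch can never arise
  by chance; detection is therefore exactly decidable from the recipe.
  The degron word replaces GWPPV inside the domain II block; a KR
  dipeptide between domains I and II and a basic cluster after domain
  IV plant the two NLS signals. A "partial" domain keeps a prefix of
  its block: fraction f leaves ≈(1−f) mismatches, so f < 0.8 falls
  below the annotator's default 20% tolerance and reads as missing.
* **Promoter motifs** — a plan of (gene, motif, offset, strand) rows;
  the concrete word is drawn uniformly from the IUPAC expansion, is
  written strand-aware twice over (relative to the promoter and to the
  gene), and overlapping plants are an error so truth stays
  unambiguous. With `motif_free_background` the background is
  rejection-resampled until scanning yields exactly the planted
  occurrences; hits implied wholly by planted letters (palindromic
  classes such as GRE, or nested classes such as AUX1⊂AUX2) are
  accepted as deterministic consequences of the plan. Planted
  positions are tracked in genomic coordinates so cleaning one
  promoter can never disturb another gene's plant.
* **Ct tables** — Ct(gene, sample) = baseCt(gene, organ) − log2FC +
  ε, ε ~ N(0, noise_sd); the reference gene (ACTIN) has log2FC ≡ 0 but
  still carries measurement noise, as a real endogenous control does.
  The default design mirrors a rhizobial-infection study: organs root
  and shoot, five biological replicates, infection timepoints
  3/6/12/24/48/72 h post inoculation (3/6/12/24 h for the auxin
  treatment), and the four conditions −Sin/−NOA (mock), +Sin/−NOA,
  −Sin/+NOA, +Sin/+NOA, where Sin is the symbiont inoculation and NOA
  the auxin-influx inhibitor. The default planted effect is ±2 log2
  units (down in roots, up in shoots) attenuated to 0.25× under the
  inhibitor, with Ct noise 0.3 — effect sizes chosen as typical of
  strong qPCR responses with clearly resolvable replicate scatter.
* **Alignments** — gap-free random protein alignments; each planted
  sister pair is a copy with a single substitution, so the pair is a
  cherry with essentially certain bootstrap support.

What the generator does **not** emulate: codon structure or realistic
base composition, transcript isoforms and UTRs (UTRs are optional and
absent by default, so ORF length may be below the summed exon length
without error), indels in alignments, amplification-efficiency
variation, or any actual rhizobial biology — effects are user-specified
numbers. Passing tests therefore demonstrate algorithmic correctness
on data where the answer is known, not biological discovery power on
real genomes.

## Family identification

The profile-HMM search of a real survey is replaced by a deterministic
conserved-pattern scan: a protein is a candidate when either PB1-like
block (domain III or IV consensus) matches in an ungapped sliding
window with at most 20% mismatches. Identical sequences are collapsed
first, keeping the lexicographically smallest id, which makes the scan
idempotent. The pattern set and tolerance are configuration inputs;
the defaults are tuned to the synthetic blocks, and a real survey
should supply its own consensus (see `scripts/external_validation.py`).

Protein statistics: length aa = ORF/3 − 1 (stop codon excluded; a
non-codon-multiple ORF is an error naming the inconsistency, and
`validate_family_table` surfaces rows whose printed ORF and aa length
disagree rather than correcting them). Molecular weight is the sum of
average residue masses plus one water, in kDa. The isoelectric point
solves net charge = 0 by bisection on pH ∈ [0, 14] with an
EMBOSS-style pKa constant set (N-term 8.6, C-term 3.6, K 10.8, R 12.5,
H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1), stopping at |charge| < 1e−4.
Published pI values come from unspecified predictors with other pKa
sets, so exact reproduction of printed pI is not an acceptance
surface; tests check the defining zero-charge property and coarse
agreement with an independent implementation.

## Domain grammar

Domains are located by best ungapped sliding-window match against the
consensus blocks with ≤20% mismatches (the same threshold decides
"partially deleted" domains; the 20% default is an artifact decision —
published surveys describe partial domains only qualitatively). The
LxLxL rule takes the leftmost window with three leucines at alternating
positions; the printed canonical example TELRLGLPG itself carries only
three leucines, so the stricter four-leucine reading is a flag, not the
default. The degron is the first x-W-P-P-x window; canonical iff the
word is exactly GWPPV, otherwise the variant word is reported. NLS
rules (window sizes and basic-residue thresholds: 10/≥3 for the second
bipartite stretch, 7/≥4 for the typical signal within 15 residues after
domain IV) are artifact decisions calibrated to the planted signals; a
missing prerequisite domain simply makes the flag false.

## Phylogeny

Distances are p-distances with pairwise deletion (a pair with no
comparable columns is an error naming the pair) — a declared stand-in
for whatever distance model produced a given published tree. Neighbor
joining follows the Saitou–Nei Q-criterion with deterministic
tie-breaking (lowest index pair in the current ordering, which is what
row-major argmin yields on exact ties); negative branch-length
estimates are clamped to zero with the deficit logged. On any additive
matrix with positive branches the algorithm provably returns the
generating topology with exact path lengths, which the tests verify to
1e−9 against planted trees, with an independent NJ implementation
(scikit-bio) as a cross-check on noisy matrices.

Bootstrap supports resample alignment columns with replacement;
support of an internal edge is the percentage of replicate trees
containing the same bipartition (bipartitions are compared as
unordered pairs of leaf-label sets, so rooted and unrooted drawings
compare equal and supports are invariant to input order). Sister
pairs are cherries with support strictly greater than the threshold
(default 99), so a 100% threshold always returns nothing by design.

## Promoter scanning

The promoter is the window (default 1000 bp) immediately 5' of the
translation start — the ATG, not the transcription start — reported in
ATG-relative offsets −window..−1 of the hit's 5'-most base; windows
truncated at a chromosome edge carry a warning. Both strands are
scanned: minus-strand hits are found by matching the reverse
complement of the degenerate word and reported with the
promoter-forward letters. All overlapping occurrences count;
deduplication applies only to identical (motif, strand, offset). A
palindromic word yields mirrored hits on both strands; a flag collapses
them, and counting both is the default because published totals rarely
state their convention. Likewise, AUX1's expansion is a subset of
AUX2's, so with the default counting every strict-core occurrence
appears in both classes (AUX2 ≥ AUX1 always) and an exclusion flag
provides the other convention. A brute-force enumerator over all
windows × strands × expansions serves as the independent oracle.

## Expression

ΔCt = Ct_gene − Ct_ref is computed per replicate (matched on replicate
index) and then averaged — not Ct-averaged first — because the
per-replicate ΔCt values are what the t-test needs and the choice
affects variance. ΔΔCt is the difference of group means, fold =
2^−ΔΔCt (amplification efficiency exactly 2; efficiency correction is
out of scope). The p-value is a classical equal-variance two-sample
Student's t-test on replicate ΔCt values (Welch via a flag); direction
is the sign of the log2 fold when p < α (default 0.05), else "ns".
Zero within-group variance is handled explicitly (equal means → p = 1,
distinct noise-free means → p = 0). No multiple-testing correction is
applied by default because the emulated analyses report per-gene
tests; a Benjamini–Hochberg step would be easy to add downstream but
would change the reported quantities.

With every Ct noisy (including the reference), a replicate ΔCt has
variance 2σ², so the ΔΔCt estimate over n replicates per group has
standard deviation 2σ/√n and expected absolute error
2σ√(2/π)/√n — the band the tests check at σ = 0.3, n = 5 (≈0.214).
Under the null the ΔCt values are i.i.d. normal in both groups, so the
t-test is exact and its type-I error equals α; the Monte-Carlo check
uses one simulated cell per timepoint so that reference noise is
independent across the 1000 cells.

Tissue profiles rescale abundance 2^(Ct_ref(o) − Ct_g(o)) so that the
reference gene's anchor-organ cell reads 1000 units ("reference
anchor / 1000 = 1") — one declared interpretation of a convention that
published figure captions leave under-specified. The alleviation score
is |log2FC(infection)| − |log2FC(infection+inhibitor)| against the
common mock; positive values mean the inhibitor damps the infection
response.

## Pipeline

Stages (identify, domains, structure, promoters, tree, express) run
independently; absent inputs skip a stage with a warning, any failure
aborts naming the stage while earlier outputs are kept. Every run
writes a manifest with the seed, a config hash and stage timings;
deterministic stages are bit-reproducible and stochastic ones
seed-reproducible (verified in tests).

## Problem sizes

Defaults used by the test-suite and the acceptance script: 17-gene /
8-chromosome genomes; 100 random additive matrices of 4–8 taxa for NJ;
17-taxon alignments of 120 columns with 100 bootstrap replicates over
10–20 seeds for the sister-pair rule (the CLI default remains 1000
replicates for real analyses); 300–500 random ≤50 bp promoters for the
scanner oracle; 250 independent cells for the error band and 1000 for
the type-I check. These sizes make the checks sharp while keeping a
full run in well under a minute per component.

## Known limitations

* The family scan is a pattern matcher, not a profile HMM; divergent
  real family members could be missed and the default patterns only
  fit the synthetic blocks.
* p-distance NJ is the only tree method; no model-based distances,
  likelihood or parsimony, and no alignment computation (alignments
  are inputs).
* Group labels (the A–E clades of published family trees) are not
  re-derived; they would require reference-taxon anchors.
* Synteny/segmental-duplication detection is out of scope; only the
  sister-pair table is produced.
* Promoter scanning is exact-match degenerate-word counting; no PWM
  scoring, no statistical enrichment model.
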