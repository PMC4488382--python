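# Methods

`luciscreen` implements the comparative-genomics chain used to nominate
coelenterazine-biosynthesis candidate genes in ctenophores: a tripeptide
motif screen over predicted proteomes, gene-family grouping by percent
identity, catalytic-residue conservation mapping, a counting estimator of
dN/dS, distance-based trees, and a presence/absence association test. A
codon-level simulator generates complete synthetic studies with known
ground truth, so every stage and the end-to-end ranking can be validated
without external downloads.

## Motif screen

Proteins are scanned for a short exact peptide (default FYY,
phenylalanine-tyrosine-tyrosine — the residues whose side chains appear in
coelenterazine). Two modes matter scientifically: *any* (the motif occurs
somewhere in the protein; in a large proteome this is common by chance)
and *c_terminal* (the motif is the protein's suffix, the configuration
compatible with autocatalytic cleavage and cyclization). A single trailing
`*` stop symbol is stripped before suffix matching; sequences with
internal stops are rejected at parse time. Summaries count gene products
carrying at least one hit, not motif copies. `X` in a target sequence
never matches a concrete pattern residue (unknown residues are treated
conservatively); `X` in the pattern is a wildcard.

## Percent identity and its two gap conventions

For an aligned pair, *ignore_gaps* divides identities by columns where
both rows carry residues; *include_gaps* divides by columns where at least
one row does. A truncated but otherwise perfect homolog scores 100 under
the first and much lower under the second, which is exactly the contrast
used to recognize partial gene models. When pairs are projected out of a
multiple alignment, columns gapped in both members are dropped first. A
zero denominator raises rather than returning a silent 0. Identities
compare case-insensitively and `X` never counts as identical.

## Alignment

Pairwise global (Needleman-Wunsch/Gotoh) and local (Smith-Waterman)
alignment use affine gaps costing `gap_open + (k-1) * gap_extend` for a
length-k gap, BLOSUM62 by default with open 10 / extend 0.5 — a standard,
reproducible parameterization chosen because the examples must be
bit-stable, not tuned to any dataset. Traceback ties resolve
match/mismatch first, then gap in the first sequence, then gap in the
second, so outputs are identical across runs and platforms. The DP kernel
is numba-compiled and shared between sequence-sequence and
profile-profile alignment.

The progressive multiple aligner builds a neighbor-joining guide tree on
`d = 1 - identity/100` from all-pairs global alignments and merges
profiles bottom-up with average-of-pairs column scoring (gap mass scores
zero). It is a deterministic stand-in for production aligners such as
MAFFT: adequate for families above roughly 60% identity with modest
indels (tests require >= 95% correct column assignment of homologous
residues at ~85% identity), not for remote homology. Externally computed
alignments in aligned FASTA or Clustal format are accepted everywhere an
MSA is consumed.

## Conservation mapping

Catalytic positions are specified 1-based on an ungapped reference
(e.g. H245, D247, H301 — the 2-His-1-carboxylate facial triad that
coordinates Fe(II) in IPNS/DAOCS-family oxidases — and the R310-x-S312
pair that binds 2-oxoglutarate or the substrate carboxylate). Positions
are mapped through the reference row to alignment columns, and every
member's residues at those columns are reported. `triad_intact` requires
H/D/H; `rxs_intact` requires R and S (the middle residue is free by
definition). Members whose leading or trailing gap run covers a mapped
column are flagged partial and excluded from conservation denominators —
truncated transcripts should not count as losses. The consensus line uses
`*` for invariant gap-free columns and `.` for columns whose residues all
fall in one ClustalX "strong" similarity group (STA, NEQK, NHQK, NDEQ,
QHRK, MILV, MILF, HY, FYW); the group table is swappable. The conserved
tyrosine (Y221) is reported but deliberately not gated on, since its
orientation differs between IPNS and DAOCS and its functional requirement
is uncertain.

## dN/dS (Nei-Gojobori 1986)

Selection is measured with the NG86 counting estimator rather than an ML
codon model: the qualitative contrast (candidate family strongly
purifying, paralogs closer to neutral) is the claim being tested, and a
counting estimator is transparent, deterministic, and verifiable by
simulation. Output headers state the estimator. Per codon position, the
synonymous-site fraction is the share of the three possible nucleotide
changes that preserve the amino acid, with changes to stop codons removed
from numerator and denominator (the original NG86 convention). Codons
differing at k positions average synonymous/nonsynonymous difference
counts over all k! substitution orderings, skipping orderings that pass
through a stop; if every ordering does, positions are counted by direct
single-site comparison and the result is flagged. Proportions are
corrected with Jukes-Cantor, `d = -(3/4) ln(1 - 4p/3)`; `p >= 3/4` is
flagged saturated and the distance left undefined, never silently
numeric. `dS = 0` flags the ratio undefined; table output renders
undefined ratios as 0 (the reporting convention for comparisons the model
cannot evaluate) while keeping machine-readable flags.

Two properties of this estimator matter when reading results. With a
transition/transversion bias (kappa > 1) it overestimates synonymous
sites' usage and so underestimates omega by roughly 10-15% at kappa = 2.
And pathway averaging can attribute a small nonsynonymous signal to
purely synonymous histories: two synonymous hits at different positions
of one codon admit an ordering whose intermediate changes the amino acid,
so dN estimated from an omega = 0 simulation is not exactly zero once
codons take multiple hits. Both behaviors are quantified by the
simulation tests.

## Trees and phenotype association

Protein distances are p-distances over both-residue columns, optionally
Poisson-corrected (`-ln(1 - p)`). Neighbor joining (Saitou-Nei, Q-matrix
selection) breaks ties by the lowest label-index pair and clamps negative
branch lengths to zero; on additive matrices it reproduces all path
lengths to 1e-9 (tested). NJ is used instead of ML inference because the
assertable claims are grouping claims — each planted or printed family
forms its own clade — and NJ is deterministic and dependency-free. Trees
are dendropy objects; Newick output uses unquoted sanitized labels with
6-significant-digit branch lengths.

Family presence/absence across species is tested against the binary
luminous phenotype with a two-sided Fisher exact test computed by full
hypergeometric enumeration (all tables with probability not exceeding the
observed one). With 20 luminous species carrying a family that both
non-luminous species lack, p = 1/C(22,2) = 1/231 ≈ 0.0043. The original
argument here is qualitative (a small natural control group); the test is an
added formalization and output labels it as such.

## Homolog search and completeness survey

Homolog detection is a seeded Smith-Waterman: candidates must share an
exact 4-mer with the query, survivors are scored by full local alignment,
and the best score wins (ties by target id). Seeds only prune; tests
check equivalence with an exhaustive scan. A hit must score at least 40
(random same-length protein pairs rarely exceed ~35 under BLOSUM62). The
transcriptome completeness survey calls a reference gene full-length at
query coverage >= 0.8 and identity >= 30, partial at coverage in
[0.3, 0.8); these thresholds are not derived from any published criterion
and are declared in output headers. BLAST tabular output (outfmt 6) can
be imported for users who prefer external search. Family grouping is
single-linkage clustering of the identity matrix: any chain of pairwise
identities above threshold merges clusters; family numbering follows the
smallest member label, so it is deterministic.

## Synthetic studies

The generator emulates the study design the analysis assumes. A Yule
(pure-birth) species tree over 20 luminous and 2 non-luminous taxa is
rescaled to unit root-to-tip depth; branch lengths are then expected
substitutions per codon. The two non-luminous species are placed as a
cherry when one exists, mirroring a non-luminous sister clade. Three gene
families evolve on the same species tree, differing only in omega:
the candidate (omega 0.1, 330 codons, FYY suffix, triad/RXS/Y anchors at
the reference-style positions 221/245/247/301/310/312) present only in
luminous species, and two paralog families (omega 0.3 and 0.5) present
everywhere. The triad and RXS sites are locked (invariant) in all three
families — in the real system all three groups retain iron-binding
residues, and the discriminating signals are the motif suffix, the
phenotype association, and omega. Paralogs and decoys carry a pinned
terminal leucine, so no non-candidate sequence can end in the motif under
any seed; decoys (5 per species, 200 codons) carry the motif internally,
which makes the anywhere-mode screen fire in every species while the
C-terminal screen fires only in luminous ones.

Codon evolution is an exact per-codon Gillespie simulation: the rate of a
single-nucleotide codon change is
`kappa^[transition] * omega^[nonsynonymous] * pi(target nucleotide)`,
changes to stops are forbidden, and rates are normalized by the mean
total rate over the root's codons so branch lengths read as expected
substitutions per codon. Position-specific nucleotide frequencies default
to F3X4 estimated from the root CDS (with a half-count pseudocount).
Per-branch random streams are split from the master seed by the CRC32 of
the sorted leaf set below the branch, so adding taxa does not perturb
existing lineages, and the full event log is retained for oracle tests
(between root and leaf, counting differences can fall short of logged
events only through multiple hits at one codon). The generator writes
per-species proteome and CDS FASTA, a phenotype table, a positions table,
the species tree, and a JSON truth manifest sufficient to recompute every
expected value downstream.

What the simulator deliberately does not model: indels (planted families
are gapless, so alignment is exercised separately on constructed
indel fixtures), rate heterogeneity beyond invariant sites, expression
noise or assembly artifacts, and contamination. Passing end-to-end tests
therefore demonstrates the pipeline's logic and statistics, not
robustness to assembly quality.

## Pipeline and ranking

The pipeline screens every proteome, clusters all pooled proteins
(all-vs-all global identity with an exact 5-mer prefilter; pairs sharing
no 5-mer get identity 0, which cannot affect clustering at the default
threshold of 40), aligns each multi-member family, maps catalytic
positions (the positions file names a reference per family), computes
median pairwise omega from back-translated codon alignments, tests
phenotype association, and ranks families lexicographically by
(C-terminal motif presence, triad-intact fraction, Fisher p, median
omega). The ranking is lexicographic because the underlying argument is a
chain of qualitative gates, not a weighted score; the order is stated in
the report header. Reruns with the same configuration and seed are
byte-identical (no timestamps in outputs).

## Problem sizes used in validation

Unit tests run the generator at 8-12 species and 80-150 codons; the
end-to-end and recovery checks use the full default study (22 species,
330 codons) and 100 two-taxon replicates of 500 codons at a total
divergence of 0.5 substitutions per codon — a mid-range divergence well
below Jukes-Cantor saturation, fixed before any estimator measurements.
The whole suite completes in about a minute on one core.
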