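# Methods

This note documents the models, parameter choices and numerical
conventions behind the package, and what the simulation-based tests do and
do not demonstrate about real data.

## Substitution model and the divergence dial

Sequences evolve under the empirical Dayhoff PAM model.  The generator is
built from the standard Dayhoff exchangeabilities and equilibrium
frequencies (`dayhoff.dat` convention, residue order ARNDCQEGHILKMFPSTWYV)
and scaled so one time unit equals 1 PAM = 0.01 expected accepted
substitutions per site.  A branch of length *d* PAM substitutes each site
by sampling from the corresponding row of the PAM-1 matrix raised to the
`round(d)`-th power; powers are computed spectrally (the model is
reversible, so the symmetrized generator has a real orthogonal eigenbasis)
and cached per integer distance.  Two leaves whose connecting path is *d*
PAM then share an expected fraction `Σ_a π_a [P^d]_aa` of identical sites,
which is 43% at 100 PAM, 18.5% at 250, and 7.1% at 700, approaching the
`Σ_a π_a²≈ 6%` random floor.

**Divergence dial.** A family's divergence is specified as the *mean
pairwise* leaf-to-leaf path length in PAM units: the generated unit-depth
clock tree is rescaled by a single factor so the mean over all unordered
leaf pairs hits the target.  (Root-to-leaf depth was the other candidate
convention; mean pairwise was chosen because it reproduces the published
identity ladder — about 10% at 550 PAM, 9.0% at 650 and 8.6% at 700 —
once the spread of pairwise distances in a clock tree is accounted for.
This convention is fixed and not revisited.)

## Trees

Three ultrametric topologies, all with unit root-to-leaf depth before
scaling:

- `yule` — pure-birth tree: exponential waiting times (rate proportional
  to the number of lineages), a uniformly chosen lineage splits; leaf
  labels are assigned in random order.
- `balanced` — near-perfect binary tree; internal node heights
  proportional to subtree depth.
- `pectinate` — caterpillar with equally spaced join heights.

A strict molecular clock is assumed throughout; rate-heterogeneous
branches are out of scope.

## Indels and the true alignment

Indel events on a branch are Poisson with expectation
`ISR × (d/100) × L` (ISR = indel events per expected substitution,
default 0.03 in the benchmark conditions; 0 gives a substitution-only
process).  Each event is an insertion or deletion with probability ½;
lengths follow a Zipf law truncated at 40 (exponent 1.7, both
config-exposed); insertions draw residues from the equilibrium
frequencies.  Every surviving alignment column is tracked through a global
linked column list, so the emitted true alignment is exact: ungapping any
row reproduces the leaf sequence, by construction and by test.

Pairwise identity is measured over residue–residue columns only (columns
where either row has a gap are excluded from numerator and denominator).
Both gap statistics are reported — indel *events* per residue and gap
*characters* per residue — because the two differ by an order of magnitude
once alignments of 100 deeply diverged sequences accumulate insertion
columns (at 550 PAM a typical family shows ~0.02 events but ~4 gap
characters per position).

## Profile library

Each query seeds a PSSM over its own coordinates (`plen` = seed length).
Gathering iterates up to 6 times at e-value cutoff 1e-6: search the
current profile against the database, add every hit below the cutoff to
the member set (the set only grows, so gathering is monotone), rebuild,
repeat until no new member.  The default database is the query set itself
— synthetic families have no outside homologs, so there is nothing else
to gather from; an external FASTA can be supplied to enrich profiles.

Member rows are weighted with position-based (Henikoff) weights,
frequencies are blended with the background through a single
background-proportional pseudocount weight (default 1.0 per column), and
scores are `log2(freq/background)`.  This is deliberately simpler than
PSI-BLAST's data-dependent pseudocounts; the practical consequence is
that a single-sequence profile scores all mismatches equally (no
substitution-similarity prior), making first-iteration gathering
conservative at high divergence.

E-values are an extreme-value stand-in for BLAST statistics: a Gumbel law
is moment-fitted to the profile's scores against shuffled database
sequences (12 shuffles by default, seeded), and the fitted tail
probability is multiplied by the database size.  Monotone in the raw
score and deterministic, but not bit-compatible with NCBI e-values.

## Alignment engine and score conventions

Query-vs-profile alignment is local Smith–Waterman/Gotoh on the profile's
score rows; a maximal gap run of length L costs `gap_open + L×gap_extend`
(defaults 11 and 1, the BLAST convention, in the profile's log2-odds
units).  Ties prefer the earlier end cell and the diagonal state, making
the traceback deterministic.  An "identical residue" means the query
residue equals the profile's *seed* residue at that position.  `alen`
counts all alignment columns, `aqlen` those carrying a query residue, and
`gap_chars = alen − aqlen` (query-gap view) — the convention forced by the
exact identity `%i × %c = (1 − p_ARP)(1 − w_g)`.  Coverage is clamped to 1
when query insertions push `aqlen` above `plen`, keeping scores in [0, 1];
product scores are kept as fractions rather than percent×percent, since
NJ topology is invariant to uniform scaling (the scale is recorded in the
matrix metadata).  The e-value ceiling of 1e10 during matrix population is
implemented literally as "keep every positive local alignment".

## Distances, trees, support

Euclidean distances over the M score coordinates are symmetrized exactly
and satisfy the metric axioms by construction.  Neighbor joining is
canonical (Q criterion, Studier–Keppler updates) with two determinism
rules: Q ties resolve to the smallest (row, column) pair in current
matrix order, and negative branch estimates clamp to 0.  BioNJ
(variance-weighted updates) is available behind the same interface.

Support resampling treats the PSSM columns of the N×M matrix as the
exchangeable unit — the method has no site matrix, so columns are the
only defensible analogue of bootstrap characters.  Bootstrap draws M
columns with replacement, the 80% jackknife draws ⌊0.8M⌋ without;
support of an internal branch is the percentage of replicate trees
containing its bipartition.

## Tree comparison

RF distance counts non-trivial bipartitions only, on unrooted trees
(PHYLIP `treedist` convention); the maximum for fully resolved trees is
2(n−3).  Consensus marks annotate each internal branch of the true tree
100 (recovered) or 50 (missed); for resolved trees the 50-count is RF/2.
"Deep nodes" — ancestors of the last two tiers of leaves — are
operationalized as internal nodes whose closest descendant leaf is ≥ 2
edges away (threshold config-exposed); the root's trivial split counts as
always recovered.

## Benchmark conditions and their rationale

The identity-calibration runs use the published conditions directly: 100
sequences, mean length 450, Yule clock trees, ISR 0.03, ten replicates
per divergence level.

The accuracy-vs-divergence benchmark (50 taxa, 5 replicates per level,
450 aa) runs on the **balanced** ("unbiased") topology rather than Yule.
The reason is identifiability, not convenience: a coalescent-height Yule
tree of 50 taxa typically contains several internal branches carrying
less than one expected substitution, and *no* method — including NJ on
p-distances from the true alignment — can recover those, so RF at low
divergence would measure tree-shape luck rather than method quality.  The
published benchmark behavior (every method near RF 0 at 100 PAM) implies
resolvable tree shapes, and balanced trees are one of that study's stated
topology conditions.  Problem sizes (replicate counts, 50 taxa) are
scaled-down choices to keep the default suite desk-scale.

The built-in baselines are computed in-repo: p-distance NJ on the true
alignment, and p-distance NJ on global pairwise alignments
(BLOSUM62, gap open/extend 11/1).  External MSA and ML/Bayesian programs
are out of scope.

## What the synthetic tests do not show

The generator emulates substitution saturation, indel load and clock-like
divergence.  It does not emulate domain shuffling, translocation,
recombination, site-rate heterogeneity, compositional drift, or the
presence of true homologs in a large background database (the published
analyses gathered profiles against nr; here profiles are enriched only
from the family itself, which weakens them at extreme divergence).
Passing the benchmark therefore shows the pipeline is correct and behaves
as published *under the model*; it does not certify accuracy on
biological families with those complications.

## Numerical and degenerate-input conventions

- Matrix powers cached per integer PAM distance; probabilities clipped at
  0 and row-renormalized to absorb spectral round-off.
- Identity of a leaf pair with no shared residue columns is 0 (distance 1
  in the p-distance baselines).
- ISR statistic is 0 for a family with no substitutions; average gap
  length is 0 for an indel-free family.
- Zero-length trees cannot be rescaled (error); zero-length branches are
  legal and simply copy sequences.
- All randomness flows from integer seeds through numpy Generators;
  per-replicate and per-stage substreams are derived with SeedSequence so
  every artifact is byte-reproducible.
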