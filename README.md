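# phyrn

Alignment-free phylogenetic inference for deeply diverged protein
families, together with the synthetic-evolution benchmark harness used to
evaluate it.

## The problem

Below ~25% pairwise identity (the "twilight zone") multiple sequence
alignments degrade; near ~10% (the "midnight zone") they are mostly
noise, and tree inference built on them fails no matter how good the tree
method is.  PHYRN sidesteps the MSA entirely: it measures every sequence
against a library of position-specific scoring matrices (PSSMs) and lets
the *pattern* of profile similarities, rather than a column-wise
alignment, carry the phylogenetic signal.

## The method

For a set of N query sequences and a library of M PSSMs (one gathered per
query by iterative profile search, 6 iterations at e-value 1e-6), each
query *n* is locally aligned to each profile *m* (Smith–Waterman, affine
gaps, position-specific scores) and the best alignment is condensed into
the **product score**

    s(n, m) = %identity × %coverage
            = (ids / alen) × (aqlen / plen)
            = (1 − p_ARP)(1 − w_g)

where `ids` is the number of identical residues, `alen` the alignment
length including gaps, `aqlen` the alignment length in the query excluding
gaps, `plen` the profile length, `p_ARP = (plen − ids)/plen` the
alignment-restricted p-distance and `w_g = gap_chars/alen` the gap weight.
Cells with no positive-scoring alignment are 0.  Each sequence is thus a
point in M-dimensional score space; pairwise distances are Euclidean,

    D(X, Y) = sqrt( Σ_m (x_m − y_m)² ),

and the tree is inferred by neighbor joining (BioNJ available behind the
same interface).  Branch support comes from resampling profile columns of
the N×M matrix: bootstrap (with replacement) or 80% jackknife.

The benchmark half of the package evolves protein families down ultrametric
clock trees under the Dayhoff PAM model (substitutions from PAM-1 matrix
powers, Poisson indel events with Zipf lengths) while recording the exact
true alignment, then scores inferred trees with the Robinson–Foulds
distance (maximum 2(n−3)), consensus 100/50 branch marks, and deep-node
recapitulation.

## Worked example

`examples/03_tree_with_support.py` simulates a 20-taxon family at 250 PAM
mean pairwise divergence, builds the profile library, scores the matrix,
infers the NJ tree and audits it against the known truth:

```
RF distance to true tree:  14 (max possible 34)
deep-node recapitulation:  33.3%
jackknife supports:        median 100%, min 40%
```

followed by the support-annotated newick tree.  Reading the numbers: 7 of
the 17 internal branches are wrong (RF counts 2 per wrong branch) — this
random clock tree contains several internal branches carrying less than
one expected substitution, which no method can recover; branches that are
recovered tend to be stable under column resampling (median support
100%).  The other example scripts cover simulation statistics
(`01`), the score matrix itself (`02`), and the accuracy-vs-divergence
benchmark against a pairwise p-distance baseline (`04`).

A command-line interface mirrors the library:

```bash
phyrn simulate --n-taxa 100 --pam 550 --out-dir fam/
phyrn build-profiles --queries fam/rep000.fasta --out lib.pssm
phyrn score --queries fam/rep000.fasta --library lib.pssm --out matrix.tsv
phyrn tree --matrix matrix.tsv --support jackknife80 --out tree.nwk
phyrn compare --true fam/rep000.true_tree.nwk --est tree.nwk --deep-nodes
phyrn run --config run.yaml      # the whole pipeline, reproducibly
```

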