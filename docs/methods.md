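# Methods

This note documents the models and procedures implemented in `virsig`,
the parameters that matter, the numerical choices made where the
design was open, and what the synthetic data can and cannot show.

## Signature model

A genome is represented by two vectors indexed against a fixed,
ordered profile database built per Baltimore group (groups VI and VII
share one database, reflecting the protein similarity between RT-RNA
and RT-DNA viruses):

* **PPHMM signature** `s ∈ R^P, s ≥ 0`: per-profile similarity score;
  0 means no significant hit. When a profile hits several regions the
  retained per-domain bit scores are summed, so the score is monotone
  in the total evidence across the genome (hit filters: conditional
  E-value ≤ 0.001 and positive score).
* **Gene-location vector** `l ∈ R^P`: the nucleotide midpoint of the
  best hit per profile, signed by strand, 0 when absent. A protein
  position `p` in forward frame `f ∈ {1,2,3}` of the six-frame
  translation maps to nucleotide `(f−1) + 3(p−1) + 2` (the codon
  midpoint, 1-based); reverse frames map through the
  reverse-complement coordinate and are negated.

A family's **genome-organisation model (GOM)** stacks its members'
location vectors. The **GOM signature** entry for family `g` is the
Székely distance correlation between the query's location vector and
the GOM matrix, pairing observations by profile index (the query
contributes a scalar per profile, the GOM a vector over members).
Indices absent from both sides are ignored; fewer than two usable
indices, or zero distance variance on either side, give 0. The
implementation is the plain double-centring formula (O(n²) in the
number of usable profiles), validated against an independent
brute-force oracle to 1e−10.

### Strand handling

Signed midpoints are not invariant under reverse-complementing the
input: a strand flip maps `v → v − sign(v)(L+1)`, which preserves
distances within a strand but not between strands. To make annotation
strand-independent the annotator always scans the canonical
orientation of the concatenated genome (the lexicographically smaller
of the sequence and its reverse complement). Genome and
reverse-complemented genome therefore produce bit-identical
signatures. For segmented genomes the canonicalisation happens after
largest-to-smallest concatenation, so invariance is exact only for
unsegmented inputs; segment-level strand conventions remain the
submitter's.

## Similarity and trees

CGJ similarity is the geometric mean of generalised Jaccard indices
over the PPHMM signatures (J_p) and GOM signatures (J_o);
`D = 1 − CGJ`. Two conventions close the degenerate cases: an empty
union (`Σ max = 0`) gives J = 0 ("no detectable similarity", D = 1),
which also means a genome whose GOM signature is all-zero is maximally
distant from everything — self-similarity equals 1 only for genomes
with at least one profile hit and one nonzero GOM-signature entry, the
situation every annotated reference genome is in.

UPGMA uses size-weighted average linkage with merge height `d/2`; ties
are broken on the lexicographically smallest pair of cluster
representative labels (the smallest member leaf), which makes trees
deterministic. The output is checked against SciPy's average-linkage
cophenetic matrices on random inputs. Cophenetic correlation is the
Pearson correlation between cophenetic (2 × LCA height) and input
distances over all pairs.

**Bootstrap.** Profile columns are resampled with replacement
(uniform, default 100 replicates); the score and location columns are
taken directly and the GOMs and GOM signatures are recomputed from the
resampled location columns. This is equivalent to re-annotating
against a resampled profile database — per-profile scores and
locations do not depend on other profiles — and orders of magnitude
faster than re-scanning. Clade support is the fraction of replicates
containing the same leaf set as a clade. Sub-clade re-bootstraps first
drop profiles no clade member hits and GOMs of families outside the
clade, which protects small genomes from "empty profile" resamples.

## Classification

1-NN on CGJ proposes the family of the most similar reference (ties:
smallest accession). Validation is two-step:

* **Threshold.** Per family, a linear SVM with balanced class weights
  is fitted to the 1-D intra- vs inter-family CGJ score distributions
  (at most 10,000 scores per side, seeded subsample); the decision
  boundary is the threshold and `cgj ≥ threshold` passes (rejection is
  defined by "less than"). Families with no intra pairs (single
  member) fall back to the largest observed inter-family score;
  no inter scores at all give threshold 0 with a warning.
* **Topology.** One joint UPGMA dendrogram holds all references and
  all co-analysed queries. A candidate is accepted when the query's
  sister clade, its immediate outgroup, or one of the two basal
  branches of its sister clade consists entirely of candidate-family
  references. Co-analysed queries carry no labels yet, so each query
  is evaluated on the joint tree restricted to the references plus
  itself (other query leaves pruned, unary nodes collapsed);
  without this restriction two same-family queries placed as sisters
  would block each other. A condition needs at least one reference
  leaf to fire.

Sub-pipelines run independently per Baltimore group; acceptance in
several is arbitrated by the highest CGJ, no acceptance anywhere means
"unclassified".

Cross-validation repeats independent random 67/33 reference/test
splits per family (families with fewer than three members, and any
family listed as always-held-out, go entirely to the test side).
Sensitivity is the fraction of test viruses from represented families
assigned to their own family; specificity the fraction of test viruses
from unrepresented families labelled unclassified.

For assembled metagenomic contigs a per-family length filter (minimum
reference genome length of the provisionally assigned family, ≥
passes) excludes obvious partials, and databases can be updated by
pooling proteins of new genomes — including those failing the length
filter — with the reference proteins and rebuilding the clustering.

## Engines

The paper-facing contribution (signatures, CGJ, GOMs, distance
correlation, UPGMA/bootstrap, classifier) is implemented here; the
standard steps delegate to established tools behind fixed interfaces,
so downstream code sees only (score, E-value, location) triples:

* Protein search: BLASTp (tabular output) when on PATH, otherwise a
  native Smith–Waterman engine (Biopython PairwiseAligner, BLOSUM62,
  gap open −11/extend −1) with Karlin–Altschul bit scores
  (λ = 0.267, K = 0.041), an `m·n` search space for the E-value, and a
  shared-4-mer prefilter (≥ 3 shared) to skip hopeless pairs. Both
  engines agree on which pairs survive the hit filter on the synthetic
  fixtures.
* Hit filter: E ≤ 0.001, identity ≥ 30%, both coverages ≥ 75%
  (coverage = aligned span of the best HSP over full length).
* MCL: native implementation — symmetric adjacency from best-hit bit
  scores, self-loops at the maximum incident weight, column
  normalisation, expansion/inflation (2.0) to convergence (max change
  < 1e−8, cap 200 iterations, entries < 1e−12 pruned); each connected
  component is clustered separately, which is equivalent and faster.
* Alignment: MAFFT (default settings) when on PATH, else a star
  alignment around the longest member from pairwise global alignments.
* Profile HMMs: pyhmmer `Builder` with default settings; scanning with
  pyhmmer's hmmscan, bias-composition filter disabled. Stops in the
  frame translations are passed to the scanner as `X`.

## Synthetic data

`simulate_reference_set` emulates the structure the classifier
assumes: families own disjoint (optionally partially shared) gene
repertoires in a conserved order and strand layout. Each gene's
ancestor is fixed at the nucleotide level; members substitute amino
acids at the per-site divergence rate (default 0.15, a level at which
homologs still clear the 30%-identity filter comfortably) and mutated
positions get a random synonymous codon. Genes are flanked by
intergenic spacers whose ends carry `TTAA`-repeat cassettes — their
own reverse complement, with stop codons in all six frames — so ORF
prediction recovers exactly the planted genes (plus occasional
"shadow ORFs": stop-free readings of a real gene in another frame,
which are family-conserved and harmless). Defaults: 12 families × 8
genomes × 6 genes of 120–250 aa, 25% reverse-strand gene slots,
unsegmented; the cross-validation analogue uses 15 + 3 held-out
families × 9 genomes, a size at which database construction and
threefold cross-validation complete in minutes on one CPU.

What this does not emulate: indels and rate heterogeneity, gene
gain/loss within families, overlapping genes, shared genes across
distant families (unless configured), database-scale unbalanced family
sizes, and sequencing artefacts. Passing tests therefore demonstrate
the machinery's correctness and its behaviour under clean family
structure, not performance on real taxonomies.

`simulate_signature_table` skips the sequence level entirely and emits
block-structured score/location tables with configurable noise for
fast tests of the similarity, dendrogram and classification layers;
its GOM signatures are computed with the real distance-correlation
machinery.

## Known limitations

* The per-profile "overall score" is the sum of retained domain
  scores, a documented approximation of a full-sequence forward score.
* Distance-correlation pairing is by profile index (the only pairing
  defined for one query against a family matrix).
* Strand invariance is exact for unsegmented genomes only (see above).
* Genus/species-level criteria, automated naming of novel groups, and
  bipartite-network views are out of scope.
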