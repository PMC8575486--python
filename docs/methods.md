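# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `gvtaxon`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic study system

Every stage of the pipeline is validated against a generator that plants
a known four-rank taxonomy (class / order / family / genus) and emits
all the data types the real procedure consumes.

**Taxonomy and tree.** Rank labels are nested by construction. The tree
is built directly from the taxonomy rather than from a birth–death
process: the most recent common ancestor of each rank-*r* taxon is
placed at a configured fraction of the root-to-tip distance
(`rank_depth_fractions`, default 0.05 / 0.20 / 0.60 / 0.85 on a
unit-depth tree). Placing depths by construction makes the per-rank RED
windows analytically known, which is what the delineation stage needs to
be testable. `branch_noise` multiplies every branch length by an
independent mean-preserving log-normal factor with the given coefficient
of variation (default 0.2 — enough to scatter node depths visibly while
keeping ranks separable). Unary chains arising from rank counts of 1 are
collapsed; branch lengths add, so depths are unchanged.

**Markers.** Amino-acid alignments are evolved site-independently along
the tree under an equal-rates (Jukes–Cantor-type) 20-state model at
`subst_rate` = 1 substitution/site per unit branch length. No indels are
simulated, so the generator's output is a valid alignment as emitted and
external aligners stay entirely out of the test path (an aligner is a
pluggable backend in the real pipeline). Marker loss (default 10% per
genome per marker) emulates the incompleteness of metagenome-assembled
genomes; paralogs (default 5%) are produced by re-evolving a genome's
ortholog for an extra 2× its terminal branch length, which guarantees
the paralog scores below the ortholog against the family profile in
expectation — the same best-hit/extra-copy dichotomy that multi-copy
capsid genes produce in real data.

**Genomes.** Nucleotide genomes (default 20 kbp) are emitted as an
ancestor plus one mutant per entry of `divergence_grid`, each site
substituted with the grid probability. Divergences above 0.5 are
rejected: at k = 16 the expected shared-k-mer fraction (1−g)^k is
already ≈ 10⁻⁵ at g = 0.5, so the Jaccard signal is saturated and a
"distance" would be meaningless.

**Bootstrap sets.** Replicate trees preserve each reference bipartition
with its planted concordance; a branch that fails its draw undergoes a
*deterministic* nearest-neighbour interchange (always the
alphabetically first child and first sibling), so every rearrangement of
a branch produces the same rival bipartition. This makes the expected
IC of a branch with concordance c exactly `ic(c, 1−c)` and lets the
support machinery be tested against a closed form.

What the generator does **not** emulate: realistic genome architecture,
gene order, GC content, indel evolution, rate heterogeneity across sites
or lineages, recombination, and compositional biases. Passing tests
demonstrate that the pipeline's logic is correct and internally
consistent, not that it is robust to every pathology of real sequence
data.

## Genome dereplication

Sketches are bottom-*s* MinHash signatures (defaults k = 16, s = 300,
matching standard sketching practice for viral genomes) over canonical
k-mers hashed with a keyed 64-bit hash; the hash seed is recorded in the
sketch header. Only the distance *semantics* of the published MinHash
method are reproduced — not its exact hash values or binary format, so
sketches are not interchangeable with other tools' sketch files. The
Jaccard index is estimated from the merged bottom-*s* sketch (shared
hashes among the s smallest of the union); j = 0 maps to a finite
distance cap of 1.0, recorded in output metadata, so distance matrices
stay finite. Single-linkage clustering at d ≤ 0.05 (≈ 95% average
nucleotide identity) uses connected components; representatives are the
highest-N50 members, with ties broken lexicographically by genome id for
reproducibility. Contigs with no entry in the external score table are
retained, since scoring is an optional upstream input.

## Orthogroups and profiles

Orthogroup inference approximates the reciprocal-near-best-hit strategy
of standard orthology tools: all-vs-all local alignment (BLOSUM62 Gotoh,
via Biopython), edges kept at e-value ≤ 1e-5, identity ≥ 25%, mutual
coverage ≥ 50%, and both directions within a 0.80 similarity factor of
the query's best hit into the target genome; groups are connected
components (no spectral partitioning). Bit scores use the standard
gapped BLOSUM62 Karlin–Altschul parameters; e-values are therefore
approximate and all thresholds are exposed as parameters.

Profiles are position-specific log-odds matrices (trimmed-alignment
columns × 20 residues, in bits, uniform background, one pseudocount)
with affine gap penalties (open 4 bits, extend 0.5 bits), scored by
local Gotoh alignment. A full profile-HMM with forward scoring would be
a legitimate upgrade; the downstream merge and annotation rules depend
only on hit *fractions*, not on any particular scorer's absolute values.
E-values come from a Gumbel null fitted to 200 seeded random sequences
drawn from the background at build time; they are calibrated to this
scorer and differ from those of external profile-search tools, which is
why every e-value threshold (1e-5, 1e-10, 1e-20) is configurable.

Alignment trimming keeps exactly the columns whose non-gap fraction is
≥ the gap threshold (default 0.1), the standard `-gt` semantics; the
operation is idempotent. Merging is a single pass: an undirected edge
joins two groups iff strictly more than half of each group's proteins
hit the other's profile (retained hits only: e ≤ 1e-20 and ≥ 30% of the
query aligned); merged groups are connected components and profiles are
rebuilt once from pooled members. Iterating the merge to a fixpoint was
considered and rejected — a single pass is deterministic, cheap, and
the chained-component behaviour already captures transitive similarity.

The prevalence threshold for candidate markers is strict (> 0.70), as is
the merge fraction (> 0.5) and the annotation consensus (> 0.5); all
three are parameters. Prevalence is computed from hits at e ≤ 1e-10 by
default; the search cutoff used for prevalence elsewhere appears as both
1e-10 and 1e-5 in the field's practice, so both are exposed.

## Marker extraction, concatenation, benchmarking

Bit-score cutoffs are the **nearest-rank** fifth percentile of the
per-genome best-hit scores (rank = ⌈p/100·n⌉, 1-indexed ascending);
linear interpolation is available as an option. Nearest-rank was chosen
because it is exact on small samples and involves no averaging of
scores from different genomes. Above-cutoff survivors per (genome,
marker) are ranked by bit score with lexicographic protein-id
tie-breaks; the top hit is the ortholog, the rest are flagged extra
copies. Note an interaction worth knowing: paralogs planted at 2× extra
divergence usually fall *below* the calibrated cutoff entirely, so they
are excluded rather than flagged; either disposition keeps them out of
the concatenated alignment, which is the property that matters.

Concatenation orders markers alphabetically (the reference
implementation's order is unspecified; alphabetical is reproducible),
gap-fills missing markers across their full partition width, and emits
partitions internally as 0-based half-open intervals, converted to the
conventional 1-based inclusive `PROT, name = start-end` text at the
file boundary.

The built-in tree backend is neighbour joining (scikit-bio) on pairwise
distances from alignment identity with the 20-state equal-rates
correction d = −(19/20)·ln(1 − 20p/19), p capped at 0.94 to keep
distances finite. The plain Poisson form −ln(1−p) was evaluated and
rejected: under a 20-state model it compresses deep branches enough to
push class-level nodes out of their RED windows even on noise-free
data, whereas the 20-state form is the exact inverse of the generator's
model. External maximum-likelihood backends plug in as callables; the
backend used is stamped into every result. Bootstrap resampling draws
sites within partitions, preserving the partition structure. The
benchmarking protocol runs each candidate set `n_runs` = 5 times with
independently seeded bootstrap sets and reports the run with the
highest relative TC.

## Tree support (IC/TC)

The IC variant is the "observed bipartitions only" form: p₁ is the
reference bipartition's frequency in the bootstrap set, p₂ the highest
frequency among observed bipartitions conflicting with it (two splits
conflict iff none of their four side-intersections is empty). The
reference tree is not added to the sample. A reference branch never
observed in the sample (p₁ = 0) gets IC from the same formula — which
yields −1 when an unopposed rival exists — and is flagged
`absent_from_sample`; a branch with p₁ = p₂ = 0 contributes 0. Relative
TC divides the IC sum by n − 3, the internal-branch count of a resolved
unrooted tree, giving the headline statistic in [−1, 1]; the raw sum is
always reported alongside.

## RED and rank delineation

RED follows the standard recursion red(n) = red(p) + x/(x+ȳ)·(1−red(p))
with the root fixed at 0 and leaves at 1; ȳ is the mean path length to
descendant tips, so polytomies are handled natively and no resolution is
performed.

The published procedure constrains ranks to nonoverlapping RED windows
but does not specify the cut algorithm or numeric windows; both are
therefore first-class, user-visible artifacts here. The cut rule is:
pre-order traversal, a clade starts at the *shallowest* node whose RED
falls in a rank's window and that is not already inside a same-rank
clade — the maximal-clade reading of the nonoverlap constraint. Windows
come either from configuration or from anchors: each rank's core
interval spans its anchored MRCAs' [min, max] RED and boundaries sit at
midpoints between adjacent ranks (and halfway to the root below classes,
halfway to the leaves above genera). Overlapping anchored ranges raise
an error demanding manual windows rather than guessing. The pipeline
default derives windows from the *noise-free twin* of the simulation
config, where rank REDs are exact by construction.

Minimum clade sizes default to 3 for families (smaller groups dissolve
to incertae sedis) and 1 elsewhere — singleton genera are legitimate and
common, and a leaf never cut at genus depth is scored as its own
singleton, so a true singleton genus flagged incertae sedis still counts
as correctly recovered. Rank decisions are independent: a long branch
that skips the family window leaves a genome family-incertae-sedis while
a deeper node can still assign its genus.

Anchored clades adopt their anchor's name (conflicting anchors in one
clade are an error listing both); unanchored families receive
order-prefixed identifiers `PREFIX_NN`, numbered by pre-order appearance
in the tree — stable under any permutation of input files — and
anchored families consume no number. A constraints hook for manual
placements (forcing a leaf set to a named rank) is applied after
delineation and logged.

## Pipeline, determinism, problem sizes

A single global seed fans out to per-stage seeds through a keyed hash of
`"{seed}:{stage}"`, so adding or removing stages never perturbs other
stages' randomness. Every stage writes its outputs plus a manifest of
SHA-256 content digests; deterministic stages reproduce digests exactly
under the same config and seed, which the acceptance suite verifies by
running the full pipeline twice.

Default problem sizes are chosen for a single CPU: the study system is
48 genomes with 7 markers (80–300 aligned residues each), bootstrap
sets are 100 replicates in the pipeline and 1000 where a binomial
tolerance is being tested, the profile null uses 200 draws, and
exhaustive oracles run at 6 leaves (all 105 topologies) and 8 leaves
(all 10,395, for split compatibility). These sizes make every
statistical tolerance in the test suite a ≥ 3-standard-deviation bound.

## Known limitations

* The profile scorer is a log-odds matrix, not a profile HMM; its
  e-values are self-calibrated and not comparable across tools.
* Orthogroup e-values use fixed Karlin–Altschul constants rather than
  per-alignment estimation.
* The built-in NJ backend is a desk-scale stand-in for maximum-likelihood
  inference; tree quality on real, rate-heterogeneous data is the ML
  backend's responsibility.
* Window derivation assumes anchored rank RED ranges are disjoint; on
  trees where ranks genuinely overlap in depth the user must supply
  windows manually.
* The generator's equal-rates, indel-free model means alignment,
  trimming and rate-model misspecification are exercised only trivially.
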