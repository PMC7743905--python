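# Methods

## The question and the measurement

Transcriptome-based ("PT") phylogenies are judged here by their
topological agreement with genome-based ("PG") references. The statistic
is the Robinson–Foulds topological distance `d_T`: the size of the
symmetric difference between the sets of non-trivial bipartitions
(splits) of the two unrooted topologies. For fully resolved binary trees
on `n` shared taxa, `d_T` is even and at most `2(n − 3)`. Branch lengths
never enter the distance; trees on different taxon sets are first
restricted to their common taxa (suppressed degree-2 nodes have their
edge lengths summed). Fewer than four common taxa leave no informative
split; `d_T` is then 0 with a warning rather than an error, so sweeping
comparisons over many tissue subsets do not abort.

An observed `d_T` is calibrated two ways:

* **Random-tree null** — `d_T` between the reference and topologies
  generated by recursive random splitting of the taxon set (each subset
  split at a uniformly chosen size into uniformly chosen halves). This
  generator is deliberately the classic `rtree`-style scheme and is *not*
  uniform over labelled topologies; a uniform-over-rooted-topologies
  coalescent mode is available (`method="coalescent"`). For 22 taxa the
  null mass sits near the maximum 38 — in 10,000 draws no sample comes
  within `d_T ≤ 16` of any fixed binary reference.
* **Tip-swap null** — `d_T` between the reference and copies of it with
  `k` sequentially drawn random tip pairs exchanged (`k` = 1, 2, 3). A
  tip may be re-drawn in a later pair by default, the simplest reading of
  "sequential" swapping; disjoint pairs are available via
  `allow_reuse=False` and change results negligibly. P-values are
  inclusive one-sided tail probabilities `P(d_null ≤ d_obs)`, so any null
  mass at the observed value counts toward p and `p ≥ 1/n_samples`
  whenever a sample ties the observation.

Paired per-tissue comparisons between two methods are summarized by the
two-tailed exact sign test at success probability ½ (ties dropped before
the call): `p = min(1, 2 Σ_{i≤min(n⁺,n⁻)} C(n,i)/2ⁿ)`. Seven concordant
comparisons give 2/2⁷ = 0.015625 ≈ 0.016.

## Ortholog identification

**Gene-tree-based pipeline** (stringent). Stages, with defaults:

1. similarity-edge filter: aligned-region fraction ≥ 0.3, identity within
   the aligned region ≥ 0.3, hit fraction ≥ 0.3, all inclusive. The hit
   fraction's denominator is not canonically defined; the default is the
   shorter sequence's length, with the query length available as an
   option.
2. Markov clustering, inflation 1.4, on max-symmetrized bitscores. MCL is
   run densely per connected component (components never merge, and the
   blocks stay small); self-loops equal each node's maximum edge weight;
   convergence is max column change < 1e-9 within 200 iterations.
3. cluster filter: members shorter than 30 residues dropped first, then
   clusters kept only if they still span ≥ ⌈0.5 × n_species⌉ species.
4. per-cluster alignment, trimmed at column occupancy 0.1; a gene tree is
   built by neighbor joining on Poisson-corrected distances (externally
   supplied Newick gene trees can be substituted per cluster).
5. spurious-terminal pruning: a tip is removed when its branch is both
   longer than 0.6 and more than 10× its sister branch (strict
   inequalities). With a multifurcating parent the longest sister branch
   is the comparator (the conservative choice). The rule is iterated to a
   fixpoint because a removal can expose a new violator; the single-pass
   alternative differs only on pathological chains.
6. isoform masking on the unrooted adjacency: wherever an internal node
   touches ≥ 2 tips of one species, only the tip with the most
   unambiguous (non-gap, non-X) characters in the trimmed alignment
   survives; degree-2 nodes are suppressed and the rule re-applied, which
   resolves paraphyletic grades while never merging same-species tips
   separated by another species' tip. Ties break to the smaller id.
7. deep-paralog cut: internal edges longer than 0.5 are severed;
   fragments with ≥ 2 tips continue.
8. extraction: a fragment becomes a one-to-one ortholog group iff no
   species repeats and ≥ ⌈0.5 × n_species⌉ species are present. The
   50%-species rule is thus applied twice — at the cluster level (as step
   3) and on the final group; where exactly the published procedure
   placed the second check is not stated, and the final-group placement
   is the stricter reading.

**Reciprocal-best-hit pipeline** (permissive). Core ortholog groups are
built from five reference genomes spread along the species list (MCL plus
strict single-copy-in-all-references filtering); the first reference
species plays the "human protein set" role. A transcript joins a core
group iff its best-scoring hit among that species' proteins is the
group's member and that protein's best hit among the transcript's
species' transcripts is the transcript itself. Best-hit ties break
lexicographically by id. A species reciprocally claimed twice by one
group is dropped from it; groups below 50% species coverage are
discarded. This route consumes *unfiltered* similarity edges — the
30/30/0.3 filter belongs to the gene-tree method's description.

**Genome route.** With complete proteomes, clusters are kept only when
exactly one member is present in every species — the conservative
paralogy guard available to phylogenomics.

## Supermatrix and trees

Per-group alignments are keyed by species, trimmed by column occupancy
(0.3 at the supermatrix stage, 0.1 at the gene-tree stage — both
inclusive "fraction of non-gap characters ≥ threshold" rules), filtered
by length (profiles: 500 columns for the permissive mammal analysis, 150
for the stringent mammal and all plant analyses; the synthetic analyses
default to 150 because the generator's genes are 250 residues), and
concatenated with all-gap fill for missing species, partitions recorded
as 0-based half-open column ranges. "Gap removal" before tree building is
interpreted as this occupancy trimming; complete deletion would empty
gap-rich transcriptome matrices.

Distances use pairwise deletion of gap/X sites and the 20-state
uniform-exchange (Poisson) correction `d = −(19/20) ln(1 − 20p/19)`,
which exactly inverts the generator's substitution model, so noise-free
simulated data yields additive distances. `p ≥ 19/20` raises a
saturation error rather than returning infinity. Neighbor joining is the
internal tree builder because it is deterministic, fast, and provably
exact on additive inputs; negative branch-length estimates are clamped
to zero with the deficit moved to the sister branch, preserving the
pair's summed length. Maximum-likelihood inference is intentionally out
of scope; externally inferred Newick trees can replace the internal
builder at every stage. Column bootstrap resamples all columns with
replacement, rebuilds per replicate (200 by default), and reports each
main-tree split's support as a percentage.

## Benchmarking

Every simulated sequence carries a gold-standard label: family plus
*root lineage* — which pre-root gene copy it descends from. This is the
synthetic analogue of a clade-level orthology-database identifier:
post-root ("in-paralog") duplicates share a label, ancient paralogs do
not. A group whose annotated members share one label is correct; two or
more distinct labels make it incorrect; unannotated members without a
conflict make it unannotated. When a group has both a conflict and an
unannotated member, incorrect wins: a conflict is positive evidence of
error, a missing annotation is not. The coefficient of variation of
group counts across conditions uses the population standard deviation.

## The synthetic-data generator

The generator's defaults define the study conditions and are not tuned
per experiment:

| parameter | default (mammal-like) | meaning |
| --- | --- | --- |
| n_species / tissues | 22 / 7 | taxa and per-species tissue panels |
| tree_height | 0.4 subs/site | mean root-to-tip path of the ultrametric pure-birth species tree |
| n_families | 200 | gene families |
| dup_rate / loss_rate | 0.1 / 0.15 per unit branch | birth–death of gene copies along the species tree |
| ancient_dup_prob / depth | 0.25 / 0.4 | probability a family enters the root as two paralogs; stem length per copy (paralog divergence ≈ 0.8 + within-tree paths) |
| n_isoforms_mean | 1.5 | shifted-Poisson isoforms per gene; extras are contiguous end truncations (5–40%) |
| seq_length | 250 residues | root gene length |
| indel_rate | 0.02 /site/unit | deletion blocks, geometric length (mean 3) |
| x_rate | 0.01 | ambiguous residues at the tips |
| dropout_prob | 0.3 | per gene per tissue expression dropout |

The plant-like preset (15 species, 3 tissues, dup_rate 0.2,
ancient_dup_prob 0.5, height 0.5) mirrors a polyploidy-rich clade.

Substitutions follow the 20-state uniform-exchange model: Poisson event
counts with mean equal to branch length, each event jumping to one of
the other 19 residues, giving the closed-form expected difference
fraction `(19/20)(1 − e^{−20b/19})` at path distance `b`. Indels are
modelled as *deletions only*, so all rows of a family stay in the root
coordinate frame and the emitted matrix is a true alignment with
explicit gaps — the generator's substitute for out-of-scope alignment
inference. Similarity edges are computed from those known coordinates
(aligned columns = both rows non-gap; identity excludes X; score =
identity count); sequences from different families produce no edge, as
their real local-alignment hits would fall below every retained
threshold. Consequences worth knowing: there is no alignment error, no
insertion drift, no assembly chimerism, and cross-family similarity is
exactly zero — all reasons the real data's method differences are larger
than the synthetic ones.

Ancient (pre-root) duplication plus differential loss is what gives the
benchmark its teeth. Without pre-root paralogy every sequence in a family
shares one label and no method can ever be "incorrect". With it, the RBH
route fails in the documented way: if the reference species lost copy A
and a query species expresses only copy A, the transcript's best hit is
the reference's copy B, the reciprocal check passes (the query's copy B
being lost or unexpressed), and the B group acquires an A member. The
gene-tree route escapes because ancient paralogs either fail the 30%
identity filter and never co-cluster, or co-cluster and are severed at
the >0.5 deep branch.

Every stage seed derives from the master seed by fixed offsets
(`(seed × 100003 + offset) mod 2³¹−1`), so one integer pins every
emitted byte.

## Observed behaviour at the study scale, and limitations

At the default scale (200 families, 30% dropout) the per-tissue
supermatrices carry 150+ groups × ~240 columns; neighbor joining then
recovers the reference topology exactly for both methods in every
tissue, and the method difference expresses itself in the ortholog
benchmark (RBH ≈ 7% incorrect groups, gene-tree-based 0%) rather than in
`d_T`. Topological separation between methods on real data rests on
noise sources the generator deliberately omits (alignment and assembly
error, compositional heterogeneity, rate variation). Relatedly, the
"stricter method finds fewer groups" direction is only weakly expressed
here: the RBH route is capped by how many core groups survive
single-copy filtering across the five reference genomes, so at some
seeds it emits marginally fewer groups than the gene-tree route, while
on real data the gap is an order of magnitude the other way.

Numerical conventions collected in one place: all threshold comparisons
are inclusive (`≥`) except the two terminal-pruning conditions and the
deep-branch cut (`>`, "more than"/"longer than"); best-hit and masking
ties break lexicographically; MCL support threshold 1e-9; NJ requires a
symmetric zero-diagonal matrix to 1e-8; floats in reports are serialized
to 12 significant digits; the default test and analysis problem sizes
(30–200 families, 8–22 species) were chosen so every documented check
runs comfortably on a single CPU.
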