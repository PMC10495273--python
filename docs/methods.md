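# Methods

## The assignment model

`demetax` treats taxonomic correction as local, distance-weighted label
smoothing on a pairwise genetic distance matrix. For a focal accession the
determined neighbours within radius `d` vote for their own taxon with
weight `exp(-λ·distance)`; the focal accession is excluded from its own
neighbourhood, so its current label never defends itself. A finite `k`
restricts the vote to the k nearest admissible neighbours (the distance
filter is applied first; neighbours tied with the rank-k distance are all
kept, so the result is permutation-invariant). With inverse-frequency
normalisation on, each taxon's summed weight is multiplied by
`n / n_T` — equivalently, taxa are compared by their *mean* neighbour
weight rather than their total. The winning taxon is suggested when its
share of the summed normalised scores reaches `r`; exact ties (relative
tolerance 1e-12) and empty neighbourhoods yield the undetermined sentinel.

Two consequences of the normalisation shape everything else:

* **Counts alone never decide.** With a flat kernel (λ = 0) every taxon
  present in a neighbourhood has the same mean weight, so any mixed
  neighbourhood is an exact tie. All discrimination comes from the
  distance structure; λ sets how sharply.
* **Regimes.** At low λ the per-taxon mean aggregates whole demes (law of
  large numbers): scattered wrong labels are diluted by their taxon's full
  in-neighbourhood count, and suggestions are extremely stable. At high λ
  the mean is dominated by each taxon's nearest representative, which
  makes the classifier behave like a soft nearest-neighbour rule and
  exposes it to whichever single accession happens to sit closest. The
  radius `d` should therefore *include* the bulk demes of potential wrong
  labels: it is the large denominator `n_T` of a wrong label's own taxon
  that cancels its inverse-frequency boost. Choosing `d` to isolate the
  focal deme looks natural but removes exactly that protection.

`classify_all` computes one suggestion per accession against the original
input table (single pass, no in-pass feedback); `iterate_classification`
optionally feeds suggestions back until a fixed point or a round limit.

## Comparators

* **k-NN voting** (`knn_classify`): the k nearest determined neighbours
  vote unweighted; the winner needs a unique plurality and a vote fraction
  ≥ `r` (reference configuration k = 6, r = 4/6). Rank-k distance ties are
  kept, mirroring the kernel rule; with fewer than k determined
  neighbours the vote is over those available.
* **UPGMA majority reassignment** (`upgma_classify`): average-linkage
  clustering of the distance matrix cut at a fixed height; within each
  cluster a taxon holding at least `majority_fraction` (default 0.8) of
  the *determined* members relabels the whole cluster, undetermined
  members included. Undetermined members are reassignable but excluded
  from the denominator, which maximises comparability with the kernel's
  undetermined handling. The cut height is dataset-specific and has no
  default.

## Curation

Rows/columns containing invalid (NA) distances are removed greedily, most
missing cells first with lexicographic tie-breaks, followed by a re-add
pass that restores accessions whose conflicts were all removed — the
result contains no missing cells and is locally maximal. Matrices read
from text are symmetrised by averaging within an absolute tolerance of
1e-8 (format round-off); larger asymmetry is an error naming the worst
cell. Duplicate sets are collapsed to one representative drawn with a
caller-supplied seed, and `propagate_assignments` copies each
representative's final label back to its whole set. Accessions absent
from the assignment table are treated as undetermined.

## Evaluation machinery

**W50** asks how many accessions can be drawn at random before the
probability of hitting at least one assignment that disagrees with a
reference exceeds one half. Draws are without replacement, so with N
accessions and E disagreements the clean-sample probability is
hypergeometric, `P(clean, n) = C(N−E, n) / C(N, n)`, and W50 is the
largest n with `P ≥ 0.5` (N when E = 0, and 1 when exactly half disagree,
since the first draw is clean with probability exactly 0.5). The test
suite checks the closed form against million-draw Monte-Carlo sampling.

**The reshuffle experiment** permutes the labels of a random fraction of
accessions among themselves (the label multiset is preserved), re-runs
each classifier, and records misassigned and undetermined fractions
against a fixed reference — conventionally the kernel output on clean
data, with a caller-supplied exclusion set (the admixed deme) removed
first. Classifiers run in *relaxed-undetermined* mode so abstention
cannot mask misassignment: k-NN and UPGMA abstain only on exact vote
ties, the kernel only when no determined neighbour lies within `d`.

## The synthetic benchmark

`capsicum_like` emulates the structure of a large, heavily imbalanced
genebank collection: six Balding–Nichols demes (per-marker ancestral
frequencies uniform on 0.05–0.95; deme frequencies Beta-drifted with
divergence 0.3) of sizes 2000/400/300/150/30/7 over 1000 biallelic
markers, chosen so the full build-and-evaluate cycle stays interactive on
one core. The 150-member deme is a 50/50 admixture of the two largest
demes and carries a mixture of their labels — a genetically coherent but
taxonomically mixed cluster. The 7-member deme drifts from the 30-member
one (sister divergence 0.2), sitting closer to it than to anything else;
this is the configuration in which nearest-neighbour voting with a large
k absorbs the small taxon into its sister while the normalised kernel
does not. Noise: 5% mislabels, 10% undetermined (disjoint, exact counts),
twenty exact-duplicate pairs, and five accessions with a few invalid
distance cells. Mislabel destinations in this preset are drawn
proportionally to taxon abundance — real passport errors overwhelmingly
carry common crop names; uniform destinations would plant dozens of
phantom labels of the 7-member taxon, each carrying a ~70× 
inverse-frequency boost, a regime in which no parameter setting recovers
the noise. (`corrupt_labels` itself defaults to uniform destinations;
the weighting is per-preset.)

IBS distance is defined as the mean absolute dosage difference divided by
two, so it lies in [0, 1]; duplicates are exact genotype copies
(distance 0).

**Calibrated settings** (frozen once, from a parameter grid over
development seeds): kernel λ = 40, d = 0.35, r = 0.5, k = ∞. The
within-deme distances concentrate near 0.20 and between-deme bulk lies
at 0.26–0.34, so d = 0.35 encompasses every deme (see the regime note
above) and λ = 40 keeps scoring in the aggregation regime. r = 0.5 sits
below the winning shares inside pure demes (≈ 0.8) and above those in the
admixed deme (≈ 0.2–0.4), which is how that deme is flagged by elevated
undetermined rates rather than absorbed. The UPGMA comparator uses cut
height 0.20 — inside the within-deme merge band, which yields the
fragmented, somewhat arbitrary clusters characteristic of single-cutoff
clustering on collections with this structure (a cut at 0.26 would
resolve the synthetic demes perfectly, an idealisation single-linkage
practice on real collections does not enjoy). k-NN uses k = 6, r = 4/6.

**What the generator does not emulate.** Real demes are internal continua
of relatedness (families, breeding series, regional gradients); the
synthetic demes are exchangeable shells in which every member is equally
far from every other. Real collections also carry linkage disequilibrium,
genotyping error and missing genotypes, none of which are modelled.
Passing tests therefore show the machinery behaves as specified in a
clean, well-separated regime — not that the calibrated constants transfer
to any real matrix, where λ and d must be re-chosen against the observed
distance scales (t-SNE inspection of candidate assignments is the
intended instrument for that).

## Known limitations

* **Tiny taxa under heavy reshuffling.** A taxon with very few labels
  (here 7) keeps a large inverse-frequency boost no matter what. When a
  reshuffle scatters most of those labels into one big deme, their
  boosted mean can overtake the deme's own label and flip it wholesale in
  relaxed-undetermined mode; with shell-like deme geometry no λ damps
  same-deme phantoms. This shows up as occasional catastrophic replicates
  (roughly one in ten at a 50% reshuffle) and is a genuine property of
  the method, not of the implementation.
* **Full permutations defeat normalisation.** Shuffling *all* labels
  scatters them proportionally, and inverse-frequency normalisation
  cancels proportional majorities exactly; under a full permutation the
  normalised kernel carries no information and only the unnormalised
  variant re-homogenises demes.
* Winning proportion is defined as share-of-total over all candidate
  scores (not ratio to the runner-up); exact ties go to undetermined at
  any r.
* t-SNE is seeded and consumes the matrix as precomputed distances, but
  coordinates are only reproducible for a fixed library version.
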