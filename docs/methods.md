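# Methods

## Scope and data model

`barcodeaudit` evaluates an *aligned* barcode library: equal-length IUPAC
nucleotide rows (COI barcodes in Lepidoptera are effectively indel-free,
so alignment is trivial and out of scope) joined to a specimen table
(`specimen_id`, `genus`, `species`, `region`). Records are never filtered:
short fragments and ambiguity-rich sequences stay in every analysis, and
the quality report only *flags* whether each record reaches the
community's minimum-length criterion for a full-quality barcode
(≥ 500 unambiguous A/C/G/T positions by default; the boundary is
inclusive and configurable). Gaps and non-N ambiguity codes are retained
in sequences but count as ambiguous positions.

## K2P distances

Pairwise divergence uses the Kimura 2-parameter model,
`d = -½ ln((1 − 2P − Q)·√(1 − 2Q))`, with `P` and `Q` the transition and
transversion proportions among *comparable* sites — sites where both
sequences carry an unambiguous base (pairwise deletion). Pairwise rather
than complete deletion is deliberate: libraries mix full-length barcodes
with ~240 bp mini-barcode fragments, and complete deletion would discard
most of the alignment for everyone. Distances are stored as proportions
and rendered as percentages only in reports.

Degenerate inputs are errors, not silent values: a pair with zero
comparable sites raises an undefined-distance error, and a non-positive
logarithm argument (substitution saturation) raises a saturation error
naming the pair — clamping would silently corrupt the divergence
histograms downstream. No other substitution model and no rate
heterogeneity correction is offered; the audit procedure is defined on
plain K2P.

The all-pairs computation runs as 0/1 matrix products in float32 (exact
for counts below 2²⁴), keeping a ~2,400-specimen matrix under a few
seconds.

## Neighbour joining

Standard agglomerative NJ: join the active pair minimizing
`Q(i,j) = (r−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k)`; branch lengths
`vᵢ = d(i,j)/2 + (Σₖd(i,k) − Σₖd(j,k))/(2(r−2))`; reduction
`d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`. Numerical conventions, chosen for
reproducibility and checked against an independent naive implementation in
the test suite:

* **Tie-breaking** — the lexicographically smallest `(i, j)` in the
  current active-node order (the first minimum in a row-major scan).
* **Negative branches** — clamped to zero with the deficit transferred to
  the sibling edge, preserving the path length through the new node; each
  clamp is logged.
* The `n = 2` tree is stored as a single edge split at its midpoint; the
  final three active nodes are resolved by the closed-form star.

For additive matrices the result reproduces all leaf-to-leaf path lengths
exactly (tested on random binary trees). Rooting is by designated
outgroup when one is known (root at the midpoint of the edge separating
the outgroup; a non-edge-separable outgroup is an error) and by midpoint
otherwise. Diagnosability below is defined on the *unrooted* topology, so
rooting affects only the paraphyletic/polyphyletic distinction and
reporting. Bootstrap support is out of scope.

## Species diagnosability

A species is diagnosable when (a) its specimens form a monophyletic
cluster — on an unrooted tree, a leaf subset separable by removing a
single edge; singletons are trivially monophyletic via their pendant
edge — and (b) none of its haplotypes is identical to another species'.
Haplotype identity is ambiguity-tolerant (agreement at every mutually
unambiguous site) with a floor of 400 comparable sites, so a single N
cannot break a true match and a short fragment cannot "match" everything.

Failures receive exactly one of five conditions via a fixed cascade.
The published condition names are verbal; the operational definitions
here are this package's interpretation, chosen so that the canonical
patterns (one enclosed congener → paraphyletic; two or more interleaved
congeners → polyphyletic; mutual blending → overlapping) emerge:

1. one specimen, no sharing → **singleton-distinct** (counted a success,
   marked "untested by replication" in reports);
2. monophyletic, no sharing → **distinct**;
3. sharing, and still non-monophyletic after pruning every specimen
   involved in cross-species identical haplotypes (both sides of each
   pair) → **identical-and-overlapping** — the overlap is not
   attributable to the shared haplotype alone;
4. any other sharing → **identical barcodes**;
5. non-monophyletic without sharing: on the rooted view, take the MRCA of
   the species' leaves and collect other species with leaves inside it;
   exactly one, itself monophyletic → **paraphyletic**; two or more →
   **polyphyletic**; exactly one, mutually non-monophyletic →
   **overlapping**.

Counting singletons as successes mirrors how comprehensive libraries
report their success rates; the alternative (excluding them) is a
one-line filter on the assessment list. Pathological root placements can
in principle swap paraphyletic/polyphyletic labels, which is why the
rooting choice is logged.

## Divergence summaries and deep splits

All `n(n−1)/2` pairs are partitioned into intraspecific, congeneric
interspecific, and cross-genus (the last excluded from both
distributions, as is standard for barcode-gap analysis). Histograms are
left-closed right-open from zero, default 1 % bins (the binning is a
reporting choice, configurable).

A multi-specimen species is flagged as a deep split when single-linkage
clustering of its specimens at the 3 % threshold (strict `>`; the
threshold is the conventional, admittedly arbitrary, barcode-gap value)
yields ≥ 2 clusters — equivalently, when its maximum intraspecific
divergence exceeds the threshold. Single linkage over the distance matrix
was chosen over cutting NJ subtrees because it is defined purely on
distances and therefore exactly reproducible; clusters are reported as
"individuals per lineage" strings (`1/20`, `2/4/3`). The per-species mean
divergence reported alongside is the mean over *all* intraspecific pairs,
not between-cluster pairs only; this interpretation is recorded in the
report metadata.

## Sampling-bias regression

Per-species mean intraspecific divergence (%) is regressed on the number
of individuals analyzed, species with `n ≥ 2` only (a singleton has no
intraspecific mean). The fit is closed-form OLS; the p-value is the
two-sided t-test on the slope with `n − 2` df (no alternative direction
is privileged). A constant predictor or fewer than three points is an
error.

## Synthetic communities

The generator's defaults describe the structure of a comprehensive
regional geometrid library: 125 genera, 400 species (each genus gets at
least one species, the rest assigned uniformly), specimens per species
truncated-geometric with mean 6 and max 46 (giving ~16 % singletons),
658 bp sequences, transition/transversion rate ratio κ = 4 (a typical
insect-mtDNA value), target mean intraspecific divergence 0.5 % and
target mean congeneric divergence 9 %.

Construction: a uniform-random global root; genus ancestors evolved from
it at 0.06 substitutions/site (keeping cross-genus divergences ~20–30 %,
far from K2P saturation); species ancestors star-like from the genus
ancestor with Gamma(shape 3)-distributed branches whose mean sets the
congeneric target; specimen tips with exponential branches whose mean
sets the intraspecific target. Evolution is per-site K2P with the exact
finite-time transition probabilities, so realized pairwise K2P distances
are consistent estimates of the generating path lengths (verified by
Monte Carlo in the tests).

Engineered conditions (applied to randomly chosen eligible species;
infeasible requests, e.g. sharing in a genus with one species, raise a
config error):

* *shared haplotype pair* — one specimen's sequence copied verbatim onto
  a congener's specimen;
* *paraphyly pair* — the outer species radiates from two internal nodes
  ~1.5 % apart (below the deep-split threshold) and the nested species'
  ancestor hangs off the inner node at ~1.2 % — deep enough for NJ to
  recover the nesting reliably at 658 bp;
* *deep split (2 or 3 clusters)* — subcluster ancestors at 0.03
  substitutions/site from the species ancestor, i.e. ~6 % between
  clusters against ~0.5 % within, comfortably astride the 3 % threshold.

Everything is driven by one `numpy` generator seeded from the config, so
a given seed yields a byte-identical community.

**What the generator does not emulate** — and hence what passing
recovery tests do not demonstrate about real data: within-genus
phylogenetic structure (species radiate star-like), geographic population
structure, rate variation among lineages and sites, indels, sequencing
error, and misidentified vouchers. The generator validates the *logic* of
the classification cascade and threshold procedures, not their robustness
to those real-world complications. Realized global intraspecific means
also sit above the 0.5 % base target when deep splits are injected, since
between-cluster pairs are intraspecific by definition — real libraries
show the same effect.

## Pipeline and problem sizes

`run_pipeline` executes every stage and writes TSV/Newick/JSON artifacts
with fixed column orders; identical config and inputs yield byte-identical
bundles. Analysis outcomes (low success rates, many deep splits) are
results, never errors.

The test suite exercises the classification-recovery property on 20
seeded communities of 50 genera / 150 species (~900 specimens each), and
`scripts/acceptance.py` reports the headline quantities from one
full-scale community (125 genera / 400 species, ~2,300 specimens) — sizes
chosen to match the target library's shape while keeping a complete audit
in the minutes range on one core.

## Known limitations

* The five failure-condition definitions are an operationalization of
  verbal criteria; the overlapping/identical-and-overlapping boundary in
  particular is a reproducible proxy for what is usually judged by eye on
  a tree.
* Replicating another laboratory's published decimals additionally
  depends on their (often unstated) deletion convention and tree-reading
  procedure; pairwise deletion and the cascade above are this package's
  documented choices.
* NJ is O(n³) with dense matrices held in memory; libraries beyond
  ~10⁴ specimens would need a different tree engine.
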