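# Methods

This note documents the model, the conventions that had to be fixed where
the science leaves them open, the synthetic-data generator, and the
numerical choices. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genome signatures and features

A genome's signature is its vector of overlapping k-mer frequencies
(k = 4 by default, 256 features, lexicographic order over A&lt;C&lt;G&lt;T).
Conventions, all fixed and tested:

- **Strand.** Counting uses the forward strand of the sequence as given.
  The original convention is not recorded anywhere authoritative; forward
  strand is the simplest reproducible choice. An off-by-default
  `add_reverse_complement` option adds reverse-complement counts for
  sensitivity checks (canonical-k-mer counting is its special case up to a
  factor of 2 in window counts).
- **Ambiguity.** Any window containing a non-ACGT character is skipped
  whole. Fractional attribution of ambiguous bases would invent information.
- **Normalization.** Input is uppercased and U→T before counting, so RNA
  and softmasked FASTA are handled; non-IUPAC characters are an error.
- **Multi-record genomes.** Counts are summed across FASTA records, never
  across record boundaries — contigs are not physically adjacent.

The model feature for a pair (virus v, host h) is x = f(v) − f(h), *virus
minus host*. The sign is arbitrary for a near-zero-mean Gaussian but must be
identical in training and scoring; it is fixed package-wide and asserted by
the antisymmetry property test. Duplicate interaction rows are rejected
rather than deduplicated, because silently dropping them would change the
effective weighting of the fit without the user noticing.

## The Gaussian host model

One multivariate normal is fitted to the training difference vectors:
μ = column means, Σ = (1/n)·XᶜᵀXᶜ + ε·I. Choices:

- **Single component, full covariance.** With one component the
  maximum-likelihood fit is closed-form (it is the fixed point of EM for a
  one-component mixture), deterministic, and needs no initialization. Full
  covariance captures the strong correlations among k-mer frequencies
  (e.g. overlapping and reverse-complement k-mers).
- **ML (1/n), not unbiased (1/(n−1)).** Matches the EM fixed point of the
  standard mixture-model families; at the training sizes involved the
  difference is far below other sources of variation.
- **Regularization ε = `reg_covar`, default 1e-6, mandatory.** Difference
  vectors sum to zero exactly, so the sample covariance is singular by
  construction (rank ≤ min(n, d) − 1). ε is a declared assumption surfaced
  in the configuration, not a tuned constant; the monotonicity of
  log|Σ| in ε is property-tested.
- **Scores are unnormalized log-densities.** Only ranking and thresholding
  are needed; converting to posterior probabilities over hosts would
  require a prior over hosts the data does not supply.

Scoring uses a cached Cholesky factor (log|Σ| from the diagonal,
Mahalanobis terms by triangular solve). The test suite checks the scoring
path against two independent oracles — an explicit inverse/determinant
implementation and `scipy.stats.multivariate_normal` — to 1e-8, and checks
that score ordering equals negative-Mahalanobis ordering.

Models persist as NumPy `.npz` archives (format_version, k, d, reg_covar,
n_train, mean, covariance row-major, JSON metadata) with full float64
precision; a round trip reproduces scores bit for bit.

## Prediction modes

- **Ranking** is per *genome*, descending score, ties broken by ascending
  genome identifier (ties are measure-zero but determinism is required for
  reproducible output). Genomes of one species are not merged before
  ranking; "the species with the highest score" is realized as the rank-1
  genome's species label.
- **Consensus of top N** votes over the taxa of the N best genomes at a
  chosen rank. Genomes with an unknown label abstain (an unknown is absence
  of information, not a candidate answer); frequency ties go to the taxon
  containing the best-scoring genome.
- **Thresholding** uses ≥ (the boundary case is measure-zero; the choice is
  documented and fixed). Recall is the fraction of viruses predicted;
  accuracy downstream is over the predicted subset, reported as NaN when
  empty.

## Evaluation protocol

- **Cluster cross-validation.** Interactions are clustered into ten folds
  by K-means (scikit-learn, k-means++ init, n_init = 10, seeded) on the raw
  difference vectors — no standardization, since all features are already
  commensurate frequencies. Training on nine folds, each held-out virus is
  ranked against the *full* host catalog, not only hosts present in
  training pairs. Folds are computed on a canonical row ordering (sorted by
  pair identifier) so the partition — hence pooled accuracy — is invariant
  to interaction-table row order; this is property-tested.
- **Accuracy at a rank** counts a prediction correct when the predicted
  genome's known taxon equals a true host's known taxon at that rank;
  unknown never matches. Lineage consistency (same genus ⇒ same family,
  order, class, phylum, etc.) is validated at load time as a hard error,
  which makes accuracy monotone non-decreasing from genus up to phylum.
  Viruses recorded with multiple true hosts count as correct when any true
  host matches.
- **Leakage filter.** When scoring a query pair against a training set that
  may contain its relatives, training interactions sharing the query's
  viral genus *and* host genus are removed (mode `"and"`, the literal
  reading); a stricter `"or"` mode removes pairs sharing either genus. The
  original behaviour between these two readings is not recorded; both are
  implemented, neither is asserted as the original.
- **Contig experiments.** For each fragment length L a fresh model is
  trained on contig-derived virus profiles within the same cluster-CV
  protocol (a flag scores contigs under the whole-genome model instead).
  Hosts are never fragmented. Contigs are exact substrings: the record is
  chosen proportionally to its number of valid starts and the start is
  uniform, making every genomic window equally likely (chi-square tested).
  Default one contig per virus per length, configurable.

## Synthetic benchmark generator

The generator emulates the statistical structure the model assumes, not
real phage biology:

- Each genus gets an order-1 Markov transition matrix: rows are
  (1 − δ)·uniform + δ·Dirichlet(1,1,1,1) with δ = `composition_divergence`
  (default 0.5). Order-1 chains induce distinctive 4-mer signatures at a
  fraction of the cost of order-3 models, and the model only observes 4-mer
  frequencies.
- Hosts within a genus share the genus matrix mixed with an independent
  random row at weight `host_jitter` = 0.02 (chosen as "same genus,
  distinguishable strains": within-genus signature distances far smaller
  than between-genus ones).
- Each virus is sampled from its true host's matrix mixed with a random row
  at weight `virus_noise` (default 0.05), so true-pair difference vectors
  are near-zero-mean while virus/non-host differences are dominated by
  between-genus composition distance.
- Taxonomy above genus groups genera in fixed blocks (2 genera per family,
  2 families per order, ...), giving consistent six-rank lineages for the
  monotonicity tests.
- Defaults (20 genera × 2 hosts × 2 viruses, 50 kb hosts, 10 kb viruses,
  seed 0) are the package's stated reference world and are what
  `scripts/acceptance.py` re-runs.

What a green end-to-end test does **not** establish: performance on real
genomes. Real phage–host signal is weaker and confounded (shared mobile
elements, amelioration time scales, GC skew, repeats, horizontal transfer),
real catalogs are 3–4 orders of magnitude larger, and real taxonomy is not
block-structured. The benchmark establishes that the pipeline recovers a
compositional signal when one is present, with the correct protocol
mechanics.

### A note on the zero-mean check

Pooled true-pair difference vectors should center on zero. The test suite
checks this as "≥ 95 % of the 256 per-feature means lie within 3 standard
errors of 0" rather than "all 256 do": with 256 simultaneous comparisons,
even an exactly zero-mean iid Gaussian sample of the same shape exceeds a
3-SE band somewhere in roughly half of all draws, so the all-features form
of the assertion rejects ideal data about as often as it accepts it. The
acceptance suite retains the strict all-features form of this check
unchanged alongside the contrast against virus/non-host pairs.

## Numerical and degenerate-input choices

- Profiles require at least one valid window; otherwise a degenerate-genome
  error names the genome.
- `fit` on zero rows is an error; n = 1 yields Σ = ε·I exactly.
- Covariance symmetry is validated to 1e-10; factorization failure after
  regularization raises a singular-model error suggesting a larger ε.
- K-means seed defaults to 0 and is configurable; all simulation entry
  points take explicit seeds and are reproducible bit for bit.
- CLI writes are atomic (write-then-rename); failures leave no partial
  files.

## Known limitations

- No protein-space or CRISPR/alignment evidence; composition only.
- The Gaussian is unimodal by design; host-range structure with several
  compositional modes would need the (deliberately omitted) multi-component
  extension.
- Scores are comparable only under a fixed model; thresholds do not
  transfer between models trained on different data or k.
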