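# Methods

## The analysis model

The package analyses site-level TMT phosphoproteomics with one pooled
internal-reference channel per plex. All inference happens on
`log2(sample / same-plex reference)` ratios: the reference cancels plex-level
instrumental scaling, and per-sample median centering removes residual
loading differences. The canonical preprocessing order is reliability filter
→ reference normalization → median centering → complete-in-all-groups filter;
centering and the completeness filter are idempotent, and each step records
itself in the matrix provenance.

No imputation is performed anywhere. Tests operate on observed values only;
features that cannot support a test (fewer than two observations per side, or
zero variance on both sides) are flagged untestable and excluded from gates
rather than guessed at.

### Differential testing

The two-group test is a two-sided Welch *t* with Satterthwaite degrees of
freedom on the log2 ratios. Welch was chosen because the four groups have
unequal sizes (10/7/10/6) and there is no reason to assume equal variances
between responders and non-responders. Selection uses the raw p-value
together with an asymmetric fold-change gate (the three shipped presets are
`broad` 1.3/0.67, `strict` 1.5/0.67 and `dav` 1.3/0.77, all at p < 0.05);
BH q-values are computed over testable features and reported for
transparency, but deliberately do not enter the gates. Fold change is
`2**(mean difference of log2 ratios)`, not a ratio of raw means, so the gate
and the test see the same quantity.

The `dav` preset's 0.77 down-gate is intentionally distinct from 0.67; both
are available, and nothing in the code privileges one reading over the
other.

### Protein rollup

Counting is protein-level for the signature. Each protein is represented by
its most significant site for the comparison at hand — smallest p, ties by
largest |log2FC|, then lexicographic site id. This "best-site" rule is a
declared convention; site-level operation remains available everywhere, and
kinase inference never uses the rollup (kinases act on sites).

### Signature subtraction

With A = differential(DA-NR vs DA-CR) and B = differential(DA-NR vs DAV-CR),
the sensitivity signature is A \ B, where "not differential in B" is
operationalized strictly as `status == ns` under the same preset as A (the
preset for B is configurable). Both comparisons must share a feature
universe; a mismatch raises rather than silently intersecting.

### Kinase-activity inference

Three schemes share one explicit kinase→substrate-site map:

- **zscore** — `z = (mean_sub − mean_all) · sqrt(m) / sd_all` with the
  population sd over all quantified site fold-changes, two-sided normal p,
  BH q. Shift- and scale-invariant in the fold-changes by construction.
- **overrep** — one-sided hypergeometric tail of the overlap between a
  kinase's quantified substrates and the regulated (gate-passing) site set
  within the tested universe.
- **smoothed** — one-step neighborhood smoothing
  `fc' = (1−λ)·fc + λ·mean(neighbor fc)` (default λ = 0.5) before the
  z-score. The default neighborhood joins sites sharing a substrate protein
  or an annotating kinase. This is an in-repo approximation to
  propagation-based kinase inference and is documented as such; it is not a
  wrapper around any external service, and results will not numerically
  match web tools with different substrate databases.

Kinases with fewer than 3 quantified substrates are not reported (the
z-score is unstable below that). The consensus is the intersection of
per-scheme top-k lists (k = 10 by default), where each list is restricted to
kinases significant in that scheme (p < 0.05) before truncation — an
intersection of unconditioned top-10-of-20 lists would almost never be empty
even under a pure null, which would make the consensus meaningless as an
activation call.

### Motif discovery

Greedy iterative search on 13-mer windows centred on the phospho-acceptor
(S and T analysed separately): at each step every unfixed (offset, residue)
pair is scored by the binomial tail `P(X ≥ k_fg | n_fg, p_bg)` with `p_bg`
the background frequency among windows matching the current fixes; the
minimum-p pair is fixed if p < `p_fix` (default 1e-6) and foreground support
≥ `min_occ` (default 20). When no pair qualifies the motif is emitted,
matched windows are removed, and the search restarts, guaranteeing
termination. Terminal padding (`_`) never matches a residue, so truncated
windows cannot inflate edge positions. An absent background residue gets a
0.5-count pseudo-frequency to keep the tail finite. The procedure is fully
deterministic; ties break by smaller p, then offset, then residue.

### Clustering, PCA, cohort statistics

Hierarchical clustering defaults to 1−Pearson distance with average linkage
(row z-scoring before feature clustering); scipy's agglomeration is used and
is checked against a naive O(n³) agglomerator in the tests. PCA standardizes
features, decomposes by SVD, and fixes component signs by making each
component's largest-magnitude loading positive; per-group "error ellipses"
use the 2-df chi-square quantile at the requested level (default 0.95) on
the group's PC1/PC2 score covariance, and are omitted with a warning for
groups of fewer than 3 samples.

Categorical cohort comparisons use exact tests under the point-probability
two-sided rule: the p-value sums the probabilities of all fixed-margin
tables whose point multivariate-hypergeometric probability does not exceed
the observed table's. For 2×2 this is scipy's Fisher test; the r×c
Freeman–Halton generalization is computed by full enumeration with a guard
at total n ≤ 60 (beyond that a Monte Carlo fallback would be needed and is
deliberately not implemented). Continuous covariates default to Welch,
with Mann-Whitney behind a flag; which test produced the original cohort
table's continuous p-values is not recoverable from printed summaries, so
those are treated as diagnostics only.

## The synthetic cohort generator

The generator emulates the four-group design directly: group sizes default
to DA-CR 10, DA-NR 7, DAV-CR 10, DAV-NR 6; ~2000 sites on 800 proteins
(Poisson(2.5) sites per protein, minimum 1); a 20-kinase × 25-substrate map
with disjoint substrate sets; three TMT plexes filled round-robin with one
pooled reference channel each.

Intensities are additive on the log2 scale:

    log2 I = protein baseline + site offset + plex batch + group effect + noise

with baseline ~ N(20, 2²), site offset ~ N(0, 1), plex batch ~ N(0, 0.3²),
noise ~ N(0, 0.5²) per cell. Real reporter-intensity distributions vary by
instrument and cohort, so the baseline/noise values are generator
conventions chosen to give realistic dynamic range and per-contrast effect
sizes (a planted 1.0 log2-unit shift yields site-level
t ≈ 4 at the default noise). The reference channel receives the pooled mean
of all simulated samples on the raw scale, then the plex batch factor, so
reference normalization cancels batch exactly — mirroring how a pooled
reference behaves in practice.

A planted effect `(kinase, TEST_vs_REF, delta)` adds `delta` to the TEST
group's offsets on that kinase's substrate sites. Because effects are
group-additive, a "DA-resistant but DAV-sensitive" scenario is planted as
two effects (shift DA-NR and DAV-CR); the standard recovery configuration
plants on DA-NR only. Motif planting overwrites the specified offsets in a
penetrance-fraction of the kinase's substrate windows; the motif-bearing
kinase's substrates are drawn exclusively from serine sites, since S/T
foregrounds are analysed separately and real kinases are residue-specific.

Missingness is MNAR: each patient cell is censored with probability
`sigmoid((t − x)/s)` where `s` is 0.3 of the global log2 sd and the
threshold `t` is calibrated by bisection so the expected missing fraction
matches the request (default 10%). Reference channels are never censored.

What the generator does **not** emulate: spectra and peptide-spectrum
matching, TMT reporter-ion interference/ratio compression, peptide-level
rollup noise, correlated biological pathways beyond the planted kinases, and
plex-by-feature interaction effects. Passing recovery tests therefore shows
that the statistics recover planted group structure under realistic noise,
censoring and batch scaling — not that they are robust to every artefact of
real MS data.

## Problem sizes in tests and the acceptance study

Recovery and calibration studies run 100 independent seeds of the standard
configuration (each ~2000 sites × 33 patients); the signature power study
uses 20 seeds with two planted effects. Exact-test oracle sweeps cover every
2×2 table with total ≤ 20 and randomized r×c and hypergeometric instances
with universes ≤ 25. These sizes make the whole suite run in a few minutes
on one CPU while keeping binomial error on the reported rates at the
few-percent level.

## Known limitations

- The kinase schemes share one substrate map; no attempt is made to
  reconcile multiple substrate databases or to reproduce specific web-tool
  outputs.
- The smoothed scheme is a one-step linear smoother, not a full
  network-propagation model.
- `exact_rxc` is exponential in table size and guarded at n ≤ 60.
- Protein rollup by best site discards within-protein heterogeneity;
  proteins with antagonistic site regulation are represented by whichever
  site is most significant.
- No moderated-variance (empirical Bayes) test is provided; with n ≤ 10 per
  group the Welch test is slightly conservative, which the null-calibration
  tests quantify rather than hide.
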