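# Methods

This note documents the statistical machinery, the conventions it pins
down, the synthetic-data regimes used to validate it, and the design
choices that were genuinely open.

## Tree metrics

A `Phylogeny` is a rooted tree with non-negative, finite branch lengths.
Zero-length edges are allowed (they arise when polytomies are resolved
under topological constraints); negative lengths are rejected.
Ultrametricity is neither required nor enforced: every metric below is
defined on arbitrary edge weights. Internal node labels survive I/O but are
ignored by all metrics, as is a root edge present in the input file.

Cophenetic (patristic) distances are computed as
d(i,j) = depth(i) + depth(j) − 2·depth(mrca(i,j)) in one postorder sweep,
O(T²) for T tips.

Faith's PD of a taxon set is the total length of the edges its spanning
subtree uses. Two conventions exist in the literature, differing in whether
the path from the subtree's most recent common ancestor up to the root is
counted. We default to **including** the root path (`include_root=True`),
matching the common reference implementation's default, and expose the flag
everywhere; the choice is recorded in pipeline logs. The same edge sets
drive the PhyloSor decomposition, so a + b = PD(community 1) holds by
construction under either convention.

## The label-shuffling null and SES indices

The null model draws a uniform random permutation of *all* tip labels of
the phylogeny (the full species pool, not just the species observed in the
matrix rows being tested) and recomputes each site's metric from the same
permutation; site rows are untouched, so richness is preserved trivially.
Null mean and standard deviation are sample statistics (n−1 denominator)
over the iterations; the defaults are 999 iterations, with the seed
mandatory in pipeline runs.

Sign conventions: NRI = −SES(MPD) and NTI = −SES(MNTD), so positive values
mean phylogenetic clustering; SES.PD is not flipped, so negative values
mean less branch length than expected. Significance is demarcated at
|index| ≥ 1.96 (two-sided 5% under a normal reference) and reported as a
boolean beside the raw value. A site with richness < 2 has undefined
MPD/MNTD (reported as NaN with the flag false) but a valid SES.PD. When the
null standard deviation is zero (e.g. a community containing the whole
pool, or a tree symmetry making the metric constant), the index is reported
as NaN — never ±∞ — with the significance flag false. The observed value's
rank within its null ensemble is emitted alongside (`*_obs_rank`) but not
further analysed.

The exhaustive mode enumerates all C(T, r) distinct communities of richness
r, which is the exact distribution induced by uniform label permutation;
moments use the same n−1 convention over the enumerated values. It is
guarded to small problems and serves as the exact reference for the
Monte-Carlo mode.

## Beta diversity

Both dissimilarity variants use the (a, b, c) algebra — shared / unique to
1 / unique to 2, as species counts or as spanning-subtree branch lengths —
with

- β_sor = (b+c)/(2a+b+c),
- β_sim = min(b,c)/(a+min(b,c)) (turnover),
- β_sne = β_sor − β_sim (nestedness).

Degenerate denominators (identical empty intersections of zero length)
return 0. A tiny negative β_sne arising from floating-point cancellation
when b ≈ c is clamped to exactly 0 with β_sim set to β_sor, keeping both
the identity and the sign invariant exact. On a star tree with unit
branches and root paths included, the phylogenetic variant reduces exactly
to the species variant.

COMDIST is the mean cophenetic distance over all between-community tip
pairs, shared species included (their zero self-distances count). The site
dendrogram is agglomerative clustering of the COMDIST matrix; linkage
defaults to average (UPGMA) since no particular linkage is canonical for
this summary, and the choice is recorded in output metadata. Heights in the
Newick serialization are **raw merge distances**, not the halved
ultrametric convention; branch lengths are parent-minus-child heights.
Tie-breaking follows the (deterministic) behaviour of the underlying
agglomerative implementation, so outputs are byte-stable across runs.

## Predictor modelling

Model scoring is Gaussian maximum likelihood, not REML and not the
unbiased-variance form: logLik = −(n/2)(log 2π + log(RSS/n) + 1), with the
residual variance counted as an estimated parameter, so k = (number of
coefficients incl. intercept) + 1, and
AICc = −2 logLik + 2k + 2k(k+1)/(n−k−1). This combination reproduces the
published ranking tables for the motivating dataset exactly at their
printed precision, which is what pins the convention down. The candidate
set is all subsets of the supplied predictors — with the three standard
predictors, eight models from null to full; no interactions. Akaike
weights are normalized within a response.

Predictors are standardized to z-scores with the sample (n−1) standard
deviation. Second-order polynomial fits orthonormalize the basis (QR) for
conditioning; the reported quadratic-term p-value is the two-sided t-test
on the highest-order coefficient, which is invariant to the basis choice
(verified against a raw-basis fit). An exactly quadratic response is
flagged (`exact=True`, p = 0) rather than producing an unbounded
likelihood.

The Mantel test is the plain Pearson form on lower-triangle entries,
one-sided greater, p = (1 + #{permuted r ≥ observed r})/(permutations+1),
permuting rows and columns of the second matrix jointly; 999 permutations
by default and seed-reproducible (the reason it is implemented in-package
rather than delegated: the established implementations expose no seed).

## Single-gap interpolation

Species' elevational ranges are assumed continuous; an absence at exactly
one site flanked by presences at the immediately adjacent lower and higher
sites is filled. The strict reading — only absence runs of length exactly
one — is the default; a looser `any-flanked` mode (fill every internal
absence between a species' lowest and highest record) is available but not
default. Terminal absences are never filled. The operation is idempotent
and never removes a presence. In the pipeline it runs once, before all
alpha/beta analyses.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the shape of the motivating study: 8 sites at
200–3700 m in 500 m steps; ~200 species (the per-site richness targets are
the published per-elevation sequenced-species counts rescaled to the pool
size, preserving the mid-elevation diversity peak); temperature declining
linearly at 0.54 °C per 100 m from 27.4 °C at the 200 m reference site
(the observed timberline value of 8.37 °C is not exactly collinear with
that lapse rate, so intercept and lapse are free parameters with these
defaults); unimodal plant richness; convex monotonically decreasing
predator abundance (deliberately not collinear with the linear temperature
profile, so that multi-predictor designs stay full rank even in the
noiseless default). Assembly regimes and their known signatures:

- `random` — SES indices centred on 0 with spread ≈ 1;
- `filtered` — high sites drawn (fraction = strength) from one clade of
  ~`filter_clade_size` tips → positive NRI/NTI;
- `overdispersed` — greedy max-min cophenetic spacing → negative NRI;
- `nested-attrition` — each site a subset of the one below → adjacent
  species β_sim = 0, signal entirely in β_sne;
- `range-turnover` — contiguous elevational windows → gradual turnover;
  interior single-site gaps cannot occur, so interpolation is a no-op.

What the generator does **not** emulate: sampling effort and detection
error, abundance structure (everything is presence/absence), phylogenetic
signal in range limits, spatial autocorrelation among sites, and the
topology-constraint artefacts of real supertrees. Passing calibration and
power checks on these simulations therefore validates the statistical
machinery, not the ecological interpretation of any real dataset.

## Validation problem sizes

The calibration and power checks run at: 200-tip Yule tree, richness-30
communities, 1,000 replicate random communities and 200 clade-filtered
replicates, 199 null iterations per SES (the default for real analyses
stays 999; 199 inflates the SES spread by < 0.3%, far inside the
calibration band); Mantel calibration at 500 replicate 10-site matrix
pairs with 99 permutations each. Replicate communities within a batch are
standardized against null ensembles that share permutations across sites —
exactly how the null is defined — with observed communities drawn
independently.

## Known limitations

- The null is taxon-label shuffling over the full pool only; frequency- or
  occupancy-weighted nulls are out of scope.
- All metrics are presence/absence; no abundance weighting.
- Multi-site (non-pairwise) beta decomposition is not implemented.
- Model averaging of coefficients is not implemented (ranking and weights
  only).
- p-values attached to individual regression terms are conditional
  frequentist t-tests; with n = 8 sites they are indicative at best, which
  is why the AICc ranking is the primary inferential output.
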