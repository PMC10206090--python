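# Methods

## Model

`transcomp` factorizes the inter-chromosomal Hi-C contact map under a
Poisson observation model. Genomes are tiled into fixed-width bins
(0-based half-open; `.pairs` input positions are 1-based and converted on
read). For M sub-compartments, bin *i* carries a nonnegative score row
C_i ∈ R^M with C_ik = B_i·P_ik: B_i ≥ 0 is a per-bin technical bias
(mappability, accessibility, ligation/PCR efficiency; units: sqrt of
expected read counts) and P_ik the probability that bin *i* resides in
sub-compartment *k* in a randomly drawn cell (Σ_k P_ik = 1). The expected
trans count for a bin pair is

    F_ij = R_ij Σ_k C_ik C_jk,
    R_ij = 1 + α·r_i·r_j + β·(r_i + r_j)·r_i·r_j,

and N_ij ~ Poisson(F_ij), giving L = Σ_ij [N_ij ln F_ij − F_ij] up to
N-only constants.

Assumptions: (1) loci on different chromosomes localize independently —
hence only trans pairs enter the likelihood, since cis contacts are
dominated by TADs and distance decay; (2) loci in different sub-compartments
do not contact each other; (3) the within-compartment contact rate is
constant. The Rabl term relaxes (1) for the known centromere/telomere
clustering: it is the symmetric third-order power series in (r_i, r_j) with
all single-variable terms dropped (those are absorbed into B_i), leaving the
α (strength) and β (centromere-vs-telomere skew) coefficients.

Two identifiability caveats are inherent to the factorized form and are
deliberately left uncorrected when reporting P:

* a per-compartment interactivity modifier S_k would enter as
  C_ik = B_i·P_ik·√S_k without changing F, so compartments with stronger
  internal contact rates report globally higher P columns — relative
  ordering between bins is preserved;
* for a mixture of two populations, F is the sum of two factorizations, so
  a fit with doubled M recovers the union of both score sets and the rows
  no longer sum to population probabilities of a single homogeneous
  population. This is a feature (mixture deconvolution), not a bug, but the
  interpretation of P changes.

## Relative arm positions

r_i ∈ [−0.5, 0.5] is computed at the bin midpoint: on an arm of length A at
arm-distance d from the centromere, r = d/A − 0.5. The bin containing the
centromere is pinned to exactly −0.5; terminal bins approach +0.5. For
chromosomes without a supplied centromere the acrocentric convention
(centromere at coordinate 0) is used, reducing to r = midpoint/length − 0.5;
this is logged. The arm-wise definition for metacentric chromosomes is this
package's choice of a monotone, per-arm coordinate; any centromere table in
(chrom, position) text form can be supplied.

## Optimization

The joint problem is non-convex, but both conditional problems are convex:

* **Score rows.** With (α, β) and all other rows fixed,
  L_i(x) = Σ_t N_t ln(x·c_t) − x·w is concave on x ≥ 0, where the linear
  term w_k = Σ_j R_ij C_jk ranges over all eligible partners. Loci on one
  chromosome share no trans pairs, so a whole chromosome is updated from
  one snapshot (exact block coordinate ascent, order-independent within the
  block). Each subproblem is solved by projected Newton on the free set
  (coordinates that are positive or have positive gradient) with
  backtracking that only accepts non-decreasing, feasible objectives; the
  termination contract is the KKT condition — gradient ≤ tol at active
  zeros, |gradient| ≤ tol at free coordinates — with the residual scaled by
  1 + w_k (w carries the counts' units). A tiny ridge (1e−12 of the mean
  diagonal) regularizes near-singular Hessians; if the Newton direction is
  not an ascent direction the solver falls back to a scaled gradient step.
  A locus with no trans reads has the exact optimum x = 0.
* **Rabl coefficients.** With all rows fixed, −L is convex in (α, β). One
  damped Newton step is taken per outer iteration (updating to convergence
  every time buys nothing, since the rows move next); the step is halved
  until L does not decrease and R stays positive. Positivity is enforced
  exactly on all observed pairs (the likelihood is −inf otherwise, so such
  a step is rejected) and on a 64×64 grid over the occupied [r_min, r_max]²
  square for unobserved pairs; with |r| ≤ 0.5 and damping this guard has
  never been binding. A singular 2×2 Hessian falls back to a gradient step.

**Zero-count pairs.** The −F term of L sums over all O(n²) trans pairs; it
is evaluated exactly in O(nM) from cached column sums: with S_k = Σ_i C_ik,
T_k = Σ_i r_i C_ik, U_k = Σ_i r_i² C_ik and per-chromosome counterparts,
Σ_{i<j trans} F_ij = Σ_k [ (S_k²−Σ_c S_ck²)/2 + α(T_k²−Σ_c T_ck²)/2 +
β(U_k T_k − Σ_c U_ck T_ck) ], minus the explicitly enumerated pairs inside
blacklisted region groups. The same caches yield the w vectors and the
(α, β) derivatives. No epsilon floors anywhere: an iterate that would give
ln(0) with N > 0 is rejected by backtracking, not clamped.

**Outer loop.** Per restart: random initialization, then sweep chromosomes
in input order, update (α, β), evaluate L, stop when the gain drops below
`rel_tol·(|L| + 1)` or after `max_outer_iters`. Every accepted step is
non-decreasing, so the per-restart trace is monotone and convergence to a
local maximum is guaranteed; the global maximum is not. Restarts draw
initial rows C_ik = T_i/√(2·T·M) · u_ik with u ~ U(0.5, 1.5), where T_i is
the bin's trans read-end total and T the dataset total — this makes the
initial F_ij match the independence-expected count T_i T_j/(2T), so early
iterations start at the right scale. The best final likelihood wins; ties
break to the lowest restart index, making fits deterministic given the
seed (a mandatory parameter, recorded in run summaries).

Defaults: `n_restarts=5`, `max_outer_iters=100`, `rel_tol=1e-6`,
`inner_tol=1e-8`, `max_inner=80`, Rabl enabled. `rabl=False` pins
α = β = 0 exactly (useful for genomes without a Rabl configuration and as
the bias-factorization special case M = 1). Blacklisted bins keep all-zero
rows throughout and are excluded from the non-empty-bin count n.

## Exclusions

ENCODE-style blacklist intervals remove bins entirely. "Region groups"
handle translocations: a translocated pair of regions produces cis-like
contact counts that masquerade as a dense trans block, so all pairs *within*
one group are dropped from the likelihood (counts at load time, expected
counts via explicit correction terms), while each member still interacts
normally with the rest of the genome.

## Model selection and heterogeneity

AIC = 2k − 2 ln L with k = nM + 2 (n non-empty bins; the two Rabl
coefficients are counted unconditionally, matching the definition used for
the likelihood; `n_extra_params=0` is available for Rabl-free comparisons).
`aic_sweep` fits a list of M values with a common seed and restart budget
and reports the argmin.

Per-bin information content IC = Σ_k p_k log2(p_k·M) generalizes the
5-compartment baseline 0.2 to 1/M: 0 bits for a uniform row (the bin is
spread over all sub-compartments across cells), log2(M) for deterministic
localization. 0·log2 0 ≡ 0; rows must sum to 1 within 1e−6; missing bins
give NaN.

Because compartment labels are arbitrary, score matrices are compared by
the column permutation maximizing total Pearson correlation (solved as a
linear assignment over the M×M correlation matrix; exact for any M), with
rows missing on either side dropped pairwise. Hard assignments take the
per-row argmax, ties to the lowest index, −1 for missing bins.

## Simulator

`simulate_contacts` draws N_ij ~ Poisson(depth_scale·F_ij) per trans bin
pair from a truth score matrix and (α, β) — exactly the generative model.
`downsample` is per-entry binomial thinning (the exact distributional
equivalent of read-level subsampling); `mix` thins the deeper of two
datasets to the shallower's total and sums them. `randomize_from_annotation`
builds truth rows from compartment labels: the annotated compartment draws
U(1−NL, 1), the others U(0, NL), rows then normalized to sum to 1 (the
row-sum normalization is this package's reading of "normalized");
NL ≤ 0.5 keeps the two ranges disjoint pre-normalization.

`make_synthetic_genome` produces block-structured truths: contiguous runs of
a dominant compartment (geometric lengths, mean 5 bins ≈ 500 kb domains),
rows drawn from a Dirichlet with concentration 6.0 on the dominant
compartment and 0.4 elsewhere (mean dominant score ≈ 0.79 — peaked but
heterogeneous, like real compartment score tracks), bias log-normal with
σ = 0.35, and acrocentric r. Bias is exposed rather than fixed because it
is locus-intrinsic; for mixture simulations the two populations share one
bias vector for the same reason.

What the simulator does **not** emulate: cis contacts, TADs/loops,
distance decay, fragment-level bias, copy-number variation, and
compartment-specific interactivity (S_k ≡ 1). Passing recovery tests
therefore demonstrates correctness of the inference under its own
generative assumptions and robustness to Poisson sampling noise and depth —
not robustness to the model violations discussed above, which on real data
change the interpretation of P as documented.

## Test and validation scale

The test suite validates derivatives against finite differences (1e−6
relative), per-locus solves against dense grid search, full fits against
exhaustive coarse grids on ≤ 6-bin instances, and parameter recovery on
simulated genomes. End-to-end checks use sizes chosen to exercise realistic
per-bin coverage while staying desk-scale: the low-depth robustness check
uses 8 × 20-Mb chromosomes at 100-kb bins (1600 bins) simulated at ~60,000
trans read-ends per bin — the per-bin coverage of a deep bulk Hi-C
experiment — thinned to 1 %, where the minimum matched-column correlation
with the truth stays above 0.9; mixture deconvolution uses 600 bins at
~1,500 ends per bin with M = 10; AIC selection uses 240-bin genomes at
~800 ends per bin over M ∈ {1..6} and 10 seeds. `scripts/acceptance.py`
re-runs the low-depth check from scratch with all randomness derived from
`--seed`.

## Known limitations

* Text `.pairs` input only (no `.hic`/`.cool` readers); counts are binned,
  not fragment-level.
* The likelihood treats read pairs as independent Poisson draws; PCR
  duplicates should be removed upstream.
* No uncertainty intervals on P (the Rabl coefficients get asymptotic
  standard errors via `rabl_standard_errors`); restarts probe, but cannot
  certify, the global optimum.
* r on metacentric chromosomes requires a centromere table; the acrocentric
  fallback misorients the p arm's r values, which weakens (not breaks) the
  Rabl correction there.
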