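# Methods

## Band-type scoring and methylation rates

Each MSAP/TMD locus yields one presence call per digest: M (*Mse*I/*Msp*I)
and H (*Mse*I/*Hpa*II).  The pair maps bijectively onto band types
I = (1,1), II = (1,0), III = (0,1), IV = (0,0).  Group rates are percentages
of pooled (sample × locus) counts:

    total = (II + III + IV) / T,  full = II / T,  hemi = III / T,  non = I / T

with T the group's complete-pair count.  Type IV is counted as methylated by
the total-rate formula even though a restriction-site mutation produces the
same pattern; the IV share is therefore also exposed separately
(`MethylationProfile.type_iv_pct`).  A missing (indistinct) band in either
digest voids the locus for that sample only; counts over any partition of
the samples sum exactly to the whole-matrix counts.

Rates are exact rationals internally.  Display rounding is round-half-up at
2 decimals, applied via decimal arithmetic so 0.005 always rounds up.  Class
means (`rate_contrasts`) are unweighted across treatment groups and are
computed from whatever precision the caller supplies; feeding 2-decimal
profiles reproduces summary statistics computed from published tables, at
the cost of one final-digit rounding ulp when a mean lands exactly on a
.xx5 boundary.  Counts are first-class inputs precisely so published count
tables can be analysed without the undeposited raw matrices.

## Diversity statistics

Every scored band (one locus × digest column) is a two-state phenotype with
observed presence frequency p.  No Hardy–Weinberg back-transformation of
dominant phenotype frequencies is attempted: the material this package
targets is highly selfing, and the phenotype-frequency model keeps H ≤ 0.5,
I ≤ ln 2 and ne ≤ 2.  Per band:

    H = 1 − p² − q²,  I = −p ln p − q ln q,  ne = 1/(p² + q²),
    PIC = 1 − p² − q² − 2p²q²          (q = 1 − p, 0 ln 0 := 0)

A band is polymorphic in a group when 0 < p < 1 over its non-missing calls.
Summaries report both an `all_loci` scope (fixed bands contribute zeros to
the H/I means) and a `polymorphic_only` scope, since legacy dominant-marker
programs are ambiguous about which they average.  The biallelic PIC maxes at
0.375; published PIC values for binary data sometimes exceed that bound
(unknown estimator), so PIC here is reported strictly under the formula
above.

## Distances, PCoA, Mantel

Samples are compared on concatenated (M, H) call vectors.  The default
metric, `squared_euclidean`, is the mismatch count on binary data — the
convention binary-marker AMOVA consumes.  Pairs with missing calls use
pairwise deletion with rescaling: mismatches over shared bands × (total
bands / shared bands), keeping sparse and complete pairs on one scale; a
pair sharing zero scored bands is an error.

PCoA double-centers −D²/2 (D² taken directly from a `squared_euclidean`
matrix, squared otherwise) and returns eigenvectors scaled by the square
root of positive eigenvalues.  Negative eigenvalues are dropped and their
total magnitude reported; no Cailliez/Lingoes correction is applied (none
is wanted when the input is an exact mismatch count).  Percent explained is
relative to the positive-eigenvalue sum.

Mantel r is the Pearson correlation of upper-triangle entries; significance
permutes rows/columns of the second matrix jointly, one-tailed (greater),
p = (1 + hits)/(B + 1).  Permutation count and seed are mandatory inputs,
and p ≥ 1/(B + 1) by construction.

## AMOVA

One-level AMOVA on squared distances:

    SS_total  = Σ_{i<j} d²ᵢⱼ / N
    SS_within = Σ_g Σ_{i<j∈g} d²ᵢⱼ / n_g
    var_within = MS_within,  var_among = (MS_among − MS_within)/n₀,
    n₀ = (N − Σ n_g²/N)/(k − 1)

ΦPT = var_among/(var_among + var_within).  Significance permutes whole
samples among groups with group sizes fixed, counting permuted among-group
variance components ≥ the observed one (999 permutations by default).  A
negative among-group estimate is truncated to zero for percentages and ΦPT;
the raw estimate is retained in the result.  df and SS additivity are
asserted on every run.  Hierarchical (multi-level) AMOVA is out of scope.

## Neighbor joining and ΔK

NJ follows Saitou–Nei: join the pair minimising
Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k); branch lengths by the standard
split formula; the last three nodes are resolved with the three-point
formula, rooting the returned tree at a degree-3 internal node (the unrooted
representation).  Ties break on the lowest (row, column) pair in current
node order, so output is deterministic.  On noisy input a negative branch
length is clamped to zero with the deficit moved to the sister branch,
preserving the pair's path length; clamps are recorded on the tree object.
Trees are `skbio.TreeNode` objects (Newick I/O, path-length queries).

Evanno ΔK consumes a plain (K, replicate, lnP) table from any external
admixture sampler: ΔK(K) = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| /
sd L(K), defined for interior K with ≥ 2 replicates; zero replicate
standard deviation leaves ΔK undefined (flagged, not infinite).  The
sampler itself is explicitly out of scope.

## Synthetic band matrices

The generator reproduces the statistical structure the analysis assumes,
not restriction-site sequence mechanics.

* Latent states per locus, baseline drawn from the marker system's state
  distribution π and shared across samples; each sample redraws its state
  from π with probability `epimutation_rate` (default 0.003).  The redraw
  leaves marginal state frequencies untouched, so it supplies within-group
  variance without biasing rates.
* Treatment demethylates each locus with
  p = 1 − exp(−(β_GR·dose + β_DNMTi·conc) · s · λ), where s ≥ 1 acts only
  when both mutagens are present and λ is a per-locus Gamma susceptibility
  (mean 1, squared CV `locus_dispersion`) shared across samples.  Marginally
  E[p] = 1 − (1 + rate·d)^(−1/d), which `expected_rates` uses.  Transitions:
  II → III with p·α, II → I with p·(1−α), III → I with p, IV → III with
  p·α.  Whether a demethylating locus stops at hemi (the α split) is drawn
  per locus: it is treated as a property of the locus's genomic context.
* Defaults: π set to the control-group state proportions of the bundled
  MSAP/TMD count tables; α = 0.3 for MSAP (mostly full demethylation) and
  0.8 for TMD (repeat-like, hemi-accumulating); β_GR = 2×10⁻⁴ Gy⁻¹ and
  β_DNMTi = 1.9×10⁻³ µM⁻¹, chosen so the expected total-methylation drops
  at 250 Gy (≈1.3 points) and 80 µM (≈4 points) match the magnitudes the
  bundled tables show; synergy s = 1.3; design 5/8·3/8·2/12·4 = 93 samples
  over 102 MSAP + 60 TMD loci.
* `epimutation_rate` and `locus_dispersion` were calibrated jointly (20
  simulated studies per candidate) so that among-class AMOVA variance on
  default simulations centers in the 20–40% band (realised mean ≈ 24–25%
  for MSAP, TMD and merged).  The Gamma susceptibility is heavy-tailed at
  1/d = 1/15, so single studies spread roughly 10–40% — a known property,
  not a defect.

What the generator does **not** emulate: linkage between the two marker
systems (baselines are independent streams), locus length/size structure,
genotyping error beyond the missing-call mechanism, dose-rate effects, and
mortality at high combined doses.  Passing recovery tests therefore shows
the scoring and partition machinery is correct under the stated model, not
that the model captures every property of real electropherogram-derived
matrices.

Because samples share per-locus baselines and susceptibilities, the
independent unit for a group's rate is the locus: recovery checks use
SE = √(q(1−q)/n_loci), an upper bound on the sampling deviation for any
[0, 1]-valued per-locus mean.

## Pipeline and reproducibility

`run_pipeline` drives load/simulate → score → diversity → distances →
AMOVA/PCoA → NJ (+ Mantel across systems) through the same public functions
a user would call, with no pipeline-only code paths.  A single global seed
fans out to per-stage seeds via a fixed CRC32 derivation of the stage name,
so adding a stage never perturbs existing streams; two runs with one seed
are byte-identical.  A stage failure leaves completed outputs in place plus
a `FAILED` marker naming the stage.

Numerical conventions: `squared_euclidean` matrices carry squared distances
and are consumed as such by PCoA and AMOVA (other metrics are squared on
the way in); PCoA eigenvalue positivity tolerance is 10⁻¹⁰ relative to the
spectral radius; permutation p-values are one-tailed with the +1
correction; all display rounding is round-half-up.

## Test problem sizes

The suite exercises: exact reproduction of all 80 published percentage
cells; AMOVA sums of squares vs a brute-force double-loop oracle on 50
random ≤ 12-sample instances (10⁻⁹); NJ inversion of 50 random 5–8 leaf
additive matrices (10⁻⁹ path lengths, identical topology); PCoA
reconstruction of Euclidean-embeddable distances (10⁻⁹); Mantel p-value
uniformity under a simulated null (200 replicates × 999 permutations,
Kolmogorov–Smirnov); and simulator calibration at 10⁴ loci × 2 groups of
50 samples × 100 replicates.  These sizes keep the full suite under half a
minute on one CPU while leaving each check statistically meaningful.
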