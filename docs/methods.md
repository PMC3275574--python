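# Methods

## Model and estimation

Expression is modeled log-linearly: the log₂ ratio of gene *g* in condition
*c* is `E[g,c] = Σ_t A[g,t]·P[t,c] + ε`, with the support of the
control-strength matrix `A` fixed by curated TF→gene connectivity and `P`
holding the latent per-condition TF activities.  `ε` is homoscedastic Gaussian
measurement noise.

**Identifiability.**  The decomposition is unique up to a per-TF scale/sign
factor when (i) the pattern admits a generically full-column-rank `A` and
(ii) deleting any TF's column together with its target rows leaves structural
column rank `n_tfs − 1`.  Both are checked on the bipartite pattern with
structural (maximum-matching) rank, which equals the generic numeric rank;
this is validated in the tests against brute-force numeric ranks of random
on-pattern fillings.  Fewer conditions than TFs is reported as a conditioning
warning, not a failure: it does not change the structural results but degrades
the activity estimates.  Since scale and sign per TF are not identified,
`A`'s columns are normalized to unit Euclidean norm with a positive
largest-magnitude entry, and all recovery comparisons align per TF by
correlation magnitude.

**Fitting.**  Alternating least squares: a P-step (unconstrained least
squares given `A`) and an A-step (per-gene least squares restricted to each
gene's regulator set, solved in batches of genes sharing a regulator set).
The residual is non-increasing by construction; iteration stops when the
relative Frobenius-residual change drops below `tol` (default 1e-6, cap 1000
iterations).  ALS is non-convex, so fits start from a projection of a
rank-`n_tfs` SVD basis onto the pattern support (ridge 1e-3; missing singular
directions are seeded with small noise so no activity row can start pinned at
zero) plus `n_restarts` random on-pattern starts (default 3), keeping the best
residual.  On noiseless identifiable instances the fit recovers the planted
activities to machine precision.

## Random-network significance

The null hypothesis for "TF *t* is perturbed" is that the expression of *t*'s
targets is exchangeable with randomly chosen genome genes.  Accordingly, ~200
random networks are formed by keeping the connectivity fixed and replacing
every gene's expression row with a row drawn (without replacement, per
network) from a background pool; each random network is fitted with identical
options and the activities pooled into per-(TF, condition) null sets.  The
observed TFA is standardized with the robust modified z-score
`z = 0.6745·(x − median)/MAD` — median/MAD rather than mean/SD so stray null
fits cannot inflate the spread — and converted to a two-tail p through the
standard normal; an empirical-tail variant and Benjamini–Hochberg control are
available behind flags but off by default.  A TF is called perturbed when any
condition reaches `p < α` (default α = 0.05); TFA-based status signatures use
the stricter per-TF t-test cut `p < 1e-4`.

Two properties of this scheme are worth recording.  First, per-cell null
medians need not be zero: networks resampled from a finite pool overlap, so
their fits partially align with the pool's leading principal direction.  The
z-score subtracts each cell's median, so only the spread matters.  Second,
the type-I rate is calibrated only when the null is true in the data: a TF
whose activity genuinely fluctuates (even with no group shift) is *not* null
with respect to random genome genes — its targets co-vary coherently — and
will legitimately score as active.

## Edge trimming

Curated connectivity contains false-positive edges (e.g. from high-throughput
binding assays).  Trimming removes edges whose fitted strength matches what
random background genes produce: per round, the network is fitted, each
edge's strength is compared by modified z-score against `n_null` (default 50)
background refits, and edges below `z_cut` (default 1.0) are dropped —
never a TF's last edge — until a round removes nothing or `max_rounds` is
reached.  Numerical choices:

* The edge statistic is `|A[g,t]|·‖P[t,:]‖`, invariant to the per-TF
  scale/sign indeterminacy, computed by truncated-SVD least squares
  (`rcond = 0.1`) of each gene's profile on its regulators' fitted activity
  rows.  Plain least squares occasionally explodes in sign-cancelling
  coefficient pairs when a null fit's activity rows are nearly collinear;
  truncation caps this while leaving well-conditioned fits at their exact
  least-squares values.  Observed and null strengths always use the same
  estimator.
* Refits after removals warm-start from the previous solution and keep the
  better of warm and cold fits; a cold restart on the pruned pattern can land
  in a worse ALS basin.

## Synthetic studies

The generator plants a ground truth with the statistical structure the
analysis assumes, at the scale of the motivating data (tens of TFs, an order
of magnitude more target genes, roughly ten targets per TF):

* **Pattern** — every TF receives one exclusive target plus random shared
  targets; identifiability holds by construction, not rejection sampling.
* **Strengths** — uniform ±[0.5, 1.5], sign random, so no true edge is
  numerically negligible.
* **Activities** — baseline `N(0, activity_sd²)` per cell (default 1).
  Perturbed TFs add a signed mean shift `effect_size` in the second condition
  group; the per-condition shifts are jittered (sd `0.5·effect_size`) and
  recentred, so the group-mean shift is exact while distinct perturbed TFs
  keep linearly independent activity patterns — with identical shift profiles
  the attribution of the shared pattern to individual TFs would not be
  unique.
* **Spurious edges** — added to the pattern with true strength zero, never on
  exclusive targets (identifiability is preserved).
* **Background pool** — ten network-sized blocks of genome-like genes, each
  regulated by its own hidden TFs.  Two genome-scale constants govern the
  pool, independent of the study network's settings: quiet baseline hidden
  activity (`pool_activity_sd = 0.4`, sized so only a few percent of
  background genes exceed a 2-fold change by chance) and a sparse strong
  responder fraction (`pool_responder_fraction = 0.02`, the order of the
  genome-wide strong-responder rate in a typical perturbation experiment,
  responding at the study's effect size).  A pool cloned from the perturbed
  study network itself would over-disperse the null (most genomes are not 20%
  strong responders) and mask real effects.

**Regimes.**  Recovery experiments use rich activities (`activity_sd = 1`):
with quiescent TFs there is nothing to recover and the activity matrix loses
row rank.  Significance experiments use quiescent unperturbed TFs
(`activity_sd = 0`): under log-ratio semantics an unperturbed TF has activity
ratio ≈ 0, which is exactly the exchangeability null the z-test assumes, and
under the global null the pool blocks reduce to noise matching the network
genes, making observed and null fits exchangeable.  Detection experiments
place all columns in the shifted group (`group_fraction = 1`), emulating an
induction design where every column is a treated-versus-reference ratio;
unshifted columns in the same fit would couple quiescent TFs to the large
signal elsewhere and inflate their activity estimates relative to any
random-gene null.

**What the generator does not emulate:** probe-level array artifacts and
normalization residue, heavy-tailed or gene-dependent noise, correlated TF
activities (the co-activity clusters real cohorts show), heteroscedastic
cohort structure, and survival times.  Passing tests demonstrate correctness
of the estimation and calibration machinery under the stated model, not
performance on real tumor cohorts.

## Study sizes used in the acceptance runs

Exact recovery: 6 TFs / 60 genes / 12 conditions, σ = 0.  Noisy recovery: the
same at σ = 0.1 over 10 seeds (median per-TF |r| ≈ 0.999).  Calibration: 20
TFs / 200 genes / 25 conditions (500 TF×condition cells), global null, 200
random networks; the p < 0.05 call rate is checked against the 99% binomial
band around 5%.  Detection: 4 perturbed of 20 TFs, shift 2, σ = 0.1, 10
seeds; all planted TFs are recovered with ≈0 false positives per run.
Trimming: 10% spurious edges at σ = 0, 6 seeds, aggregate 100% spurious
removal with ≥95% true-edge retention.  Cohort clustering: a 40-sample
two-block TFA signature (shift 3, jitter 0.2) is recovered exactly (ARI 1.0)
with χ² association p < 1e-6.  Null-network fits in the calibration and
detection runs use a 150-iteration cap and the deterministic start only;
observed and null fits always share options.

## Known limitations

* Activity estimates for quiescent TFs inherit error proportional to the
  signal amplitude elsewhere in the fit (shared genes couple the columns), so
  false-positive control depends on the background pool containing realistic
  gene variability — a pure-noise pool is anti-conservative.
* The modified z-to-normal-tail conversion assumes roughly Gaussian null TFA
  marginals; with very few conditions the null becomes bounded and the
  conversion conservative.  The empirical-tail option sidesteps this at the
  cost of p-value granularity (~1/n_networks).
* Trimming decisions near the cutoff are Monte-Carlo noisy (50 background
  refits); weak true edges (|CS| near 0.5) sit closest to the null and are
  the ones occasionally lost.
* The χ² association uses the group-1-versus-rest scheme with 1 df and no
  continuity correction; group 1 is defined as the smallest cluster, the
  convention for singling out the aberrant tumor group.
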