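# Methods

## The two-stage read-count model

`tcrdetect` models the number of sequencing reads of one target T-cell
receptor (TCR) clonotype in a bulk TCR-seq experiment as the composition of
two random stages.

**Sampling stage.** A blood draw contains `T_samp` T cells, each carrying one
receptor. If the target clonotype has frequency `f_body` among all T cells in
the body, the number of target cells in the sample is

    C_samp ~ Poisson(f_body · T_samp),

which assumes homogeneous mixing of T cells in peripheral blood. The model is
not appropriate for spatially structured material such as tissue biopsies.

**Read stage.** Given `C_samp = c`, the target's in-sample frequency is
`f_samp = c / T_samp`, and its read count is negative binomial,

    C_read ~ NB(mu, sigma^2),   mu = f_samp · r_e · T_read,
                                sigma^2 = mu + eta · mu^lam,

where `T_read` is the total read depth for the chain. The read efficiency
`r_e ∈ [0, 1]` captures how many reads a unit of in-sample frequency buys;
`eta ≥ 0` and the exponent `lam` describe the extra-Poisson variance
introduced by library preparation and PCR (at `eta = 0` the stage is exactly
Poisson). The mean/variance pair is converted to the standard size/probability
parameterization by `size = mu^(2 − lam) / eta`, `p = size / (size + mu)`,
using the continuous (gamma-function) pmf since the size is generally not an
integer.

The marginal read-count distribution sums the read stage over the sampling
stage. Detection at read threshold `c_thresh` means `C_read > c_thresh`
(strictly), so power is `1 − Σ_{i≤c_thresh} P(C_read = i)`.

## Numerical choices

- All pmfs are evaluated in log space and exponentiated at the interface.
- The sampling-stage sum is truncated: the support is the union of the
  mean ± 10·sd window and the two-sided Poisson quantile window at tail mass
  1e-15, then terms below 1e-16 of the modal Poisson mass are dropped. The
  quantile window matters at small rates, where mean + 10·sd undershoots the
  discrete upper tail; with both cuts the truncation error is below 1e-12,
  comfortably inside the 1e-10 agreement demonstrated against exhaustive
  summation. The `c_samp = 0` term is always kept so the marginal pmf
  normalizes; it never contributes to detection. Both thresholds are
  configurable.
- When `size > 1e12` the negative binomial is numerically Poisson and the
  Poisson pmf is used; `size < 1e-12` (astronomically large variance) raises
  an error rather than returning garbage.
- The threshold sum in the power computation is always evaluated directly;
  supported thresholds are small (a typical cutoff is 18 reads), so no
  complementary-tail evaluation is needed.
- Root finding (detection limit, minimal detectable `f_body`) uses monotone
  bisection on log frequency: relative tolerance 1e-6 on the detection limit,
  power tolerance 1e-4 on the minimal body frequency.
- Power grids precompute the truncated sampling support once per `T_samp`
  (it is independent of read depth) and reuse it along the row. The 95%
  contour is extracted by linear interpolation on the log read-depth axis.

**A monotonicity caveat.** Power is non-decreasing in `f_body`, `T_read` and
`r_e` everywhere, but monotonicity in `T_samp` holds only in the operating
regime where the expected read count `f_body · r_e · T_read` exceeds the
threshold. Below it, a smaller sample concentrates the same expected reads on
fewer cells, fattening the upper tail of `C_read` and *raising* the
probability of clearing the threshold. Grid-shape guarantees (monotone rows
and columns, the rectangular-with-rounded-corner 95% region) are therefore
stated and tested for grids in the operating regime.

## Calibration

Spike-in clonotypes have known in-sample frequencies, so the sampling stage
drops out of the likelihood and `(r_e, eta, lam)` are estimated from the read
stage alone by maximum likelihood. The optimizer is Nelder-Mead on a
transformed scale — logit `r_e`, log `eta` (bounded in [1e-8, 1e4]), `lam`
boxed in [0.5, 3.0] by default — started from a method-of-moments point
(ratio estimator for `r_e`; log-regression of per-tier excess variance on
mean for `eta`, `lam`) plus a fixed 3×3 grid, since the likelihood can be
multimodal in `(eta, lam)`. An explicit `eta = 0` Poisson submodel (whose
`r_e` MLE is closed form) is compared by likelihood; when the negative
binomial improves on it by less than 1e-6 log-likelihood units the Poisson
fit is reported with `eta = 0` exactly. At least three distinct spike-in
frequencies are required, otherwise `lam` is unidentifiable.

Parameter covariance is the inverse of a central-difference numeric Hessian
of the log likelihood at the optimum, symmetrized and eigenvalue-clipped to
positive semi-definite. Each chain × experiment-set combination is calibrated
independently.

**Detection limit.** `f_samp95` is the in-sample frequency at which
`P(C_read > c_thresh) = 0.95` (defaults: `T_read = 1e6`, `c_thresh = 0`),
solved by bisection. Its confidence interval comes from a seeded parametric
bootstrap: 1000 parameter vectors drawn from the multivariate normal at the
MLE, clipped to the feasible box (clipping rather than rejection — the
parameter uncertainty is small, so the boundary mass is negligible), each
mapped through the detection-limit solve, summarized by the 2.5/97.5
percentiles. A Wald/delta-method interval on the log limit is available as an
alternative and agrees to well within a factor of two on calibrated fits.

## The synthetic-data generator

The generator reproduces the statistical structure of the calibration study:
45 spike-in clonotypes in nine frequency tiers (1, 3, 10, 50, 300, 1000,
3000, 10 000, 50 000 per million; five clones per tier), six replicates, TRA
and TRB chains, and a background repertoire whose frequencies follow a
discretized power law (exponent 2 by default) over the remaining ~0.68 of
frequency mass — mirroring the long-tailed shape of in-vivo repertoires and
the roughly one-third/two-thirds spike-in/background RNA split of the study
design. Spike-in counts are drawn from the same gamma-Poisson mixture that
the pmf code evaluates, so parameter-recovery tests are exact model-vs-model
comparisons. CDR3s are random A/C/G/T strings of length 24–60 in multiples of
three, unique within a chain.

Per-clone counts are drawn independently, so replicate totals fluctuate
around `T_read`; an exact-totals mode redraws counts from a multinomial when
frequency-sum invariants are needed. Optional plants exercise the processing
pipeline: all-zero dropout clones, exclusive low-count false positives with
caller-chosen counts, and index-hopping false positives planted at
`round(ratio · source_count)` reads from caller-supplied source clonotypes
(default ratio 0.01, i.e. the 1–2 log depression characteristic of hopping).

What the generator does **not** emulate: V/J segment structure, sequencing
errors at the base level, PCR-cycle mechanics, chain pairing within a cell,
or any correlation between clones. Passing tests therefore demonstrate
internal consistency of the model, estimator and pipeline — not that the
model describes any particular laboratory protocol; for that, the calculator
must be recalibrated on real spike-in pilot data.

## Fixture scales and defaults

Simulation-backed tests use the study-scale design (9 tiers × 5 clones × 6
replicates = 270 observations per chain, `T_read = 1e6`) with generating
truth `r_e = 0.7`, `eta = 1.5`, `lam = 1.3`; parameter-recovery coverage is
assessed over 50 fixed seeds. Oracle-equivalence checks run on instances with
`T_samp ≤ 100`, where exhaustive double summation is exact and fast.
Planted-artifact fixtures raise the lowest spike-in tier to 5e-5 (expected
count 35) so that no clone can plausibly drop out by chance and the planted
dropouts are recovered exactly. Canonical defaults throughout: detection
probability 0.95, `T_read = 1e6`, `c_thresh = 0` for detection limits and 18
for the worked power example.

## Known limitations

- The sampling stage assumes one receptor per cell and homogeneous mixing.
- Calibration requires ground-truth spike-in data; parameters are specific to
  a library-preparation and sequencing protocol and do not transfer.
- No family-wise or false-discovery extension across sets of TCRs.
- Index hopping is detected and reported, not corrected.
- The bootstrap interval reflects parameter uncertainty at the MLE only; it
  does not propagate model misspecification.
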