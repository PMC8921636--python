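# tcrdetect

Calibrated statistical power calculations for detecting a target T-cell
receptor (TCR) clonotype by bulk TCR sequencing.

Many diagnostically relevant T-cell clonotypes circulate at frequencies down
to one per million T cells. Whether a sequencing experiment can detect such a
clonotype depends on four things: the clonotype's frequency in the body, how
many T cells the blood sample contains, the sequencing read depth, and the
read cutoff used to suppress false positives. `tcrdetect` quantifies
detection probability as a function of all four, for experimentalists and
diagnostic developers planning bulk TCR-seq (AIRR-seq) studies.

## The model

Detection is modelled in two stages:

1. **Blood sampling** — the number of target cells in a sample of `T_samp`
   T cells is `C_samp ~ Poisson(f_body · T_samp)`, where `f_body` is the
   clonotype frequency in the body.
2. **Sequencing** — given the in-sample frequency `f_samp = C_samp / T_samp`,
   the read count is negative binomial,
   `C_read ~ NB(μ, σ²)` with `μ = f_samp · r_e · T_read` and
   `σ² = μ + η μ^λ`,
   where `r_e` is the read efficiency of the protocol and `η, λ` shape the
   extra-Poisson variance from library preparation and PCR.

Marginalizing over `C_samp` gives `P(C_read)`, and the detection power at
read threshold `c_thresh` is `P(C_read > c_thresh)`. The protocol parameters
`(r_e, η, λ)` are estimated by maximum likelihood from pilot sequencing of
spike-in clonotypes with known in-sample frequencies; from the calibrated
model the package derives the minimal detectable in-sample frequency at 95%
confidence (`f_samp95`, with bootstrap confidence intervals), the minimal
detectable body frequency, and power grids over `(T_samp, T_read)`.

A seeded synthetic-experiment generator reproduces the calibration study
design (nine frequency tiers of five spike-in clones, 1e-6 to 5e-2, six
replicates, long-tailed background repertoire) with optional planted
dropouts and false positives, enabling fully self-contained parameter
recovery and pipeline tests. Utilities are included for MiXCR-export-style
clonotype tables: IMGT CDR3 conversion, spike-in matching, dropout
exclusion, frequency-linearity and dispersion statistics, and the
false-positive / read-cutoff analysis. See `docs/methods.md` for details and
limitations.

## Worked example

```python
from tcrdetect import *

# Synthetic pilot experiment at the study design, then calibration.
truth = ReadModelParams(r_e=0.7, eta=1.5, lam=1.3)
exp = generate_spikein_experiment(SpikeInDesign(seed=1), truth, t_read=10**6)
res = fit_read_model(exp.calibration_observations("TRB"), t_read=10**6)
print(f"r_e = {res.params.r_e:.3f}, eta = {res.params.eta:.3f}, "
      f"lam = {res.params.lam:.3f}")

lim = detection_limit(res)                      # alpha=0.95, T_read=1e6
lo, hi = detection_limit_ci(res, seed=0)
print(f"f_samp95 = {lim.f_samp95:.3e}  (95% CI [{lo:.3e}, {hi:.3e}])")

p = detection_power(PowerQuery(SamplingContext(1e-4, 10**6),
                               SequencingContext(10**7, 18), res.params))
print(f"power = {p:.4f}")
```

prints

```
r_e = 0.698, eta = 1.705, lam = 1.292
f_samp95 = 9.194e-06  (95% CI [7.428e-06, 1.063e-05])
power = 1.0000
```

The fit recovers the generating parameters; with this protocol, a clonotype
at one-in-ten-thousand body frequency is detected essentially always when
sampling 1e6 T cells at 1e7 reads, even with a stringent 18-read cutoff —
while the detection limit shows that at 1e6 reads nothing rarer than ~9 per
million in the sample is reliably seen without replicates.

The same operations are available from the shell:

```sh
tcrdetect simulate --seed 1 --outdir pilot/
tcrdetect calibrate --table calib.tsv --t-read 1000000 --out fit.json
tcrdetect power --params-json fit.json --f-body 1e-4 --c-thresh 18 \
    --t-samp-axis 1e4,1e5,1e6 --t-read-axis 1e6,1e7,1e8 --out-prefix grid
tcrdetect process --manifest tables.yaml --outdir processed/
```

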