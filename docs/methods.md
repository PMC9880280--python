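# Methods

`adexbrain` simulates wake-like and sleep-like cortical dynamics across three
scales — spiking networks, population mean-fields, and a connectome-coupled
whole-brain model — with spike-frequency adaptation as the state variable
that switches between regimes. This note documents the models, the
calibrations, the numerical choices, and the known limitations.

## Spiking level

The microscopic model is the adaptive exponential integrate-and-fire (AdEx)
neuron with conductance-based synapses:

    c_m dv/dt = g_L (E_L - v) + g_L Δ exp((v - v_thr)/Δ) - w + G_e (E_e - v) + G_i (E_i - v)
    u_w dw/dt = -w + a (v - E_L),          w -> w + b at each spike

Spikes are detected at `v_peak`, after which `v` is clamped at `v_reset` for
`T_refr = 5` ms (`w` keeps evolving during refractoriness). Synaptic
conductances decay exponentially (`u_e = u_i = 5` ms) and jump by the quantal
`Q_e = 1.5` nS / `Q_i = 5` nS on presynaptic spikes. Two cell classes share
one network: regular-spiking excitatory cells (80%, `Δ = 2` mV,
`E_L = -63` mV, adaptation `b` in pA) and fast-spiking inhibitory cells
(20%, `Δ = 0.5` mV, `E_L = -65` mV, no adaptation). The default network has
N = 10⁴ neurons wired as a directed Erdős–Rényi graph with p = 0.05.

Integration is forward Euler at dt = 0.1 ms with the exponential argument
clamped at +10 (consequence-free, since spikes are detected at `v_peak`
first); conductance decay uses the exact per-step factor. Halving dt changes
the 3-s mean population rate by well under 5% (tested). Initial voltages are
spread uniformly between rest and threshold so the network ignites without
depending on the drive for the first spikes.

**External drive.** Each neuron receives an independent Poisson train through
`Q_e` synapses, parameterized as a per-synapse rate on K_ext = 400 inputs.
The rate is not constrained by any published value; it was calibrated once so
that the default network sustains asynchronous-irregular (AI) firing at b = 0
while keeping Up–Down alternation at b = 60 pA, giving **0.4 Hz** per
synapse. The drive targets all neurons (both populations), mirroring the
network-level mean-field convention below. At 0.3 Hz the b = 0 network shows
occasional network-wide silences; at 0.7 Hz the b = 60 network loses its
Down states — the default sits comfortably inside the window.

**Regime classification.** A population-rate series (0.5-ms bins) is labeled
Up–Down when more than 10% of 20-ms blocks fall below 1 Hz after a 500-ms
transient, else AI. With defaults, b = 0 → AI and b = 60 → Up–Down across
seeds.

## Transfer function

The mean-field rests on the population transfer function F(ν_e, ν_i, W): the
stationary firing rate of one neuron receiving K_e = 400 excitatory and
K_i = 100 inhibitory Poisson trains at the given rates with a frozen
adaptation current W. It is evaluated semi-analytically,

    ν_out = erfc((V_thr_eff - μ_V) / (√2 σ_V)) / (2 τ_V),

with shot-noise membrane moments: μ_Ge = ν_e K_e u_e Q_e (and analogously
for inhibition), μ_V = (μ_Ge E_e + μ_Gi E_i + g_L E_L − W)/μ_G, per-synapse
efficacies U_s = (Q_s/μ_G)(E_s − μ_V), effective membrane time
τ_m = c_m/μ_G, σ_V² = Σ_s K_s ν_s (U_s u_s)²/(2(τ_m + u_s)), and τ_V the
ratio of the same spectral moments. Adaptation enters only through μ_V, as a
subtractive current. V_thr_eff is a second-order polynomial (10
coefficients) in the rescaled (μ_V, σ_V, τ_V g_L/c_m).

**Fitting.** For each point of a 10×10 rate grid (0.5–40 Hz, denser at low
rates) × 3 adaptation levels (0/40/80 pA for RS; W = 0 for FS), 20
independent neurons are simulated for 10 s at dt = 0.05 ms and the
stationary rate measured. Fitting is two-stage: (1) linear least squares in
threshold space, inverting the erfc formula at points with ≥ 10 spikes and
2 τ_V ν < 2 (the domain of erfcinv); (2) nonlinear least squares on rate
residuals over the whole grid, weighted by 1/√(1+ν) so accuracy concentrates
in the low-rate band where the recurrent network operates. The shipped fits
achieve ≈ 0.3 Hz (RS) and ≈ 0.2 Hz (FS) RMS error for observed rates
≤ 40 Hz; the saturation corner (> 100 Hz output) is fitted loosely on
purpose. Fitted coefficient sets for the default parameters ship as JSON and
are loaded by `default_transfer_functions()`; refitting is one function (or
CLI) call.

## Single-region mean-field

Two populations (ν_e, ν_i) plus the excitatory adaptation current W:

    T dν_μ/dt = F_μ(ν_input, ν_i, W) − ν_μ
    dW/dt     = −W/u_w + b ν_e + a (μ_V − E_L)

with an Ornstein–Uhlenbeck afferent-rate drive ξ(t) added to the
transfer-function *input* (never the state): mean 0.4 Hz (matched to the
spiking drive), SD 0.1 Hz, correlation time 5 ms, exact one-step OU update.
By default the drive enters both F_e and F_i (`drive_symmetric=True`),
matching the network-level input convention and the spiking setup; the
excitatory-only variant is available but pairs poorly with a spiking network
whose populations are both driven. The population timescale defaults to
T = 25 ms, chosen phenomenologically inside the admissible 5–40 ms range so
that the coupled model's wake-state resonance falls in the alpha band (see
below).

Integration is stochastic Heun at dt = 0.1 ms; rates are clipped at zero
after every step (the model can transiently undershoot near the Down state).
Halving dt changes the stationary wake rate by < 0.1%.

The **second-order Master Equation** adds the 2×2 rate covariance c_λη,
integrated alongside the rates: the rate equations gain the curvature
correction ½ c_λη ∂²F/∂ν_λ∂ν_η, and c follows source (finite-size, ∝ 1/N),
drift-product, Jacobian-amplification and relaxation terms. Derivatives of F
are central finite differences with h = 0.5 Hz. Only (c_ee, c_ei, c_ii) are
integrated, so symmetry is structural; diagonal entries are clipped at zero.

**Fixed points.** For each ν_e on a scan grid the inhibitory rate is solved
self-consistently (ν_i = F_i), then identity crossings of
ν_e → F_e(ν_e, ν_i*(ν_e)) are bracketed at 0.1-Hz resolution and refined by
bisection; stability follows the crossing direction. The default bracket is
(0, 50] Hz — the transfer function's calibrated domain; beyond the fitted
grid the threshold polynomial extrapolates and can manufacture spurious
crossings near the 1/T_refr ceiling. At b = 0 the finder returns an
unstable crossing at ≈ 0.55 Hz and a stable one at ≈ 7.4 Hz; the silent
state at ν = 0 is a boundary equilibrium of the clipped dynamics (reported
with `include_zero=True`), which is how the bistability that sustains
slow-wave alternation is realized here.

## Whole-brain network

N regions (68 by default), each a first-order mean-field, coupled through a
connectome with axonal delays:

    ν_input(k, t) = ν_drive(k, t) + ν_e(k, t) + S Σ_{j≠k} C_jk ν_e(j, t − L_jk/v_c)

Both F_e and F_i of a region receive ν_input (+ ν_aff, default 0). The self
term enters with unit weight and is not scaled by the global coupling S
(default 0.1); delays are tract length over v_c = 3 mm/ms, rounded to the
nearest 0.1-ms step and served from a ring buffer warmed up with the initial
state. Per-region OU drives are independent, with per-region streams derived
from the master seed. A square-wave stimulus (default 0.1 Hz, 50 ms) can be
added to the excitatory transfer-function input of one region.

With the default synthetic connectome, b = 0 gives asynchronous regional
activity with a spectral peak near 10 Hz (the damped E–I resonance of each
region, f ≈ gain/2πT, which motivated T = 25 ms), and b = 60 gives global
slow waves with a delta-band peak (≈ 2 Hz), strongly increased inter-region
Pearson correlation, and inhibitory-rate correlations significantly
exceeding excitatory ones — in the wake-like state the two are statistically
indistinguishable.

## Synthetic connectome

The reference dataset for this kind of model is a subject-specific 68-region
tractography connectome, which requires a download; the packaged generator
emulates its statistics so everything runs self-contained. Region centres
are sampled in two mirrored ellipsoids (inter-centre distances up to
≈ 90 mm); tract lengths are Euclidean distances × 1.3 tortuosity; weights
are log-normal (σ = 2, giving skewness ≫ 1), decay with distance
(λ = 30 mm), are 0.3× across hemispheres, symmetric, max-normalized, and —
as in human tractography — homotopic mirror pairs receive a strong callosal
connection (8× the largest background weight before renormalization). The
homotopic tracts put a heavy coupling mass at intermediate (≈ 40–65 mm)
distances; without them the sleep-state PLI grows monotonically with
distance instead of showing any mid-range structure. Mean column
strength is ≈ 1.1, so the default S = 0.1 keeps long-range input comparable
to the drive. What the generator does **not** emulate: community structure
beyond hemispheres, hub-periphery organization, distance-dependent weight
noise correlations, or any subject specificity — conclusions about those
features cannot be drawn from tests on this fixture.

Weight normalization from raw tractography follows
w_jk = fibers_jk/(vol_j + vol_k) with a global rescale to max 1 (the
coupling strength S carries all magnitude, keeping S scans comparable
across connectomes). The shuffled-connectome null permutes each region's
outgoing off-diagonal weights (per-row multiset preserved) and leaves tract
lengths untouched.

## Analyses

* **Spectra**: Welch periodogram on the region-averaged excitatory rate, 4-s
  Hann windows, 50% overlap, peak searched in 0.1–100 Hz. Rate series are
  recorded at 1 kHz (1-ms sampling), far above all frequencies of interest.
* **FC**: pairwise Pearson correlation of the full post-transient series
  (2-s transient discarded); zero-variance regions yield flagged NaNs.
* **PLI**: Hilbert phase per 1-s epoch, PLI_ij = |⟨sign(sin(ψ_i − ψ_j))⟩_t|
  (the sine wraps the phase difference), averaged over epochs. 0 for
  identical signals or random phases, 1 for constant lag.
* **Distance profiles**: inter-centre Euclidean distances (delays use tract
  lengths; both are exposed) cut into 5 equal-width bins; Kruskal–Wallis
  omnibus across bins, Mann–Whitney U of the middle bin against each other
  bin, and a least-squares slope. Empty bins merge leftward and are logged.
* **E/I comparison**: independent two-sample t-test on the off-diagonal FC
  entries, signed excitatory-minus-inhibitory.
* **Conover–Iman post-hoc** (after Kruskal–Wallis) is implemented from the
  standard rank formulation with Holm adjustment.

## Perturbation and PCI

40 trials deliver the same square-wave stimulus to the right premotor
region (label-matched, configurable) with independent noise and onsets
randomized within a 500-ms window after a 2-s settle; trials are aligned on
onset keeping 300 ms on each side (1-ms bins). Binarization z-scores each
region by its own pre-stimulus mean/SD pooled over the 20-trial series
(per-region, not node-averaged: a shared scalar SD lets high-variance
regions dominate the null maximum and abolishes detection), builds the null
by bootstrap-resampling all pre-stimulus values across time bins 500 times
(resampling with replacement: a pure permutation would leave the maximum
invariant), and sets T_sig at the 99th percentile of the per-repetition
maxima. s(t) = 1 wherever post-stimulus z exceeds T_sig. Under a null
stimulus the fraction of significant bins stays below 1 − percentile
(max-statistic control is conservative by design). Onset maps require two
consecutive significant bins.

Per trial, the region×time significance matrix is flattened to S and
summarized by PCI = LZ(S)/H(S): LZ is a sequential-dictionary word count
(the growing word is emitted whenever it is new; the trailing word counts),
H the binary plug-in entropy; H = 0 ⇒ PCI ≡ 0 (a response carrying no
information carries no complexity). Because H can be ≪ 1 for sparse
responses, PCI values for a 20 400-bit vector range into the tens of
thousands; only comparisons across conditions are meaningful.

At the default calibration, PCI separates states sharply: wake-like (b = 0,
20) trials respond in ≈ 90% of cases with high PCI; b = 60 responds in
< 10% with a wide relative spread. The AI→Up–Down transition of the coupled
model falls between b = 20 and 40 pA here — the transition point moves with
S, T and the leak reversals (that is what the parameter scan maps), so the
b = 40 condition is already slow-wave-like, while remaining clearly more
responsive than b = 60.

## Parameter scan

The scan driver takes any sub-grid of (S, E_L_e, E_L_i, T, b_e) over their
physiological ranges (16 evenly spaced values per axis if not given
explicitly), runs a 7-s simulation per configuration (2-s transient
discarded), and tabulates rate means/SDs, mean FC, and the regime label.
Per-configuration seeds derive from the master seed and row index, so the
table is identical for any worker count. The full 16⁵ factorial is a
cluster-scale job; the driver is deliberately an embarrassingly parallel
map, shardable by row range.

## Known limitations

* The second-order Master Equation is a small-fluctuation closure. At the
  default wake operating point the fitted transfer functions give a
  near-marginally damped E–I loop (Jacobian eigenvalues of (J − I) ≈
  −0.004 ± 1.69i), so the predicted stationary covariance is much larger
  than the spiking network's binned-rate variance and feeds a sizeable
  curvature correction back into the means; the first-order model is the
  faithful reduction in this regime and is what the network level uses.
  The N → ∞ limit correctly collapses the second-order model onto the
  first-order one (tested).
* The mean-field is calibrated for adaptation up to ≈ 100 pA and slow
  collective dynamics; gamma-band phenomena, spindles and ripples are
  outside its validity.
* The transfer function is trusted on its fitted domain (input rates
  ≤ 40 Hz); fixed-point searches beyond it are extrapolation.
* All regions share one parameter set; no regional heterogeneity, no
  thalamic afferents (ν_aff defaults to 0), no plasticity.
* Test problem sizes (5-s spiking runs, 12-s brain runs, 40-trial PCI
  ensembles on the synthetic connectome) are the package's default
  experiment sizes; they reproduce regime-level contrasts, not
  subject-level quantitative detail.
* Distance-resolved phase structure is the least robust regime signature on
  the synthetic connectome: under the documented default conditions the
  sleep-state PLI shows a significant mid-distance elevation that shuffling
  the weights removes, but across other noise realizations (and in longer
  runs) the profile flattens, and the shuffled null can retain distance
  structure through the (unshuffled) delay matrix. The phenomenon appears
  to depend on the full weighted graph structure of an empirical human
  connectome, which the synthetic generator only partially emulates; with a
  real tractography connectome the same analysis pipeline applies
  unchanged. The robust distance signature here is the wake-state decay of
  Pearson FC with distance.
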