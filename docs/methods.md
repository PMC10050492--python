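# Methods

## Model

The network is a one-dimensional continuous attractor model of the grid-cell
circuit in the superficial medial entorhinal cortex: N_E = 1024 excitatory
principal cells and N_I = 256 inhibitory interneurons, each population laid
out uniformly on its own ring and labelled by angular position θ. Every
neuron is a conductance-based leaky integrate-and-fire unit,

    C_m dV/dt = −g_L (V − V_L) − I_syn + I_ext ,

with a spike emitted when V reaches V_th = −50 mV, followed by a clamp at
V_reset = −60 mV for the absolute refractory period. Principal cells:
C_m = 0.5 nF, g_L = 25 nS, τ_ref = 2 ms (τ_m = 20 ms, rheobase 500 pA);
interneurons: C_m = 0.2 nF, g_L = 20 nS, τ_ref = 1 ms (τ_m = 10 ms,
rheobase 400 pA); V_L = −70 mV for both.

There is no recurrent excitation between principal cells in the default
configuration. E→I excitation is NMDAR-mediated: the current to interneuron
i is

    I_NMDA,i = g_NMDA (V_i − V_E) B(V_i) Σ_j W_ij S_NMDA,j ,
    B(V) = 1 / (1 + [Mg²⁺] e^{−0.062 V} / 3.57) ,

with g_NMDA = 0.4 nS, V_E = 0 mV, [Mg²⁺] = 1 mM. The gating obeys the
standard two-variable saturating kinetics

    dS/dt = −S/τ_NMDA + α x (1 − S),   dx/dt = −x/τ_x + Σ_k δ(t − t_k) ,

τ_NMDA = 100 ms, α = 0.5 kHz, τ_x = 2 ms; S stays in [0, 1] because of the
(1 − S) factor. Inhibition is GABA_A-mediated, first order with τ_GABA =
10 ms, reversal V_I = −70 mV, g_GABA = 2.4 nS onto principal cells and
0.04 nS between interneurons.

### Connectivity

Weights depend only on the circular angular difference Δθ ∈ [0°, 180°]:

* E→I: W(Δθ) = J⁻ + (J⁺ − J⁻) exp(−Δθ²/2σ²), J⁺ = 1.6, σ = 30°, peaked at
  zero offset;
* I→E: W(Δθ) = G exp(−(Δθ − μ)²/2σ²), μ = 90°, σ = 30° — two maxima at
  signed offsets ±90°, which is what spaces two bump attractors 180° apart;
* I→I: uniform, W ≡ 1 (structured unimodal/bimodal variants available).

J⁻ and G follow from the normalization ⟨W⟩ = 1 over angular offsets. We
apply it as the **discrete mean over each row's actual presynaptic offset
grid**, so every row mean equals 1 exactly (machine precision); the
continuous-integral alternative is available as an option and differs by
~5·10⁻⁶ relative at this network size. For the I→E matrix the four offset
residue classes of E cells relative to the coarser interneuron grid make a
single amplitude G impossible to reconcile with exact row means (the
circular-distance kink at 0°/180° aliases at ~7·10⁻⁶); per-row
normalization keeps the matrix a function of Δθ within each residue class
and exactly circulant under the common rotation group (multiples of
360°/N_I). With the defaults, J⁻ = 0.84158 and G = 2.40015.

The optional E→E variant is a zero-peaked Gaussian with the autapse
(diagonal) removed before row normalization; the choice to exclude
autapses follows the convention of recurrent-excitation network models and
is quantitatively irrelevant at N_E = 1024.

### External input

Principal cells receive a constant background I_Back^E = 750 pA;
interneurons receive I_Back^I = 325 pA plus the medial-septum (MS) input
I_MS(t) = I_MS,0 + A cos(2π f_MS t), default I_MS,0 = −100 pA (constant
GABAergic inhibition), A = 0. Every neuron receives an independent
Ornstein–Uhlenbeck noise current

    τ_N dI/dt = −I + η √τ_N n(t) ,

η = 150 pA, τ_N = 2 ms, whose stationary SD is η/√2 ≈ 106.07 pA. Because
η is sometimes quoted as "the" noise SD, a convention switch
(`noise_convention="target_sd"`) rescales the process so the stationary SD
equals η; the default follows the equation as written. The OU update uses
the exact exponential discretization (decay e^{−dt/τ}, matching Gaussian
innovation), which is correct at any step size; noise is initialized from
the stationary distribution and held constant within each integration
step.

A bump-seeding cue of +200 pA is applied to principal cells within
[67.5°, 112.5°] ∪ [247.5°, 292.5°] for the first 500 ms, fixing the two
attractors near 90°/270° across trials. An optional suppression protocol
applies −200 pA to interneurons within half-width w of 0° and 180°
(between the bumps) for the whole trial.

A Poisson input variant replaces the constant background and MS currents
with exponentially filtered homogeneous Poisson trains (excitatory filter
τ = 2 ms, inhibitory τ = 10 ms; default rates 1000/1000/500 Hz); unit
charges are chosen so the filtered means equal the constants they replace.
The published description of this variant omits its rates and unitary
sizes, so these are free configuration parameters here.

## Numerical integration

Heun's method (explicit trapezoidal second-order Runge–Kutta) with
dt = 0.02 ms on the coupled smooth ODEs. Conventions, chosen where the
source description is silent:

* threshold crossings are detected on the post-step potential and stamped
  with the end-of-step time (no within-step interpolation; at dt = 0.02 ms
  the induced bias is far below every reported statistic — halving dt
  moves early spike times by < 0.01 ms);
* a spike increments its presynaptic gating at the start of the next step
  (one-step latency, no axonal delay);
* refractory neurons sit at V_reset while their gating and noise continue
  to evolve;
* noise (and the Poisson-filtered inputs) are updated once per step,
  before the two stages, and held constant within the step.

Initial membrane potentials are uniform on (−60, −50) mV (or all −60 mV in
the deterministic protocol); all gating starts at zero.

### Fast path and its verification

The per-step cost is dominated by three weighted gating sums
(W_EI·S_NMDA, W_IE·S_GABA, W_II·S_GABA). Between spikes the gating ODEs are
linear, so the production integrator advances each sum directly with the
same Heun update: a scalar decay factor per step, rank-one column
additions at presynaptic spikes, and a sparse correction over the set of
principal cells whose intermediate gating x exceeds 10⁻¹⁴ (the only
nonlinear coupling). The sums are recomputed densely every 25 000 steps to
keep round-off from accumulating. This path is algebraically identical to
dense evaluation; the test suite verifies spike-for-spike agreement with a
plain dense NumPy implementation over 100 ms (membrane potentials agree to
~10⁻¹³). Spiking networks are chaotic, so *any* two arithmetic orderings
diverge eventually once a neuron crosses threshold within round-off; the
equivalence test therefore starts away from such razor-edge conditions.

## Analysis

All statistics exclude the cue and transient, using 1–8 s.

* **pLFP** — population mean of the τ_GABA-delayed GABA current onto
  principal cells, a standard LFP proxy for point-neuron networks; sampled
  at 200 Hz (delay = 2 samples).
* **Spectra** — Welch PSD: Hamming window, 256-sample segments, 128
  overlap, 1024-point FFT, per-segment mean removal (resolution
  ≈ 0.195 Hz). The primary peak is the argmax over (0, 50] Hz (DC bin
  excluded). The *peak power* relates the 2-Hz band centred on the peak to
  0–50 Hz as a **ratio of mean spectral densities** (so a pure line
  approaches 25, not 1); this is the convention consistent with the
  published values above 1 and with the theta-power definition below. The
  integrated-power fraction (∈ [0, 1]) is available as an option. *Theta
  power* is the 4–12 Hz mean density over the 0–50 Hz mean density.
* **PAV** — rates per principal cell in 400-ms windows sliding every 5 ms;
  angles are doubled before the rate-weighted resultant
  P = (1/N_E) Σ f_i e^{j2θ_i} so the two antipodal bumps superimpose;
  θ_PAV = arg(P)/2 with the 180°-branch chosen by continuity, initialized
  at the branch nearer 90°. Across-trial spread σ_PAV is the circular SD
  on doubled angles, halved. As a drift statistic at small trial counts we
  additionally use the **angular diffusion rate** (mean squared θ_PAV
  displacement per second over 1-s lags, pooled across trials): the SD at
  a single time point is dominated by sampling noise below ~20 trials,
  whereas each trial contributes seven independent random-walk increments
  to the diffusion estimate.
* **Bump profile** — height (peak rate), FWHM (linear interpolation of the
  half-maximum crossings), and sharpness S = ⟨F δ⁴⟩/⟨F δ²⟩² over the
  half-ring centred on the bump (3.0 for a Gaussian, 1.8 for a top-hat;
  invariant to rate rescaling). Because the bump drifts, profiles are
  averaged after re-centring each 400-ms window on its own θ_PAV
  (`bump_profile_aligned`); a fixed-centre variant exists for static
  profiles.
* **Phase locking** — the reference (pLFP) is zero-phase band-passed
  (order-4 Butterworth, 4–12 Hz, forward–backward) and Hilbert-transformed;
  the analytic-signal angle is 0° at the filtered wave's peaks. Spike
  phases are interpolated on the unwrapped phase; the Rayleigh vector
  Φ = (1/N_s) Σ e^{jφ_i} gives locking strength |Φ| and preferred phase
  arg(Φ). For a rhythmic MS input the phase is read directly from the
  cosine argument. Trial averages take the plain mean of |Φ| and the
  circular mean of arg(Φ). Zero-spike cases are flagged undefined rather
  than zero.
* **Attractor presence** (MS-strength sweeps) — the time-median |P| must
  exceed 10× the same statistic after shuffling neuron identities of the
  whole raster. The shuffle preserves spike times and window sampling
  noise; the factor is calibrated to sit inside the measured gap between
  the no-attractor regime (transient clustering keeps the ratio near 4)
  and persistent attractors (ratio ≥ 14), with the crossover at the
  published ±50 pA MS-strength boundary.

## Protocols and study conditions

* default: 8 s, cue on for 0.5 s, full noise; headline statistics average
  10 independent trials (the published versions use 100; the published
  across-trial SDs serve as acceptance tolerances for the reduced count);
* deterministic: 8 s, no noise, no cue, all V_m = −60 mV, reduced drive
  (I_Back^E = 325 pA, I_Back^I = 100 pA, MS off);
* suppression and MS-strength sweeps: 5-s trials, 3 per point;
* τ_NMDA drift sweep: 8-s trials, 6 per point, seed-paired across points;
* rhythmic MS: 8-s trials, 3 per point.

**A note on the deterministic scenario.** With the stated constants the
reduced principal-cell drive (325 pA) lies strictly below the
principal-cell rheobase g_L (V_th − V_L) = 500 pA, and principal cells
receive no recurrent excitation — only GABAergic inhibition, which cannot
depolarize above V_I = −70 mV. The membrane potential is therefore bounded
by V_L + I/g_L = −57 mV < V_th for all time: the protocol provably settles
into a silent fixed point (the simulator reproduces exactly this, E cells
at −57 mV, interneurons at −65 mV). The synchronous-firing rates sometimes
quoted for this scenario (≈5 Hz principal cells, ≈100 Hz interneurons)
cannot arise from these equations with these constants; reproducing them
would require a supra-rheobase drive (e.g. ≥ 500 pA to principal cells).
The protocol is kept at face value and the corresponding checks report the
computed (zero) rates.

## What the simulations do and do not show

All data are generated by the model itself; there is no external data
path. The default protocol reproduces, at 10-trial scale: a pLFP theta
peak near 9 Hz with the published peak-power ratio, matching theta peaks
in population spike counts and single-cell membrane potential, bump-cell
peak rates near 3.6 Hz, PAV-magnitude CV near 0.14, and anti-phase spike
locking to the pLFP (E preferred phase ≈ 230°, strong moduli). Trends —
theta power falling with interneuron suppression width, drift falling with
τ_NMDA, attractor collapse below 50 pA of MS inhibition, entrainment to
fast rhythmic MS input and persistence of the intrinsic rhythm against
slow input — hold at 3–6 trials per point. None of this validates the
biological interpretation (real grid-cell circuits have 2-D toroidal
topology, heterogeneous cells, conduction delays and plasticity, all
absent here); passing tests show only that this implementation realizes
this model's stated dynamics.

## Known limitations

* 1-D ring only; no 2-D torus, no velocity-driven bump motion, no phase
  precession.
* The drift of the bumps is somewhat larger at these settings than the
  published 100-trial figures suggest, which depresses single-cell
  statistics that assume the bump stays near its seeded position (the
  90°-cell's Vm spectrum and locking modulus vary strongly across trials).
* The Poisson-input variant's rates/unitary charges are conventions of
  this package, not published values.
* Per-trial wall time is ~15 s (8 s simulated) on one CPU core; the first
  call pays a one-off compilation cost.
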