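# Methods

`ghasort` re-implements, as tested software, a multi-channel online
spike-sorting pipeline of the kind used in implantable recording ASICs:
nonlinear-energy-operator (NEO) detection with peak alignment, feature
extraction by the generalized Hebbian algorithm (GHA, Sanger's rule) in
either double precision or an emulated 17-bit fixed-point datapath, a
closed-form capacity/latency model of the time-multiplexed hardware, and
a fuzzy-c-means (FCM) evaluation protocol on synthetic recordings with
ground truth.  This note records the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## Detection

For a sampled trace s the NEO is `psi_k = s_k^2 - s_{k-1} s_{k+1}`
(endpoints defined as 0).  A spike is detected at sample k when
`psi_k > gamma`.  Software additions around the bare operator:

* **Threshold.** `gamma` may be given absolutely; by default it is
  `c_mult * mean(psi)` with `c_mult = 8`, the standard automatic NEO
  threshold.  An all-zero trace yields a degenerate threshold of 0 and a
  warning.
* **Peak refinement.** A hit additionally requires `s_k` to equal the
  maximum of the raw trace over `[k - dead_time, k + dead_time]`
  (clipped at the trace bounds).  This makes the "threshold crossing at
  the peak" idealization robust to noise.
* **Alignment and suppression.** The emitted waveform is the m-sample
  window (default m = 64) with the peak at `peak_offset` (default 16 =
  m/4 pre-peak samples, capturing depolarization onset); windows that
  would overrun the trace are discarded.  Hits closer than `dead_time`
  (default m/2 = 32 samples) to the previous accepted hit are
  suppressed, earliest wins.  Coordinates are 0-based, half-open.

Multi-channel recordings are processed channel by channel and merged in
round-robin order (time, then channel index).

## Feature extraction

With p weight vectors `w_j` (p = 2 throughout the reference design) and
an aligned spike x, the service-mode feature vector is `y_j = <w_j, x>`.
Training uses the factored form of Sanger's rule,

    z_0 = x,  z_j = z_{j-1} - y_j w_j,  w_j <- w_j + eta * y_j * z_j,

with y computed from the pre-update weights.  This is algebraically
identical to the textbook update (property-tested to 1e-12 relative)
but needs only a running residual, which is what the hardware's
sum-of-products (SOP) and weight-update (SWU) units implement.  The
weight vectors converge to the leading eigenvectors of the *uncentered*
input correlation matrix (spikes are not mean-subtracted, matching the
hardware); eigenvector sign is arbitrary, so all comparisons use
absolute cosines.

**Segmentation.** The hardware streams m-vectors through L-wide
arithmetic in `b = m/L` segments.  `gha_update_segmented` reproduces the
per-segment arithmetic order; it differs from the unsegmented update
only by floating-point reassociation (<= 1e-10, bit-identical at L = m)
and reports the modeled cycle count.

**Optimizer settings.** The learning rate defaults to `eta = 0.02` with
a `1/(1 + n/tau)` decay, `tau = 2000` presentations, for 30 epochs over
the detected-spike set.  A constant small rate (0.005, 10 epochs) leaves
the second component far from convergence on benchmark-sized spike sets
(a few hundred spikes): the second eigenvalue of the uncentered spike
correlation is one to two orders of magnitude below the first, so the
effective time constant `1/(eta * lambda_2)` exceeds the total number of
presentations.  The decaying schedule converges (`||w_j|| -> 1` within
5%, |cos| >= 0.99 against the batch eigenvectors on Gaussian data) while
keeping the late-training variance small.  Weights initialize i.i.d.
uniform(-0.01, 0.01) from a seed; training is stream-order dependent and
bit-reproducible for a fixed seed and order.

**Normalization.** Spike sets are scaled by their global peak magnitude
into [-1, 1) before training — required by the fixed-point range and
applied identically in float mode so the two backends see the same
inputs.

## Fixed-point emulation

The hardware datapath uses 17-bit fixed point.  The published material
does not give the integer/fraction split, rounding mode, or accumulator
width, so this package emulates a concrete, configurable choice:

* **Q1.16** (1 sign bit, 16 fractional) for samples, weights and
  residuals: multiples of 2^-16 in [-1, 1 - 2^-16].
* **Round to nearest, ties to even**, saturation on overflow (truncation
  and wraparound are available for sensitivity studies).
* A **wider accumulator** with 6 integer guard bits (range ±64, same
  grid) for the m-term inner products and the y-register, preventing
  pathological mid-sum saturation.

Values are held as doubles that are exact grid multiples; products of
two 16-fraction-bit values need 32 mantissa bits, so the double-based
emulation is exact (verified against rational arithmetic).  Per
operation the rounding error is at most half an LSB (2^-17).  Because
the emulation is cleaner than a real netlist (no internal truncation
beyond the modeled points), its accuracy loss versus the float backend
is small — classification results below degrade by well under the
2-point gap a real 17-bit circuit shows.

## Capacity and latency model

One detection core and one GHA core are shared by M channels.  With
sampling rate `rs` (period Ts), clock `rc` (period Tc), per-spike GHA
latency P and minimum inter-peak gap Q samples per channel:

* fetch feasibility: `M <= floor(Ts/Tc)` (one sample per channel per
  sampling period, round robin);
* no-discard condition: with one-spike-per-channel buffers and FCFS
  service, the worst-case backlog of M spikes must drain within Q
  sampling periods, `M * P * Tc <= Q * Ts`;
* hence `Mmax = floor((Q/P) * Ts/Tc)` if `Q < P`, else `floor(Ts/Tc)`.

The latency model is `P = 2*p*b + 8` cycles (`b = m/L`): p·b
segment-cycles for the SOP stage, p·b for the SWU stage, and a fixed
8-cycle overhead.  The coefficients are the unique fit of the family
`a*p*b + c` to the six published (L, P) pairs of the m = 64, p = 2
reference design; extrapolation in p follows the same formula but has no
hardware reference point and is not asserted by any test.

A behavioral queue simulator (`streamsim`) replays detected or
synthetic hit schedules through the one-slot-per-channel buffer, the
pending-channel FIFO and the FCFS server.  An overwrite removes the
stale FIFO entry and re-enqueues the channel at the tail (whether real
hardware re-enqueues or keeps the original position is unspecified; the
discard count is identical under the one-slot assumption, only the log
order differs).  Hits are timed at the fetch cycle of the last sample of
the aligned window; this shifts all arrivals per channel by a constant
and cannot change discard counts.  Property tests confirm the
closed-form bound: zero discards at Mmax and at least one at Mmax + 1
under worst-case gap-Q traffic.  `busy_fraction` provides the idle/active
cycle accounting that motivates clock gating in hardware; gate-level
behavior is out of scope.

## Synthetic recordings

The generator emulates the statistical structure of the standard
simulated extracellular benchmarks: 2–3 neurons per channel firing fixed
unit-peak templates, Poisson event times (default 8 Hz per neuron)
thinned to a refractory gap (default 96 samples = 4 ms at 24 kHz),
superposition of overlapping spikes allowed, one neuron population per
channel, independent channels.

* **Templates** are smooth tri/tetra-phasic pulses: a sharp positive
  depolarization lobe (Gaussian half-widths 1.0–2.5 samples, i.e. rise
  times ~40–100 µs, independently drawn left/right for asymmetry), a
  slower negative after-wave, an optional leading dip and late rebound,
  cosine-tapered ends.  The sharp lobe is required to be the global
  extremum; pairs with zero-lag correlation >= 0.8 are redrawn by
  default (0.95 is the hard ceiling at which two shapes are effectively
  one unit).
* **Noise** is an equal-variance mixture (configurable) of (a)
  "far-field" activity — a dense superposition of low-amplitude spike
  shapes (2000 events/s at relative amplitudes 0.02–0.15), giving
  colored, spike-like noise — and (b) Gaussian noise band-limited to
  300–5000 Hz, the standard front-end passband.  The summed noise is
  rescaled so its empirical SD hits the SNR target exactly.
* **SNR definition (prominent).**  `snr_db = 20*log10(template RMS /
  noise SD)`, template RMS taken over the m-sample support and averaged
  over the population.  With unit-peak templates, 6/8/10 dB then
  corresponds to a noise SD of ~0.09–0.15 of the peak — the regime of
  the spike-superposition simulators this generator emulates.  A
  peak-referenced definition would map the same decibels to ~3.5× more
  noise and describes a different, much harder problem.

What the generator does **not** model: bursting and amplitude
adaptation, electrode drift, cross-channel leakage of single units, and
biophysical waveform variability.  Passing tests therefore demonstrate
correctness of the algorithms and faithfulness to the modeled
conditions, not performance on real tissue recordings.

## Evaluation protocol

For each SNR in {6, 8, 10} dB and each seed: generate a recording,
detect, pair detections with ground-truth peaks within ±3 samples
(greedy in time, each true event used once; unmatched detections are
counted as false alarms and excluded from scoring, misses are reported
separately), train the GHA on all detections in stream order, project,
cluster the matched feature vectors with FCM (k = number of neurons,
fuzzifier 2.0, tolerance 1e-6, max 300 iterations, 5 seeded restarts
keeping the best objective), and score the classification success rate
(CSR): the percentage of matched spikes assigned to the right neuron
under the best injective cluster-to-neuron assignment (exhaustive for
k <= 8).  The FCM objective is checked non-increasing on every run.

Problem sizes: 10 s single-channel recordings at 24,000 samples/s, two
or three neurons at 8 Hz each (~150–250 spikes per run), 10 seeds per
SNR for headline numbers and 3–5 seeds in unit tests.  With the 17-bit
fixed-point backend the minimum mean CSR across SNR levels for two
neurons is ~99% (floor of interest: 97%), and fixed-point CSR tracks
float CSR to well within 3 points on matched seeds.

## Numerical and degenerate-input choices

Ties in the peak local-max test are resolved by the suppression rule
(earliest accepted); FCM distances are floored at 1e-300 before the
membership power to keep coincident points finite, and a membership row
for a point exactly on a center is the standard limit (all weight on
that center via the dominant inverse distance); duplicate FCM initial
centers are redrawn (bounded retries); `Mmax` uses exact rational
arithmetic before the floor so table entries cannot be off by one from
binary rounding; zero-rate recordings are valid (pure noise, empty
ground truth); an infeasible firing rate (more than one event per
refractory window) is rejected at configuration time.
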