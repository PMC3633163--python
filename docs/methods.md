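# Methods

## Model

The network is a two-layer feedforward circuit on a ring. `N` input (LGN)
neurons and `N` output (V1) neurons share a uniform grid of receptive-field
centers on `[-L, L]`; the grid is closed (both endpoints stored) and all
distances are evaluated with the periodic metric `d = |a-b|` if `|a-b| < L`,
else `2L - |a-b|`, so the stimulus can be displaced arbitrarily without
boundary effects. The periodic metric is applied to the weight kernel as
well as the input kernel; with the default widths the numerical difference
from an open-boundary weight kernel is below 1e-11, and using it throughout
makes the network exactly translation invariant on the ring. Because the
closed grid stores the seam point twice, exact invariance of summed rates
holds for displacements that are multiples of the grid spacing; generic
displacements are invariant to ~1e-4 relative, which is the one place the
discretisation is visible.

Input neurons fire Poisson trains with rates
`R_j = A exp(-d(x_j, x_f)^2 / sigma1^2)`; weights are
`W_ij = exp(-d(x_j, x_i)^2 / sigma2^2)`. Output neurons are leaky
integrators with exact exponential leak toward `V0` and delta-pulse input:
each input spike advances every target by
`dV_i = (g W_ij S_j / tau_m)(V_E - V_i)` using the pre-jump potential, so
repeated pulses approach but never exceed the excitatory reversal. The
`1/tau_m` in the jump follows from integrating the membrane equation across
the delta; the delivered strength is the pre-depletion `S_j` (the
transmitter released by a spike is what drives the postsynaptic response).
There is no refractory period, synaptic delay, inhibition, or noise beyond
the Poisson input.

Depression follows the depletion/recovery scheme: `S -> f S` at each
presynaptic spike and exponential recovery toward 1 with time constant
`tau_S` between spikes. Both pieces have closed forms, and the simulator
uses them exactly (recovery is never Euler-stepped), so the per-synapse
trajectory equals the event-driven closed-form evolution of the recorded
spike train to machine precision; the test suite asserts this synapse by
synapse.

Three characterisations of the adapted strength under drive at rate `R` are
exposed: the classical high-rate approximation `1/(f + (1-f) R tau_S)`, the
exact fixed point under periodic spiking
`(1 - e^(-1/(R tau_S))) / (1 - f e^(-1/(R tau_S)))`, and the exact
stationary time average under Poisson drive `1/(1 + (1-f) R tau_S)` (by
PASTA, Poisson spikes sample the time average, which closes the stationarity
equation). At the default operating point (`R = 50 /s`, `f = 0.75`,
`tau_S = 200 ms`) these are 0.3077, 0.2961 and 0.2857: the high-rate formula
overestimates the true Poisson mean by ~7%, which matters when comparing
simulated averages against it.

## Integration scheme

Time is discretised at `dt = 0.1 ms` (configurable; the Bernoulli step
probability `R dt` stays below 0.005 at default rates). One step performs:
rate update from the protocol, input-spike draw (each neuron independently
with probability `R_j dt`, at most one spike per neuron per step), leak
decay over the step, sequential pulse delivery with pre-depletion
strengths, depletion, recovery, and threshold/reset detection at the step
end. Input spikes are stamped at the start of their step, output spikes at
its end; initial conditions are `V = V0`, `S = 1` ("start of fixation").

The implementation evaluates these semantics event-driven rather than
neuron-by-neuron per step: per-neuron Bernoulli sequences are generated by
exact geometric skips held in a time-bucket ring (redrawn whenever the rate
field changes), synaptic recovery is applied lazily with the exact
exponential, and the common leak decay is applied lazily as well — between
deliveries every potential only decays toward `V0 < V_th`, so threshold
crossings can only occur in steps containing a delivery. This is
distribution-identical to the naive loop and roughly an order of magnitude
faster. Runs are bit-reproducible from their seed; enabling state recording
never perturbs the spike sequence because recording consumes no random
numbers. One user seed fans out into independent streams (saccade-train
generation vs. input spiking vs. sweep coordinates) via `SeedSequence`.

## Protocols

Brightness is piecewise constant: stationary, or a flash cycle `T_on`
on / `T_off` off starting with an on-phase at t = 0 (`T_off = 0`
degenerates to stationary). Saccade trains are single events, periodic
trains at frequency `F`, or homogeneous Poisson trains at rate `F`
(truncated, not conditioned — overlap is avoided in practice by using low
rates, not by imposing refractoriness). Each event's direction is drawn
uniformly from {+1, -1} by default (configurable: fixed or alternating; the
alternating policy makes the dot return to its previous position, i.e. a
return-to-center schedule). The fixation point random-walks on the ring
with wrap. Saccade trains run through off-phases as well; events during an
off-phase displace the dot but evoke nothing. In velocity mode the dot
moves linearly over a fixed 15 ms duration, reflecting the approximately
constant microsaccade duration in humans, so velocity and magnitude are
locked by `Delta_M = v * 15 ms`.

## Response measures

The response measure is the population spike count of a layer in a moving
50 ms window advanced in 1 ms steps (window starts are reported; with
50 ms steps the windows tile the run and counts sum to the total spike
count). Derived measures: the evoked peak is the maximum count in the
200 ms after an event (long enough to bracket the peak, short enough not
to capture the next event at 4 Hz); "complete fading" is the first window
after the evoked peak whose count is zero, reported relative to the event;
average activity discards the first 500 ms (the fixation-onset burst); the
sensitivity of activity to saccade frequency is the central-difference
slope over the frequency grid; peaks are raw maxima with no baseline
subtraction. The network-averaged synaptic strength is the unweighted mean
over all `N` synapses, with a rate-weighted variant available where the
stimulated subpopulation is of interest.

Sweep experiments replicate each grid point over independent seeds and
report per-replicate samples with dispersion: frequency sweeps (activity
and sensitivity vs. `F`), magnitude and velocity sweeps (evoked peak vs.
`Delta_M` or `v`, from the adapted state after a 2 s warm-up), the
flash-interval analysis (evoked peak and mean strength vs. the lag between
flash onset and saccade, against a stationary baseline), the flash-onset
peak vs. `T_off`, and the `(T_on, T_off)` phase diagram of evoked peaks and
their ratio to the stationary reference, using only saccades whose
measurement window lies inside an on-phase.

## Default problem sizes

Fading and reset experiments use 4.5 s runs; frequency sweeps 30 s per run,
16 frequencies, 20 seeds; magnitude/velocity sweeps 3 s per run, 20 seeds;
flashing-vs-stationary comparisons 100 s per condition and seed. These
lengths give replicate standard errors a few percent of the measured means
and are the sizes at which all reported numbers were computed.

## Behaviour at the reference operating point, and limitations

With the reference parameters the adapted-state mean potential of the
best-driven output neurons sits ~1.4 mV below threshold (mean-field value
-56.4 mV). Because all output neurons share the same input spike trains,
potential fluctuations (sigma ~ 0.5 mV) are strongly correlated across the
population, and the adapted state emits rare synchronized bursts (~2 per
second of a few tens of spikes) rather than being strictly silent. The
qualitative ordering is robust — fresh synapses drive the layer well above
threshold (~-41 mV), adapted synapses below it — but statements of absolute
silence hold only in the time between bursts. Delivering the post-depletion
or midpoint strength instead would lower the adapted state to -59/-58 mV
and silence it completely, at the cost of shortening the post-saccade
response to ~50-90 ms; the pre-depletion convention was kept as the
physically standard choice.

Two further consequences of this operating point are worth knowing. At the
strong-drive configuration (g=0.2, A=100) the adapted state is itself
suprathreshold, so magnitude/velocity sweeps measure peaks riding on a
sustained baseline (their saturation behaviour is unaffected). And the
average-activity-vs-frequency curve at `Delta_M = 2.0` is concave from the
lowest rates — isolated saccades of that size always land on
well-recovered synapses, so activity grows ~linearly with `F` before
saturating; a convex rise with a pronounced knee appears only for smaller
saccades (`Delta_M ~ 1`), whose responses require the cumulative
displacement of several events.

The synthetic protocols emulate fixation with idealised microsaccades
only: no drift or tremor trajectories, one-dimensional retinotopy, a
single stimulus dot, no inhibition or corticocortical coupling, and no
retinal adaptation. Passing tests therefore demonstrate the internal
consistency of the depression mechanism, not a fit to physiological
recordings.

## Numerical notes

- Halving `dt` to 0.05 ms changes evoked peaks by well under 10%.
- The periodic-metric tie at exactly `|a-b| = L` is immaterial: both
  branches give the same distance `L`.
- `evolve_train` and `fit_depression_params` operate on pre-spike
  strengths; the fit solves the one-step recurrence by bounded
  least squares and recovers `(f, tau_S)` to (0.05, 20 ms) from ~100 s of
  50 /s data.
- Spike-buffer capacities are estimated from the expected input rate and
  doubled on overflow with a deterministic rerun, so results never depend
  on the initial allocation.
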