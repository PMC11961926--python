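# Methods

## The model

`stresswm` simulates a small model of rodent prefrontal working memory:
four *selective groups*, each a population of excitatory (E) and inhibitory
(I) integrate-and-fire neurons, wired so that excitatory coupling is
stronger within a group than between groups while inhibition projects
more strongly *across* groups. A short-term recall task (fixation →
memory stimulus → delay → brief cue) drives all excitatory neurons with
Poisson input; a group that keeps firing through the delay has "remembered"
the stimulus, and the number of such groups is the network's working-memory
capacity (at most 4, the number of structural groups).

### Membrane and compartments

Each neuron is a leaky integrate-and-fire unit,

    C_m dV/dt = -g_L (V - V_L) + I_drive,

with a hard threshold `V_th`, reset `V_reset` and absolute refractory
period `t_ref`. The subthreshold equation does not fix the spiking
mechanism, so threshold, reset and refractory values are configuration
parameters with conventional cortical defaults (−50 mV, −60 mV, 2 ms for E;
−50 mV, −58 mV, 1 ms for I).

Neurons are two-compartment: the receptor currents are also combined into a
dendritic compartment whose output passes a saturating transfer

    I_soma,dend = c1 · tanh((I_exc + c3·I_inh + c4) / (c5 · exp(−I_inh/c6))) + c2,

bounded in `[c2−|c1|, c2+|c1|]`, before adding to the somatic drive. The
bracket placement in this family of transfer functions varies between
formulations; we use the two-compartment convention above (inhibition
shifts the transfer via `c3` and rescales its input gain via `c6`) and
expose the constants as configuration.

### Synapses

Receptor gating fractions `s_AMPA`, `s_NMDA`, `s_GABA` per presynaptic
neuron decay exponentially (τ = 2, 100, 5 ms) and jump on presynaptic
spikes. Short-term plasticity modulates the glutamatergic jumps through
utilization `u` (facilitation, baseline `U = 0.15`, τ_u = 1500 ms) and
resources `x` (depression, τ_x = 2 ms):

    on an excitatory spike:  u ← u + U(1−u)
                             s_AMPA ← s_AMPA + x·u·γ_AMPA
                             s_NMDA ← s_NMDA + x·u·(1−s_NMDA)·γ_NMDA
                             x ← x − u·x
    on an inhibitory spike:  s_GABA ← s_GABA + γ_I

The discrete ordering (u-jump first, post-jump `u` in the gating and
resource updates) is a convention we fix and test; the continuous-time
equations treat the jumps as simultaneous. The `(1−s)` factor keeps
`s_NMDA` ≤ 1 by construction whenever `γ_NMDA ≤ 1`; the property suite
verifies the bound over random spike trains. Between spikes all five
variables follow their exact exponential relaxations (not Euler), which is
equivalent in the small-step limit and exact for the no-spike case.

Postsynaptic currents use a common reversal potential equal to the resting
potential — a deliberate simplification of this model family in which every
receptor shares the leak driving force:

    I_NMDA = μ^NMDA g_NMDA (V−V_L) / (1 + γ_mg e^{−β_mg V}) Σ_j w_j s_j u_j
    I_AMPA,rec = μ^AMPA g_AMPA (V−V_L) Σ_j w_j s_j u_j
    I_AMPA,ext = g_ext (V−V_L) Σ_j s_j^ext
    I_GABA = μ^GABA g_GABA (V−V_L) Σ_j s_j

with the Brunel–Wang magnesium-block constants γ_mg = 0.2801, β_mg =
0.062 mV⁻¹. Two consequences are worth stating plainly. First, **all
synaptic currents vanish at rest** (V = V_L), so a constant background
current `I_bg` (120 pA to E, 70 pA to I by default) holds neurons a few
millivolts above rest; without it no input could move the network. Second,
all currents share a sign, so the engine feeds GABA into the total current
with a negative sign (excitation depolarizes, inhibition hyperpolarizes) —
a single signed-sum adapter in front of the membrane equation.

The GABA current in this model carries no per-synapse weight factor, only
the summed gating; `gaba_current` therefore defaults to unit weights, but
the engine passes the connection-weight row so that rescaling I→E / I→I
blocks — an operation the model explicitly supports — has an effect. With
all inhibitory weights near 1 the two forms coincide.

The total somatic drive is

    I_total = β_NMDA·I_NMDA + I_AMPA,ext + β_AMPA·I_AMPA,rec
              − I_GABA + I_soma,dend + I_bg.

### Effective synapse counts (spines)

Receptor multipliers μ derive from mean dendritic-spine counts: for
excitatory neurons `EXN·(1−fac)` spines split between NMDA and AMPA pools
via the excitatory input fraction (halved between the two receptor types)
and a GABA pool via the inhibitory input fraction `EXN_IN`; interneuron
multipliers use the same halved form for bipolar and multipolar counts
(deliberately including their GABA entry, so all three interneuron
multipliers coincide). Chronic stress enters here:
`fac = 0.16` multiplies every EXN-derived μ by exactly 0.84. The shipped
spine-count defaults (EXN = 100, BP = 40, MP = 60, fractions 0.20 / 0.35 /
0.25) are stand-ins for anatomical tables that are not reproduced here;
they are configuration, not constants.

### Stress conditions

- **Acute** (swim preset): β_NMDA = 425/197 ≈ 2.157 and β_AMPA =
  98.8/58.6 ≈ 1.686, the ratios of stressed to control EPSC amplitudes in
  prefrontal pyramidal neurons. Purely dynamical; the network structure is
  untouched. Restraint/platform presets accept their own EPSC pairs
  (`acute_scaling_from_epsc`) and default to the swim values as documented
  placeholders.
- **Chronic**: `fac = 0.16` spine loss, optionally a rescaled GABA gating
  increment (γ_I) and within-group connection-block rescaling.
- **Ketamine-style**: chronic base plus an NMDA fractional-strength
  increase (default β_NMDA = 1.5), exposed as a preset.

Control is the identity by construction and is validated as such.

## Numerical scheme

Fixed-step forward Euler for the membrane (default dt = 0.05 ms; the
shipped example configs use 0.1 ms, which reproduces the same attractor
behavior at desk scale), exact exponential updates for gating/STP, a
one-step synaptic delay, and per-step Poisson draws for external input
(distributionally identical to binning pre-generated spike trains; the
protocol module also generates explicit spike-time lists for inspection).
Membrane blow-up raises an error naming the step and neurons. Spikes are
recorded exactly; population-mean receptor currents at a 1 ms stride
(recording is passive and does not perturb the dynamics).

## Network defaults and how they were chosen

The connection probabilities, weights and conductances that the in-vivo
literature would supply are not reproducible here, so the shipped defaults
were calibrated once, at desk scale, to put the control network in the
competitive working-memory regime the model describes:

- within-group E–E coupling stronger than between-group (w 1.0 vs 0.25 at
  p 0.35 vs 0.10);
- cross-group I→E denser than within-group (p 0.45 vs 0.25 at w 0.5 vs
  0.8), putting the net cross-group inhibitory drive slightly above the
  within-group one — the competition knob: raising it sharpens
  winner-take-all until capacity pins at one group, lowering it lets
  every group coexist;
- NMDA-dominated recurrence (g_NMDA = 0.2 nS vs g_AMPA = 0.03 nS per unit
  μ) so that delay activity is carried by the slow, saturating receptor;
- a smaller AMPA conductance onto interneurons (0.008 nS) than onto
  pyramidal cells, so that fast glutamatergic strength supports selective
  E–E maintenance more than it drives feedback inhibition;
- parameter heterogeneity with cv = 0.25 (truncated Gaussians), which
  staggers the groups' intrinsic excitability and smooths the capacity
  transition — with nearly identical groups the network snaps between 0
  and 4.

Under these defaults the control network typically retains one or two of
the four groups; pushing glutamatergic strength or within-group E–E
coupling up recruits more groups, and pushing GABA strength up silences
them. These qualitative directions — not any particular capacity value —
are what the trend suite asserts.

## Measurement layer

**Capacity.** A group counts as "maintaining" if ≥ 50% of its excitatory
neurons fire ≥ 10 Hz during the last 200 ms of the delay. The published
definition is conceptual (groups that keep discharging); this
operationalization is ours, all three thresholds are configuration, and
every reported capacity records the criterion used.

**Intrinsic timescale.** Spike trains are binned at 50 ms; the Pearson
correlation between count-matrix columns lagged by Δ is computed across
units and averaged over all column pairs at that lag (units that never
fire are dropped — they carry no signal). The decay
`ρ(Δ) = a(exp(−Δ/τ) + b)` is fitted by damped (Levenberg–Marquardt-style)
nonlinear least squares with a = 1, b = 0, τ = 2 bins initialization and
τ > 0 bounds. A per-unit autocorrelation pooling scheme is available by
flag (`scheme="per_unit"`); it is noticeably biased low when τ approaches
the analysis span, which is why the cross-unit scheme is the default.
Fits are flagged non-converged — never clamped — when the amplitude
collapses, the fitted curve is flat across the observed lags, or τ
extrapolates beyond five times the longest lag. Epoch-anchored timescales
start the count matrix at the memory or cue onset, separately for E and I
populations.

**Sweeps.** Grids over γ_AMPA, γ_NMDA, γ_I, β factors, connection-block
scales and `fac` rerun the full protocol per point × replicate with a
shared network realization (isolating the swept factor) and per-replicate
seeds; rows record capacity, epoch timescales, mean receptor currents, and
errors (failures do not stop the sweep; tables are resumable). Pearson r
and p between an axis and an outcome come from `sweep_correlation`.

## Synthetic fixtures: what they do and do not show

`make_capacity_raster` produces Poisson rasters in which a chosen subset of
groups sustains delay firing — ground truth for the capacity counter.
`make_ar1_counts` produces doubly-stochastic Poisson count matrices whose
latent log-rate is AR(1) with autocorrelation `exp(−Δ/τ₀)` (log-rate keeps
rates positive; default 50 units at 20 Hz with σ_log = 0.5). These
fixtures validate the *estimators*: that the capacity counter counts and
the timescale fitter recovers a known τ. They contain none of the
structure of real (or simulated) network activity — no oscillations, no
cross-neuron correlations, no rate drift — so passing them says nothing
about whether the network itself maintains memories; that is what the
end-to-end competition and trend tests are for.

## Problem sizes

Default network: 4 groups × (80 E + 20 I) = 400 neurons — a deliberate
desk-scale stand-in (the group counts of the modeled cortical circuit are
not published). Default protocol: 1000/400/1000/5 ms epochs plus 600 ms
post-cue (long enough to anchor the cue-phase timescale analysis), ~3 s
simulated at dt = 0.05–0.1 ms. The trend suite keeps the default network
size and shrinks the *grids* instead (3 values per axis, 3 seeds each):
the attractor regime the defaults realize does not survive naive
down-sizing, because recurrent drive scales with group size. The
competition check runs the full default network over 8–10 seeds.

## Known limitations

- All reversal potentials collapse onto the resting potential (the model's
  simplification); inhibition below rest would be excitatory, so the
  dynamics are only meaningful at or above `V_L`, and background current
  keeps them there.
- The common `(V−V_L)` driving force makes recurrent excitation
  regenerative (conductance positive feedback); stability relies on NMDA
  saturation, STP depression and feedback inhibition, which constrains how
  far the conductance defaults can be pushed before runaway.
- Group-level behavior is sensitive to the competition parameters; the
  shipped defaults are one working point, not a fit to data.
- The homogeneous network mode shares the engine and is exercised by the
  unit suite, but the headline trend checks run on the heterogeneous
  default.
- `fac` rescales effective synapse counts only; it does not remove
  individual synapses, so chronic stress does not change the realized
  connectivity graph.
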