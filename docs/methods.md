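# Methods

`adloop` simulates a closed-loop, multiscale model of Alzheimer's disease
progression: a heterodimer model of amyloid-beta (Aβ) and
hyperphosphorylated-tau (hp-tau) production, conversion and spread on a
structural connectome, coupled in both directions to a brain-network model
(BNM) of delayed, noisy Jansen–Rit (JR) neural masses. Proteinopathy damages
neural parameters; the resulting changes in regional firing rate feed back
onto Aβ production and toxic-tau transport. This note documents the model,
its numerical treatment, and the design choices made where the problem was
genuinely open.

## Neural dynamics

Each region is a JR column: pyramidal cells, excitatory and inhibitory
interneurons, with postsynaptic potentials `y0, y1, y2` (mV) and their
derivatives `y3, y4, y5`. Voltage is converted to firing rate by the
sigmoid `S(v) = 2 e0 / (1 + exp(r (v0 − v)))`, with `S(v0) = e0 =
0.0025 ms⁻¹`. Region *i* receives
`I_i(t) = η_i(t) + g Σ_j w_ji S[y1_j(t−d_ji) − y2_j(t−d_ji)]`, where
`η_i ~ N(p, σ)` is an intrinsic noisy input rate (`p = 0.1085 ms⁻¹`,
`σ = 0.022 ms⁻¹`), `g = 25` the global coupling on max-normalized weights,
and `d_ji = L_ji / s` the conduction delay from tract length `L_ji` (mm)
and speed `s = 20 m/s`. A single-node simulation drops the coupling term;
the noise mean `p` stands in for the missing afferences.

Numerics (the integration scheme is a package choice):

* **Stochastic Heun at dt = 1 ms** (configurable). Noise is sampled once
  per step per region and held through both Heun stages — it is an input
  firing rate, not a Wiener increment, so no `√dt` scaling is applied.
* **Delays** are rounded to the nearest integer step and served from a
  ring buffer; history before t = 0 returns the initial state.
* **Initial state: the depolarized equilibrium branch.** At the default
  drive the JR node is bistable: an alpha-band (≈10 Hz) limit cycle
  coexists with a stable low-activity fixed point. The basin of the alpha
  cycle contains the upper (depolarized) equilibrium, which we locate by
  root-finding on the scalar fixed-point condition and use as the initial
  state of every region. Initializing at zero lands in the low basin and
  yields a 2–3 Hz noise-driven spectrum instead of the alpha rhythm that
  characterizes the healthy baseline.
* A run aborts with a diagnostic if any state exceeds 10⁶ mV.

The accuracy of the dt = 1 ms Heun scheme is guarded by a refinement test
(noiseless trajectory error < 5% against dt = 0.1 ms).

## Proteinopathy

Four pools per region: healthy/toxic Aβ and tau (M). Healthy protein is
produced (`prod`, M/yr) and cleared (`clear`, 1/yr); conversion to the
toxic isoform is autocatalytic (`trans`, 1/(M·yr)); toxic pools clear more
slowly and diffuse along tracts. A synergy term (`syn`, 1/(M²·yr)) converts
healthy tau faster where toxic Aβ is present. The hyperactivity factor
`q_ha` multiplies Aβ production and the toxic-tau diffusion term, biasing
spread toward hyperactive regions. With default constants the healthy
equilibrium is `Aβ = T = prod/clear = 1 M`, toxic pools zero; all disease
dynamics are attributable to the seeded toxic deposits (Aβ̃ = 0.0125 M at
six bilateral cortical pairs, T̃ = 0.0025 M at the entorhinal-homolog
pair).

**Diffusion operator.** Transport uses the graph Laplacian of the
length-scaled adjacency `a_ij = w_ij / L_ij` with `L_ij` in cm, multiplied
by the diffusion constant `ρ = 50 cm/yr`. Dividing by tract length makes
the units coherent (`ρ·a` is 1/yr) and gives edge transport rates of order
0.1–5 /yr on realistic networks, so toxic tau crosses the connectome over
years — the staged, wavefront-like progression the model is built to
study. Applying ρ directly to the dimensionless max-normalized weights
would produce rates of order 50/yr, homogenizing concentrations within
weeks and erasing any staging.

**Integration.** The year-scale ODEs (proteins, damage, parameters,
weights) are advanced with adaptive RK45 (`scipy.solve_ivp`,
rtol 1e-8) across each 0.25-year exchange interval. The 0.25-year cadence
is the protein/neural exchange and recording step; the inner steps are
adaptive because diffusion on small or strongly weighted networks can be
fast enough to destabilize a fixed quarter-year step. Negative undershoots
are clipped to zero with a warning.

## Damage and parameter transfer

Toxic load accumulates into bounded damage variables,
`dq/dt = c·(toxic)·(1 − q)`, separately for Aβ̃ and T̃. Damage relaxes the
JR parameters exponentially toward disease limits:

| channel | effect | limit |
| --- | --- | --- |
| Aβ̃ → `He` | excitatory gain rises (glutamate reuptake disruption) | 3.65 mV |
| Aβ̃, T̃ → `Cip` | inhibitory contacts fall (GABAergic loss, spine loss) | 13.25 |
| T̃ → `Cep` | excitatory contacts fall (spine loss) | 28 |
| T̃ (both ends) → `w_ij` | tract weights fall | `w⁰(1 − 0.3)` |

The two inhibitory channels can be disabled independently to isolate the
Aβ and tau contributions.

Hyperactivity damage follows
`dq_ha/dt = c_ha (Δha − q_ha)(q_max − q_ha) q_ha` with `Δha = ha/ha⁰`, the
regional firing rate relative to a proteinopathy-free baseline.
`q_ha = 1` is neutral; sustained ratios above `q_max = 2` saturate at 2.
`q_ha` starts at 1 (the equation is multiplicative in `q_ha`, so 0 would
be absorbing).

## The closed-loop schedule

1. One baseline BNM evaluation (default parameters, pristine weights)
   fixes `ha⁰` per region; it aborts if any baseline rate underflows.
2. Each simulated year: four 0.25-yr exchange steps of the joint
   protein/damage/parameter/weight system, then one BNM evaluation (10 s,
   first 2 s discarded) with the current `He`, `Cip`, `Cep`, `w` to
   measure firing rates, spectra and alpha-band phase locking.
3. `Δha` is held piecewise-constant between BNM evaluations (it is only
   observable when the BNM runs); the `q_ha` ODE is integrated jointly
   with the other year-scale equations using the held value.
4. Each evaluation draws its noise from a seed derived deterministically
   from `(rng_seed, year)`, so runs are reproducible while evaluations
   stay independent.

Firing rate `ha_i` is the time-average of `S[y1_i − y2_i]` over the
retained 8 s window.

## Metrics

* Spectra: Welch periodograms, 2 s Hann segments (0.5 Hz resolution), 50%
  overlap; peak frequency searched in 2–40 Hz so that noisy fixed-point
  regimes report low in-band peaks rather than DC artifacts; relative band
  powers are fractions of the 2–40 Hz total.
* Phase-locking value: order-4 Butterworth band-pass applied forward and
  backward (zero phase), analytic-signal phase, 10% of samples trimmed at
  each edge, `PLV = |⟨exp(iΔφ)⟩|`.
* Braak sequences: mean toxic tau per stage group (I–V) at each recorded
  step, ranked in descending concentration with ties broken in canonical
  stage order; steps where no stage mean exceeds 10⁻⁴ M are ignored; the
  modal ranking over time is the dominant sequence. (The ranking-based
  reading of staging is an interpretation; the floor and tie-break are
  explicit constants.)
* Time-to-peak: 3-point moving-average smoothing, argmax year, flagged
  when the peak sits on the series boundary.

## Synthetic connectomes

The generator produces bilateral networks of `2·n_pairs` regions whose
two hemispheric blocks are exact mirrors. `n_pairs = 20` reuses the
bundled cingulum-bundle annotation (40 regions, Braak stages I–V, one
tau-seed pair, six Aβ-seed pairs); other sizes use a generic schema with
the same structure. The annotation marks the inferior parietal pair as
Braak stage IV in both hemispheres (the one-sided marking in the source
staging table is treated as a typo). Anterior/posterior classes are
derived from the anatomical group: frontal + anterior cingulate are
anterior, parietal + posterior cingulate posterior, the rest excluded.
With this rule the bundled annotation has only five posterior pairs, so
posterior-restricted Aβ seeding (six pairs) is only possible on generic
annotations with at least 17 pairs — restricted-seeding experiments use
those.

Topologies:

* `modular` (default): mirrored intra-hemispheric graphs at 25% density
  with lognormal (heavy-tailed) weights, a spanning path guaranteeing
  connectivity, sparse homotopic bridges, and one dominant homotopic
  tract at the subcortical pair. The dominant tract anchors the
  max-normalization so that every cortical region's total incoming
  coupling stays weak; this is a deliberate calibration: with the
  coupling equation above, a JR region holds its alpha rhythm at baseline
  only when its summed afference (times g = 25) is a small perturbation,
  and the baseline network must be in the alpha regime for the disease
  course to start from a healthy state. Tract lengths are uniform on
  15–150 mm.
* `distance`: mirrored 3-D embeddings with exponentially
  distance-decaying weights.
* `path`: a Hamiltonian path per hemisphere visiting regions in Braak
  order plus one interhemispheric link at the stage-I homologs; used for
  wavefront checks, where arrival times must be ordered by graph distance
  from the seed.

What the generator does *not* emulate: empirical streamline-count
distributions, geometric consistency between weights and lengths in the
modular topology, inter-subject variability, and any asymmetry between
hemispheres. Passing tests on these networks show that the model's
mechanisms behave as designed — not that the empirical connectome would
produce the same quantitative timings or Braak dominance percentages.

## Problem sizes and runtimes

The default disease simulation is 40 regions × 40 years with one 10 s
BNM evaluation per year at dt = 1 ms (about 41 evaluations), which runs
in roughly a minute on a laptop-class CPU. Unit tests use smaller
networks (10–12 regions) and shorter horizons; the single-node
experiments use the 20 s / 12 s-discard protocol.

## Known limitations

* The closed loop's qualitative course (rise and decay of firing rate,
  alpha power and alpha PLV; frequency slowing) is demonstrated on
  synthetic connectomes; empirical-connectome results (specific peak-year
  windows, Braak dominance percentages) are out of scope.
* Neuroinflammation and glial clearance are not modeled; toxic tau shows
  no late decay.
* The weak-coupling operating point means structural-weight damage has
  little effect on the simulated activity — consistent with the model's
  attribution of activity changes to local parameters, but it makes the
  `sc_dam` channel nearly inert at the network level.
* Baseline bistability makes the network state sensitive to
  initialization; the equilibrium-branch initialization documented above
  is required for a healthy alpha baseline.
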