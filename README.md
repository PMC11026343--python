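# adloop

Closed-loop multiscale simulation of Alzheimer's disease (AD) progression.

`adloop` couples two models that live on a shared structural connectome:

* a **heterodimer proteinopathy model** — healthy and toxic amyloid-β
  (Aβ, Aβ̃) and tau (T, T̃) are produced, cleared, converted
  (prion-like: `trans·c·c̃`) and diffuse along white-matter tracts via a
  graph Laplacian, over a timescale of years;
* a **Jansen–Rit brain-network model** — one neural mass per region with
  conduction delays `d_ji = L_ji/s` and noisy input
  `η ~ N(p, σ)`, producing alpha-band (8–12 Hz) oscillations, simulated
  over seconds.

The loop closes in both directions. Toxic load accumulates into bounded
damage variables `q = 1 − e^{−c∫c̃ dt}`-style dynamics that push the
neural parameters toward disease limits (excitatory gain `He` ↑,
inhibitory contacts `Cip` ↓, excitatory contacts `Cep` ↓, tract weights
`w_ij` ↓). In return, the regional firing rate relative to a healthy
baseline (`Δha = ha/ha⁰`) drives a hyperactivity damage factor that
scales Aβ production and biases toxic-tau transport toward hyperactive
regions. The package reproduces the canonical electrophysiological
signatures of the AD continuum on synthetic connectomes — rise and decay
of firing rate, relative alpha power and alpha-band phase locking, alpha
frequency slowing — and the Braak-like staged spread of tau from the
entorhinal seed.

Intended users: computational neuroscientists studying multiscale disease
mechanisms, and modellers who need a reproducible, fully synthetic test
bed for proteinopathy–activity feedback hypotheses.

See `docs/methods.md` for the model equations' treatment, numerical
choices and limitations.

## Worked example

A single default Jansen–Rit node, simulated for 20 s with the first 12 s
discarded:

```python
import adloop as al
import adloop.metrics as m

rec = al.integrate_network(None, duration_ms=20_000, discard_ms=12_000,
                           rng_seed=0)
print("peak:", m.spectral_peak(rec, 0), "Hz")
print("rate:", round(al.regional_firing_rate(rec)[0], 5), "ms^-1")
print("relative alpha:", round(m.relative_band_power(rec, 0, m.ALPHA), 3))
```

prints

```
peak: 10.0 Hz
rate: 0.00302 ms^-1
relative alpha: 0.984
```

— the healthy node oscillates at 10 Hz with nearly all 2–40 Hz power in
the alpha band, and a mean pyramidal firing rate just above the sigmoid's
half-activation value e0 = 0.0025 ms⁻¹.

A full disease course on a synthetic 40-region bilateral connectome
(about one minute of compute):

```python
con = al.synthetic_connectome(20, "modular", rng_seed=1)
traj = al.run_closed_loop(con, al.ClosedLoopConfig(rng_seed=1))
print(m.time_to_peak(traj.ha, years=traj.years))
print(m.time_to_peak(traj.mean_plv, years=traj.years))
```

prints

```
TimeToPeak(year=12.0, interior=True)
TimeToPeak(year=7.0, interior=True)
```

— mean alpha synchrony peaks years before the firing rate does: in this
model cellular hyperactivity and interregional hypersynchrony are
dissociated in time. `traj` also records the yearly protein
concentrations, damage variables, neural parameters, spectra and PLV
matrices (`traj.to_frame()`, `traj.save(dir)`).

Batch experiments (single-node parameter sweeps, limit-of-change sweeps,
Aβ/tau isolation, seeding Monte Carlo) are available as functions in
`adloop.experiments` and as CLI subcommands:

```bash
adloop sweep-node --seed 1 --out out/
adloop montecarlo --synthetic 18 --strategy abeta_posterior --n-runs 20 \
    --seed 1 --out out/
```

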