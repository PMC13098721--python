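# smfretsim

Stochastic simulator of time-resolved confocal single-molecule FRET
experiments, built to study how dye-linker motion and transition-dipole
orientation dynamics shape the joint FRET-efficiency / donor-lifetime
distribution and its **dynamic shift** — the signed deviation of a
per-burst (efficiency, normalized lifetime) point from the static line
`E = 1 - tau`.

The pipeline:

1. **Translational dye dynamics** (`smfretsim.linker_models`) — isotropic
   or anisotropic Ornstein–Uhlenbeck springs (with spring constants
   derivable from C–C linker chemistry treated as springs in series) and a
   stochastic elastic pendulum in spherical coordinates, integrated with a
   Stratonovich-consistent Euler–Heun scheme.
2. **Dipole rotation** (`smfretsim.dipole_dynamics`) — spherical Brownian
   motion of each dye's transition dipole, with diffusion coefficients
   optionally derived from `kT / (8 pi nu R_h^3)`.
3. **Photon emission** (`smfretsim.photon_engine`) — each excitation event
   is a competing-risk race between donor decay (rate `k_D`) and energy
   transfer with the time-inhomogeneous hazard
   `k_ET(t) = k_D C kappa2(t) / r(t)^6`, sampled by integrated-hazard
   inversion (an independent Ogata-thinning sampler cross-validates it).
   Bursts repeat excitation at a fixed laser repetition period with the
   dye state propagating through the interphoton dead time. Photon
   arrival statistics are emergent — no homogeneous-Poisson assumption.
4. **Analysis** (`smfretsim.shift_analysis`) — per-burst dynamic shift
   `(E + tau - 1)/sqrt(E^2 + tau^2)`, distribution summaries, a
   moment-difference diagnostic, and a two-state switching reference model
   whose switching-rate sweep traces the mixing arc.

Core closed-form FRET math (orientation factor, Förster rate, static and
path-dependent efficiencies, intensity/lifetime estimators, the Jensen
lifetime inequality) lives in `smfretsim.fret_core`. Configuration,
presets, fixtures and delimited I/O live in `smfretsim.config`,
`smfretsim.fixtures` and `smfretsim.cli`.

Units are ns / nm throughout; all defaults live in
`src/smfretsim/presets.yaml`.

## CLI

```sh
# simulate a burst experiment from a preset (or --config file.yaml)
smfretsim simulate --preset pendulum_dynamic --bursts 1000 --seed 1 \
    --out bursts.tsv [--photons photons.tsv]

# dynamic-shift distribution of a burst table
smfretsim shift --in bursts.tsv --out shift.tsv

# two-state switching-rate sweep (mixing arc)
smfretsim twostate --e1 0.3 --e2 0.8 --lambdas 1e-5,1e-3,1e-2,1e-1 \
    --bursts 200 --seed 1 --out sweep.tsv

# deterministic toy fixtures
smfretsim fixtures --outdir fixtures/ --seed 0
```

Presets: `iso_spring`, `aniso_spring`, `pendulum` (static
`kappa2 = 2/3`), `pendulum_dynamic` (per-event spherical-Brownian
dipoles), and `rotdiff_{slow_slow,slow_fast,fast_fast}` rotational-
diffusion comparisons. Every output carries a provenance header
(version, config hash, seed); reruns with the same flags are
byte-identical.

Example config file (any subset of keys; unknown keys are rejected):

```yaml
model: pendulum          # iso_spring | aniso_spring | pendulum
kappa2_mode: dynamic     # static | dynamic
n_bursts: 500
seed: 7
rotation: {D_rot_donor: 0.01, D_rot_acceptor: 0.01, units: rad2_per_ns}
burst: {n_excitations: 400, eff_donor: 0.375, eff_acceptor: 0.375}
```

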