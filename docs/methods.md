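# Methods

## 1. Kinetic model

State variables: linker RNA concentration `rna` (nM), fuel `ntp` (µM).
Enzyme activities `t7`, `rnaseh` in U/µl, DNA template `temp` in nM.

```
d[rna]/dt = k1·t7·temp·ntp − k2·rnaseh·rna
d[ntp]/dt = −k3·t7·temp·ntp
```

Transcription is treated as first order in fuel (the NTP pool is the limiting
substrate over the modelled range), degradation as first order in linker
(RNaseH acts catalytically on linker·DNA duplexes, which track the linker
level), and fuel drain as proportional to transcription activity. The system
is linear and has the closed form

```
ntp(t) = ntp0·e^(−λt)
rna(t) = rna0·e^(−μt) + A·(e^(−λt) − e^(−μt)) / (μ − λ)
```

with lumped rates `A = k1·t7·temp·ntp0` (nM/min), `λ = k3·t7·temp` (1/min),
`μ = k2·rnaseh` (1/min). The confluent case `μ ≈ λ` (relative gap below
1e-10) uses `(rna0 + A·t)·e^(−λt)`. Derived quantities: peak time
`ln(μ/λ)/(μ−λ)` (or `1/λ` in the confluent limit), steady state `A/μ` when
fuel consumption is switched off.

### Parameters (defaults and rationale)

| parameter | default | units | rationale |
|---|---|---|---|
| `k1` | 2.5e-3 | nM RNA · (U/µl)⁻¹ · nM⁻¹ · µM⁻¹ · min⁻¹ | with the defaults below gives A ≈ 4.7 nM/min, a pulse peaking near 100 nM |
| `k2` | 0.136 | (U/µl)⁻¹ · min⁻¹ | μ ≈ 0.026 min⁻¹ at 0.19 U/µl RNaseH: linker half-life ≈ 27 min |
| `k3` | 5.3e-4 | (U/µl)⁻¹ · nM⁻¹ · min⁻¹ | λ ≈ 0.01 min⁻¹: fuel hour-scale depletion, peak near 60 min |
| `t7` | 3.75 | U/µl | typical working polymerase activity |
| `temp` | 5.0 | nM | DNA template |
| `rnaseh` | 0.19 | U/µl | degradation level at which the pulse lasts a few hours |
| `ntp0` | 100.0 | µM | initial fuel |
| `rna0` | 0.0 | nM | no linker at start |

The rate constants are illustrative: they were chosen analytically (before
any fitting experiments) so that the default condition produces a pulse
with onset ≈ 14 min, peak ≈ 100 nM at 60 min and lifetime ≈ 160 min at a
50 nM threshold — the hour-scale transient regime the model is meant to
explore. They are not measured values.

### Numerics

`simulate` uses `scipy.integrate.solve_ivp` (RK45, rtol 1e-8, atol 1e-10) on
a user grid that must start at 0 and be strictly increasing. Verified against
the closed form over a 4×4×4 sweep of (A, λ, μ) ∈ {0, 0.01, 0.1, 1}³ to a
relative error below 1e-6 (observed ≈ 7e-9). Fuel bookkeeping uses the exact
identity `ntp0 − ntp(t) = (k3/k1)·∫ k1·t7·temp·ntp dt`; the integral is
evaluated with cumulative Simpson quadrature (`scipy.integrate.
cumulative_simpson`), giving residuals ≈ 1e-10 on 1000-point grids where
trapezoidal quadrature leaves ≈ 2e-6.

Pulse metrics (onset = first up-crossing, offset = last down-crossing,
lifetime = offset − onset) use linear interpolation between grid samples.

## 2. Hybridisation equilibria

Strand pool: linker, its full complement, the two docking strands, and the
two degradation fragments. Each duplex `i·j` obeys mass action,
`[ij] = K_ij·[i]·[j]` with totals conserved. Association constants follow
`K = K0·exp(γ·overlap)` with `K0 = 1e-6 nM⁻¹` and `γ = 0.7 per nt` — a
nearest-neighbour-style exponential in duplex length chosen so that a 14-nt
duplex is moderately stable (K ≈ 18 nM⁻¹) and a 38-nt duplex is effectively
irreversible (K ≈ 3.6e5 nM⁻¹). Pairable strands and overlap lengths are
derived from the packaged FASTA (`colloidpulse/data/sequences.fasta`) by a
longest-common-substring search against the reverse complement (U ≡ T).

The equilibrium is computed by a damped fixed-point iteration on free
concentrations, `x_i ← T_i / (1 + Σ_j K_ij x_j)`, with geometric (square
root) damping; the map has a unique positive fixed point for this pairwise
reaction network. Convergence tolerance 1e-12, with a final undamped update
so mass conservation holds to ≈ 1e-12 (verified on 100 random pools and
against the quadratic closed form, free fraction (√5−1)/2 at K = T = 1).

`threshold_transform` maps an RNA trajectory to the *effective* free-linker
trajectory in the presence of a fully complementary sequestering strand:
50 nM of complement delays a 25 nM onset crossing by ≈ 19 min and shortens
the decay phase, since the complement both subtracts early linker and caps
the effective pulse.

## 3. Fluorescence fitting

Synthetic traces model an intercalating-dye signal:
`signal = slope·(temp + rna + φ·fragments) − dip·e^(−t/τ) + noise`, where
fragments accumulate as `∫ μ·rna dt`, the dip term mimics the early heating
artefact of a plate reader, and noise is i.i.d. Gaussian scaled to the clean
signal (multiplicative dye noise).

Calibration estimates the slope as `min(signal after t_min_fit) / temp`; the
minimum must fall where RNA ≈ 0, so dip-free synthetic traces use
`t_min_fit = 0` while traces with a heating dip exclude the first 10 min
(default). Full-pulse fitting runs `scipy.optimize.least_squares` (trust
region reflective, non-negative bounds) from three heuristic starts (early
slope and tail log-slope), with **relative residuals**
`(model − data)/(w0 + model)`, `w0` = 5 % of the data maximum — the correct
weighting for multiplicative noise and the step that brings joint-fit errors
from >10 % to a few per cent. Because the double exponential is symmetric
under λ↔μ exchange, single-trace fits report the smaller rate as λ;
identifiability is restored by the joint fit across RNaseH levels, which
shares (A, λ) and fits `k2` through `μ_i = k2·rnaseh_i`. At 5 % noise and
180 samples, lumped rates are recovered within 10 % and `k2` within ≈ 2 %
at the canonical seed.

## 4. Spatial chamber model

A 200×20 lattice (10 µm cells, dt 0.5 min) with a production reservoir in
the first 10 columns. Operator splitting per step: (i) diffusion as a
Gaussian blur with `σ = √(2·D·dt)/dx` (`scipy.ndimage.gaussian_filter`,
reflect boundary — a symmetric kernel with reflecting boundaries conserves
mass exactly); (ii) production `prod_rate·dt·e^(−λt)` in the reservoir and
exponential decay `e^(−μ·dt)` everywhere. D = 4000 µm²/min gives a
penetration length `√(D/μ) ≈ 52` cells, so probes at columns 30 and 70 sit
at ≈ 0.4 and 1.2 penetration lengths.

Colloids random-walk (4 directions, periodic in x, reflecting in y), bind
when local RNA ≥ `theta_on·(1 + β·h)` with at least one 8-neighbour contact,
and unbind below `theta_off·(1 + β·h)`; `h` accrues degradation exposure
`μ·rna·dt` while bound. All colloids update synchronously (vectorised);
bound colloids do not move. The exposure gain β sets the front direction
when the pulse collapses: at β = 0 the far, late, weakly-supplied regions
disaggregate first (backward front); at the default β = 0.02 near colloids
accumulate exposure fastest and release first (forward front). The dichotomy
is deterministic across seeds at the default geometry. Uniform-production
runs agree with the ODE closed form within 0.1 % at dt = 0.1.

## 5. Imaging

Binarisation by Otsu threshold (rejected on constant images) or a fixed
level, with configurable dark/light polarity; component labelling via
`skimage.measure.label` (4- or 8-connectivity, default 8) with a 5-px
minimum size filter; statistics report cluster count, mean pixel area, and
mean disc-equivalent diameter `2·√(area/π)·pixel_size`. On synthetic images
with planted cluster areas the pipeline recovers counts exactly and mean
sizes within 0.5 % over 20 seeds.

## 6. Synthetic-data scope and limitations

All ground-truth data in the tests is generated by `colloidpulse.synth`;
none of it is experimental. Consequences:

- Rate constants are illustrative, not measured; only their *relationships*
  (regimes, monotonic trends, recovery of planted values) are claims.
- The hybridisation K(overlap) law is a one-parameter caricature of duplex
  thermodynamics; it preserves ordering by overlap length, not absolute
  free energies.
- The chamber model uses threshold binding with a scalar exposure history,
  not explicit multivalent colloid–colloid bonds; it reproduces the
  qualitative front dichotomy, not aggregate microstructure.
- Binding/unbinding thresholds act on total local RNA rather than the free
  fraction; hybridisation corrections enter only through
  `threshold_transform` in the well-mixed analyses.
- Calibration assumes a time window where RNA ≈ 0; traces that start
  mid-pulse would bias the slope.
- Image noise is Gaussian and clusters are non-overlapping by construction;
  touching clusters would merge under connected-component labelling.
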