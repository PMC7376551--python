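# Methods

## Scope and model

`retenphys` analyses the quantitative physiology of aerobic, glucose-limited
chemostat and retentostat cultures. It covers five connected pieces:

1. **Steady-state chemostat balances.** At steady state the biomass balance
   gives μ = D and the substrate balance gives q_S = D·(C_S,in − C_S,res)/C_X.
   Off-gas exchange rates come from the inert-gas balance: the non-O2,
   non-CO2 molar flow passes through unchanged, fixing the outlet flow
   F_out = F_in·(1 − y_O2,in − y_CO2,in)/(1 − y_O2,out − y_CO2,out), after
   which q_O2 and q_CO2 follow from the inlet/outlet mole-fraction
   differences. Carbon recovery counts glucose carbon (6 C per molecule)
   leaving as CO2 plus biomass carbon at 0.48 g C per g dry weight.

2. **Maintenance-energy estimation.** The linear substrate-partition model
   q_S = μ/Y_X/S^max + m_S is fitted by ordinary least squares of q_S on μ;
   the intercept is the maintenance coefficient m_S (g glucose·g biomass⁻¹·h⁻¹)
   and the reciprocal slope the maximum biomass yield. SE(Y_X/S^max) uses
   first-order propagation SE(1/s) = SE(s)/s². Replicate steady states enter
   as individual points by default (a means-based mode exists). Negative
   fitted intercepts are reported with a warning, never clamped.

3. **Retentostat forward model.** With complete cell retention, biomass obeys
   dC_X/dt = (μ − k_d)·C_X with the quasi-steady substrate balance
   q_S·C_X = D·C_mix(t) (residual glucose ≈ 0, consistent with
   below-detection chemostat residuals of <0.002 g/L against a 5 g/L feed)
   and the partition closure q_S = μ/Y_X/S^max + m_S(μ). The feed transition
   runs through a mixing vessel: C_mix(t) = C_new + (C_old − C_new)·e^(−F·t/V_M),
   F = D·V_R (time constant ≈ 34.3 h for the default geometry). For constant
   m_S the system is linear and the closed-form solution (implemented as
   `constant_maintenance_solution`) serves as an independent benchmark for
   the numerical integrator; its long-run asymptote is D·C_feed/m_S. For
   μ-dependent maintenance, μ is solved per step by damped fixed-point
   iteration of μ ← Y·(q_S − m_S(μ)) to |Δμ| < 1e−12 (damping 0.5; the
   saturating law reduces to a quadratic whose positive root the iteration
   must match, which the tests verify).

   μ is *not* floored at zero: once supply falls below maintenance demand
   the closure yields a slightly negative μ (endogenous consumption of
   biomass to cover maintenance), bounded below by −Y·m_S automatically.
   Flooring μ at zero would freeze the small overshoot that the feed
   transient produces in the weakly-coupled preset and leave the trajectory
   ~6% above its analytic asymptote; the unfloored model reproduces the
   closed form to machine precision. A first-order death/lysis rate k_d is
   exposed (default 0, since measured viability in such cultures stays near
   100%), as is an optional per-sampling-event broth withdrawal that dilutes
   biomass by (1 − v/V_R) per event (default off).

4. **Time-resolved maintenance from biomass trajectories.** Between adjacent
   samples, μ = ln(C_X,2/C_X,1)/Δt (exact for exponential segments) and
   q_S = D·⟨C_mix⟩/logmean(C_X,1, C_X,2), where ⟨C_mix⟩ is the analytic
   time-average of the mixing-vessel law over the interval and the
   logarithmic mean is the time-average of an exponential segment. The
   biomass-averaging choice matters below 0.1% at observed growth rates but
   is fixed for determinism. A 5-point moving window of (μ, q_S) pairs is
   refitted by OLS; each window's intercept (± SE) is one time-resolved m_S
   estimate, timestamped at the mean of the member interval midpoints.
   Windows are computed per reactor and never span replicates; windows with
   zero μ spread are skipped with a log message. Chemostat-derived pairs can
   be prepended so early windows are anchored by steady-state data (pipeline
   default: all chemostat pairs).

   Two estimator properties to keep in mind. First, the interval estimator's
   discretization error is O(Δt) and concentrates in the feed transient: at
   48-h sampling only the first interval (≈1.4 mixing time constants)
   deviates ~3% from the generating line, later intervals <1%. Second, for a
   μ-dependent maintenance law the window intercept estimates the local
   tangent intercept m(μ̄) − μ̄·m′(μ̄), not m(μ̄) itself; it approaches the
   true maintenance floor only as μ̄ → 0. Windowed estimates are therefore
   read as "maintenance extrapolated to zero growth from the window's μ
   range", which is also how the declining-maintenance phenotype is defined.

5. **Respiratory-chain coupling arithmetic.** ATP conserved per NADH is
   proportional to charges translocated per 2 e⁻ at fixed ATP-synthase
   stoichiometry. Defaults: complex I pumps 4 charges per 2 e⁻, complexes
   III+IV together 6, the alternative (Ndh2-type) dehydrogenase 0. Replacing
   complex I by a non-pumping dehydrogenase then forfeits 4/10 = 40% of ATP
   conservation per NADH; the charge counts are explicit, overridable model
   fields. The 40% figure is independent of the charges-per-ATP of the ATP
   synthase, which is deliberately left unspecified. Relative in vivo P/O
   ratios are inferred from biomass-per-oxygen yields only under the
   explicit assumption of equal Y_X/ATP between strains (carried as a flag);
   with that assumption, (Y_ref − Y_test)/Y_ref is the fractional P/O
   reduction.

## Parameters and defaults

| Parameter | Default | Units | Why |
|---|---|---|---|
| V_R, V_M | 1.4, 1.2 | L | working volumes of the reactor and mixing vessel |
| D | 0.025 | 1/h | retentostat (and preceding chemostat) dilution rate |
| feed, chemostat → retentostat phase | 10 → 5 | g/L | halves the carbon load as biomass accumulates |
| m_S, Y_X/S^max (wild-type preset) | 0.0142, 0.545 | g/(g·h), g/g | chemostat-derived reference physiology |
| m_S, Y_X/S^max (complex-I-deficient preset) | 0.0241, 0.485 | g/(g·h), g/g | weaker respiratory coupling |
| maintenance relaxation fold | 2.75 | — | m_min = m_max/2.75 in the adaptive presets |
| k_mu | 0.005 | 1/h | half-saturation of the maintenance decline; see below |
| biomass CV, feed CV | 0.02, 0.005 | — | log-normal (mean-one) measurement noise |
| glucose detection limit | 10 μM (0.0018 g/L) | — | below-detection residuals are set to 0, flagged, and bracketed |
| gas molar volume | 22.414 | L/mol | dried, cooled off-gas referenced to 0 °C, 1 atm; configurable |
| ODE tolerances | rtol 1e−9, atol 1e−12 | — | integrator error far below measurement noise |

**Choice of k_mu.** Only the fold-change of the maintenance decline
(2.5–3×) is an empirical anchor; its μ-dependence is not. The saturating
form needs a half-saturation rate, set a priori to 0.005 1/h: an order of
magnitude below the chemostat dilution rates (0.025–0.1 1/h), where no
decline is observed, and several-fold above the final retentostat growth
rates (~0.001 1/h), where the decline is fully expressed. With this value
the adaptive wild-type scenario ends its 23-day run at μ ≈ 7e−4 1/h with
windowed m_S ≈ 1.04·m_min, a 2.6-fold drop against the constant chemostat
estimate. A consequence worth noting: because maintenance starts relaxing
already at μ ≈ 0.01 1/h, the synthetic scenario accumulates biomass well
beyond the constant-m_S ceiling (≈17 vs 8.8 g/L at 23 days) — more than
real cultures show. A smaller k_mu tempers the over-accumulation but caps
the windowed decline below 2.5-fold; the chosen value favours reproducing
the maintenance phenotype.

## What the synthetic data do and do not emulate

The generator reproduces: duplicate chemostats at two dilution rates with
below-detection residual glucose and off-gas fractions constructed from
stoichiometric respiration (carbon balance closed at RQ = 1); 23-day
retentostat biomass trajectories (12 samples, denser early) with mean-one
multiplicative log-normal noise and viability near 1.0; and full ground
truth emitted alongside (`truth.json`). It does not emulate analyzer drift,
autocorrelated assay error, by-product formation, filter fouling, changing
biomass composition, or any omics readout. Passing recovery tests therefore
show the estimators are unbiased and noise-robust under the stated error
model, not that real cultures satisfy that error model.

## Numerical and design choices

- Uptake rates are handled as positive magnitudes everywhere; signs are an
  I/O convention. Internal canonical units are h, g/L and g/(g·h); molar
  rates appear only at the I/O boundary via `MolarConstants`.
- Two-group comparisons use the pooled-variance Student's t test (not
  Welch); two zero-variance groups with equal means return p = 1 by
  convention.
- The instantaneous-feed-switch mode (`instant_feed_switch`) bypasses the
  mixing vessel for sensitivity analysis; the mixing-vessel mode is the
  default and matches the physical setup.
- All randomness flows from one top-level seed expanded per pipeline stage
  via `numpy.random.SeedSequence`, so outputs are byte-identical across
  runs and adding a stage never shifts another stage's stream.
- Artifact CSVs carry `#`-prefixed provenance headers (package version,
  configuration hash, seed); floats are written at 17 significant digits so
  writer/reader pairs round-trip exactly.

## Problem sizes used in the test and acceptance suites

Monte-Carlo checks use 100 seeds for pipeline parameter recovery (both
constant presets, CV 2%), 500 replications for the ±2·SE coverage check of
the maintenance intercept, and 1000 replicates for the mean-one noise
check; asymptote checks integrate 4000 h (~30 biomass time constants).
These sizes give stable pass/fail margins while keeping the full suite in a
few seconds.

## Known limitations

- The quasi-steady substrate assumption breaks down if the feed transition
  were fast relative to uptake; for the default geometry it is excellent.
- The saturating maintenance law is phenomenological; the data constrain
  its endpoints, not its shape between them.
- Windowed m_S estimates inherit the tangent-intercept bias described above
  whenever maintenance varies within a window's μ range.
- The carbon balance assumes a fixed 0.48 g C/g biomass; real biomass
  composition shifts slightly at near-zero growth.
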