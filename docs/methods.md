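# Methods

This note documents the models behind `thermopulse`, the defaults and
why they were chosen, the numerical scheme, and what the synthetic data
can and cannot say about real measurements.

## Sensor model

The device is a 9 mm × 9 mm copper meander (15 µm thick, 100 µm track
and spacing) on a 40 µm polyimide foil, mounted over an air cut-out
with the liquid culture above the foil. We model the meander as a
uniform planar heat source: the pulse penetrates ≲ 1 mm of liquid in
1 s, far less than the 9 mm lateral extent, so conduction is treated as
one-dimensional through the plane. The heater is a lumped node with
areal heat capacity 51.7 J m⁻² K⁻¹ (15 µm of copper at
ρc_p = 3.45 MJ m⁻³ K⁻¹). The default stack is

```
adiabatic backing | heater | polyimide 40 µm | (cell layer) | semi-infinite medium
```

The air cut-out behind the heater is approximated as adiabatic (air
carries < 0.1 % of the heat of the water side); a semi-infinite air
backing is available in the configuration for sensitivity checks. The
substrate sits **between** the heater and the culture — this is what
motivates the regression window below: at its 25.6 ms start the probing
depth `2√(a t)` in polyimide is ≈ 89 µm, comfortably past the 40 µm
foil, so the window senses the liquid side.

Electrically, `R = R_ref [1 + α (T − T_ref)]` with α = 3.818 × 10⁻³ K⁻¹
(copper, determined for these devices) and R_ref ∈ [7, 10] Ω at 20 °C.
Pulses are driven at constant current `I = √(P / R_init)` so all
sensors dissipate the same nominal power; the within-pulse power rise
from the warming track (order α·ΔT ≈ 2–4 %) can be switched on via the
electro-thermal coupling option but is off by default, since the
percent-change normalisation cancels its first-order effect. Cooling
intervals (60 s sedimentation, 300 s proliferation) are assumed to
restore ambient exactly; each pulse starts from a uniform temperature
field.

Read noise is additive white Gaussian voltage noise, default
sd 0.2 mV. No noise figure is published for this class of device; the
value is the simplest choice that leaves every in-window regression
with R² well above the 0.98 floor reported for the physical sensor
(simulated runs sit near R² ≈ 0.983–0.997). An optional uniform
quantisation step is not modelled.

## Numerical scheme

`simulate_step_response` integrates the 1-D heat equation by backward
Euler (unconditionally stable) on a finite-volume grid: films are
meshed at ≤ 1 µm (at least 8 cells per film, so sub-micron cell layers
remain resolved and the response varies smoothly with thickness), the
semi-infinite medium is meshed geometrically (ratio 1.15) out to 5 mm,
where a zero-flux boundary truncates the domain — the 1 s penetration
depth in water is ≈ 0.8 mm, so the truncation is invisible. Four
implicit sub-steps are taken per 500 Hz output sample; the system is
factorised once per pulse (banded Cholesky) and re-solved per step.
Symmetric finite-volume conductances make the scheme exactly
energy-conserving on the truncated domain.

Validation: against the constant-flux semi-infinite closed form
(`ΔT = 2q/e · √(t/π)`), the solver tracks within 0.2 % for
t ≥ 25.6 ms, and the analysis-window slope agrees to 0.2 % (the test
bound is 2 %). Halving the spatial step and doubling the sub-steps
moves the window slope by < 0.5 %. A coarse preset (`FAST_GRID`) is
used in parameter-sweep tests; its window-slope error against the
default grid is well under 1 %.

## Analysis pipeline

Voltage transients convert to temperature by `R(t) = V(t)/I` and the
inverted resistance law — an affine map, so regressing in the voltage
or the temperature domain gives identical percent-change series
(property-tested to 1e-9). The regression window is the closed
interval [0.16, 0.56] √s on sample timestamps; at 500 Hz (samples at
k·2 ms, k = 1…500) this selects 144 points. Whether the bounds are
closed or half-open, or whether midpoint times are used, changes the
selection by at most one sample and the slope negligibly; closed bounds
on timestamps are used and documented. Percent change is normalised to
the first pulse (the field convention); an optional mean-of-first-k
baseline is available for noise robustness but off by default. Pulses
containing non-finite samples are dropped with a logged warning.
Endpoint statistics default to the 2–12 h window of a settled
sedimentation run; shorter simulated runs pass explicit windows sized
to end after the settling transit time.

## Synthetic cultures

**Sedimentation.** A uniform suspension of concentration c (mg/mL) in a
column of height H settles at the Stokes velocity
`v_s = (2/9) Δρ g r² / μ`; the deposited fraction is `min(1, v_s t/H)`
and the plateau areal biovolume is `c·H/ρ_cell` by mass balance.
Defaults: r = 2.5 µm, Δρ = 100 kg m⁻³, μ = 1 mPa s (v_s ≈ 1.36 µm/s)
and H = 5.3 mm (1.5 mL in a 19 mm tube), giving complete settling in
≈ 1.1 h — consistent with the observed "first 1.5 h" window. The
dilution ladder is the stock series 8 → 0.125 mg/mL plus a water
control.

**Proliferation.** The population (in OD600-equivalent units) holds at
the inoculum through a fixed 5 h lag, then follows a logistic with
exponential-limit rate `ln2 / T_d` (T_d = 90 min for budding yeast) and
carrying capacity `K = OD_0 + Y·G` with G the supplied glucose (g/L)
and Y = 0.4 OD per g/L — a plausible fermentative yield; only ratios
and orderings of K are relied on, never its absolute value.

**Mapping to a thermal layer.** Biomass maps to areal biovolume by a
single conversion per unit: `c·H/ρ_cell` for sedimentation (physical
mass balance) and 10 µm³/µm² per OD600 unit for proliferation. The OD
conversion is a configuration constant, chosen so a fully grown culture
(K ≈ 4.2 OD) forms a ≈ 65 µm interface layer — inside the regime where
the window slope is affine in thickness (deviation from the secant
< 5 % up to ≈ 60 µm, property-tested), which is the modelling
assumption that lets percent change stand in for biomass. The layer is
a cell/medium composite at packing fraction φ = 0.64 (random close
packing): thickness = biovolume/φ, conductivity by the Maxwell–Eucken
rule with the medium continuous (always between the series and parallel
bounds), density and heat capacity volume-weighted. Cell properties
default to k = 0.45 W m⁻¹ K⁻¹, ρ = 1100 kg m⁻³, c_p = 3500 J kg⁻¹ K⁻¹ —
literature-plausible values, explicitly assumptions rather than claims;
all that the conclusions need is cell conductivity below the medium's.

A calibration-mode generator bypasses the physics and draws endpoint
percent changes directly from the sensor's empirical response line
`y = 0.7806·c − 0.2194` (percent vs mg/mL, interpreted on a linear
abscissa) plus Gaussian noise. It exists so calibration recovery can be
tested independently of the assumed cell thermal properties. The
inverse-prediction uncertainty is reported by the delta method,
`residual sd / |slope|`.

## Growth-parameter estimation

The growth fit is a **lagged logistic**: percent change flat at a
baseline through a fitted lag, then `c₀ + c₁(N/N₀ − 1)` with `N/N₀` a
logistic rising from 1 to a fitted fold-expansion. A plain 4-parameter
logistic is retained as an option, but fitting it across a long flat
lag biases the rate upward by ≈ 9 % at these conditions (measured on
noiseless input), because the logistic's left tail cannot hold a flat
segment; the explicit lag removes that bias (noiseless recovery is
exact on trajectory-level input). The least-squares surface has a
ridge along fold/lag/rate, so the solver is multi-started from a grid
of fold-expansions and rates and the lowest-cost solution kept.
Convergence is flagged, not assumed: flat series return a
non-converged fit with NaN rate.

Doubling-time information in one channel is limited: at the default
read noise the per-pulse percent-change uncertainty is ≈ 0.3–0.4 points
against a ≈ 4-point amplitude, and the Cramér–Rao bound for the 5-free-
parameter fit is ≈ 10–13 % on the rate — no estimator can do better
from a single series. Multi-channel rigs measure four sensors of one
culture sequentially, so the estimator of record
(`fit_growth_multichannel`) re-centres each channel on its lag-phase
median and fits the pooled data, bringing the spread to ≈ 4–5 % with a
small (≈ −3 %) residual bias from the mild thickness-nonlinearity of
the slope response. Recovery at default noise: bias < 5 %,
RMSE < 10 % over 20 trials (tested at the slope level; one full-physics
recovery is tested end-to-end).

Phase segmentation is heuristic: the lag ends at the first sustained
(3-sample) exceedance of the early baseline by 3 baseline standard
deviations — on noisy data this marks where growth becomes
*observable*, typically ~1 h after the true lag — and the stationary
phase starts at the plateau time (first time from which the series
stays within tolerance of its tail mean).

## Test design and problem sizes

Simulated test runs are sized to the shortest window that contains the
feature under test: sedimentation runs 1.8 h (settling ends ≈ 1.1 h)
with endpoints over 1.3–1.8 h, glucose-series runs 16 h, starting-
density runs 24 h (the lowest inoculum saturates ≈ 19 h), and the
doubling-time recovery uses the full 18 h protocol. A session-wide
solver cache reuses thermal solves between tests and replicate
channels. Qualitative orderings (endpoint vs concentration, final rise
vs glucose, onset vs inoculum, plateau equality) are asserted on
noise-free pipelines: they are deterministic properties of the physics,
and at default noise the single-run percent-change uncertainty
(≈ 0.4 percentage points, dominated by the first-pulse baseline slope)
exceeds the endpoint gap between the two lowest dilution steps —
mirroring the physical sensor, whose stated concentration uncertainty
(0.29 mg/mL) also exceeds that 0.125 mg/mL spacing. Noise robustness
is covered separately by the R² floor, calibration-recovery and
doubling-time-recovery tests.

## Known limitations

- One-dimensional conduction only: no meander-resolved 2-D/3-D
  effects, no convection or evaporation in the liquid, no metabolic
  heat.
- The cell layer is a homogeneous effective medium; no cell-size
  distributions, biofilm matrix, or compaction dynamics.
- OD-to-biovolume and yield constants are conventions; simulations
  support ratios and orderings, not absolute biomass claims.
- Percent change is treated as proportional to biomass only within the
  thin-layer regime; thick beds (≳ 100 µm) saturate the response.
- Sedimentation and growth are decoupled idealisations: settling is
  instantaneous relative to growth in proliferation mode (biomass is
  placed at the interface directly).
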