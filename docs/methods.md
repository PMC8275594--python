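# Methods

## Model

The tissue is a stack of homogeneous slabs, laterally 13 mm wide and
13 mm deep, bounded above by air. Each layer is characterised by an
absorption coefficient μa, a scattering coefficient μs, the
Henyey–Greenstein anisotropy g = 0.9 and refractive index n = 1.4,
identical in every layer, so refraction and reflection occur only at
the air–tissue surface; internal interfaces change the coefficients but
not the direction of flight.

### Layer stack

| layer | thickness (mm) | V_blood | V_water | V_melanin | scatter class |
|---|---|---|---|---|---|
| stratum corneum | 0.02 | 0 | 0.05 | 0 | skin |
| epidermis | 0.25 | 0 | 0.20 | 0.02 | skin |
| papillary dermis | 0.10 | 0.04 | 0.50 | 0 | skin |
| upper blood net dermis | 0.08 | 0.30 | 0.60 | 0 | skin |
| reticular dermis | 0.20 | 0.04 | 0.70 | 0 | skin |
| deep blood net dermis | 0.30 | 0.10 | 0.70 | 0 | skin |
| hypodermis | to 13 mm | 0.05 | 0.70 | 0 | fat |

The dermal sublayer thicknesses and blood/water contents are the
published finger anatomy. Three gaps are filled by package defaults,
all configurable through the model YAML:

* stratum corneum 0.02 mm and epidermis 0.25 mm, chosen so the
  papillary dermis spans 0.27–0.37 mm (consistent with the reported
  shallowest penetration being "within papillary dermis" at ≤ 0.37 mm);
* hypodermis fractions V_b = 0.05, V_w = 0.70, following the
  Meglinski–Matcher multilayer skin lineage from which this finger
  model descends;
* blood lipid fraction V_lip = 0.01 and epidermal melanin
  V_mel = 0.02. Melanin is not part of the published mixing rule but
  its absorption coefficient is tabulated, so it enters exactly one
  layer (the epidermis), inside the residual-volume budget.

### Absorption

Per layer, μa = V_b·μa_b + V_w·μa_w + V_mel·μa_mel +
[1 − (V_b + V_w + V_mel)]·μa_t with the blood coefficient
μa_b = V_lact·μa_lact + V_lip·μa_lip and the absorber-free baseline
μa_t = 7.84·10⁸·λ⁻³·²⁵⁵ (λ in nm, result in mm⁻¹, matching the table's
units; the constant is overridable in case a per-cm convention is
preferred — at SWIR wavelengths the baseline is ~0.01–0.06 mm⁻¹ and
nearly negligible either way). The lactate volume fraction is
V_lact = C_lact/100 mmol L⁻¹ because the tabulated lactate column is
the absorption of the 100 mmol/L in-vitro reference solution.

### Scattering convention

The property table's two scattering columns are interpreted as
*transport (reduced)* scattering coefficients μs′, and the engine
transports with μs = μs′/(1 − g) under g = 0.9. Three observations
force this reading:

1. the tabulated skin values (1.88–4.9 mm⁻¹, decreasing with λ) have
   the magnitude and trend of published *reduced* skin coefficients in
   SWIR; the unreduced μs of skin is 10–30 mm⁻¹;
2. taken at face value with g = 0.9 (μs′ ≈ 0.2–0.5 mm⁻¹) the simulated
   penetration depths are 1.5 mm and detected powers ~0.1 % — an order
   of magnitude away from the study's own reported depth bounds
   (≤ 0.37/0.99/1.23 mm) and powers; the reduced reading reproduces
   every depth bound, every power ordering and the 0–6 a.u. absorbance
   range;
3. the study notes that varying g does not influence its outcomes,
   which is true precisely when μs′ is what the table fixes
   (similarity), and false under the face-value reading.

`build_finger_model(..., scatter_convention="as_tabulated")` restores
the face-value behaviour. The fat column's header/caption disagree in
the source (absorption vs scattering label); it is treated as the fat
scattering column, the only reading with scattering-scale values.

Even under the reduced reading, the absolute detected powers land
below the published table — by roughly ×0.5 at 0.7 mm and ×0.2 at
1.5 mm separation — while every printed *ordering* (decreasing with d
at every wavelength, maximum at 1310 nm/0.7 mm, minimum at 1920 nm) is
reproduced. The published power-vs-distance falloff (e.g. 1.28 % →
0.55 % over 0.7 → 1.5 mm at 1684 nm, an effective attenuation of
~1.1 mm⁻¹) is shallower than radiative transport permits for the
published water content (μ_eff = √(3 μa μ_tr) ≈ 1.8 mm⁻¹ with
μa ≈ 0.32 mm⁻¹); no self-consistent parameter reading closes that gap,
and the published table itself carries a tenfold internal conflict for
one cell. The package therefore reports what the physics of the stated
model yields and documents the discrepancy rather than fitting to it.

## Transport engine

Implicit-capture weighted packets: each packet starts with weight
1 − R_spec (R_spec = ((n−1)/(n+1))² ≈ 0.0278), loses the fraction
μa/μt of its weight at every interaction, scatters through a
Henyey–Greenstein deflection with uniform azimuth, and draws
exponential free paths that are clipped at layer interfaces with the
dimensionless optical path μt·s conserved across the crossing (the
step resumes in the next layer's μt). At the surface, unpolarised
Fresnel statistics decide escape versus internal reflection, with
total internal reflection beyond θc = asin(1/1.4) ≈ 45.6°. A packet
escaping the top surface is *detected* if its exit point lies on the
detector disk of radius 0.2 mm centred at (d, 0) (boundary inclusive);
other top exits, lateral exits and bottom exits are pooled as escaped
weight and terminated (the 13 mm lateral extent is several transport
lengths at every study wavelength, so this semi-infinite approximation
is benign). Low-weight packets (< 10⁻⁴) enter Russian roulette with
survival probability 0.1 (survivors ×10), which is unbiased in
expectation; with roulette disabled the energy balance
launched = detected + absorbed + escaped closes to < 10⁻⁹ relative,
and that identity is a standing test.

The source is a normally incident Gaussian beam of 1/e² radius 0.1 mm
truncated at two radii (a flat-top profile is available). The beam can
be displaced off-axis, and the detector switched to an annulus, for
symmetry diagnostics.

The kernel is a single-threaded numba routine, bit-reproducible for a
given seed; the photon budget can be split over derived-seed chunks
(`n_workers`), which is deterministic for a fixed worker count. The
interaction-event map accumulates voxel counts (0.02 mm voxels in a
window around the source–detector axis) along detected-photon paths
only, by default, producing the source-to-detector "banana"; a flag
records all paths instead.

## Summary statistics

* Mean penetration depth D_M: unweighted mean over detected packets of
  the maximum z reached along the path (a weighted variant exists
  behind a flag). Statistically undefined with zero detections — an
  error carrying the count, not a silent NaN.
* Relative power: 100 × detected weight / incident weight, normalised
  to the *pre-specular* beam so it reads as "% of input power". The
  equivalent mean-intensity × detector-area formulation is computed
  alongside and asserted equal.
* Absorbance A = −log₁₀(detected/incident); zero detection returns an
  infinite-absorbance sentinel with a warning.
* Concentration sweeps (1–6 mmol/L): lactate changes blood-layer
  absorption by only ~4·10⁻⁴ mm⁻¹ per mmol/L, so the absorbance deltas
  (~10⁻³–10⁻⁴ a.u.) are far below independent-run Monte Carlo noise at
  any affordable packet count. The default sweep therefore uses exact
  correlated sampling: one reference-concentration run per (λ, d)
  cell, with every other concentration scored on the *same* detected
  paths through the perturbation factor exp(−Σ_l Δμa,l·L_l), where
  L_l is the packet's path length in layer l (recorded by the kernel).
  Because scattering is unchanged, this likelihood ratio is exact for
  the implicit-capture estimator — (1 − μa/μt)·μt = μs cancels between
  numerator and denominator — not a first-order expansion, and it is
  validated against independent re-simulation in the test suite. A
  literal common-random-number rerun mode is retained. Distinct cells
  always use independently derived seeds.

## Design scoring

Noise criterion: D_M must exceed the bloodless-layer bottom (0.27 mm).
Power criterion: relative power ≥ 0.1 % (the study accepts ~1 % and
rejects 0.005 %). Sensitivity: |OLS slope| of raw absorbance against
concentration, from the closed-form normal equations (a normalised
variant is available). The selector keeps cells passing both boolean
criteria and maximises sensitivity, tie-breaking to larger λ then
smaller d. This is one deterministic formalisation of a qualitative
judgement. With exact (correlated-sampling) sensitivities the
separation behaves as published — the 1.5 mm cells fall below the
power threshold and sensitivity grows with separation among the
remaining cells, so 1.0 mm wins — but the wavelength ranking puts
1310 nm narrowly above 1684 nm: in the additive mixing rule lactate
only ever *adds* absorption in proportion to the blood path length,
so the deepest-penetrating wavelength is structurally the most
sensitive. A wavelength-specific ranking like the published one
(1684 nm first, with absorbance *falling* at some other lactate-peak
wavelengths) requires competition between lactate and the water or
lipid it displaces, which the mixing rule as published does not
encode. The selector reports what the model implies rather than
being steered to the published cell.

## Synthetic validation fixtures

The fixtures module builds degenerate media whose answers come from
outside the engine: a scatter-free slab (ballistic Beer–Lambert
transmittance e^(−μa·L)), semi-infinite albedo-0.9 media (exact
H-function value 0.414947 for the matched isotropic case; frozen
unweighted brute-force MC values 0.41392 ± 0.00049 matched and
0.25825 ± 0.00044 under the n = 1.4 Fresnel boundary, 10⁶ photons,
generated before the engine was written), azimuthal-symmetry checks
with a ring detector and an off-centre negative control, and
log-normally perturbed property tables for robustness experiments.
Oracle values are frozen constants; the brute-force simulator ships in
the package so the provenance is reproducible.

What the fixtures do *not* emulate: real tissue heterogeneity, curved
finger geometry, discrete vessels, hemoglobin (absent from the mixing
rule by design), or instrument noise. Passing them shows the transport
physics and statistics are right, not that the anatomical defaults
match any individual finger.

## Problem sizes and numerical choices

The packaged studies run 10⁵–10⁶ packets per grid cell (the original
study quotes 10⁹–10¹⁰, but those were evidently analog packets;
implicit capture with roulette reaches comparable variance orders of
magnitude sooner — the two counts are not equivalent and are not
treated as such). Detected-power standard errors are computed from the
per-packet weight moments and reported with every sweep row. Roulette
threshold 10⁻⁴ and survival 0.1 follow standard multilayer-MC
practice. The event cap (10⁵ interactions) exists as a safety valve;
residual weight of capped packets is pooled with escapes and a warning
is raised if more than 0.1 % of packets hit it (none do in the
packaged configurations with roulette on). Layer intervals are
half-open [top, bottom); the detector boundary is inclusive; depth
z = 0 is the surface with +z downward and the detector centre on +x.

## Known limitations

* The absolute detected powers sit below the published table by the
  factors given above; orderings, depth bounds and absorbance ranges
  reproduce. Use the relative structure, not the absolute percentages,
  when extrapolating to hardware.
* No polarisation, fluence, time-of-flight or GPU pathways.
* The design selector formalises a qualitative published judgement;
  its thresholds are honest defaults, not fitted quantities.
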