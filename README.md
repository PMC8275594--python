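# swirmc

Monte Carlo design studies for non-invasive short-wave-infrared (SWIR)
blood-lactate sensing.

Blood lactate above ~2 mmol/L is an early marker of sepsis, heart
failure and other hypoperfusion states, but today it is measured by
drawing blood. Lactate has absorption features in the SWIR window
(1300–2500 nm) that survive the dominating water absorption, so a
reflectance probe on a finger — a source fibre and a detector fibre a
millimetre apart — could in principle read it optically. Whether that
works depends on questions no spectrometer can answer: how deep the
photons actually go, whether they reach perfused dermis, and how much
power comes back at a given wavelength and source–detector separation.

`swirmc` answers those questions in silico for anyone designing such a
probe. It provides:

* a ten-wavelength SWIR optical-property table (μa of water, lactate,
  lipid, melanin; transport scattering of skin and hypodermal fat, all
  in mm⁻¹) and the volume-fraction mixing rules

  μa,T = V_b·μa,b + V_w·μa,w [+ V_mel·μa,mel] + (1 − V_b − V_w [− V_mel])·μa,t,
  μa,b = V_lact·μa,lact + V_lip·μa,lip,
  μa,t(λ) = 7.84·10⁸ · λ⁻³·²⁵⁵,

  with V_lact = C_lact / 100 mmol L⁻¹ (the tabulated lactate column is
  the absorption of a 100 mmol/L reference solution);
* an eight-layer semi-infinite finger model (stratum corneum →
  hypodermal fat, 13 mm × 13 mm) with per-layer blood/water/melanin
  content, g = 0.9, n = 1.4;
* a compiled weighted-photon (implicit-capture) Monte Carlo engine with
  Henyey–Greenstein scattering, Fresnel/total-internal-reflection
  boundary physics, Russian roulette, per-photon maximum-depth records
  and voxelised "banana" interaction-event maps;
* the sensor summary statistics: mean penetration depth
  D_M = ⟨max z⟩ over detected photons, relative detected power (% of
  incident), absorbance A = −log₁₀(detected/incident), and
  concentration sweeps over the physiological 1–6 mmol/L range using
  common random numbers;
* a three-criteria design optimiser (penetration past the bloodless
  layers, absorbance-vs-concentration sensitivity, minimum detected
  power) over the 10-wavelength × 3-separation study grid.

## Worked example

```python
from swirmc import (default_table, build_finger_model, SensorGeometry,
                    TransportConfig, run_simulation,
                    relative_power, mean_penetration_depth, absorbance)

table = default_table()
model = build_finger_model(table, wavelength_nm=1684, c_lactate_mmol_l=2.0)
geo = SensorGeometry(separation_mm=1.0)
res = run_simulation(model, geo, TransportConfig(n_photons=200_000, seed=7))
print(f"relative power {relative_power(res):.3f} %")
print(f"mean penetration depth {mean_penetration_depth(res):.3f} mm")
print(f"absorbance {absorbance(res):.3f} a.u.")
```

prints (numbers from this exact run):

```
relative power 0.260 %
mean penetration depth 0.808 mm
absorbance 2.585 a.u.
```

i.e. at 1684 nm and 1 mm separation about 0.26 % of the incident power
reaches the detector, and the detected photons dived on average 0.81 mm
deep — through the papillary, upper-blood-net and reticular dermis into
the deep blood net, which is what makes the signal lactate-bearing
rather than surface noise.

The same pipeline is scriptable from the shell:

```bash
swirmc sweep --photons 50000 --seed 1 --out rows.csv
swirmc score rows.csv --out scored.csv
swirmc select scored.csv
```

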