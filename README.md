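# hydromix

Quantitative analysis of mixing effects in high-solids enzymatic hydrolysis
of pretreated lignocellulose in a stirred tank. The package chains a
WIS-dependent power-law rheology through the Metzner–Otto average shear
rate, the impeller Reynolds number and a two-parameter power-number
correlation (`P0 = K1/Re + K2`) to instantaneous power draw
(`P = P0·ρ·N³·D⁵`) and cumulative mixing energy, driven by an
anchor-calibrated glucan-conversion generator. On top of that it provides
correlation fitting, enzyme-dosing and dilution stoichiometry, and a
second-order response surface of conversion versus (energy input, time).

## Layout

| module | contents |
|---|---|
| `hydromix.rheology` | power-law apparent viscosity `μ = a·WIS^b·γ^(n−1)`, Metzner–Otto shear rate, anchor calibration of the prefactor |
| `hydromix.mixing_power` | Reynolds number, power-number correlation (evaluation + least-squares fitting), power draw, baseline subtraction, trapezoidal cumulative energy |
| `hydromix.synthetic_data` | conversion-curve generator calibrated to four printed anchor conversions, slurry composition/dilution mass balances, noisy glucose sampling, simulated power-number observations |
| `hydromix.pipeline` | end-to-end trajectory (conversion → WIS → μ → Re → P0 → P → energy), mean volumetric power, enzyme-load energy comparison, response surface, conversion/energy frontier |
| `hydromix.io` / `hydromix.cli` | YAML config with validation, CSV/JSON surfaces with metadata headers, `hydromix` command line |
| `hydromix.defaults` | calibrated default parameters (see below) |

## Calibrated defaults

Defaults are pinned to the few quantitative anchors available:

- conversion generator `X(t;N,E) = min(1,(E/20)^p·(c0+c1·N))·(1−e^(−t/τ))`
  calibrated so the four anchor conversions — 57% (500 rpm, 20 FPU/g, 48 h),
  26% (25 rpm, 20 FPU/g, 48 h), 72% (500 rpm, 20 FPU/g, 96 h), 54%
  (500 rpm, 10 FPU/g, 96 h) — are matched exactly (τ ≈ 36.0 h, p ≈ 0.415);
- power-number correlation (K1, K2) = (346.7, 1.27);
- rheology: n_PL = 0.5, K_s = 11.5; the prefactor `a` is pinned by the
  2.0 Pa·s (12% WIS, 50 s⁻¹) viscosity anchor and the WIS exponent `b` is
  solved numerically so the reference run (500 rpm, 20 FPU/g, 0–96 h)
  averages 1.5 kW/m³;
- bench geometry: 130 mm tank, 70 mm pitched-blade impeller, 980 mL
  working volume, slurry density 1000 kg/m³ (configurable).

## Command line

`hydromix` (or `python -m hydromix.cli`) takes global flags
`--config PATH` (YAML, defaults to the packaged example config),
`--seed INT`, `--out DIR`, `--log-level`, `--quiet`, `--version`, and the
subcommands

```sh
hydromix --out out simulate                  # seeded synthetic fixtures
hydromix --out out trajectory --speed 500 --load 20
hydromix --out out sweep                     # all configured conditions
hydromix --out out fit-correlation out/power_observations.csv
hydromix --out out surface                   # per-load response surfaces
hydromix --out out report                    # everything above
```

`fit-correlation` accepts either direct `(re, p0)` observation tables or
motor-power measurements (`rpm, motor_power_loaded_W, motor_power_air_W`);
the latter are converted with the configured rheology and geometry after
subtracting the air (idle-motor) baseline. The packaged example config is
at `src/hydromix/data/example_config.yaml` and documents every block.

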