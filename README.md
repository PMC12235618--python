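# endortools

Analysis toolkit for nuclear decoherence of ¹⁹F/¹H nuclei hyperfine-coupled
to Gd(III) spin labels:

- **Powder ENDOR simulation & fitting** — forward simulation of the
  central-transition Mims-ENDOR doublet with point-dipole hyperfine
  coupling and optional ¹⁹F chemical-shift anisotropy, powder averaging
  over a hemispheric orientation grid, Gaussian lineshape convolution and
  optional Mims blind-spot weighting; nonlinear least-squares fitting of
  the Gd–F distance, CSA orientation angles (γ, ρ), linewidth and
  amplitude with 1σ uncertainties from the covariance matrix.
- **Relaxation-trace fitting** — stretched-exponential saturation/inversion
  recovery fits with first-moment averaging of the rate distribution
  (T̄₁ₑ), mono- and biexponential nuclear-spin-echo (NSE) decay fits with a
  configurable early-decay window, and linear regression of 1/T₂ₙ against
  1/T̄₁ₑ.
- **Decoherence theory** — the Solomon–Bloembergen–Morgan fast-relaxation
  limit and the slow-relaxation limit T₂ₙ = 2 T₁ₑ, regime classification,
  the maximum distance resolvable from the doublet splitting, and the r⁻⁶
  ENDOR-efficiency penalty.
- **Synthetic data** — seeded generators for every input the pipeline
  consumes (recovery traces, ¹⁹F NSE decays tied to the electron T₁ₑ by
  the slow limit, two-population ¹H NSE decays, noisy powder spectra),
  emitted in the same plain-text TSV formats the readers consume.
- **Pipeline + CLI** — a YAML-configured generate → fit → regress →
  theory-compare pipeline producing TSV tables and a JSON summary,
  reproducible byte-for-byte from config + seed.

## Package layout

| Module | Contents |
| --- | --- |
| `endortools.spin_physics` | constants, `SpinSystem`/`CSTensor` types, dipolar coupling, CSA-shifted Larmor frequency, ENDOR doublet frequencies |
| `endortools.endor_spectra` | `simulate_powder_spectrum`, `fit_spectrum`, Mims response |
| `endortools.relaxation_analysis` | `fit_recovery`, `mean_T1e`, `fit_nse_mono`, `fit_nse_biexp`, `regress_rates` |
| `endortools.decoherence_theory` | `sbm_t2n`, `slow_limit_t2n`, `classify_regime`, `max_resolvable_distance` |
| `endortools.synthetic_data` | seeded generators + `write_dataset` |
| `endortools.pipeline`, `endortools.cli` | orchestration, YAML config, `endortools` console entry point |
| `endortools.io` | TSV trace/spectrum readers and writers |

## CLI

```sh
# synthetic dataset (TSV traces + spectrum + manifest.json)
endortools simulate --seed 7 --out synthetic/

# fit a single trace or spectrum
endortools fit-trace synthetic/nse_19F_10K.tsv --window-max-us 200
endortools fit-spectrum synthetic/spectrum_19F.tsv --start-r 10

# full pipeline: generate, fit everything, regress, compare with theory
endortools analyze --config config.yml --seed 1 --out run1/
endortools report run1/summary.json
```

A config file only needs the keys you want to override; everything else
falls back to the bundled defaults (ge = 1.992, ¹⁹F reference Larmor
frequency 136.4 MHz, temperatures {3.7, 5, 7, 10} K, 2 % noise):

```yaml
seed: 1
noise_frac: 0.02
spin_system: {nucleus: 19F, r_GdF: 10.2, ge: 1.992, S: 3.5}
spectrum:
  enabled: true
  tau_ns: 2000
  lw_fwhm_khz: 15
regression: {through_origin: true}
```

## File formats

Traces and spectra are two-column TSV files preceded by `# key: value`
metadata lines:

```text
# kind: nse
# nucleus: 19F
# temperature_K: 10
t_us	intensity
0	1
5.12821	0.893342
...
```

Spectra use `offset_khz` (RF offset from the reference Larmor frequency)
instead of `t_us`, with `tau_ns` and `nu_ref_mhz` metadata.
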