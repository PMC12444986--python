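# eemquench

Quenching-based diagnostics for excitation–emission matrix (EEM)
fluorescence monitoring of water quality.

Each physical sample is measured twice — once as-is, once after dosing an
extrinsic fluorescence quencher (e.g. potassium iodide). A nonnegative
PARAFAC decomposition of the paired EEM stack yields per-component
intensities (Fmax), and the ratio of a component's Fmax before vs after
dosing — the **apparent F0/F** — is a composition-sensitive indicator:
compounds sharing one fluorophore but differing in quenching sensitivity
shift it even when the plain spectra cannot tell them apart. The package
uses this indicator to cluster samples, to detect abnormal compositions,
and to flag unreliable concentration predictions in real time.

## Components

| Module | Role |
| --- | --- |
| `eemquench.core` | EEM / absorbance / sample-pair types, wide-CSV I/O, manifests, regridding |
| `eemquench.preprocess` | inner-filter-effect correction, Rayleigh/Raman scatter removal + interpolation, median filter |
| `eemquench.parafac` | nonnegative HALS PARAFAC, Fmax, NNLS projection onto fixed components, split-half component selection, Tucker congruence matching |
| `eemquench.quench` | Stern–Volmer models (incl. a two-quencher interaction form), apparent F0/F, mixture closed-form oracle, peak-picked comparison |
| `eemquench.cluster` | F0/F-driven K-PARAFACs: per-cluster PARAFAC models with F0/F-homogeneous assignments |
| `eemquench.monitor` | train/predict workflow: Fmax→target calibration, z-trimmed F0/F reference ranges, outlier flags, HIX/BIX/AQY/reconstruction-error comparison indicators |
| `eemquench.synth` | physics-based synthetic EEM simulator (Gaussian compound spectra, exact low-rank structure, seeded noise) |
| `eemquench.cli` | `eemquench` command-line interface |

## CLI

Every subcommand takes `--seed` (all randomness flows from it) and
`--log-level`; logs go to stderr.

```bash
# 1. generate a synthetic mixing-design dataset from a scenario config
cat > scenario.json <<'EOF'
{"kind": "mixture_series",
 "params": {"Q_e_levels": [2.5], "grid_ex_step": 6.0, "grid_em_step": 4.76},
 "seed": 0}
EOF
eemquench simulate --config scenario.json --out data/

# 2. preprocess (IFE -> scatter removal -> median filter)
eemquench preprocess --manifest data/manifest.csv --out clean/ --no-ife

# 3. choose the component count by split-half similarity
eemquench select-components --manifest clean/manifest.csv --r-min 1 --r-max 4 --seed 0

# 4. fit PARAFAC and tabulate apparent F0/F
eemquench fit --manifest clean/manifest.csv --r 1 --out model/ --seed 0
eemquench f0f --manifest clean/manifest.csv --model model/ --out f0f.csv

# 5. cluster by apparent F0/F
eemquench cluster --manifest clean/manifest.csv --k 2 --r 1 --out clusters/ --seed 0

# 6. train + predict for real-time monitoring
eemquench train --manifest train/manifest.csv --target doc --r 3 --out bundle/ --seed 0
eemquench predict --manifest test/manifest.csv --train-dir bundle/ --out verdicts.csv

# bulk indices (HIX, BIX, AQY, reconstruction errors)
eemquench indices --manifest clean/manifest.csv --model model/ --out indices.csv
```

### File formats

* **EEM**: wide CSV — first row emission wavelengths (nm), first column
  excitation wavelengths, numeric body; masked cells are `nan`.
* **Absorbance**: two-column CSV (`wavelength_nm`, `absorbance`).
* **Manifest**: CSV with `sample_id`, `eem_original`, `eem_quenched`,
  `quencher_conc`, optional `absorbance`, `tcc`, `doc`, plus free label
  columns; paths relative to the manifest.

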