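# mocospect

Fully synthetic pipeline for studying how respiratory motion affects
SPECT-based radioembolization (SIRT) planning dosimetry, and how much a
data-driven motion-compensated reconstruction recovers.

The package simulates breathing-corrupted ⁹⁹ᵐTc-MAA SPECT acquisitions of a
digital liver/lung/tumor phantom, reconstructs them with and without motion
compensation, and quantifies the dosimetric impact per volume of interest.

## Components

| module | role |
|---|---|
| `mocospect.phantom` | seeded 4D digital phantom: liver/lungs/tumors, rigid cosine breathing of the liver complex, cohort samplers |
| `mocospect.projector` | attenuated parallel-beam projector with depth-dependent Gaussian PSF and an exact algebraic adjoint |
| `mocospect.acquisition` | step-and-shoot list-mode simulator: dual energy windows, kernel scatter surrogate, Poisson events with timestamps |
| `mocospect.respiratory` | data-driven gating: Laplacian eigenmap of rebinned list-mode frames, phase splitting, reference-phase selection |
| `mocospect.recon` | OSEM with attenuation/DEW-scatter/PSF modeling; gated 4D reconstruction; motion-compensated reconstruction via per-phase 2D affine correction of events |
| `mocospect.voi` | the seven planning VOIs (liver, lungs, tumors, PL, HR, HPL, HL) by 5 %-of-max thresholding and set algebra |
| `mocospect.dose` | activity calibration, Y-90 dose rate (dose-point-kernel convolution or local deposition), 64 h mono-exponential decay integration, activity prescription |
| `mocospect.metrics` | PDD / LSF / TN ratio / PDA / DAD, Bland–Altman, mutual-information amplitude estimation, tumor geometric predictors, paired statistics suite |
| `mocospect.pipeline` | end-to-end cohort orchestration, tables, figures, reports |

The dose engine is a deterministic dose-point-kernel substitute for Monte
Carlo particle transport; the scatter model is a broad-kernel surrogate whose
only purpose is to exercise the dual-energy-window correction pathway.

## CLI

```bash
mocospect run-all  --out out/            # desk-scale cohort study
mocospect simulate --out sim/            # phantoms + list-mode CSV + NIfTI
mocospect run-patient --patient 0 --out out/
mocospect analyze  --table out/cohort_table.csv --out report/
```

A YAML/JSON config overrides the desk preset, e.g.

```yaml
preset: desk
n_patients: 5
seed: 3
dose_engine: local
```

Outputs: `cohort_table.csv` (one row per patient: per-VOI doses for both
arms and ground truth, LSF, TN ratio, prescribed activities, PDD/PDA,
amplitude estimates, lesion features), `cohort_stats.json` (normality-gated
paired tests and Spearman screens), and PDD boxplots, Bland–Altman and
scatter figures.

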