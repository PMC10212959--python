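# coughvc

Cough-sound based vital-capacity (VC) estimation and screening, as a tested,
reusable pipeline:

1. **acoustics** — raw cough recordings (mono WAV, voltage samples) are
   band-pass filtered (140–2000 Hz, zero-phase Butterworth), a 5-s segment
   containing the loudest sample is extracted, and a session sound pressure
   level (SPL, dB re 20 µPa) is computed from ≥ 3 trials via the microphone
   sensitivity.
2. **cough_flow** — cough peak flow computed from sound:
   `CPS = (a1 + a2·age)(exp(β·SPL) − 1)`, with the algebraic inverse and a
   least-squares calibration fit of the constants.
3. **reference_vc** — LMS reference vital capacity from sex, height and age,
   and the lower limit of normal (LLN) percentile.
4. **estimator** — a from-scratch 2-input, H-hidden-unit tanh perceptron
   (4H + 1 parameters) trained to minimize RMSE, with leave-one-out nested
   cross-validation selecting H ∈ {1,2,3} without leakage. Two input
   variants: `[CPS, VC_LMS]` (NNVC_CPS) and `[SPL, VC_LMS]` (NNVC_SPL).
5. **evaluation** — squared-error tables, Spearman correlation,
   Bland–Altman agreement (limits at mean ± 2·SD) with fixed/proportional
   bias tests, Friedman + Holm posthoc, rank tests, ROC/AUC, the DeLong
   comparison of correlated AUCs, and LLN screening confusion rates.
6. **synthetic_data** — seeded two-generation cohorts (young/elderly) with
   latent true VC tied to the LMS reference, correlated cough peak flow, and
   tone-burst cough waveforms whose peak pressure encodes that flow, plus
   out-of-band contamination to exercise the band-pass.
7. **pipeline** — CLI orchestration with CSV/JSON/WAV intermediates.

## CLI

```bash
coughvc simulate --seed 7 --out runs/demo      # cohort + WAVs + truth tables
coughvc extract  --seed 7 --out runs/demo      # features.csv (SPL, CPS, VC_LMS, LLN)
coughvc model    --seed 7 --out runs/demo      # nested-CV predictions.csv
coughvc evaluate --seed 7 --out runs/demo      # report.json + figure CSVs
coughvc all      --seed 7 --out runs/demo      # everything
```

A YAML config (`--config run.yaml`) can override the microphone model,
filter band/order, flow-model constants, LMS/LLN configuration, cohort
generator settings, the H grid and training hyperparameters; `--seed` and
`--out` always win over the file.

Note: the shipped flow-model constants (`DEFAULT_CPS_PARAMS`) and the LLN
sigma/lambda defaults are documented package choices for synthetic demos —
they are **not** calibrated clinical values. Supply your own via config for
real data.

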