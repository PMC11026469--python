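# holterhrv

Analysis of annotated Holter beat streams from longitudinal canine
recordings: ECG interval summaries with rate-corrected QT (four formulas and
a data-driven selection procedure), ventricular-ectopy quantification with
Lown severity grading, time-domain / Poincaré / frequency-domain
heart-rate-variability indices, and cohort-level statistics (per-timepoint
Fisher-LSD group contrasts and Spearman screens of early indices against a
late outcome). A deterministic synthetic generator (IPFM beat streams with
band-structured modulators, ectopy grammar and full cohorts with planted
ground truth) makes every stage testable by parameter recovery.

## Data formats

* **beats-csv** — one annotated beat per row, header
  `t_r_ms,label,morph_id,p_on_ms,qrs_on_ms,qrs_off_ms,t_end_ms,fqrs`;
  times in ms from recording start, labels `N/V/S/A`, empty cells = absent.
* **manifest CSV** — `subject,group,age_months,recording_path` plus optional
  covariate columns `lvfs_24m,ctni,ntprobnp`.

## Command line

```bash
holterhrv simulate   --spec cohort.yaml --out data/           # synthetic cohort
holterhrv trace      --in beats.csv --out trace.json          # full per-recording summary
holterhrv intervals  --in beats.csv --qtc-mode per-beat --out intervals.csv
holterhrv qtc-select --manifest data/manifest.csv --group healthy --out sel.json
holterhrv arrhythmia --in beats.csv --out arr.json
holterhrv hrv-time   --in beats.csv --out hrv.json --poincare-csv points.csv
holterhrv hrv-freq   --in beats.csv --resample-hz 2.0 --epoch-min 15 --out spec.json
holterhrv cohort     --manifest data/manifest.csv \
                     --screen vlf_ms2@4,hr_bpm@4 --outcome lvfs_24m --out results/
```

A YAML config passed with `--config` mirrors all analysis flags; explicit
flags override it. Every output records the package version and a hash of
the analysis configuration.

## Analysis conventions

* NN intervals keep only RR flanked by two normal beats (dropping the
  intervals before and after every ectopic/artifact beat); a configurable
  plausibility guard of 200–3000 ms removes telemetry dropouts.
* Successive-difference indices (RMSSD, pNN50, pNN10%(meanNN), Poincaré)
  use only pairs contiguous in time across the cleaning.
* Poincaré STV is the dispersion about the identity line, so
  STV = RMSSD/√2 holds exactly; LTV is the mean-removed dispersion along it.
* Spectra: NN tachogram linearly resampled at 2 Hz (gaps > 5 s split the
  epoch), 15-min epochs with ≥ 80 % NN coverage, Welch-averaged 512-point
  rectangular segments with 50 % overlap and per-segment mean removal,
  density scaling in ms²; bands VLF 0.003–0.04, LF 0.04–0.15,
  HF 0.15–0.4 Hz; total power = VLF + LF + HF; HF n.u. = HF/(LF+HF).
* Lown grading: 5 (R-on-T) > 4b (run > 3) > 4a (doublets/triplets) >
  3b (bigeminy) > 3a (isolated polymorphic) > 2 (isolated ≥ 30/hr) >
  1 (< 30/hr) > 0; a rate of exactly 30/hr grades 2.

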