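# myotex

Quantitative analysis pipeline for preclinical muscle MRI and functional
trials: per-voxel T2 mapping from multi-echo spin-echo series, 3D
gray-level run-length texture biomarkers per segmented muscle with
proportional-volume-weighted composites, functional endpoint reductions
(torque→force, body-mass correction, eccentric-contraction force
deficit), histopathology percent-rescue composite scoring, and a
Welch-t / Benjamini–Hochberg group-comparison layer. A seeded synthetic
generator (multi-echo phantoms with patchy hyperintense lesions, cohort
tables, histology marker tables) makes every stage testable without any
external data.

## Modules

| Module | What it does |
| --- | --- |
| `myotex.synthetic_data` | Seeded phantoms (mono-exponential decay + spherical lesion patches), four-group cohorts, paired histology tables |
| `myotex.t2_mapping` | Log-linear (default) or nonlinear voxelwise fit of `S(TE) = S0·exp(−TE/T2)`, with validity masking and fit-quality maps |
| `myotex.texture_analysis` | ROI quantization, 3D run-length matrices over 13 directions, SLI (short run emphasis), HI (run-length non-uniformity), histogram entropy, per-muscle features, volume-weighted composites |
| `myotex.biomechanics` | Torque↔force via the 75 % hock-to-digit moment arm, per-kg correction, force deficit `Fd`, percent change, circumference index, group summaries |
| `myotex.histo_scoring` | Percent rescue per muscle × marker, marker averages with per-marker exclusion rules, final composite score |
| `myotex.group_stats` | Welch / pooled t (summary or raw data), BH FDR, significance (<0.05) and trend (<0.2) flagging |
| `myotex.pipeline` / `myotex.cli` | YAML-configured end-to-end runs with a reproducibility manifest |

## CLI

```bash
myotex demo-config --out cfg.yaml                 # editable demo configuration
myotex run --config cfg.yaml --seed 1 --out out/  # full pipeline bundle

# individual stages
myotex simulate phantom --config cfg.yaml --out ph/
myotex t2map ph/multi_echo.nii.gz --echoes ph/echoes.json --out t2/
myotex texture t2/ ph/labels.nii.gz --names ph/labels.csv --out features.csv
myotex simulate cohort --config cfg.yaml --out coh/
myotex biomech coh/cohort.csv --out endpoints.csv
myotex stats coh/cohort.csv --groups GRMD,GRMD+NBD --out stats.csv
myotex simulate histo --config cfg.yaml --out hi/
myotex histo hi/histo_untreated.csv hi/histo_treated.csv --out rescue.csv
```

`myotex run` emits `cohort.csv`, `functional_summary.csv`,
`functional_stats.csv`, `imaging_features.csv`, `imaging_summary.csv`,
`imaging_stats.csv`, `histo_rescue.csv`, `histo_summary.json`, and a
`manifest.json` (seed, config hash, version). Identical config + seed
reproduce the bundle byte for byte.

## Notes on texture comparisons

Per-ROI min–max quantization (the single-ROI default) rescales a
lesion-free noisy ROI into maximal salt-and-pepper texture and inverts
group contrasts; for any comparison across groups use `fixed_range`
binning so the gray-level scale is common, as the demo configuration
does. Absolute SLI/HI magnitudes depend on the quantization level count,
the direction set, and ROI size — only comparisons holding those fixed
are meaningful.
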