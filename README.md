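# blockmvpa

Synthetic block-design fMRI simulation and multivoxel pattern decoding.
The package generates multi-session BOLD data with a known category /
identity code and runs the complete analysis chain on it: localizer GLM,
fixed-size contiguous ROI construction, plateau percent-signal-change,
leave-one-session-out linear-SVM decoding, overlapping-box search-light
mapping, and the associated group statistics and stimulus pixel-correlation
checks — all validated against independent brute-force oracles, with no
real imaging data required.

## Layout

| module | purpose |
|---|---|
| `blockmvpa.design` | block schedules (triplet structure, counterbalancing) and one-back trial sequences |
| `blockmvpa.hemo` | double-gamma HRF kernel and block-regressor construction |
| `blockmvpa.simulate` | multi-session 4-D BOLD simulation with a tunable multivoxel identity code |
| `blockmvpa.glm` | OLS block GLM, contrast t/z maps, plateau (TR 4–10) percent signal change |
| `blockmvpa.roi` | greedy fixed-size contiguous ROI growth and full-cluster flood fill |
| `blockmvpa.decode` | detrend → z-score → lag-shift preprocessing, block patterns, per-condition mean subtraction, LOSO linear-SVM |
| `blockmvpa.searchlight` | 3×3×3 box search-light with per-voxel accuracy averaging (step 1) and the non-overlapping step-3 control |
| `blockmvpa.stats` | one-sample / paired / Welch t-tests, Bonferroni, Benjamini–Hochberg FDR |
| `blockmvpa.stimsim` | within/between image-set pixel-correlation similarity reports |
| `blockmvpa.io` | NIfTI / CSV / JSON readers-writers, pipeline config, end-to-end experiment driver |

## Command line

```sh
# simulate one subject (NIfTI runs, schedule sidecar, ground-truth masks)
blockmvpa simulate --seed 1 --out scratch/sim

# full synthetic experiment: localize on session 1, decode on the rest
blockmvpa run-all --seed 1 --out scratch/results

# stage-wise commands on files
blockmvpa localize --bold run0.nii --schedule schedule.csv --out roi.nii
blockmvpa decode --bold run1.nii --bold run2.nii --schedule schedule.csv --mask roi.nii
blockmvpa searchlight --bold run1.nii --bold run2.nii --schedule schedule.csv --mask mask.nii --out accmap.nii
blockmvpa stimsim --set1 a1.png --set1 a2.png --set2 b1.png --set2 b2.png --out report.json
```

`run-all` writes `accuracy.csv`, `psc.csv`, `roi_summary.csv`,
`group_stats.json`, `provenance.json` and `config.json`; every output embeds
the seed and a configuration hash. A JSON config matching
`blockmvpa.io.PipelineConfig` can be passed with `--config`.

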