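# opwf — ocular pulse-waveform analysis for LSFG MBR sequences

`opwf` is a tested, reusable pipeline for ocular blood-flow pulse-waveform
(PWF) analysis of laser speckle flowgraphy (LSFG) mean-blur-rate (MBR)
recordings: from multi-frame MBR image stacks, through cardiac-cycle
synchronization and vessel/tissue region extraction, to the PWF parameter
set (MBR/DC, MBRmax, MBRmin, AC, BOS, BOT, RR, FR, FAI, ATI, RI, S1/S2
areas, half width), neurological/behavioral assessment (NBA) scoring,
longitudinal statistics, and classification of the vessel state into a
vessel-resistance phase (VRP: BOS rising; FAI, RI, AC falling) or a
vessel-elasticity phase (VEP: BOS, BOT, FR, FAI, RI, AC all falling).

Because no raw per-animal LSFG data are public, the package ships a
first-class synthetic-data module that generates seeded acquisitions and
full longitudinal studies with known ground truth; every downstream stage
is tested against those closed forms.

## Modules

| Module | Purpose |
| --- | --- |
| `opwf.synthetic` | Pulse templates (triangular / gamma-like), seeded MBR frame-stack simulation with known vessel masks, longitudinal study simulation with VRP/VEP drift regimes and coupled NBA scores, percent-stenosis helper |
| `opwf.segmentation` | ROI cropping, Otsu/quantile vessel–tissue segmentation of the time-mean map, MA/MV/MT region-mean series extraction |
| `opwf.waveform` | Cardiac-cycle synchronization (autocorrelation period + minima onsets), extrema, blowout score/time, rising/falling rates, FAI, ATI, RI, quadratic-fit S1/S2 areas, `compute_pwf` |
| `opwf.nba` | The 11-item NBA rubric (max 19 alive, 20 = death), validation, scoring, daily aggregation |
| `opwf.stats` | Baseline normalization, Tukey outlier removal, RM-ANOVA/Friedman with normality gate, Pearson/Spearman correlation, multivariate OLS with standardized betas, trend fitting and VRP/VEP phase classification |
| `opwf.io`, `opwf.pipeline`, `opwf.cli` | CSV/TIFF/YAML round-tripping, the five-stage pipeline with a hashed artifact manifest, and the `opwf` CLI |

## CLI

```bash
opwf run --out out/ --seed 1          # full pipeline: simulate -> segment -> analyze -> score-nba -> stats
opwf simulate --out out/ --seed 1     # synthetic study + exemplar frame stack
opwf segment  --out out/ --roi 8,8,48,48
opwf analyze  --out out/ --n-frames 30
opwf score-nba --in out/nba.csv --out out/nba_rescored.csv
opwf stats    --out out/ --phase-window 1:19
```

All stages also accept `--config <yaml>` (see `opwf.io.load_pipeline_config`
for the schema: `out_dir`, `seed`, a `study:` block mirroring
`StudyConfig`, and an `analysis:` block with `n_frames`,
`segmentation_method`, `roi`, `vrp_window`, `vep_window`, `alpha`).
Outputs are plain CSV/JSON plus float32 TIFF stacks; `manifest.json` lists
every artifact with a SHA-256 hash, and a fixed config + seed reproduces
identical hashes.

## Conventions

* Cycle onset is the waveform minimum; integrals run against the `y = 0`
  baseline; ties at the half level count as "above"; a flat wave has
  BOT = 100 by convention.
* ATI is defined as `100 x time-to-peak / F` (conventional
  acceleration-time construction).
* Coordinates are 0-based, half-open, row-major; MBR is in arbitrary units.
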