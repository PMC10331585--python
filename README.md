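# nmjscreen

Analysis pipeline for a multilevel phenotypic drug screen in a zebrafish
disease model, plus synthetic generators for every input it consumes.

The pipeline mirrors a four-stage funnel:

1. **Primary behavioral screen** (`behavior_scoring`) — per-plate Z′-factor
   quality control, median normalization by wild-type controls, per-fish
   robust z-scores (median/MAD), and four-way drug classification
   (TOXIC / NON_HIT / HIT_A / HIT_B).
2. **Rescreen** (`behavior_scoring.rescreen`) — normalized percent
   activation (NPA, 0 = morphant median, 100 = wild-type median) with an
   inclusive 50% pass cutoff, plus dose–response summaries with toxicity
   flagging.
3. **Target-recurrence network filter** (`target_network`) — drug→target
   pairs restricted to hits, target–target edges kept at confidence ≥ 0.7,
   target recurrence counts, and partition of hits into favorites
   (recurrent-target drugs), unknowns (no annotated target), and others.
4. **NMJ image quantification + cellular refinement** (`nmj_imaging`,
   `cellular_scoring`) — body detection, 7-px ROI shrink, AChR spot
   detection, axonal-region segmentation, spot/axon co-localization,
   spinal-cord extraction by 20-px median smoothing, per-axon skeleton
   lengths (√2 diagonal rule), <70 µm short-axon fraction, and per-drug
   3-parameter z-scoring against wild-type embryos with final-hit calls.

`synthetic_data` generates behavioral screen tables (96-well layout,
controls in columns 1 and 12, quadruplicate treatments), drug–target
tables with designed recurrence, and two-channel NMJ TIFFs with full
ground truth. `screen_data` holds the data model and CSV I/O. `pipeline`
wires everything into a deterministic end-to-end demo.

## CLI

A single `nmjscreen` executable with subcommands:

```bash
nmjscreen simulate --n-drugs 80 --seed 1 --out screen.csv
nmjscreen score-screen --table screen.csv --out scores.csv --report report.json
nmjscreen rescreen --table rescreen.csv --npa-cutoff 50 --out npa.csv
nmjscreen netfilter --pairs pairs.tsv --edges edges.tsv --hits hits.txt --out-dir net/
nmjscreen simulate-images --n-images 8 --seed 1 --out-dir imgs/
nmjscreen quantify-images --in-dir imgs/ --out metrics.csv
nmjscreen cellscore --metrics metrics.csv --out scores.csv --stats-out stats.json
nmjscreen demo --seed 1 --out-dir demo/          # full synthetic funnel
nmjscreen dose-response --table 1.0 d1.csv --table 10.0 d10.csv --out dr.json
```

`demo` accepts a YAML config covering every pipeline knob (see
`nmjscreen.pipeline.PipelineConfig`); unknown keys are rejected.

## File formats

- Screen tables: CSV with columns
  `plate,row,column,fish_index,group,drug_id,alive,distance_m,excluded`.
- Networks: TSV `(drug_id, target_id)` and `(target_a, target_b, confidence)`;
  exports as `nodes.tsv` / `edges.tsv` / `report.json`.
- Images: 2-channel 16-bit TIFF (channel 0 = axon marker, channel 1 = AChR
  marker) with a JSON sidecar (`pixel_size_um`, `embryo_id`, `group`,
  `drug_id`).
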