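# calscreen

Analysis toolkit for phenotypic high-content calcium-imaging drug screens,
plus the downstream assays that characterize screening hits. It covers:

- **Synthetic data generation** — ground-truthed multi-channel time-lapse
  image stacks of ratiometric-sensor cells (donor/acceptor + far-red nuclear
  channel) for whole 384-well plates, dose–response tables and
  sandwich-immunoassay plates with calibration standards. Every generator is
  a pure function of (parameters, seed).
- **Segmentation** — nuclei detection (Otsu + distance-transform watershed),
  seeded cell-boundary growing on the cytoplasmic signal, strict
  border-touching edge-cell exclusion, and field-level mean intensity for
  dye-based (e.g. TMRM) readouts.
- **Calcium kinetics** — per-cell acceptor/donor ratio traces,
  dF/F0 = (F − F0)/F0 normalization against the pre-stimulus baseline,
  post-stimulus peak amplitude, responder filtering (default peak ≥ 0.1),
  and responder-mean well summaries.
- **Screening** — vehicle (DMSO) normalization (vehicle mean ≡ 1), replicate
  aggregation, hit calling at normalized readout < 0.9 (strict), positive
  control plate QC, toxicity-interference well exclusion, and one-way ANOVA
  with Dunnett's many-to-one post hoc plus significance stars.
- **Pharmacology** — four-parameter-logistic machinery (predict /
  closed-form invert / least-squares fit) for EC50/IC50 and immunoassay
  standard-curve back-calculation, vehicle-normalized secretion profiles
  (Aβ38/40/42, Aβ42/40 ratio, sAPPα/β), mechanism-of-action classification
  (γ-inhibitor / γ-modulator / inverse modulator / β-cleavage reduction /
  no effect), and structure–activity grouping by substituent class.
- **CLI / pipeline** — a `calscreen` command with `simulate`, `screen`,
  `quantify-calcium`, `fit-dose`, `quantify-elisa`, `classify`, `report` and
  `run-all` subcommands, seeded and reproducible end to end.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (dF/F0 exactness,
segmentation recovery vs ground truth, screening sensitivity/specificity,
null-plate type-I calibration, 4PL recovery, Dunnett oracle equivalence,
mechanism truth table, EC50 self-consistency).

## Quick start

```bash
# full demo pipeline (simulate -> segment -> quantify -> screen -> fit ->
# classify -> report), deterministic under a fixed seed
calscreen run-all --seed 1 --out-dir results/demo

# simulate a plate to TIFFs, then screen it
calscreen simulate --plate-map plate.csv --out-dir scratch/stacks --seed 7
calscreen screen --plate-map plate.csv --stacks-dir scratch/stacks \
    --threshold 0.9 --responder-theta 0.1 --out hits.csv

# dose-response fitting from a CSV (compound_id,conc_uM,replicate,response)
calscreen fit-dose --csv dose.csv --direction up --out fits.csv
```

Plate maps are CSV with columns
`address,role,compound_id,concentration_uM,replicate_group`, where role is
one of `test`, `vehicle`, `positive_control`, `untreated`.

## Layout

```
src/calscreen/
  core.py       plate maps, acquisition schedules, result I/O
  synth.py      synthetic stacks / plates / dose tables / immunoassays
  segment.py    nuclei + cell segmentation, edge exclusion, field intensity
  kinetics.py   ratio traces, dF/F0, peaks, well summaries
  screen.py     normalization, hit calling, QC, ANOVA + Dunnett
  pharm.py      4PL machinery, profiles, mechanism classes, SAR
  pipeline.py   orchestration and report rendering
  cli.py        click-based command line
```
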