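# audiogain

Analysis pipeline for auditory evoked potentials and quantitative cortical
histology in a two-genotype mouse cohort, together with a synthetic-cohort
generator so the whole chain is testable end to end without any external
data.

The pipeline covers:

- **Waveform features** — ABR sweeps are bandpass filtered (100–3000 Hz,
  5th-order Butterworth, zero-phase by default) and trial-averaged; ABR
  wave I amplitude is measured from stimulus onset to the first post-onset
  peak, and cortical AEP components are window extrema (P1: max on
  15–30 ms, N1: min on 25–60 ms, P2: max on 60–110 ms). Central auditory
  gain is the AEP complex amplitude (P1−N1 or N1−P2) divided by ABR wave I
  amplitude.
- **Audiometry** — per-ear ABR threshold detection across a level series
  (peak-to-peak response criterion against pre-stimulus noise, with
  supra-threshold consistency), hearing classification against a
  wild-type cutoff (mean + 2.5 SD of WT ear thresholds, strict
  inequality), animal-level dB HL, age-window summaries of longitudinal
  measurements, and impairment prevalence.
- **Histology** — PV⁺ density over a full region polygon, NeuN⁺ density
  within a pia-to-white-matter rectangular strip through the region centre
  (5 % of region area), normalized laminar depth along the local pia
  normal, and equal-depth bin profiles (5/10/20 bins).
- **Statistics** — Wilcoxon rank-sum and signed-rank tests (exact
  enumeration at small n, tie/continuity-corrected normal approximation
  otherwise), Spearman rank correlation (exact permutation for n ≤ 10),
  pooled-variance and paired t tests, and one-way ANOVA with Fisher's LSD
  post-hoc tests gate-kept on omnibus significance. All tests two-tailed,
  α = 0.05.
- **Synthetic cohorts** — seeded generator producing ground-truth
  manifests, multi-trial ABR/AEP sweep sets (Gaussian-bump templates with
  linear amplitude growth above threshold, optional multiplicative AEP
  gain in impaired animals), and Poisson cell maps whose PV density
  declines linearly with hearing loss.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked-example
arithmetic on published counts plus Monte-Carlo recovery, geometry-oracle
and statistical-calibration suites); the full run takes a few minutes
because it executes ~200 replicate pipelines.

## CLI

```bash
audiogain simulate --seed 1 --out runs/sim            # cohort manifest
audiogain report   --seed 1 --out runs/full           # full pipeline
audiogain classify --audiograms aud.csv --genotypes geno.csv --out status.csv
audiogain prevalence --audiograms aud.csv --genotypes geno.csv --out prev.json
audiogain histo    --cells cells.csv --geometry geo.json --marker PV --out d.json
audiogain stats    --test anova-lsd --data tidy.csv --out res.json
```

`audiogain report` writes the result bundle (audiograms, hearing status,
prevalence, evoked-potential features and gains, densities, laminar
profiles, statistics, sample accounting) as plain CSV/JSON files; runs are
bit-reproducible given the config and seed.

## Layout

```
src/audiogain/
  synth.py       # synthetic cohort generator + file I/O
  waveforms.py   # SweepSet, filtering, averaging, feature extraction
  audiometry.py  # threshold detection, classification, prevalence
  histology.py   # densities, strip sampling, laminar depths
  stats.py       # rank tests, Spearman, t tests, ANOVA + LSD
  pipeline.py    # end-to-end orchestration and result tables
  cli.py         # click CLI (`audiogain ...`)
```
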