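# invisidec

Multivoxel decoding pipeline for object categories presented under normal
viewing and under two invisibility-inducing methods (continuous flash
suppression, CFS; chromatic flicker fusion, CFF).  The package re-implements
the full analysis chain as tested, reusable components and exercises it
end-to-end on synthetic multivoxel data with the statistical structure the
analysis assumes:

- **`invisidec.design`** — randomized run-order generation minimizing
  first- and second-order category-transition predictability (48 trials per
  run = 8 exemplars x 2 colors x 3 methods; 2-s trials, 6/8-s ISIs, runs
  padded to 242 two-second volumes).
- **`invisidec.synthetic_data`** — multi-subject, ROI-structured voxel
  pattern simulation with planted, method-dependent category coding axes
  (tunable cross-method overlap `rho`), double-gamma HRF time series with
  AR(1) noise, and behavioral records (chance guessing, rare breakthrough,
  near-ceiling visible performance).
- **`invisidec.qc`** — behavioral exclusions: breakthrough trials, the
  >75% guess-accuracy binomial run exclusion (exact tail probabilities),
  and the minimum-usable-exemplars rule.
- **`invisidec.decoding`** — cross-exemplar leave-one-run-out and
  cross-method fold plans, run x method x category x exemplar-set pattern
  averaging, linear SVM classification, pooled-confusion d-prime scoring
  with log-linear correction.
- **`invisidec.group_inference`** — one-sided t-tests against chance,
  Benjamini-Hochberg FDR, visible-ROI gating of all invisible and
  cross-method families, and directional paired method contrasts.
- **`invisidec.io`** — NIfTI volumes and label parcellations (with
  bilateral L/R ROI assembly), BIDS-events-like TSVs, results tables, JSON
  reports.

## Command line

```sh
invisidec design   --subjects 1 --runs 8 --candidates 10000 --seed 1 --out out/design
invisidec simulate --scenario paper_like --subjects 17 --runs 8 --seed 1 --out out/data
invisidec qc       --data-dir out/data --out out/qc
invisidec decode   --data-dir out/data --regimes within:VIS,within:CFS,within:CFF --out out/decode
invisidec analyze  --results out/decode/results.tsv --out out/analysis
invisidec report   --results out/decode/results.tsv --out out/report.json
invisidec pipeline --scenario paper_like --subjects 17 --runs 8 --seed 1 --out out/pipeline
```

`analyze` emits the within-method group table (per-ROI mean d-prime, t,
FDR-corrected significance), the cross-method tables, the paired-contrast
table, and a machine-readable JSON report.  Scenario presets: `paper_like`
(visible signal everywhere, CFS signal in lateral-occipital ROIs, CFF
signal in lingual/fusiform/precentral ROIs, axis overlap high only in
posterior-occipital ROIs), `null` (no signal), `full_transfer`
(identical axes across methods).

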