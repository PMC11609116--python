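# elscape

Channel-level, data-driven **energy-landscape analysis** of multichannel
task-state hemodynamic (fNIRS-style) signals, as a tested, reusable Python
pipeline:

1. **synth** — synthetic two-group cohort generator (60 + 60 style) whose
   binarized 7-channel dynamics follow group-specific Boltzmann
   distributions with planted landscape differences (more local minima,
   smaller energy gaps, smaller basin-size spread, longer global-minimum
   dwell in the patient-like group).
2. **io** — TSV + JSON-sidecar recording format, zero-phase Butterworth
   band-pass (0.01–0.2 Hz), stimulus segmentation (happy/calm/fear/full);
   optional SNIRF (HDF5) reader.
3. **chansel** — CANDECOMP/PARAFAC tensor decomposition (seeded ALS with
   restarts) of the cohort tensor (time × channels × subjects) and channel
   ranking by row means of the Pearson correlation matrix of the
   channel-mode factors; top-7 selection per stimulus.
4. **pmem** — mean-threshold binarization, empirical state statistics,
   pairwise maximum-entropy (Ising) fitting by pseudo-likelihood ascent
   (learning rate 0.1, stopping tolerance 5e-6) or exact-gradient moment
   matching, independent-model baseline, and the accuracy index
   r = (K1 − K2)/K1 from base-2 KL divergences.
5. **landscape** — energies on the 2^C hypercube, strict local minima,
   steepest-descent basins, Metropolis random walks (20 000 steps) and
   dwell/occupancy features; shared ("major") states across landscapes.
6. **stats** — Shapiro–Wilk normality gating into two-way ANOVA (+ Tukey
   HSD) or Kruskal–Wallis group/stimulus tests; demographics block
   (t-tests + chi-square).
7. **classify** — RBF-kernel SVM (class-balanced, tol 1e-3) with
   leave-one-out cross-validation; min–max scaling and the (C, γ) grid
   search are fit inside each training fold (nested protocol; a leaky
   `flat` mode is provided for comparison).  Connectivity features (upper
   triangle of J) vs energy features (128 state energies + 4 landscape
   features).

## CLI

```bash
elscape simulate --out cohort/ --seed 1 --n-per-group 30
elscape preprocess --in cohort/hc000.tsv --band 0.01 0.2 --segment fear --out fear.tsv
elscape select-channels --cohort cohort/ --category fear --rank 8 --k 7
elscape fit-pmem --states states.tsv --mode pl --lr 0.1 --tol 5e-6 --out model.json
elscape landscape --model model.json --steps 20000 --seed 1
elscape stats --features features.tsv --out report.json
elscape classify --cohort cohort/ --features energy --stimulus fear --seed 1
```

## Notes and caveats

- Spin convention is internal {−1, +1}; display strings map +1 to "1" with
  the first (highest-ranked) channel leftmost.
- Synthetic recordings carry the planted binary dynamics broadband, so the
  state-level analysis binarizes unfiltered signals; the band-pass is
  applied for channel selection (and for real hemodynamic data).
- Group statistics treat each participant × stimulus row as independent
  (matching the residual degrees of freedom the method reports, e.g.
  F(1, 472) for 2 × 4 × 60); within-participant correlation across stimuli
  is a known caveat, and the "full" segment is by construction correlated
  with the other three.
- Real clinical recordings are not public; all cohort-level numbers in the
  tests are properties of the synthetic generator, not reproductions of the
  study's clinical values.
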