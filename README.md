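# nucphase

Nucleosome phasing analysis for paired-end MNase-seq fragments.

Micrococcal nuclease digestion followed by paired-end sequencing yields
millions of nucleosome-protected DNA fragments together with their exact
lengths. Restricting to core-particle-length fragments (147–152 bp) turns
each fragment into a precise measurement of one nucleosome's position in one
cell. `nucphase` implements the analyses that extract chromatin organisation
from such data:

- **Distance auto-correlation (DAC)** — for every pair of nucleosome anchor
  positions on a chromosome, the product of their occurrence counts is added
  to the histogram bin of their separating distance:

  DAC(d) = Σ_{i<j, x_j − x_i = d} c_i · c_j,

  summed over left and right fragment anchors ("both strands"). Two
  positions occupied 5 and 10 times contribute 5 × 10 = 50 — multiplicity
  weighting makes the statistic sensitive to local re-positioning, unlike
  the coincidence-number variant (each occupied position counted once),
  which is available as an option. The **distance cross-correlation (DCC)**
  is the analogous histogram between two datasets.
- **Periodicity estimation** — peaks of the DAC are regressed on their
  harmonic indices; the slope estimates the nucleosome repeat length
  (~162 bp in budding yeast) from the main peaks and the DNA helical
  period (~10.25 bp) from the sub-peak fine structure, which arises because
  overlapping alternative positions within a cluster are rotationally
  related. An envelope diagnostic scores discontinuities in the sub-peak
  envelope, the signature of coexisting array spacings.
- **Occupancy and dyad maps** — per-bp coverage normalized to a genome-wide
  mean of 1, TSS-aligned composite profiles, and per-locus dyad (fragment
  midpoint, round-half-up) histograms.
- **Sequence patterns** — WW/SS dinucleotide profiles of center-aligned
  fragments with linker extension (the ~10-bp rotational positioning
  signal), MNase cleavage consensus around fragment ends (W|W preference),
  the end-filtered robustness subset, ±1/+2 nucleosome selection by dyad
  window, and induction-based gene grouping.
- **Simulation** — cell ensembles of nucleosome arrays with configurable
  spacing mixtures, rotational cluster jitter on the 10.25-bp lattice,
  genomes with planted periodic WW/SS signal, and MNase-like biased cuts;
  every run emits a ground-truth record for recovery tests.

## Worked example

Simulate an ensemble of 2000 cells carrying 162-bp-spaced arrays whose
nucleosomes jitter between rotationally related positions, then recover
both periods from the DAC:

```python
import nucphase as np_

cfg = np_.ArraySimConfig.uniform(spacing=162, n_cells=2000, seed=1)
fragments, truth = np_.simulate_arrays(cfg)          # 23698 fragments

hist = np_.compute_dac(np_.position_counts(fragments, "start"), 1000)

main = np_.find_peaks(hist, smoothing_window=21, search_range=(80, 1000))
print(np_.fit_period(main.positions, np_.assign_indices(main.positions, 162)).summary())
# period fit: slope = 161.5354 bp/index, intercept = 0.81 bp, r = 0.9989, n = 27

sub = np_.find_peaks(hist, smoothing_window=3, search_range=(5, 70))
print(list(sub.positions))
# [10, 20, 30, 41, 51, 61]
print(np_.fit_period(sub.positions, np_.assign_indices(sub.positions, 10.25)).summary())
# period fit: slope = 10.2571 bp/index, intercept = -0.40 bp, r = 0.9999, n = 6
```

The main-peak slope recovers the planted 162-bp repeat to within a base
pair; the sub-peaks sit on the 10/10/10/11-bp lattice and regress to the
10.25-bp helical period.

The same analyses are available from the shell:

```sh
nucphase simulate arrays --preset uniform --n-cells 2000 --seed 1 --out-prefix sim
nucphase dac --fragments sim.fragments.bed --max-distance 1000 --out dac.tsv
nucphase fit-period --histogram dac.tsv --mode sub --out fit.json
nucphase verify-paper   # runs the five built-in worked checks
```

Subcommands: `filter`, `dac`, `dcc`, `fit-period`, `occupancy`,
`composite`, `dyads`, `dinuc`, `mnase-ends`, `plus-one`, `simulate`,
`verify-paper`. Every run writes a JSON parameter manifest beside its
outputs; identical manifests give identical outputs.

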