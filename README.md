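# lacoresect

Single-cell analysis of DNA double-strand-break (DSB) end resection from
live-cell fluorescence movies, for the LacO/LacI-GFP "resection ruler"
assay in fission yeast, plus the orthogonal population-level
ApoI-protection qPCR assay.

## The problem

Long-range 5' end resection converts DSB ends into kb-scale ssDNA tracts
and commits a break to homologous recombination. Population assays blur the
cell-to-cell variation in resection speed. In the imaging assay this
package analyzes, each cell carries one inducible HO cut site with a
10.3 kb LacO array 3.57 kb downstream, bound by LacI-GFP. After cutting,
Rad52-mCherry loads on the resected end (a focus appears at the array), and
as resection proceeds through the array the GFP focus fades and vanishes.
The time from Rad52-focus appearance to total GFP-focus loss is the time to
resect the full 13.87 kb, giving a per-cell rate:

    rate [kb/hr] = 13.87 / (duration_min / 60)

A duration of 150 min gives 5.55 kb/hr; 140 min gives 5.94 kb/hr. Cells
whose GFP focus survives the whole 5-hr acquisition are *censored*: their
rate is only bounded above, by 13.87/5 ≈ 2.8 kb/hr. Medians are taken over
uncensored cells per genotype, and genotype differences are assessed with
two-tailed t-tests under a Bonferroni correction.

## What the package does

* `lacoresect.geometry` — the cassette layout and duration → rate
  conversion (including censored upper bounds).
* `lacoresect.simulate` — a seeded synthetic-data generator: ground-truth
  event tables, rendered two-channel 5-D movies (Gaussian PSF, shot/read
  noise, photobleaching), and qPCR plates, so every downstream stage is
  testable without external data.
* `lacoresect.focus_quant` — LoG focus detection, subpixel centroids, and
  cylinder/shell background-subtracted photometry on full Z-stacks.
* `lacoresect.event_calling` — on-target co-localization, Rad52 onset,
  irreversible GFP loss, censoring, a photobleach control on uncut cells,
  and manifest blinding/randomization.
* `lacoresect.rate_stats` — per-genotype rate tables, medians with "N.D."
  handling, Welch/Student pairwise tests with Bonferroni correction, and a
  dot-plot report.
* `lacoresect.calibration` — focus intensity → molecule-count intervals via
  a reference focus of known stoichiometry, and molecule counts → minimum
  resected ssDNA per sister chromatid.
* `lacoresect.qpcr` — ΔΔCq ApoI-protection fractions, HO cut fraction, and
  population resection rates from multi-site half-max timing.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate a small experiment (12 cut cells each of a WT-like and a fast
rev7∆-like genotype), quantify, call events and compare genotypes:

```python
from lacoresect.config import RunConfig, save_config
from lacoresect.simulate import SimulationConfig, GenotypeRateModel

cfg = RunConfig()
cfg.simulation = SimulationConfig(
    n_cells=12, cut_fraction=1.0, n_frames=31, z_slices=25,
    genotype_rate_model={"WT": GenotypeRateModel(7.6),
                         "rev7d": GenotypeRateModel(10.4)},
    seed=1)
save_config(cfg, "demo.yaml")
```

```sh
lacoresect pipeline --config demo.yaml --out-dir demo_run
```

prints

```
genotype  n  n_censored  median_kb_per_hr label  max_upper_bound_kb_per_hr
      WT 12           0          7.250227  7.25                        NaN
   rev7d 12           0         11.888571 11.89                        NaN
```

and writes `comparisons.csv`:

```
genotype_a,genotype_b,n_a,n_b,t,p_raw,p_adj,m,significant
WT,rev7d,12,12,-5.035428342632231,0.0001199502864926496,0.0001199502864926496,1,True
```

Read: the recovered WT-like median rate is 7.25 kb/hr against a generator
median of 7.6 (frame quantization and sampling at n = 12 account for the
difference); the fast genotype recovers 11.89 against 10.4; one Welch
t-test (m = 1, so the Bonferroni-adjusted p equals the raw p) separates the
two at p ≈ 1.2 × 10⁻⁴. Each subcommand (`simulate`, `quantify`, `call`,
`rates`, `qpcr`, `blind`) also runs standalone on the documented CSV/TIFF
formats; `lacoresect init-config` writes the default configuration.

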