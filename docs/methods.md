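# Methods

## The assay and its statistic

`lacoresect` analyzes a live-cell assay for long-range 5' end resection of a
single DNA double-strand break (DSB) in fission yeast. A reporter cassette
carries an HO endonuclease cut site (HOcs) and, 3.57 kb away, a 10.3 kb
LacO array bound by LacI-GFP, visible as one bright focus. After the break,
Rad52-mCherry loads on the resected end and forms a focus at the array
position; as resection converts the array to ssDNA, LacI-GFP is displaced
and the GFP focus fades to nothing. The per-cell statistic is

    rate = total_distance_kb / (duration / 60)   [kb/hr]

where `total_distance_kb = 3.57 + 10.3 = 13.87` and `duration` is the time,
in minutes, from the first frame with a detectable on-target Rad52 focus to
the first frame with total GFP-focus loss. A cell whose GFP focus survives
the whole movie is **censored**: its rate is bounded above by
`13.87 / (window/60)`; for the standard 5-hr window this bound is
~2.8 kb/hr. Censored cells never enter averages or tests; a genotype whose
events are mostly censored is reported "N.D.".

Two worked numbers fix the convention: durations of 150 and 140 min give
5.55 and 5.94 kb/hr at 2-decimal display rounding (values are kept at full
precision internally and rounded only for reports).

## Simulation model (module `simulate`)

The generator produces ground-truth event tables, rendered movies and qPCR
plates under the same statistical structure the analysis assumes.

**Event model.** Each cell is cut with probability `cut_fraction`
(default 0.15, matching the induction efficiency of the assay) at a time
uniform on a 2-hr window. Resection is two-phase:

1. *Initiation*: a short tract (`initiation_tract_kb`, default 0.3 kb,
   matching the <300 nt of resection needed before a Rad52 focus becomes
   visible) is traversed during the Rad52 visibility delay, uniform on
   30–60 min after cutting. This is why ApoI protection at a site 168 nt
   from the cut precedes Rad52-focus appearance in the simulated qPCR data.
2. *Long-range*: from the Rad52-visibility time the front advances at a
   constant per-cell rate drawn from a genotype-specific log-normal
   (medians 7.6, 13.9, 10.4 kb/hr for WT-, crb2∆- and rev7∆-like models;
   an exo1∆-like model uses median 1.5 kb/hr, comfortably below the 5-hr
   censoring bound, since the real rate is only known to be <2.8 kb/hr).
   The log-sd defaults to 0.25; single-cell dispersion is not quantified
   numerically anywhere we could anchor it, so it is a free parameter.

GFP loss occurs when the long-range front passes the distal array end:
`gfp_loss = rad52_visible + 60·(13.87 − 0.3)/rate`. Measuring the duration
from Rad52 onset therefore recovers the long-range rate with a ~2% upward
bias (the initiation tract is excluded from the traversed distance but the
full 13.87 kb is used in the conversion) — negligible against frame
quantization.

**Rendering.** Each cell is a 28-px tile in a grid; the GFP focus intensity
is `photons × ds_fraction × (1 − bleach)^frame`, where `ds_fraction` is 1
until the front reaches the proximal array edge and declines linearly to 0
at the distal edge. The Rad52 focus appears at its visibility time at half
its plateau (so it is detectable from the first visible frame, the
operational meaning of "visible") and grows with the resected tract. Foci
are anisotropic Gaussian PSF blobs (σ_xy 1.1 px, σ_z 1.5 slices) over a
uniform cytoplasmic background (30 photons/voxel); the camera applies
Poisson shot noise, gain 1, offset 100 and Gaussian read noise (SD 5),
roughly an EMCCD operating regime. Defaults follow the acquisition
protocol: 10-min frames, 25 z-slices at 0.26 µm, 31 frames (5 hr).

Free imaging parameters were set once to a realistic regime: 5000 photons
in the GFP focus and 2500 at the mCherry plateau give integrated-intensity
SNR ≈ 50 and ≈ 15 respectively. Photobleaching is 1.5% per exposure,
multiplicative and identical in cut and uncut cells; over a 5-hr movie an
uncut focus retains ~63% of its intensity, far above the loss threshold, so
the photobleach control has a clean null, while a 10× bleach rate drives
uncut foci below the noise floor and must flag the dataset.

**What the simulator does not model:** cell growth, motility and division
(the mitotic GFP dip is handled downstream by the irreversibility guard,
not generated by default), spectral bleed-through, chromatic shift, focus
z-drift, replication-associated spontaneous DSBs (an optional decoy-focus
mode places off-target mCherry foci for co-localization testing), and any
within-cell rate variation. Passing recovery tests therefore demonstrates
that the measurement chain is unbiased under the assay's own model, not
that it is robust to every real-data artifact.

## Focus quantification (module `focus_quant`)

Detection is automated (the original scoring was manual on blinded,
contrast-fixed images): a Laplacian-of-Gaussian band-pass over the full 3-D
volume, local maxima above a threshold expressed in multiples of the robust
SD (1.4826·MAD) of the filtered volume (default 5) so it transfers across
noise levels. Candidates within 2 voxels of the volume border are discarded
because boundary reflection inflates the filter response there. Subpixel
centers are background-subtracted intensity-weighted centroids in a
5×7×7-voxel window.

Intensities are measured in a cylinder approximating the PSF around the
subpixel center — radius 2.4 px (≈ the Rayleigh radius at NA 1.2 converted
to 0.107 µm pixels), half-height 2 z-slices — with a concentric cylindrical
shell (gap 1 px, width 2 px, same z extent, volumetric) supplying the
background: `integrated = Σ(cylinder) − n_cyl · median(shell)`. The shell
statistic is the median for robustness to nearby foci. Voxel membership is
decided at center-of-voxel resolution, which is exactly testable against a
brute-force enumeration oracle and adequate at this sampling; partial-voxel
integration is deliberately not attempted. Measurements whose shell crosses
the image border are flagged invalid, not clipped silently. The shell's
robust SD is propagated to the SD of the integrated value
(`σ_voxel · sqrt(n_cyl(1 + n_cyl/n_shell))`) and reused downstream as the
noise floor.

Traces track the brightest persistent focus per ROI (nearest-to-previous
association, ROIs supplied externally or by the simulator truth table);
frames without a detectable focus are still measured at the last known
center so disappearance is quantified, not just noted.

## Event calling (module `event_calling`)

* **On-target**: the Rad52 focus must lie within 3 px (xy) of the GFP focus
  in ≥ 2 frames where both are detected.
* **Onset**: first frame beginning a run of ≥ 2 on-target Rad52 detections;
  the persistence rule suppresses single-frame noise, and restricting the
  clock to array-colocalized detections keeps spontaneous DSB foci
  elsewhere in the nucleus from starting it.
* **Loss**: first frame at which the GFP intensity falls below
  `k · noise_sd` (default k = 3) *and stays below for every later frame*.
  The irreversibility guard absorbs single-frame dropouts at low SNR and
  the transient GFP dip at mitosis without explicit mitosis detection. The
  original criterion was visual disappearance; k·SD is the stated,
  configurable stand-in.
* **Censoring**: no qualifying loss frame ⇒ the event carries only its
  observed window. Censoring is consistent under window extension: the same
  trace continued past the true loss time becomes uncensored.

Blinding support mirrors the acquisition workflow: manifests are
deterministically permuted under a seed, identifying columns are moved to a
key file, and identical display-contrast metadata is attached to every
blinded row.

## Rate statistics (module `rate_stats`)

Medians are computed on uncensored rates only, reported next to the
censored count. Pairwise genotype comparisons are two-tailed two-sample
t-tests — Welch's by default (the variance structure across genotypes is
unknown; Student's is available via `equal_var=True`) — with Bonferroni
correction `p_adj = min(1, p·m)`. The family size m is the number of pairs
actually tested in the invocation, matching per-figure comparison families;
pairs lacking two uncensored rates per side are skipped with a notice and
do not inflate m. Replicates are pooled before testing. A survival-analysis
treatment of censored durations would be a natural extension and is
deliberately out of scope.

## Molecule calibration (module `calibration`)

A reference focus of known stoichiometry (the spindle-pole-body protein
Sad1, 450–1030 molecules per focus) imaged under identical parameters fixes
an intensity-per-molecule interval by range inversion; focus intensities
convert to molecule intervals linearly. A configured imaging signature
mismatch is a hard error because cross-exposure linearity cannot be
assumed. The minimum resected tract per sister is
`(molecules / n_sisters) · nt_per_molecule`, with `nt_per_molecule = 6` and
`n_sisters = 2` by default — the parameterization under which ~30 detected
molecules imply ≥ 90 nt of ssDNA per sister. The per-molecule footprint is
contested in the literature, so it is configuration, not a constant.

## qPCR resection assay (module `qpcr`)

ssDNA generated by resection resists ApoI digestion, so amplification
across an ApoI site measures the resected fraction. With amplification
efficiency E (default 2.0, configurable):
`protection = E^−[(Cq_dig − Cq_mock) − (Cq_ctrl_dig − Cq_ctrl_mock)]`,
clipped to [0, 1] with a flag. The mock digestion and the control locus
(Ncb2, no ApoI site in the amplicon) normalize template load and plate
offsets — the statistic is invariant to a constant shift of all four Cq
values. The cut fraction from a HOcs-spanning amplicon is
`1 − E^−ΔΔCq(t vs t0)`, referenced to the earliest timepoint. The
population rate interpolates, per site, the time of half-maximal resected
fraction (t50; linear interpolation between bracketing timepoints — curves
are reported, not fitted to a kinetic model) and reports Δdistance/Δt50 per
site pair plus a pooled least-squares slope; when ≥ 2 replicates each yield
a slope, a 95% CI from the replicate spread (t-distribution) is attached.
Sites that never cross half-max, or start above it, are excluded with a
notice; identical t50s yield an infinite, flagged rate. Background
protection (incomplete digestion of unresected duplex) is estimated from
uninduced/t0 samples and subtracted before normalizing by the cut fraction.

## Numerical and testing choices

* All randomness flows from integer seeds through `numpy.random.Generator`;
  identical seed + config is bit-identical, including rendered movies.
* Frame quantization bounds duration error: onset and loss are each called
  within about one frame, so recovered durations sit within ±2 frame
  intervals of truth; the validation suite requires this for ≥95% of
  completing events and requires genotype medians recovered within 15%.
* Validation problem sizes were chosen to keep the suite quick while
  retaining statistical meaning: 56 rendered cells per genotype for
  recovery, 100 uncut cells for the photobleach control, 1000 simulated
  families for the family-wise-error check, populations of 1500–2000 cells
  for qPCR curves.
* Degenerate inputs are defined outcomes, not crashes: empty/flat volumes
  detect nothing; a flat centroid window returns the seed voxel flagged
  low-confidence; empty event tables produce empty summaries; a missing
  uncut-cell pool skips the photobleach control with a warning.
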