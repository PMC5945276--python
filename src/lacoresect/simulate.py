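"""Synthetic-data generator: truth event tables, rendered movies, qPCR plates.

The generator emulates the live-cell resection assay so the whole analysis
chain can be exercised against known ground truth:

* ~15% of cells acquire a site-specific DSB within the first ~2 hr of
  induction (binomial cut with uniform cut times);
* resection proceeds in two phases — a short initiation tract (default
  0.3 kb) traversed during the 30–60 min lag before the Rad52-mCherry focus
  becomes visible, then long-range resection at a constant per-cell rate
  drawn from a genotype-specific log-normal distribution;
* the LacO/LacI-GFP focus intensity is proportional to the double-stranded
  fraction of the 10.3 kb array (flat until the front reaches the proximal
  array edge 3.57 kb from the cut, then linear to zero at the distal edge),
  multiplied by per-exposure photobleaching;
* the Rad52-mCherry focus appears at its visibility time at half its plateau
  intensity and grows with the resected tract;
* foci are rendered as anisotropic Gaussian PSF blobs in one tile (nucleus
  region) per cell, with Poisson shot noise, EMCCD offset, and Gaussian
  read noise.

Everything is driven by a single integer seed; identical seed + config
yields bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import CassetteGeometry, DEFAULT_GEOMETRY
from .stack import ImageStack

__all__ = [
    "GenotypeRateModel",
    "SimulationConfig",
    "TruthEvent",
    "LayoutError",
    "DEFAULT_GENOTYPE_RATE_MODELS",
    "simulate_events",
    "events_frame",
    "render_stack",
    "gfp_intensity_fraction",
    "mcherry_intensity_fraction",
    "front_passed_time",
    "simulate_qpcr_plate",
    "simulate_hocs_qpcr",
]


class LayoutError(ValueError):
    """Raised when the requested cells cannot be laid out in the stack."""


@dataclass(frozen=True)
class GenotypeRateModel:
    """Log-normal model of the per-cell long-range resection rate.

    ``median_kb_per_hr`` is the distribution median (log-normal location);
    ``sigma_log`` is the SD of log-rate, a free dispersion parameter.
    """

    median_kb_per_hr: float
    sigma_log: float = 0.25

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if not self.median_kb_per_hr > 0:
            raise ValueError("rate median must be positive")
        return self.median_kb_per_hr * np.exp(rng.normal(0.0, self.sigma_log, size))


# Medians: WT-like 7.6, crb2∆-like 13.9, rev7∆-like 10.4 kb/hr. The
# exo1∆-like model sits well below the 5-hr censoring bound (~2.8 kb/hr) so
# its events never complete inside the default window.
DEFAULT_GENOTYPE_RATE_MODELS: dict[str, GenotypeRateModel] = {
    "WT": GenotypeRateModel(7.6),
    "crb2d": GenotypeRateModel(13.9),
    "rev7d": GenotypeRateModel(10.4),
    "exo1d": GenotypeRateModel(1.5, sigma_log=0.2),
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic assay.

    ``n_cells`` is per genotype. Times are minutes, distances kb, image
    quantities in pixels/slices/camera counts.
    """

    n_cells: int = 50
    frame_interval_min: float = 10.0
    n_frames: int = 31
    z_slices: int = 25
    z_spacing_um: float = 0.26
    pixel_size_xy_um: float = 0.107
    cut_fraction: float = 0.15
    cut_time_window_min: float = 120.0
    rad52_delay_min_range: tuple[float, float] = (30.0, 60.0)
    initiation_tract_kb: float = 0.3
    genotype_rate_model: dict[str, GenotypeRateModel] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_RATE_MODELS)
    )
    bleach_rate_per_frame: float = 0.015
    psf_sigma_xy_px: float = 1.1
    psf_sigma_z_slices: float = 1.5
    gfp_focus_photons: float = 5000.0
    mcherry_plateau_photons: float = 2500.0
    mcherry_initial_fraction: float = 0.5
    background_photons_per_voxel: float = 30.0
    camera_offset: float = 100.0
    camera_gain: float = 1.0
    read_noise_sd: float = 5.0
    shot_noise: bool = True
    tile_px: int = 28
    decoy_foci_per_cell: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cut_fraction <= 1.0:
            raise ValueError(f"cut_fraction must be in [0, 1], got {self.cut_fraction}")
        lo, hi = self.rad52_delay_min_range
        if lo < 0 or hi < lo:
            raise ValueError(f"delay range must be ordered and non-negative, got ({lo}, {hi})")
        if self.n_cells < 0 or self.n_frames < 1 or self.z_slices < 1:
            raise ValueError("n_cells must be >= 0 and n_frames, z_slices >= 1")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if self.initiation_tract_kb < 0:
            raise ValueError("initiation_tract_kb must be non-negative")
        if not 0.0 <= self.bleach_rate_per_frame < 1.0:
            raise ValueError("bleach_rate_per_frame must be in [0, 1)")

    @property
    def acquisition_window_min(self) -> float:
        """Minutes from the first to the last acquired frame."""
        return (self.n_frames - 1) * self.frame_interval_min


@dataclass
class TruthEvent:
    """Ground truth for one simulated cell."""

    cell_id: str
    genotype: str
    is_cut: bool
    cut_time_min: float
    rad52_visible_time_min: float
    true_rate_kb_per_hr: float
    gfp_loss_time_min: float
    completes_in_window: bool


def _long_range_tract_kb(config: SimulationConfig, geometry: CassetteGeometry) -> float:
    # The initiation tract is resected before the Rad52 focus is visible;
    # the measured interval covers the remainder of the cassette.
    return max(geometry.total_distance_kb - config.initiation_tract_kb, 1e-9)


def simulate_events(
    config: SimulationConfig, geometry: CassetteGeometry = DEFAULT_GEOMETRY
) -> list[TruthEvent]:
    """Draw per-cell ground-truth events for every genotype in the config.

    Cut status is Bernoulli(cut_fraction); cut times are uniform on the cut
    window; the Rad52 visibility delay is uniform on its range; per-cell
    rates come from the genotype's log-normal model. GFP loss occurs when
    the long-range front (starting at the end of the initiation tract at
    Rad52-visibility time) passes the distal array end.
    """
    rng = np.random.default_rng(config.seed)
    events: list[TruthEvent] = []
    tract = _long_range_tract_kb(config, geometry)
    for genotype, model in config.genotype_rate_model.items():
        n = config.n_cells
        is_cut = rng.random(n) < config.cut_fraction
        cut_time = rng.uniform(0.0, config.cut_time_window_min, n)
        delay = rng.uniform(*config.rad52_delay_min_range, n)
        rate = model.draw(rng, n)
        for i in range(n):
            cid = f"{genotype}_{i:04d}"
            if not is_cut[i]:
                events.append(
                    TruthEvent(cid, genotype, False, math.nan, math.nan, math.nan, math.nan, False)
                )
                continue
            visible = cut_time[i] + delay[i]
            loss = visible + 60.0 * tract / rate[i]
            events.append(
                TruthEvent(
                    cid,
                    genotype,
                    True,
                    float(cut_time[i]),
                    float(visible),
                    float(rate[i]),
                    float(loss),
                    bool(loss <= config.acquisition_window_min),
                )
            )
    return events


def events_frame(events: list[TruthEvent]) -> pd.DataFrame:
    """Truth events as a tidy table."""
    return pd.DataFrame([vars(e) for e in events])


def _resected_kb(event: TruthEvent, t_min: float, config: SimulationConfig) -> float:
    """Front position (kb from the cut site) of one cell at time t."""
    if not event.is_cut or t_min <= event.cut_time_min:
        return 0.0
    init = config.initiation_tract_kb
    delay = event.rad52_visible_time_min - event.cut_time_min
    if t_min < event.rad52_visible_time_min:
        # initiation phase: linear progress through the initiation tract
        if delay <= 0:
            return init
        return init * (t_min - event.cut_time_min) / delay
    return init + event.true_rate_kb_per_hr * (t_min - event.rad52_visible_time_min) / 60.0


def gfp_intensity_fraction(
    event: TruthEvent,
    t_min: float,
    config: SimulationConfig,
    geometry: CassetteGeometry = DEFAULT_GEOMETRY,
) -> float:
    """Pre-noise, pre-bleach GFP focus intensity as a fraction of baseline.

    1 while the front is proximal to the array, declining linearly with the
    single-stranded fraction of the array, 0 once the distal edge is passed.
    """
    front = _resected_kb(event, t_min, config)
    if front <= geometry.hocs_to_array_kb:
        return 1.0
    remaining = (geometry.total_distance_kb - front) / geometry.array_length_kb
    return float(np.clip(remaining, 0.0, 1.0))


def mcherry_intensity_fraction(
    event: TruthEvent,
    t_min: float,
    config: SimulationConfig,
    geometry: CassetteGeometry = DEFAULT_GEOMETRY,
) -> float:
    """Pre-noise Rad52 focus intensity as a fraction of its plateau.

    Zero before the visibility time; jumps to ``mcherry_initial_fraction``
    (so the focus is detectable from its first visible frame) and grows with
    the resected tract toward the plateau.
    """
    if not event.is_cut or t_min < event.rad52_visible_time_min:
        return 0.0
    front = _resected_kb(event, t_min, config)
    c0 = config.mcherry_initial_fraction
    grow = c0 + (1.0 - c0) * front / geometry.total_distance_kb
    return float(np.clip(grow, 0.0, 1.0))


def front_passed_time(
    event: TruthEvent,
    site_kb: float,
    config: SimulationConfig,
) -> float:
    """Time (min) at which the resection front passes a site; inf if uncut."""
    if not event.is_cut:
        return math.inf
    init = config.initiation_tract_kb
    delay = event.rad52_visible_time_min - event.cut_time_min
    if site_kb <= init:
        frac = site_kb / init if init > 0 else 0.0
        return event.cut_time_min + delay * frac
    return event.rad52_visible_time_min + 60.0 * (site_kb - init) / event.true_rate_kb_per_hr


def _add_gaussian_blob(
    volume: np.ndarray,
    center_zyx: tuple[float, float, float],
    sigma_zyx: tuple[float, float, float],
    total_photons: float,
) -> None:
    """Add a normalized anisotropic Gaussian blob in place (±4σ support)."""
    if total_photons <= 0:
        return
    cz, cy, cx = center_zyx
    sz, sy, sx = sigma_zyx
    nz, ny, nx = volume.shape
    z0, z1 = max(0, int(math.floor(cz - 4 * sz))), min(nz, int(math.ceil(cz + 4 * sz)) + 1)
    y0, y1 = max(0, int(math.floor(cy - 4 * sy))), min(ny, int(math.ceil(cy + 4 * sy)) + 1)
    x0, x1 = max(0, int(math.floor(cx - 4 * sx))), min(nx, int(math.ceil(cx + 4 * sx)) + 1)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz = np.arange(z0, z1, dtype=np.float64) - cz
    yy = np.arange(y0, y1, dtype=np.float64) - cy
    xx = np.arange(x0, x1, dtype=np.float64) - cx
    gz = np.exp(-0.5 * (zz / sz) ** 2) / (sz * math.sqrt(2 * math.pi))
    gy = np.exp(-0.5 * (yy / sy) ** 2) / (sy * math.sqrt(2 * math.pi))
    gx = np.exp(-0.5 * (xx / sx) ** 2) / (sx * math.sqrt(2 * math.pi))
    blob = total_photons * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    volume[z0:z1, y0:y1, x0:x1] += blob


@dataclass
class _Decoy:
    dy: float
    dx: float
    dz: float
    first_frame: int
    last_frame: int
    photons: float


def render_stack(
    events: list[TruthEvent],
    config: SimulationConfig,
    geometry: CassetteGeometry = DEFAULT_GEOMETRY,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a two-channel movie with one tile per cell; returns truth table.

    The truth table carries each cell's event fields plus its ROI bounds
    (``y0:y1, x0:x1``) and true focus center, which downstream quantification
    uses in place of cell segmentation.
    """
    n = len(events)
    if n == 0:
        raise LayoutError("no events to render")
    tile = config.tile_px
    # the whole cylinder + background shell of the default aperture must fit
    min_tile = int(math.ceil(8 * config.psf_sigma_xy_px + 12))
    if tile < min_tile:
        raise LayoutError(f"tile_px={tile} too small for focus + background shell (need >= {min_tile})")
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    ny, nx = nrows * tile, ncols * tile
    nz, nt = config.z_slices, config.n_frames
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7]))

    # per-cell focus placement: tile center plus a small jitter
    rows = []
    centers = []
    mch_offsets = []
    decoys: list[list[_Decoy]] = []
    for i, ev in enumerate(events):
        r, c = divmod(i, ncols)
        y0, x0 = r * tile, c * tile
        cy = y0 + tile / 2 + rng.uniform(-3, 3)
        cx = x0 + tile / 2 + rng.uniform(-3, 3)
        cz = (nz - 1) / 2 + rng.uniform(-1.5, 1.5) if nz > 3 else (nz - 1) / 2
        centers.append((cz, cy, cx))
        mch_offsets.append(rng.normal(0.0, 0.3, 3))
        cell_decoys: list[_Decoy] = []
        if config.decoy_foci_per_cell > 0:
            for _ in range(rng.poisson(config.decoy_foci_per_cell)):
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(10.0, tile / 2 - 2)
                f0 = int(rng.integers(0, nt))
                cell_decoys.append(
                    _Decoy(
                        dy=rad * math.sin(ang),
                        dx=rad * math.cos(ang),
                        dz=rng.uniform(-1, 1),
                        first_frame=f0,
                        last_frame=min(nt - 1, f0 + int(rng.integers(2, 7))),
                        photons=0.8 * config.mcherry_plateau_photons,
                    )
                )
        decoys.append(cell_decoys)
        rows.append(
            dict(
                vars(ev),
                y0=y0,
                y1=y0 + tile,
                x0=x0,
                x1=x0 + tile,
                focus_z=cz,
                focus_y=cy,
                focus_x=cx,
            )
        )

    sig = (config.psf_sigma_z_slices, config.psf_sigma_xy_px, config.psf_sigma_xy_px)
    out = np.empty((nt, 2, nz, ny, nx), dtype=np.float32)
    for f in range(nt):
        t = f * config.frame_interval_min
        bleach = (1.0 - config.bleach_rate_per_frame) ** f
        photons = np.full((2, nz, ny, nx), config.background_photons_per_voxel, dtype=np.float64)
        for i, ev in enumerate(events):
            cz, cy, cx = centers[i]
            gfp = config.gfp_focus_photons * gfp_intensity_fraction(ev, t, config, geometry) * bleach
            _add_gaussian_blob(photons[0], (cz, cy, cx), sig, gfp)
            mch = config.mcherry_plateau_photons * mcherry_intensity_fraction(
                ev, t, config, geometry
            )
            if mch > 0:
                oz, oy, ox = mch_offsets[i]
                _add_gaussian_blob(photons[1], (cz + oz, cy + oy, cx + ox), sig, mch)
            for d in decoys[i]:
                if d.first_frame <= f <= d.last_frame:
                    _add_gaussian_blob(
                        photons[1], (cz + d.dz, cy + d.dy, cx + d.dx), sig, d.photons
                    )
        if config.shot_noise:
            counts = config.camera_gain * rng.poisson(photons).astype(np.float64)
        else:
            counts = config.camera_gain * photons
        counts += config.camera_offset
        if config.read_noise_sd > 0:
            counts += rng.normal(0.0, config.read_noise_sd, counts.shape)
        np.clip(counts, 0.0, None, out=counts)
        out[f] = counts.astype(np.float32)

    stack = ImageStack(
        data=out,
        pixel_size_xy_um=config.pixel_size_xy_um,
        z_spacing_um=config.z_spacing_um,
        frame_interval_min=config.frame_interval_min,
        channel_names=("GFP", "mCherry"),
    )
    return stack, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR plate simulation
# ---------------------------------------------------------------------------


def _qpcr_cqs(
    rng: np.random.Generator,
    protection: float,
    base_cq: float,
    control_cq: float,
    efficiency: float,
    cq_noise_sd: float,
) -> tuple[float, float, float, float]:
    ddcq = -math.log(max(protection, 1e-4)) / math.log(efficiency)
    noise = rng.normal(0.0, cq_noise_sd, 4)
    cq_digested = base_cq + ddcq + noise[0]
    cq_mock = base_cq + noise[1]
    cq_control_digested = control_cq + noise[2]
    cq_control_mock = control_cq + noise[3]
    return cq_digested, cq_mock, cq_control_digested, cq_control_mock


def simulate_qpcr_plate(
    config: SimulationConfig,
    site_distances_kb: list[float],
    timepoints_min: list[float],
    geometry: CassetteGeometry = DEFAULT_GEOMETRY,
    genotypes: list[str] | None = None,
    n_technical: int = 3,
    n_biological: int = 2,
    cq_noise_sd: float = 0.1,
    background_protection: float = 0.05,
    base_cq: float = 24.0,
    control_cq: float = 22.0,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Simulate an ApoI-protection qPCR plate as a long-format record table.

    Per biological replicate a fresh population of cells is drawn; the true
    protected fraction at a site/time is the background (incomplete ApoI
    digestion of unresected duplex) plus the fraction of chromosomes whose
    resection front has passed the site. Cq quadruplets are generated by
    inverting the ΔΔCq protection model at the given amplification
    efficiency with Gaussian Cq noise.
    """
    if not site_distances_kb or not timepoints_min:
        raise ValueError("need at least one site distance and one timepoint")
    if any(s <= 0 for s in site_distances_kb):
        raise ValueError("site distances must be positive")
    genotypes = genotypes or list(config.genotype_rate_model)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))
    rows = []
    for genotype in genotypes:
        for b in range(n_biological):
            sub = replace(
                config,
                genotype_rate_model={genotype: config.genotype_rate_model[genotype]},
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            evs = simulate_events(sub, geometry)
            passed = {
                s: np.array([front_passed_time(e, s, sub) for e in evs])
                for s in site_distances_kb
            }
            for s in site_distances_kb:
                for t in timepoints_min:
                    resected = float(np.mean(passed[s] <= t))
                    p = background_protection + (1.0 - background_protection) * resected
                    for k in range(n_technical):
                        cqd, cqm, ccd, ccm = _qpcr_cqs(
                            rng, p, base_cq, control_cq, efficiency, cq_noise_sd
                        )
                        rows.append(
                            dict(
                                genotype=genotype,
                                timepoint_min=t,
                                site_distance_kb=s,
                                cq_digested=cqd,
                                cq_mock=cqm,
                                cq_control_digested=ccd,
                                cq_control_mock=ccm,
                                replicate=f"b{b}t{k}",
                                true_protection=p,
                            )
                        )
    return pd.DataFrame(rows)


def simulate_hocs_qpcr(
    config: SimulationConfig,
    timepoints_min: list[float],
    genotype: str = "WT",
    geometry: CassetteGeometry = DEFAULT_GEOMETRY,
    n_biological: int = 2,
    cq_noise_sd: float = 0.05,
    base_cq: float = 23.0,
    control_cq: float = 22.0,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Simulate the HOcs-spanning amplicon used to monitor cut efficiency.

    Cutting destroys the template spanning the cut site, shifting Cq up by
    -log_E(remaining fraction). Timepoint 0 must be included by the caller
    if downstream cut-fraction analysis needs a reference.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 13]))
    rows = []
    for b in range(n_biological):
        sub = replace(
            config,
            genotype_rate_model={genotype: config.genotype_rate_model[genotype]},
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        evs = simulate_events(sub, geometry)
        cut_times = np.array([e.cut_time_min if e.is_cut else math.inf for e in evs])
        for t in timepoints_min:
            cut = float(np.mean(cut_times <= t))
            remaining = max(1.0 - cut, 1e-4)
            cq = base_cq - math.log(remaining) / math.log(efficiency) + rng.normal(0, cq_noise_sd)
            cq_control = control_cq + rng.normal(0, cq_noise_sd)
            rows.append(
                dict(
                    time_min=t,
                    cq=cq,
                    cq_control=cq_control,
                    replicate=f"b{b}",
                    true_cut_fraction=cut,
                )
            )
    return pd.DataFrame(rows)
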