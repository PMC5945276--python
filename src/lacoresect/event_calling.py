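"""Resection event calling from paired GFP / Rad52 focus traces.

An event's duration runs from the first frame with a detectable, on-target
Rad52-mCherry focus (sustained for at least ``persistence_frames`` frames to
suppress single-frame noise) to the first frame with irreversible total loss
of the LacO/LacI-GFP focus. "Total loss" is operationalized as the
background-subtracted intensity falling below ``k`` robust SDs of the
background shell and never recovering (the irreversibility guard absorbs
single-frame dropouts and the transient GFP dip at mitosis). Events whose
GFP focus persists to the end of acquisition are censored: they carry an
observation window rather than a duration.

A photobleach control checks that GFP foci in cells without induced DSBs do
not meet the loss criterion; a dataset where they do is flagged, since focus
disappearance could then reflect bleaching rather than resection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .focus_quant import FocusTrace

__all__ = [
    "EventParams",
    "LossParams",
    "ResectionEvent",
    "PhotobleachReport",
    "call_on_target",
    "call_rad52_onset",
    "call_gfp_loss",
    "call_event",
    "events_to_frame",
    "events_from_frame",
    "photobleach_control",
    "blind_and_randomize",
    "unblind",
]


@dataclass(frozen=True)
class LossParams:
    """GFP total-loss criterion: intensity < k · shell robust SD, forever."""

    k_noise_sd: float = 3.0


@dataclass(frozen=True)
class EventParams:
    """Event-calling thresholds."""

    max_colocalization_dist_px: float = 3.0
    min_colocalized_frames: int = 2
    persistence_frames: int = 2
    loss: LossParams = LossParams()


@dataclass
class ResectionEvent:
    """One called resection event (possibly censored)."""

    cell_id: str
    genotype: str
    rad52_onset_frame: int
    gfp_loss_frame: int | None
    duration_min: float
    censored: bool
    observed_window_min: float

    def __post_init__(self) -> None:
        if self.censored:
            if not self.observed_window_min > 0:
                raise ValueError("censored event needs a positive observed window")
        else:
            if self.gfp_loss_frame is None or self.gfp_loss_frame <= self.rad52_onset_frame:
                raise ValueError("uncensored event needs gfp_loss_frame > rad52_onset_frame")
            if not self.duration_min > 0:
                raise ValueError("uncensored event needs a positive duration")


def call_on_target(
    gfp_trace: FocusTrace,
    rad52_trace: FocusTrace,
    max_dist_px: float = 3.0,
    min_frames: int = 2,
) -> bool:
    """True iff the Rad52 focus co-localizes with the GFP focus long enough.

    Co-localization is counted on frames where both foci are detected and
    their xy centers lie within ``max_dist_px``; at least ``min_frames``
    such frames are required (default 2, rejecting the many spontaneous
    off-target Rad52 foci).
    """
    if len(gfp_trace) != len(rad52_trace):
        raise ValueError(
            f"traces on different frame grids: {len(gfp_trace)} vs {len(rad52_trace)}"
        )
    both = gfp_trace.detected & rad52_trace.detected
    if not both.any():
        return False
    gc = gfp_trace.centers
    rc = rad52_trace.centers
    d = np.hypot(gc[:, 1] - rc[:, 1], gc[:, 2] - rc[:, 2])
    return int(np.count_nonzero(both & (d <= max_dist_px))) >= min_frames


def _first_sustained(flags: np.ndarray, persistence_frames: int) -> int | None:
    p = max(1, int(persistence_frames))
    for i in range(len(flags) - p + 1):
        if flags[i : i + p].all():
            return i
    return None


def call_rad52_onset(rad52_trace: FocusTrace, persistence_frames: int = 2) -> int | None:
    """First frame starting a run of ≥ persistence_frames detections; None if never."""
    return _first_sustained(rad52_trace.detected, persistence_frames)


def _on_target_flags(
    gfp_trace: FocusTrace, rad52_trace: FocusTrace, max_dist_px: float
) -> np.ndarray:
    """Frames where a detected Rad52 focus sits at the array position.

    The GFP center of frames where the array focus itself is undetected
    (e.g. after complete loss) is its last tracked position, so proximity
    stays well-defined through the whole movie.
    """
    gc = gfp_trace.centers
    rc = rad52_trace.centers
    d = np.hypot(gc[:, 1] - rc[:, 1], gc[:, 2] - rc[:, 2])
    return rad52_trace.detected & (d <= max_dist_px)


def call_gfp_loss(gfp_trace: FocusTrace, loss: LossParams = LossParams()) -> int | None:
    """First frame of irreversible total GFP-focus loss; None means censored.

    The loss frame is the smallest index at which the background-subtracted
    intensity sits below k·(shell robust SD of the integrated measurement)
    and stays below it for every later frame.
    """
    inten = gfp_trace.intensities
    noise = gfp_trace.noise_sds
    # fall back to the trace-median noise scale where a frame's shell was degenerate
    med_noise = float(np.nanmedian(noise)) if np.isfinite(noise).any() else 0.0
    noise = np.where(np.isfinite(noise) & (noise > 0), noise, med_noise)
    below = inten < loss.k_noise_sd * noise
    if not below.any():
        return None
    suffix_all = np.logical_and.accumulate(below[::-1])[::-1]
    if not suffix_all.any():
        return None
    return int(np.argmax(suffix_all))


def call_event(
    gfp_trace: FocusTrace,
    rad52_trace: FocusTrace,
    params: EventParams = EventParams(),
) -> ResectionEvent | None:
    """Assemble a resection event from one cell's trace pair.

    Returns None when there is no on-target event (no sustained Rad52
    focus, or the Rad52 focus never co-localizes with the array).
    """
    if not call_on_target(
        gfp_trace,
        rad52_trace,
        params.max_colocalization_dist_px,
        params.min_colocalized_frames,
    ):
        return None
    # onset counts only on-target (array-colocalized) Rad52 detections, so
    # spontaneous DSB foci elsewhere in the nucleus cannot start the clock
    flags = _on_target_flags(
        gfp_trace, rad52_trace, params.max_colocalization_dist_px
    )
    onset = _first_sustained(flags, params.persistence_frames)
    if onset is None:
        return None
    loss_frame = call_gfp_loss(gfp_trace, params.loss)
    n = len(gfp_trace)
    dt = gfp_trace.frame_interval_min
    window = (n - 1 - onset) * dt
    if loss_frame is not None and loss_frame <= onset:
        # GFP gone before a sustained Rad52 focus: not a scorable event
        return None
    if loss_frame is None:
        return ResectionEvent(
            cell_id=gfp_trace.cell_id,
            genotype=gfp_trace.genotype,
            rad52_onset_frame=onset,
            gfp_loss_frame=None,
            duration_min=math.nan,
            censored=True,
            observed_window_min=window,
        )
    return ResectionEvent(
        cell_id=gfp_trace.cell_id,
        genotype=gfp_trace.genotype,
        rad52_onset_frame=onset,
        gfp_loss_frame=loss_frame,
        duration_min=(loss_frame - onset) * dt,
        censored=False,
        observed_window_min=window,
    )


def events_to_frame(events: list[ResectionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                cell_id=e.cell_id,
                genotype=e.genotype,
                onset_frame=e.rad52_onset_frame,
                loss_frame=-1 if e.gfp_loss_frame is None else e.gfp_loss_frame,
                duration_min=e.duration_min,
                censored=e.censored,
                window_min=e.observed_window_min,
            )
            for e in events
        ]
    )


def events_from_frame(df: pd.DataFrame) -> list[ResectionEvent]:
    out = []
    for r in df.itertuples():
        loss = None if int(r.loss_frame) < 0 else int(r.loss_frame)
        out.append(
            ResectionEvent(
                cell_id=str(r.cell_id),
                genotype=str(r.genotype),
                rad52_onset_frame=int(r.onset_frame),
                gfp_loss_frame=loss,
                duration_min=float(r.duration_min),
                censored=bool(r.censored),
                observed_window_min=float(r.window_min),
            )
        )
    return out


@dataclass
class PhotobleachReport:
    """Outcome of the uncut-cell photobleach control."""

    n_cells: int
    n_false_loss: int
    false_loss_fraction: float
    tolerance: float
    flagged: bool
    skipped: bool = False


def photobleach_control(
    uncut_traces: list[FocusTrace],
    loss: LossParams = LossParams(),
    tolerance: float = 0.05,
) -> PhotobleachReport:
    """Fraction of uncut cells whose GFP focus meets the loss criterion.

    Exceeding ``tolerance`` flags the dataset: GFP-focus disappearance can
    then not be attributed to resection. With no uncut cells the control is
    skipped with an explicit warning.
    """
    if not uncut_traces:
        warnings.warn("photobleach control skipped: no uncut cells available", stacklevel=2)
        return PhotobleachReport(0, 0, math.nan, tolerance, flagged=False, skipped=True)
    n_false = sum(1 for tr in uncut_traces if call_gfp_loss(tr, loss) is not None)
    frac = n_false / len(uncut_traces)
    flagged = frac > tolerance
    if flagged:
        warnings.warn(
            f"photobleach control failed: {n_false}/{len(uncut_traces)} uncut cells "
            f"({frac:.1%}) lost their GFP focus (tolerance {tolerance:.0%})",
            stacklevel=2,
        )
    return PhotobleachReport(len(uncut_traces), n_false, frac, tolerance, flagged)


def blind_and_randomize(
    manifest: pd.DataFrame,
    seed: int,
    identity_columns: tuple[str, ...] = ("field_id", "genotype"),
    contrast: tuple[float, float] = (0.0, 1000.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blind a field manifest for unbiased scoring.

    Rows are deterministically permuted (seeded) and identifying columns are
    replaced by opaque ids; every blinded row carries identical
    display-contrast metadata so scoring cannot be biased by scaling. The
    returned key maps blinded ids back to the original rows
    (:func:`unblind` inverts the operation exactly).
    """
    id_col = identity_columns[0]
    if id_col not in manifest.columns:
        raise ValueError(f"manifest lacks identity column {id_col!r}")
    if manifest[id_col].duplicated().any():
        raise ValueError("duplicate ids in manifest")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(manifest))
    shuffled = manifest.iloc[perm].reset_index(drop=True)
    blind_ids = [f"blind_{i + 1:04d}" for i in range(len(shuffled))]
    key = shuffled.copy()
    key.insert(0, "blind_id", blind_ids)
    key["orig_row"] = manifest.index.to_numpy()[perm]
    blinded = shuffled.drop(columns=[c for c in identity_columns if c in shuffled.columns])
    blinded.insert(0, "blind_id", blind_ids)
    blinded["contrast_min"] = contrast[0]
    blinded["contrast_max"] = contrast[1]
    return blinded, key


def unblind(blinded: pd.DataFrame, key: pd.DataFrame) -> pd.DataFrame:
    """Recover the original manifest from a blinded manifest and its key."""
    merged = key.set_index("blind_id").loc[blinded["blind_id"]]
    merged = merged.sort_values("orig_row")
    out = merged.drop(columns=["orig_row"]).reset_index(drop=True)
    return out
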