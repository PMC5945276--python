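"""Reporter-cassette geometry and the duration → rate conversion.

The assay's core statistic is a per-cell long-range resection rate: the time
from Rad52-mCherry focus appearance to complete LacO/LacI-GFP focus loss is
the time needed to resect from the HO cut site through the distal end of the
LacO array, so

    rate [kb/hr] = total_distance_kb / (duration_min / 60)

The default cassette places a 10.3 kb, 256-copy LacO array 3.57 kb from the
HO cut site (HOcs), i.e. 13.87 kb from the cut to the distal array end.
Events whose GFP focus survives the whole acquisition window only bound the
rate from above: a window of ``w`` minutes implies rate ≤ total / (w/60).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CassetteGeometry",
    "GeometryError",
    "DEFAULT_GEOMETRY",
    "total_distance",
    "duration_to_rate",
    "censored_upper_bound",
    "format_rate",
]


class GeometryError(ValueError):
    """Raised for an invalid cassette configuration."""


@dataclass(frozen=True)
class CassetteGeometry:
    """Genomic layout of the HO cut site, spacer and LacO array.

    Parameters
    ----------
    hocs_to_array_kb
        Distance in kb from the HO cut site to the proximal edge of the
        LacO array (default 3.57).
    array_length_kb
        Length of the LacO array in kb (default 10.3).
    """

    hocs_to_array_kb: float = 3.57
    array_length_kb: float = 10.3

    def __post_init__(self) -> None:
        if not (self.hocs_to_array_kb > 0 and self.array_length_kb > 0):
            raise GeometryError(
                "cassette distances must be strictly positive, got "
                f"spacer={self.hocs_to_array_kb}, array={self.array_length_kb}"
            )

    @property
    def total_distance_kb(self) -> float:
        """kb from the cut site to the distal end of the array."""
        return self.hocs_to_array_kb + self.array_length_kb


DEFAULT_GEOMETRY = CassetteGeometry()


def total_distance(geometry: CassetteGeometry) -> float:
    """Total resection distance of a completing event, in kb."""
    return geometry.total_distance_kb


def duration_to_rate(duration_min: float, geometry: CassetteGeometry = DEFAULT_GEOMETRY) -> float:
    """Convert a completed-event duration (minutes) into a rate in kb/hr.

    The value is returned at full precision; round only for display
    (:func:`format_rate`).
    """
    if not duration_min > 0:
        raise ValueError(f"duration must be positive, got {duration_min}")
    return geometry.total_distance_kb / (duration_min / 60.0)


def censored_upper_bound(
    acquisition_window_min: float, geometry: CassetteGeometry = DEFAULT_GEOMETRY
) -> float:
    """Upper bound (kb/hr) on the rate of an event that never completes.

    A GFP focus persisting through an observation window of ``w`` minutes
    means resection did not traverse the full cassette in ``w`` minutes; the
    true rate is therefore at most ``total / (w/60)``. Numerically identical
    to :func:`duration_to_rate` applied to the window length.
    """
    if not acquisition_window_min > 0:
        raise ValueError(f"window must be positive, got {acquisition_window_min}")
    return geometry.total_distance_kb / (acquisition_window_min / 60.0)


def format_rate(rate_kb_per_hr: float, decimals: int = 2) -> float:
    """Display rounding for report output; internal values stay unrounded."""
    return round(rate_kb_per_hr, decimals)
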