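"""Molecule-count calibration from a reference focus of known stoichiometry.

The spindle-pole-body protein Sad1 forms a single focus containing a known
range of molecule copies (450–1030). Imaging it under the same parameters as
the experiment fixes an intensity-per-molecule interval; any focus intensity
then converts to a molecule-count interval, and a molecule count converts to
a minimum resected single-stranded tract (molecules are shared across the
two sister chromatids present in G2, each binding ``nt_per_molecule`` nt).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "IntensityCalibration",
    "CalibrationError",
    "molecules_from_intensity",
    "min_resected_nt",
]


class CalibrationError(ValueError):
    """Raised for invalid calibration inputs or mismatched imaging metadata."""


@dataclass(frozen=True)
class IntensityCalibration:
    """Reference-focus calibration.

    ``reference_intensity`` is the background-subtracted integrated
    intensity of the reference focus; ``reference_molecule_range`` its known
    copy-number interval. ``nt_per_molecule`` is the ssDNA footprint per
    loaded molecule (configurable — the true footprint is contested), and
    ``n_sisters`` the number of sister chromatids sharing loaded molecules.
    ``imaging_signature`` identifies the acquisition settings; conversions
    are only meaningful when experiment and reference share it.
    """

    reference_intensity: float
    reference_molecule_range: tuple[float, float] = (450.0, 1030.0)
    nt_per_molecule: float = 6.0
    n_sisters: int = 2
    imaging_signature: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.reference_molecule_range
        if not (self.reference_intensity > 0 and 0 < lo <= hi):
            raise CalibrationError("reference intensity and molecule range must be positive")
        if not (self.nt_per_molecule > 0 and self.n_sisters > 0):
            raise CalibrationError("nt_per_molecule and n_sisters must be positive")

    @property
    def intensity_per_molecule_range(self) -> tuple[float, float]:
        """(low, high) counts per molecule: the range inverts the copy range."""
        lo, hi = self.reference_molecule_range
        return (self.reference_intensity / hi, self.reference_intensity / lo)


def molecules_from_intensity(
    intensity: float,
    cal: IntensityCalibration,
    imaging_signature: str | None = None,
) -> tuple[float, float]:
    """Molecule-count interval implied by a background-subtracted intensity.

    Linearity across foci holds only under identical imaging parameters;
    a signature mismatch is a hard error, not a warning.
    """
    if cal.imaging_signature is not None and imaging_signature != cal.imaging_signature:
        raise CalibrationError(
            f"imaging parameters differ from calibration reference: "
            f"{imaging_signature!r} != {cal.imaging_signature!r}"
        )
    if not intensity > 0:
        raise CalibrationError(f"intensity must be positive for a molecule estimate, got {intensity}")
    ipm_lo, ipm_hi = cal.intensity_per_molecule_range
    return (intensity / ipm_hi, intensity / ipm_lo)


def min_resected_nt(molecules: float, cal: IntensityCalibration) -> float:
    """Lower bound on resected ssDNA per sister implied by a molecule count."""
    if not molecules > 0:
        raise CalibrationError(f"molecule count must be positive, got {molecules}")
    return (molecules / cal.n_sisters) * cal.nt_per_molecule
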