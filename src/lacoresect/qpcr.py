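"""ApoI-protection qPCR resection assay analysis.

Resection converts the region downstream of the HO cut to ssDNA, which a
restriction enzyme (ApoI) cannot cut; amplification across an ApoI site
therefore measures the resected fraction of chromosomes. Each measurement is
a Cq quadruplet: target and control (Ncb2) amplicons, each after ApoI and
mock digestion. With amplification efficiency E,

    ΔCq_target  = Cq_digested − Cq_mock
    ΔCq_control = Cq_control_digested − Cq_control_mock
    protection  = E^−(ΔCq_target − ΔCq_control)        (clipped to [0, 1])

A primer pair spanning the cut site itself monitors cut efficiency: cutting
destroys that template, so the cut fraction at time t is
1 − E^−ΔΔCq(t vs t0). Population resection kinetics follow from the times at
which sites at different distances reach half-maximal resected fraction:
rate = Δdistance / Δt50.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrRecord",
    "ProtectionResult",
    "PopulationRateResult",
    "protection_fraction",
    "records_from_frame",
    "protection_table",
    "cut_fraction",
    "resected_fraction_among_cut",
    "population_rate",
]


@dataclass(frozen=True)
class QpcrRecord:
    """One site/timepoint Cq quadruplet (digested/mock × target/control)."""

    genotype: str
    timepoint_min: float
    site_distance_kb: float
    cq_digested: float
    cq_mock: float
    cq_control_digested: float
    cq_control_mock: float
    replicate: str = "r0"

    def __post_init__(self) -> None:
        cqs = (self.cq_digested, self.cq_mock, self.cq_control_digested, self.cq_control_mock)
        if not all(math.isfinite(c) and c > 0 for c in cqs):
            raise ValueError(f"Cq values must be positive and finite, got {cqs}")
        if not self.site_distance_kb > 0:
            raise ValueError(f"site distance must be positive, got {self.site_distance_kb}")


class ProtectionResult(NamedTuple):
    fraction: float
    clipped: bool


def protection_fraction(rec: QpcrRecord, efficiency: float = 2.0) -> ProtectionResult:
    """Protected (resected) template fraction from one Cq quadruplet.

    Invariant to a constant plate offset on all four Cq values. Values
    outside [0, 1] (noise, enzyme failure) are clipped and flagged.
    """
    if not efficiency > 1:
        raise ValueError("amplification efficiency must exceed 1")
    ddcq = (rec.cq_digested - rec.cq_mock) - (rec.cq_control_digested - rec.cq_control_mock)
    raw = efficiency**-ddcq
    clipped = raw < 0.0 or raw > 1.0
    return ProtectionResult(float(np.clip(raw, 0.0, 1.0)), clipped)


def records_from_frame(df: pd.DataFrame) -> list[QpcrRecord]:
    """Build records from a wide table with the simulator's column layout."""
    required = {
        "genotype",
        "timepoint_min",
        "site_distance_kb",
        "cq_digested",
        "cq_mock",
        "cq_control_digested",
        "cq_control_mock",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for r in df.itertuples():
        out.append(
            QpcrRecord(
                genotype=str(r.genotype),
                timepoint_min=float(r.timepoint_min),
                site_distance_kb=float(r.site_distance_kb),
                cq_digested=float(r.cq_digested),
                cq_mock=float(r.cq_mock),
                cq_control_digested=float(r.cq_control_digested),
                cq_control_mock=float(r.cq_control_mock),
                replicate=str(getattr(r, "replicate", "r0")),
            )
        )
    return out


def protection_table(records: list[QpcrRecord], efficiency: float = 2.0) -> pd.DataFrame:
    """Tidy per-record protection fractions."""
    rows = []
    for rec in records:
        res = protection_fraction(rec, efficiency)
        rows.append(
            dict(
                genotype=rec.genotype,
                timepoint_min=rec.timepoint_min,
                site_distance_kb=rec.site_distance_kb,
                replicate=rec.replicate,
                protection=res.fraction,
                clipped=res.clipped,
            )
        )
    return pd.DataFrame(rows)


def cut_fraction(df: pd.DataFrame, efficiency: float = 2.0, t0_min: float | None = None) -> pd.DataFrame:
    """Cut fraction over time from a HOcs-spanning amplicon.

    ``df`` needs columns time_min, cq, cq_control (replicates averaged).
    The earliest timepoint (or ``t0_min``) is the uncut reference; cutting
    shifts the normalized Cq up, and cut(t) = 1 − E^−ΔΔCq, clipped to [0,1].
    """
    for col in ("time_min", "cq", "cq_control"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    mean = df.groupby("time_min", as_index=False)[["cq", "cq_control"]].mean()
    t0 = float(mean["time_min"].min()) if t0_min is None else float(t0_min)
    ref = mean[mean["time_min"] == t0]
    if ref.empty:
        raise ValueError(f"reference timepoint t0={t0} not present")
    ref_delta = float(ref["cq"].iloc[0] - ref["cq_control"].iloc[0])
    delta = (mean["cq"] - mean["cq_control"]) - ref_delta
    frac = 1.0 - efficiency ** (-delta)
    return pd.DataFrame(
        {"time_min": mean["time_min"], "cut_fraction": np.clip(frac, 0.0, 1.0)}
    )


def resected_fraction_among_cut(protection: float, background: float, cut: float) -> float:
    """Fraction of cut chromosomes resected past a site.

    ``protection`` is the plate-level protected fraction, ``background`` the
    protection of uninduced (or t0) samples, ``cut`` the cut fraction.
    """
    if not cut > 0:
        raise ValueError(f"cut fraction must be positive, got {cut}")
    return float(np.clip((protection - background) / cut, 0.0, 1.0))


def _t50(times: np.ndarray, fracs: np.ndarray, half_level: float | None) -> float | None:
    """Linearly interpolated first crossing of the half-maximal level."""
    if len(times) < 2:
        return None
    target = 0.5 * float(np.max(fracs)) if half_level is None else half_level
    if target <= 0:
        return None
    if fracs[0] >= target:
        return None  # cannot bracket the crossing
    above = np.nonzero(fracs >= target)[0]
    if len(above) == 0:
        return None
    i = int(above[0])
    t0, t1 = times[i - 1], times[i]
    f0, f1 = fracs[i - 1], fracs[i]
    if f1 == f0:
        return float(t1)
    return float(t0 + (target - f0) * (t1 - t0) / (f1 - f0))


@dataclass
class PopulationRateResult:
    """Population-level resection rate from multi-site t50 spacing."""

    rate_kb_per_hr: float
    per_pair: pd.DataFrame
    t50_by_site: dict[float, float]
    excluded_sites: list[float] = field(default_factory=list)
    ci95_kb_per_hr: tuple[float, float] | None = None
    n_replicates: int = 0


def population_rate(
    curves: pd.DataFrame,
    half_level: float | None = None,
) -> PopulationRateResult:
    """Rate (kb/hr) from resected-fraction time courses at ≥ 2 site distances.

    ``curves`` needs columns site_kb, time_min, fraction and optionally
    replicate. Per site the time of half-maximal resected fraction (t50) is
    linearly interpolated on the replicate-mean curve; the pooled rate is
    the slope of distance vs t50 (least squares over all usable sites), and
    per-pair rates Δd/Δt50 are reported for every site pair. Sites whose
    curve never crosses half-max (or starts above it) are excluded with a
    notice. When ≥ 2 replicates each yield a usable slope, a 95% CI from the
    replicate spread (t-distribution) is attached.
    """
    for col in ("site_kb", "time_min", "fraction"):
        if col not in curves.columns:
            raise ValueError(f"missing column {col!r}")

    def site_t50s(df: pd.DataFrame) -> tuple[dict[float, float], list[float]]:
        t50s: dict[float, float] = {}
        excluded: list[float] = []
        for s, g in df.groupby("site_kb"):
            g = g.groupby("time_min", as_index=False)["fraction"].mean().sort_values("time_min")
            t = _t50(g["time_min"].to_numpy(float), g["fraction"].to_numpy(float), half_level)
            if t is None:
                excluded.append(float(s))
            else:
                t50s[float(s)] = t
        return t50s, excluded

    t50s, excluded = site_t50s(curves)
    for s in excluded:
        warnings.warn(f"site {s} kb excluded: curve never crosses half-max", stacklevel=2)
    if len(t50s) < 2:
        raise ValueError(f"need >= 2 sites with a half-max crossing, got {len(t50s)}")

    sites = sorted(t50s)
    pair_rows = []
    for a, b in itertools.combinations(sites, 2):
        dt = t50s[b] - t50s[a]
        if dt == 0:
            warnings.warn(
                f"sites {a} and {b} kb have identical t50; pair rate is infinite "
                "(out of model)",
                stacklevel=2,
            )
            rate = math.inf
        else:
            rate = (b - a) / (dt / 60.0)
        pair_rows.append(dict(site_a_kb=a, site_b_kb=b, rate_kb_per_hr=rate))
    per_pair = pd.DataFrame(pair_rows)

    d = np.array(sites)
    t = np.array([t50s[s] for s in sites])
    if np.ptp(t) == 0:
        pooled = math.inf
    else:
        slope = np.polyfit(t, d, 1)[0]  # kb per min
        pooled = slope * 60.0

    ci = None
    n_reps = 0
    if "replicate" in curves.columns and curves["replicate"].nunique() > 1:
        rep_rates = []
        for _, g in curves.groupby("replicate"):
            rt50s, _ = site_t50s(g)
            if len(rt50s) < 2:
                continue
            rs = sorted(rt50s)
            rt = np.array([rt50s[s] for s in rs])
            if np.ptp(rt) == 0:
                continue
            rep_rates.append(np.polyfit(rt, np.array(rs), 1)[0] * 60.0)
        n_reps = len(rep_rates)
        if n_reps >= 2:
            mean = float(np.mean(rep_rates))
            sem = float(np.std(rep_rates, ddof=1) / math.sqrt(n_reps))
            tcrit = float(stats.t.ppf(0.975, n_reps - 1))
            ci = (mean - tcrit * sem, mean + tcrit * sem)

    return PopulationRateResult(
        rate_kb_per_hr=float(pooled),
        per_pair=per_pair,
        t50_by_site=t50s,
        excluded_sites=excluded,
        ci95_kb_per_hr=ci,
        n_replicates=n_reps,
    )
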