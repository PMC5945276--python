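"""Genotype-level rate aggregation, medians, and corrected pairwise tests.

Uncensored events convert to rates through the cassette geometry; censored
events contribute only an upper bound (the rate an event exactly filling the
observed window would have) and never enter hypothesis tests. Pairwise
genotype comparisons use two-tailed two-sample t-tests (Welch by default)
with a Bonferroni correction whose family size is the number of pairs
actually tested in the invocation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .event_calling import ResectionEvent
from .geometry import CassetteGeometry, DEFAULT_GEOMETRY, censored_upper_bound, duration_to_rate

__all__ = [
    "GenotypeRateTable",
    "events_to_rates",
    "pairwise_tests",
    "plot_rates",
]


@dataclass
class GenotypeRateTable:
    """Per-cell rates with genotype labels.

    ``per_cell`` columns: genotype, cell_id, rate_kb_per_hr (NaN when
    censored), upper_bound_kb_per_hr (NaN when uncensored), censored.
    """

    per_cell: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["genotype", "cell_id", "rate_kb_per_hr", "upper_bound_kb_per_hr", "censored"]
        )
    )

    def rates(self, genotype: str) -> np.ndarray:
        """Uncensored rates for one genotype."""
        df = self.per_cell
        sel = (df["genotype"] == genotype) & (~df["censored"])
        return df.loc[sel, "rate_kb_per_hr"].to_numpy(dtype=float)

    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.per_cell["genotype"]))

    def summary(self) -> pd.DataFrame:
        """Per-genotype n, censored count, and median of uncensored rates.

        A genotype whose events are mostly censored gets median NaN and the
        label "N.D." — its rate cannot be determined, only bounded.
        """
        rows = []
        for g in self.genotypes():
            sub = self.per_cell[self.per_cell["genotype"] == g]
            n_cens = int(sub["censored"].sum())
            unc = sub.loc[~sub["censored"], "rate_kb_per_hr"].to_numpy(dtype=float)
            determined = len(unc) > 0 and len(unc) >= n_cens
            median = float(np.median(unc)) if determined else float("nan")
            rows.append(
                dict(
                    genotype=g,
                    n=len(sub),
                    n_censored=n_cens,
                    median_kb_per_hr=median,
                    label=f"{median:.2f}" if determined else "N.D.",
                    max_upper_bound_kb_per_hr=(
                        float(sub.loc[sub["censored"], "upper_bound_kb_per_hr"].max())
                        if n_cens
                        else float("nan")
                    ),
                )
            )
        return pd.DataFrame(rows)


def events_to_rates(
    events: list[ResectionEvent], geometry: CassetteGeometry = DEFAULT_GEOMETRY
) -> GenotypeRateTable:
    """Map called events to per-cell rates / censored upper bounds."""
    rows = []
    for e in events:
        if e.censored:
            rows.append(
                dict(
                    genotype=e.genotype,
                    cell_id=e.cell_id,
                    rate_kb_per_hr=float("nan"),
                    upper_bound_kb_per_hr=censored_upper_bound(e.observed_window_min, geometry),
                    censored=True,
                )
            )
        else:
            rows.append(
                dict(
                    genotype=e.genotype,
                    cell_id=e.cell_id,
                    rate_kb_per_hr=duration_to_rate(e.duration_min, geometry),
                    upper_bound_kb_per_hr=float("nan"),
                    censored=False,
                )
            )
    if not rows:
        return GenotypeRateTable()
    return GenotypeRateTable(per_cell=pd.DataFrame(rows))


def pairwise_tests(
    table: GenotypeRateTable,
    pairs: list[tuple[str, str]] | None = None,
    equal_var: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-tailed pairwise t-tests with Bonferroni correction.

    ``pairs`` defaults to all genotype pairs with ≥ 2 uncensored rates each;
    pairs with insufficient n are skipped with a notice and do not count
    toward the Bonferroni family size m. adjusted p = min(1, raw p × m).
    """
    if pairs is None:
        gs = [g for g in table.genotypes() if len(table.rates(g)) >= 2]
        pairs = list(itertools.combinations(gs, 2))
    tested = []
    for a, b in pairs:
        ra, rb = table.rates(a), table.rates(b)
        if len(ra) < 2 or len(rb) < 2:
            warnings.warn(
                f"pair ({a}, {b}) skipped: needs >= 2 uncensored rates per genotype "
                f"(got {len(ra)}, {len(rb)})",
                stacklevel=2,
            )
            continue
        res = stats.ttest_ind(ra, rb, equal_var=equal_var)
        tested.append((a, b, len(ra), len(rb), float(res.statistic), float(res.pvalue)))
    m = len(tested)
    rows = [
        dict(
            genotype_a=a,
            genotype_b=b,
            n_a=na,
            n_b=nb,
            t=t,
            p_raw=p,
            p_adj=min(1.0, p * m),
            m=m,
            significant=min(1.0, p * m) < alpha,
        )
        for a, b, na, nb, t, p in tested
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "genotype_a",
            "genotype_b",
            "n_a",
            "n_b",
            "t",
            "p_raw",
            "p_adj",
            "m",
            "significant",
        ],
    )


def plot_rates(table: GenotypeRateTable, path, seed: int = 0) -> None:
    """Dot plot of single-cell rates with a median bar per genotype."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(1.2 * max(1, len(table.genotypes())) + 1.5, 4))
    for i, g in enumerate(table.genotypes()):
        r = table.rates(g)
        if len(r):
            x = i + rng.uniform(-0.15, 0.15, len(r))
            ax.plot(x, r, "o", ms=4, alpha=0.6, color="C0")
            ax.hlines(np.median(r), i - 0.25, i + 0.25, color="red", lw=2)
        sub = table.per_cell[(table.per_cell["genotype"] == g) & table.per_cell["censored"]]
        if len(sub):
            ub = sub["upper_bound_kb_per_hr"].to_numpy()
            x = i + rng.uniform(-0.15, 0.15, len(ub))
            ax.plot(x, ub, "v", ms=4, alpha=0.5, color="gray")
    ax.set_xticks(range(len(table.genotypes())))
    ax.set_xticklabels(table.genotypes())
    ax.set_ylabel("long-range resection rate (kb/hr)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
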