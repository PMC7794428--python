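"""Fertilisation dosing arithmetic and the dose-response correlation.

The number of motile sperm offered per egg is the planning quantity: it is
linear in the dose volume and motile concentration and inverse-linear in the
egg count, and fertilisation success is tested against its base-10 logarithm
with a Pearson correlation (log-transformed because success rises roughly
linearly with the log of the dose).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FertilisationRecord",
    "CorrelationResult",
    "egg_sperm_ratio",
    "required_volume",
    "fertilisation_rate",
    "fert_correlation",
    "plot_fert_correlation",
]


@dataclass(frozen=True)
class FertilisationRecord:
    """One in-vitro cross: dose on one side, cleavage outcome on the other."""

    sample_id: str
    motile_concentration_cells_ml: float
    sperm_volume_ul: float
    n_eggs: int
    n_cleaved: int | None = None
    n_uncleaved: int | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.n_eggs < 0:
            raise ValueError("n_eggs cannot be negative")
        if not self.sperm_volume_ul > 0:
            raise ValueError("sperm_volume_ul must be positive")
        if self.motile_concentration_cells_ml < 0:
            raise ValueError("motile concentration cannot be negative")
        if self.has_outcome:
            if self.n_cleaved < 0 or self.n_uncleaved < 0:
                raise ValueError("cleavage counts cannot be negative")
            if self.n_cleaved + self.n_uncleaved != self.n_eggs:
                raise ValueError(
                    f"cleaved + uncleaved ({self.n_cleaved} + {self.n_uncleaved}) "
                    f"must equal n_eggs ({self.n_eggs})"
                )

    @property
    def has_outcome(self) -> bool:
        return self.n_cleaved is not None and self.n_uncleaved is not None

    @property
    def ratio_cells_per_egg(self) -> float:
        return egg_sperm_ratio(
            self.motile_concentration_cells_ml, self.sperm_volume_ul, self.n_eggs
        )

    @property
    def fertilisation_rate_pct(self) -> float:
        if not self.has_outcome:
            raise ValueError(f"record {self.sample_id} has no cleavage outcome")
        return fertilisation_rate(self.n_cleaved, self.n_uncleaved)


def egg_sperm_ratio(
    motile_concentration_cells_ml: float, sperm_volume_ul: float, n_eggs: int
) -> float:
    """Motile cells offered per egg: ``conc x volume(mL) / eggs``."""
    if n_eggs < 1:
        raise ValueError(f"n_eggs must be at least 1, got {n_eggs}")
    if not sperm_volume_ul > 0:
        raise ValueError("sperm_volume_ul must be positive")
    return motile_concentration_cells_ml * sperm_volume_ul * 1e-3 / n_eggs


def required_volume(
    target_ratio_cells_per_egg: float,
    motile_concentration_cells_ml: float,
    n_eggs: int,
) -> float:
    """Dose volume (µL) delivering a target motile-cells-per-egg ratio.

    Exact inverse of :func:`egg_sperm_ratio`:
    ``required_volume(egg_sperm_ratio(c, v, n), c, n) == v``.
    """
    if not motile_concentration_cells_ml > 0:
        raise ValueError("motile concentration must be positive")
    if n_eggs < 1:
        raise ValueError(f"n_eggs must be at least 1, got {n_eggs}")
    return target_ratio_cells_per_egg * n_eggs / motile_concentration_cells_ml * 1e3


def fertilisation_rate(n_cleaved: int, n_uncleaved: int) -> float:
    """Percentage of counted eggs that cleaved."""
    total = n_cleaved + n_uncleaved
    if total < 1:
        raise ValueError("need at least one counted egg")
    if n_cleaved < 0 or n_uncleaved < 0:
        raise ValueError("egg counts cannot be negative")
    return 100.0 * n_cleaved / total


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of success vs log10(motile cells per egg)."""

    r: float
    p_value: float
    slope: float  # percentage points per log10(cells/egg)
    intercept: float
    n: int

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p_value": self.p_value,
            "slope_pct_per_log10": self.slope,
            "intercept_pct": self.intercept,
            "n": self.n,
        }


def _ratios_and_rates(
    records: list[FertilisationRecord],
) -> tuple[np.ndarray, np.ndarray]:
    scored = [r for r in records if r.has_outcome]
    if len(scored) < 3:
        raise ValueError(
            f"need at least 3 records with cleavage outcomes, got {len(scored)}"
        )
    ratios = np.array([r.ratio_cells_per_egg for r in scored])
    if (ratios <= 0).any():
        bad = [r.sample_id for r, x in zip(scored, ratios) if x <= 0]
        raise ValueError(
            f"records {bad} have non-positive motile-cells-per-egg ratios; "
            "the log transform requires strictly positive doses"
        )
    rates = np.array([r.fertilisation_rate_pct for r in scored])
    return ratios, rates


def fert_correlation(records: list[FertilisationRecord]) -> CorrelationResult:
    """Pearson r (two-sided p) and least-squares line of success vs log dose.

    The predictor is log10 of motile cells per egg; r itself is invariant to
    the logarithm base (only the fitted slope rescales).
    """
    ratios, rates = _ratios_and_rates(records)
    log_ratio = np.log10(ratios)
    fit = stats.linregress(log_ratio, rates)
    return CorrelationResult(
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(ratios),
    )


def plot_fert_correlation(records: list[FertilisationRecord], path: str) -> None:
    """Scatter of fertilisation success vs dose on a log-scaled x axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ratios, rates = _ratios_and_rates(records)
    result = fert_correlation(records)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ratios, rates, s=18, alpha=0.8)
    grid = np.geomspace(ratios.min(), ratios.max(), 100)
    ax.plot(grid, result.intercept + result.slope * np.log10(grid), "k--", lw=1)
    ax.set_xscale("log")
    ax.set_xlabel("motile sperm per egg")
    ax.set_ylabel("fertilisation success (%)")
    ax.set_title(f"r = {result.r:.3f}, p = {result.p_value:.2e}, n = {result.n}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
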