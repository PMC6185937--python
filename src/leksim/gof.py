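"""Binned Pearson chi-squared compatibility test for point patterns.

An observed neighbor-count distribution T(n) is compared with a model
distribution F(n) after aggregating counts into five bins
{n < 5, n = 5, n = 6, n = 7, n > 7}:

    chi2 = N0 * [ (sum_{n<5} (F - T))^2 / sum_{n<5} F
                + (F(5) - T(5))^2 / F(5)
                + (F(6) - T(6))^2 / F(6)
                + (F(7) - T(7))^2 / F(7)
                + (sum_{n>7} (F - T))^2 / sum_{n>7} F ],

where N0 is the size of the *observed* sample, and the statistic is
referred to a chi-squared distribution with 4 degrees of freedom
(5 bins - 1; no reduction for scanned model parameters).  At the 0.05
level the critical value is 9.49.  Scanning the test over a grid of
model parameter cells yields the compatibility map: the region of
(phi, rho) space whose converged configurations are statistically
indistinguishable from the observed pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "BIN_LABELS",
    "BinnedDistribution",
    "bin_distribution",
    "chi2_statistic",
    "chi2_test",
    "critical_value",
    "GofResult",
    "compatibility_map",
]

BIN_LABELS = ("n<5", "n=5", "n=6", "n=7", "n>7")
DOF = 4
ALPHA = 0.05


@dataclass(frozen=True)
class BinnedDistribution:
    """Five-bin probability masses over neighbor counts plus sample size."""

    masses: np.ndarray  # shape (5,), sums to 1
    n_obs: int

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        if m.shape != (5,):
            raise ValueError("masses must have exactly five bins")
        if np.any(m < 0) or abs(m.sum() - 1.0) > 1e-12:
            raise ValueError("masses must be non-negative and sum to 1")
        object.__setattr__(self, "masses", m)


def bin_distribution(dist: Mapping[int, int] | np.ndarray) -> BinnedDistribution:
    """Aggregate a frequency map {neighbor count -> count} into the five bins.

    Also accepts a raw array of per-individual neighbor counts.
    """
    if isinstance(dist, Mapping):
        items = [(int(n), int(c)) for n, c in dist.items()]
        if any(c < 0 for _, c in items):
            raise ValueError("counts must be non-negative")
        values = np.array([n for n, _ in items])
        counts = np.array([c for _, c in items], dtype=float)
    else:
        values, raw = np.unique(np.asarray(dist, dtype=int), return_counts=True)
        counts = raw.astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("distribution has no observations")
    bins = np.zeros(5)
    bins[0] = counts[values < 5].sum()
    bins[1] = counts[values == 5].sum()
    bins[2] = counts[values == 6].sum()
    bins[3] = counts[values == 7].sum()
    bins[4] = counts[values > 7].sum()
    return BinnedDistribution(masses=bins / total, n_obs=int(total))


def chi2_statistic(T: BinnedDistribution, F: BinnedDistribution) -> float:
    """The binned Pearson statistic N0 * sum (F - T)^2 / F.

    N0 is the observed sample size ``T.n_obs``.  Every model bin mass
    must be positive; a zero F bin makes the statistic undefined.
    """
    f = F.masses
    t = T.masses
    if np.any(f <= 0):
        empty = [BIN_LABELS[i] for i in np.nonzero(f <= 0)[0]]
        raise ValueError(
            f"model distribution has zero mass in bin(s) {empty}; "
            "pool bins or use a model with full support"
        )
    return float(T.n_obs * np.sum((f - t) ** 2 / f))


def critical_value(alpha: float = ALPHA) -> float:
    """Upper critical value of chi-squared with 4 dof at level alpha."""
    return float(chi2_dist.ppf(1.0 - alpha, DOF))


@dataclass(frozen=True)
class GofResult:
    chi2: float
    dof: int
    p_value: float
    accepted: bool


def chi2_test(chi2: float, alpha: float = ALPHA) -> GofResult:
    """Refer a statistic to chi-squared with 4 dof; accept iff p >= alpha."""
    if chi2 < 0:
        raise ValueError("chi-squared statistic must be non-negative")
    p = float(chi2_dist.sf(chi2, DOF))
    return GofResult(chi2=float(chi2), dof=DOF, p_value=p, accepted=bool(p >= alpha))


def compatibility_map(
    observed: Mapping[int, int] | np.ndarray,
    model_dists: Mapping[tuple[float, float], Mapping[int, int] | None],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Chi-squared compatibility of an observed pattern across parameter cells.

    Parameters
    ----------
    observed
        Neighbor-count frequency map (or raw counts) of the observed
        pattern; its total is the N0 entering every statistic.
    model_dists
        Mapping ``(phi, rho) -> pooled model frequency map`` from a
        parameter sweep; ``None`` marks cells without any converged
        replicate, which are reported as unavailable.

    Returns
    -------
    DataFrame with columns phi, rho, chi2, p, accepted, available.
    """
    T = bin_distribution(observed)
    rows = []
    for (phi, rho), dist in sorted(model_dists.items()):
        if dist is None:
            rows.append(
                {"phi": phi, "rho": rho, "chi2": np.nan, "p": np.nan,
                 "accepted": False, "available": False}
            )
            continue
        F = bin_distribution(dist)
        # a bin empty in the model but occupied in the observation is
        # incompatible outright (the statistic diverges); a bin empty
        # in both contributes nothing
        zero = F.masses <= 0
        if np.any(zero & (T.masses > 0)):
            res = GofResult(chi2=float("inf"), dof=DOF, p_value=0.0, accepted=False)
        else:
            keep = ~zero
            stat = float(T.n_obs * np.sum((F.masses[keep] - T.masses[keep]) ** 2 / F.masses[keep]))
            res = chi2_test(stat, alpha=alpha)
        rows.append(
            {"phi": phi, "rho": rho, "chi2": res.chi2, "p": res.p_value,
             "accepted": res.accepted, "available": True}
        )
    return pd.DataFrame(rows)
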