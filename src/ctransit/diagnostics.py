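"""Homogeneity diagnostics and pooling of backward transit-time densities.

Two dimensionless ratios summarize how far a transit-time distribution
is from the one-pool (exponential) limit:

* ``h = median / (ln 2 * mean)`` — equals 1 for an exponential
  distribution (whose median is ln 2 times its mean) and shrinks as a
  long tail of old carbon inflates the mean relative to the median;
* ``h' = mean transit time / mean system age`` — equals 1 for a
  one-pool system, where stored and respired carbon share one age
  distribution.

The aggregation operator pools BTT distributions of independent
sub-systems ("grid cells") sharing an age grid by summing their
respiration-age densities — mass-weighted, never on normalized pdfs, so
pooling is well defined; normalization happens last.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nonautonomous import BTTDistribution

__all__ = ["homogeneity_h", "homogeneity_hprime", "homogeneity_series", "aggregate_btt"]

LN2 = float(np.log(2.0))


def homogeneity_h(median, mean):
    """Homogeneity ratio ``h = median / (ln 2 * mean)`` (vectorized)."""
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("mean transit time must be positive")
    out = np.asarray(median, dtype=float) / (LN2 * mean)
    return float(out) if out.ndim == 0 else out


def homogeneity_hprime(mean_transit_time, mean_system_age):
    """Ratio ``h' = E_b / E_A`` of mean transit time to mean system age."""
    ea = np.asarray(mean_system_age, dtype=float)
    if np.any(ea <= 0):
        raise ValueError("mean system age must be positive")
    out = np.asarray(mean_transit_time, dtype=float) / ea
    return float(out) if out.ndim == 0 else out


def homogeneity_series(summary: pd.DataFrame) -> pd.DataFrame:
    """Diagnostics table from a BTT summary series.

    Expects columns ``time``, ``mean_btt``, ``median_btt`` and
    optionally ``mean_age`` (for ``h_prime``).
    """
    out = pd.DataFrame({"time": summary["time"]})
    out["h"] = homogeneity_h(summary["median_btt"].to_numpy(), summary["mean_btt"].to_numpy())
    if "mean_age" in summary.columns:
        out["h_prime"] = homogeneity_hprime(summary["mean_btt"].to_numpy(), summary["mean_age"].to_numpy())
    return out


def aggregate_btt(cells: list[BTTDistribution]) -> BTTDistribution:
    """Pool the respiration-age densities of several sub-systems.

    All members must share the age grid and evaluation time (no silent
    resampling — it can shift medians at the 0.1-yr scale that matters).
    Total respiration adds exactly; summaries are recomputed from the
    pooled density.
    """
    if not cells:
        raise ValueError("nothing to aggregate")
    first = cells[0]
    for c in cells[1:]:
        if c.ages.shape != first.ages.shape or not np.array_equal(c.ages, first.ages):
            raise ValueError("age grids differ between aggregated distributions")
        if c.time != first.time:
            raise ValueError("evaluation times differ between aggregated distributions")
    return BTTDistribution(
        time=first.time,
        ages=first.ages.copy(),
        density=np.sum([c.density for c in cells], axis=0),
        overflow_mass=float(sum(c.overflow_mass for c in cells)),
        overflow_moment=float(sum(c.overflow_moment for c in cells)),
    )
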