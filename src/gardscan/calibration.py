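"""Logit recentering of a p-value collection.

Gene-level aggregation tests can produce badly mis-centred null p-value
distributions (e.g. a mass of p-values piled near 1).  The logit
adjustment transforms p to z = ln(p/(1-p)), subtracts a location statistic
(median by default) so the logit values are centred at zero, and maps
back.  The transform is strictly monotone, so ranks — and hence every
rank-based downstream analysis — are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CalibratedPvalues", "logit_adjust"]


@dataclass
class CalibratedPvalues:
    table: pd.DataFrame          # columns: unit, p_raw, p_adjusted
    center: float                # the subtracted logit offset

    def as_dict(self) -> dict:
        return dict(zip(self.table["unit"], self.table["p_adjusted"]))


def logit_adjust(pvalues, units=None, center_stat: str = "median",
                 clamp_eps: float = 1e-15) -> CalibratedPvalues:
    """Centre logit p-values at zero, keeping rank order.

    Parameters
    ----------
    pvalues : array-like of p in (0, 1]
        At least 3 values.  Values are clamped to
        ``[clamp_eps, 1 - clamp_eps]`` before the transform, so ties at
        p = 1 stay tied.
    units : sequence, optional
        Labels (gene or term names); defaults to positional indices.
    center_stat : {"median", "mean"}
        Location statistic subtracted on the logit scale.  The median is
        the default because a cluster of p near 1 would dominate a mean.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 3:
        raise ValueError("need at least 3 p-values")
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if units is None:
        units = np.arange(p.size)
    pc = np.clip(p, clamp_eps, 1 - clamp_eps)
    z = np.log(pc / (1 - pc))
    if center_stat == "median":
        center = float(np.median(z))
    elif center_stat == "mean":
        center = float(np.mean(z))
    else:
        raise ValueError(f"unknown center_stat {center_stat!r}")
    adj = 1.0 / (1.0 + np.exp(-(z - center)))
    # recentering can push an extreme logit past float resolution at the
    # ends of (0,1); clamp so adjusted values stay strictly inside
    adj = np.clip(adj, clamp_eps, 1 - clamp_eps)
    table = pd.DataFrame({"unit": list(units), "p_raw": p, "p_adjusted": adj})
    return CalibratedPvalues(table=table, center=center)
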