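"""The comparator: RD from the pooled 2x2 table, ignoring centers.

rd = e1/n1 - e0/n0 with the Wald standard error
sqrt(p1(1-p1)/n1 + p0(1-p0)/n0) and interval rd ± 1.96 * SE.  No cluster
adjustment and no small-sample correction apply.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data import TrialData, summarize_2x2
from .exceptions import DataError

__all__ = ["unadjusted_rd"]


def unadjusted_rd(data_or_counts, *counts) -> "RDEstimate":
    """Unadjusted 2x2 risk difference.

    Accepts either a :class:`~rdgee.data.TrialData` or four integers
    ``(n1, e1, n0, e0)`` — active size/events then control size/events.
    """
    from .estimate import RDEstimate, Z95  # deferred: estimate imports this module

    if isinstance(data_or_counts, TrialData):
        n1, e1, n0, e0 = summarize_2x2(data_or_counts)
    else:
        n1, e1, n0, e0 = (int(data_or_counts), *map(int, counts))
    if n1 <= 0 or n0 <= 0:
        raise DataError("both arms must be non-empty")
    if not (0 <= e1 <= n1 and 0 <= e0 <= n0):
        raise DataError("events must lie in [0, arm size]")
    p1, p0 = e1 / n1, e0 / n0
    rd = p1 - p0
    se = float(np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0))
    if se == 0.0:
        warnings.warn(
            "degenerate 2x2 table (boundary proportions): Wald SE is 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return RDEstimate(
        rd=float(rd),
        se_raw=se,
        se_corrected=se,  # no small-sample correction for the pooled table
        ci_low=float(rd - Z95 * se),
        ci_high=float(rd + Z95 * se),
        method="unadjusted",
        n_used=n1 + n0,
    )
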