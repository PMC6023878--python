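"""Nonparametric statistics helpers shared by the pipeline stages."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["wilcoxon_signed_rank_one_sample", "bonferroni"]


def wilcoxon_signed_rank_one_sample(
    values: np.ndarray, null_median: float = 0.0
) -> tuple[float, float]:
    """Two-sided one-sample Wilcoxon signed-rank test against `null_median`.

    Returns (statistic, p).  Values equal to the null median are discarded
    (standard practice); an all-tied sample is rejected.
    """
    x = np.asarray(values, dtype=float) - null_median
    x = x[np.isfinite(x)]
    x = x[x != 0]
    if x.size == 0:
        raise ValueError("all values equal the null median; test undefined")
    res = sps.wilcoxon(x, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: np.ndarray) -> np.ndarray:
    """Bonferroni adjustment: p * m clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * p.size, 1.0)
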