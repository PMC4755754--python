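"""Statistical helpers: Welch t-test and Holm–Bonferroni adjustment."""
from __future__ import annotations

import numpy as np
from scipy import stats as _scipy_stats
from statsmodels.stats.multitest import multipletests

__all__ = ["holm_bonferroni", "two_sample_t"]


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, ≥ raw, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="holm")
    return adjusted


def two_sample_t(a, b) -> tuple[float, float]:
    """Welch (unequal-variance) two-sample t-test: (statistic, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    t, p = _scipy_stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
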