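"""Cross-site combination of comorbidity Z scores.

Per-site comorbidity Zs for a phecode pair are combined into one measure by
the shared-patient-weighted average

    Z_combined = sum_s(Z_s * N_s) / sum_s(N_s)

where N_s is the number of patients who are cases for both phecodes at site
s.  Two-sided p-values follow from the standard normal, and multiple
testing is controlled by Bonferroni over the number of tests actually
performed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_TINY = np.nextafter(0.0, 1.0)


def combine_sites(site_results: pd.DataFrame) -> pd.DataFrame:
    """Weighted-average Z over sites, one row per phecode pair.

    ``site_results`` needs columns ``phecode_a, phecode_b, site, z_site,
    n_shared``.  Sites with a missing ``z_site`` are dropped for that pair;
    if every contributing site has zero shared cases the unweighted mean is
    used (logged).  Pairs with no usable site are reported with NaN.
    Output columns: ``phecode_a, phecode_b, z_combined, n_shared_total,
    n_sites, single_site``.
    """
    rows = []
    for (a, b), grp in site_results.groupby(["phecode_a", "phecode_b"], sort=True):
        usable = grp[np.isfinite(grp["z_site"])]
        n_total = int(grp["n_shared"].sum())
        if usable.empty:
            rows.append((a, b, np.nan, n_total, 0, False))
            continue
        z = usable["z_site"].to_numpy(float)
        w = usable["n_shared"].to_numpy(float)
        if w.sum() > 0:
            z_comb = float(np.sum(z * w) / w.sum())
        else:
            logger.info("pair (%s,%s): all weights zero, unweighted mean used", a, b)
            z_comb = float(z.mean())
        rows.append((a, b, z_comb, n_total, len(usable), len(usable) == 1))
    out = pd.DataFrame(
        rows,
        columns=[
            "phecode_a", "phecode_b", "z_combined",
            "n_shared_total", "n_sites", "single_site",
        ],
    )
    return out


def z_to_p(z) -> np.ndarray | float:
    """Two-sided normal p-value: p = 2 * Phi(-|z|); non-finite z -> NaN."""
    z = np.asarray(z, dtype=float)
    p = np.where(np.isfinite(z), 2.0 * stats.norm.cdf(-np.abs(z)), np.nan)
    # never report exactly 0: underflow is clamped to the smallest positive float
    p = np.where(p == 0.0, _TINY, p)
    return p if p.ndim else float(p)


def bonferroni_flag(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float, int]:
    """Bonferroni flags over the tests actually performed.

    Returns (flags, threshold, n_tests) with threshold = alpha / n_tests
    and flag <=> p < threshold (strict).  NaN p-values do not count as
    tests and are never flagged.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    n_tests = int(np.isfinite(p).sum())
    if n_tests == 0:
        raise ValueError("no finite p-values supplied")
    threshold = alpha / n_tests
    flags = np.where(np.isfinite(p), p < threshold, False)
    return flags, threshold, n_tests


def profile_correlation(vec_a, vec_b) -> tuple[float, float]:
    """Pearson correlation of two aligned Z-score profiles.

    Missing entries are pairwise-dropped; fewer than 3 shared finite
    entries is an error.  Returns (r, two-sided p from the t transform).
    """
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must be aligned to the same length")
    keep = np.isfinite(a) & np.isfinite(b)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 shared finite entries")
    res = stats.pearsonr(a[keep], b[keep])
    return float(res.statistic), float(res.pvalue)
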