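"""Equivalence testing of polygenic-score distributions by TOST.

The two one-sided tests (TOST) procedure declares the score distributions
of phenotype cases and controls statistically *equivalent* when both
one-sided tests reject: one against the hypothesis that the standardized
mean difference lies at or below the lower bound, one against the
hypothesis that it lies at or above the upper bound.  Bounds are given as
Cohen's d (default +/-0.2) and converted to the raw scale with
s_pool = sqrt((sd1^2 + sd2^2) / 2).  The one-sided tests are Welch t tests
with Satterthwaite degrees of freedom (a pooled-variance variant is
available).  Per-site TOST p-values for one phenotype are combined across
sites by Fisher's method: chi2 = -2 sum(ln p), referred to a chi-square
with 2k degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_TINY = np.nextafter(0.0, 1.0)

DEFAULT_BOUNDS = (-0.2, 0.2)


@dataclass(frozen=True)
class TostInput:
    phecode: str
    site: str
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float
    d_low: float = DEFAULT_BOUNDS[0]
    d_high: float = DEFAULT_BOUNDS[1]

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("TOST needs n >= 2 in each group")
        if not (self.sd1 > 0 and self.sd2 > 0):
            raise ValueError("TOST needs positive SD in each group")
        if not self.d_low < 0 < self.d_high:
            raise ValueError("equivalence bounds must straddle zero")


@dataclass(frozen=True)
class TostResult:
    phecode: str
    site: str
    t_lower: float
    t_upper: float
    p_lower: float
    p_upper: float
    p_tost: float
    df: float


@dataclass(frozen=True)
class MetaEquivalence:
    phecode: str
    chi2: float
    df: int
    p_meta: float
    n_sites: int
    clamped: bool = False


def tost_from_summary(
    n1, mean1, sd1, n2, mean2, sd2,
    d_low: float = DEFAULT_BOUNDS[0],
    d_high: float = DEFAULT_BOUNDS[1],
    variant: str = "welch",
):
    """Vectorized TOST from group summary statistics.

    Cohen's-d bounds are converted to raw bounds via
    s_pool = sqrt((sd1^2 + sd2^2)/2); then

        t_upper = ((m1 - m2) - d_low * s_pool) / SE   rejects d <= d_low
        t_lower = ((m1 - m2) - d_high * s_pool) / SE  rejects d >= d_high

    with SE and df from Welch (default) or pooled-variance t.  Each
    one-sided p rejects toward the interior of the bounds; the TOST p is
    the larger of the two.  All arguments broadcast.

    Returns a dict of arrays (scalars in -> scalars out):
    ``t_lower, t_upper, p_lower, p_upper, p_tost, df``.
    """
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    mean1 = np.asarray(mean1, float)
    mean2 = np.asarray(mean2, float)
    sd1 = np.asarray(sd1, float)
    sd2 = np.asarray(sd2, float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("TOST needs n >= 2 in each group")
    if np.any(sd1 <= 0) or np.any(sd2 <= 0):
        raise ValueError("TOST needs positive SD in each group")
    if not d_low < 0 < d_high:
        raise ValueError("equivalence bounds must straddle zero")

    v1, v2 = sd1**2, sd2**2
    s_pool = np.sqrt((v1 + v2) / 2.0)
    if variant == "welch":
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    elif variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        raise ValueError(f"unknown TOST variant {variant!r}")

    diff = mean1 - mean2
    t_upper = (diff - d_low * s_pool) / se
    t_lower = (diff - d_high * s_pool) / se
    p_upper = stats.t.sf(t_upper, df)   # H0: d <= d_low, reject for large t
    p_lower = stats.t.cdf(t_lower, df)  # H0: d >= d_high, reject for small t
    p_tost = np.maximum(p_lower, p_upper)
    squeeze = lambda x: float(x) if np.ndim(x) == 0 else x
    return {
        "t_lower": squeeze(t_lower),
        "t_upper": squeeze(t_upper),
        "p_lower": squeeze(p_lower),
        "p_upper": squeeze(p_upper),
        "p_tost": squeeze(p_tost),
        "df": squeeze(df),
    }


def tost_equivalence(inp: TostInput, variant: str = "welch") -> TostResult:
    """TOST of one phenotype at one site from summary statistics."""
    r = tost_from_summary(
        inp.n1, inp.mean1, inp.sd1, inp.n2, inp.mean2, inp.sd2,
        inp.d_low, inp.d_high, variant,
    )
    return TostResult(
        phecode=inp.phecode, site=inp.site,
        t_lower=r["t_lower"], t_upper=r["t_upper"],
        p_lower=r["p_lower"], p_upper=r["p_upper"],
        p_tost=r["p_tost"], df=r["df"],
    )


def tost_from_scores(
    phecode: str, site: str, case_scores, control_scores,
    d_low: float = DEFAULT_BOUNDS[0], d_high: float = DEFAULT_BOUNDS[1],
    variant: str = "welch",
) -> TostResult:
    """TOST from raw per-individual scores (summarized internally)."""
    x = np.asarray(case_scores, float)
    y = np.asarray(control_scores, float)
    inp = TostInput(
        phecode, site,
        n1=len(x), mean1=float(x.mean()), sd1=float(x.std(ddof=1)),
        n2=len(y), mean2=float(y.mean()), sd2=float(y.std(ddof=1)),
        d_low=d_low, d_high=d_high,
    )
    return tost_equivalence(inp, variant)


def fisher_combine(p_values, phecode: str = "") -> MetaEquivalence:
    """Fisher's method across sites: chi2 = -2 sum(ln p) on 2k df.

    Zero p-values are clamped to the smallest positive float and flagged.
    With a single p the combination is the identity.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    clamped = bool(np.any(p == 0))
    p = np.where(p == 0, _TINY, p)
    chi2 = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    p_meta = float(stats.chi2.sf(chi2, df))
    return MetaEquivalence(
        phecode=phecode, chi2=chi2, df=df, p_meta=max(p_meta, _TINY),
        n_sites=p.size, clamped=clamped,
    )


def flag_equivalent(
    meta: list[MetaEquivalence] | pd.DataFrame,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> tuple[np.ndarray, float]:
    """Bonferroni flags for equivalence: p_meta < alpha / n_tests (strict).

    ``n_tests`` defaults to the number of phenotypes that entered the
    meta-analysis.  Returns (flags, threshold).
    """
    if isinstance(meta, pd.DataFrame):
        p = meta["p_meta"].to_numpy(float)
    else:
        p = np.array([m.p_meta for m in meta], float)
    if n_tests is None:
        n_tests = p.size
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    threshold = alpha / n_tests
    return p < threshold, threshold
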