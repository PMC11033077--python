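"""Phenome-wide pairwise logistic comorbidity scan against an index phecode.

Each ordered (outcome, predictor) phecode pair is fitted per site as a
logistic regression of outcome case status on the predictor-case indicator
plus demographic covariates and the log number of unique phecodes (total
illness).  The two directional Wald Z scores are then combined into one
per-site comorbidity Z (default: arithmetic mean of the converged
directions).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .phecodes import CASE, CONTROL, PhenotypeStatusMatrix

logger = logging.getLogger(__name__)

DIRECTION_RULES = ("mean", "outcome_direction_only", "stouffer")

#: covariate specification used throughout the comorbidity scan:
#: (numeric columns, categorical columns) drawn from the demographics table
DEFAULT_COVARIATES = (
    ("current_age", "ehr_age", "log_unique_phecodes"),
    ("sex", "race"),
)

# |beta| beyond this is treated as (quasi-)separation even if the optimiser
# claims convergence
_BETA_CAP = 15.0


@dataclass(frozen=True)
class DirectionalAssociation:
    outcome_phecode: str
    predictor_phecode: str
    site: str
    beta: float
    se: float
    z: float
    n_case: int
    n_control: int
    converged: bool
    skip_reason: str | None = None


@dataclass(frozen=True)
class SitePairComorbidity:
    phecode_a: str  # index phecode
    phecode_b: str
    site: str
    z_forward: float  # outcome = b, predictor = a
    z_reverse: float  # outcome = a, predictor = b
    z_site: float
    n_shared: int
    n_case: int
    n_control: int
    converged_forward: bool
    converged_reverse: bool


def build_design(
    demo: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Covariate design matrix: numeric columns plus dummy-coded categoricals.

    The reference level of each categorical is its modal category;
    "unknown" is always a retained (non-reference) level unless it is
    itself the mode.
    """
    numeric, categorical = covariates
    parts = [demo[list(numeric)].astype(float)] if numeric else []
    for col in categorical:
        series = demo[col].astype(str)
        ref = series.mode().iloc[0]
        levels = [lv for lv in sorted(series.unique()) if lv != ref]
        for lv in levels:
            parts.append((series == lv).astype(float).rename(f"{col}[{lv}]"))
    if not parts:
        return pd.DataFrame(index=demo.index)
    return pd.concat(parts, axis=1)


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Logistic ML fit; returns the statsmodels result or None on
    separation/non-convergence."""
    model = sm.Logit(y, X)
    try:
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            res = model.fit(disp=0, maxiter=100, warn_convergence=False)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return None
    if not res.mle_retvals.get("converged", False):
        return None
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > _BETA_CAP):
        return None
    return res


def fit_pairwise_logistic(
    status: PhenotypeStatusMatrix,
    demo: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates=DEFAULT_COVARIATES,
    min_cases: int = 20,
    site: str = "",
) -> DirectionalAssociation:
    """Logistic regression of ``outcome`` case status on ``predictor`` case status.

    Patients with missing status for either phecode are dropped; the fit
    runs on the remaining case (1) vs control (0) patients with the
    predictor-case indicator and the covariate design.  Non-convergence or
    separation yields ``converged=False`` with ``z`` missing.
    """

    def _skip(reason: str, n_case=0, n_control=0) -> DirectionalAssociation:
        return DirectionalAssociation(
            outcome, predictor, site, np.nan, np.nan, np.nan,
            n_case, n_control, False, reason,
        )

    y_all = status.status[outcome]
    x_all = status.status[predictor]
    keep = (y_all != -1) & (x_all != -1)
    idx = status.patients[keep].intersection(demo.index)
    y = y_all.loc[idx].to_numpy()
    x = x_all.loc[idx].to_numpy().astype(float)
    n_case, n_control = int((y == CASE).sum()), int((y == CONTROL).sum())
    if n_case < min_cases or int(x.sum()) < min_cases:
        return _skip("min_cases", n_case, n_control)
    if n_case == 0 or n_control == 0:
        return _skip("degenerate_outcome", n_case, n_control)
    # perfect concordance of outcome and predictor separates exactly
    if np.array_equal(y.astype(float), x) or np.array_equal(1.0 - y, x):
        return _skip("separation", n_case, n_control)

    X = build_design(demo.loc[idx], covariates)
    X.insert(0, "predictor", x)
    X.insert(0, "const", 1.0)
    res = _fit_logit(y, X)
    if res is None:
        return _skip("nonconvergence", n_case, n_control)
    beta = float(res.params["predictor"])
    se = float(res.bse["predictor"])
    return DirectionalAssociation(
        outcome, predictor, site, beta, se, beta / se, n_case, n_control, True
    )


def combine_directions(
    forward: DirectionalAssociation,
    reverse: DirectionalAssociation,
    rule: str = "mean",
) -> float:
    """One per-site comorbidity Z from the two directional fits.

    Rules: ``mean`` (default) — arithmetic mean of converged Zs;
    ``outcome_direction_only`` — the forward (index-as-predictor) Z;
    ``stouffer`` — sum of converged Zs over sqrt(k).  When only one
    direction converged, every rule returns that Z; when neither did,
    returns NaN.
    """
    if rule not in DIRECTION_RULES:
        raise ValueError(f"unknown direction rule {rule!r}")
    zs = [d.z for d in (forward, reverse) if d.converged and np.isfinite(d.z)]
    if not zs:
        return float("nan")
    if len(zs) == 1:
        return float(zs[0])
    if rule == "mean":
        return float(np.mean(zs))
    if rule == "outcome_direction_only":
        return float(forward.z)
    return float(np.sum(zs) / np.sqrt(len(zs)))


def count_shared_cases(status: PhenotypeStatusMatrix, a: str, b: str) -> int:
    """Number of patients who are cases for both phecodes."""
    return int(((status.status[a] == CASE) & (status.status[b] == CASE)).sum())


def scheduled_regressions(
    universe: list[str], index_phecode: str, full_grid: bool = False
) -> Iterator[tuple[str, str]]:
    """Enumerate the directional (outcome, predictor) regressions of a scan.

    Full-grid mode schedules every ordered pair over the universe
    (n x n regressions, diagonal included); index mode schedules the two
    directions of each (index, other) pair.  Returns a lazy iterator: the
    full grid over a phenome-sized universe runs to millions of jobs.
    """
    universe = sorted(universe)
    if not universe:
        raise ValueError("empty phecode universe")
    if full_grid:
        return itertools.product(universe, universe)
    return itertools.chain.from_iterable(
        ((other, index_phecode), (index_phecode, other)) for other in universe
    )


def phecode_universe(status: PhenotypeStatusMatrix, index_phecode: str) -> list[str]:
    """Phecodes occurring (count >= 1) in at least one index-phecode case."""
    if index_phecode not in status.status.columns:
        raise ValueError(f"index phecode {index_phecode!r} absent from status matrix")
    case_rows = status.status[index_phecode] == CASE
    occ = (status.counts.loc[case_rows] >= 1).any(axis=0)
    return sorted(c for c in occ.index[occ] if c != index_phecode)


def run_phenome_scan(
    status: PhenotypeStatusMatrix,
    demo: pd.DataFrame,
    index_phecode: str,
    universe: list[str] | None = None,
    covariates=DEFAULT_COVARIATES,
    min_cases: int = 20,
    rule: str = "mean",
    site: str = "",
) -> pd.DataFrame:
    """Scan every (index, other) pair at one site.

    Returns one row per pair, ordered by phecode string:
    ``phecode_a, phecode_b, site, z_forward, z_reverse, z_site, n_shared,
    n_case, n_control, converged_forward, converged_reverse``.
    """
    if universe is None:
        universe = phecode_universe(status, index_phecode)
    if not universe:
        raise ValueError("empty phecode universe")
    demo = demo.loc[demo.index.intersection(status.patients)]
    rows = []
    for other in sorted(universe):
        forward = fit_pairwise_logistic(
            status, demo, other, index_phecode, covariates, min_cases, site
        )
        reverse = fit_pairwise_logistic(
            status, demo, index_phecode, other, covariates, min_cases, site
        )
        z_site = combine_directions(forward, reverse, rule)
        rows.append(
            SitePairComorbidity(
                phecode_a=index_phecode,
                phecode_b=other,
                site=site,
                z_forward=forward.z,
                z_reverse=reverse.z,
                z_site=z_site,
                n_shared=count_shared_cases(status, index_phecode, other),
                n_case=forward.n_case,
                n_control=forward.n_control,
                converged_forward=forward.converged,
                converged_reverse=reverse.converged,
            )
        )
    return pd.DataFrame(rows)
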