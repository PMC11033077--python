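"""Polygenic-score PheWAS per site and fixed-effect cross-site meta-analysis.

Each phecode's case/control status is regressed on a standardized polygenic
score with covariates of sex, current age, the first 10 ancestry principal
components and record length.  Index-disorder cases are removed by default
so associations reflect genetic effects independent of the diagnosis
itself.  Site results are combined by fixed-effect inverse-variance
weighting:

    beta_meta = sum(beta_i / se_i^2) / sum(1 / se_i^2)
    se_meta   = (sum 1/se_i^2)^(-1/2)

Variance explained is the Nagelkerke pseudo-R^2 difference between the
full model and the covariate-only model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .phecodes import CASE, CONTROL, PhenotypeStatusMatrix, SchemaError
from .comorbidity import _fit_logit, build_design

logger = logging.getLogger(__name__)

PC_COLUMNS = tuple(f"PC{i}" for i in range(1, 11))

#: PheWAS covariates: sex, current age, record length + the 10 PCs
PHEWAS_COVARIATES = (("current_age", "record_length"), ("sex",))


@dataclass(frozen=True)
class PrsAssociation:
    phecode: str
    site: str
    beta: float
    se: float
    p: float
    n_case: int
    n_control: int
    converged: bool
    ve_pct: float = np.nan
    skip_reason: str | None = None


@dataclass(frozen=True)
class MetaPrsAssociation:
    phecode: str
    meta_beta: float
    meta_se: float
    meta_p: float
    n_sites: int
    single_site: bool


def read_score_file(path) -> pd.DataFrame:
    """Read a per-individual polygenic score file.

    Accepts a plain TSV ``patient_id  score`` or a PLINK-style score output
    (``IID`` plus ``SCORESUM``/``SCORE1_SUM``/``SCORE`` columns, detected
    by header).  Returns a DataFrame with columns ``patient_id, score``.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {c.upper().lstrip("#"): c for c in df.columns}
    if "PATIENT_ID" in cols and "SCORE" in cols:
        out = df[[cols["PATIENT_ID"], cols["SCORE"]]]
    elif "IID" in cols:
        score_col = next(
            (cols[k] for k in ("SCORESUM", "SCORE1_SUM", "SCORE1_AVG", "SCORE")
             if k in cols),
            None,
        )
        if score_col is None:
            raise SchemaError(f"no score column found in {path}")
        out = df[[cols["IID"], score_col]]
    else:
        raise SchemaError(f"unrecognized score file header in {path}")
    out = out.set_axis(["patient_id", "score"], axis=1)
    if out["patient_id"].duplicated().any():
        raise SchemaError("duplicate patient ids in score file")
    if not np.isfinite(out["score"]).all():
        raise SchemaError("non-finite scores in score file")
    return out


def standardize_score(score: pd.Series) -> tuple[pd.Series, float, float]:
    """Scale a score to mean 0, SD 1 within the analysis sample.

    Returns (standardized, mean, sd); a constant score is an error.
    """
    mean, sd = float(score.mean()), float(score.std(ddof=0))
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("polygenic score has zero variance in the analysis sample")
    return (score - mean) / sd, mean, sd


def _nagelkerke(ll_full: float, ll_null: float, n: int) -> float:
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_r2 = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / max_r2) if max_r2 > 0 else 0.0


def fit_prs_association(
    status: PhenotypeStatusMatrix,
    demo: pd.DataFrame,
    prs: pd.DataFrame,
    phecode: str,
    index_phecode: str | None = None,
    exclude_index_cases: bool = True,
    covariates=PHEWAS_COVARIATES,
    min_cases: int = 20,
    site: str = "",
    compute_ve: bool = True,
) -> PrsAssociation:
    """Logistic association of one phecode's status with the polygenic score.

    ``prs`` carries ``patient_id, score`` and optionally PC1..PC10 columns;
    PCs present in the table are always included as covariates.  Patients
    missing for the phecode (single instance or exclusion-range carriers)
    are dropped, as are index-disorder cases when ``exclude_index_cases``.
    """

    def _skip(reason: str, n_case=0, n_control=0) -> PrsAssociation:
        return PrsAssociation(
            phecode, site, np.nan, np.nan, np.nan, n_case, n_control, False,
            skip_reason=reason,
        )

    y_all = status.status[phecode]
    keep = y_all != -1
    if exclude_index_cases and index_phecode is not None:
        if index_phecode not in status.status.columns:
            raise ValueError(f"index phecode {index_phecode!r} not in status matrix")
        keep &= status.status[index_phecode] != CASE

    prs_idx = prs.set_index("patient_id")
    idx = status.patients[keep].intersection(demo.index).intersection(prs_idx.index)
    y = y_all.loc[idx].to_numpy()
    n_case, n_control = int((y == CASE).sum()), int((y == CONTROL).sum())
    if n_case < min_cases:
        return _skip("min_cases", n_case, n_control)
    if n_control == 0:
        return _skip("degenerate_outcome", n_case, n_control)

    try:
        score_std, _, _ = standardize_score(prs_idx.loc[idx, "score"])
    except ValueError:
        return _skip("constant_score", n_case, n_control)

    X = build_design(demo.loc[idx], covariates)
    pc_cols = [c for c in PC_COLUMNS if c in prs_idx.columns]
    if pc_cols:
        X = pd.concat([X, prs_idx.loc[idx, pc_cols].astype(float)], axis=1)
    X.insert(0, "score", score_std.to_numpy())
    X.insert(0, "const", 1.0)

    res = _fit_logit(y, X)
    if res is None:
        return _skip("nonconvergence", n_case, n_control)
    beta = float(res.params["score"])
    se = float(res.bse["score"])
    z = beta / se
    p = float(2.0 * stats.norm.cdf(-abs(z)))

    ve_pct = np.nan
    if compute_ve:
        res0 = _fit_logit(y, X.drop(columns="score"))
        if res0 is not None:
            n = len(y)
            ll_null = sm_null_loglik(y)
            r2_full = _nagelkerke(res.llf, ll_null, n)
            r2_cov = _nagelkerke(res0.llf, ll_null, n)
            ve_pct = 100.0 * max(r2_full - r2_cov, 0.0)
    return PrsAssociation(
        phecode, site, beta, se, p, n_case, n_control, True, ve_pct
    )


def sm_null_loglik(y: np.ndarray) -> float:
    """Log-likelihood of the intercept-only Bernoulli model."""
    k, n = float(np.sum(y)), len(y)
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return k * np.log(p) + (n - k) * np.log(1 - p)


def variance_explained(full_llf: float, cov_llf: float, null_llf: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 difference (full minus covariate-only), percent."""
    if full_llf < cov_llf - 1e-8:
        raise ValueError("full model log-likelihood below nested covariate model")
    return 100.0 * max(
        _nagelkerke(full_llf, null_llf, n) - _nagelkerke(cov_llf, null_llf, n), 0.0
    )


def ivw_meta(site_results: list[PrsAssociation]) -> MetaPrsAssociation:
    """Fixed-effect inverse variance-weighted meta-analysis of one phecode.

    Non-converged site results are excluded; a single usable site passes
    through with the ``single_site`` flag.  No usable site is an error.
    """
    usable = [r for r in site_results if r.converged and np.isfinite(r.se) and r.se > 0]
    if not usable:
        raise ValueError("no converged site results to meta-analyze")
    phecodes = {r.phecode for r in usable}
    if len(phecodes) != 1:
        raise ValueError("meta-analysis mixes phecodes")
    w = np.array([1.0 / r.se**2 for r in usable])
    beta = np.array([r.beta for r in usable])
    meta_beta = float(np.sum(w * beta) / np.sum(w))
    meta_se = float(np.sum(w) ** -0.5)
    z = meta_beta / meta_se
    meta_p = float(2.0 * stats.norm.cdf(-abs(z)))
    return MetaPrsAssociation(
        phecode=usable[0].phecode,
        meta_beta=meta_beta,
        meta_se=meta_se,
        meta_p=meta_p,
        n_sites=len(usable),
        single_site=len(usable) == 1,
    )


def run_prs_phewas(
    sites: dict[str, tuple[PhenotypeStatusMatrix, pd.DataFrame, pd.DataFrame]],
    phecodes: list[str],
    index_phecode: str,
    exclude_index_cases: bool = True,
    min_cases: int = 20,
    require_all_sites: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PheWAS across sites plus IVW meta-analysis.

    ``sites`` maps site id -> (status, demographics, prs table).  Returns
    (per-site results, meta results) as DataFrames.  With
    ``require_all_sites`` (default) the meta table only contains phecodes
    converged at every site, mirroring a both-site analysis set.
    """
    site_rows: list[PrsAssociation] = []
    for site_id, (status, demo, prs) in sites.items():
        for phecode in sorted(phecodes):
            if phecode not in status.status.columns:
                site_rows.append(
                    PrsAssociation(phecode, site_id, np.nan, np.nan, np.nan,
                                   0, 0, False, skip_reason="absent")
                )
                continue
            site_rows.append(
                fit_prs_association(
                    status, demo, prs, phecode, index_phecode,
                    exclude_index_cases, min_cases=min_cases, site=site_id,
                )
            )
    site_df = pd.DataFrame([r.__dict__ for r in site_rows])

    meta_rows = []
    n_sites = len(sites)
    for phecode, grp in site_df.groupby("phecode", sort=True):
        usable = grp[grp["converged"]]
        if usable.empty:
            continue
        if require_all_sites and len(usable) < n_sites:
            continue
        assoc = [
            PrsAssociation(row.phecode, row.site, row.beta, row.se, row.p,
                           row.n_case, row.n_control, True)
            for row in usable.itertuples()
        ]
        meta_rows.append(ivw_meta(assoc).__dict__)
    meta_df = pd.DataFrame(
        meta_rows,
        columns=["phecode", "meta_beta", "meta_se", "meta_p", "n_sites", "single_site"],
    )
    return site_df, meta_df
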