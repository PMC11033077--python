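"""Tier classification of comorbidities by genetic-evidence profile.

The three result streams — combined comorbidity significance, polygenic-
score meta-association, and TOST equivalence — are intersected into nested
tiers of "genetically unrelated comorbidity" candidates:

* ``EQUIVALENT_COMORBID``: significantly comorbid and significantly
  equivalent in score distributions (the score association may still be
  significant with a tiny effect);
* ``EQUIVALENT_PRS_NONSIG_CORRECTED``: additionally the score association
  is not significant after Bonferroni correction;
* ``EQUIVALENT_PRS_NONSIG_NOMINAL``: additionally the score association is
  not even nominally significant (p > 0.05) — the strongest candidates for
  treatment-, behavior- or environment-driven comorbidity;
* ``PRS_ASSOC_NOT_COMORBID``: score-associated but not comorbid (nominal
  comorbidity p > 0.05);
* ``OTHER``: everything else.

The enum stored per phenotype is the most specific applicable tier; the
boolean columns preserve the nesting.  A hypergeometric upper-tail test
quantifies overlap of an EHR-derived comorbidity set with a
literature-derived set.
"""

from __future__ import annotations

import enum
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats


class Tier(str, enum.Enum):
    EQUIVALENT_PRS_NONSIG_NOMINAL = "EQUIVALENT_PRS_NONSIG_NOMINAL"
    EQUIVALENT_PRS_NONSIG_CORRECTED = "EQUIVALENT_PRS_NONSIG_CORRECTED"
    EQUIVALENT_COMORBID = "EQUIVALENT_COMORBID"
    PRS_ASSOC_NOT_COMORBID = "PRS_ASSOC_NOT_COMORBID"
    OTHER = "OTHER"


def assign_tiers(
    combined: pd.DataFrame,
    prs_meta: pd.DataFrame,
    equiv: pd.DataFrame,
    alpha: float = 0.05,
    prs_n_tests: int | None = None,
) -> pd.DataFrame:
    """Deterministic tier per phecode from the three result streams.

    ``combined`` needs columns ``phecode_b (or phecode), p, significant``;
    ``prs_meta`` needs ``phecode, meta_p``; ``equiv`` needs ``phecode,
    equivalent``.  A phecode missing from any stream gets tier OTHER with
    ``missing_data=True``.  The output is keyed and sorted on phecode and
    is idempotent under re-application.
    """
    com = combined.rename(columns={"phecode_b": "phecode"}).set_index("phecode")
    prs = prs_meta.set_index("phecode")
    eq = equiv.set_index("phecode")
    if prs_n_tests is None:
        prs_n_tests = int(prs["meta_p"].notna().sum()) or 1
    prs_threshold = alpha / prs_n_tests

    universe = sorted(set(com.index) | set(prs.index) | set(eq.index))
    rows = []
    for phecode in universe:
        in_com = phecode in com.index
        in_prs = phecode in prs.index and np.isfinite(prs.loc[phecode, "meta_p"])
        in_eq = phecode in eq.index
        # absence from the equivalence stream just means "not shown
        # equivalent" (non-significant comorbidities never enter TOST);
        # absence of comorbidity or PRS results is missing data
        missing = not (in_com and in_prs)

        comorbid_sig = bool(com.loc[phecode, "significant"]) if in_com else False
        comorbid_p = float(com.loc[phecode, "p"]) if in_com else np.nan
        prs_p = float(prs.loc[phecode, "meta_p"]) if in_prs else np.nan
        prs_sig_corrected = in_prs and prs_p < prs_threshold
        prs_nominal = in_prs and prs_p < alpha
        equivalent = bool(eq.loc[phecode, "equivalent"]) if in_eq else False

        equiv_comorbid = comorbid_sig and equivalent and not missing
        nonsig_corrected = equiv_comorbid and not prs_sig_corrected
        nonsig_nominal = nonsig_corrected and not prs_nominal

        if missing:
            tier = Tier.OTHER
        elif nonsig_nominal:
            tier = Tier.EQUIVALENT_PRS_NONSIG_NOMINAL
        elif nonsig_corrected:
            tier = Tier.EQUIVALENT_PRS_NONSIG_CORRECTED
        elif equiv_comorbid:
            tier = Tier.EQUIVALENT_COMORBID
        elif prs_sig_corrected and in_com and np.isfinite(comorbid_p) and comorbid_p > alpha:
            # score-associated but not even nominally comorbid
            tier = Tier.PRS_ASSOC_NOT_COMORBID
        else:
            tier = Tier.OTHER

        rows.append({
            "phecode": phecode,
            "comorbid_significant": comorbid_sig,
            "comorbid_p": comorbid_p,
            "prs_meta_p": prs_p,
            "prs_significant_corrected": prs_sig_corrected,
            "prs_nominal": prs_nominal,
            "equivalent": equivalent,
            "equivalent_comorbid": equiv_comorbid,
            "equivalent_prs_nonsig_corrected": nonsig_corrected,
            "equivalent_prs_nonsig_nominal": nonsig_nominal,
            "tier": tier.value,
            "missing_data": missing,
        })
    return pd.DataFrame(rows)


def tier_counts(verdicts: pd.DataFrame) -> dict[str, int]:
    counts = verdicts["tier"].value_counts().to_dict()
    return {tier.value: int(counts.get(tier.value, 0)) for tier in Tier}


def hypergeometric_overlap(
    universe_n: int, set_a_n: int, set_b_n: int, overlap_k: int
) -> float:
    """Upper-tail hypergeometric overlap p-value: P(X >= overlap_k).

    X counts the overlap of a random ``set_b_n``-subset of the universe
    with a fixed ``set_a_n``-subset.
    """
    if not 0 <= overlap_k <= min(set_a_n, set_b_n) <= universe_n:
        raise ValueError("inconsistent hypergeometric margins")
    if max(set_a_n, set_b_n) > universe_n:
        raise ValueError("set sizes exceed the universe")
    return float(stats.hypergeom.sf(overlap_k - 1, universe_n, set_a_n, set_b_n))


def load_literature_phecodes() -> pd.DataFrame:
    """Literature-reported index-disorder comorbidities (transcribed metadata).

    Columns: ``phecode, description, category``.  The list is editable data
    shipped with the package, not code.
    """
    with resources.files("equicomorb.data").joinpath(
        "literature_phecodes.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"phecode": str}, comment="#")
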