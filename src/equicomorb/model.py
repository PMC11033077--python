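"""Model/Results facade over the full comorbidity-equivalence pipeline.

`ComorbidityEquivalenceModel` is constructed from per-site cohort tables
(code events, demographics, polygenic scores, ancestry PCs) plus a phecode
map; `fit()` runs phecode consolidation, the per-site comorbidity scan,
cross-site weighted-Z combination, the polygenic-score PheWAS with
fixed-effect meta-analysis, TOST equivalence testing with Fisher
combination, and tier classification, returning a
`ComorbidityEquivalenceResults` carrying every intermediate table, the
thresholds used and a text `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import classify, combine, comorbidity, phecodes, phewas, tost

__all__ = ["SiteCohort", "ComorbidityEquivalenceModel", "ComorbidityEquivalenceResults"]


@dataclass
class SiteCohort:
    """Raw pipeline inputs for one site."""

    events: pd.DataFrame
    demographics: pd.DataFrame
    prs: pd.DataFrame | None = None      # patient_id, score
    pcs: pd.DataFrame | None = None      # patient_id, PC1..PC10

    def prs_table(self) -> pd.DataFrame | None:
        """Score table with PCs merged in, ready for the PheWAS."""
        if self.prs is None:
            return None
        table = self.prs
        if self.pcs is not None:
            table = table.merge(self.pcs, on="patient_id", how="inner")
        return table


@dataclass
class ComorbidityEquivalenceResults:
    """Fitted results: estimates, thresholds, diagnostics and tier calls."""

    site_scan: pd.DataFrame            # per-site directional + combined Zs
    comorbidity: pd.DataFrame          # combined Z, p, significance per pair
    prs_site: pd.DataFrame             # per-site PheWAS rows
    prs_meta: pd.DataFrame             # IVW meta rows
    tost_site: pd.DataFrame            # per-site TOST rows
    equivalence: pd.DataFrame          # Fisher-combined equivalence rows
    verdicts: pd.DataFrame             # per-phecode tier assignment
    thresholds: dict[str, float]
    config: dict = field(default_factory=dict)

    @property
    def tier_counts(self) -> dict[str, int]:
        return classify.tier_counts(self.verdicts)

    def cross_site_comorbidity_r(self) -> tuple[float, float]:
        """Pearson r of per-site comorbidity Zs (exactly two sites)."""
        sites = sorted(self.site_scan["site"].unique())
        if len(sites) != 2:
            raise ValueError("cross-site correlation needs exactly two sites")
        wide = self.site_scan.pivot(index="phecode_b", columns="site", values="z_site")
        return combine.profile_correlation(wide[sites[0]], wide[sites[1]])

    def significant_comorbidities(self) -> pd.DataFrame:
        return self.comorbidity[self.comorbidity["significant"]]

    def summary(self) -> str:
        lines = ["Comorbidity-equivalence pipeline results", "=" * 42]
        n_pairs = int(self.comorbidity["p"].notna().sum())
        lines.append(f"Comorbidity pairs tested:        {n_pairs}")
        lines.append(
            f"Bonferroni threshold (comorbid): {self.thresholds['comorbidity']:.3g}"
        )
        lines.append(
            f"Significant comorbidities:       {int(self.comorbidity['significant'].sum())}"
        )
        try:
            r, p = self.cross_site_comorbidity_r()
            lines.append(f"Cross-site comorbidity r:        {r:.3f} (p = {p:.3g})")
        except ValueError:
            pass
        if not self.prs_meta.empty:
            n_prs = len(self.prs_meta)
            n_sig = int((self.prs_meta["meta_p"] < self.thresholds["prs"]).sum())
            lines.append(f"PRS meta-analyzed phecodes:      {n_prs}")
            lines.append(f"Bonferroni threshold (PRS):      {self.thresholds['prs']:.3g}")
            lines.append(f"Significant PRS associations:    {n_sig}")
        if not self.equivalence.empty:
            lines.append(f"Phecodes entering TOST meta:     {len(self.equivalence)}")
            lines.append(
                f"Bonferroni threshold (TOST):     {self.thresholds['tost']:.3g}"
            )
            lines.append(
                f"Significantly equivalent:        {int(self.equivalence['equivalent'].sum())}"
            )
        lines.append("Tier counts:")
        for tier, count in self.tier_counts.items():
            lines.append(f"  {tier:<34s} {count}")
        return "\n".join(lines)


class ComorbidityEquivalenceModel:
    """Phenome-wide comorbidity + polygenic-score equivalence model.

    Parameters
    ----------
    sites
        Mapping of site id to :class:`SiteCohort`.
    phecode_map
        :class:`~equicomorb.phecodes.PhecodeMap` covering both vocabularies.
    index_phecode
        The index disorder phecode every other phenotype is tested against.
    alpha
        Family-wise error target for every Bonferroni correction.
    min_cases
        Minimum analyzable case count per logistic fit.
    direction_rule
        How the two directional comorbidity Zs combine per site.
    tost_bounds
        Cohen's-d equivalence bounds (low, high).
    exclude_index_cases
        Drop index-disorder cases from the PheWAS and TOST samples.
    """

    def __init__(
        self,
        sites: Mapping[str, SiteCohort],
        phecode_map: phecodes.PhecodeMap,
        index_phecode: str = "295.1",
        alpha: float = 0.05,
        min_cases: int = 20,
        direction_rule: str = "mean",
        tost_bounds: tuple[float, float] = tost.DEFAULT_BOUNDS,
        exclude_index_cases: bool = True,
        tost_variant: str = "welch",
    ) -> None:
        if not sites:
            raise ValueError("at least one site is required")
        if direction_rule not in comorbidity.DIRECTION_RULES:
            raise ValueError(f"unknown direction rule {direction_rule!r}")
        self.sites = dict(sites)
        self.phecode_map = phecode_map
        self.index_phecode = index_phecode
        self.alpha = alpha
        self.min_cases = min_cases
        self.direction_rule = direction_rule
        self.tost_bounds = tuple(tost_bounds)
        self.exclude_index_cases = exclude_index_cases
        self.tost_variant = tost_variant

    @classmethod
    def from_cohort_bundle(cls, bundle, **kwargs) -> "ComorbidityEquivalenceModel":
        """Construct from a :class:`~equicomorb.simulate.CohortBundle`."""
        sites = {
            site: SiteCohort(d.events, d.demographics, d.prs, d.pcs)
            for site, d in bundle.sites.items()
        }
        return cls(sites, bundle.phecode_map, **kwargs)

    # ------------------------------------------------------------------ fit

    def _prepare_site(self, cohort: SiteCohort):
        counts = phecodes.consolidate_phecodes(cohort.events, self.phecode_map)
        status = phecodes.assign_status(
            counts, self.phecode_map, patients=cohort.demographics["patient_id"]
        )
        demo = phecodes.compute_demographic_covariates(
            cohort.events, cohort.demographics, status
        )
        return status, demo

    def fit(self) -> ComorbidityEquivalenceResults:
        prepared = {
            site: self._prepare_site(cohort) for site, cohort in self.sites.items()
        }

        # per-site phenome scan against the index phecode
        scans = []
        for site, (status, demo) in prepared.items():
            scans.append(
                comorbidity.run_phenome_scan(
                    status, demo, self.index_phecode,
                    min_cases=self.min_cases, rule=self.direction_rule, site=site,
                )
            )
        site_scan = pd.concat(scans, ignore_index=True)

        # cross-site weighted-Z combination + Bonferroni
        combined = combine.combine_sites(site_scan)
        combined["p"] = combine.z_to_p(combined["z_combined"])
        flags, com_threshold, n_com_tests = combine.bonferroni_flag(
            combined["p"], self.alpha
        )
        combined["significant"] = flags

        # polygenic-score PheWAS + IVW meta
        phewas_sites = {
            site: (status, demo, self.sites[site].prs_table())
            for site, (status, demo) in prepared.items()
            if self.sites[site].prs_table() is not None
        }
        if phewas_sites:
            all_phecodes = sorted(
                {p for status, _, _ in phewas_sites.values() for p in status.phecodes}
                - {self.index_phecode}
            )
            prs_site, prs_meta = phewas.run_prs_phewas(
                phewas_sites, all_phecodes, self.index_phecode,
                self.exclude_index_cases, self.min_cases,
            )
            prs_threshold = self.alpha / max(len(prs_meta), 1)
        else:
            prs_site = pd.DataFrame()
            prs_meta = pd.DataFrame(
                columns=["phecode", "meta_beta", "meta_se", "meta_p",
                         "n_sites", "single_site"]
            )
            prs_threshold = np.nan

        # TOST equivalence on significant comorbidities with meta PRS results
        tost_site, equivalence, tost_threshold = self._run_tost(
            prepared, combined, prs_meta
        )

        verdicts = classify.assign_tiers(
            combined[["phecode_b", "p", "significant"]],
            prs_meta[["phecode", "meta_p"]],
            equivalence[["phecode", "equivalent"]],
            alpha=self.alpha,
            prs_n_tests=max(len(prs_meta), 1),
        )

        return ComorbidityEquivalenceResults(
            site_scan=site_scan,
            comorbidity=combined,
            prs_site=prs_site,
            prs_meta=prs_meta,
            tost_site=tost_site,
            equivalence=equivalence,
            verdicts=verdicts,
            thresholds={
                "comorbidity": com_threshold,
                "comorbidity_n_tests": n_com_tests,
                "prs": prs_threshold,
                "prs_n_tests": len(prs_meta),
                "tost": tost_threshold,
                "alpha": self.alpha,
            },
            config={
                "index_phecode": self.index_phecode,
                "min_cases": self.min_cases,
                "direction_rule": self.direction_rule,
                "tost_bounds": self.tost_bounds,
                "exclude_index_cases": self.exclude_index_cases,
                "tost_variant": self.tost_variant,
            },
        )

    def _run_tost(self, prepared, combined: pd.DataFrame, prs_meta: pd.DataFrame):
        """TOST per site on the phecodes that are significantly comorbid and
        carry a cross-site meta PRS result; Fisher-combined across sites."""
        eligible = sorted(
            set(combined.loc[combined["significant"], "phecode_b"])
            & set(prs_meta["phecode"])
        )
        d_low, d_high = self.tost_bounds
        site_rows, meta_rows = [], []
        for phecode in eligible:
            per_site_p = []
            ok = True
            for site, (status, demo) in prepared.items():
                prs_table = self.sites[site].prs_table()
                if prs_table is None:
                    continue
                scores = prs_table.set_index("patient_id")["score"]
                keep = status.status[phecode] != -1
                if self.exclude_index_cases:
                    keep &= status.status[self.index_phecode] != phecodes.CASE
                idx = status.patients[keep].intersection(scores.index)
                y = status.status[phecode].loc[idx]
                case_scores = scores.loc[idx[y == phecodes.CASE]]
                control_scores = scores.loc[idx[y == phecodes.CONTROL]]
                if len(case_scores) < 2 or len(control_scores) < 2:
                    ok = False
                    continue
                result = tost.tost_from_scores(
                    phecode, site, case_scores, control_scores,
                    d_low, d_high, self.tost_variant,
                )
                site_rows.append(result.__dict__)
                per_site_p.append(result.p_tost)
            if ok and per_site_p:
                meta_rows.append(tost.fisher_combine(per_site_p, phecode).__dict__)

        tost_site = pd.DataFrame(
            site_rows,
            columns=["phecode", "site", "t_lower", "t_upper", "p_lower",
                     "p_upper", "p_tost", "df"],
        )
        equivalence = pd.DataFrame(
            meta_rows,
            columns=["phecode", "chi2", "df", "p_meta", "n_sites", "clamped"],
        )
        if len(equivalence):
            flags, threshold = tost.flag_equivalent(equivalence, self.alpha)
            equivalence["equivalent"] = flags
            equivalence["threshold"] = threshold
        else:
            threshold = np.nan
            equivalence["equivalent"] = pd.Series(dtype=bool)
            equivalence["threshold"] = pd.Series(dtype=float)
        return tost_site, equivalence, threshold
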