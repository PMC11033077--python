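"""ICD-to-phecode consolidation and case/control/missing status assignment.

Billing codes (ICD-9 or ICD-10) are consolidated into phecodes — curated
phenotype groupings with per-phenotype *exclusion ranges* that disqualify
clinically similar patients from serving as controls.  A patient is a case
for a phecode when it was recorded on two or more distinct calendar dates,
missing when it was recorded exactly once, and otherwise a control unless
an exclusion-range phecode is present, in which case the patient is removed
from the controls (missing).  No cross-mapping between ICD-9 and ICD-10 is
performed: each vocabulary contributes only through its own map entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VOCABULARIES = ("ICD9", "ICD10")

#: integer codes used inside the status matrix
CASE, CONTROL, MISSING = 1, 0, -1

EVENT_COLUMNS = ["patient_id", "vocabulary", "code", "date"]
DEMOGRAPHICS_COLUMNS = ["patient_id", "current_age", "ehr_age", "sex", "race"]


class SchemaError(ValueError):
    """Raised when an input table violates its documented schema."""


def _phecode_sort_key(code: str) -> tuple[float, str]:
    try:
        return (float(code), code)
    except (TypeError, ValueError):
        return (float("inf"), str(code))


@dataclass(frozen=True)
class PhecodeMap:
    """Many-to-one map from (vocabulary, ICD code) to phecode, with exclusions.

    Parameters
    ----------
    entries
        DataFrame with columns ``vocabulary``, ``code``, ``phecode``.
    exclusions
        Mapping from phecode to the frozen set of phecodes whose presence
        removes a patient from that phecode's controls.
    """

    entries: pd.DataFrame
    exclusions: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entries.empty:
            raise SchemaError("phecode map is empty")
        missing = {"vocabulary", "code", "phecode"} - set(self.entries.columns)
        if missing:
            raise SchemaError(f"phecode map lacks columns: {sorted(missing)}")
        bad = set(self.entries["vocabulary"].unique()) - set(VOCABULARIES)
        if bad:
            raise SchemaError(f"unknown vocabularies in map: {sorted(bad)}")
        # exclusion phecodes without their own definition are legal but flagged
        universe = set(self.entries["phecode"].unique())
        orphans = {
            p for excl in self.exclusions.values() for p in excl if p not in universe
        }
        if orphans:
            logger.warning(
                "%d exclusion phecodes have no map definition (kept)", len(orphans)
            )

    @property
    def phecodes(self) -> list[str]:
        return sorted(self.entries["phecode"].unique(), key=_phecode_sort_key)

    def exclusions_for(self, phecode: str) -> frozenset[str]:
        return self.exclusions.get(phecode, frozenset())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PhecodeMap":
        """Build from a long table in the published phecode-1.2 dialect.

        Expected columns: ``code``, ``vocabulary``, ``phecode`` and an
        optional ``exclude_range`` column holding "lo-hi" phecode intervals
        (comma-separated; empty for none).  Intervals are expanded against
        the numeric phecode universe of the map itself, inclusively.
        """
        frame = frame.copy()
        required = {"code", "vocabulary", "phecode"}
        if not required <= set(frame.columns):
            raise SchemaError(f"map file needs columns {sorted(required)}")
        frame["phecode"] = frame["phecode"].astype(str)
        frame["code"] = frame["code"].astype(str)
        entries = frame[["vocabulary", "code", "phecode"]].drop_duplicates()

        exclusions: dict[str, set[str]] = {}
        if "exclude_range" in frame.columns:
            universe = entries["phecode"].unique()
            numeric = np.array([_phecode_sort_key(p)[0] for p in universe])
            spec = (
                frame[["phecode", "exclude_range"]]
                .fillna("")
                .drop_duplicates()
                .itertuples(index=False)
            )
            for phecode, ranges in spec:
                for rng in str(ranges).split(","):
                    rng = rng.strip()
                    if not rng:
                        continue
                    try:
                        lo, hi = (float(x) for x in rng.split("-"))
                    except ValueError as err:
                        raise SchemaError(
                            f"bad exclusion range {rng!r} for phecode {phecode}"
                        ) from err
                    hit = universe[(numeric >= lo) & (numeric <= hi)]
                    excl = exclusions.setdefault(phecode, set())
                    excl.update(p for p in hit if p != phecode)
        return cls(entries, {k: frozenset(v) for k, v in exclusions.items()})

    @classmethod
    def from_csv(cls, path) -> "PhecodeMap":
        return cls.from_frame(pd.read_csv(path, dtype=str, comment="#"))


def _validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise SchemaError(f"code-event table lacks columns: {sorted(missing)}")
    bad = set(events["vocabulary"].unique()) - set(VOCABULARIES)
    if bad:
        raise SchemaError(f"unknown vocabulary values: {sorted(bad)}")
    if events["date"].isna().any():
        raise SchemaError("code events contain missing dates")
    if (events["code"].astype(str).str.len() == 0).any():
        raise SchemaError("code events contain empty codes")
    return events


def consolidate_phecodes(
    events: pd.DataFrame, phecode_map: PhecodeMap
) -> pd.DataFrame:
    """Consolidate code events into per-patient phecode distinct-date counts.

    For each patient and phecode the count is the number of *distinct
    calendar dates* on which any mapped code occurred: several codes
    mapping to the same phecode on one day count once.  Counts aggregate
    over the entire record, all encounter types alike.  Unmapped codes are
    dropped (a tally is logged).

    Returns a long DataFrame ``patient_id, phecode, count`` with count >= 1.
    """
    events = _validate_events(events)
    merged = events.merge(
        phecode_map.entries, on=["vocabulary", "code"], how="left"
    )
    unmapped = merged["phecode"].isna()
    if unmapped.any():
        logger.info("dropped %d events with unmapped codes", int(unmapped.sum()))
    merged = merged[~unmapped]
    counts = (
        merged.drop_duplicates(["patient_id", "phecode", "date"])
        .groupby(["patient_id", "phecode"], sort=False, observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return counts


@dataclass
class PhenotypeStatusMatrix:
    """Patient x phecode status lattice with values in {case, control, missing}.

    ``status`` is an int8 DataFrame (1 = case, 0 = control, -1 = missing)
    indexed by patient, one column per phecode; ``counts`` is the aligned
    distinct-date occurrence count matrix.
    """

    status: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.status.index.equals(self.counts.index) or not (
            self.status.columns.equals(self.counts.columns)
        ):
            raise ValueError("status and counts must be aligned")

    @property
    def patients(self) -> pd.Index:
        return self.status.index

    @property
    def phecodes(self) -> list[str]:
        return list(self.status.columns)

    def cases(self, phecode: str) -> pd.Index:
        col = self.status[phecode]
        return col.index[col == CASE]

    def n_cases(self, phecode: str) -> int:
        return int((self.status[phecode] == CASE).sum())

    def unique_phecode_counts(self) -> pd.Series:
        """Number of phecodes with >= 1 occurrence per patient."""
        return (self.counts >= 1).sum(axis=1).astype(int)


def assign_status(
    counts: pd.DataFrame,
    phecode_map: PhecodeMap,
    patients=None,
) -> PhenotypeStatusMatrix:
    """Assign case/control/missing status from distinct-date counts.

    Rules: count >= 2 -> case; count == 1 -> missing; count == 0 -> missing
    if any phecode in the exclusion set has count >= 1 (removed from the
    controls), else control.  Exclusion removal never demotes a case or a
    single-instance missing.  ``patients`` extends the universe to patients
    with no mapped events (all-control rows).
    """
    if counts.empty and patients is None:
        raise ValueError("no counts and no patient universe given")
    wide = counts.pivot_table(
        index="patient_id", columns="phecode", values="count", fill_value=0
    ).astype(np.int32)
    if patients is not None:
        wide = wide.reindex(pd.Index(patients, name="patient_id"), fill_value=0)
    known = set(phecode_map.phecodes)
    novel = [p for p in wide.columns if p not in known]
    if novel:
        logger.info(
            "%d phecodes in counts absent from map; treated as standalone", len(novel)
        )
    universe = sorted(known | set(wide.columns), key=_phecode_sort_key)
    wide = wide.reindex(universe, axis=1, fill_value=0)

    arr = wide.to_numpy()
    status = np.where(arr >= 2, CASE, np.where(arr == 1, MISSING, CONTROL)).astype(
        np.int8
    )
    col_idx = {p: i for i, p in enumerate(wide.columns)}
    present = arr >= 1
    for j, phecode in enumerate(wide.columns):
        excl = [col_idx[e] for e in phecode_map.exclusions_for(phecode) if e in col_idx]
        if not excl:
            continue
        hit = present[:, excl].any(axis=1)
        demote = hit & (status[:, j] == CONTROL)
        status[demote, j] = MISSING
    status_df = pd.DataFrame(status, index=wide.index, columns=wide.columns)
    return PhenotypeStatusMatrix(status=status_df, counts=wide)


def compute_demographic_covariates(
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    status: PhenotypeStatusMatrix,
) -> pd.DataFrame:
    """Assemble the regression covariate table.

    Adds to the supplied demographics: ``record_length`` (days between first
    and last code event), ``unique_phecode_count`` (phecodes with >= 1
    occurrence, single-instance codes included) and ``log_unique_phecodes``
    = ln(count + 1), the total-illness covariate.  Missing categoricals map
    to an explicit "unknown" level.  Patients present in the event stream
    but absent from demographics are excluded (count logged).
    """
    missing_cols = set(DEMOGRAPHICS_COLUMNS) - set(demographics.columns)
    if missing_cols:
        raise SchemaError(f"demographics lacks columns: {sorted(missing_cols)}")
    demo = demographics.set_index("patient_id").copy()
    if demo.index.has_duplicates:
        raise SchemaError("duplicate patient_id in demographics")
    event_patients = pd.Index(events["patient_id"].unique())
    lost = event_patients.difference(demo.index)
    if len(lost):
        logger.info("%d patients with events but no demographics excluded", len(lost))
    demo = demo.reindex(status.patients.intersection(demo.index))

    dates = pd.to_datetime(events["date"])
    span = (
        pd.DataFrame({"patient_id": events["patient_id"], "date": dates})
        .groupby("patient_id")["date"]
        .agg(["min", "max"])
    )
    record_length = (span["max"] - span["min"]).dt.days
    demo["record_length"] = record_length.reindex(demo.index).fillna(0).astype(int)

    uniq = status.unique_phecode_counts().reindex(demo.index).fillna(0).astype(int)
    demo["unique_phecode_count"] = uniq
    demo["log_unique_phecodes"] = np.log1p(uniq)

    for col in ("sex", "race"):
        demo[col] = demo[col].fillna("unknown").replace("", "unknown").astype(str)
    for col in ("current_age", "ehr_age"):
        demo[col] = pd.to_numeric(demo[col])
        if (demo[col] < 0).any():
            raise SchemaError(f"negative values in {col}")
    if (demo["ehr_age"] > demo["current_age"] + 1e-9).any():
        raise SchemaError("ehr_age exceeds current_age")
    return demo
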