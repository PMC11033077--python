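"""Two-site synthetic EHR + polygenic-score cohorts with known ground truth.

The generator emulates the data regime the pipeline targets: a standard-
normal polygenic score, a liability-threshold index disorder (liability =
sqrt(h2_s) * score + sqrt(1 - h2_s) * noise, case above the prevalence
threshold), and comorbid phenotypes whose case status follows a logistic
model

    logit P(case) = logit(prevalence) + site effect + g * score
                    + c * 1[index case] + b * z_utilization
                    + age and sex terms

so that each phenotype's coupling to the index disorder is a tunable mix
of shared genetic loading (g), case-status-driven consequence coupling (c)
and health-care-utilization confounding (b).  Cases emit two or more code
events on distinct calendar dates; sub-threshold carriers may emit exactly
one (exercising the single-instance-missing rule); exclusion-range decoy
phecodes are emitted for a configurable subset of phenotypes; filler
phecodes proportional to utilization give the total-illness covariate a
job.  Every phenotype carries a ground-truth class label (genetic /
consequence / mixed / null) that appears in no pipeline-input file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit as logit_fn
from scipy.stats import norm

from .phecodes import PhecodeMap

EPOCH = np.datetime64("2005-01-01")


def classify_phenotype(g: float, c: float) -> str:
    if g != 0 and c != 0:
        return "mixed"
    if g != 0:
        return "genetic"
    if c != 0:
        return "consequence"
    return "null"


@dataclass(frozen=True)
class PhenotypeSpec:
    """One comorbid phenotype: label, prevalence and coupling coefficients."""

    phecode: str
    prevalence: float
    g: float = 0.0   # log-odds per SD of polygenic score
    c: float = 0.0   # log-odds increment for index-disorder cases
    b: float = 0.0   # log-odds per SD of log-utilization
    has_exclusion_decoy: bool = False

    @property
    def truth_class(self) -> str:
        return classify_phenotype(self.g, self.c)


def default_phenotypes(
    n_per_class: int = 10,
    prevalence: float = 0.05,
    g: float = 0.15,
    c: float = 1.0,
    b: float = 0.25,
) -> list[PhenotypeSpec]:
    """The benchmark phenome: equal blocks of genetic, consequence, mixed
    and null phenotypes; the first phenotype of each block carries an
    exclusion-range decoy."""
    specs: list[PhenotypeSpec] = []
    blocks = [
        (300, g, 0.0),    # genetic
        (400, 0.0, c),    # consequence
        (500, g, c),      # mixed
        (600, 0.0, 0.0),  # null
    ]
    for base, gj, cj in blocks:
        for i in range(1, n_per_class + 1):
            specs.append(
                PhenotypeSpec(
                    phecode=f"{base + i}.1",
                    prevalence=prevalence,
                    g=gj, c=cj, b=b,
                    has_exclusion_decoy=(i == 1),
                )
            )
    return specs


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic two-site cohort."""

    n_patients: int = 20_000
    seed: int = 1
    sites: tuple[str, ...] = ("siteA", "siteB")
    site_vocabularies: tuple[tuple[str, ...], ...] = (("ICD9",), ("ICD9", "ICD10"))
    index_phecode: str = "295.1"
    index_prevalence: float = 0.02
    h2_score: float = 0.10           # liability variance explained by the score
    phenotypes: tuple[PhenotypeSpec, ...] = field(
        default_factory=lambda: tuple(default_phenotypes())
    )
    site_effects: tuple[float, ...] = (0.0, -0.15)   # phenotype intercept shifts
    log_visits_mu: float = float(np.log(8.0))
    log_visits_sigma: float = 0.6
    index_log_visits_shift: float = 0.25             # utilization confounding path
    age_effect: float = 0.005                        # per year, centered at 50
    sex_effect: float = 0.15                         # male vs female
    single_instance_rate: float = 0.04
    decoy_carrier_rate: float = 0.03
    n_filler_phecodes: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.index_prevalence < 1:
            raise ValueError("index prevalence must lie in (0, 1)")
        if not 0 <= self.h2_score < 1:
            raise ValueError("h2_score must lie in [0, 1)")
        for spec in self.phenotypes:
            if not 0 < spec.prevalence < 1:
                raise ValueError(f"prevalence of {spec.phecode} outside (0, 1)")
        if len(self.site_effects) < len(self.sites):
            raise ValueError("need one site effect per site")
        if len(self.site_vocabularies) < len(self.sites):
            raise ValueError("need one vocabulary tuple per site")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be a non-negative 31-bit integer")

    @property
    def filler_phecodes(self) -> list[str]:
        return [f"{700 + i}.1" for i in range(1, self.n_filler_phecodes + 1)]

    @staticmethod
    def decoy_for(phecode: str) -> str:
        base = phecode.split(".")[0]
        return f"{base}.2"


@dataclass
class SiteData:
    """Pipeline inputs for one site, in the documented external formats."""

    site: str
    events: pd.DataFrame        # patient_id, vocabulary, code, date
    demographics: pd.DataFrame  # patient_id, current_age, ehr_age, sex, race
    prs: pd.DataFrame           # patient_id, score
    pcs: pd.DataFrame           # patient_id, PC1..PC10


@dataclass
class CohortBundle:
    sites: dict[str, SiteData]
    map_frame: pd.DataFrame     # code, vocabulary, phecode, exclude_range
    ground_truth: pd.DataFrame  # phecode, g, c, b, class

    @property
    def phecode_map(self) -> PhecodeMap:
        return PhecodeMap.from_frame(self.map_frame)


def build_map_frame(config: GeneratorConfig) -> pd.DataFrame:
    """Toy ICD->phecode map covering both vocabularies independently.

    Each phecode gets two ICD-9 and two ICD-10 codes (no cross-mapping);
    phenotypes flagged with a decoy get an exclusion range covering their
    sibling decoy phecode.
    """
    rows = []

    def add(phecode: str, exclude_range: str = "") -> None:
        for vocab, tag in (("ICD9", "9"), ("ICD10", "10")):
            for suffix in ("a", "b"):
                rows.append((f"{tag}-{phecode}{suffix}", vocab, phecode, exclude_range))

    add(config.index_phecode)
    for spec in config.phenotypes:
        if spec.has_exclusion_decoy:
            base = spec.phecode.split(".")[0]
            add(spec.phecode, f"{base}-{base}.99")
            add(config.decoy_for(spec.phecode))
        else:
            add(spec.phecode)
    for filler in config.filler_phecodes:
        add(filler)
    return pd.DataFrame(rows, columns=["code", "vocabulary", "phecode", "exclude_range"])


def _distinct_days(rng: np.random.Generator, counts: np.ndarray, spans: np.ndarray):
    """For each row draw ``counts[i]`` distinct integer day offsets in
    [0, spans[i]).  Returns (row_index, day) arrays.

    Uses the order-statistics trick: k sorted uniforms scaled to span-k+1
    plus arange(k) are k distinct integers.
    """
    row_idx_parts, day_parts = [], []
    for k in np.unique(counts):
        if k == 0:
            continue
        rows = np.flatnonzero(counts == k)
        u = np.sort(rng.random((len(rows), k)), axis=1)
        scale = (spans[rows] - k + 1).clip(min=1)[:, None]
        days = np.floor(u * scale).astype(np.int64) + np.arange(k)[None, :]
        row_idx_parts.append(np.repeat(rows, k))
        day_parts.append(days.ravel())
    if not row_idx_parts:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    return np.concatenate(row_idx_parts), np.concatenate(day_parts)


def _emit_events(
    rng: np.random.Generator,
    patient_pos: np.ndarray,
    n_events: np.ndarray,
    phecode: str,
    record_start: np.ndarray,
    record_span: np.ndarray,
    vocabularies: tuple[str, ...],
    out: list,
) -> None:
    """Append (patient position, vocabulary, code, date) event rows for one
    phecode, on distinct dates per patient."""
    active = n_events > 0
    pos = patient_pos[active]
    rows, days = _distinct_days(rng, n_events[active], record_span[pos])
    if len(rows) == 0:
        return
    who = pos[rows]
    vocab = np.asarray(vocabularies)[rng.integers(0, len(vocabularies), len(who))]
    suffix = np.where(rng.random(len(who)) < 0.5, "a", "b")
    tag = np.where(vocab == "ICD9", "9", "10")
    codes = np.char.add(np.char.add(np.char.add(tag, "-"), phecode), suffix)
    dates = EPOCH + record_start[who] + days
    out.append((who, vocab, codes, dates))


def _generate_site(
    config: GeneratorConfig, site_index: int
) -> tuple[SiteData, pd.DataFrame]:
    site = config.sites[site_index]
    vocabularies = config.site_vocabularies[site_index]
    rng = np.random.default_rng([config.seed, site_index])
    n = config.n_patients

    patient_ids = np.array([f"{site}-{i:06d}" for i in range(n)])

    # demographics
    current_age = np.round(rng.uniform(18, 85, n), 1)
    ehr_age = np.round(np.maximum(current_age - rng.uniform(0, 5, n), 18.0), 1)
    sex = rng.choice(["male", "female", "unknown"], n, p=[0.48, 0.50, 0.02])
    race = rng.choice(
        ["white", "black", "asian", "other", "unknown"],
        n, p=[0.60, 0.20, 0.08, 0.07, 0.05],
    )

    # polygenic score, ancestry PCs, liability-threshold index disorder
    score = rng.standard_normal(n)
    pcs = rng.standard_normal((n, 10))
    a = np.sqrt(config.h2_score)
    liability = a * score + np.sqrt(1 - config.h2_score) * rng.standard_normal(n)
    threshold = norm.isf(config.index_prevalence)
    index_case = liability > threshold

    # utilization (log visit intensity); index cases use more care
    log_u = rng.normal(config.log_visits_mu, config.log_visits_sigma, n)
    log_u = log_u + config.index_log_visits_shift * index_case
    z_u = (log_u - config.log_visits_mu) / config.log_visits_sigma

    # record window
    record_start = rng.integers(0, 3650, n)          # days after EPOCH
    record_span = rng.integers(365, 5475, n)         # 1-15 years

    site_effect = config.site_effects[site_index]
    age_term = config.age_effect * (current_age - 50.0)
    sex_term = config.sex_effect * (sex == "male")

    events_parts: list = []

    # index phecode events
    n_index = np.where(
        index_case,
        2 + rng.poisson(1.0, n),
        (rng.random(n) < config.single_instance_rate).astype(np.int64),
    )
    _emit_events(rng, np.arange(n), n_index, config.index_phecode,
                 record_start, record_span, vocabularies, events_parts)

    # comorbid phenotypes
    truth_rows = []
    for spec in config.phenotypes:
        eta = (
            logit_fn(spec.prevalence) + site_effect
            + spec.g * score + spec.c * index_case + spec.b * z_u
            + age_term + sex_term
        )
        case = rng.random(n) < expit(eta)
        n_ev = np.where(
            case,
            2 + rng.poisson(1.0, n),
            (rng.random(n) < config.single_instance_rate).astype(np.int64),
        )
        _emit_events(rng, np.arange(n), n_ev, spec.phecode,
                     record_start, record_span, vocabularies, events_parts)
        truth_rows.append((spec.phecode, spec.g, spec.c, spec.b, spec.truth_class))

        if spec.has_exclusion_decoy:
            decoy = config.decoy_for(spec.phecode)
            carrier = (rng.random(n) < config.decoy_carrier_rate) & ~case
            n_decoy = np.where(carrier, 2 + rng.poisson(1.0, n), 0)
            _emit_events(rng, np.arange(n), n_decoy, decoy,
                         record_start, record_span, vocabularies, events_parts)
            truth_rows.append((decoy, 0.0, 0.0, 0.0, "decoy"))

    # filler phecodes: event count proportional to utilization
    fillers = config.filler_phecodes
    n_filler_events = rng.poisson(np.exp(log_u))
    total = int(n_filler_events.sum())
    who = np.repeat(np.arange(n), n_filler_events)
    which = rng.integers(0, len(fillers), total)
    days = (rng.random(total) * record_span[who]).astype(np.int64)
    vocab = np.asarray(vocabularies)[rng.integers(0, len(vocabularies), total)]
    tag = np.where(vocab == "ICD9", "9", "10")
    filler_codes = np.asarray(fillers)[which]
    suffix = np.where(rng.random(total) < 0.5, "a", "b")
    codes = np.char.add(np.char.add(np.char.add(tag, "-"), filler_codes), suffix)
    dates = EPOCH + record_start[who] + days
    events_parts.append((who, vocab, codes, dates))
    for filler in fillers:
        truth_rows.append((filler, 0.0, 0.0, np.nan, "filler"))

    events = pd.DataFrame({
        "patient_id": patient_ids[np.concatenate([p[0] for p in events_parts])],
        "vocabulary": np.concatenate([p[1] for p in events_parts]),
        "code": np.concatenate([p[2] for p in events_parts]),
        "date": np.concatenate([p[3] for p in events_parts]).astype("datetime64[D]"),
    })
    events["date"] = events["date"].astype(str)
    events = (
        events.drop_duplicates(["patient_id", "code", "date"])
        .sort_values(["patient_id", "date", "code"], kind="mergesort")
        .reset_index(drop=True)
    )

    demographics = pd.DataFrame({
        "patient_id": patient_ids,
        "current_age": current_age,
        "ehr_age": ehr_age,
        "sex": sex,
        "race": race,
    })
    prs = pd.DataFrame({"patient_id": patient_ids, "score": score})
    pcs_df = pd.DataFrame(pcs, columns=[f"PC{i}" for i in range(1, 11)])
    pcs_df.insert(0, "patient_id", patient_ids)

    truth = pd.DataFrame(truth_rows, columns=["phecode", "g", "c", "b", "class"])
    return SiteData(site, events, demographics, prs, pcs_df), truth


def generate_cohort(config: GeneratorConfig) -> CohortBundle:
    """Generate all sites of the synthetic cohort.

    Each site draws from its own pseudo-random stream keyed on
    (seed, site index), so cohorts are byte-identical for a fixed seed and
    sites can be regenerated independently.
    """
    sites: dict[str, SiteData] = {}
    truth: pd.DataFrame | None = None
    for i, _ in enumerate(config.sites):
        data, site_truth = _generate_site(config, i)
        sites[data.site] = data
        truth = site_truth  # identical by construction across sites
    index_row = pd.DataFrame(
        [(config.index_phecode, np.sqrt(config.h2_score), 0.0, 0.0, "index")],
        columns=["phecode", "g", "c", "b", "class"],
    )
    ground_truth = pd.concat([index_row, truth], ignore_index=True)
    return CohortBundle(
        sites=sites, map_frame=build_map_frame(config), ground_truth=ground_truth
    )


def make_benchmark(config: GeneratorConfig, out_dir) -> dict[str, Path]:
    """Write the benchmark fixture to disk in the pipeline's input formats.

    Per site: ``<site>_events.tsv``, ``<site>_demographics.tsv``,
    ``<site>_prs.tsv``, ``<site>_pcs.tsv``; shared ``phecode_map.csv`` and
    ``ground_truth.tsv`` (the latter is never a pipeline input).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_cohort(config)
    paths: dict[str, Path] = {}
    for site, data in bundle.sites.items():
        for kind, frame in (
            ("events", data.events),
            ("demographics", data.demographics),
            ("prs", data.prs),
            ("pcs", data.pcs),
        ):
            path = out / f"{site}_{kind}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            paths[f"{site}_{kind}"] = path
    map_path = out / "phecode_map.csv"
    bundle.map_frame.to_csv(map_path, index=False)
    paths["phecode_map"] = map_path
    truth_path = out / "ground_truth.tsv"
    bundle.ground_truth.to_csv(truth_path, sep="\t", index=False)
    paths["ground_truth"] = truth_path
    return paths
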