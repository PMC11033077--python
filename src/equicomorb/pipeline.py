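"""End-to-end pipeline orchestration with config validation and provenance.

A `PipelineConfig` (YAML on disk) names the per-site input files and every
analysis knob; `run_pipeline` validates it, fits the
:class:`~equicomorb.model.ComorbidityEquivalenceModel` and writes one TSV
per stage plus a tier-count JSON.  Every output carries header comments
with the tool version, a hash of the fully-serialized config and the
thresholds used, so a rerun with the same config and inputs is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .model import ComorbidityEquivalenceModel, ComorbidityEquivalenceResults, SiteCohort
from .phecodes import (
    DEMOGRAPHICS_COLUMNS,
    EVENT_COLUMNS,
    PhecodeMap,
    SchemaError,
)
from .phewas import PC_COLUMNS, read_score_file

logger = logging.getLogger(__name__)

_SITE_KEYS = {"events", "demographics", "prs", "pcs"}
_CONFIG_KEYS = {
    "sites", "phecode_map", "index_phecode", "alpha", "min_cases",
    "direction_rule", "tost_bounds", "exclude_index_cases", "tost_variant",
    "out_dir",
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    sites: dict[str, dict[str, str]]
    phecode_map: str
    out_dir: str = "equicomorb_out"
    index_phecode: str = "295.1"
    alpha: float = 0.05
    min_cases: int = 20
    direction_rule: str = "mean"
    tost_bounds: tuple[float, float] = (-0.2, 0.2)
    exclude_index_cases: bool = True
    tost_variant: str = "welch"

    def __post_init__(self) -> None:
        if not self.sites:
            raise SchemaError("config defines no sites")
        for site, paths in self.sites.items():
            unknown = set(paths) - _SITE_KEYS
            if unknown:
                raise SchemaError(f"site {site}: unknown keys {sorted(unknown)}")
            if not {"events", "demographics"} <= set(paths):
                raise SchemaError(f"site {site}: events and demographics required")
        self.tost_bounds = tuple(float(b) for b in self.tost_bounds)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SchemaError("config must be a mapping")
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def serialized(self) -> str:
        payload = dict(self.__dict__)
        payload["tost_bounds"] = list(self.tost_bounds)
        return yaml.safe_dump(payload, sort_keys=True)

    def digest(self) -> str:
        """Hash of the analysis-relevant config (the output location does
        not change the results, so it is excluded)."""
        payload = dict(self.__dict__)
        payload.pop("out_dir")
        payload["tost_bounds"] = list(self.tost_bounds)
        text = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


# --------------------------------------------------------------- validation

def _check_table(path: str, reader, checks) -> dict:
    entry = {"path": str(path), "ok": True, "messages": []}

    def fail(msg: str) -> None:
        entry["ok"] = False
        if len(entry["messages"]) < 100:
            entry["messages"].append(msg)

    try:
        frame = reader(path)
    except FileNotFoundError:
        fail("file not found")
        return entry
    except Exception as err:  # unreadable or malformed
        fail(f"unreadable: {err}")
        return entry
    checks(frame, fail)
    return entry


def _events_checks(frame: pd.DataFrame, fail) -> None:
    missing = set(EVENT_COLUMNS) - set(frame.columns)
    if missing:
        fail(f"missing columns: {sorted(missing)}")
        return
    parsed = pd.to_datetime(frame["date"], format="%Y-%m-%d", errors="coerce")
    for line in frame.index[parsed.isna()][:100]:
        fail(f"line {line + 2}: unparseable ISO-8601 date {frame.at[line, 'date']!r}")
    bad_vocab = ~frame["vocabulary"].isin(["ICD9", "ICD10"])
    for line in frame.index[bad_vocab][:100]:
        fail(f"line {line + 2}: unknown vocabulary {frame.at[line, 'vocabulary']!r}")


def _demographics_checks(frame: pd.DataFrame, fail) -> None:
    missing = set(DEMOGRAPHICS_COLUMNS) - set(frame.columns)
    if missing:
        fail(f"missing columns: {sorted(missing)}")
        return
    dup = frame["patient_id"].duplicated()
    for line in frame.index[dup][:100]:
        fail(f"line {line + 2}: duplicate patient_id {frame.at[line, 'patient_id']!r}")
    for col in ("current_age", "ehr_age"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        for line in frame.index[vals.isna() | (vals < 0)][:100]:
            fail(f"line {line + 2}: bad {col} {frame.at[line, col]!r}")


def _score_checks(path: str) -> dict:
    entry = {"path": str(path), "ok": True, "messages": []}
    try:
        read_score_file(path)
    except FileNotFoundError:
        entry["ok"] = False
        entry["messages"].append("file not found")
    except SchemaError as err:
        entry["ok"] = False
        entry["messages"].append(str(err))
    return entry


def _pcs_checks(frame: pd.DataFrame, fail) -> None:
    missing = {"patient_id", *PC_COLUMNS} - set(frame.columns)
    if missing:
        fail(f"missing columns: {sorted(missing)}")
    elif frame["patient_id"].duplicated().any():
        fail("duplicate patient ids")


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Per-file pass/fail report with row-level diagnostics (capped at 100)."""
    read_tsv = lambda p: pd.read_csv(p, sep="\t", dtype=str, comment="#")
    report = [
        _check_table(
            config.phecode_map,
            lambda p: pd.read_csv(p, dtype=str, comment="#"),
            lambda f, fail: (
                fail(f"missing columns: {sorted({'code', 'vocabulary', 'phecode'} - set(f.columns))}")
                if not {"code", "vocabulary", "phecode"} <= set(f.columns)
                else None
            ),
        )
    ]
    for site, paths in sorted(config.sites.items()):
        report.append(_check_table(paths["events"], read_tsv, _events_checks))
        report.append(_check_table(paths["demographics"], read_tsv, _demographics_checks))
        if "prs" in paths:
            report.append(_score_checks(paths["prs"]))
        if "pcs" in paths:
            report.append(
                _check_table(
                    paths["pcs"],
                    lambda p: pd.read_csv(p, sep="\t", comment="#"),
                    _pcs_checks,
                )
            )
    return report


# ---------------------------------------------------------------- execution

def load_model(config: PipelineConfig) -> ComorbidityEquivalenceModel:
    phecode_map = PhecodeMap.from_csv(config.phecode_map)
    sites = {}
    for site, paths in config.sites.items():
        events = pd.read_csv(paths["events"], sep="\t", dtype=str, comment="#")
        demo = pd.read_csv(paths["demographics"], sep="\t", dtype=str, comment="#")
        prs = read_score_file(paths["prs"]) if "prs" in paths else None
        pcs = (
            pd.read_csv(paths["pcs"], sep="\t", comment="#")
            if "pcs" in paths else None
        )
        sites[site] = SiteCohort(events, demo, prs, pcs)
    return ComorbidityEquivalenceModel(
        sites,
        phecode_map,
        index_phecode=config.index_phecode,
        alpha=config.alpha,
        min_cases=config.min_cases,
        direction_rule=config.direction_rule,
        tost_bounds=config.tost_bounds,
        exclude_index_cases=config.exclude_index_cases,
        tost_variant=config.tost_variant,
    )


def _provenance(config: PipelineConfig, results: ComorbidityEquivalenceResults) -> list[str]:
    lines = [
        f"# equicomorb {__version__}",
        f"# config_hash {config.digest()}",
    ]
    for key, value in sorted(results.thresholds.items()):
        lines.append(f"# threshold {key}={value}")
    return lines


def write_tsv(frame: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> ComorbidityEquivalenceResults:
    """Execute every stage and write the result bundle to ``config.out_dir``.

    A failing stage raises :class:`StageError` naming the stage; partial
    outputs are removed.
    """
    report = validate_inputs(config)
    bad = [e for e in report if not e["ok"]]
    if bad:
        detail = "; ".join(f"{e['path']}: {e['messages'][:3]}" for e in bad)
        raise SchemaError(f"input validation failed: {detail}")

    try:
        model = load_model(config)
    except Exception as err:
        raise StageError(f"stage load_inputs: {err}") from err
    try:
        results = model.fit()
    except Exception as err:
        raise StageError(f"stage fit: {err}") from err

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = _provenance(config, results)
    written: list[Path] = []
    try:
        tables = {
            "site_scan.tsv": results.site_scan,
            "comorbidity_combined.tsv": results.comorbidity,
            "prs_phewas_site.tsv": results.prs_site,
            "prs_phewas_meta.tsv": results.prs_meta,
            "tost_site.tsv": results.tost_site,
            "equivalence_meta.tsv": results.equivalence,
            "classification.tsv": results.verdicts,
        }
        for name, frame in tables.items():
            path = out_dir / name
            write_tsv(frame, path, header)
            written.append(path)
        summary_path = out_dir / "tier_counts.json"
        summary_path.write_text(
            json.dumps(
                {
                    "version": __version__,
                    "config_hash": config.digest(),
                    "thresholds": {
                        k: (float(v) if v == v else None)
                        for k, v in results.thresholds.items()
                    },
                    "tier_counts": results.tier_counts,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        written.append(summary_path)
    except Exception as err:
        for path in written:
            path.unlink(missing_ok=True)
        raise StageError(f"stage write_outputs: {err}") from err
    logger.info("pipeline complete: %d tables in %s", len(written), out_dir)
    return results
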