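"""Machine-readable study report models.

Pydantic models defining (and validating) the JSON report emitted by
the end-to-end pipeline; ``schemas/study_report.schema.json`` in the
package is the published JSON schema generated from these models.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Optional

from pydantic import BaseModel, Field


class Provenance(BaseModel):
    seed: int
    config_sha256: str
    package_version: str


class SummaryBlock(BaseModel):
    n: int
    mean_R: float
    sd_R: float
    var_R: float
    q25: float
    median: float
    q75: float
    min: float
    max: float
    n_open: int
    n_closed: int
    frac_open: float
    frac_above: dict[str, float]


class ConditionReport(BaseModel):
    condition: str
    n_molecules: int = Field(description="molecules simulated for this condition")
    n_detected: int
    n_labeled: int
    n_excluded: int
    summary: SummaryBlock
    truth_summary: SummaryBlock
    open_fraction_error: float = Field(
        description="measured frac_open minus ground-truth frac_open")


class ComparisonReport(BaseModel):
    open_counts: list[int]
    group_sizes: list[int]
    open_percent: list[float]
    proportion_z: float
    proportion_z_p: float
    fisher_odds_ratio: float
    fisher_p: float
    mannwhitney_U: float
    mannwhitney_p: float


class AfmStudyReport(BaseModel):
    conditions: dict[str, ConditionReport]
    comparison: ComparisonReport


class BasinBlock(BaseModel):
    delta_g_kj_mol: float
    occupancy: float


class FlexibilityFixtureReport(BaseModel):
    fixture: str
    n_frames: int
    n_basins: int
    basins: list[BasinBlock]
    occupancy_ratio: Optional[float]
    barrier_kj_mol: Optional[float]
    pc1_variance_fraction: float
    truth_occupancy_ratio: Optional[float]


class FlexibilityStudyReport(BaseModel):
    fixtures: dict[str, FlexibilityFixtureReport]


class StudyReport(BaseModel):
    provenance: Provenance
    afm: Optional[AfmStudyReport] = None
    flexibility: Optional[FlexibilityStudyReport] = None

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)


def config_sha256(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def published_schema() -> dict:
    """The JSON schema shipped with the package."""
    text = resources.files("conformetry").joinpath(
        "schemas/study_report.schema.json").read_text()
    return json.loads(text)


def validate_report_json(text: str) -> StudyReport:
    """Parse + validate a report JSON document against the schema models."""
    return StudyReport.model_validate_json(text)
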