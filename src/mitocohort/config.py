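"""Run configuration and run report.

One flat JSON document drives a whole reproducible run: the seed, the cohort
design, and every analysis tunable.  Unknown keys are rejected so a typo in a
config file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from pydantic import BaseModel, ConfigDict

from .synthgen.cohort import CohortSimConfig


class RunConfig(BaseModel):
    """Flat, serializable description of one end-to-end run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "results"
    # cohort design
    group_sizes: dict[str, int] = {
        "Control": 49, "ART-naive": 49, "2NRTI+1PI/r": 27,
        "2NRTI+1NNRTI": 27, "3NRTI": 27,
    }
    n_lymph_events: int = 15000
    n_mono_events: int = 3000
    images_per_subject: int = 30
    imaging_subjects_per_group: int = 3
    # stage toggles
    run_simulate: bool = True
    run_morphometry: bool = True
    run_cytometry: bool = True
    run_discrim: bool = True
    run_stats: bool = True
    # analysis tunables
    ros_delta_decades: float = 0.15
    ros_min_weight: float = 0.01
    circle_confidence: float = 0.95
    quartile_method: str = "linear"
    # lymphocyte scatter gate rectangle (linear intensities)
    gate_fsc_min: float = 10**1.85
    gate_fsc_max: float = 10**2.15
    gate_ssc_min: float = 10**1.50
    gate_ssc_max: float = 10**1.90

    def cohort_config(self) -> CohortSimConfig:
        return CohortSimConfig(
            group_sizes=dict(self.group_sizes),
            n_lymph_events=self.n_lymph_events,
            n_mono_events=self.n_mono_events,
            images_per_subject=self.images_per_subject,
            imaging_subjects_per_group=self.imaging_subjects_per_group,
            seed=self.seed,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class RunReport:
    """Counts, warnings and exclusions of one run; every exclusion carries a
    reason so nothing disappears silently."""

    config_hash: str = ""
    seed: int = 0
    stage_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    exclusions: list = field(default_factory=list)  # {stage, item, reason}
    versions: dict = field(default_factory=dict)

    def exclude(self, stage: str, item: str, reason: str) -> None:
        self.exclusions.append({"stage": stage, "item": item, "reason": reason})

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")
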