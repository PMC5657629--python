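"""Pipeline configuration: every free parameter in one (YAML-able) place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kinematics import DescriptorConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the train/classify pipeline.

    The three KNN stages (per-frame training confidence, time-label
    estimation, classification) share K = 5 by default but may be set
    independently.  ``onset_threshold`` (Th) is in squared coordinate
    units because the motion statistic is a variance of coordinates.
    """

    descriptor: DescriptorConfig = field(default_factory=DescriptorConfig)
    # motion-onset detection
    onset_window: int = 5            # T, frames (odd)
    onset_threshold: float = 0.005   # Th, squared coordinate units
    onset_rms: bool = False          # compare sqrt(S) instead of S
    monitored_joints: tuple[str, ...] | None = None  # default: descriptor subset
    # KNN stages
    k_confidence: int = 5
    k_time: int = 5
    k_classify: int = 5
    time_bin_width: int = 1          # b, frames
    voting_halfwidth: int = 5        # w_t, frames
    metric: str = "euclidean"
    # streaming decision gate
    alpha_dec: float = 0.5           # minimum winning vote fraction
    t_th: int = 15                   # frames observed before a decision
    tally_reset: str = "full"        # or "decay"
    tally_decay: float = 0.5         # used when tally_reset == "decay"
    use_sensor_confidence: bool = False

    def __post_init__(self) -> None:
        if self.onset_window % 2 == 0 or self.onset_window < 3:
            raise ValueError("onset_window must be odd and >= 3")
        if not (0 < self.alpha_dec <= 1):
            raise ValueError("alpha_dec must be in (0, 1]")
        for k in (self.k_confidence, self.k_time, self.k_classify):
            if k < 1:
                raise ValueError("K must be >= 1")
        if self.tally_reset not in ("full", "decay"):
            raise ValueError("tally_reset must be 'full' or 'decay'")

    @property
    def monitored(self) -> tuple[str, ...]:
        return self.monitored_joints or self.descriptor.selected_joints

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["descriptor"]["selected_joints"] = list(self.descriptor.selected_joints)
        if self.monitored_joints is not None:
            d["monitored_joints"] = list(self.monitored_joints)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        desc = d.pop("descriptor", {})
        if isinstance(desc, dict):
            desc = dict(desc)
            if "selected_joints" in desc:
                desc["selected_joints"] = tuple(desc["selected_joints"])
            desc = DescriptorConfig(**desc)
        if d.get("monitored_joints") is not None:
            d["monitored_joints"] = tuple(d["monitored_joints"])
        return cls(descriptor=desc, **d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
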