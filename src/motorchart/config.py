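"""Category inventories, frame-timing constants, and generator configuration.

The wearable pipeline operates on label streams at a fixed frame hop of
1.15 s (2.3 s frames with 50% overlap), so one hour corresponds to 3,130
frames.  Ages are real-valued months; day counts convert at 30.4375
days/month.
"""

from __future__ import annotations

import copy
import dataclasses
from importlib import resources
from typing import Any

import yaml

HOP_SECONDS: float = 1.15
FRAME_SECONDS: float = 2.3
SAMPLE_RATE_HZ: float = 52.0
FRAMES_PER_HOUR: int = int(3600.0 / HOP_SECONDS)  # 3130
DAYS_PER_MONTH: float = 30.4375

SUPER_SEGMENT_FRAMES: int = 520  # 10-minute windows of 1.15 s frames
SUPER_SEGMENT_OVERLAP: float = 0.5

MIN_PLAYTIME_HOURS: float = 1.0 / 3.0  # recordings below this are excluded
EPOCH_MIN_PLAYTIME_HOURS: float = 2.0  # noise analysis needs > 2 h playtime


def _load_defaults() -> dict[str, Any]:
    text = resources.files("motorchart").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


_DEFAULTS = _load_defaults()

POSTURES: tuple[str, ...] = tuple(_DEFAULTS["categories"]["postures"])
MOVEMENTS: tuple[str, ...] = tuple(_DEFAULTS["categories"]["movements"])


def default_parameters() -> dict[str, Any]:
    """Deep copy of the documented default generator parameters."""
    return copy.deepcopy(_DEFAULTS)


@dataclasses.dataclass
class SyntheticConfig:
    """Full parameterization of the synthetic cohort generator.

    Defaults come from ``defaults.yaml`` (packaged alongside this module),
    which documents every trajectory and noise parameter.  ``seed`` controls
    all randomness; identical configs produce byte-identical cohorts.
    """

    n_subjects: int = _DEFAULTS["cohort"]["n_subjects"]
    age_range_months: tuple[float, float] = tuple(_DEFAULTS["cohort"]["age_range_months"])
    recordings_per_subject: tuple[int, int] = tuple(_DEFAULTS["cohort"]["recordings_per_subject"])
    session_hours: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULTS["cohort"]["session_hours"])
    )
    playtime_fraction: float = _DEFAULTS["cohort"]["playtime_fraction"]
    carried_fraction: float = _DEFAULTS["cohort"]["carried_fraction"]
    lowquality_fraction: float = _DEFAULTS["cohort"]["lowquality_fraction"]
    mean_block_minutes: float = _DEFAULTS["cohort"]["mean_block_minutes"]
    mean_play_block_minutes: float = _DEFAULTS["cohort"]["mean_play_block_minutes"]
    sigma_dev: float = _DEFAULTS["cohort"]["sigma_dev"]
    sigma_sess: float = _DEFAULTS["cohort"]["sigma_sess"]
    p_stay: float = _DEFAULTS["cohort"]["p_stay"]
    visits_per_subject: tuple[int, int] = tuple(_DEFAULTS["cohort"]["visits_per_subject"])
    posture_trajectories: dict[str, list[float]] = dataclasses.field(
        default_factory=lambda: copy.deepcopy(_DEFAULTS["posture_trajectories"])
    )
    movement_maturation: dict[str, Any] = dataclasses.field(
        default_factory=lambda: copy.deepcopy(_DEFAULTS["movement_maturation"])
    )
    nonplay_distribution: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=lambda: copy.deepcopy(_DEFAULTS["nonplay_distribution"])
    )
    physical_curves: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=lambda: copy.deepcopy(_DEFAULTS["physical_curves"])
    )
    postures: tuple[str, ...] = POSTURES
    movements: tuple[str, ...] = MOVEMENTS
    dataset_tag: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lo, hi = self.age_range_months
        if not (0 <= lo < hi):
            raise ValueError(f"invalid age range [{lo}, {hi}]: need 0 <= lo < hi")
        occupied = self.playtime_fraction + self.carried_fraction + self.lowquality_fraction
        if occupied > 1 + 1e-9:
            raise ValueError(
                "playtime + carried + low-quality fractions exceed 1 "
                f"({occupied:.3f})"
            )
        for name in ("playtime_fraction", "carried_fraction", "lowquality_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 <= self.p_stay < 1):
            raise ValueError(f"p_stay must lie in [0, 1), got {self.p_stay}")
        for name in ("sigma_dev", "sigma_sess"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["age_range_months"] = list(self.age_range_months)
        doc["recordings_per_subject"] = list(self.recordings_per_subject)
        doc["visits_per_subject"] = list(self.visits_per_subject)
        doc["postures"] = list(self.postures)
        doc["movements"] = list(self.movements)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        for key in ("age_range_months", "recordings_per_subject", "visits_per_subject",
                    "postures", "movements"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def hours_to_frames(hours: float) -> int:
    """Whole frames in ``hours`` of recording at the 1.15 s hop (rounded down)."""
    return int(hours * 3600.0 / HOP_SECONDS)


def frames_to_hours(n_frames: int) -> float:
    return n_frames * HOP_SECONDS / 3600.0
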