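"""Per-subject outcome metrics and their tabular serialization."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

GROUP_LABELS = ("KL0", "KL2", "KL3")

_COLUMNS = [
    "subject_id",
    "group_label",
    "max_degeneration_femoral",
    "max_degeneration_tibial",
    "degenerated_volume_femoral",
    "degenerated_volume_tibial",
]


@dataclass
class SubjectResult:
    """Endpoint metrics of one simulated subject.

    Degeneration is reported as 1 - D (0 = intact collagen network,
    1 = fully degenerated), so metrics increase with disease severity.
    Volumes are in mm^3 of elements showing any degeneration.
    """

    subject_id: str
    group_label: str
    max_degeneration_femoral: float
    max_degeneration_tibial: float
    degenerated_volume_femoral: float
    degenerated_volume_tibial: float

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group_label!r}")
        for name in _COLUMNS[2:4]:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")
        for name in _COLUMNS[4:]:
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")


def results_frame(results: list[SubjectResult]) -> pd.DataFrame:
    if not results:
        raise ValueError("results must be non-empty")
    return pd.DataFrame([vars(r) for r in results], columns=_COLUMNS)


def write_results(results: list[SubjectResult], path: str | Path) -> None:
    """Write one CSV row per subject; floats keep 17 significant digits so
    the table round-trips bit-exactly."""
    results_frame(results).to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | Path) -> list[SubjectResult]:
    df = pd.read_csv(path)
    return [SubjectResult(**{c: row[c] for c in _COLUMNS}) for _, row in df.iterrows()]
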