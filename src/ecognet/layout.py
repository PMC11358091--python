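"""Electrode layout and cortical region assignment.

Ten epidural screw electrodes are placed relative to the anterior
fontanel (x: mm lateral, positive right; y: mm anteroposterior, positive
anterior) and grouped into three cortical regions: frontal (FL1, FR1,
FL2, FR2), parietal (PL1, PR1, PL2, PR2) and occipital (OL, OR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

REGIONS = ("F", "P", "O")

# (label, x mm, y mm, region)
_DEFAULT_ENTRIES = [
    ("FL1", -1.5, 4.5, "F"),
    ("FR1", 1.5, 4.5, "F"),
    ("FL2", -1.5, 1.5, "F"),
    ("FR2", 1.5, 1.5, "F"),
    ("PL1", -1.5, -1.5, "P"),
    ("PR1", 1.5, -1.5, "P"),
    ("PL2", -1.5, -4.5, "P"),
    ("PR2", 1.5, -4.5, "P"),
    ("OL", -3.0, -7.0, "O"),
    ("OR", 3.0, -7.0, "O"),
]


@dataclass(frozen=True)
class ElectrodeLayout:
    """Channel label -> (x, y) position and region membership."""

    entries: tuple = field(default_factory=lambda: tuple(_DEFAULT_ENTRIES))

    def __post_init__(self):
        labels = [e[0] for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate electrode labels in layout")

    @property
    def labels(self) -> list[str]:
        return [e[0] for e in self.entries]

    def region_of(self, label: str) -> str:
        for lab, _x, _y, region in self.entries:
            if lab == label:
                return region
        raise KeyError(f"unknown electrode label: {label!r}")

    def region_channels(self, region: str) -> list[str]:
        return [e[0] for e in self.entries if e[3] == region]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["label", "x_mm", "y_mm", "region"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ElectrodeLayout":
        cols = ["label", "x_mm", "y_mm", "region"]
        return cls(tuple(tuple(row) for row in df[cols].itertuples(index=False)))


def default_layout() -> ElectrodeLayout:
    """The 10-electrode frontal/parietal/occipital layout used throughout."""
    return ElectrodeLayout()


def assign_regions(layout: ElectrodeLayout, labels: list[str]) -> dict[str, str]:
    """Map each channel label to its region (``F``/``P``/``O``/``none``).

    Raises ``KeyError`` naming the first label absent from the layout.
    """
    known = {e[0]: e[3] for e in layout.entries}
    out: dict[str, str] = {}
    for lab in labels:
        if lab not in known:
            raise KeyError(f"label {lab!r} not present in electrode layout")
        out[lab] = known[lab] if known[lab] in REGIONS else "none"
    return out
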