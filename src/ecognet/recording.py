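"""The multichannel epoch container and its CSV on-disk form.

One :class:`Recording` is a single subject-condition-epoch: a channels x
time matrix in microvolts with a sampling rate, channel labels and a
per-sample usability mask. Epochs are written as plain CSV (columns =
channel labels, rows = samples) with the sampling rate carried in a
``# fs=<Hz>`` header line, plus a cohort manifest CSV indexing the files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Recording:
    samples: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    condition: str = ""  # "normal" | "scz"
    day: int = 0
    epoch: int = 0
    artifact_mask: np.ndarray | None = None  # True = usable
    excluded: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match channel count")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.artifact_mask is None:
            self.artifact_mask = np.ones(self.samples.shape[1], dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape[0] != self.samples.shape[1]:
                raise ValueError("artifact_mask length must equal sample length")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label: {label!r}") from None
        return self.samples[i]

    def with_samples(self, samples: np.ndarray, fs: float | None = None,
                     artifact_mask: np.ndarray | None = None) -> "Recording":
        """Copy with new sample matrix (and optionally new fs / mask)."""
        return replace(
            self,
            samples=samples,
            fs=self.fs if fs is None else fs,
            artifact_mask=artifact_mask,
        )

    def masked_samples(self) -> np.ndarray:
        """Channels x time restricted to artifact-free samples."""
        return self.samples[:, self.artifact_mask]


def write_epoch_csv(rec: Recording, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        df = pd.DataFrame(rec.samples.T, columns=rec.channel_labels)
        df.to_csv(fh, index=False, float_format="%.6f")


def read_epoch_csv(path: str | Path, **meta) -> Recording:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' header line")
        fs = float(header.strip().split("=", 1)[1])
        df = pd.read_csv(io.StringIO(fh.read()))
    return Recording(
        samples=df.to_numpy().T,
        fs=fs,
        channel_labels=list(df.columns),
        **meta,
    )


MANIFEST_COLUMNS = ["subject", "condition", "day", "epoch", "path"]


def write_manifest(rows: list[dict], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest, validating columns and file existence per row."""
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest {path}: missing columns {sorted(missing_cols)}")
    base = path.parent
    problems = []
    for i, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            problems.append(f"row {i} (subject={row['subject']}, epoch={row['epoch']}): missing file {p}")
    if problems:
        raise FileNotFoundError("manifest refers to missing epochs:\n" + "\n".join(problems))
    return df


def load_manifest_epochs(manifest: pd.DataFrame, base: str | Path = ".") -> list[Recording]:
    base = Path(base)
    recs = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        recs.append(
            read_epoch_csv(
                p,
                subject_id=str(row["subject"]),
                condition=str(row["condition"]),
                day=int(row["day"]),
                epoch=int(row["epoch"]),
            )
        )
    return recs
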