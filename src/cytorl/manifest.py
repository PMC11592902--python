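"""Dataset manifest: the on-disk contract between generation and loading.

A manifest lists every image with its integer class label and clinical group
flag (normal / abnormal / benign), mirroring a ``<root>/<class>/<index>.png``
directory tree plus a ``manifest.csv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["ManifestRecord", "DatasetManifest"]

VALID_GROUPS = ("normal", "abnormal", "benign")


@dataclass(frozen=True)
class ManifestRecord:
    path: Path
    label: int
    group: str


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    class_names: dict[int, str] = field(default_factory=dict)
    root: Path | None = None

    @property
    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return dict(sorted(counts.items()))

    @property
    def n_classes(self) -> int:
        return len({r.label for r in self.records})

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, indices) -> "DatasetManifest":
        return DatasetManifest(
            [self.records[i] for i in indices], dict(self.class_names), self.root
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path": [str(r.path) for r in self.records],
                "class": [self.class_names.get(r.label, str(r.label)) for r in self.records],
                "label": [r.label for r in self.records],
                "group": [r.group for r in self.records],
            }
        )

    def save_csv(self, path: Path | str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Path | str) -> "DatasetManifest":
        df = pd.read_csv(path)
        records = [
            ManifestRecord(Path(p), int(lbl), str(grp))
            for p, lbl, grp in zip(df["path"], df["label"], df["group"])
        ]
        names = {int(l): str(c) for l, c in zip(df["label"], df["class"])}
        return cls(records, names, Path(path).parent)

    def validate(self) -> None:
        total = sum(self.class_counts.values())
        if total != len(self.records):
            raise ValueError("class counts do not sum to record count")
        for r in self.records:
            if r.group not in VALID_GROUPS:
                raise ValueError(f"unknown group flag {r.group!r} for {r.path}")
            if not Path(r.path).exists():
                raise FileNotFoundError(f"manifest refers to missing file: {r.path}")
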