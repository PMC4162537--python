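"""Core containers: expression matrices, sample metadata, probe maps.

An :class:`ExpressionMatrix` is a miRNA × sample numeric matrix tagged with
the measuring platform (``ngs`` or ``microarray``) and the value scale
(``raw`` counts/signals, ``log``, or ``zscore``).  Missing values (e.g. a
log of a non-positive raw value) are stored as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

PLATFORMS = ("ngs", "microarray")
SCALES = ("raw", "log", "zscore")
LABELS = ("tumor", "control", "unknown")


class MatrixError(ValueError):
    """Invalid matrix contents or metadata."""


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise MatrixError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """miRNA × sample matrix with platform and scale tags.

    Parameters
    ----------
    values
        2-D float array of shape ``(len(mirna_ids), len(sample_ids))``.
    mirna_ids, sample_ids
        Ordered, unique row / column identifiers.
    platform
        ``"ngs"`` or ``"microarray"``.
    scale
        ``"raw"``, ``"log"`` or ``"zscore"``.
    """

    values: np.ndarray
    mirna_ids: list[str]
    sample_ids: list[str]
    platform: str
    scale: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mirna_ids = [str(m) for m in self.mirna_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.platform not in PLATFORMS:
            raise MatrixError(f"unknown platform {self.platform!r}")
        if self.scale not in SCALES:
            raise MatrixError(f"unknown scale {self.scale!r}")
        if self.values.ndim != 2:
            raise MatrixError("values must be 2-D")
        if self.values.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise MatrixError(
                f"shape {self.values.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs × {len(self.sample_ids)} samples"
            )
        _check_unique(self.mirna_ids, "miRNA")
        _check_unique(self.sample_ids, "sample")
        if self.scale == "raw":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and finite.min() < 0:
                raise MatrixError("raw values must be non-negative")
            if self.platform == "ngs":
                if finite.size and not np.allclose(finite, np.round(finite)):
                    raise MatrixError("raw NGS counts must be integers")

    # -- convenience ----------------------------------------------------

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def mirna_index(self, mirna_id: str) -> int:
        try:
            return self.mirna_ids.index(mirna_id)
        except ValueError:
            raise KeyError(f"unknown miRNA id {mirna_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_index(sample_id)]

    def subset_mirnas(self, ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.mirna_index(m) for m in ids]
        return replace(self, values=self.values[idx, :], mirna_ids=list(ids))

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_index(s) for s in ids]
        return replace(self, values=self.values[:, idx], sample_ids=list(ids))

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "ExpressionMatrix":
        return replace(self, values=values, scale=scale or self.scale)

    def equals(self, other: "ExpressionMatrix", rtol: float = 0.0, atol: float = 0.0) -> bool:
        return (
            self.mirna_ids == other.mirna_ids
            and self.sample_ids == other.sample_ids
            and self.platform == other.platform
            and self.scale == other.scale
            and np.allclose(self.values, other.values, rtol=rtol, atol=atol, equal_nan=True)
        )


@dataclass
class SampleRecord:
    sample_id: str
    label: str = "unknown"
    replicate_group: str = ""
    platforms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        label = str(self.label).strip().lower()
        if label not in LABELS:
            raise MatrixError(f"unknown label {self.label!r} for sample {self.sample_id!r}")
        self.label = label
        if not self.replicate_group:
            self.replicate_group = self.sample_id
        self.platforms = frozenset(self.platforms)
        bad = self.platforms - set(PLATFORMS)
        if bad:
            raise MatrixError(f"unknown platforms {sorted(bad)} for sample {self.sample_id!r}")


@dataclass
class SampleTable:
    """Per-sample metadata: class label, replicate grouping, platforms."""

    records: list[SampleRecord]

    def __post_init__(self) -> None:
        _check_unique([r.sample_id for r in self.records], "sample")

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def record(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(f"unknown sample id {sample_id!r}")

    def label_of(self, sample_id: str) -> str:
        return self.record(sample_id).label

    def labels_for(self, sample_ids: Iterable[str]) -> list[str]:
        return [self.label_of(s) for s in sample_ids]

    def samples_with_label(self, label: str) -> list[str]:
        return [r.sample_id for r in self.records if r.label == label]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ProbeMap:
    """Many-to-one map from microarray probe id to mature miRNA id."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        self.mapping = dict(self.mapping)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.mapping

    def __getitem__(self, probe_id: str) -> str:
        return self.mapping[probe_id]

    def items(self):
        return self.mapping.items()

    def mirnas(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.mapping.values():
            seen.setdefault(m)
        return list(seen)

    def __len__(self) -> int:
        return len(self.mapping)
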