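"""Filtering of novel miRNA candidate calls.

A candidate locus (keyed by id, with a 1-based inclusive genomic
coordinate string ``chrom:start-end:strand``) is retained when it is
called with an estimated true-positive probability above a threshold in
at least a minimum number of distinct samples.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CandidateCall", "parse_coordinate", "filter_novel_candidates", "candidate_report"]

_COORD_RE = re.compile(r"^([^\s:]+):(\d+)-(\d+):([+-])$")


class CoordinateError(ValueError):
    """Malformed genomic coordinate string."""


def parse_coordinate(coord: str) -> tuple[str, int, int, str]:
    """Parse ``chrom:start-end:strand`` (1-based inclusive)."""
    m = _COORD_RE.match(coord)
    if not m:
        raise CoordinateError(f"malformed coordinate {coord!r}")
    chrom, start, end, strand = m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
    if start < 1 or end < start:
        raise CoordinateError(f"invalid interval in {coord!r}")
    return chrom, start, end, strand


@dataclass(frozen=True)
class CandidateCall:
    """One per-sample discovery call for a candidate locus."""

    candidate_id: str
    coordinate: str  # chrom:start-end:strand, 1-based inclusive
    probability: float  # estimated true-positive probability, percent
    sample_id: str
    read_support: int = 0
    mature_sequence: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 100.0:
            raise ValueError(
                f"probability {self.probability} outside [0, 100] for {self.candidate_id!r}"
            )
        if self.read_support < 0:
            raise ValueError(f"negative read support for {self.candidate_id!r}")


def _validate_calls(calls: Iterable[CandidateCall]) -> tuple[list[CandidateCall], int]:
    ok: list[CandidateCall] = []
    rejected = 0
    for call in calls:
        try:
            parse_coordinate(call.coordinate)
        except CoordinateError as exc:
            rejected += 1
            logger.warning("rejecting call for %s in %s: %s", call.candidate_id, call.sample_id, exc)
            continue
        ok.append(call)
    return ok, rejected


def filter_novel_candidates(
    calls: Sequence[CandidateCall],
    min_probability: float = 80.0,
    min_samples: int = 4,
    per_sample_probability: bool = True,
) -> pd.DataFrame:
    """Retain candidates called convincingly in enough distinct samples.

    With ``per_sample_probability`` (default, the stricter reading) a sample
    counts toward ``min_samples`` only when its own call has probability
    strictly above ``min_probability``; with ``False`` a candidate needs
    any call above the threshold plus detection in ``min_samples`` samples.
    Records with malformed coordinates are rejected individually (logged).
    Output order is deterministic (by candidate id).
    """
    valid, rejected = _validate_calls(calls)
    if rejected:
        logger.warning("filter_novel_candidates: rejected %d malformed calls", rejected)
    by_id: dict[str, list[CandidateCall]] = {}
    for call in valid:
        by_id.setdefault(call.candidate_id, []).append(call)

    rows = []
    for cid in sorted(by_id):
        group = by_id[cid]
        qualifying = {c.sample_id for c in group if c.probability > min_probability}
        detected = {c.sample_id for c in group}
        max_p = max(c.probability for c in group)
        if per_sample_probability:
            retained = len(qualifying) >= min_samples
        else:
            retained = max_p > min_probability and len(detected) >= min_samples
        if retained:
            rows.append(
                {
                    "candidate_id": cid,
                    "coordinate": group[0].coordinate,
                    "n_samples_qualifying": len(qualifying),
                    "n_samples_detected": len(detected),
                    "max_probability": max_p,
                }
            )
    columns = [
        "candidate_id",
        "coordinate",
        "n_samples_qualifying",
        "n_samples_detected",
        "max_probability",
    ]
    return pd.DataFrame(rows, columns=columns)


def candidate_report(retained: pd.DataFrame, calls: Sequence[CandidateCall]) -> pd.DataFrame:
    """Per-retained-candidate summary: coordinate, distinct-sample count,
    total read support, and mature sequence when available."""
    valid, _ = _validate_calls(calls)
    by_id: dict[str, list[CandidateCall]] = {}
    for call in valid:
        by_id.setdefault(call.candidate_id, []).append(call)
    rows = []
    for cid in sorted(retained["candidate_id"]) if len(retained) else []:
        group = by_id.get(cid, [])
        seqs = {c.mature_sequence for c in group if c.mature_sequence}
        rows.append(
            {
                "candidate_id": cid,
                "coordinate": group[0].coordinate if group else "",
                "n_samples": len({c.sample_id for c in group}),
                "total_read_support": int(sum(c.read_support for c in group)),
                "mature_sequence": sorted(seqs)[0] if seqs else "",
            }
        )
    columns = ["candidate_id", "coordinate", "n_samples", "total_read_support", "mature_sequence"]
    return pd.DataFrame(rows, columns=columns)
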