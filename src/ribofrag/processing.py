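"""Footprint read processing: length filter, UMI deduplication, P-site profiles.

Ribosome-protected fragments are handled in transcript space, 0-based.  A
read's P site is estimated from its 5' end by a fixed offset (default +12 nt),
the convention used for 25-34 nt footprints.  Profiles store per-position
P-site mass per transcript; mass may be fractional when multimapping reads
contribute fractional weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

MIN_FOOTPRINT_LEN = 25
MAX_FOOTPRINT_LEN = 34
PSITE_OFFSET = 12

__all__ = [
    "FootprintRead",
    "OccupancyProfileSet",
    "MissingUMIError",
    "UnknownTranscriptError",
    "filter_by_length",
    "dedup_umi",
    "assign_psite",
    "build_profiles",
    "normalize_rpm",
]


class MissingUMIError(ValueError):
    """Raised when UMI deduplication is requested on reads lacking UMIs."""


class UnknownTranscriptError(KeyError):
    """Raised when a read references a transcript absent from the annotation."""


@dataclass(frozen=True)
class FootprintRead:
    """One ribosome-protected fragment.

    Attributes
    ----------
    transcript_id : str
    pos5 : int
        0-based transcript coordinate of the read 5' end.
    length : int
        Footprint length in nt.
    umi : str or None
        7-nt unique molecular identifier, if the library carries them.
    weight : float
        Fractional count (multimapper weight), > 0.
    """

    transcript_id: str
    pos5: int
    length: int
    umi: str | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.pos5 < 0:
            raise ValueError(f"pos5 must be >= 0, got {self.pos5}")
        if self.length <= 0:
            raise ValueError(f"length must be positive, got {self.length}")
        if not self.weight > 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")


def filter_by_length(
    reads: Iterable[FootprintRead],
    min_len: int = MIN_FOOTPRINT_LEN,
    max_len: int = MAX_FOOTPRINT_LEN,
) -> list[FootprintRead]:
    """Keep reads with min_len <= length <= max_len, preserving order."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in reads if min_len <= r.length <= max_len]


def dedup_umi(reads: Iterable[FootprintRead]) -> list[FootprintRead]:
    """Collapse PCR duplicates: one read per (transcript, pos5, length, UMI).

    The first read of each duplicate group survives; reads with distinct UMIs
    at the same position are distinct molecules and all survive.  Idempotent.
    """
    seen: set[tuple[str, int, int, str]] = set()
    out: list[FootprintRead] = []
    for r in reads:
        if r.umi is None:
            raise MissingUMIError(
                f"read at {r.transcript_id}:{r.pos5} has no UMI; "
                "skip deduplication for UMI-less libraries"
            )
        key = (r.transcript_id, r.pos5, r.length, r.umi)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def assign_psite(read: FootprintRead, offset: int = PSITE_OFFSET) -> int:
    """P-site coordinate of a read: its 5' end shifted 3' by ``offset`` nt."""
    return read.pos5 + offset


@dataclass
class OccupancyProfileSet:
    """Per-transcript P-site mass vectors with library normalization state.

    ``profiles`` maps transcript id to a float vector of per-position P-site
    mass.  ``library_size`` is the total counted read weight (raw counts even
    after rpm scaling, so normalization is reproducible).  ``dropped`` counts
    reads whose P site fell outside the transcript.
    """

    profiles: dict[str, np.ndarray]
    library_size: float
    normalized: bool = False
    dropped: int = 0
    offset: int = PSITE_OFFSET

    def total_mass(self) -> float:
        return float(sum(p.sum() for p in self.profiles.values()))

    def __getitem__(self, transcript_id: str) -> np.ndarray:
        return self.profiles[transcript_id]

    def copy(self) -> "OccupancyProfileSet":
        return OccupancyProfileSet(
            {t: p.copy() for t, p in self.profiles.items()},
            self.library_size,
            self.normalized,
            self.dropped,
            self.offset,
        )


def build_profiles(
    reads: Iterable[FootprintRead],
    lengths: Mapping[str, int],
    offset: int = PSITE_OFFSET,
) -> OccupancyProfileSet:
    """Accumulate read weights at P-site positions into per-transcript vectors.

    ``lengths`` maps transcript id to transcript length; every transcript in
    the annotation gets a vector (all-zero if unread).  Reads whose P site
    falls at or beyond the transcript end are dropped and tallied, not clamped.
    Reads on transcripts absent from ``lengths`` raise
    :class:`UnknownTranscriptError`.
    """
    profiles = {t: np.zeros(int(n), dtype=float) for t, n in lengths.items()}
    library_size = 0.0
    dropped = 0
    for r in reads:
        if r.transcript_id not in profiles:
            raise UnknownTranscriptError(
                f"read references unknown transcript {r.transcript_id!r}"
            )
        p = assign_psite(r, offset)
        vec = profiles[r.transcript_id]
        if p >= vec.shape[0]:
            dropped += 1
            continue
        vec[p] += r.weight
        library_size += r.weight
    return OccupancyProfileSet(profiles, library_size, normalized=False,
                               dropped=dropped, offset=offset)


def normalize_rpm(profile_set: OccupancyProfileSet) -> OccupancyProfileSet:
    """Scale profiles to reads per million; idempotent via the normalized flag."""
    if profile_set.normalized:
        return profile_set
    if profile_set.library_size <= 0:
        raise ValueError("cannot rpm-normalize an empty library")
    scale = 1e6 / profile_set.library_size
    out = profile_set.copy()
    for vec in out.profiles.values():
        vec *= scale
    out.normalized = True
    return out
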