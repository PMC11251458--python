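"""Metagene profiles: average P-site occupancy anchored at ORF boundaries.

Transcripts are aligned at the main-ORF start codon (offset 0 = first CDS nt)
or at the stop codon (offset 0 = first nt of the stop codon, i.e. cds_end-3),
and occupancy is averaged per offset across the cohort.  Offsets a transcript
cannot cover (short UTRs) simply do not contribute to that offset's average —
there is no zero-padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .processing import OccupancyProfileSet
from .simulate import TranscriptModel

__all__ = ["MetageneProfile", "metagene_profile"]

DEFAULT_WINDOWS = {"start": (50, 150), "stop": (150, 150)}


@dataclass
class MetageneProfile:
    """Average occupancy per offset relative to an anchor.

    ``offsets`` runs from -upstream to +downstream inclusive; ``mean`` is the
    across-transcript average at each offset and ``n`` the number of
    transcripts contributing there.  ``anchor_convention`` records where
    offset 0 sits.
    """

    anchor: str
    offsets: np.ndarray
    mean: np.ndarray
    n: np.ndarray
    normalization: str
    anchor_convention: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean,
                             "n": self.n})

    def window_mean(self, lo: int, hi: int) -> float:
        """Mean of per-offset means over offsets in (lo, hi]."""
        mask = (self.offsets > lo) & (self.offsets <= hi) & (self.n > 0)
        if not mask.any():
            return float("nan")
        return float(self.mean[mask].mean())


def metagene_profile(
    profile_set: OccupancyProfileSet,
    transcripts: Sequence[TranscriptModel],
    anchor: Literal["start", "stop"] = "stop",
    window: tuple[int, int] | None = None,
    normalization: Literal["per-gene-mean", "pooled"] = "per-gene-mean",
    min_gene_mass: float = 1.0,
) -> MetageneProfile:
    """Average occupancy across transcripts around a shared anchor.

    ``window=(upstream, downstream)`` spans offsets [-upstream, +downstream].
    ``per-gene-mean`` divides each transcript's profile by its mean main-ORF
    occupancy before averaging (equal gene weighting, invariant to library
    scaling); ``pooled`` averages the profiles as-is (depth-weighted).
    Transcripts whose total mass is below ``min_gene_mass`` (raw counts) are
    excluded; if none qualify this is an error.
    """
    if window is None:
        window = DEFAULT_WINDOWS[anchor]
    up, down = window
    if up < 0 or down < 0:
        raise ValueError("window extents must be nonnegative")
    offsets = np.arange(-up, down + 1)
    total = np.zeros(offsets.size)
    n = np.zeros(offsets.size, dtype=int)

    scale_to_raw = 1.0
    if profile_set.normalized and profile_set.library_size > 0:
        scale_to_raw = profile_set.library_size / 1e6

    used = 0
    for t in transcripts:
        vec = profile_set[t.id]
        if vec.sum() * scale_to_raw < min_gene_mass:
            continue
        if normalization == "per-gene-mean":
            orf_mean = vec[t.cds_start:t.cds_end].mean()
            if orf_mean <= 0:
                continue
            vec = vec / orf_mean
        a = t.cds_start if anchor == "start" else t.cds_end - 3
        pos = a + offsets
        valid = (pos >= 0) & (pos < t.length)
        total[valid] += vec[pos[valid]]
        n[valid] += 1
        used += 1
    if used == 0:
        raise ValueError(f"no transcript passes min_gene_mass={min_gene_mass}")

    mean = np.divide(total, n, out=np.zeros_like(total), where=n > 0)
    convention = ("offset 0 = first CDS nt (cds_start)" if anchor == "start"
                  else "offset 0 = first nt of stop codon (cds_end - 3)")
    return MetageneProfile(anchor, offsets, mean, n, normalization, convention)
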