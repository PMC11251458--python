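"""Region-level occupancy metrics: UTR:ORF ratios, uORF rules, cohort summaries.

The altORF-translation signature is an excess of ribosome P-site mass in
untranslated regions relative to the main ORF.  This module partitions each
transcript's occupancy into 5'UTR / ORF / 3'UTR, forms UTR:ORF ratios (as
total-mass ratios or per-nt density ratios), applies the uORF-overlap rule
(mass in a uORF that overlaps the main ORF is assigned to the UTR side), and
summarizes cohorts of ratios as notched boxplots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .processing import OccupancyProfileSet
from .simulate import TranscriptModel

DEFAULT_MIN_ORF_MASS = 16.0

__all__ = [
    "RegionDensities",
    "RatioRecord",
    "BoxplotSummary",
    "region_density",
    "utr_orf_ratio",
    "uorf_main_ratio",
    "cohort_summary",
    "cohort_ratios",
]


@dataclass(frozen=True)
class RegionDensities:
    """Occupancy mass and length per transcript region.

    Masses are in the profile's units (raw counts or rpm); the three region
    masses partition the transcript total exactly.
    """

    transcript_id: str
    utr5_mass: float
    orf_mass: float
    utr3_mass: float
    utr5_len: int
    orf_len: int
    utr3_len: int

    @property
    def total(self) -> float:
        return self.utr5_mass + self.orf_mass + self.utr3_mass

    def density(self, region: Literal["utr5", "orf", "utr3"]) -> float:
        mass = getattr(self, f"{region}_mass")
        n = getattr(self, f"{region}_len")
        return mass / n if n > 0 else float("nan")


@dataclass(frozen=True)
class RatioRecord:
    transcript_id: str
    ratio: float | None
    mode: str
    numerator: str
    denominator: str
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.ratio is not None


@dataclass(frozen=True)
class BoxplotSummary:
    """Notched-boxplot statistics of a ratio cohort.

    Whiskers extend to the most extreme data point within 1.5 x IQR of the
    quartiles (so whisker bounds always lie within the data range); the notch
    half-width is 1.58 x IQR / sqrt(N) by default, with the verbatim /N
    variant available.  Quartiles use linear interpolation between order
    statistics.
    """

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    notch: float
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def region_density(profile: np.ndarray, transcript: TranscriptModel
                   ) -> RegionDensities:
    """Sum P-site mass over 5'UTR, main ORF and 3'UTR (half-open intervals)."""
    if profile.shape[0] != transcript.length:
        raise ValueError(
            f"{transcript.id}: profile length {profile.shape[0]} != "
            f"transcript length {transcript.length}"
        )
    cs, ce = transcript.cds_start, transcript.cds_end
    return RegionDensities(
        transcript_id=transcript.id,
        utr5_mass=float(profile[:cs].sum()),
        orf_mass=float(profile[cs:ce].sum()),
        utr3_mass=float(profile[ce:].sum()),
        utr5_len=cs,
        orf_len=ce - cs,
        utr3_len=transcript.length - ce,
    )


def utr_orf_ratio(
    densities: RegionDensities,
    which_utr: Literal["5p", "3p"] = "3p",
    mode: Literal["per-nt-density", "total"] = "per-nt-density",
    min_orf_mass: float = DEFAULT_MIN_ORF_MASS,
) -> RatioRecord:
    """UTR:ORF occupancy ratio for one transcript.

    ``total`` divides UTR mass by ORF mass; ``per-nt-density`` divides the
    per-nt densities (mass/length each side), so the ratio is invariant to
    region length and to library scaling.  Transcripts with ORF mass below
    ``min_orf_mass`` are excluded (ratio undefined with a reason), as are
    zero-length UTRs.
    """
    utr_mass = densities.utr5_mass if which_utr == "5p" else densities.utr3_mass
    utr_len = densities.utr5_len if which_utr == "5p" else densities.utr3_len
    num = f"{which_utr}utr"
    if densities.orf_mass < min_orf_mass:
        return RatioRecord(densities.transcript_id, None, mode, num, "orf",
                           reason="low-orf-mass")
    if utr_len == 0:
        return RatioRecord(densities.transcript_id, None, mode, num, "orf",
                           reason="zero-length-utr")
    if mode == "total":
        val = utr_mass / densities.orf_mass
    else:
        val = (utr_mass / utr_len) / (densities.orf_mass / densities.orf_len)
    return RatioRecord(densities.transcript_id, val, mode, num, "orf")


def uorf_main_ratio(
    profile: np.ndarray,
    transcript: TranscriptModel,
    min_orf_mass: float = 0.0,
) -> RatioRecord:
    """uORF+5'UTR : main-ORF occupancy ratio with the overlap rule.

    The numerator is all mass 5' of the main ORF plus the mass in any uORF
    interval that overlaps the main ORF (the overlap region is assigned to
    the UTR side, as for stress-responsive uORF genes whose last uORF runs
    into the CDS); the denominator is the remaining main-ORF mass.  Without
    uORFs this reduces to the plain 5'UTR:ORF total ratio.
    """
    if profile.shape[0] != transcript.length:
        raise ValueError(f"{transcript.id}: profile/annotation length mismatch")
    cs, ce = transcript.cds_start, transcript.cds_end
    utr_mass = float(profile[:cs].sum())
    overlap = np.zeros(transcript.length, dtype=bool)
    for us, ue in transcript.uorfs:
        os_, oe = max(us, cs), min(ue, ce)
        if oe > os_:
            overlap[os_:oe] = True
    overlap_mass = float(profile[overlap].sum())
    orf_mask = np.zeros(transcript.length, dtype=bool)
    orf_mask[cs:ce] = True
    orf_mask &= ~overlap
    main_mass = float(profile[orf_mask].sum())
    if main_mass < min_orf_mass or main_mass == 0:
        return RatioRecord(transcript.id, None, "uorf-overlap", "5putr+uorf-overlap",
                           "main-orf", reason="low-orf-mass")
    return RatioRecord(transcript.id, (utr_mass + overlap_mass) / main_mass,
                       "uorf-overlap", "5putr+uorf-overlap", "main-orf")


def cohort_ratios(
    profile_set: OccupancyProfileSet,
    transcripts: Sequence[TranscriptModel],
    which_utr: Literal["5p", "3p"] = "3p",
    mode: Literal["per-nt-density", "total"] = "per-nt-density",
    min_orf_mass: float = DEFAULT_MIN_ORF_MASS,
) -> list[RatioRecord]:
    """UTR:ORF ratios for every transcript in a profile set.

    ``min_orf_mass`` is applied on raw counts when the set is normalized
    (threshold rescaled by library size), so inclusion does not depend on
    sequencing depth units.
    """
    thresh = min_orf_mass
    if profile_set.normalized and profile_set.library_size > 0:
        thresh = min_orf_mass * 1e6 / profile_set.library_size
    out = []
    for t in transcripts:
        dens = region_density(profile_set[t.id], t)
        out.append(utr_orf_ratio(dens, which_utr, mode, thresh))
    return out


def cohort_summary(
    ratios: Iterable[RatioRecord | float],
    notch_denominator: Literal["sqrt", "n"] = "sqrt",
) -> BoxplotSummary:
    """Notched-boxplot summary of the defined ratios in a cohort."""
    vals = []
    for r in ratios:
        if isinstance(r, RatioRecord):
            if r.defined:
                vals.append(r.ratio)
        else:
            vals.append(float(r))
    if not vals:
        raise ValueError("empty cohort: no defined ratios")
    x = np.sort(np.asarray(vals, dtype=float))
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    n = x.size
    denom = np.sqrt(n) if notch_denominator == "sqrt" else n
    return BoxplotSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_lo=float(inside[0]), whisker_hi=float(inside[-1]),
        notch=float(1.58 * iqr / denom), n=int(n),
    )
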