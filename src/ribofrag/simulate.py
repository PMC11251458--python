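"""Synthetic fragmentation-and-translation simulator.

Generates annotated transcriptomes and matched ribosome-footprint / RNA-seq
libraries under a parameterized endonucleolytic-cleavage model, so every
downstream stage of the pipeline has ground truth.

The generative model
--------------------
1. Transcripts carry a 5'UTR, a main ORF and a 3'UTR; a configurable fraction
   carry an upstream ORF (uORF) in the 5'UTR.
2. A single-strand endonuclease cuts 3' of sequence motifs.  Presets:
   RNase L (UU/UA dinucleotides), RNase A (pyrimidines U/C), IRE1 (UGC).
3. Each transcript copy survives a global "baseline loss" of the mRNA pool
   (binomial thinning, modulated by a per-gene resistance factor) and then
   receives a Poisson number of cuts with rate intensity x sum(motif weights),
   producing 5'/internal/3' fragments.
4. Translation: intact copies put footprints uniformly over the main ORF;
   uncapped (internal and 3') fragments re-initiate with probability
   ``reinit_prob`` at the first AUG-started ORF downstream of the fragment
   5' end — which may run out of frame and into the 3'UTR; 5' fragments whose
   cut truncates the main ORF additionally pile ribosomes up at the fragment
   3' terminus (ribosomes reach the end without a stop codon).
5. RNA-seq counts per gene are negative binomial with mean proportional to
   surviving fragment mass overlapping the CDS.

All sampling is driven by explicit integer seeds; every call is
bit-reproducible given (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .processing import FootprintRead

__all__ = [
    "TranscriptModel",
    "NucleaseSpec",
    "FragmentationParams",
    "ExpressionState",
    "TranslationParams",
    "FragmentEntry",
    "FragmentPool",
    "RNASE_L",
    "RNASE_A",
    "IRE1",
    "ConfigurationError",
    "build_transcriptome",
    "cleavage_sites",
    "fragment_pool",
    "simulate_footprints",
    "simulate_rnaseq",
    "simulate_count_tables",
]

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})
_BASES = np.array(list("ACGU"))


class ConfigurationError(ValueError):
    """Raised when simulator parameters are infeasible."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's sequence and region structure in 0-based half-open
    transcript coordinates: 5'UTR=[0, cds_start), ORF=[cds_start, cds_end),
    3'UTR=[cds_end, len)."""

    id: str
    sequence: str
    cds_start: int
    cds_end: int
    uorfs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (0 <= self.cds_start < self.cds_end <= n):
            raise ValueError(
                f"{self.id}: CDS [{self.cds_start},{self.cds_end}) "
                f"outside transcript of length {n}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(f"{self.id}: CDS length not divisible by 3")
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise ValueError(f"{self.id}: non-RNA characters {sorted(bad)}")
        for s, e in self.uorfs:
            if not (0 <= s < e <= self.cds_end):
                raise ValueError(f"{self.id}: uORF [{s},{e}) outside [0,{self.cds_end})")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def utr5(self) -> tuple[int, int]:
        return (0, self.cds_start)

    @property
    def cds(self) -> tuple[int, int]:
        return (self.cds_start, self.cds_end)

    @property
    def utr3(self) -> tuple[int, int]:
        return (self.cds_end, self.length)


@dataclass(frozen=True)
class NucleaseSpec:
    """A single-strand endonuclease as a map from short sequence motifs to
    relative cleavage weights."""

    name: str
    motif_weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.motif_weights:
            raise ValueError("nuclease needs at least one motif")
        for m, w in self.motif_weights.items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"motif {m!r}: weight must be finite and >= 0")
        if not any(w > 0 for w in self.motif_weights.values()):
            raise ValueError("at least one motif must have positive weight")


RNASE_L = NucleaseSpec("rnasel", {"UU": 1.0, "UA": 1.0})
RNASE_A = NucleaseSpec("rnasea", {"U": 1.0, "C": 1.0})
IRE1 = NucleaseSpec("ire1", {"UGC": 1.0})

PRESET_NUCLEASES = {"rnasel": RNASE_L, "rnasea": RNASE_A, "ire1": IRE1}


@dataclass(frozen=True)
class FragmentationParams:
    """Cleavage regime.

    intensity : expected cuts per motif occurrence per transcript copy.
    baseline_loss_fraction : fraction of the mRNA pool degraded outright,
        in [0, 1] (spike-in studies place the realistic regime at ~0.6-0.99).
    """

    intensity: float = 0.0
    baseline_loss_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if not (0.0 <= self.baseline_loss_fraction <= 1.0):
            raise ValueError("baseline_loss_fraction must be in [0,1]")


@dataclass
class ExpressionState:
    """Per-gene expression under one condition.

    baseline : copies per gene (> 0).
    resistance : multiplies survival under cleavage (>= 0; 1 = typical gene).
    induction : multiplies abundance under treatment (1 in untreated cells).
    """

    baseline: dict[str, float]
    resistance: dict[str, float] = field(default_factory=dict)
    induction: dict[str, float] = field(default_factory=dict)

    @classmethod
    def uniform(cls, transcripts: Sequence[TranscriptModel], copies: float = 50.0
                ) -> "ExpressionState":
        return cls({t.id: float(copies) for t in transcripts})

    def copies(self, tid: str) -> int:
        return int(round(self.baseline[tid] * self.induction.get(tid, 1.0)))

    def res(self, tid: str) -> float:
        return self.resistance.get(tid, 1.0)


@dataclass(frozen=True)
class TranslationParams:
    """Ribosome-loading model for the footprint simulator.

    density : footprints per nt of translated ORF per transcript copy.
    reinit_prob : probability an uncapped fragment is translated from the
        first available ORF downstream of its 5' end.
    stall_weight : extra footprint mass (in ORF-nt equivalents) placed with
        P site at the 3' terminus of ORF-truncating 5' fragments.
    uorf_density : footprints per nt on annotated uORFs of intact copies.
    min_len, max_len : footprint length bounds (drawn uniformly).
    psite_offset : 5'-end-to-P-site shift used to place read 5' ends.
    min_altorf_codons : minimum length for a fragment ORF to be translated.
    """

    density: float = 0.05
    reinit_prob: float = 0.0
    stall_weight: float = 0.0
    uorf_density: float = 0.0
    min_len: int = 25
    max_len: int = 34
    psite_offset: int = 12
    min_altorf_codons: int = 5
    dispersion: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.reinit_prob <= 1.0):
            raise ValueError("reinit_prob must be in [0,1]")
        if self.stall_weight < 0:
            raise ValueError("stall_weight must be >= 0")
        if not (25 <= self.min_len <= self.max_len <= 34):
            raise ValueError("footprint lengths restricted to [25,34]")


@dataclass(frozen=True)
class FragmentEntry:
    transcript_id: str
    start: int
    end: int
    abundance: float
    provenance: str  # intact | 5p | internal | 3p

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad fragment [{self.start},{self.end})")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")


@dataclass
class FragmentPool:
    """Multiset of cleavage fragments with abundances."""

    entries: list[FragmentEntry]

    def total_nt(self) -> float:
        return sum((e.end - e.start) * e.abundance for e in self.entries)

    def by_transcript(self) -> dict[str, list[FragmentEntry]]:
        out: dict[str, list[FragmentEntry]] = {}
        for e in self.entries:
            out.setdefault(e.transcript_id, []).append(e)
        return out

    def cds_mass(self, transcripts: Mapping[str, TranscriptModel]) -> dict[str, float]:
        """Fragment mass (nt x copies) overlapping each gene's CDS."""
        mass = {tid: 0.0 for tid in transcripts}
        for e in self.entries:
            t = transcripts[e.transcript_id]
            ov = min(e.end, t.cds_end) - max(e.start, t.cds_start)
            if ov > 0:
                mass[e.transcript_id] += ov * e.abundance
        return mass


# ---------------------------------------------------------------------------
# transcriptome construction

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def build_transcriptome(
    n_genes: int,
    utr5_range: tuple[int, int] = (30, 100),
    cds_codons_range: tuple[int, int] = (60, 200),
    utr3_range: tuple[int, int] = (60, 200),
    uorf_fraction: float = 0.3,
    seed: int = 0,
) -> list[TranscriptModel]:
    """Generate random annotated transcripts.

    CDS length is drawn in codons (so always divisible by 3); the first codon
    is forced to AUG and the last to UAA.  With probability ``uorf_fraction``
    a transcript receives one AUG...stop uORF inside its 5'UTR.  Deterministic
    given ``seed``.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    for name, (lo, hi) in [("utr5", utr5_range), ("cds_codons", cds_codons_range),
                           ("utr3", utr3_range)]:
        if lo < 1 or hi < lo:
            raise ConfigurationError(f"infeasible {name} range ({lo},{hi})")
    if cds_codons_range[0] < 2:
        raise ConfigurationError("CDS needs at least start and stop codons")
    if uorf_fraction > 0 and utr5_range[0] < 9:
        raise ConfigurationError("5'UTR min length < 9 nt cannot host a uORF")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    out: list[TranscriptModel] = []
    for i in range(n_genes):
        u5 = int(rng.integers(utr5_range[0], utr5_range[1] + 1))
        ncod = int(rng.integers(cds_codons_range[0], cds_codons_range[1] + 1))
        u3 = int(rng.integers(utr3_range[0], utr3_range[1] + 1))
        cds_start, cds_end = u5, u5 + 3 * ncod
        seq = _random_seq(rng, cds_end + u3)
        seq[cds_start:cds_start + 3] = list("AUG")
        seq[cds_end - 3:cds_end] = list("UAA")
        uorfs: tuple[tuple[int, int], ...] = ()
        if rng.random() < uorf_fraction:
            # uORF of 2..8 codons fully inside the 5'UTR
            max_cod = min(8, u5 // 3)
            ucod = int(rng.integers(2, max(3, max_cod + 1)))
            ulen = 3 * ucod
            ustart = int(rng.integers(0, u5 - ulen + 1))
            seq[ustart:ustart + 3] = list("AUG")
            seq[ustart + ulen - 3:ustart + ulen] = list("UAA")
            # an accidental in-frame stop before the planted one just
            # shortens the uORF biologically; the annotation records the
            # planted interval, which is what region metrics consume
            uorfs = ((ustart, ustart + ulen),)
        out.append(TranscriptModel(
            id=f"g{i:0{width}d}",
            sequence="".join(seq),
            cds_start=cds_start,
            cds_end=cds_end,
            uorfs=uorfs,
        ))
    return out


# ---------------------------------------------------------------------------
# cleavage

def cleavage_sites(transcript: TranscriptModel, spec: NucleaseSpec
                   ) -> list[tuple[int, float]]:
    """Every motif occurrence as a cut position with its weight.

    Cleavage occurs 3' of the motif's last base: a cut at position p splits
    the transcript into [0, p) and [p, len).  Weights at identical positions
    (from different motifs) are summed.  Sorted by position.
    """
    seq = transcript.sequence
    acc: dict[int, float] = {}
    for motif, w in spec.motif_weights.items():
        if w <= 0:
            continue
        start = seq.find(motif)
        while start != -1:
            pos = start + len(motif)
            acc[pos] = acc.get(pos, 0.0) + w
            start = seq.find(motif, start + 1)
    return sorted(acc.items())


def fragment_pool(
    transcripts: Sequence[TranscriptModel],
    expression: ExpressionState,
    spec: NucleaseSpec,
    params: FragmentationParams,
) -> FragmentPool:
    """Cleave an expressed transcript pool into a fragment multiset.

    Per transcript copy: survival of baseline loss is Bernoulli with
    p = min(1, (1 - baseline_loss) * resistance); the number of cuts is
    Poisson with rate intensity x sum(site weights) / resistance; cut
    positions are drawn from the motif sites proportionally to weight,
    without replacement.  intensity=0 and loss=0 return the intact pool.
    """
    rng = np.random.default_rng(params.seed)
    agg: dict[tuple[str, int, int, str], float] = {}

    for t in transcripts:
        n = expression.copies(t.id)
        if n <= 0:
            continue
        res = expression.res(t.id)
        p_surv = min(1.0, (1.0 - params.baseline_loss_fraction) * res)
        n_surv = int(rng.binomial(n, p_surv)) if p_surv < 1.0 else n
        if n_surv == 0:
            continue
        sites = cleavage_sites(t, spec)
        positions = np.array([p for p, _ in sites if 0 < p < t.length], dtype=int)
        weights = np.array([w for p, w in sites if 0 < p < t.length], dtype=float)
        total_w = sum(w for _, w in sites)
        rate = params.intensity * total_w / res if res > 0 else 0.0

        if rate == 0.0 or positions.size == 0:
            key = (t.id, 0, t.length, "intact")
            agg[key] = agg.get(key, 0.0) + n_surv
            continue

        ncuts = rng.poisson(rate, size=n_surv)
        n_intact = int(np.sum(ncuts == 0))
        if n_intact:
            key = (t.id, 0, t.length, "intact")
            agg[key] = agg.get(key, 0.0) + n_intact
        probs = weights / weights.sum()
        for k in ncuts[ncuts > 0]:
            k = min(int(k), positions.size)
            cuts = np.sort(rng.choice(positions, size=k, replace=False, p=probs))
            bounds = [0, *cuts.tolist(), t.length]
            for j in range(len(bounds) - 1):
                s, e = bounds[j], bounds[j + 1]
                if e <= s:
                    continue
                prov = ("5p" if j == 0 else
                        "3p" if j == len(bounds) - 2 else "internal")
                key = (t.id, s, e, prov)
                agg[key] = agg.get(key, 0.0) + 1

    entries = [FragmentEntry(tid, s, e, a, prov)
               for (tid, s, e, prov), a in sorted(agg.items())]
    return FragmentPool(entries)


# ---------------------------------------------------------------------------
# translation of fragments -> footprints

def first_downstream_orf(
    sequence: str, start: int, end: int, min_codons: int = 5
) -> tuple[int, int] | None:
    """First AUG-initiated ORF of >= min_codons within [start, end).

    Scans 5'->3' from ``start`` for an AUG (any frame relative to the
    annotation), then translates until an in-frame stop codon or the end of
    the window.  AUGs whose ORF is shorter than ``min_codons`` are skipped in
    favour of the next AUG.  Returns the translated interval [orf_start,
    orf_end) excluding the stop codon, or None.
    """
    q = sequence.find("AUG", start)
    while q != -1 and q + 3 <= end:
        stop = None
        for c in range(q, end - 2, 3):
            if sequence[c:c + 3] in STOP_CODONS:
                stop = c
                break
        orf_end = stop if stop is not None else end - (end - q) % 3
        if (orf_end - q) // 3 >= min_codons:
            return q, orf_end
        q = sequence.find("AUG", q + 1)
    return None


def _emit_reads(
    rng: np.random.Generator,
    tid: str,
    tlen: int,
    psites: np.ndarray,
    tparams: TranslationParams,
    out: list[FootprintRead],
) -> None:
    if psites.size == 0:
        return
    lengths = rng.integers(tparams.min_len, tparams.max_len + 1, size=psites.size)
    umi_idx = rng.integers(0, 4, size=(psites.size, 7))
    for p, L, ui in zip(psites, lengths, umi_idx):
        pos5 = int(p) - tparams.psite_offset
        if pos5 < 0:
            continue
        L = int(L)
        if pos5 + L > tlen:
            L = tlen - pos5
            if L < tparams.min_len:
                continue
        out.append(FootprintRead(tid, pos5, L, "".join(_BASES[ui]), 1.0))


def simulate_footprints(
    pool: FragmentPool,
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    tparams: TranslationParams,
    seed: int | None = None,
) -> list[FootprintRead]:
    """Generate ribosome footprints from a fragment pool.

    Intact copies: P sites uniform over the main ORF (plus optional uORF
    occupancy).  Uncapped (internal/3') fragments: with probability
    ``reinit_prob`` translated from the first available downstream ORF.
    5' fragments truncating the main ORF: P sites uniform over the retained
    ORF portion, plus ``stall_weight`` ORF-nt-equivalents of mass at the
    fragment 3' terminus.  Read 5' ends are back-computed from P sites with
    the configured offset; lengths uniform in [min_len, max_len]; random
    7-nt UMIs.  Deterministic given the seed.
    """
    if not isinstance(transcripts, Mapping):
        transcripts = {t.id: t for t in transcripts}
    rng = np.random.default_rng(tparams.seed if seed is None else seed)
    d = tparams.density
    reads: list[FootprintRead] = []

    for e in pool.entries:
        t = transcripts[e.transcript_id]
        if e.provenance == "intact":
            orf_len = t.cds_end - t.cds_start
            n = rng.poisson(d * orf_len * e.abundance)
            ps = rng.integers(t.cds_start, t.cds_end, size=n)
            _emit_reads(rng, t.id, t.length, ps, tparams, reads)
            if tparams.uorf_density > 0:
                for us, ue in t.uorfs:
                    n = rng.poisson(tparams.uorf_density * (ue - us) * e.abundance)
                    ps = rng.integers(us, ue, size=n)
                    _emit_reads(rng, t.id, t.length, ps, tparams, reads)
        elif e.provenance == "5p":
            lo, hi = max(e.start, t.cds_start), min(e.end, t.cds_end)
            if hi <= lo:
                continue
            n = rng.poisson(d * (hi - lo) * e.abundance)
            ps = rng.integers(lo, hi, size=n)
            _emit_reads(rng, t.id, t.length, ps, tparams, reads)
            if e.end < t.cds_end and tparams.stall_weight > 0:
                # ORF truncated: ribosomes run to the fragment 3' end
                n = rng.poisson(d * tparams.stall_weight * e.abundance)
                ps = np.full(n, e.end - 1, dtype=int)
                _emit_reads(rng, t.id, t.length, ps, tparams, reads)
        else:  # internal or 3p: uncapped, may re-initiate
            if tparams.reinit_prob <= 0:
                continue
            n_init = rng.binomial(int(round(e.abundance)), tparams.reinit_prob)
            if n_init == 0:
                continue
            orf = first_downstream_orf(t.sequence, e.start, e.end,
                                       tparams.min_altorf_codons)
            if orf is None:
                continue
            qs, qe = orf
            n = rng.poisson(d * (qe - qs) * n_init)
            ps = rng.integers(qs, qe, size=n)
            _emit_reads(rng, t.id, t.length, ps, tparams, reads)
    return reads


# ---------------------------------------------------------------------------
# matched RNA-seq arm

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float
             ) -> np.ndarray:
    """NB(mean, dispersion) with Var = mu + dispersion*mu^2; Poisson at 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size, p[pos])
    return out


def simulate_rnaseq(
    pool: FragmentPool,
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    depth: float,
    dispersion: float = 0.02,
    seed: int = 0,
    n_replicates: int = 1,
    prefix: str = "s",
) -> pd.DataFrame:
    """Per-gene RNA-seq count table from a fragment pool.

    Gene counts are negative binomial with mean proportional to the surviving
    fragment mass overlapping the CDS, scaled to ``depth`` total expected
    reads per replicate.  Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not isinstance(transcripts, Mapping):
        transcripts = {t.id: t for t in transcripts}
    rng = np.random.default_rng(seed)
    mass = pool.cds_mass(transcripts)
    genes = sorted(transcripts)
    m = np.array([mass[g] for g in genes], dtype=float)
    total = m.sum()
    means = depth * m / total if total > 0 else np.zeros_like(m)
    data = {f"{prefix}{r + 1}": _nb_draw(rng, means, dispersion)
            for r in range(n_replicates)}
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def simulate_count_tables(
    n_genes: int = 2000,
    depth: float = 2e6,
    dispersion: float = 0.02,
    n_replicates: int = 3,
    baseline_loss: float = 0.9,
    resistant_genes: Mapping[str, float] | None = None,
    te_shift_genes: Mapping[str, float] | None = None,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Matched RNA-seq and footprint count tables for a cleavage experiment.

    A fast count-level generative model (no per-read simulation) for the
    differential-expression and translational-efficiency stages:

    - every gene has lognormal baseline abundance;
    - under treatment, gene survival is (1 - baseline_loss) x resistance
      (``resistant_genes`` maps gene id -> resistance factor; default 1);
    - footprint means are RNA means x per-gene ribosome loading;
      ``te_shift_genes`` maps gene id -> fold change of loading under
      treatment (the simulated TE shift);
    - counts are negative binomial per replicate.

    Returns a dict with keys rna_control, rna_treated, rp_control, rp_treated.
    """
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"g{i:0{width}d}" for i in range(n_genes)]
    resistant_genes = dict(resistant_genes or {})
    te_shift_genes = dict(te_shift_genes or {})

    base = rng.lognormal(mean=0.0, sigma=0.6, size=n_genes)
    res = np.array([resistant_genes.get(g, 1.0) for g in genes])
    te = np.array([te_shift_genes.get(g, 1.0) for g in genes])
    loading = np.ones(n_genes)

    rna_c = base
    rna_t = base * (1.0 - baseline_loss) * res
    rp_c = rna_c * loading
    rp_t = rna_t * loading * te

    out: dict[str, pd.DataFrame] = {}
    for name, rel in [("rna_control", rna_c), ("rna_treated", rna_t),
                      ("rp_control", rp_c), ("rp_treated", rp_t)]:
        means = depth * rel / rel.sum()
        data = {f"{name}_{r + 1}": _nb_draw(rng, means, dispersion)
                for r in range(n_replicates)}
        out[name] = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    return out
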