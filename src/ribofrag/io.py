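"""Readers and writers for the pipeline's on-disk formats.

Transcript sequences travel as FASTA (via Biopython); annotations, reads and
count matrices as TSV; per-transcript P-site coverage as fixedStep wiggle
tracks.  All transcript coordinates are 0-based half-open on disk except wig,
which is 1-based per the wiggle standard.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .processing import FootprintRead, OccupancyProfileSet
from .simulate import TranscriptModel

__all__ = [
    "write_fasta", "read_fasta",
    "write_annotation", "read_annotation",
    "write_reads", "read_reads",
    "write_counts", "read_counts",
    "write_wig", "read_wig",
    "write_fixture", "read_fixture",
]


# -- FASTA -------------------------------------------------------------------

def write_fasta(transcripts: Sequence[TranscriptModel], path: str) -> None:
    records = [SeqRecord(Seq(t.sequence), id=t.id, description="")
               for t in transcripts]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# -- annotation --------------------------------------------------------------

def write_annotation(transcripts: Sequence[TranscriptModel], path: str) -> None:
    rows = []
    for t in transcripts:
        uorfs = ";".join(f"{s}-{e}" for s, e in t.uorfs)
        rows.append((t.id, t.length, t.cds_start, t.cds_end, uorfs))
    df = pd.DataFrame(rows, columns=["transcript_id", "length", "cds_start",
                                     "cds_end", "uorfs"])
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path: str, sequences: Mapping[str, str] | None = None
                    ) -> list[TranscriptModel] | pd.DataFrame:
    """Read an annotation TSV.

    With ``sequences`` (id -> RNA string, e.g. from :func:`read_fasta`)
    returns full :class:`TranscriptModel` objects; without, the raw table.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str},
                     keep_default_na=False)
    if sequences is None:
        return df
    out = []
    for row in df.itertuples(index=False):
        uorfs = tuple(
            tuple(int(x) for x in pair.split("-"))
            for pair in str(row.uorfs).split(";") if pair
        )
        out.append(TranscriptModel(row.transcript_id, sequences[row.transcript_id],
                                   int(row.cds_start), int(row.cds_end), uorfs))
    return out


# -- reads -------------------------------------------------------------------

def write_reads(reads: Iterable[FootprintRead], path: str) -> None:
    df = pd.DataFrame(
        [(r.transcript_id, r.pos5, r.length, r.umi if r.umi is not None else "",
          r.weight) for r in reads],
        columns=["transcript_id", "pos5", "length", "umi", "weight"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_reads(path: str) -> list[FootprintRead]:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "umi": str},
                     keep_default_na=False)
    return [FootprintRead(r.transcript_id, int(r.pos5), int(r.length),
                          r.umi if r.umi else None, float(r.weight))
            for r in df.itertuples(index=False)]


# -- counts ------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


# -- wig ---------------------------------------------------------------------

def write_wig(profile_set: OccupancyProfileSet, path: str,
              track_name: str = "psite") -> None:
    """fixedStep wiggle export of P-site coverage.

    One fixedStep declaration per contiguous run of nonzero positions
    (step=1, span=1); positions converted to 1-based per the wig standard.
    Zeros are implicit, so a round trip through :func:`read_wig` is lossless.
    """
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track_name}"\n')
        for tid in sorted(profile_set.profiles):
            vec = profile_set.profiles[tid]
            nz = np.flatnonzero(vec)
            if nz.size == 0:
                continue
            # split into contiguous runs
            breaks = np.flatnonzero(np.diff(nz) > 1) + 1
            for run in np.split(nz, breaks):
                fh.write(f"fixedStep chrom={tid} start={run[0] + 1} step=1\n")
                for pos in run:
                    v = vec[pos]
                    fh.write(f"{v:.6g}\n" if v != int(v) else f"{int(v)}\n")


def read_wig(path: str, lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Parse fixedStep wig back into full-length per-transcript vectors."""
    profiles = {t: np.zeros(int(n), dtype=float) for t, n in lengths.items()}
    tid, pos = None, 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                tid = fields["chrom"]
                pos = int(fields["start"]) - 1
                if int(fields.get("step", 1)) != 1:
                    raise ValueError("only step=1 wig tracks are supported")
                if tid not in profiles:
                    raise KeyError(f"wig references unknown transcript {tid!r}")
                continue
            if tid is None:
                raise ValueError("wig data line before any fixedStep declaration")
            profiles[tid][pos] = float(line)
            pos += 1
    return profiles


# -- whole-fixture round trip ------------------------------------------------

def write_fixture(
    directory: str,
    transcripts: Sequence[TranscriptModel],
    reads: Sequence[FootprintRead] | None = None,
    profile_set: OccupancyProfileSet | None = None,
    counts: Mapping[str, pd.DataFrame] | None = None,
) -> dict[str, str]:
    """Write a simulated dataset as plain-text files; returns name -> path."""
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(directory, name)
        return paths[name]

    try:
        write_fasta(transcripts, _p("transcripts.fa"))
        write_annotation(transcripts, _p("annotation.tsv"))
        if reads is not None:
            write_reads(reads, _p("reads.tsv"))
        if profile_set is not None:
            write_wig(profile_set, _p("psite.wig"))
        for name, table in (counts or {}).items():
            write_counts(table, _p(f"counts_{name}.tsv"))
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return paths


def read_fixture(directory: str) -> dict[str, object]:
    """Read back everything :func:`write_fixture` wrote."""
    seqs = read_fasta(os.path.join(directory, "transcripts.fa"))
    transcripts = read_annotation(os.path.join(directory, "annotation.tsv"), seqs)
    out: dict[str, object] = {"transcripts": transcripts}
    rp = os.path.join(directory, "reads.tsv")
    if os.path.exists(rp):
        out["reads"] = read_reads(rp)
    wp = os.path.join(directory, "psite.wig")
    if os.path.exists(wp):
        lengths = {t.id: t.length for t in transcripts}
        out["profiles"] = read_wig(wp, lengths)
    counts = {}
    for fname in sorted(os.listdir(directory)):
        if fname.startswith("counts_") and fname.endswith(".tsv"):
            counts[fname[len("counts_"):-len(".tsv")]] = read_counts(
                os.path.join(directory, fname))
    if counts:
        out["counts"] = counts
    return out
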