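"""Transcript-coordinate data model and I/O for ribosome footprint tracks.

All coordinates throughout the package are 0-based half-open intervals in
transcript space (the spliced mRNA, 5' cap at position 0). A transcript is
partitioned as 5'UTR | CDS | 3'UTR; the CDS starts with its AUG and ends
one past its stop codon. Footprint tracks store one non-negative integer
count per nucleotide per transcript; each sequenced read contributes a
single assigned position (read 5' end plus a configurable species-specific
offset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

STOP_CODONS = ("TAA", "TAG", "TGA")

#: read-length windows retained after size selection, inclusive bounds
LENGTH_WINDOWS = {"80S": (25, 35), "40S": (20, 80)}

#: single-mismatch variants of ATG accepted as near-cognate start codons
NEAR_COGNATE_STARTS = ("CTG", "GTG", "TTG", "ACG", "ATA", "ATT", "ATC", "AAG", "AGG")


class Interval(NamedTuple):
    """Half-open [start, end) interval in transcript coordinates."""

    start: int
    end: int

    def __len__(self) -> int:  # type: ignore[override]
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class UORF:
    """An upstream ORF: AUG (or near-cognate) start to one past its stop codon."""

    start: int
    stop_end: int
    frame: int = 0  # phase of the start within the transcript (start % 3)
    start_codon: str = "ATG"
    translated: bool | None = None

    @property
    def length(self) -> int:
        return self.stop_end - self.start

    def validate(self) -> None:
        if self.length < 6 or self.length % 3 != 0:
            raise ValueError(
                f"uORF [{self.start},{self.stop_end}) must span >=6 nt in multiples of 3"
            )


@dataclass
class TranscriptModel:
    """One transcript: coordinate frame, optional sequence, annotated uORFs."""

    transcript_id: str
    utr5: Interval
    cds: Interval
    utr3: Interval
    sequence: str | None = None
    uorfs: list[UORF] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.utr5 = Interval(*self.utr5)
        self.cds = Interval(*self.cds)
        self.utr3 = Interval(*self.utr3)

    @property
    def length(self) -> int:
        return self.utr3.end

    @property
    def cds_length(self) -> int:
        return self.cds.length

    def validate(self) -> None:
        if not (0 <= self.utr5.start < self.utr5.end == self.cds.start < self.cds.end
                == self.utr3.start <= self.utr3.end):
            raise ValueError(f"{self.transcript_id}: inconsistent UTR/CDS intervals")
        if self.cds.length % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not divisible by 3")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(f"{self.transcript_id}: sequence length mismatch")
            if self.sequence[self.cds.start:self.cds.start + 3] != "ATG":
                raise ValueError(f"{self.transcript_id}: CDS does not begin with ATG")
        for u in self.uorfs:
            u.validate()
            if u.stop_end > self.cds.start:
                raise ValueError(f"{self.transcript_id}: uORF extends past mORF start")


@dataclass
class FootprintTrack:
    """Per-nucleotide assigned footprint counts for one library.

    ``counts`` maps transcript_id to an integer vector of the transcript
    length; ``library_size`` is always the total of all assigned reads.
    """

    library_id: str
    species: str  # "40S" | "80S"
    mode: str  # "total" | "selective"
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in ("40S", "80S"):
            raise ValueError(f"unknown ribosomal species {self.species!r}")
        if self.mode not in ("total", "selective"):
            raise ValueError(f"unknown track mode {self.mode!r}")
        self.counts = {t: np.asarray(v, dtype=np.int64) for t, v in self.counts.items()}

    @property
    def library_size(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))

    def vector(self, transcript_id: str) -> np.ndarray:
        try:
            return self.counts[transcript_id]
        except KeyError:
            raise KeyError(f"transcript {transcript_id!r} not in track {self.library_id!r}")


def region_sum(track: FootprintTrack, transcript_id: str, interval: Interval | tuple[int, int]) -> int:
    """Exact read count over a half-open interval of one transcript."""
    start, end = interval
    vec = track.vector(transcript_id)
    if not (0 <= start <= end <= len(vec)):
        raise ValueError(
            f"interval [{start},{end}) outside transcript {transcript_id!r} of length {len(vec)}"
        )
    return int(vec[start:end].sum())


def filter_by_length(reads: pd.DataFrame, species: str,
                     window: tuple[int, int] | None = None) -> pd.DataFrame:
    """Retain raw reads whose fragment length falls in the size-selection window.

    ``reads`` has columns (transcript_id, position, length, count). Windows
    mirror gel size selection: 25-35 nt for 80S, 20-80 nt for 40S libraries,
    bounds inclusive.
    """
    if window is None:
        window = LENGTH_WINDOWS[species]
    lo, hi = window
    if (reads["length"] <= 0).any():
        raise ValueError("read lengths must be positive")
    return reads[(reads["length"] >= lo) & (reads["length"] <= hi)].reset_index(drop=True)


def detected_transcripts(transcripts: Sequence[TranscriptModel],
                         total_80s_tracks: Iterable[FootprintTrack],
                         min_counts: int = 32) -> list[str]:
    """Transcripts with at least ``min_counts`` total-80S CDS reads in every library.

    Ratio statistics are unstable on sparse genes; this is the detection
    filter applied before scoring and selectivity analyses.
    """
    tracks = list(total_80s_tracks)
    out = []
    for t in transcripts:
        if all(region_sum(tr, t.transcript_id, t.cds) >= min_counts for tr in tracks):
            out.append(t.transcript_id)
    return out


# ---------------------------------------------------------------------------
# annotation I/O


def write_annotation_gff3(transcripts: Sequence[TranscriptModel], path) -> None:
    """Write transcript models as GFF3 in transcript coordinates (1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            sid = t.transcript_id
            rows = [
                (sid, "transcript", 1, t.length, f"ID={sid}"),
                (sid, "five_prime_UTR", t.utr5.start + 1, t.utr5.end, f"ID={sid}.utr5;Parent={sid}"),
                (sid, "CDS", t.cds.start + 1, t.cds.end, f"ID={sid}.cds;Parent={sid}"),
            ]
            if t.utr3.length > 0:
                rows.append((sid, "three_prime_UTR", t.utr3.start + 1, t.utr3.end,
                             f"ID={sid}.utr3;Parent={sid}"))
            for i, u in enumerate(t.uorfs):
                rows.append((sid, "uORF", u.start + 1, u.stop_end,
                             f"ID={sid}.uorf{i};Parent={sid};start_codon={u.start_codon}"))
            for seqid, ftype, start, end, attrs in rows:
                fh.write(f"{seqid}\triboselect\t{ftype}\t{start}\t{end}\t.\t+\t.\t{attrs}\n")


def read_annotation(path, sequences: Mapping[str, str] | None = None) -> list[TranscriptModel]:
    """Read transcript models from GFF3 or BED12 (sniffed from content).

    Coordinates are converted to 0-based half-open transcript space.
    Transcripts whose CDS length is not divisible by 3 are skipped with a
    warning.
    """
    with open(path) as fh:
        head = fh.read(2048)
    if head.startswith("##gff") or "\ttranscript\t" in head or "\tCDS\t" in head:
        models = _read_gff3(path)
    else:
        models = _read_bed12(path)
    out = []
    for m in models:
        if sequences is not None and m.transcript_id in sequences:
            m.sequence = sequences[m.transcript_id]
        try:
            m.validate()
        except ValueError as exc:
            warnings.warn(f"skipping transcript: {exc}")
            continue
        out.append(m)
    return out


def _read_gff3(path) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models = []
    for tr in db.features_of_type("transcript"):
        sid = tr.seqid
        length = tr.end  # transcript feature spans 1..length
        cds_feats = [f for f in db.region(seqid=sid, featuretype="CDS")]
        if not cds_feats:
            warnings.warn(f"transcript {sid}: no CDS feature, skipped")
            continue
        cds_start = min(f.start for f in cds_feats) - 1
        cds_end = max(f.end for f in cds_feats)
        uorfs = []
        for f in db.region(seqid=sid, featuretype="uORF"):
            start = f.start - 1
            codon = f.attributes.get("start_codon", ["ATG"])[0]
            uorfs.append(UORF(start=start, stop_end=f.end, frame=start % 3,
                              start_codon=codon))
        uorfs.sort(key=lambda u: u.start)
        models.append(TranscriptModel(
            transcript_id=tr.id or sid,
            utr5=Interval(0, cds_start),
            cds=Interval(cds_start, cds_end),
            utr3=Interval(cds_end, length),
            uorfs=uorfs,
        ))
    return models


_BED12_COLS = ["chrom", "start", "end", "name", "score", "strand", "thickStart",
               "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts"]


def _read_bed12(path) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED12_COLS, comment="#")
    models = []
    for row in df.itertuples(index=False):
        if row.start != 0:
            raise ValueError(f"{row.name}: BED12 in transcript space must start at 0")
        models.append(TranscriptModel(
            transcript_id=str(row.name),
            utr5=Interval(0, int(row.thickStart)),
            cds=Interval(int(row.thickStart), int(row.thickEnd)),
            utr3=Interval(int(row.thickEnd), int(row.end)),
        ))
    return models


def write_annotation_bed12(transcripts: Sequence[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write("\t".join(map(str, [
                t.transcript_id, 0, t.length, t.transcript_id, 0, "+",
                t.cds.start, t.cds.end, "0", 1, t.length, 0,
            ])) + "\n")


def write_sequences_fasta(transcripts: Sequence[TranscriptModel], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
               for t in transcripts if t.sequence is not None]
    SeqIO.write(records, str(path), "fasta")


def read_sequences_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# track I/O (bedGraph in transcript coordinates)


def write_track_bedgraph(track: FootprintTrack, path) -> None:
    """Write a track as 4-column bedGraph (transcript, start, end, count)."""
    with open(path, "w") as fh:
        fh.write(f"# library_id={track.library_id} species={track.species} mode={track.mode}\n")
        for tid in sorted(track.counts):
            vec = track.counts[tid]
            # run-length encode constant stretches
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                if vec[s] != 0:
                    fh.write(f"{tid}\t{s}\t{e}\t{int(vec[s])}\n")


def read_track(path, transcripts: Sequence[TranscriptModel], species: str,
               mode: str, library_id: str | None = None) -> FootprintTrack:
    """Read a bedGraph/TSV coverage file into a dense FootprintTrack.

    Positions beyond the annotated transcript length raise an error naming
    the offending transcript; records at the same position are summed.
    """
    lengths = {t.transcript_id: t.length for t in transcripts}
    counts = {tid: np.zeros(n, dtype=np.int64) for tid, n in lengths.items()}
    if library_id is None:
        library_id = str(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["transcript_id", "start", "end", "count"])
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["transcript_id", "start", "end", "count"])
    for row in df.itertuples(index=False):
        tid = str(row.transcript_id)
        if tid not in counts:
            raise ValueError(f"track references unannotated transcript {tid!r}")
        if row.end > lengths[tid] or row.start < 0:
            raise ValueError(
                f"record [{row.start},{row.end}) beyond transcript {tid!r} "
                f"of length {lengths[tid]}")
        counts[tid][int(row.start):int(row.end)] += int(row.count)
    return FootprintTrack(library_id=library_id, species=species, mode=mode, counts=counts)


def reads_to_track(reads: pd.DataFrame, transcripts: Sequence[TranscriptModel],
                   species: str, mode: str, library_id: str = "reads",
                   offset: int = 0) -> FootprintTrack:
    """Assign raw (transcript, position, length, count) reads to single
    nucleotides at position + offset and accumulate a dense track."""
    lengths = {t.transcript_id: t.length for t in transcripts}
    counts = {tid: np.zeros(n, dtype=np.int64) for tid, n in lengths.items()}
    for row in reads.itertuples(index=False):
        tid = str(row.transcript_id)
        pos = int(row.position) + offset
        if tid not in counts:
            raise ValueError(f"read references unannotated transcript {tid!r}")
        if 0 <= pos < lengths[tid]:
            counts[tid][pos] += int(row.count)
    return FootprintTrack(library_id=library_id, species=species, mode=mode, counts=counts)
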