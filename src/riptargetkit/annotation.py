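"""Transcript models from GTF annotation and feature-sequence extraction.

Coordinates are 0-based half-open internally; GTF's 1-based inclusive
convention is converted at the I/O boundary. A transcript's four sequence
features — spliced exon, intron, 5'UTR and 3'UTR — are reported in
transcript (mRNA) orientation, i.e. minus-strand transcripts are
reverse-complemented so every sequence reads 5'->3' of the mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from gffutils.feature import feature_from_line

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FEATURES = ("exon", "intron", "utr5", "utr3")


class AnnotationError(ValueError):
    """Malformed annotation input (parse or validation failure)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"interval start must precede end: [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are sorted by start and non-overlapping; ``cds_start``/
    ``cds_end`` bound the full coding span in genomic coordinates
    (half-open, spanning introns) and are ``None`` for non-coding models.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(
                f"transcript {self.transcript_id}: CDS bounds must come in pairs"
            )
        if self.cds_start is not None:
            if not (self.exons[0].start <= self.cds_start < self.cds_end <= self.exons[-1].end):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: CDS outside exon span"
                )

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def transcript_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class FeatureSequences:
    """Per-transcript sequences and lengths of the four features.

    All sequences are uppercase DNA in transcript orientation. For coding
    transcripts ``len(utr5) + cds_length + len(utr3) == transcript_length``.
    """

    transcript_id: str
    gene_id: str
    exon: str
    intron: str
    utr5: str
    utr3: str

    @property
    def transcript_length(self) -> int:
        return len(self.exon)

    def feature(self, name: str) -> str:
        if name not in FEATURES:
            raise KeyError(name)
        return getattr(self, name)

    @property
    def lengths(self) -> dict[str, int]:
        return {f: len(self.feature(f)) for f in FEATURES}

    @property
    def is_complete(self) -> bool:
        return all(len(self.feature(f)) > 0 for f in FEATURES)


def read_gtf(path) -> list[TranscriptModel]:
    """Parse a GTF file into transcript models.

    Only ``exon`` and ``CDS`` rows are consumed; each must carry
    ``gene_id`` and ``transcript_id`` attributes. Per transcript, CDS rows
    are collapsed to the outermost coding span. Raises
    :class:`AnnotationError` naming the offending line on malformed input.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    cds: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise AnnotationError(
                    f"{path}: malformed GTF at line {lineno}: expected 9 tab-separated fields"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise AnnotationError(f"{path}: malformed GTF at line {lineno}: {exc}") from exc
            if feat.featuretype not in ("exon", "CDS"):
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except (KeyError, IndexError):
                raise AnnotationError(
                    f"{path}: line {lineno} lacks gene_id/transcript_id attributes"
                )
            start, end = feat.start - 1, feat.end  # 1-based inclusive -> half-open
            if start >= end:
                raise AnnotationError(f"{path}: line {lineno}: empty interval")
            known = meta.setdefault(tid, (gid, feat.seqid, feat.strand))
            if known != (gid, feat.seqid, feat.strand):
                raise AnnotationError(
                    f"{path}: line {lineno}: transcript {tid} changes gene/chrom/strand"
                )
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
            if feat.featuretype == "exon":
                exons[tid].append(GenomicInterval(feat.seqid, start, end, feat.strand))
            else:
                cds.setdefault(tid, []).append((start, end))

    models = []
    for tid in order:
        gid, chrom, strand = meta[tid]
        if not exons[tid]:
            raise AnnotationError(f"transcript {tid} has CDS but no exon rows")
        bounds = cds.get(tid)
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=exons[tid],
                cds_start=min(s for s, _ in bounds) if bounds else None,
                cds_end=max(e for _, e in bounds) if bounds else None,
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path) -> None:
    """Write transcript models as GTF exon/CDS rows (round-trip safe)."""
    with open(path, "w") as fh:
        for t in models:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\trip-target-kit\texon\t{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.is_coding:
                for e in t.exons:
                    s = max(e.start, t.cds_start)
                    x = min(e.end, t.cds_end)
                    if s < x:
                        fh.write(
                            f"{t.chrom}\trip-target-kit\tCDS\t{s + 1}\t{x}\t.\t{t.strand}\t.\t{attrs}\n"
                        )


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Slice [start, end) from a pyfaidx Fasta or a plain mapping of strings."""
    try:
        record = genome[chrom]
    except KeyError:
        raise AnnotationError(f"chromosome {chrom!r} absent from sequence store")
    if end > len(record):
        raise AnnotationError(
            f"interval [{start},{end}) exceeds {chrom} length {len(record)}"
        )
    piece = record[start:end]
    seq = piece if isinstance(piece, str) else str(piece)
    return seq.upper()


def extract_features(t: TranscriptModel, genome) -> FeatureSequences:
    """Derive the four feature sequences of a transcript from the genome.

    ``genome`` may be a ``pyfaidx.Fasta`` or any mapping of chromosome name
    to sequence string. Exonic sequence 5' of the CDS start (in transcript
    orientation) is the 5'UTR; 3' of the CDS end, the 3'UTR; inter-exon
    gaps concatenate into the intron feature. Non-coding transcripts get
    empty UTRs.
    """
    exon_parts = [_fetch(genome, t.chrom, e.start, e.end) for e in t.exons]
    intron_parts = [
        _fetch(genome, t.chrom, a.end, b.start)
        for a, b in zip(t.exons, t.exons[1:])
        if a.end < b.start
    ]
    spliced = "".join(exon_parts)
    intron = "".join(intron_parts)
    if t.strand == "-":
        spliced = reverse_complement(spliced)
        intron = reverse_complement(intron)

    utr5 = utr3 = ""
    if t.is_coding:
        # map genomic CDS bounds to spliced coordinates (genomic orientation)
        def spliced_pos(gpos: int) -> int:
            acc = 0
            for e in t.exons:
                if gpos <= e.start:
                    return acc
                if gpos < e.end:
                    return acc + (gpos - e.start)
                acc += len(e)
            return acc

        lo, hi = spliced_pos(t.cds_start), spliced_pos(t.cds_end)
        if t.strand == "+":
            utr5, utr3 = spliced[:lo], spliced[hi:]
        else:
            n = len(spliced)
            utr5, utr3 = spliced[: n - hi], spliced[n - lo:]
    return FeatureSequences(
        transcript_id=t.transcript_id,
        gene_id=t.gene_id,
        exon=spliced,
        intron=intron,
        utr5=utr5,
        utr3=utr3,
    )


def complete_transcripts(features: Iterable[FeatureSequences]) -> list[FeatureSequences]:
    """Keep transcripts whose four features are all non-empty.

    Single-exon transcripts (no intron) and transcripts lacking an
    annotated UTR on either side are dropped, mirroring the requirement of
    complete annotation for all four features.
    """
    return [f for f in features if f.is_complete]


def feature_length_table(features: Iterable[FeatureSequences]):
    """Per-transcript feature lengths as a DataFrame (TSV-ready)."""
    import pandas as pd

    rows = [
        {
            "transcript_id": f.transcript_id,
            "gene_id": f.gene_id,
            "transcript_length": f.transcript_length,
            **{f"{name}_length": len(f.feature(name)) for name in FEATURES},
        }
        for f in features
    ]
    return pd.DataFrame(rows)
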