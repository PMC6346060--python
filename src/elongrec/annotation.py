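"""Transcript models, length stratification and id-set arithmetic.

Internal exon coordinates are 0-based half-open; the GTF reader/writer
converts from/to the 1-based closed convention at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils

from .errors import FormatError, ParameterError, ValidationError

__all__ = [
    "TranscriptAnnotation",
    "LengthStrata",
    "OverlapResult",
    "read_gtf",
    "write_gtf",
    "stratify_by_length",
    "set_overlap",
    "annotation_index",
]

STRATA = ("short", "mid", "long")


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript: exon structure, strand, and summed exon length.

    ``exons`` are ``(start, end)`` pairs in 0-based half-open genomic
    coordinates, sorted by genomic start and non-overlapping.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(tuple(map(int, e)) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if end <= start:
                raise ValidationError(
                    f"transcript {self.transcript_id}: empty exon ({start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping or unsorted "
                    f"exons at ({start}, {end})"
                )
            prev_end = end

    @property
    def length(self) -> int:
        """Transcript length in nt: sum of exon lengths."""
        return sum(end - start for start, end in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_lengths_5p_to_3p(self) -> list[int]:
        """Exon lengths ordered 5'->3' (genomic order reversed on '-')."""
        lens = [end - start for start, end in self.exons]
        return lens[::-1] if self.strand == "-" else lens

    def genomic_to_transcript_order(self) -> list[int]:
        """Genomic exon indices listed in 5'->3' transcript order."""
        idx = list(range(len(self.exons)))
        return idx[::-1] if self.strand == "-" else idx


@dataclass(frozen=True)
class LengthStrata:
    """Tripartition of transcripts by length with inclusive upper bounds.

    short: L <= b1; mid: b1 < L <= b2; long: L > b2.
    """

    boundaries: tuple[int, int]
    assignment: Mapping[str, str] = field(repr=False)

    def members(self, stratum: str) -> set[str]:
        if stratum not in STRATA:
            raise ParameterError(f"unknown stratum {stratum!r}")
        return {t for t, s in self.assignment.items() if s == stratum}

    def sizes(self) -> dict[str, int]:
        out = {s: 0 for s in STRATA}
        for s in self.assignment.values():
            out[s] += 1
        return out


@dataclass(frozen=True)
class OverlapResult:
    """Set arithmetic between two id-sets (Venn-diagram cells)."""

    only_a: frozenset
    only_b: frozenset
    common: frozenset
    union_count: int


def stratify_by_length(
    transcripts: Iterable[TranscriptAnnotation] | Mapping[str, int],
    b1: int = 175,
    b2: int = 1300,
) -> LengthStrata:
    """Assign each transcript to a length stratum.

    Accepts either TranscriptAnnotation records or a ``transcript_id ->
    length`` mapping. Boundaries are inclusive on the short side:
    ``length == b1`` is short and ``length == b2`` is mid.
    """
    if b1 >= b2:
        raise ParameterError(f"stratum boundaries must satisfy b1 < b2, got {b1} >= {b2}")
    if isinstance(transcripts, Mapping):
        lengths = dict(transcripts)
    else:
        lengths = {t.transcript_id: t.length for t in transcripts}
    assignment = {}
    for tid, length in lengths.items():
        if length < 1:
            raise ValidationError(f"transcript {tid}: length {length} < 1")
        if length <= b1:
            assignment[tid] = "short"
        elif length <= b2:
            assignment[tid] = "mid"
        else:
            assignment[tid] = "long"
    return LengthStrata(boundaries=(b1, b2), assignment=assignment)


def set_overlap(a: Iterable, b: Iterable) -> OverlapResult:
    """Partition two id-sets into exclusive and shared members."""
    sa, sb = frozenset(a), frozenset(b)
    common = sa & sb
    return OverlapResult(
        only_a=sa - common,
        only_b=sb - common,
        common=common,
        union_count=len(sa | sb),
    )


def _prescan_gtf(path: Path) -> None:
    """Cheap structural check so errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 tab-separated fields")
            if fields[2] != "exon":
                continue
            attrs = fields[8]
            for required in ("transcript_id", "gene_id"):
                if required not in attrs:
                    raise FormatError(
                        f"{path}: line {lineno}: exon feature missing "
                        f"{required} attribute"
                    )


def read_gtf(path: str | Path) -> list[TranscriptAnnotation]:
    """Read exon features from a GTF file into transcript records.

    Coordinates are converted from GTF 1-based closed to internal 0-based
    half-open. Exons are grouped by ``transcript_id`` and sorted by genomic
    start; overlapping exons within one transcript raise ValidationError.
    """
    path = Path(path)
    _prescan_gtf(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        rec = grouped.setdefault(
            tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        rec["exons"].append((feat.start - 1, feat.end))
    out = []
    for tid, rec in grouped.items():
        out.append(
            TranscriptAnnotation(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
            )
        )
    return out


def write_gtf(transcripts: Iterable[TranscriptAnnotation], path: str | Path) -> None:
    """Write exon features (GTF2.2 attribute syntax), one line per exon."""
    with open(path, "w") as fh:
        for t in transcripts:
            for i, (start, end) in enumerate(t.exons):
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'exon_number "{i + 1}";'
                )
                fh.write(
                    f"{t.chrom}\telongrec\texon\t{start + 1}\t{end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def annotation_index(
    transcripts: Iterable[TranscriptAnnotation] | Mapping[str, TranscriptAnnotation],
) -> dict[str, TranscriptAnnotation]:
    """Index transcripts by id (pass-through for an existing mapping)."""
    if isinstance(transcripts, Mapping):
        return dict(transcripts)
    return {t.transcript_id: t for t in transcripts}
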