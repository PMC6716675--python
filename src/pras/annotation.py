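"""Transcript annotation: GTF parsing, representative selection, coordinate mapping.

Everything downstream of this module lives in a single unambiguous coordinate
frame: genomic intervals are 0-based half-open, transcript positions are
0-based offsets along the *spliced* transcript measured from its 5' end
(strand-aware). GTF's 1-based closed coordinates are converted on read.

The four candidate reference anchors of a transcript — transcription start
site (TSS), translation initiation site (TIS), translation termination site
(TTS, stop codon included) and transcription end site (TES, the
polyadenylation site) — are exposed through :class:`SiteKind` and
:meth:`TranscriptModel.reference_position`.
"""

from __future__ import annotations

import re
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Literal, Optional, Sequence

__all__ = [
    "SiteKind",
    "TranscriptModel",
    "TranscriptCatalog",
    "GtfParseError",
    "parse_gtf",
    "select_representative",
]


class GtfParseError(ValueError):
    """Raised for malformed GTF input; the message names the offending line."""


class SiteKind(str, Enum):
    """Candidate reference anchors on a transcript.

    TIS and TTS are only defined for coding transcripts (a CDS is required).
    """

    TSS = "tss"  #: transcription start site, transcript position 0
    TIS = "tis"  #: translation initiation site, first base of the CDS
    TTS = "tts"  #: translation termination site, last base of the stop codon
    TES = "tes"  #: transcription end site / polyadenylation site, last base

    def requires_cds(self) -> bool:
        return self in (SiteKind.TIS, SiteKind.TTS)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure and CDS of one transcript.

    Parameters
    ----------
    transcript_id, gene_id : str
    chrom : str
    strand : str
        ``"+"`` or ``"-"``.
    exons : tuple of (start, end)
        Genomic half-open intervals, non-overlapping, sorted by start.
    cds_span : (start, end) or None
        Genomic half-open span from the first to the last coding base,
        stop codon included. ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_span: Optional[tuple[int, int]] = None

    # per-exon cumulative spliced offsets, filled in __post_init__
    _starts: tuple[int, ...] = field(init=False, repr=False, compare=False)
    _offsets: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        prev_end = None
        for s, e in exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e
        object.__setattr__(self, "exons", exons)
        offsets, total = [], 0
        for s, e in exons:
            offsets.append(total)
            total += e - s
        object.__setattr__(self, "_starts", tuple(s for s, _ in exons))
        object.__setattr__(self, "_offsets", tuple(offsets))
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if not (cs < ce):
                raise ValueError(f"{self.transcript_id}: empty CDS span")
            if (
                self.genomic_to_transcript(cs) is None
                or self.genomic_to_transcript(ce - 1) is None
            ):
                raise ValueError(
                    f"{self.transcript_id}: CDS span endpoints fall outside exons"
                )
            object.__setattr__(self, "cds_span", (int(cs), int(ce)))

    # ------------------------------------------------------------------ lengths

    @property
    def spliced_length(self) -> int:
        """Total exonic length in nt."""
        last_s, last_e = self.exons[-1]
        return self._offsets[-1] + (last_e - last_s)

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None

    def _cds_bounds(self) -> tuple[int, int]:
        """(TIS, TTS) transcript positions; requires a CDS."""
        assert self.cds_span is not None
        a = self.genomic_to_transcript(self.cds_span[0])
        b = self.genomic_to_transcript(self.cds_span[1] - 1)
        assert a is not None and b is not None
        return (min(a, b), max(a, b))

    @property
    def utr5_length(self) -> int:
        if not self.is_coding:
            return 0
        return self._cds_bounds()[0]

    @property
    def cds_length(self) -> int:
        if not self.is_coding:
            return 0
        tis, tts = self._cds_bounds()
        return tts - tis + 1

    @property
    def utr3_length(self) -> int:
        if not self.is_coding:
            return 0
        return self.spliced_length - 1 - self._cds_bounds()[1]

    # --------------------------------------------------------------- coordinates

    def genomic_to_transcript(self, gpos: int) -> Optional[int]:
        """Map a genomic position to its spliced-transcript coordinate.

        Returns ``None`` (not an error) when ``gpos`` is intronic or outside
        the transcript. The result is measured from the transcript 5' end,
        so on the minus strand larger genomic positions map to smaller
        transcript positions.
        """
        i = bisect_right(self._starts, gpos) - 1
        if i < 0:
            return None
        s, e = self.exons[i]
        if gpos >= e:
            return None
        plus = self._offsets[i] + (gpos - s)
        if self.strand == "+":
            return plus
        return self.spliced_length - 1 - plus

    def transcript_to_genomic(self, tpos: int) -> int:
        """Inverse of :meth:`genomic_to_transcript` for valid positions."""
        L = self.spliced_length
        if not (0 <= tpos < L):
            raise ValueError(
                f"{self.transcript_id}: transcript position {tpos} outside [0,{L})"
            )
        plus = tpos if self.strand == "+" else L - 1 - tpos
        i = bisect_right(self._offsets, plus) - 1
        s, _ = self.exons[i]
        return s + (plus - self._offsets[i])

    def reference_position(self, kind: SiteKind) -> int:
        """Transcript coordinate of a candidate reference anchor.

        TSS is position 0; TES is the last transcribed base
        (``spliced_length - 1``); TIS is the first base of the CDS; TTS is
        the last base of the CDS with the stop codon counted inside it.
        """
        kind = SiteKind(kind)
        if kind is SiteKind.TSS:
            return 0
        if kind is SiteKind.TES:
            return self.spliced_length - 1
        if not self.is_coding:
            raise ValueError(
                f"{kind.value.upper()} undefined for non-coding transcript "
                f"{self.transcript_id}"
            )
        tis, tts = self._cds_bounds()
        return tis if kind is SiteKind.TIS else tts


@dataclass
class TranscriptCatalog:
    """Transcripts keyed by id, with an optional gene -> representative map."""

    transcripts: dict[str, TranscriptModel]
    representative: Optional[dict[str, str]] = None

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def genes(self) -> dict[str, list[TranscriptModel]]:
        out: dict[str, list[TranscriptModel]] = {}
        for t in self:
            out.setdefault(t.gene_id, []).append(t)
        return out

    def representatives(self) -> list[TranscriptModel]:
        """Representative transcripts, one per gene; requires selection first."""
        if self.representative is None:
            raise ValueError(
                "no representatives selected; call select_representative first"
            )
        return [self.transcripts[tid] for tid in self.representative.values()]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_KEPT_FEATURES = frozenset({"exon", "CDS", "stop_codon"})


def _parse_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(raw))
    if not attrs:
        raise GtfParseError(f"line {lineno}: malformed attribute string: {raw!r}")
    return attrs


def parse_gtf(path) -> TranscriptCatalog:
    """Parse transcript models from a GTF file.

    Only ``exon``, ``CDS`` and ``stop_codon`` features are used. GTF's
    1-based closed coordinates are converted to 0-based half-open on read;
    a separately annotated stop codon is folded into the CDS span. Both
    Ensembl and GENCODE attribute dialects (with or without trailing
    semicolons) are accepted.

    Raises
    ------
    GtfParseError
        For malformed lines, naming the line number. Transcripts with CDS
        but no exon features are skipped with a warning, not fatally.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame = fields[:8]
            if feature not in _KEPT_FEATURES:
                continue
            try:
                g0, g1 = int(start) - 1, int(end)  # to 0-based half-open
            except ValueError:
                raise GtfParseError(
                    f"line {lineno}: non-integer coordinates {start!r}/{end!r}"
                ) from None
            if g0 < 0 or g0 >= g1:
                raise GtfParseError(f"line {lineno}: invalid interval {start}-{end}")
            attrs = _parse_attributes(fields[8], lineno)
            try:
                gid, tid = attrs["gene_id"], attrs["transcript_id"]
            except KeyError as exc:
                raise GtfParseError(
                    f"line {lineno}: missing required attribute {exc.args[0]}"
                ) from None
            known = meta.setdefault(tid, (gid, chrom, strand))
            if known != (gid, chrom, strand):
                raise GtfParseError(
                    f"line {lineno}: transcript {tid} has inconsistent "
                    "gene/chrom/strand across features"
                )
            if feature == "exon":
                exons.setdefault(tid, []).append((g0, g1))
            else:  # CDS or stop_codon both count toward the coding span
                cds.setdefault(tid, []).append((g0, g1))

    transcripts: dict[str, TranscriptModel] = {}
    for tid, (gid, chrom, strand) in meta.items():
        if tid not in exons:
            warnings.warn(
                f"transcript {tid} has no exon features; skipped", stacklevel=2
            )
            continue
        span = None
        if tid in cds:
            span = (min(s for s, _ in cds[tid]), max(e for _, e in cds[tid]))
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            exons=tuple(exons[tid]),
            cds_span=span,
        )
    return TranscriptCatalog(transcripts)


Policy = Literal["longest_3utr", "longest_transcript", "explicit_list"]


def select_representative(
    catalog: TranscriptCatalog,
    policy: Policy = "longest_3utr",
    explicit: Optional[Iterable[str]] = None,
) -> TranscriptCatalog:
    """Retain exactly one transcript per gene.

    Under ``longest_3utr`` the transcript with the longest 3' UTR wins
    (non-coding transcripts count as UTR length 0); ties go to the larger
    spliced length, then the lexicographically smallest transcript id.
    ``longest_transcript`` uses spliced length directly. ``explicit_list``
    keeps exactly the transcripts named in ``explicit``.
    """
    if not catalog.transcripts:
        raise ValueError("empty catalog")
    chosen: dict[str, str] = {}
    if policy == "explicit_list":
        if explicit is None:
            raise ValueError("policy explicit_list requires an explicit id list")
        wanted = list(explicit)
        missing = [tid for tid in wanted if tid not in catalog]
        if missing:
            raise ValueError(f"unknown transcript ids: {', '.join(sorted(missing))}")
        for tid in wanted:
            t = catalog[tid]
            if t.gene_id in chosen and chosen[t.gene_id] != tid:
                raise ValueError(
                    f"explicit list names two transcripts for gene {t.gene_id}"
                )
            chosen[t.gene_id] = tid
    else:
        if policy == "longest_3utr":
            key = lambda t: (-t.utr3_length, -t.spliced_length, t.transcript_id)
        elif policy == "longest_transcript":
            key = lambda t: (-t.spliced_length, t.transcript_id)
        else:
            raise ValueError(f"unknown policy {policy!r}")
        for gid, ts in catalog.genes().items():
            chosen[gid] = sorted(ts, key=key)[0].transcript_id
    kept = {tid: catalog[tid] for tid in chosen.values()}
    return TranscriptCatalog(transcripts=kept, representative=chosen)
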