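"""Cross-link sites and peak clusters: BED I/O, merging, normalization, mapping.

CLIP-seq significant cross-linking sites arrive as BED6 intervals whose
score column carries the read count (intensity). Sites within a small gap
of each other (default 20 nt of empty space between intervals) are merged
transitively into peak clusters; a cluster's intensity ``r`` is the sum of
its member intensities, its position is the interval midpoint. An optional
control track attaches a background count ``c`` to each cluster for
enrichment normalization ``r * log2(r/c)``.
"""

from __future__ import annotations

import logging
import math
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .annotation import SiteKind, TranscriptCatalog, TranscriptModel

__all__ = [
    "CrossLinkSite",
    "PeakCluster",
    "MappedPeak",
    "BedParseError",
    "read_bed",
    "sites_to_clusters",
    "merge_sites",
    "attach_control",
    "normalize_intensity",
    "map_peaks",
]

logger = logging.getLogger(__name__)


class BedParseError(ValueError):
    pass


@dataclass(frozen=True)
class CrossLinkSite:
    """One significant cross-linking site (or called peak) from a BED record."""

    chrom: str
    strand: str
    start: int
    end: int
    intensity: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start},{self.end})")
        if self.intensity < 0:
            raise ValueError("negative intensity")


@dataclass(frozen=True)
class PeakCluster:
    """A merged run of nearby cross-linking sites.

    ``r`` is the summed raw intensity, ``c`` the optional control count
    attached by :func:`attach_control`.
    """

    chrom: str
    strand: str
    start: int
    end: int
    r: float
    c: Optional[float] = None

    @property
    def midpoint(self) -> int:
        return (self.start + self.end - 1) // 2


@dataclass(frozen=True)
class MappedPeak:
    """A peak cluster placed on a transcript, with its anchor distance.

    ``tpos`` is the transcript coordinate of the cluster midpoint and ``d``
    its absolute distance (nt, along the spliced transcript) to the
    reference position the peaks were mapped against.
    """

    cluster: PeakCluster
    transcript: TranscriptModel
    tpos: int
    d: int

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


def read_bed(path, unstranded: bool = False) -> list[CrossLinkSite]:
    """Read cross-link sites from a BED6 (or BED6+) file.

    Column 5 is the intensity, column 6 the strand. A file with no score
    column yields intensity 1 per site with a warning. Files without a
    strand column are rejected unless ``unstranded=True`` (sites then get
    strand ``"."`` and strand checks are skipped downstream).
    """
    sites: list[CrossLinkSite] = []
    warned_score = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 BED columns")
            chrom = f[0]
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates {f[1]!r}/{f[2]!r}"
                ) from None
            if start >= end:
                raise BedParseError(f"line {lineno}: start >= end ({start} >= {end})")
            if len(f) >= 5:
                try:
                    intensity = float(f[4])
                except ValueError:
                    raise BedParseError(
                        f"line {lineno}: non-numeric score {f[4]!r}"
                    ) from None
            else:
                intensity = 1.0
                if not warned_score:
                    warnings.warn(
                        f"{path}: no score column; using intensity 1 per site",
                        stacklevel=2,
                    )
                    warned_score = True
            if len(f) >= 6:
                strand = f[5]
                if strand not in ("+", "-", "."):
                    raise BedParseError(f"line {lineno}: invalid strand {strand!r}")
                if strand == "." and not unstranded:
                    raise BedParseError(
                        f"line {lineno}: strand is '.'; supply stranded BED6 "
                        "or pass unstranded=True (--unstranded)"
                    )
            elif unstranded:
                strand = "."
            else:
                raise BedParseError(
                    f"line {lineno}: no strand column; supply BED6 or pass "
                    "unstranded=True (--unstranded)"
                )
            sites.append(CrossLinkSite(chrom, strand, start, end, intensity))
    return sites


def sites_to_clusters(sites: Iterable[CrossLinkSite]) -> list[PeakCluster]:
    """Wrap each site as its own single-member cluster (no merging).

    Metagene profiles are built from site-level coverage — the read counts
    within significant peaks at each position — because painting a merged
    cluster's summed intensity over its union span double-counts positions
    where sites crowd together and distorts the decay estimate.
    """
    return [
        PeakCluster(s.chrom, s.strand, s.start, s.end, s.intensity) for s in sites
    ]


def merge_sites(sites: Iterable[CrossLinkSite], gap: int = 20) -> list[PeakCluster]:
    """Merge nearby sites into peak clusters (transitively).

    Two sites on the same chromosome and strand join one cluster when the
    empty space between their intervals is at most ``gap`` nt; with
    ``gap=0`` only touching or overlapping intervals merge. The cluster
    interval is the union span and its intensity the member sum. Output is
    sorted by (chrom, start).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    by_group: dict[tuple[str, str], list[CrossLinkSite]] = {}
    for s in sites:
        by_group.setdefault((s.chrom, s.strand), []).append(s)
    clusters: list[PeakCluster] = []
    for (chrom, strand), group in by_group.items():
        group = sorted(group, key=lambda s: (s.start, s.end))
        cur_start, cur_end, cur_r = group[0].start, group[0].end, group[0].intensity
        for s in group[1:]:
            if s.start - cur_end <= gap:
                cur_end = max(cur_end, s.end)
                cur_r += s.intensity
            else:
                clusters.append(PeakCluster(chrom, strand, cur_start, cur_end, cur_r))
                cur_start, cur_end, cur_r = s.start, s.end, s.intensity
        clusters.append(PeakCluster(chrom, strand, cur_start, cur_end, cur_r))
    clusters.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return clusters


def attach_control(
    clusters: Sequence[PeakCluster],
    control_sites: Iterable[CrossLinkSite],
    unstranded: bool = False,
) -> list[PeakCluster]:
    """Attach control counts: a control site counts toward a cluster's ``c``
    when its midpoint falls inside the cluster interval (same chrom/strand
    unless ``unstranded``)."""
    mids: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for s in control_sites:
        key = (s.chrom, "." if unstranded else s.strand)
        mids.setdefault(key, []).append(((s.start + s.end - 1) // 2, s.intensity))
    for v in mids.values():
        v.sort()
    out: list[PeakCluster] = []
    for cl in clusters:
        key = (cl.chrom, "." if unstranded else cl.strand)
        pts = mids.get(key, [])
        lo = bisect_left(pts, (cl.start, -math.inf))
        hi = bisect_left(pts, (cl.end, -math.inf))
        c = sum(w for _, w in pts[lo:hi])
        out.append(replace(cl, c=c))
    return out


def normalize_intensity(r: float, c: float, pseudocount: float = 1.0) -> float:
    """Control-normalized peak intensity ``max(0, r * log2((r+pc)/(c+pc)))``.

    The enrichment ratio ``r * log2(r/c)`` is clamped at 0 when the peak is
    not enriched over the control, and a pseudocount (default 1) guards the
    ratio when either count is 0.
    """
    if r < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    num, den = r + pseudocount, c + pseudocount
    if num <= 0 or den <= 0:
        return 0.0
    return max(0.0, r * math.log2(num / den))


def map_peaks(
    clusters: Sequence[PeakCluster],
    catalog: TranscriptCatalog,
    kind: SiteKind,
    unstranded: bool = False,
) -> list[MappedPeak]:
    """Place peak clusters on representative transcripts.

    A cluster maps to every representative transcript whose exons contain
    its midpoint on the matching strand (any strand when ``unstranded``);
    a peak overlapping two genes therefore contributes to both. ``d`` is
    the spliced-transcript distance from the midpoint to the ``kind``
    anchor. Intronic/intergenic clusters are dropped and tallied to the
    module logger; transcripts lacking a CDS are skipped for TIS/TTS.
    """
    kind = SiteKind(kind)
    trees: dict[str, IntervalTree] = {}
    refpos: dict[str, int] = {}
    n_noncoding = 0
    for t in catalog.representatives():
        if kind.requires_cds() and not t.is_coding:
            n_noncoding += 1
            continue
        refpos[t.transcript_id] = t.reference_position(kind)
        tree = trees.setdefault(t.chrom, IntervalTree())
        for s, e in t.exons:
            tree.addi(s, e, t)
    mapped: list[MappedPeak] = []
    n_unmapped = 0
    for cl in clusters:
        mid = cl.midpoint
        hits = trees.get(cl.chrom, IntervalTree())[mid]
        found = False
        for iv in hits:
            t: TranscriptModel = iv.data
            if not unstranded and cl.strand != "." and cl.strand != t.strand:
                continue
            tpos = t.genomic_to_transcript(mid)
            if tpos is None:  # pragma: no cover - exon hit guarantees mapping
                continue
            mapped.append(
                MappedPeak(cl, t, tpos, abs(tpos - refpos[t.transcript_id]))
            )
            found = True
        if not found:
            n_unmapped += 1
    if n_unmapped:
        logger.info(
            "map_peaks: %d/%d clusters not exonic in any representative "
            "transcript (dropped)", n_unmapped, len(clusters)
        )
    if n_noncoding:
        logger.info(
            "map_peaks: %d non-coding representatives skipped for %s",
            n_noncoding, kind.value.upper(),
        )
    mapped.sort(key=lambda m: (m.transcript_id, m.tpos))
    return mapped
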