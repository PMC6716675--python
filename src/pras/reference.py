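"""Metagene profiles, reference-site auto-selection and decay-constant estimation.

The exponential weight in the association score is ``w = exp(-d/d0)``. The
decay constant ``d0`` is estimated from a metagene profile: the average
peak-intensity coverage at each signed distance from an anchor, pooled over
transcripts. With the profile maximum ``p_max`` at distance ``d_peak`` from
the anchor and the density ``p_far`` at a far distance, the observed weight
over the span ``d = far - d_peak`` is ``w = p_far / p_max`` and inverting
the weighting formula gives ``d0 = -d / ln(w)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotation import SiteKind
from .peaks import MappedPeak

__all__ = [
    "MetageneProfile",
    "DecayModel",
    "metagene_profile",
    "auto_select_reference",
    "decay_constant",
    "estimate_d0",
]

#: Tie-break priority when candidate anchors carry equal signal mass:
#: 3'-UTR-associated anchors win (decay regulators act there most often).
_PRIORITY = {SiteKind.TES: 3, SiteKind.TTS: 2, SiteKind.TIS: 1, SiteKind.TSS: 0}


@dataclass
class MetageneProfile:
    """Average peak-intensity coverage around an anchor.

    ``grid`` holds signed anchor-relative distances (negative = 5' of the
    anchor along the transcript) covering ``[-window, +window]``;
    ``avg_intensity[i]`` is the summed cluster intensity covering that
    offset across transcripts, divided by ``n_transcripts`` (the number of
    transcripts with at least one mapped peak).
    """

    kind: SiteKind
    window: int
    grid: np.ndarray
    avg_intensity: np.ndarray
    n_transcripts: int

    def value_at(self, rel: int) -> float:
        """Average intensity at signed anchor-relative distance ``rel``."""
        if abs(rel) > self.window:
            raise ValueError(f"{rel} outside profile window ±{self.window}")
        return float(self.avg_intensity[rel + self.window])

    @property
    def total_mass(self) -> float:
        return float(self.avg_intensity.sum())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("distance\tavg_intensity\n")
            for g, v in zip(self.grid, self.avg_intensity):
                fh.write(f"{g}\t{v:.6g}\n")


@dataclass(frozen=True)
class DecayModel:
    """A reference-site kind plus exponential decay constant ``d0`` (nt)."""

    kind: SiteKind
    d0: float
    w: Optional[float] = None       # observed density ratio, when estimated
    d_peak: Optional[int] = None    # distance of the profile maximum

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")

    def weight(self, d: float) -> float:
        """Exponential decay weight ``exp(-d/d0)`` at distance ``d`` nt."""
        return math.exp(-d / self.d0)


def metagene_profile(
    mapped: Sequence[MappedPeak],
    kind: SiteKind,
    window: int = 2000,
    smooth: int = 25,
) -> MetageneProfile:
    """Build the average peak-intensity profile around the ``kind`` anchor.

    Each mapped cluster adds its intensity ``r`` to every anchor-relative
    offset its interval covers (in spliced-transcript coordinates);
    positions beyond a transcript's extent simply contribute nothing.
    The per-offset sums are divided by the number of distinct transcripts
    carrying peaks, then smoothed with a centred moving average of
    half-width ``smooth`` nt (``smooth=0`` disables smoothing).
    """
    kind = SiteKind(kind)
    if window <= 0:
        raise ValueError("window must be positive")
    if not mapped:
        raise ValueError("empty profile: no mapped peaks")
    cov = np.zeros(2 * window + 1)
    tids = set()
    for mp in mapped:
        t = mp.transcript
        tids.add(t.transcript_id)
        ref = t.reference_position(kind)
        cl = mp.cluster
        a = t.genomic_to_transcript(cl.start)
        b = t.genomic_to_transcript(cl.end - 1)
        if a is not None and b is not None:
            lo, hi = min(a, b) - ref, max(a, b) - ref
            lo, hi = max(lo, -window), min(hi, window)
            if lo <= hi:
                cov[lo + window : hi + window + 1] += cl.r
        else:
            # cluster straddles an exon boundary: fall back per position
            for g in range(cl.start, cl.end):
                tp = t.genomic_to_transcript(g)
                if tp is None:
                    continue
                rel = tp - ref
                if -window <= rel <= window:
                    cov[rel + window] += cl.r
    avg = cov / len(tids)
    if smooth > 0:
        k = np.full(2 * smooth + 1, 1.0 / (2 * smooth + 1))
        avg = np.convolve(avg, k, mode="same")
    return MetageneProfile(
        kind=kind,
        window=window,
        grid=np.arange(-window, window + 1),
        avg_intensity=avg,
        n_transcripts=len(tids),
    )


def auto_select_reference(
    profiles: Mapping[SiteKind, MetageneProfile]
) -> SiteKind:
    """Pick the anchor whose profile carries the most signal.

    Returns the :class:`SiteKind` with the largest total average intensity
    inside the window; exact ties fall to the fixed priority
    TES > TTS > TIS > TSS. All profiles must share one window.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 candidate profiles")
    windows = {p.window for p in profiles.values()}
    if len(windows) != 1:
        raise ValueError("candidate profiles must share the same window")
    return max(
        profiles, key=lambda k: (profiles[k].total_mass, _PRIORITY[SiteKind(k)])
    )


def decay_constant(d: float, w: float) -> int:
    """Invert the weighting formula ``w = exp(-d/d0)`` for ``d0``.

    Given an observed weight ``w`` (0 < w < 1) over a distance span ``d``
    nt, returns ``d0 = -d / ln(w)`` rounded to the nearest nucleotide.
    """
    if not 0.0 < w < 1.0:
        raise ValueError(f"weight must lie in (0,1), got {w}")
    if d <= 0:
        raise ValueError("distance span must be positive")
    return round(-d / math.log(w))


def estimate_d0(profile: MetageneProfile, far_distance: int = 1000) -> DecayModel:
    """Estimate the decay constant from a metagene profile.

    Locates the profile maximum ``p_max`` at distance ``d_peak`` from the
    anchor, reads the density ``p_far`` at ``far_distance`` on the same
    side of the anchor as the maximum (5' side when the maximum sits on
    the anchor), and returns ``d0 = -d / ln(w)`` with ``w = p_far/p_max``
    and ``d = far_distance - d_peak``.
    """
    if not 0 < far_distance <= profile.window:
        raise ValueError("far_distance must lie inside the profile window")
    avg = profile.avg_intensity
    i_max = int(np.argmax(avg))
    rel_max = int(profile.grid[i_max])
    p_max = float(avg[i_max])
    if p_max <= 0:
        raise ValueError("profile maximum is not strictly positive")
    side = 1 if rel_max > 0 else -1
    d_peak = abs(rel_max)
    p_far = profile.value_at(side * far_distance)
    d = far_distance - d_peak
    if d <= 0:
        raise ValueError(
            "far_distance not beyond the profile maximum; increase it"
        )
    if p_far <= 0:
        raise ValueError(
            "no signal at far_distance; choose a nearer far_distance or "
            "set d0 manually"
        )
    w = p_far / p_max
    if w >= 1:
        raise ValueError(
            "no decay between the maximum and far_distance; choose a "
            "different far_distance or set d0 manually"
        )
    return DecayModel(kind=profile.kind, d0=decay_constant(d, w), w=w, d_peak=d_peak)
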