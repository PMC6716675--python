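"""Seeded synthetic CLIP datasets with planted positional structure.

The generator emulates the situation the scoring model assumes: a set of
coding transcripts on a toy chromosome; cross-link sites whose distance to
a true reference anchor follows an exponential law with decay constant
``d0_true`` (truncated to the transcript, so sites never fall off its
ends); intensities drawn from a geometric distribution; a uniform
background control track; and a knockout-style expression table whose log
fold changes are negatively coupled to the true association score plus
Gaussian noise.

One master seed drives everything; per-stage generators are derived
deterministically with ``numpy.random.SeedSequence`` so that annotation,
peaks and expression can be regenerated independently. All outputs are
byte-identical for an identical :class:`SimConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import SiteKind, TranscriptCatalog, TranscriptModel
from .peaks import CrossLinkSite
from .scoring import TargetScore

__all__ = [
    "SimConfig",
    "simulate_annotation",
    "simulate_peaks",
    "simulate_expression",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic dataset.

    Defaults describe the reference simulation used throughout the test
    suite: 2000 genes, peaks planted around the transcription end site
    with decay constant 500 nt, expression knocked down in proportion to
    the true association score with moderate noise.
    """

    seed: int = 0
    n_genes: int = 2000
    chrom: str = "chrS"
    chrom_length: Optional[int] = None  # None: auto-sized to fit the genes
    exons_per_transcript: tuple[int, int] = (1, 4)
    utr5_range: tuple[int, int] = (100, 300)
    cds_range: tuple[int, int] = (600, 1800)
    utr3_range: tuple[int, int] = (1000, 3000)
    intron_range: tuple[int, int] = (50, 500)
    intergenic_range: tuple[int, int] = (200, 1000)
    ref_site_true: SiteKind = SiteKind.TES
    d0_true: float = 500.0
    peaks_per_gene_mean: float = 5.0
    intensity_mean: float = 8.0       # geometric, so intensities are >= 1
    site_width: int = 10
    control_rate: float = 2.0         # mean background control sites per gene
    control_intensity_mean: float = 2.0
    coupling: float = 1.0             # strength of the negative LFC-score link
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("exons_per_transcript", "utr5_range", "cds_range",
                     "utr3_range", "intron_range", "intergenic_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.n_genes <= 0 or self.d0_true <= 0 or self.site_width <= 0:
            raise ValueError("n_genes, d0_true and site_width must be positive")


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


def _split_lengths(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """Split ``total`` nt into ``parts`` positive chunks."""
    if parts == 1 or total <= parts:
        return [total]
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [total]])
    return list(np.diff(bounds).astype(int))


def simulate_annotation(cfg: SimConfig, path=None) -> TranscriptCatalog:
    """Lay out ``cfg.n_genes`` non-overlapping coding genes on a toy chromosome.

    Each gene carries one transcript with 5'UTR/CDS/3'UTR lengths drawn
    from the config ranges, split across a random number of exons, on a
    random strand. When ``path`` is given a GTF file (1-based closed,
    exon + CDS features) is written that round-trips through
    :func:`pras.annotation.parse_gtf`. The returned catalog already has
    each gene's single transcript selected as representative.
    """
    rng = _rng(cfg, 0)
    transcripts: dict[str, TranscriptModel] = {}
    rep: dict[str, str] = {}
    cursor = 0
    for i in range(cfg.n_genes):
        gid, tid = f"G{i + 1:05d}", f"T{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        utr5 = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
        cds = int(rng.integers(cfg.cds_range[0], cfg.cds_range[1] + 1))
        utr3 = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))
        L = utr5 + cds + utr3
        n_exons = int(
            rng.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1)
        )
        chunks = _split_lengths(rng, L, n_exons)  # transcript (5'->3') order
        introns = [
            int(rng.integers(cfg.intron_range[0], cfg.intron_range[1] + 1))
            for _ in range(len(chunks) - 1)
        ]
        cursor += int(
            rng.integers(cfg.intergenic_range[0], cfg.intergenic_range[1] + 1)
        )
        # genomic exon order: reversed transcript order on the minus strand
        glens = chunks if strand == "+" else chunks[::-1]
        gintrons = introns if strand == "+" else introns[::-1]
        exons, g = [], cursor
        for k, ln in enumerate(glens):
            exons.append((g, g + ln))
            g += ln + (gintrons[k] if k < len(gintrons) else 0)
        cursor = g
        shell = TranscriptModel(tid, gid, cfg.chrom, strand, tuple(exons))
        g1 = shell.transcript_to_genomic(utr5)            # TIS
        g2 = shell.transcript_to_genomic(utr5 + cds - 1)  # TTS (stop incl.)
        cds_span = (min(g1, g2), max(g1, g2) + 1)
        transcripts[tid] = TranscriptModel(
            tid, gid, cfg.chrom, strand, tuple(exons), cds_span
        )
        rep[gid] = tid
    if cfg.chrom_length is not None and cursor > cfg.chrom_length:
        raise ValueError(
            f"genes need {cursor} nt but chrom_length is {cfg.chrom_length}; "
            "packing infeasible"
        )
    catalog = TranscriptCatalog(transcripts, representative=rep)
    if path is not None:
        _write_gtf(catalog, path)
    return catalog


def _write_gtf(catalog: TranscriptCatalog, path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(catalog.transcripts):
            t = catalog[tid]
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tpras_sim\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.cds_span is not None:
                cs, ce = t.cds_span
                for s, e in t.exons:
                    lo, hi = max(s, cs), min(e, ce)
                    if lo < hi:
                        fh.write(
                            f"{t.chrom}\tpras_sim\tCDS\t{lo + 1}\t{hi}\t.\t"
                            f"{t.strand}\t0\t{attrs}\n"
                        )


def _truncated_exp(rng: np.random.Generator, d0: float, extent: int) -> float:
    """Draw from Exp(1/d0) truncated to [0, extent]."""
    mass = 1.0 - math.exp(-extent / d0)
    u = rng.random()
    return -d0 * math.log1p(-u * mass)


def _site_at(t: TranscriptModel, tpos: int, width: int) -> tuple[int, int]:
    """Genomic interval of a site of ``width`` nt centred at transcript
    position ``tpos``, clipped to the containing exon so it stays exonic."""
    L = t.spliced_length
    p = tpos if t.strand == "+" else L - 1 - tpos  # plus-orientation offset
    # locate the containing exon in plus-offset space
    off = 0
    for s, e in t.exons:
        ln = e - s
        if p < off + ln:
            half = width // 2
            lo = max(off, p - half)
            hi = min(off + ln - 1, lo + width - 1)
            lo = max(off, hi - width + 1)
            return (s + (lo - off), s + (hi - off) + 1)
        off += ln
    raise AssertionError("tpos outside transcript")  # pragma: no cover


def simulate_peaks(
    catalog: TranscriptCatalog,
    cfg: SimConfig,
    path=None,
    control_path=None,
) -> tuple[list[CrossLinkSite], list[CrossLinkSite]]:
    """Plant cross-link sites with exponential positional decay.

    Per transcript, a Poisson(``peaks_per_gene_mean``) number of sites is
    placed; each site's spliced distance to the true reference anchor is
    drawn from an exponential law with constant ``d0_true`` truncated to
    the transcript (sides weighted by their truncated mass), intensities
    from a geometric law with the configured mean. Control sites are
    placed uniformly along transcripts at rate ``control_rate``. Both
    tracks are returned and optionally written as BED6.
    """
    rng = _rng(cfg, 1)
    sites: list[CrossLinkSite] = []
    controls: list[CrossLinkSite] = []
    kind = SiteKind(cfg.ref_site_true)
    for tid in sorted(catalog.transcripts):
        t = catalog[tid]
        L = t.spliced_length
        ref = t.reference_position(kind)
        ext_left, ext_right = ref, L - 1 - ref
        mass_l = 1.0 - math.exp(-ext_left / cfg.d0_true) if ext_left > 0 else 0.0
        mass_r = 1.0 - math.exp(-ext_right / cfg.d0_true) if ext_right > 0 else 0.0
        n = int(rng.poisson(cfg.peaks_per_gene_mean))
        for _ in range(n):
            if mass_l + mass_r <= 0:
                tpos = ref
            else:
                go_left = rng.random() < mass_l / (mass_l + mass_r)
                extent = ext_left if go_left else ext_right
                d = _truncated_exp(rng, cfg.d0_true, extent)
                tpos = ref + (-1 if go_left else 1) * int(round(d))
                tpos = min(max(tpos, 0), L - 1)
            gs, ge = _site_at(t, tpos, cfg.site_width)
            intensity = float(rng.geometric(1.0 / cfg.intensity_mean))
            sites.append(CrossLinkSite(t.chrom, t.strand, gs, ge, intensity))
        m = int(rng.poisson(cfg.control_rate))
        for _ in range(m):
            tpos = int(rng.integers(0, L))
            gs, ge = _site_at(t, tpos, cfg.site_width)
            intensity = float(rng.geometric(1.0 / cfg.control_intensity_mean))
            controls.append(CrossLinkSite(t.chrom, t.strand, gs, ge, intensity))
    sites.sort(key=lambda s: (s.chrom, s.start, s.end, s.strand))
    controls.sort(key=lambda s: (s.chrom, s.start, s.end, s.strand))
    if path is not None:
        _write_bed(sites, path, "site")
    if control_path is not None:
        _write_bed(controls, control_path, "ctrl")
    return sites, controls


def _write_bed(sites: Sequence[CrossLinkSite], path, prefix: str) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sites, start=1):
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{prefix}_{i:06d}\t"
                f"{s.intensity:g}\t{s.strand}\n"
            )


def simulate_expression(
    true_scores: Sequence[TargetScore],
    cfg: SimConfig,
    path=None,
) -> pd.DataFrame:
    """Knockout-style expression LFCs coupled to the true scores.

    ``lfc_g = -coupling * z(log10(1 + S_g)) + Normal(0, noise_sd)`` where
    ``z`` standardizes across genes: strongly bound (high-S) targets lose
    the most expression on knockout. Returned (and optionally written) as
    a two-column table gene_id / lfc.
    """
    rng = _rng(cfg, 2)
    genes = [s.gene_id for s in true_scores]
    x = np.log10(1.0 + np.array([s.S for s in true_scores], dtype=float))
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    lfc = -cfg.coupling * z + rng.normal(0.0, cfg.noise_sd, size=len(z))
    df = pd.DataFrame({"gene_id": genes, "lfc": lfc})
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df


def simulate_dataset(cfg: SimConfig, out_dir) -> dict[str, str]:
    """Write a complete dataset (annotation.gtf, peaks.bed, control.bed,
    expression.tsv, truth.tsv) under ``out_dir`` and return the paths.

    The truth table carries each gene's true association score computed
    with the planted reference site and decay constant; the expression
    table is coupled to those scores.
    """
    import os

    from .peaks import map_peaks, merge_sites
    from .reference import DecayModel
    from .scoring import score_all, scores_to_frame

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        name: os.path.join(out_dir, fname)
        for name, fname in [
            ("annotation", "annotation.gtf"),
            ("peaks", "peaks.bed"),
            ("control", "control.bed"),
            ("expression", "expression.tsv"),
            ("truth", "truth.tsv"),
        ]
    }
    catalog = simulate_annotation(cfg, paths["annotation"])
    sites, _ = simulate_peaks(catalog, cfg, paths["peaks"], paths["control"])
    clusters = merge_sites(sites)
    mapped = map_peaks(clusters, catalog, cfg.ref_site_true)
    decay = DecayModel(kind=SiteKind(cfg.ref_site_true), d0=cfg.d0_true)
    truth = score_all(catalog, mapped, decay)
    scores_to_frame(truth).rename(columns={"pras_score": "true_S"}).to_csv(
        paths["truth"], sep="\t", index=False, float_format="%.6g"
    )
    simulate_expression(truth, cfg, paths["expression"])
    return paths
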