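"""Shared fixtures: hand-built transcripts and the reference simulation."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from pras import (
    PRAS,
    DecayModel,
    SimConfig,
    SiteKind,
    TranscriptCatalog,
    TranscriptModel,
    map_peaks,
    merge_sites,
    score_all,
    simulate_annotation,
    simulate_expression,
    simulate_peaks,
)


def make_transcript(
    exons,
    strand="+",
    cds=None,
    tid="T1",
    gid="G1",
    chrom="chr1",
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_span=cds,
    )


def make_catalog(*transcripts) -> TranscriptCatalog:
    cat = TranscriptCatalog({t.transcript_id: t for t in transcripts})
    cat.representative = {t.gene_id: t.transcript_id for t in transcripts}
    return cat


@dataclass
class BigSim:
    """The reference simulation: 2000 genes, peaks planted at the TES with
    true decay constant 500 nt, knockout expression coupled to true scores."""

    cfg: SimConfig
    catalog: TranscriptCatalog
    sites: list
    controls: list
    clusters: list
    mapped: list  # merged clusters mapped against the true anchor
    truth: list   # TargetScore records under the true reference and d0
    expression: object  # DataFrame gene_id / lfc
    model: PRAS


@pytest.fixture(scope="session")
def big_sim() -> BigSim:
    cfg = SimConfig(seed=1)
    catalog = simulate_annotation(cfg)
    sites, controls = simulate_peaks(catalog, cfg)
    clusters = merge_sites(sites)
    mapped = map_peaks(clusters, catalog, cfg.ref_site_true)
    truth = score_all(
        catalog, mapped, DecayModel(SiteKind(cfg.ref_site_true), cfg.d0_true)
    )
    expression = simulate_expression(truth, cfg)
    model = PRAS(catalog, sites, controls)
    return BigSim(
        cfg=cfg,
        catalog=catalog,
        sites=sites,
        controls=controls,
        clusters=clusters,
        mapped=mapped,
        truth=truth,
        expression=expression,
        model=model,
    )
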