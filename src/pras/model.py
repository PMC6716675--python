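"""High-level modelling interface: build once, ``fit()``, inspect results.

:class:`PRAS` bundles the full pipeline — site merging, control
attachment, reference-site selection (user-specified or automatic from
metagene profiles), decay-constant handling and per-transcript scoring —
behind a statsmodels-like surface::

    model = PRAS.from_files("annotation.gtf", "peaks.bed")
    res = model.fit(ref_site="tes", d0=1000)
    print(res.summary())
    ev = res.evaluate(expression_df, design="ko")

The functional building blocks live in :mod:`pras.annotation`,
:mod:`pras.peaks`, :mod:`pras.reference`, :mod:`pras.scoring` and
:mod:`pras.evaluation`; this module only orchestrates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__ as _version
from .annotation import (
    SiteKind,
    TranscriptCatalog,
    parse_gtf,
    select_representative,
)
from .evaluation import (
    CorrelationCurve,
    correlation_by_cutoff,
    labels_from_lfc,
    roc_auc,
)
from .peaks import (
    CrossLinkSite,
    attach_control,
    map_peaks,
    merge_sites,
    read_bed,
    sites_to_clusters,
)
from .reference import (
    DecayModel,
    MetageneProfile,
    auto_select_reference,
    estimate_d0,
    metagene_profile,
)
from .scoring import Mode, TargetScore, score_all, scores_to_frame

__all__ = ["PRAS", "PRASResults", "EvaluationResult"]

#: Fallback decay constant (nt) when neither given nor estimated.
DEFAULT_D0 = 1000.0


class PRAS:
    """Protein-RNA association model for one CLIP experiment.

    Parameters
    ----------
    catalog : TranscriptCatalog
        Transcript annotation; representatives are selected on
        construction if they are not already.
    sites : list of CrossLinkSite
        Significant cross-linking sites (or called peaks).
    control_sites : list of CrossLinkSite, optional
        Background track for enrichment normalization (``mode="norm"``).
    merge_gap : int
        Maximum empty space (nt) between sites merged into one cluster.
    unstranded : bool
        Ignore strand when mapping peaks onto transcripts.
    """

    def __init__(
        self,
        catalog: TranscriptCatalog,
        sites: Sequence[CrossLinkSite],
        control_sites: Optional[Sequence[CrossLinkSite]] = None,
        merge_gap: int = 20,
        unstranded: bool = False,
        representative_policy: str = "longest_3utr",
    ) -> None:
        if catalog.representative is None:
            catalog = select_representative(catalog, representative_policy)
        self.catalog = catalog
        self.sites = list(sites)
        self.merge_gap = merge_gap
        self.unstranded = unstranded
        self.clusters = merge_sites(self.sites, gap=merge_gap)
        if control_sites is not None:
            self.clusters = attach_control(
                self.clusters, control_sites, unstranded=unstranded
            )
        self.has_control = control_sites is not None

    @classmethod
    def from_files(
        cls,
        gtf: str,
        peaks_bed: str,
        control_bed: Optional[str] = None,
        merge_gap: int = 20,
        unstranded: bool = False,
        representative_policy: str = "longest_3utr",
    ) -> "PRAS":
        """Build the model from a GTF annotation and BED peak file(s)."""
        catalog = parse_gtf(gtf)
        sites = read_bed(peaks_bed, unstranded=unstranded)
        control = read_bed(control_bed, unstranded=unstranded) if control_bed else None
        return cls(
            catalog,
            sites,
            control,
            merge_gap=merge_gap,
            unstranded=unstranded,
            representative_policy=representative_policy,
        )

    # ------------------------------------------------------------------ fitting

    def profiles(
        self, window: int = 2000, smooth: int = 25
    ) -> dict[SiteKind, MetageneProfile]:
        """Metagene profiles around every applicable candidate anchor.

        Profiles are built from site-level intensity coverage (reads within
        significant peaks per position) rather than merged-cluster coverage;
        see :func:`pras.peaks.sites_to_clusters`.
        """
        site_clusters = sites_to_clusters(self.sites)
        out: dict[SiteKind, MetageneProfile] = {}
        for kind in (SiteKind.TSS, SiteKind.TIS, SiteKind.TTS, SiteKind.TES):
            mapped = map_peaks(
                site_clusters, self.catalog, kind, unstranded=self.unstranded
            )
            if mapped:
                out[kind] = metagene_profile(mapped, kind, window, smooth)
        return out

    def fit(
        self,
        ref_site: Union[str, SiteKind] = "auto",
        d0: Optional[float] = None,
        estimate_decay: bool = False,
        mode: Mode = "raw",
        flank: int = 200,
        window: int = 2000,
        smooth: int = 25,
        far_distance: int = 1000,
    ) -> "PRASResults":
        """Score every transcript and return the fitted results.

        ``ref_site="auto"`` selects the anchor whose metagene profile
        carries the most signal; ``estimate_decay=True`` derives ``d0``
        from that profile (otherwise ``d0`` defaults to 1000 nt).
        """
        profiles = None
        if ref_site == "auto":
            profiles = self.profiles(window=window, smooth=smooth)
            if len(profiles) < 2:
                raise ValueError(
                    "automatic reference selection needs signal around at "
                    "least two candidate anchors; specify ref_site instead"
                )
            kind = auto_select_reference(profiles)
        else:
            kind = SiteKind(ref_site)
        mapped = map_peaks(
            self.clusters, self.catalog, kind, unstranded=self.unstranded
        )
        if not mapped:
            raise ValueError("no peaks map onto representative transcripts")
        profile = None
        if profiles is not None:
            profile = profiles[kind]
        elif estimate_decay:
            site_mapped = map_peaks(
                sites_to_clusters(self.sites),
                self.catalog,
                kind,
                unstranded=self.unstranded,
            )
            profile = metagene_profile(site_mapped, kind, window, smooth)
        if d0 is None:
            if estimate_decay:
                decay = estimate_d0(profile, far_distance=far_distance)
            else:
                decay = DecayModel(kind=kind, d0=DEFAULT_D0)
        else:
            decay = DecayModel(kind=kind, d0=float(d0))
        if decay.kind != kind:
            decay = DecayModel(kind=kind, d0=decay.d0, w=decay.w, d_peak=decay.d_peak)
        scores = score_all(self.catalog, mapped, decay, mode=mode, flank=flank)
        return PRASResults(
            model=self,
            scores=scores,
            decay=decay,
            ref_site=kind,
            mode=mode,
            flank=flank,
            profile=profile,
            candidate_profiles=profiles,
        )


@dataclass
class EvaluationResult:
    """Ranking-vs-expression diagnostics for one fitted score column."""

    curve: CorrelationCurve
    auc: Optional[float]
    n_genes: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        auc = f"{self.auc:.3f}" if self.auc is not None else "n/a"
        return (
            f"EvaluationResult(n_genes={self.n_genes}, auc={auc}, "
            f"mean|rho|={self.curve.mean_abs_rho():.3f})"
        )


@dataclass
class PRASResults:
    """Fitted per-transcript scores plus the parameters that produced them."""

    model: PRAS
    scores: list[TargetScore]
    decay: DecayModel
    ref_site: SiteKind
    mode: str
    flank: int
    profile: Optional[MetageneProfile] = None
    candidate_profiles: Optional[dict[SiteKind, MetageneProfile]] = None
    _frame: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def frame(self) -> pd.DataFrame:
        """Score table in rank order (one row per transcript)."""
        if self._frame is None:
            self._frame = scores_to_frame(self.scores)
        return self._frame

    def gene_scores(self, column: str = "pras_score") -> pd.Series:
        """Per-gene score series (max over a gene's transcripts)."""
        return self.frame.groupby("gene_id")[column].max()

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary with the top-ranked targets."""
        lines = [
            "Protein-RNA Association Strength",
            "=" * 48,
            f"transcripts scored:   {len(self.scores)}",
            f"reference site:       {self.ref_site.value.upper()}",
            f"decay constant d0:    {self.decay.d0:g} nt"
            + (f" (estimated, w={self.decay.w:.3f})" if self.decay.w else ""),
            f"intensity mode:       {self.mode}",
            f"flank (expressRNA):   ±{self.flank} nt",
            "-" * 48,
        ]
        head = self.frame.head(top)
        lines.append(head.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        """Write the score table with a provenance header."""
        with open(path, "w") as fh:
            fh.write(f"# pras {_version}\n")
            fh.write(
                f"# ref_site={self.ref_site.value} d0={self.decay.d0:g} "
                f"mode={self.mode} flank={self.flank} "
                f"merge_gap={self.model.merge_gap}\n"
            )
            fh.write(
                "# coordinates: transcript 0-based spliced; distances along "
                "the spliced transcript; stop codon inside CDS\n"
            )
            self.frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    def evaluate(
        self,
        expression: pd.DataFrame,
        design: str = "ko",
        column: str = "pras_score",
    ) -> EvaluationResult:
        """Correlate a score column with expression LFCs and, when both
        stabilized and degraded genes are present, compute the ROC AUC of
        the score against sign-derived labels."""
        expr = expression.set_index("gene_id")["lfc"]
        scores = self.gene_scores(column)
        curve = correlation_by_cutoff(scores, expr)
        shared = scores.index.intersection(expr.index)
        labels = labels_from_lfc(expr.loc[shared].to_numpy(), design=design)
        auc = None
        if 0 < labels.sum() < len(labels):
            auc = roc_auc(scores.loc[shared].to_numpy(), labels)
        return EvaluationResult(curve=curve, auc=auc, n_genes=len(shared))

    def plot_profile(self, ax=None):  # pragma: no cover - plotting helper
        """Plot the metagene profile the fit used (requires matplotlib)."""
        if self.profile is None:
            raise ValueError("fit carried no metagene profile")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.profile.grid, self.profile.avg_intensity, lw=1)
        ax.axvline(0, color="k", lw=0.5, ls="--")
        ax.set_xlabel(f"distance to {self.ref_site.value.upper()} (nt)")
        ax.set_ylabel("average peak intensity")
        return ax
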