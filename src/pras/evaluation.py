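"""Evaluate a target ranking against expression-perturbation data.

Three complementary checks:

* ROC/AUC on binary stabilized/degraded labels derived from the sign of
  the expression log fold change (LFC) under the perturbation design;
* Spearman correlation between score and LFC across increasingly stringent
  |LFC|-quantile cutoffs (the 19-point curve, quantiles 0.05..0.95);
* a one-sided Mann-Whitney test comparing two methods' per-dataset |rho|
  vectors.

All statistics are computed on raw scores — AUC and Spearman are rank
based, so monotone transforms (e.g. log10 for plotting) do not affect them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "labels_from_lfc",
    "roc_auc",
    "CorrelationCurve",
    "correlation_by_cutoff",
    "MannWhitneyResult",
    "compare_methods",
    "read_expression",
    "DEFAULT_QUANTILES",
]

Design = Literal["ko", "oe"]

#: |LFC| quantile grid for the correlation curve: 0.05 to 0.95, step 0.05.
DEFAULT_QUANTILES = np.round(np.arange(0.05, 0.951, 0.05), 2)


def read_expression(path) -> pd.DataFrame:
    """Read a gene-level expression table (TSV: gene_id, lfc[, adj_p])."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols or "lfc" not in cols:
        raise ValueError(
            "expression table must have columns gene_id and lfc "
            f"(found: {list(df.columns)})"
        )
    df = df.rename(columns={cols["gene_id"]: "gene_id", cols["lfc"]: "lfc"})
    if "adj_p" in cols:
        df = df.rename(columns={cols["adj_p"]: "adj_p"})
    return df


def labels_from_lfc(lfc: Sequence[float], design: Design = "ko") -> np.ndarray:
    """Binary "stabilized-by-RBP" labels from LFC signs.

    In a knockout/knockdown design (``ko``) a stabilized target loses
    expression when the RBP is removed, so LFC < 0 labels it positive; in
    an overexpression design (``oe``) the sign flips.
    """
    lfc = np.asarray(lfc, dtype=float)
    if design == "ko":
        return lfc < 0
    if design == "oe":
        return lfc > 0
    raise ValueError(f"unknown design {design!r}")


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve of ``scores`` against binary ``labels``.

    Equals the Mann-Whitney probability that a random positive outscores a
    random negative, with tied scores counted half.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present for ROC analysis")
    return float(roc_auc_score(labels, scores))


@dataclass
class CorrelationCurve:
    """Spearman rho of (LFC, score) across |LFC|-quantile cutoffs."""

    table: pd.DataFrame  # columns: quantile, cutoff, n_genes, rho

    @property
    def quantiles(self) -> np.ndarray:
        return self.table["quantile"].to_numpy()

    @property
    def rho(self) -> np.ndarray:
        return self.table["rho"].to_numpy()

    def mean_abs_rho(self) -> float:
        """Mean |rho| over cutoffs where rho is defined."""
        r = self.table["rho"].dropna()
        if r.empty:
            raise ValueError("rho undefined at every cutoff")
        return float(r.abs().mean())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def correlation_by_cutoff(
    scores: pd.Series,
    lfc: pd.Series,
    quantiles: Optional[Sequence[float]] = None,
    min_genes: int = 3,
) -> CorrelationCurve:
    """Spearman correlation of score with LFC at rising |LFC| cutoffs.

    For each quantile ``q`` of the |LFC| distribution (over genes shared
    between the two series), the gene subset with ``|lfc| >= quantile_q``
    is extracted and Spearman's rho between LFC and score computed on it.
    Subsets smaller than ``min_genes`` yield NaN rho (reported, not fatal).
    """
    if quantiles is None:
        quantiles = DEFAULT_QUANTILES
    shared = scores.index.intersection(lfc.index)
    if len(shared) < min_genes:
        raise ValueError(
            f"only {len(shared)} genes shared between scores and LFC table"
        )
    s = scores.loc[shared].astype(float)
    f = lfc.loc[shared].astype(float)
    abs_f = f.abs()
    rows = []
    for q in quantiles:
        cut = float(abs_f.quantile(q))
        mask = abs_f >= cut
        n = int(mask.sum())
        if n >= min_genes:
            rho = float(stats.spearmanr(f[mask], s[mask]).statistic)
        else:
            rho = float("nan")
        rows.append({"quantile": float(q), "cutoff": cut, "n_genes": n, "rho": rho})
    return CorrelationCurve(pd.DataFrame(rows))


class MannWhitneyResult(NamedTuple):
    U: float
    p: float


def compare_methods(
    a: Sequence[float], b: Sequence[float]
) -> MannWhitneyResult:
    """One-sided Mann-Whitney test that ``a`` is stochastically larger than ``b``.

    Intended for paired vectors of per-dataset |rho| values from two
    methods. Uses the exact null distribution when both samples have at
    most 20 values and no ties, the normal approximation otherwise;
    completely tied input returns p = 0.5 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per method")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return MannWhitneyResult(U=len(a) * len(b) / 2.0, p=0.5)
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue))
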