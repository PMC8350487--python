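"""Transcriptome-wide spatial-similarity screen.

Each gene's regional expression profile is correlated with a regional
connectivity map; the full transcriptome's score distribution serves as the
empirical null, and genes beyond k standard deviations (default 2) of its
mean form the candidate tails.  The lower tail — genes highly expressed
where connectivity is low — is the default downstream candidate list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .parcellation import RegionalMap

__all__ = ["ExpressionMatrix", "SimilarityResult", "gene_similarity", "null_and_select", "shared_genes"]

#: genes x regions expression table
ExpressionMatrix = pd.DataFrame


@dataclass
class SimilarityResult:
    scores: pd.Series  # per-gene spatial correlation, NaN for zero-variance genes
    null_mean: float | None = None
    null_sd: float | None = None
    k_sd: float = 2.0
    lower_tail: list = field(default_factory=list)
    upper_tail: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"score": self.scores})
        df["tail"] = ""
        df.loc[df.index.isin(self.lower_tail), "tail"] = "lower"
        df.loc[df.index.isin(self.upper_tail), "tail"] = "upper"
        return df


def gene_similarity(
    expr: pd.DataFrame, regional: RegionalMap, method: str = "pearson"
) -> SimilarityResult:
    """Per-gene spatial correlation across the shared, identically ordered regions.

    ``method`` is ``pearson`` (default) or ``spearman``.  Zero-variance genes
    score NaN and are excluded from the empirical null downstream.
    """
    target = regional.as_series()
    shared = [r for r in expr.columns if r in set(target.index)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared regions, got {len(shared)}")
    E = expr[shared].to_numpy(float)
    y = target.loc[shared].to_numpy(float)
    if method == "spearman":
        E = stats.rankdata(E, axis=1)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method: {method}")
    Ec = E - E.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Ec * Ec).sum(axis=1)) * np.sqrt((yc * yc).sum())
    if (yc == 0).all():
        raise ValueError("regional map has zero variance over shared regions")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ec @ yc) / denom
    r[denom == 0] = np.nan
    scores = pd.Series(np.clip(r, -1.0, 1.0), index=expr.index, name="score")
    scores[np.isnan(r)] = np.nan
    return SimilarityResult(scores=scores)


def null_and_select(res: SimilarityResult, k_sd: float = 2.0) -> SimilarityResult:
    """Empirical-null moments from all scored genes; populate the +/- k SD tails."""
    scored = res.scores.dropna()
    if len(scored) < 100:
        raise ValueError(f"need >= 100 scored genes for stable null moments, got {len(scored)}")
    mu = float(scored.mean())
    sd = float(scored.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null: all similarity scores identical")
    lower = scored.index[scored < mu - k_sd * sd].tolist()
    upper = scored.index[scored > mu + k_sd * sd].tolist()
    return SimilarityResult(
        scores=res.scores, null_mean=mu, null_sd=sd, k_sd=k_sd,
        lower_tail=lower, upper_tail=upper,
    )


def shared_genes(a, b) -> list:
    """Set intersection preserving the input order of ``a``."""
    bset = set(b)
    return [g for g in a if g in bset]
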