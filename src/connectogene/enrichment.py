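"""Overrepresentation analysis of candidate gene lists against annotation sets.

For each term with K genes in a background universe of N, a candidate list
of n genes containing k term members is scored by

    FE = (k / n) / (K / N)                         (fold enrichment)
    p  = P[X >= k],  X ~ Hypergeometric(N, K, n)   (one-sided Fisher exact)

with Bonferroni correction across tested terms.  A term is reported
significant when FE exceeds ``fe_min`` (default 2) and the corrected q
stays under ``q_max`` (default 0.05) — the convention of PANTHER-style
overrepresentation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from scipy import stats

__all__ = ["AnnotationCollection", "read_gmt", "write_gmt", "overrepresentation"]


@dataclass
class AnnotationCollection:
    terms: dict[str, tuple[str, set]] = field(default_factory=dict)  # id -> (name, genes)
    background: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.background:
            self.background = set().union(*(g for _, g in self.terms.values())) if self.terms else set()
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid} is empty")
            stray = genes - self.background
            if stray:
                raise ValueError(f"term {tid} has genes outside the background: {sorted(stray)[:5]}")


def read_gmt(path) -> AnnotationCollection:
    """Standard GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, tuple[str, set]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
            terms[fields[0]] = (fields[1], set(g for g in fields[2:] if g))
    return AnnotationCollection(terms=terms)


def write_gmt(ann: AnnotationCollection, path) -> None:
    with open(path, "w") as fh:
        for tid, (name, genes) in ann.terms.items():
            fh.write("\t".join([tid, name, *sorted(genes)]) + "\n")


def overrepresentation(
    candidates: Iterable,
    ann: AnnotationCollection,
    fe_min: float = 2.0,
    q_max: float = 0.05,
    background: Iterable | None = None,
) -> pd.DataFrame:
    """One-sided overrepresentation test of ``candidates`` against every term.

    ``background`` overrides the collection's universe (by default the
    screen that produced the candidates defines it).  Returns a DataFrame
    indexed by term id with k, K, n, N, fold_enrichment, p, q (Bonferroni)
    and a ``significant`` flag, sorted by p.
    """
    bg = set(background) if background is not None else set(ann.background)
    cand = list(dict.fromkeys(candidates))
    stray = [g for g in cand if g not in bg]
    if stray:
        raise ValueError(f"candidate genes absent from background: {stray[:10]}")
    n = len(cand)
    N = len(bg)
    cand_set = set(cand)
    rows = []
    for tid, (name, genes) in ann.terms.items():
        term = genes & bg
        K = len(term)
        if K == 0:
            continue
        k = len(term & cand_set)
        fe = (k / n) / (K / N) if n else 0.0
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((tid, name, k, K, n, N, fe, p))
    df = pd.DataFrame(
        rows, columns=["term_id", "name", "k", "K", "n", "N", "fold_enrichment", "p"]
    ).set_index("term_id")
    n_terms = len(df)
    df["q"] = (df["p"] * n_terms).clip(upper=1.0)
    df["significant"] = (df["fold_enrichment"] > fe_min) & (df["q"] < q_max)
    return df.sort_values("p")
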