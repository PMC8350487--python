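"""Semantic-distance creativity scoring.

Divergent-thinking (DT) responses to prompts (Alternate Uses Task items)
are scored by semantic distance: 1 minus the cosine similarity between the
embedding of the prompt and the embedding of the response, so identical
meanings score 0 and opposed meanings score 2.  Multi-word responses use
the element-wise mean of their word vectors (additive composition).  Five
vector spaces are scored in parallel; a latent DT score per subject is the
first principal component of the column-standardized subject-by-space
distance matrix, sign-aligned so loadings are predominantly positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

__all__ = [
    "VectorSpace",
    "ResponseRecord",
    "semantic_distance",
    "multiword_vector",
    "score_responses",
    "aggregate_subject",
    "latent_dt_score",
    "read_vector_space_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class VectorSpace:
    name: str
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dims = {v.size for v in self.vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"space {self.name}: inconsistent vector dimensions {dims}")
        for w, v in self.vectors.items():
            if np.linalg.norm(v) == 0:
                raise ValueError(f"space {self.name}: zero vector for word {w!r}")

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[word]


@dataclass
class ResponseRecord:
    subject_id: str
    item: str
    response: str
    distances: dict[str, float] = field(default_factory=dict)  # space name -> distance


def semantic_distance(prompt_vec: np.ndarray, response_vec: np.ndarray) -> float:
    """1 - cosine similarity; 0 identical, 1 orthogonal, 2 antiparallel."""
    u = np.asarray(prompt_vec, dtype=float)
    v = np.asarray(response_vec, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must share a dimension")
    uu, vv = float(u @ u), float(v @ v)
    if uu == 0 or vv == 0:
        raise ValueError("zero-norm vector has no direction")
    # sqrt of the product of squared norms keeps the parallel /
    # antiparallel / orthogonal cases exact in floating point
    cos = float(u @ v) / float(np.sqrt(uu * vv))
    return 1.0 - max(-1.0, min(1.0, cos))


def multiword_vector(words, space: VectorSpace) -> np.ndarray:
    """Element-wise mean of the resolvable word vectors."""
    if isinstance(words, str):
        words = words.split()
    found = [space[w] for w in words if w in space]
    skipped = [w for w in words if w not in space]
    if skipped:
        logger.info("space %s: unresolvable words %s", space.name, skipped)
    if not found:
        raise ValueError(f"no word of {list(words)!r} resolves in space {space.name}")
    return np.mean(np.stack(found), axis=0)


def score_responses(responses: pd.DataFrame, spaces: list[VectorSpace]) -> list[ResponseRecord]:
    """Score (subject_id, item, response) rows in every space where both
    prompt and response resolve."""
    records = []
    for row in responses.itertuples(index=False):
        rec = ResponseRecord(str(row.subject_id), str(row.item), str(row.response))
        for sp in spaces:
            try:
                d = semantic_distance(multiword_vector(rec.item, sp), multiword_vector(rec.response, sp))
            except ValueError:
                continue
            rec.distances[sp.name] = d
        records.append(rec)
    return records


def aggregate_subject(records: list[ResponseRecord]) -> pd.DataFrame:
    """Mean distance per subject and space over all scored responses.

    Subjects with no scored response are excluded with a logged notice.
    """
    rows = [
        {"subject_id": r.subject_id, "space": s, "distance": d}
        for r in records
        for s, d in r.distances.items()
    ]
    scored = {r["subject_id"] for r in rows}
    for r in records:
        if r.subject_id not in scored:
            logger.info("subject %s has no scored response; excluded", r.subject_id)
    if not rows:
        raise ValueError("no scored responses")
    long = pd.DataFrame(rows)
    return long.pivot_table(index="subject_id", columns="space", values="distance", aggfunc="mean")


def latent_dt_score(distances: pd.DataFrame, method: str = "pca") -> pd.Series:
    """Latent DT score: shared variance of the per-space distance columns.

    Default is the first principal component of the column-standardized
    matrix (``method='fa'`` fits a one-factor model instead), sign-aligned
    so that loadings are predominantly positive.
    """
    if distances.shape[1] < 2 or distances.shape[0] < 3:
        raise ValueError("need >= 2 spaces and >= 3 subjects")
    sd = distances.std(ddof=1)
    flat = sd[sd == 0]
    if len(flat):
        raise ValueError(f"constant distance column for space(s): {list(flat.index)}")
    Z = ((distances - distances.mean()) / sd).to_numpy(float)
    if method == "pca":
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        loadings = Vt[0]
        score = Z @ loadings
    elif method == "fa":
        fa = FactorAnalysis(n_components=1, random_state=0)
        score = fa.fit_transform(Z)[:, 0]
        loadings = fa.components_[0]
    else:
        raise ValueError(f"unknown method: {method}")
    if loadings.sum() < 0:
        score = -score
    return pd.Series(score, index=distances.index, name="dt_score")


def read_vector_space_tsv(path, name: str | None = None) -> VectorSpace:
    """TSV of word then coordinates, no header."""
    df = pd.read_csv(path, sep="\t", header=None)
    vectors = {str(r[0]): np.asarray(r[1:], dtype=float) for r in df.itertuples(index=False)}
    return VectorSpace(name=name or str(path), vectors=vectors)
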