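"""Synthetic inputs with planted effects for every pipeline stage.

The generators emulate the study design end to end: a modular ("planted
partition") connectivity backbone; a resting-scan cohort whose per-subject
time series follow that backbone, with links incident to a designated
module weakened in proportion to the subject's divergent-thinking (DT)
score (a negative WD-DT effect); a gene-by-region expression matrix in
which planted genes are anti-correlated with a supplied regional map;
annotation terms and an interaction network concentrated on the planted
genes; and five word-embedding spaces with responses whose prompt-response
angle encodes a planted novelty trait.

Every generator is a pure function of its spec (seed included): the same
spec yields byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .connectivity_core import AssociationMatrix
from .parcellation import RegionalMap
from .enrichment import AnnotationCollection

__all__ = [
    "SyntheticSpec",
    "generate_modular_network",
    "generate_cohort",
    "generate_expression",
    "generate_annotations",
    "generate_interactome",
    "generate_embeddings",
]

logger = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic cohort.

    Cohort sizes are scaled down from a full resting-state study (175
    subjects, 5,742 voxel nodes) to sizes a laptop handles: 60 subjects,
    120 nodes in 4 modules.  Timepoints default to 150 — a 5-minute scan
    at TR = 2 s.  Ages draw from N(22.7, 6.4) and sex is ~73% female,
    matching a young, mostly-female cohort.  The planted DT effect scales
    link weights incident to the nodes of one module by
    (1 + effect_size * z(DT)), so effect_size = -0.5 plants the negative
    WD-DT association the regression stage must recover.
    """

    n_subjects: int = 60
    n_nodes: int = 120
    n_modules: int = 4
    n_timepoints: int = 150
    effect_nodes: tuple = ()  # empty -> all nodes of module 0
    effect_size: float = -0.5
    n_genes: int = 2000
    n_planted: int = 50
    expr_noise_sd: float = 0.5
    n_regions: int = 68
    p_within: float = 0.35
    p_between: float = 0.06
    w_within: tuple = (0.4, 0.9)
    w_between: tuple = (0.1, 0.4)
    cov_scale: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 2:
            raise ValueError("need at least 2 modules")
        if not (0 <= self.p_between < self.p_within <= 1):
            raise ValueError("require within-module edge probability > between-module")
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted exceeds n_genes")
        if self.effect_nodes and max(self.effect_nodes) >= self.n_nodes:
            raise ValueError("effect_nodes outside the node range")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def membership(self) -> np.ndarray:
        """Module label per node, contiguous blocks."""
        return np.arange(self.n_nodes) * self.n_modules // self.n_nodes

    def resolved_effect_nodes(self) -> np.ndarray:
        if self.effect_nodes:
            return np.asarray(sorted(self.effect_nodes), dtype=int)
        return np.flatnonzero(self.membership() == 0)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["effect_nodes"] = list(d["effect_nodes"])
        d["w_within"] = list(d["w_within"])
        d["w_between"] = list(d["w_between"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("effect_nodes", "w_within", "w_between"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _connected(W: np.ndarray) -> bool:
    from scipy.sparse.csgraph import connected_components

    ncomp, _ = connected_components((W > 0).astype(int), directed=False)
    return ncomp == 1


def generate_modular_network(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> AssociationMatrix:
    """Weighted planted-partition graph: dense strong links within modules,
    sparse weaker links between them.  Retries up to 50 draws for a
    connected realization."""
    rng = rng or spec.rng(stream=1)
    member = spec.membership()
    n = spec.n_nodes
    same = member[:, None] == member[None, :]
    for _ in range(50):
        p = np.where(same, spec.p_within, spec.p_between)
        present = rng.random((n, n)) < p
        w = np.where(
            same,
            rng.uniform(*spec.w_within, size=(n, n)),
            rng.uniform(*spec.w_between, size=(n, n)),
        )
        W = np.triu(present * w, k=1)
        W = W + W.T
        if spec.p_between == 0 or _connected(W):
            return AssociationMatrix(W, [f"n{i}" for i in range(n)])
    raise ValueError("could not draw a connected modular network in 50 attempts")


def _nearest_pd_correlation(S: np.ndarray, floor: float = 0.05) -> np.ndarray:
    """Eigenvalue-floor repair, rescaled back to unit diagonal."""
    vals, vecs = np.linalg.eigh(S)
    if vals.min() < floor:
        logger.info("target covariance repaired: min eigenvalue %.3g", vals.min())
        vals = np.maximum(vals, floor)
        S = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
    return S


def generate_cohort(spec: SyntheticSpec):
    """Per-subject time series plus a phenotype table.

    Returns ``(timeseries, pheno, base_network, effect_nodes)`` where
    ``timeseries`` is (n_subjects, n_timepoints, n_nodes).  Each subject's
    series is multivariate Gaussian with correlation I + cov_scale * W_s
    (PD-repaired), where W_s is the base modular network with links
    incident to the effect nodes scaled by (1 + effect_size * z(DT_s)),
    clipped at 0.05.
    """
    base = generate_modular_network(spec)
    effect = spec.resolved_effect_nodes()
    rng = spec.rng(stream=2)
    n_sub = spec.n_subjects

    dt = rng.standard_normal(n_sub)
    z = (dt - dt.mean()) / dt.std(ddof=0)
    age = rng.normal(22.7, 6.4, size=n_sub).clip(18, 60)
    sex = rng.choice(["F", "M"], size=n_sub, p=[0.73, 0.27])
    pheno = pd.DataFrame(
        {
            "subject_id": [f"sub{i:03d}" for i in range(n_sub)],
            "dt_score": dt,
            "age": age,
            "sex": sex,
        }
    )

    incident = np.zeros((spec.n_nodes, spec.n_nodes), dtype=bool)
    incident[effect, :] = True
    incident[:, effect] = True
    np.fill_diagonal(incident, False)

    series = np.empty((n_sub, spec.n_timepoints, spec.n_nodes))
    for i in range(n_sub):
        factor = max(1.0 + spec.effect_size * z[i], 0.05)
        Ws = np.where(incident, base.r * factor, base.r)
        S = np.eye(spec.n_nodes) + spec.cov_scale * Ws
        S = _nearest_pd_correlation(S)
        L = np.linalg.cholesky(S)
        series[i] = rng.standard_normal((spec.n_timepoints, spec.n_nodes)) @ L.T
    return series, pheno, base, effect


def generate_expression(
    spec: SyntheticSpec, regional: RegionalMap, rng: np.random.Generator | None = None
):
    """Gene-by-region expression with planted anti-correlated genes.

    Planted genes are -standardize(map) plus Gaussian noise of sd
    ``expr_noise_sd``; background genes are independent standard Gaussians.
    Returns ``(expression DataFrame, planted gene ids)``.
    """
    rng = rng or spec.rng(stream=3)
    m = regional.values
    sd = m.std(ddof=0)
    if sd == 0:
        raise ValueError("regional map is constant; cannot standardize")
    mz = (m - m.mean()) / sd
    n_reg = m.size
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    planted_idx = rng.choice(spec.n_genes, size=spec.n_planted, replace=False)
    E = rng.standard_normal((spec.n_genes, n_reg))
    E[planted_idx] = -mz + spec.expr_noise_sd * rng.standard_normal((spec.n_planted, n_reg))
    expr = pd.DataFrame(E, index=gene_ids, columns=list(regional.region_ids))
    planted = [gene_ids[i] for i in sorted(planted_idx)]
    return expr, planted


def generate_annotations(
    planted,
    background,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    n_decoys: int = 25,
    decoy_size: int = 50,
    planted_in_term: int | None = None,
) -> AnnotationCollection:
    """One term concentrated in the planted genes plus uniform decoy terms."""
    rng = rng or spec.rng(stream=4)
    planted = list(planted)
    background = list(background)
    take = planted_in_term if planted_in_term is not None else max(1, int(0.8 * len(planted)))
    take = min(take, len(planted))
    core = list(rng.choice(planted, size=take, replace=False))
    pad = list(rng.choice(background, size=min(10, len(background)), replace=False))
    terms = {"TERM_PLANTED": ("planted process", set(core) | set(pad))}
    for d in range(n_decoys):
        size = min(decoy_size, len(background))
        terms[f"TERM_DECOY{d:03d}"] = (
            f"decoy process {d}",
            set(rng.choice(background, size=size, replace=False)),
        )
    return AnnotationCollection(terms=terms, background=set(planted) | set(background))


def generate_interactome(
    planted,
    background,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    p_core: float = 0.5,
    p_periphery: float = 0.01,
    p_cross: float = 0.02,
):
    """Dense core among planted genes, sparse periphery among background.

    Returns a networkx Graph with confidence weights in (0, 1].
    """
    import networkx as nx

    rng = rng or spec.rng(stream=5)
    planted = list(planted)
    background = list(background)
    G = nx.Graph()
    G.add_nodes_from(planted + background)
    nodes = planted + background
    is_core = np.array([g in set(planted) for g in nodes])
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if is_core[i] and is_core[j]:
                p, lo = p_core, 0.5
            elif is_core[i] or is_core[j]:
                p, lo = p_cross, 0.1
            else:
                p, lo = p_periphery, 0.1
            if rng.random() < p:
                G.add_edge(nodes[i], nodes[j], weight=float(rng.uniform(lo, 1.0)))
    return G


def generate_embeddings(
    spec: SyntheticSpec,
    vocab_size: int = 300,
    dim: int = 50,
    n_spaces: int = 5,
    space_noise: float = 0.07,
    items: tuple = ("box", "rope"),
    novelty_slope: float = 0.15,
    rng: np.random.Generator | None = None,
):
    """Five vector spaces as noisy rotations of one base space, plus prompt
    /response pairs whose angle encodes a planted per-subject novelty trait.

    Returns ``(spaces, responses, novelty)`` — a list of VectorSpace, a
    DataFrame of (subject_id, item, response), and the per-subject latent
    novelty Series the distance scores should recover.
    """
    from .semantic import VectorSpace

    rng = rng or spec.rng(stream=6)
    words = list(items) + [f"w{i:04d}" for i in range(vocab_size)]
    base = {}
    for w in words:
        v = rng.standard_normal(dim)
        base[w] = v / np.linalg.norm(v)

    novelty = pd.Series(
        rng.standard_normal(spec.n_subjects),
        index=[f"sub{i:03d}" for i in range(spec.n_subjects)],
        name="novelty",
    )
    rows = []
    for sid, nov in novelty.items():
        target_d = float(np.clip(0.5 + novelty_slope * nov, 0.05, 0.95))
        cos = 1.0 - target_d
        for item in items:
            u = base[item]
            r = rng.standard_normal(dim)
            r -= (r @ u) * u
            r /= np.linalg.norm(r)
            resp_word = f"resp_{sid}_{item}"
            base[resp_word] = cos * u + np.sqrt(1.0 - cos**2) * r
            rows.append({"subject_id": sid, "item": item, "response": resp_word})
    responses = pd.DataFrame(rows)

    spaces = []
    for s in range(n_spaces):
        vecs = {}
        for w, v in base.items():
            noisy = v + space_noise * rng.standard_normal(dim)
            vecs[w] = noisy / np.linalg.norm(noisy)
        spaces.append(VectorSpace(name=f"space{s}", vectors=vecs))
    return spaces, responses, novelty
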