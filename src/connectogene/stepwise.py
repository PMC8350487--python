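"""Stepwise, local and distributed connectivity chains and weighted-degree maps.

Stepwise functional connectivity (SFC) measures how strongly two nodes are
linked through walks of exactly s steps.  Starting from the fully
preprocessed association matrix NSFC_1, each further step is the matrix
product with NSFC_1 (diagonal zeroed, then min-max normalized):

    SFC_s(i,j)  = sum_k NSFC_{s-1}(i,k) NSFC_1(k,j)     (i != j)
    NSFC_s      = (SFC_s - min SFC_s) / (max SFC_s - min SFC_s)

The local chain restricts step 1 to links that also have a 2-step
alternative path (links inside modules) and propagates with its own first
step; the distributed chain seeds from node pairs with no 1- or 2-step
connection but a 4-step one (links bridging modules) and propagates with
NSFC_1 — the asymmetry between the two recursions is deliberate.

Weighted degree (WD) per node is the sum of its link weights over the
normalized step matrices of steps 2-7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity_core import AssociationMatrix

__all__ = [
    "StepwiseChain",
    "LocalChain",
    "DistributedChain",
    "WeightedDegreeMap",
    "stepwise_chain",
    "local_chain",
    "distributed_chain",
    "weighted_degree",
]

#: post-normalization zeros are exact minima, but products accumulate rounding
ZERO_TOL = 1e-12

_WD_STEPS = range(2, 8)


@dataclass
class StepwiseChain:
    matrices: list[np.ndarray]
    node_ids: list[str] = field(default_factory=list)

    @property
    def max_step(self) -> int:
        return len(self.matrices)

    def step(self, s: int) -> np.ndarray:
        """1-based access: step(1) is NSFC_1."""
        return self.matrices[s - 1]


@dataclass
class LocalChain(StepwiseChain):
    mask_count: int = 0


@dataclass
class DistributedChain(StepwiseChain):
    pass


@dataclass
class WeightedDegreeMap:
    values: np.ndarray
    flavor: str = "local"  # local | distributed | stepwise
    subject_id: str | None = None
    node_ids: list[str] = field(default_factory=list)


def _check_preprocessed(r: np.ndarray) -> None:
    off = r[~np.eye(r.shape[0], dtype=bool)]
    if off.min() < -ZERO_TOL or off.max() > 1 + 1e-9:
        raise ValueError("association matrix must be preprocessed to [0, 1]")
    if not np.allclose(r, r.T):
        raise ValueError("association matrix must be symmetric")


def _scale01(m: np.ndarray, what: str, step: int) -> np.ndarray:
    """Chain-step normalization (m - min) / (max - min) over the full matrix.

    The step equations define the diagonal as 0 (i != j), so for the
    nonnegative walk-weight matrices the minimum is exactly 0 and this is a
    pure rescale by the maximum — zero entries (no walk) stay zero, which
    the local/distributed support masks rely on.
    """
    out = m.copy()
    np.fill_diagonal(out, 0.0)
    lo, hi = out.min(), out.max()
    if hi - lo <= 0:
        raise ValueError(f"{what} chain degenerate at step {step}: constant matrix")
    out = (out - lo) / (hi - lo)
    np.fill_diagonal(out, 0.0)
    return out


def _advance(prev: np.ndarray, propagator: np.ndarray, step: int, what: str) -> np.ndarray:
    prod = prev @ propagator
    # zeroing the diagonal before each product drops node-specific self-walk
    # terms, which leaves the raw product slightly asymmetric; average the
    # i->j and j->i walk weights (supports are identical either way) to keep
    # every step matrix an undirected association
    prod = (prod + prod.T) / 2.0
    np.fill_diagonal(prod, 0.0)
    return _scale01(prod, what, step)


def stepwise_chain(a: AssociationMatrix, max_step: int = 7) -> StepwiseChain:
    """NSFC_1..NSFC_S from a preprocessed association matrix."""
    if max_step < 1:
        raise ValueError("max_step must be >= 1")
    _check_preprocessed(a.r)
    mats = [a.r.copy()]
    for s in range(2, max_step + 1):
        mats.append(_advance(mats[-1], mats[0], s, "stepwise"))
    return StepwiseChain(matrices=mats, node_ids=list(a.node_ids))


def local_chain(a: AssociationMatrix, nsfc: StepwiseChain, max_step: int = 7) -> LocalChain:
    """Chain restricted to direct links with a 2-step alternative path.

    NLC_1 keeps NSFC_1 only where NSFC_2 is nonzero (the link has at least
    one common neighbour), rescaled so the surviving weights span [0, 1].
    """
    if nsfc.max_step < 2:
        raise ValueError("stepwise chain must include at least 2 steps")
    mask = np.abs(nsfc.step(2)) > ZERO_TOL
    np.fill_diagonal(mask, False)
    seed = np.where(mask, a.r, 0.0)
    if np.abs(seed).max() <= ZERO_TOL:
        raise ValueError("empty local mask: no direct link has a 2-step alternative path")
    count = int(np.count_nonzero(seed) // 2)
    mats = [_scale01(seed, "local", 1)]
    for s in range(2, max_step + 1):
        mats.append(_advance(mats[-1], mats[0], s, "local"))
    return LocalChain(matrices=mats, node_ids=list(a.node_ids), mask_count=count)


def distributed_chain(a: AssociationMatrix, nsfc: StepwiseChain, max_step: int = 7) -> DistributedChain:
    """Chain seeded from pairs with no 1- or 2-step walk but a 4-step one.

    NDC_1 takes NSFC_4 where NSFC_1 and NSFC_2 are both zero; further steps
    propagate with NSFC_1 (not with NDC_1).
    """
    if nsfc.max_step < 4:
        raise ValueError("stepwise chain must include at least 4 steps")
    mask = (np.abs(nsfc.step(1)) <= ZERO_TOL) & (np.abs(nsfc.step(2)) <= ZERO_TOL)
    np.fill_diagonal(mask, False)
    seed = np.where(mask, nsfc.step(4), 0.0)
    if np.abs(seed).max() <= ZERO_TOL:
        raise ValueError("empty distributed seed: no node pair is distributed at this scale")
    mats = [_scale01(seed, "distributed", 1)]
    for s in range(2, max_step + 1):
        mats.append(_advance(mats[-1], nsfc.step(1), s, "distributed"))
    return DistributedChain(matrices=mats, node_ids=list(a.node_ids))


def weighted_degree(chain: StepwiseChain, flavor: str | None = None) -> WeightedDegreeMap:
    """Per-node sum of link weights over the normalized step-2..7 matrices."""
    if chain.max_step < max(_WD_STEPS):
        raise ValueError(f"chain has {chain.max_step} steps; weighted degree needs 7")
    wd = np.zeros(chain.step(1).shape[0])
    for s in _WD_STEPS:
        wd += chain.step(s).sum(axis=1)
    if flavor is None:
        flavor = {LocalChain: "local", DistributedChain: "distributed"}.get(type(chain), "stepwise")
    return WeightedDegreeMap(values=wd, flavor=flavor, node_ids=list(chain.node_ids))
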