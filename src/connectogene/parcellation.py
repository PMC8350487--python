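"""Summarize a node-level statistic map into region-level means.

Used to project node maps onto a cortical parcellation (e.g. the 68-region
Desikan-Killiany atlas) so they can be compared with regional gene
expression.  Region values are unweighted arithmetic means of member nodes;
label 0 marks unassigned nodes, which are ignored; regions with no members
are omitted, not zero-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RegionalMap", "parcel_mean", "read_labels_tsv"]

logger = logging.getLogger(__name__)


@dataclass
class RegionalMap:
    values: np.ndarray
    region_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.region_ids) != self.values.size:
            raise ValueError("region_ids length does not match values")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.region_ids, name="value")


def parcel_mean(node_map: np.ndarray, labels: np.ndarray, region_ids=None) -> RegionalMap:
    """Mean of ``node_map`` within each region of ``labels`` (0 = unassigned)."""
    node_map = np.asarray(node_map, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != node_map.shape:
        raise ValueError("labels must cover all nodes")
    assigned = labels != 0 if labels.dtype.kind in "iuf" else labels.astype(str) != "0"
    s = pd.Series(node_map[assigned]).groupby(pd.Series(labels[assigned])).mean()
    if region_ids is not None:
        missing = [r for r in region_ids if r not in s.index]
        if missing:
            logger.info("regions with no member nodes omitted: %s", missing)
        s = s.loc[[r for r in region_ids if r in s.index]]
    return RegionalMap(values=s.to_numpy(), region_ids=list(s.index))


def read_labels_tsv(path) -> pd.DataFrame:
    """TSV of (node_id, region_id)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("label file needs node_id and region_id columns")
    return df
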