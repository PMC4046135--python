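"""Kinase inhibition sensitivity scoring (KISS) and addiction networks.

KISS aggregates one sample's differential drug sensitivity (dDSS) onto
kinase targets through a binary drug x kinase selectivity matrix: for each
kinase the dDSS of the selective inhibitors that target it (and whose
response distribution shows significant positive skew across the cohort) is
averaged over the n_k contributing inhibitors.  High-KISS kinases and the
similarity of their inhibitor-selectivity profiles form the sample's
addiction network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TargetMatrix",
    "KissProfile",
    "kiss_profile",
    "addiction_network",
    "export_network",
    "read_target_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetMatrix:
    """Binary drug x kinase selectivity matrix.

    Affinity matrices (nM) are binarized with ``from_affinity`` at a
    user-set threshold (default: affinity < 1000 nM means "targets").
    """

    values: pd.DataFrame  # drugs x kinases, entries in {0, 1}

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.has_duplicates or vals.columns.has_duplicates:
            raise ValueError("drug and kinase ids must be unique")
        arr = vals.to_numpy()
        if not np.isin(arr[np.isfinite(arr)], (0, 1)).all():
            raise ValueError("target matrix must be binary; use from_affinity to threshold")

    @classmethod
    def from_affinity(cls, affinities: pd.DataFrame, threshold_nM: float = 1000.0) -> "TargetMatrix":
        binary = (affinities < threshold_nM).astype(int)
        binary[affinities.isna()] = 0
        return cls(binary)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def kinase_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class KissProfile:
    """Per-kinase addiction scores for one sample.

    Kinases with no eligible targeting inhibitor are absent (not zero);
    ``n_contributing`` records how many inhibitors informed each score.
    """

    sample_id: str
    kiss_of: Mapping[str, float]
    n_contributing: Mapping[str, int] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.kiss_of), name=self.sample_id, dtype=float)


def kiss_profile(ddss: pd.Series, targets: TargetMatrix, skew_p: pd.Series,
                 alpha: float = 0.05, sample_id: str = "",
                 aggregate: str = "mean") -> KissProfile:
    """Compute the KISS profile of one sample.

    ``ddss`` maps drug -> differential score for the sample; ``skew_p`` maps
    drug -> one-sided D'Agostino p of that drug's cohort distribution.
    Eligible inhibitors are those with ``skew_p < alpha``; per kinase the
    eligible targeting inhibitors' dDSS is aggregated (mean by default,
    ``aggregate='sum'`` for the raw sum).
    """
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    common = [d for d in targets.drug_ids if d in ddss.index and d in skew_p.index]
    eligible = [d for d in common
                if np.isfinite(skew_p[d]) and skew_p[d] < alpha and np.isfinite(ddss[d])]
    if not eligible:
        logger.warning("sample %s: no inhibitor passes the skewness eligibility filter",
                       sample_id or "<unnamed>")
        return KissProfile(sample_id, {}, {})
    sub = targets.values.loc[eligible]
    scores: dict[str, float] = {}
    counts: dict[str, int] = {}
    for kinase in targets.kinase_ids:
        hits = sub.index[sub[kinase] == 1]
        if len(hits) == 0:
            continue
        vals = ddss[hits].to_numpy(dtype=float)
        total = float(vals.sum())
        scores[kinase] = total / len(hits) if aggregate == "mean" else total
        counts[kinase] = int(len(hits))
    return KissProfile(sample_id, scores, counts)


def addiction_network(profile: KissProfile, targets: TargetMatrix,
                      kiss_threshold: float = 5.0, corr_threshold: float = 0.5,
                      expressed: Sequence[str] | None = None) -> nx.Graph:
    """Build the sample's kinase addiction network.

    Nodes are kinases with KISS strictly above ``kiss_threshold`` (optionally
    intersected with an expressed-kinase list); an undirected edge joins two
    kinases whose drug-selectivity columns have Spearman correlation above
    ``corr_threshold``.  Node attribute ``kiss``, edge attribute ``rho``.
    """
    nodes = [k for k, v in profile.kiss_of.items() if v > kiss_threshold]
    if expressed is not None:
        allowed = set(expressed)
        nodes = [k for k in nodes if k in allowed]
    nodes = [k for k in nodes if k in targets.values.columns]
    g = nx.Graph(sample_id=profile.sample_id)
    for k in nodes:
        g.add_node(k, kiss=float(profile.kiss_of[k]),
                   n_contributing=int(profile.n_contributing.get(k, 0)))
    for i, ka in enumerate(nodes):
        for kb in nodes[i + 1:]:
            col_a = targets.values[ka].to_numpy(dtype=float)
            col_b = targets.values[kb].to_numpy(dtype=float)
            if np.ptp(col_a) == 0 or np.ptp(col_b) == 0:
                continue
            rho = sps.spearmanr(col_a, col_b).statistic
            if np.isfinite(rho) and rho > corr_threshold:
                g.add_edge(ka, kb, rho=float(rho))
    return g


def export_network(network: nx.Graph, path, fmt: str = "SIF") -> None:
    """Write a network as SIF (``a pp b`` lines, isolated nodes bare) or GraphML."""
    fmt = fmt.upper()
    if fmt == "SIF":
        lines = [f"{a}\tpp\t{b}" for a, b in sorted(network.edges())]
        lines += [str(n) for n in sorted(network.nodes()) if network.degree(n) == 0]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "GRAPHML":
        nx.write_graphml(network, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}; use SIF or GraphML")


def read_target_matrix(path, affinity_threshold_nM: float | None = None) -> TargetMatrix:
    """Read a drug x kinase CSV (first column = drug id).

    Binary matrices load directly; pass ``affinity_threshold_nM`` to
    binarize an affinity matrix.
    """
    df = pd.read_csv(path, index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if affinity_threshold_nM is not None:
        return TargetMatrix.from_affinity(df, affinity_threshold_nM)
    return TargetMatrix(df)
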