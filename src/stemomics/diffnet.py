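"""Differential co-expression networks between two conditions.

For a pathway gene panel, pairwise Pearson correlations are computed
separately within the parental (P) and stem-like (S) samples.  Negative
correlations are removed — an edge exists only where r > 0 — and the
*differential* edge set keeps gene pairs whose correlation gained more than
a threshold tau (default 0.6) in one condition: the default ``S_gain``
direction selects pairs with r_S > 0 and r_S - r_P > tau, i.e. genes
strongly co-expressed in the stem-like cells but not in the parental cells.
Hubs are the highest-degree genes of the selected edge set.

Correlations over fewer than ~8 samples per condition are extremely noisy;
the constructor demands >= 3 and warns loudly below 8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import FeatureMatrix, GeneSet, SampleSheet

logger = logging.getLogger("stemomics")

__all__ = [
    "condition_correlations",
    "positive_filter",
    "select_differential_edges",
    "DiffNetwork",
    "build_diffnet",
    "hub_ranking",
]

Pair = frozenset


def _resolve_genes(X: FeatureMatrix, genes) -> list[str]:
    if genes is None:
        return list(X.features)
    members = genes.members if isinstance(genes, GeneSet) else list(genes)
    present = [g for g in members if g in X.features]
    absent = [g for g in members if g not in X.features]
    if absent:
        logger.warning("dropping %d gene-set member(s) absent from the "
                       "matrix: %s", len(absent), ", ".join(absent[:10]))
    if not present:
        raise ValueError("no gene-set members present in the matrix")
    return present


def condition_correlations(X: FeatureMatrix, sheet: SampleSheet, genes=None,
                           condition: str = "S") -> pd.DataFrame:
    """Pairwise Pearson r between panel genes over one condition's samples.

    Zero-variance genes get missing (NaN) off-diagonal entries; the diagonal
    is always 1.  Requires >= 3 samples in the condition (warns below 8).
    """
    panel = _resolve_genes(X, genes)
    samples = [s for s in X.samples if s in set(sheet.samples_in(condition))]
    if len(samples) < 3:
        raise ValueError(
            f"condition {condition!r} has {len(samples)} samples; "
            "need >= 3 for correlations"
        )
    if len(samples) < 8:
        logger.warning(
            "condition %s: only %d samples — pairwise correlations at this "
            "n are extremely noisy", condition, len(samples),
        )
    sub = X.subset_features(panel).subset_samples(samples)
    V = sub.values
    if np.isnan(V).any():
        raise ValueError("correlation input contains missing values")
    sd = V.std(axis=1, ddof=1)
    degenerate = np.isclose(sd, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(V)
    R = np.clip(R, -1.0, 1.0)
    for i in np.nonzero(degenerate)[0]:
        logger.warning("gene %s has zero variance in condition %s; "
                       "correlations set missing", panel[i], condition)
        R[i, :] = np.nan
        R[:, i] = np.nan
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=panel, columns=panel)


def positive_filter(r_matrix: pd.DataFrame) -> set[Pair]:
    """Edges with strictly positive correlation; r = 0 and missing excluded."""
    genes = list(r_matrix.index)
    R = r_matrix.to_numpy()
    edges: set[Pair] = set()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if R[i, j] > 0:
                edges.add(Pair((genes[i], genes[j])))
    return edges


def select_differential_edges(r_P: pd.DataFrame, r_S: pd.DataFrame,
                              tau: float = 0.6,
                              direction: str = "S_gain") -> set[Pair]:
    """Gene pairs whose correlation gained more than tau in one condition.

    ``S_gain``: r_S > 0 and r_S - r_P > tau (strict).  ``P_gain`` is the
    mirror image; ``both`` is the union.  Pairs with a missing correlation
    on either side never qualify.
    """
    if not (0.0 < tau < 2.0):
        raise ValueError(f"tau must lie in (0, 2), got {tau}")
    if list(r_P.index) != list(r_S.index) or r_P.shape != r_S.shape:
        raise ValueError("correlation matrices must share the same gene order")
    if direction not in ("S_gain", "P_gain", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    genes = list(r_P.index)
    RP, RS = r_P.to_numpy(), r_S.to_numpy()
    selected: set[Pair] = set()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            rp, rs = RP[i, j], RS[i, j]
            if np.isnan(rp) or np.isnan(rs):
                continue
            s_gain = rs > 0 and (rs - rp) > tau
            p_gain = rp > 0 and (rp - rs) > tau
            if (direction == "S_gain" and s_gain) or \
               (direction == "P_gain" and p_gain) or \
               (direction == "both" and (s_gain or p_gain)):
                selected.add(Pair((genes[i], genes[j])))
    return selected


@dataclass
class DiffNetwork:
    """Per-condition correlation structure plus the selected differential
    edge set at threshold tau."""

    genes: list[str]
    r_P: pd.DataFrame
    r_S: pd.DataFrame
    tau: float
    direction: str
    edges_P: set[Pair] = field(default_factory=set)
    edges_S: set[Pair] = field(default_factory=set)
    selected: set[Pair] = field(default_factory=set)

    @property
    def degree(self) -> dict[str, int]:
        deg = {g: 0 for g in self.genes}
        for pair in self.selected:
            for g in pair:
                deg[g] += 1
        return deg

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(tau=self.tau, direction=self.direction)
        g.add_nodes_from(self.genes)
        for pair in sorted(self.selected, key=sorted):
            a, b = sorted(pair)
            g.add_edge(a, b, r_P=float(self.r_P.loc[a, b]),
                       r_S=float(self.r_S.loc[a, b]),
                       delta=float(self.r_S.loc[a, b] - self.r_P.loc[a, b]))
        return g


def build_diffnet(X: FeatureMatrix, sheet: SampleSheet, genes=None,
                  tau: float = 0.6, direction: str = "S_gain") -> DiffNetwork:
    """End-to-end construction: per-condition correlations, positive filter,
    differential selection."""
    r_P = condition_correlations(X, sheet, genes, "P")
    r_S = condition_correlations(X, sheet, genes, "S")
    return DiffNetwork(
        genes=list(r_P.index),
        r_P=r_P,
        r_S=r_S,
        tau=tau,
        direction=direction,
        edges_P=positive_filter(r_P),
        edges_S=positive_filter(r_S),
        selected=select_differential_edges(r_P, r_S, tau, direction),
    )


def hub_ranking(net: DiffNetwork, top_k: int | None = None) -> list[str]:
    """Genes ordered by degree over the selected edges (ties lexicographic);
    genes with no selected edge are omitted."""
    deg = net.degree
    ranked = sorted((g for g in net.genes if deg[g] > 0),
                    key=lambda g: (-deg[g], g))
    return ranked if top_k is None else ranked[:top_k]
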