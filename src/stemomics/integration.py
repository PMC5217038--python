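"""Gene-metabolite correlation integration.

Per condition, a metabolites x genes Pearson correlation matrix is computed
over paired samples (pairing by identical sample id across the two omics
layers; no imputation).  Gene columns are then hierarchically clustered —
average linkage on the distance 1 - r between their correlation profiles —
and the tree is cut into k sub-clusters (default 10).  For display export
the correlation values are clipped to +/- c (default 0.7); all statistics
use the uncapped values.  A per-cluster report summarizes the mean
correlation with each metabolite in P and S and flags clusters whose
association flips between conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dataio import FeatureMatrix, GeneSet, SampleSheet

logger = logging.getLogger("stemomics")

__all__ = [
    "gene_metabolite_correlations",
    "cluster_genes",
    "cap_matrix",
    "differential_association_report",
    "CorrelationClusterMap",
    "build_cluster_map",
]


def gene_metabolite_correlations(expr: FeatureMatrix, metab: FeatureMatrix,
                                 sheet: SampleSheet, condition: str,
                                 genes=None, metabolites=None) -> pd.DataFrame:
    """Metabolites x genes Pearson matrix over one condition's paired samples.

    Samples must pair one-to-one by sample id across both matrices within
    the condition; unpaired samples are a hard error.  Zero-variance genes
    or metabolites give missing entries (logged).
    """
    cond_samples = [s for s in sheet.samples_in(condition)]
    in_expr = set(expr.samples)
    in_metab = set(metab.samples)
    unpaired = [s for s in cond_samples
                if (s in in_expr) != (s in in_metab)]
    if unpaired:
        raise ValueError(f"unpaired samples in condition {condition!r}: "
                         f"{unpaired}")
    paired = [s for s in cond_samples if s in in_expr and s in in_metab]
    if len(paired) < 3:
        raise ValueError(
            f"condition {condition!r} has {len(paired)} paired samples; "
            "need >= 3"
        )
    gene_list = (genes.members if isinstance(genes, GeneSet)
                 else list(genes) if genes is not None else list(expr.features))
    gene_list = [g for g in gene_list if g in expr.features]
    metab_list = (list(metabolites) if metabolites is not None
                  else list(metab.features))
    E = expr.subset_features(gene_list).subset_samples(paired).values
    M = metab.subset_features(metab_list).subset_samples(paired).values
    if np.isnan(E).any() or np.isnan(M).any():
        raise ValueError("correlation input contains missing values")

    def _standardize(V: np.ndarray, names: list[str], what: str) -> np.ndarray:
        sd = V.std(axis=1, ddof=1)
        bad = np.isclose(sd, 0)
        for i in np.nonzero(bad)[0]:
            logger.warning("%s %s has zero variance in condition %s; "
                           "correlations set missing", what, names[i], condition)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (V - V.mean(axis=1, keepdims=True)) / sd[:, None]
        Z[bad] = np.nan
        return Z

    Zg = _standardize(E, gene_list, "gene")
    Zm = _standardize(M, metab_list, "metabolite")
    R = (Zm @ Zg.T) / (len(paired) - 1)
    R = np.where(np.isnan(R), np.nan, np.clip(R, -1.0, 1.0))
    return pd.DataFrame(R, index=metab_list, columns=gene_list)


def cluster_genes(r_matrix: pd.DataFrame, k: int = 10
                  ) -> tuple[dict[str, int], np.ndarray]:
    """Cut an average-linkage tree over gene columns into exactly k clusters.

    The distance between two genes is 1 - Pearson r between their
    metabolite-correlation profiles (columns of ``r_matrix``).  Cluster ids
    are contiguous 1..k, numbered by first appearance in the input gene
    order, so relabeling genes relabels clusters.  Returns (assignment,
    linkage matrix).
    """
    genes = list(r_matrix.columns)
    if k > len(genes):
        raise ValueError(f"k = {k} exceeds the number of genes ({len(genes)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    V = r_matrix.to_numpy()
    if np.isnan(V).all(axis=0).any():
        j = int(np.nonzero(np.isnan(V).all(axis=0))[0][0])
        raise ValueError(f"gene column {genes[j]!r} is entirely missing")
    profile_corr = np.corrcoef(V.T)
    D = 1.0 - np.clip(profile_corr, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # exact symmetry for squareform
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # renumber contiguously in order of first appearance
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for g, lab in zip(genes, labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        assignment[g] = remap[lab]
    return assignment, Z


def cap_matrix(r_matrix: pd.DataFrame, c: float = 0.7) -> pd.DataFrame:
    """Clip correlations to [-c, +c] for display export; statistics always
    use the uncapped matrix."""
    if not c > 0:
        raise ValueError("cap must be > 0")
    return r_matrix.clip(lower=-c, upper=c)


def differential_association_report(r_P: pd.DataFrame, r_S: pd.DataFrame,
                                    clusters: dict[str, int], *,
                                    flag_delta: float = 0.5) -> pd.DataFrame:
    """Per cluster x metabolite summary of condition-specific association.

    Columns: mean r in P, mean r in S, delta = mean_r_S - mean_r_P,
    sign_flip (the mean association changes sign between conditions) and
    flagged (|delta| >= flag_delta — a planted or biological S-specific
    coupling shows up here even when the P-side mean hovers around 0).
    """
    if list(r_P.index) != list(r_S.index) or \
            list(r_P.columns) != list(r_S.columns):
        raise ValueError("correlation matrices must be aligned")
    rows = []
    ks = sorted(set(clusters.values()))
    for cid in ks:
        members = [g for g in r_P.columns if clusters.get(g) == cid]
        for m in r_P.index:
            mp = float(np.nanmean(r_P.loc[m, members]))
            ms = float(np.nanmean(r_S.loc[m, members]))
            rows.append(
                {
                    "cluster": cid,
                    "metabolite": m,
                    "n_genes": len(members),
                    "mean_r_P": mp,
                    "mean_r_S": ms,
                    "delta": ms - mp,
                    "sign_flip": mp * ms < 0,
                    "flagged": abs(ms - mp) >= flag_delta,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CorrelationClusterMap:
    """Both conditions' gene x metabolite correlation structure with the
    gene clustering and display cap."""

    genes: list[str]
    metabolites: list[str]
    r_P: pd.DataFrame
    r_S: pd.DataFrame
    gene_clusters: dict[str, int]
    k: int
    display_cap: float = 0.7
    linkage: str = "average"
    distance: str = "one_minus_r"

    def capped(self, condition: str) -> pd.DataFrame:
        r = self.r_P if condition == "P" else self.r_S
        return cap_matrix(r, self.display_cap)

    def report(self, flag_delta: float = 0.5) -> pd.DataFrame:
        return differential_association_report(
            self.r_P, self.r_S, self.gene_clusters, flag_delta=flag_delta
        )


def build_cluster_map(expr: FeatureMatrix, metab: FeatureMatrix,
                      sheet: SampleSheet, genes=None, metabolites=None,
                      k: int = 10, display_cap: float = 0.7,
                      cluster_on: str = "S") -> CorrelationClusterMap:
    """Compute both condition matrices and cluster gene columns on one of
    them (default S, where the condition-specific structure lives)."""
    r_P = gene_metabolite_correlations(expr, metab, sheet, "P", genes,
                                       metabolites)
    r_S = gene_metabolite_correlations(expr, metab, sheet, "S", genes,
                                       metabolites)
    # genes with an all-missing profile (zero variance in a condition, e.g.
    # rank-constant after quantile normalization) carry no correlation
    # information and cannot be clustered
    dead = sorted(set(r_P.columns[r_P.isna().all(axis=0)]) |
                  set(r_S.columns[r_S.isna().all(axis=0)]))
    if dead:
        logger.warning("dropping %d gene(s) with all-missing correlation "
                       "profiles: %s", len(dead), ", ".join(dead[:10]))
        r_P = r_P.drop(columns=dead)
        r_S = r_S.drop(columns=dead)
        k = min(k, len(r_P.columns))
    basis = r_S if cluster_on == "S" else r_P
    assignment, _ = cluster_genes(basis, k)
    return CorrelationClusterMap(
        genes=list(r_P.columns),
        metabolites=list(r_P.index),
        r_P=r_P,
        r_S=r_S,
        gene_clusters=assignment,
        k=k,
        display_cap=display_cap,
    )
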