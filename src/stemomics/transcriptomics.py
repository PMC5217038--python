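"""Expression preprocessing, per-gene statistics and KS gene-set enrichment.

Preprocessing follows the classic microarray recipe: quantile normalization
(all columns forced onto the mean sorted distribution, ties sharing the mean
of their would-be values), then log2 transform and per-gene mean-centering.

Differential expression offers the ordinary Student t-test and a
random-variance (moderated) t-test: per-gene variances are shrunk toward an
inverse-gamma prior fitted across genes by maximum likelihood, which buys
extra degrees of freedom at small sample sizes.  Under the prior model the
residual variance s^2 is marginally distributed as b * F(n-2, 2a); the
shrunken variance is s~^2 = ((n-2) s^2 + 2ab) / ((n-2) + 2a) and the test
statistic is referred to t with n - 2 + 2a degrees of freedom.

Enrichment uses the classic (unweighted) Kolmogorov-Smirnov running-sum
statistic over a ranked gene list, with a gene-set membership permutation
null and a +1/+1 empirical p-value; a rank-weighted variant is available
behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataio import FeatureMatrix, GeneSet, MatrixKind, SampleSheet

logger = logging.getLogger("stemomics")

__all__ = [
    "quantile_normalize",
    "log2_center",
    "collapse_probes",
    "fit_variance_prior",
    "differential_expression",
    "enrichment_score",
    "enrichment_ks",
]


def quantile_normalize(X: FeatureMatrix) -> FeatureMatrix:
    """Force every sample column onto the mean sorted distribution.

    After normalization every column's sorted values equal the row-wise mean
    of the input's sorted columns; tied values within a column share the
    mean of the reference values their ranks span.  Missing values are not
    supported here (quantile matching is undefined for ragged columns).
    """
    V = X.values
    if V.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if np.isnan(V).all(axis=0).any():
        j = int(np.nonzero(np.isnan(V).all(axis=0))[0][0])
        raise ValueError(f"column {X.samples[j]!r} is entirely missing")
    if np.isnan(V).any():
        raise ValueError("quantile normalization requires a complete matrix")
    n = V.shape[0]
    ref = np.sort(V, axis=0).mean(axis=1)
    out = np.empty_like(V)
    for j in range(V.shape[1]):
        col = V[:, j]
        order = np.argsort(col, kind="stable")
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col[order[k + 1]] == col[order[i]]:
                k += 1
            out[order[i:k + 1], j] = ref[i:k + 1].mean()
            i = k + 1
    return FeatureMatrix(list(X.features), list(X.samples), out, X.kind)


def log2_center(X: FeatureMatrix) -> FeatureMatrix:
    """log2-transform, then center each gene to its mean (row means 0)."""
    V = X.values
    bad = np.argwhere(~(V > 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive value at ({X.features[i]}, {X.samples[j]}): "
            f"{V[i, j]!r} cannot be log2-transformed"
        )
    L = np.log2(V)
    L = L - L.mean(axis=1, keepdims=True)
    return FeatureMatrix(list(X.features), list(X.samples), L,
                         MatrixKind.expression_log2)


def collapse_probes(X: FeatureMatrix, probe_to_gene: dict[str, str]
                    ) -> FeatureMatrix:
    """Collapse probes to genes keeping, per gene, the probe with the highest
    mean intensity (ties broken by probe id)."""
    best: dict[str, tuple[float, str, int]] = {}
    for i, probe in enumerate(X.features):
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        key = (float(np.nanmean(X.values[i])), probe)
        if gene not in best or (key[0], key[1]) > (best[gene][0], best[gene][1]):
            best[gene] = (key[0], probe, i)
    if not best:
        raise ValueError("no probes mapped to genes")
    genes = sorted(best)
    rows = [best[g][2] for g in genes]
    return FeatureMatrix(genes, list(X.samples), X.values[rows], X.kind)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def fit_variance_prior(s2: np.ndarray, m: int) -> tuple[float, float]:
    """ML fit of the inverse-gamma variance prior (a, b).

    Marginally s^2 ~ b * F(m, 2a); the likelihood is maximized over
    (log a, log b), with a confined to [1e-3, 1e4] — the upper bound is the
    homogeneous-variance limit where shrinkage is total and the extra
    degrees of freedom saturate.  Genes with zero residual variance are
    excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 10:
        raise ValueError("too few positive variances to fit the prior")

    def nll(theta: np.ndarray) -> float:
        a, b = np.exp(theta)
        return -float(np.sum(stats.f.logpdf(s2 / b, m, 2.0 * a) - np.log(b)))

    med = float(np.median(s2))
    res = optimize.minimize(
        nll, x0=np.array([np.log(2.0), np.log(med)]),
        method="Powell",
        bounds=[(np.log(1e-3), np.log(1e4)),
                (np.log(med) - 15.0, np.log(med) + 15.0)],
        options={"xtol": 1e-8, "ftol": 1e-10, "maxiter": 10000},
    )
    if not res.success or not np.isfinite(res.fun):
        raise RuntimeError(f"variance prior fit did not converge: {res.message}")
    a, b = np.exp(res.x)
    return float(a), float(b)


def shrunken_variance(s2: np.ndarray, m: int, a: float, b: float) -> np.ndarray:
    """s~^2 = (m s^2 + 2ab) / (m + 2a); a -> 0 recovers s^2."""
    return (m * np.asarray(s2, dtype=float) + 2.0 * a * b) / (m + 2.0 * a)


def differential_expression(X: FeatureMatrix, sheet: SampleSheet,
                            method: str = "random_variance") -> pd.DataFrame:
    """Per-gene S vs. P t-tests on (log2-scale) expression.

    ``method='ordinary'`` is the pooled-variance Student t with n - 2 df;
    ``'random_variance'`` shrinks each gene's variance toward the ML-fitted
    inverse-gamma prior and gains 2a df.  If the prior fit fails the method
    falls back to the ordinary test with a warning.  log2_fc is the S - P
    mean difference (log2-scale input assumed).
    """
    if method not in ("ordinary", "random_variance"):
        raise ValueError(f"unknown method {method!r}")
    sp = set(sheet.samples_in("P"))
    ss = set(sheet.samples_in("S"))
    ip = [i for i, s in enumerate(X.samples) if s in sp]
    is_ = [i for i, s in enumerate(X.samples) if s in ss]
    n1, n2 = len(ip), len(is_)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per condition")
    A = X.values[:, ip]
    B = X.values[:, is_]
    if np.isnan(A).any() or np.isnan(B).any():
        raise ValueError("differential expression requires a complete matrix")
    m = n1 + n2 - 2
    mean_p, mean_s = A.mean(axis=1), B.mean(axis=1)
    s2 = ((n1 - 1) * A.var(axis=1, ddof=1) + (n2 - 1) * B.var(axis=1, ddof=1)) / m
    se_factor = 1.0 / n1 + 1.0 / n2
    used = method
    if method == "random_variance":
        try:
            a, b = fit_variance_prior(s2, m)
            var = shrunken_variance(s2, m, a, b)
            df = m + 2.0 * a
        except (ValueError, RuntimeError) as exc:
            logger.warning("variance prior fit failed (%s); falling back to "
                           "the ordinary t-test", exc)
            used = "ordinary"
    if used == "ordinary":
        var = s2
        df = float(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_s - mean_p) / np.sqrt(var * se_factor)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {
            "t_stat": t,
            "p_value": p,
            "log2_fc": mean_s - mean_p,
            "method": used,
        },
        index=pd.Index(X.features, name="gene"),
    )


# ---------------------------------------------------------------------------
# gene-set enrichment (classic KS running sum)
# ---------------------------------------------------------------------------

def enrichment_score(ranked_genes, members, weights=None) -> float:
    """Signed maximum deviation of the KS running sum over a ranked list.

    Unweighted (classic KS): hits step up by 1/Nh, misses step down by
    1/(N - Nh), so |ES| <= 1.  With ``weights`` (aligned to ranked_genes),
    hit steps are proportional to |weight|.
    """
    ranked = list(ranked_genes)
    mem = set(members) & set(ranked)
    N, nh = len(ranked), len(mem)
    if nh == 0 or nh == N:
        raise ValueError("gene set overlap is empty or the whole ranking")
    is_hit = np.array([g in mem for g in ranked])
    if weights is None:
        up = np.where(is_hit, 1.0 / nh, 0.0)
    else:
        w = np.abs(np.asarray(weights, dtype=float))
        hit_w = np.where(is_hit, w, 0.0)
        total = hit_w.sum()
        if total <= 0:
            up = np.where(is_hit, 1.0 / nh, 0.0)
        else:
            up = hit_w / total
    down = np.where(is_hit, 0.0, 1.0 / (N - nh))
    running = np.cumsum(up - down)
    return float(running[np.argmax(np.abs(running))])


def enrichment_ks(ranked_stats: pd.Series, sets, n_perm: int = 1000,
                  seed: int | None = None, *, min_overlap: int = 5,
                  weighted: bool = False) -> pd.DataFrame:
    """KS enrichment of each gene set in a stat-ranked gene list.

    Genes are ranked by decreasing statistic (ties broken by gene id for
    determinism), so a positive ES means the set concentrates among
    S-up-regulated genes.  Nominal p comes from ``n_perm`` random same-size
    membership draws (two-sided on |ES|, +1/+1 estimator); q is
    Benjamini-Hochberg across the reported sets.  Sets overlapping the
    ranking in fewer than ``min_overlap`` genes are skipped with a log line.
    """
    s = pd.Series(ranked_stats).astype(float)
    order = sorted(s.index, key=lambda g: (-s[g], str(g)))
    stats_sorted = s.loc[order].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for gs in sets:
        members = gs.members if isinstance(gs, GeneSet) else list(gs)
        name = gs.name if isinstance(gs, GeneSet) else "set"
        overlap = set(members) & set(order)
        if len(overlap) < min_overlap:
            logger.warning("gene set %s: overlap %d < %d; skipped",
                           name, len(overlap), min_overlap)
            continue
        if len(overlap) == len(order):
            logger.warning("gene set %s covers the whole ranking; skipped", name)
            continue
        w = stats_sorted if weighted else None
        es = enrichment_score(order, overlap, weights=w)
        k = len(overlap)
        exceed = 0
        for _ in range(n_perm):
            draw = rng.choice(len(order), size=k, replace=False)
            perm_members = {order[i] for i in draw}
            es_p = enrichment_score(order, perm_members, weights=w)
            if abs(es_p) >= abs(es):
                exceed += 1
        rows.append(
            {
                "set": name,
                "ES": es,
                "nominal_p": (1 + exceed) / (n_perm + 1),
                "direction": "up_in_S" if es >= 0 else "down_in_S",
                "n_overlap": k,
            }
        )
    out = pd.DataFrame(rows, columns=["set", "ES", "nominal_p", "direction",
                                      "n_overlap"]).set_index("set")
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(out["nominal_p"], method="fdr_bh")[1]
    return out
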