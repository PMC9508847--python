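"""Inhibitor classification and gene clustering from fitness profiles.

Inhibitors are compared by Pearson correlation of their log2 fitness
profiles over the significant-union genes and hierarchically clustered
(average linkage on 1 - r); the final partition into named classes is a
human step, so only the correlation matrix, dendrogram, and an optional
cut-height convenience are emitted.

Genes are clustered with a k-component Gaussian mixture whose components
share a single isotropic covariance sigma^2 I (the "EII" model family:
spherical, equal volume), fit by EM from k-means++ initializations, then
ordered within each cluster by hierarchical clustering for heat-map export
in CDT format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster, leaves_list
from scipy.spatial.distance import squareform
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from . import io as cgio

_SIGMA_FLOOR = 1e-8


@dataclass
class CorrelationResult:
    corr: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str

    def cut(self, height: float) -> pd.Series:
        labels = fcluster(self.linkage, t=height, criterion="distance")
        return pd.Series(labels, index=self.corr.index, name="class")


@dataclass
class GeneClustering:
    labels: pd.Series              # gene -> cluster id in 1..k
    means: np.ndarray              # k x p
    weights: np.ndarray            # k, sums to 1
    sigma2: float
    loglik_trace: list[float]      # non-decreasing within the final EM run
    n_reseeds: int
    converged: bool
    n_imputed: int = 0
    start_logliks: list[float] = field(default_factory=list)


def correlation_matrix(profiles: pd.DataFrame,
                       min_complete: int = 3) -> CorrelationResult:
    """Pairwise Pearson correlation of inhibitor columns with average-linkage
    clustering on 1 - r.

    Correlations use pairwise-complete rows; a constant column (zero
    variance) or a column pair with fewer than ``min_complete`` complete
    rows is an error naming the offender.
    """
    for col in profiles.columns:
        v = profiles[col].dropna()
        if len(v) >= 1 and float(v.std(ddof=0)) == 0.0:
            raise ValueError(f"column {col!r} is constant; correlation undefined")
    cols = list(profiles.columns)
    complete = profiles.notna().astype(int).T @ profiles.notna().astype(int)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            if complete.iloc[i, j] < min_complete:
                raise ValueError(
                    f"columns {a!r}/{cols[j]!r}: only {complete.iloc[i, j]} "
                    f"complete rows (< {min_complete})")
    corr = profiles.corr(method="pearson", min_periods=min_complete)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = average(squareform(dist, checks=False))
    order = [cols[i] for i in leaves_list(linkage)]
    newick = cgio.linkage_to_newick(linkage, cols)
    return CorrelationResult(corr=corr, linkage=linkage, leaf_order=order,
                             newick=newick)


# ---------------------------------------------------------------------------
# EII Gaussian mixture


def _em_eii(X: np.ndarray, k: int, rng: np.random.Generator,
            tol: float, max_iter: int) -> dict:
    n, p = X.shape
    means, _ = kmeans_plusplus(X, n_clusters=k,
                               random_state=int(rng.integers(2**31 - 1)))
    weights = np.full(k, 1.0 / k)
    d2 = ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
    sigma2 = max(float(d2.min(axis=1).mean() / p), _SIGMA_FLOOR)

    trace: list[float] = []
    n_reseeds = 0
    converged = False
    prev = -np.inf
    for _ in range(max_iter):
        # E-step
        d2 = ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        log_comp = (np.log(np.maximum(weights, 1e-300))[None, :]
                    - 0.5 * p * np.log(2 * np.pi * sigma2)
                    - 0.5 * d2 / sigma2)
        norm = logsumexp(log_comp, axis=1)
        ll = float(norm.sum())
        resp = np.exp(log_comp - norm[:, None])
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        # M-step
        nk = resp.sum(axis=0)
        empty = nk < 1e-8
        if empty.any():
            # re-seed dead components at the worst-explained points
            n_reseeds += int(empty.sum())
            worst = np.argsort(resp.max(axis=1))
            for rank, j in enumerate(np.flatnonzero(empty)):
                means[j] = X[worst[rank % n]]
                nk[j] = 1.0
                resp[worst[rank % n]] = 0.0
                resp[worst[rank % n], j] = 1.0
            nk = resp.sum(axis=0)
            trace = [ll]   # monotonicity guaranteed only after the reseed
            prev = -np.inf
        weights = nk / nk.sum()
        means = (resp.T @ X) / nk[:, None]
        d2 = ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        sigma2 = max(float((resp * d2).sum() / (n * p)), _SIGMA_FLOOR)
    return {"means": means, "weights": weights, "sigma2": sigma2,
            "trace": trace, "final_ll": trace[-1], "reseeds": n_reseeds,
            "converged": converged}


def cluster_genes_eii(profiles: pd.DataFrame, k: int, n_starts: int = 10,
                      seed: int = 0, tol: float = 1e-6,
                      max_iter: int = 500) -> GeneClustering:
    """EM fit of a k-component shared-spherical-covariance Gaussian mixture.

    Missing log2 effects are imputed as 0 (no fitness effect) before
    clustering; the count is reported on the result. The best of
    ``n_starts`` k-means++ initializations by final log-likelihood wins, and
    genes are hard-assigned by maximum responsibility.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > profiles.shape[0]:
        raise ValueError(f"k={k} exceeds n_genes={profiles.shape[0]}")
    X = profiles.to_numpy(dtype=float)
    n_imputed = int(np.isnan(X).sum())
    X = np.nan_to_num(X, nan=0.0)
    seeds = np.random.SeedSequence(seed).spawn(n_starts)
    best = None
    start_lls = []
    for ss in seeds:
        fit = _em_eii(X, k, np.random.default_rng(ss), tol, max_iter)
        start_lls.append(fit["final_ll"])
        if best is None or fit["final_ll"] > best["final_ll"]:
            best = fit
    d2 = ((X[:, None, :] - best["means"][None, :, :]) ** 2).sum(axis=2)
    log_comp = (np.log(np.maximum(best["weights"], 1e-300))[None, :]
                - 0.5 * d2 / best["sigma2"])
    labels = log_comp.argmax(axis=1) + 1
    return GeneClustering(
        labels=pd.Series(labels, index=profiles.index, name="cluster"),
        means=best["means"], weights=best["weights"], sigma2=best["sigma2"],
        loglik_trace=best["trace"], n_reseeds=best["reseeds"],
        converged=best["converged"], n_imputed=n_imputed,
        start_logliks=start_lls)


# ---------------------------------------------------------------------------
# within-cluster ordering and CDT export


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; constant rows get distance 1
    to everything (correlation undefined)."""
    centered = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered ** 2).sum(axis=1))
    ok = sd > 0
    denom = np.outer(sd, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (centered @ centered.T) / denom
    r[~ok, :] = 0.0
    r[:, ~ok] = 0.0
    np.fill_diagonal(r, 1.0)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def order_within_clusters(profiles: pd.DataFrame,
                          clustering: GeneClustering
                          ) -> dict[int, list[str]]:
    """Average-linkage (1 - Pearson) leaf order of genes inside each cluster.

    Deterministic: scipy's agglomeration with ties broken by input order;
    singleton clusters return themselves.
    """
    X = np.nan_to_num(profiles.to_numpy(dtype=float), nan=0.0)
    orders: dict[int, list[str]] = {}
    for cid in sorted(clustering.labels.unique()):
        genes = list(clustering.labels.index[clustering.labels == cid])
        if len(genes) <= 2:
            orders[cid] = genes
            continue
        sub = X[[profiles.index.get_loc(g) for g in genes]]
        linkage = average(squareform(_pearson_distance(sub), checks=False))
        orders[cid] = [genes[i] for i in leaves_list(linkage)]
    return orders


def export_cdt(profiles: pd.DataFrame, clustering: GeneClustering,
               orders: dict[int, list[str]], path) -> pd.DataFrame:
    """Write the cluster-ordered matrix as a CDT file and return the
    reordered frame (clusters ascending, genes in leaf order)."""
    ordered_genes = [g for cid in sorted(orders) for g in orders[cid]]
    reordered = profiles.loc[ordered_genes]
    names = {g: f"cluster_{clustering.labels[g]}" for g in ordered_genes}
    cgio.write_cdt(reordered, path, gene_names=names)
    return reordered
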