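"""Shared-Coexpression-Matrix (SCM) clustering of PPR genes with C-to-U
edited target genes.

The premise: a PPR protein binds its target transcripts directly, so PPR
expression should track the abundance of *edited* target transcripts. The
expression of each edited gene is therefore first multiplied by its mean
editing degree (approximating the number of edited transcripts), a Spearman
rank coexpression network is built over PPR + target genes, and the network's
Shared Coexpression Matrix — scm(i,j) = number of genes coexpressed with both
i and j — is greedily decomposed into clusters:

1. the unassigned pair with the largest SCM entry seeds a cluster (ties:
   higher rho, then lexicographically smallest ids);
2. the third gene with the most significant shared-neighbour overlap with both
   seeds joins (each overlap must pass the hypergeometric threshold; a seed
   pair that cannot recruit a third gene is dissolved and masked);
3. any gene with significant overlap with at least three current members
   joins, repeated to a fixpoint;
4. the cluster closes, its members are removed from the network (they no
   longer count as shared neighbours), and the next round begins.

Significance of a shared-neighbour count is the upper-tail hypergeometric
probability of the observed overlap given the two genes' degrees (neighbours
other than the partner), drawn from the other n-2 genes of the full network;
the universe stays the full gene set across rounds even as removed members
stop counting as shared neighbours, so late clusters are tested against the
same null as early ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin

from .enrichment import hypergeom_tail

logger = logging.getLogger("nucredit")


# ----------------------------------------------------------------- adjusting

def adjust_expression(
    expr: pd.DataFrame, degrees: Mapping[str, float]
) -> pd.DataFrame:
    """Multiply each gene's expression profile by its mean editing degree.

    Genes absent from ``degrees`` (e.g. unedited PPR genes) keep degree 1.
    """
    factors = []
    for gene in expr.index:
        d = degrees.get(gene, 1.0)
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"{gene}: editing degree {d} outside [0,1]")
        factors.append(d)
    return expr.mul(pd.Series(factors, index=expr.index), axis=0)


# ------------------------------------------------------------------- network

@dataclass
class CoexpressionNetwork:
    """Spearman coexpression network over genes (rows of the input matrix)."""

    genes: list[str]
    rho: np.ndarray
    p_values: np.ndarray
    adjacency: np.ndarray  # boolean, symmetric, zero diagonal

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def spearman_network(
    adjusted: pd.DataFrame,
    rho_threshold: float = 0.7,
    p_threshold: float = 0.05,
) -> CoexpressionNetwork:
    """Tie-corrected Spearman correlations between all gene pairs; an edge
    requires rho >= rho_threshold and correlation p <= p_threshold.

    Genes with constant profiles have undefined correlations and get no edges.
    Requires at least 5 samples.
    """
    if adjusted.shape[1] < 5:
        raise ValueError("need >= 5 samples for stable rank correlations")
    genes = list(adjusted.index)
    # average-rank transform + Pearson = tie-corrected Spearman; computed
    # directly so constant genes yield NaN rows instead of collapsing the
    # whole matrix (scipy.stats.spearmanr scalarizes on constant input)
    ranks = adjusted.rank(axis=1).to_numpy()
    n_samples = ranks.shape[1]
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.atleast_2d(rho)
    rho[sd == 0, :] = np.nan
    rho[:, sd == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho * np.sqrt((n_samples - 2) / (1.0 - rho**2))
        pval = 2.0 * stats.t.sf(np.abs(tstat), df=n_samples - 2)
    pval[np.isinf(tstat)] = 0.0  # |rho| == 1 exactly
    n_const = int(np.isnan(rho).any(axis=1).sum())
    if n_const:
        logger.info("spearman_network: %d genes with undefined correlations", n_const)
    with np.errstate(invalid="ignore"):
        adjacency = (rho >= rho_threshold) & (pval <= p_threshold)
    adjacency &= ~np.isnan(rho)
    np.fill_diagonal(adjacency, False)
    adjacency = adjacency & adjacency.T  # enforce symmetry
    return CoexpressionNetwork(genes, rho, pval, adjacency)


def build_scm(network: CoexpressionNetwork) -> np.ndarray:
    """scm(i,j) = number of genes coexpressed with both i and j."""
    A = network.adjacency.astype(np.int64)
    scm = A @ A
    np.fill_diagonal(scm, 0)
    return scm


def shared_significance(
    scm_ij: int, deg_i: int, deg_j: int, n_genes: int
) -> float:
    """Upper-tail hypergeometric p for observing ``scm_ij`` shared neighbours
    between genes of degrees ``deg_i`` and ``deg_j`` among ``n_genes`` genes.

    The population excludes the pair itself (N = n_genes - 2); the degrees
    should count each gene's neighbours other than the partner. Degrees are
    clipped to the population so forced-overlap supports are handled exactly.
    """
    N = max(n_genes - 2, 0)
    K = min(deg_i, N)
    n = min(deg_j, N)
    k = min(scm_ij, min(K, n))
    if N == 0:
        return 1.0
    return hypergeom_tail(k, K, n, N)


# ----------------------------------------------------------------- decompose

@dataclass
class Cluster:
    """One decomposed cluster: members, the seed pair, and the join order."""

    members: list[str]
    seed: tuple[str, str]
    growth_trace: list[str] = field(default_factory=list)


def decompose(
    scm: np.ndarray,
    network: CoexpressionNetwork,
    p_threshold: float = 0.05,
    min_size: int = 3,
) -> list[Cluster]:
    """Greedy decomposition of the SCM into disjoint clusters (see module
    docstring for the growth rules). Deterministic for identical inputs."""
    genes = network.genes
    n_total = len(genes)
    order = {g: i for i, g in enumerate(genes)}
    active = np.ones(n_total, dtype=bool)
    masked: set[tuple[int, int]] = set()
    clusters: list[Cluster] = []

    while True:
        idx = np.flatnonzero(active)
        if len(idx) < min_size:
            break
        subA = network.adjacency[np.ix_(idx, idx)]
        sub_scm = (subA.astype(np.int64) @ subA.astype(np.int64))
        np.fill_diagonal(sub_scm, 0)
        deg = subA.sum(axis=1)
        n_active = len(idx)

        def sig(a: int, b: int) -> float:
            # degrees exclude the partner edge; the universe stays the full
            # network (removed genes leave the SCM but not the null's gene set)
            link = int(subA[a, b])
            return shared_significance(
                int(sub_scm[a, b]), int(deg[a]) - link, int(deg[b]) - link, n_total
            )

        # step 1: seed pair with the largest shared-neighbour count
        best = None
        for a in range(n_active):
            for b in range(a + 1, n_active):
                if sub_scm[a, b] <= 0:
                    continue
                gi, gj = idx[a], idx[b]
                if (gi, gj) in masked:
                    continue
                key = (
                    int(sub_scm[a, b]),
                    float(network.rho[gi, gj]),
                    -order[genes[gi]],
                    -order[genes[gj]],
                )
                if best is None or key > best[0]:
                    best = (key, a, b)
        if best is None:
            break
        _, a, b = best

        # step 2: the third gene with the most significant joint overlap
        g3 = None
        g3_key = None
        for c in range(n_active):
            if c in (a, b):
                continue
            pa, pb = sig(a, c), sig(b, c)
            if pa <= p_threshold and pb <= p_threshold:
                key = (max(pa, pb), pa + pb, order[genes[idx[c]]])
                if g3_key is None or key < g3_key:
                    g3, g3_key = c, key
        if g3 is None:
            masked.add((idx[a], idx[b]))  # dissolved seed pair
            continue

        members = [a, b, g3]
        trace = [genes[idx[a]], genes[idx[b]], genes[idx[g3]]]

        # step 3: grow to fixpoint — significant overlap with >= 3 members
        while True:
            additions = []
            member_set = set(members)
            for c in range(n_active):
                if c in member_set:
                    continue
                n_sig = sum(1 for m in members if sig(c, m) <= p_threshold)
                if n_sig >= 3:
                    additions.append(c)
            if not additions:
                break
            additions.sort(key=lambda c: order[genes[idx[c]]])
            members.extend(additions)
            trace.extend(genes[idx[c]] for c in additions)

        if len(members) >= min_size:
            clusters.append(
                Cluster(
                    members=sorted(trace, key=order.get),
                    seed=(genes[idx[a]], genes[idx[b]]),
                    growth_trace=trace,
                )
            )
            active[[idx[m] for m in members]] = False
        else:  # unreachable with min_size <= 3, kept as a guard
            masked.add((idx[a], idx[b]))
    return clusters


def cluster_report(
    clusters: Sequence[Cluster], labels: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster counts of PPR genes and edited (target) genes, with totals.

    ``labels`` is indexed by gene with a 0/1 ``ppr`` column; when an
    ``organelle`` 0/1 column is present the organelle-targeted fraction of each
    cluster's edited genes is reported too.
    """
    rows = []
    has_org = "organelle" in labels.columns
    for cid, cl in enumerate(clusters, start=1):
        ppr = [g for g in cl.members if g in labels.index and labels.at[g, "ppr"] == 1]
        edited = [g for g in cl.members if g not in ppr]
        row = {
            "cluster": cid,
            "n_edited_genes": len(edited),
            "n_ppr": len(ppr),
        }
        if has_org and edited:
            row["organelle_fraction"] = float(
                np.mean([labels.at[g, "organelle"] for g in edited if g in labels.index])
            )
        rows.append(row)
    df = pd.DataFrame(
        rows, columns=["cluster", "n_edited_genes", "n_ppr"]
        + (["organelle_fraction"] if has_org else [])
    )
    if not df.empty:
        totals = {"cluster": "total",
                  "n_edited_genes": int(df["n_edited_genes"].sum()),
                  "n_ppr": int(df["n_ppr"].sum())}
        df = pd.concat([df, pd.DataFrame([totals])], ignore_index=True)
    return df


# ----------------------------------------------------------------- estimator

class SCMCluster(BaseEstimator, ClusterMixin):
    """sklearn-style wrapper around the SCM decomposition.

    fit(X) expects a genes x samples frame (or array); the fitted attributes
    are ``network_``, ``scm_``, ``clusters_`` and ``labels_`` (cluster index
    per gene, -1 for unassigned).
    """

    def __init__(
        self,
        rho_threshold: float = 0.7,
        p_threshold: float = 0.05,
        min_size: int = 3,
    ):
        self.rho_threshold = rho_threshold
        self.p_threshold = p_threshold
        self.min_size = min_size

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.index = [f"g{i}" for i in range(len(X))]
        self.network_ = spearman_network(
            X, rho_threshold=self.rho_threshold, p_threshold=self.p_threshold
        )
        self.scm_ = build_scm(self.network_)
        self.clusters_ = decompose(
            self.scm_, self.network_,
            p_threshold=self.p_threshold, min_size=self.min_size,
        )
        labels = np.full(len(X), -1, dtype=int)
        pos = {g: i for i, g in enumerate(self.network_.genes)}
        for cid, cl in enumerate(self.clusters_):
            for g in cl.members:
                labels[pos[g]] = cid
        self.labels_ = labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
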