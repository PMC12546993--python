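"""Taxon-taxon co-occurrence networks.

Edges are statistically significant Spearman rank correlations of abundance
across samples: rho is the Pearson correlation of mid-ranks, p-values come
from a (seeded) permutation test, Benjamini-Hochberg controls the FDR over
the D(D-1)/2 unique pairs, and pairs with adjusted p > alpha are removed.
The surviving signed adjacency is symmetrically normalized with self-loops,
Ahat = Dg^{-1/2} (|A| + I) Dg^{-1/2}, for use as graph-convolution weights.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .tables_io import AbundanceTable

__all__ = [
    "CooccurrenceNetwork",
    "spearman_rho",
    "permutation_pvalue",
    "bh_adjust",
    "build_network",
    "normalize_adjacency",
    "network_summary",
    "build_cooccurrence",
]


@dataclass
class CooccurrenceNetwork:
    """Correlation matrices, significance, and the thresholded graph."""

    taxon_ids: list[str]
    rho: np.ndarray
    pvals: np.ndarray
    padj: np.ndarray
    adjacency: np.ndarray
    normalized_adjacency: np.ndarray
    alpha: float = 0.05
    empty: bool = False  # warning flag: no edge survived thresholding

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_taxa, k=1)
        return int(np.count_nonzero(self.adjacency[iu]))

    def edge_list(self) -> pd.DataFrame:
        """Significant edges as (taxon_a, taxon_b, rho, pval, padj) rows."""
        rows = []
        iu = zip(*np.triu_indices(self.n_taxa, k=1))
        for i, j in iu:
            if self.adjacency[i, j] != 0:
                rows.append(
                    (
                        self.taxon_ids[i],
                        self.taxon_ids[j],
                        self.rho[i, j],
                        self.pvals[i, j],
                        self.padj[i, j],
                    )
                )
        return pd.DataFrame(
            rows, columns=["taxon_a", "taxon_b", "rho", "pval", "padj"]
        )

    def save(self, outdir: str | Path, prefix: str = "network") -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        edges = outdir / f"{prefix}_edges.tsv"
        self.edge_list().to_csv(edges, sep="\t", index=False, float_format="%.10g")
        written.append(edges)
        for name, mat in (
            ("adjacency", self.adjacency),
            ("normalized_adjacency", self.normalized_adjacency),
        ):
            path = outdir / f"{prefix}_{name}.tsv"
            pd.DataFrame(
                mat, index=self.taxon_ids, columns=self.taxon_ids
            ).to_csv(path, sep="\t", float_format="%.10g")
            written.append(path)
        return written


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Spearman correlation as Pearson correlation of mid-ranks.

    Ties receive average ranks. Returns ``(rho, degenerate)``; a constant
    vector has undefined rank correlation, reported as rho 0 with the
    degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return 0.0, True
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    return float(np.clip(rho, -1.0, 1.0)), False


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt((cx @ cx) * (cy @ cy))
    return float(cx @ cy / denom) if denom > 0 else 0.0


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "montecarlo",
) -> tuple[float, bool]:
    """Two-sided permutation p-value for the Spearman correlation.

    Monte Carlo mode draws ``n_perm`` random permutations of y and uses the
    add-one estimator (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm), which
    never returns 0. Exhaustive mode enumerates all n! permutations (n <= 7)
    and returns the exact proportion. Constant input yields p = 1 with the
    degenerate flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D arrays, n >= 3")
    rho_obs, degenerate = spearman_rho(x, y)
    if degenerate:
        return 1.0, True
    rx = rankdata(x)
    ry = rankdata(y)
    thresh = abs(rho_obs) - 1e-12  # tolerate float noise in |rho| ties
    if mode == "exhaustive":
        if x.size > 7:
            raise ValueError("exhaustive mode supports n <= 7 only")
        count = total = 0
        for perm in itertools.permutations(range(x.size)):
            total += 1
            if abs(_rho_from_ranks(rx, ry[list(perm)])) >= thresh:
                count += 1
        return count / total, False
    if mode != "montecarlo":
        raise ValueError(f"unknown mode {mode!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    cx = rx - rx.mean()
    nx = math.sqrt(cx @ cx)
    cy = ry - ry.mean()
    ny = math.sqrt(cy @ cy)
    count = 0
    for _ in range(n_perm):
        rho_p = cx @ rng.permutation(cy) / (nx * ny)
        if abs(rho_p) >= thresh:
            count += 1
    return (1 + count) / (1 + n_perm), False


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1 or pvals.size == 0:
        raise ValueError("pvals must be a non-empty 1-D array")
    if np.any((pvals < 0) | (pvals > 1)) or not np.all(np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def build_network(
    rho: np.ndarray,
    padj: np.ndarray,
    alpha: float = 0.05,
    taxon_ids: list[str] | None = None,
    pvals: np.ndarray | None = None,
) -> CooccurrenceNetwork:
    """Threshold rho by adjusted significance into a signed adjacency.

    An edge keeps its signed rho where padj <= alpha (strictly greater
    values are removed, so exactly-alpha edges survive); the diagonal is
    forced to zero and the result symmetrically normalized.
    """
    rho = np.asarray(rho, dtype=float)
    padj = np.asarray(padj, dtype=float)
    if rho.shape != padj.shape or rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise ValueError("rho and padj must be square matrices of one shape")
    if not np.allclose(rho, rho.T) or not np.allclose(padj, padj.T):
        raise ValueError("rho and padj must be symmetric")
    adjacency = np.where(padj <= alpha, rho, 0.0)
    np.fill_diagonal(adjacency, 0.0)
    adjacency = (adjacency + adjacency.T) / 2  # exact symmetry
    if taxon_ids is None:
        taxon_ids = [f"taxon_{i}" for i in range(rho.shape[0])]
    if pvals is None:
        pvals = padj
    empty = not np.any(adjacency)
    return CooccurrenceNetwork(
        taxon_ids=list(taxon_ids),
        rho=rho,
        pvals=np.asarray(pvals, dtype=float),
        padj=padj,
        adjacency=adjacency,
        normalized_adjacency=normalize_adjacency(adjacency),
        alpha=alpha,
        empty=empty,
    )


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops.

    Ahat = Dg^{-1/2} (|A| + I) Dg^{-1/2} where |A| drops edge signs (the
    aggregation weights must be non-negative) and Dg is the degree matrix
    of |A| + I. The self-loop guarantees every degree is positive.
    """
    adjacency = np.asarray(adjacency, dtype=float)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    a = np.abs(adjacency) + np.eye(adjacency.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a.sum(axis=1))
    return a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def network_summary(
    net: CooccurrenceNetwork, phylum_labels: list[str]
) -> dict:
    """Node/edge counts plus the internal vs external association split.

    Internal associations join taxa of the same phylum; external join
    different phyla. Nodes are taxa with at least one edge.
    """
    if len(phylum_labels) != net.n_taxa:
        raise ValueError("need one phylum label per taxon")
    degree = np.count_nonzero(net.adjacency, axis=1)
    connected = degree >= 1
    internal = external = 0
    per_phylum: dict[str, int] = {}
    for i in np.flatnonzero(connected):
        per_phylum[phylum_labels[i]] = per_phylum.get(phylum_labels[i], 0) + 1
    for i, j in zip(*np.triu_indices(net.n_taxa, k=1)):
        if net.adjacency[i, j] != 0:
            if phylum_labels[i] == phylum_labels[j]:
                internal += 1
            else:
                external += 1
    return {
        "n_nodes": int(connected.sum()),
        "n_edges": net.n_edges,
        "nodes_per_phylum": per_phylum,
        "internal_edges": internal,
        "external_edges": external,
    }


def build_cooccurrence(
    table: AbundanceTable,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    mode: str = "montecarlo",
) -> CooccurrenceNetwork:
    """Full pipeline: pairwise rho + permutation p, BH over unique pairs,
    thresholding and normalization. Deterministic given the seed.
    """
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples")
    if table.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    d = table.n_taxa
    rho = np.eye(d)
    pvals = np.zeros((d, d))
    iu = np.triu_indices(d, k=1)
    flat_p = []
    ss = np.random.SeedSequence(seed)
    pair_seeds = ss.generate_state(len(iu[0]))
    for k, (i, j) in enumerate(zip(*iu)):
        r, _ = spearman_rho(table.values[i], table.values[j])
        p, _ = permutation_pvalue(
            table.values[i],
            table.values[j],
            n_perm=n_perm,
            seed=int(pair_seeds[k]),
            mode=mode,
        )
        rho[i, j] = rho[j, i] = r
        pvals[i, j] = pvals[j, i] = p
        flat_p.append(p)
    padj_flat = bh_adjust(np.array(flat_p))
    padj = np.zeros((d, d))
    padj[iu] = padj_flat
    padj = padj + padj.T
    return build_network(
        rho, padj, alpha=alpha, taxon_ids=table.taxon_ids, pvals=pvals
    )
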