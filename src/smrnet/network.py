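"""Province similarity network with entropy-maximizing hard thresholding.

Provinces are compared by the absolute Spearman correlation of their
indicator vectors: d_ij = |rho(x_i, x_j)|, so strongly anti-correlated
provinces are maximally similar.  The binary adjacency keeps an edge where
d_ij >= th; the threshold is chosen to maximize the Shannon entropy of the
betweenness-centrality distribution, i.e. the configuration in which
shortest-path load is spread most evenly over provinces.  Betweenness is
normalized to a probability distribution before taking the entropy, which
makes the objective scale-free (the raw betweenness values depend on the
node count).

From the chosen network four per-province centrality features are
extracted — degree, betweenness, closeness and eigenvector centrality —
and appended to the indicator panel as a robustness check of the
regression models.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ProvinceNetwork:
    """Similarity matrix, chosen threshold, adjacency and entropy curve."""

    D: np.ndarray
    threshold: float
    C: np.ndarray
    entropy_curve: list[tuple[float, float]]
    node_ids: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.C)

    def edge_list(self) -> list[tuple]:
        ids = self.node_ids if self.node_ids is not None else np.arange(self.n_nodes)
        i, j = np.nonzero(np.triu(self.C, 1))
        return [(ids[a], ids[b]) for a, b in zip(i, j)]


def spearman_abs_matrix(panel_year: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Absolute Spearman correlation between province indicator vectors.

    Ranks use average tie handling.  A province with a constant indicator
    vector has degenerate ranks and is an error.
    """
    M = np.asarray(panel_year, dtype=float)
    if M.ndim != 2 or M.shape[1] < 3:
        raise ValueError("need a province x indicator matrix with >= 3 indicators")
    constant = np.all(M == M[:, :1], axis=1)
    if constant.any():
        raise ValueError(f"constant indicator vector for province rows {np.flatnonzero(constant)}")
    rho = stats.spearmanr(M.T).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    D = np.abs(rho)
    np.fill_diagonal(D, 1.0)
    return D


def adjacency(D: np.ndarray, th: float) -> np.ndarray:
    """Hard threshold: c_ij = 1 iff d_ij >= th and i != j."""
    C = (np.asarray(D) >= th).astype(int)
    np.fill_diagonal(C, 0)
    return C


def betweenness(C: np.ndarray) -> np.ndarray:
    """Freeman betweenness: per node, sum over pairs of geodesic fractions.

    Unordered pairs (j, k), both distinct from i; pairs in different
    components contribute 0.
    """
    C = np.asarray(C)
    G = nx.from_numpy_array(C)
    bc = nx.betweenness_centrality(G, normalized=False)
    return np.array([bc[i] for i in range(len(C))])


def entropy_of_betweenness(C: np.ndarray) -> float:
    """Shannon entropy (bits) of the normalized betweenness distribution.

    Betweenness values are scaled to sum to one; 0*log(0) is taken as 0 and
    an all-zero betweenness vector has entropy 0 by convention.
    """
    b = betweenness(C)
    total = b.sum()
    if total == 0:
        return 0.0
    p = b[b > 0] / total
    return float(-(p * np.log2(p)).sum())


def threshold_scan(
    D: np.ndarray, thresholds: np.ndarray | None = None, node_ids: np.ndarray | None = None
) -> ProvinceNetwork:
    """Pick the threshold maximizing betweenness entropy.

    Candidates default to all distinct off-diagonal similarity values
    (exhaustive over realizable adjacency matrices); ties break toward the
    smallest threshold, i.e. the densest of the maximizing networks.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or len(D) < 2:
        raise ValueError("D must be a square similarity matrix with >= 2 nodes")
    if not np.allclose(D, D.T):
        raise ValueError("D must be symmetric")
    if thresholds is None:
        off = D[~np.eye(len(D), dtype=bool)]
        thresholds = np.unique(off)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    curve = []
    best_th, best_h = None, -np.inf
    for th in thresholds:
        h = entropy_of_betweenness(adjacency(D, th))
        curve.append((float(th), float(h)))
        if h > best_h:  # strict: first (smallest) threshold wins ties
            best_th, best_h = float(th), float(h)
    return ProvinceNetwork(D, best_th, adjacency(D, best_th), curve, node_ids)


def eigenvector_centrality(C: np.ndarray, tol: float = 1e-10, max_iter: int = 10000) -> np.ndarray:
    """Principal eigenvector of the adjacency, nonnegative with unit norm.

    Power iteration on C + I from a uniform start; the identity shift keeps
    the iteration convergent on bipartite graphs without changing the
    eigenvectors.  An edgeless graph returns the zero vector.
    """
    C = np.asarray(C, dtype=float)
    n = len(C)
    if C.sum() == 0:
        return np.zeros(n)
    A = C + np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        w = A @ v
        w /= np.linalg.norm(w)
        if np.abs(w - v).max() < tol:
            v = w
            break
        v = w
    return np.maximum(v, 0.0) / np.linalg.norm(np.maximum(v, 0.0))


def centrality_features(net: ProvinceNetwork) -> pd.DataFrame:
    """Degree, betweenness, closeness and eigenvector centrality per node.

    Closeness uses the Wasserman-Faust convention: computed within a node's
    component and scaled by (n_c - 1)/(N - 1); isolated nodes get 0.
    """
    C = net.C
    G = nx.from_numpy_array(C)
    n = len(C)
    cc = nx.closeness_centrality(G, wf_improved=True)
    return pd.DataFrame(
        {
            "degree": C.sum(axis=1),
            "betweenness": betweenness(C),
            "closeness": [cc[i] for i in range(n)],
            "eigenvector": eigenvector_centrality(C),
        },
        index=net.node_ids if net.node_ids is not None else np.arange(n),
    )


def augment_panel(panel_year: pd.DataFrame, feats: pd.DataFrame) -> pd.DataFrame:
    """Append the four centrality columns to a per-year indicator matrix."""
    if not panel_year.index.equals(feats.index):
        if set(panel_year.index) != set(feats.index):
            raise ValueError("province ids of panel and centrality features do not match")
        feats = feats.loc[panel_year.index]
    out = pd.concat([panel_year, feats], axis=1)
    if out.shape[1] != panel_year.shape[1] + 4:
        raise ValueError("centrality features must contribute exactly 4 columns")
    return out


#: category label for the appended centrality columns
NETWORK_CATEGORY = "Network"
NETWORK_FEATURES = ("degree", "betweenness", "closeness", "eigenvector")


def export_network(net: ProvinceNetwork, edges_path, entropy_path) -> None:
    """Write the edge list (TSV: source, target) and the entropy curve CSV."""
    pd.DataFrame(net.edge_list(), columns=["source", "target"]).to_csv(
        edges_path, sep="\t", index=False
    )
    pd.DataFrame(net.entropy_curve, columns=["threshold", "entropy"]).to_csv(
        entropy_path, index=False
    )
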