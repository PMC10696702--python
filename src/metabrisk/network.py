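"""Gaussian graphical model estimation and network characterisation.

A Gaussian graphical model draws an edge between two metabolites when their
*partial* correlation — association conditioned on all remaining metabolites
— is non-zero, which removes most of the spurious links marginal correlation
networks show.  Partial correlations come from the inverse of the
(optionally shrinkage-regularised) covariance matrix:
``pcor_ij = -omega_ij / sqrt(omega_ii * omega_jj)``.

Edge significance uses the Fisher z-transform of the partial correlation
with variance ``1 / (n - (p - 2) - 3)`` (the conditioning set has p - 2
variables), two-sided p-values and Benjamini-Hochberg adjustment across all
pairs; edges are kept at q < 0.05.  Node importance is unnormalised
betweenness centrality on the significant-edge graph, and each node carries
a between-group effect z-score (Welch t on log abundances mapped through its
t distribution to a standard-normal quantile) with its own BH q-value.

The "cutoff" on centrality is a display threshold: nodes below it are
flagged, never removed.  An alternative reading — dropping weak edges before
computing centrality — is available via ``edge_cutoff``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from sklearn.covariance import LedoitWolf
from statsmodels.stats.multitest import multipletests


def partial_correlations(X: np.ndarray, shrinkage: str | float = "auto"
                         ) -> np.ndarray:
    """Partial-correlation matrix from (shrinkage-regularised) inverse covariance.

    ``shrinkage="auto"`` applies Ledoit-Wolf analytic shrinkage toward the
    scaled identity when p/n > 0.2 and no shrinkage otherwise; a float in
    [0, 1) mixes the empirical covariance with its average-variance diagonal;
    0 uses the plain inverse and raises on (near-)singular covariance.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= 3 or p < 2:
        raise ValueError("need n > 3 samples and p >= 2 variables")
    S = np.cov(X, rowvar=False, ddof=1)
    if shrinkage == "auto":
        if p / n > 0.2:
            S = LedoitWolf(assume_centered=False).fit(X).covariance_
    elif isinstance(shrinkage, (int, float)):
        a = float(shrinkage)
        if not (0.0 <= a < 1.0):
            raise ValueError("shrinkage value must lie in [0, 1)")
        if a > 0:
            S = (1 - a) * S + a * (np.trace(S) / p) * np.eye(p)
        else:
            if np.linalg.cond(S) > 1e12:
                raise ValueError(
                    "covariance is singular or ill-conditioned with shrinkage=0; "
                    "use shrinkage='auto' or a positive value")
    else:
        raise ValueError("shrinkage must be 'auto' or a number in [0, 1)")
    omega = np.linalg.inv(S)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    pcor = (pcor + pcor.T) / 2.0
    np.fill_diagonal(pcor, 1.0)
    return pcor


def edge_tests(pcor: np.ndarray, n: int, q_threshold: float = 0.05
               ) -> pd.DataFrame:
    """Fisher-z tests of all partial correlations with BH adjustment.

    The effective degrees of freedom account for the p - 2 conditioning
    variables: z = atanh(r) has standard error 1/sqrt(n - (p - 2) - 3).
    Returns one row per unordered pair (i, j, r, z, p, q, significant).
    """
    p_vars = pcor.shape[0]
    df_term = n - (p_vars - 2) - 3
    if df_term < 2:
        raise ValueError(
            f"insufficient degrees of freedom for Fisher z (n - (p-2) - 3 = {df_term})")
    iu = np.triu_indices(p_vars, k=1)
    r = np.clip(pcor[iu], -1 + 1e-15, 1 - 1e-15)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(df_term)
    pvals = 2.0 * stats.norm.sf(np.abs(z) / se)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"i": iu[0], "j": iu[1], "r": pcor[iu], "z": z,
                         "p_value": pvals, "q_value": qvals,
                         "significant": qvals < q_threshold})


def betweenness_centrality(edges: pd.DataFrame | list[tuple[int, int]],
                           nodes) -> pd.Series:
    """Unnormalised betweenness (shortest-path counts) per node.

    ``edges`` is either the frame from :func:`edge_tests` (significant rows
    are used) or a list of (i, j) pairs; in both cases i and j are positional
    indices into ``nodes``.  Isolated nodes score 0.
    """
    nodes = list(nodes)
    if isinstance(edges, pd.DataFrame):
        sub = edges[edges["significant"]] if "significant" in edges else edges
        pairs = list(zip(sub["i"].astype(int), sub["j"].astype(int)))
    else:
        pairs = [(int(i), int(j)) for i, j in edges]
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    g.add_edges_from(pairs)
    bc = nx.betweenness_centrality(g, normalized=False)
    return pd.Series([bc[k] for k in range(len(nodes))], index=nodes)


def node_effect_z(abundance: pd.DataFrame, groups: pd.Series,
                  case_label: str = "case", q_threshold: float = 0.05
                  ) -> pd.DataFrame:
    """Per-metabolite between-group effect z-scores with BH adjustment.

    The z-score is the Welch t statistic of log abundance (case vs. control)
    mapped through its t distribution onto the standard-normal scale, so
    magnitudes are comparable across metabolites with different group
    variances.  Zero variance in both groups yields a flagged, undefined z.
    """
    is_case = (groups == case_label).to_numpy()
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    logged = np.log(abundance.to_numpy(dtype=float))
    a, b = logged[is_case], logged[~is_case]
    rows = []
    for k, feat in enumerate(abundance.columns):
        if a[:, k].var(ddof=1) == 0 and b[:, k].var(ddof=1) == 0:
            rows.append({"feature": feat, "z": np.nan, "p_value": np.nan,
                         "computed": False})
            continue
        res = stats.ttest_ind(a[:, k], b[:, k], equal_var=False)
        # map through the t df to a standard-normal quantile, keeping the sign
        p_two = float(res.pvalue)
        z = float(np.sign(res.statistic) * stats.norm.isf(
            max(p_two, 1e-300) / 2.0))
        rows.append({"feature": feat, "z": z, "p_value": p_two, "computed": True})
    out = pd.DataFrame(rows).set_index("feature")
    q = np.full(len(out), np.nan)
    mask = out["computed"].to_numpy()
    if mask.any():
        q[mask] = multipletests(out.loc[mask, "p_value"], method="fdr_bh")[1]
    out["q_value"] = q
    out["significant"] = out["q_value"] < q_threshold
    return out


@dataclass
class NetworkModel:
    """Estimated metabolite network: partial correlations, edges, centrality,
    per-node effect z-scores."""

    nodes: list[str]
    pcor: np.ndarray
    edges: pd.DataFrame           # i, j, r, z, p_value, q_value, significant
    betweenness: pd.Series
    node_stats: pd.DataFrame      # z, p_value, q_value, significant per node
    centrality_cutoff: float = 0.5

    @property
    def displayed(self) -> pd.Series:
        """Nodes at or above the centrality display cutoff (flag, not filter)."""
        return self.betweenness >= self.centrality_cutoff

    def edge_list(self) -> pd.DataFrame:
        out = self.edges.copy()
        out.insert(0, "node_i", [self.nodes[i] for i in out["i"]])
        out.insert(1, "node_j", [self.nodes[j] for j in out["j"]])
        return out

    def node_table(self) -> pd.DataFrame:
        out = self.node_stats.copy()
        out["betweenness"] = self.betweenness.reindex(out.index)
        out["displayed"] = self.displayed.reindex(out.index)
        return out

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            st = self.node_stats.loc[node]
            g.add_node(node, z=float(st["z"]), q=float(st["q_value"]),
                       betweenness=float(self.betweenness[node]))
        for _, row in self.edges[self.edges["significant"]].iterrows():
            g.add_edge(self.nodes[int(row["i"])], self.nodes[int(row["j"])],
                       r=float(row["r"]), p=float(row["p_value"]),
                       q=float(row["q_value"]))
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), path)


def build_network(abundance: pd.DataFrame, scaled: pd.DataFrame,
                  groups: pd.Series, shrinkage: str | float = "auto",
                  q_threshold: float = 0.05, centrality_cutoff: float = 0.5,
                  edge_cutoff: float | None = None) -> NetworkModel:
    """Estimate the full network model for a set of metabolites.

    ``scaled`` (samples × metabolites, log + Pareto) drives the partial
    correlations; ``abundance`` (raw scale) drives the per-node effect
    z-scores.  ``edge_cutoff`` optionally drops edges with |r| below the
    cutoff before centrality — the alternative reading of a "0.5 cutoff";
    by default the cutoff is applied to centrality display flags only.
    """
    nodes = list(scaled.columns)
    pcor = partial_correlations(scaled.to_numpy(dtype=float), shrinkage=shrinkage)
    edges = edge_tests(pcor, n=scaled.shape[0], q_threshold=q_threshold)
    cedges = edges[edges["significant"]]
    if edge_cutoff is not None:
        cedges = cedges[cedges["r"].abs() >= edge_cutoff]
    bc = betweenness_centrality(list(zip(cedges["i"], cedges["j"])),
                                nodes=range(len(nodes)))
    bc.index = nodes
    stats_tab = node_effect_z(abundance.loc[:, nodes], groups,
                              q_threshold=q_threshold)
    return NetworkModel(nodes=nodes, pcor=pcor, edges=edges, betweenness=bc,
                        node_stats=stats_tab, centrality_cutoff=centrality_cutoff)
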