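"""Metabolite-taxon correlation network integration.

Builds the tumour and normal-mucosa correlation networks between bucketed
metabolite intensities and genus relative abundances: Spearman rank
correlation per pair, a p (or BH-q) threshold to define edges, set
comparisons between tissue-class networks, stage-consistent signed edges,
and a seeded force-directed (spring-embedded) layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EdgeSet",
    "Layout",
    "integrate_metabolites",
    "correlate",
    "threshold_network",
    "compare_networks",
    "stage_consistency",
    "spring_layout",
    "plot_network",
]


@dataclass
class EdgeSet:
    """Bipartite metabolite-taxon network with per-edge statistics."""

    nodes: pd.DataFrame   # index = node label, column "kind" in {metabolite, taxon}
    edges: pd.DataFrame   # columns: node_a, node_b, rho, p, q, sign

    def __post_init__(self) -> None:
        e = self.edges
        if len(e):
            if (e["node_a"] == e["node_b"]).any():
                raise ValueError("self-edges are not allowed")
            if (e["rho"].abs() > 1 + 1e-12).any():
                raise ValueError("|rho| must be <= 1")
            pairs = e.apply(lambda r: frozenset((r["node_a"], r["node_b"])), axis=1)
            if pairs.duplicated().any():
                raise ValueError("duplicate edges for an unordered pair")

    def signed_edges(self) -> set[tuple[frozenset, int]]:
        return {
            (frozenset((r.node_a, r.node_b)), int(r.sign))
            for r in self.edges.itertuples()
        }

    def summary(self) -> dict:
        n_nodes = len(self.nodes)
        n_edges = len(self.edges)
        return {
            "n_nodes": n_nodes,
            "n_edges": n_edges,
            "mean_degree": (2 * n_edges / n_nodes) if n_nodes else 0.0,
        }

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for label, row in self.nodes.iterrows():
            g.add_node(label, kind=row["kind"])
        for r in self.edges.itertuples():
            g.add_edge(r.node_a, r.node_b, rho=r.rho, p=r.p, q=r.q, sign=int(r.sign))
        return g


def integrate_metabolites(
    matrix, regions: Mapping[str, Sequence[tuple[float, float]]]
) -> pd.DataFrame:
    """Sum bin intensities over each metabolite's chemical-shift windows.

    ``regions`` maps metabolite name to a list of (lo_ppm, hi_ppm) windows;
    the result is one bucketed intensity per metabolite per sample, the
    node-level features used by the network (rather than all 20000 bins).
    """
    out = {}
    for name, windows in regions.items():
        mask = np.zeros(matrix.bins.size, dtype=bool)
        for lo, hi in windows:
            mask |= (matrix.bins >= lo) & (matrix.bins <= hi)
        if not mask.any():
            raise ValueError(f"metabolite {name!r}: no bins inside its windows")
        out[name] = matrix.X[:, mask].sum(axis=1)
    return pd.DataFrame(out, index=matrix.sample_ids)


def metabolite_regions_from_templates(
    templates, halfwidth: float = 0.02
) -> dict[str, list[tuple[float, float]]]:
    """Integration windows of +-``halfwidth`` ppm around each template peak."""
    return {
        tpl.name: [(c - halfwidth, c + halfwidth) for c, *_ in tpl.peaks]
        for tpl in templates
    }


def correlate(
    metab: pd.DataFrame, taxa: pd.DataFrame, method: str = "spearman"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p for every metabolite-taxon pair.

    Ranks use midranks for ties; p-values come from the t-approximation on
    rho.  Constant columns give NaN (recorded missing).  ``method`` may also
    be ``"regression"`` for a univariate linear-regression slope/p
    alternative.
    """
    if not metab.index.equals(taxa.index):
        raise ValueError("metabolite and taxon tables must share the same sample order")
    if len(metab) < 4:
        raise ValueError("need at least 4 samples to correlate")
    rho = pd.DataFrame(index=metab.columns, columns=taxa.columns, dtype=float)
    pv = pd.DataFrame(index=metab.columns, columns=taxa.columns, dtype=float)
    if method == "spearman":
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.spearmanr(metab.to_numpy(), taxa.to_numpy())
        m = metab.shape[1]
        if np.ndim(res.statistic) == 0:  # scipy collapses the 2-column case
            rho.iloc[0, 0] = res.statistic
            pv.iloc[0, 0] = res.pvalue
        else:
            rho.loc[:, :] = res.statistic[:m, m:]
            pv.loc[:, :] = res.pvalue[:m, m:]
        const_m = metab.std(axis=0) == 0
        const_t = taxa.std(axis=0) == 0
        rho.loc[const_m[const_m].index, :] = np.nan
        rho.loc[:, const_t[const_t].index] = np.nan
        pv[rho.isna()] = np.nan
    elif method == "regression":
        for mcol in metab.columns:
            for tcol in taxa.columns:
                x, y = taxa[tcol].to_numpy(), metab[mcol].to_numpy()
                if x.std() == 0 or y.std() == 0:
                    rho.loc[mcol, tcol] = np.nan
                    pv.loc[mcol, tcol] = np.nan
                    continue
                fit = stats.linregress(x, y)
                rho.loc[mcol, tcol] = fit.rvalue
                pv.loc[mcol, tcol] = fit.pvalue
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return rho, pv


def threshold_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    alpha: float = 0.05,
    fdr: bool = False,
    keep_isolated: bool = False,
) -> EdgeSet:
    """Keep metabolite-taxon edges with p < alpha (or BH q < alpha).

    BH-FDR is computed across all non-missing tested pairs.  Isolated nodes
    are dropped unless ``keep_isolated``.
    """
    records = []
    flat_p = p.to_numpy().ravel()
    valid = np.isfinite(flat_p)
    q_flat = np.full_like(flat_p, np.nan)
    if valid.any():
        q_flat[valid] = multipletests(flat_p[valid], method="fdr_bh")[1]
    q = pd.DataFrame(q_flat.reshape(p.shape), index=p.index, columns=p.columns)
    for m in rho.index:
        for t in rho.columns:
            r, pval, qval = rho.loc[m, t], p.loc[m, t], q.loc[m, t]
            if not np.isfinite(pval):
                continue
            crit = qval if fdr else pval
            if crit < alpha:
                records.append(
                    {"node_a": m, "node_b": t, "rho": r, "p": pval, "q": qval,
                     "sign": int(np.sign(r))}
                )
    edges = pd.DataFrame(records, columns=["node_a", "node_b", "rho", "p", "q", "sign"])
    if keep_isolated:
        labels = list(rho.index) + list(rho.columns)
        kinds = ["metabolite"] * len(rho.index) + ["taxon"] * len(rho.columns)
    else:
        used = set(edges["node_a"]) | set(edges["node_b"])
        labels = [m for m in rho.index if m in used] + [t for t in rho.columns if t in used]
        kinds = ["metabolite" if l in set(rho.index) else "taxon" for l in labels]
    nodes = pd.DataFrame({"kind": kinds}, index=pd.Index(labels, name="node"))
    return EdgeSet(nodes=nodes, edges=edges)


def compare_networks(a: EdgeSet, b: EdgeSet) -> dict:
    """Shared/unique nodes and signed edges plus connectivity summaries."""
    nodes_a, nodes_b = set(a.nodes.index), set(b.nodes.index)
    edges_a, edges_b = a.signed_edges(), b.signed_edges()
    return {
        "shared_nodes": sorted(nodes_a & nodes_b),
        "nodes_only_a": sorted(nodes_a - nodes_b),
        "nodes_only_b": sorted(nodes_b - nodes_a),
        "shared_edges": sorted(
            (tuple(sorted(pair)), sign) for pair, sign in edges_a & edges_b
        ),
        "edges_only_a": sorted(
            (tuple(sorted(pair)), sign) for pair, sign in edges_a - edges_b
        ),
        "edges_only_b": sorted(
            (tuple(sorted(pair)), sign) for pair, sign in edges_b - edges_a
        ),
        "summary_a": a.summary(),
        "summary_b": b.summary(),
    }


def stage_consistency(edge_sets: Mapping[str, EdgeSet]) -> list[tuple[tuple, int]]:
    """Signed edges present (same pair, same sign) in every stage network."""
    if len(edge_sets) < 2:
        raise ValueError("need at least two stage networks")
    sets = [es.signed_edges() for es in edge_sets.values()]
    common = set.intersection(*sets)
    return sorted((tuple(sorted(pair)), sign) for pair, sign in common)


@dataclass
class Layout:
    positions: dict = field(default_factory=dict)
    iterations: int = 0
    seed: int = 0


def spring_layout(
    e: EdgeSet,
    iterations: int = 50,
    seed: int = 0,
    separate_components: bool = True,
) -> Layout:
    """Fruchterman-Reingold force-directed placement, attraction weighted by |rho|.

    Deterministic under ``seed``.  With ``separate_components`` each connected
    component is laid out on its own and components are tiled on a grid so
    their bounding boxes cannot overlap.
    """
    if len(e.nodes) < 1:
        raise ValueError("layout needs at least one node")
    g = e.to_graph()
    for u, v, data in g.edges(data=True):
        data["weight"] = abs(data.get("rho", 1.0))
    if not separate_components:
        pos = nx.spring_layout(g, iterations=iterations, seed=seed, weight="weight")
        return Layout(positions={n: (float(x), float(y)) for n, (x, y) in pos.items()},
                      iterations=iterations, seed=seed)
    positions: dict = {}
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)[0]))
    n_cols = int(np.ceil(np.sqrt(len(comps))))
    spacing = 3.0  # component layouts live in [-1, 1]^2; 3 units apart cannot overlap
    for idx, comp in enumerate(comps):
        sub = g.subgraph(comp)
        pos = nx.spring_layout(sub, iterations=iterations, seed=seed + idx, weight="weight")
        ox, oy = spacing * (idx % n_cols), spacing * (idx // n_cols)
        for node, (x, y) in pos.items():
            positions[node] = (float(x) + ox, float(y) + oy)
    return Layout(positions=positions, iterations=iterations, seed=seed)


def plot_network(e: EdgeSet, layout: Layout, path, title: str = "") -> None:
    """Render the network: metabolites as squares, taxa as circles, edges
    green (positive rho) or red (negative), width scaled by |rho|."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    for r in e.edges.itertuples():
        (x1, y1), (x2, y2) = layout.positions[r.node_a], layout.positions[r.node_b]
        ax.plot([x1, x2], [y1, y2],
                color="seagreen" if r.sign >= 0 else "firebrick",
                linewidth=0.5 + 2.0 * abs(r.rho), alpha=0.7, zorder=1)
    for label, row in e.nodes.iterrows():
        x, y = layout.positions[label]
        marker = "s" if row["kind"] == "metabolite" else "o"
        ax.scatter([x], [y], marker=marker, s=60, color="steelblue", zorder=2)
        ax.annotate(label, (x, y), fontsize=6, ha="center", va="bottom",
                    xytext=(0, 5), textcoords="offset points")
    ax.set_title(title)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
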