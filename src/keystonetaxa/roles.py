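"""Module detection, Zi/Pi node topology, and keystone role classification.

Modules come from fast-greedy (Clauset-Newman-Moore) modularity
maximisation on the unweighted thresholded graph.  Each node is then placed
in the within-module degree (Zi) vs among-module connectivity (Pi) plane:

    Zi = (k_within - mean k_within of the module) / population sd
    Pi = 1 - sum_s (k_is / k)^2        (participation coefficient)

and classified with the Guimera-Amaral-style cutoffs used throughout the
microbial-network literature:

    peripheral    Zi <= 2.5, Pi <= 0.62
    connector     Zi <= 2.5, Pi >  0.62
    module hub    Zi >  2.5, Pi <= 0.62
    network hub   Zi >  2.5, Pi >  0.62

Connectors and hubs are the keystone candidates: removal of a connector
decouples modules, removal of a module hub disintegrates its module.
"""

from __future__ import annotations

from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .rmt import NetworkModel
from .table_io import TraitTable

__all__ = [
    "fast_greedy_partition",
    "modularity",
    "modularity_exact",
    "node_topology",
    "classify_role",
    "role_census",
    "module_trait_correlation",
    "annotate_network",
]

ZI_CUTOFF = 2.5
PI_CUTOFF = 0.62


def fast_greedy_partition(network: NetworkModel | nx.Graph) -> tuple[dict, float]:
    """Fast-greedy modularity partition of the unweighted graph.

    Runs Clauset-Newman-Moore greedy agglomeration followed by a
    deterministic single-node refinement sweep (greedy moves that strictly
    increase Q) — plain CNM is known to misplace individual border nodes.
    Module ids are assigned in decreasing module-size order.  Raises on an
    edgeless graph.
    """
    g = network.graph if isinstance(network, NetworkModel) else network
    if g.number_of_edges() == 0:
        raise ValueError("cannot partition a graph with no edges")
    communities = nx.algorithms.community.greedy_modularity_communities(g, weight=None)
    module_of = {node: m for m, comm in enumerate(communities) for node in comm}
    module_of = _refine_partition(g, module_of)
    # relabel in decreasing module-size order
    sizes: dict = {}
    for m in module_of.values():
        sizes[m] = sizes.get(m, 0) + 1
    order = {m: i for i, m in enumerate(sorted(sizes, key=lambda m: (-sizes[m], m)))}
    module_of = {n: order[m] for n, m in module_of.items()}
    q = modularity(g, module_of)
    if isinstance(network, NetworkModel):
        network.module_of = module_of
        network.Q = q
    return module_of, q


def _refine_partition(g: nx.Graph, module_of: dict, max_sweeps: int = 50) -> dict:
    """Greedy single-node moves to adjacent modules while Q increases."""
    from collections import defaultdict

    module_of = dict(module_of)
    m = g.number_of_edges()
    deg = dict(g.degree())
    tot: dict = defaultdict(int)
    for n, c in module_of.items():
        tot[c] += deg[n]
    for _ in range(max_sweeps):
        moved = False
        for n in g.nodes:
            c0 = module_of[n]
            links: dict = defaultdict(int)
            for nb in g.neighbors(n):
                links[module_of[nb]] += 1
            best_gain, best_c = 0.0, c0
            for c, l in links.items():
                if c == c0:
                    continue
                gain = (l - links.get(c0, 0)) / m - deg[n] * (
                    tot[c] - (tot[c0] - deg[n])
                ) / (2 * m * m)
                if gain > best_gain + 1e-15:
                    best_gain, best_c = gain, c
            if best_c != c0:
                module_of[n] = best_c
                tot[c0] -= deg[n]
                tot[best_c] += deg[n]
                moved = True
        if not moved:
            break
    return module_of


def modularity(g: nx.Graph, module_of: dict) -> float:
    """Newman modularity Q = sum_m (e_mm - a_m^2) of a partition."""
    return float(modularity_exact(g, module_of))


def modularity_exact(g: nx.Graph, module_of: dict) -> Fraction:
    """Q as an exact rational: e_mm is the fraction of edges inside module m,
    a_m the fraction of edge ends attached to module m."""
    m_edges = g.number_of_edges()
    if m_edges == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    modules = set(module_of.values())
    q = Fraction(0)
    for mod in modules:
        members = {n for n, mm in module_of.items() if mm == mod}
        internal = sum(1 for u, v in g.edges if u in members and v in members)
        degree_sum = sum(d for n, d in g.degree(members))
        q += Fraction(internal, m_edges) - Fraction(degree_sum, 2 * m_edges) ** 2
    return q


def node_topology(
    network: NetworkModel | nx.Graph, module_of: dict | None = None
) -> pd.DataFrame:
    """Per-node degree, within-module degree, Zi, Pi, and role.

    Zi uses the population standard deviation of within-module degrees over
    the node's module and is set to 0 when that sd is 0 (degenerate module);
    Pi is 0 for isolated nodes.  Returns a DataFrame indexed by node with
    columns module, k, k_within, Zi, Pi, role.
    """
    g = network.graph if isinstance(network, NetworkModel) else network
    if module_of is None:
        module_of = network.module_of if isinstance(network, NetworkModel) else None
    if module_of is None:
        raise ValueError("no module partition available; run fast_greedy_partition")
    missing = [n for n in g.nodes if n not in module_of]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")

    nodes = list(g.nodes)
    k_within = {}
    k_per_module = {}
    for n in nodes:
        per = {}
        for nb in g.neighbors(n):
            m = module_of[nb]
            per[m] = per.get(m, 0) + 1
        k_per_module[n] = per
        k_within[n] = per.get(module_of[n], 0)

    # module-wise mean/sd of within-degree
    by_module: dict = {}
    for n in nodes:
        by_module.setdefault(module_of[n], []).append(k_within[n])
    mod_stats = {
        m: (np.mean(v), np.std(v, ddof=0)) for m, v in by_module.items()
    }

    rows = []
    for n in nodes:
        k = g.degree(n)
        mean, sd = mod_stats[module_of[n]]
        zi = 0.0 if sd == 0 else (k_within[n] - mean) / sd
        pi = 0.0
        if k > 0:
            pi = 1.0 - sum((c / k) ** 2 for c in k_per_module[n].values())
        rows.append(
            {
                "node": n,
                "module": module_of[n],
                "k": k,
                "k_within": k_within[n],
                "Zi": zi,
                "Pi": pi,
                "role": classify_role(zi, pi),
            }
        )
    frame = pd.DataFrame(rows).set_index("node")
    if isinstance(network, NetworkModel):
        network.topology = frame
    return frame


def classify_role(zi: float, pi: float) -> str:
    """Four-way keystone role from the (Zi, Pi) plane; boundaries are
    inclusive on the peripheral side (Zi = 2.5, Pi = 0.62 is peripheral)."""
    if not (np.isfinite(zi) and np.isfinite(pi)):
        raise ValueError("Zi and Pi must be finite")
    if zi <= ZI_CUTOFF:
        return "peripheral" if pi <= PI_CUTOFF else "connector"
    return "module hub" if pi <= PI_CUTOFF else "network hub"


def role_census(topology: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per role (all four roles always listed)."""
    roles = ["peripheral", "connector", "module hub", "network hub"]
    counts = topology["role"].value_counts().reindex(roles, fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame(
        {"count": counts, "fraction": counts / total if total else 0.0}
    ).rename_axis("role")


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "#"
    return ""


def module_trait_correlation(
    transformed: pd.DataFrame,
    module_of: dict,
    traits: TraitTable,
    method: str = "pearson",
    min_module_size: int = 3,
    summary: str = "mean",
) -> pd.DataFrame:
    """Correlate each module's summary profile with each host trait.

    The module summary per sample is the mean of the z-scored transformed
    abundances of its member taxa (so duplicating a member changes
    nothing); ``summary="pc1"`` uses the first principal component
    (eigengene) instead.  Pearson by default; Spearman available.  Modules
    smaller than ``min_module_size`` are skipped.  Significance stars
    follow the # / * / ** convention at P < 0.1 / 0.05 / 0.01.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if summary not in ("mean", "pc1"):
        raise ValueError("summary must be 'mean' or 'pc1'")
    samples = [s for s in traits.sample_ids if s in transformed.columns]
    if len(samples) < 4:
        raise ValueError("need >= 4 samples shared between abundances and traits")
    x = transformed[samples]
    sd = x.std(axis=1, ddof=0).replace(0, 1.0)
    z = x.sub(x.mean(axis=1), axis=0).div(sd, axis=0)

    modules: dict = {}
    for taxon, m in module_of.items():
        if taxon in z.index:
            modules.setdefault(m, []).append(taxon)

    rows = []
    for m, members in sorted(modules.items()):
        if len(members) < min_module_size:
            continue
        block = z.loc[members]
        if summary == "mean":
            profile = block.mean(axis=0)
        else:
            # eigengene: first right singular vector, oriented with the mean
            _, _, vt = np.linalg.svd(block.to_numpy(), full_matrices=False)
            pc1 = pd.Series(vt[0], index=block.columns)
            if pc1.corr(block.mean(axis=0)) < 0:
                pc1 = -pc1
            profile = pc1
        for name in traits.trait_names:
            tv = pd.to_numeric(traits.data.loc[samples, name], errors="coerce")
            ok = tv.notna()
            if ok.sum() < 4:
                continue
            if method == "pearson":
                r, p = sps.pearsonr(profile[ok], tv[ok])
            else:
                r, p = sps.spearmanr(profile[ok], tv[ok])
            rows.append(
                {
                    "module": m,
                    "n_taxa": len(members),
                    "trait": name,
                    "r": float(r),
                    "p": float(p),
                    "stars": _stars(float(p)),
                }
            )
    return pd.DataFrame(rows)


def annotate_network(network: NetworkModel) -> NetworkModel:
    """Partition + topology in one call, stored on the model."""
    fast_greedy_partition(network)
    node_topology(network)
    return network
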