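"""Thresholded Spearman co-occurrence networks and their topology.

A network's edges are ASV pairs whose tie-corrected Spearman correlation
passes both an absolute-rho threshold and a Benjamini-Hochberg FDR threshold
(defaults |rho| > 0.6, q < 0.001, over the top 300 most abundant ASVs).
Modules come from modularity maximisation; node roles on the Zi-Pi plane
(within-module degree z-score vs participation coefficient) classify
keystone candidates as module hubs, connectors or network hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceTable, top_n_asvs

__all__ = [
    "CooccurrenceNetwork",
    "TopologyPanel",
    "NodeRole",
    "spearman_matrix",
    "bh_fdr",
    "build_network",
    "topology_panel",
    "zipi",
    "write_network",
    "read_network",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class CooccurrenceNetwork:
    """Undirected signed weighted graph over ASV nodes plus module map.

    Edge attributes: ``weight`` (signed Spearman rho) and ``q`` (BH-adjusted
    p). ``modules`` maps node -> integer module id.
    """

    graph: nx.Graph
    modules: dict[str, int] = field(default_factory=dict)
    rho_threshold: float = 0.6
    q_threshold: float = 0.001

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_signs(self) -> np.ndarray:
        return np.array([np.sign(d["weight"]) for _, _, d in self.graph.edges(data=True)])


@dataclass
class TopologyPanel:
    """One row of network summary statistics (Table-2 style panel)."""

    edges: int
    nodes: int
    positive_links_pct: float
    negative_links_pct: float
    powerlaw_R2: float
    avgK: float
    avgCC: float
    GD: float
    E: float
    HD: float
    D: float
    Con: float
    RM: float | None = None

    def to_series(self, name: str = "network") -> pd.Series:
        return pd.Series(self.__dict__, name=name)


@dataclass
class NodeRole:
    asv_id: str
    module: int
    zi: float
    pi: float
    role: str  # module hub | connector | network hub | peripheral


def spearman_matrix(table: AbundanceTable) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise tie-corrected Spearman rho and two-sided p over ASVs.

    ASVs that are constant across samples get NaN rho/p against every
    partner (they can never form an edge).
    """
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples for meaningful correlations")
    x = table.counts.astype(float)
    n, m = x.shape
    constant = np.ptp(x, axis=0) == 0
    if m == 1:
        return np.ones((1, 1)), np.zeros((1, 1))
    # tie-corrected Spearman = Pearson correlation of average ranks;
    # p from the t approximation (scipy's default for spearmanr)
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = np.corrcoef(ranks, rowvar=False)
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.abs(rho) >= 1.0] = 0.0
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    p[constant, :] = np.nan
    p[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return rho, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _detect_modules(graph: nx.Graph, method: str = "greedy", seed: int = 0) -> dict:
    """Modularity-based module detection on the positive-association subgraph.

    Modules are groups of co-occurring taxa, so community detection runs on
    positive-weight edges only (negative associations separate modules
    rather than bind them). Greedy modularity maximisation (deterministic)
    by default; Louvain (seeded) by flag. Nodes without a positive edge get
    their own singleton modules.
    """
    if graph.number_of_edges() == 0:
        return {n: i for i, n in enumerate(graph.nodes)}
    pos = nx.Graph()
    pos.add_nodes_from(graph.nodes)
    pos.add_weighted_edges_from(
        (u, v, d.get("weight", 1.0))
        for u, v, d in graph.edges(data=True)
        if d.get("weight", 1.0) > 0
    )
    if pos.number_of_edges() == 0:
        return {n: i for i, n in enumerate(graph.nodes)}
    if method == "greedy":
        comms = nx.community.greedy_modularity_communities(pos, weight="weight")
    elif method == "louvain":
        comms = nx.community.louvain_communities(pos, weight="weight", seed=seed)
    else:
        raise ValueError(f"unknown module detection method {method!r}")
    return {n: i for i, com in enumerate(comms) for n in com}


def build_network(
    table: AbundanceTable,
    rho_threshold: float = 0.6,
    q_threshold: float = 0.001,
    top_n: int | None = 300,
    module_method: str = "greedy",
    seed: int = 0,
) -> CooccurrenceNetwork:
    """Build the thresholded co-occurrence network from a (rarefied) table.

    Keeps edges with |rho| > rho_threshold AND BH-q < q_threshold among the
    ``top_n`` most abundant ASVs; ASVs with no passing edge are excluded
    from the node set. Modules assigned by modularity maximisation.
    """
    if not (0 < rho_threshold <= 1) or not (0 < q_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    sub = top_n_asvs(table, top_n) if top_n is not None else table
    sub = sub.drop_empty_asvs()
    rho, p = spearman_matrix(sub)
    m = sub.n_asvs
    iu = np.triu_indices(m, k=1)
    pvec = p[iu]
    qvec = bh_fdr(pvec)
    rvec = rho[iu]
    passing = (
        ~np.isnan(rvec)
        & ~np.isnan(qvec)
        & (np.abs(rvec) > rho_threshold)
        & (qvec < q_threshold)
    )
    graph = nx.Graph()
    ids = sub.asv_ids
    for k in np.flatnonzero(passing):
        i, j = iu[0][k], iu[1][k]
        graph.add_edge(ids[i], ids[j], weight=float(rvec[k]), q=float(qvec[k]))
    if graph.number_of_edges() == 0:
        warnings.warn("no ASV pair passes both thresholds: empty network", stacklevel=2)
    modules = _detect_modules(graph, method=module_method, seed=seed)
    return CooccurrenceNetwork(graph, modules, rho_threshold, q_threshold)


def topology_panel(
    net: CooccurrenceNetwork,
    n_null: int = 100,
    seed: int = 0,
    compute_rm: bool = True,
    module_method: str = "greedy",
) -> TopologyPanel:
    """Full topology summary of a network.

    avgK = 2E/N, D = 2E/(N(N-1)), avgCC = mean local clustering (degree < 2
    contributes 0), GD = mean geodesic over connected pairs, E = mean of 1/d
    over all pairs (unreachable -> 0), HD = 1/E, Con = fraction of reachable
    pairs, powerlaw_R2 = OLS R^2 of log frequency vs log degree, RM =
    relative modularity against ``n_null`` degree-preserving rewirings.
    """
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    signs = net.edge_signs()
    pos_pct = 100.0 * (signs > 0).sum() / e if e else 0.0
    neg_pct = 100.0 - pos_pct if e else 0.0
    avg_k = 2 * e / n
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    avg_cc = nx.average_clustering(g) if n else 0.0

    # geodesics over connected pairs
    total_pairs = n * (n - 1) / 2
    dist_sum = 0.0
    inv_sum = 0.0
    reachable = 0
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            if dst == src:
                continue
            dist_sum += d
            inv_sum += 1.0 / d
            reachable += 1
    reachable //= 2  # counted both directions
    dist_sum /= 2
    inv_sum /= 2
    gd = dist_sum / reachable if reachable else float("nan")
    eff = inv_sum / total_pairs if total_pairs else 0.0
    hd = 1.0 / eff if eff > 0 else float("inf")
    con = reachable / total_pairs if total_pairs else 0.0

    # degree distribution power-law fit on the log-log histogram
    degrees = np.array([d for _, d in g.degree()])
    vals, freq = np.unique(degrees[degrees > 0], return_counts=True)
    if len(vals) >= 2:
        lx, ly = np.log(vals), np.log(freq)
        slope, intercept = np.polyfit(lx, ly, 1)
        resid = ly - (slope * lx + intercept)
        sst = ((ly - ly.mean()) ** 2).sum()
        r2 = 1.0 - (resid**2).sum() / sst if sst > 0 else 0.0
    else:
        r2 = 0.0

    rm = None
    if compute_rm and e > 0:
        if n_null < 1:
            raise ValueError("n_null must be >= 1 when RM is requested")
        rm = _relative_modularity(net, n_null=n_null, seed=seed, module_method=module_method)

    return TopologyPanel(
        edges=e,
        nodes=n,
        positive_links_pct=float(pos_pct),
        negative_links_pct=float(neg_pct),
        powerlaw_R2=float(r2),
        avgK=float(avg_k),
        avgCC=float(avg_cc),
        GD=float(gd),
        E=float(eff),
        HD=float(hd),
        D=float(density),
        Con=float(con),
        RM=rm,
    )


def _modularity(graph: nx.Graph, modules: dict) -> float:
    # unweighted modularity of the partition on the unsigned skeleton, so
    # observed and degree-preserving null graphs are scored identically
    comms: dict[int, set] = {}
    for node, mod in modules.items():
        comms.setdefault(mod, set()).add(node)
    return nx.community.modularity(graph, comms.values(), weight=None)


def _relative_modularity(
    net: CooccurrenceNetwork, n_null: int, seed: int, module_method: str = "greedy"
) -> float:
    """(M_obs - mean M_null) / mean M_null over degree-preserving rewirings."""
    g = net.graph
    m_obs = _modularity(g, net.modules)
    rng = np.random.default_rng(seed)
    nulls = []
    n_swaps = max(1, 2 * g.number_of_edges())
    for _ in range(n_null):
        h = g.copy()
        try:
            nx.double_edge_swap(
                h, nswap=n_swaps, max_tries=20 * n_swaps, seed=int(rng.integers(2**31))
            )
        except nx.NetworkXException:
            pass  # too few swappable edges (e.g. near-complete graph);
            # score the possibly partial rewiring
        mods = _detect_modules(h, method=module_method, seed=int(rng.integers(2**31)))
        nulls.append(_modularity(h, mods))
    m_null = float(np.mean(nulls))
    if m_null == 0:
        return float("nan")
    return float((m_obs - m_null) / m_null)


def zipi(net: CooccurrenceNetwork) -> list[NodeRole]:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi = (k_within - mean module within-degree) / sd, Zi = 0 when sd = 0;
    Pi = 1 - sum_s (k_is / k_i)^2. Roles by the four-quadrant thresholds
    Zi 2.5 / Pi 0.62, boundary equality resolved toward the low quadrant.
    """
    g = net.graph
    modules = net.modules
    missing = [n for n in g.nodes if n not in modules]
    if missing:
        raise ValueError(f"nodes without module assignment: {missing[:5]}")
    members: dict[int, list] = {}
    for node in g.nodes:
        members.setdefault(modules[node], []).append(node)

    within_degree = {
        node: sum(1 for nb in g.neighbors(node) if modules[nb] == modules[node])
        for node in g.nodes
    }
    mod_stats = {}
    for mod, nodes in members.items():
        kw = np.array([within_degree[n] for n in nodes], dtype=float)
        mod_stats[mod] = (kw.mean(), kw.std(ddof=0))

    roles = []
    for node in g.nodes:
        k = g.degree(node)
        mean_kw, sd_kw = mod_stats[modules[node]]
        zi = (within_degree[node] - mean_kw) / sd_kw if sd_kw > 0 else 0.0
        if k == 0:
            pi = 0.0
        else:
            per_module: dict[int, int] = {}
            for nb in g.neighbors(node):
                per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in per_module.values())
        roles.append(
            NodeRole(str(node), modules[node], float(zi), float(pi), classify_role(zi, pi))
        )
    return roles


def classify_role(zi: float, pi: float) -> str:
    """Four-quadrant Zi-Pi role; strict inequalities, equality -> low side."""
    hub = zi > ZI_THRESHOLD
    conn = pi > PI_THRESHOLD
    if hub and conn:
        return "network hub"
    if hub:
        return "module hub"
    if conn:
        return "connector"
    return "peripheral"


def roles_to_dataframe(roles: list[NodeRole]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.asv_id, r.module, r.zi, r.pi, r.role) for r in roles],
        columns=["asv_id", "module", "Zi", "Pi", "role"],
    )


# ---------------------------------------------------------------------------
# network IO


def write_network(net: CooccurrenceNetwork, path, format: str = "edgelist") -> None:
    """Write a network as GraphML or 3-column signed weighted edge list."""
    if format == "graphml":
        g = net.graph.copy()
        for node in g.nodes:
            g.nodes[node]["module"] = int(net.modules.get(node, -1))
        nx.write_graphml(g, path)
    elif format == "edgelist":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\tq\n")
            for u, v, d in net.graph.edges(data=True):
                fh.write(f"{u}\t{v}\t{d['weight']:.10g}\t{d.get('q', float('nan')):.10g}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edgelist") -> CooccurrenceNetwork:
    if format == "graphml":
        g = nx.read_graphml(path)
        modules = {n: int(d.get("module", -1)) for n, d in g.nodes(data=True)}
        for n in g.nodes:
            g.nodes[n].pop("module", None)
        return CooccurrenceNetwork(g, modules)
    if format == "edgelist":
        g = nx.Graph()
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        for row in df.itertuples(index=False):
            g.add_edge(row.source, row.target, weight=float(row.weight), q=float(row.q))
        return CooccurrenceNetwork(g, _detect_modules(g))
    raise ValueError(f"unknown network format {format!r}")
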