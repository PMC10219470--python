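"""Co-occurrence network construction, module detection, and keystone taxa.

A molecular ecological network is built per condition group: OTUs present
in more than half the samples are kept, every OTU pair is scored by
Spearman correlation, and only robust relationships (|rho| > 0.6 with
two-sided p < 0.05, t-approximation) become edges.  Modules are found by
modularity maximization; each node then gets a within-module degree
z-score (Zi) and a participation coefficient (Pi), and is classified as a
peripheral, connector, provincial hub, or kinless hub at the conventional
Guimera-Amaral cutoffs Zi = 2.5 and Pi = 0.62.  Connectors and both hub
classes together form the keystone set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62
ROLE_PERIPHERAL = "peripheral"
ROLE_CONNECTOR = "connector"
ROLE_PROVINCIAL = "provincial_hub"
ROLE_KINLESS = "kinless_hub"
KEYSTONE_ROLES = (ROLE_CONNECTOR, ROLE_PROVINCIAL, ROLE_KINLESS)


def prevalence_filter(table: pd.DataFrame, min_prevalence: float = 0.5) -> pd.DataFrame:
    """Keep OTUs with nonzero counts in strictly more than ``min_prevalence``
    of the samples (23/44 passes at 0.5; 22/44 does not)."""
    if not 0 < min_prevalence <= 1:
        raise ValueError(f"min_prevalence must be in (0, 1], got {min_prevalence}")
    prev = (table > 0).mean(axis=0)
    kept = prev.index[prev > min_prevalence]
    if len(kept) == 0:
        raise ValueError(
            f"no OTU exceeds prevalence {min_prevalence} (max observed {prev.max():.3f})")
    return table[kept]


def correlation_edges(table: pd.DataFrame, rho_min: float = 0.6,
                      p_max: float = 0.05) -> pd.DataFrame:
    """All-pairs Spearman screen; returns the retained edge list.

    Pairs are kept when |rho| > rho_min and p < p_max (two-sided,
    t-approximation; average ranks on ties).  Pairs involving a
    zero-variance OTU are undefined and excluded with a warning count.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 samples for a correlation network")
    variances = table.to_numpy(float).var(axis=0)
    constant = variances == 0
    if constant.any():
        warnings.warn(f"excluding {int(constant.sum())} zero-variance OTU(s) "
                      f"({constant.sum() * (len(table.columns) - 1)} pairs affected)",
                      stacklevel=2)
    cols = table.columns[~constant]
    empty = pd.DataFrame({"otu_a": pd.Series(dtype=str), "otu_b": pd.Series(dtype=str),
                          "rho": pd.Series(dtype=float), "p": pd.Series(dtype=float)})
    if len(cols) < 2:
        return empty
    sub = table[cols]
    rho, p = stats.spearmanr(sub.to_numpy(float), axis=0)
    if np.ndim(rho) == 0:       # scipy collapses the 2-column case to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    iu, ju = np.triu_indices(len(cols), k=1)
    keep = (np.abs(rho[iu, ju]) > rho_min) & (p[iu, ju] < p_max)
    return pd.DataFrame({
        "otu_a": cols[iu[keep]],
        "otu_b": cols[ju[keep]],
        "rho": rho[iu, ju][keep],
        "p": p[iu, ju][keep],
    })


def build_network(table: pd.DataFrame, tax: pd.DataFrame | None = None,
                  rho_min: float = 0.6, p_max: float = 0.05,
                  group: str | None = None) -> nx.Graph:
    """Assemble the co-occurrence graph from a (filtered) count table.

    Nodes are the table's OTUs, annotated with mean relative abundance and
    phylum; edges carry the signed correlation, |rho| as weight, and the
    sign label used for display.  Isolated OTUs remain in the graph — the
    topology summary, however, reports only connected nodes, matching how
    such networks are conventionally counted.
    """
    edges = correlation_edges(table, rho_min=rho_min, p_max=p_max)
    rel = table.div(table.sum(axis=1), axis=0)
    net = nx.Graph()
    if group is not None:
        net.graph["group"] = group
    for otu in table.columns:
        phylum = tax.loc[otu, "phylum"] if tax is not None and otu in tax.index else "unclassified"
        net.add_node(otu, abundance=float(rel[otu].mean()), phylum=str(phylum))
    for row in edges.itertuples(index=False):
        net.add_edge(row.otu_a, row.otu_b, rho=float(row.rho),
                     weight=float(abs(row.rho)),
                     sign="positive" if row.rho > 0 else "negative",
                     p=float(row.p))
    return net


def modularity_q(net: nx.Graph, modules: dict) -> float:
    """Newman-Girvan modularity Q = sum_m (e_m/E - (d_m/2E)^2) of a
    partition, computed on the unweighted graph."""
    e = net.number_of_edges()
    if e == 0:
        return 0.0
    intra: dict = {}
    degsum: dict = {}
    for node in net.nodes:
        degsum[modules[node]] = degsum.get(modules[node], 0) + net.degree(node)
    for u, v in net.edges:
        if modules[u] == modules[v]:
            intra[modules[u]] = intra.get(modules[u], 0) + 1
    return float(sum(intra.get(m, 0) / e - (degsum.get(m, 0) / (2 * e)) ** 2
                     for m in set(modules.values())))


def detect_modules(net: nx.Graph, seed: int | None = 0) -> tuple[dict, float]:
    """Louvain modularity maximization on the unweighted, unsigned graph.

    Returns (node -> module id, Q).  An edgeless graph puts every node in
    its own module with Q = 0.  The partition is deterministic under a
    fixed seed.
    """
    if net.number_of_edges() == 0:
        modules = {node: i for i, node in enumerate(net.nodes)}
        return modules, 0.0
    communities = nx.community.louvain_communities(net, weight=None, seed=seed)
    communities = sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))
    modules = {node: i for i, comm in enumerate(communities) for node in comm}
    return modules, modularity_q(net, modules)


@dataclass
class NodeRole:
    otu: str
    zi: float
    pi: float
    role: str


def classify_role(zi: float, pi: float, zi_threshold: float = ZI_THRESHOLD,
                  pi_threshold: float = PI_THRESHOLD) -> str:
    """Four-way Zi-Pi classification; exact threshold values fall to the
    lower category, so the four roles partition the plane."""
    high_z = zi > zi_threshold
    high_p = pi > pi_threshold
    if high_z and high_p:
        return ROLE_KINLESS
    if high_z:
        return ROLE_PROVINCIAL
    if high_p:
        return ROLE_CONNECTOR
    return ROLE_PERIPHERAL


def zi_pi(net: nx.Graph, modules: dict, use_sample_sd: bool = False) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    Zi standardizes a node's links into its own module against the
    distribution of that quantity over the module's members (population
    standard deviation by default; ``use_sample_sd`` switches the
    convention).  A module whose members all have identical within-module
    degree has sd 0 and its members get Zi = 0.  Pi = 1 - sum_t
    (k_it / k_i)^2 over modules t, with Pi = 0 for isolated nodes.
    """
    nodes = list(net.nodes)
    links_to: dict = {}          # node -> module -> link count
    for node in nodes:
        cnt: dict = {}
        for nbr in net.neighbors(node):
            cnt[modules[nbr]] = cnt.get(modules[nbr], 0) + 1
        links_to[node] = cnt
    members: dict = {}
    for node in nodes:
        members.setdefault(modules[node], []).append(node)
    rows = []
    for node in nodes:
        mod = modules[node]
        k_in = np.array([links_to[j].get(mod, 0) for j in members[mod]], float)
        sd = k_in.std(ddof=1 if use_sample_sd else 0) if len(k_in) > 1 else 0.0
        own = links_to[node].get(mod, 0)
        zi = float((own - k_in.mean()) / sd) if sd > 0 else 0.0
        k = net.degree(node)
        pi = float(1.0 - sum((c / k) ** 2 for c in links_to[node].values())) if k > 0 else 0.0
        rows.append(NodeRole(otu=node, zi=zi, pi=pi, role=classify_role(zi, pi)))
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("otu")
    df["module"] = [modules[n] for n in nodes]
    return df


@dataclass
class KeystoneReport:
    """Keystone (non-peripheral) nodes of one group's network, with genus,
    relative-abundance range across samples, and the set's read share."""
    group: str | None
    table: pd.DataFrame
    share: float


def keystone_taxa(roles: pd.DataFrame, tax: pd.DataFrame, table: pd.DataFrame,
                  group: str | None = None) -> KeystoneReport:
    """Extract connectors and hubs and summarize their abundances.

    ``table`` holds the counts of the samples the network was built from;
    the report's ``share`` is total keystone reads over total reads.
    """
    keystones = roles.index[roles["role"].isin(KEYSTONE_ROLES)]
    rel = table.div(table.sum(axis=1), axis=0)
    rows = []
    for otu in keystones:
        genus = str(tax.loc[otu, "genus"]) if otu in tax.index else "unclassified"
        r = rel[otu] if otu in rel.columns else pd.Series(0.0, index=rel.index)
        rows.append({
            "otu": otu, "genus": genus,
            "zi": roles.loc[otu, "zi"], "pi": roles.loc[otu, "pi"],
            "role": roles.loc[otu, "role"],
            "abundance_min": float(r.min()), "abundance_max": float(r.max()),
            "abundance_mean": float(r.mean()),
        })
    report = pd.DataFrame(rows, columns=["otu", "genus", "zi", "pi", "role",
                                         "abundance_min", "abundance_max", "abundance_mean"])
    if len(report):
        report = report.set_index("otu")
    total = float(table.to_numpy().sum())
    key_reads = float(table[[o for o in keystones if o in table.columns]].to_numpy().sum())
    return KeystoneReport(group=group, table=report,
                          share=key_reads / total if total > 0 else 0.0)


def compare_keystones(report_a: KeystoneReport, report_b: KeystoneReport,
                      table: pd.DataFrame, metadata: pd.DataFrame,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Between-group abundance test for every keystone of either network.

    Two-sided Wilcoxon rank-sum on relative abundances across all samples,
    Benjamini-Hochberg adjusted; ``significant`` flags adjusted p < alpha
    and ``higher_in`` names the group with the larger mean.
    """
    otus = sorted(set(report_a.table.index) | set(report_b.table.index))
    missing = [o for o in otus if o not in table.columns]
    if missing:
        warnings.warn(f"skipping keystone OTU(s) absent from the table: {missing}",
                      stacklevel=2)
        otus = [o for o in otus if o in table.columns]
    rel = table.div(table.sum(axis=1), axis=0)
    groups = metadata.loc[table.index, "group"]
    g1, g2 = sorted(groups.unique())
    rows = []
    for otu in otus:
        a, b = rel.loc[groups == g1, otu], rel.loc[groups == g2, otu]
        if np.ptp(rel[otu].to_numpy()) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"otu": otu, "p": p,
                     "higher_in": g1 if a.mean() >= b.mean() else g2})
    out = pd.DataFrame(rows, columns=["otu", "p", "higher_in"])
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
        out = out.set_index("otu")
    return out


@dataclass
class TopologySummary:
    node_count: int
    edge_count: int
    positive_edge_fraction: float
    average_degree: float
    average_clustering: float
    average_path_length: float
    modularity: float
    module_count: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def topology_summary(net: nx.Graph, modules: dict | None = None,
                     q: float | None = None) -> TopologySummary:
    """Standard topological features of one group's network.

    Node and edge counts cover non-isolated nodes; clustering is the mean
    local clustering coefficient (0 for degree < 2); the average path
    length is taken over connected pairs of the largest connected
    component, since thresholded correlation networks are fragmented.
    """
    connected = [n for n, d in net.degree() if d > 0]
    sub = net.subgraph(connected)
    n, e = sub.number_of_nodes(), sub.number_of_edges()
    if n == 0:
        warnings.warn("empty network: all-zero topology summary", stacklevel=2)
        return TopologySummary(0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0)
    pos = sum(1 for _, _, d in sub.edges(data=True) if d.get("rho", 1.0) > 0)
    if modules is None:
        modules, q = detect_modules(net)
    if q is None:
        q = modularity_q(net, modules)
    giant = sub.subgraph(max(nx.connected_components(sub), key=len))
    apl = nx.average_shortest_path_length(giant) if giant.number_of_nodes() > 1 else 0.0
    module_count = len({modules[x] for x in connected}) if connected else 0
    return TopologySummary(
        node_count=n, edge_count=e,
        positive_edge_fraction=pos / e if e else 0.0,
        average_degree=2.0 * e / n,
        average_clustering=float(nx.average_clustering(sub)),
        average_path_length=float(apl),
        modularity=float(q),
        module_count=module_count,
    )
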