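"""Co-occurrence network construction and subcommunity statistics.

The procedure: pairwise Spearman correlation between OTU abundance profiles,
Benjamini-Hochberg adjustment over all distinct pairs, an edge for every pair
with ``|rho| >= 0.6`` and BH-adjusted ``p < 0.01``, removal of small connected
components (< 4 nodes — path- or cycle-shaped fragments alike), and
decomposition of the surviving graph into subcommunities (SCs). Per sample and
SC, two statistics summarise how much of a subcommunity a host carries:

* co-occurrence percentage (completeness):
  ``100 × (number of the SC's OTUs present in the sample) / (SC size)``
* total abundance (richness): the sum of the sample's relative abundances of
  the SC's OTUs.

Group differences in either statistic are tested with two-sided Wilcoxon
rank-sum tests, BH-adjusted over the whole family of (group pair × SC ×
metric) comparisons.
"""

from __future__ import annotations

import itertools
import logging
import string
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import RelAbundanceTable, SampleMetadata, TaxonomyMap

__all__ = [
    "CorrelationResult",
    "spearman_matrix",
    "bh_adjust",
    "CooccurrenceNetwork",
    "build_network",
    "prune_network",
    "Subcommunity",
    "extract_subcommunities",
    "SCSampleStats",
    "sc_sample_stats",
    "compare_sc_groups",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlation

@dataclass
class CorrelationResult:
    """Pairwise Spearman correlations with raw and BH-adjusted p-values."""

    otu_ids: list[str]
    rho: np.ndarray  # symmetric, unit diagonal
    p_raw: np.ndarray
    q_bh: np.ndarray  # BH over the lower-triangle family

    def pair(self, a: str, b: str) -> tuple[float, float, float]:
        i, j = self.otu_ids.index(a), self.otu_ids.index(b)
        return float(self.rho[i, j]), float(self.p_raw[i, j]), float(self.q_bh[i, j])


def spearman_matrix(rel: RelAbundanceTable) -> CorrelationResult:
    """All-pairs Spearman rank correlation between OTU abundance profiles.

    rho is the Pearson correlation of midranks; p-values come from the
    t-distribution approximation ``t = rho·sqrt((n−2)/(1−rho²))`` with n−2
    degrees of freedom (adequate for the sample sizes this pipeline targets).
    Constant OTU profiles have undefined correlation; those entries are
    recorded as rho = 0, p = 1 and logged. BH adjustment is applied to the
    n(n−1)/2 distinct pairs as a single family.
    """
    x = rel.fractions
    n, m = x.shape
    if m < 2:
        raise ValueError("need at least 2 OTUs")
    if n < 4:
        raise ValueError("need at least 4 samples for meaningful pairwise p-values")
    ranks = stats.rankdata(x, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho, dtype=float)
    bad = ~np.isfinite(rho)
    if bad.any():
        logger.info(
            "spearman_matrix: %d undefined pair(s) (constant profiles) set to rho=0, p=1",
            int(bad.sum() // 2),
        )
        rho[bad] = 0.0
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / (1.0 - rho**2))  # |rho| = 1 -> t = inf -> p = 0
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[bad] = 1.0
    np.fill_diagonal(p, 0.0)
    il = np.tril_indices(m, k=-1)
    q_flat = bh_adjust(p[il])
    q = np.zeros_like(p)
    q[il] = q_flat
    q = q + q.T
    return CorrelationResult(list(rel.otu_ids), rho, p, q)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# network

@dataclass
class CooccurrenceNetwork:
    """OTU co-occurrence graph; nodes carry SC labels, edges carry rho/q/sign."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "rho": d["rho"], "q_value": d["q"], "sign": d["sign"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "q_value", "sign"])

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"otu_id": n, "sc_label": d.get("sc"), "degree": self.graph.degree(n)}
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["otu_id", "sc_label", "degree"])


def build_network(
    corr: CorrelationResult,
    rho_min: float = 0.6,
    q_max: float = 0.01,
) -> CooccurrenceNetwork:
    """Threshold the correlation matrix into a signed co-occurrence graph.

    An edge joins OTUs i, j iff ``|rho_ij| >= rho_min`` and the BH-adjusted
    p-value ``q_ij < q_max``. Edge sign follows the sign of rho. Only OTUs
    incident to at least one edge become nodes.
    """
    if not 0 < rho_min <= 1:
        raise ValueError("rho_min must be in (0, 1]")
    if not 0 < q_max <= 1:
        raise ValueError("q_max must be in (0, 1]")
    m = len(corr.otu_ids)
    g = nx.Graph()
    il = np.tril_indices(m, k=-1)
    keep = (np.abs(corr.rho[il]) >= rho_min) & (corr.q_bh[il] < q_max)
    for i, j in zip(il[0][keep], il[1][keep]):
        rho = float(corr.rho[i, j])
        g.add_edge(
            corr.otu_ids[j],
            corr.otu_ids[i],
            rho=rho,
            q=float(corr.q_bh[i, j]),
            sign="positive" if rho > 0 else "negative",
        )
    return CooccurrenceNetwork(graph=g)


def prune_network(net: CooccurrenceNetwork, min_component_size: int = 4) -> CooccurrenceNetwork:
    """Drop connected components smaller than ``min_component_size`` nodes.

    A component with fewer than 4 nodes is necessarily a small path or cycle;
    both shapes are removed by the single size rule. Removals are logged with
    their membership.
    """
    g = net.graph.copy()
    removed = [c for c in nx.connected_components(g) if len(c) < min_component_size]
    for comp in removed:
        logger.info("prune_network: removing component of %d node(s): %s", len(comp), sorted(comp))
        g.remove_nodes_from(comp)
    if g.number_of_nodes() == 0 and (removed or net.n_nodes == 0):
        warnings.warn("pruning left an empty network", stacklevel=2)
    return CooccurrenceNetwork(graph=g)


# ---------------------------------------------------------------------------
# subcommunities

def _sc_labels():
    # a, b, ..., z, aa, ab, ... — conventional lowercase SC labels
    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_lowercase, repeat=size):
            yield "".join(combo)


@dataclass
class Subcommunity:
    """A cohesive subgraph of the pruned network."""

    label: str
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)

    def class_composition(self, taxonomy: TaxonomyMap) -> pd.Series:
        """Share of member OTUs per taxonomic class (unannotated → '')."""
        classes = [taxonomy.rank(o, "class") if o in taxonomy else "" for o in self.members]
        return pd.Series(classes).value_counts(normalize=True)


def extract_subcommunities(net: CooccurrenceNetwork, method: str = "components") -> list[Subcommunity]:
    """Partition the pruned network into labelled subcommunities.

    Default: connected components, labelled a, b, c, … by descending size
    (ties by lexicographically smallest member). ``method="modularity"``
    refines with greedy modularity maximisation, which can split a single
    giant component. Node attributes ``sc`` are set in place.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        warnings.warn("empty network: no subcommunities", stacklevel=2)
        return []
    if method == "components":
        groups = [sorted(c) for c in nx.connected_components(g)]
    elif method == "modularity":
        groups = [sorted(c) for c in nx.community.greedy_modularity_communities(g)]
    else:
        raise ValueError(f"method must be 'components' or 'modularity', got {method!r}")
    groups.sort(key=lambda c: (-len(c), c[0]))
    scs = []
    for label, members in zip(_sc_labels(), groups):
        scs.append(Subcommunity(label=label, members=members))
        for m in members:
            g.nodes[m]["sc"] = label
    return scs


# ---------------------------------------------------------------------------
# per-sample SC statistics

@dataclass
class SCSampleStats:
    """Per (sample, SC): completeness percentage and total relative abundance."""

    percent: pd.DataFrame  # samples × SC labels, values in [0, 100]
    total_abundance: pd.DataFrame  # samples × SC labels, values in [0, 1]

    def long_format(self) -> pd.DataFrame:
        recs = []
        for metric, frame in (("cooccurrence_percent", self.percent), ("total_abundance", self.total_abundance)):
            melted = frame.reset_index(names="sample_id").melt(
                id_vars="sample_id", var_name="sc_label", value_name="value"
            )
            melted["metric"] = metric
            recs.append(melted)
        return pd.concat(recs, ignore_index=True)[["sample_id", "sc_label", "metric", "value"]]


def sc_sample_stats(
    rel: RelAbundanceTable,
    scs: list[Subcommunity],
    presence_threshold: float = 0.0,
) -> SCSampleStats:
    """Completeness and richness of each subcommunity in each sample.

    completeness % = 100 × |{SC members with abundance > presence_threshold}| / |SC|;
    richness = Σ member relative abundances. Both zero when no member occurs.
    """
    otu_index = {o: k for k, o in enumerate(rel.otu_ids)}
    percent = {}
    abundance = {}
    for sc in scs:
        if sc.size == 0:
            raise ValueError(f"subcommunity {sc.label!r} is empty")
        missing = [m for m in sc.members if m not in otu_index]
        if missing:
            raise ValueError(f"SC {sc.label!r} members missing from the table: {missing}")
        cols = [otu_index[m] for m in sc.members]
        sub = rel.fractions[:, cols]
        percent[sc.label] = 100.0 * (sub > presence_threshold).sum(axis=1) / sc.size
        abundance[sc.label] = sub.sum(axis=1)
    idx = pd.Index(rel.sample_ids, name="sample_id")
    return SCSampleStats(
        percent=pd.DataFrame(percent, index=idx),
        total_abundance=pd.DataFrame(abundance, index=idx),
    )


# ---------------------------------------------------------------------------
# group comparisons

def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact when both n ≤ 8 and tie-free,
    otherwise tie-corrected normal approximation with continuity correction."""
    exact_ok = x.size <= 8 and y.size <= 8 and np.unique(np.concatenate([x, y])).size == x.size + y.size
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact_ok else "asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def compare_sc_groups(
    sc_stats: SCSampleStats,
    meta: SampleMetadata,
    *,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Pairwise diet-group comparisons of both SC statistics.

    Every (group pair × SC × metric) cell gets a two-sided Wilcoxon rank-sum
    test; BH adjustment runs over the entire family at once. Groups with
    fewer than ``min_group_size`` samples are skipped with a warning.

    Returns a DataFrame with columns group_a, group_b, sc_label, metric,
    statistic, p_raw, p_adjusted.
    """
    samples = list(sc_stats.percent.index)
    meta.require_samples(samples)
    groups = meta.diet_groups(samples)
    sizes = groups.value_counts()
    usable = sorted(sizes[sizes >= min_group_size].index)
    skipped = sorted(set(groups) - set(usable))
    if skipped:
        warnings.warn(f"groups with < {min_group_size} samples skipped: {skipped}", stacklevel=2)
    rows = []
    for ga, gb in itertools.combinations(usable, 2):
        ia = groups[groups == ga].index
        ib = groups[groups == gb].index
        for metric, frame in (
            ("cooccurrence_percent", sc_stats.percent),
            ("total_abundance", sc_stats.total_abundance),
        ):
            for sc_label in frame.columns:
                x = frame.loc[ia, sc_label].to_numpy(dtype=float)
                y = frame.loc[ib, sc_label].to_numpy(dtype=float)
                u = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
                rows.append(
                    {
                        "group_a": ga,
                        "group_b": gb,
                        "sc_label": sc_label,
                        "metric": metric,
                        "statistic": u,
                        "p_raw": _rank_sum_p(x, y),
                    }
                )
    result = pd.DataFrame(rows, columns=["group_a", "group_b", "sc_label", "metric", "statistic", "p_raw"])
    result["p_adjusted"] = bh_adjust(result["p_raw"].to_numpy()) if len(result) else []
    return result
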