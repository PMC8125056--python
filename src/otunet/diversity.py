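"""Alpha/beta diversity and distance-matrix inference.

Alpha diversity: Chao1 (bias-corrected), Shannon entropy and Faith's
phylogenetic diversity. Beta diversity: Bray-Curtis dissimilarity, classical
principal-coordinates analysis (PCoA), single-factor PERMANOVA with seeded
label permutation, UPGMA dendrograms, and the Mantel test between distance
matrices. Every permutation test also offers an exhaustive mode that
enumerates all label arrangements, feasible for small n and used as its own
exactness check.

All distance matrices are :class:`skbio.DistanceMatrix` (symmetric, hollow,
nonnegative — validated on construction).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.alpha import chao1 as _skbio_chao1

from .containers import OtuTable, RelAbundanceTable, SampleMetadata

__all__ = [
    "chao1",
    "shannon",
    "faith_pd",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "PcoaResult",
    "permanova",
    "PermanovaResult",
    "upgma",
    "patristic_distances",
    "mantel",
    "MantelResult",
    "permutation_t_test",
    "diet_distance_matrix",
    "host_patristic_distance_matrix",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# alpha diversity

def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate for one sample's integer count vector.

    The bias-corrected form ``S_obs + F1(F1-1)/(2(F2+1))`` (F1/F2 = number of
    singletons/doubletons) is the default and stays finite when no doubletons
    are observed; the classic ``S_obs + F1^2/(2 F2)`` is available via
    ``bias_corrected=False``.
    """
    arr = np.asarray(counts)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    if not np.all(arr == np.floor(arr)):
        raise ValueError("Chao1 requires integer counts (singletons/doubletons undefined otherwise)")
    return float(_skbio_chao1(arr.astype(np.int64), bias_corrected=bias_corrected))


def shannon(values, base: float = math.e) -> float:
    """Shannon entropy −Σ p log p of a count or fraction vector."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("abundances must be nonnegative")
    total = arr.sum()
    if total == 0:
        raise ValueError("Shannon entropy undefined for an all-zero vector")
    p = arr[arr > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def faith_pd(observed_ids, tree: TreeNode) -> float:
    """Faith's phylogenetic diversity ("PD whole tree") of a set of observed taxa.

    Sum of branch lengths of the minimal rooted subtree spanning the observed
    leaves (the stem to the root is included). Observed ids missing from the
    tree are dropped with a logged count — reference trees and OTU tables
    routinely disagree on a few names.
    """
    observed = set(observed_ids)
    if not observed:
        raise ValueError("empty observed set")
    tips = {t.name: t for t in tree.tips()}
    matched = sorted(observed & tips.keys())
    if not matched:
        raise ValueError("no observed ids found among tree leaves")
    if len(matched) < len(observed):
        logger.warning("faith_pd: dropped %d observed id(s) not in tree", len(observed) - len(matched))
    # walk each observed tip to the root, summing every branch at most once
    visited: set[int] = set()
    total = 0.0
    for name in matched:
        node = tips[name]
        while node.parent is not None and id(node) not in visited:
            if node.length is None:
                raise ValueError("tree has missing branch lengths")
            visited.add(id(node))
            total += node.length
            node = node.parent
    return total


def alpha_diversity(table: OtuTable, tree: TreeNode | None = None, *, base: float = math.e) -> pd.DataFrame:
    """Per-sample Chao1, Shannon and (if a tree is given) Faith's PD."""
    rows = {}
    for sid in table.sample_ids:
        counts = table.data.loc[sid].to_numpy()
        rec = {
            "chao1": chao1(counts),
            "shannon": shannon(counts, base=base),
        }
        if tree is not None:
            present = [o for o, c in zip(table.otu_ids, counts) if c > 0]
            rec["faith_pd"] = faith_pd(present, tree)
        rows[sid] = rec
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# beta diversity

def bray_curtis(table: OtuTable | RelAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d(x,y) = Σ|x−y| / Σ(x+y)."""
    x = np.asarray(table.data.to_numpy(), dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    zero = np.where(x.sum(axis=1) == 0)[0]
    if zero.size:
        raise ValueError(f"sample {table.sample_ids[zero[0]]!r} is all-zero")
    condensed = pdist(x, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class PcoaResult:
    """Classical-scaling embedding of a distance matrix."""

    coordinates: pd.DataFrame  # samples × retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over positive eigenvalues only

    @property
    def n_negative_eigenvalues(self) -> int:
        return int((self.eigenvalues < 0).sum())


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Principal-coordinates analysis by Gower double-centering.

    Eigendecomposes ``-0.5 · J D² J`` (J the centering projector). Axes are
    ordered by descending eigenvalue; negative eigenvalues (non-Euclidean
    distances) are reported but excluded from the variance denominators and
    no correction (Lingoes/Cailliez) is applied.
    """
    d = dm.data
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    if (evals < 0).any():
        logger.info("pcoa: %d negative eigenvalue(s) excluded from variance denominators", int((evals < 0).sum()))
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.zeros(0)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=evals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Within-group and total sums of squared distances (Anderson's partition)."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.where(codes == g)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    return ss_within, ss_total


def permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    *,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Single-factor PERMANOVA on a distance matrix.

    The pseudo-F statistic is built from within/between sums of squared
    distances; significance comes from unrestricted permutation of the group
    labels, ``p = (#{F_perm ≥ F_obs} + 1) / (n_permutations + 1)``. With
    ``exhaustive=True`` all distinct label arrangements are enumerated
    instead (p = #{F_perm ≥ F_obs} / #arrangements, identity included) —
    only feasible for small n.
    """
    groups = pd.Series(list(groups), index=list(dm.ids)) if not isinstance(groups, pd.Series) else groups.loc[list(dm.ids)]
    labels = groups.astype(str).to_numpy()
    uniq, codes = np.unique(labels, return_inverse=True)
    a, n = uniq.size, len(labels)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    d2 = dm.data**2

    def f_stat(codes_: np.ndarray) -> tuple[float, float]:
        ss_w, ss_t = _permanova_ss(d2, codes_, a)
        ss_a = ss_t - ss_w
        f = (ss_a / (a - 1)) / (ss_w / (n - a))
        return f, ss_a / ss_t

    f_obs, r2 = f_stat(codes)
    if exhaustive:
        arrangements = sorted({tuple(p) for p in itertools.permutations(codes)})
        hits = sum(f_stat(np.array(p))[0] >= f_obs - 1e-12 for p in arrangements)
        return PermanovaResult(f_obs, r2, hits / len(arrangements), len(arrangements) - 1, n, a)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if f_stat(perm)[0] >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(f_obs, r2, p, n_permutations, n, a)


# ---------------------------------------------------------------------------
# UPGMA

def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration into an ultrametric rooted dendrogram.

    Clusters are merged at height d/2 so every leaf sits at the same depth
    below the root. Ties are broken deterministically: among equally close
    pairs the pair whose (lexicographically smallest member, then second
    member) sorts first is merged.
    """
    d = np.asarray(dm.data, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    ids = list(dm.ids)
    if len(ids) < 2:
        raise ValueError("UPGMA needs at least 2 samples")
    # cluster state: key -> (TreeNode, size, height, smallest member id)
    nodes = {i: (TreeNode(name=ids[i]), 1, 0.0, ids[i]) for i in range(len(ids))}
    dist = {frozenset((i, j)): d[i, j] for i in range(len(ids)) for j in range(i + 1, len(ids))}
    next_key = len(ids)
    while len(nodes) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(nodes[k][3] for k in kv[0]))),
        )
        (pair, dmin) = best
        i, j = sorted(pair, key=lambda k: nodes[k][3])
        node_i, size_i, h_i, min_i = nodes.pop(i)
        node_j, size_j, h_j, min_j = nodes.pop(j)
        height = dmin / 2.0
        node_i.length = height - h_i
        node_j.length = height - h_j
        parent = TreeNode(children=[node_i, node_j])
        for other in nodes:
            d_new = (size_i * dist.pop(frozenset((i, other))) + size_j * dist.pop(frozenset((j, other)))) / (size_i + size_j)
            dist[frozenset((next_key, other))] = d_new
        del dist[pair]
        nodes[next_key] = (parent, size_i + size_j, height, min(min_i, min_j))
        next_key += 1
    (root, _, _, _) = next(iter(nodes.values()))
    root.length = None
    return root


# ---------------------------------------------------------------------------
# patristic distances and Mantel

def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path lengths (sums of branch lengths)."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("tree has missing branch lengths; load with an explicit policy first")
    return tree.tip_tip_distances()


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    method: str


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: str = "pearson",
    n_permutations: int = 9999,
    seed: int | None = None,
    *,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel test of correlation between two distance matrices.

    ``r`` is the Pearson (default) or Spearman correlation of the strictly
    lower-triangular entries after aligning ids. The null distribution
    permutes one matrix's rows and columns jointly; the one-sided p-value is
    ``(#{r_perm ≥ r_obs} + 1)/(n_permutations + 1)``. ``exhaustive=True``
    enumerates all n! relabelings (small n only).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    ids1, ids2 = set(dm1.ids), set(dm2.ids)
    if ids1 != ids2:
        raise ValueError(
            f"id mismatch: only in first {sorted(ids1 - ids2)}, only in second {sorted(ids2 - ids1)}"
        )
    dm2 = dm2.filter(dm1.ids)
    n = len(dm1.ids)
    iu = np.triu_indices(n, k=1)
    v1 = dm1.data[iu]
    m2 = np.array(dm2.data, dtype=float)
    if method == "spearman":
        v1 = rankdata(v1)
        r2 = np.zeros_like(m2)
        r2[iu] = rankdata(m2[iu])
        m2 = r2 + r2.T
    v1c = v1 - v1.mean()
    denom1 = np.sqrt((v1c**2).sum())
    if denom1 == 0:
        raise ValueError("first distance matrix is constant off-diagonal")

    def corr(perm: np.ndarray) -> float:
        v2 = m2[np.ix_(perm, perm)][iu]
        v2c = v2 - v2.mean()
        denom2 = np.sqrt((v2c**2).sum())
        if denom2 == 0:
            return 0.0
        return float((v1c * v2c).sum() / (denom1 * denom2))

    identity = np.arange(n)
    r_obs = corr(identity)
    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        hits = sum(corr(np.array(p)) >= r_obs - 1e-12 for p in perms)
        return MantelResult(r_obs, hits / len(perms), len(perms) - 1, method)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if corr(rng.permutation(n)) >= r_obs - 1e-12:
            hits += 1
    return MantelResult(r_obs, (hits + 1) / (n_permutations + 1), n_permutations, method)


# ---------------------------------------------------------------------------
# permutation t-test

def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / x.size + vy / y.size
    if se2 == 0:
        return 0.0 if mx == my else math.inf
    return (mx - my) / math.sqrt(se2)


def permutation_t_test(
    x,
    y,
    n_permutations: int = 999,
    seed: int | None = None,
    *,
    exhaustive: bool = False,
) -> float:
    """Two-sided permutation test on the Welch t statistic.

    Group labels are permuted over the pooled values;
    ``p = (#{|t_perm| ≥ |t_obs|} + 1)/(n_permutations + 1)``. With
    ``exhaustive=True`` all C(n, n_x) splits are enumerated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([x, y])
    t_obs = abs(_welch_t(x, y))
    n, nx = pooled.size, x.size
    if exhaustive:
        splits = list(itertools.combinations(range(n), nx))
        hits = 0
        for split in splits:
            mask = np.zeros(n, dtype=bool)
            mask[list(split)] = True
            if abs(_welch_t(pooled[mask], pooled[~mask])) >= t_obs - 1e-12:
                hits += 1
        return hits / len(splits)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if abs(_welch_t(pooled[perm[:nx]], pooled[perm[nx:]])) >= t_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# metadata-derived distance matrices for Mantel

def diet_distance_matrix(meta: SampleMetadata, sample_ids) -> DistanceMatrix:
    """Euclidean distance between one-hot encodings of the diet-type group."""
    sample_ids = list(sample_ids)
    meta.require_samples(sample_ids)
    onehot = pd.get_dummies(meta.diet_groups(sample_ids)).to_numpy(dtype=float)
    return DistanceMatrix(squareform(pdist(onehot, metric="euclidean")), ids=sample_ids)


def host_patristic_distance_matrix(tree: TreeNode, meta: SampleMetadata, sample_ids) -> DistanceMatrix:
    """Sample-level host-phylogeny distances.

    The patristic distance between two samples' host species (zero when two
    samples come from the same species). Every host species must be a leaf of
    the tree.
    """
    sample_ids = list(sample_ids)
    meta.require_samples(sample_ids)
    species = meta.host_species(sample_ids)
    sp_dm = patristic_distances(tree)
    missing = sorted(set(species) - set(sp_dm.ids))
    if missing:
        raise ValueError(f"host species missing from tree: {missing}")
    idx = [list(sp_dm.ids).index(s) for s in species]
    d = sp_dm.data[np.ix_(idx, idx)].copy()
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=sample_ids)
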