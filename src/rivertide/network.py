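"""Signed-hybrid co-occurrence network: TOM, modules, eigengenes, traits.

A weighted co-occurrence network is built from Pearson correlations of genome
abundance time series within one compartment. The signed-hybrid adjacency
keeps only positive correlations, a_ij = r_ij^beta for r_ij > 0 (beta 14 for
surface water, 8 for pore water by default), and the topological
overlap measure (TOM) augments direct adjacency with shared neighbours.
Modules are clusters of the TOM dissimilarity tree, each summarized by its
eigengene (first principal component of the standardized member profiles);
modules whose eigengenes correlate above 1 - merge_cut_height are merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from rivertide.core_io import AbundanceMatrix, ValidationError

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class NetworkParams:
    power: int = 14  # SW default; PW uses 8
    min_module_size: int = 20
    merge_cut_height: float = 0.3
    reassign_threshold: float = 0.0
    cut_height: float = 0.995  # static cut on the TOM-dissimilarity scale
    correlation: str = "pearson"
    transform: str = "log"  # correlate log10 abundance over jointly detected
    # samples (absences are non-detections, not zeros); "raw" correlates the
    # abundance values as given, zeros included
    min_joint_samples: int = 10  # pairs with fewer joint detections get r = 0

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValidationError("power must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValidationError("merge_cut_height must be in (0, 1)")
        if self.correlation not in ("pearson", "spearman"):
            raise ValidationError("correlation must be pearson or spearman")


@dataclass
class ModuleResult:
    genome_ids: list[str]
    labels: dict[str, str]  # genome -> module name ("unassigned" for none)
    eigengenes: pd.DataFrame  # samples x modules, unit variance
    membership: dict[str, float]  # correlation with own module eigengene
    scale_free_r2: float


def _pearson_matrix(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations (genomes x samples input)."""
    xs = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((xs**2).sum(axis=1))
    sd[sd == 0] = np.nan
    r = (xs @ xs.T) / np.outer(sd, sd)
    return np.clip(r, -1.0, 1.0)


def _pairwise_complete_corr(x: np.ndarray, mask: np.ndarray, min_joint: int = 5) -> np.ndarray:
    """Pearson correlation over jointly observed samples only.

    ``mask`` flags observed entries; pairs with fewer than ``min_joint`` joint
    observations get correlation 0 (no evidence of co-occurrence).
    """
    xm = np.ma.masked_array(x, mask=~mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.ma.corrcoef(xm).filled(0.0)
    joint = mask.astype(np.int64) @ mask.T.astype(np.int64)
    r[joint < min_joint] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def build_tom(
    abund: AbundanceMatrix, params: NetworkParams = NetworkParams()
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Signed-hybrid adjacency and TOM similarity.

    Returns (genome_ids, adjacency, tom); zero-variance genomes are excluded
    with a warning in the id list ordering. a_ij = r_ij^beta if r_ij > 0 else
    0, a_ii = 0; t_ij = (sum_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 - a_ij),
    t_ii = 1.
    """
    if len(abund.genome_ids) < 2 or len(abund.sample_ids) < 5:
        raise ValidationError("need >= 2 genomes and >= 5 samples")
    x = abund.values
    sd = x.std(axis=1)
    keep = sd > 0
    ids = [g for g, k in zip(abund.genome_ids, keep) if k]
    if len(ids) < len(abund.genome_ids):
        import warnings

        dropped = [g for g, k in zip(abund.genome_ids, keep) if not k]
        warnings.warn(f"excluded zero-variance genomes: {dropped}")
    xk = x[keep]
    if params.transform == "log":
        # zeros are non-detections, not measured zeros: correlate log
        # abundance over jointly detected samples (pairwise complete)
        detected = xk > 0
        med = np.array([np.median(row[row > 0]) if (row > 0).any() else 1.0 for row in xk])
        xl = np.log10(np.where(detected, xk, med[:, None]))
        if params.correlation == "spearman":
            from scipy.stats import rankdata

            xl = rankdata(xl, axis=1)
        r = _pairwise_complete_corr(xl, detected, params.min_joint_samples)
    else:
        if params.correlation == "spearman":
            from scipy.stats import rankdata

            xk = rankdata(xk, axis=1)
        r = _pearson_matrix(xk)
    adj = np.where(r > 0, r, 0.0) ** params.power
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    shared = adj @ adj
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + adj) / (kmin + 1.0 - adj)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2, 0.0, 1.0)
    return ids, adj, tom


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log linear fit of the binned connectivity distribution."""
    k = adj.sum(axis=1)
    k = k[k > 0]
    if k.size < n_bins:
        return float("nan")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    centers, freqs = [], []
    for lo, hi in zip(edges, edges[1:]):
        sel = (k >= lo) & (k <= hi if hi == edges[-1] else k < hi)
        if sel.sum() == 0:
            continue
        centers.append(k[sel].mean())
        freqs.append(sel.mean())
    lx, ly = np.log10(centers), np.log10(freqs)
    if len(lx) < 3:
        return float("nan")
    r = np.corrcoef(lx, ly)[0, 1]
    return float(r**2)


def _eigengene(values: np.ndarray) -> np.ndarray:
    """First principal component of standardized member profiles (samples,),
    unit variance, sign-oriented so mean member correlation is positive."""
    x = values - values.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    x = x / sd  # genomes x samples
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eg = vt[0]
    eg = (eg - eg.mean()) / eg.std()
    cors = np.array([np.corrcoef(eg, row)[0, 1] for row in x])
    if np.nanmean(cors) < 0:
        eg = -eg
    return eg


def _tree_clusters(
    link: np.ndarray, values: np.ndarray, params: "NetworkParams"
) -> list[np.ndarray]:
    """Static cut with heterogeneity splitting.

    The dendrogram (average linkage of 1 - TOM) is traversed from the root.
    Merges at or above ``cut_height`` are always split (genuine modules
    coalesce well below it while unstructured genomes merge near
    dissimilarity 1). Below the cut, a node is still split when its two
    subtrees carry distinct signals — eigengene dissimilarity at least
    ``merge_cut_height``, the same criterion the merge step uses, so a split
    is never undone by merging. A heterogeneous side too small to be a module
    is pruned (left unassigned) rather than absorbed.
    """
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(link)
    min_size = params.min_module_size

    def leaves(node) -> list[int]:
        return node.pre_order(lambda x: x.id)

    def recurse(node) -> list[list[int]]:
        if node.is_leaf():
            return [[node.id]]
        if node.dist >= params.cut_height:
            return recurse(node.left) + recurse(node.right)
        la, lb = leaves(node.left), leaves(node.right)
        eg_a = _eigengene(values[la, :]) if len(la) > 1 else _eigengene(values[la + la, :])
        eg_b = _eigengene(values[lb, :]) if len(lb) > 1 else _eigengene(values[lb + lb, :])
        diss = 1.0 - np.corrcoef(eg_a, eg_b)[0, 1]
        if diss >= params.merge_cut_height:
            if len(la) >= min_size and len(lb) >= min_size:
                return recurse(node.left) + recurse(node.right)
            if len(la) >= min_size:
                return recurse(node.left)  # small heterogeneous fringe dropped
            if len(lb) >= min_size:
                return recurse(node.right)
        return [la + lb]

    return [np.asarray(sorted(c)) for c in recurse(root)]


def detect_modules(
    genome_ids: Sequence[str],
    tom: np.ndarray,
    abund: AbundanceMatrix,
    params: NetworkParams = NetworkParams(),
    adjacency: Optional[np.ndarray] = None,
) -> ModuleResult:
    """Average-linkage clustering of 1 - TOM with a static cut, size floor,
    eigengene computation and iterative merging of similar modules.

    Input order does not affect labels: genomes are processed in a canonical
    id-sorted order and module names are assigned by size then member id.
    """
    genome_ids = list(genome_ids)
    order = np.argsort(genome_ids, kind="stable")
    ids_sorted = [genome_ids[i] for i in order]
    tom_s = tom[np.ix_(order, order)]
    gidx = {g: abund.genome_ids.index(g) for g in ids_sorted}
    values = abund.values[[gidx[g] for g in ids_sorted], :]

    dist = 1.0 - tom_s
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    clusters = _tree_clusters(link, values, params)
    # enforce the size floor
    clusters = [c for c in clusters if c.size >= params.min_module_size]
    # deterministic naming: by size desc then smallest member id
    clusters.sort(key=lambda c: (-c.size, ids_sorted[c.min()]))
    module_members = {f"M{i+1:02d}": list(c) for i, c in enumerate(clusters)}

    # iterative eigengene merging
    while True:
        names = sorted(module_members)
        if len(names) < 2:
            break
        egs = {m: _eigengene(values[module_members[m], :]) for m in names}
        best = None
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                diss = 1.0 - np.corrcoef(egs[names[i]], egs[names[j]])[0, 1]
                if diss < params.merge_cut_height and (best is None or diss < best[0]):
                    best = (diss, names[i], names[j])
        if best is None:
            break
        _, a, b = best
        module_members[a] = sorted(module_members[a] + module_members[b])
        del module_members[b]

    # final naming and eigengenes
    final = sorted(module_members.values(), key=lambda c: (-len(c), ids_sorted[min(c)]))
    label_map: dict[str, str] = {}
    eig_cols = {}
    membership: dict[str, float] = {}
    for i, members in enumerate(final):
        name = f"M{i+1:02d}"
        eg = _eigengene(values[members, :])
        eig_cols[name] = eg
        for m in members:
            label_map[ids_sorted[m]] = name
    for g in ids_sorted:
        label_map.setdefault(g, UNASSIGNED)
    for g in ids_sorted:
        lab = label_map[g]
        if lab == UNASSIGNED:
            membership[g] = float("nan")
        else:
            row = values[ids_sorted.index(g), :]
            membership[g] = float(np.corrcoef(row, eig_cols[lab])[0, 1])
    eigengenes = pd.DataFrame(eig_cols, index=abund.sample_ids)
    sfr2 = scale_free_fit(adjacency) if adjacency is not None else float("nan")
    return ModuleResult(
        genome_ids=ids_sorted,
        labels=label_map,
        eigengenes=eigengenes,
        membership=membership,
        scale_free_r2=sfr2,
    )


def module_trait_statistics(
    abund: AbundanceMatrix,
    modules: ModuleResult,
    trait: pd.Series,
) -> pd.DataFrame:
    """Per-genome genome significance |cor(series, trait)| and module
    membership cor(series, own eigengene)."""
    t = trait.loc[abund.sample_ids].to_numpy(dtype=float)
    if t.std() == 0:
        raise ValidationError("zero-variance trait")
    rows = []
    for g in modules.genome_ids:
        x = abund.values[abund.genome_ids.index(g), :]
        if x.std() == 0:
            gs = float("nan")
        else:
            gs = float(abs(np.corrcoef(x, t)[0, 1]))
        rows.append(
            {
                "genome_id": g,
                "module": modules.labels[g],
                "genome_significance": gs,
                "module_membership": modules.membership[g],
            }
        )
    return pd.DataFrame(rows, columns=["genome_id", "module", "genome_significance", "module_membership"])
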