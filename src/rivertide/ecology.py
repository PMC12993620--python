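"""Diversity, ordination, and multivariate community statistics.

Implements the vegan-style toolbox the temporal analysis rests on: Shannon
diversity on TMM abundances, Bray-Curtis distance matrices (genomes filtered
to those present in more than 3 samples of the compartment), non-metric
multidimensional scaling (Kruskal stress-1, isotonic regression with weak
ties, majorization updates, multiple restarts), one- and two-factor PERMANOVA
with sequential sums of squares, envfit-style vector fitting, a Procrustes
superimposition test, permutation species-accumulation curves with the exact
rarefaction expectation, and ANOSIM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from rivertide.core_io import AbundanceMatrix, ValidationError


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("distance matrix shape mismatch")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValidationError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max() > 0:
            raise ValidationError("distance matrix diagonal not zero")
        self.values = v

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coords: np.ndarray  # (n, k), centred, principal-axis rotated
    stress: float
    n_restarts: int
    converged: bool


@dataclass(frozen=True)
class MultivarTest:
    statistic: str  # pseudo_F | r2 | m2 | corr | R
    value: float
    permutations: int
    p: float


def diversity(abund: AbundanceMatrix, sample_id: str) -> tuple[int, float]:
    """Richness and Shannon H' (natural log) for one sample."""
    x = abund.values[:, abund.sample_ids.index(sample_id)]
    total = x.sum()
    if total <= 0:
        raise ValidationError(f"sample {sample_id} is all-zero")
    pos = x[x > 0]
    p = pos / total
    return int(pos.size), float(-(p * np.log(p)).sum())


def bray_curtis_matrix(abund: AbundanceMatrix, min_samples_present: int = 4) -> DistanceMatrix:
    """Pairwise Bray-Curtis over genomes present in > 3 samples (strict)."""
    keep = (abund.values > 0).sum(axis=1) >= min_samples_present
    vals = abund.values[keep, :]
    zero = vals.sum(axis=0) == 0
    if zero.any():
        bad = [s for s, z in zip(abund.sample_ids, zero) if z]
        raise ValidationError(f"samples with all-zero retained abundances: {bad}")
    d = squareform(pdist(vals.T, metric="braycurtis"))
    return DistanceMatrix(list(abund.sample_ids), d)


# ---------------------------------------------------------------------------
# NMDS


def _stress1(dhat: np.ndarray, e: np.ndarray) -> float:
    return float(np.sqrt(np.sum((dhat - e) ** 2) / np.sum(e**2)))


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    coords = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    return coords @ vt.T


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(lam)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Kruskal non-metric MDS minimizing stress-1 by majorization (SMACOF)
    with isotonic regression (weak ties averaged) of configuration distances
    on the observed dissimilarity ranks. First start is classical metric
    scaling; the remaining starts are random."""
    dv = d.condensed
    n = d.values.shape[0]
    if n < k + 2:
        raise ValidationError("need at least k+2 samples")
    order = np.argsort(dv, kind="stable")
    iso = IsotonicRegression(increasing=True)
    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for restart in range(n_restarts):
        if restart == 0:
            x = _classical_mds(d.values, k)
        else:
            x = rng.normal(size=(n, k))
        prev_stress = np.inf
        converged = False
        for _ in range(max_iter):
            e = pdist(x)
            if (e == 0).any():
                e = e + 1e-12
            # isotonic fit of e on d (in rank order of d)
            dhat = np.empty_like(e)
            dhat[order] = iso.fit_transform(np.arange(dv.size), e[order])
            stress = _stress1(dhat, e)
            if prev_stress - stress < tol:
                converged = True
                break
            prev_stress = stress
            # Guttman transform toward the disparities
            ratio = squareform(dhat / e, checks=False)
            bmat = -ratio
            np.fill_diagonal(bmat, ratio.sum(axis=1))
            x = bmat @ x / n
        e = pdist(x)
        dhat = np.empty_like(e)
        dhat[order] = iso.fit_transform(np.arange(dv.size), e[order])
        stress = _stress1(dhat, e)
        any_converged = any_converged or converged
        if best is None or stress < best[0]:
            best = (stress, x)
    stress, x = best
    return OrdinationResult(
        sample_ids=list(d.sample_ids),
        coords=_principal_axes(x),
        stress=float(stress),
        n_restarts=n_restarts,
        converged=any_converged,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d**2) @ j


def _permanova_f(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and group labels.

    SS_total = sum_{i<j} d2_ij / n; SS_within = sum over groups of the
    group-internal sum_{i<j} d2_ij / n_g (equivalent to the trace of the
    group-block-centred Gower matrix).
    """
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    labels = np.unique(groups)
    for lab in labels:
        idx = np.where(groups == lab)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    ng = labels.size
    f = (ss_between / (ng - 1)) / (ss_within / (n - ng))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> MultivarTest:
    """One-factor PERMANOVA: pseudo-F, R^2, permutation p.

    With ``exhaustive=True`` the p-value enumerates every distinct label
    assignment instead of sampling (feasible at small n; the identity
    assignment counts as one of them)."""
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2 or (counts < 2).any():
        raise ValidationError("need >= 2 groups each with >= 2 samples")
    d2 = d.values**2
    f_obs, r2 = _permanova_f(d2, groups)
    if exhaustive:
        from itertools import permutations

        seen = set()
        hits = total = 0
        for perm in permutations(groups):
            if perm in seen:
                continue
            seen.add(perm)
            f_p, _ = _permanova_f(d2, np.asarray(perm))
            total += 1
            hits += f_p >= f_obs - 1e-12
        return MultivarTest("pseudo_F", float(f_obs), total, hits / total)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        f_p, _ = _permanova_f(d2, perm)
        if f_p >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return MultivarTest("pseudo_F", float(f_obs), n_perm, float(p))


def permanova_r2(d: DistanceMatrix, groups: Sequence[str]) -> float:
    _, r2 = _permanova_f(d.values**2, np.asarray(groups))
    return float(r2)


def permanova_sequential(
    d: DistanceMatrix, groups: Sequence[str], time_values: Sequence[float]
) -> tuple[float, float]:
    """Sequential (Type-I) R^2: compartment first, then time.

    Returns (r2_groups, additional r2 of the time factor after groups),
    with time treated as a continuous predictor via the distance-based
    regression of the Gower-centred matrix on the hat matrix of [1, time].
    """
    g = _gower_center(d.values)
    groups = np.asarray(groups)
    ss_total = np.trace(g)
    _, r2_groups = _permanova_f(d.values**2, groups)
    # model matrix: group indicators then time
    x1 = pd.get_dummies(pd.Series(groups)).to_numpy(dtype=float)
    t = np.asarray(time_values, dtype=float)[:, None]
    x2 = np.hstack([x1, t])

    def ss_model(x: np.ndarray) -> float:
        q, _ = np.linalg.qr(x - x.mean(axis=0))
        h = q @ q.T
        return float(np.trace(h @ g @ h))

    ss1 = ss_model(x1)
    ss12 = ss_model(x2)
    return float(ss1 / ss_total), float((ss12 - ss1) / ss_total)


# ---------------------------------------------------------------------------
# envfit


def envfit_vectors(
    ord_result: OrdinationResult,
    variables: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Vector fitting of each variable onto a 2-D ordination.

    Per variable: least-squares fit of the centred variable on the ordination
    coordinates; r^2 = 1 - SS_res/SS_tot; direction = normalized coefficient
    vector; p from permuting the variable across samples. Zero-variance
    variables are reported skipped (r2 NaN).
    """
    coords = ord_result.coords - ord_result.coords.mean(axis=0)
    variables = variables.loc[ord_result.sample_ids]
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(coords)
    rows = []
    for name in variables.columns:
        y = variables[name].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValidationError(f"variable {name} has missing values")
        yc = y - y.mean()
        ss_tot = float(yc @ yc)
        if ss_tot == 0:
            rows.append({"variable": name, "dir1": np.nan, "dir2": np.nan,
                         "r2": np.nan, "p": np.nan, "skipped": True})
            continue
        beta, *_ = np.linalg.lstsq(coords, yc, rcond=None)
        fit = q @ (q.T @ yc)
        r2_obs = float(fit @ fit) / ss_tot
        direction = beta / np.linalg.norm(beta) if np.linalg.norm(beta) > 0 else beta
        hits = 0
        yp = yc.copy()
        for _ in range(n_perm):
            rng.shuffle(yp)
            fit_p = q @ (q.T @ yp)
            if float(fit_p @ fit_p) / ss_tot >= r2_obs:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        rows.append({"variable": name, "dir1": float(direction[0]),
                     "dir2": float(direction[1]), "r2": r2_obs, "p": float(p),
                     "skipped": False})
    return pd.DataFrame(rows, columns=["variable", "dir1", "dir2", "r2", "p", "skipped"])


# ---------------------------------------------------------------------------
# Procrustes


def _procrustes_m2(a: np.ndarray, b: np.ndarray) -> float:
    """Residual m^2 after centring, unit-scaling and optimal rotation."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("degenerate configuration (all points identical)")
    a, b = a / na, b / nb
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    return float(1 - s.sum() ** 2)


def procrustes_test(
    ord_a: OrdinationResult | np.ndarray,
    ord_b: OrdinationResult | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[MultivarTest, float]:
    """Procrustes m^2 with permutation p; returns (test, correlation).

    correlation = sqrt(1 - m^2); p from permuting the row order of the second
    configuration.
    """
    a = ord_a.coords if isinstance(ord_a, OrdinationResult) else np.asarray(ord_a, dtype=float)
    b = ord_b.coords if isinstance(ord_b, OrdinationResult) else np.asarray(ord_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("configurations must have the same shape")
    m2 = _procrustes_m2(a, b)
    corr = float(np.sqrt(max(0.0, 1 - m2)))
    rng = np.random.default_rng(seed)
    hits = 0
    idx = np.arange(a.shape[0])
    for _ in range(n_perm):
        rng.shuffle(idx)
        if _procrustes_m2(a, b[idx]) <= m2:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return MultivarTest("m2", m2, n_perm, float(p)), corr


# ---------------------------------------------------------------------------
# species accumulation


def species_accumulation(
    present: np.ndarray, n_perm: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Permutation species-accumulation curve plus the exact rarefaction
    expectation E[S_k] = sum_g [1 - C(n - n_g, k)/C(n, k)].

    ``present``: genome x sample boolean matrix of one compartment.
    """
    present = np.asarray(present, dtype=bool)
    n = present.shape[1]
    if n < 2:
        raise ValidationError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    cum = np.zeros(n)
    sq = np.zeros(n)
    for _ in range(n_perm):
        order = rng.permutation(n)
        seen = np.cumsum(present[:, order], axis=1) > 0
        richness = seen.sum(axis=0)
        cum += richness
        sq += richness.astype(float) ** 2
    mean = cum / n_perm
    sd = np.sqrt(np.maximum(sq / n_perm - mean**2, 0.0))
    n_g = present.sum(axis=1)
    from scipy.special import gammaln

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    exact = np.empty(n)
    for k in range(1, n + 1):
        ok = (n - n_g) >= k
        term = np.zeros_like(n_g, dtype=float)
        term[ok] = np.exp(log_comb(n - n_g[ok], k) - log_comb(n, k))
        exact[k - 1] = float(np.sum(1.0 - term))
    return pd.DataFrame(
        {"k": np.arange(1, n + 1), "mean_richness": mean, "sd": sd, "exact": exact}
    )


# ---------------------------------------------------------------------------
# ANOSIM


def anosim(
    d: DistanceMatrix, groups: Sequence[str], n_perm: int = 999, seed: int = 0
) -> MultivarTest:
    """ANOSIM R statistic with permutation p (rank-based)."""
    from scipy.stats import rankdata

    groups = np.asarray(groups)
    dv = d.condensed
    ranks = rankdata(dv)
    n = d.values.shape[0]
    iu = np.triu_indices(n, 1)
    same = groups[iu[0]] == groups[iu[1]]

    def r_stat(same_mask: np.ndarray) -> float:
        rb = ranks[~same_mask].mean()
        rw = ranks[same_mask].mean()
        return (rb - rw) / (dv.size / 2)

    r_obs = r_stat(same)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        same_p = perm[iu[0]] == perm[iu[1]]
        if r_stat(same_p) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return MultivarTest("R", float(r_obs), n_perm, float(p))


def pca(variables: pd.DataFrame, k: int = 2) -> OrdinationResult:
    """Centred, unit-scaled principal components of a chemistry table."""
    x = variables.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x = x / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :k] * s[:k]
    return OrdinationResult(list(variables.index), coords, 0.0, 1, True)
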