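"""Sparse partial least squares (sPLS1) with VIP scores and permutation p.

One chemistry variable is regressed on the standardized abundances of one
module's genomes. Each component keeps the ``keep_x`` largest-magnitude
entries of X'y (computed on the deflated residuals), normalized to unit norm;
scores t_h = X_res w_h; X and y are deflated by regression on t_h. The fit is
summarized by the in-sample R^2 over all components, a permutation p-value
obtained by refitting on y permuted across samples, and per-predictor
variable-importance-in-projection scores,

    VIP_j = sqrt( p * sum_h SS_h (w_jh / ||w_h||)^2 / sum_h SS_h ),

with p the number of predictors and SS_h the variance of y explained by
component h. VIP > 1 marks influential predictors; sum_j VIP_j^2 = p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from rivertide.core_io import ValidationError


@dataclass(frozen=True)
class SPLSParams:
    n_components: int = 2
    keep_x: Optional[int] = None  # default: max(module_size // 2, 5)
    n_perm: int = 999
    r2_min: float = 0.3
    alpha: float = 0.05
    vip_min: float = 1.0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")


@dataclass
class SPLSFit:
    module: str
    predictor_ids: list[str]
    weights: np.ndarray  # (p, H), each column <= keep_x nonzeros, unit norm
    scores: np.ndarray  # (n, H)
    ss_h: np.ndarray  # variance of y explained per component
    r2: float
    p_perm: float
    vip: np.ndarray
    significant: bool


def _standardize(a: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=0)
    sd = a.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return a / sd


def _spls_core(x: np.ndarray, y: np.ndarray, n_components: int, keep_x: int):
    """Returns (weights, scores, ss_h, r2). x standardized, y centred."""
    n, p = x.shape
    x_res = x.copy()
    y_res = y.copy()
    ss_tot = float(y @ y)
    weights = np.zeros((p, n_components))
    scores = np.zeros((n, n_components))
    ss_h = np.zeros(n_components)
    for h in range(n_components):
        w = x_res.T @ y_res
        if np.allclose(w, 0):
            break
        if keep_x < p:
            thresh_idx = np.argsort(np.abs(w), kind="stable")[: p - keep_x]
            w[thresh_idx] = 0.0
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        t = x_res @ w
        tt = float(t @ t)
        if tt == 0:
            break
        # deflation by regression on t
        c = float(t @ y_res) / tt
        ss_h[h] = c**2 * tt  # variance of y explained by this component
        y_res = y_res - c * t
        x_res = x_res - np.outer(t, (x_res.T @ t) / tt)
        weights[:, h] = w
        scores[:, h] = t
    ss_res = float(y_res @ y_res)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return weights, scores, ss_h, r2


def spls_fit(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    params: SPLSParams = SPLSParams(),
    seed: int = 0,
    module: str = "",
    predictor_ids: Optional[Sequence[str]] = None,
) -> SPLSFit:
    """Fit sPLS1 of one chemistry variable on one module's genome abundances.

    X columns and y are standardized internally. The permutation p-value
    refits on y permuted across samples ``n_perm`` times:
    p = (1 + #{R2_perm >= R2_obs}) / (1 + n_perm).
    """
    if isinstance(x, pd.DataFrame):
        predictor_ids = list(x.columns)
        x = x.to_numpy(dtype=float)
    if isinstance(y, pd.Series):
        y = y.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("module must have at least 2 predictors")
    if np.std(y) == 0:
        raise ValidationError("constant response")
    if predictor_ids is None:
        predictor_ids = [f"g{i}" for i in range(x.shape[1])]
    n, p = x.shape
    keep_x = params.keep_x if params.keep_x is not None else max(p // 2, min(5, p))
    keep_x = min(keep_x, p)
    xs = _standardize(x)
    ys = (y - y.mean()) / y.std(ddof=1)
    weights, scores, ss_h, r2 = _spls_core(xs, ys, params.n_components, keep_x)
    rng = np.random.default_rng(seed)
    hits = 0
    yp = ys.copy()
    for _ in range(params.n_perm):
        rng.shuffle(yp)
        ypc = yp - yp.mean()
        _, _, _, r2p = _spls_core(xs, ypc, params.n_components, keep_x)
        if r2p >= r2:
            hits += 1
    p_perm = (1 + hits) / (1 + params.n_perm)
    fit = SPLSFit(
        module=module,
        predictor_ids=list(predictor_ids),
        weights=weights,
        scores=scores,
        ss_h=ss_h,
        r2=float(r2),
        p_perm=float(p_perm),
        vip=np.zeros(p),
        significant=bool(r2 > params.r2_min and p_perm < params.alpha),
    )
    fit.vip = vip_scores(fit)
    return fit


def vip_scores(fit: SPLSFit) -> np.ndarray:
    """Variable importance in projection; sum of squares equals p."""
    w = fit.weights
    ss = fit.ss_h
    used = ss > 0
    if not used.any():
        raise ValidationError("zero total explained variance")
    w = w[:, used]
    ss = ss[used]
    norms = np.linalg.norm(w, axis=0)
    norms[norms == 0] = 1.0
    wn2 = (w / norms) ** 2
    p = w.shape[0]
    return np.sqrt(p * (wn2 @ ss) / ss.sum())
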