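"""Persistence and abundance-stability classification, compartment comparison.

Persistence classes follow the occupancy thresholds of Fuhrman-style temporal
metrics: persistent when detected in >= 75% of a compartment's samples,
ephemeral when <= 25%, intermittent in between. Abundance stability is scored
only for persistent genomes: a sample counts as fluctuating when TMM abundance
deviates from the genome's median (over all compartment samples, zeros
included) by strictly more than 25% of that median; stable <= 25% of samples
fluctuating, unstable >= 75%, else intermediate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from rivertide.abundance import PresenceMatrix
from rivertide.core_io import AbundanceMatrix, SampleRecord, ValidationError


@dataclass(frozen=True)
class PersistenceParams:
    persistent_min: float = 0.75  # inclusive
    ephemeral_max: float = 0.25  # inclusive

    def __post_init__(self) -> None:
        if not 0 < self.ephemeral_max < self.persistent_min <= 1:
            raise ValidationError("require 0 < ephemeral_max < persistent_min <= 1")


@dataclass(frozen=True)
class PersistenceCall:
    genome_id: str
    compartment: str
    n_detected: int
    n_samples: int
    fraction: float
    persistence_class: str  # persistent | intermittent | ephemeral


@dataclass(frozen=True)
class StabilityParams:
    deviation_fraction: float = 0.25  # of the median, strict >
    stable_max: float = 0.25
    unstable_min: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.stable_max < self.unstable_min <= 1:
            raise ValidationError("require 0 < stable_max < unstable_min <= 1")


@dataclass(frozen=True)
class StabilityCall:
    genome_id: str
    compartment: str
    median_abundance: float
    n_fluctuating: int
    n_samples: int
    stability_class: str  # stable | intermediate | unstable


def classify_persistence(
    presence: PresenceMatrix,
    compartment: str,
    params: PersistenceParams = PersistenceParams(),
) -> list[PersistenceCall]:
    """Classify each genome of one compartment's presence matrix."""
    n = len(presence.sample_ids)
    if n < 4:
        raise ValidationError("persistence classes undefined below 4 samples")
    calls = []
    for g, row in zip(presence.genome_ids, presence.present):
        n_det = int(row.sum())
        if n_det == 0:
            raise ValidationError(
                f"genome {g}: zero detections reached persistence classification "
                "(should have been removed upstream)"
            )
        frac = n_det / n
        if frac >= params.persistent_min:
            cls = "persistent"
        elif frac <= params.ephemeral_max:
            cls = "ephemeral"
        else:
            cls = "intermittent"
        calls.append(PersistenceCall(g, compartment, n_det, n, frac, cls))
    return calls


def classify_stability(
    abund: AbundanceMatrix,
    persistent: Sequence[PersistenceCall],
    params: StabilityParams = StabilityParams(),
) -> list[StabilityCall]:
    """Score abundance stability of persistent genomes on TMM abundances."""
    if abund.state != "tmm":
        raise ValidationError("stability is scored on TMM-normalized abundances")
    assert PersistenceParams().persistent_min > 0.5  # guarantees median > 0
    idx = {g: i for i, g in enumerate(abund.genome_ids)}
    calls = []
    for pc in persistent:
        if pc.persistence_class != "persistent":
            continue
        x = abund.values[idx[pc.genome_id]]
        med = float(np.median(x))
        if med == 0:
            raise ValidationError(
                f"genome {pc.genome_id}: zero median abundance for a persistent genome"
            )
        n_fluct = int(np.sum(np.abs(x - med) > params.deviation_fraction * med))
        frac = n_fluct / x.size
        if frac <= params.stable_max:
            cls = "stable"
        elif frac >= params.unstable_min:
            cls = "unstable"
        else:
            cls = "intermediate"
        calls.append(StabilityCall(pc.genome_id, pc.compartment, med, n_fluct, x.size, cls))
    return calls


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """BC(x, y) = sum|x-y| / sum(x+y)."""
    denom = float(np.sum(x + y))
    if denom == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero samples")
    return float(np.sum(np.abs(x - y)) / denom)


def consecutive_bray_curtis(
    abund: AbundanceMatrix, samples: Sequence[SampleRecord]
) -> list[tuple[str, float]]:
    """BC between each sample and its prior timepoint, in time order."""
    by_id = {s.sample_id: s for s in samples}
    ordered = sorted(abund.sample_ids, key=lambda s: by_id[s].time_h)
    if len(ordered) < 2:
        raise ValidationError("need at least 2 timepoints")
    col = {s: i for i, s in enumerate(abund.sample_ids)}
    out = []
    for prev, cur in zip(ordered, ordered[1:]):
        bc = bray_curtis(abund.values[:, col[prev]], abund.values[:, col[cur]])
        out.append((cur, bc))
    return out


def compare_compartments(
    values_sw: Sequence[float], values_pw: Sequence[float]
) -> tuple[float, float, float]:
    """Welch two-sample t test (unpaired, unequal variances), two-sided."""
    a = np.asarray(values_sw, dtype=float)
    b = np.asarray(values_pw, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, float(a.size + b.size - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Fisher's exact test on class-count tables


def _table_logprob(table: np.ndarray, lgamma=math.lgamma) -> float:
    """Log probability of an RxC table under the conditional (margins-fixed)
    multivariate hypergeometric distribution."""
    t = np.asarray(table)
    n = t.sum()
    lp = (
        sum(lgamma(r + 1) for r in t.sum(axis=1))
        + sum(lgamma(c + 1) for c in t.sum(axis=0))
        - lgamma(n + 1)
        - sum(lgamma(v + 1) for v in t.ravel())
    )
    return lp


def _enumerate_2xc(row0: int, col_sums: Sequence[int]):
    """All 2xC tables with first-row sum row0 and the given column sums."""
    c = len(col_sums)

    def rec(j: int, remaining: int, prefix: list[int]):
        if j == c - 1:
            if 0 <= remaining <= col_sums[j]:
                yield prefix + [remaining]
            return
        for v in range(0, min(col_sums[j], remaining) + 1):
            yield from rec(j + 1, remaining - v, prefix + [v])

    yield from rec(0, row0, [])


def fisher_class_counts(
    table: Sequence[Sequence[int]],
    monte_carlo_draws: int = 100_000,
    enumeration_max_total: int = 500,
    seed: int = 0,
) -> float:
    """Fisher's exact test for a 2x2 or 2xC count table (two-sided).

    2x2 uses the hypergeometric sum of tables at most as probable as the
    observed one. 2xC is enumerated exactly over the conditional distribution
    when the grand total is <= ``enumeration_max_total``; larger tables use a
    seeded Monte Carlo estimate over random tables drawn by permutation.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValidationError("expect a 2xC table")
    if (t < 0).any():
        raise ValidationError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("empty row or column margin")
    if t.shape == (2, 2):
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    row0 = int(t.sum(axis=1)[0])
    col_sums = t.sum(axis=0).tolist()
    obs_lp = _table_logprob(t)
    tol = 1e-9  # tables equal in probability count as extreme
    if t.sum() <= enumeration_max_total:
        p = 0.0
        for first_row in _enumerate_2xc(row0, col_sums):
            cand = np.array([first_row, [c - v for c, v in zip(col_sums, first_row)]])
            lp = _table_logprob(cand)
            if lp <= obs_lp + tol:
                p += math.exp(lp)
        return float(min(p, 1.0))
    # Monte Carlo: permute group labels over individual observations
    rng = np.random.default_rng(seed)
    cats = np.repeat(np.arange(t.shape[1]), col_sums)
    hits = 0
    for _ in range(monte_carlo_draws):
        rng.shuffle(cats)
        first = np.bincount(cats[:row0], minlength=t.shape[1])
        cand = np.vstack([first, np.asarray(col_sums) - first])
        if _table_logprob(cand) <= obs_lp + tol:
            hits += 1
    return float((hits + 1) / (monte_carlo_draws + 1))


def stability_class_table(
    calls_sw: Sequence[StabilityCall], calls_pw: Sequence[StabilityCall]
) -> np.ndarray:
    """2x3 table of stability classes (rows SW/PW, columns stable/intermediate/unstable)."""
    classes = ["stable", "intermediate", "unstable"]
    out = np.zeros((2, 3), dtype=np.int64)
    for i, calls in enumerate((calls_sw, calls_pw)):
        for c in calls:
            out[i, classes.index(c.stability_class)] += 1
    return out
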