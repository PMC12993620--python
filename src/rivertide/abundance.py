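"""Presence calling, compartment assignment, TMM normalization, ANI clustering.

Detection follows the read-mapping summary thresholds: a genome is present in
a sample when breadth of coverage is at least 75% of its length and mean depth
is at least 3x (both inclusive). Occupancy above 10% of a compartment's
samples (strict) assigns the genome to that compartment; genomes above the
threshold in both compartments are "both", genomes below in both are removed.

TMM (trimmed mean of M-values) computes one positive scaling factor per
sample against a reference sample, from library-size-adjusted log ratios with
two-sided trimming on both the log-ratio (M) and absolute-intensity (A) axes,
precision-weighted; factors are rescaled to geometric mean 1 and abundances
reported as counts per million after factor adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from rivertide.core_io import (
    AbundanceMatrix,
    Compartment,
    CoverageMatrix,
    GenomeRecord,
    SampleRecord,
    ValidationError,
)

logger = logging.getLogger("rivertide")


@dataclass(frozen=True)
class DetectionParams:
    min_breadth: float = 0.75
    min_depth: float = 3.0
    occupancy_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.min_breadth <= 1:
            raise ValidationError("min_breadth must be in (0, 1]")
        if self.min_depth <= 0:
            raise ValidationError("min_depth must be > 0")
        if not 0 < self.occupancy_fraction < 1:
            raise ValidationError("occupancy_fraction must be in (0, 1)")


@dataclass
class PresenceMatrix:
    genome_ids: list[str]
    sample_ids: list[str]
    present: np.ndarray  # bool (G, S)

    def subset_samples(self, sample_ids: Sequence[str]) -> "PresenceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return PresenceMatrix(list(self.genome_ids), list(sample_ids), self.present[:, idx])


@dataclass(frozen=True)
class CompartmentLabel:
    genome_id: str
    label: str  # pore | surface | both | removed
    pw_fraction: float
    sw_fraction: float


@dataclass(frozen=True)
class TMMParams:
    logratio_trim: float = 0.30
    abs_trim: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.logratio_trim < 0.5 and 0 <= self.abs_trim < 0.5):
            raise ValidationError("trims must be in [0, 0.5)")


@dataclass(frozen=True)
class ClusterParams:
    min_ani: float = 0.95
    min_aligned_fraction: float = 0.85


def apply_detection(cov: CoverageMatrix, params: DetectionParams = DetectionParams()) -> PresenceMatrix:
    """Presence: breadth >= min_breadth AND depth >= min_depth (inclusive)."""
    present = (cov.breadth >= params.min_breadth) & (cov.depth >= params.min_depth)
    return PresenceMatrix(list(cov.genome_ids), list(cov.sample_ids), present)


def assign_compartments(
    presence: PresenceMatrix,
    samples: Sequence[SampleRecord],
    params: DetectionParams = DetectionParams(),
) -> list[CompartmentLabel]:
    """Label each genome pore/surface/both/removed by strict >10% occupancy."""
    by_id = {s.sample_id: s for s in samples}
    comps = np.array([by_id[s].compartment.value for s in presence.sample_ids])
    pw_mask = comps == "PW"
    sw_mask = comps == "SW"
    if pw_mask.sum() == 0 or sw_mask.sum() == 0:
        raise ValidationError("each compartment needs at least one sample")
    pw_frac = presence.present[:, pw_mask].mean(axis=1)
    sw_frac = presence.present[:, sw_mask].mean(axis=1)
    thr = params.occupancy_fraction
    labels = []
    for g, pf, sf in zip(presence.genome_ids, pw_frac, sw_frac):
        in_pw, in_sw = pf > thr, sf > thr
        if in_pw and in_sw:
            lab = "both"
        elif in_pw:
            lab = "pore"
        elif in_sw:
            lab = "surface"
        else:
            lab = "removed"
        labels.append(CompartmentLabel(g, lab, float(pf), float(sf)))
    return labels


def split_by_compartment(
    matrix: AbundanceMatrix | PresenceMatrix,
    samples: Sequence[SampleRecord],
    labels: Sequence[CompartmentLabel],
) -> dict[str, AbundanceMatrix | PresenceMatrix]:
    """Per-compartment views: PW keeps pore+both genomes, SW surface+both."""
    by_id = {s.sample_id: s for s in samples}
    out = {}
    for comp, keep in (("PW", {"pore", "both"}), ("SW", {"surface", "both"})):
        sample_ids = [s for s in matrix.sample_ids if by_id[s].compartment.value == comp]
        genome_ids = [l.genome_id for l in labels if l.label in keep]
        sub = matrix.subset_samples(sample_ids)
        if isinstance(sub, PresenceMatrix):
            idx = [sub.genome_ids.index(g) for g in genome_ids]
            sub = PresenceMatrix(genome_ids, sample_ids, sub.present[idx, :])
        else:
            sub = sub.subset_genomes(genome_ids)
        out[comp] = sub
    return out


# ---------------------------------------------------------------------------
# TMM


def _trimmed_weighted_logfc(
    y_k: np.ndarray, y_r: np.ndarray, n_k: float, n_r: float, params: TMMParams
) -> float:
    """Weighted mean of M over doubly trimmed genomes, in log2 units."""
    keep = (y_k > 0) & (y_r > 0)
    if not keep.any():
        return np.nan
    yk, yr = y_k[keep].astype(float), y_r[keep].astype(float)
    m = np.log2((yk / n_k) / (yr / n_r))
    a = 0.5 * np.log2((yk / n_k) * (yr / n_r))
    lo_m, hi_m = np.quantile(m, [params.logratio_trim, 1 - params.logratio_trim])
    lo_a, hi_a = np.quantile(a, [params.abs_trim, 1 - params.abs_trim])
    sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not sel.any():
        return 0.0
    w = (n_k - yk[sel]) / (n_k * yk[sel]) + (n_r - yr[sel]) / (n_r * yr[sel])
    if w.sum() <= 0:
        return float(np.mean(m[sel]))
    return float(np.sum(w * m[sel]) / np.sum(w))


def tmm_normalize(
    cov: CoverageMatrix | AbundanceMatrix,
    params: TMMParams = TMMParams(),
) -> AbundanceMatrix:
    """Trimmed-mean-of-M-values normalization to counts per million.

    Reference sample: the sample whose 75th-percentile count/library-size
    statistic is closest to the mean of that statistic. A sample sharing no
    nonzero genome with the reference gets factor 1 with a warning.
    """
    if isinstance(cov, CoverageMatrix):
        counts = cov.reads.astype(float)
        genome_ids, sample_ids = list(cov.genome_ids), list(cov.sample_ids)
    else:
        counts = cov.values.astype(float)
        genome_ids, sample_ids = list(cov.genome_ids), list(cov.sample_ids)
    n_samples = counts.shape[1]
    if n_samples < 2:
        raise ValidationError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValidationError("every sample needs a positive library size")
    q75 = np.array([np.quantile(counts[:, k] / lib[k], 0.75) for k in range(n_samples)])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    log_factors = np.zeros(n_samples)
    for k in range(n_samples):
        if k == ref:
            continue
        lf = _trimmed_weighted_logfc(counts[:, k], counts[:, ref], lib[k], lib[ref], params)
        if np.isnan(lf):
            warnings.warn(
                f"sample {sample_ids[k]} shares no nonzero genome with the "
                f"reference {sample_ids[ref]}; factor set to 1"
            )
            lf = 0.0
        log_factors[k] = lf
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    values = counts / (lib * factors) * 1e6
    return AbundanceMatrix(
        genome_ids=genome_ids,
        sample_ids=sample_ids,
        values=values,
        state="tmm",
        norm_factors=factors,
        library_sizes=lib,
    )


# ---------------------------------------------------------------------------
# population clustering


def cluster_populations(
    members: Sequence[GenomeRecord],
    pairs: pd.DataFrame,
    params: ClusterParams = ClusterParams(),
) -> dict[str, str]:
    """Greedy ANI clustering: longest genome seeds, absorbs unassigned genomes
    with ani >= min_ani and aligned_fraction (of the shorter) >= threshold.

    ``pairs`` columns: a, b, ani, aligned_fraction. Symmetrized on load.
    """
    ids = {m.genome_id for m in members}
    for col in ("a", "b"):
        unknown = set(pairs[col]) - ids
        if unknown:
            raise ValidationError(f"pair table references unknown genomes {sorted(unknown)}")
    edge: dict[tuple[str, str], tuple[float, float]] = {}
    for _, row in pairs.iterrows():
        key = (row["a"], row["b"])
        edge[key] = (float(row["ani"]), float(row["aligned_fraction"]))
        edge[(key[1], key[0])] = edge[key]
    order = sorted(members, key=lambda m: (-m.length_bp, m.genome_id))
    assigned: dict[str, str] = {}
    for seed in order:
        if seed.genome_id in assigned:
            continue
        assigned[seed.genome_id] = seed.genome_id
        for other in order:
            if other.genome_id in assigned:
                continue
            ani, af = edge.get((seed.genome_id, other.genome_id), (0.0, 0.0))
            if ani >= params.min_ani and af >= params.min_aligned_fraction:
                assigned[other.genome_id] = seed.genome_id
    return assigned


def kmer_pair_table(members: Sequence[GenomeRecord], k: int = 21) -> pd.DataFrame:
    """Optional built-in pair estimator from exact shared k-mers.

    aligned_fraction proxy: shared distinct k-mer containment of the shorter
    sequence; ANI from the Mash-distance transform of the k-mer Jaccard,
    ani = 1 + log(2j/(1+j))/k.
    """
    sets = {}
    for m in members:
        if m.sequence is None:
            raise ValidationError(f"genome {m.genome_id} has no sequence")
        s = m.sequence
        sets[m.genome_id] = {
            s[i : i + k] for i in range(len(s) - k + 1) if "N" not in s[i : i + k]
        }
    rows = []
    ms = list(members)
    for i in range(len(ms)):
        for j in range(i + 1, len(ms)):
            a, b = ms[i], ms[j]
            sa, sb = sets[a.genome_id], sets[b.genome_id]
            inter = len(sa & sb)
            union = len(sa | sb)
            shorter = sa if a.length_bp <= b.length_bp else sb
            af = inter / len(shorter) if shorter else 0.0
            jac = inter / union if union else 0.0
            if jac > 0:
                ani = 1.0 + np.log(2 * jac / (1 + jac)) / k
            else:
                ani = 0.0
            rows.append({"a": a.genome_id, "b": b.genome_id, "ani": max(ani, 0.0), "aligned_fraction": af})
    return pd.DataFrame(rows, columns=["a", "b", "ani", "aligned_fraction"])
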