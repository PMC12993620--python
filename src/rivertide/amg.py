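"""Auxiliary metabolic gene (AMG) scoring and compartment enrichment.

A candidate is any annotated gene carrying a metabolic function id on a viral
contig. Its auxiliary score ranks the confidence that the gene is genuinely
virus-encoded, from the viral context on its flanks (a flank is everything to
that side of the gene on the contig):

* score 1 — at least one viral hallmark gene on both flanks;
* score 2 — a hallmark on one flank and a viral-like gene on the other;
* score 3 — viral-like genes on both flanks (and nothing granting 1 or 2).

The lowest (best) applicable score wins. Calls at a contig end or with a
transposon-like candidate never pass filtering (the score is still reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rivertide.core_io import GeneCall, GeneCategory, ValidationError
from rivertide.temporal import fisher_class_counts


@dataclass(frozen=True)
class AMGCall:
    contig_id: str
    index: int
    auxiliary_score: Optional[int]  # 1..3, None when no viral context
    passes_filters: bool
    function_id: str
    module_header: Optional[str]


def assign_auxiliary_scores(genes: Sequence[GeneCall]) -> list[AMGCall]:
    """Score every gene with a metabolic function id; apply end/transposon filters."""
    by_contig: dict[str, list[GeneCall]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    calls = []
    for contig in sorted(by_contig):
        cg = sorted(by_contig[contig], key=lambda g: g.index)
        if [g.index for g in cg] != list(range(len(cg))):
            raise ValidationError(f"contig {contig}: gene indices not contiguous")
        cats = [g.category for g in cg]
        for g in cg:
            if g.function_id is None:
                continue
            left = cats[: g.index]
            right = cats[g.index + 1 :]
            h_l = GeneCategory.viral_hallmark in left
            h_r = GeneCategory.viral_hallmark in right
            v_l = h_l or GeneCategory.viral_like in left
            v_r = h_r or GeneCategory.viral_like in right
            if h_l and h_r:
                score: Optional[int] = 1
            elif (h_l and v_r) or (v_l and h_r):
                score = 2
            elif v_l and v_r:
                score = 3
            else:
                score = None
            calls.append(
                AMGCall(
                    contig_id=contig,
                    index=g.index,
                    auxiliary_score=score,
                    passes_filters=not (g.at_contig_end or g.is_transposon_like),
                    function_id=g.function_id,
                    module_header=g.module_header,
                )
            )
    return calls


def compartment_enrichment(
    calls: Sequence[AMGCall],
    compartment_of_contig: Mapping[str, str],
    genes: Sequence[GeneCall],
    grouping: str = "function_id",
) -> tuple[pd.DataFrame, float]:
    """Hypergeometric enrichment of AMG groups per compartment, plus an
    overall 2x2 Fisher test of AMG vs non-AMG gene counts by compartment.

    For each (group, compartment): population = all passing scored AMGs,
    successes = AMGs of that group, draws = AMGs in that compartment;
    both the upper tail P(X >= observed) and lower tail P(X <= observed)
    are reported (the enrichment direction is ambiguous a priori).
    """
    if grouping not in ("function_id", "module_header"):
        raise ValidationError("grouping must be function_id or module_header")
    amgs = [c for c in calls if c.passes_filters and c.auxiliary_score is not None]
    if not amgs:
        raise ValidationError("no passing AMG calls")
    df = pd.DataFrame(
        {
            "group": [getattr(c, grouping) or "" for c in amgs],
            "compartment": [compartment_of_contig[c.contig_id] for c in amgs],
        }
    )
    n_total = len(df)
    rows = []
    for group in sorted(df["group"].unique()):
        k_group = int((df["group"] == group).sum())
        for comp in sorted(df["compartment"].unique()):
            n_comp = int((df["compartment"] == comp).sum())
            obs = int(((df["group"] == group) & (df["compartment"] == comp)).sum())
            p_upper = float(stats.hypergeom.sf(obs - 1, n_total, k_group, n_comp))
            p_lower = float(stats.hypergeom.cdf(obs, n_total, k_group, n_comp))
            rows.append(
                {
                    "group": group,
                    "compartment": comp,
                    "n_group_in_compartment": obs,
                    "n_group_total": k_group,
                    "n_compartment": n_comp,
                    "n_total": n_total,
                    "p_enriched": min(p_upper, 1.0),
                    "p_depleted": min(p_lower, 1.0),
                }
            )
    per_group = pd.DataFrame(rows)
    # overall 2x2: AMG / non-AMG gene x compartment
    amg_keys = {(c.contig_id, c.index) for c in amgs}
    comps = sorted({compartment_of_contig[g.contig_id] for g in genes
                    if g.contig_id in compartment_of_contig})
    if len(comps) != 2:
        raise ValidationError("overall Fisher test needs exactly 2 compartments")
    table = np.zeros((2, 2), dtype=np.int64)
    for g in genes:
        comp = compartment_of_contig.get(g.contig_id)
        if comp is None:
            continue
        i = 0 if (g.contig_id, g.index) in amg_keys else 1
        table[i, comps.index(comp)] += 1
    fisher_p = fisher_class_counts(table)
    return per_group, float(fisher_p)
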