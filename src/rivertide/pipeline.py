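"""End-to-end orchestration of the temporal river-virome analysis.

``run_pipeline`` exercises every stage on a synthetic community with planted
truth: coverage simulation, presence calling, compartment assignment, TMM
normalization, persistence/stability classification, consecutive Bray-Curtis
with the compartment comparison, ordination and multivariate tests,
co-occurrence module detection, module-chemistry sparse PLS, virus-host
linkage on simulated genomes, and AMG scoring on simulated annotations.
It returns the recovery metrics against the planted truth plus the headline
statistics, and optionally writes all stage tables to an output directory.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from rivertide import abundance as ab
from rivertide import amg as amg_mod
from rivertide import ecology as eco
from rivertide import hostlink as hl
from rivertide import network as nw
from rivertide import spls as sp
from rivertide import synthetic_data as sd
from rivertide import temporal as tmp
from rivertide.core_io import RunConfig, write_run_metadata, write_table

logger = logging.getLogger("rivertide")


def _chem_frame(design) -> pd.DataFrame:
    return pd.DataFrame(
        {v: {s.sample_id: s.chemistry[v] for s in design} for v in design[0].chemistry}
    )


def community_analysis(
    seed: int,
    n_viral: int = 350,
    n_microbial: int = 150,
    out_dir: Optional[Path] = None,
) -> dict:
    """Community stages on the default synthetic dataset (500 genomes, 32 samples)."""
    cov, design, truth = sd.simulate_community(
        n_viral=n_viral, n_microbial=n_microbial, seed=seed
    )
    pres = ab.apply_detection(cov)
    labels = ab.assign_compartments(pres, design)
    tmm = ab.tmm_normalize(cov)
    pres_split = ab.split_by_compartment(pres, design, labels)
    tmm_split = ab.split_by_compartment(tmm, design, labels)
    by_id = {s.sample_id: s for s in design}

    metrics: dict = {}
    # persistence and stability ------------------------------------------------
    persistence, stability = {}, {}
    n_ok, n_tot = 0, 0
    for comp in ("SW", "PW"):
        calls = tmp.classify_persistence(pres_split[comp], comp)
        persistence[comp] = calls
        stability[comp] = tmp.classify_stability(tmm_split[comp], calls)
        for c in calls:
            planted = truth.persistence_class[c.genome_id].get(comp)
            if planted is not None:
                n_tot += 1
                n_ok += c.persistence_class == planted
    metrics["persistence_recovery"] = n_ok / n_tot
    frac_persistent = {
        comp: np.mean([c.persistence_class == "persistent" for c in persistence[comp]])
        for comp in ("SW", "PW")
    }
    metrics["sw_persistent_fraction"] = float(frac_persistent["SW"])
    metrics["pw_persistent_fraction"] = float(frac_persistent["PW"])

    # consecutive Bray-Curtis and the compartment comparison -------------------
    bc = {
        comp: [v for _, v in tmp.consecutive_bray_curtis(
            tmm_split[comp], [s for s in design if s.compartment.value == comp]
        )]
        for comp in ("SW", "PW")
    }
    t_stat, df, p = tmp.compare_compartments(bc["SW"], bc["PW"])
    metrics["bc_t_statistic"] = float(t_stat)
    metrics["bc_t_p"] = float(p)
    metrics["mean_bc_sw"] = float(np.mean(bc["SW"]))
    metrics["mean_bc_pw"] = float(np.mean(bc["PW"]))
    table = tmp.stability_class_table(stability["SW"], stability["PW"])
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        metrics["stability_fisher_p"] = tmp.fisher_class_counts(table, seed=seed)

    # ordination, PERMANOVA, Procrustes ----------------------------------------
    d_all = eco.bray_curtis_matrix(tmm)
    groups = [by_id[s].compartment.value for s in d_all.sample_ids]
    perma = eco.permanova(d_all, groups, n_perm=999, seed=seed)
    metrics["permanova_r2"] = eco.permanova_r2(d_all, groups)
    metrics["permanova_p"] = perma.p
    viral_ids = [g for g, k in zip(truth.genome_ids, truth.kinds) if k == "viral"]
    microbial_ids = [g for g in truth.genome_ids if g not in set(viral_ids)]
    ords = {}
    for name, ids in (("viral", viral_ids), ("microbial", microbial_ids)):
        sub = tmm.subset_genomes(ids)
        d = eco.bray_curtis_matrix(sub)
        ords[name] = eco.nmds(d, seed=seed)
        metrics[f"nmds_stress_{name}"] = ords[name].stress
    proc, corr = eco.procrustes_test(ords["viral"], ords["microbial"], seed=seed)
    metrics["procrustes_m2"] = proc.value
    metrics["procrustes_corr"] = corr
    metrics["procrustes_p"] = proc.p

    # modules and sPLS ----------------------------------------------------------
    chem = _chem_frame(design)
    module_rows = []
    spls_rows = []
    for comp, power in (("SW", 14), ("PW", 8)):
        sub = tmm_split[comp]
        params = nw.NetworkParams(power=power)
        ids, adj, tom = nw.build_tom(sub, params)
        modules = nw.detect_modules(ids, tom, sub, params, adjacency=adj)
        pred = [modules.labels[g] for g in ids]
        true = [truth.module_of[g] or "none" for g in ids]
        planted_here = {m for g, m in zip(ids, true) if m != "none"}
        if planted_here:
            metrics[f"module_ari_{comp.lower()}"] = adjusted_rand_score(true, pred)
        for g in ids:
            module_rows.append({"compartment": comp, "genome_id": g, "module": modules.labels[g]})
        chem_comp = chem.loc[sub.sample_ids]
        for mod in sorted(set(modules.labels.values()) - {nw.UNASSIGNED}):
            members = [g for g in ids if modules.labels[g] == mod]
            x = pd.DataFrame(
                sub.values[[sub.genome_ids.index(g) for g in members], :].T,
                index=sub.sample_ids,
                columns=members,
            )
            for var in chem_comp.columns:
                fit = sp.spls_fit(x, chem_comp[var], sp.SPLSParams(n_perm=199), seed=seed,
                                  module=mod)
                spls_rows.append(
                    {
                        "compartment": comp,
                        "module": mod,
                        "variable": var,
                        "n_members": len(members),
                        "r2": fit.r2,
                        "p": fit.p_perm,
                        "significant": fit.significant,
                        "n_vip_gt1": int((fit.vip > 1).sum()),
                    }
                )
    spls_df = pd.DataFrame(spls_rows)
    if not spls_df.empty:
        sig = spls_df[spls_df["significant"]]
        metrics["n_significant_module_chem"] = int(
            sig.groupby(["compartment", "module"]).ngroups
        )
        metrics["best_module_chem_r2"] = float(spls_df["r2"].max())

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from rivertide.core_io import records_to_frame, write_coverage, write_metadata

        write_coverage(cov, out_dir / "coverage.tsv")
        write_metadata(design, out_dir / "metadata.tsv")
        write_table(truth.truth_frame(), out_dir / "truth_community.tsv")
        pers = [c for comp in ("SW", "PW") for c in persistence[comp]]
        write_table(
            records_to_frame(
                pers,
                ["genome_id", "compartment", "n_detected", "n_samples", "fraction",
                 "persistence_class"],
            ),
            out_dir / "persistence.tsv",
        )
        stab = [c for comp in ("SW", "PW") for c in stability[comp]]
        write_table(
            records_to_frame(
                stab,
                ["genome_id", "compartment", "median_abundance", "n_fluctuating",
                 "n_samples", "stability_class"],
            ),
            out_dir / "stability.tsv",
        )
        write_table(pd.DataFrame(module_rows), out_dir / "modules.tsv")
        write_table(spls_df, out_dir / "spls_fits.tsv")
    return metrics


def hostlink_analysis(seed: int, n_hosts: int = 10, n_linked: int = 10,
                      n_unlinked: int = 10, out_dir: Optional[Path] = None) -> dict:
    """Virus-host linkage recovery on simulated genomes with planted evidence."""
    records, link_truth = sd.simulate_genomes(
        n_hosts=n_hosts, n_linked_viruses=n_linked, n_unlinked_viruses=n_unlinked,
        seed=seed,
    )
    hosts = [r for r in records if r.kind.value == "microbial"]
    viruses = [r for r in records if r.kind.value == "viral"]
    preds = hl.predict_hosts(viruses, hosts)
    true_pairs = {(v, h) for v, h, _ in link_truth.pairs}
    accepted = {(p.virus_id, p.host_id) for p in preds if p.accepted}
    tp_n = len(accepted & true_pairs)
    metrics = {
        "hostlink_precision": tp_n / len(accepted) if accepted else 0.0,
        "hostlink_recall": tp_n / len(true_pairs),
        "n_accepted_links": len(accepted),
    }
    # planted spacer recovery
    n_spacer_found = 0
    for v, h, _ in link_truth.pairs:
        hit = [p for p in preds if p.virus_id == v and p.host_id == h and p.spacer_hits > 0]
        n_spacer_found += bool(hit)
    metrics["spacer_recovery"] = n_spacer_found / len(true_pairs)
    d2_linked = [p.d2star for p in preds if (p.virus_id, p.host_id) in true_pairs]
    d2_unlinked = [p.d2star for p in preds if (p.virus_id, p.host_id) not in true_pairs]
    metrics["median_d2star_linked"] = float(np.median(d2_linked))
    metrics["median_d2star_unlinked"] = float(np.median(d2_unlinked))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "virus_id": p.virus_id, "host_id": p.host_id, "d2star": p.d2star,
                "is_best_d2star_hit": p.is_best_d2star_hit, "shared_kmers": p.shared_kmers,
                "phist_p_raw": p.phist_p_raw, "phist_p_adj": p.phist_p_adj,
                "spacer_hits": p.spacer_hits, "evidence": p.evidence or "",
                "accepted": p.accepted,
            }
            for p in preds
        ]
        write_table(pd.DataFrame(rows), out_dir / "host_predictions.tsv")
    return metrics


def amg_analysis(seed: int, n_contigs: int = 24, out_dir: Optional[Path] = None) -> dict:
    """Auxiliary-score recovery on planted annotation configurations."""
    genes, truth = sd.simulate_annotations(n_contigs=n_contigs, seed=seed)
    calls = amg_mod.assign_auxiliary_scores(genes)
    call_idx = {(c.contig_id, c.index): c for c in calls}
    n_ok = 0
    for row in truth.itertuples():
        call = call_idx.get((row.contig_id, row.index))
        expected = int(row.expected_score) if row.expected_score != "" else None
        got = call.auxiliary_score if call else None
        passes = call.passes_filters if call else False
        n_ok += (got == expected) and (passes == bool(row.expected_pass))
    metrics = {"amg_score_accuracy": n_ok / len(truth)}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "contig_id": c.contig_id, "index": c.index,
                "auxiliary_score": c.auxiliary_score if c.auxiliary_score else "",
                "passes_filters": c.passes_filters, "function_id": c.function_id,
                "module_header": c.module_header or "",
            }
            for c in calls
        ]
        write_table(pd.DataFrame(rows), out_dir / "amg_calls.tsv")
        write_table(truth, out_dir / "truth_amg.tsv")
    return metrics


def run_pipeline(seed: int = 0, out_dir: Optional[str | Path] = None,
                 n_viral: int = 350, n_microbial: int = 150) -> dict:
    """All stages on the default synthetic dataset; returns recovery metrics."""
    t0 = time.time()
    out = Path(out_dir) if out_dir is not None else None
    metrics = {}
    metrics.update(community_analysis(seed, n_viral=n_viral, n_microbial=n_microbial,
                                      out_dir=out))
    metrics.update(hostlink_analysis(seed, out_dir=out))
    metrics.update(amg_analysis(seed, out_dir=out))
    metrics["runtime_s"] = time.time() - t0
    if out is not None:
        write_run_metadata(out / "run_metadata.yaml", RunConfig(seed=seed, out_dir=str(out)))
    return metrics
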