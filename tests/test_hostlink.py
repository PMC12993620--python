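import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rivertide import hostlink as hl
from rivertide.core_io import GenomeKind, GenomeRecord, ValidationError


def random_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# d2*


def oracle_d2star(seq_a, seq_b, k=6, m=2):
    """Literal per-word enumeration over all 4^k words, independent of the
    vectorized counter."""

    def counts(seq, klen):
        c = Counter()
        for s in (seq, hl.reverse_complement(seq)):
            for i in range(len(s) - klen + 1):
                w = s[i : i + klen]
                if "N" not in w:
                    c[w] += 1
        return c

    def probs(seq):
        c3 = counts(seq, m + 1)
        ctx = Counter()
        for w, v in c3.items():
            ctx[w[:m]] += v
        total = sum(ctx.values())
        p = {}
        for word in map("".join, itertools.product("ACGT", repeat=k)):
            pw = ctx.get(word[:m], 0) / total
            for i in range(m, k):
                den = ctx.get(word[i - m : i], 0)
                pw *= c3.get(word[i - m : i + 1], 0) / den if den else 0.0
            p[word] = pw
        return p

    ca, cb = counts(seq_a, k), counts(seq_b, k)
    na, nb = sum(ca.values()), sum(cb.values())
    pa, pb = probs(seq_a), probs(seq_b)
    num = da = db = 0.0
    for word, pwa in pa.items():
        pwb = pb[word]
        if pwa > 0 and pwb > 0:
            ea, eb = na * pwa, nb * pwb
            xt, yt = ca.get(word, 0) - ea, cb.get(word, 0) - eb
            num += xt * yt / math.sqrt(ea * eb)
            da += xt * xt / ea
            db += yt * yt / eb
    return 0.5 * (1 - num / math.sqrt(da * db))


def test_d2star_self_and_symmetry():
    a, b = random_seq(5000, 1), random_seq(5000, 2)
    assert hl.d2star(a, a) == pytest.approx(0.0, abs=1e-12)
    assert hl.d2star(a, b) == hl.d2star(b, a)
    assert 0.0 <= hl.d2star(a, b) <= 1.0


def test_d2star_matches_word_enumeration_oracle():
    a, b = random_seq(20000, 3), random_seq(20000, 4)
    assert hl.d2star(a, b) == pytest.approx(oracle_d2star(a, b), abs=1e-10)


def test_d2star_rejects_degenerate_input():
    with pytest.raises(ValidationError):
        hl.d2star("ACG", random_seq(1000, 0))
    with pytest.raises(ValidationError):
        hl.d2star("N" * 500, random_seq(1000, 0))


def test_d2star_shared_suffix_lowers_dissimilarity():
    """Appending the same long suffix to both sequences moves composition
    together (checked in aggregate over 30 draws)."""
    rng = np.random.default_rng(9)
    deltas = []
    for i in range(30):
        a = random_seq(4000, 100 + i)
        b = random_seq(4000, 200 + i)
        suffix = random_seq(12000, 300 + i)
        before = hl.d2star(a, b)
        after = hl.d2star(a + suffix, b + suffix)
        deltas.append(before - after)
    assert np.mean(deltas) > 0
    assert np.mean(np.array(deltas) > 0) > 0.8


# ---------------------------------------------------------------------------
# shared k-mers


def test_shared_kmer_zero_overlap_gives_p_one():
    v = GenomeRecord("v", GenomeKind.viral, 2000, random_seq(2000, 5))
    h = GenomeRecord("h", GenomeKind.microbial, 2000, random_seq(2000, 6))
    shared, p = hl.shared_kmer_test(v, h, host_panel_kmer_universe=10**7)
    assert shared == 0
    assert p == 1.0


def test_shared_kmer_p_matches_closed_form():
    """p equals the hypergeometric survival sum evaluated from log-gammas."""
    n_universe, k_host, n_virus, shared = 10**6, 10**4, 10**3, 50

    def log_comb(a, b):
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    p_direct = sum(
        math.exp(
            log_comb(k_host, x)
            + log_comb(n_universe - k_host, n_virus - x)
            - log_comb(n_universe, n_virus)
        )
        for x in range(shared, n_virus + 1)
    )
    p_impl = float(stats.hypergeom.sf(shared - 1, n_universe, k_host, n_virus))
    assert p_impl == pytest.approx(p_direct, rel=1e-12)


def test_planted_pair_shares_copied_window(planted_genomes):
    records, truth = planted_genomes
    by_id = {r.genome_id: r for r in records}
    v_id, h_id, _ = truth.pairs[0]
    universe = 10**7
    shared, p = hl.shared_kmer_test(by_id[v_id], by_id[h_id], universe)
    assert shared >= 976
    assert p < 1e-10


def test_canonical_kmers_are_strand_invariant():
    s = random_seq(3000, 7)
    fwd = hl.canonical_kmer_set(s, 25)
    rev = hl.canonical_kmer_set(hl.reverse_complement(s), 25)
    np.testing.assert_array_equal(fwd, rev)


# ---------------------------------------------------------------------------
# CRISPR arrays and spacer matching


def test_planted_crispr_array_recovered(planted_genomes):
    records, truth = planted_genomes
    hosts = {r.genome_id: r for r in records if r.kind.value == "microbial"}
    host_with_one_virus = [h for h in hosts if int(h.split("_")[1]) < 10]
    arrays = hl.find_crispr_arrays(hosts["host_003"])
    assert len(arrays) >= 1
    assert any(len(a.spacers) == 3 for a in arrays)
    a = max(arrays, key=lambda x: len(x.spacers))
    assert 21 <= len(a.repeat_seq) <= 48
    assert all(20 <= len(s) <= 60 for s in a.spacers)


def test_no_arrays_on_plain_markov_sequence():
    """Random-sequence false positives are rare (0 arrays in >= 19 of 20)."""
    hits = 0
    for i in range(20):
        g = GenomeRecord(f"r{i}", GenomeKind.microbial, 50_000, random_seq(50_000, 40 + i))
        hits += bool(hl.find_crispr_arrays(g))
    assert hits <= 1


def test_wide_gaps_break_an_array():
    repeat = random_seq(28, 50)
    spacer = random_seq(500, 51)  # far outside the spacer length range
    seq = (repeat + spacer) * 9 + repeat
    g = GenomeRecord("g", GenomeKind.microbial, len(seq), seq)
    assert hl.find_crispr_arrays(g) == []


def test_spacer_matching_mismatch_boundary():
    virus_seq = random_seq(5000, 60)
    spacer = virus_seq[1000:1032]
    mutated = spacer[:10] + ("A" if spacer[10] != "A" else "C") + spacer[11:]
    arr_exact = hl.SpacerArray("h", "R" * 0 + random_seq(28, 61), (spacer,), 0)
    arr_mut = hl.SpacerArray("h", random_seq(28, 62), (mutated,), 0)
    virus = GenomeRecord("v", GenomeKind.viral, len(virus_seq), virus_seq)
    hits0 = hl.match_spacers([arr_mut], [virus], hl.HostLinkParams(spacer_max_mismatch=0))
    hits1 = hl.match_spacers([arr_mut], [virus], hl.HostLinkParams(spacer_max_mismatch=1))
    assert hits0.empty
    assert hits1["n_spacer_hits"].tolist() == [1]
    exact = hl.match_spacers([arr_exact], [virus], hl.HostLinkParams(spacer_max_mismatch=0))
    assert exact["n_spacer_hits"].tolist() == [1]


def naive_best_mismatch(text, pattern):
    best = len(pattern)
    for probe in (pattern, hl.reverse_complement(pattern)):
        for i in range(len(text) - len(probe) + 1):
            d = sum(1 for a, b in zip(text[i : i + len(probe)], probe) if a != b)
            best = min(best, d)
    return best


def test_spacer_scan_agrees_with_naive_oracle():
    rng = np.random.default_rng(3)
    for trial in range(25):
        text = random_seq(800, 400 + trial)
        pattern = random_seq(24, 500 + trial)
        if trial % 3 == 0:  # plant an exact or near-exact occurrence
            pos = int(rng.integers(0, len(text) - 24))
            text = text[:pos] + pattern + text[pos + 24 :]
        prof_f = hl._mismatch_profile(text, pattern)
        prof_r = hl._mismatch_profile(text, hl.reverse_complement(pattern))
        assert min(prof_f.min(), prof_r.min()) == naive_best_mismatch(text, pattern)


# ---------------------------------------------------------------------------
# consensus


def _frames(d2_rows, ph_rows, sp_rows):
    return (
        pd.DataFrame(d2_rows, columns=["virus_id", "host_id", "d2star"]),
        pd.DataFrame(ph_rows, columns=["virus_id", "host_id", "shared_kmers", "p_raw"]),
        pd.DataFrame(sp_rows, columns=["host_id", "virus_id", "n_spacer_hits"]),
    )


def test_consensus_rules():
    d2, ph, sp = _frames(
        [("v1", "h1", 0.15), ("v1", "h2", 0.30), ("v2", "h1", 0.15), ("v2", "h2", 0.5),
         ("v3", "h1", 0.9), ("v3", "h2", 0.95)],
        [("v1", "h1", 100, 1e-6), ("v2", "h1", 5, 0.9), ("v3", "h2", 0, 1.0)],
        [("h2", "v3", 2)],
    )
    preds = {(p.virus_id, p.host_id): p for p in hl.consensus_linkage(d2, ph, sp)}
    # best hit, d2* < 0.2, adjusted p < 0.05 -> consensus
    assert preds[("v1", "h1")].accepted and preds[("v1", "h1")].evidence == "consensus"
    # best hit with good d2* but insignificant k-mer p -> rejected
    assert not preds[("v2", "h1")].accepted
    # spacer hit alone -> crispr evidence, regardless of d2*
    assert preds[("v3", "h2")].accepted and preds[("v3", "h2")].evidence == "crispr"
    # non-best pair never gets consensus
    assert not preds[("v1", "h2")].accepted


def test_consensus_rejects_unknown_ids():
    d2, ph, sp = _frames([("v1", "h1", 0.1)], [("vX", "h1", 3, 0.5)], [])
    with pytest.raises(ValidationError, match="unknown"):
        hl.consensus_linkage(d2, ph, sp)


def test_bh_adjustment_is_monotone():
    rng = np.random.default_rng(12)
    p = rng.uniform(size=40)
    adj = hl.benjamini_hochberg(p)
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()
    assert (adj >= p - 1e-15).all() and (adj <= 1).all()


# ---------------------------------------------------------------------------
# virus-bacteria ratio


def test_vbr_identity_and_scaling():
    host = np.array([2.0, 3.0, 4.0, 5.0])
    vbr, mean_vbr, r, p = hl.virus_host_ratio(host, host)
    np.testing.assert_allclose(vbr, 1.0)
    assert mean_vbr == 1.0 and r == pytest.approx(1.0)
    vbr10, mean10, r10, _ = hl.virus_host_ratio(10 * host, host)
    assert mean10 == pytest.approx(10.0)
    assert r10 == pytest.approx(1.0)


def test_vbr_excludes_zero_host_timepoints():
    virus = np.array([1.0, 2.0, 3.0, 4.0])
    host = np.array([1.0, 0.0, 3.0, 4.0])
    vbr, mean_vbr, _, _ = hl.virus_host_ratio(virus, host)
    assert np.isnan(vbr[1])
    assert mean_vbr == pytest.approx(1.0)


def test_vbr_correlation_p_consistent_with_permutation():
    rng = np.random.default_rng(5)
    virus = rng.lognormal(0, 0.5, size=14)
    host = virus * rng.lognormal(0, 0.35, size=14)
    _, _, r_obs, p_obs = hl.virus_host_ratio(virus, host)
    n_perm = 2000
    hits = 0
    h = host.copy()
    for _ in range(n_perm):
        rng.shuffle(h)
        hits += abs(np.corrcoef(virus, h)[0, 1]) >= abs(r_obs)
    p_perm = (1 + hits) / (1 + n_perm)
    se = math.sqrt(max(p_obs * (1 - p_obs), 1e-6) / n_perm)
    assert abs(p_perm - p_obs) <= 4 * se + 0.01
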