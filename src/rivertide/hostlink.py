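"""Alignment-free virus-host prediction and the virus-bacteria ratio.

Three evidence channels, mirroring the common composition / exact-match /
CRISPR triad of host-prediction tools:

* **d2\\*** — dissimilarity between k-word (default k=6) count vectors of the
  two genomes after centring each by the expected counts of an order-2 Markov
  model fitted to that genome; low values indicate host-adapted nucleotide
  composition. Words are counted on both strands.
* **shared k-mers** — number of distinct canonical 25-mers shared between
  virus and host, with an upper-tail hypergeometric p-value against the k-mer
  universe of the host panel; p-values Benjamini-Hochberg adjusted across all
  virus x host pairs.
* **CRISPR spacers** — direct-repeat arrays detected on host genomes by a
  seed-and-extend repeat finder; a spacer hitting the virus (either strand,
  bounded mismatches) is direct evidence of past infection.

A pair is accepted when it has a spacer hit (evidence ``crispr``), or when the
host is the virus's best (minimum) d2* hit with d2* < 0.2 AND the adjusted
shared-k-mer p < 0.05 (evidence ``consensus``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from rivertide.core_io import GenomeRecord, ValidationError

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class HostLinkParams:
    d2star_word_k: int = 6
    d2star_markov_order: int = 2
    d2star_max: float = 0.2  # strict <
    phist_k: int = 25
    phist_alpha: float = 0.05  # adjusted, strict <
    spacer_max_mismatch: int = 1
    repeat_len_range: tuple[int, int] = (21, 48)
    spacer_len_range: tuple[int, int] = (20, 60)
    min_repeat_copies: int = 3

    def __post_init__(self) -> None:
        if self.d2star_markov_order > self.d2star_word_k - 2:
            raise ValidationError("markov_order must be <= word_k - 2")


@dataclass(frozen=True)
class SpacerArray:
    host_id: str
    repeat_seq: str
    spacers: tuple[str, ...]
    start: int


@dataclass(frozen=True)
class HostPrediction:
    virus_id: str
    host_id: str
    d2star: float
    is_best_d2star_hit: bool
    shared_kmers: int
    phist_p_raw: float
    phist_p_adj: float
    spacer_hits: int
    evidence: Optional[str]  # crispr | consensus | None
    accepted: bool


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _word_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-words without N, 2 bits per base."""
    enc = _encode(seq)
    if enc.size < k:
        return np.empty(0, dtype=np.int64)
    win = sliding_window_view(enc, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win[valid].astype(np.int64) @ powers


def _word_counts_both_strands(seq: str, k: int) -> tuple[np.ndarray, int]:
    """k-word count vector over 4^k words, sequence plus reverse complement."""
    counts = np.zeros(4**k, dtype=np.int64)
    for s in (seq, reverse_complement(seq)):
        codes = _word_codes(s, k)
        counts += np.bincount(codes, minlength=4**k)
    return counts, int(counts.sum())


def markov_word_probs(seq: str, k: int, order: int) -> np.ndarray:
    """Per-word probability under an order-``order`` Markov model fitted to the
    sequence's (order+1)-mer frequencies (both strands)."""
    m = order
    c_next, _ = _word_counts_both_strands(seq, m + 1)  # (m+1)-mer counts
    c_ctx = c_next.reshape(4**m, 4).sum(axis=1).astype(float)  # context totals
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = np.where(c_ctx[:, None] > 0, c_next.reshape(4**m, 4) / c_ctx[:, None], 0.0)
    ctx_total = c_ctx.sum()
    p_ctx = c_ctx / ctx_total if ctx_total > 0 else np.zeros_like(c_ctx)
    words = np.arange(4**k, dtype=np.int64)
    bases = [(words >> (2 * (k - 1 - i))) & 3 for i in range(k)]
    ctx = np.zeros(4**k, dtype=np.int64)
    for i in range(m):
        ctx = ctx * 4 + bases[i]
    p = p_ctx[ctx].astype(float)
    roll = 4 ** (m - 1) if m > 1 else 1
    for i in range(m, k):
        p *= trans[ctx, bases[i]]
        # slide the m-mer context one base to the right
        if m > 1:
            ctx = (ctx % roll) * 4 + bases[i]
        elif m == 1:
            ctx = bases[i]
    return p


def d2star(seq_a: str, seq_b: str, params: HostLinkParams = HostLinkParams()) -> float:
    """d2* dissimilarity in [0, 1]; 0 for identical composition."""
    k, m = params.d2star_word_k, params.d2star_markov_order
    for s in (seq_a, seq_b):
        if len(s.replace("N", "")) < k:
            raise ValidationError("sequence shorter than word length (or all N)")
        if len(s) < 10 * 4**k:
            warnings.warn("sequence shorter than the recommended 10*4^k for d2*")
    xa, na = _word_counts_both_strands(seq_a, k)
    xb, nb = _word_counts_both_strands(seq_b, k)
    pa = markov_word_probs(seq_a, k, m)
    pb = markov_word_probs(seq_b, k, m)
    ok = (pa > 0) & (pb > 0)
    ea, eb = na * pa[ok], nb * pb[ok]
    xt = xa[ok] - ea
    yt = xb[ok] - eb
    num = np.sum(xt * yt / np.sqrt(ea * eb))
    den = np.sqrt(np.sum(xt**2 / ea) * np.sum(yt**2 / eb))
    if den == 0:
        raise ValidationError("degenerate d2* denominator")
    d2s = 0.5 * (1 - num / den)
    return float(min(max(d2s, 0.0), 1.0))


# ---------------------------------------------------------------------------
# shared k-mers (PHIST-style)


def canonical_kmer_set(seq: str, k: int = 25) -> np.ndarray:
    """Distinct canonical k-mer codes (lexicographic min of word and its
    reverse complement); N-containing k-mers dropped."""
    enc = _encode(seq)
    if enc.size < k:
        return np.empty(0, dtype=np.int64)
    win = sliding_window_view(enc, k)
    valid = (win >= 0).all(axis=1)
    win = win[valid].astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ powers
    rev = (3 - win) @ powers[::-1]
    return np.unique(np.minimum(fwd, rev))


def shared_kmer_test(
    virus: GenomeRecord,
    host: GenomeRecord,
    host_panel_kmer_universe: int,
    params: HostLinkParams = HostLinkParams(),
    virus_set: Optional[np.ndarray] = None,
    host_set: Optional[np.ndarray] = None,
) -> tuple[int, float]:
    """Shared distinct canonical 25-mers and upper-tail hypergeometric p.

    p = P(X >= shared) with X ~ Hypergeom(N=universe, K=|host set|,
    n=|virus set|). Precomputed k-mer sets may be supplied to amortize work.
    """
    if virus_set is None:
        virus_set = canonical_kmer_set(virus.sequence, params.phist_k)
    if host_set is None:
        host_set = canonical_kmer_set(host.sequence, params.phist_k)
    n, kk = len(virus_set), len(host_set)
    if host_panel_kmer_universe < max(n, kk):
        raise ValidationError("k-mer universe smaller than a member set")
    shared = int(np.intersect1d(virus_set, host_set, assume_unique=True).size)
    p_raw = float(stats.hypergeom.sf(shared - 1, host_panel_kmer_universe, kk, n))
    return shared, min(p_raw, 1.0)


# ---------------------------------------------------------------------------
# CRISPR arrays


def find_crispr_arrays(
    host: GenomeRecord, params: HostLinkParams = HostLinkParams(), seed_len: int = 21
) -> list[SpacerArray]:
    """Seed-and-extend direct-repeat finder.

    A seed word of length 21 occurring >= min_repeat_copies times with
    successive gaps inside the spacer length range nominates an array; repeats
    are extended maximally while all copies agree, arrays kept when the final
    repeat length falls inside ``repeat_len_range``.
    """
    seq = host.sequence
    if seq is None:
        raise ValidationError(f"genome {host.genome_id} has no sequence")
    lo_s, hi_s = params.spacer_len_range
    lo_r, hi_r = params.repeat_len_range
    positions: dict[str, list[int]] = {}
    for i in range(len(seq) - seed_len + 1):
        w = seq[i : i + seed_len]
        if "N" in w:
            continue
        positions.setdefault(w, []).append(i)
    arrays: dict[tuple[int, str], SpacerArray] = {}
    for word, pos in positions.items():
        if len(pos) < params.min_repeat_copies:
            continue
        # chains of consecutive occurrences with admissible gaps
        chain = [pos[0]]
        chains = []
        for p in pos[1:]:
            gap = p - (chain[-1] + seed_len)
            if lo_s - (hi_r - seed_len) <= gap <= hi_s + (hi_r - seed_len):
                chain.append(p)
            else:
                chains.append(chain)
                chain = [p]
        chains.append(chain)
        for chain in chains:
            if len(chain) < params.min_repeat_copies:
                continue
            starts, rep_len = _extend_repeats(seq, chain, seed_len)
            if not (lo_r <= rep_len <= hi_r):
                continue
            spacers = []
            ok = True
            for a, b in zip(starts, starts[1:]):
                sp = seq[a + rep_len : b]
                if not (lo_s <= len(sp) <= hi_s):
                    ok = False
                    break
                spacers.append(sp)
            if not ok:
                continue
            key = (starts[0], seq[starts[0] : starts[0] + rep_len])
            arrays[key] = SpacerArray(
                host_id=host.genome_id,
                repeat_seq=seq[starts[0] : starts[0] + rep_len],
                spacers=tuple(spacers),
                start=starts[0],
            )
    return [arrays[k] for k in sorted(arrays)]


def _extend_repeats(seq: str, starts: list[int], seed_len: int) -> tuple[list[int], int]:
    """Extend identical copies left and right while all agree."""
    left = 0
    while all(s - left - 1 >= 0 for s in starts):
        chars = {seq[s - left - 1] for s in starts}
        if len(chars) != 1:
            break
        left += 1
        # avoid running one copy into the previous one
        if any(starts[i] - left <= starts[i - 1] + seed_len for i in range(1, len(starts))):
            left -= 1
            break
    right = 0
    while all(s + seed_len + right < len(seq) for s in starts):
        chars = {seq[s + seed_len + right] for s in starts}
        if len(chars) != 1:
            break
        right += 1
        if any(starts[i - 1] + seed_len + right >= starts[i] - left for i in range(1, len(starts))):
            right -= 1
            break
    return [s - left for s in starts], seed_len + left + right


def _mismatch_profile(text: str, pattern: str) -> np.ndarray:
    """Hamming distance of `pattern` against every window of `text`."""
    t = _encode(text)
    p = _encode(pattern)
    if t.size < p.size:
        return np.empty(0, dtype=np.int64)
    win = sliding_window_view(t, p.size)
    return (win != p).sum(axis=1)


def match_spacers(
    arrays: Sequence[SpacerArray],
    viruses: Sequence[GenomeRecord],
    params: HostLinkParams = HostLinkParams(),
) -> pd.DataFrame:
    """Spacer hits: spacer or its reverse complement occurs in the virus with
    <= spacer_max_mismatch mismatches. Returns host_id, virus_id, n_spacer_hits."""
    rows = []
    for virus in viruses:
        if virus.sequence is None:
            raise ValidationError(f"virus {virus.genome_id} has no sequence")
        for arr in arrays:
            hits = 0
            for sp in arr.spacers:
                found = False
                for probe in (sp, reverse_complement(sp)):
                    prof = _mismatch_profile(virus.sequence, probe)
                    if prof.size and prof.min() <= params.spacer_max_mismatch:
                        found = True
                        break
                if found:
                    hits += 1
            if hits:
                rows.append({"host_id": arr.host_id, "virus_id": virus.genome_id, "n_spacer_hits": hits})
    df = pd.DataFrame(rows, columns=["host_id", "virus_id", "n_spacer_hits"])
    if not df.empty:
        df = df.groupby(["host_id", "virus_id"], as_index=False)["n_spacer_hits"].sum()
    return df


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone in the raw p ranking)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def consensus_linkage(
    d2_results: pd.DataFrame,
    phist_results: pd.DataFrame,
    spacer_hits: pd.DataFrame,
    params: HostLinkParams = HostLinkParams(),
) -> list[HostPrediction]:
    """Combine the three evidence channels into accepted predictions.

    ``d2_results``: virus_id, host_id, d2star (all scored pairs).
    ``phist_results``: virus_id, host_id, shared_kmers, p_raw.
    ``spacer_hits``: host_id, virus_id, n_spacer_hits.
    """
    d2 = d2_results.copy()
    known = set(d2["virus_id"]) | set(d2["host_id"])
    for df, cols in ((phist_results, ("virus_id", "host_id")), (spacer_hits, ("virus_id", "host_id"))):
        if df.empty:
            continue
        ids = set(df[cols[0]]) | set(df[cols[1]])
        unknown = ids - known
        if unknown:
            raise ValidationError(f"evidence table references unknown genomes {sorted(unknown)}")
    # best d2* hit per virus, ties broken by host_id
    d2 = d2.sort_values(["virus_id", "d2star", "host_id"], kind="stable")
    best = d2.groupby("virus_id").head(1)[["virus_id", "host_id"]]
    best_pairs = set(map(tuple, best.to_numpy()))
    ph = phist_results.copy()
    if not ph.empty:
        ph["p_adj"] = benjamini_hochberg(ph["p_raw"].to_numpy())
    else:
        ph["p_adj"] = []
    ph_idx = {(r.virus_id, r.host_id): r for r in ph.itertuples()}
    sp_idx = {}
    if not spacer_hits.empty:
        sp_idx = {
            (r.virus_id, r.host_id): int(r.n_spacer_hits) for r in spacer_hits.itertuples()
        }
    preds = []
    for r in d2.itertuples():
        pair = (r.virus_id, r.host_id)
        phr = ph_idx.get(pair)
        p_raw = float(phr.p_raw) if phr is not None else 1.0
        p_adj = float(phr.p_adj) if phr is not None else 1.0
        shared = int(phr.shared_kmers) if phr is not None else 0
        n_sp = sp_idx.get(pair, 0)
        is_best = pair in best_pairs
        if n_sp >= 1:
            evidence, accepted = "crispr", True
        elif is_best and r.d2star < params.d2star_max and p_adj < params.phist_alpha:
            evidence, accepted = "consensus", True
        else:
            evidence, accepted = None, False
        preds.append(
            HostPrediction(
                virus_id=r.virus_id,
                host_id=r.host_id,
                d2star=float(r.d2star),
                is_best_d2star_hit=is_best,
                shared_kmers=shared,
                phist_p_raw=p_raw,
                phist_p_adj=p_adj,
                spacer_hits=n_sp,
                evidence=evidence,
                accepted=accepted,
            )
        )
    return preds


def predict_hosts(
    viruses: Sequence[GenomeRecord],
    hosts: Sequence[GenomeRecord],
    params: HostLinkParams = HostLinkParams(),
) -> list[HostPrediction]:
    """Full pipeline: d2* all pairs, shared-k-mer test, CRISPR spacers, consensus."""
    host_sets = {h.genome_id: canonical_kmer_set(h.sequence, params.phist_k) for h in hosts}
    virus_sets = {v.genome_id: canonical_kmer_set(v.sequence, params.phist_k) for v in viruses}
    universe = int(np.unique(np.concatenate([s for s in host_sets.values()])).size)
    d2_rows, ph_rows = [], []
    host_probs = {h.genome_id: None for h in hosts}
    for v in viruses:
        for h in hosts:
            d2_rows.append({"virus_id": v.genome_id, "host_id": h.genome_id,
                            "d2star": d2star(v.sequence, h.sequence, params)})
            shared, p_raw = shared_kmer_test(
                v, h, universe, params, virus_set=virus_sets[v.genome_id],
                host_set=host_sets[h.genome_id],
            )
            ph_rows.append({"virus_id": v.genome_id, "host_id": h.genome_id,
                            "shared_kmers": shared, "p_raw": p_raw})
    arrays = []
    for h in hosts:
        arrays.extend(find_crispr_arrays(h, params))
    sp = match_spacers(arrays, viruses, params)
    return consensus_linkage(pd.DataFrame(d2_rows), pd.DataFrame(ph_rows), sp, params)


# ---------------------------------------------------------------------------
# virus-bacteria ratio


def virus_host_ratio(
    virus_series: Sequence[float], host_series: Sequence[float]
) -> tuple[np.ndarray, float, float, float]:
    """Per-timepoint VBR, mean VBR, and Pearson correlation of the two series.

    Timepoints with zero host abundance yield undefined VBR (NaN, excluded
    from the mean). Correlation uses all timepoints of both series.
    """
    v = np.asarray(virus_series, dtype=float)
    h = np.asarray(host_series, dtype=float)
    if v.shape != h.shape:
        raise ValidationError("series lengths differ")
    valid = h > 0
    if valid.sum() < 3:
        raise ValidationError("fewer than 3 valid timepoints for VBR")
    vbr = np.where(valid, v / np.where(valid, h, 1.0), np.nan)
    mean_vbr = float(np.nanmean(vbr))
    r, p = stats.pearsonr(v, h)
    return vbr, mean_vbr, float(r), float(p)
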