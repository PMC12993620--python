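"""Synthetic communities, genomes and annotations with planted ground truth.

The generator produces the sampling design this package targets: a 48-hour
time series sampled every 3 hours in two river compartments (15 surface-water
and 17 pore-water metagenomes), compartment-specific occupancy with planted
persistence classes, latent-factor-driven co-occurrence modules coupled to
water chemistry, Markov-chain genome sequences with planted shared 25-mer
windows and CRISPR spacer arrays for linked virus-host pairs, and gene
annotation tables covering every auxiliary-score configuration.

One integer seed drives everything; each sub-simulation derives a named
substream so that, e.g., adding genomes does not perturb chemistry draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from rivertide.core_io import (
    Compartment,
    CoverageMatrix,
    GeneCall,
    GeneCategory,
    GenomeKind,
    GenomeRecord,
    SampleRecord,
    ValidationError,
)

# Default class fractions per compartment (persistent / intermittent /
# ephemeral): a strongly persistent surface-water community against a
# predominantly ephemeral pore-water community.
DEFAULT_CLASS_FRACTIONS = {
    "SW": (0.70, 0.25, 0.05),
    "PW": (0.11, 0.26, 0.63),
}
# Bernoulli detection probability per planted class; chosen so expected
# detection fractions sit inside the class intervals with margin at 15-17
# timepoints.
CLASS_OCCUPANCY = {"persistent": 0.90, "intermittent": 0.50, "ephemeral": 0.12}

CHEM_NAMES = [
    "nitrate",
    "sulfate",
    "ammonium",
    "iron_total",
    "doc",
    "temperature",
    "manganese",
    "calcium",
]

READ_LEN = 150
VIRAL_LEN = 25_000
MICROBIAL_LEN = 50_000


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream of the run seed (stable across runs and platforms)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def default_design(seed: int = 0) -> list[SampleRecord]:
    """15 SW + 17 PW samples at 3-h spacing over 48 h.

    Pore water is sampled at all 17 timepoints; two fixed surface-water
    timepoints are absent (failed libraries are routine in field campaigns,
    and unequal compartment coverage must be handled downstream). Library
    sizes are drawn log-uniformly over one decade.
    """
    rng = _rng(seed, "design")
    times = [3.0 * i for i in range(17)]
    sw_missing = {24.0, 39.0}
    samples = []
    for t in times:
        lib = int(10 ** rng.uniform(7.6, 8.6))
        samples.append(
            SampleRecord(f"PW_{int(t):02d}h", Compartment.PW, t, lib)
        )
    for t in times:
        if t in sw_missing:
            continue
        lib = int(10 ** rng.uniform(7.6, 8.6))
        samples.append(
            SampleRecord(f"SW_{int(t):02d}h", Compartment.SW, t, lib)
        )
    return samples


@dataclass
class CommunityTruth:
    """Planted ground truth sufficient to score every downstream stage."""

    genome_ids: list[str]
    kinds: list[str]
    lengths: list[int]
    compartment: dict[str, str]  # genome -> pore | surface | both
    persistence_class: dict[str, dict[str, str]]  # genome -> {SW/PW: class}
    module_of: dict[str, Optional[str]]
    loading: dict[str, float]  # b_g, log10 units (0 when no module)
    latents: pd.DataFrame  # timepoint index x module
    chem_loadings: pd.DataFrame  # chemistry variable x module
    planted_presence: pd.DataFrame  # genome x sample booleans (occupancy draws)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for g, kind, length in zip(self.genome_ids, self.kinds, self.lengths):
            rows.append(
                {
                    "genome_id": g,
                    "kind": kind,
                    "length_bp": length,
                    "compartment": self.compartment[g],
                    "class_sw": self.persistence_class[g].get("SW", ""),
                    "class_pw": self.persistence_class[g].get("PW", ""),
                    "module": self.module_of[g] or "",
                    "loading": self.loading[g],
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class LinkTruth:
    pairs: tuple[tuple[str, str, frozenset], ...]  # (virus_id, host_id, evidence)

    def linked_virus_ids(self) -> set[str]:
        return {v for v, _, _ in self.pairs}


def simulate_community(
    n_viral: int = 350,
    n_microbial: int = 150,
    design: Optional[Sequence[SampleRecord]] = None,
    class_fractions: Optional[dict[str, tuple[float, float, float]]] = None,
    n_modules: int = 3,
    module_size: int = 30,
    compartment_fractions: tuple[float, float, float] = (0.45, 0.45, 0.10),
    loading_range: tuple[float, float] = (0.5, 0.8),
    background_mass: float = 3.0,
    seed: int = 0,
) -> tuple[CoverageMatrix, list[SampleRecord], CommunityTruth]:
    """Simulate a genome x sample coverage table with planted truth.

    Occupancy: a genome is present in a sample of its compartment with the
    Bernoulli probability of its planted class (0.90 / 0.50 / 0.12); it is
    absent from the other compartment (cross-compartment zeroes are real
    zeroes). Abundance when present is log-normal (log10-mean ~ U(1, 3),
    sigma 0.15); module members add b_g * z_m(t) in log10 units, where z_m is
    a standard AR(1) latent (coefficient 0.7, innovation sd 1) over the
    timepoint grid. Chemistry variable j is sum_m c_jm z_m(t) + N(0, 0.25).
    Read counts are Poisson(relative abundance x library size); mean depth is
    count * read_length / genome_length and breadth is 1 - exp(-depth).
    """
    if design is None:
        design = default_design(seed)
    if class_fractions is None:
        class_fractions = DEFAULT_CLASS_FRACTIONS
    for comp, fr in class_fractions.items():
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValidationError(f"class fractions for {comp} must sum to 1")
    timepoints = sorted({s.time_h for s in design})
    if len(timepoints) < 4:
        raise ValidationError("persistence classes undefined below 4 timepoints")
    comp_of_sample = {s.sample_id: s.compartment.value for s in design}
    sample_ids = [s.sample_id for s in design]
    n_genomes = n_viral + n_microbial

    # --- genome identities -------------------------------------------------
    genome_ids = [f"vMAG_{i:04d}" for i in range(n_viral)] + [
        f"MAG_{i:04d}" for i in range(n_microbial)
    ]
    kinds = ["viral"] * n_viral + ["microbial"] * n_microbial
    lengths = [VIRAL_LEN] * n_viral + [MICROBIAL_LEN] * n_microbial

    rng_comp = _rng(seed, "compartments")
    comp_labels = rng_comp.choice(
        ["surface", "pore", "both"], size=n_genomes, p=list(compartment_fractions)
    )
    compartment = dict(zip(genome_ids, comp_labels))

    rng_class = _rng(seed, "classes")
    persistence_class: dict[str, dict[str, str]] = {}
    class_names = ["persistent", "intermittent", "ephemeral"]
    for g, lab in zip(genome_ids, comp_labels):
        comps = {"surface": ["SW"], "pore": ["PW"], "both": ["SW", "PW"]}[lab]
        persistence_class[g] = {
            c: str(rng_class.choice(class_names, p=list(class_fractions[c]))) for c in comps
        }

    # --- latent module structure ------------------------------------------
    rng_lat = _rng(seed, "latents")
    tp_index = {t: i for i, t in enumerate(timepoints)}
    z = np.zeros((len(timepoints), n_modules))
    for m in range(n_modules):
        z[0, m] = rng_lat.normal(0, 1 / np.sqrt(1 - 0.7**2))  # stationary start
        for t in range(1, len(timepoints)):
            z[t, m] = 0.7 * z[t - 1, m] + rng_lat.normal(0, 1)
    if n_modules > 1:
        # decorrelate latents across modules (finite AR(1) series can correlate
        # strongly by chance at ~17 timepoints, which would make planted
        # modules unidentifiable); rescale to the original per-series sd
        sds = z.std(axis=0, ddof=1)
        q, _ = np.linalg.qr(z - z.mean(axis=0))
        z = q * sds / q.std(axis=0, ddof=1)
    module_names = [f"mod{m+1}" for m in range(n_modules)]
    latents = pd.DataFrame(z, index=timepoints, columns=module_names)

    rng_mod = _rng(seed, "modules")
    module_of: dict[str, Optional[str]] = {g: None for g in genome_ids}
    loading: dict[str, float] = {g: 0.0 for g in genome_ids}
    def persistent_pool(comp: str) -> list[str]:
        comp_key = "SW" if comp == "surface" else "PW"
        return [
            g
            for g in genome_ids
            if compartment[g] == comp
            and persistence_class[g].get(comp_key) == "persistent"
            and module_of[g] is None
        ]

    module_comp = ["surface", "pore"]
    for m, name in enumerate(module_names):
        # alternate compartments, but only plant where enough persistent
        # genomes remain (an all-surface design hosts all modules in SW)
        candidates = [module_comp[m % 2], module_comp[(m + 1) % 2]]
        comp = next(
            (c for c in candidates if len(persistent_pool(c)) >= module_size),
            max(candidates, key=lambda c: len(persistent_pool(c))),
        )
        pool = persistent_pool(comp)
        take = min(module_size, len(pool))
        for g in rng_mod.choice(pool, size=take, replace=False):
            module_of[g] = name
            loading[g] = float(rng_mod.uniform(*loading_range))

    # --- chemistry ---------------------------------------------------------
    rng_chem = _rng(seed, "chemistry")
    n_chem = min(n_modules + 2, len(CHEM_NAMES))
    chem_names = CHEM_NAMES[:n_chem]
    c = np.zeros((n_chem, n_modules))
    for j in range(min(n_modules, n_chem)):
        c[j, j] = 1.0
    chem_loadings = pd.DataFrame(c, index=chem_names, columns=module_names)
    chem_values = {}
    for s in design:
        t_i = tp_index[s.time_h]
        vals = c @ z[t_i] + rng_chem.normal(0, 0.25, size=n_chem)
        chem_values[s.sample_id] = dict(zip(chem_names, vals.tolist()))
    design = [
        SampleRecord(s.sample_id, s.compartment, s.time_h, s.library_size,
                     chem_values[s.sample_id])
        for s in design
    ]

    # --- occupancy and abundance -------------------------------------------
    rng_occ = _rng(seed, "occupancy")
    rng_ab = _rng(seed, "abundance")
    mu = rng_ab.uniform(1, 3, size=n_genomes)
    present = np.zeros((n_genomes, len(sample_ids)), dtype=bool)
    log10x = np.full((n_genomes, len(sample_ids)), -np.inf)
    comp_key_of = {"SW": "SW", "PW": "PW"}
    for gi, g in enumerate(genome_ids):
        classes = persistence_class[g]
        for si, s in enumerate(design):
            ck = comp_key_of[s.compartment.value]
            cls = classes.get(ck)
            if cls is None:
                continue  # genome absent from this compartment
            if rng_occ.random() < CLASS_OCCUPANCY[cls]:
                present[gi, si] = True
    for gi, g in enumerate(genome_ids):
        mod = module_of[g]
        for si, s in enumerate(design):
            if not present[gi, si]:
                continue
            val = mu[gi] + rng_ab.normal(0, 0.15)
            if mod is not None:
                val += loading[g] * z[tp_index[s.time_h], module_names.index(mod)]
            log10x[gi, si] = val

    x = np.where(present, 10.0 ** np.where(np.isfinite(log10x), log10x, 0.0), 0.0)
    col_sums = x.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    # reads also recruit to an unmodeled stable background community
    # (unbinned fraction), which damps compositional swings of the total
    bg = background_mass * col_sums.mean()
    rel = x / (col_sums + bg)
    rng_counts = _rng(seed, "counts")
    libs = np.array([s.library_size for s in design], dtype=float)
    reads = rng_counts.poisson(rel * libs)
    length_arr = np.array(lengths, dtype=float)[:, None]
    depth = reads * READ_LEN / length_arr
    breadth = np.clip(1.0 - np.exp(-depth), 0.0, 1.0)

    cov = CoverageMatrix(genome_ids, sample_ids, reads, breadth, depth)
    truth = CommunityTruth(
        genome_ids=genome_ids,
        kinds=kinds,
        lengths=lengths,
        compartment=compartment,
        persistence_class=persistence_class,
        module_of=module_of,
        loading=loading,
        latents=latents,
        chem_loadings=chem_loadings,
        planted_presence=pd.DataFrame(present, index=genome_ids, columns=sample_ids),
    )
    return cov, list(design), truth


# ---------------------------------------------------------------------------
# genome sequences with planted linkage evidence


def _markov_chain(rng: np.random.Generator, order: int = 2) -> np.ndarray:
    """Transition matrix (4^order x 4) with Dirichlet(1) rows."""
    return rng.dirichlet(np.ones(4), size=4**order)


def _sample_sequence(rng: np.random.Generator, trans: np.ndarray, length: int,
                     order: int = 2) -> str:
    cum = np.cumsum(trans, axis=1)
    bases = "ACGT"
    seq = [int(rng.integers(4)) for _ in range(order)]
    ctx = 0
    for b in seq:
        ctx = ctx * 4 + b
    roll = 4 ** (order - 1)
    u = rng.random(length - order)
    for i in range(length - order):
        b = int(np.searchsorted(cum[ctx], u[i], side="right"))
        b = min(b, 3)
        seq.append(b)
        ctx = (ctx % roll) * 4 + b
    return "".join(bases[b] for b in seq)


def simulate_genomes(
    n_hosts: int = 10,
    n_linked_viruses: int = 10,
    n_unlinked_viruses: int = 10,
    seed: int = 0,
    host_len: int = 100_000,
    virus_len: int = 25_000,
    copied_window: int = 1_000,
    repeat_len: int = 28,
    spacer_len: int = 32,
    repeat_copies: int = 4,
) -> tuple[list[GenomeRecord], LinkTruth]:
    """Markov-chain genomes with planted virus-host linkage evidence.

    Each host is a 100 kb sequence from a host-specific order-2 Markov chain.
    A linked virus is 25 kb sampled from its host's chain (compositional
    signal), carries one 1 kb window copied verbatim from the host (shared
    25-mers), and the host carries a CRISPR array — ``repeat_copies`` copies
    of a ``repeat_len`` bp repeat separated by ``spacer_len`` bp spacers, the
    middle spacer copied verbatim from the virus. Unlinked viruses come from
    independent chains with no copied windows or spacer matches.
    """
    if n_hosts < 1:
        raise ValidationError("need at least one host")
    records: list[GenomeRecord] = []
    pairs = []
    host_seqs: dict[str, str] = {}
    host_chains: dict[int, np.ndarray] = {}
    for i in range(n_hosts):
        rng = _rng(seed, f"host_{i}")
        host_chains[i] = _markov_chain(rng)
        host_seqs[f"host_{i:03d}"] = _sample_sequence(rng, host_chains[i], host_len)
    for j in range(n_linked_viruses):
        hi = j % n_hosts
        host_id = f"host_{hi:03d}"
        virus_id = f"virus_linked_{j:03d}"
        rng = _rng(seed, f"linked_virus_{j}")
        trans = host_chains[hi]
        vseq = _sample_sequence(rng, trans, virus_len)
        hseq = host_seqs[host_id]
        # (a) copy a 1 kb host window into the virus verbatim
        h_start = int(rng.integers(0, len(hseq) - copied_window))
        v_start = int(rng.integers(0, len(vseq) - copied_window))
        vseq = vseq[:v_start] + hseq[h_start : h_start + copied_window] + vseq[v_start + copied_window :]
        # (b) plant a CRISPR array on the host with one spacer from the virus
        repeat = _sample_sequence(rng, trans, repeat_len)
        sp_src = int(rng.integers(0, len(vseq) - spacer_len))
        spacers = []
        for s in range(repeat_copies - 1):
            if s == 1:
                spacers.append(vseq[sp_src : sp_src + spacer_len])
            else:
                spacers.append(_sample_sequence(rng, trans, spacer_len))
        array = repeat + "".join(sp + repeat for sp in spacers)
        # overwrite a host region away from the copied window
        while True:
            a_start = int(rng.integers(0, len(hseq) - len(array)))
            if a_start + len(array) <= h_start or a_start >= h_start + copied_window:
                break
        hseq = hseq[:a_start] + array + hseq[a_start + len(array) :]
        host_seqs[host_id] = hseq
        records.append(GenomeRecord(virus_id, GenomeKind.viral, len(vseq), vseq))
        pairs.append(
            (virus_id, host_id, frozenset({"markov_composition", "shared_kmers", "crispr_spacer"}))
        )
    for j in range(n_unlinked_viruses):
        rng = _rng(seed, f"unlinked_virus_{j}")
        trans = _markov_chain(rng)
        vseq = _sample_sequence(rng, trans, virus_len)
        records.append(
            GenomeRecord(f"virus_unlinked_{j:03d}", GenomeKind.viral, len(vseq), vseq)
        )
    for i in range(n_hosts):
        host_id = f"host_{i:03d}"
        seq = host_seqs[host_id]
        records.append(GenomeRecord(host_id, GenomeKind.microbial, len(seq), seq))
    return records, LinkTruth(tuple(pairs))


# ---------------------------------------------------------------------------
# annotation tables with planted auxiliary-score configurations


_CASES = [
    "score1",  # hallmark on both flanks
    "score2",  # hallmark one flank, viral-like the other
    "score3",  # viral-like on both flanks
    "contig_end",  # candidate at index 0
    "transposon",  # score-1 context but transposon-like candidate
    "no_context",  # candidate with no viral genes around
]
_FUNCTIONS = ["K00001", "K01601", "K02588", "K10944", "K00370"]
_HEADERS = ["carbon utilization", "nitrogen metabolism", "energy", "transporters"]


def simulate_annotations(
    n_contigs: int = 12, seed: int = 0
) -> tuple[list[GeneCall], pd.DataFrame]:
    """Annotation tables covering every auxiliary-score configuration.

    Returns the gene calls plus a truth table (contig_id, index, case,
    expected_score — empty when no score applies — and expected_pass).
    """
    if n_contigs < 1:
        raise ValidationError("need at least one contig")
    rng = _rng(seed, "annotations")
    calls: list[GeneCall] = []
    truth_rows = []
    H, V, O = GeneCategory.viral_hallmark, GeneCategory.viral_like, GeneCategory.other
    for ci in range(n_contigs):
        case = _CASES[ci % len(_CASES)]
        contig = f"contig_{ci:03d}"
        fn = str(rng.choice(_FUNCTIONS))
        hdr = str(rng.choice(_HEADERS))
        transposon = case == "transposon"
        if case == "contig_end":
            cats = [None, H, O]  # candidate first gene
            cand_idx = 0
        elif case == "no_context":
            cats = [O, None, O]
            cand_idx = 1
        elif case == "score1" or case == "transposon":
            cats = [O, H, None, H, O]
            cand_idx = 2
        elif case == "score2":
            left_first = bool(rng.integers(2))
            cats = [O, H, None, V, O] if left_first else [O, V, None, H, O]
            cand_idx = 2
        else:  # score3
            cats = [O, V, None, V, O]
            cand_idx = 2
        n = len(cats)
        for idx, cat in enumerate(cats):
            is_cand = cat is None
            calls.append(
                GeneCall(
                    contig_id=contig,
                    index=idx,
                    category=O if is_cand else cat,
                    function_id=fn if is_cand else None,
                    module_header=hdr if is_cand else None,
                    is_transposon_like=transposon and is_cand,
                    at_contig_end=idx in (0, n - 1),
                )
            )
        expected_score = {"score1": 1, "transposon": 1, "score2": 2, "score3": 3}.get(case)
        # the end/transposon filters are orthogonal to scoring: an unscored
        # mid-contig candidate still passes them
        expected_pass = case not in ("contig_end", "transposon")
        truth_rows.append(
            {
                "contig_id": contig,
                "index": cand_idx,
                "case": case,
                "expected_score": expected_score if expected_score is not None else "",
                "expected_pass": expected_pass,
            }
        )
    truth = pd.DataFrame(truth_rows, columns=["contig_id", "index", "case", "expected_score", "expected_pass"])
    return calls, truth
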