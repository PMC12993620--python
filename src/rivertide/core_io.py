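"""Domain types and readers/writers for the table and sequence formats.

Canonical table dialect is TSV (tab-separated, UTF-8, '.' decimal). Genome
sequences are uppercased on read; ``N`` is allowed but excluded from k-mer
operations downstream. All downstream operations consume the in-memory types
defined here, never file paths.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("rivertide")

_FLOAT_FMT = "%.6g"


class Compartment(str, enum.Enum):
    SW = "SW"
    PW = "PW"


class GenomeKind(str, enum.Enum):
    viral = "viral"
    microbial = "microbial"


class GeneCategory(str, enum.Enum):
    viral_hallmark = "viral_hallmark"
    viral_like = "viral_like"
    other = "other"


class ValidationError(ValueError):
    """Input violates a documented contract (named offenders in the message)."""


@dataclass(frozen=True)
class SampleRecord:
    """One metagenome sample: compartment, time since first sample, chemistry."""

    sample_id: str
    compartment: Compartment
    time_h: float
    library_size: int
    chemistry: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValidationError(f"sample {self.sample_id}: time_h < 0")
        if self.library_size < 1:
            raise ValidationError(f"sample {self.sample_id}: library_size < 1")


@dataclass(frozen=True)
class GenomeRecord:
    """A viral or microbial genome (or large assembled fragment)."""

    genome_id: str
    kind: GenomeKind
    length_bp: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError(f"genome {self.genome_id}: length_bp <= 0")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise ValidationError(
                f"genome {self.genome_id}: length_bp {self.length_bp} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class GeneCall:
    """One annotated gene on a contig, in gene order."""

    contig_id: str
    index: int
    category: GeneCategory
    function_id: Optional[str] = None
    module_header: Optional[str] = None
    is_transposon_like: bool = False
    at_contig_end: bool = False


@dataclass
class CoverageMatrix:
    """Dense genome x sample grid of read count, breadth and mean depth.

    Depth is mean depth across the whole genome length (conservative with the
    3x floor). Breadth is the covered fraction of positions in [0, 1].
    """

    genome_ids: list[str]
    sample_ids: list[str]
    reads: np.ndarray  # int, (G, S)
    breadth: np.ndarray  # float in [0,1], (G, S)
    depth: np.ndarray  # float >= 0, (G, S)

    def __post_init__(self) -> None:
        g, s = len(self.genome_ids), len(self.sample_ids)
        for name in ("reads", "breadth", "depth"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (g, s):
                raise ValidationError(f"{name} shape {arr.shape} != ({g}, {s})")
            if np.isnan(arr).any():
                raise ValidationError(f"{name} contains NaN")
        if len(set(self.genome_ids)) != g:
            raise ValidationError("duplicate genome_ids in CoverageMatrix")
        if len(set(self.sample_ids)) != s:
            raise ValidationError("duplicate sample_ids in CoverageMatrix")
        self.reads = np.asarray(self.reads)
        if (self.reads < 0).any():
            raise ValidationError("negative read counts")
        self.breadth = np.asarray(self.breadth, dtype=float)
        if ((self.breadth < 0) | (self.breadth > 1)).any():
            raise ValidationError("breadth outside [0, 1]")
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise ValidationError("negative depth")

    def subset_samples(self, sample_ids: Sequence[str]) -> "CoverageMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CoverageMatrix(
            genome_ids=list(self.genome_ids),
            sample_ids=list(sample_ids),
            reads=self.reads[:, idx],
            breadth=self.breadth[:, idx],
            depth=self.depth[:, idx],
        )


@dataclass
class AbundanceMatrix:
    """Non-negative genome x sample abundances, raw or TMM-normalized."""

    genome_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (G, S)
    state: str = "raw"  # "raw" | "tmm"
    norm_factors: Optional[np.ndarray] = None  # per sample, state == "tmm"
    library_sizes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genome_ids), len(self.sample_ids)):
            raise ValidationError("AbundanceMatrix shape mismatch")
        if (self.values < 0).any() or np.isnan(self.values).any():
            raise ValidationError("abundances must be finite and non-negative")
        if self.state == "tmm":
            if self.norm_factors is None or len(self.norm_factors) != len(self.sample_ids):
                raise ValidationError("tmm state requires one factor per sample")
            if (np.asarray(self.norm_factors) <= 0).any():
                raise ValidationError("TMM factors must be positive")

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceMatrix(
            genome_ids=list(self.genome_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            state=self.state,
            norm_factors=None if self.norm_factors is None else np.asarray(self.norm_factors)[idx],
            library_sizes=None if self.library_sizes is None else np.asarray(self.library_sizes)[idx],
        )

    def subset_genomes(self, genome_ids: Sequence[str]) -> "AbundanceMatrix":
        idx = [self.genome_ids.index(g) for g in genome_ids]
        return AbundanceMatrix(
            genome_ids=list(genome_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
            state=self.state,
            norm_factors=self.norm_factors,
            library_sizes=self.library_sizes,
        )


@dataclass
class RunConfig:
    """Run-wide configuration: seed, output directory, stage thresholds."""

    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            seed=int(raw.pop("seed", 0)),
            out_dir=str(raw.pop("out_dir", ".")),
            log_level=str(raw.pop("log_level", "INFO")),
            params=raw,
        )


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | Path, kind: GenomeKind = GenomeKind.viral) -> list[GenomeRecord]:
    """Read a multi-record FASTA; sequences uppercased, ACGTN enforced."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValidationError(f"{path}: record {rec.id} has non-ACGTN symbols {sorted(bad)}")
        records.append(GenomeRecord(genome_id=rec.id, kind=kind, length_bp=len(seq), sequence=seq))
    ids = [r.genome_id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicate genome ids {sorted(dupes)}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.sequence is None:
                raise ValidationError(f"genome {rec.genome_id} has no sequence to write")
            fh.write(f">{rec.genome_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read sample metadata TSV: sample_id, compartment, time_h, library_size,
    plus any extra numeric columns treated as chemistry variables."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "compartment", "time_h", "library_size"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {sorted(missing)}")
    chem_cols = [c for c in df.columns if c not in required]
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dupes}")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            SampleRecord(
                sample_id=row["sample_id"],
                compartment=Compartment(row["compartment"]),
                time_h=float(row["time_h"]),
                library_size=int(row["library_size"]),
                chemistry={c: float(row[c]) for c in chem_cols},
            )
        )
    return samples


def write_metadata(samples: Sequence[SampleRecord], path: str | Path) -> None:
    chem_vars = sorted({v for s in samples for v in s.chemistry})
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "compartment": s.compartment.value,
            "time_h": s.time_h,
            "library_size": s.library_size,
        }
        row.update({v: s.chemistry.get(v, np.nan) for v in chem_vars})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_coverage(path: str | Path) -> CoverageMatrix:
    """Read a long-form coverage TSV (genome_id, sample_id, reads, breadth, depth)."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "sample_id": str})
    required = {"genome_id", "sample_id", "reads", "breadth", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing coverage columns {sorted(missing)}")
    genome_ids = sorted(df["genome_id"].unique())
    sample_ids = sorted(df["sample_id"].unique())
    gi = {g: i for i, g in enumerate(genome_ids)}
    si = {s: i for i, s in enumerate(sample_ids)}
    shape = (len(genome_ids), len(sample_ids))
    reads = np.zeros(shape, dtype=np.int64)
    breadth = np.zeros(shape)
    depth = np.zeros(shape)
    r = df["genome_id"].map(gi).to_numpy()
    c = df["sample_id"].map(si).to_numpy()
    reads[r, c] = df["reads"].to_numpy()
    breadth[r, c] = df["breadth"].to_numpy()
    depth[r, c] = df["depth"].to_numpy()
    return CoverageMatrix(genome_ids, sample_ids, reads, breadth, depth)


def write_coverage(cov: CoverageMatrix, path: str | Path) -> None:
    g_idx, s_idx = np.meshgrid(
        np.arange(len(cov.genome_ids)), np.arange(len(cov.sample_ids)), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "genome_id": np.array(cov.genome_ids)[g_idx.ravel()],
            "sample_id": np.array(cov.sample_ids)[s_idx.ravel()],
            "reads": cov.reads.ravel(),
            "breadth": cov.breadth.ravel(),
            "depth": cov.depth.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_annotations(path: str | Path) -> list[GeneCall]:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    calls = []
    for _, row in df.iterrows():
        calls.append(
            GeneCall(
                contig_id=row["contig_id"],
                index=int(row["index"]),
                category=GeneCategory(row["category"]),
                function_id=None if pd.isna(row.get("function_id")) else str(row["function_id"]),
                module_header=None
                if pd.isna(row.get("module_header"))
                else str(row["module_header"]),
                is_transposon_like=bool(row.get("is_transposon_like", False)),
                at_contig_end=bool(row.get("at_contig_end", False)),
            )
        )
    _validate_gene_calls(calls)
    return calls


def write_annotations(calls: Sequence[GeneCall], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "contig_id": c.contig_id,
                "index": c.index,
                "category": c.category.value,
                "function_id": c.function_id if c.function_id is not None else "",
                "module_header": c.module_header if c.module_header is not None else "",
                "is_transposon_like": c.is_transposon_like,
                "at_contig_end": c.at_contig_end,
            }
            for c in calls
        ],
        columns=[
            "contig_id",
            "index",
            "category",
            "function_id",
            "module_header",
            "is_transposon_like",
            "at_contig_end",
        ],
    )
    df.to_csv(path, sep="\t", index=False)


def _validate_gene_calls(calls: Sequence[GeneCall]) -> None:
    by_contig: dict[str, list[GeneCall]] = {}
    for c in calls:
        by_contig.setdefault(c.contig_id, []).append(c)
    for contig, genes in by_contig.items():
        idx = sorted(g.index for g in genes)
        if idx != list(range(len(genes))):
            raise ValidationError(f"contig {contig}: gene indices not 0..n-1")
        n = len(genes)
        for g in genes:
            expected_end = g.index in (0, n - 1)
            if g.at_contig_end != expected_end:
                raise ValidationError(
                    f"contig {contig} gene {g.index}: at_contig_end flag inconsistent"
                )


def load_dataset(
    coverage_path: str | Path,
    metadata_path: str | Path,
    fasta_paths: Optional[Mapping[str, str | Path]] = None,
    annotation_path: Optional[str | Path] = None,
) -> tuple[CoverageMatrix, list[SampleRecord], list[GenomeRecord], list[GeneCall]]:
    """Load and cross-validate a full dataset.

    ``fasta_paths`` maps genome kind ("viral"/"microbial") to a FASTA path.
    Raises :class:`ValidationError` naming unmatched sample or genome ids.
    """
    cov = read_coverage(coverage_path)
    samples = read_metadata(metadata_path)
    meta_ids = {s.sample_id for s in samples}
    cov_ids = set(cov.sample_ids)
    extra = sorted(cov_ids - meta_ids)
    missing = sorted(meta_ids - cov_ids)
    if extra or missing:
        raise ValidationError(
            f"coverage/metadata sample mismatch: in coverage only {extra}, "
            f"in metadata only {missing}"
        )
    genomes: list[GenomeRecord] = []
    if fasta_paths:
        for kind, path in fasta_paths.items():
            genomes.extend(read_fasta(path, GenomeKind(kind)))
        ids = [g.genome_id for g in genomes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate genome ids across FASTAs: {dupes}")
        unknown = sorted(set(g.genome_id for g in genomes) - set(cov.genome_ids))
        if unknown:
            logger.warning("FASTA genomes without coverage rows: %s", unknown)
    annotations: list[GeneCall] = []
    if annotation_path is not None:
        annotations = read_annotations(annotation_path)
    return cov, samples, genomes, annotations


# ---------------------------------------------------------------------------
# writers for stage outputs


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table: TSV, deterministic column order as given,
    floats at 6 significant digits. Empty frames produce a header-only file."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def write_run_metadata(path: str | Path, config: RunConfig, **extra) -> Path:
    """Sidecar with seed, parameters and package version for reproducibility."""
    from rivertide import __version__

    payload = {
        "seed": config.seed,
        "log_level": config.log_level,
        "params": config.params,
        "version": __version__,
    }
    payload.update(extra)
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path


def records_to_frame(records: Sequence, columns: Sequence[str]) -> pd.DataFrame:
    """Dataclass records -> DataFrame with a fixed column order."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        rows.append({c: (d[c].value if isinstance(d[c], enum.Enum) else d[c]) for c in columns})
    return pd.DataFrame(rows, columns=list(columns))
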