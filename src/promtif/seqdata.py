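"""Spacer sequence handling for sort-seq promoter libraries.

A promoter library randomizes only the spacer between the conserved -35 and
-10 elements of a sigma-factor-specific chassis.  Sequencing reads are 51 bp
single-end amplicons in which the spacer occupies a fixed variable window;
everything outside that window must match the chassis template exactly.

This module owns the chassis description, read -> spacer extraction with
rejection bookkeeping, one-hot encoding for the neural network, promoter
assembly, and I/O for per-bin FASTQ files and sequence x bin-count tables.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
N_BINS = 12
READ_LENGTH = 51

#: spacer lengths per sigma factor chassis
SPACER_LENGTHS = {"sigma70": 17, "sigmaB": 12, "sigmaF": 15, "sigmaW": 16}


class SpacerError(ValueError):
    """Raised for spacers violating length or alphabet constraints."""


@dataclass(frozen=True)
class ChassisSpec:
    """Fixed promoter scaffold around the variable spacer window.

    The 51-bp read layout is ``upstream_flank + spacer + downstream_flank``;
    the flanks are trimmed/validated so their total length plus
    ``spacer_length`` equals the read length.  For the E. coli sigma70
    chassis the upstream flank ends in the -35 element ``TTTACG`` and the
    downstream flank starts with the -10 element ``TATAAT``.
    """

    name: str
    spacer_length: int
    upstream_flank: str
    downstream_flank: str

    def __post_init__(self) -> None:
        for flank in (self.upstream_flank, self.downstream_flank):
            if set(flank) - set(ALPHABET):
                raise ValueError(f"flank contains non-ACGT characters: {flank}")
        if self.spacer_length < 1:
            raise ValueError("spacer_length must be positive")

    @property
    def read_length(self) -> int:
        return len(self.upstream_flank) + self.spacer_length + len(self.downstream_flank)

    @property
    def spacer_window(self) -> tuple[int, int]:
        """0-based half-open [start, stop) of the spacer within a read."""
        start = len(self.upstream_flank)
        return start, start + self.spacer_length

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "spacer_length": self.spacer_length,
            "upstream_flank": self.upstream_flank,
            "downstream_flank": self.downstream_flank,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChassisSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            name=d["name"],
            spacer_length=int(d["spacer_length"]),
            upstream_flank=d["upstream_flank"].upper(),
            downstream_flank=d["downstream_flank"].upper(),
        )


# Default sigma70 chassis: 17 nt of flank on either side of the 17 nt spacer
# (17 + 17 + 17 = 51 bp read), drawn from the insulated proD-derived promoter.
SIGMA70 = ChassisSpec(
    name="sigma70",
    spacer_length=17,
    upstream_flank="TGCTGGATAACTTTACG",
    downstream_flank="TATAATATATTCAGGGA",
)

assert SIGMA70.read_length == READ_LENGTH
assert SIGMA70.upstream_flank.endswith("TTTACG")
assert SIGMA70.downstream_flank.startswith("TATAAT")


def validate_spacer(seq: str, chassis: ChassisSpec | None = None) -> str:
    """Uppercase and validate a spacer string; return it.

    Raises :class:`SpacerError` on non-ACGT characters or (when a chassis
    is given) a length mismatch.
    """
    seq = seq.upper()
    if set(seq) - set(ALPHABET):
        raise SpacerError(f"ambiguous_base: {seq!r}")
    if chassis is not None and len(seq) != chassis.spacer_length:
        raise SpacerError(
            f"spacer_length_mismatch: got {len(seq)}, expected {chassis.spacer_length}"
        )
    return seq


def extract_spacer(read: str, chassis: ChassisSpec) -> tuple[str | None, str | None]:
    """Extract the variable spacer window from a 51-bp read.

    Returns ``(spacer, None)`` on success or ``(None, reason)`` where reason
    is one of ``bad_length``, ``ambiguous_base``, ``flank_mismatch``.  Reads
    are accepted on the given strand only and must match the chassis
    template exactly outside the spacer window (flank-mutated amplicons are
    removed rather than repaired).
    """
    read = read.upper()
    if len(read) != chassis.read_length:
        return None, "bad_length"
    if set(read) - set(ALPHABET):
        return None, "ambiguous_base"
    start, stop = chassis.spacer_window
    if read[:start] != chassis.upstream_flank or read[stop:] != chassis.downstream_flank:
        return None, "flank_mismatch"
    return read[start:stop], None


def assemble_promoter(spacer: str, chassis: ChassisSpec) -> str:
    """Insert a spacer into the chassis, reproducing the sequenced amplicon."""
    spacer = validate_spacer(spacer, chassis)
    return chassis.upstream_flank + spacer + chassis.downstream_flank


def one_hot_encode(spacer: str) -> np.ndarray:
    """Encode a spacer as a 4 x L binary matrix (rows A,C,G,T; columns 5'->3')."""
    spacer = validate_spacer(spacer)
    mat = np.zeros((4, len(spacer)), dtype=np.float64)
    for j, base in enumerate(spacer):
        mat[BASE_INDEX[base], j] = 1.0
    return mat


def one_hot_decode(mat: np.ndarray) -> str:
    """Invert :func:`one_hot_encode`."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != 4:
        raise ValueError("expected a 4 x L matrix")
    if not np.array_equal(mat.sum(axis=0), np.ones(mat.shape[1])):
        raise ValueError("columns must one-hot encode a single base")
    return "".join(ALPHABET[i] for i in mat.argmax(axis=0))


def encode_batch(spacers: Sequence[str]) -> np.ndarray:
    """One-hot encode equal-length spacers into an (n, 4, L) array."""
    if not spacers:
        raise ValueError("empty sequence list")
    L = len(spacers[0])
    idx = np.frombuffer("".join(spacers).encode(), dtype=np.uint8).reshape(len(spacers), L)
    codes = np.full(256, -1, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        codes[ord(b)] = i
    rows = codes[idx]
    if (rows < 0).any():
        raise SpacerError("ambiguous_base in batch")
    out = np.zeros((len(spacers), 4, L), dtype=np.float64)
    n_idx = np.arange(len(spacers))[:, None]
    pos = np.arange(L)[None, :]
    out[n_idx, rows, pos] = 1.0
    return out


@dataclass
class BinTable:
    """One unique spacer with its read counts across the sorting bins."""

    spacer: str
    r: np.ndarray  # integer counts, one entry per bin

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.int64)
        if (self.r < 0).any():
            raise ValueError("negative read count")
        if self.r.sum() < 1:
            raise ValueError("empty_table")

    @property
    def r_tot(self) -> int:
        return int(self.r.sum())

    @property
    def n_bins(self) -> int:
        return len(self.r)


@dataclass
class RejectionLog:
    """Per-reason tally of reads discarded during spacer extraction."""

    counts: collections.Counter = field(default_factory=collections.Counter)

    def add(self, reason: str) -> None:
        self.counts[reason] += 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _read_fastq_spacers(path: Path, chassis: ChassisSpec, log: RejectionLog) -> Iterable[str]:
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        spacer, reason = extract_spacer(str(rec.seq), chassis)
        if spacer is None:
            log.add(reason)
        else:
            yield spacer


def load_bin_counts_fastq(
    bin_paths: Sequence[str | Path],
    chassis: ChassisSpec,
) -> tuple[list[BinTable], RejectionLog]:
    """Build per-spacer bin-count tables from one FASTQ file per sorting bin.

    ``bin_paths[i]`` holds the reads sorted into bin ``i``.  Quality scores
    are ignored (no quality filter is applied); reads with any ambiguous
    base, wrong length, or a mismatch in the constant flanks are tallied in
    the rejection log.  Conservation holds: accepted + rejected = input reads.
    """
    n_bins = len(bin_paths)
    if n_bins not in (2, N_BINS):
        raise ValueError(f"expected 2 or {N_BINS} bin files, got {n_bins}")
    log = RejectionLog()
    counts: dict[str, np.ndarray] = {}
    for b, path in enumerate(bin_paths):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"missing bin file: {path}")
        for spacer in _read_fastq_spacers(path, chassis, log):
            if spacer not in counts:
                counts[spacer] = np.zeros(n_bins, dtype=np.int64)
            counts[spacer][b] += 1
    tables = [BinTable(s, r) for s, r in counts.items()]
    return tables, log


def tables_to_frame(tables: Sequence[BinTable]) -> pd.DataFrame:
    """Represent BinTables as a DataFrame with columns sequence, bin_0..bin_{k-1}."""
    if not tables:
        raise ValueError("empty table collection")
    n_bins = tables[0].n_bins
    data = {"sequence": [t.spacer for t in tables]}
    mat = np.stack([t.r for t in tables])
    for b in range(n_bins):
        data[f"bin_{b}"] = mat[:, b]
    return pd.DataFrame(data)


def frame_to_tables(df: pd.DataFrame) -> list[BinTable]:
    bin_cols = [c for c in df.columns if c.startswith("bin_")]
    bin_cols.sort(key=lambda c: int(c.split("_")[1]))
    mat = df[bin_cols].to_numpy(dtype=np.int64)
    return [BinTable(s, row) for s, row in zip(df["sequence"], mat)]


def write_count_table(tables: Sequence[BinTable], path: str | Path) -> None:
    tables_to_frame(tables).to_csv(path, sep="\t", index=False)


def load_count_table(path: str | Path, chassis: ChassisSpec | None = None) -> list[BinTable]:
    """Load a TSV count table (``sequence\\tbin_0...``) written by this module."""
    df = pd.read_csv(path, sep="\t")
    if "sequence" not in df.columns:
        raise ValueError("count table must have a 'sequence' column")
    if chassis is not None:
        for s in df["sequence"]:
            validate_spacer(s, chassis)
    return frame_to_tables(df)


def load_bin_counts(
    source: Sequence[str | Path] | str | Path,
    chassis: ChassisSpec,
) -> tuple[list[BinTable], RejectionLog]:
    """Dispatch: a list of FASTQ paths (one per bin) or a single TSV table."""
    if isinstance(source, (str, Path)):
        return load_count_table(source, chassis), RejectionLog()
    return load_bin_counts_fastq(source, chassis)
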