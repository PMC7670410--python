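"""Read-distribution consistency filtering and ordinal labeling.

Each unique spacer carries a vector of read counts across the 12 sorting
bins.  Because a single promoter's fluorescence is roughly Gaussian, its
reads should concentrate in one bin or a few adjacent ones; reads scattered
into distant bins signal sorting or amplification artefacts.  Three
per-sequence properties capture this:

* ``r_tot`` — total reads across bins;
* ``n_maxima`` — the number of local maxima of similar height, where a
  secondary peak M2 qualifies against the global peak M1 when
  ``r[M2] / r[M1] > 0.66`` and ``r[M1] > r[M2] > 0``;
* ``max_maxima_distance`` — the largest bin separation between the global
  peak and any qualifying secondary peak.

Sequences whose value on any property strictly exceeds that property's 95th
percentile (computed over multi-read sequences) are removed.  Surviving
sequences are labeled with the bin holding the most reads; bin 0 (background
fluorescence) is excluded for TIF models, so bins 1-11 map to ordinal
classes 0-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .seqdata import BinTable

SIMILAR_HEIGHT_RATIO = 0.66
N_CLASSES = 11


@dataclass(frozen=True)
class ReadProperties:
    """Distribution-consistency statistics of one bin-count vector."""

    r_tot: int
    n_maxima: int
    max_maxima_distance: int


def _local_maxima(r: np.ndarray) -> np.ndarray:
    """Bins b with r[b-1] < r[b] > r[b+1]; out-of-range neighbors count as 0.

    Plateaus (equal adjacent counts) are not maxima: strict inequality is
    required on both sides.
    """
    padded = np.concatenate(([0], r, [0]))
    left = padded[:-2]
    right = padded[2:]
    return np.nonzero((r > left) & (r > right))[0]


def compute_properties(table: BinTable) -> ReadProperties:
    """Compute the three outlier-screening properties for one sequence.

    The similar-height test pairs each secondary local maximum with the
    global-maximum bin M1 only: M2 qualifies iff ``r[M2]/r[M1] > 0.66`` and
    ``r[M1] > r[M2] > 0``.  The distance is the largest ``|M1 - M2|`` over
    qualifying peaks, 0 when the sequence has a single qualifying maximum.
    """
    r = table.r
    if r.sum() < 1:
        raise ValueError("empty_table")
    maxima = _local_maxima(r)
    # the primary bin M1 is the global maximum (lowest bin among ties),
    # whether or not it is a strict local maximum (plateaus are not)
    m1 = int(r.argmax())
    qualifying = [
        b for b in maxima
        if b != m1 and r[m1] > r[b] > 0 and r[b] / r[m1] > SIMILAR_HEIGHT_RATIO
    ]
    n_maxima = 1 + len(qualifying)
    distance = max((abs(int(m1) - int(b)) for b in qualifying), default=0)
    return ReadProperties(r_tot=int(r.sum()), n_maxima=n_maxima, max_maxima_distance=distance)


@dataclass
class LabeledExample:
    spacer: str
    y: int          # ordinal class 0..10
    source_bin: int  # sorting bin 1..11


@dataclass
class FilteredDataset:
    """Outcome of filtering + labeling: the model-ready training set."""

    examples: list[LabeledExample]
    exclusion_report: dict[str, int] = field(default_factory=dict)

    @property
    def sequences(self) -> list[str]:
        return [e.spacer for e in self.examples]

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.y for e in self.examples], dtype=np.int64)

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=N_CLASSES)

    def class_weights(self) -> np.ndarray:
        return class_weights(self.class_counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sequence": self.sequences, "class": self.labels})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FilteredDataset":
        df = pd.read_csv(path, sep="\t")
        examples = [
            LabeledExample(s, int(y), int(y) + 1)
            for s, y in zip(df["sequence"], df["class"])
        ]
        return cls(examples=examples)


def class_weights(class_counts: Sequence[int]) -> np.ndarray:
    """Inverse-frequency loss weights, w_c = N / (K * n_c).

    Balanced classes give all weights 1, so weighted training collapses to
    unweighted training on balanced data; doubling every count changes
    nothing.
    """
    counts = np.asarray(class_counts, dtype=np.float64)
    if (counts < 1).any():
        raise ValueError("empty_class")
    return counts.sum() / (len(counts) * counts)


def filter_outliers(
    tables: Sequence[BinTable],
    percentile: float = 0.95,
) -> tuple[list[BinTable], dict[str, int]]:
    """Remove sequences exceeding the per-property upper percentile.

    Properties (and the percentile thresholds) are computed over multi-read
    sequences only; single-read sequences bypass the screen.  A sequence is
    removed when ANY property strictly exceeds its threshold (linear-
    interpolation percentile), so exact ties survive.  Thresholds are
    computed once and applied once, making the filter idempotent.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("empty input")
    multi = [t for t in tables if t.r_tot > 1]
    report = {"r_tot": 0, "n_maxima": 0, "max_maxima_distance": 0, "removed_total": 0}
    if not multi:
        return tables, report
    props = np.array(
        [
            (p.r_tot, p.n_maxima, p.max_maxima_distance)
            for p in (compute_properties(t) for t in multi)
        ],
        dtype=np.float64,
    )
    thresholds = np.percentile(props, 100 * percentile, axis=0, method="linear")
    exceed = props > thresholds  # strict
    names = ["r_tot", "n_maxima", "max_maxima_distance"]
    for j, name in enumerate(names):
        report[name] = int(exceed[:, j].sum())
    removed_mask = exceed.any(axis=1)
    report["removed_total"] = int(removed_mask.sum())
    removed_set = {id(t) for t, bad in zip(multi, removed_mask) if bad}
    kept = [t for t in tables if id(t) not in removed_set]
    return kept, report


def assign_label(table: BinTable, exclude_bin0: bool = True) -> LabeledExample | None:
    """Label a sequence with its modal sorting bin, mapped to class 0-10.

    With ``exclude_bin0`` (TIF models), bin-0 counts are zeroed before the
    argmax and bin-0-only sequences are rejected (returns None): background
    fluorescence can reflect vector mutations or cell defects rather than
    promoter TIF.  Ties go to the lowest tied bin, which never overstates
    the TIF.
    """
    r = table.r.copy()
    if exclude_bin0:
        r[0] = 0
    if r.sum() == 0:
        return None
    best = int(r.argmax())  # argmax takes the lowest index among ties
    return LabeledExample(spacer=table.spacer, y=best - 1, source_bin=best)


def build_dataset(
    tables: Sequence[BinTable],
    percentile: float = 0.95,
    exclude_bin0: bool = True,
) -> FilteredDataset:
    """Filter outliers then label: the full selection pipeline."""
    kept, report = filter_outliers(tables, percentile=percentile)
    examples = []
    bin0_only = 0
    for t in kept:
        ex = assign_label(t, exclude_bin0=exclude_bin0)
        if ex is None:
            bin0_only += 1
        else:
            examples.append(ex)
    report["bin0_only"] = bin0_only
    return FilteredDataset(examples=examples, exclusion_report=report)


def _pct(num: int, den: int) -> float:
    """Percentage rounded to 2 decimals, half away from zero."""
    if den == 0:
        return 0.0
    x = 100.0 * num / den
    return float(np.floor(x * 100 + 0.5) / 100)


def summarize_selection(
    total_reads: int,
    unique_sequences: int,
    multi_read: int,
    multi_bin: int,
    retained_sequences: int,
    retained_reads: int,
) -> dict[str, float]:
    """Data-selection accounting as reported fractions.

    Percentages: unique sequences over total reads, multi-read and
    multi-bin over unique sequences, retained sequences/reads over their
    totals; each rounded to two decimals (half-up).
    """
    return {
        "total_reads": total_reads,
        "unique_sequences": unique_sequences,
        "multi_read": multi_read,
        "multi_bin": multi_bin,
        "retained_sequences": retained_sequences,
        "retained_reads": retained_reads,
        "pct_unique_of_reads": _pct(unique_sequences, total_reads),
        "pct_multi_read_of_unique": _pct(multi_read, unique_sequences),
        "pct_multi_bin_of_unique": _pct(multi_bin, unique_sequences),
        "pct_retained_sequences": _pct(retained_sequences, unique_sequences),
        "pct_retained_reads": _pct(retained_reads, total_reads),
    }


def summarize_tables(
    raw_tables: Sequence[BinTable],
    filtered: FilteredDataset,
    rejected_reads: int = 0,
) -> dict[str, float]:
    """Selection accounting computed from actual tables rather than totals."""
    total_reads = sum(t.r_tot for t in raw_tables) + rejected_reads
    unique = len(raw_tables)
    multi_read = sum(1 for t in raw_tables if t.r_tot > 1)
    multi_bin = sum(1 for t in raw_tables if int((t.r > 0).sum()) > 1)
    retained_seq = len(filtered.examples)
    retained = {e.spacer for e in filtered.examples}
    retained_reads = sum(t.r_tot for t in raw_tables if t.spacer in retained)
    return summarize_selection(
        total_reads, unique, multi_read, multi_bin, retained_seq, retained_reads
    )
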