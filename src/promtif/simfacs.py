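"""Synthetic sort-seq generator for promoter-spacer libraries.

Emulates the statistical structure the analysis pipeline assumes, without
any sequencing data: random spacers, a planted additive (optionally
epistatic) sequence -> TIF map on the log-expression scale, Gaussian
intrinsic noise per cell, 12 fluorescence gates with discarded buffer
regions between adjacent bins, and per-bin read subsampling.  The planted
latent value and its noiseless gate are retained per sequence, so
downstream models can be scored against ground truth.

What it does not emulate: sequencing errors inside the spacer, extrinsic
noise (plasmid copy number, cell size — the real assay normalises these via
a constitutive reference), and the empirical gate boundaries of a real
sorter.  Passing pipeline tests on this generator therefore demonstrates
correct statistical machinery, not performance on real libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binfilter import build_dataset
from .seqdata import ALPHABET, BASE_INDEX, BinTable, N_BINS


@dataclass
class TruthModel:
    """Planted sequence -> latent TIF map: additive + pairwise + GC terms."""

    position_weights: np.ndarray  # (4, L)
    interactions: list[tuple[int, str, int, str, float]] = field(default_factory=list)
    gc_coefficient: float = 0.0

    @property
    def length(self) -> int:
        return self.position_weights.shape[1]

    def score(self, spacer: str) -> float:
        w = self.position_weights
        total = sum(w[BASE_INDEX[b], j] for j, b in enumerate(spacer))
        for pi, bi, pj, bj, effect in self.interactions:
            if spacer[pi] == bi and spacer[pj] == bj:
                total += effect
        if self.gc_coefficient:
            gc = (spacer.count("G") + spacer.count("C")) / len(spacer)
            total += self.gc_coefficient * gc
        return float(total)

    def score_batch(self, spacers: Sequence[str]) -> np.ndarray:
        return np.array([self.score(s) for s in spacers])

    @classmethod
    def random_additive(cls, L: int, rng: np.random.Generator,
                        standardize: bool = True) -> "TruthModel":
        """Random per-position base effects, standardised so that a uniform
        random spacer has latent mean ~0 and variance ~1."""
        w = rng.normal(0.0, 1.0, size=(4, L))
        if standardize:
            w -= w.mean(axis=0, keepdims=True)          # zero mean per position
            var = (w ** 2).mean(axis=0).sum()            # latent variance over positions
            w /= np.sqrt(var)
        return cls(position_weights=w)


def default_gate_edges() -> np.ndarray:
    """12 gates on the standardised latent scale: 10 interior bins of width
    0.5 spanning [-2.5, 2.5], with open-ended outermost gates capturing the
    tails (so extreme TIFs are represented, mirroring the very small
    outer-bin population fractions of a real sort)."""
    inner = np.linspace(-2.5, 2.5, 11)
    return np.concatenate(([-np.inf], inner, [np.inf]))


@dataclass
class SortSimConfig:
    """Study conditions for one synthetic sorting experiment."""

    n_sequences: int = 20_000
    L: int = 17
    truth_model: TruthModel | None = None
    intrinsic_sd: float = 0.35        # log-expression noise per cell
    cells_per_sequence: int = 50
    gate_edges: np.ndarray = field(default_factory=default_gate_edges)
    buffer_width: float = 0.025       # 5% of the 0.5 bin width, per internal edge
    reads_per_bin: int | dict | None = None  # None: keep every sorted cell as a read
    seed: int = 0

    def __post_init__(self) -> None:
        edges = np.asarray(self.gate_edges, dtype=np.float64)
        if len(edges) != N_BINS + 1 or (np.diff(edges) <= 0).any():
            raise ValueError("gate_edges must be 13 strictly ascending values")
        finite = np.isfinite(edges)
        widths = np.diff(edges[finite])
        if self.buffer_width < 0 or (widths.size and self.buffer_width >= widths.min()):
            raise ValueError("buffer_width must be >= 0 and smaller than the narrowest bin")
        self.gate_edges = edges


@dataclass
class SyntheticLibrary:
    sequences: list[str]
    true_latent: np.ndarray
    true_class: np.ndarray            # noiseless gate of true_latent, bin 0..11
    bin_tables: list[BinTable]
    config: SortSimConfig

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sequence": self.sequences,
            "true_latent": self.true_latent,
            "true_class": self.true_class,
        })


def random_spacers(n: int, L: int, rng: np.random.Generator) -> list[str]:
    """n distinct uniform-random ACGT spacers of length L."""
    if n > 4 ** L:
        raise ValueError(f"cannot draw {n} distinct sequences of length {L}")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), L))
        for row in draw:
            s = "".join(ALPHABET[i] for i in row)
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def planted_tif(spacer: str, truth_model: TruthModel) -> float:
    return truth_model.score(spacer)


def simulate_cells(latent: float, config: SortSimConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-cell log-expression: latent + Normal(0, intrinsic_sd)."""
    return latent + rng.normal(0.0, config.intrinsic_sd, size=config.cells_per_sequence)


def gate_assign(values: np.ndarray, config: SortSimConfig) -> np.ndarray:
    """Assign values to bins 0..11, or -1 for draws landing in a buffer.

    Buffers carve ``buffer_width / 2`` from each side of every internal gate
    edge; cells falling there are discarded, mimicking the gaps a sorter
    leaves between adjacent gates to limit cross-bin contamination.
    """
    edges = config.gate_edges
    bins = np.searchsorted(edges, values, side="right") - 1
    bins = np.clip(bins, 0, N_BINS - 1)
    if config.buffer_width > 0:
        half = config.buffer_width / 2.0
        for e in edges[1:-1]:
            if np.isfinite(e):
                bins[np.abs(values - e) < half] = -1
    return bins


def sort_and_sequence(sequences: Sequence[str], latents: np.ndarray,
                      config: SortSimConfig,
                      rng: np.random.Generator) -> list[BinTable]:
    """Simulate sorting + per-bin sequencing; one BinTable per sequence.

    Cells are drawn per sequence, gated (buffer cells discarded), then each
    bin's pooled cells are subsampled without replacement to the requested
    read depth (the whole pool, with a warning, when depth exceeds it).
    """
    n = len(sequences)
    counts = np.zeros((n, N_BINS), dtype=np.int64)
    for i, latent in enumerate(latents):
        draws = simulate_cells(latent, config, rng)
        bins = gate_assign(draws, config)
        for b in bins[bins >= 0]:
            counts[i, b] += 1

    if config.reads_per_bin is not None:
        depth = config.reads_per_bin
        depths = {b: depth for b in range(N_BINS)} if isinstance(depth, int) else dict(depth)
        for b in range(N_BINS):
            pool = int(counts[:, b].sum())
            want = int(depths.get(b, pool))
            if want >= pool:
                if want > pool:
                    import warnings
                    warnings.warn(f"bin {b}: requested depth {want} exceeds pool {pool}")
                continue
            # multivariate hypergeometric subsample of the per-sequence pool
            counts[:, b] = rng.multivariate_hypergeometric(counts[:, b], want)

    return [BinTable(s, counts[i]) for i, s in enumerate(sequences)
            if counts[i].sum() > 0]


def simulate_library(config: SortSimConfig) -> SyntheticLibrary:
    """Full generator: spacers, planted latents, sorted-and-sequenced tables."""
    rng = np.random.default_rng(config.seed)
    truth = config.truth_model or TruthModel.random_additive(config.L, rng)
    sequences = random_spacers(config.n_sequences, config.L, rng)
    latents = truth.score_batch(sequences)
    true_class = gate_assign_noiseless(latents, config)
    tables = sort_and_sequence(sequences, latents, config, rng)
    cfg = SortSimConfig(**{**config.__dict__, "truth_model": truth})
    return SyntheticLibrary(sequences, latents, true_class, tables, cfg)


def gate_assign_noiseless(latents: np.ndarray, config: SortSimConfig) -> np.ndarray:
    """Gate the noise-free latent directly (no buffers): the 'true class'."""
    bins = np.searchsorted(config.gate_edges, latents, side="right") - 1
    return np.clip(bins, 0, N_BINS - 1)


def make_fixture(config: SortSimConfig | None = None,
                 out_dir: str | Path | None = None):
    """SyntheticLibrary + filtered labeled dataset + orthogonality labels.

    The labeled dataset runs the real selection pipeline (outlier filter,
    bin-0 exclusion, modal-bin labeling).  Orthogonality labels are planted
    from a second, independent additive truth model thresholded at its
    median: above = fluorescent under the noncognate sigma (positive class,
    loss of orthogonality).
    """
    config = config or SortSimConfig()
    library = simulate_library(config)
    dataset = build_dataset(library.bin_tables)

    rng = np.random.default_rng(config.seed + 1)
    ortho_truth = TruthModel.random_additive(config.L, rng)
    ortho_scores = ortho_truth.score_batch(library.sequences)
    ortho_labels = (ortho_scores > np.median(ortho_scores)).astype(np.int64)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .seqdata import write_count_table
        write_count_table(library.bin_tables, out_dir / "bin_counts.tsv")
        library.truth_frame().to_csv(out_dir / "truth.tsv", sep="\t", index=False)
        dataset.to_tsv(out_dir / "labeled.tsv")
        pd.DataFrame({"sequence": library.sequences, "label": ortho_labels}).to_csv(
            out_dir / "orthogonality.tsv", sep="\t", index=False)
    return library, dataset, ortho_labels
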