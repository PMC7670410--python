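"""Forward engineering of promoter spacers from a trained TIF model.

Random candidate spacers are scored with a fitted ordinal model, annotated
with their Hamming distance to the nearest training sequence, and
down-selected into a panel covering every predicted class plus a "high"
class — the class-10 candidates with the largest Pr(y = 10).  Novelty is
enforced by a distance band (default 2-5 mutations from the nearest
training sequence), so panel members are never training sequences nor
trivial single-mutation neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ordnet import PredictionResult, TIFResults
from .seqdata import ChassisSpec, assemble_promoter


def generate_random_spacers(n: int, L: int, seed: int) -> list[str]:
    """n distinct i.i.d.-uniform ACGT spacers of length L (seeded)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    from .simfacs import random_spacers
    return random_spacers(n, L, np.random.default_rng(seed))


def _encode_uint8(sequences: Sequence[str]) -> np.ndarray:
    L = len(sequences[0])
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    return arr.reshape(len(sequences), L)


def nearest_hamming_distance(candidate: str, training_set: Sequence[str] | np.ndarray) -> int:
    """Minimum positionwise mismatch count to any training sequence."""
    enc = training_set if isinstance(training_set, np.ndarray) else _encode_uint8(list(training_set))
    cand = np.frombuffer(candidate.encode(), dtype=np.uint8)
    if cand.size != enc.shape[1]:
        raise ValueError("length mismatch")
    return int((enc != cand).sum(axis=1).min())


def nearest_hamming_distances(candidates: Sequence[str],
                              training_set: Sequence[str],
                              chunk: int = 512) -> np.ndarray:
    """Vectorised min-Hamming distance of each candidate to the training set."""
    enc_train = _encode_uint8(list(training_set))
    enc_cand = _encode_uint8(list(candidates))
    if enc_cand.shape[1] != enc_train.shape[1]:
        raise ValueError("length mismatch")
    out = np.empty(len(candidates), dtype=np.int64)
    for start in range(0, len(candidates), chunk):
        block = enc_cand[start:start + chunk]          # (c, L)
        mism = (block[:, None, :] != enc_train[None, :, :]).sum(axis=2)
        out[start:start + chunk] = mism.min(axis=1)
    return out


@dataclass
class DesignCandidate:
    spacer: str
    predicted_class: int
    class_probs: np.ndarray
    latent_score: float
    nearest_train_distance: int
    full_promoter: str | None = None


@dataclass
class DesignPanel:
    members: list[DesignCandidate]
    shortfalls: dict[int, int] = field(default_factory=dict)
    high_class_members: list[DesignCandidate] = field(default_factory=list)

    @property
    def class_coverage(self) -> dict[int, int]:
        cov: dict[int, int] = {}
        for m in self.members:
            cov[m.predicted_class] = cov.get(m.predicted_class, 0) + 1
        return cov

    def to_frame(self) -> pd.DataFrame:
        high = {id(m) for m in self.high_class_members}
        rows = []
        for m in self.members:
            row = {
                "spacer": m.spacer,
                "predicted_class": m.predicted_class,
                "latent_score": m.latent_score,
                "nearest_train_distance": m.nearest_train_distance,
                "high": id(m) in high,
                "full_promoter": m.full_promoter,
            }
            for c, p in enumerate(m.class_probs):
                row[f"p_class_{c}"] = p
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, m in enumerate(self.members):
                seq = m.full_promoter or m.spacer
                fh.write(f">design_{i}_class{m.predicted_class}\n{seq}\n")


def rank_candidates(results: TIFResults, spacers: Sequence[str]) -> tuple[list[str], PredictionResult, np.ndarray]:
    """Order candidates by predicted class, then by that class's probability.

    Stable descending sort, so the ordering is deterministic and invariant
    to the input permutation (ties keep lexicographic spacer order).
    """
    spacers = sorted(set(spacers))
    pred = results.predict(spacers)
    conf = pred.class_probs[np.arange(len(spacers)), pred.predicted_class]
    order = np.lexsort((spacers, -conf, -pred.predicted_class))
    ranked = [spacers[i] for i in order]
    reordered = PredictionResult(
        pred.latent_score[order], pred.thresholds[order],
        pred.class_probs[order], pred.predicted_class[order],
        pred.monotonicity_warning,
    )
    return ranked, reordered, order


def select_panel(
    ranked: Sequence[str],
    prediction: PredictionResult,
    distances: np.ndarray,
    per_class: int = 4,
    distance_band: tuple[int, int] = (2, 5),
    high_count: int = 10,
    n_classes: int = 11,
    chassis: ChassisSpec | None = None,
) -> DesignPanel:
    """Pick up to ``per_class`` novel candidates per class plus a high class.

    Candidates must sit within the Hamming-distance band from the nearest
    training sequence (band low >= 1 guarantees no training sequence is
    selected).  Classes without enough qualifying candidates are recorded as
    shortfalls, never padded from other classes.  The "high" class adds the
    ``high_count`` class-10 candidates with the largest Pr(y = 10) not
    already selected.
    """
    if not ranked:
        raise ValueError("empty candidate list")
    lo, hi = distance_band
    if lo < 1:
        raise ValueError("distance band must start at >= 1 to enforce novelty")
    ok = (distances >= lo) & (distances <= hi)

    members: list[DesignCandidate] = []
    chosen: set[int] = set()
    shortfalls: dict[int, int] = {}

    def make(i: int) -> DesignCandidate:
        spacer = ranked[i]
        return DesignCandidate(
            spacer=spacer,
            predicted_class=int(prediction.predicted_class[i]),
            class_probs=prediction.class_probs[i],
            latent_score=float(prediction.latent_score[i]),
            nearest_train_distance=int(distances[i]),
            full_promoter=assemble_promoter(spacer, chassis) if chassis else None,
        )

    for c in range(n_classes):
        idx = [i for i in range(len(ranked))
               if prediction.predicted_class[i] == c and ok[i]]
        take = idx[:per_class]
        for i in take:
            members.append(make(i))
            chosen.add(i)
        if len(take) < per_class:
            shortfalls[c] = per_class - len(take)

    high_members: list[DesignCandidate] = []
    p_top = prediction.class_probs[:, n_classes - 1]
    high_idx = [i for i in range(len(ranked))
                if prediction.predicted_class[i] == n_classes - 1
                and ok[i] and i not in chosen]
    high_idx.sort(key=lambda i: (-p_top[i], ranked[i]))
    for i in high_idx[:high_count]:
        cand = make(i)
        members.append(cand)
        high_members.append(cand)
        chosen.add(i)
    if len(high_idx) < high_count:
        shortfalls[n_classes] = high_count - len(high_idx)

    return DesignPanel(members=members, shortfalls=shortfalls,
                       high_class_members=high_members)


def design_panel(
    results: TIFResults,
    training_sequences: Sequence[str],
    n_candidates: int = 50_000,
    seed: int = 0,
    per_class: int = 4,
    distance_band: tuple[int, int] = (2, 5),
    high_count: int = 10,
    chassis: ChassisSpec | None = None,
) -> DesignPanel:
    """End-to-end forward design: sample, rank, annotate distances, select."""
    L = results.model.net_config.input_length
    candidates = generate_random_spacers(n_candidates, L, seed)
    training = set(training_sequences)
    candidates = [c for c in candidates if c not in training]
    ranked, pred, _ = rank_candidates(results, candidates)
    distances = nearest_hamming_distances(ranked, list(training_sequences))
    return select_panel(ranked, pred, distances, per_class=per_class,
                        distance_band=distance_band, high_count=high_count,
                        n_classes=results.model.net_config.n_classes,
                        chassis=chassis)
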