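"""Tripeptide statistics in intrinsically disordered regions of RBPs.

Given per-residue disorder scores (e.g. from an external disorder
predictor), each residue is labeled disordered when its score is >= 0.5.
For every tripeptide the disorder fraction is the number of its occurrences
lying entirely inside disordered regions divided by its total number of
occurrences in the RBP set. A tripeptide occurrence counts as disordered
only when all three residues are disordered (windows spanning a boundary
count as ordered); windows containing ambiguity letters are excluded
entirely, mirroring featurization.

Relating these fractions to the SVM feature-importance ranking asks whether
the k-mers the classifier leans on live preferentially in disordered
segments: tripeptides are sorted by decreasing |weight|, the fraction is
smoothed with a moving average, and the mean fraction in the top decile of
|weight| is contrasted with the bottom decile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .exceptions import DisorderTrackError
from .io import DisorderTrack, ProteinRecord
from .kernel import KernelConfig, index_to_kmer, kmer_indices
from .svm import FeatureWeights

logger = logging.getLogger(__name__)

DISORDER_THRESHOLD = 0.5


@dataclass
class DisorderStats:
    """Per-tripeptide totals: (kmer, n_total, n_disordered, fraction)."""

    frame: pd.DataFrame
    k: int

    def fraction_of(self, kmer: str) -> float:
        row = self.frame[self.frame["kmer"] == kmer]
        if row.empty:
            raise KeyError(f"tripeptide {kmer!r} never occurs in the RBP set")
        return float(row["fraction"].iloc[0])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class WeightDisorderProfile:
    """Disorder fractions ordered by decreasing |feature weight|."""

    frame: pd.DataFrame
    window: int
    top_decile_mean: float
    bottom_decile_mean: float

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def binarize_disorder(track: DisorderTrack, threshold: float = DISORDER_THRESHOLD) -> np.ndarray:
    """Residue labels: disordered (1) iff score >= threshold.

    Tracks already holding binary labels pass through unchanged.
    """
    scores = np.asarray(track.scores, dtype=float)
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise DisorderTrackError(
            f"{track.protein_id}: disorder scores outside [0, 1]"
        )
    return (scores >= threshold).astype(int)


def disorder_fraction(
    rbps: Sequence[ProteinRecord],
    tracks: Dict[str, DisorderTrack],
    k: int = 3,
    threshold: float = DISORDER_THRESHOLD,
) -> DisorderStats:
    """Aggregate per-tripeptide disorder counts over a set of RBPs."""
    config = KernelConfig(k=k)
    totals: Dict[int, int] = {}
    disordered: Dict[int, int] = {}
    for record in rbps:
        track = tracks.get(record.id)
        if track is None:
            raise DisorderTrackError(f"no disorder track for protein {record.id!r}")
        if len(track) != len(record.sequence):
            raise DisorderTrackError(
                f"{record.id}: track length {len(track)} != sequence length "
                f"{len(record.sequence)}"
            )
        labels = binarize_disorder(track, threshold)
        indices, positions = kmer_indices(record.sequence, config, return_positions=True)
        for idx, pos in zip(indices.tolist(), positions.tolist()):
            totals[idx] = totals.get(idx, 0) + 1
            if labels[pos : pos + k].all():
                disordered[idx] = disordered.get(idx, 0) + 1
    rows = [
        {
            "kmer": index_to_kmer(idx, config),
            "n_total": n,
            "n_disordered": disordered.get(idx, 0),
            "fraction": disordered.get(idx, 0) / n,
        }
        for idx, n in sorted(totals.items())
    ]
    frame = pd.DataFrame(rows, columns=["kmer", "n_total", "n_disordered", "fraction"])
    logger.info(
        "disorder stats over %d RBP(s): %d distinct %d-mers, %d windows",
        len(rbps),
        len(frame),
        k,
        int(frame["n_total"].sum()) if len(frame) else 0,
    )
    return DisorderStats(frame=frame, k=k)


def weight_disorder_profile(
    stats: DisorderStats,
    weights: FeatureWeights,
    window: int = 50,
) -> WeightDisorderProfile:
    """Disorder fraction along the |weight| ranking, smoothed.

    Tripeptides absent from the weight vector get weight 0. The sort is
    stable (ties keep the stats row order). ``window`` = 1 reproduces the
    raw sorted fractions.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    frame = stats.frame.copy()
    frame["weight"] = frame["kmer"].map(weights.value)
    frame["abs_weight"] = frame["weight"].abs()
    frame = frame.sort_values("abs_weight", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
    frame["rank"] = np.arange(1, len(frame) + 1)
    frame["smoothed_fraction"] = (
        frame["fraction"].rolling(window=window, min_periods=1, center=True).mean()
    )
    decile = max(1, len(frame) // 10)
    top_mean = float(frame["fraction"].iloc[:decile].mean())
    bottom_mean = float(frame["fraction"].iloc[-decile:].mean())
    return WeightDisorderProfile(
        frame=frame[
            ["rank", "kmer", "weight", "abs_weight", "n_total", "n_disordered",
             "fraction", "smoothed_fraction"]
        ],
        window=window,
        top_decile_mean=top_mean,
        bottom_decile_mean=bottom_mean,
    )
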