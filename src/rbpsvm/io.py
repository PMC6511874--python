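"""Readers and writers for every external representation the tool touches.

FASTA protein sequences, three-column annotation tables (protein_id,
annotation_type, value), per-residue disorder tracks, prediction tables and
the self-describing JSON model archive. All readers are strict: nothing is
silently dropped, and accepted/rejected row counts are logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__ as _tool_version
from .alphabet import AMBIGUOUS, VALID_LETTERS
from .exceptions import (
    AnnotationError,
    DisorderTrackError,
    FastaError,
    ModelFormatError,
)
from .kernel import KernelConfig, SpectrumVector
from .svm import TrainedModel

logger = logging.getLogger(__name__)

ANNOTATION_TYPES = ("go_term", "keyword", "pfam_domain")
MODEL_FORMAT = "rbpsvm-model"
MODEL_FORMAT_VERSION = 1


@dataclass
class ProteinRecord:
    """A protein: unique id, validated amino-acid sequence, optional label.

    Sequences are upper-case over the 20 standard letters plus the tolerated
    ambiguity letters B, J, O, U, X, Z; ``label`` is 1 for RBP, 0 for
    non-RBP, None when unknown.
    """

    id: str
    sequence: str
    label: Optional[int] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("protein id must be non-empty")
        if not self.sequence:
            raise FastaError(f"{self.id}: sequence must be non-empty")
        bad = set(self.sequence) - VALID_LETTERS
        if bad:
            raise FastaError(
                f"{self.id}: invalid sequence letters {sorted(bad)} "
                "(allowed: 20 standard amino acids plus B, J, O, U, X, Z)"
            )
        if self.label is not None and self.label not in (0, 1):
            raise FastaError(f"{self.id}: label must be 0, 1 or None")


@dataclass
class AnnotationTable:
    """Deduplicated (protein_id, annotation_type, value) rows."""

    frame: pd.DataFrame

    def ids_with(self, annotation_type: str, values: Set[str]) -> Set[str]:
        """Protein ids carrying any of ``values`` under ``annotation_type``."""
        if annotation_type not in ANNOTATION_TYPES:
            raise AnnotationError(f"unknown annotation_type {annotation_type!r}")
        mask = (self.frame["annotation_type"] == annotation_type) & self.frame[
            "value"
        ].isin(values)
        return set(self.frame.loc[mask, "protein_id"])

    def annotations_for(self, protein_id: str) -> pd.DataFrame:
        return self.frame[self.frame["protein_id"] == protein_id]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class DisorderTrack:
    """Per-residue disorder scores in [0, 1], one per residue."""

    protein_id: str
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.scores)


def read_fasta(path, policy: str = "keep") -> List[ProteinRecord]:
    """Read a protein FASTA file into validated records.

    ``policy`` controls ambiguity letters: "keep" retains them in the
    sequence (they are excluded later, at featurization); "reject" drops
    records containing any, with a logged count. Ids are the first
    whitespace-delimited header token and must be unique; sequences are
    upper-cased and must be non-empty.
    """
    if policy not in ("keep", "reject"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}: line {lineno}: expected a '>' header before "
                        f"sequence data"
                    )
                break
        else:
            raise FastaError(f"{path}: empty FASTA file")
    records: List[ProteinRecord] = []
    seen: Set[str] = set()
    n_rejected = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise FastaError(f"{path}: entry {entry.id!r} has an empty sequence")
        if entry.id in seen:
            raise FastaError(f"{path}: duplicate protein id {entry.id!r}")
        seen.add(entry.id)
        if policy == "reject" and set(seq) & set(AMBIGUOUS):
            n_rejected += 1
            continue
        records.append(
            ProteinRecord(id=entry.id, sequence=seq, description=entry.description)
        )
    logger.info(
        "read %d protein(s) from %s (%d rejected by ambiguity policy)",
        len(records),
        path,
        n_rejected,
    )
    return records


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def _read_tsv(path, expected_columns: Tuple[str, ...], error_cls) -> pd.DataFrame:
    try:
        frame = pd.read_csv(
            path, sep="\t", header=None, dtype=str, comment=None, skip_blank_lines=True
        )
    except Exception as exc:  # pandas raises several flavors on ragged input
        raise error_cls(f"{path}: cannot parse TSV: {exc}") from exc
    if frame.shape[1] != len(expected_columns):
        raise error_cls(
            f"{path}: expected {len(expected_columns)} tab-separated columns "
            f"{expected_columns}, found {frame.shape[1]}"
        )
    frame.columns = expected_columns
    # an optional header row repeating the column names is tolerated
    if tuple(frame.iloc[0]) == expected_columns:
        frame = frame.iloc[1:].reset_index(drop=True)
    return frame


def read_annotations(path) -> AnnotationTable:
    """Load a (protein_id, annotation_type, value) table; duplicates collapse."""
    frame = _read_tsv(path, ("protein_id", "annotation_type", "value"), AnnotationError)
    unknown = sorted(set(frame["annotation_type"]) - set(ANNOTATION_TYPES))
    if unknown:
        raise AnnotationError(
            f"{path}: unknown annotation_type value(s) {unknown}; "
            f"allowed: {ANNOTATION_TYPES}"
        )
    before = len(frame)
    frame = frame.drop_duplicates().reset_index(drop=True)
    logger.info(
        "read %d annotation row(s) from %s (%d duplicate(s) collapsed)",
        len(frame),
        path,
        before - len(frame),
    )
    return AnnotationTable(frame=frame)


def read_disorder(path, proteins: Sequence[ProteinRecord]) -> Dict[str, DisorderTrack]:
    """Load per-residue disorder scores; positions must tile 1..len exactly."""
    frame = _read_tsv(path, ("protein_id", "position", "score"), DisorderTrackError)
    try:
        frame = frame.assign(
            position=frame["position"].astype(int), score=frame["score"].astype(float)
        )
    except ValueError as exc:
        raise DisorderTrackError(f"{path}: non-numeric position/score: {exc}") from exc
    bad = frame[(frame["score"] < 0) | (frame["score"] > 1)]
    if len(bad):
        row = bad.iloc[0]
        raise DisorderTrackError(
            f"{path}: score {row['score']} for {row['protein_id']} position "
            f"{row['position']} outside [0, 1]"
        )
    lengths = {r.id: len(r.sequence) for r in proteins}
    tracks: Dict[str, DisorderTrack] = {}
    for pid, group in frame.groupby("protein_id", sort=False):
        if pid not in lengths:
            raise DisorderTrackError(f"{path}: unknown protein id {pid!r}")
        expected = lengths[pid]
        positions = group["position"].to_numpy()
        wanted = np.arange(1, expected + 1)
        if len(positions) != expected or not np.array_equal(np.sort(positions), wanted):
            missing = sorted(set(wanted.tolist()) - set(positions.tolist()))
            raise DisorderTrackError(
                f"{path}: {pid}: positions must cover 1..{expected} exactly once "
                f"(first missing/mismatched: {missing[:3] or 'duplicates present'})"
            )
        ordered = group.sort_values("position")["score"].to_numpy(dtype=float)
        tracks[pid] = DisorderTrack(protein_id=pid, scores=ordered)
    logger.info("read disorder tracks for %d protein(s) from %s", len(tracks), path)
    return tracks


def write_disorder(tracks: Dict[str, DisorderTrack], path) -> None:
    rows = [
        (pid, pos + 1, float(score))
        for pid, track in tracks.items()
        for pos, score in enumerate(track.scores)
    ]
    pd.DataFrame(rows, columns=["protein_id", "position", "score"]).to_csv(
        path, sep="\t", index=False
    )


def write_predictions(path, rows: Iterable[Tuple]) -> None:
    """Write (id, decision_value, probability-or-None, label) rows as TSV.

    Decision values are printed with 8 significant digits; probability is
    "NA" when the model is uncalibrated. Row order is preserved.
    """
    with open(path, "w") as handle:
        handle.write("protein_id\tdecision_value\tprobability\tpredicted_label\n")
        for pid, decision, prob, label in rows:
            prob_str = "NA" if prob is None or (isinstance(prob, float) and np.isnan(prob)) else f"{prob:.8g}"
            handle.write(f"{pid}\t{decision:.8g}\t{prob_str}\t{int(label)}\n")


def read_predictions(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    expected = ["protein_id", "decision_value", "probability", "predicted_label"]
    if list(frame.columns) != expected:
        raise AnnotationError(
            f"{path}: expected columns {expected}, found {list(frame.columns)}"
        )
    return frame


def save_model(model: TrainedModel, path) -> None:
    """Serialize a model as a self-describing JSON archive.

    Floats survive the round trip exactly (shortest-repr JSON encoding), so
    decision values are preserved bit-for-bit.
    """
    payload = {
        "format": MODEL_FORMAT,
        "format_version": MODEL_FORMAT_VERSION,
        "tool_version": _tool_version,
        "kernel": {
            "k": model.config.k,
            "normalized": model.config.normalized,
            "alphabet": model.config.alphabet,
        },
        "cost": model.cost,
        "class_weights": list(model.class_weights),
        "bias": model.bias,
        "dual_coefs": model.dual_coefs.tolist(),
        "support_vectors": [sv.counts for sv in model.support_vectors],
        "calibration": list(model.calibration) if model.calibration else None,
    }
    with open(path, "w") as handle:
        json.dump(payload, handle)


def load_model(path) -> TrainedModel:
    """Load a model archive written by :func:`save_model`."""
    try:
        with open(path) as handle:
            payload = json.load(handle)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"{path}: corrupt or truncated model file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ModelFormatError(f"{path}: not a {MODEL_FORMAT} archive")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported format version {payload.get('format_version')!r}"
        )
    try:
        kernel_cfg = payload["kernel"]
        config = KernelConfig(
            k=int(kernel_cfg["k"]),
            normalized=bool(kernel_cfg["normalized"]),
            alphabet=str(kernel_cfg["alphabet"]),
        )
        support_vectors = [
            SpectrumVector({str(m): int(c) for m, c in sv.items()}, config.k)
            for sv in payload["support_vectors"]
        ]
        calibration = payload.get("calibration")
        model = TrainedModel(
            support_vectors=support_vectors,
            dual_coefs=np.asarray(payload["dual_coefs"], dtype=float),
            bias=float(payload["bias"]),
            config=config,
            cost=float(payload["cost"]),
            class_weights=tuple(float(w) for w in payload["class_weights"]),
            calibration=tuple(calibration) if calibration else None,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"{path}: invalid model archive: {exc}") from exc
    except Exception as exc:  # e.g. KernelError on an invalid k / alphabet
        raise ModelFormatError(f"{path}: invalid model archive: {exc}") from exc
    if len(model.support_vectors) != len(model.dual_coefs):
        raise ModelFormatError(
            f"{path}: {len(model.support_vectors)} support vectors but "
            f"{len(model.dual_coefs)} dual coefficients"
        )
    return model


def read_labels(path) -> Dict[str, int]:
    """Read a (protein_id, label) TSV into a dict; labels must be 0/1."""
    frame = _read_tsv(path, ("protein_id", "label"), AnnotationError)
    try:
        labels = frame["label"].astype(int)
    except ValueError as exc:
        raise AnnotationError(f"{path}: non-integer label: {exc}") from exc
    if not set(labels.unique()) <= {0, 1}:
        raise AnnotationError(f"{path}: labels must be 0 or 1")
    if frame["protein_id"].duplicated().any():
        dup = frame.loc[frame["protein_id"].duplicated(), "protein_id"].iloc[0]
        raise AnnotationError(f"{path}: duplicate protein id {dup!r}")
    return dict(zip(frame["protein_id"], labels))


def write_labels(records: Sequence[ProteinRecord], path) -> None:
    pd.DataFrame(
        {"protein_id": [r.id for r in records], "label": [r.label for r in records]}
    ).to_csv(path, sep="\t", index=False)


def attach_labels(
    records: Sequence[ProteinRecord], labels: Dict[str, int]
) -> List[ProteinRecord]:
    """Return copies of ``records`` with labels attached; every record needs one."""
    missing = [r.id for r in records if r.id not in labels]
    if missing:
        raise AnnotationError(
            f"{len(missing)} protein(s) without a label (first: {missing[0]!r})"
        )
    return [dataclasses.replace(r, label=int(labels[r.id])) for r in records]
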