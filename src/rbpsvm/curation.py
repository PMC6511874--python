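"""Training-set curation from local annotation tables.

Positives are proteins annotated with the GO term "RNA binding"
(GO:0003723) or any term from a user-supplied sub-term closure list.
Negatives start from the whole proteome and pass a strict ordered filter
chain: (1) keep lengths in [50, 6000] residues; (2) drop proteins carrying
an excluded keyword or GO term (nucleotide binders); (3) drop proteins with
a hit in an excluded Pfam RNA-binding-domain list; (4) drop anything
positive-annotated; (5) redundancy reduction at 90% sequence identity.
Every step logs how many proteins it removed.

Redundancy reduction is greedy incremental clustering in order of
decreasing sequence length: a sequence joins an existing cluster when its
global-alignment identity to the cluster representative is strictly greater
than the threshold; cluster founders are the survivors. Identity is the
maximal number of matched positions in a global alignment divided by the
shorter sequence length (the CD-HIT convention). This is exact
dynamic-programming identity, not a word-filter heuristic, so borderline
pairs may cluster slightly differently than under CD-HIT.

The shipped excluded-keyword / GO / Pfam lists are editable defaults;
users with authoritative exports should substitute their own files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Sequence, Set, Tuple

from Bio import Align

from .exceptions import CurationError
from .io import AnnotationTable, ProteinRecord

logger = logging.getLogger(__name__)


def _load_list(name: str) -> Set[str]:
    text = resources.files("rbpsvm.data").joinpath(name).read_text()
    return {
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }


def read_term_list(path) -> Set[str]:
    """Read a one-term-per-line list file; '#' lines and blanks are ignored."""
    with open(path) as handle:
        return {
            line.strip()
            for line in handle
            if line.strip() and not line.startswith("#")
        }


@dataclass
class CurationConfig:
    """Term lists and thresholds driving the positive/negative filter chain."""

    positive_go_terms: Set[str] = field(
        default_factory=lambda: _load_list("positive_go_terms.txt")
    )
    excluded_keywords: Set[str] = field(
        default_factory=lambda: _load_list("excluded_keywords.txt")
    )
    excluded_go_terms: Set[str] = field(
        default_factory=lambda: _load_list("excluded_go_terms.txt")
    )
    excluded_pfam_domains: Set[str] = field(
        default_factory=lambda: _load_list("excluded_pfam_domains.txt")
    )
    min_len: int = 50
    max_len: int = 6000
    identity_threshold: float = 0.90

    def __post_init__(self) -> None:
        if self.min_len >= self.max_len:
            raise CurationError("min_len must be smaller than max_len")
        if not 0.0 < self.identity_threshold <= 1.0:
            raise CurationError("identity_threshold must lie in (0, 1]")


@dataclass
class CurationLogRow:
    step: str
    removed: int
    remaining: int


CurationLog = List[CurationLogRow]


def write_curation_log(log: CurationLog, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(r.step, r.removed, r.remaining) for r in log],
        columns=["step", "removed_count", "remaining_count"],
    ).to_csv(path, sep="\t", index=False)


# Global aligner maximizing matched positions (match 1, mismatch/gap 0):
# the optimal score is then exactly the maximal number of identically
# aligned residues over all global alignments.
_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=0.0,
    open_gap_score=0.0,
    extend_gap_score=0.0,
)


def sequence_identity(a: str, b: str) -> float:
    """Matched positions of the best global alignment / shorter length."""
    if not a or not b:
        raise CurationError("cannot align empty sequences")
    matches = _ALIGNER.score(a, b)
    return float(matches) / min(len(a), len(b))


def redundancy_reduce(
    records: Sequence[ProteinRecord], identity_threshold: float = 0.90
) -> List[ProteinRecord]:
    """Greedy representative selection at the given identity threshold.

    Sequences are visited in order of decreasing length (ties by id); a
    sequence is absorbed by the first representative it matches with
    identity strictly above the threshold, otherwise it founds a new
    cluster. Returns the representatives in visit order.
    """
    if not records:
        raise CurationError("redundancy_reduce requires a non-empty dataset")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    representatives: List[ProteinRecord] = []
    for record in ordered:
        absorbed = False
        for rep in representatives:
            if sequence_identity(record.sequence, rep.sequence) > identity_threshold:
                absorbed = True
                break
        if not absorbed:
            representatives.append(record)
    logger.info(
        "redundancy reduction at >%.0f%% identity: %d -> %d sequences",
        identity_threshold * 100,
        len(records),
        len(representatives),
    )
    return representatives


def _positive_ids(annotations: AnnotationTable, config: CurationConfig) -> Set[str]:
    return annotations.ids_with("go_term", config.positive_go_terms)


def build_positive_set(
    proteome: Sequence[ProteinRecord],
    annotations: AnnotationTable,
    config: CurationConfig,
) -> Tuple[List[ProteinRecord], CurationLog]:
    """Proteins with >= 1 positive GO annotation, redundancy-reduced."""
    log: CurationLog = []
    positive_ids = _positive_ids(annotations, config)
    kept = [r for r in proteome if r.id in positive_ids]
    log.append(CurationLogRow("positive_go_annotation", len(proteome) - len(kept), len(kept)))
    if not kept:
        logger.warning("positive set is empty: no protein carries a positive GO term")
        return [], log
    reduced = redundancy_reduce(kept, config.identity_threshold)
    log.append(CurationLogRow("redundancy_reduction", len(kept) - len(reduced), len(reduced)))
    for row in log:
        logger.info("positive set: %s removed=%d remaining=%d", row.step, row.removed, row.remaining)
    return reduced, log


def build_negative_set(
    proteome: Sequence[ProteinRecord],
    annotations: AnnotationTable,
    config: CurationConfig,
) -> Tuple[List[ProteinRecord], CurationLog]:
    """Apply the ordered negative filter chain; per-step counts are logged."""
    log: CurationLog = []
    kept = list(proteome)

    def _step(name: str, survivors: List[ProteinRecord]) -> List[ProteinRecord]:
        log.append(CurationLogRow(name, len(kept) - len(survivors), len(survivors)))
        return survivors

    kept = _step(
        "length_filter",
        [r for r in kept if config.min_len <= len(r.sequence) <= config.max_len],
    )
    excluded_kw = {k.lower() for k in config.excluded_keywords}
    keyword_ids = {
        pid
        for pid in annotations.frame.loc[
            annotations.frame["annotation_type"] == "keyword", "protein_id"
        ]
        if any(
            value.lower() in excluded_kw
            for value in annotations.frame.loc[
                (annotations.frame["protein_id"] == pid)
                & (annotations.frame["annotation_type"] == "keyword"),
                "value",
            ]
        )
    }
    go_ids = annotations.ids_with("go_term", config.excluded_go_terms)
    kept = _step(
        "keyword_go_filter",
        [r for r in kept if r.id not in keyword_ids and r.id not in go_ids],
    )
    pfam_ids = annotations.ids_with("pfam_domain", config.excluded_pfam_domains)
    kept = _step("pfam_rbd_filter", [r for r in kept if r.id not in pfam_ids])
    positive_ids = _positive_ids(annotations, config)
    kept = _step("remove_positives", [r for r in kept if r.id not in positive_ids])
    if kept:
        reduced = redundancy_reduce(kept, config.identity_threshold)
    else:
        reduced = []
    log.append(CurationLogRow("redundancy_reduction", len(kept) - len(reduced), len(reduced)))
    for row in log:
        logger.info("negative set: %s removed=%d remaining=%d", row.step, row.removed, row.remaining)
    return reduced, log
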