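"""Synthetic labeled proteomes with planted tripeptide enrichment.

Sequences are drawn residue-wise from a background amino-acid distribution
(uniform over the 20 standard letters by default). Class signal is planted
by insertion: for each planted k-mer and each sequence of the matching
class, the number of inserted copies is Poisson with mean
(lambda - 1) * (L - k + 1) * p(kmer), where p(kmer) is the background
probability of the k-mer; each copy overwrites a random window. Together
with the ~1x background expectation, planted k-mers then occur about
lambda-fold above background, and lambda = 1 plants nothing, making the
positive and negative sequence distributions identical (a null dataset).
Insertion (rather than biased residue sampling) gives exact control over
the planted windows, which is what parameter-recovery and disorder tests
need.

Optionally each inserted window, expanded by a small margin, is marked as
an intrinsically disordered segment (score 0.9 vs 0.1 background), which
emulates RBPs whose informative tripeptides sit in disordered regions.

Everything is deterministic given the seed. ``fixture_suite`` packages the
named study datasets used throughout the tests:

* ``separable``       - strong disjoint signal in both classes (lambda 20),
                        500 + 2833 proteins (15% positives);
* ``imbalanced-15pct``- moderate positive-only signal (lambda 5), 150 + 850;
* ``null``            - no signal (lambda 1), 300 + 1700;
* ``disorder-toy``    - planted positives with disorder tracks, plus three
                        hand-written proteins whose per-tripeptide disorder
                        fractions are hand-countable;
* ``curation-toy``    - ten hand-written proteins + annotations covering
                        every branch of the curation filter chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alphabet import ALPHABET
from .exceptions import SimulationError
from .io import AnnotationTable, DisorderTrack, ProteinRecord
from .kernel import KernelConfig

logger = logging.getLogger(__name__)

#: planted k-mer sets: K/R/G-rich for RBPs, L/E-rich for non-RBPs (the
#: residue chemistry the two classes actually differ in)
POS_KMERS = ("KKR", "RKK", "KRK", "RRK", "KRR", "RKR", "GRG", "RGG", "KGK", "RSR")
NEG_KMERS = ("LLL", "LEL", "ELL", "LLE", "EEL", "ELE", "LEE", "EEE", "VLL", "LLV")


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults mirror a 15%-positive training regime."""

    n_pos: int = 150
    n_neg: int = 850
    length_range: Tuple[int, int] = (50, 500)
    planted_pos_kmers: Tuple[str, ...] = ()
    lambda_pos: float = 1.0
    planted_neg_kmers: Tuple[str, ...] = ()
    lambda_neg: float = 1.0
    background: Optional[Tuple[float, ...]] = None
    disorder_segments: bool = False
    disorder_margin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0 or self.n_pos + self.n_neg == 0:
            raise SimulationError("need a non-empty dataset")
        lo, hi = self.length_range
        if lo < 1 or lo > hi:
            raise SimulationError(f"invalid length_range {self.length_range}")
        if self.lambda_pos < 1.0 or self.lambda_neg < 1.0:
            raise SimulationError("enrichment multipliers must be >= 1")
        for kmer in (*self.planted_pos_kmers, *self.planted_neg_kmers):
            if not kmer or any(c not in ALPHABET for c in kmer):
                raise SimulationError(
                    f"planted k-mer {kmer!r} contains non-alphabet letters"
                )
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or bg.min() < 0 or abs(bg.sum() - 1.0) > 1e-9:
                raise SimulationError("background must be 20 frequencies summing to 1")


@dataclass
class GroundTruth:
    """What was planted where, for parameter-recovery checks."""

    planted_pos_kmers: Tuple[str, ...]
    planted_neg_kmers: Tuple[str, ...]
    lambda_pos: float
    lambda_neg: float
    insertion_counts: Dict[str, int]
    intervals: Dict[str, List[Tuple[int, int]]]
    seed: int


def generate(
    config: SimConfig,
) -> Tuple[List[ProteinRecord], GroundTruth, Dict[str, DisorderTrack]]:
    """Draw a labeled synthetic proteome.

    Returns the records, the ground truth, and disorder tracks (empty dict
    unless ``config.disorder_segments``).
    """
    rng = np.random.default_rng(config.seed)
    background = (
        np.asarray(config.background, dtype=float)
        if config.background is not None
        else np.full(20, 1.0 / 20.0)
    )
    letters = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)
    kmer_codes = {
        kmer: np.array([ALPHABET.index(c) for c in kmer], dtype=np.int64)
        for kmer in (*config.planted_pos_kmers, *config.planted_neg_kmers)
    }
    kmer_prob = {
        kmer: float(np.prod(background[codes])) for kmer, codes in kmer_codes.items()
    }
    insertion_counts: Dict[str, int] = {k: 0 for k in kmer_codes}
    intervals: Dict[str, List[Tuple[int, int]]] = {}
    records: List[ProteinRecord] = []
    tracks: Dict[str, DisorderTrack] = {}
    lo, hi = config.length_range

    plan = [(1, i) for i in range(config.n_pos)] + [(0, i) for i in range(config.n_neg)]
    for label, serial in plan:
        pid = f"{'POS' if label else 'NEG'}_{serial + 1:05d}"
        length = int(rng.integers(lo, hi + 1))
        codes = rng.choice(20, size=length, p=background)
        planted = config.planted_pos_kmers if label else config.planted_neg_kmers
        lam = config.lambda_pos if label else config.lambda_neg
        spans: List[Tuple[int, int]] = []
        for kmer in planted:
            k = len(kmer)
            if length < k:
                continue
            mean = (lam - 1.0) * (length - k + 1) * kmer_prob[kmer]
            n_insert = int(rng.poisson(mean))
            for start in rng.integers(0, length - k + 1, size=n_insert):
                codes[start : start + k] = kmer_codes[kmer]
                spans.append((int(start), int(start) + k))
                insertion_counts[kmer] += 1
        sequence = letters[codes].tobytes().decode("ascii")
        records.append(ProteinRecord(id=pid, sequence=sequence, label=label))
        intervals[pid] = spans
        if config.disorder_segments:
            scores = np.full(length, 0.1)
            for start, stop in spans:
                a = max(0, start - config.disorder_margin)
                b = min(length, stop + config.disorder_margin)
                scores[a:b] = 0.9
            tracks[pid] = DisorderTrack(protein_id=pid, scores=scores)
    truth = GroundTruth(
        planted_pos_kmers=config.planted_pos_kmers,
        planted_neg_kmers=config.planted_neg_kmers,
        lambda_pos=config.lambda_pos,
        lambda_neg=config.lambda_neg,
        insertion_counts=insertion_counts,
        intervals=intervals,
        seed=config.seed,
    )
    logger.info(
        "generated %d positives + %d negatives (lengths %d-%d, seed %d)",
        config.n_pos,
        config.n_neg,
        lo,
        hi,
        config.seed,
    )
    return records, truth, tracks


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

SEPARABLE_CONFIG = SimConfig(
    n_pos=500,
    n_neg=2833,
    planted_pos_kmers=POS_KMERS,
    lambda_pos=20.0,
    planted_neg_kmers=NEG_KMERS,
    lambda_neg=20.0,
    seed=20190,
)

IMBALANCED_CONFIG = SimConfig(
    n_pos=150,
    n_neg=850,
    planted_pos_kmers=POS_KMERS,
    lambda_pos=5.0,
    seed=20191,
)

NULL_CONFIG = SimConfig(n_pos=300, n_neg=1700, seed=20192)

DISORDER_CONFIG = SimConfig(
    n_pos=60,
    n_neg=340,
    planted_pos_kmers=POS_KMERS,
    lambda_pos=20.0,
    disorder_segments=True,
    seed=20193,
)


@dataclass
class Fixture:
    """A named bundle: records plus whatever extras the scenario needs."""

    name: str
    records: List[ProteinRecord]
    ground_truth: Optional[GroundTruth] = None
    tracks: Dict[str, DisorderTrack] = field(default_factory=dict)
    annotations: Optional[AnnotationTable] = None
    expected: Dict[str, object] = field(default_factory=dict)
    hand_records: List[ProteinRecord] = field(default_factory=list)
    hand_tracks: Dict[str, DisorderTrack] = field(default_factory=dict)


def _hand_disorder_trio() -> Tuple[List[ProteinRecord], Dict[str, DisorderTrack]]:
    """Three tiny proteins whose tripeptide disorder fractions are hand-countable."""
    records = [
        ProteinRecord(id="D1", sequence="KKKKR", label=1),
        ProteinRecord(id="D2", sequence="GRGRG", label=1),
        ProteinRecord(id="D3", sequence="LLLLL", label=1),
    ]
    tracks = {
        "D1": DisorderTrack("D1", np.array([1.0, 1.0, 1.0, 0.0, 1.0])),
        "D2": DisorderTrack("D2", np.array([0.9, 0.9, 0.9, 0.9, 0.9])),
        "D3": DisorderTrack("D3", np.array([0.0, 0.0, 0.0, 0.0, 0.0])),
    }
    return records, tracks


def _curation_toy() -> Fixture:
    """Ten hand-written proteins exercising every curation filter branch.

    Hand trace (default term lists, min_len 50, max_len 6000, identity 0.90):
    positives = {P01, P02}; negative survivors = {P04, P10}; P03/P05 fall to
    the length filter; P01 (GO:0003723 is also an excluded term), P06
    (keyword) and P07 (GO) to the keyword/GO filter; P08 to the Pfam filter;
    P02 to positive removal; P09 (duplicate of P04) to redundancy. P10
    shares exactly 45/50 matched positions with P04 (identity 0.90, not
    > 0.90), so both survive the strict threshold.
    """
    seq60_a = "MKRGGRKKSEQWFYNDHICATGAVLPSEHNQRYFDWIAGTSACELKRKGPKNMTVHWDE"
    seq60_b = "GAVLPSEHNQRYFDWIAGTSACELMKPTAVHSEQWFYNDKICARTGWDEHAMNQRSTVY"
    base50 = "MKRLLPTAVAGHSEQWFYNDKICMRTGAVLPSEHNQRYFDWIKGTSACEL"
    # provable 90%-identity boundary pair: common K-run + letter-disjoint tails
    boundary_a = "K" * 45 + "MRTGA"
    boundary_b = "K" * 45 + "CHSEQ"
    records = [
        ProteinRecord(id="P01", sequence=seq60_a, label=None),
        ProteinRecord(id="P02", sequence=seq60_b, label=None),
        ProteinRecord(id="P03", sequence=base50[:49], label=None),
        ProteinRecord(id="P04", sequence=boundary_a, label=None),
        ProteinRecord(id="P05", sequence=(ALPHABET * 301)[:6001], label=None),
        ProteinRecord(id="P06", sequence=base50, label=None),
        ProteinRecord(id="P07", sequence=base50[::-1], label=None),
        ProteinRecord(id="P08", sequence=seq60_a[::-1], label=None),
        ProteinRecord(id="P09", sequence=boundary_a, label=None),
        ProteinRecord(id="P10", sequence=boundary_b, label=None),
    ]
    import pandas as pd

    rows = [
        ("P01", "go_term", "GO:0003723"),   # positive: root RNA-binding term
        ("P02", "go_term", "GO:0000049"),   # positive: sub-term (tRNA binding)
        ("P04", "keyword", "Cytoplasm"),    # benign keyword, kept
        ("P05", "keyword", "Metal-binding"),  # benign, removed by length anyway
        ("P06", "keyword", "ATP-binding"),  # excluded keyword
        ("P07", "go_term", "GO:0000166"),   # excluded GO (nucleotide binding)
        ("P08", "pfam_domain", "PF00076"),  # excluded Pfam RBD (RRM)
        ("P08", "pfam_domain", "PF00076"),  # duplicate row, collapses on load
    ]
    annotations = AnnotationTable(
        frame=pd.DataFrame(
            rows, columns=["protein_id", "annotation_type", "value"]
        ).drop_duplicates().reset_index(drop=True)
    )
    expected = {
        "positives": {"P01", "P02"},
        "negatives": {"P04", "P10"},
        "negative_removals": {
            "length_filter": 2,        # P03 (49 AA), P05 (6001 AA)
            "keyword_go_filter": 3,    # P01 (excluded GO), P06 (keyword), P07 (GO)
            "pfam_rbd_filter": 1,      # P08
            "remove_positives": 1,     # P02
            "redundancy_reduction": 1,  # P09 == P04
        },
    }
    return Fixture(
        name="curation-toy",
        records=records,
        annotations=annotations,
        expected=expected,
    )


def make_fixture(name: str) -> Fixture:
    """Build one named fixture (deterministic: seeds are part of the recipe)."""
    if name == "separable":
        records, truth, _ = generate(SEPARABLE_CONFIG)
        return Fixture(name=name, records=records, ground_truth=truth)
    if name == "imbalanced-15pct":
        records, truth, _ = generate(IMBALANCED_CONFIG)
        return Fixture(name=name, records=records, ground_truth=truth)
    if name == "null":
        records, truth, _ = generate(NULL_CONFIG)
        return Fixture(name=name, records=records, ground_truth=truth)
    if name == "disorder-toy":
        records, truth, tracks = generate(DISORDER_CONFIG)
        hand_records, hand_tracks = _hand_disorder_trio()
        return Fixture(
            name=name,
            records=records,
            ground_truth=truth,
            tracks=tracks,
            hand_records=hand_records,
            hand_tracks=hand_tracks,
        )
    if name == "curation-toy":
        return _curation_toy()
    raise SimulationError(f"unknown fixture {name!r}")


FIXTURE_NAMES = ("separable", "imbalanced-15pct", "null", "disorder-toy", "curation-toy")


def fixture_suite() -> Dict[str, Fixture]:
    """All named fixtures, regenerated deterministically."""
    return {name: make_fixture(name) for name in FIXTURE_NAMES}
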