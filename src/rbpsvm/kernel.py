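"""k-mer spectrum featurization and the spectrum string kernel.

The k-spectrum of a protein sequence is the multiset of all overlapping
length-k substrings over the 20-letter amino-acid alphabet; its feature map
Phi_k(x) is the (sparse) vector of k-mer occurrence counts in a
20^k-dimensional space. The spectrum kernel is the dot product

    K_k(x, y) = <Phi_k(x), Phi_k(y)>,

optionally cosine-normalized so that K(x, x) = 1, which removes the bias of
raw counts toward long sequences. Windows containing ambiguity letters
(B, J, O, U, X, Z) are skipped, keeping counts integral and the feature
space fixed at 20^k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.preprocessing import normalize as _l2_normalize

from .alphabet import ALPHABET
from .exceptions import KernelError

logger = logging.getLogger(__name__)

_CODE_TABLES: dict = {}


def _code_table(alphabet: str) -> np.ndarray:
    """Map byte values to alphabet codes; anything else (incl. ambiguity) -> -1."""
    table = _CODE_TABLES.get(alphabet)
    if table is None:
        table = np.full(256, -1, dtype=np.int64)
        for i, letter in enumerate(alphabet):
            table[ord(letter)] = i
        _CODE_TABLES[alphabet] = table
    return table


@dataclass(frozen=True)
class KernelConfig:
    """Spectrum-kernel configuration: substring length k, normalization flag
    and the ordered 20-letter alphabet. Feature-space dimension is 20^k."""

    k: int = 3
    normalized: bool = True
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        if self.k < 1:
            raise KernelError(f"k must be >= 1, got {self.k}")
        if len(self.alphabet) != 20 or len(set(self.alphabet)) != 20:
            raise KernelError("alphabet must contain exactly 20 distinct letters")

    @property
    def dim(self) -> int:
        return len(self.alphabet) ** self.k

    @property
    def powers(self) -> np.ndarray:
        return 20 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)


@dataclass
class SpectrumVector:
    """Sparse k-mer count vector Phi_k(x): k-mer string -> occurrence count.

    Absent keys mean zero; stored values are >= 1.
    """

    counts: Dict[str, int]
    k: int

    def __post_init__(self) -> None:
        for kmer, count in self.counts.items():
            if len(kmer) != self.k:
                raise KernelError(f"k-mer {kmer!r} has length != k={self.k}")
            if count < 1:
                raise KernelError(f"count for {kmer!r} must be >= 1, got {count}")

    def dot(self, other: "SpectrumVector") -> float:
        if self.k != other.k:
            raise KernelError(f"k mismatch: {self.k} vs {other.k}")
        small, big = (self.counts, other.counts)
        if len(big) < len(small):
            small, big = big, small
        return float(sum(c * big.get(m, 0) for m, c in small.items()))

    def norm(self) -> float:
        return float(np.sqrt(sum(c * c for c in self.counts.values())))

    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


def kmer_to_index(kmer: str, config: KernelConfig) -> int:
    idx = 0
    for letter in kmer:
        code = config.alphabet.find(letter)
        if code < 0:
            raise KernelError(f"letter {letter!r} not in alphabet")
        idx = idx * 20 + code
    return idx


def index_to_kmer(index: int, config: KernelConfig) -> str:
    letters = []
    for _ in range(config.k):
        index, rem = divmod(index, 20)
        letters.append(config.alphabet[rem])
    return "".join(reversed(letters))


def kmer_indices(sequence: str, config: KernelConfig, return_positions: bool = False):
    """Feature-space indices of all valid (ambiguity-free) windows.

    Returns the int64 index array, or ``(indices, start_positions)`` when
    ``return_positions`` is true.
    """
    k = config.k
    empty = np.empty(0, dtype=np.int64)
    if len(sequence) < k:
        if return_positions:
            return empty, empty
        return empty
    try:
        raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise KernelError(f"non-ASCII character in sequence: {exc}") from exc
    codes = _code_table(config.alphabet)[raw]
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    indices = windows[valid] @ config.powers
    if return_positions:
        return indices, np.flatnonzero(valid)
    return indices


def featurize(sequence: str, config: KernelConfig) -> SpectrumVector:
    """Count all overlapping k-windows of ``sequence``.

    Sequences shorter than k yield the zero vector with a logged warning
    (curation normally enforces length >= 50, so this is a soft failure).
    """
    if len(sequence) < config.k:
        logger.warning(
            "sequence of length %d shorter than k=%d; zero spectrum vector",
            len(sequence),
            config.k,
        )
        return SpectrumVector({}, config.k)
    indices = kmer_indices(sequence, config)
    uniq, counts = np.unique(indices, return_counts=True)
    return SpectrumVector(
        {index_to_kmer(int(i), config): int(c) for i, c in zip(uniq, counts)},
        config.k,
    )


def featurize_csr(sequences: Sequence[str], config: KernelConfig) -> sp.csr_matrix:
    """Raw (unnormalized) spectrum count matrix, one row per sequence."""
    indptr = [0]
    all_indices: List[np.ndarray] = []
    all_data: List[np.ndarray] = []
    n_short = 0
    for seq in sequences:
        if len(seq) < config.k:
            n_short += 1
        idx = kmer_indices(seq, config)
        uniq, counts = np.unique(idx, return_counts=True)
        all_indices.append(uniq)
        all_data.append(counts.astype(np.float64))
        indptr.append(indptr[-1] + len(uniq))
    if n_short:
        logger.warning("%d sequence(s) shorter than k=%d: zero rows", n_short, config.k)
    data = np.concatenate(all_data) if all_data else np.empty(0)
    indices = np.concatenate(all_indices) if all_indices else np.empty(0, dtype=np.int64)
    return sp.csr_matrix(
        (data, indices, np.asarray(indptr)), shape=(len(sequences), config.dim)
    )


def vectors_to_csr(vectors: Sequence[SpectrumVector], config: KernelConfig) -> sp.csr_matrix:
    indptr = [0]
    indices: List[int] = []
    data: List[float] = []
    for vec in vectors:
        if vec.k != config.k:
            raise KernelError(f"vector k={vec.k} does not match config k={config.k}")
        items = sorted((kmer_to_index(m, config), c) for m, c in vec.counts.items())
        indices.extend(i for i, _ in items)
        data.extend(float(c) for _, c in items)
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=np.int64), np.asarray(indptr)),
        shape=(len(vectors), config.dim),
    )


def maybe_normalize(matrix: sp.csr_matrix, config: KernelConfig) -> sp.csr_matrix:
    """L2-normalize rows when the config asks for the normalized kernel.

    Zero rows (short / all-ambiguity sequences) stay zero.
    """
    if not config.normalized:
        return matrix
    return _l2_normalize(matrix, norm="l2", copy=True)


def kernel(x: SpectrumVector, y: SpectrumVector, config: KernelConfig) -> float:
    """Spectrum kernel between two vectors produced under ``config``.

    Normalized variant is K(x,y)/sqrt(K(x,x) K(y,y)), defined as 0 when
    either vector is empty.
    """
    if x.k != config.k or y.k != config.k:
        raise KernelError(
            f"vector k ({x.k}, {y.k}) does not match config k={config.k}"
        )
    raw = x.dot(y)
    if not config.normalized:
        return raw
    nx, ny = x.norm(), y.norm()
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return raw / (nx * ny)


def kernel_matrix(vectors: Sequence[SpectrumVector], config: KernelConfig) -> np.ndarray:
    """Dense Gram matrix M[i, j] = K(v_i, v_j); symmetric and PSD."""
    if len(vectors) == 0:
        raise KernelError("kernel_matrix requires a non-empty dataset")
    X = maybe_normalize(vectors_to_csr(vectors, config), config)
    gram = (X @ X.T).toarray()
    return (gram + gram.T) / 2.0  # enforce exact symmetry against fp noise


def write_spectrum_tsv(vector: SpectrumVector, path) -> None:
    """Debugging dump of a spectrum vector as a (kmer, count) TSV."""
    import pandas as pd

    frame = pd.DataFrame(
        sorted(vector.counts.items()), columns=["kmer", "count"]
    )
    frame.to_csv(path, sep="\t", index=False)
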