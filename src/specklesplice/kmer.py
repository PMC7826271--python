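"""k-mer vocabulary and per-k-mer free-energy tables.

Short RNA words (k-mers) stand in for splicing regulatory elements: each word
carries a transfer free energy ``dG_i`` (in units of kT) for moving from the
nucleoplasm into the nuclear-speckle phase.  Negative values mark
speckle-favoring, SR-protein-like words; positive values mark
nucleoplasm-favoring, hnRNP-like words.  A complete table over the 4**k words
is the parameterisation of every downstream computation.

Sequences are accepted as DNA or RNA; ``T`` is canonicalised to ``U`` and any
other letter outside ``{A, C, G, U}`` (including IUPAC ambiguity codes) is
rejected, because the model is defined only over concrete words.
"""

from __future__ import annotations

import hashlib
import itertools
from collections import Counter
from collections.abc import Iterable, Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

RNA_ALPHABET = "ACGU"
MIN_K = 1
MAX_K = 8

_CODES = np.full(256, -1, dtype=np.int16)
for _i, _base in enumerate(RNA_ALPHABET):
    _CODES[ord(_base)] = _i
_BASES = np.array(list(RNA_ALPHABET))


def canonicalize(sequence: str) -> str:
    """Uppercase a nucleotide string and convert DNA ``T`` to RNA ``U``.

    Raises
    ------
    ValueError
        If the sequence contains any character outside ``{A, C, G, U, T}``
        (case-insensitive), including IUPAC ambiguity codes.
    """
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set(RNA_ALPHABET)
    if bad:
        raise ValueError(
            f"sequence contains characters outside A/C/G/U/T: {sorted(bad)!r}"
        )
    return seq


def encode(sequence: str) -> np.ndarray:
    """Canonicalize and encode a sequence as base-4 digits (A=0 C=1 G=2 U=3)."""
    seq = canonicalize(sequence)
    if not seq:
        return np.zeros(0, dtype=np.int64)
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODES[raw].astype(np.int64)


def decode(codes: Iterable[int]) -> str:
    """Inverse of :func:`encode`."""
    return "".join(_BASES[np.asarray(list(codes), dtype=np.int64)])


def _check_k(k: int) -> int:
    if not (MIN_K <= int(k) <= MAX_K):
        raise ValueError(f"k must be in [{MIN_K}, {MAX_K}], got {k}")
    return int(k)


def window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of all overlapping k-windows along the last axis.

    For input of length ``L`` (last axis) returns ``L - k + 1`` window codes,
    one per start position; works on batches of sequences (2-D input).
    """
    codes = np.asarray(codes, dtype=np.int64)
    if codes.shape[-1] < k:
        raise ValueError(
            f"sequence of length {codes.shape[-1]} is shorter than k={k}"
        )
    windows = sliding_window_view(codes, k, axis=-1)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows @ weights


def kmer_code(word: str, k: int | None = None) -> int:
    """Base-4 code of a single k-mer word."""
    codes = encode(word)
    if k is not None and len(codes) != k:
        raise ValueError(f"expected a {k}-mer, got {word!r} (length {len(codes)})")
    return int(window_codes(codes, len(codes))[0])


def decode_kmer(code: int, k: int) -> str:
    """k-mer word for a base-4 code."""
    digits = (code // 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)) % 4
    return decode(digits)


def all_kmers(k: int) -> list[str]:
    """All 4**k words over {A,C,G,U} in lexicographic order."""
    _check_k(k)
    return ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=k)]


def count_kmers(sequence: str, k: int) -> Counter[str]:
    """Counts of all overlapping k-mer occurrences in a sequence.

    Every start position ``0..L-k`` contributes one occurrence, so a sequence
    of length ``L`` yields ``L - k + 1`` occurrences in total (with
    multiplicity for repeated words).

    Raises
    ------
    ValueError
        If the canonicalized sequence is shorter than ``k`` or contains an
        invalid character.
    """
    _check_k(k)
    codes = window_codes(encode(sequence), k)
    values, counts = np.unique(codes, return_counts=True)
    return Counter(
        {decode_kmer(int(c), k): int(n) for c, n in zip(values, counts)}
    )


class KmerEnergyTable:
    """Complete table of per-k-mer transfer free energies, in kT units.

    Stores one finite value for every one of the ``4**k`` words.  Sparse
    specifications (a mapping of only some words) are completed with zeros.

    Parameters
    ----------
    k : int
        Word length, between 1 and 8.
    values : array-like of shape (4**k,)
        Free energy ``dG_i`` per word, indexed by the base-4 code of the word
        (A=0, C=1, G=2, U=3; lexicographic order).
    """

    __slots__ = ("k", "values")

    def __init__(self, k: int, values) -> None:
        self.k = _check_k(k)
        arr = np.asarray(values, dtype=np.float64).copy()
        if arr.shape != (4**self.k,):
            raise ValueError(
                f"expected {4**self.k} values for k={self.k}, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("all free energies must be finite")
        self.values = arr

    # -- constructors ------------------------------------------------------
    @classmethod
    def zeros(cls, k: int) -> "KmerEnergyTable":
        """The null model: every word has dG_i = 0."""
        return cls(k, np.zeros(4 ** _check_k(k)))

    @classmethod
    def from_dict(cls, k: int, entries: Mapping[str, float]) -> "KmerEnergyTable":
        """Sparse construction; words absent from ``entries`` get 0."""
        table = cls.zeros(k)
        for word, value in entries.items():
            value = float(value)
            if not np.isfinite(value):
                raise ValueError(f"non-finite energy for word {word!r}")
            table.values[kmer_code(word, k)] = value
        return table

    @classmethod
    def random(
        cls, k: int, scale: float = 0.25, seed: int | np.random.Generator = 0
    ) -> "KmerEnergyTable":
        """Dense table with i.i.d. Normal(0, scale) energies."""
        rng = np.random.default_rng(seed)
        return cls(k, rng.normal(0.0, scale, size=4 ** _check_k(k)))

    @classmethod
    def from_motif_sets(
        cls,
        k: int,
        speckle_words: Iterable[str],
        nucleoplasm_words: Iterable[str] = (),
        speckle_dg: float = -1.0,
        nucleoplasm_dg: float = 1.0,
    ) -> "KmerEnergyTable":
        """Assign one energy to SR-like words and another to hnRNP-like words.

        ``speckle_words`` get ``speckle_dg`` (negative by default: they favor
        the speckle phase); ``nucleoplasm_words`` get ``nucleoplasm_dg``.
        A word listed in both sets is an error.
        """
        speckle = list(speckle_words)
        nucleo = list(nucleoplasm_words)
        overlap = set(speckle) & set(nucleo)
        if overlap:
            raise ValueError(f"words in both motif sets: {sorted(overlap)}")
        entries = {w: float(speckle_dg) for w in speckle}
        entries.update({w: float(nucleoplasm_dg) for w in nucleo})
        return cls.from_dict(k, entries)

    # -- access ------------------------------------------------------------
    def __getitem__(self, word: str) -> float:
        return float(self.values[kmer_code(word, self.k)])

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Energies for an array of base-4 window codes."""
        return self.values[np.asarray(codes, dtype=np.int64)]

    @property
    def kmers(self) -> list[str]:
        return all_kmers(self.k)

    def nonzero(self) -> dict[str, float]:
        """Mapping of the words with a nonzero energy."""
        (idx,) = np.nonzero(self.values)
        return {decode_kmer(int(i), self.k): float(self.values[i]) for i in idx}

    def __neg__(self) -> "KmerEnergyTable":
        return KmerEnergyTable(self.k, -self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerEnergyTable):
            return NotImplemented
        return self.k == other.k and np.array_equal(self.values, other.values)

    def __hash__(self) -> int:  # tables are mutable via .values; identity hash
        return id(self)

    def __repr__(self) -> str:
        n = int(np.count_nonzero(self.values))
        return f"KmerEnergyTable(k={self.k}, {n}/{4**self.k} nonzero)"

    def checksum(self) -> str:
        """Short content hash identifying the table (used in manifests)."""
        digest = hashlib.sha256()
        digest.update(str(self.k).encode())
        digest.update(np.ascontiguousarray(self.values).tobytes())
        return digest.hexdigest()[:12]


def build_kmer_table(k: int, spec=None, **kwargs) -> KmerEnergyTable:
    """Build a complete table from one of the supported specifications.

    ``spec`` may be ``None`` (all-zero), a mapping word -> dG, or one of the
    strings ``"zero"`` / ``"random"`` / ``"motifs"`` with keyword arguments
    forwarded to the corresponding constructor.
    """
    if spec is None or spec == "zero":
        return KmerEnergyTable.zeros(k)
    if isinstance(spec, Mapping):
        return KmerEnergyTable.from_dict(k, spec)
    if spec == "random":
        return KmerEnergyTable.random(k, **kwargs)
    if spec == "motifs":
        return KmerEnergyTable.from_motif_sets(k, **kwargs)
    raise ValueError(f"unknown table specification {spec!r}")
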