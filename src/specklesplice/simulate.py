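"""Synthetic two-splice-site reporter libraries.

Emulates a massively parallel reporter assay in which two competing 5'
splice sites flank a short random region: each reporter gets an i.i.d.
uniform random region, its true usage probability follows the two-state
Boltzmann model under a ground-truth energy table, and observed reads are
drawn per reporter from a Binomial distribution.  Everything flows from a
single seeded NumPy generator, so identical seeds reproduce identical
libraries bit for bit.

The default library size mirrors the ~3e5-reporter scale of real assays of
this design; tests and examples use smaller libraries for desk-scale
runtimes.  Sequencing noise beyond the binomial (PCR duplicates,
overdispersion) is deliberately not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .kmer import _BASES, KmerEnergyTable, all_kmers, encode, window_codes
from .thermo import ThermoConfig

#: Assay-scale default number of reporters.
DEFAULT_N_REPORTERS = 300_000
#: Default random-region length: holds 20 overlapping 6-mers, enough for
#: multi-element combination effects.
DEFAULT_REGION_LENGTH = 25
DEFAULT_READS = 100
#: Haldane–Anscombe pseudocount keeping empirical log ratios finite.
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class Reporter:
    """One reporter: its random region, ground truth, and sampled reads."""

    region: str
    true_delta_g: float
    true_p_upstream: float
    reads_upstream: int
    reads_downstream: int

    @property
    def total_reads(self) -> int:
        return self.reads_upstream + self.reads_downstream


@dataclass(frozen=True)
class LibraryParams:
    """Generation parameters of a library (recorded for reproducibility)."""

    n_reporters: int
    region_length: int
    reads_per_reporter: int
    seed: int | None
    k: int
    kT: float
    table_id: str


class ReporterLibrary:
    """A homogeneous collection of simulated (or re-loaded) reporters.

    Data are held column-wise in NumPy arrays; :class:`Reporter` objects are
    materialised on demand.  ``truth_table`` carries the generating energy
    table when known, enabling parameter-recovery evaluation.
    """

    def __init__(
        self,
        codes: np.ndarray,
        true_delta_g: np.ndarray,
        true_p_upstream: np.ndarray,
        reads_upstream: np.ndarray,
        reads_downstream: np.ndarray,
        params: LibraryParams,
        truth_table: KmerEnergyTable | None = None,
    ) -> None:
        self.codes = np.asarray(codes, dtype=np.int64)
        n, L = self.codes.shape
        self.true_delta_g = np.asarray(true_delta_g, dtype=np.float64)
        self.true_p_upstream = np.asarray(true_p_upstream, dtype=np.float64)
        self.reads_upstream = np.asarray(reads_upstream, dtype=np.int64)
        self.reads_downstream = np.asarray(reads_downstream, dtype=np.int64)
        for arr in (
            self.true_delta_g,
            self.true_p_upstream,
            self.reads_upstream,
            self.reads_downstream,
        ):
            if arr.shape != (n,):
                raise ValueError("all per-reporter arrays must have the same length")
        if (self.reads_upstream < 0).any() or (self.reads_downstream < 0).any():
            raise ValueError("read counts must be non-negative")
        self.params = params
        self.truth_table = truth_table
        self._regions: list[str] | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self.codes.shape[0]

    def __getitem__(self, i: int) -> Reporter:
        return Reporter(
            region=self.regions[i],
            true_delta_g=float(self.true_delta_g[i]),
            true_p_upstream=float(self.true_p_upstream[i]),
            reads_upstream=int(self.reads_upstream[i]),
            reads_downstream=int(self.reads_downstream[i]),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @property
    def region_length(self) -> int:
        return self.codes.shape[1]

    @property
    def regions(self) -> list[str]:
        """Region strings (materialised lazily from the code matrix)."""
        if self._regions is None:
            chars = _BASES[self.codes]
            self._regions = ["".join(row) for row in chars]
        return self._regions

    def empirical_log_ratios(self, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
        """Per-reporter ln((reads_up + a) / (reads_down + a))."""
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        return np.log(
            (self.reads_upstream + pseudocount) / (self.reads_downstream + pseudocount)
        )

    def true_log_ratios(self, kT: float | None = None) -> np.ndarray:
        kT = self.params.kT if kT is None else kT
        return -self.true_delta_g / kT

    def window_code_matrix(self, k: int | None = None) -> np.ndarray:
        """(n, L-k+1) matrix of base-4 window codes per reporter."""
        k = self.params.k if k is None else k
        return window_codes(self.codes, k)

    def subset(self, indices) -> "ReporterLibrary":
        """View-like sub-library (copies the selected rows)."""
        idx = np.asarray(indices)
        return ReporterLibrary(
            self.codes[idx],
            self.true_delta_g[idx],
            self.true_p_upstream[idx],
            self.reads_upstream[idx],
            self.reads_downstream[idx],
            self.params,
            self.truth_table,
        )

    def __repr__(self) -> str:
        return (
            f"ReporterLibrary(n={len(self)}, L={self.region_length}, "
            f"reads={self.params.reads_per_reporter}, seed={self.params.seed})"
        )


def simulate_library(
    n: int,
    L: int,
    table: KmerEnergyTable,
    reads: int = DEFAULT_READS,
    seed: int = 0,
    config: ThermoConfig | None = None,
) -> ReporterLibrary:
    """Simulate a reporter library under a ground-truth energy table.

    Parameters
    ----------
    n : int
        Number of reporters (>= 1).
    L : int
        Random-region length; must be at least ``table.k``.
    table : KmerEnergyTable
        Ground-truth per-k-mer transfer energies.
    reads : int
        Total reads per reporter (>= 1); upstream reads are
        ``Binomial(reads, p_upstream)``.
    seed : int
        Seed of the single generator from which all draws flow.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if reads < 1:
        raise ValueError(f"reads must be >= 1, got {reads}")
    if L < table.k:
        raise ValueError(f"region length L={L} is shorter than k={table.k}")
    config = config or ThermoConfig(k=table.k)
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n, L), dtype=np.int64)
    wc = window_codes(codes, table.k)
    dg = table.lookup(wc).sum(axis=1)
    p_up = expit(-dg / config.kT)
    reads_up = rng.binomial(reads, p_up)
    params = LibraryParams(
        n_reporters=n,
        region_length=L,
        reads_per_reporter=reads,
        seed=seed,
        k=table.k,
        kT=config.kT,
        table_id=table.checksum(),
    )
    return ReporterLibrary(
        codes, dg, p_up, reads_up, reads - reads_up, params, truth_table=table
    )


def empirical_log_ratio(reporter, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """ln((reads_up + a)/(reads_down + a)) for one reporter or (up, down) pair."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if isinstance(reporter, Reporter):
        up, down = reporter.reads_upstream, reporter.reads_downstream
    else:
        up, down = reporter
    if up < 0 or down < 0:
        raise ValueError("read counts must be non-negative")
    return math.log((up + pseudocount) / (down + pseudocount))


def sparse_benchmark_table(
    k: int = 6,
    n_words: int = 20,
    magnitude: float = 1.0,
    seed: int = 0,
) -> KmerEnergyTable:
    """Sparse ground-truth table for recovery benchmarks.

    Picks ``n_words`` distinct words uniformly at random and assigns half of
    them ``-magnitude`` (speckle-favoring) and half ``+magnitude``
    (nucleoplasm-favoring); all other words are neutral.
    """
    rng = np.random.default_rng(seed)
    n_total = 4**k
    if n_words > n_total:
        raise ValueError(f"cannot pick {n_words} distinct {k}-mers (only {n_total})")
    chosen = rng.choice(n_total, size=n_words, replace=False)
    values = np.zeros(n_total)
    half = n_words // 2
    values[chosen[:half]] = -magnitude
    values[chosen[half:]] = magnitude
    return KmerEnergyTable(k, values)
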