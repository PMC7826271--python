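"""Inference of per-k-mer effect scores from reporter libraries.

The generative model is log-linear: a reporter's log usage ratio is the sum
over its overlapping k-mers of per-word log scores (equivalently, the ratio
is the product of per-word multiplicative scores, and score and transfer
energy are related by ``dG_i = -kT ln s_i``).  Two consistent estimators are
provided:

* **enrichment** — a read-weighted frequency-ratio estimator with additive
  smoothing: each word's score is the ratio of its smoothed relative
  frequency among upstream-assigned reads to that among downstream-assigned
  reads;
* **ridge regression** — penalised least squares of empirical log ratios on
  per-word occurrence counts (no intercept by default: the two-state model
  has no offset when the flanks are fixed).

The public surface follows the statsmodels idiom: build a
:class:`SpliceUsageModel` from a library, call :meth:`~SpliceUsageModel.fit`,
and work with the returned :class:`SpliceUsageResults` (parameters, standard
errors, prediction, evaluation, summary table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .kmer import KmerEnergyTable, all_kmers, encode, window_codes
from .simulate import DEFAULT_PSEUDOCOUNT, ReporterLibrary
from .thermo import ThermoConfig

#: Prior scale (kT) of per-word log scores used by the "auto" ridge penalty:
#: most words are expected to carry effects of a small fraction of kT.
PRIOR_LOG_SCORE_SD = 0.1

__all__ = [
    "ScoreTable",
    "ScoreEvaluation",
    "SpliceUsageModel",
    "SpliceUsageResults",
    "estimate_scores_enrichment",
    "estimate_scores_regression",
    "predict_and_evaluate",
    "train_test_split",
]


@dataclass
class ScoreTable:
    """Complete per-word multiplicative effect scores.

    ``scores[i] > 1`` means word ``i`` enhances upstream usage.  Convertible
    to and from a :class:`KmerEnergyTable` via ``dG_i = -kT ln s_i``.
    """

    k: int
    scores: np.ndarray
    method: str = "unspecified"
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (4**self.k,):
            raise ValueError(
                f"expected {4**self.k} scores for k={self.k}, got {self.scores.shape}"
            )
        if not np.all(np.isfinite(self.scores)) or (self.scores <= 0).any():
            raise ValueError("scores must be strictly positive and finite")

    @property
    def log_scores(self) -> np.ndarray:
        return np.log(self.scores)

    @classmethod
    def from_log_scores(cls, k, log_scores, method="unspecified", pseudocount=None):
        return cls(k, np.exp(np.asarray(log_scores, dtype=np.float64)), method, pseudocount)

    @classmethod
    def from_energy_table(
        cls, table: KmerEnergyTable, kT: float = 1.0, method: str = "truth"
    ) -> "ScoreTable":
        """Exact scores implied by an energy table: s_i = exp(-dG_i/kT)."""
        return cls(table.k, np.exp(-table.values / kT), method=method)

    def to_energy_table(self, kT: float = 1.0) -> KmerEnergyTable:
        return KmerEnergyTable(self.k, -kT * self.log_scores)

    def __getitem__(self, word: str) -> float:
        from .kmer import kmer_code

        return float(self.scores[kmer_code(word, self.k)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"kmer": all_kmers(self.k), "score": self.scores, "log_score": self.log_scores}
        )


@dataclass
class ScoreEvaluation:
    """Predicted-vs-observed log ratios and parameter-recovery metrics.

    All metrics are computed only over the reporters/words passing the
    recorded filters; ``recovery_pearson`` compares inferred log scores to
    ``-dG_i/kT`` of the generating table over words occurring in at least
    ``min_occurrence`` reporters (NaN when no ground truth is attached).
    """

    predicted_log_ratio: np.ndarray
    observed_log_ratio: np.ndarray
    true_log_ratio: np.ndarray | None
    pearson: float
    spearman: float
    rmse: float
    pearson_vs_true: float
    recovery_pearson: float
    recovery_n_words: int
    filters: dict = field(default_factory=dict)

    @property
    def n_reporters(self) -> int:
        return len(self.predicted_log_ratio)

    def header_lines(self) -> list[str]:
        lines = [f"# {key}={value}" for key, value in sorted(self.filters.items())]
        lines += [
            f"# n_reporters={self.n_reporters}",
            f"# pearson={self.pearson:.6f}",
            f"# spearman={self.spearman:.6f}",
            f"# rmse={self.rmse:.6f}",
            f"# pearson_vs_true={self.pearson_vs_true:.6f}",
            f"# recovery_pearson={self.recovery_pearson:.6f}",
            f"# recovery_n_words={self.recovery_n_words}",
        ]
        return lines

    def summary(self) -> str:
        return "\n".join(
            ["Score evaluation", "=" * 16]
            + [line.lstrip("# ") for line in self.header_lines()]
        )


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def _safe_spearman(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def reporters_per_word(window_code_matrix: np.ndarray, n_words: int) -> np.ndarray:
    """Number of reporters containing each word at least once."""
    n = window_code_matrix.shape[0]
    pairs = window_code_matrix + np.arange(n, dtype=np.int64)[:, None] * n_words
    unique = np.unique(pairs)
    return np.bincount(unique % n_words, minlength=n_words)


class SpliceUsageModel:
    """Log-linear splice-site usage model over k-mer occurrence counts.

    Parameters
    ----------
    library : ReporterLibrary
        Observed (or simulated) reporters with read counts.
    k : int, optional
        Word length; defaults to the library's generation k.

    Examples
    --------
    >>> from specklesplice import simulate_library, KmerEnergyTable
    >>> lib = simulate_library(2000, 25, KmerEnergyTable.zeros(6), reads=100, seed=0)
    >>> res = SpliceUsageModel(lib).fit(method="enrichment")
    >>> res.params.shape
    (4096,)
    """

    def __init__(self, library: ReporterLibrary, k: int | None = None) -> None:
        if len(library) == 0:
            raise ValueError("library must be non-empty")
        self.library = library
        self.k = library.params.k if k is None else int(k)
        if self.k > library.region_length:
            raise ValueError(
                f"k={self.k} exceeds region length {library.region_length}"
            )
        self.n_words = 4**self.k
        self._wc = library.window_code_matrix(self.k)

    @property
    def nobs(self) -> int:
        return len(self.library)

    def occurrence_matrix(self) -> sp.csr_matrix:
        """Sparse (n_reporters, 4**k) matrix of overlapping occurrence counts."""
        n, W = self._wc.shape
        rows = np.repeat(np.arange(n, dtype=np.int64), W)
        mat = sp.coo_matrix(
            (np.ones(n * W), (rows, self._wc.ravel())),
            shape=(n, self.n_words),
        )
        return mat.tocsr()

    # -- estimators --------------------------------------------------------
    def _fit_enrichment(self, pseudocount: float):
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        n, W = self._wc.shape
        flat = self._wc.ravel()
        up_w = np.repeat(self.library.reads_upstream.astype(np.float64), W)
        down_w = np.repeat(self.library.reads_downstream.astype(np.float64), W)
        U_i = np.bincount(flat, weights=up_w, minlength=self.n_words)
        D_i = np.bincount(flat, weights=down_w, minlength=self.n_words)
        U, D = U_i.sum(), D_i.sum()
        log_scores = (
            np.log(U_i + pseudocount)
            - np.log(U + pseudocount * self.n_words)
            - np.log(D_i + pseudocount)
            + np.log(D + pseudocount * self.n_words)
        )
        # delta-method SE of the smoothed log frequency ratio
        bse = np.sqrt(1.0 / (U_i + pseudocount) + 1.0 / (D_i + pseudocount))
        return log_scores, bse, {"pseudocount": pseudocount}

    def _fit_regression(
        self,
        ridge,
        pseudocount: float,
        response: str,
        intercept: bool,
    ):
        X = self.occurrence_matrix()
        if response == "empirical":
            y = self.library.empirical_log_ratios(pseudocount)
        elif response == "true":
            y = self.library.true_log_ratios()
        else:
            raise ValueError(f"response must be 'empirical' or 'true', got {response!r}")
        if ridge == "auto":
            # MAP ridge under a Gaussian prior on per-word log scores with a
            # fixed scale PRIOR_LOG_SCORE_SD: lambda = sigma^2 / tau^2, with
            # the response variance as an upper bound on the noise variance.
            ridge = float(np.var(y)) / PRIOR_LOG_SCORE_SD**2
        ridge = float(ridge)
        if ridge < 0:
            raise ValueError("ridge penalty must be >= 0")
        if intercept:
            X = sp.hstack([X, np.ones((self.nobs, 1))]).tocsr()
        xtx = np.asarray((X.T @ X).todense())
        xty = X.T @ y
        if ridge > 0:
            xtx = xtx + ridge * np.eye(xtx.shape[0])
        try:
            beta = np.linalg.solve(xtx, xty)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                "singular occurrence design with ridge=0; the log-linear model "
                "is not identifiable on this library — use a positive ridge "
                "penalty or more reporters"
            ) from err
        intercept_value = float(beta[-1]) if intercept else 0.0
        log_scores = beta[: self.n_words]
        info = {
            "ridge": ridge,
            "pseudocount": pseudocount,
            "response": response,
            "intercept": intercept_value if intercept else None,
        }
        return log_scores, None, info

    def fit(
        self,
        method: str = "enrichment",
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        ridge="auto",
        response: str = "empirical",
        intercept: bool = False,
    ) -> "SpliceUsageResults":
        """Estimate the per-word log scores.

        Parameters
        ----------
        method : {"enrichment", "ridge"}
            Estimator; see the module docstring.
        pseudocount : float
            Additive smoothing for read counts (both estimators use it when
            forming smoothed frequencies / empirical log ratios).
        ridge : float or "auto"
            L2 penalty for the regression estimator (ignored by enrichment).
            ``"auto"`` sets it from the response variance and the fixed prior
            scale :data:`PRIOR_LOG_SCORE_SD`.
        response : {"empirical", "true"}
            Regression response: observed log ratios or the library's true
            log ratios (a noiseless diagnostic mode).
        intercept : bool
            Include a free offset in the regression (misspecification check;
            the model itself has none).
        """
        if method == "enrichment":
            log_scores, bse, info = self._fit_enrichment(pseudocount)
        elif method in ("ridge", "regression"):
            log_scores, bse, info = self._fit_regression(
                ridge, pseudocount, response, intercept
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        return SpliceUsageResults(self, method, log_scores, bse, info)


class SpliceUsageResults:
    """Fitted per-word scores with uncertainties and evaluation utilities."""

    def __init__(self, model, method, log_scores, bse, info) -> None:
        self.model = model
        self.method = method
        self._log_scores = np.asarray(log_scores, dtype=np.float64)
        self._bse = None if bse is None else np.asarray(bse, dtype=np.float64)
        self.info = dict(info)
        self._index = pd.Index(all_kmers(model.k), name="kmer")

    # -- statsmodels-flavored accessors -------------------------------------
    @property
    def params(self) -> pd.Series:
        """Per-word log scores, indexed by k-mer."""
        return pd.Series(self._log_scores, index=self._index, name="log_score")

    @property
    def bse(self) -> pd.Series | None:
        """Delta-method standard errors (enrichment estimator only)."""
        if self._bse is None:
            return None
        return pd.Series(self._bse, index=self._index, name="bse")

    @property
    def tvalues(self) -> pd.Series | None:
        if self._bse is None:
            return None
        return pd.Series(self._log_scores / self._bse, index=self._index, name="z")

    @property
    def score_table(self) -> ScoreTable:
        return ScoreTable.from_log_scores(
            self.model.k,
            self._log_scores,
            method=self.method,
            pseudocount=self.info.get("pseudocount"),
        )

    # -- prediction ---------------------------------------------------------
    def predict(self, regions=None) -> np.ndarray:
        """Predicted log usage ratio: sum of log scores over region windows.

        ``regions`` may be a list of sequences, a :class:`ReporterLibrary`,
        or ``None`` for the training library.
        """
        return predict_log_ratio(
            self.model.library if regions is None else regions,
            self.score_table,
        ) + (self.info.get("intercept") or 0.0)

    def evaluate(
        self,
        library: ReporterLibrary | None = None,
        holdout: float = 0.0,
        min_occurrence: int = 10,
        pseudocount: float | None = None,
        split_seed: int = 0,
    ) -> ScoreEvaluation:
        """Evaluate predictions on a library (the training one by default)."""
        return predict_and_evaluate(
            library if library is not None else self.model.library,
            self.score_table,
            holdout=holdout,
            min_occurrence=min_occurrence,
            pseudocount=pseudocount,
            split_seed=split_seed,
        )

    def summary(self, top: int = 8) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        lines = [
            "Splice-site usage model results",
            "=" * 46,
            f"method:            {self.method}",
            f"k:                 {self.model.k} ({self.model.n_words} words)",
            f"reporters:         {self.model.nobs}",
        ]
        for key, value in sorted(self.info.items()):
            lines.append(f"{key + ':':<19}{value}")
        order = np.argsort(np.abs(self._log_scores))[::-1][:top]
        lines += ["", f"{'kmer':<8}{'score':>10}{'log_score':>12}" + ("" if self._bse is None else f"{'z':>9}")]
        for i in order:
            row = f"{self._index[i]:<8}{np.exp(self._log_scores[i]):>10.4f}{self._log_scores[i]:>12.4f}"
            if self._bse is not None:
                row += f"{self._log_scores[i] / self._bse[i]:>9.2f}"
            lines.append(row)
        return "\n".join(lines)


# -- module-level operation wrappers ---------------------------------------

def estimate_scores_enrichment(
    library: ReporterLibrary,
    k: int | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ScoreTable:
    """Read-weighted enrichment scores (see :class:`SpliceUsageModel`)."""
    return SpliceUsageModel(library, k).fit("enrichment", pseudocount=pseudocount).score_table


def estimate_scores_regression(
    library: ReporterLibrary,
    k: int | None = None,
    ridge="auto",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    response: str = "empirical",
    intercept: bool = False,
) -> ScoreTable:
    """Penalised least-squares scores (see :class:`SpliceUsageModel`)."""
    res = SpliceUsageModel(library, k).fit(
        "ridge", pseudocount=pseudocount, ridge=ridge, response=response, intercept=intercept
    )
    return res.score_table


def predict_log_ratio(regions, scores: ScoreTable) -> np.ndarray:
    """Predicted log usage ratios for sequences under a score table."""
    log_s = scores.log_scores
    if isinstance(regions, ReporterLibrary):
        wc = regions.window_code_matrix(scores.k)
        return log_s[wc].sum(axis=1)
    if isinstance(regions, str):
        regions = [regions]
    out = np.empty(len(regions))
    for i, seq in enumerate(regions):
        wc = window_codes(encode(seq), scores.k)
        out[i] = log_s[wc].sum()
    return out


def train_test_split(
    library: ReporterLibrary, test_fraction: float, seed: int = 0
) -> tuple[ReporterLibrary, ReporterLibrary]:
    """Seeded reporter-level split into (train, test) sub-libraries."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(library)
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    return library.subset(perm[n_test:]), library.subset(perm[:n_test])


def predict_and_evaluate(
    library: ReporterLibrary,
    scores: ScoreTable,
    holdout: float = 0.0,
    min_occurrence: int = 10,
    pseudocount: float | None = None,
    split_seed: int = 0,
) -> ScoreEvaluation:
    """Predict per-reporter log ratios under ``scores`` and score the fit.

    With ``holdout > 0`` metrics are computed on a seeded held-out fraction
    of ``library`` only (note: for genuinely out-of-sample evaluation the
    scores must have been fitted elsewhere, e.g. on the complementary split
    from :func:`train_test_split`).  Recovery metrics against the generating
    table are included when the library carries one, restricted to words
    occurring in at least ``min_occurrence`` reporters.
    """
    if scores.k > library.region_length:
        raise ValueError("score table k exceeds the library's region length")
    if not (0 <= holdout < 1):
        raise ValueError("holdout must be in [0, 1)")
    if pseudocount is None:
        pseudocount = scores.pseudocount or DEFAULT_PSEUDOCOUNT
    if holdout > 0:
        _, eval_lib = train_test_split(library, holdout, seed=split_seed)
    else:
        eval_lib = library
    if len(eval_lib) == 0:
        raise ValueError("no reporters pass the evaluation filters")

    predicted = predict_log_ratio(eval_lib, scores)
    observed = eval_lib.empirical_log_ratios(pseudocount)
    true = eval_lib.true_log_ratios() if np.all(np.isfinite(eval_lib.true_delta_g)) else None

    recovery_pearson, recovery_n = float("nan"), 0
    if library.truth_table is not None and library.truth_table.k == scores.k:
        counts = reporters_per_word(library.window_code_matrix(scores.k), 4**scores.k)
        mask = counts >= min_occurrence
        recovery_n = int(mask.sum())
        if recovery_n >= 2:
            kT = library.params.kT
            recovery_pearson = _safe_pearson(
                scores.log_scores[mask], -library.truth_table.values[mask] / kT
            )

    return ScoreEvaluation(
        predicted_log_ratio=predicted,
        observed_log_ratio=observed,
        true_log_ratio=true,
        pearson=_safe_pearson(predicted, observed),
        spearman=_safe_spearman(predicted, observed),
        rmse=float(np.sqrt(np.mean((predicted - observed) ** 2))),
        pearson_vs_true=float("nan") if true is None else _safe_pearson(predicted, true),
        recovery_pearson=recovery_pearson,
        recovery_n_words=recovery_n,
        filters={
            "holdout": holdout,
            "min_occurrence": min_occurrence,
            "pseudocount": pseudocount,
            "split_seed": split_seed,
            "method": scores.method,
        },
    )
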