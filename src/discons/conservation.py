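"""Column-wise conservation of sequence and of disorder, binned to 0-9.

Sequence conservation follows the Jensen-Shannon divergence scorer of the
Capra & Singh framework: each column's (weighted, pseudocounted) residue
distribution is compared with a background distribution; high divergence
marks a conserved, background-atypical column.  A 1-minus-normalized
Shannon entropy scorer is available as an alternative.  Scores can be gap
penalized and smoothed over a symmetric column window.

Disorder conservation at a column is simply the fraction of sequences whose
residue at that column is predicted disordered (gaps are not residues and
are excluded from the denominator).

Both raw scores live in [0, 1] and are binned to the integer scale 0 (very
diverse) .. 9 (highly conserved) by ``clamp(floor(10 * raw), 0, 9)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _entropy

from .alignment_io import AMINO_ACIDS, GAP, Msa
from .disorder import AlignedDisorderMatrix, _window_sums

log = logging.getLogger(__name__)

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# BLOSUM62-derived amino-acid background frequencies (Henikoff & Henikoff
# alignment-block counts, as shipped with the Capra & Singh scorer);
# renormalized because the printed table sums to 1.002.
_BLOSUM62_RAW = {
    "A": 0.078, "R": 0.051, "N": 0.041, "D": 0.052, "C": 0.024,
    "Q": 0.034, "E": 0.059, "G": 0.083, "H": 0.025, "I": 0.062,
    "L": 0.092, "K": 0.056, "M": 0.024, "F": 0.044, "P": 0.043,
    "S": 0.059, "T": 0.055, "W": 0.014, "Y": 0.034, "V": 0.072,
}
BLOSUM62_BACKGROUND = np.array([_BLOSUM62_RAW[a] for a in AMINO_ACIDS])
BLOSUM62_BACKGROUND = BLOSUM62_BACKGROUND / BLOSUM62_BACKGROUND.sum()
UNIFORM20_BACKGROUND = np.full(20, 1.0 / 20.0)

_BACKGROUNDS = {
    "blosum62_frequencies": BLOSUM62_BACKGROUND,
    "uniform20": UNIFORM20_BACKGROUND,
}


class ScoreValidationError(ValueError):
    """An input to a scoring function violates its contract."""


class UndefinedColumnError(ValueError):
    """A column carries no observed residues (all gaps / all NA)."""


@dataclass(frozen=True)
class ConservationConfig:
    """Parameters of the column-scoring step.

    ``window_size`` is the half-width in columns (the window averages the
    column itself plus ``window_size`` columns on each side, truncated at
    the alignment ends); ``window_weight`` mixes the windowed mean into the
    column's own score.
    """

    method: str = "jsd"  # "jsd" | "shannon_entropy"
    background: str = "blosum62_frequencies"  # or "uniform20"
    lambda_prior: float = 0.5
    pseudocount: float = 1e-7
    gap_penalty: bool = True
    window_size: int = 3
    window_weight: float = 0.5
    sequence_weighting: str = "henikoff"  # or "uniform"

    def __post_init__(self) -> None:
        if self.method not in ("jsd", "shannon_entropy"):
            raise ScoreValidationError(f"unknown method {self.method!r}")
        if self.background not in _BACKGROUNDS:
            raise ScoreValidationError(f"unknown background {self.background!r}")
        if not 0.0 < self.lambda_prior < 1.0:
            raise ScoreValidationError("lambda_prior must be in (0, 1)")
        if self.pseudocount < 0:
            raise ScoreValidationError("pseudocount must be >= 0")
        if self.window_size < 0:
            raise ScoreValidationError("window_size must be >= 0")
        if not 0.0 <= self.window_weight <= 1.0:
            raise ScoreValidationError("window_weight must be in [0, 1]")
        if self.sequence_weighting not in ("henikoff", "uniform"):
            raise ScoreValidationError(
                f"unknown weighting {self.sequence_weighting!r}"
            )

    @property
    def background_vector(self) -> np.ndarray:
        return _BACKGROUNDS[self.background]


@dataclass(frozen=True)
class ColumnScores:
    """Raw and binned conservation pair for one alignment column."""

    column: int  # 1-based
    seq_raw: float
    dis_raw: float
    seq_bin: int
    dis_bin: int
    n_nongap: int


def sequence_weights(msa: Msa, scheme: str = "henikoff") -> np.ndarray:
    """Per-record weights, normalized to sum to 1.

    The Henikoff & Henikoff position-based scheme: at every column each
    distinct symbol receives equal share, split evenly among the sequences
    carrying it; a sequence's weight is its mean share over all columns.
    Gap and 'X' count as ordinary symbols here (they only drop out of the
    residue-distribution estimate, not of the weighting).
    """
    n = len(msa.records)
    if scheme == "uniform":
        return np.full(n, 1.0 / n)
    if scheme != "henikoff":
        raise ScoreValidationError(f"unknown weighting scheme {scheme!r}")
    rows = [seq for _, seq in msa.records]
    contrib = np.zeros(n)
    for col in range(msa.n_columns):
        symbols = [row[col] for row in rows]
        counts: dict[str, int] = {}
        for s in symbols:
            counts[s] = counts.get(s, 0) + 1
        r = len(counts)
        for i, s in enumerate(symbols):
            contrib[i] += 1.0 / (r * counts[s])
    weights = contrib / msa.n_columns
    return weights / weights.sum()


def column_distribution(
    msa: Msa,
    column: int,
    weights: np.ndarray,
    pseudocount: float = 0.0,
) -> np.ndarray | None:
    """Weighted amino-acid distribution of one column (1-based).

    Gaps and 'X' are excluded from the estimate.  Returns ``None`` for an
    undefined column (no observed residues).
    """
    if not 1 <= column <= msa.n_columns:
        raise IndexError(
            f"column {column} out of range 1..{msa.n_columns}"
        )
    counts = np.zeros(20)
    observed = False
    for (_, seq), w in zip(msa.records, weights):
        ch = seq[column - 1]
        if ch == GAP or ch == "X":
            continue
        counts[AA_INDEX[ch]] += w
        observed = True
    if not observed:
        return None
    counts = counts + pseudocount
    return counts / counts.sum()


def jsd_score(
    p: np.ndarray, q: np.ndarray, lambda_prior: float = 0.5
) -> float:
    """Jensen-Shannon divergence between a column distribution and background.

    ``JSD(p, q) = H(lam*p + (1-lam)*q) - lam*H(p) - (1-lam)*H(q)`` with
    entropies in bits; for ``lambda_prior = 0.5`` the value lies in [0, 1]
    and needs no extra normalization.  Higher means more conserved (more
    divergent from the background).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for name, v in (("p", p), ("q", q)):
        if v.ndim != 1 or v.size != 20:
            raise ScoreValidationError(f"{name} must be a 20-vector")
        if np.any(v < 0):
            raise ScoreValidationError(f"{name} has negative entries")
        if abs(float(v.sum()) - 1.0) > 1e-9:
            raise ScoreValidationError(
                f"{name} is not normalized (sum={float(v.sum())!r})"
            )
    if not 0.0 < lambda_prior < 1.0:
        raise ScoreValidationError("lambda_prior must be in (0, 1)")
    lam = lambda_prior
    m = lam * p + (1.0 - lam) * q
    score = float(
        _entropy(m, base=2) - lam * _entropy(p, base=2) - (1.0 - lam) * _entropy(q, base=2)
    )
    return max(score, 0.0)


def shannon_score(p: np.ndarray) -> float:
    """1 - normalized Shannon entropy of a column distribution (in [0, 1])."""
    return max(0.0, 1.0 - float(_entropy(np.asarray(p, dtype=float), base=2)) / math.log2(20))


def apply_gap_penalty_and_window(
    raw_scores: np.ndarray,
    gap_fractions: np.ndarray,
    config: ConservationConfig,
) -> np.ndarray:
    """Gap-penalize and window-smooth per-column scores.

    First ``score *= (1 - gap_fraction)`` if the penalty is enabled, then
    each score is mixed with the mean over ``column +/- window_size``
    (window truncated at the ends, center column included):
    ``(1 - w) * score + w * window_mean``.  Output clamped to [0, 1].
    """
    scores = np.asarray(raw_scores, dtype=float).copy()
    gaps = np.asarray(gap_fractions, dtype=float)
    if scores.shape != gaps.shape:
        raise ScoreValidationError("score and gap-fraction vectors differ in length")
    if config.gap_penalty:
        scores = scores * (1.0 - gaps)
    if config.window_size > 0 and config.window_weight > 0:
        window_mean = _window_sums(scores, config.window_size) / _window_sums(
            np.ones_like(scores), config.window_size
        )
        scores = (1.0 - config.window_weight) * scores + config.window_weight * window_mean
    return np.clip(scores, 0.0, 1.0)


def disorder_conservation(matrix: AlignedDisorderMatrix, column: int) -> float:
    """Fraction of sequences predicted disordered at one column (1-based).

    Gap cells (NA) are excluded from the denominator: a gap is not a
    residue.  Raises :class:`UndefinedColumnError` on an all-NA column.
    """
    if not 1 <= column <= matrix.n_columns:
        raise IndexError(f"column {column} out of range 1..{matrix.n_columns}")
    cells = matrix.values[:, column - 1]
    known = ~np.isnan(cells)
    if not known.any():
        raise UndefinedColumnError(f"column {column} has no non-gap cells")
    return float(cells[known].mean())


def bin_score(raw: float) -> int:
    """Map a raw [0, 1] score onto the printed 0-9 scale: floor by deciles.

    ``clamp(floor(10 * raw), 0, 9)``, so raw = 1.0 maps to 9 and the
    categorical threshold "5 or greater" corresponds to raw >= 0.5.
    """
    if not -1e-9 <= raw <= 1.0 + 1e-9:
        raise ScoreValidationError(f"raw score {raw!r} outside [0, 1]")
    raw = min(max(raw, 0.0), 1.0)
    return min(int(math.floor(10.0 * raw)), 9)


def score_columns(
    msa: Msa,
    matrix: AlignedDisorderMatrix,
    config: ConservationConfig | None = None,
) -> list[ColumnScores]:
    """Score every alignment column for sequence- and disorder conservation.

    Undefined columns (all gaps, or all-'X' for the sequence estimate) are
    assigned raw score 0 with a logged warning rather than aborting the run.
    """
    if config is None:
        config = ConservationConfig()
    weights = sequence_weights(msa, config.sequence_weighting)
    background = config.background_vector
    n_cols = msa.n_columns
    n_rows = len(msa.records)

    seq_raw = np.zeros(n_cols)
    gap_fractions = np.zeros(n_cols)
    n_nongap = np.zeros(n_cols, dtype=int)
    for col in range(1, n_cols + 1):
        chars = [seq[col - 1] for _, seq in msa.records]
        n_obs = sum(1 for c in chars if c != GAP and c != "X")
        n_nongap[col - 1] = sum(1 for c in chars if c != GAP)
        gap_fractions[col - 1] = 1.0 - n_obs / n_rows
        dist = column_distribution(msa, col, weights, config.pseudocount)
        if dist is None:
            log.warning("column %d has no observed residues; sequence score 0", col)
            seq_raw[col - 1] = 0.0
        elif config.method == "jsd":
            seq_raw[col - 1] = jsd_score(dist, background, config.lambda_prior)
        else:
            seq_raw[col - 1] = shannon_score(dist)
    seq_final = apply_gap_penalty_and_window(seq_raw, gap_fractions, config)

    dis_raw = np.zeros(n_cols)
    for col in range(1, n_cols + 1):
        try:
            dis_raw[col - 1] = disorder_conservation(matrix, col)
        except UndefinedColumnError:
            log.warning("column %d is all gaps; disorder conservation 0", col)
            dis_raw[col - 1] = 0.0

    return [
        ColumnScores(
            column=col,
            seq_raw=float(seq_final[col - 1]),
            dis_raw=float(dis_raw[col - 1]),
            seq_bin=bin_score(float(seq_final[col - 1])),
            dis_bin=bin_score(float(dis_raw[col - 1])),
            n_nongap=int(n_nongap[col - 1]),
        )
        for col in range(1, n_cols + 1)
    ]
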