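"""Per-residue disorder tracks and their projection into alignment columns.

Two routes produce a track for each (ungapped) sequence:

* the bundled FoldIndex predictor — Uversky's charge/hydropathy
  unfoldability index evaluated over a sliding window,
  ``2.785*<H> - |<R>| - 1.151``, where ``<H>`` is the mean Kyte-Doolittle
  hydropathy rescaled to [0, 1] and ``<R>`` the mean net charge; a negative
  index predicts an intrinsically unfolded (disordered) segment;
* external predictor output (IUPred / VSL2 / ESpritz style) ingested from
  plain two-column score files on a [0, 1] disorder scale.

Raw scores are reduced to a binary scale (1 = disordered, 0 = ordered):
external scores of 0.5 or greater count as disordered; a FoldIndex value is
disordered iff it is strictly negative.  The binary tracks are then laid
into alignment-column space, with NaN marking gap cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alignment_io import GAP, Msa, coordinate_map

#: Kyte & Doolittle (1982) residue hydropathy values.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: formal side-chain charges at neutral pH; His carries 0 by convention here
RESIDUE_CHARGE: dict[str, float] = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

FOLDINDEX_DEFAULT_WINDOW = 51
EXTERNAL_DISORDER_THRESHOLD = 0.5


def _window_sums(values: np.ndarray, half: int) -> np.ndarray:
    """Sliding sums over ``i - half .. i + half``, truncated at the ends."""
    n = values.size
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return csum[hi] - csum[lo]


class DisorderInputError(ValueError):
    """Malformed disorder input (empty sequence, bad window, bad score file)."""


class CoverageError(DisorderInputError):
    """A score file does not cover every residue exactly once."""


class TrackConsistencyError(ValueError):
    """Track length disagrees with the sequence it is supposed to describe."""


@dataclass(frozen=True)
class DisorderTrack:
    """Raw and binarized per-residue disorder for one ungapped sequence."""

    seq_id: str
    raw: tuple[float, ...]
    binary: tuple[int, ...]
    predictor: str  # "foldindex" | "external"

    def __post_init__(self) -> None:
        if len(self.raw) != len(self.binary):
            raise TrackConsistencyError(
                f"track {self.seq_id!r}: raw length {len(self.raw)} != "
                f"binary length {len(self.binary)}"
            )
        if any(b not in (0, 1) for b in self.binary):
            raise TrackConsistencyError(f"track {self.seq_id!r}: non-binary flag")

    def __len__(self) -> int:
        return len(self.raw)


def foldindex_scores(
    sequence: str, window: int = FOLDINDEX_DEFAULT_WINDOW
) -> np.ndarray:
    """FoldIndex unfoldability profile of an ungapped sequence.

    The window (odd, ``window // 2`` residues each side) is truncated at the
    sequence ends: means are taken over the in-bounds residues only.  'X'
    residues carry no hydropathy or charge and are excluded from the window
    means (the window renormalizes over the known residues).

    Positive values predict folded, negative values intrinsically unfolded.
    """
    if not sequence:
        raise DisorderInputError("empty sequence")
    if window < 1 or window % 2 == 0:
        raise DisorderInputError(f"window must be an odd integer >= 1, got {window}")
    seq = sequence.upper()
    if GAP in seq:
        raise DisorderInputError("foldindex_scores expects an ungapped sequence")
    known = np.array([c != "X" for c in seq], dtype=float)
    hyd = np.array(
        [(KYTE_DOOLITTLE[c] + 4.5) / 9.0 if c != "X" else 0.0 for c in seq]
    )
    chg = np.array([RESIDUE_CHARGE.get(c, 0.0) for c in seq])
    half = window // 2
    n_known = _window_sums(known, half)
    sum_h = _window_sums(hyd * known, half)
    sum_r = _window_sums(chg * known, half)
    denom = np.maximum(n_known, 1.0)
    index = 2.785 * (sum_h / denom) - np.abs(sum_r / denom) - 1.151
    # windows containing no known residue carry no signal; report 0 (ordered)
    return np.where(n_known > 0, index, 0.0)


def binarize(raw: Sequence[float], predictor: str) -> np.ndarray:
    """Reduce raw scores to flags (1 = disordered, 0 = ordered).

    External predictors score disorder on [0, 1]: a residue with score 0.5
    or greater is disordered.  FoldIndex is not on that scale; its published
    decision boundary is the sign, so a residue is disordered iff the index
    is strictly negative (index exactly 0 is ordered).
    """
    arr = np.asarray(raw, dtype=float)
    if arr.size == 0:
        raise DisorderInputError("cannot binarize an empty track")
    if predictor == "foldindex":
        return (arr < 0.0).astype(int)
    if predictor == "external":
        return (arr >= EXTERNAL_DISORDER_THRESHOLD).astype(int)
    raise DisorderInputError(f"unknown predictor {predictor!r}")


def foldindex_track(
    seq_id: str, sequence: str, window: int = FOLDINDEX_DEFAULT_WINDOW
) -> DisorderTrack:
    """Convenience: FoldIndex profile + sign binarization as a track."""
    raw = foldindex_scores(sequence, window=window)
    return DisorderTrack(
        seq_id=seq_id,
        raw=tuple(float(x) for x in raw),
        binary=tuple(int(b) for b in binarize(raw, "foldindex")),
        predictor="foldindex",
    )


def read_disorder_file(
    path: str | Path, seq_id: str, expected_length: int
) -> DisorderTrack:
    """Read an external per-residue disorder score file.

    Format: whitespace- or tab-separated ``residue_index  score`` rows
    (1-based indices), ``#`` comment lines allowed.  The file must cover
    residues 1..expected_length exactly once.
    """
    scores: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise DisorderInputError(
                    f"{path}:{lineno}: expected 'index score', got {line!r}"
                )
            try:
                idx = int(parts[0])
                score = float(parts[1])
            except ValueError as exc:
                raise DisorderInputError(f"{path}:{lineno}: {exc}") from None
            if idx in scores:
                raise CoverageError(f"{path}: duplicate residue index {idx}")
            scores[idx] = score
    missing = [i for i in range(1, expected_length + 1) if i not in scores]
    if missing:
        raise CoverageError(
            f"{path}: missing residue indices {missing[:5]}"
            f"{'...' if len(missing) > 5 else ''}"
        )
    if len(scores) != expected_length:
        raise TrackConsistencyError(
            f"{path}: {len(scores)} scores for sequence {seq_id!r} of "
            f"length {expected_length}"
        )
    raw = tuple(scores[i] for i in range(1, expected_length + 1))
    return DisorderTrack(
        seq_id=seq_id,
        raw=raw,
        binary=tuple(int(b) for b in binarize(raw, "external")),
        predictor="external",
    )


@dataclass(frozen=True)
class AlignedDisorderMatrix:
    """Binary disorder flags laid out on alignment coordinates.

    ``values`` is an (n_records, n_columns) float array with cells in
    {0.0, 1.0, NaN}; NaN marks exactly the gap cells of the alignment.
    Row order matches the alignment record order.
    """

    ids: tuple[str, ...]
    values: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def align_disorder(
    msa: Msa, tracks: Mapping[str, DisorderTrack]
) -> AlignedDisorderMatrix:
    """Project per-sequence binary tracks into alignment-column space."""
    values = np.full((len(msa.records), msa.n_columns), np.nan)
    for row, (seq_id, aligned) in enumerate(msa.records):
        if seq_id not in tracks:
            raise KeyError(f"no disorder track for alignment record {seq_id!r}")
        track = tracks[seq_id]
        ungapped_len = len(aligned) - aligned.count(GAP)
        if len(track) != ungapped_len:
            raise TrackConsistencyError(
                f"track {seq_id!r} has {len(track)} residues; ungapped "
                f"sequence has {ungapped_len}"
            )
        cmap = coordinate_map(msa, seq_id)
        for col, res in cmap.col_to_res.items():
            values[row, col - 1] = track.binary[res - 1]
    return AlignedDisorderMatrix(ids=msa.ids, values=values)
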