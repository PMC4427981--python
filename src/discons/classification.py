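"""Four-category residue classification from paired conservation scores.

Each query residue carries a (sequence, disorder) conservation pair on the
0-9 scale and falls into exactly one category:

* ``S`` (structured): disorder conservation 0 — the position completely
  lacks disorder across the family;
* ``C`` (constrained): both scores 5 or greater — sequence and the
  disordered state are jointly conserved (SLiM/MoRF-like positions);
* ``F`` (flexible): disorder conservation 5 or greater but sequence
  conservation below 5 — disorder as a feature is conserved while the
  underlying sequence drifts (entropic linkers);
* ``N`` (non-conserved): disorder conservation between 1 and 4 — partial,
  non-conserved disorder.

The thresholds 5/5/0 are constants of the method, not configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment_io import Msa, coordinate_map
from .conservation import ColumnScores

CATEGORIES = ("C", "F", "N", "S")


@dataclass(frozen=True)
class ProfileRecord:
    """Classification of a single query residue."""

    query_pos: int  # 1-based position in the ungapped query
    residue: str
    column: int  # 1-based alignment column
    seq_bin: int
    dis_bin: int
    category: str


@dataclass(frozen=True)
class Profile:
    """Per-residue classification of the whole query sequence."""

    query_id: str
    records: tuple[ProfileRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def categories(self) -> str:
        return "".join(r.category for r in self.records)

    @property
    def sequence(self) -> str:
        return "".join(r.residue for r in self.records)


@dataclass(frozen=True)
class CategoryFractions:
    """Fractions of query residues per category; they sum to 1."""

    fraction_C: float
    fraction_F: float
    fraction_N: float
    fraction_S: float
    n_positions: int


@dataclass(frozen=True)
class ConstrainedSegment:
    """A maximal run of consecutive 'C' positions on the query (inclusive)."""

    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start + 1


def classify(seq_bin: int, dis_bin: int) -> str:
    """Category letter for one (sequence, disorder) 0-9 score pair."""
    for name, val in (("seq_bin", seq_bin), ("dis_bin", dis_bin)):
        if not isinstance(val, (int,)) or not 0 <= val <= 9:
            raise ValueError(f"{name} must be an integer in 0..9, got {val!r}")
    if dis_bin == 0:
        return "S"
    if dis_bin >= 5:
        return "C" if seq_bin >= 5 else "F"
    return "N"


def build_profile(msa: Msa, scores: list[ColumnScores]) -> Profile:
    """Project column scores onto the query's ungapped residues.

    Columns gapped in the query produce no record; the profile has exactly
    one record per query residue, in sequence order.
    """
    by_column = {s.column: s for s in scores}
    missing = [c for c in range(1, msa.n_columns + 1) if c not in by_column]
    if missing:
        raise ValueError(f"missing scores for columns {missing[:5]}")
    query = msa.query_id
    ungapped = msa.ungap(query)
    cmap = coordinate_map(msa, query)
    records = []
    for col in sorted(cmap.col_to_res):
        res = cmap.col_to_res[col]
        s = by_column[col]
        records.append(
            ProfileRecord(
                query_pos=res,
                residue=ungapped[res - 1],
                column=col,
                seq_bin=s.seq_bin,
                dis_bin=s.dis_bin,
                category=classify(s.seq_bin, s.dis_bin),
            )
        )
    return Profile(query_id=query, records=tuple(records))


def category_fractions(profile: Profile) -> CategoryFractions:
    """Fraction of query residues in each of the four categories."""
    n = len(profile)
    if n == 0:
        raise ValueError("empty profile")
    counts = {c: 0 for c in CATEGORIES}
    for rec in profile:
        counts[rec.category] += 1
    return CategoryFractions(
        fraction_C=counts["C"] / n,
        fraction_F=counts["F"] / n,
        fraction_N=counts["N"] / n,
        fraction_S=counts["S"] / n,
        n_positions=n,
    )


def constrained_segments(
    profile: Profile, min_length: int = 5
) -> list[ConstrainedSegment]:
    """Maximal runs of consecutive constrained residues of length >= min_length.

    Stretches of constrained disorder are the positions most likely to
    correspond to functional elements such as linear motifs or MoRFs; they
    are reported in query coordinates with their subsequence.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    segments: list[ConstrainedSegment] = []
    run_start: int | None = None
    run_seq: list[str] = []

    def flush(end_pos: int) -> None:
        nonlocal run_start, run_seq
        if run_start is not None and end_pos - run_start + 1 >= min_length:
            segments.append(
                ConstrainedSegment(
                    start=run_start, end=end_pos, sequence="".join(run_seq)
                )
            )
        run_start = None
        run_seq = []

    prev_pos = None
    for rec in profile:
        if rec.category == "C":
            if run_start is None:
                run_start = rec.query_pos
            run_seq.append(rec.residue)
        else:
            if prev_pos is not None:
                flush(prev_pos)
            run_start = None
            run_seq = []
        prev_pos = rec.query_pos
    if prev_pos is not None:
        flush(prev_pos)
    return segments
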