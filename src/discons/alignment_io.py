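"""Aligned-FASTA input/output and column <-> residue coordinate bookkeeping.

The multiple sequence alignment (MSA) is the coordinate frame for every
downstream score: conservation is computed per alignment column, while the
final profile is reported per residue of one designated *query* row.  This
module owns the validated :class:`Msa` container and the bijection between
alignment columns and ungapped residue positions.

All user-facing coordinates are 1-based and inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: legal alignment characters: the 20 standard residues, 'X', and the gap
LEGAL_CHARS = frozenset(AMINO_ACIDS) | {"X", GAP}


class MsaValidationError(ValueError):
    """The alignment violates a structural invariant (ragged rows, bad characters, ...)."""


class UnknownSequenceError(KeyError):
    """A sequence identifier does not occur in the alignment."""


@dataclass(frozen=True)
class Msa:
    """A validated multiple sequence alignment with one designated query row.

    ``records`` is an ordered tuple of ``(identifier, aligned_sequence)``
    pairs; ``query_index`` addresses the query row.  Construct through
    :meth:`from_records` (or :func:`read_msa`) so the invariants hold.
    """

    records: tuple[tuple[str, str], ...]
    query_index: int

    @classmethod
    def from_records(
        cls,
        records: list[tuple[str, str]] | tuple[tuple[str, str], ...],
        query_id: str | None = None,
    ) -> "Msa":
        records = tuple((str(i), str(s)) for i, s in records)
        if len(records) < 2:
            raise MsaValidationError(
                f"alignment has {len(records)} record(s); conservation over "
                "fewer than 2 sequences is undefined"
            )
        ids = [i for i, _ in records]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise MsaValidationError(f"duplicate sequence identifier {i!r}")
            seen.add(i)
        n_cols = len(records[0][1])
        for ident, seq in records:
            if len(seq) != n_cols:
                raise MsaValidationError(
                    f"ragged alignment: record {ident!r} has length "
                    f"{len(seq)}, expected {n_cols}"
                )
            for pos, ch in enumerate(seq, start=1):
                if ch not in LEGAL_CHARS:
                    raise MsaValidationError(
                        f"illegal character {ch!r} in record {ident!r} "
                        f"at column {pos}"
                    )
        if n_cols < 1:
            raise MsaValidationError("alignment has zero columns")
        if query_id is None:
            q_index = 0
            log.info("no query id given; defaulting to first record %r", ids[0])
        else:
            try:
                q_index = ids.index(query_id)
            except ValueError:
                raise UnknownSequenceError(
                    f"query id {query_id!r} not found in alignment"
                ) from None
        msa = cls(records=records, query_index=q_index)
        if not msa.ungap(msa.query_id):
            raise MsaValidationError(
                f"query {msa.query_id!r} is all gaps (empty ungapped sequence)"
            )
        return msa

    # -- accessors ---------------------------------------------------------

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.records)

    @property
    def query_id(self) -> str:
        return self.records[self.query_index][0]

    def index_of(self, seq_id: str) -> int:
        for k, (ident, _) in enumerate(self.records):
            if ident == seq_id:
                return k
        raise UnknownSequenceError(f"sequence id {seq_id!r} not in alignment")

    def aligned(self, seq_id: str) -> str:
        """The aligned (gapped) row for ``seq_id``."""
        return self.records[self.index_of(seq_id)][1]

    def ungap(self, seq_id: str) -> str:
        """The row for ``seq_id`` with all gap characters removed."""
        return self.aligned(seq_id).replace(GAP, "")


@dataclass(frozen=True)
class CoordinateMap:
    """Bijection between alignment columns and ungapped residue positions.

    Both directions are 1-based; ``col_to_res`` is defined exactly on the
    non-gap columns of the sequence.
    """

    seq_id: str
    col_to_res: Mapping[int, int] = field(repr=False)
    res_to_col: Mapping[int, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.col_to_res)


def coordinate_map(msa: Msa, seq_id: str) -> CoordinateMap:
    """Column <-> residue mapping for one sequence of the alignment."""
    aligned = msa.aligned(seq_id)
    col_to_res: dict[int, int] = {}
    res = 0
    for col, ch in enumerate(aligned, start=1):
        if ch != GAP:
            res += 1
            col_to_res[col] = res
    res_to_col = {r: c for c, r in col_to_res.items()}
    return CoordinateMap(seq_id=seq_id, col_to_res=col_to_res, res_to_col=res_to_col)


def ungap(msa: Msa, seq_id: str) -> str:
    """Ungapped sequence for ``seq_id`` (predictors run on this, never on rows)."""
    return msa.ungap(seq_id)


def read_msa(path: str | Path, query_id: str | None = None) -> Msa:
    """Read an aligned-FASTA file into a validated :class:`Msa`.

    Sequences are upper-cased on ingest and '.' gaps are converted to '-'
    (with a logged warning).  ``query_id=None`` selects the first record.
    """
    records: list[tuple[str, str]] = []
    dotted = False
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "." in seq:
            dotted = True
            seq = seq.replace(".", GAP)
        records.append((rec.id, seq))
    if dotted:
        log.warning("converted '.' gap characters to '-' while reading %s", path)
    if not records:
        raise MsaValidationError(f"no FASTA records found in {path}")
    return Msa.from_records(records, query_id=query_id)


def write_msa(msa: Msa, path: str | Path) -> None:
    """Write the alignment as aligned FASTA (wrapped at 60 columns)."""
    seq_records = [
        SeqRecord(Seq(seq), id=ident, description="") for ident, seq in msa.records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
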