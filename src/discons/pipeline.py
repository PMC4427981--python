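"""End-to-end run orchestration plus text writers/readers for all outputs.

The core pipeline is deterministic: identical inputs and configuration
produce byte-identical output files.  Outputs follow the prefix convention
``{prefix}.profile.tsv``, ``{prefix}.fractions.tsv`` and
``{prefix}.constrained.fasta``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import alignment_io, classification, conservation, disorder
from .alignment_io import Msa
from .classification import (
    CategoryFractions,
    ConstrainedSegment,
    Profile,
    ProfileRecord,
)
from .conservation import ColumnScores, ConservationConfig

log = logging.getLogger(__name__)

PROFILE_HEADER = ("query_pos", "residue", "column", "seq_bin", "dis_bin", "category")


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    msa_path: str
    query_id: str | None = None
    predictor: str = "foldindex"  # "foldindex" | "external"
    disorder_manifest: str | None = None
    foldindex_window: int = disorder.FOLDINDEX_DEFAULT_WINDOW
    conservation: ConservationConfig = field(default_factory=ConservationConfig)
    min_length: int = 5
    out_prefix: str | None = None

    def __post_init__(self) -> None:
        if self.predictor not in ("foldindex", "external"):
            raise ValueError(f"unknown predictor {self.predictor!r}")
        if self.predictor == "external" and not self.disorder_manifest:
            raise ValueError(
                "predictor 'external' requires a disorder-score manifest"
            )
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class PipelineResult:
    msa: Msa
    column_scores: list[ColumnScores]
    profile: Profile
    fractions: CategoryFractions
    segments: list[ConstrainedSegment]


def _load_tracks(config: RunConfig, msa: Msa) -> dict[str, disorder.DisorderTrack]:
    tracks: dict[str, disorder.DisorderTrack] = {}
    if config.predictor == "foldindex":
        for seq_id in msa.ids:
            tracks[seq_id] = disorder.foldindex_track(
                seq_id, msa.ungap(seq_id), window=config.foldindex_window
            )
        return tracks
    with open(config.disorder_manifest) as fh:
        manifest = yaml.safe_load(fh) or {}
    if not isinstance(manifest, dict):
        raise ValueError("disorder manifest must map seq_id -> score-file path")
    base = Path(config.disorder_manifest).parent
    missing = [i for i in msa.ids if i not in manifest]
    if missing:
        raise ValueError(f"manifest lacks score files for records {missing}")
    for seq_id in msa.ids:
        score_path = Path(manifest[seq_id])
        if not score_path.is_absolute():
            score_path = base / score_path
        tracks[seq_id] = disorder.read_disorder_file(
            score_path, seq_id, expected_length=len(msa.ungap(seq_id))
        )
    return tracks


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute alignment -> disorder -> conservation -> classification.

    Writes profile/fractions/segment files when ``out_prefix`` is set and
    returns the in-memory results either way.  Errors are re-raised as
    :class:`PipelineError` tagged with the failing stage.
    """
    cc = config.conservation
    log.info(
        "run settings: predictor=%s foldindex_window=%d method=%s "
        "background=%s lambda=%g pseudocount=%g gap_penalty=%s "
        "window_size=%d window_weight=%g weighting=%s min_length=%d "
        "binning=floor(10*raw) thresholds C/F>=5, S==0",
        config.predictor, config.foldindex_window, cc.method, cc.background,
        cc.lambda_prior, cc.pseudocount, cc.gap_penalty, cc.window_size,
        cc.window_weight, cc.sequence_weighting, config.min_length,
    )
    try:
        msa = alignment_io.read_msa(config.msa_path, query_id=config.query_id)
    except Exception as exc:
        raise PipelineError("alignment_io", exc) from exc
    try:
        tracks = _load_tracks(config, msa)
        matrix = disorder.align_disorder(msa, tracks)
    except Exception as exc:
        raise PipelineError("disorder_profiles", exc) from exc
    try:
        scores = conservation.score_columns(msa, matrix, cc)
    except Exception as exc:
        raise PipelineError("conservation", exc) from exc
    try:
        profile = classification.build_profile(msa, scores)
        fractions = classification.category_fractions(profile)
        segments = classification.constrained_segments(
            profile, min_length=config.min_length
        )
    except Exception as exc:
        raise PipelineError("classification", exc) from exc

    if config.out_prefix:
        try:
            prefix = Path(config.out_prefix)
            prefix.parent.mkdir(parents=True, exist_ok=True)
            write_profile(profile, f"{prefix}.profile.tsv")
            write_fractions(fractions, f"{prefix}.fractions.tsv")
            write_segments_fasta(
                segments, profile.query_id, f"{prefix}.constrained.fasta"
            )
        except Exception as exc:
            raise PipelineError("cli_outputs", exc) from exc
    return PipelineResult(
        msa=msa,
        column_scores=scores,
        profile=profile,
        fractions=fractions,
        segments=segments,
    )


# -- writers / readers -----------------------------------------------------


def write_profile(profile: Profile, path: str | Path) -> None:
    """Tab-separated profile: one row per query residue, with header."""
    with open(path, "w") as fh:
        fh.write("\t".join(PROFILE_HEADER) + "\n")
        for rec in profile:
            fh.write(
                f"{rec.query_pos}\t{rec.residue}\t{rec.column}\t"
                f"{rec.seq_bin}\t{rec.dis_bin}\t{rec.category}\n"
            )


def read_profile(path: str | Path, query_id: str = "query") -> Profile:
    """Read a profile TSV back into a :class:`Profile`."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PROFILE_HEADER:
            raise ValueError(f"{path}: unexpected profile header {header}")
        for line in fh:
            pos, res, col, sb, db, cat = line.rstrip("\n").split("\t")
            records.append(
                ProfileRecord(
                    query_pos=int(pos),
                    residue=res,
                    column=int(col),
                    seq_bin=int(sb),
                    dis_bin=int(db),
                    category=cat,
                )
            )
    return Profile(query_id=query_id, records=tuple(records))


def write_fractions(fractions: CategoryFractions, path: str | Path) -> None:
    """Two-column key/value table: four category fractions plus n_positions."""
    with open(path, "w") as fh:
        fh.write(f"fraction_C\t{fractions.fraction_C:.6f}\n")
        fh.write(f"fraction_F\t{fractions.fraction_F:.6f}\n")
        fh.write(f"fraction_N\t{fractions.fraction_N:.6f}\n")
        fh.write(f"fraction_S\t{fractions.fraction_S:.6f}\n")
        fh.write(f"n_positions\t{fractions.n_positions}\n")


def read_fractions(path: str | Path) -> CategoryFractions:
    values: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            key, val = line.rstrip("\n").split("\t")
            values[key] = val
    return CategoryFractions(
        fraction_C=float(values["fraction_C"]),
        fraction_F=float(values["fraction_F"]),
        fraction_N=float(values["fraction_N"]),
        fraction_S=float(values["fraction_S"]),
        n_positions=int(values["n_positions"]),
    )


def write_segments_fasta(
    segments: list[ConstrainedSegment], query_id: str, path: str | Path
) -> None:
    """Constrained segments as FASTA, headers ``{id}|constrained|{start}-{end}``."""
    records = [
        SeqRecord(
            Seq(seg.sequence),
            id=f"{query_id}|constrained|{seg.start}-{seg.end}",
            description="",
        )
        for seg in segments
    ]
    SeqIO.write(records, str(path), "fasta")


def read_segments_fasta(path: str | Path) -> list[ConstrainedSegment]:
    segments = []
    for rec in SeqIO.parse(str(path), "fasta"):
        *_, span = rec.id.split("|")
        start, end = span.split("-")
        segments.append(
            ConstrainedSegment(
                start=int(start), end=int(end), sequence=str(rec.seq)
            )
        )
    return segments
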