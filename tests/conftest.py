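import logging

import pytest

from discons import Msa, align_disorder, build_profile, score_columns
from discons.disorder import foldindex_track
from discons.fixtures import default_plan, generate_family

logging.getLogger("discons").setLevel(logging.ERROR)


@pytest.fixture
def toy_msa():
    """Four ungapped rows with one variable column."""
    return Msa.from_records(
        [("s1", "AAEE"), ("s2", "AAEE"), ("s3", "AAEE"), ("s4", "ACEE")]
    )


@pytest.fixture
def gapped_msa():
    return Msa.from_records(
        [("q", "A-CD"), ("h1", "AEC-"), ("h2", "-ECD")], query_id="q"
    )


@pytest.fixture(scope="session")
def family_seed7():
    """A full synthetic family plus its truth labels (seed 7)."""
    return generate_family(default_plan(seed=7))


def run_foldindex_pipeline(msa, config=None):
    """Shared in-memory pipeline: FoldIndex tracks -> scores -> profile."""
    tracks = {i: foldindex_track(i, msa.ungap(i)) for i in msa.ids}
    matrix = align_disorder(msa, tracks)
    scores = score_columns(msa, matrix, config)
    return matrix, scores, build_profile(msa, scores)


@pytest.fixture(scope="session")
def family_seed7_profile(family_seed7):
    msa, _ = family_seed7
    return run_foldindex_pipeline(msa)
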