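"""Deterministic synthetic homolog families with planted regional truth.

The generator builds an ancestor sequence from a region plan, then samples
descendant rows by per-region substitution, producing an alignment in which
every query position has a known true label:

* ``structured`` — hydrophobic composition, low substitution rate: every
  family member is predicted folded; columns have zero disorder
  conservation;
* ``constrained`` — disorder-promoting (charged, low-hydropathy)
  composition, very low substitution rate: disorder and sequence are both
  conserved;
* ``flexible`` — a broad disorder-promoting composition (basic residues
  carrying the net charge) with a high substitution rate confined to that
  alphabet: disorder is conserved while the sequence drifts;
* ``nonconserved`` — a fixed minority of family members keeps the
  disorder-promoting composition while the rest are substituted toward the
  hydrophobic alphabet, so the column disorder fraction lands strictly
  between 0 and 0.5.

Compositions are weighted so that pure disorder-promoting and pure
hydrophobic windows sit at comparable FoldIndex magnitudes on either side
of zero.  With the long smoothing window the predicted order/disorder
transition then falls on the planted region boundary instead of several
residues inside one of the regions, which is what makes the planted
architecture recoverable end to end.

The query row is the unmutated ancestor, so truth labels map 1:1 onto
query positions even when descendants carry deletions.  All randomness
flows from the single plan seed through one NumPy generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment_io import Msa
from .disorder import FOLDINDEX_DEFAULT_WINDOW

log = logging.getLogger(__name__)

REGION_LABELS = ("constrained", "flexible", "nonconserved", "structured")

#: truth label -> expected profile category letter
LABEL_TO_CATEGORY = {
    "constrained": "C",
    "flexible": "F",
    "nonconserved": "N",
    "structured": "S",
}

# Compositions are chosen so that pure windows of the three flavors sit at
# FoldIndex ~ +1.02 (structured), ~ -1.45 (constrained, acid-heavy) and
# ~ -1.05 (flexible, diverse); comparable magnitudes put the window-smoothed
# order/disorder crossing essentially on the region boundary itself, which
# is what keeps the planted architecture recoverable despite the long
# smoothing window.

#: concentrated acid-heavy composition (net charge ~ -0.7 per residue);
#: used for constrained regions and for nonconserved disorder-keepers
DISORDER_ALPHABET = "EDKRSPQ"
DISORDER_WEIGHTS = np.array([0.50, 0.25, 0.02, 0.02, 0.09, 0.06, 0.06])

# Diverse disorder-promoting composition for flexible linkers: as close to
# the BLOSUM background as the FoldIndex constraint allows (basic residues
# carry the charge), so variable columns score low against it while every
# family member stays predicted disordered.
FLEXIBLE_ALPHABET = "EDKRSPQGTNAH"
FLEXIBLE_WEIGHTS = np.array(
    [0.05, 0.05, 0.22, 0.26, 0.06, 0.05, 0.05, 0.07, 0.05, 0.06, 0.05, 0.03]
)

#: hydrophobic alphabet for structured regions (Ala-rich to moderate the
#: hydropathy so boundary windows are not dragged toward order)
ORDER_ALPHABET = "ILVFAW"
ORDER_WEIGHTS = np.array([0.12, 0.15, 0.12, 0.08, 0.43, 0.10])

DEFAULT_MUTATION_RATES = {
    "constrained": 0.02,
    "flexible": 0.9,
    "nonconserved": 0.5,
    "structured": 0.05,
}

#: fraction of family members that keep disorder in nonconserved regions
DISORDER_KEEP_FRACTION = 0.3
#: substitution rate toward the hydrophobic alphabet for the converted rows
NONCONSERVED_CONVERT_RATE = 0.75


@dataclass(frozen=True)
class RegionPlan:
    """Blueprint of a synthetic family: regions, rates, family size, seed."""

    regions: tuple[tuple[str, int], ...]
    n_sequences: int = 20
    mutation_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_RATES)
    )
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("plan needs at least one region")
        for label, length in self.regions:
            if label not in REGION_LABELS:
                raise ValueError(f"unknown region label {label!r}")
            if length < 1:
                raise ValueError(f"region length must be >= 1, got {length}")
        if self.n_sequences < 2:
            raise ValueError("a family needs at least 2 sequences")
        for label, rate in self.mutation_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"mutation rate for {label!r} outside [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate outside [0, 1]")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.regions)


def default_plan(seed: int = 1, n_sequences: int = 20) -> RegionPlan:
    """The standard 4-region recovery plan: S(60) C(20) F(40) S(60)."""
    return RegionPlan(
        regions=(
            ("structured", 60),
            ("constrained", 20),
            ("flexible", 40),
            ("structured", 60),
        ),
        n_sequences=n_sequences,
        seed=seed,
    )


def nonconserved_plan(seed: int = 1, n_sequences: int = 20) -> RegionPlan:
    """A 3-region plan exercising partial disorder: S(60) N(40) S(60)."""
    return RegionPlan(
        regions=(
            ("structured", 60),
            ("nonconserved", 40),
            ("structured", 60),
        ),
        n_sequences=n_sequences,
        seed=seed,
    )


def _draw(rng: np.random.Generator, alphabet: str, weights: np.ndarray, size: int):
    return rng.choice(list(alphabet), size=size, p=weights / weights.sum())


def _substitute(
    rng: np.random.Generator, current: str, alphabet: str, weights: np.ndarray
) -> str:
    """Draw a replacement residue different from ``current`` when possible."""
    letters = list(alphabet)
    if current in letters:
        w = weights.astype(float).copy()
        w[letters.index(current)] = 0.0
        return str(rng.choice(letters, p=w / w.sum()))
    return str(rng.choice(letters, p=weights / weights.sum()))


def _region_alphabet(label: str) -> tuple[str, np.ndarray]:
    if label == "structured":
        return ORDER_ALPHABET, ORDER_WEIGHTS
    if label == "flexible":
        return FLEXIBLE_ALPHABET, FLEXIBLE_WEIGHTS
    return DISORDER_ALPHABET, DISORDER_WEIGHTS


def generate_family(plan: RegionPlan) -> tuple[Msa, tuple[str, ...]]:
    """Sample a synthetic homolog family and its per-position truth labels.

    Returns a validated :class:`Msa` whose first record ``Q1`` is the
    (unmutated) ancestor query, plus one truth label per query position.
    """
    rng = np.random.default_rng(plan.seed)
    short = [
        (label, length)
        for label, length in plan.regions
        if label != "structured" and length < FOLDINDEX_DEFAULT_WINDOW
    ]
    if short:
        log.warning(
            "region(s) %s are shorter than the FoldIndex smoothing window "
            "(%d); planted labels near their boundaries may not be fully "
            "recoverable",
            short,
            FOLDINDEX_DEFAULT_WINDOW,
        )

    # ancestor and truth
    ancestor: list[str] = []
    truth: list[str] = []
    for label, length in plan.regions:
        alphabet, weights = _region_alphabet(label)
        ancestor.extend(_draw(rng, alphabet, weights, length))
        truth.extend([label] * length)

    n_desc = plan.n_sequences - 1
    # which descendants keep disorder inside nonconserved regions: a fixed
    # count so the column disorder fraction is stable across seeds.  The
    # query is always a keeper (it is the unmutated ancestor).
    n_keep_total = max(1, round(DISORDER_KEEP_FRACTION * plan.n_sequences))
    keep_desc = set(
        rng.choice(n_desc, size=max(0, n_keep_total - 1), replace=False).tolist()
    ) if n_desc > 0 else set()

    rows: list[tuple[str, str]] = [("Q1", "".join(ancestor))]
    for d in range(n_desc):
        row = list(ancestor)
        offset = 0
        for label, length in plan.regions:
            rate = plan.mutation_rates.get(label, DEFAULT_MUTATION_RATES[label])
            alphabet, weights = _region_alphabet(label)
            if label == "nonconserved" and d not in keep_desc:
                alphabet, weights = ORDER_ALPHABET, ORDER_WEIGHTS
                rate = NONCONSERVED_CONVERT_RATE
            hit = rng.random(length) < rate
            for pos in np.nonzero(hit)[0]:
                row[offset + pos] = _substitute(
                    rng, row[offset + pos], alphabet, weights
                )
            if plan.indel_rate > 0 and label != "structured":
                gaps = rng.random(length) < plan.indel_rate
                for pos in np.nonzero(gaps)[0]:
                    row[offset + pos] = "-"
            offset += length
        rows.append((f"H{d + 2:02d}", "".join(row)))

    msa = Msa.from_records(rows, query_id="Q1")
    return msa, tuple(truth)
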