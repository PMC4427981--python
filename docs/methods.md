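# Methods

## Pipeline

The unit of analysis is an alignment column. The pipeline runs four
stages: alignment ingestion and validation → per-sequence disorder
prediction and binarization → column scoring (sequence and disorder
conservation, binned 0–9) → per-query-residue classification and export.
Everything downstream of the alignment is deterministic; identical inputs
and configuration give byte-identical output files.

Coordinates are 1-based and inclusive everywhere user-facing. The gap
character is `-`; `.` is converted on ingest with a warning. Legal residue
letters are the 20 standard amino acids plus `X`. `X` has no defined
hydropathy, charge or substitution statistics, so it is excluded from
disorder window means (the window renormalizes over known residues) and
from column residue distributions (it behaves like a gap for scoring).

## Disorder prediction and binarization

The bundled predictor is the charge/hydropathy unfoldability index
`I = 2.785·⟨H⟩ − |⟨R⟩| − 1.151`, with `⟨H⟩` the window mean of
Kyte–Doolittle hydropathy rescaled by `(KD + 4.5)/9` and `⟨R⟩` the window
mean of formal side-chain charge (K, R = +1; D, E = −1; His = 0; terminal
charges ignored). The default window is 51 residues (odd; half-window 25
each side), truncated at sequence ends — a long smoothing window is the
standard choice for charge/hydropathy profiles, which detect regional
rather than per-residue disorder. Predictors always run on ungapped
sequences: a gap is an alignment artifact, not a residue.

Binarization: a FoldIndex value is disordered iff strictly negative (the
sign is the published decision boundary; an index of exactly 0 counts as
ordered). External predictors on a [0,1] disorder scale use the inclusive
threshold: disordered iff score ≥ 0.5. External scores are ingested from
plain two-column files (`residue_index score`, `#` comments), one file per
sequence, routed by a YAML manifest; the file must cover each residue
exactly once.

## Column scoring

**Sequence conservation** follows the Jensen–Shannon divergence scorer of
the Capra & Singh conservation framework. Defaults (all overridable by
config file or CLI flag, and logged at run time):

| parameter | default | meaning |
|---|---|---|
| method | `jsd` | `shannon_entropy` (1 − normalized entropy) available |
| background | BLOSUM62 frequencies | `uniform20` for testing |
| λ (mixture prior) | 0.5 | with log₂ entropies, bounds JSD by 1 |
| pseudocount | 1e-7 | breaks zero-entropy degeneracy invisibly |
| gap penalty | on | `s ← s·(1 − gap fraction)` |
| window half-width | 3 columns | smoothing `s ← 0.5·s + 0.5·mean(s±3)` |
| window weight | 0.5 | mix of own vs windowed score |
| sequence weighting | Henikoff | position-based; `uniform` available |

Henikoff weighting treats `-` and `X` as ordinary column symbols (they
drop out only of the residue-distribution estimate); per column each
distinct symbol's unit share is split among its carriers, and a sequence's
weight is its mean share over columns, normalized to sum to 1. The gap
penalty is applied before window smoothing; the smoothed score is clamped
to [0, 1].

**Disorder conservation** of a column is the fraction of sequences whose
residue at the column is flagged disordered. Gaps are excluded from the
denominator — the score asks "of the residues actually present, how many
are disordered". A config flag can instead count gaps as ordered.

**Binning.** Raw scores map to the 0–9 scale by `clamp(⌊10·raw⌋, 0, 9)`
(floor by deciles), so raw = 1.0 bins to 9 and the categorical threshold
"bin ≥ 5" corresponds exactly to raw ≥ 0.5, mirroring the 0.5 disorder
threshold. Degenerate columns (all gaps, or no observed residues) are
scored 0 with a logged warning rather than aborting a run, which keeps
ragged homolog families usable.

## Classification and export

Category is a pure function of the binned pair: disorder bin 0 → `S`;
disorder bin ≥ 5 → `C` if sequence bin ≥ 5 else `F`; disorder bin 1–4 →
`N`. The thresholds are constants of the method, not configuration. The
profile reports one record per query residue (columns gapped in the query
are invisible). Constrained segments are maximal runs of `C` with length
≥ 5 by default — the smallest stratum in which consecutive constrained
stretches are typically interpreted — exported as FASTA with headers
`{query_id}|constrained|{start}-{end}`.

## Synthetic families

The fixture generator plants a known regional architecture so the whole
pipeline (not a mock) can be tested end to end. An ancestor sequence is
drawn region by region from weighted alphabets; descendants substitute
residues per region at label-specific rates (a substitution always draws
a different residue). The query row is the unmutated ancestor, so truth
labels map 1:1 to query positions; optional indels (deletions only) are
confined to non-structured regions.

Compositions are the load-bearing design choice. Because the 51-residue
disorder window averages across region boundaries, the predicted
order/disorder transition sits where the window's mixture crosses the
index zero; the alphabets are weighted so pure regional windows sit at
comparable index magnitudes on both sides of zero (structured ≈ +1.0,
constrained ≈ −1.45, flexible ≈ −1.05), which pins that crossing to the
planted boundary itself:

- **structured**: hydrophobic `{I,L,V,F,A,W}`, Ala-rich, substitution
  rate 0.05 — folded everywhere, disorder fraction 0;
- **constrained**: concentrated acid-heavy `{E,D,K,R,S,P,Q}` (net charge
  ≈ −0.7/residue), rate 0.02 — both signals conserved;
- **flexible**: a broad disorder-promoting composition over
  `{E,D,K,R,S,P,Q,G,T,N,A,H}` with basic residues carrying the charge,
  chosen by constrained optimization to lie as close to the BLOSUM62
  background as the disorder-index constraint allows; substitution rate
  0.9 confined to that alphabet. The high rate is deliberate: with a
  20-sequence family, finite-sample inflation of column JSD means a column
  in which half the members still carry the ancestral residue scores
  ≈ 0.55 — above the constrained threshold — whatever the composition;
  linker-like columns must be close to exchangeable to be diverse *as
  measured*;
- **nonconserved**: a fixed ≈ 30% of family members keep the acid-heavy
  disordered composition (rate 0.5) while the rest are substituted toward
  the hydrophobic alphabet (rate 0.75), so the column disorder fraction
  lands near 0.3 — partial, non-conserved disorder. The per-sequence
  (rather than per-residue) split is what makes the fraction land strictly
  inside (0.1, 0.5) despite the long smoothing window.

The default recovery plan is 20 sequences over
structured(60)–constrained(20)–flexible(40)–structured(60); a second
3-region plan structured(60)–nonconserved(40)–structured(60) exercises
partial disorder. These sizes keep every test and the acceptance script
comfortably small while leaving each region longer than the score-smoothing
window; the disordered regions are still shorter than the 51-residue
disorder window, which the generator warns about and which shows up as
1–3 residues of boundary blur in recovered segments.

What the generator does *not* emulate: phylogenetic structure (descendants
are iid draws from the ancestor, not a tree), insertion columns, alignment
error, and predictor disagreement. Passing recovery tests therefore shows
that the scoring and classification machinery is correct under the planted
regimes, not that any particular real protein family will be classified
correctly — on real data the alignment quality dominates.

## Numerical choices and edge cases

- Entropies in bits with λ = 0.5 keep JSD in [0, 1] without extra
  normalization; tiny negative rounding is clipped to 0.
- Distribution inputs to the JSD scorer must sum to 1 within 1e-9.
- Raw scores outside [0, 1] by more than 1e-9 are rejected; within that
  tolerance they are clamped before binning.
- Sliding windows (disorder and column smoothing) are computed with
  cumulative sums and truncated means, so windows wider than the sequence
  or alignment degrade gracefully to global means.
- Windows consisting entirely of `X` yield index 0 (ordered) — no signal,
  no disorder claim.
- An all-gap query is rejected at validation; all-gap columns score 0 with
  a warning; duplicate sequence identifiers are rejected rather than
  silently merged.

## Scope

The tool starts from a user-supplied alignment ("from alignment"
operation). Homolog search and alignment construction (BLAST/MAFFT) are
upstream concerns left to the user, as is running external disorder
predictors; their per-residue output is ingested as files. Reported
category fractions and segments describe the designated query only.
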