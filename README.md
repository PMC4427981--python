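# discons

Classify every residue of a query protein by the *joint* evolutionary
conservation of its amino-acid sequence and of its predicted intrinsic
disorder across a family of homologs.

## The problem

Intrinsically disordered regions (IDRs) often evolve quickly at the
sequence level, so a conventional conservation analysis misses them even
when the *property* of being disordered is strongly maintained — as it is
in entropic linkers — or when a short, binding-competent element (a SLiM or
MoRF) keeps both its sequence and its disorder. Scoring the two signals
per alignment column and combining them separates these regimes.

Given a multiple sequence alignment (MSA) with a designated query row:

1. **Disorder conservation.** A per-residue disorder predictor is run on
   every ungapped sequence (the bundled predictor is the charge/hydropathy
   unfoldability index `I = 2.785·⟨H⟩ − |⟨R⟩| − 1.151` over a sliding
   window, where `⟨H⟩` is mean Kyte–Doolittle hydropathy rescaled to [0,1]
   and `⟨R⟩` mean net charge; `I < 0` predicts disorder). Scores are
   reduced to binary flags (external [0,1]-scale predictors: disordered iff
   score ≥ 0.5) and laid into alignment columns; the disorder-conservation
   score of a column is the fraction of non-gap sequences flagged
   disordered, `d_raw ∈ [0,1]`.
2. **Sequence conservation.** Each column's weighted residue distribution
   `p_c` is scored by Jensen–Shannon divergence from a background `q`
   (BLOSUM62 frequencies by default):
   `JSD(p_c, q) = H(λp_c + (1−λ)q) − λH(p_c) − (1−λ)H(q)` in bits with
   λ = 0.5, so `s_raw ∈ [0,1]`; Henikoff sequence weighting, a gap penalty
   `s ← s·(1 − gap fraction)` and a ±3-column smoothing window are applied.
3. **Classification.** Both raw scores are binned to 0–9 by
   `⌊10·raw⌋` (clamped). Each query residue is then
   - `S` (structured) if the disorder bin is 0,
   - `C` (constrained) if both bins are ≥ 5,
   - `F` (flexible) if the disorder bin is ≥ 5 but the sequence bin < 5,
   - `N` (non-conserved) if the disorder bin is 1–4.

Outputs are a per-residue profile (TSV), the four category fractions
(TSV), and the maximal runs of consecutive `C` residues (FASTA) — the
segments most likely to be functional elements such as SLiMs or MoRFs.

## Worked example

Generate a synthetic homolog family with a planted architecture
(60 structured / 20 constrained / 40 flexible / 60 structured residues,
20 sequences), then classify it:

```sh
discons-fixtures --seed 1 --out fam.fa --truth truth.tsv
discons --msa fam.fa --query Q1 --out run
```

prints

```
180 query residues: C 0.128  F 0.206  N 0.028  S 0.639
1 constrained segment(s) of length >= 5
  59-81  AAEEDDSEEDSQEEPEDEDPSPP
```

The planted constrained block (query positions 61–80) is recovered as one
constrained segment (59–81; the two-residue overhangs are boundary blur
from the 51-residue disorder-prediction window), the flexible linker
contributes the `F` fraction (0.206 ≈ 40/180), and the hydrophobic core
regions are structured. `run.profile.tsv` holds the per-residue table
(position, residue, column, sequence bin, disorder bin, category),
`run.fractions.tsv` the category fractions, and `run.constrained.fasta`
the segment sequences.

To use an external disorder predictor (IUPred/VSL2/ESpritz-style output)
instead of the bundled index, pass `--predictor external
--disorder-manifest manifest.yaml`, where the manifest maps each sequence
id to a two-column `residue_index score` file.

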