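# pprcode

Predicting C-to-U RNA editing target sites in plant organelles from the
repeat structure of pentatricopeptide repeat (PPR) editing factors.

Editing-class PPR proteins are tandem arrays of ~31–40 amino-acid repeats
(classes P, L, S and the C-terminal variants L2, S2, followed by E/DYW
extensions) that bind RNA one repeat per nucleotide immediately 5′ of the
edited cytidine.  Two residues per repeat — position 6 of the repeat and
position 1′, the first residue of the next C-terminal repeat (for S2, its
own residue 33) — discriminate the bound nucleotide.  `pprcode` learns
this amino-acid → nucleotide code from factor/target training pairs,
including the L, L2 and S2 repeats that older P+S-only codes treated as
spacers, and uses it to rank candidate editing sites.

## Method

For each residue key (motif class; position 6, position 1′, or their
combination), contacts across the training compendium are counted and
converted to background-adjusted **binding values**

    AN(n) = R(n) / NP(n),       R(n) = N(n) / Σ_m N(m),

where `NP` is the nucleotide composition of organellar coding sequence
(shipped totals: 12035 A, 7634 C, 8633 G, 13724 U).  Entries seen in
fewer than 3 factors or 8 contacts, or failing a per-nucleotide G-test
against background (P ≥ 0.1 for all four nucleotides), are discarded.
For L repeats, a position-6 residue in {I, L, P, T, M} overrules the 1′
position.

To score a protein, its repeats are aligned to the RNA with the
C-terminal repeat (S2) facing nucleotide −4 relative to the edited C and
N-terminal repeats extending 5′, one nucleotide per repeat, with no
loop-outs.  Binding-value columns are normalized to probabilities with a
pseudocount, converted to log-odds (bits) against the zero-order
background, and every candidate window is scored at that single fixed
alignment.  P-values are exact: the distribution of the total score of a
random background sequence is computed by per-position convolution over
discretized scores, and sites are ranked by ascending p-value.

## Worked example

Everything below runs offline on a synthetic benchmark with a planted
code (the `simulate` command; real inputs use the same TSV/FASTA
dialects).

```bash
pprcode simulate --seed 7 --out bench --n-factors 3 --n-sites 80 --noise 0.0
pprcode train-code --motifs bench/motifs.tsv --sites bench/sites.tsv \
    --fasta bench/transcripts.fasta --truth bench/truth.tsv \
    --out code.tsv --min-factors 1 --min-incidences 1
# -> 50 candidate entries: kept 35, dropped 0 (insufficient evidence),
#    dropped 15 (G-test screen)
pprcode predict --code code.tsv --motifs bench/motifs.tsv \
    --protein factor00 --sites bench/sites.tsv \
    --fasta bench/transcripts.fasta --out preds.tsv --top 5
head -4 preds.tsv
```

```
rank  site_id  score_bits  p_value      mode
1     s0028    16.947      2.22839e-06  classes=L+L2+P+S+S2,offset=-4
2     s0077    -8.325      0.00275814   classes=L+L2+P+S+S2,offset=-4
3     s0024    -18.911     0.0304917    classes=L+L2+P+S+S2,offset=-4
```

`s0028` is factor00's planted target: it scores 16.9 bits above random
expectation and ranks 1 of 80 candidates with exact p-value 2.2e-06.
(`s0077`, rank 2, is another factor's planted site.)  The same pipeline
is available as a library of scikit-learn-style estimators:

```python
from pprcode import PPRCode, PPRTargetRanker

code = PPRCode(min_factors=3, min_incidences=8, alpha=0.1).fit(pairs)
ranker = PPRTargetRanker(code=code.code_table_).fit(protein)
predictions = ranker.predict(windows)   # ranked by exact p-value
```

Other subcommands: `build-matrix` (MEME minimal motif export of a
protein's scoring matrix), `scan-transcriptome` (rank every C in every
transcript), and `compare` (known-target ranks with all repeats vs a
P+S-only scan).

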