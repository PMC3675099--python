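# Methods

## Model

Editing-class PPR proteins are modelled as ordered arrays of typed
repeats (P/L/S/L2/S2, then E and optionally DYW extensions), each
repeat contacting exactly one nucleotide.  The protein is anchored on
the RNA by the convention that the C-terminal-most repeat — S2 when
present — faces the nucleotide at position −4 relative to the edited
cytidine, with repeats toward the N-terminus facing consecutively more
5′ nucleotides.  Alignments are rigid: no loop-outs of repeats or
nucleotides are allowed, and windows are scored at this single anchor,
not slid.  The anchor offset is configurable (`offset`, default −4);
shifting it to −5 reproduces the behaviour of factors whose binding
register is displaced by one nucleotide.

Nucleotide recognition is attributed to two residues per repeat:
position 6 of the repeat and position 1′, the first residue of the next
C-terminal element.  S2 is the exception — its 1′ is its own residue 33,
because the E domain by convention begins only after residue 36.  As a
consequence no repeat ever takes its 1′ residue from inside the E
domain.  If an (atypical) annotation has no element following its last
repeat, that repeat's 1′ is unknown (`X`) and the repeat scores
neutrally.  E and DYW elements never occupy nucleotide positions.

## Training the code

Every aligned (repeat, nucleotide) contact in the training compendium is
counted under three keys per repeat class: the (6, 1′) residue
combination and each position singly.  For L repeats a fourth,
stratified 1′ marginal is kept that excludes contacts whose position-6
residue is in the overruling set {I, L, P, T, M}; at lookup time an L
repeat with an overruling position-6 residue never consults the 1′
marginal at all.  Counts become binding values by background adjustment,
`AN(n) = (N(n)/ΣN)/NP(n)`, so `AN ≡ 1` for an entry whose composition
matches the background.

Entries are screened on evidence and significance:

| parameter        | default | meaning                                         |
|------------------|---------|-------------------------------------------------|
| `min_factors`    | 3       | distinct factors an entry must appear in        |
| `min_incidences` | 8       | total contacts an entry must have               |
| `alpha`          | 0.1     | G-test screen: keep if P < alpha for some nt    |

The G-test is per-nucleotide by default: four 2-category goodness-of-fit
tests (one nucleotide against the other three pooled, 1 df), matching a
screen that asks for significance at *some* nucleotide; a joint
4-category (3 df) variant is available (`gtest_mode="joint"`).  No
multiple-testing correction is applied — the screen is a filter, not an
inference.  "Incidences" count contacts, not sites, when a factor edits
several sites through the same repeat.  The shipped background pools
mitochondrial mRNA coding regions with edited plastid ORFs (totals
12035/7634/8633/13724 for A/C/G/U); organelle-specific backgrounds can
be supplied wherever a `Background` is accepted.

## Scoring and exact p-values

A protein's binding matrix has one column per scoring repeat, looked up
with precedence combination → position 6 → position 1′; a repeat with no
surviving entry (or unknown residues) gets the neutral all-ones column.
Columns are normalized to probabilities with a pseudocount
(`p(n) = (AN(n)+c)/Σ(AN+c)`, default `c = 0.01`).  The pseudocount keeps
zero binding values scoreable and bounds the worst single-column
penalty: with the default background, an `AN = 0` nucleotide in an
otherwise MEF11-like column costs about −4.7 bits rather than −∞.
Log-odds are `log2(p/NP)` in bits.

P-values assume a zero-order background: candidate sequences are i.i.d.
draws from `NP`.  Column scores are discretized to multiples of `step`
(default 10⁻³ bits) and the exact distribution of the total score is
built by per-position convolution; a window's p-value is the tail
probability at its (identically discretized) total, so p-values are
right-continuous, non-increasing in score, and 1 at the minimum
achievable score.  Enumeration over all 4^L sequences bounds the
discretization error at ≤ L·step in score, which the oracle tests
verify.  `N` bases (5′ window padding) contribute their column's
background-expected score, keeping padded windows comparable.  Ties are
broken by score descending, then site id — an arbitrary but
deterministic rule.

One property of this construction is worth noting: a code-less (neutral)
column normalizes to uniform 25%, which is *not* the organellar
background, so it still contributes a small composition-dependent score
to every window.  Dropping neutral C-terminal-truncated columns is
therefore exactly rank-preserving only under a uniform background.  This
is inherited from building probability columns as percentages of the
binding values; the alternative (neutral = background) would decouple
the matrix from the code-table semantics in which `AN = 1` means
"background ratio observed".

Scan modes restrict scoring to repeat classes (`include_classes`), with
excluded classes either neutralized in place (default, the spacer
interpretation) or dropped so the remaining repeats close ranks
(`excluded="drop"`); `cterm_k` keeps only the k C-terminal repeats.

## Synthetic benchmarks

The generator emulates the statistical structure of a real editing
compendium without reproducing any real sequence:

- **Planted code** — per (class, aa6, aa1p) key, a preference vector
  drawn from Dirichlet(κ·NP).  κ ≤ 0.3 yields sharp, near one-hot
  preferences.  A `fraction_neutral` share (default 0.45) of L/L2
  entries is exactly uniform, mirroring the roughly 45% of L-type
  repeats that show no nucleotide preference.  The default repertoire is
  4 keys per class; benchmarks below use 8, the scale of the surviving
  real code.
- **Factors** — repeat arrays following the P-L-S grammar with terminal
  L2-S2-E, discriminating residues planted consistently (the 1′ of
  repeat k is residue 1 of repeat k+1).
- **Targets** — aligned positions drawn from the planted preference with
  probability 1−noise, else from background; all other window positions
  are background.  Noise is positionwise substitution only — no indels,
  matching the no-loop-out scope.
- **Benchmarks** — 430 candidate sites by default (the size of the
  mitochondrial editing-site compendium), each a genuine C in a
  background transcriptome, with the true targets' upstream signal
  written into the transcripts.  A fixed seed regenerates every file
  byte-identically.

What passing these benchmarks does *not* show: real compendia have
correlated repeat usage, non-uniform residue frequencies, codon
structure and editing-efficiency variation, none of which are simulated;
recovery rates on synthetic data are therefore an upper bound on real
performance.

## Evaluation experiments and problem sizes

The shipped experiments use sizes chosen to mirror the real study while
remaining desk-scale:

- **Code recovery** — a 43-factor compendium of 14-repeat factors, 15
  target sites each, one key per class so every combination entry
  accumulates ≥ 500 contacts; recovered binding values are compared to
  the planted preference/background ratios (≤ 10% relative error for
  nucleotides with planted probability ≥ 0.1).
- **Rank recovery** — 100 replicates; each trains on a fresh 41-factor
  compendium (8–16 repeats, noise 0.05, κ = 0.2, 8 keys per class) and
  scans a 14-repeat query factor against 430 candidate sites.  The query
  is fixed at 14 repeats — the scale of the factors used for the
  original rank-1-of-430 demonstrations — because short queries (5–10
  repeats) genuinely rank worse, as observed for the shortest real
  factors; with a randomly sized query the rank-1 rate drops to ~0.9.
- **Mode comparison** — 30 short factors (5–9 repeats, where the L/L2/S2
  contribution matters most), all-repeat vs P+S-only ranks of each known
  target; with planted L/L2/S2 signal the all-repeat mode improves far
  more targets than it worsens.

## Degenerate inputs and numerical choices

- Residue `X` at position 6 or 1′ removes the affected key(s) from
  counting and lookup (neutral column).
- All-zero binding columns become uniform after the pseudocount.
- Windows shorter than a matrix span are a hard error in ranking;
  repeats aligned 5′ of the window are dropped from scoring (logged,
  not an error) when matrices are truncated to a window.
- A candidate position whose transcript base is not C warns but is still
  scored (genomic T may be pre-edited in cDNA-derived references).
- Probability columns sum to 1 within 10⁻⁹; score-distribution masses
  sum to 1 within 10⁻⁶.

## Known limitations

- The real published code values cannot be re-derived here: the original
  training compendium exists only in supplementary material, so in-paper
  numbers (background totals, the S2/1′=D counts, one trained column)
  serve as fixtures and the rest of the validation is synthetic.
- No gapped alignments, no joint multi-factor scans, no FDR across
  proteins, no RNA secondary structure, no modelling of the E/DYW
  domains' sequence preferences near the edited position.
- The documented case of an external scanner reporting a "p-value > 1"
  for one real short-factor target is not reproducible under any proper
  tail-probability definition and is not emulated.
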