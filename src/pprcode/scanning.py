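"""Position-dependent scoring, exact p-values and site ranking.

A trained code table turns a protein into a per-position matrix of
binding values (one column per aligned repeat).  Columns are normalized
to probabilities with a pseudocount, converted to log-odds against the
zero-order background, and each candidate window is scored at the single
fixed alignment.  P-values are exact: the full distribution of the total
score of a random i.i.d.-background sequence is computed by per-position
convolution over discretized scores, and a window's p-value is the
probability of a total at least as high.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .alignment import (
    DEFAULT_OFFSET,
    DEFAULT_WINDOW,
    AlignmentError,
    SiteWindow,
    windows_for_all_cytidines,
)
from .motifs import PPR_CLASSES, PPRProtein, discriminators
from .training import Background, CodeTable, NUCLEOTIDES

_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

NEUTRAL_COLUMN = {n: 1.0 for n in NUCLEOTIDES}

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_STEP = 1e-3


@dataclass(frozen=True)
class ScanMode:
    """Which repeats score, and where the C-terminal repeat aligns.

    ``include_classes`` restricts scoring to a subset of repeat classes;
    excluded classes either keep their position with a neutral column
    (``excluded='neutral'``, the spacer interpretation) or are dropped so
    the remaining repeats close ranks (``excluded='drop'``).
    ``cterm_k`` keeps only the k C-terminal repeats.  ``offset`` is the
    upstream position of the C-terminal repeat.
    """

    include_classes: frozenset[str] = frozenset(PPR_CLASSES)
    cterm_k: int | None = None
    offset: int = DEFAULT_OFFSET
    excluded: str = "neutral"

    def __post_init__(self) -> None:
        unknown = set(self.include_classes) - set(PPR_CLASSES)
        if unknown:
            raise ValueError(f"unknown repeat classes {sorted(unknown)}")
        if not self.include_classes:
            raise ValueError("include_classes must be non-empty")
        if self.cterm_k is not None and self.cterm_k < 1:
            raise ValueError("cterm_k must be >= 1")
        if self.offset > -1:
            raise ValueError("offset must be <= -1")
        if self.excluded not in ("neutral", "drop"):
            raise ValueError("excluded must be 'neutral' or 'drop'")

    def describe(self) -> str:
        classes = "+".join(sorted(self.include_classes))
        parts = [f"classes={classes}", f"offset={self.offset}"]
        if self.cterm_k is not None:
            parts.append(f"cterm_k={self.cterm_k}")
        if self.excluded != "neutral":
            parts.append(f"excluded={self.excluded}")
        return ",".join(parts)


ALL_MOTIFS = ScanMode()
P_AND_S_ONLY = ScanMode(include_classes=frozenset({"P", "S"}))


@dataclass(frozen=True)
class BindingMatrix:
    """Per-position binding-value columns for one protein.

    Columns run 5'->3' (most negative position first, i.e. N- to
    C-terminal repeat order).  Repeats with no code-table entry get the
    neutral all-ones column.
    """

    protein_id: str
    positions: tuple[int, ...]
    columns: tuple[Mapping[str, float], ...]
    mode: ScanMode = field(default=ALL_MOTIFS)

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.columns):
            raise ValueError("positions and columns length mismatch")
        if list(self.positions) != sorted(self.positions):
            raise ValueError("positions must ascend (most negative first)")

    @property
    def span(self) -> int:
        """Window width required to host the matrix."""
        return -self.positions[0] if self.positions else 0

    def truncate_to_window(self, W: int) -> "BindingMatrix":
        """Drop columns whose position falls 5' of a W-wide window."""
        keep = [i for i, p in enumerate(self.positions) if p >= -W]
        return BindingMatrix(
            protein_id=self.protein_id,
            positions=tuple(self.positions[i] for i in keep),
            columns=tuple(self.columns[i] for i in keep),
            mode=self.mode,
        )


def binding_matrix(
    protein: PPRProtein, code: CodeTable, mode: ScanMode = ALL_MOTIFS
) -> BindingMatrix:
    """Build the position-dependent binding-value matrix of a protein."""
    motifs = protein.ppr_motifs
    if not motifs:
        raise ValueError(f"{protein.protein_id}: no PPR-class motifs")
    pairs = discriminators(protein)
    if mode.cterm_k is not None:
        motifs = motifs[-mode.cterm_k :]
        pairs = pairs[-mode.cterm_k :]
    if mode.excluded == "drop":
        kept = [
            (m, d) for m, d in zip(motifs, pairs)
            if m.motif_class in mode.include_classes
        ]
        if not kept:
            raise ValueError(
                f"{protein.protein_id}: no motifs left after class restriction"
            )
        motifs = [m for m, _ in kept]
        pairs = [d for _, d in kept]
    columns = []
    for motif, pair in zip(motifs, pairs):
        if motif.motif_class not in mode.include_classes:
            columns.append(dict(NEUTRAL_COLUMN))
            continue
        col = code.lookup_binding(pair.motif_class, pair.aa6, pair.aa1p)
        columns.append(dict(NEUTRAL_COLUMN) if col is None else col)
    n = len(columns)
    positions = tuple(mode.offset - (n - 1) + k for k in range(n))
    return BindingMatrix(
        protein_id=protein.protein_id,
        positions=positions,
        columns=tuple(columns),
        mode=mode,
    )


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Pseudocount-normalized probability columns of a binding matrix."""

    protein_id: str
    positions: tuple[int, ...]
    columns: tuple[Mapping[str, float], ...]
    pseudocount: float
    mode: ScanMode = field(default=ALL_MOTIFS)

    def __post_init__(self) -> None:
        for pos, col in zip(self.positions, self.columns):
            total = sum(col[n] for n in NUCLEOTIDES)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"column at {pos} sums to {total}, not 1")

    @property
    def span(self) -> int:
        return -self.positions[0] if self.positions else 0

    def as_array(self) -> np.ndarray:
        """(L, 4) array, rows 5'->3', columns in A,C,G,U order."""
        return np.array(
            [[col[n] for n in NUCLEOTIDES] for col in self.columns], dtype=float
        )


def to_probability_matrix(
    bm: BindingMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> ProbabilityMatrix:
    """Normalize binding-value columns to probabilities.

    ``p(n) = (AN(n) + pseudocount) / sum_m (AN(m) + pseudocount)``.  The
    pseudocount keeps zero binding values scoreable and bounds the worst
    single-column log-odds penalty.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    columns = []
    for pos, col in zip(bm.positions, bm.columns):
        vals = {n: col[n] for n in NUCLEOTIDES}
        if any(v < 0 for v in vals.values()):
            raise ValueError(f"negative binding value in column at {pos}")
        total = sum(vals.values()) + 4 * pseudocount
        columns.append({n: (vals[n] + pseudocount) / total for n in NUCLEOTIDES})
    return ProbabilityMatrix(
        protein_id=bm.protein_id,
        positions=bm.positions,
        columns=tuple(columns),
        pseudocount=pseudocount,
        mode=bm.mode,
    )


@dataclass(frozen=True)
class ScoreMatrix:
    """Log-odds scores (bits) of a probability matrix vs background."""

    protein_id: str
    positions: tuple[int, ...]
    scores: np.ndarray  # (L, 4), A,C,G,U order
    mode: ScanMode = field(default=ALL_MOTIFS)


def log_odds(pm: ProbabilityMatrix, background: Background) -> ScoreMatrix:
    """s(pos, n) = log2(p(pos, n) / NP(n))."""
    bg = background.as_array()
    if np.any(bg <= 0):
        raise ValueError("background probabilities must all be positive")
    probs = pm.as_array()
    if np.any(probs <= 0):
        raise ValueError("probability matrix entries must all be positive")
    return ScoreMatrix(
        protein_id=pm.protein_id,
        positions=pm.positions,
        scores=np.log2(probs / bg),
        mode=pm.mode,
    )


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact distribution of the total score under the background model.

    Scores are discretized to integer multiples of *step* (bits); the
    total-score pmf is the per-position convolution of the column pmfs,
    the candidate sequence being i.i.d. background at every position.
    """

    step: float
    min_bin: int
    pmf: np.ndarray
    survival: np.ndarray  # survival[i] = P(total_bin >= min_bin + i)
    column_bins: np.ndarray  # (L, 4) discretized column scores
    expected_bins: np.ndarray  # per-column background-expected bin ('N' score)

    def pvalue_of_bin(self, total_bin: int) -> float:
        idx = total_bin - self.min_bin
        if idx <= 0:
            return 1.0
        if idx >= len(self.survival):
            idx = len(self.survival) - 1  # rounding past the max achievable
        return float(self.survival[idx])

    def pvalue(self, score_bits: float) -> float:
        return self.pvalue_of_bin(int(round(score_bits / self.step)))


def exact_pvalues(
    sm: ScoreMatrix, background: Background, step: float = DEFAULT_STEP
) -> ScoreDistribution:
    """Exact total-score distribution by discretized convolution."""
    if step <= 0:
        raise ValueError("step must be positive")
    if not np.all(np.isfinite(sm.scores)):
        raise ValueError("score matrix contains non-finite values")
    bins = np.rint(sm.scores / step).astype(np.int64)
    bg = background.as_array()
    pmf = np.array([1.0])
    base = 0
    for row in bins:
        lo, hi = int(row.min()), int(row.max())
        new = np.zeros(len(pmf) + hi - lo)
        for b, w in zip(row, bg):
            shift = int(b) - lo
            new[shift : shift + len(pmf)] += w * pmf
        pmf = new
        base += lo
    survival = np.cumsum(pmf[::-1])[::-1]
    expected = np.rint(bins @ bg).astype(np.int64)
    return ScoreDistribution(
        step=step,
        min_bin=base,
        pmf=pmf,
        survival=survival,
        column_bins=bins,
        expected_bins=expected,
    )


@dataclass(frozen=True)
class RankedPrediction:
    """One scored candidate site."""

    site_id: str
    score_bits: float
    p_value: float
    rank: int
    column_scores: tuple[float, ...]
    mode: str = ""


def _window_bins(
    window: SiteWindow, positions: Sequence[int], dist: ScoreDistribution
) -> np.ndarray:
    out = np.empty(len(positions), dtype=np.int64)
    for i, pos in enumerate(positions):
        base = window.base_at(pos)
        if base == "N":
            out[i] = dist.expected_bins[i]
        else:
            out[i] = dist.column_bins[i, _NT_INDEX[base]]
    return out


def scan_and_rank(
    pm: ProbabilityMatrix,
    windows: Sequence[SiteWindow],
    background: Background,
    step: float = DEFAULT_STEP,
) -> list[RankedPrediction]:
    """Score every window at the fixed alignment and rank by p-value.

    'N' bases contribute the background-expected score of their column,
    so 5'-padded windows remain comparable to full ones.  Ties break by
    score descending, then site_id.
    """
    sm = log_odds(pm, background)
    dist = exact_pvalues(sm, background, step=step)
    span = pm.span
    short = [w.site_id for w in windows if w.width < span]
    if short:
        raise AlignmentError(
            f"window(s) shorter than the {span}-nt matrix span: "
            f"{', '.join(short[:5])}"
        )
    scored = []
    for w in windows:
        col_bins = _window_bins(w, pm.positions, dist)
        total = int(col_bins.sum())
        scored.append(
            (
                dist.pvalue_of_bin(total),
                -(total * step),
                w.site_id,
                tuple(float(b * step) for b in col_bins),
            )
        )
    scored.sort()
    mode = pm.mode.describe()
    return [
        RankedPrediction(
            site_id=site_id,
            score_bits=-neg_score,
            p_value=p,
            rank=rank,
            column_scores=cols,
            mode=mode,
        )
        for rank, (p, neg_score, site_id, cols) in enumerate(scored, start=1)
    ]


def scan_transcriptome(
    pm: ProbabilityMatrix,
    sequences: Mapping[str, str] | str | Path | IO[str],
    background: Background,
    W: int | None = None,
    step: float = DEFAULT_STEP,
) -> list[RankedPrediction]:
    """Rank every C in every transcript as a candidate editing site."""
    if W is None:
        W = max(DEFAULT_WINDOW, pm.span)
    windows = windows_for_all_cytidines(sequences, W=W)
    if not windows:
        return []
    return scan_and_rank(pm, windows, background, step=step)


def predictions_to_frame(predictions: Iterable[RankedPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": p.rank,
                "site_id": p.site_id,
                "score_bits": p.score_bits,
                "p_value": p.p_value,
                "mode": p.mode,
            }
            for p in predictions
        ],
        columns=["rank", "site_id", "score_bits", "p_value", "mode"],
    )


def write_predictions(
    predictions: Iterable[RankedPrediction], target: str | IO[str]
) -> None:
    predictions_to_frame(predictions).to_csv(
        target, sep="\t", index=False, float_format="%.6g"
    )


def to_meme(pm: ProbabilityMatrix, background: Background) -> str:
    """Render the matrix in MEME minimal motif text format (ACGU)."""
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGU",
        "",
        "Background letter frequencies",
        " ".join(
            f"{n} {background.probs[n]:.6f}" for n in NUCLEOTIDES
        ),
        "",
        f"MOTIF {pm.protein_id}",
        (
            f"letter-probability matrix: alphabet= ACGU w= {len(pm.columns)} "
            f"nsites= 20 E= 0"
        ),
    ]
    for col in pm.columns:
        lines.append(" " + " ".join(f"{col[n]:.6f}" for n in NUCLEOTIDES))
    lines.append("")
    return "\n".join(lines)


class PPRTargetRanker(BaseEstimator):
    """Estimator that ranks candidate editing sites for one protein.

    Parameters are the trained ``code`` table, the :class:`ScanMode`,
    the column pseudocount and the p-value discretization step.  ``fit``
    takes the protein and precomputes its matrices and exact score
    distribution; ``predict`` ranks a list of windows.

    Attributes
    ----------
    binding_matrix_ : BindingMatrix
    probability_matrix_ : ProbabilityMatrix
    score_matrix_ : ScoreMatrix
    score_distribution_ : ScoreDistribution
    """

    def __init__(
        self,
        code: CodeTable | None = None,
        mode: ScanMode = ALL_MOTIFS,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        step: float = DEFAULT_STEP,
        background: Background | None = None,
        max_window: int | None = None,
    ) -> None:
        self.code = code
        self.mode = mode
        self.pseudocount = pseudocount
        self.step = step
        self.background = background
        self.max_window = max_window

    def _bg(self) -> Background:
        if self.background is not None:
            return self.background
        if self.code is not None and self.code.background is not None:
            return self.code.background
        from .training import ORGANELLAR_BACKGROUND

        return ORGANELLAR_BACKGROUND

    def fit(self, X: PPRProtein, y: None = None) -> "PPRTargetRanker":
        if self.code is None:
            raise ValueError("PPRTargetRanker requires a trained code table")
        bm = binding_matrix(X, self.code, mode=self.mode)
        if self.max_window is not None:
            bm = bm.truncate_to_window(self.max_window)
        self.binding_matrix_ = bm
        self.probability_matrix_ = to_probability_matrix(
            bm, pseudocount=self.pseudocount
        )
        self.score_matrix_ = log_odds(self.probability_matrix_, self._bg())
        self.score_distribution_ = exact_pvalues(
            self.score_matrix_, self._bg(), step=self.step
        )
        return self

    def predict(self, X: Sequence[SiteWindow]) -> list[RankedPrediction]:
        """Rank candidate windows by exact p-value."""
        return scan_and_rank(
            self.probability_matrix_, X, self._bg(), step=self.step
        )

    def score_samples(self, X: Sequence[SiteWindow]) -> np.ndarray:
        """Total log-odds score (bits) of each window, input order."""
        dist = self.score_distribution_
        return np.array(
            [
                _window_bins(w, self.probability_matrix_.positions, dist).sum()
                * self.step
                for w in X
            ]
        )
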