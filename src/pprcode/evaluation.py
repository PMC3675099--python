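"""Comparison experiments: target ranks across scoring modes and offsets.

The headline questions these helpers answer: does including the L, L2
and S2 repeats improve the rank of known targets over a P+S-only scan,
do the eight C-terminal repeats suffice, and does shifting the alignment
offset (e.g. -5 instead of -4) help a particular factor?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .alignment import SiteWindow
from .motifs import PPRProtein
from .scanning import (
    ALL_MOTIFS,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_STEP,
    PPRTargetRanker,
    RankedPrediction,
    ScanMode,
)
from .training import Background, CodeTable

__all__ = [
    "ScanMode",
    "ComparisonRow",
    "ModeComparison",
    "rank_of_targets",
    "compare_modes",
    "offset_scan",
]


def rank_of_targets(
    predictions: Sequence[RankedPrediction], known: Iterable[str]
) -> dict[str, int]:
    """1-based rank of each known target site among the predictions."""
    by_site = {p.site_id: p.rank for p in predictions}
    known = list(known)
    missing = sorted(set(known) - set(by_site))
    if missing:
        raise KeyError(f"site(s) not among predictions: {', '.join(missing)}")
    return {site: by_site[site] for site in known}


@dataclass(frozen=True)
class ComparisonRow:
    """Rank of one known target under two scan modes."""

    protein_id: str
    site_id: str
    rank_mode_a: int
    rank_mode_b: int
    n_candidates: int


@dataclass(frozen=True)
class ModeComparison:
    """Per-target ranks plus the improved/equal/worse tally (a vs b)."""

    rows: tuple[ComparisonRow, ...]
    improved: int  # mode_a ranked the target strictly better (smaller)
    equal: int
    worse: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "protein_id": r.protein_id,
                    "site_id": r.site_id,
                    "rank_mode_a": r.rank_mode_a,
                    "rank_mode_b": r.rank_mode_b,
                    "n_candidates": r.n_candidates,
                }
                for r in self.rows
            ],
            columns=[
                "protein_id",
                "site_id",
                "rank_mode_a",
                "rank_mode_b",
                "n_candidates",
            ],
        )

    def summary(self) -> str:
        return (
            f"mode_a better: {self.improved}, equal: {self.equal}, "
            f"mode_b better: {self.worse}"
        )


def _ranks_under_mode(
    protein: PPRProtein,
    code: CodeTable,
    windows: Sequence[SiteWindow],
    background: Background,
    mode: ScanMode,
    known: Iterable[str],
    pseudocount: float,
    step: float,
) -> dict[str, int]:
    ranker = PPRTargetRanker(
        code=code,
        mode=mode,
        pseudocount=pseudocount,
        step=step,
        background=background,
    ).fit(protein)
    return rank_of_targets(ranker.predict(windows), known)


def compare_modes(
    protein: PPRProtein,
    code: CodeTable,
    windows: Sequence[SiteWindow],
    background: Background,
    mode_a: ScanMode,
    mode_b: ScanMode,
    known: Iterable[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    step: float = DEFAULT_STEP,
) -> ModeComparison:
    """Rank the known targets of one factor under two scan modes."""
    known = sorted(set(known))
    ranks_a = _ranks_under_mode(
        protein, code, windows, background, mode_a, known, pseudocount, step
    )
    ranks_b = _ranks_under_mode(
        protein, code, windows, background, mode_b, known, pseudocount, step
    )
    rows = tuple(
        ComparisonRow(
            protein_id=protein.protein_id,
            site_id=site,
            rank_mode_a=ranks_a[site],
            rank_mode_b=ranks_b[site],
            n_candidates=len(windows),
        )
        for site in known
    )
    improved = sum(r.rank_mode_a < r.rank_mode_b for r in rows)
    worse = sum(r.rank_mode_a > r.rank_mode_b for r in rows)
    return ModeComparison(
        rows=rows,
        improved=improved,
        equal=len(rows) - improved - worse,
        worse=worse,
    )


def combine_comparisons(parts: Iterable[ModeComparison]) -> ModeComparison:
    """Pool per-factor comparisons into one tally."""
    rows: list[ComparisonRow] = []
    for part in parts:
        rows.extend(part.rows)
    improved = sum(r.rank_mode_a < r.rank_mode_b for r in rows)
    worse = sum(r.rank_mode_a > r.rank_mode_b for r in rows)
    return ModeComparison(
        rows=tuple(rows),
        improved=improved,
        equal=len(rows) - improved - worse,
        worse=worse,
    )


def offset_scan(
    protein: PPRProtein,
    code: CodeTable,
    windows: Sequence[SiteWindow],
    background: Background,
    offsets: Sequence[int],
    known: Iterable[str],
    base_mode: ScanMode = ALL_MOTIFS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    step: float = DEFAULT_STEP,
) -> dict[int, dict[str, int]]:
    """Known-target ranks at each candidate alignment offset."""
    if any(o > -1 for o in offsets):
        raise ValueError("offsets must all be <= -1")
    known = sorted(set(known))
    out: dict[int, dict[str, int]] = {}
    for offset in offsets:
        mode = ScanMode(
            include_classes=base_mode.include_classes,
            cterm_k=base_mode.cterm_k,
            offset=offset,
            excluded=base_mode.excluded,
        )
        out[offset] = _ranks_under_mode(
            protein, code, windows, background, mode, known, pseudocount, step
        )
    return out


def best_offset(offset_ranks: Mapping[int, Mapping[str, int]]) -> int:
    """Offset whose summed known-target rank is smallest (ties: nearest -4)."""
    return min(
        offset_ranks,
        key=lambda o: (sum(offset_ranks[o].values()), abs(o + 4), o),
    )


def write_comparison(comparison: ModeComparison, target: str | IO[str]) -> None:
    comparison.to_frame().to_csv(target, sep="\t", index=False)
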