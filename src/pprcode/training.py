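"""Learning the amino-acid -> nucleotide code from factor/target pairs.

Each aligned (repeat, nucleotide) contact across a training compendium is
counted three ways: by the combination of discriminating residues
(position 6 and 1'), and by each single position on its own.  Raw counts
are turned into background-adjusted binding values

    AN(n) = R(n) / NP(n),       R(n) = N(n) / sum_m N(m),

where NP is the nucleotide composition of organellar coding sequence, so
AN = 1 everywhere when a residue key shows no preference beyond
background.  Entries backed by too little evidence (fewer than 3 factors
or 8 contacts) or failing a G-test against background (P >= 0.1 for all
four nucleotides) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import rel_entr
from sklearn.base import BaseEstimator

from .alignment import DEFAULT_OFFSET, SiteWindow, align
from .motifs import PPRProtein, discriminators

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "U")

#: Position-6 residues in L repeats that overrule the 1' position: when one
#: of these is present, the 1' residue carries no usable signal.
L_OVERRULE = frozenset("ILPTM")

KEY_KINDS = ("combo", "pos6", "pos1p", "pos1p_ex")


@dataclass(frozen=True)
class Background:
    """Zero-order nucleotide composition of organellar transcripts."""

    probs: Mapping[str, float]
    counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        total = sum(self.probs.get(n, 0.0) for n in NUCLEOTIDES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background probabilities sum to {total}, not 1")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "Background":
        counts = {n: int(counts.get(n, 0)) for n in NUCLEOTIDES}
        if any(c < 0 for c in counts.values()):
            raise ValueError("negative nucleotide count")
        total = sum(counts.values())
        if total == 0:
            raise ValueError("all-zero nucleotide counts")
        probs = {n: c / total for n, c in counts.items()}
        return cls(probs=probs, counts=counts)

    def as_array(self) -> np.ndarray:
        return np.array([self.probs[n] for n in NUCLEOTIDES], dtype=float)


def background_from_counts(counts: Mapping[str, int]) -> Background:
    """Build a :class:`Background` from raw nucleotide totals."""
    return Background.from_counts(counts)


#: Nucleotide totals of the pooled organellar coding regions used to train
#: and screen the code (mitochondrial mRNAs plus edited plastid ORFs).
ORGANELLAR_BACKGROUND = Background.from_counts(
    {"A": 12035, "C": 7634, "G": 8633, "U": 13724}
)


class CodeKey(NamedTuple):
    """Identifies one code-table entry.

    ``key_kind`` is ``combo`` (positions 6 and 1' jointly), ``pos6`` or
    ``pos1p`` (single-position marginals), or ``pos1p_ex`` -- the 1'
    marginal of L repeats restricted to contacts whose position-6 residue
    is outside the overruling set {I,L,P,T,M}.
    """

    motif_class: str
    key_kind: str
    aa6: str | None
    aa1p: str | None


@dataclass
class _Tally:
    counts: dict[str, int] = field(
        default_factory=lambda: {n: 0 for n in NUCLEOTIDES}
    )
    factors: set[str] = field(default_factory=set)

    @property
    def n_incidences(self) -> int:
        return sum(self.counts.values())


class CooccurrenceTable:
    """Raw contact counts per (motif class, residue key, nucleotide)."""

    def __init__(self) -> None:
        self.entries: dict[CodeKey, _Tally] = {}

    def _bump(self, key: CodeKey, nucleotide: str, factor_id: str) -> None:
        tally = self.entries.setdefault(key, _Tally())
        tally.counts[nucleotide] += 1
        tally.factors.add(factor_id)

    def add_contact(
        self,
        motif_class: str,
        aa6: str,
        aa1p: str,
        nucleotide: str,
        factor_id: str,
    ) -> None:
        """Record one repeat/nucleotide contact under all applicable keys.

        Unknown residues ('X') make the affected key(s) unusable and are
        skipped; unknown bases ('N') are skipped entirely.
        """
        if nucleotide not in NUCLEOTIDES:
            return
        if aa6 != "X" and aa1p != "X":
            self._bump(CodeKey(motif_class, "combo", aa6, aa1p), nucleotide, factor_id)
        if aa6 != "X":
            self._bump(CodeKey(motif_class, "pos6", aa6, None), nucleotide, factor_id)
        if aa1p != "X":
            self._bump(CodeKey(motif_class, "pos1p", None, aa1p), nucleotide, factor_id)
            if motif_class == "L" and aa6 not in L_OVERRULE:
                self._bump(
                    CodeKey(motif_class, "pos1p_ex", None, aa1p),
                    nucleotide,
                    factor_id,
                )

    def __len__(self) -> int:
        return len(self.entries)


def count_cooccurrences(
    pairs: Iterable[tuple[PPRProtein, SiteWindow]],
    offset: int = DEFAULT_OFFSET,
) -> CooccurrenceTable:
    """Tally repeat/nucleotide contacts over aligned factor/target pairs."""
    table = CooccurrenceTable()
    for protein, window in pairs:
        pair_list = discriminators(protein)
        alignment = align(protein, window, offset=offset)
        in_window = {id(m): pos for m, pos in alignment.assignments}
        for motif, pair in zip(protein.ppr_motifs, pair_list):
            pos = in_window.get(id(motif))
            if pos is None:
                continue  # motif fell 5' of the window
            table.add_contact(
                pair.motif_class,
                pair.aa6,
                pair.aa1p,
                window.base_at(pos),
                protein.protein_id,
            )
    return table


def adjusted_ratios(
    counts: Mapping[str, int], background: Background
) -> dict[str, float]:
    """Background-adjusted binding values AN(n) = (N(n)/sum N)/NP(n)."""
    total = sum(counts.get(n, 0) for n in NUCLEOTIDES)
    if total <= 0:
        raise ValueError("adjusted_ratios requires a positive total count")
    out = {}
    for n in NUCLEOTIDES:
        c = counts.get(n, 0)
        np_n = background.probs[n]
        if np_n == 0:
            if c > 0:
                raise ValueError(
                    f"nucleotide {n} observed but has zero background probability"
                )
            out[n] = 0.0
        else:
            out[n] = (c / total) / np_n
    return out


@dataclass(frozen=True)
class GTestResult:
    """Per-nucleotide goodness-of-fit G statistics against background."""

    g: Mapping[str, float]
    p: Mapping[str, float]
    mode: str = "per_nucleotide"

    @property
    def min_p(self) -> float:
        return min(self.p.values())


def g_test(
    observed: Mapping[str, int],
    background: Background,
    mode: str = "per_nucleotide",
) -> GTestResult:
    """G-test of observed nucleotide counts against the background.

    ``per_nucleotide`` (default) runs four 2-category tests, each pitting
    one nucleotide against the other three pooled (1 df) -- the form that
    matches a screen asking for P < alpha at *some* nucleotide.  ``joint``
    runs a single 4-category test (3 df) reported under every nucleotide.
    """
    total = sum(observed.get(n, 0) for n in NUCLEOTIDES)
    if total <= 0:
        raise ValueError("g_test requires a positive total count")
    if mode == "per_nucleotide":
        g, p = {}, {}
        for n in NUCLEOTIDES:
            o = np.array([observed.get(n, 0), total - observed.get(n, 0)], float)
            e = np.array(
                [total * background.probs[n], total * (1 - background.probs[n])]
            )
            stat = 2.0 * rel_entr(o, e).sum()  # 0*ln0 handled as 0
            g[n] = float(stat)
            p[n] = float(stats.chi2.sf(stat, df=1))
        return GTestResult(g=g, p=p, mode=mode)
    if mode == "joint":
        o = np.array([observed.get(n, 0) for n in NUCLEOTIDES], float)
        e = total * np.array([background.probs[n] for n in NUCLEOTIDES])
        stat = float(2.0 * rel_entr(o, e).sum())
        pval = float(stats.chi2.sf(stat, df=3))
        return GTestResult(
            g={n: stat for n in NUCLEOTIDES},
            p={n: pval for n in NUCLEOTIDES},
            mode=mode,
        )
    raise ValueError(f"unknown g_test mode {mode!r}")


@dataclass(frozen=True)
class CodeEntry:
    """One retained code-table entry with its binding values."""

    an: Mapping[str, float]
    n_factors: int
    n_incidences: int
    min_p: float


class CodeTable:
    """Filtered, background-adjusted recognition code."""

    def __init__(
        self, entries: Mapping[CodeKey, CodeEntry], background: Background
    ) -> None:
        self.entries = dict(entries)
        self.background = background

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: CodeKey) -> bool:
        return key in self.entries

    def get(self, key: CodeKey) -> CodeEntry | None:
        return self.entries.get(key)

    def lookup_binding(
        self, motif_class: str, aa6: str, aa1p: str
    ) -> dict[str, float] | None:
        """Binding-value column for one repeat, or None (neutral).

        Precedence: joint (6,1') entry, then position 6 alone, then
        position 1' alone.  For L repeats the 1' marginal is only
        consulted when position 6 is outside the overruling set
        {I,L,P,T,M}, and the stratified (overrule-excluded) marginal is
        preferred.
        """
        if aa6 != "X" and aa1p != "X":
            entry = self.entries.get(CodeKey(motif_class, "combo", aa6, aa1p))
            if entry is not None:
                return dict(entry.an)
        if aa6 != "X":
            entry = self.entries.get(CodeKey(motif_class, "pos6", aa6, None))
            if entry is not None:
                return dict(entry.an)
        if aa1p != "X":
            if motif_class == "L":
                if aa6 in L_OVERRULE:
                    return None
                entry = self.entries.get(
                    CodeKey(motif_class, "pos1p_ex", None, aa1p)
                )
                if entry is not None:
                    return dict(entry.an)
            entry = self.entries.get(CodeKey(motif_class, "pos1p", None, aa1p))
            if entry is not None:
                return dict(entry.an)
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.entries, key=lambda k: (k.motif_class, k.key_kind, k.aa6 or ".", k.aa1p or ".")):
            e = self.entries[key]
            rows.append(
                {
                    "motif_class": key.motif_class,
                    "key_kind": key.key_kind,
                    "aa6": key.aa6 or ".",
                    "aa1p": key.aa1p or ".",
                    **{f"AN_{n}": e.an[n] for n in NUCLEOTIDES},
                    "n_factors": e.n_factors,
                    "n_incidences": e.n_incidences,
                    "min_p": e.min_p,
                }
            )
        columns = (
            ["motif_class", "key_kind", "aa6", "aa1p"]
            + [f"AN_{n}" for n in NUCLEOTIDES]
            + ["n_factors", "n_incidences", "min_p"]
        )
        return pd.DataFrame(rows, columns=columns)

    def write_tsv(self, target: str | IO[str]) -> None:
        """Serialize to TSV (6 significant digits on real values)."""
        self.to_frame().to_csv(target, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read_tsv(
        cls, source: str | IO[str], background: Background | None = None
    ) -> "CodeTable":
        df = pd.read_csv(source, sep="\t", dtype={"aa6": str, "aa1p": str})
        entries = {}
        for row in df.itertuples():
            key = CodeKey(
                motif_class=row.motif_class,
                key_kind=row.key_kind,
                aa6=None if row.aa6 == "." else row.aa6,
                aa1p=None if row.aa1p == "." else row.aa1p,
            )
            if key.key_kind not in KEY_KINDS:
                raise ValueError(f"unknown key_kind {key.key_kind!r}")
            entries[key] = CodeEntry(
                an={n: float(getattr(row, f"AN_{n}")) for n in NUCLEOTIDES},
                n_factors=int(row.n_factors),
                n_incidences=int(row.n_incidences),
                min_p=float(row.min_p),
            )
        return cls(entries, background or ORGANELLAR_BACKGROUND)


@dataclass
class TrainingReport:
    """Bookkeeping of the evidence and significance screens."""

    n_counted: int = 0
    n_kept: int = 0
    dropped_evidence: int = 0
    dropped_gtest: int = 0

    def summary(self) -> str:
        return (
            f"{self.n_counted} candidate entries: kept {self.n_kept}, "
            f"dropped {self.dropped_evidence} (insufficient evidence), "
            f"dropped {self.dropped_gtest} (G-test screen)"
        )


def build_code_table(
    table: CooccurrenceTable,
    background: Background,
    min_factors: int = 3,
    min_incidences: int = 8,
    alpha: float = 0.1,
    gtest_mode: str = "per_nucleotide",
    report: TrainingReport | None = None,
) -> CodeTable:
    """Screen counted entries and compute their binding values.

    An entry survives when it was seen in at least *min_factors* distinct
    factors AND at least *min_incidences* contacts AND its G-test reaches
    P < *alpha* for at least one nucleotide.
    """
    report = report if report is not None else TrainingReport()
    report.n_counted = len(table.entries)
    kept: dict[CodeKey, CodeEntry] = {}
    for key, tally in table.entries.items():
        if len(tally.factors) < min_factors or tally.n_incidences < min_incidences:
            report.dropped_evidence += 1
            continue
        gres = g_test(tally.counts, background, mode=gtest_mode)
        if gres.min_p >= alpha:
            report.dropped_gtest += 1
            continue
        kept[key] = CodeEntry(
            an=adjusted_ratios(tally.counts, background),
            n_factors=len(tally.factors),
            n_incidences=tally.n_incidences,
            min_p=gres.min_p,
        )
    report.n_kept = len(kept)
    return CodeTable(kept, background)


class PPRCode(BaseEstimator):
    """Estimator that learns the recognition code from factor/target pairs.

    Parameters
    ----------
    min_factors, min_incidences
        Evidence floors: an entry must appear in this many distinct
        factors and contacts.
    alpha
        G-test screen: keep an entry only if P < alpha for at least one
        nucleotide.
    gtest_mode
        ``per_nucleotide`` (four 1-df tests) or ``joint`` (one 3-df test).
    offset
        Alignment offset of the C-terminal repeat (default -4).
    background
        :class:`Background` to adjust against; defaults to the pooled
        organellar composition.

    Attributes
    ----------
    code_table_ : CodeTable
    cooccurrence_ : CooccurrenceTable
    report_ : TrainingReport
    """

    def __init__(
        self,
        min_factors: int = 3,
        min_incidences: int = 8,
        alpha: float = 0.1,
        gtest_mode: str = "per_nucleotide",
        offset: int = DEFAULT_OFFSET,
        background: Background | None = None,
    ) -> None:
        self.min_factors = min_factors
        self.min_incidences = min_incidences
        self.alpha = alpha
        self.gtest_mode = gtest_mode
        self.offset = offset
        self.background = background

    def fit(
        self,
        X: Sequence[tuple[PPRProtein, SiteWindow]],
        y: None = None,
    ) -> "PPRCode":
        """Count contacts over aligned pairs and build the code table."""
        bg = self.background or ORGANELLAR_BACKGROUND
        self.background_ = bg
        self.cooccurrence_ = count_cooccurrences(X, offset=self.offset)
        self.report_ = TrainingReport()
        self.code_table_ = build_code_table(
            self.cooccurrence_,
            bg,
            min_factors=self.min_factors,
            min_incidences=self.min_incidences,
            alpha=self.alpha,
            gtest_mode=self.gtest_mode,
            report=self.report_,
        )
        return self
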