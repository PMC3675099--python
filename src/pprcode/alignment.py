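"""Protein-to-RNA alignment around candidate C-to-U editing sites.

Editing factors bind immediately 5' of the cytidine they serve.  The
alignment convention is fixed, not slid: the C-terminal-most repeat (S2
when present) faces the nucleotide at offset -4 relative to the edited C,
and each repeat toward the N-terminus faces the next nucleotide 5' (one
position more negative).  Upstream positions are labelled with negative
integers, -1 being the base immediately 5' of the edited C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .motifs import Motif, PPRProtein

DEFAULT_OFFSET = -4
DEFAULT_WINDOW = 30

_RNA = set("ACGUN")


class AlignmentError(ValueError):
    """Window/offset geometry that cannot host an alignment."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class SiteWindow:
    """Upstream sequence context of one candidate edited C.

    ``upstream`` runs 5'->3' and covers positions ``-W .. -1``; windows
    reaching past the transcript start are 5'-padded with ``N`` (which
    scores neutrally).
    """

    site_id: str
    transcript_id: str
    edited_pos: int  # 1-based position of the edited C in the transcript
    upstream: str

    def __post_init__(self) -> None:
        bad = set(self.upstream) - _RNA
        if bad:
            raise AlignmentError(
                f"{self.site_id}: non-RNA characters {sorted(bad)} in window"
            )

    @property
    def width(self) -> int:
        return len(self.upstream)

    def base_at(self, position: int) -> str:
        """Nucleotide at a negative upstream position (-1 = nearest the C)."""
        if not -self.width <= position <= -1:
            raise AlignmentError(
                f"{self.site_id}: position {position} outside window "
                f"-{self.width}..-1"
            )
        return self.upstream[self.width + position]


@dataclass(frozen=True)
class MotifAlignment:
    """Assignment of a protein's scoring motifs to upstream positions."""

    offset: int
    #: (motif, position) for motifs inside the window, N- to C-terminal.
    assignments: tuple[tuple[Motif, int], ...]
    #: Motifs whose position falls 5' of the window, excluded from scoring.
    out_of_window: tuple[Motif, ...] = field(default=())

    @property
    def positions(self) -> list[int]:
        return [pos for _, pos in self.assignments]


def align(
    protein: PPRProtein,
    window: SiteWindow | int,
    offset: int = DEFAULT_OFFSET,
) -> MotifAlignment:
    """Assign each scoring motif of *protein* to an upstream position.

    With M scoring motifs the covered positions are
    ``offset, offset-1, ..., offset-(M-1)``: the C-terminal-most repeat
    sits at *offset* and N-terminal repeats extend 5'.  Motifs falling 5'
    of the window are flagged ``out_of_window``.

    *window* may be a :class:`SiteWindow` or a bare window width.
    """
    width = window if isinstance(window, int) else window.width
    if offset > -1:
        raise AlignmentError(f"offset must be <= -1, got {offset}")
    if width < -offset:
        raise AlignmentError(
            f"window of {width} nt cannot host offset {offset}"
        )
    motifs = protein.ppr_motifs
    if not motifs:
        raise AlignmentError(f"{protein.protein_id}: no PPR-class motifs")
    assignments = []
    outside = []
    # C-terminal-most motif at `offset`; walk N-terminally 5'-ward.
    for k, motif in enumerate(reversed(motifs)):
        pos = offset - k
        if pos < -width:
            outside.append(motif)
        else:
            assignments.append((motif, pos))
    assignments.reverse()
    outside.reverse()
    return MotifAlignment(
        offset=offset,
        assignments=tuple(assignments),
        out_of_window=tuple(outside),
    )


def read_site_table(source: str | IO[str] | pd.DataFrame) -> pd.DataFrame:
    """Read a TSV of candidate sites: site_id, transcript_id, edited_pos."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype={"site_id": str, "transcript_id": str})
    missing = {"site_id", "transcript_id", "edited_pos"} - set(df.columns)
    if missing:
        raise AlignmentError(f"site table missing columns: {sorted(missing)}")
    df["edited_pos"] = df["edited_pos"].astype(int)
    return df


def write_site_table(sites: pd.DataFrame, target: str | IO[str]) -> None:
    sites[["site_id", "transcript_id", "edited_pos"]].to_csv(
        target, sep="\t", index=False
    )


def read_fasta(source: str | Path | IO[str] | Mapping[str, str]) -> dict[str, str]:
    """Load transcript sequences, normalized to RNA uppercase."""
    if isinstance(source, Mapping):
        return {k: normalize_rna(v) for k, v in source.items()}
    return {
        rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(source, "fasta")
    }


def extract_windows(
    sequences: Mapping[str, str] | str | Path | IO[str],
    sites: pd.DataFrame | str | IO[str],
    W: int = DEFAULT_WINDOW,
) -> list[SiteWindow]:
    """Cut the W-nucleotide upstream window of every candidate site.

    Transcript coordinates are 1-based; the window covers transcript
    positions ``edited_pos-W .. edited_pos-1``, 5'-padded with ``N`` when
    the site lies within the first W bases.  A site whose transcript base
    is not C triggers a warning (genomic T may be pre-edited), not an
    error.
    """
    seqs = read_fasta(sequences)
    table = read_site_table(sites)
    missing = sorted(
        set(table.loc[~table["transcript_id"].isin(seqs), "site_id"])
    )
    if missing:
        raise AlignmentError(
            f"transcript missing for site(s): {', '.join(missing)}"
        )
    windows = []
    for row in table.itertuples():
        seq = seqs[row.transcript_id]
        pos = int(row.edited_pos)
        if not 1 <= pos <= len(seq):
            raise AlignmentError(
                f"{row.site_id}: edited_pos {pos} outside transcript "
                f"{row.transcript_id} (length {len(seq)})"
            )
        if seq[pos - 1] != "C":
            warnings.warn(
                f"{row.site_id}: transcript base at edited_pos is "
                f"{seq[pos - 1]}, not C",
                stacklevel=2,
            )
        start = max(0, pos - 1 - W)
        upstream = seq[start : pos - 1]
        upstream = "N" * (W - len(upstream)) + upstream
        windows.append(
            SiteWindow(
                site_id=str(row.site_id),
                transcript_id=str(row.transcript_id),
                edited_pos=pos,
                upstream=upstream,
            )
        )
    return windows


def windows_for_all_cytidines(
    sequences: Mapping[str, str] | str | Path | IO[str],
    W: int = DEFAULT_WINDOW,
) -> list[SiteWindow]:
    """Every C in every transcript as a candidate site window."""
    seqs = read_fasta(sequences)
    rows = [
        (f"{tid}-{i + 1}", tid, i + 1)
        for tid, seq in seqs.items()
        for i, base in enumerate(seq)
        if base == "C"
    ]
    sites = pd.DataFrame(rows, columns=["site_id", "transcript_id", "edited_pos"])
    if sites.empty:
        return []
    return extract_windows(seqs, sites, W=W)


def iter_window_pairs(
    proteins: Iterable[PPRProtein],
    windows: Iterable[SiteWindow],
    truth: Mapping[str, Iterable[str]],
) -> list[tuple[PPRProtein, SiteWindow]]:
    """Pair each factor with the windows of its known target sites."""
    by_id = {w.site_id: w for w in windows}
    pairs = []
    for protein in proteins:
        for site_id in truth.get(protein.protein_id, ()):
            if site_id not in by_id:
                raise AlignmentError(
                    f"{protein.protein_id}: unknown target site {site_id}"
                )
            pairs.append((protein, by_id[site_id]))
    return pairs
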