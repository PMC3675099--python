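"""PPR protein models: typed motif arrays and discriminating residues.

Editing-class pentatricopeptide repeat (PPR) proteins are tandem arrays of
~31-40 amino-acid helical repeats that bind RNA one repeat per nucleotide.
The repeats come in length classes P (normal), L (long) and S (short),
usually alternating P-L-S, with divergent C-terminal variants L2 and S2
immediately before the E (and optionally DYW) extension domains.

Two residues per repeat discriminate the bound nucleotide: position 6 of
the repeat itself and position 1' -- the first residue of the next
C-terminal repeat.  The S2 repeat is a special case: its 1' residue is its
own position 33, because by convention the E domain starts only after
residue 36.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable

import pandas as pd

PPR_CLASSES: tuple[str, ...] = ("P", "L", "S", "L2", "S2")
EXTENSION_CLASSES: tuple[str, ...] = ("E", "DYW")
MOTIF_CLASSES: tuple[str, ...] = PPR_CLASSES + EXTENSION_CLASSES

#: 20 one-letter amino-acid codes plus 'X' for unknown residues.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X"}

#: Residue index (0-based) of discriminating position 6.
_POS6 = 5
#: Residue index (0-based) of the S2-internal 1' position (residue 33).
_S2_POS1P = 32


class MotifTableError(ValueError):
    """Malformed motif annotation input."""


@dataclass(frozen=True)
class Motif:
    """One PPR repeat (or E/DYW extension element) of a protein.

    Parameters
    ----------
    index
        1-based ordinal position in the protein, N- to C-terminal.
    motif_class
        One of ``P, L, S, L2, S2, E, DYW``.
    residues
        One-letter amino-acid string; ``X`` marks unknown residues.
    """

    index: int
    motif_class: str
    residues: str

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise MotifTableError(
                f"unknown motif class {self.motif_class!r} "
                f"(allowed: {', '.join(MOTIF_CLASSES)})"
            )
        if not self.residues:
            raise MotifTableError(f"motif {self.index}: empty residue string")
        bad = set(self.residues.upper()) - AMINO_ACIDS
        if bad:
            raise MotifTableError(
                f"motif {self.index}: invalid residue(s) {sorted(bad)}"
            )
        if self.is_ppr and len(self.residues) < _POS6 + 1:
            raise MotifTableError(
                f"motif {self.index} ({self.motif_class}): length "
                f"{len(self.residues)} < 6, position 6 does not exist"
            )

    @property
    def is_ppr(self) -> bool:
        """True for the RNA-contacting repeat classes (P/L/S/L2/S2)."""
        return self.motif_class in PPR_CLASSES

    @property
    def aa6(self) -> str:
        return self.residues[_POS6].upper()


@dataclass
class PPRProtein:
    """An editing factor: ordered motifs, N-terminal first."""

    protein_id: str
    motifs: list[Motif] = field(default_factory=list)
    organelle: str = "mitochondrion"

    def __post_init__(self) -> None:
        self.motifs = sorted(self.motifs, key=lambda m: m.index)
        indices = [m.index for m in self.motifs]
        if len(set(indices)) != len(indices):
            raise MotifTableError(
                f"{self.protein_id}: duplicate motif indices {indices}"
            )
        n_s2 = sum(m.motif_class == "S2" for m in self.motifs)
        n_l2 = sum(m.motif_class == "L2" for m in self.motifs)
        if n_s2 > 1 or n_l2 > 1:
            raise MotifTableError(
                f"{self.protein_id}: at most one S2 and one L2 motif allowed"
            )
        classes = [m.motif_class for m in self.motifs]
        if n_s2 and n_l2:
            if classes.index("S2") != classes.index("L2") + 1:
                raise MotifTableError(
                    f"{self.protein_id}: L2 must immediately precede S2"
                )
        if n_s2:
            # S2 is the C-terminal-most RNA-contacting repeat.
            after = classes[classes.index("S2") + 1 :]
            if any(c in PPR_CLASSES for c in after):
                raise MotifTableError(
                    f"{self.protein_id}: PPR-class motif follows S2"
                )

    @property
    def ppr_motifs(self) -> list[Motif]:
        """The RNA-contacting (scoring) motifs, N- to C-terminal."""
        return [m for m in self.motifs if m.is_ppr]

    def __len__(self) -> int:
        return len(self.motifs)


@dataclass(frozen=True)
class DiscriminatorPair:
    """Discriminating residues (position 6, position 1') of one repeat."""

    motif_class: str
    aa6: str
    aa1p: str


def discriminators(protein: PPRProtein) -> list[DiscriminatorPair]:
    """Extract the (position 6, position 1') residue pair of every repeat.

    One pair is returned per PPR-class motif, in N- to C-terminal order.
    For P/L/S/L2 repeats, 1' is the first residue of whatever element
    follows (including E/DYW); a repeat with nothing following gets
    ``aa1p='X'`` and will score neutrally.  For S2, 1' is residue 33 of
    the S2 motif itself.

    Raises
    ------
    MotifTableError
        If the protein has no PPR-class motif, or its S2 motif is shorter
        than 33 residues.
    """
    if not protein.ppr_motifs:
        raise MotifTableError(f"{protein.protein_id}: no PPR-class motifs")
    pairs: list[DiscriminatorPair] = []
    for i, motif in enumerate(protein.motifs):
        if not motif.is_ppr:
            continue
        if motif.motif_class == "S2":
            if len(motif.residues) < _S2_POS1P + 1:
                raise MotifTableError(
                    f"{protein.protein_id}: S2 motif has "
                    f"{len(motif.residues)} residues, position 33 missing"
                )
            aa1p = motif.residues[_S2_POS1P].upper()
        elif i + 1 < len(protein.motifs):
            aa1p = protein.motifs[i + 1].residues[0].upper()
        else:
            aa1p = "X"
        pairs.append(DiscriminatorPair(motif.motif_class, motif.aa6, aa1p))
    return pairs


_MOTIF_COLUMNS = ["protein_id", "motif_index", "motif_class", "residues"]


def parse_motif_table(source: str | IO[str] | pd.DataFrame) -> list[PPRProtein]:
    """Read a motif annotation table (TSV) into :class:`PPRProtein` objects.

    Expected columns: ``protein_id, motif_index, motif_class, residues``.
    Proteins come back in first-appearance order, motifs sorted by index.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    missing = set(_MOTIF_COLUMNS) - set(df.columns)
    if missing:
        raise MotifTableError(f"motif table missing columns: {sorted(missing)}")
    proteins: list[PPRProtein] = []
    for pid, group in df.groupby("protein_id", sort=False):
        motifs = []
        for row in group.itertuples():
            try:
                motifs.append(
                    Motif(
                        index=int(row.motif_index),
                        motif_class=str(row.motif_class),
                        residues=str(row.residues).upper(),
                    )
                )
            except MotifTableError as exc:
                raise MotifTableError(
                    f"protein {pid}, motif_index {row.motif_index}: {exc}"
                ) from exc
        protein = PPRProtein(protein_id=str(pid), motifs=motifs)
        _warn_on_broken_alternation(protein)
        proteins.append(protein)
    return proteins


def _warn_on_broken_alternation(protein: PPRProtein) -> None:
    # Editing factors usually alternate P-L-S; deviations are common in
    # real annotations, so this is advisory only.
    classes = [m.motif_class for m in protein.ppr_motifs if m.motif_class in "PLS"]
    expected_next = {"P": "L", "L": "S", "S": "P"}
    breaks = sum(
        1 for a, b in zip(classes, classes[1:]) if expected_next[a] != b
    )
    if classes and breaks > len(classes) // 2:
        warnings.warn(
            f"{protein.protein_id}: motif classes deviate strongly from "
            "P-L-S alternation",
            stacklevel=3,
        )


def write_motif_table(
    proteins: Iterable[PPRProtein], target: str | IO[str]
) -> None:
    """Write proteins back to the motif annotation TSV dialect."""
    rows = [
        (p.protein_id, m.index, m.motif_class, m.residues)
        for p in proteins
        for m in p.motifs
    ]
    pd.DataFrame(rows, columns=_MOTIF_COLUMNS).to_csv(
        target, sep="\t", index=False
    )
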