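"""Shared construction helpers for the test suite."""

from __future__ import annotations

from pprcode.motifs import Motif, PPRProtein
from pprcode.synthetic import MOTIF_LENGTHS
from pprcode.training import CodeEntry, CodeKey, CodeTable, NUCLEOTIDES


def build_protein(
    classes: list[str],
    pairs: list[tuple[str, str]],
    protein_id: str = "test-protein",
    filler: str = "V",
    with_e: bool = True,
) -> PPRProtein:
    """Construct a protein with chosen discriminating residues.

    *classes* and *pairs* describe the scoring motifs N- to C-terminal;
    each pair is (aa6, aa1p).  For non-S2 motifs the aa1p is written into
    the first residue of the following element, for S2 into its own
    residue 33.  An E element is appended unless ``with_e=False``.
    """
    if len(classes) != len(pairs):
        raise ValueError("classes and pairs must have equal length")
    residues = [[filler] * MOTIF_LENGTHS[cls] for cls in classes]
    if with_e:
        residues.append([filler] * MOTIF_LENGTHS["E"])
    for i, (cls, (aa6, aa1p)) in enumerate(zip(classes, pairs)):
        residues[i][5] = aa6
        if cls == "S2":
            residues[i][32] = aa1p
        elif i + 1 < len(residues):
            residues[i + 1][0] = aa1p
    motifs = [
        Motif(index=i + 1, motif_class=cls, residues="".join(r))
        for i, (cls, r) in enumerate(
            zip(classes + (["E"] if with_e else []), residues)
        )
    ]
    return PPRProtein(protein_id=protein_id, motifs=motifs)


def code_table_from_columns(
    entries: dict[CodeKey, dict[str, float]], background
) -> CodeTable:
    """Wrap raw binding-value columns into a CodeTable."""
    return CodeTable(
        {
            key: CodeEntry(
                an={n: col.get(n, 0.0) for n in NUCLEOTIDES},
                n_factors=5,
                n_incidences=20,
                min_p=0.01,
            )
            for key, col in entries.items()
        },
        background,
    )
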