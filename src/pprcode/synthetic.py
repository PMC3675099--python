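"""Synthetic factor/target benchmarks with a planted recognition code.

The generator emulates the statistical structure of a real editing-factor
compendium: repeat arrays following the P-L-S grammar with terminal L2-S2
elements, a planted amino-acid -> nucleotide preference code (sharp for
most entries, with a configurable fraction of L/L2 entries exactly
neutral, mirroring the roughly 45% of L-type repeats that show no
nucleotide preference), target windows whose aligned positions are drawn
from the planted preferences, and decoy candidate sites drawn from the
organellar background composition.  Default benchmark sizes mirror the
real compendium: 430 candidate sites per scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import (
    DEFAULT_OFFSET,
    DEFAULT_WINDOW,
    SiteWindow,
    align,
    extract_windows,
    iter_window_pairs,
    write_site_table,
)
from .motifs import Motif, PPRProtein, discriminators, write_motif_table
from .training import (
    NUCLEOTIDES,
    ORGANELLAR_BACKGROUND,
    Background,
    CodeEntry,
    CodeKey,
    CodeTable,
)

_AA20 = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Repeat lengths used for generated proteins (S2 at the 36-residue
#: convention so its internal 1' position, residue 33, always exists).
MOTIF_LENGTHS = {"P": 35, "L": 36, "S": 31, "L2": 36, "S2": 36, "E": 34}

DEFAULT_N_SITES = 430


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PlantedCode:
    """Ground-truth nucleotide preferences per (class, aa6, aa1p) key."""

    entries: Mapping[tuple[str, str, str], np.ndarray]
    kappa: float
    background: Background = field(default=ORGANELLAR_BACKGROUND)

    def keys_for_class(self, motif_class: str) -> list[tuple[str, str, str]]:
        return sorted(k for k in self.entries if k[0] == motif_class)

    def preference(self, motif_class: str, aa6: str, aa1p: str) -> np.ndarray | None:
        return self.entries.get((motif_class, aa6, aa1p))

    def exact_code_table(self) -> CodeTable:
        """The code table an infinite training compendium would yield."""
        bg = self.background.as_array()
        entries = {}
        for (cls, aa6, aa1p), pref in self.entries.items():
            entries[CodeKey(cls, "combo", aa6, aa1p)] = CodeEntry(
                an={n: float(pref[i] / bg[i]) for i, n in enumerate(NUCLEOTIDES)},
                n_factors=10**6,
                n_incidences=10**6,
                min_p=0.0,
            )
        return CodeTable(entries, self.background)


def make_code(
    seed: int | np.random.Generator,
    n_entries_per_class: int = 4,
    kappa: float = 0.3,
    fraction_neutral: float = 0.45,
    background: Background = ORGANELLAR_BACKGROUND,
) -> PlantedCode:
    """Draw a planted code: Dirichlet(kappa * background) preferences.

    Small *kappa* gives sharp, near one-hot preferences.  A
    *fraction_neutral* share of L and L2 entries is set exactly uniform
    (spacer repeats with no nucleotide preference).
    """
    if not 0.0 <= fraction_neutral <= 1.0:
        raise ValueError("fraction_neutral must lie in [0, 1]")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    rng = _rng(seed)
    alpha = kappa * background.as_array()
    entries: dict[tuple[str, str, str], np.ndarray] = {}
    for cls in ("P", "L", "S", "L2", "S2"):
        pairs: set[tuple[str, str]] = set()
        while len(pairs) < n_entries_per_class:
            pairs.add(
                (str(rng.choice(_AA20)), str(rng.choice(_AA20)))
            )
        ordered = sorted(pairs)
        n_neutral = (
            int(round(fraction_neutral * len(ordered))) if cls in ("L", "L2") else 0
        )
        for i, (aa6, aa1p) in enumerate(ordered):
            if i < n_neutral:
                pref = np.full(4, 0.25)
            else:
                pref = _dirichlet(rng, alpha, background)
            entries[(cls, aa6, aa1p)] = pref
    return PlantedCode(entries=entries, kappa=kappa, background=background)


def _dirichlet(
    rng: np.random.Generator, alpha: np.ndarray, background: Background
) -> np.ndarray:
    # Gamma construction; guards against underflow at very small kappa,
    # where the draw degenerates to a one-hot preference.
    g = rng.gamma(shape=alpha)
    total = g.sum()
    if not np.isfinite(total) or total <= 0:
        pref = np.zeros(4)
        pref[rng.choice(4, p=background.as_array())] = 1.0
        return pref
    return g / total


def sample_factor(
    code: PlantedCode,
    n_ppr: int,
    seed: int | np.random.Generator,
    protein_id: str = "synthetic-factor",
    organelle: str = "mitochondrion",
) -> PPRProtein:
    """Generate a repeat array following the editing-factor grammar.

    Classes cycle P-L-S and terminate with L2, S2 and an E extension;
    discriminating residues (position 6, and position 1' of the following
    element) are planted consistently from keys of the given code.
    """
    if n_ppr < 2:
        raise ValueError("n_ppr must be >= 2 (L2 and S2 are always present)")
    rng = _rng(seed)
    m = n_ppr - 2
    cycle = ("P", "L", "S")
    phase = (2 - (m - 1)) % 3 if m else 0  # last pre-L2 repeat is an S
    classes = [cycle[(phase + i) % 3] for i in range(m)] + ["L2", "S2"]
    keys = []
    for cls in classes:
        candidates = code.keys_for_class(cls)
        if not candidates:
            raise ValueError(f"planted code has no entries for class {cls}")
        keys.append(candidates[int(rng.integers(len(candidates)))])
    residues = [
        [_AA20[i] for i in rng.integers(20, size=MOTIF_LENGTHS[cls])]
        for cls in classes
    ]
    residues.append([_AA20[i] for i in rng.integers(20, size=MOTIF_LENGTHS["E"])])
    for i, (cls, (_, aa6, aa1p)) in enumerate(zip(classes, keys)):
        residues[i][5] = aa6
        if cls == "S2":
            residues[i][32] = aa1p
        else:
            residues[i + 1][0] = aa1p
    motifs = [
        Motif(index=i + 1, motif_class=cls, residues="".join(r))
        for i, (cls, r) in enumerate(zip(classes + ["E"], residues))
    ]
    return PPRProtein(protein_id=protein_id, motifs=motifs, organelle=organelle)


def sample_target(
    factor: PPRProtein,
    code: PlantedCode,
    noise: float,
    seed: int | np.random.Generator,
    W: int = DEFAULT_WINDOW,
    offset: int = DEFAULT_OFFSET,
    site_id: str = "target",
    transcript_id: str = "synthetic",
    edited_pos: int | None = None,
) -> SiteWindow:
    """Draw a target window bound by *factor* under the planted code.

    Aligned positions are drawn from the planted preference with
    probability ``1 - noise`` and from the background otherwise; all
    other positions are background.
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0, 1]")
    rng = _rng(seed)
    bg = code.background.as_array()
    chars = [
        NUCLEOTIDES[i] for i in rng.choice(4, size=W, p=bg)
    ]
    alignment = align(factor, W, offset=offset)
    pair_by_motif = {
        id(m): d for m, d in zip(factor.ppr_motifs, discriminators(factor))
    }
    for motif, pos in alignment.assignments:
        pair = pair_by_motif[id(motif)]
        pref = code.preference(pair.motif_class, pair.aa6, pair.aa1p)
        if pref is None or rng.random() < noise:
            probs = bg
        else:
            probs = pref
        chars[W + pos] = NUCLEOTIDES[int(rng.choice(4, p=probs))]
    return SiteWindow(
        site_id=site_id,
        transcript_id=transcript_id,
        edited_pos=edited_pos if edited_pos is not None else W + 1,
        upstream="".join(chars),
    )


@dataclass
class SyntheticBench:
    """A complete planted benchmark: factors, sites, transcriptome, truth."""

    seed: int
    code: PlantedCode
    factors: list[PPRProtein]
    sites: pd.DataFrame
    transcripts: dict[str, str]
    truth: dict[str, list[str]]
    W: int = DEFAULT_WINDOW
    params: dict = field(default_factory=dict)

    def windows(self) -> list[SiteWindow]:
        return extract_windows(self.transcripts, self.sites, W=self.W)

    def training_pairs(self) -> list[tuple[PPRProtein, SiteWindow]]:
        return iter_window_pairs(self.factors, self.windows(), self.truth)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "transcripts.fasta", "w") as fh:
            for tid in sorted(self.transcripts):
                fh.write(f">{tid}\n{self.transcripts[tid]}\n")
        write_site_table(self.sites, outdir / "sites.tsv")
        write_motif_table(self.factors, outdir / "motifs.tsv")
        rows = [
            {"protein_id": pid, "site_id": sid}
            for pid in sorted(self.truth)
            for sid in self.truth[pid]
        ]
        pd.DataFrame(rows, columns=["protein_id", "site_id"]).to_csv(
            outdir / "truth.tsv", sep="\t", index=False
        )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(
                {"seed": self.seed, "W": self.W, **self.params},
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def make_bench(
    seed: int,
    n_factors: int = 5,
    n_sites: int = DEFAULT_N_SITES,
    noise: float = 0.0,
    sites_per_factor: int = 1,
    n_ppr_range: tuple[int, int] = (8, 16),
    scan_ppr: int | None = None,
    n_entries_per_class: int = 4,
    kappa: float = 0.3,
    fraction_neutral: float = 0.45,
    code: PlantedCode | None = None,
    transcript_len: int = 4000,
    W: int = DEFAULT_WINDOW,
    offset: int = DEFAULT_OFFSET,
    background: Background = ORGANELLAR_BACKGROUND,
) -> SyntheticBench:
    """Generate a benchmark with planted targets among background decoys.

    Every candidate site gets a C at its edited position; the true target
    sites additionally carry the factor-specific upstream signal.  The
    same seed regenerates the benchmark byte-identically.

    ``scan_ppr`` pins the repeat count of the first factor (the
    designated scan query) so rank-recovery experiments can probe a
    factor of a chosen scale against a compendium of mixed sizes.
    """
    if n_sites <= 0 or transcript_len <= 0 or sites_per_factor <= 0:
        raise ValueError("sizes must be positive")
    n_truth = n_factors * sites_per_factor
    if n_truth > n_sites:
        raise ValueError("more planted targets than candidate sites")
    rng = np.random.default_rng(seed)
    if code is None:
        code = make_code(
            rng,
            n_entries_per_class=n_entries_per_class,
            kappa=kappa,
            fraction_neutral=fraction_neutral,
            background=background,
        )
    factors = [
        sample_factor(
            code,
            (
                scan_ppr
                if i == 0 and scan_ppr is not None
                else int(rng.integers(n_ppr_range[0], n_ppr_range[1] + 1))
            ),
            rng,
            protein_id=f"factor{i:02d}",
        )
        for i in range(n_factors)
    ]
    slot_w = W + 5
    slots_per_transcript = max(1, transcript_len // slot_w)
    n_transcripts = ceil(n_sites / slots_per_transcript)
    bg = background.as_array()
    transcripts = {
        f"tx{t:02d}": [
            NUCLEOTIDES[i] for i in rng.choice(4, size=transcript_len, p=bg)
        ]
        for t in range(n_transcripts)
    }
    site_rows = []
    for k in range(n_sites):
        tid = f"tx{k // slots_per_transcript:02d}"
        edited_pos = ((k % slots_per_transcript) + 1) * slot_w  # 1-based, > W
        transcripts[tid][edited_pos - 1] = "C"
        site_rows.append((f"s{k:04d}", tid, edited_pos))
    sites = pd.DataFrame(
        site_rows, columns=["site_id", "transcript_id", "edited_pos"]
    )
    truth_slots = rng.permutation(n_sites)[:n_truth]
    truth: dict[str, list[str]] = {}
    for f, factor in enumerate(factors):
        ids = []
        for j in range(sites_per_factor):
            slot = int(truth_slots[f * sites_per_factor + j])
            site_id, tid, edited_pos = site_rows[slot]
            target = sample_target(
                factor,
                code,
                noise,
                rng,
                W=W,
                offset=offset,
                site_id=site_id,
                transcript_id=tid,
                edited_pos=edited_pos,
            )
            transcripts[tid][edited_pos - 1 - W : edited_pos - 1] = list(
                target.upstream
            )
            ids.append(site_id)
        truth[factor.protein_id] = ids
    return SyntheticBench(
        seed=int(seed),
        code=code,
        factors=factors,
        sites=sites,
        transcripts={tid: "".join(chars) for tid, chars in transcripts.items()},
        truth=truth,
        W=W,
        params={
            "n_factors": n_factors,
            "n_sites": n_sites,
            "noise": noise,
            "sites_per_factor": sites_per_factor,
            "n_ppr_range": list(n_ppr_range),
            "scan_ppr": scan_ppr,
            "n_entries_per_class": n_entries_per_class,
            "kappa": kappa,
            "fraction_neutral": fraction_neutral,
            "transcript_len": transcript_len,
            "offset": offset,
        },
    )
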