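"""Synthetic transposase reference panel.

Mariner subfamily classification in this package is nearest-reference: a
lineage's conceptual translation is aligned against a panel of transposases
labelled by subfamily, plus Tc1-family decoys used to exclude Tc1-like
clusters. Real-data runs would load a curated panel FASTA; for self-contained
runs this module generates a deterministic synthetic panel: 345-aa proteins
carrying the mariner DD34D catalytic triad (or DD34E for the Tc1 decoys),
two per subfamily, mutually unrelated. The first mauritiana entry is named
Mos1 after the canonical active mariner transposase.

The panel is synthetic: sequences are random apart from the planted motif
and share nothing with any real transposase.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .model import GenomeSequence
from .io import read_fasta, write_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"
SUBFAMILIES = ("mauritiana", "mellifera", "irritans", "vertumnana", "drosophila")

# fixed triad layout: D, then D, then 34 residues, then D (mariner) or E (Tc1)
_TRIAD = (156, 248, 283)
_PANEL_SEED = 910207


@dataclass(frozen=True)
class PanelEntry:
    name: str
    subfamily: str
    family: str  # "mariner" | "tc1_like"
    sequence: str


def _random_protein(rng: np.random.Generator, length: int = 345) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def plant_triad(protein: str, last_residue: str = "D") -> str:
    """Plant the DD34(D/E) catalytic triad at the panel's fixed positions."""
    p = list(protein)
    d1, d2, d3 = _TRIAD
    p[d1], p[d2], p[d3] = "D", "D", last_residue
    return "".join(p)


def dd_motif(protein: str) -> str | None:
    """Report 'DD34D' or 'DD34E' if a catalytic-triad spacing is present.

    Looks for D..D separated from a terminal D/E by exactly 34 residues,
    with at least one earlier D (the first aspartate of the triad).
    """
    n = len(protein)
    for j in range(1, n - 35):
        if protein[j] != "D":
            continue
        last = protein[j + 35]
        if last in "DE" and "D" in protein[:j]:
            return f"DD34{last}"
    return None


@lru_cache(maxsize=1)
def default_panel() -> tuple[PanelEntry, ...]:
    """Deterministic synthetic reference panel: 10 mariner + 3 Tc1 decoys."""
    rng = np.random.default_rng(_PANEL_SEED)
    entries: list[PanelEntry] = []
    canonical = {"mauritiana": "Mos1"}
    for subfamily in SUBFAMILIES:
        for idx in (1, 2):
            if idx == 1 and subfamily in canonical:
                name = canonical[subfamily]
            else:
                name = f"syn_{subfamily[:4]}{idx}"
            seq = plant_triad(_random_protein(rng), "D")
            entries.append(PanelEntry(name, subfamily, "mariner", seq))
    for idx in (1, 2, 3):
        seq = plant_triad(_random_protein(rng), "E")
        entries.append(PanelEntry(f"syn_tc1_{idx}", "tc1_like", "tc1_like", seq))
    return tuple(entries)


def panel_entry(name: str) -> PanelEntry:
    for e in default_panel():
        if e.name == name:
            return e
    raise KeyError(name)


def write_panel_fasta(path, panel=None) -> None:
    panel = panel or default_panel()
    write_fasta([(f"{e.name}|{e.family}|{e.subfamily}", e.sequence) for e in panel],
                path)


def read_panel_fasta(path) -> tuple[PanelEntry, ...]:
    """Load a panel FASTA whose headers are 'name|family|subfamily'."""
    entries = []
    for rec in read_fasta_proteins(path):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(f"panel header must be name|family|subfamily: {rec.id!r}")
        entries.append(PanelEntry(parts[0], parts[2], parts[1], rec.residues))
    return tuple(entries)


def read_fasta_proteins(path) -> list[GenomeSequence]:
    """FASTA reader without the DNA alphabet normalization (for proteins)."""
    from Bio import SeqIO
    out = [GenomeSequence(rec.id, str(rec.seq).upper())
           for rec in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out
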