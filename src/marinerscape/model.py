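"""Core datatypes shared across the pipeline.

Coordinates are 0-based half-open internally; every emitted file (GFF3, BLAST
tabular) uses the 1-based inclusive convention of the respective format.
"""
from __future__ import annotations

from dataclasses import dataclass, field


COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One scaffold/contig of an assembly, uppercase over {A,C,G,T,N}."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval on a named scaffold."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    def overlap(self, other: "Interval") -> int:
        if self.scaffold_id != other.scaffold_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Hit:
    """One homology high-scoring pair on a genome sequence.

    ``frame`` is -3..-1/1..3 for protein-vs-translated-DNA hits and 0 for
    nucleotide hits; ``location`` is always on the forward strand of the
    subject with orientation carried by ``location.strand``.
    """

    query_id: str
    location: Interval
    bit_score: float
    identity_fraction: float
    frame: int = 0
    raw_score: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.identity_fraction <= 1.0):
            raise ValueError("identity_fraction outside [0, 1]")


@dataclass
class TECopy:
    """An assembled TE occurrence with flanks and bookkeeping flags.

    ``residues`` is the element sequence strand-normalized to the consensus
    orientation; flanks are given in the same orientation (left = upstream of
    the element 5' end).
    """

    id: str
    location: Interval
    residues: str = ""
    left_flank: str = ""
    right_flank: str = ""
    at_contig_end: bool = False
    n_adjacent: bool = False
    lineage_id: str | None = None
    is_duplicate: bool = False

    @property
    def length(self) -> int:
        return self.location.length


@dataclass
class BreakpointSignature:
    """Ordered internal-deletion intervals and optional 5'->3' rearrangement.

    Deletions are (start, end) half-open intervals in consensus coordinates.
    ``rearrangement`` is None or ``(kept_5prime_end, inverted_5prime_len)``
    for copies of the form  C[0:x] + revcomp(C[0:y]).
    """

    deletions: list[tuple[int, int]] = field(default_factory=list)
    rearrangement: tuple[int, int] | None = None

    def __post_init__(self):
        self.deletions = sorted(self.deletions)
        last = -1
        for s, e in self.deletions:
            if s < last or e <= s:
                raise ValueError("deletion intervals must be sorted and disjoint")
            last = e

    @property
    def is_empty(self) -> bool:
        return not self.deletions and self.rearrangement is None

    def matches(self, other: "BreakpointSignature", tol: int = 5) -> bool:
        """Signature equality with per-breakpoint tolerance ``tol`` nt."""
        if len(self.deletions) != len(other.deletions):
            return False
        for (s1, e1), (s2, e2) in zip(self.deletions, other.deletions):
            if abs(s1 - s2) > tol or abs(e1 - e2) > tol:
                return False
        if (self.rearrangement is None) != (other.rearrangement is None):
            return False
        if self.rearrangement is not None:
            x1, y1 = self.rearrangement
            x2, y2 = other.rearrangement
            if abs(x1 - x2) > tol or abs(y1 - y2) > tol:
                return False
        return True


@dataclass
class CopyAnnotation:
    """Structural annotation of a single copy."""

    copy_id: str
    has_left_tir: bool = False
    has_right_tir: bool = False
    longest_orf_codons: int = 0
    signature: BreakpointSignature = field(default_factory=BreakpointSignature)
    left_truncation_nt: int = 0
    right_truncation_nt: int = 0
    is_mite: bool = False
    mite_sublineage_id: str | None = None

    @property
    def potentially_coding(self) -> bool:
        return 330 <= self.longest_orf_codons <= 363

    @property
    def potentially_mobilizable(self) -> bool:
        return self.has_left_tir and self.has_right_tir


@dataclass
class CopyEventCount:
    """Per-copy mutation accounting relative to the lineage consensus."""

    substitutions: int = 0
    internal_deletion_events: int = 0
    internal_deletion_nt: int = 0
    truncation_nt: int = 0
    insertion_events: int = 0
    insertion_nt: int = 0
    aligned_nt: int = 0


@dataclass
class DecayProfile:
    """Lineage-level decay summary (deletions vs substitutions)."""

    lineage_id: str
    n_copies: int
    mean_divergence: float
    mean_size: float
    substitutions: int
    nt_lost: int
    nt_gained: int
    internal_deletion_nt_dedup: int
    truncation_nt_dedup: int
    del_sub_ratio: float
    internal_deletion_rate: float
    truncation_rate: float
    small_lineage: bool = False


@dataclass
class SiteBiasProfile:
    """T/A bias around the TA target-site duplication.

    ``offsets`` run -5..-1, 1..5 around the (collapsed) central TA.
    Fractions are the proportion of T-or-A at each offset; the background is
    measured over every TA occurrence in the supplied genomes.
    """

    offsets: list[int]
    observed: list[float]
    background: list[float]
    information_content: list[float]
    n_sites: int
    n_background: int
    n_excluded: int
    trinucleotides_5p: dict[str, int]
    trinucleotides_3p: dict[str, int]


@dataclass
class LTTCurve:
    """Lineage-through-time summary for one TE (sub)lineage.

    Node ages are substitutions/site before present, sorted oldest first;
    ``cumulative`` climbs by one per node so the final count is n_leaves - 1.
    """

    node_ages: list[float]
    cumulative: list[int]
    n_leaves: int
    bin_edges: list[float]
    bin_events: list[int]
    bin_copy_time: list[float]
    rate_per_copy: list[float]
    null_rate: float
    label: str = ""
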