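"""Assemble high-scoring pairs into TE copies and filter to the clean dataset.

The merge rule follows the discovery procedure for mariner copies: two hits
on the same scaffold merge when they share orientation and their centers lie
closer than 1000 bp, applied transitively so a copy fragmented into several
HSPs (e.g. by internal deletions) reunites. A copy interrupted by an
insertion longer than the merge distance stays split, by design. Copies keep
250 nt of flanking sequence on each side; copies with identical flanks
(segmental duplications) and copies truncated by the assembly (contig ends,
N runs) are flagged and excluded from the clean dataset used for statistics.
"""
from __future__ import annotations

import re
from collections import defaultdict

from .model import GenomeSequence, Hit, Interval, TECopy, revcomp

_N_RUN = re.compile(r"N{10,}")


def merge_hits(hits: list[Hit], max_center_distance: float = 1000.0) -> list[TECopy]:
    """Merge hits into copies: transitive closure of the center-distance rule.

    Hits on the same scaffold and strand whose centers lie strictly closer
    than ``max_center_distance`` belong to the same copy; the copy spans
    min(start)..max(end). Hits on different strands never merge.
    """
    groups: dict[tuple[str, str], list[Hit]] = defaultdict(list)
    for h in hits:
        groups[(h.location.scaffold_id, h.location.strand)].append(h)
    copies: list[TECopy] = []
    for (scaffold, strand), ghits in sorted(groups.items()):
        ghits.sort(key=lambda h: h.location.center)
        # on a line, the transitive closure of |c_i - c_j| < d is given by
        # chaining consecutive centers
        runs: list[list[Hit]] = [[ghits[0]]]
        for h in ghits[1:]:
            if h.location.center - runs[-1][-1].location.center < max_center_distance:
                runs[-1].append(h)
            else:
                runs.append([h])
        for run in runs:
            start = min(h.location.start for h in run)
            end = max(h.location.end for h in run)
            copies.append(TECopy(
                id=f"{scaffold}:{start}-{end}({strand})",
                location=Interval(scaffold, start, end, strand)))
    copies.sort(key=lambda c: (c.location.scaffold_id, c.location.start))
    return copies


def filter_min_length(copies: list[TECopy], min_length: int = 400) -> list[TECopy]:
    """Retain copies with length >= min_length (inclusive boundary)."""
    return [c for c in copies if c.length >= min_length]


def extract_with_flanks(copy: TECopy, genome: GenomeSequence,
                        flank_length: int = 250) -> TECopy:
    """Fill residues and flanks from the genome, strand-normalized.

    Flanks are clipped at scaffold boundaries. ``at_contig_end`` is set when
    either flank is shorter than ``flank_length`` or when a run of >=10 N
    lies within the flank window (``n_adjacent``).
    """
    if genome.id != copy.location.scaffold_id:
        raise KeyError(
            f"scaffold {copy.location.scaffold_id!r} does not match genome {genome.id!r}")
    s, e = copy.location.start, copy.location.end
    seq = genome.residues
    left_w = seq[max(0, s - flank_length):s]
    right_w = seq[e:e + flank_length]
    short = len(left_w) < flank_length or len(right_w) < flank_length
    n_adj = bool(_N_RUN.search(left_w)) or bool(_N_RUN.search(right_w))
    element = seq[s:e]
    if copy.location.strand == "-":
        element = revcomp(element)
        left_flank, right_flank = revcomp(right_w), revcomp(left_w)
    else:
        left_flank, right_flank = left_w, right_w
    return TECopy(id=copy.id, location=copy.location, residues=element,
                  left_flank=left_flank, right_flank=right_flank,
                  at_contig_end=short or n_adj, n_adjacent=n_adj,
                  lineage_id=copy.lineage_id, is_duplicate=copy.is_duplicate)


def _flank_identity(a: str, b: str) -> float:
    """Coverage-aware identity of two flank sequences (0 for an empty flank)."""
    from .lineages import coverage_identity  # local import: avoids import cycle
    if not a or not b:
        return 0.0
    return coverage_identity(a, b)


def _kmer_set(seq: str, k: int = 12) -> set[str]:
    return {seq[i:i + k] for i in range(0, max(0, len(seq) - k + 1))}


def dedup_segmental(copies: list[TECopy],
                    flank_identity_min: float = 0.90) -> list[TECopy]:
    """Flag segmental duplications: copies whose BOTH flanks match another's.

    Copies are grouped transitively when both flank pairs align at
    >= ``flank_identity_min``; one representative per group (longest copy,
    ties by smallest id) stays, the rest are flagged ``is_duplicate``.
    Candidate pairs are prefiltered by shared 12-mers in the left flank.
    """
    n = len(copies)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    kmer_index: dict[str, list[int]] = defaultdict(list)
    for i, c in enumerate(copies):
        for km in _kmer_set(c.left_flank):
            kmer_index[km].append(i)
    pair_votes: dict[tuple[int, int], int] = defaultdict(int)
    for km, idxs in kmer_index.items():
        if len(idxs) < 2 or len(idxs) > 50:
            continue
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                pair_votes[(idxs[ai], idxs[bi])] += 1
    for (i, j), votes in sorted(pair_votes.items()):
        if votes < 5 or find(i) == find(j):
            continue
        ci, cj = copies[i], copies[j]
        if _flank_identity(ci.left_flank, cj.left_flank) >= flank_identity_min and \
           _flank_identity(ci.right_flank, cj.right_flank) >= flank_identity_min:
            union(i, j)
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(i)
    out: list[TECopy] = []
    for members in groups.values():
        members.sort(key=lambda i: (-copies[i].length, copies[i].id))
        for rank, i in enumerate(members):
            c = copies[i]
            out.append(TECopy(id=c.id, location=c.location, residues=c.residues,
                              left_flank=c.left_flank, right_flank=c.right_flank,
                              at_contig_end=c.at_contig_end, n_adjacent=c.n_adjacent,
                              lineage_id=c.lineage_id, is_duplicate=rank > 0))
    out.sort(key=lambda c: (c.location.scaffold_id, c.location.start))
    return out


def clean_dataset(copies: list[TECopy]) -> list[TECopy]:
    """Independent, non-duplicated, non-contig-end copies."""
    return [c for c in copies if not c.is_duplicate and not c.at_contig_end]
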