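"""Cluster TE copies into lineages and build per-lineage consensus sequences.

A lineage is a cluster of copies sharing a recent ancestral sequence:
copies are clustered greedily (longest first) against cluster centroids at
a nucleotide identity threshold (default 80%), aligned, and summarized by a
relative-majority consensus in which terminal gaps (truncations) do not
vote and a majority internal gap yields a gap (the column is dropped from
the consensus). Clusters whose conceptual translation is closer to a
Tc1-family transposase than to any mariner reference are excluded.

Identity here is matches / alignment columns excluding terminal-gap
columns, a deliberately version-independent definition documented so the
0.80 threshold stays meaningful.
"""
from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .model import GenomeSequence, Interval, TECopy, revcomp
from .assembly import (dedup_segmental, extract_with_flanks, filter_min_length,
                       merge_hits)
from .search import NucleotideSearchParams, nucleotide_search


@lru_cache(maxsize=1)
def _global_nt_aligner() -> PairwiseAligner:
    # end gaps are nearly free (truncated copies must not pay for their
    # missing ends) but not exactly free: with zero-cost end gaps the
    # aligner staggers terminal mismatches into end gaps, which would make
    # "AAAA" vs "AAAT" read as 100% identity over a 3-column overlap
    al = PairwiseAligner()
    al.mode = "global"
    al.match_score = 2.0
    al.mismatch_score = -3.0
    al.open_gap_score = -5.0
    al.extend_gap_score = -2.0
    al.open_end_gap_score = -5.0
    al.extend_end_gap_score = -0.05
    return al


@lru_cache(maxsize=1)
def consensus_aligner() -> PairwiseAligner:
    """Copy-vs-consensus aligner: free end gaps, long-gap friendly.

    The stiff gap-open/soft gap-extend combination keeps one biological
    deletion as one gap block: with a cheaper open penalty the aligner
    splits long gaps around chance match islands, which would turn a
    single ancestral deletion into two spurious breakpoints.
    """
    al = PairwiseAligner()
    al.mode = "global"
    al.match_score = 2.0
    al.mismatch_score = -3.0
    al.open_gap_score = -24.0
    al.extend_gap_score = -0.25
    al.end_gap_score = 0.0
    return al


@lru_cache(maxsize=1)
def _protein_aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


def _gapped_rows(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def identity_from_rows(row_a: str, row_b: str) -> float:
    """Matches / alignment columns, excluding terminal-gap columns."""
    def span(row: str) -> tuple[int, int]:
        first = len(row) - len(row.lstrip("-"))
        last = len(row.rstrip("-"))
        return first, last

    a0, a1 = span(row_a)
    b0, b1 = span(row_b)
    lo, hi = max(a0, b0), min(a1, b1)
    if hi <= lo:
        return 0.0
    matches = sum(1 for x, y in zip(row_a[lo:hi], row_b[lo:hi]) if x == y and x != "-")
    return matches / (hi - lo)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity of two DNA sequences.

    Terminal-gap columns are excluded, so a fragment scores by how well it
    matches the region it covers rather than by its length.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _global_nt_aligner().align(a, b)[0]
    return identity_from_rows(*_gapped_rows(aln))


def coverage_identity(a: str, b: str) -> float:
    """Identity with a coverage floor: matches / max(overlap, min length).

    With free end gaps two unrelated sequences "align" over a few lucky
    columns at perfect identity; dividing by at least the shorter sequence
    length makes the score mean what clustering and flank comparison need
    (a fragment must still cover the shorter partner).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    row_a, row_b = _gapped_rows(_global_nt_aligner().align(a, b)[0])

    def span(row: str) -> tuple[int, int]:
        return len(row) - len(row.lstrip("-")), len(row.rstrip("-"))

    a0, a1 = span(row_a)
    b0, b1 = span(row_b)
    lo, hi = max(a0, b0), min(a1, b1)
    if hi <= lo:
        return 0.0
    matches = sum(1 for x, y in zip(row_a[lo:hi], row_b[lo:hi])
                  if x == y and x != "-")
    return matches / max(hi - lo, min(len(a), len(b)))


def _flip(copy: TECopy) -> TECopy:
    loc = copy.location
    return TECopy(id=copy.id,
                  location=Interval(loc.scaffold_id, loc.start, loc.end,
                                    "-" if loc.strand == "+" else "+"),
                  residues=revcomp(copy.residues),
                  left_flank=revcomp(copy.right_flank),
                  right_flank=revcomp(copy.left_flank),
                  at_contig_end=copy.at_contig_end, n_adjacent=copy.n_adjacent,
                  lineage_id=copy.lineage_id, is_duplicate=copy.is_duplicate)


def greedy_cluster(copies: list[TECopy], threshold: float = 0.80
                   ) -> list[list[TECopy]]:
    """Greedy centroid clustering, longest copy first.

    Each copy joins the first existing centroid it matches at
    >= ``threshold`` identity (its reverse complement is tested too, and the
    copy is re-oriented on joining); otherwise it founds a new centroid.
    """
    ordered = sorted(copies, key=lambda c: (-len(c.residues), c.id))
    centroids: list[str] = []
    clusters: list[list[TECopy]] = []
    for copy in ordered:
        placed = False
        for ci, cen in enumerate(centroids):
            fwd = coverage_identity(copy.residues, cen)
            rev = coverage_identity(revcomp(copy.residues), cen)
            if max(fwd, rev) >= threshold:
                clusters[ci].append(copy if fwd >= rev else _flip(copy))
                placed = True
                break
        if not placed:
            centroids.append(copy.residues)
            clusters.append([copy])
    return clusters


# ---------------------------------------------------------------------------
# multiple alignment and consensus
# ---------------------------------------------------------------------------

def build_msa(seqs: list[tuple[str, str]], threads: int = 1
              ) -> list[tuple[str, str]]:
    """Progressive multiple alignment of (name, sequence) pairs via MAFFT.

    Input order is preserved; a single sequence aligns to itself. Only the
    contract matters downstream (the consensus and breakpoint logic never
    depend on MAFFT internals).
    """
    if not seqs:
        return []
    if len(seqs) == 1:
        return list(seqs)
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fa"
        with open(inp, "w") as fh:
            for i, (_name, seq) in enumerate(seqs):
                fh.write(f">s{i}\n{seq}\n")
        res = subprocess.run(
            ["mafft", "--retree", "2", "--maxiterate", "0", "--quiet",
             "--thread", str(threads), str(inp)],
            capture_output=True, text=True, check=True)
    rows: dict[int, str] = {}
    cur = None
    buf: list[str] = []
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            if cur is not None:
                rows[cur] = "".join(buf)
            cur = int(line[2:])
            buf = []
        else:
            buf.append(line.strip())
    if cur is not None:
        rows[cur] = "".join(buf)
    return [(seqs[i][0], rows[i].upper()) for i in range(len(seqs))]


def _terminal_mask(mat: np.ndarray) -> np.ndarray:
    """Boolean mask of terminal-gap cells in a rows x columns gap matrix."""
    gaps = mat == "-"
    lead = np.cumsum(~gaps, axis=1) == 0
    trail = (np.cumsum(~gaps[:, ::-1], axis=1) == 0)[:, ::-1]
    return gaps & (lead | trail)


def consensus_from_alignment(rows: list[str], tie_priority: str = "ACGT-",
                             end_trim_support: float = 0.30,
                             boundary_rule: str = "support",
                             boundary_window: int = 10,
                             ) -> tuple[str, list[int]]:
    """Relative-majority consensus of a gapped alignment.

    Per column the most frequent symbol wins; terminal gaps do not vote;
    a majority internal gap puts a gap in the consensus (the column is
    dropped), as are all-gap columns. Ties resolve by the fixed priority
    A>C>G>T>gap.

    Consensus ends are trimmed deterministically (a stand-in for manual
    end curation). boundary_rule "support": keep the outermost columns
    with >= ``end_trim_support`` residue support. boundary_rule
    "conservation": keep the span between the outermost runs of
    ``boundary_window`` consecutive columns whose winning base is carried
    by a strict majority of rows -- the rule used when copies are aligned
    together with their genomic flanks, where per-copy random flank
    sequence keeps high occupancy but never sustained majority agreement.
    Returns the consensus and the alignment-column index of each
    consensus position.
    """
    if not rows:
        return "", []
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment")
    mat = np.array([list(r) for r in rows])
    terminal = _terminal_mask(mat)
    n_rows = len(rows)
    counts = {}
    for sym in "ACGT":
        counts[sym] = ((mat == sym) & ~terminal).sum(axis=0)
    counts["-"] = ((mat == "-") & ~terminal).sum(axis=0)
    if boundary_rule == "conservation":
        # windowed mean winner-fraction: random per-copy flanks (even
        # A/T-biased ones, whose vote splits between A and T) cannot
        # sustain it, while alignment wobble at the element junction only
        # dilutes a few columns and is absorbed by the window mean
        winner = np.maximum.reduce([counts[s] for s in "ACGT"]) / n_rows
        window = max(boundary_window, 20)
        if winner.size < window:
            return "", []
        means = np.convolve(winner, np.ones(window) / window, mode="valid")
        run_ids = np.nonzero(means >= 0.6)[0]
        if run_ids.size == 0:
            return "", []
        c0 = int(run_ids[0])
        c1 = int(run_ids[-1]) + window
    elif boundary_rule == "support":
        support = sum(counts[s] for s in "ACGT") / n_rows
        kept_cols = np.nonzero(support >= end_trim_support)[0]
        if kept_cols.size == 0:
            return "", []
        c0, c1 = int(kept_cols[0]), int(kept_cols[-1]) + 1
    else:
        raise ValueError(f"unknown boundary rule {boundary_rule!r}")
    consensus: list[str] = []
    col_map: list[int] = []
    for col in range(c0, c1):
        best_sym, best_n = None, 0
        for sym in tie_priority:
            n = int(counts[sym][col])
            if n > best_n:
                best_sym, best_n = sym, n
        if best_sym is None or best_sym == "-":
            continue  # all-gap or majority-internal-gap column: gap in consensus
        consensus.append(best_sym)
        col_map.append(col)
    cons = "".join(consensus)
    if boundary_rule == "conservation" and len(cons) > 8 and \
            cons.startswith("TA") and cons.endswith("TA"):
        # the duplicated target TA is conserved on both sides of every copy
        # and survives the conservation rule; it is TSD, not element
        cons = cons[2:-2]
        col_map = col_map[2:-2]
    return cons, col_map


def refine_element_boundaries(consensus_ext: str, window: int = 500,
                              min_tir: int = 20, min_identity: float = 0.75
                              ) -> tuple[str, int] | None:
    """Trim a flank-extended consensus to its element span via the TIRs.

    Mariner elements begin and end with terminal inverted repeats, so the
    element span inside a consensus that still carries flanking junk is
    delimited by the best inverted-repeat match between the two ends.
    Returns (trimmed consensus, TIR length), or None when no credible TIR
    pair is found (e.g. a decayed lineage with degraded ends).
    """
    from .search import _nt_aligner
    L = len(consensus_ext)
    if L < 120:
        return None
    w = min(window, L // 2)
    head = consensus_ext[:w]
    rc_tail = revcomp(consensus_ext[-w:])
    aln = _nt_aligner(1.0, -2.0, -2.5).align(head, rc_tail)
    if len(aln) == 0:
        return None
    tblocks, qblocks = aln[0].aligned
    if len(tblocks) == 0:
        return None
    t1 = int(tblocks[-1][1])
    # per-column (head_pos, rc_tail_pos, match) of the local alignment
    cols: list[tuple[int, int, bool]] = []
    matches = 0
    columns = 0
    prev = None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if prev is not None:
            columns += (ts - prev[0]) + (qs - prev[1])
        for k in range(te - ts):
            m = head[ts + k] == rc_tail[qs + k]
            cols.append((ts + k, qs + k, m))
            matches += m
            columns += 1
        prev = (te, qe)
    span = t1 - int(tblocks[0][0])
    if span < min_tir or columns == 0 or matches / columns < min_identity:
        return None
    # chance matches drag the alignment outward into flank junk: anchor the
    # outer boundary at the first run of 6 consecutive exact matches
    run = 0
    anchor = None
    for idx, (_hp, _qp, m) in enumerate(cols):
        run = run + 1 if m else 0
        if run == 6:
            anchor = idx - 5
            break
    if anchor is None:
        return None
    start = cols[anchor][0]
    end = L - cols[anchor][1]
    # the duplicated target TA flanks the element on both sides and matches
    # itself under reverse complement; strip it when present on both ends
    if consensus_ext[start:start + 2] == "TA" and \
       consensus_ext[end - 2:end] == "TA":
        start += 2
        end -= 2
    if end - start < 100:
        return None
    return consensus_ext[start:end], span


# ---------------------------------------------------------------------------
# family / subfamily classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyCall:
    family_call: str      # "mariner" | "tc1_like" | "other"
    subfamily: str        # subfamily label, or "other"
    catalytic_motif: str | None  # secondary flag: "DD34D"/"DD34E"/None
    best_reference: str | None
    score: float


def classify_family(consensus_aa: str, panel, score_floor: float = 60.0
                    ) -> FamilyCall:
    """Nearest-reference family and subfamily call for a lineage transposase.

    The best-scoring panel member under local protein alignment determines
    the family; among mariner references the best hit's subfamily label is
    assigned. The DD34D-vs-DD34E catalytic-triad check is reported as a
    secondary flag, never overriding the alignment call.
    """
    from .panel import dd_motif
    motif = dd_motif(consensus_aa) if consensus_aa else None
    if not consensus_aa:
        return FamilyCall("other", "other", motif, None, 0.0)
    aligner = _protein_aligner()
    best = None
    best_score = 0.0
    for entry in panel:
        score = float(aligner.score(entry.sequence, consensus_aa))
        if best is None or score > best_score:
            best, best_score = entry, score
    if best is None or best_score < score_floor:
        return FamilyCall("other", "other", motif, None, best_score)
    subfamily = best.subfamily if best.family == "mariner" else "other"
    return FamilyCall(best.family, subfamily, motif, best.name, best_score)


def conceptual_translation(consensus_nt: str) -> str:
    """Translate the longest stop-free codon run of the consensus."""
    from .annotation import longest_orf_region
    from .search import translate
    frame, start, n_codons = longest_orf_region(consensus_nt)
    if n_codons == 0:
        return ""
    sub = consensus_nt[start:start + 3 * n_codons]
    return translate(sub, 1)


# ---------------------------------------------------------------------------
# consensus-driven second-pass copy recovery
# ---------------------------------------------------------------------------

def recover_all_copies(consensus_nt: str, genomes: list[GenomeSequence],
                       first_pass: list[TECopy] | None = None,
                       nt_params: NucleotideSearchParams | None = None,
                       max_center_distance: float = 1000.0,
                       min_length: int = 400, flank_length: int = 250,
                       flank_identity_min: float = 0.90,
                       query_id: str = "consensus") -> list[TECopy]:
    """Find every copy of a lineage by nucleotide search with its consensus.

    Hits are merged, flank-extracted and deduplicated exactly as in the
    first pass; recovered copies supersede first-pass copies they overlap
    by >= 50% (of the shorter interval). This recovers short internally
    deleted derivatives that carry no recognizable transposase.
    """
    first_pass = first_pass or []
    copies: list[TECopy] = []
    for genome in genomes:
        hits = nucleotide_search(consensus_nt, genome, nt_params, query_id=query_id)
        merged = merge_hits(hits, max_center_distance)
        merged = filter_min_length(merged, min_length)
        copies.extend(extract_with_flanks(c, genome, flank_length) for c in merged)
    copies = dedup_segmental(copies, flank_identity_min)
    out = list(copies)
    for fp in first_pass:
        superseded = False
        for sp in copies:
            ov = fp.location.overlap(sp.location)
            if ov >= 0.5 * min(fp.length, sp.length):
                superseded = True
                break
        if not superseded:
            out.append(fp)
    out.sort(key=lambda c: (c.location.scaffold_id, c.location.start))
    return out
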