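"""Structural annotation of TE copies.

Each copy is aligned to its lineage consensus; from that single alignment
come the TIR presence calls, the internal-deletion breakpoints (terminal
gap runs are truncations, not deletions), the insertion record, and the
5'->3' rearrangement test. Breakpoint signatures key MITE sublineages:
short copies (< 1000 nt) carrying both TIRs and a shared deletion or
rearrangement signature form a sublineage, accepted as a MITE only when
at least two members sit at genuinely different loci (different flanks),
i.e. show evidence of transposition rather than segmental duplication.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BreakpointSignature, CopyAnnotation, TECopy, revcomp
from .lineages import consensus_aligner, identity_from_rows, _gapped_rows
from .search import _nt_aligner


@dataclass
class CopyProfile:
    """A copy expressed in consensus coordinates.

    ``profile`` has exactly one symbol per consensus position: the copy's
    residue, or '-' where the copy lacks that position. ``insertions`` are
    (consensus_position, inserted_sequence) for copy residues that fall
    opposite consensus gaps.
    """

    copy_id: str
    profile: str
    insertions: list[tuple[int, str]]


def align_to_consensus(copy_seq: str, consensus: str) -> tuple[str, str]:
    """Globally align a copy to the consensus with free end gaps.

    Returns (consensus_row, copy_row) as gapped strings of equal length.
    """
    aln = consensus_aligner().align(consensus, copy_seq)[0]
    return _gapped_rows(aln)


def profile_from_rows(cons_row: str, copy_row: str,
                      copy_id: str = "") -> CopyProfile:
    """Project an aligned copy row onto consensus coordinates."""
    profile: list[str] = []
    insertions: list[tuple[int, str]] = []
    pos = 0
    pending: list[str] = []
    for c_sym, k_sym in zip(cons_row, copy_row):
        if c_sym == "-":
            if k_sym != "-":
                pending.append(k_sym)
        else:
            if pending:
                insertions.append((pos, "".join(pending)))
                pending = []
            profile.append(k_sym)
            pos += 1
    if pending:
        insertions.append((pos, "".join(pending)))
    return CopyProfile(copy_id=copy_id, profile="".join(profile),
                       insertions=insertions)


def build_profile(copy_seq: str, consensus: str, copy_id: str = "") -> CopyProfile:
    cons_row, copy_row = align_to_consensus(copy_seq, consensus)
    return profile_from_rows(cons_row, copy_row, copy_id)


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf_region(seq: str) -> tuple[int, int, int]:
    """(frame, start_nt, n_codons) of the longest stop-free codon run.

    Only the three forward frames are scanned (copies are strand-normalized
    upstream); a start codon is not required, so relic copies with a
    degraded ATG still report their frame length.
    """
    best = (0, 0, 0)
    for frame in range(3):
        n_codons = (len(seq) - frame) // 3
        run_start = 0
        run_len = 0
        for ci in range(n_codons):
            codon = seq[frame + 3 * ci: frame + 3 * ci + 3]
            if codon in _STOPS:
                run_len = 0
                run_start = ci + 1
            else:
                run_len += 1
                if run_len > best[2]:
                    best = (frame, frame + 3 * run_start, run_len)
    return best


def scan_orf(copy_residues: str) -> int:
    """Longest stop-free codon run over the three forward frames, in codons."""
    return longest_orf_region(copy_residues)[2]


# ---------------------------------------------------------------------------
# TIRs, breakpoints, rearrangements
# ---------------------------------------------------------------------------

def detect_tirs(profile: CopyProfile, consensus: str, mode: str = "paper",
                end_window: int = 5, strict_tir_len: int = 30,
                strict_identity: float = 0.80) -> tuple[bool, bool]:
    """TIR presence calls for one copy.

    Mode "paper": a TIR is present iff the copy's alignment reaches within
    ``end_window`` columns of the consensus terminus on that side (the copy
    is not end-truncated). Mode "strict" additionally requires the terminal
    ``strict_tir_len`` nt to match the consensus TIR at >= 80% identity.
    """
    if len(consensus) < 2 * strict_tir_len:
        raise ValueError("consensus too short for TIR calling")
    prof = profile.profile
    L = len(prof)
    first = L - len(prof.lstrip("-"))
    last = len(prof.rstrip("-"))  # exclusive
    left = first <= end_window
    right = (L - last) <= end_window
    if mode == "strict":
        def term_identity(sl: slice) -> float:
            seg = prof[sl]
            ref = consensus[sl]
            matches = sum(1 for a, b in zip(seg, ref) if a == b and a != "-")
            return matches / len(ref)
        left = left and term_identity(slice(0, strict_tir_len)) >= strict_identity
        right = right and term_identity(slice(L - strict_tir_len, L)) >= strict_identity
    elif mode != "paper":
        raise ValueError(f"unknown TIR mode {mode!r}")
    return left, right


def call_breakpoints(profile: CopyProfile) -> tuple[BreakpointSignature, int, int]:
    """Deletion intervals (consensus coordinates) and truncation lengths.

    Maximal internal gap runs in the copy row become deletion intervals;
    terminal gap runs are truncations and never count as deletions.
    Returns (signature, left_truncation_nt, right_truncation_nt).
    """
    prof = profile.profile
    L = len(prof)
    first = L - len(prof.lstrip("-"))
    last = len(prof.rstrip("-"))
    deletions: list[tuple[int, int]] = []
    run_start = None
    for i in range(first, last):
        if prof[i] == "-":
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                deletions.append((run_start, i))
                run_start = None
    return BreakpointSignature(deletions=deletions), first, L - last


def detect_rearrangement(copy_seq: str, consensus: str,
                         min_match: int = 50, min_identity: float = 0.80,
                         end_slack: int = 30) -> tuple[int, int] | None:
    """Detect 3'-replaced-by-inverted-5' copies: C[0:x] + revcomp(C[0:y]).

    The copy's 3' region is aligned to the reverse complement of the
    consensus 5' region; a match of >= ``min_match`` nt at >=
    ``min_identity`` reaching the copy's 3' end and the consensus 5'
    terminus reports (x, y). The minimum TIR-sized hit is rejected by the
    length floor, so ordinary full-length copies (whose right TIR is the
    inverted left TIR) do not trigger.
    """
    if len(copy_seq) < 200:
        return None
    half = len(consensus) // 2 + 100
    target_rc = revcomp(consensus[:half])
    aligner = _nt_aligner(1.0, -2.0, -2.5)
    alns = aligner.align(target_rc, copy_seq)
    if len(alns) == 0:
        return None
    aln = alns[0]
    tblocks, qblocks = aln.aligned
    if len(tblocks) == 0:
        return None
    t0, t1 = int(tblocks[0][0]), int(tblocks[-1][1])
    q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
    matches = 0
    columns = 0
    prev = None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        matches += sum(1 for a, b in zip(target_rc[ts:te], copy_seq[qs:qe]) if a == b)
        columns += te - ts
        if prev is not None:
            columns += (ts - prev[0]) + (qs - prev[1])
        prev = (te, qe)
    span = t1 - t0
    if span < min_match or columns == 0 or matches / columns < min_identity:
        return None
    # the inverted fragment must reach the copy's 3' end and the consensus
    # 5' terminus (i.e. the end of revcomp(consensus 5' region))
    if len(copy_seq) - q1 > end_slack or half - t1 > end_slack:
        return None
    if q0 < 30:
        return None        # pure inverted fragment, not a 5'+inverted-5' structure
    # refine the junction x: local alignments over-extend by chance matches,
    # so place the breakpoint where cumulative forward-match support before x
    # plus inverted-match support after x is maximal
    fwd_match = _per_position_matches_global(copy_seq, consensus)
    inv_match, inv_tpos = _per_position_matches_local(aln, len(copy_seq))
    n = len(copy_seq)
    pre = np.cumsum(np.concatenate([[0], fwd_match]))
    post = np.cumsum(np.concatenate([[0], inv_match[::-1]]))[::-1]
    lo, hi = max(0, q0 - 40), min(n, q0 + 41)
    best_x, best_val = q0, -1
    for j in range(lo, hi):
        val = pre[j] + post[j]
        if val > best_val or (val == best_val and abs(j - q0) < abs(best_x - q0)):
            best_val, best_x = val, j
    x = int(best_x)
    tx = inv_tpos[x] if x < n and inv_tpos[x] >= 0 else None
    if tx is None:
        # x beyond/before the inverted alignment: fall back to its raw start
        tx = t0 + max(0, x - q0)
    y = half - int(tx)
    if y < min_match:
        return None
    return (x, y)


def _per_position_matches_global(copy_seq: str, consensus: str) -> "np.ndarray":
    """match indicator per copy position under the free-end global alignment."""
    cons_row, copy_row = align_to_consensus(copy_seq, consensus)
    out = np.zeros(len(copy_seq), dtype=np.int32)
    pos = 0
    for c_sym, k_sym in zip(cons_row, copy_row):
        if k_sym != "-":
            if c_sym == k_sym:
                out[pos] = 1
            pos += 1
    return out


def _per_position_matches_local(aln, n: int) -> tuple["np.ndarray", "np.ndarray"]:
    """(match indicator, aligned target position) per copy position of a
    local alignment (target positions -1 outside the aligned span)."""
    out = np.zeros(n, dtype=np.int32)
    tpos = np.full(n, -1, dtype=np.int32)
    tblocks, qblocks = aln.aligned
    target, query = aln.target, aln.query
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for k in range(qe - qs):
            tpos[qs + k] = ts + k
            if target[ts + k] == query[qs + k]:
                out[qs + k] = 1
    return out, tpos


# ---------------------------------------------------------------------------
# MITE sublineages
# ---------------------------------------------------------------------------

def _distinct_flanks(a: TECopy, b: TECopy, flank_identity_max: float) -> bool:
    """True when the two copies sit at different loci (transposition evidence)."""
    from .lineages import coverage_identity
    for fa, fb in ((a.left_flank, b.left_flank), (a.right_flank, b.right_flank)):
        if not fa or not fb:
            return True
        if coverage_identity(fa, fb) < flank_identity_max:
            return True
    return False


def group_mite_sublineages(copies: list[TECopy],
                           annotations: dict[str, CopyAnnotation],
                           lineage_id: str = "lineage",
                           max_length: int = 999,
                           breakpoint_tolerance: int = 5,
                           flank_identity_max: float = 0.90
                           ) -> list[list[str]]:
    """Group short two-TIR copies into MITE sublineages by shared signature.

    Candidates are copies < 1000 nt with both TIRs and a non-empty
    deletion/rearrangement signature. Candidates whose signatures agree
    within the breakpoint tolerance group transitively; a group becomes a
    sublineage iff at least two members have pairwise-distinct flanking
    regions. Accepted members get ``is_mite`` and a sublineage id; the
    caller separates them from the full-length lineage for statistics.
    """
    cands = [c for c in copies
             if len(c.residues) <= max_length
             and c.id in annotations
             and annotations[c.id].potentially_mobilizable
             and not annotations[c.id].signature.is_empty]
    n = len(cands)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            si = annotations[cands[i].id].signature
            sj = annotations[cands[j].id].signature
            if si.matches(sj, breakpoint_tolerance):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    accepted: list[list[str]] = []
    for members in groups.values():
        if len(members) < 2:
            continue
        ok = any(_distinct_flanks(cands[i], cands[j], flank_identity_max)
                 for ai, i in enumerate(members) for j in members[ai + 1:])
        if ok:
            accepted.append(sorted(cands[i].id for i in members))
    accepted.sort(key=lambda g: (-len(g), g[0]))
    for k, group in enumerate(accepted, start=1):
        sub_id = f"{lineage_id}_M{k}"
        for cid in group:
            annotations[cid].is_mite = True
            annotations[cid].mite_sublineage_id = sub_id
    return accepted


def annotate_copy(copy: TECopy, consensus: str, tir_mode: str = "paper"
                  ) -> tuple[CopyAnnotation, CopyProfile]:
    """Full structural annotation of one copy against its consensus.

    For rearranged copies (3' replaced by inverted 5') the breakpoint
    profile is computed from the kept forward part only, so the inverted
    tail does not produce spurious deletion calls; the inverted terminus
    acts as the copy's (long) right TIR.
    """
    rearr = detect_rearrangement(copy.residues, consensus)
    if rearr is not None:
        x, _y = rearr
        profile = build_profile(copy.residues[:x], consensus, copy.id)
        left, _ = detect_tirs(profile, consensus, mode=tir_mode)
        right = True  # the inverted 5' fragment carries the element terminus
        signature, ltrunc, rtrunc = call_breakpoints(profile)
        signature = BreakpointSignature(deletions=signature.deletions,
                                        rearrangement=rearr)
    else:
        profile = build_profile(copy.residues, consensus, copy.id)
        left, right = detect_tirs(profile, consensus, mode=tir_mode)
        signature, ltrunc, rtrunc = call_breakpoints(profile)
    ann = CopyAnnotation(copy_id=copy.id, has_left_tir=left, has_right_tir=right,
                         longest_orf_codons=scan_orf(copy.residues),
                         signature=signature, left_truncation_nt=ltrunc,
                         right_truncation_nt=rtrunc)
    return ann, profile
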