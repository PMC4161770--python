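"""Decay, divergence, insertion-site bias and gene-proximity statistics.

Divergence of a copy from its lineage consensus counts substitutions plus
indel EVENTS over the nucleotides aligning with the consensus; truncations
and large insertions (> 1000 nt, indicative of a nested element) stay out
of the numerator. At the lineage level, deletion events shared by several
copies (they occurred before transposition) are counted once, which is why
the deletion/substitution ratio needs the event-matching tolerance rather
than a naive per-copy sum.
"""
from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy import special, stats as sps

from .model import (CopyEventCount, DecayProfile, GenomeSequence, Interval,
                    SiteBiasProfile, TECopy)
from .annotation import CopyProfile, call_breakpoints

LARGE_INSERTION_NT = 1000


def count_events(profile: CopyProfile, consensus: str) -> CopyEventCount:
    """Per-copy substitution / indel accounting relative to the consensus."""
    prof = profile.profile
    if len(prof) != len(consensus):
        raise ValueError("profile/consensus length mismatch")
    signature, ltrunc, rtrunc = call_breakpoints(profile)
    subs = sum(1 for a, b in zip(prof, consensus) if a != "-" and a != b)
    aligned = sum(1 for a in prof if a != "-")
    del_nt = sum(e - s for s, e in signature.deletions)
    ins_events = 0
    ins_nt = 0
    for _pos, seq in profile.insertions:
        ins_nt += len(seq)
        if len(seq) <= LARGE_INSERTION_NT:
            ins_events += 1
    return CopyEventCount(substitutions=subs,
                          internal_deletion_events=len(signature.deletions),
                          internal_deletion_nt=del_nt,
                          truncation_nt=ltrunc + rtrunc,
                          insertion_events=ins_events,
                          insertion_nt=ins_nt,
                          aligned_nt=aligned)


def copy_divergence(events: CopyEventCount) -> float:
    """(substitutions + deletion events + insertion events) / aligned nt."""
    if events.aligned_nt == 0:
        raise ValueError("copy does not align to the consensus")
    return (events.substitutions + events.internal_deletion_events
            + events.insertion_events) / events.aligned_nt


def _dedup_intervals(intervals: list[tuple[int, int]], tol: int
                     ) -> list[tuple[int, int]]:
    """Collapse intervals identical within +-tol at both ends (shared events)."""
    unique: list[tuple[int, int]] = []
    for iv in sorted(intervals):
        if not any(abs(iv[0] - u[0]) <= tol and abs(iv[1] - u[1]) <= tol
                   for u in unique):
            unique.append(iv)
    return unique


def lineage_decay_profile(lineage_id: str,
                          copies: list[TECopy],
                          profiles: list[CopyProfile],
                          consensus: str,
                          min_copies: int = 10,
                          breakpoint_tolerance: int = 5) -> DecayProfile:
    """Lineage-level decay summary with shared deletions counted once.

    Internal deletions (and truncation boundaries) matching within the
    breakpoint tolerance across copies are redundant -- they predate a
    transposition -- and enter ``nt_lost`` exactly once. Substitutions are
    summed per copy. Lineages below ``min_copies`` are flagged rather than
    rejected.
    """
    per_copy = [count_events(p, consensus) for p in profiles]
    all_dels: list[tuple[int, int]] = []
    truncs: list[tuple[int, int]] = []  # (side marker, boundary) as intervals
    for prof in profiles:
        sig, lt, rt = call_breakpoints(prof)
        all_dels.extend(sig.deletions)
        if lt:
            truncs.append((0, lt))
        if rt:
            truncs.append((len(consensus) - rt, len(consensus)))
    uniq_dels = _dedup_intervals(all_dels, breakpoint_tolerance)
    uniq_truncs = _dedup_intervals(truncs, breakpoint_tolerance)
    del_nt = sum(e - s for s, e in uniq_dels)
    trunc_nt = sum(e - s for s, e in uniq_truncs)
    nt_lost = del_nt + trunc_nt
    nt_gained = sum(ev.insertion_nt for ev in per_copy)
    subs = sum(ev.substitutions for ev in per_copy)
    divs = [copy_divergence(ev) for ev in per_copy if ev.aligned_nt > 0]
    sizes = [len(c.residues) for c in copies]
    ratio = nt_lost / subs if subs > 0 else 0.0
    return DecayProfile(
        lineage_id=lineage_id, n_copies=len(copies),
        mean_divergence=float(np.mean(divs)) if divs else 0.0,
        mean_size=float(np.mean(sizes)) if sizes else 0.0,
        substitutions=subs, nt_lost=nt_lost, nt_gained=nt_gained,
        internal_deletion_nt_dedup=del_nt, truncation_nt_dedup=trunc_nt,
        del_sub_ratio=ratio,
        internal_deletion_rate=del_nt / subs if subs > 0 else 0.0,
        truncation_rate=trunc_nt / subs if subs > 0 else 0.0,
        small_lineage=len(copies) < min_copies)


def size_divergence_regression(profiles: list[DecayProfile]
                               ) -> tuple[float, float, float]:
    """OLS of lineage mean copy size on lineage divergence: (slope, intercept, r)."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 lineages for the regression")
    x = np.array([p.mean_divergence for p in profiles])
    y = np.array([p.mean_size for p in profiles])
    if np.allclose(y, y[0]):
        return 0.0, float(y[0]), 0.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


# ---------------------------------------------------------------------------
# TA insertion-site bias
# ---------------------------------------------------------------------------

OFFSETS = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5)


def _ta_context_background(genomes: list[GenomeSequence]
                           ) -> tuple[np.ndarray, int]:
    """%T-or-A at offsets +-1..5 over every TA occurrence in the genomes."""
    frac = np.zeros(10)
    counts = np.zeros(10)
    total = 0
    for g in genomes:
        arr = np.frombuffer(g.residues.encode("ascii"), dtype=np.uint8)
        is_t = arr == ord("T")
        is_a = arr == ord("A")
        ta = np.nonzero(is_t[:-1] & is_a[1:])[0]  # TA at (i, i+1)
        ta = ta[(ta >= 5) & (ta + 6 < len(arr))]
        total += ta.size
        at = is_t | is_a
        for k, off in enumerate(OFFSETS):
            pos = ta + off if off < 0 else ta + 1 + off
            frac[k] += at[pos].sum()
            counts[k] += pos.size
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, frac / counts, np.nan), total


def insertion_site_profile(copies: list[TECopy],
                           genomes: list[GenomeSequence],
                           trinucleotide_min_count: int = 5
                           ) -> SiteBiasProfile:
    """T/A fraction around insertion sites vs the genome-wide TA background.

    Each copy must carry the duplicated target TA on both flanks; the
    element is removed and the duplicated TA collapsed to a single central
    TA before offsets are read. Copies without a flanking TA on both sides
    are excluded (their count is reported). Information content per
    position is 2 - Shannon entropy (bits) of the 4-symbol column;
    trinucleotide tallies are reported only above ``trinucleotide_min_count``.
    """
    contexts: list[tuple[str, str]] = []
    n_excluded = 0
    for c in copies:
        lf, rf = c.left_flank, c.right_flank
        if len(lf) >= 7 and len(rf) >= 7 and lf.endswith("TA") and rf.startswith("TA"):
            contexts.append((lf[:-2][-5:], rf[2:][:5]))
        else:
            n_excluded += 1
    observed = []
    info = []
    tri5: Counter = Counter()
    tri3: Counter = Counter()
    cols: dict[int, Counter] = {k: Counter() for k in range(10)}
    for left5, right5 in contexts:
        for k, off in enumerate(OFFSETS):
            sym = left5[5 + off] if off < 0 else right5[off - 1]
            cols[k][sym] += 1
        tri5[left5[-3:]] += 1
        tri3[right5[:3]] += 1
    for k in range(10):
        col = cols[k]
        n = sum(col.values())
        if n == 0:
            observed.append(float("nan"))
            info.append(0.0)
            continue
        observed.append((col["T"] + col["A"]) / n)
        ent = 0.0
        for sym in "ACGT":
            p = col[sym] / n
            if p > 0:
                ent -= p * math.log2(p)
        info.append(2.0 - ent)
    background, n_bg = _ta_context_background(genomes)
    return SiteBiasProfile(
        offsets=list(OFFSETS), observed=observed,
        background=[float(b) for b in background],
        information_content=info, n_sites=len(contexts),
        n_background=n_bg, n_excluded=n_excluded,
        trinucleotides_5p={t: n for t, n in sorted(tri5.items())
                           if n > trinucleotide_min_count},
        trinucleotides_3p={t: n for t, n in sorted(tri3.items())
                           if n > trinucleotide_min_count})


# ---------------------------------------------------------------------------
# gene proximity
# ---------------------------------------------------------------------------

def distance_to_cds(copies: list[TECopy], cds_features: list[Interval]
                    ) -> tuple[dict[str, int], float]:
    """Distance from each copy to the nearest CDS on its scaffold.

    Returns (distances by copy id, fraction of copies on CDS-bearing
    scaffolds). Copies on scaffolds without any CDS are excluded from the
    distance table but remain in the fraction's denominator. Overlap
    counts as distance 0.
    """
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for f in cds_features:
        by_scaffold.setdefault(f.scaffold_id, []).append((f.start, f.end))
    for ivs in by_scaffold.values():
        ivs.sort()
    distances: dict[str, int] = {}
    n_on = 0
    for c in copies:
        ivs = by_scaffold.get(c.location.scaffold_id)
        if not ivs:
            continue
        n_on += 1
        best = None
        for s, e in ivs:
            if e <= c.location.start:
                d = c.location.start - e
            elif s >= c.location.end:
                d = s - c.location.end
            else:
                d = 0
            best = d if best is None else min(best, d)
        distances[c.id] = int(best)
    fraction = n_on / len(copies) if copies else 0.0
    return distances, fraction


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the maximum absolute ECDF difference; the p-value comes from the
    asymptotic Kolmogorov distribution at the effective sample size
    sqrt(n_x n_y / (n_x + n_y)), with the usual finite-sample argument
    correction (sqrt(en) + 0.12 + 0.11/sqrt(en)) that keeps the size of
    the test close to nominal at moderate n.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / x.size
    cdf_y = np.searchsorted(y, grid, side="right") / y.size
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = math.sqrt(x.size * y.size / (x.size + y.size))
    arg = (en + 0.12 + 0.11 / en) * d
    p = float(special.kolmogorov(arg))
    return d, min(1.0, p)
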