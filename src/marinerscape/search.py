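"""Built-in seeded homology search.

Two BLAST-like passes keep the pipeline self-contained: a protein query
against the six-frame translation of a genome (exact amino-acid seeding,
ungapped X-drop extension under BLOSUM62) and a nucleotide query against
both strands (exact-word seeding, gapped local extension). Real-assembly
runs can bypass both via externally computed BLAST tabular hits
(:func:`marinerscape.io.read_tabular_hits`).

No E-value statistics are attempted: the protein pass reports a
database-size-independent bit score ``(lambda*S - ln K)/ln 2`` with the
ungapped BLOSUM62 constants, thresholded at 50 bits by default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

from .model import GenomeSequence, Hit, Interval, revcomp

# Karlin-Altschul constants for ungapped BLOSUM62 (used only to put raw
# scores on the familiar bit scale; not for E-values).
_LAMBDA = 0.3176
_K = 0.134
_LN2 = math.log(2.0)


def bit_score(raw: float) -> float:
    return (_LAMBDA * raw - math.log(_K)) / _LN2


@dataclass
class ProteinSearchParams:
    seed_length: int = 4
    xdrop: float = 30.0
    min_bit_score: float = 50.0
    max_extension: int = 600


@dataclass
class NucleotideSearchParams:
    word_size: int = 20
    min_identity: float = 0.80
    min_length: int = 100
    diag_tolerance: int = 50
    chain_gap: int = 400
    pad: int = 150
    match: float = 1.0
    mismatch: float = -2.0
    gap: float = -2.5


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _codon_map() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def translate(dna: str, frame: int = 1) -> str:
    """Translate one frame (+1..+3 forward, -1..-3 on the reverse complement).

    Stops are emitted as '*'; codons containing N (or any non-ACGT symbol)
    are emitted as 'X'.
    """
    cmap = _codon_map()
    seq = dna if frame > 0 else revcomp(dna)
    off = abs(frame) - 1
    out = []
    for i in range(off, len(seq) - 2, 3):
        out.append(cmap.get(seq[i:i + 3], "X"))
    return "".join(out)


def translate_six_frames(dna: str) -> dict[int, str]:
    """All six conceptual translations, keyed by frame (1,2,3,-1,-2,-3)."""
    if len(dna) < 3:
        return {f: "" for f in (1, 2, 3, -1, -2, -3)}
    return {f: translate(dna, f) for f in (1, 2, 3, -1, -2, -3)}


# ---------------------------------------------------------------------------
# protein vs six-frame DNA
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _blosum_lut() -> np.ndarray:
    """128x128 int16 lookup of BLOSUM62 scores indexed by ASCII code."""
    mat = substitution_matrices.load("BLOSUM62")
    lut = np.full((128, 128), -4, dtype=np.int16)
    alphabet = mat.alphabet
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            lut[ord(a), ord(b)] = int(mat[i, j])
    return lut


def _ascii(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    n = len(codes) - k + 1
    h = np.zeros(n, dtype=np.int64)
    mult = 1
    for j in range(k):
        h += codes[j:j + n].astype(np.int64) * mult
        mult *= 128
    return h


def _xdrop_extend(scores: np.ndarray, xdrop: float) -> tuple[int, float]:
    """Length and score of the best X-drop prefix of a per-position score vector."""
    if scores.size == 0:
        return 0, 0.0
    cum = np.cumsum(scores, dtype=np.float64)
    run_max = np.maximum.accumulate(cum)
    dropped = np.nonzero(run_max - cum > xdrop)[0]
    stop = dropped[0] if dropped.size else scores.size
    if stop == 0:
        return 0, 0.0
    best = int(np.argmax(cum[:stop]))
    if cum[best] <= 0:
        return 0, 0.0
    return best + 1, float(cum[best])


def protein_dna_search(query: str, genome: GenomeSequence,
                       params: ProteinSearchParams | None = None,
                       query_id: str = "query") -> list[Hit]:
    """Search a protein query against the six-frame translation of a genome.

    Exact ``seed_length``-mer amino-acid seeds are extended ungapped in both
    directions under BLOSUM62 with an X-drop rule; hits at or above the bit
    threshold are reported with forward-strand DNA coordinates and strand
    taken from the frame sign.
    """
    params = params or ProteinSearchParams()
    k = params.seed_length
    if len(query) < k:
        raise ValueError(f"query shorter than seed length {k}")
    lut = _blosum_lut()
    q = _ascii(query.upper())
    qh = _kmer_hashes(q, k)
    qpos_by_hash: dict[int, list[int]] = {}
    for pos, h in enumerate(qh):
        qpos_by_hash.setdefault(int(h), []).append(pos)
    q_hash_set = np.array(sorted(qpos_by_hash), dtype=np.int64)

    hits: list[Hit] = []
    L = genome.length
    for frame, prot in translate_six_frames(genome.residues).items():
        if len(prot) < k:
            continue
        f = _ascii(prot)
        fh = _kmer_hashes(f, k)
        cand = np.nonzero(np.isin(fh, q_hash_set))[0]
        covered: dict[int, list[tuple[int, int]]] = {}
        frame_hits: dict[tuple[int, int], tuple[float, float]] = {}
        for fpos in cand:
            for qpos in qpos_by_hash[int(fh[fpos])]:
                diag = int(fpos) - qpos
                skip = False
                for s, e in covered.get(diag, ()):
                    if s <= fpos < e:
                        skip = True
                        break
                if skip:
                    continue
                seed_score = float(lut[q[qpos:qpos + k], f[fpos:fpos + k]].sum())
                w = min(qpos, int(fpos), params.max_extension)
                lvec = lut[q[qpos - w:qpos][::-1], f[fpos - w:fpos][::-1]]
                llen, lscore = _xdrop_extend(lvec, params.xdrop)
                w = min(len(q) - qpos - k, len(f) - int(fpos) - k,
                        params.max_extension)
                rvec = lut[q[qpos + k:qpos + k + w], f[fpos + k:fpos + k + w]]
                rlen, rscore = _xdrop_extend(rvec, params.xdrop)
                qs, qe = qpos - llen, qpos + k + rlen
                fs, fe = int(fpos) - llen, int(fpos) + k + rlen
                covered.setdefault(diag, []).append((fs, fe))
                raw = seed_score + lscore + rscore
                bits = bit_score(raw)
                if bits < params.min_bit_score:
                    continue
                ident = float(np.mean(q[qs:qe] == f[fs:fe]))
                key = (fs, fe)
                if key not in frame_hits or frame_hits[key][0] < raw:
                    frame_hits[key] = (raw, ident)
        # drop hits contained in a higher-scoring hit of the same frame
        items = sorted(frame_hits.items(),
                       key=lambda kv: (-(kv[0][1] - kv[0][0]), -kv[1][0]))
        kept: list[tuple[tuple[int, int], tuple[float, float]]] = []
        for (fs, fe), val in items:
            if any(ks <= fs and fe <= ke for (ks, ke), _ in kept):
                continue
            kept.append(((fs, fe), val))
        off = abs(frame) - 1
        for (fs, fe), (raw, ident) in kept:
            if frame > 0:
                ds, de = off + 3 * fs, off + 3 * fe
                strand = "+"
            else:
                ds, de = L - (off + 3 * fe), L - (off + 3 * fs)
                strand = "-"
            hits.append(Hit(query_id=query_id,
                            location=Interval(genome.id, ds, de, strand),
                            bit_score=bit_score(raw), identity_fraction=ident,
                            frame=frame, raw_score=raw))
    hits.sort(key=lambda h: (h.location.start, h.location.end, h.frame))
    return hits


# ---------------------------------------------------------------------------
# nucleotide vs nucleotide
# ---------------------------------------------------------------------------

_DNA_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _DNA_CODE[ord(_b)] = _i


def _dna_kmer_positions(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(hashes, valid_mask) of all k-mers of a DNA string; N invalidates."""
    codes = _DNA_CODE[_ascii(seq)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    h = np.zeros(n, dtype=np.int64)
    mult = 1
    for j in range(k):
        h += np.minimum(codes[j:j + n], 3).astype(np.int64) * mult
        mult *= 4
    bad = (codes == 255).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return h, valid


@lru_cache(maxsize=8)
def _nt_aligner(match: float, mismatch: float, gap: float) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap
    al.extend_gap_score = gap
    return al


def _alignment_stats(alignment) -> tuple[int, int, int, int, int, int, int]:
    """(t_begin, t_end, q_begin, q_end, matches, columns, raw span) of a local alignment."""
    tblocks, qblocks = alignment.aligned
    target, query = alignment.target, alignment.query
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        seg_t = target[ts:te]
        seg_q = query[qs:qe]
        matches += sum(a == b for a, b in zip(seg_t, seg_q))
        columns += te - ts
        if prev_t is not None:
            columns += (ts - prev_t) + (qs - prev_q)
        prev_t, prev_q = te, qe
    t0, t1 = int(tblocks[0][0]), int(tblocks[-1][1])
    q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
    return t0, t1, q0, q1, matches, columns, t1 - t0


def _chain_seeds(seeds: list[tuple[int, int]], diag_tol: int, gap: int
                 ) -> list[tuple[int, int, int, int]]:
    """Cluster (qpos, tpos) seeds into diagonal-consistent candidate regions."""
    if not seeds:
        return []
    seeds = sorted(seeds, key=lambda s: (s[1] - s[0], s[1]))
    clusters = []
    cq0, ct0 = seeds[0]
    cq1, ct1 = seeds[0]
    cur_diag = seeds[0][1] - seeds[0][0]
    for qpos, tpos in seeds[1:]:
        diag = tpos - qpos
        if abs(diag - cur_diag) <= diag_tol and 0 <= tpos - ct1 <= gap:
            cq0, cq1 = min(cq0, qpos), max(cq1, qpos)
            ct1 = tpos
            cur_diag = diag
        else:
            clusters.append((cq0, cq1, ct0, ct1))
            cq0, cq1, ct0, ct1 = qpos, qpos, tpos, tpos
            cur_diag = diag
    clusters.append((cq0, cq1, ct0, ct1))
    return clusters


def nucleotide_search(query: str, genome: GenomeSequence,
                      params: NucleotideSearchParams | None = None,
                      query_id: str = "query") -> list[Hit]:
    """Search a nucleotide query against both strands of a genome.

    Exact ``word_size``-mers seed diagonal-consistent candidate regions,
    each realigned with a gapped local aligner (match/mismatch/gap from
    ``params``). Hits below ``min_identity`` or shorter than ``min_length``
    on the subject are suppressed.
    """
    params = params or NucleotideSearchParams()
    k = params.word_size
    if len(query) < k:
        raise ValueError(f"query shorter than word size {k}")
    gh, gvalid = _dna_kmer_positions(genome.residues, k)
    if gh.size == 0:
        return []
    aligner = _nt_aligner(params.match, params.mismatch, params.gap)
    hits: list[Hit] = []
    for strand in "+-":
        qseq = query if strand == "+" else revcomp(query)
        qh, qvalid = _dna_kmer_positions(qseq, k)
        qpos_by_hash: dict[int, list[int]] = {}
        for pos in np.nonzero(qvalid)[0]:
            qpos_by_hash.setdefault(int(qh[pos]), []).append(int(pos))
        qset = np.array(sorted(qpos_by_hash), dtype=np.int64)
        cand = np.nonzero(np.isin(gh, qset) & gvalid)[0]
        seeds = [(qpos, int(t)) for t in cand for qpos in qpos_by_hash[int(gh[t])]]
        for cq0, cq1, ct0, ct1 in _chain_seeds(seeds, params.diag_tolerance,
                                               params.chain_gap):
            # when the seed chain starts/ends near a query terminus, extend
            # the realignment window to the full query end: a divergent
            # terminal stretch may simply lack exact words
            q0 = 0 if cq0 < 2 * params.pad else cq0 - params.pad
            q1 = len(qseq) if len(qseq) - (cq1 + k) < 2 * params.pad \
                else cq1 + k + params.pad
            t0 = max(0, ct0 - (cq0 - q0) - 60)
            t1 = min(genome.length, ct1 + k + (q1 - (cq1 + k)) + 60)
            aln = aligner.align(genome.residues[t0:t1], qseq[q0:q1])
            if len(aln) == 0:
                continue
            tb, te, _qb, _qe, matches, columns, span = _alignment_stats(aln[0])
            if columns == 0 or span < params.min_length:
                continue
            ident = matches / columns
            if ident < params.min_identity:
                continue
            hits.append(Hit(query_id=query_id,
                            location=Interval(genome.id, t0 + tb, t0 + te, strand),
                            bit_score=float(aln.score),
                            identity_fraction=ident, frame=0,
                            raw_score=float(aln.score)))
    # containment dedup (multiple seed clusters can expand to the same region)
    hits.sort(key=lambda h: (h.location.strand, -(h.location.length), -h.raw_score))
    kept: list[Hit] = []
    for h in hits:
        contained = any(
            o.location.strand == h.location.strand
            and o.location.start <= h.location.start
            and h.location.end <= o.location.end
            and o.raw_score >= h.raw_score
            for o in kept)
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: (h.location.start, h.location.end))
    return kept
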