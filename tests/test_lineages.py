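"""Clustering, alignment, consensus and subfamily classification."""
import numpy as np
import pytest

from marinerscape.lineages import (build_msa, classify_family,
                                   consensus_from_alignment, coverage_identity,
                                   greedy_cluster, pairwise_identity,
                                   recover_all_copies, refine_element_boundaries)
from marinerscape.model import GenomeSequence, Interval, TECopy, revcomp
from marinerscape.panel import default_panel
from marinerscape.simulate import (_random_background, generate_master,
                                   mutate_protein, star_lineage)

from conftest import make_genome


def _gotoh_score(a: str, b: str, match=2.0, mismatch=-3.0,
                 open_=-5.0, extend=-2.0, end_open=-5.0, end_extend=-0.05
                 ) -> float:
    """Independent affine-gap global alignment score (cheap end gaps)."""
    n, m = len(a), len(b)
    NEG = -1e18

    def end_gap(k: int) -> float:
        return 0.0 if k == 0 else end_open + end_extend * (k - 1)

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = end_gap(i)
    for j in range(1, m + 1):
        Y[0, j] = end_gap(j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend)
    best = NEG
    for i in range(n + 1):
        best = max(best, M[i, m] + end_gap(n - i), X[i, m] if i else NEG)
    for j in range(m + 1):
        best = max(best, M[n, j] + end_gap(m - j), Y[n, j] if j else NEG)
    return float(best)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_three_quarters(self):
        assert pairwise_identity("AAAA", "AAAT") == 0.75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    @pytest.mark.parametrize("seed", range(10))
    def test_substitution_pairs_match_dp_oracle(self, seed):
        """Pairs diverged by substitutions only: the optimal alignment is
        gapless and identity equals the direct Hamming identity (and the
        alignment engine's score equals the independent Gotoh DP score)."""
        r = np.random.default_rng(seed)
        a = _random_background(r, 200, 0.5)
        arr = np.frombuffer(a.encode(), np.uint8).copy()
        pos = r.choice(200, size=20, replace=False)
        for p in pos:
            alts = [x for x in b"ACGT" if x != arr[p]]
            arr[p] = alts[int(r.integers(3))]
        b = arr.tobytes().decode()
        expect = sum(1 for x, y in zip(a, b) if x == y) / 200
        assert pairwise_identity(a, b) == pytest.approx(expect, abs=1e-12)
        from marinerscape.lineages import _global_nt_aligner
        assert float(_global_nt_aligner().score(a, b)) == \
            pytest.approx(_gotoh_score(a, b), abs=1e-9)

    def test_indel_pair_score_matches_gotoh(self, rng):
        a = _random_background(rng, 150, 0.5)
        b = a[:60] + a[90:]
        from marinerscape.lineages import _global_nt_aligner
        assert float(_global_nt_aligner().score(a, b)) == \
            pytest.approx(_gotoh_score(a, b), abs=1e-9)


def test_coverage_identity_penalizes_tiny_overlap(rng):
    a = _random_background(rng, 400, 0.5)
    b = _random_background(np.random.default_rng(999), 400, 0.5)
    # unrelated sequences: free-end alignments find small lucky overlaps,
    # the coverage floor keeps the score low
    assert coverage_identity(a, b) < 0.5
    assert coverage_identity(a, a) == 1.0


class TestGreedyCluster:
    def _copies(self, seqs):
        return [TECopy(id=f"c{i}", location=Interval("s", 1000 * i, 1000 * i + len(s)),
                       residues=s) for i, s in enumerate(seqs)]

    def test_identical_copies_one_cluster(self, rng):
        s = _random_background(rng, 600, 0.5)
        assert len(greedy_cluster(self._copies([s, s, s]))) == 1

    def test_seventy_percent_identity_two_clusters(self, rng):
        a = _random_background(rng, 500, 0.5)
        arr = np.frombuffer(a.encode(), np.uint8).copy()
        pos = rng.choice(500, size=150, replace=False)  # 30% substituted
        for p in pos:
            alts = [x for x in b"ACGT" if x != arr[p]]
            arr[p] = alts[int(rng.integers(3))]
        b = arr.tobytes().decode()
        assert pairwise_identity(a, b) < 0.80
        assert len(greedy_cluster(self._copies([a, b]))) == 2

    def test_reverse_complement_joins_and_reorients(self, rng):
        s = _random_background(rng, 600, 0.5)
        clusters = greedy_cluster(self._copies([s, revcomp(s)]))
        assert len(clusters) == 1
        assert all(c.residues == s for c in clusters[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_three_planted_lineages_recovered(self, seed):
        """Three lineages below 70% cross-identity with <10% within-lineage
        divergence cluster into exactly three groups with perfect membership."""
        r = np.random.default_rng(seed)
        seqs, labels = [], []
        for li in range(3):
            master, copies = star_lineage(5, 0.04, r, length=1286)
            seqs.extend(copies)
            labels.extend([li] * 5)
        copies = [TECopy(id=f"L{labels[i]}_{i}",
                         location=Interval("s", 2000 * i, 2000 * i + len(s)),
                         residues=s) for i, s in enumerate(seqs)]
        clusters = greedy_cluster(copies)
        assert len(clusters) == 3
        for cl in clusters:
            assert len({c.id.split("_")[0] for c in cl}) == 1

    def test_partition_invariant_under_shuffling(self, rng):
        master, copies = star_lineage(6, 0.05, rng)
        master2, copies2 = star_lineage(6, 0.05, rng)
        tes = self._copies(copies + copies2)
        ref = sorted(sorted(c.id for c in cl) for cl in greedy_cluster(tes))
        for _ in range(10):
            rng.shuffle(tes)
            got = sorted(sorted(c.id for c in cl) for cl in greedy_cluster(tes))
            assert got == ref


class TestBuildMsa:
    def test_identical_sequences_gap_free(self, rng):
        s = _random_background(rng, 300, 0.5)
        msa = build_msa([("a", s), ("b", s)])
        assert all("-" not in row for _n, row in msa)

    def test_single_member_identity(self):
        assert build_msa([("a", "ACGT")]) == [("a", "ACGT")]

    def test_internal_deletion_becomes_one_gap_block(self, rng):
        s = _random_background(rng, 400, 0.5)
        deleted = s[:200] + s[230:]
        msa = dict(build_msa([("full", s), ("del", deleted)]))
        row = msa["del"]
        gaps = row.count("-")
        assert gaps == 30
        first = row.index("-")
        assert row[first:first + 30] == "-" * 30

    def test_sum_of_pairs_not_worse_than_stacking(self, rng):
        base = _random_background(rng, 600, 0.5)
        master, copies = star_lineage(4, 0.08, rng, master=base)

        def sp(rows):
            total = 0
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    total += sum(1 if a == b and a != "-" else -1
                                 for a, b in zip(rows[i], rows[j]))
            return total

        aligned = [row for _n, row in build_msa([(f"c{i}", s)
                                                 for i, s in enumerate(copies)])]
        width = max(len(s) for s in copies)
        stacked = [s + "-" * (width - len(s)) for s in copies]
        assert sp(aligned) >= sp(stacked)


class TestConsensus:
    def test_relative_majority(self):
        cons, _ = consensus_from_alignment(["A", "A", "G"])
        assert cons == "A"

    def test_majority_internal_gap_drops_column(self):
        rows = ["C-G", "C-G", "CAG"]
        cons, _ = consensus_from_alignment(rows)
        assert cons == "CG"

    def test_terminal_gaps_do_not_vote(self):
        # first row's leading gap is a truncation: the column reads A by 2/2
        rows = ["-CC", "ACC", "ACC"]
        cons, _ = consensus_from_alignment(rows)
        assert cons == "ACC"

    def test_tie_resolved_by_fixed_priority(self):
        cons, _ = consensus_from_alignment(["A", "A", "G", "G"])
        assert cons == "A"
        cons2, _ = consensus_from_alignment(["C", "C", "T", "T"])
        assert cons2 == "C"

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_column_tally_oracle(self, seed):
        r = np.random.default_rng(seed)
        width = 40
        rows = ["".join(r.choice(list("ACGT-"), width)) for _ in range(7)]

        def oracle(rows):
            out = []
            n = len(rows)
            spans = [(width - len(row.lstrip("-")), len(row.rstrip("-")))
                     for row in rows]
            for col in range(width):
                counts = {sym: 0 for sym in "ACGT-"}
                for ri, row in enumerate(rows):
                    lo, hi = spans[ri]
                    if row[col] == "-" and not (lo <= col < hi):
                        continue  # terminal gap does not vote
                    counts[row[col]] += 1
                best, bn = None, 0
                for sym in "ACGT-":
                    if counts[sym] > bn:
                        best, bn = sym, counts[sym]
                if best and best != "-":
                    out.append(best)
            return "".join(out)

        cons, _ = consensus_from_alignment(rows, end_trim_support=0.0)
        assert cons == oracle(rows)

    def test_consensus_close_to_master(self):
        """>= 10 copies at <= 5% divergence give a consensus within 1% of
        the true master element."""
        r = np.random.default_rng(11)
        master, copies = star_lineage(10, 0.05, r)
        msa = build_msa([(f"c{i}", s) for i, s in enumerate(copies)])
        cons, _ = consensus_from_alignment([row for _n, row in msa])
        assert len(cons) == len(master)
        ham = sum(1 for a, b in zip(cons, master) if a != b)
        assert ham / len(master) <= 0.01


class TestClassifyFamily:
    def test_panel_member_maps_to_itself(self):
        panel = default_panel()
        call = classify_family(panel[0].sequence, panel)
        assert call.family_call == "mariner"
        assert call.subfamily == panel[0].subfamily
        assert call.best_reference == panel[0].name

    def test_mutated_transposase_keeps_subfamily(self, rng):
        """15%-mutated Mos1 classifies as mauritiana; cross-checked by a
        nearest-reference oracle using alignment-free identity."""
        panel = default_panel()
        mos1 = next(e for e in panel if e.name == "Mos1")
        mutated = mutate_protein(mos1.sequence, 0.15, rng)
        call = classify_family(mutated, panel)
        assert call.subfamily == "mauritiana"
        # independent oracle: positional identity against every entry
        idents = {e.name: sum(a == b for a, b in zip(e.sequence, mutated))
                  for e in panel}
        assert max(idents, key=idents.get) == "Mos1"

    def test_tc1_like_is_excluded_from_mariner(self, rng):
        panel = default_panel()
        tc1 = next(e for e in panel if e.family == "tc1_like")
        mutated = mutate_protein(tc1.sequence, 0.10, rng)
        # keep the DD34E triad of the source (mutate_protein replants DD34D)
        mutated = mutated[:283] + "E" + mutated[284:]
        call = classify_family(mutated, panel)
        assert call.family_call == "tc1_like"
        assert call.catalytic_motif == "DD34E"

    def test_unrelated_sequence_is_other(self, rng):
        junk = "".join(rng.choice(list("LIVF"), 50))
        assert classify_family(junk, default_panel()).family_call == "other"


def test_refine_element_boundaries_trims_flank_junk(rng):
    master = generate_master(rng)
    ext = _random_background(rng, 180, 0.5) + master + _random_background(rng, 220, 0.5)
    refined = refine_element_boundaries(ext)
    assert refined is not None
    trimmed, tir_len = refined
    # within a few nt of the element span (chance junk matches adjacent to
    # the TIR can shift the anchor by 1-2 nt; downstream TSD calibration
    # resolves the remainder)
    start = ext.find(trimmed[4:40]) - 4
    assert abs(start - 180) <= 3
    assert abs(len(trimmed) - len(master)) <= 6
    assert tir_len >= 20


class TestRecoverAllCopies:
    def test_deleted_copy_recovered_by_consensus_search(self, rng):
        """A short internally deleted copy without a transposase domain is
        found by the consensus nucleotide search."""
        master = generate_master(rng)
        deriv = master[:280] + master[880:]  # 686 nt derivative
        genome = make_genome(21, 60000, inserts=[(10000, master), (40000, deriv)])
        copies = recover_all_copies(master, [genome])
        ivs = sorted((c.location.start, c.location.end) for c in copies)
        # sequential planting shifts the second insert by len(master)
        d0 = 40000 + len(master)
        assert any(abs(s - d0) <= 5 and abs(e - (d0 + len(deriv))) <= 5
                   for s, e in ivs)
        assert any(abs(s - 10000) <= 5 and abs(e - 11286) <= 5 for s, e in ivs)

    def test_overlapping_first_pass_counted_once(self, rng):
        master = generate_master(rng)
        genome = make_genome(22, 40000, inserts=[(15000, master)])
        first = TECopy(id="fp", location=Interval("g", 15010, 16200, "+"),
                       residues=genome.residues[15010:16200])
        copies = recover_all_copies(master, [genome], first_pass=[first])
        near = [c for c in copies if c.location.overlap(Interval("g", 14900, 16400))]
        assert len(near) == 1
        assert near[0].id != "fp"  # second pass supersedes

    def test_no_additional_copies_keeps_input(self, rng):
        master = generate_master(rng)
        genome = make_genome(23, 30000)  # no copies planted
        fp = TECopy(id="fp", location=Interval("g", 100, 700, "+"),
                    residues=genome.residues[100:700])
        copies = recover_all_copies(master, [genome], first_pass=[fp])
        assert [c.id for c in copies] == ["fp"]
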