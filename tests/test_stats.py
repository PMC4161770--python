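"""Decay accounting, divergence, insertion-site bias, KS."""
import numpy as np
import pytest

from marinerscape.annotation import build_profile
from marinerscape.model import GenomeSequence, Interval, TECopy
from marinerscape.simulate import _random_background, star_lineage
from marinerscape.stats import (copy_divergence, count_events, distance_to_cds,
                                insertion_site_profile, ks_two_sample,
                                lineage_decay_profile,
                                size_divergence_regression)


def _te(cid, residues, lf="", rf="", scaffold="s", start=0):
    return TECopy(id=cid, location=Interval(scaffold, start, start + max(len(residues), 1)),
                  residues=residues, left_flank=lf, right_flank=rf)


class TestCountEvents:
    def test_identical_copy_all_zero(self, master):
        ev = count_events(build_profile(master, master), master)
        assert (ev.substitutions, ev.internal_deletion_events, ev.insertion_nt,
                ev.truncation_nt) == (0, 0, 0, 0)
        assert ev.aligned_nt == len(master)

    def test_substitutions_and_deletion(self, master):
        seq = list(master)
        for p in (5, 100, 400, 700, 1100):
            seq[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[seq[p]]
        copy = "".join(seq[:500] + seq[530:])
        ev = count_events(build_profile(copy, master), master)
        assert ev.substitutions == 5
        assert ev.internal_deletion_events == 1
        assert ev.internal_deletion_nt == 30
        assert ev.truncation_nt == 0

    def test_terminal_gap_counts_as_truncation(self, master):
        ev = count_events(build_profile(master[:-200], master), master)
        assert ev.truncation_nt == 200
        assert ev.internal_deletion_events == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_conservation_invariant(self, seed, master):
        """consensus length = aligned + internal deletion + truncation nt."""
        r = np.random.default_rng(seed)
        seq = master
        if r.random() < 0.7:  # random internal deletion
            size = int(r.integers(20, 300))
            start = int(r.integers(50, len(seq) - size - 50))
            seq = seq[:start] + seq[start + size:]
        if r.random() < 0.5:  # truncation
            cut = int(r.integers(10, 200))
            seq = seq[cut:] if r.random() < 0.5 else seq[:-cut]
        ev = count_events(build_profile(seq, master), master)
        assert ev.aligned_nt + ev.internal_deletion_nt + ev.truncation_nt \
            == len(master)


class TestCopyDivergence:
    def test_formula(self):
        from marinerscape.model import CopyEventCount
        ev = CopyEventCount(substitutions=5, internal_deletion_events=1,
                            insertion_events=0, aligned_nt=1000)
        assert copy_divergence(ev) == pytest.approx(0.006)

    def test_identical_copy_zero(self):
        from marinerscape.model import CopyEventCount
        assert copy_divergence(CopyEventCount(aligned_nt=100)) == 0.0

    def test_zero_aligned_rejected(self):
        from marinerscape.model import CopyEventCount
        with pytest.raises(ValueError):
            copy_divergence(CopyEventCount(aligned_nt=0))


class TestLineageDecay:
    def test_shared_deletion_counted_once(self, master, rng):
        """Ten copies sharing one ancestral 100-nt deletion contribute the
        deletion to nt_lost once, not ten times."""
        deriv = master[:500] + master[600:]
        copies, profiles = [], []
        for i in range(10):
            arr = np.frombuffer(deriv.encode(), np.uint8).copy()
            pos = rng.choice(len(arr), size=12, replace=False)
            for p in pos:
                alts = [x for x in b"ACGT" if x != arr[p]]
                arr[p] = alts[int(rng.integers(3))]
            seq = arr.tobytes().decode()
            copies.append(_te(f"c{i}", seq))
            profiles.append(build_profile(seq, master, f"c{i}"))
        prof = lineage_decay_profile("L", copies, profiles, master)
        assert prof.nt_lost == 100
        naive = sum(count_events(p, master).internal_deletion_nt for p in profiles)
        assert naive == 1000
        assert prof.nt_lost <= naive

    def test_no_indels_zero_ratio(self, master):
        copies = [_te(f"c{i}", master) for i in range(3)]
        profiles = [build_profile(master, master, f"c{i}") for i in range(3)]
        prof = lineage_decay_profile("L", copies, profiles, master)
        assert prof.nt_lost == 0 and prof.del_sub_ratio == 0.0
        assert prof.small_lineage  # fewer than 10 copies is flagged

    def test_distinct_deletions_counted_separately(self, master):
        a = master[:300] + master[400:]
        b = master[:800] + master[900:]
        copies = [_te("a", a), _te("b", b)]
        profiles = [build_profile(a, master, "a"), build_profile(b, master, "b")]
        prof = lineage_decay_profile("L", copies, profiles, master)
        assert prof.nt_lost == 200


class TestRegression:
    def _prof(self, div, size):
        from marinerscape.model import DecayProfile
        return DecayProfile(lineage_id="x", n_copies=10, mean_divergence=div,
                            mean_size=size, substitutions=1, nt_lost=0,
                            nt_gained=0, internal_deletion_nt_dedup=0,
                            truncation_nt_dedup=0, del_sub_ratio=0,
                            internal_deletion_rate=0, truncation_rate=0)

    def test_collinear_gives_unit_correlation(self):
        profs = [self._prof(d, 1300 - 1000 * d) for d in (0.01, 0.05, 0.1)]
        slope, intercept, r = size_divergence_regression(profs)
        assert r == pytest.approx(-1.0)
        assert slope == pytest.approx(-1000.0)

    def test_constant_sizes_zero_slope(self):
        profs = [self._prof(d, 900.0) for d in (0.01, 0.05, 0.1)]
        slope, _i, r = size_divergence_regression(profs)
        assert slope == 0.0 and r == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            size_divergence_regression([self._prof(0.1, 900)] * 2)


class TestInsertionSiteProfile:
    def test_all_at_context_reads_one(self):
        lf = "C" * 240 + "ATATA" + "TA"
        rf = "TA" + "TATAT" + "C" * 240
        copies = [_te("c", "GGGG", lf, rf)]
        genome = GenomeSequence("g", "CCTAGG" * 100)
        prof = insertion_site_profile(copies, [genome])
        assert all(v == 1.0 for v in prof.observed)
        assert prof.n_sites == 1

    def test_copies_without_flanking_ta_excluded(self):
        copies = [_te("c", "GGGG", "C" * 250, "C" * 250)]
        genome = GenomeSequence("g", "CCTAGG" * 100)
        prof = insertion_site_profile(copies, [genome])
        assert prof.n_sites == 0 and prof.n_excluded == 1

    def test_information_content_bounds(self, rng):
        from marinerscape.simulate import plant_insertions
        elem = _random_background(rng, 60, 0.5)
        _g, copies, bg = plant_insertions(200_000, 0.5, elem, 200, 0.7, rng)
        prof = insertion_site_profile(copies, [bg])
        assert all(0.0 <= ic <= 2.0 for ic in prof.information_content)
        assert all(n > 5 for n in prof.trinucleotides_5p.values())


class TestDistanceToCds:
    def test_overlap_is_zero(self):
        copies = [_te("c", "A" * 100, scaffold="s", start=1000)]
        d, frac = distance_to_cds(copies, [Interval("s", 1050, 1200)])
        assert d["c"] == 0 and frac == 1.0

    def test_gap_distance(self):
        copies = [_te("c", "A" * 1000, scaffold="s", start=1000)]
        d, _ = distance_to_cds(copies, [Interval("s", 2500, 3000)])
        assert d["c"] == 500

    def test_scaffold_without_cds_excluded_from_distances(self):
        copies = [_te("a", "A" * 100, scaffold="s1", start=0),
                  _te("b", "A" * 100, scaffold="s2", start=0)]
        d, frac = distance_to_cds(copies, [Interval("s1", 500, 600)])
        assert set(d) == {"a"} and frac == 0.5


class TestKs:
    def test_identical_samples_d_zero(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_disjoint_samples_d_one(self):
        d, _p = ks_two_sample([1, 2], [3, 4])
        assert d == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_d_matches_ecdf_sweep_oracle(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=8)
        y = r.normal(size=8)
        d, _ = ks_two_sample(x, y)

        def ecdf(sample, t):
            return np.mean(np.asarray(sample) <= t)

        oracle = max(abs(ecdf(x, t) - ecdf(y, t))
                     for t in np.concatenate([x, y]))
        assert d == pytest.approx(oracle, abs=1e-12)

    def test_type_one_error_calibrated(self):
        """Same-distribution samples (n=100, 1000 reps) reject at alpha=0.05
        within the binomial 99% band around 0.05."""
        r = np.random.default_rng(3)
        rej = sum(ks_two_sample(r.normal(size=100), r.normal(size=100))[1] < 0.05
                  for _ in range(1000))
        rate = rej / 1000
        half = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert 0.05 - half <= rate <= 0.05 + half
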