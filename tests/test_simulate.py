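"""Forward simulator: TSD insertion, lineage evolution, truth bookkeeping."""
import hashlib

import numpy as np
import pytest
from scipy import stats as sps

from marinerscape.model import GenomeSequence, revcomp
from marinerscape.panel import dd_motif, default_panel
from marinerscape.simulate import (LineageSpec, MiteEvent, RateFunction,
                                   SimConfig, _random_background,
                                   back_translate, emit, evolve_lineage,
                                   generate_master, insert_at_ta,
                                   run_simulation, sample_insertion_site,
                                   ta_sites_and_weights)


class TestInsertAtTa:
    def test_tsd_duplication(self):
        assert insert_at_ta("CCTAGG", "XXXX", 2) == "CCTAXXXXTAGG"

    def test_zero_length_element_pure_tsd(self):
        assert insert_at_ta("CCTAGG", "", 2) == "CCTATAGG"

    def test_removal_restores_original(self):
        g = "CCTAGG"
        out = insert_at_ta(g, "XXXX", 2)
        restored = out[:4] + out[4 + 4 + 2:]
        assert restored == g

    def test_non_ta_site_rejected(self):
        with pytest.raises(ValueError):
            insert_at_ta("CCCCGG", "XX", 2)


class TestSampleInsertionSite:
    def test_single_ta_genome_deterministic(self):
        rng = np.random.default_rng(0)
        assert sample_insertion_site("CCCTACCC", 0.5, rng) == 3

    def test_unbiased_sampling_is_uniform(self):
        """chi-square over 3000 draws against the uniform expectation."""
        g = _random_background(np.random.default_rng(4), 20000, 0.5)
        rng = np.random.default_rng(5)
        sites, _w = ta_sites_and_weights(g, 0.5, margin=0)
        draws = [sample_insertion_site(g, 0.5, rng) for _ in range(3000)]
        counts = {int(s): 0 for s in sites}
        for d in draws:
            counts[d] += 1
        chi2, p = sps.chisquare(list(counts.values()))
        assert p > 0.01

    def test_no_ta_rejected(self):
        with pytest.raises(ValueError):
            sample_insertion_site("CCCCCC", 0.5, np.random.default_rng(0))


class TestGenerateMaster:
    def test_structure(self, rng):
        m = generate_master(rng)
        assert len(m) == 1286
        assert m[-30:] == revcomp(m[:30])  # terminal inverted repeats
        from marinerscape.annotation import scan_orf
        assert scan_orf(m) == 345

    def test_panel_derived_transposase_keeps_motif(self, rng):
        from marinerscape.search import translate
        from marinerscape.annotation import longest_orf_region
        prot = default_panel()[0].sequence
        m = generate_master(rng, protein=prot)
        frame, start, n = longest_orf_region(m)
        assert translate(m[start:start + 3 * n], 1) == prot
        assert dd_motif(prot) == "DD34D"


class TestEvolveLineage:
    def test_all_rates_zero_single_unchanged_master(self):
        spec = LineageSpec(name="z", rate=RateFunction(kind="constant", rate=0.0),
                           substitution_rate=0.0)
        res = evolve_lineage(spec, 0.3, np.random.default_rng(1))
        assert len(res.copies) == 1
        assert res.copies[0].sequence == res.master

    def test_constant_rate_expected_copy_number(self):
        """Empirical mean copy count within 3 standard errors of e^{rT}
        over 200 replicates of a pure birth process."""
        spec = LineageSpec(name="b", rate=RateFunction(kind="constant", rate=5.0),
                           substitution_rate=0.0, master_sequence="ACGT" * 40)
        ns = [len(evolve_lineage(spec, 0.3, np.random.default_rng(1000 + i)).copies)
              for i in range(200)]
        se = np.std(ns) / np.sqrt(len(ns))
        assert abs(np.mean(ns) - np.exp(1.5)) <= 3 * se

    def test_mite_event_creates_short_sublineage(self):
        spec = LineageSpec(
            name="m", rate=RateFunction(kind="burst", center_age=0.2, width=0.05,
                                        height=40.0),
            master_length=1300, substitution_rate=0.1,
            mite_event=MiteEvent(time=0.06, type="deletion", start=263, end=1037))
        for seed in range(6):
            res = evolve_lineage(spec, 0.3, np.random.default_rng(seed))
            mites = [c for c in res.copies if c.is_mite]
            if len(mites) >= 2:
                founders = [c for c in mites if c.mite_founder]
                assert len(founders) == 1
                assert all(len(c.res) <= 1300 - 774 + 40 for c in mites)
                break
        else:
            pytest.fail("no seed produced a transposed MITE sublineage")

    def test_parent_child_divergence_grows_with_separation(self):
        """Rank correlation between child age and parent-child divergence is
        positive on average over 20 seeds."""
        spec = LineageSpec(name="d", rate=RateFunction(kind="constant", rate=12.0),
                           substitution_rate=1.0)
        corrs = []
        for seed in range(20):
            res = evolve_lineage(spec, 0.25, np.random.default_rng(seed),
                                 max_copies=64)
            by_id = {c.id: c for c in res.copies}
            xs, ys = [], []
            for c in res.copies:
                if c.parent is None or len(c.res) != len(by_id[c.parent].res):
                    continue
                div = np.mean(np.frombuffer(c.res, np.uint8)
                              != np.frombuffer(by_id[c.parent].res, np.uint8))
                xs.append(0.25 - c.birth_time)
                ys.append(div)
            if len(xs) >= 5:
                corrs.append(sps.spearmanr(xs, ys).statistic)
        assert np.nanmean(corrs) > 0


@pytest.fixture(scope="module")
def small_sim():
    cfg = SimConfig(
        genome_length=150_000, gc_content=0.45, seed=5,
        lineages=(LineageSpec(name="m",
                              rate=RateFunction(kind="burst", center_age=0.1,
                                                width=0.02, height=40.0),
                              substitution_rate=0.3, min_copies=5),))
    return cfg, run_simulation(cfg)


class TestRunSimulation:
    def test_genome_length_bookkeeping(self, small_sim):
        cfg, sim = small_sim
        planted_nt = sum(len(c.res) + 2 for c in sim.copies
                         if not c.is_segmental_duplicate)
        dup_nt = sim.genome.length - cfg.genome_length - planted_nt
        # remaining growth must be exactly the duplicated blocks (here none)
        assert dup_nt == 0

    def test_truth_intervals_extract_to_logged_sequences(self, small_sim):
        _cfg, sim = small_sim
        g = sim.genome.residues
        for c in sim.copies:
            seg = g[c.location.start:c.location.end]
            expect = c.sequence if c.strand == "+" else revcomp(c.sequence)
            assert seg == expect
            # duplicated target TA on both sides
            assert g[c.location.start - 2:c.location.start] == "TA"
            assert g[c.location.end:c.location.end + 2] == "TA"

    def test_emit_is_byte_deterministic(self, small_sim, tmp_path):
        cfg, _sim = small_sim
        digests = []
        for rep in range(2):
            sim = run_simulation(cfg)
            paths = emit(sim, tmp_path / f"r{rep}")
            blob = b"".join(sorted(p.read_bytes() for p in paths.values()))
            digests.append(hashlib.sha256(blob).hexdigest())
        assert digests[0] == digests[1]

    def test_empty_lineage_list_background_only(self, tmp_path):
        cfg = SimConfig(genome_length=5000, gc_content=0.5, seed=1, lineages=())
        sim = run_simulation(cfg)
        assert sim.genome.length == 5000
        paths = emit(sim, tmp_path / "bg")
        assert paths["truth_copies"].read_text().count("\n") == 1  # header only

    def test_unknown_config_keys_rejected(self):
        with pytest.raises(ValueError):
            SimConfig.from_dict({"genome_length": 100, "gc_content": 0.5,
                                 "seed": 1, "lineages": [], "bogus": 2})
        with pytest.raises(ValueError):
            LineageSpec.from_dict({"name": "x", "rate": {"kind": "constant"},
                                   "nope": 1})


def test_default_scenario_loads():
    from marinerscape.simulate import default_scenario
    cfg = default_scenario()
    assert cfg.genome_length == 2_000_000
    assert len(cfg.lineages) == 3
    kinds = [sp.rate.kind for sp in cfg.lineages]
    assert kinds == ["burst", "burst", "ongoing"]
    assert any(sp.mite_event is not None for sp in cfg.lineages)
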