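"""Forward simulator: root genome, time segmentation, event accounting."""

import numpy as np
import pytest
from scipy import stats

from corephylo import (
    Alignment,
    RecombinationEvent,
    SimConfig,
    SimResult,
    SpeciesParams,
    evolve,
    measure_rm,
    read_newick,
    root_sequence,
    time_segments,
)


class TestRootSequence:
    def test_pure_gc(self):
        seq = root_sequence(500, 1.0, np.random.default_rng(0))
        assert set(np.unique(seq)) <= {1, 2}  # C, G codes

    def test_gc_fraction_binomial(self):
        seq = root_sequence(100_000, 0.5, np.random.default_rng(1))
        gc = np.isin(seq, [1, 2]).mean()
        assert gc == pytest.approx(0.5, abs=0.005)

    def test_deterministic(self):
        a = root_sequence(100, 0.4, np.random.default_rng(7))
        b = root_sequence(100, 0.4, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_gc_out_of_range(self):
        with pytest.raises(ValueError):
            root_sequence(10, 1.5, np.random.default_rng(0))


class TestTimeSegments:
    def test_non_ultrametric_hand_example(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        segs = time_segments(tree)
        assert [(s[0], s[1]) for s in segs] == [(0.0, 1.0), (1.0, 2.0)]
        assert segs[0][2] == frozenset({"node1", "C"})
        assert segs[1][2] == frozenset({"A", "B", "C"})

    def test_ultrametric_balanced_four_leaves(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        segs = time_segments(tree)
        assert len(segs) == 2
        assert len(segs[0][2]) == 2 and len(segs[1][2]) == 4

    def test_intervals_partition_depth_range(self, species20):
        segs = time_segments(species20.tree)
        for (_, d1, _), (d0, _, _) in zip(segs[:-1], segs[1:]):
            assert d1 == d0
        assert segs[0][0] == 0.0


def _tiny_params(**kw):
    defaults = dict(gc=0.5, kappa=2.0, length=2_000)
    defaults.update(kw)
    return SpeciesParams(**defaults)


class TestEvolve:
    def test_seed_is_mandatory(self, species20):
        with pytest.raises(ValueError, match="reproducib"):
            SimConfig(tree=species20.tree, params=species20.params, rho=0.0)

    def test_clonal_run_has_no_recombination(self, clonal_result):
        assert clonal_result.n_events == 0
        assert clonal_result.r_total == 0
        assert clonal_result.rm == 0.0

    def test_same_seed_bit_identical(self, species20):
        cfg = SimConfig(tree=species20.tree, params=_tiny_params(), rho=1.0, rng_seed=9)
        a, b = evolve(cfg), evolve(cfg)
        assert np.array_equal(a.alignment.data, b.alignment.data)
        assert a.events == b.events
        assert a.m_realized == b.m_realized

    def test_realized_rho_m_matches_configured_rho(self, recombining_result):
        res = recombining_result
        se = np.sqrt(res.n_events) / res.m_realized
        assert res.rho_m == pytest.approx(1.0, abs=3 * se)

    def test_transition_fraction_follows_kappa(self, recombining_result, species20):
        res = recombining_result
        kappa = species20.params.kappa
        expected = kappa / (kappa + 2.0)
        frac = res.ti_realized / res.m_realized
        se = np.sqrt(expected * (1 - expected) / res.m_realized)
        assert frac == pytest.approx(expected, abs=4 * se)

    def test_total_substitutions_poisson_dispersion(self):
        """m_realized across replicates is Poisson with mean = total tree
        length x genome length (variance/mean dispersion test)."""
        tree = read_newick("((A:0.004,B:0.004):0.004,C:0.008);")
        params = _tiny_params(length=1_000)
        counts = [
            evolve(SimConfig(tree=tree, params=params, rho=0.0, rng_seed=s)).m_realized
            for s in range(200)
        ]
        counts = np.asarray(counts, float)
        expected_mean = 0.024 * 1_000
        assert counts.mean() == pytest.approx(expected_mean, rel=0.15)
        # index of dispersion ~ chi2(n-1)/(n-1) under the Poisson law
        disp = (len(counts) - 1) * counts.var(ddof=1) / counts.mean()
        lo, hi = stats.chi2.ppf([0.0005, 0.9995], df=len(counts) - 1)
        assert lo < disp < hi

    def test_codon_rates_zero_zero_three_hits_third_positions_only(self, species20):
        params = _tiny_params(codon_rates=(0.0, 0.0, 3.0), length=3_000)
        res = evolve(SimConfig(tree=species20.tree, params=params, rho=0.0, rng_seed=3))
        diffs = res.alignment.data != res.root_seq[None, :]
        changed_sites = np.flatnonzero(diffs.any(axis=0))
        assert res.m_realized > 0
        assert np.all(changed_sites % 3 == 2)

    def test_r_total_increases_with_rho(self, species20):
        params = _tiny_params(length=10_000)
        means = []
        for rho in (0.5, 1.0, 2.0):
            totals = [
                evolve(
                    SimConfig(tree=species20.tree, params=params, rho=rho, rng_seed=s)
                ).r_total
                for s in range(20)
            ]
            means.append(np.mean(totals))
        assert means[0] < means[1] < means[2]

    def test_recombining_identical_sequences_transfers_nothing(self):
        """With essentially no mutational input every tract copy is a
        no-op: events happen but no alleles move."""
        tree = read_newick("((A:1e-7,B:1e-7):1e-7,(C:1e-7,D:1e-7):1e-7);")
        params = _tiny_params(length=1_000)
        res = evolve(SimConfig(tree=tree, params=params, rho=5e6, rng_seed=1))
        assert res.n_events > 100
        assert res.r_total == 0
        assert all(ev.alleles_transferred == 0 for ev in res.events)

    def test_tract_geometry(self, recombining_result):
        for ev in recombining_result.events[:200]:
            assert 0 <= ev.start < recombining_result.alignment.length
            assert ev.start + ev.tract_length <= recombining_result.alignment.length
            assert 0 <= ev.alleles_transferred <= ev.tract_length
            assert ev.donor != ev.recipient


class TestMeasureRm:
    def test_hand_built_event_log(self):
        aln = Alignment.from_strings([("A", "ACGT"), ("B", "ACGT")])
        events = (
            RecombinationEvent(0.0, "A", "B", 0, 100, 5),
            RecombinationEvent(0.0, "B", "A", 0, 100, 3),
        )
        res = SimResult(
            alignment=aln, events=events, m_realized=100, n_events=2,
            r_total=8, tract_bp_total=200,
        )
        rm, nu, rho_m = measure_rm(res)
        assert rm == pytest.approx(0.08)
        assert nu == pytest.approx(0.04)
        assert rho_m == pytest.approx(0.02)

    def test_bookkeeping_identity(self, recombining_result):
        rm, nu, rho_m = measure_rm(recombining_result)
        delta_real = recombining_result.delta_realized
        assert abs(rm - rho_m * delta_real * nu) / rm < 1e-6

    def test_zero_substitutions_rejected(self):
        aln = Alignment.from_strings([("A", "ACGT"), ("B", "ACGT")])
        res = SimResult(alignment=aln, events=(), m_realized=0, n_events=0,
                        r_total=0, tract_bp_total=0)
        with pytest.raises(ValueError):
            measure_rm(res)
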