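import numpy as np
import pytest
from dataclasses import replace

from shredsim.drive_genetics import DRIVE, XO, XX, XY
from shredsim.engine import (
    SERIES,
    coarse_to_fine_threshold,
    find_eradication_threshold,
    initialize_population,
    run_replicate_batch,
    run_replicates,
    run_simulation,
    step_cycle,
    summarize_replicates,
)
from shredsim.params import DemogParams, DriveParams, SimConfig, Strategy
from shredsim.population import Population


def _g_allele_freq(result, row=-1):
    n = result.data[row, 0]
    if n == 0:
        return np.nan
    wg, gg, gr = (result.data[row, SERIES.index(k)] for k in ("WG", "GG", "GR"))
    return (wg + 2 * gg + gr) / (2 * n)


def _r_allele_freq(result, row=-1):
    n = result.data[row, 0]
    if n == 0:
        return np.nan
    wr, gr, rr = (result.data[row, SERIES.index(k)] for k in ("WR", "GR", "RR"))
    return (wr + 2 * rr + gr) / (2 * n)


class TestInitializePopulation:
    def test_yshredder_inoculation(self, rng):
        cfg = SimConfig(demog=DemogParams(carrying_capacity=10_000), inoculum_size=100)
        pop = initialize_population(cfg, rng)
        assert pop.size == 10_100
        counts = pop.allosome_counts()
        assert counts[0] == 5_100 and counts[1] == 5_000 and counts[2] == 0
        auto = dict(zip(("WW", "WG", "GG", "WR", "GR", "RR"), pop.autosome_counts()))
        assert auto["WG"] == 100 and auto["WW"] == 10_000
        # inoculants are XX females
        assert np.all(pop.allo[pop.drive_carrier_mask()] == XX)

    def test_wildtype_control(self, rng):
        cfg = SimConfig(demog=DemogParams(carrying_capacity=400), inoculum_size=0)
        pop = initialize_population(cfg, rng)
        assert pop.size == 400
        assert not pop.drive_carrier_mask().any()
        assert np.all(pop.sites_m == cfg.drive.n_guides)

    def test_xshredder_inoculation(self, rng):
        cfg = SimConfig(
            demog=DemogParams(carrying_capacity=400),
            inoculum_size=20,
            strategy="xshredder",
        )
        pop = initialize_population(cfg, rng)
        assert (pop.y_drive != 0).sum() == 20
        assert np.all(pop.allo[pop.y_drive != 0] == XY)
        assert not pop.drive_carrier_mask().any()  # cassette is Y-linked, not autosomal

    def test_odd_k_rejected(self, rng):
        cfg = SimConfig(demog=DemogParams(carrying_capacity=401))
        with pytest.raises(ValueError):
            initialize_population(cfg, rng)


class TestStepCycle:
    def test_empty_population_absorbing(self, rng):
        cfg = SimConfig(demog=DemogParams(carrying_capacity=100))
        assert step_cycle(Population.empty(), cfg, rng).size == 0

    def test_all_female_population_shrinks(self, rng):
        cfg = SimConfig(demog=DemogParams(carrying_capacity=200), inoculum_size=0)
        pop = Population.zeros(200)
        pop.allo[:] = XX
        pop.sites_m[:] = 3
        pop.sites_p[:] = 3
        out = step_cycle(pop, cfg, rng)
        assert out.size <= 200
        assert np.all(out.age >= 1)  # no newborns

    def test_drive_free_equilibrium_at_k(self):
        cfg = SimConfig(demog=DemogParams(carrying_capacity=2000), inoculum_size=0)
        rng = np.random.default_rng(0)
        sizes = []
        for seed in range(20):
            pop = initialize_population(cfg, np.random.default_rng(seed))
            sizes.append(step_cycle(pop, cfg, rng).size)
        assert abs(np.mean(sizes) / 2000 - 1.0) < 0.05


class TestRunSimulation:
    def test_bitwise_determinism(self, small_config):
        a = run_simulation(small_config, seed=99)
        b = run_simulation(small_config, seed=99)
        assert np.array_equal(a.data, b.data)
        assert a.eradication_cycle == b.eradication_cycle
        c = run_simulation(small_config, seed=100)
        assert not np.array_equal(a.data, c.data)

    def test_genotype_bookkeeping_conservation(self, small_config):
        res = run_simulation(small_config, seed=3)
        n = res.data[:, 0]
        assert np.all(res.data[:, 1:4].sum(axis=1) == n)  # allosomes
        assert np.all(res.data[:, 4:].sum(axis=1) == n)  # autosomes

    def test_no_yo_and_no_resistant_without_nhej(self, small_config):
        cfg = small_config.with_(drive=replace(small_config.drive, nhej_prob=0.0))
        res = run_simulation(cfg, seed=5)
        for name in ("WR", "GR", "RR"):
            assert np.all(res.series(name) == 0)

    def test_disabled_shredder_spreads_without_eradication(self, small_config):
        cfg = small_config.with_(
            drive=replace(small_config.drive, shred_prob=0.0, nhej_prob=0.0),
            years=5,
        )
        res = run_simulation(cfg, seed=11)
        assert not res.eradicated
        # sex ratio stays ~1:1 (no XO ever)
        assert np.all(res.series("XO") == 0)
        xx, xy = res.series("XX")[-1], res.series("XY")[-1]
        assert abs(xx / (xx + xy) - 0.5) < 0.1
        assert _g_allele_freq(res) > _g_allele_freq(res, row=0)

    def test_full_shredding_eradicates_small_population(self, small_config):
        cfg = small_config.with_(drive=replace(small_config.drive, nhej_prob=0.0))
        res = run_simulation(cfg, seed=2)
        assert res.eradicated and res.final_n == 0
        assert res.eradication_cycle == res.data.shape[0] - 1

    def test_no_xy_drive_carriers_under_certain_shredding(self):
        cfg = SimConfig(demog=DemogParams(carrying_capacity=600), inoculum_size=30,
                        drive=DriveParams(shred_prob=1.0, nhej_prob=0.0))
        rng = np.random.default_rng(17)
        pop = initialize_population(cfg, rng)
        for _ in range(20):
            pop = step_cycle(pop, cfg, rng)
            carriers = pop.drive_carrier_mask()
            assert not np.any(carriers & (pop.allo == XY))
            assert np.all(np.isin(pop.allo, (XX, XY, XO)))  # YO never exists

    def test_fixation_with_suppression(self):
        # weak shredding, no NHEJ: drive fixes but population persists
        cfg = SimConfig(
            demog=DemogParams(carrying_capacity=2000),
            drive=DriveParams(shred_prob=0.5, nhej_prob=0.0),
            inoculum_size=100,
            seed=4,
        )
        res = run_simulation(cfg)
        assert not res.eradicated
        assert res.final_n > 0
        assert _g_allele_freq(res) > 0.99

    def test_noncoding_resistance_rebound(self):
        cfg = SimConfig(
            demog=DemogParams(carrying_capacity=2000, max_mates=3),
            drive=DriveParams(shred_prob=1.0, nhej_prob=0.1, placement="noncoding"),
            inoculum_size=100,
            seed=8,
        )
        res = run_simulation(cfg)
        assert not res.eradicated
        assert _r_allele_freq(res) > 0.5
        assert res.final_n > 0.8 * 2000


class TestReplicates:
    def test_single_replicate_summary_matches_run(self, small_config):
        batch = run_replicate_batch(small_config, replicates=1)
        summary = summarize_replicates(batch)
        assert summary.n_replicates == 1
        assert summary.eradication_probability == float(batch[0].eradicated)
        assert np.array_equal(summary.mean, batch[0].padded().astype(float))

    def test_guaranteed_eradication_small_scale(self, small_config):
        cfg = small_config.with_(drive=replace(small_config.drive, nhej_prob=0.0))
        summary = run_replicates(cfg, replicates=10)
        assert summary.eradication_probability == 1.0

    def test_control_population_never_eradicates(self, small_config):
        cfg = small_config.with_(inoculum_size=0)
        summary = run_replicates(cfg, replicates=10)
        assert summary.eradication_probability == 0.0
        assert summary.lo[0, 0] <= summary.mean[0, 0] <= summary.hi[0, 0]


class TestThreshold:
    def test_bounded_and_found_at_small_scale(self, small_config):
        cfg = small_config.with_(drive=replace(small_config.drive, nhej_prob=0.0))
        thr = find_eradication_threshold(cfg, [0.0, 1.0], replicates=5)
        assert thr == 1.0  # P_Y=0 cannot eradicate, P_Y=1 does at this scale

    def test_validation(self, small_config):
        with pytest.raises(ValueError):
            find_eradication_threshold(small_config, [])
        with pytest.raises(ValueError):
            find_eradication_threshold(small_config, [0.9, 0.5])
        with pytest.raises(ValueError):
            find_eradication_threshold(small_config, [0.5], required_fraction=0.0)

    def test_none_when_no_point_qualifies(self, small_config):
        cfg = small_config.with_(inoculum_size=0)
        assert find_eradication_threshold(cfg, [0.5, 1.0], replicates=3) is None

    def test_coarse_to_fine_agrees_with_direct_search(self, small_config):
        cfg = small_config.with_(drive=replace(small_config.drive, nhej_prob=0.0))
        thr = coarse_to_fine_threshold(cfg, lo=0.5, hi=1.0, coarse_step=0.25,
                                       fine_step=0.05, replicates=5)
        assert thr is not None and 0.5 <= thr <= 1.0
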