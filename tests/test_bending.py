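import math

import numpy as np
import pytest

import minifil as mf
from minifil.bending import max_overlap


def arc_aware_contour(xyz, radius, arc_len, overlap, spacing):
    """Path length along straight/arc/straight segments from site coordinates."""
    chords = np.sqrt((np.diff(xyz, axis=0) ** 2).sum(axis=1))
    n = len(xyz)
    # contour-from-tip of each segment's midpoint decides its regime
    c_mid = (n - 1 - np.arange(1, n)) * spacing + spacing / 2
    on_arc = (c_mid > overlap) & (c_mid < overlap + arc_len)
    lengths = chords.copy()
    lengths[on_arc] = 2 * radius * np.arcsin(np.clip(chords[on_arc] / (2 * radius), -1, 1))
    return lengths.sum()


class TestBendingEnergy:
    def test_zero_arc_and_straight_limit(self):
        assert mf.bending_energy(100.0, 0.0) == 0.0
        assert mf.bending_energy(math.inf, 25.0) == 0.0

    def test_wlc_value(self):
        assert mf.bending_energy(130.0, 20.0, 130.0) == pytest.approx(20 / (2 * 130))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mf.bending_energy(-1.0, 10.0)
        with pytest.raises(ValueError):
            mf.bending_energy(100.0, -1.0)

    def test_monotone_in_radius_and_arc_length(self):
        r = np.linspace(75, 300, 10)
        e_r = [mf.bending_energy(x, 20.0) for x in r]
        assert all(a > b for a, b in zip(e_r, e_r[1:]))
        la = np.linspace(15, 40, 10)
        e_la = [mf.bending_energy(130.0, x) for x in la]
        assert all(a < b for a, b in zip(e_la, e_la[1:]))


class TestWLCParams:
    def test_default_grid_bounds_are_the_model_ranges(self):
        w = mf.WLCParams()
        assert w.persistence_length == 130.0
        assert (w.r_grid[0], w.r_grid[-1]) == (75.0, 300.0)
        assert (w.la_grid[0], w.la_grid[-1]) == (15.0, 40.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            mf.WLCParams(persistence_length=-1)
        with pytest.raises(ValueError):
            mf.WLCParams(r_steps=1)
        with pytest.raises(ValueError):
            mf.WLCParams(r_range=(300.0, 75.0))


class TestBentRodCoordinates:
    def setup_method(self):
        self.chain = mf.ChargeChain("c", np.zeros(400))
        self.p = mf.ElectrostaticParams()

    def test_straight_sentinel_matches_straight_pair_antiparallel(self):
        s = 10.0
        xyz = mf.bent_rod_coordinates(
            self.chain, s, 20.0, math.inf, 0.0, "antiparallel", self.p,
            partner_length=self.chain.rod_length,
        )
        _, ref = mf.place_straight_pair(self.chain, self.chain, "antiparallel", s, self.p)
        assert np.allclose(xyz, ref)

    def test_straight_sentinel_parallel_tip_anchored(self):
        """Straight limit: collinear rod with its tip s before the partner's."""
        s = 10.0
        xyz = mf.bent_rod_coordinates(
            self.chain, s, 20.0, math.inf, 0.0, "parallel", self.p,
            partner_length=self.chain.rod_length,
        )
        assert np.allclose(xyz[:, 1], self.p.lateral_separation)
        assert xyz[-1, 2] == pytest.approx(self.chain.rod_length - s)  # C tip
        assert xyz[0, 2] == pytest.approx(-s)  # N terminus

    @pytest.mark.parametrize("orientation", ["parallel", "antiparallel"])
    def test_tangent_turn_equals_la_over_r(self, orientation):
        r_bend, la, lo = 120.0, 30.0, 15.0
        xyz = mf.bent_rod_coordinates(
            self.chain, 5.0, lo, r_bend, la, orientation, self.p,
            partner_length=self.chain.rod_length,
        )
        tang = np.diff(xyz, axis=0)
        c_mid = (len(xyz) - 1 - np.arange(1, len(xyz))) * self.chain.spacing
        before = tang[np.argmin(np.abs(c_mid - lo + 1))]
        after = tang[c_mid > lo + la][-1]
        cosang = before @ after / np.linalg.norm(before) / np.linalg.norm(after)
        assert math.acos(np.clip(cosang, -1, 1)) == pytest.approx(la / r_bend, rel=1e-3)

    def test_departure_distance_non_decreasing(self):
        xyz = mf.bent_rod_coordinates(
            self.chain, 5.0, 12.0, 90.0, 35.0, "parallel", self.p,
            partner_length=self.chain.rod_length,
        )
        y = xyz[::-1, 1]  # tip-first order
        assert (np.diff(y) >= -1e-12).all()

    def test_contour_length_preserved(self):
        r_bend, la, lo = 100.0, 35.0, 30.0
        xyz = mf.bent_rod_coordinates(
            self.chain, 14.3, lo, r_bend, la, "parallel", self.p,
            partner_length=self.chain.rod_length,
        )
        contour = arc_aware_contour(xyz, r_bend, la, lo, self.chain.spacing)
        assert abs(contour - self.chain.rod_length) < 1e-6

    def test_overlong_arc_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="minifil"):
            mf.bent_rod_coordinates(
                self.chain, 0.0, self.chain.rod_length - 10.0, 100.0, 35.0,
                "antiparallel", self.p, partner_length=self.chain.rod_length,
            )
        assert any("clamped" in r.message for r in caplog.records)


class TestOptimizeBend:
    def brute(self, a, b, orientation, s, lo, e, w):
        """Independent exhaustive enumeration over the (R, L_a) grid."""
        za = a.axial_positions
        ca = np.column_stack([np.zeros_like(za), np.zeros_like(za), za])
        best = None
        cands = []
        if w.include_straight and lo >= max_overlap(a, b, s) - 1e-9:
            cands.append((math.inf, 0.0))
        for r_bend in w.r_grid[::-1]:
            for la in w.la_grid:
                cands.append((float(r_bend), float(la)))
        for r_bend, la in cands:
            la_eff = la if math.isinf(r_bend) else min(la, max(b.rod_length - lo, 0.0))
            cb = mf.bent_rod_coordinates(
                b, s, lo, r_bend, la_eff, orientation, e, partner_length=a.rod_length
            )
            etot = mf.chain_interaction_energy(a.charges, ca, b.charges, cb, e) + \
                mf.bending_energy(r_bend, la_eff, w.persistence_length)
            if best is None or etot < best[0] - 1e-12:
                best = (etot, r_bend, la_eff)
        return best

    @pytest.mark.parametrize("orientation", ["parallel", "antiparallel"])
    def test_equals_exhaustive_enumeration(self, orientation):
        rng = np.random.default_rng(2)
        a = mf.ChargeChain("a", rng.choice([-2.0, 0.0, 2.0], 40))
        b = mf.ChargeChain("b", rng.choice([-2.0, 0.0, 2.0], 40))
        e = mf.ElectrostaticParams()
        w = mf.WLCParams(r_steps=4, la_steps=3)
        for s, lo in [(0.5824, 1.0), (1.456, 2.912), (2.912, max_overlap(a, b, 2.912))]:
            bg = mf.optimize_bend(a, b, orientation, s, lo, e, w)
            etot, r_bend, la = self.brute(a, b, orientation, s, lo, e, w)
            assert bg.total_energy == pytest.approx(etot, abs=1e-10)
            assert bg.radius == r_bend and bg.arc_length == la

    def test_neutral_chains_minimal_bend_inner_cell(self):
        chain = mf.ChargeChain("n", np.zeros(200))
        e, w = mf.ElectrostaticParams(), mf.WLCParams()
        bg = mf.optimize_bend(chain, chain, "parallel", 0.0, 5.0, e, w)
        # gentlest admissible arc: largest R, smallest L_a
        assert bg.radius == 300.0 and bg.arc_length == 15.0
        assert bg.total_energy == pytest.approx(130 * 15 / (2 * 300**2))

    def test_neutral_chains_straight_wins_at_top_cell(self):
        chain = mf.ChargeChain("n", np.zeros(200))
        e, w = mf.ElectrostaticParams(), mf.WLCParams()
        lmax = max_overlap(chain, chain, 0.0)
        bg = mf.optimize_bend(chain, chain, "parallel", 0.0, lmax, e, w)
        assert bg.is_straight and bg.total_energy == 0.0

    def test_overlap_beyond_lmax_rejected(self, toy_pair):
        a, b = toy_pair
        with pytest.raises(ValueError, match="exceeds"):
            mf.optimize_bend(a, b, "parallel", 5.0, b.rod_length + 1.0)


@pytest.fixture(scope="module")
def toy_landscapes():
    rng = np.random.default_rng(4)
    q = rng.choice([-2.0, 0.0, 2.0], 80, p=[0.25, 0.5, 0.25])
    a = mf.ChargeChain("a", q)
    b = mf.ChargeChain("b", q.copy())
    e, w = mf.ElectrostaticParams(), mf.WLCParams()
    out = {}
    for orientation in ("parallel", "antiparallel"):
        out[orientation] = (
            mf.energy_landscape(a, b, orientation, engine="fast",
                                e_params=e, wlc_params=w),
            mf.energy_landscape(a, b, orientation, engine="reference",
                                e_params=e, wlc_params=w),
        )
    return out


class TestEnergyLandscape:
    @pytest.mark.parametrize("orientation", ["parallel", "antiparallel"])
    def test_fast_engine_matches_reference(self, toy_landscapes, orientation):
        fast, ref = toy_landscapes[orientation]
        assert np.nanmax(np.abs(fast.e_total - ref.e_total)) < 5e-3
        assert np.max(np.abs(fast.top_e_total - ref.top_e_total)) < 5e-3

    @pytest.mark.parametrize("orientation", ["parallel", "antiparallel"])
    def test_energy_decomposition_exact(self, toy_landscapes, orientation):
        fast, _ = toy_landscapes[orientation]
        acc = fast.accessible & ~np.isnan(fast.e_total)
        assert np.allclose(
            fast.e_total[acc], fast.e_bend[acc] + fast.e_elec[acc], atol=1e-12
        )
        assert (fast.e_bend[acc] >= 0).all()

    def test_mask_and_lmax(self, toy_landscapes):
        fast, _ = toy_landscapes["parallel"]
        assert np.allclose(fast.lmax, fast.lmax[0] - fast.staggers)
        assert np.isnan(fast.e_total[~fast.accessible]).all()

    def test_top_cell_not_above_straight_rod_energy(self, default_rod, e_params, wlc_params):
        """Minimisation can only improve on the straight configuration at L_max."""
        sp = default_rod.spacing
        land = mf.energy_landscape(
            default_rod, default_rod, "parallel",
            s_grid=np.array([98, 294]) * sp, e_params=e_params, wlc_params=wlc_params,
        )
        scan = mf.stagger_scan_straight(
            default_rod, default_rod, "parallel", params=e_params
        )
        for i, ks in enumerate((98, 294)):
            assert land.top_e_total[i] <= scan.energies[ks] + 1e-9

    def test_fast_engine_matches_reference_cell_at_rod_scale(
        self, default_rod, e_params, wlc_params
    ):
        """One full-size cell: engine lookup table vs literal pairwise sums."""
        sp = default_rod.spacing
        s, lo = 98 * sp, 210 * sp
        land = mf.energy_landscape(
            default_rod, default_rod, "parallel", s_grid=np.array([s]),
            lo_step=210 * sp, e_params=e_params, wlc_params=wlc_params,
        )
        ref = mf.optimize_bend(
            default_rod, default_rod, "parallel", s, lo, e_params, wlc_params
        )
        j = int(np.argmin(np.abs(land.overlaps - lo)))
        assert land.e_total[0, j] == pytest.approx(ref.total_energy, abs=5e-3)

    def test_neutral_chains_near_zero_landscape(self):
        chain = mf.ChargeChain("n", np.zeros(150))
        land = mf.energy_landscape(chain, chain, "parallel", engine="fast")
        acc = land.accessible & ~np.isnan(land.e_total)
        min_bend = 130 * 15 / (2 * 300**2)
        assert np.nanmax(np.abs(land.e_total[acc])) <= min_bend + 1e-9
        assert np.allclose(land.top_e_total, 0.0)

    def test_off_lattice_stagger_rejected_by_fast_engine(self, toy_pair):
        a, b = toy_pair
        with pytest.raises(ValueError, match="lattice"):
            mf.energy_landscape(a, b, "parallel", s_grid=np.array([0.1]))


class TestOverlapPotential:
    def test_column_extraction_matches_cells(self, default_rod, e_params, wlc_params):
        sp = default_rod.spacing
        land = mf.energy_landscape(
            default_rod, default_rod, "antiparallel",
            s_grid=np.array([490, 889]) * sp, e_params=e_params, wlc_params=wlc_params,
        )
        pot = mf.overlap_potential(land, 889 * sp)
        acc = land.accessible[1]
        stored = land.e_total[1, acc]
        assert np.allclose(pot.energies[: stored.size], stored)
        assert pot.l_max == pytest.approx(land.lmax[1])
        assert pot.energies[-1] == pytest.approx(land.top_e_total[1])

    def test_outside_grid_rejected(self, default_rod, e_params, wlc_params):
        sp = default_rod.spacing
        land = mf.energy_landscape(
            default_rod, default_rod, "parallel", s_grid=np.array([98]) * sp,
            e_params=e_params, wlc_params=wlc_params,
        )
        with pytest.raises(ValueError, match="outside"):
            mf.overlap_potential(land, 140.0)
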