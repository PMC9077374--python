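"""Synthetic 1-ps track configurations: inventories, geometry, ensembles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from trackchem import tracks


def _spur_params(**kw):
    return tracks.SpurModelParams(**kw)


class TestSampleSpur:
    def test_zero_yields_give_empty_spur(self, rng):
        p = _spur_params(g_1ps={})
        names, pos = tracks.sample_spur(50.0, p, rng)
        assert names == [] and len(pos) == 0

    def test_mean_counts_match_yields(self):
        """E[count] = g E/100: 2.0 hydrated electrons for a 50 eV spur at
        g = 4.0 (Poisson mean, checked to 3 sigma over 1e5 spurs)."""
        p = _spur_params(g_1ps={"e_aq-": 4.0, "H3O+": 4.0})
        rng = np.random.default_rng(7)
        n = 100_000
        counts = np.array([
            sum(1 for s in tracks.sample_spur(50.0, p, rng)[0] if s == "e_aq-")
            for _ in range(n)])
        expect = 2.0
        z = abs(counts.mean() - expect) / (np.sqrt(expect) / np.sqrt(n))
        assert z < 3.0

    @given(energy=st.floats(6.6, 100.0), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_exact_charge_neutrality(self, network, energy, seed):
        p = _spur_params()
        names, _ = tracks.sample_spur(energy, p, np.random.default_rng(seed))
        q = sum(network.species[s].charge for s in names)
        assert q == 0

    def test_neutrality_invariant_enforced(self):
        with pytest.raises(ValueError, match="neutrality"):
            _spur_params(g_1ps={"e_aq-": 4.2, "OH-": 0.5, "H3O+": 4.2})

    def test_electron_class_is_wider(self, rng):
        """Hydrated electrons thermalize farther out than heavy species."""
        p = _spur_params()
        re, rh = [], []
        for _ in range(400):
            names, pos = tracks.sample_spur(80.0, p, rng)
            r = np.linalg.norm(pos, axis=1)
            for s, ri in zip(names, r):
                (re if s == "e_aq-" else rh).append(ri)
        assert np.mean(re) > 2.0 * np.mean(rh)


class TestGammaSegment:
    def test_deposited_energy_tracks_let(self, rng):
        """150 um at 0.3 eV/nm deposits ~45 keV."""
        mode = tracks.TrackModeParams(mode="gamma")
        p = _spur_params()
        es = [tracks.generate_gamma_segment(mode, p, rng).deposited_energy
              for _ in range(10)]
        assert np.mean(es) == pytest.approx(45_000, rel=0.10)

    def test_mean_spur_spacing(self, rng):
        mode = tracks.TrackModeParams(mode="gamma", segment_length_um=300.0)
        p = _spur_params()
        cfg = tracks.generate_gamma_segment(mode, p, rng)
        n_spurs = cfg.deposited_energy / p.mean_spur_energy
        spacing = mode.segment_length_um * 1e3 / n_spurs
        assert spacing == pytest.approx(p.mean_spur_energy / mode.LET, rel=0.15)

    def test_vanishing_let_leaves_single_spur(self, rng):
        mode = tracks.TrackModeParams(mode="gamma", LET=1e-9)
        cfg = tracks.generate_gamma_segment(mode, _spur_params(), rng)
        # only the first energy-loss event fits in the segment
        assert cfg.deposited_energy <= 100.0

    def test_wrong_mode_rejected(self, rng):
        mode = tracks.TrackModeParams(mode="tritium")
        with pytest.raises(ValueError):
            tracks.generate_gamma_segment(mode, _spur_params(), rng)


class TestTritiumTrack:
    def test_deposits_exact_electron_energy(self, rng):
        mode = tracks.TrackModeParams(mode="tritium")
        cfg = tracks.generate_tritium_track(mode, _spur_params(), rng)
        assert cfg.deposited_energy == 7800.0

    def test_path_length_is_energy_over_let(self, rng):
        """Total path ~ 7800/5.9 = 1322 nm."""
        mode = tracks.TrackModeParams(mode="tritium")
        p = _spur_params()
        ymax = [tracks.generate_tritium_track(mode, p, rng).positions[:, 1].max()
                for _ in range(40)]
        assert np.mean(ymax) == pytest.approx(1322.0, rel=0.15)

    def test_denser_than_gamma(self, rng):
        """Nearest-neighbour distances shrink with LET (5.9 vs 0.3 eV/nm)."""
        p = _spur_params()
        tri = tracks.generate_tritium_track(
            tracks.TrackModeParams(mode="tritium"), p, rng)
        gam = tracks.generate_gamma_segment(
            tracks.TrackModeParams(mode="gamma", segment_length_um=10.0), p, rng)

        def mean_nn(cfg):
            d, _ = cKDTree(cfg.positions).query(cfg.positions, k=2)
            return d[:, 1].mean()

        assert mean_nn(tri) < mean_nn(gam)

    def test_pairwise_density_exceeds_gamma(self, rng):
        """Pairs within 10 nm per 100 eV: the geometric driver of the higher
        molecular yields in the short-track geometry."""
        p = _spur_params()

        def density(cfg):
            pairs = cKDTree(cfg.positions).query_pairs(10.0)
            return 100.0 * len(pairs) / cfg.deposited_energy

        tri = np.mean([density(tracks.generate_tritium_track(
            tracks.TrackModeParams(mode="tritium"), p, rng)) for _ in range(5)])
        gam = np.mean([density(tracks.generate_gamma_segment(
            tracks.TrackModeParams(mode="gamma", segment_length_um=20.0), p,
            rng)) for _ in range(5)])
        assert tri > gam


class TestEnsembleYields:
    @pytest.mark.parametrize("mode_name", ["gamma", "tritium"])
    def test_one_ps_g_values_reproduce_inputs(self, mode_name):
        """Ensemble 100 * count / energy at 1 ps recovers the configured
        yields within Monte Carlo error for both radiation modes."""
        p = _spur_params()
        mode = tracks.TrackModeParams(mode=mode_name)
        rng = np.random.default_rng(11)
        counts = {s: 0.0 for s in p.g_1ps}
        e_tot = 0.0
        n = 2000 if mode_name == "gamma" else 8
        for _ in range(n):
            cfg = tracks.generate_configuration(mode, p, rng)
            e_tot += cfg.deposited_energy
            for s in cfg.species:
                counts[s] += 1
        for s, g in p.g_1ps.items():
            got = 100.0 * counts[s] / e_tot
            sigma = 100.0 * np.sqrt(g * e_tot / 100.0) / e_tot
            assert abs(got - g) < 4.0 * sigma, (s, got, g)

    def test_empty_snapshot_keeps_energy(self):
        """Zero-particle events keep their energy in the denominator (a
        rejection loop here would bias every ensemble yield upward)."""
        p = _spur_params()
        rng = np.random.default_rng(3)
        cfgs = [tracks.generate_spur_history(p, rng) for _ in range(4000)]
        assert any(len(c) == 0 for c in cfgs)
        assert all(c.deposited_energy > 0 for c in cfgs)


class TestSerialization:
    def test_projection_plot_hook(self, rng):
        import matplotlib

        matplotlib.use("Agg")
        cfg = tracks.generate_tritium_track(
            tracks.TrackModeParams(mode="tritium"), _spur_params(), rng)
        ax = tracks.plot_configuration(cfg)
        assert ax.get_xlabel() == "x (nm)"

    def test_csv_round_trip(self, tmp_path, rng):
        cfg = tracks.generate_spur_history(_spur_params(), rng)
        path = tmp_path / "spur.csv"
        cfg.save_csv(path)
        back = tracks.InitialConfiguration.load_csv(path, cfg.deposited_energy)
        assert back.species == cfg.species
        np.testing.assert_allclose(back.positions, cfg.positions, rtol=1e-12)
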