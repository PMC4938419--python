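import numpy as np
import pytest

import hiergst as hg
from hiergst.popdata import ValidationError
from hiergst.simulate import SelectedLocus, _migration_matrix, _population_labels


class TestScenarioConfig:
    def test_default_design_is_sixteen_populations(self):
        cfg = hg.ScenarioConfig()
        assert cfg.n_populations == 16
        assert (cfg.N, cfg.L) == (200, 100)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValidationError):
            hg.ScenarioConfig(m1=0.05, m2=0.01, m3=0.002)  # wrong ordering
        with pytest.raises(ValidationError):
            hg.ScenarioConfig(selected=[SelectedLocus(200, "divergent", 0.1)])
        with pytest.raises(ValidationError):
            SelectedLocus(0, "stabilizing", 0.1)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = hg.ScenarioConfig(L=20, selected=[SelectedLocus(3, "divergent", 0.25)],
                                seed=9)
        path = tmp_path / "scenario.yaml"
        cfg.write(path)
        assert hg.ScenarioConfig.read(path) == cfg


class TestMigrationMatrix:
    def test_rows_are_stochastic(self):
        cfg = hg.ScenarioConfig()
        pops, clus, sub, *_ = _population_labels(cfg)
        A = _migration_matrix(cfg, pops, clus, sub)
        assert np.allclose(A.sum(axis=1), 1.0)
        assert A.min() >= 0

    def test_single_site_design_drops_empty_levels(self):
        cfg = hg.ScenarioConfig(n_clusters=1, n_subclusters=1, n_sites=1, N=50)
        pops, clus, sub, *_ = _population_labels(cfg)
        A = _migration_matrix(cfg, pops, clus, sub)
        # only m3 applies between the two elevations
        assert A.shape == (2, 2)
        assert A[0, 1] == pytest.approx(cfg.m3)
        assert A[0, 0] == pytest.approx(1 - cfg.m3)


class TestSimulate:
    def test_seed_determinism(self):
        cfg = hg.ScenarioConfig(L=10, N=30, generations=40)
        a = hg.simulate(cfg, seed=5)
        b = hg.simulate(cfg, seed=5)
        c = hg.simulate(cfg, seed=6)
        assert a.dataset == b.dataset
        assert a.dataset != c.dataset

    def test_frequencies_and_counts_conserved(self, neutral_sim):
        f = neutral_sim.final_freqs
        assert np.all((f >= 0) & (f <= 1))
        ds = neutral_sim.dataset
        # every population carries exactly 2N allele copies per locus
        _, n, N = ds.counts_matrix()
        assert np.all(N == 2 * neutral_sim.scenario.N)

    def test_truth_covers_selected_loci_only(self):
        cfg = hg.scenario_from_table2("divergent", 3, 0.5, seed=1)
        sim = hg.simulate(cfg)
        assert sim.selected_loci == {"L001", "L002", "L003"}
        assert all(regime == "divergent" and s == 0.5
                   for regime, s in sim.truth.values())

    def test_drift_decay_oracle(self):
        """With no migration and no selection, expected heterozygosity
        decays by (1 - 1/2N) per generation."""
        cfg = hg.ScenarioConfig(m1=0, m2=0, m3=0, N=50, L=300,
                                generations=60, seed=2)
        sim = hg.simulate(cfg)
        f = sim.final_freqs
        het = np.mean(2 * f * (1 - f))
        expected = 0.5 * (1 - 1 / (2 * cfg.N)) ** cfg.generations
        assert het == pytest.approx(expected, rel=0.05)

    def test_strong_divergent_selection_separates_elevations(self):
        """s = 0.99 drives near-fixation of opposite alleles at the two
        elevations (deterministic selection-equilibrium oracle)."""
        hits = total = 0
        for seed in range(10):
            cfg = hg.scenario_from_table2("divergent", 2, 0.99, seed=seed)
            sim = hg.simulate(cfg)
            is_high = np.array([sim.hierarchy.elevation_of[p] == "high"
                                for p in sim.hierarchy.populations])
            for loc in sorted(sim.selected_loci):
                j = sim.dataset.loci.index(loc)
                dp = abs(sim.final_freqs[~is_high, j].mean()
                         - sim.final_freqs[is_high, j].mean())
                total += 1
                hits += dp > 0.8
        assert hits >= 0.9 * total

    def test_neutral_gst_ordering_matches_migration_hierarchy(self, neutral_sim):
        """m1 < m2 < m3 implies mean GST: cluster > sub-cluster > elevation
        (island-model equilibrium ordering)."""
        ds, _ = hg.filter_monomorphic(neutral_sim.dataset)
        g = hg.gst_median_matrix(ds, n_samples=500, seed=3)
        d = hg.build_design(neutral_sim.hierarchy)
        w = g.wide().mean(axis=0).to_numpy()
        m_clus = w[d["k_clus"] == 1].mean()
        m_sub = w[d["k_subclus"] == 1].mean()
        m_elev = w[(d["k_clus"] == 0) & (d["k_subclus"] == 0) & (d["k_elev"] == 1)].mean()
        assert m_clus > m_sub > m_elev

    def test_homogenizing_depresses_elevation_gst(self):
        cfg = hg.scenario_from_table2("homogenizing", 3, 0.1, seed=4)
        sim = hg.simulate(cfg)
        f = sim.final_freqs
        # selected loci end near the same fixation point everywhere
        sel = [sim.dataset.loci.index(l) for l in sorted(sim.selected_loci)]
        assert np.all(f[:, sel].min(axis=0) > 0.8)


class TestScenarioFromTable2:
    def test_divergent_row(self):
        cfg = hg.scenario_from_table2("divergent", 5, 0.1, seed=0)
        assert cfg.n_populations == 16 and cfg.N == 200
        assert [s.locus for s in cfg.selected] == [0, 1, 2, 3, 4]
        assert all(s.s == 0.1 and s.regime == "divergent" for s in cfg.selected)

    def test_no_selection_row(self):
        cfg = hg.scenario_from_table2("no selection", 0, None, seed=0)
        assert cfg.selected == []

    def test_mixed_row(self):
        cfg = hg.scenario_from_table2("homogenizing/divergent", (2, 2), 0.1, seed=0)
        regimes = [s.regime for s in cfg.selected]
        assert regimes == ["homogenizing", "homogenizing", "divergent", "divergent"]

    def test_variable_strength_row_draws_within_range(self):
        cfg = hg.scenario_from_table2("divergent", 10, (0.06, 0.24), seed=1)
        ss = np.array([s.s for s in cfg.selected])
        assert len(ss) == 10
        assert np.all((ss >= 0.06) & (ss <= 0.24))
        assert len(np.unique(ss)) == 10
        # same seed -> same draws
        cfg2 = hg.scenario_from_table2("divergent", 10, (0.06, 0.24), seed=1)
        assert [s.s for s in cfg2.selected] == [s.s for s in cfg.selected]

    def test_within_site_design(self):
        cfg = hg.scenario_from_table2("divergent", 10, 0.5, within_site=True, seed=2)
        assert cfg.n_populations == 2 and cfg.N == 1600

    def test_unknown_row_rejected(self):
        with pytest.raises(KeyError):
            hg.scenario_from_table2("background", 1, 0.1)
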