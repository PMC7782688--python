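"""Simulator: scenario presets, sweep dynamics, truth tables, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from islandsweep import simdata
from islandsweep.genotypes import NO_ALLELE

from conftest import tiny_config


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

class TestScenarios:
    def test_no_geneflow_preset(self):
        cfg = simdata.make_scenario("no_geneflow")
        assert cfg.migration_rate == 0.0 and not cfg.pair_migration
        assert set(cfg.causal_positions) == {"kauai"}

    def test_neutral_preset(self):
        cfg = simdata.make_scenario("neutral")
        assert cfg.causal_positions == {}
        assert cfg.selection.w_normal == 1.0

    def test_parallel_split_times_in_generations(self):
        # 800 / 570 / 400 years at 4 generations per year
        assert simdata.make_scenario("parallel").split_times == (3200, 2280, 1600)

    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(ValueError, match="parallel"):
            simdata.make_scenario("amigration")

    def test_invalid_configs_rejected(self):
        cfg = simdata.make_scenario("parallel")
        cfg.split_times = (1600, 2280, 3200)
        with pytest.raises(ValueError, match="decreasing"):
            cfg.validate()
        cfg = simdata.make_scenario("parallel")
        cfg.selection.w_normal = 0.0
        with pytest.raises(ValueError, match="w_normal"):
            cfg.validate()
        cfg = simdata.make_scenario("parallel")
        cfg.migration_rate = 1.5
        with pytest.raises(ValueError):
            cfg.validate()


# ---------------------------------------------------------------------------
# sweep trajectories
# ---------------------------------------------------------------------------

def reference_recursion(w, p0, generations):
    """Independent deterministic oracle for the X-linked recursion."""
    p_f = p_m = p0
    pheno = []
    for _ in range(generations + 1):
        p_m_star = p_m / (p_m + w * (1 - p_m))
        pheno.append(p_m_star)
        p_f, p_m = (p_f + p_m_star) / 2, p_f
    return np.array(pheno)


class TestSweepTrajectory:
    def test_absorbing_at_one(self):
        tr = simdata.sweep_trajectory(200, 0.5, 1.0, 25, seed=0)
        assert np.all(tr.p_f == 1.0) and np.all(tr.p_m == 1.0)
        assert tr.fixed

    def test_absorbing_at_zero(self):
        tr = simdata.sweep_trajectory(200, 0.5, 0.0, 25, seed=0)
        assert np.all(tr.p_f == 0.0) and tr.lost

    def test_deterministic_limit_matches_reference(self):
        det = simdata.deterministic_trajectory(0.1, 0.005, 40)
        ref = reference_recursion(0.1, 0.005, 40)
        np.testing.assert_allclose(det.male_phenotype_freq, ref, rtol=1e-12)
        # strong selection drives the adult flatwing fraction past 95%
        # within roughly a dozen generations
        assert 6 <= int(np.argmax(ref >= 0.95)) <= 12

    def test_stochastic_sweep_reaches_95pct_by_gen30(self):
        # conditioned on non-loss, the median replicate tracks the
        # deterministic recursion
        vals = []
        for seed in range(40):
            tr = simdata.sweep_trajectory(1000, 0.1, 0.005, 30, seed=seed)
            if not tr.lost:
                vals.append(tr.male_phenotype_freq[30])
        assert len(vals) >= 5
        assert np.median(vals) >= 0.95

    def test_neutral_allele_drifts_without_direction(self):
        # w = 1, start at 1/2: the per-generation change is symmetric, so
        # the sign of the change is a fair coin (sign test, alpha = 0.01)
        ups = downs = 0
        for seed in range(1500):
            tr = simdata.sweep_trajectory(
                100, 1.0, 0.5, 1, seed=(9, seed)
            )
            x0 = (tr.p_f[0] + tr.p_m[0]) / 2
            x1 = (tr.p_f[1] + tr.p_m[1]) / 2
            if x1 > x0:
                ups += 1
            elif x1 < x0:
                downs += 1
        p = stats.binomtest(ups, ups + downs, 0.5).pvalue
        assert p > 0.01

    def test_balanced_model_equilibrates_near_target(self):
        tr = simdata.sweep_trajectory(
            2000, 0.6, 0.2, 150, seed=3,
            balanced_equilibrium=0.45, balance_strength=4.0,
        )
        assert 0.3 < np.mean(tr.male_phenotype_freq[-50:]) < 0.6

    def test_deme_without_causal_locus_errors(self):
        cfg = simdata.make_scenario("no_geneflow")
        with pytest.raises(ValueError, match="causal"):
            simdata.simulate_sweep_trajectory(cfg, "oahu", seed=0)


# ---------------------------------------------------------------------------
# demography / dataset assembly
# ---------------------------------------------------------------------------

class TestSimulateDemography:
    def test_zero_scaffolds_errors(self):
        cfg = tiny_config("neutral")
        cfg.genome_layout = []
        with pytest.raises(ValueError, match="scaffold"):
            simdata.simulate_demography(cfg, seed=1)

    def test_males_haploid_on_x(self, datasets):
        ds = datasets("parallel")
        for m in ds.matrices:
            if m.is_x:
                assert np.all(m.ploidy == 1)
                assert np.all(m.alleles[:, :, 1] == NO_ALLELE)
                # X allele counts per deme = number of (male) individuals
                for deme in simdata.ISLANDS:
                    ids = ds.samples_where(deme=deme)
                    _, n_called = m.allele_counts(m.sample_index(ids))
                    assert np.all(n_called == len(ids))

    def test_morph_derives_from_causal_genotype(self, datasets):
        ds = datasets("parallel")
        gm = ds.matrix("scaffold_X1")
        for deme, pos in ds.config.causal_positions.items():
            i = int(np.searchsorted(gm.positions, pos))
            assert gm.positions[i] == pos
            for sid, morph in zip(ds.metadata["id"], ds.metadata["morph"]):
                if ds.metadata.set_index("id").loc[sid, "deme"] != deme:
                    continue
                j = gm.samples.index(sid)
                carrier = gm.alleles[i, j, 0] == 1
                assert carrier == (morph == "flatwing")

    def test_outgroup_polarisable(self, datasets):
        # the outgroup lineage is long enough to carry many fixed
        # differences, the prerequisite for ABBA-BABA polarisation
        ds = datasets("parallel")
        gm = ds.matrix("scaffold_A1")
        out = gm.sample_index(ds.samples_where(deme="outgroup"))
        isl = gm.sample_index(
            [s for d in simdata.ISLANDS for s in ds.samples_where(deme=d)]
        )
        n_alt_o, n_o = gm.allele_counts(out)
        n_alt_i, n_i = gm.allele_counts(isl)
        fixed_diff = np.sum((n_alt_o == n_o) & (n_alt_i == 0))
        assert fixed_diff > 100

    def test_trajectory_truth_within_bounds(self, datasets):
        tr = datasets("parallel").truth.trajectories
        for col in ("p_f", "p_m", "male_phenotype_freq"):
            assert ((tr[col] >= 0) & (tr[col] <= 1)).all()

    def test_introgression_truth_traces_to_origin(self, datasets):
        ds = datasets("introgression")
        assert set(ds.truth.causal_loci["origin_deme"]) == {"kauai"}
        assert len(set(ds.truth.causal_loci["position"])) == 1
        anc = ds.truth.ancestry.set_index("id")
        carriers = ds.metadata[
            ds.metadata.carrier & ds.metadata.deme.isin(["oahu", "hilo"])
        ]["id"]
        assert (anc.loc[carriers, "anc_kauai"] > 0).all()

    def test_migration_truth_tracks_configured_rate(self):
        cfg = tiny_config("neutral")
        cfg.migration_rate = 0.004
        cfg.migration_start_generation = 400
        cfg.deme_sizes = {**cfg.deme_sizes, "kauai": 200, "oahu": 200, "hilo": 200}
        rng = np.random.default_rng(11)
        _, rec = simdata._track_ancestry(cfg, rng)
        # with 2 other islands, expected in-migrant fraction is 2m per deme
        for deme, grp in rec.groupby("deme"):
            frac = grp["migrant_fraction"].to_numpy()
            se = frac.std(ddof=1) / np.sqrt(len(frac))
            assert abs(frac.mean() - 2 * 0.004) < 3 * se + 1e-12

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = tiny_config("parallel")
        outs = []
        for sub in ("a", "b"):
            ds = simdata.simulate_demography(cfg, seed=42)
            simdata.write_dataset(ds, tmp_path / sub)
            outs.append((tmp_path / sub / "genotypes.vcf").read_bytes())
        assert outs[0] == outs[1]


# ---------------------------------------------------------------------------
# truth serialisation
# ---------------------------------------------------------------------------

class TestTruthIO:
    def test_roundtrip(self, tmp_path):
        ds = simdata.simulate_demography(tiny_config("parallel"), seed=5)
        simdata.write_truth(ds, tmp_path)
        back = simdata.read_truth(tmp_path)
        pd.testing.assert_frame_equal(
            back.causal_loci, ds.truth.causal_loci, check_dtype=False
        )
        np.testing.assert_allclose(
            back.ancestry[["anc_kauai", "anc_oahu", "anc_hilo"]].to_numpy(),
            ds.truth.ancestry[["anc_kauai", "anc_oahu", "anc_hilo"]].to_numpy(),
            atol=1e-9,
        )

    def test_neutral_truth_has_empty_causal_table(self, tmp_path):
        ds = simdata.simulate_demography(tiny_config("neutral"), seed=5)
        simdata.write_truth(ds, tmp_path)
        assert len(simdata.read_truth(tmp_path).causal_loci) == 0
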