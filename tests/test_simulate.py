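"""Synthetic-data generator: determinism, calibration and truth structure."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import binom

from herbcode.distances import k2p_distance, p_distance
from herbcode.simulate import (
    CATEGORIES,
    ConfigurationError,
    SimulationConfig,
    default_chem_specs,
    evolve,
    simulate_chemistry,
    simulate_queries,
    simulate_reference_library,
)


def _tiny(**kw):
    base = dict(
        n_genera=2, species_per_genus=2, refs_per_species=5, n_offtarget_genera=1,
        n_queries=20, seq_length_per_marker={"matK": 300}, seed=7,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ConfigurationError, match="sum"):
            _tiny(p_authentic=0.5, p_congeneric_sub=0.1, p_intergeneric_sub=0.1)

    def test_scale_ordering_enforced(self):
        with pytest.raises(ConfigurationError, match="intra_scale"):
            _tiny(intra_scale=0.05, inter_scale=0.03)

    def test_intergeneric_substitutes_need_offtarget_genera(self):
        with pytest.raises(ConfigurationError, match="off-target"):
            _tiny(n_offtarget_genera=0)


class TestReferenceLibrary:
    def test_zero_intraspecific_scale_gives_identical_vouchers(self):
        sim = simulate_reference_library(_tiny(intra_scale=0.0))
        by_species = {}
        for s in sim.sequences["matK"]:
            by_species.setdefault(s.species_label, set()).add(s.bases)
        assert all(len(v) == 1 for v in by_species.values())

    def test_determinism_byte_identical(self, tmp_path):
        from herbcode.pipeline import simulate_dataset

        d1 = simulate_dataset(_tiny(), tmp_path / "a")
        d2 = simulate_dataset(_tiny(), tmp_path / "b")
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_library_shape(self):
        cfg = _tiny()
        sim = simulate_reference_library(cfg)
        n_species = (cfg.n_genera + cfg.n_offtarget_genera) * cfg.species_per_genus
        assert len(sim.sequences["matK"]) == n_species * cfg.refs_per_species
        assert len(sim.taxonomy) == n_species
        assert len(sim.target_species) == cfg.n_genera

    def test_conspecific_divergence_matches_independent_site_oracle(self):
        """Observed conspecific p-distance vs an expm-based site-process oracle.

        The oracle builds the two-rate generator matrix, exponentiates it with
        scipy (an independent route to the transition probabilities), and
        simulates 10,000 site-wise draws of a conspecific pair.
        """
        intra, kappa, L = 0.002, 2.0, 500
        cfg = _tiny(intra_scale=intra, seq_length_per_marker={"matK": L}, seed=1)
        sim = simulate_reference_library(cfg)
        obs = []
        for sp in sim.species:
            seqs = [s for s in sim.sequences["matK"] if s.species_label == sp]
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    obs.append(p_distance(seqs[i].codes, seqs[j].codes)[0])
        obs = np.asarray(obs)

        beta = 1.0 / (kappa + 2.0)
        alpha = kappa * beta
        # bases ordered A,G,C,T: transitions within purines/pyrimidines
        Q = np.array(
            [
                [-(alpha + 2 * beta), alpha, beta, beta],
                [alpha, -(alpha + 2 * beta), beta, beta],
                [beta, beta, -(alpha + 2 * beta), alpha],
                [beta, beta, alpha, -(alpha + 2 * beta)],
            ]
        )
        P = expm(Q * intra / 2.0)
        rng = np.random.default_rng(123)
        n_draws = 10_000
        roots = rng.integers(0, 4, n_draws)
        a = np.array([rng.choice(4, p=P[x]) for x in roots])
        b = np.array([rng.choice(4, p=P[x]) for x in roots])
        oracle_mean = (a != b).mean()
        se = obs.std(ddof=1) / np.sqrt(len(obs))
        mc_se = np.sqrt(oracle_mean * (1 - oracle_mean) / n_draws)
        assert abs(obs.mean() - oracle_mean) <= 3 * np.hypot(se, mc_se)

    def test_divergence_ordering(self):
        cfg = SimulationConfig(
            n_genera=2, species_per_genus=3, refs_per_species=6, n_offtarget_genera=1,
            n_queries=5, seq_length_per_marker={"matK": 400}, seed=3,
        )
        sim = simulate_reference_library(cfg)
        seqs = sim.sequences["matK"]
        intra, inter, between = [], [], []
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                d = k2p_distance(seqs[i].codes, seqs[j].codes).value
                gi = sim.taxonomy[seqs[i].species_label][0]
                gj = sim.taxonomy[seqs[j].species_label][0]
                if seqs[i].species_label == seqs[j].species_label:
                    intra.append(d)
                elif gi == gj:
                    inter.append(d)
                else:
                    between.append(d)
        assert min(len(intra), len(inter), len(between)) >= 100
        assert np.mean(intra) < np.mean(inter) < np.mean(between)


class TestQueries:
    def test_all_authentic_when_probability_one(self):
        cfg = _tiny(p_authentic=1.0, p_congeneric_sub=0.0, p_intergeneric_sub=0.0,
                    p_marker_dropout=0.0)
        sim = simulate_reference_library(cfg)
        q = simulate_queries(cfg, sim)
        assert (q.truth.category == "authentic").all()
        assert (q.truth.true_species == q.truth.labelled_species).all()
        assert (q.truth.markers == "matK").all()

    def test_total_dropout_leaves_no_sequences(self):
        cfg = _tiny(p_marker_dropout=1.0)
        sim = simulate_reference_library(cfg)
        q = simulate_queries(cfg, sim)
        assert (q.truth.markers.fillna("") == "").all()
        assert all(len(v) == 0 for v in q.sequences.values())

    def test_truth_table_partitions_queries(self):
        cfg = _tiny(n_queries=50)
        sim = simulate_reference_library(cfg)
        q = simulate_queries(cfg, sim)
        assert q.truth.sample_id.is_unique and len(q.truth) == 50
        assert set(q.truth.category) <= set(CATEGORIES)
        authentic = q.truth.category == "authentic"
        assert (q.truth.true_species[authentic] == q.truth.labelled_species[authentic]).all()
        assert (q.truth.true_species[~authentic] != q.truth.labelled_species[~authentic]).all()

    def test_category_fraction_within_binomial_interval(self):
        cfg = SimulationConfig(
            n_genera=2, species_per_genus=2, refs_per_species=2, n_offtarget_genera=1,
            n_queries=1000, p_authentic=0.6, p_congeneric_sub=0.1, p_intergeneric_sub=0.3,
            seq_length_per_marker={"matK": 100}, seed=3,
        )
        sim = simulate_reference_library(cfg)
        q = simulate_queries(cfg, sim)
        k = int((q.truth.category == "intergeneric_substitute").sum())
        lo, hi = binom.ppf([0.005, 0.995], 1000, 0.3)
        assert lo <= k <= hi

    def test_short_fragments_are_under_200bp(self):
        cfg = _tiny(p_short_fragment=1.0, p_marker_dropout=0.0)
        sim = simulate_reference_library(cfg)
        q = simulate_queries(cfg, sim)
        assert all(len(s.bases) < 200 for s in q.sequences["matK"])


class TestChemistry:
    def _truth(self, cfg):
        sim = simulate_reference_library(cfg)
        q = simulate_queries(cfg, sim)
        return sim, q.truth

    def test_no_cross_reactivity_means_no_substitute_markers(self):
        cfg = _tiny(chem_cross_react=0.0, n_queries=50)
        sim, truth = self._truth(cfg)
        assay = simulate_chemistry(truth, default_chem_specs(sim), cfg)
        merged = truth.merge(assay, on="sample_id")
        subs = merged[merged.category != "authentic"]
        assert not subs.chem_marker_present.any()

    def test_degenerate_noise_hits_one_and_a_half_times_minimum(self):
        cfg = _tiny(conc_lognorm_sigma=0.0, p_authentic=1.0, p_congeneric_sub=0.0,
                    p_intergeneric_sub=0.0)
        sim, truth = self._truth(cfg)
        specs = default_chem_specs(sim)
        assay = simulate_chemistry(truth, specs, cfg)
        for row in assay.itertuples():
            labelled = truth.set_index("sample_id").loc[row.sample_id, "labelled_species"]
            assert row.concentration == pytest.approx(1.5 * specs[labelled].min_concentration)
            assert row.tlc == "present"

    def test_cross_reactivity_rate_within_binomial_interval(self):
        cfg = SimulationConfig(
            n_genera=2, species_per_genus=2, refs_per_species=2, n_offtarget_genera=1,
            n_queries=500, p_authentic=0.0, p_congeneric_sub=0.0, p_intergeneric_sub=1.0,
            chem_cross_react=0.1, seq_length_per_marker={"matK": 100}, seed=11,
        )
        sim, truth = self._truth(cfg)
        assay = simulate_chemistry(truth, default_chem_specs(sim), cfg)
        k = int(assay.chem_marker_present.sum())
        lo, hi = binom.ppf([0.005, 0.995], 500, 0.1)
        assert lo <= k <= hi

    def test_missing_spec_rejected(self):
        cfg = _tiny()
        sim, truth = self._truth(cfg)
        with pytest.raises(KeyError, match="specification"):
            simulate_chemistry(truth, {}, cfg)

    def test_tlc_consistent_with_detection_floor(self):
        cfg = _tiny(n_queries=60)
        sim, truth = self._truth(cfg)
        specs = default_chem_specs(sim)
        assay = simulate_chemistry(truth, specs, cfg, detection_floor_frac=0.3)
        labelled = truth.set_index("sample_id").labelled_species
        for row in assay.itertuples():
            floor = 0.3 * specs[labelled.loc[row.sample_id]].min_concentration
            assert (row.tlc == "present") == (row.concentration > floor)
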