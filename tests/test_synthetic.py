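"""Count simulation, the surrogate detector, and surface generation."""

import numpy as np
import pytest

import dbltune as dt
from dbltune.rsm import quadratic_terms
from dbltune.synthetic import SimulationParams, SurrogateConfig


class TestSimulateCounts:
    def test_label_count_matches_rounded_rate(self):
        ds = dt.simulate_counts(
            SimulationParams(n_droplets=1000, doublet_rate=0.10, seed=0)
        )
        assert ds.labels.sum() == 100
        assert ds.counts.shape == (500, 1000)
        assert (ds.counts >= 0).all()

    def test_same_seed_is_byte_identical(self, tiny_dataset):
        again = dt.simulate_counts(tiny_dataset.params)
        assert np.array_equal(tiny_dataset.counts, again.counts)
        assert np.array_equal(tiny_dataset.labels, again.labels)

    def test_determinism_and_label_invariants_across_parameter_draws(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            params = SimulationParams(
                n_droplets=int(rng.integers(40, 120)),
                n_genes=int(rng.integers(50, 120)),
                n_cell_types=int(rng.integers(1, 4)),
                doublet_rate=float(rng.uniform(0.05, 0.4)),
                dispersion=float(rng.uniform(0.5, 5.0)),
                seed=int(rng.integers(0, 2**31)),
            )
            a = dt.simulate_counts(params)
            b = dt.simulate_counts(params)
            assert np.array_equal(a.counts, b.counts)
            assert a.labels.sum() == round(params.n_droplets * params.doublet_rate)
            assert a.counts.min() >= 0

    def test_zero_doublets_after_rounding_is_an_error(self):
        with pytest.raises(ValueError, match="0 doublets"):
            dt.simulate_counts(SimulationParams(n_droplets=20, doublet_rate=0.01))

    def test_cell_types_are_better_correlated_within_than_between(self):
        ds = dt.simulate_counts(
            SimulationParams(
                n_droplets=300, n_genes=400, n_cell_types=2, doublet_rate=0.1,
                seed=9, type_spread=1.0,
            )
        )
        singlets = ds.labels == 0
        logc = np.log1p(ds.counts[:, singlets].astype(float))
        types = ds.cell_types[singlets]
        corr = np.corrcoef(logc.T)
        same = types[:, None] == types[None, :]
        off_diag = ~np.eye(len(types), dtype=bool)
        within = corr[same & off_diag].mean()
        between = corr[~same].mean()
        assert within > between


class TestSurrogateDetector:
    def test_output_contract(self, two_type_dataset):
        res = dt.surrogate_detect(two_type_dataset, SurrogateConfig(seed=1))
        assert res.scores.shape == (two_type_dataset.n_droplets,)
        assert (res.scores >= 0).all() and (res.scores <= 1).all()
        assert np.array_equal(res.labels, two_type_dataset.labels)

    def test_deterministic_given_seed(self, tiny_dataset):
        cfg = SurrogateConfig(nf=100, pc=5, seed=4)
        a = dt.surrogate_detect(tiny_dataset, cfg)
        b = dt.surrogate_detect(tiny_dataset, cfg)
        assert np.array_equal(a.scores, b.scores)

    def test_detects_doublets_above_prevalence(self, two_type_dataset):
        # prevalence baseline is 0.2; a working detector clears 0.5
        for seed in (1, 2, 3):
            res = dt.surrogate_detect(two_type_dataset, SurrogateConfig(seed=seed))
            assert dt.auprc(res) > 0.5

    def test_labels_are_never_consulted(self, tiny_dataset):
        import copy

        shuffled = copy.deepcopy(tiny_dataset)
        rng = np.random.default_rng(0)
        shuffled.labels = rng.permutation(shuffled.labels)
        cfg = SurrogateConfig(nf=100, pc=5, seed=4)
        a = dt.surrogate_detect(tiny_dataset, cfg)
        b = dt.surrogate_detect(shuffled, cfg)
        assert np.array_equal(a.scores, b.scores)

    @pytest.mark.parametrize(
        "field,values",
        [("nf", (50, 250)), ("pc", (2, 20)), ("depth", (1, 6))],
    )
    def test_hyperparameters_are_live(self, tiny_dataset, field, values):
        # a dead hyperparameter would make the response surface degenerate
        base = dict(nf=250, pc=20, depth=4, seed=4)
        scores = []
        for v in values:
            cfg = SurrogateConfig(**{**base, field: v})
            scores.append(dt.surrogate_detect(tiny_dataset, cfg).scores)
        assert not np.array_equal(scores[0], scores[1])

    def test_pc_exceeding_dimensions_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="pc"):
            dt.surrogate_detect(tiny_dataset, SurrogateConfig(nf=50, pc=60))

    def test_nf_exceeding_genes_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="nf"):
            dt.surrogate_detect(tiny_dataset, SurrogateConfig(nf=10**6))


class TestResponseSurfaceGenerator:
    def test_zero_noise_is_exactly_polynomial(self, scdbl_space, eq_reduced_coeffs):
        mats = dt.simulate_response_surface(
            scdbl_space, eq_reduced_coeffs, noise_sd=0.0, n_datasets=3, seed=1
        )
        assert len(mats) == 3
        for m in mats[1:]:
            assert np.array_equal(m.response, mats[0].response)
        # spot-check the polynomial by hand at one point
        p = {"nf": 500.0, "pc": 5.0, "depth": 2.0}
        expected = (
            5.444e-1 + 1.016e-5 * 500 + 1.336e-3 * 5
            - 3.760e-9 * 500**2 - 3.484e-5 * 25
        )
        i = mats[0].points.index(p)
        assert mats[0].response[i] == pytest.approx(expected, rel=1e-12)

    def test_grid_argmax_of_published_surface(self, scdbl_space, eq_reduced_coeffs):
        # interior maximum (1351, 19.2) -> nearest grid point nf=1500, pc=20
        m = dt.simulate_response_surface(scdbl_space, eq_reduced_coeffs, 0.0, 1, 0)[0]
        best = m.points[int(np.argmax(m.response))]
        assert (best["nf"], best["pc"]) == (1500, 20)

    def test_noise_differs_across_replicates(self, scdbl_space, eq_reduced_coeffs):
        a, b = dt.simulate_response_surface(
            scdbl_space, eq_reduced_coeffs, noise_sd=1e-3, n_datasets=2, seed=2
        )
        assert not np.array_equal(a.response, b.response)

    def test_beta_as_sequence_in_canonical_order(self, scdbl_space, eq_reduced_coeffs):
        terms = quadratic_terms(scdbl_space.factor_names)
        beta_seq = [eq_reduced_coeffs.get(t, 0.0) for t in terms]
        a = dt.simulate_response_surface(scdbl_space, beta_seq, 0.0, 1, 0)[0]
        b = dt.simulate_response_surface(scdbl_space, eq_reduced_coeffs, 0.0, 1, 0)[0]
        assert np.array_equal(a.response, b.response)

    def test_rejects_bad_inputs(self, scdbl_space):
        with pytest.raises(KeyError):
            dt.simulate_response_surface(scdbl_space, {"bogus": 1.0}, 0.0, 1, 0)
        two = dt.HyperparameterSpace(scdbl_space.factors[:2])
        with pytest.raises(ValueError, match="3 factors"):
            dt.simulate_response_surface(two, {}, 0.0, 1, 0)
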