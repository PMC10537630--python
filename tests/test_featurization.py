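"""Descriptors, fingerprints, chemotype matching, GA subset selection."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from mnqsar.featurization import (
    ChemotypeSet,
    FeatureMatrix,
    GAConfig,
    PrefilterConfig,
    compute_chemotype_fingerprint,
    compute_descriptors,
    compute_fingerprint,
    ga_select_features,
    prefilter_descriptors,
)


class TestDescriptors:
    def test_ethanol_molecular_weight(self):
        fm = compute_descriptors(["CCO"])
        mw = fm.values[0, fm.feature_names.index("MolWt")]
        # 2 C + 6 H + 1 O from standard atomic masses
        assert mw == pytest.approx(2 * 12.011 + 6 * 1.008 + 15.999, abs=0.02)

    def test_empty_input_gives_zero_row_full_column_matrix(self):
        fm = compute_descriptors([])
        assert fm.values.shape[0] == 0
        assert fm.n_features > 200

    def test_deterministic_rows(self):
        fm = compute_descriptors(["c1ccccc1O", "c1ccccc1O"])
        assert np.array_equal(fm.values[0], fm.values[1])


class TestPrefilter:
    def _matrix(self, columns, names=None):
        arr = np.column_stack(columns)
        names = names or [f"d{i}" for i in range(arr.shape[1])]
        return FeatureMatrix(arr, names, "descriptor", False,
                             [f"c{i}" for i in range(arr.shape[0])])

    def test_constant_and_low_variance_columns_removed(self):
        rng = np.random.default_rng(0)
        good = rng.normal(scale=5.0, size=50)
        constant = np.full(50, 5.0)
        low_var = rng.normal(scale=0.4, size=50)  # std < 0.5
        fm = prefilter_descriptors(
            self._matrix([good, constant, low_var], ["good", "const", "low"])
        )
        assert fm.feature_names == ["good"]

    def test_duplicate_column_keeps_exactly_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(scale=3.0, size=40)
        fm = prefilter_descriptors(self._matrix([x, x.copy()], ["first", "second"]))
        assert fm.feature_names == ["first"]

    def test_survivors_keep_original_order(self):
        rng = np.random.default_rng(2)
        cols = [rng.normal(scale=2.0, size=60) for _ in range(5)]
        fm = prefilter_descriptors(self._matrix(cols))
        order = [fm.feature_names.index(n) for n in fm.feature_names]
        assert order == sorted(order)

    def test_no_surviving_pair_exceeds_r2_threshold(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=80)
        cols = [base + rng.normal(scale=s, size=80) * 3 for s in (0.01, 0.02, 1, 2, 3)]
        cfg = PrefilterConfig(r2_max=0.9, std_min=0.0)
        fm = prefilter_descriptors(self._matrix(cols), cfg)
        corr = np.corrcoef(fm.values.T)
        off_diag = corr[~np.eye(len(corr), dtype=bool)]
        assert (off_diag**2 <= cfg.r2_max).all()

    def test_too_few_compounds_error(self):
        with pytest.raises(ValueError, match="3 compounds"):
            prefilter_descriptors(self._matrix([np.array([1.0, 2.0])]))


class TestFingerprints:
    @pytest.mark.parametrize("kind,kwargs,length", [
        ("maccs", {}, 166),
        ("path_fp", {"nbits": 2048}, 2048),
        ("ecfp", {"radius": 2, "nbits": 1024}, 1024),
        ("fcfp", {"radius": 2, "nbits": 1024}, 1024),
    ])
    def test_length_binary_and_determinism(self, kind, kwargs, length):
        a = compute_fingerprint("CC(=O)Nc1ccc(O)cc1", kind, **kwargs)
        b = compute_fingerprint("CC(=O)Nc1ccc(O)cc1", kind, **kwargs)
        assert a.shape == (length,)
        assert set(np.unique(a)) <= {0, 1}
        assert np.array_equal(a, b)

    def test_methane_single_environment(self):
        fp = compute_fingerprint("C", "ecfp", radius=1, nbits=1024)
        assert 1 <= fp.sum() <= 2

    def test_ecfp_and_fcfp_differ(self):
        smiles = "c1ccccc1CCN"
        e = compute_fingerprint(smiles, "ecfp", radius=2, nbits=2048)
        f = compute_fingerprint(smiles, "fcfp", radius=2, nbits=2048)
        assert not np.array_equal(e, f)

    def test_unknown_kind_and_bad_radius(self):
        with pytest.raises(ValueError, match="unknown fingerprint"):
            compute_fingerprint("CCO", "topological_torsion")
        with pytest.raises(ValueError, match="radius"):
            compute_fingerprint("CCO", "ecfp", radius=4)


class TestChemotypes:
    def test_urethane_matches_carbamate(self):
        # urethane is the textbook carbamate exemplar
        cts = ChemotypeSet([("carbamate", "[NX3][CX3](=O)[OX2]")])
        bits = compute_chemotype_fingerprint("CCOC(N)=O", cts)
        assert bits.tolist() == [1]

    def test_benzene_has_no_nitroso(self):
        cts = ChemotypeSet([("nitroso", "[NX2]=O")])
        assert compute_chemotype_fingerprint("c1ccccc1", cts).tolist() == [0]

    def test_empty_set_gives_empty_vector(self):
        cts = ChemotypeSet([])
        assert compute_chemotype_fingerprint("CCO", cts).shape == (0,)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ChemotypeSet([("a", "C"), ("a", "N")])

    def test_bad_smarts_rejected(self):
        with pytest.raises(ValueError, match="compile"):
            ChemotypeSet([("broken", "[[[")])

    def test_default_set_loads_and_compiles(self):
        cts = ChemotypeSet.default()
        assert len(cts) >= 25
        assert len(set(cts.names)) == len(cts)

    def test_tsv_parsing_skips_comments(self, tmp_path):
        path = tmp_path / "cts.tsv"
        path.write_text("# comment\nnitroso\t[NX2]=O\n\nepoxide\tC1OC1\n")
        cts = ChemotypeSet.from_tsv(path)
        assert cts.names == ["nitroso", "epoxide"]


class TestGASelection:
    def _planted_matrix(self, n=200, p=12, seed=7):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, p))
        X[:, 4] = y + rng.normal(scale=0.05, size=n)  # informative column
        names = [f"d{i}" for i in range(p)]
        fm = FeatureMatrix(X, names, "descriptor", False,
                           [f"c{i}" for i in range(n)])
        return fm, y

    def _cfg(self, **kw):
        defaults = dict(population_size=12, generations=6, subset_size_target=4,
                        inner_folds=3, seed=5)
        defaults.update(kw)
        return GAConfig(**defaults)

    def test_informative_column_selected(self, fast_rf_factory):
        fm, y = self._planted_matrix()
        # oracle: the planted column separates classes almost perfectly
        assert roc_auc_score(y, fm.values[:, 4]) > 0.99
        selected = ga_select_features(fm, y, self._cfg(),
                                      estimator_factory=fast_rf_factory)
        assert "d4" in selected
        assert len(selected) <= 4

    def test_same_seed_same_subset(self, fast_rf_factory):
        fm, y = self._planted_matrix()
        a = ga_select_features(fm, y, self._cfg(), estimator_factory=fast_rf_factory)
        b = ga_select_features(fm, y, self._cfg(), estimator_factory=fast_rf_factory)
        assert a == b

    def test_target_at_full_size_returns_everything(self, fast_rf_factory):
        fm, y = self._planted_matrix()
        cfg = self._cfg(subset_size_target=fm.n_features)
        assert ga_select_features(fm, y, cfg,
                                  estimator_factory=fast_rf_factory) == fm.feature_names

    def test_single_class_labels_error(self, fast_rf_factory):
        fm, _ = self._planted_matrix()
        with pytest.raises(ValueError, match="both classes"):
            ga_select_features(fm, np.zeros(fm.n_compounds, dtype=int),
                               self._cfg(), estimator_factory=fast_rf_factory)

    def test_selected_subset_beats_random_subsets(self, fast_rf_factory):
        """GA fitness must be at least the mean of random same-size draws."""
        from mnqsar.featurization import _subset_fitness

        fm, y = self._planted_matrix()
        cfg = self._cfg()
        selected = ga_select_features(fm, y, cfg,
                                      estimator_factory=fast_rf_factory)
        idx = tuple(sorted(fm.feature_names.index(n) for n in selected))
        cache = {}
        ga_fit = _subset_fitness(fm.values, y, idx, cfg, fast_rf_factory, cache)
        rng = np.random.default_rng(cfg.seed)
        random_fits = []
        for _ in range(20):
            draw = tuple(sorted(rng.choice(fm.n_features, size=len(idx),
                                           replace=False).tolist()))
            random_fits.append(
                _subset_fitness(fm.values, y, draw, cfg, fast_rf_factory, cache)
            )
        assert ga_fit >= np.mean(random_fits)
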