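"""Network structure, EM fitting, posterior inference and sampling."""

import numpy as np
import pytest

import promgram as pg
from promgram.bayesnet import (CLASS_STATES, BNModel, _class_logliks,
                               _encode_rows, _log_prior_penalty, fit, sample)
from promgram.features import DEFAULT_BINS, MISSING, FeatureTable, bin_labels
from promgram.pwm import ParameterError

from _oracles import enumerate_posterior, random_model, random_vector
from conftest import make_vector


class TestBuildStructure:
    def test_full_structure_node_and_edge_counts(self):
        st = pg.build_structure(8)
        assert len(st.nodes) == 24
        assert len(st.class_edges) == 23
        assert len(st.augmenting_edges) == 22  # 7 M-M + 8 M-S + 7 M-L

    def test_naive_structure_has_class_edges_only(self):
        st = pg.build_structure(8, naive=True)
        assert len(st.edges) == 23

    def test_two_position_structure(self):
        st = pg.build_structure(2)
        assert sorted(st.nodes) == ["Class", "L2_1", "M1", "M2", "S1", "S2"]

    def test_invalid_positions_raise(self):
        with pytest.raises(ParameterError):
            pg.build_structure(0)

    def test_acyclic_and_single_augmenting_parent(self):
        st = pg.build_structure(8)
        children = [c for _, c in st.augmenting_edges]
        assert len(children) == len(set(children))  # at most one aug parent


def toy_complete_table():
    """Six complete 2-position rows with hand-countable statistics."""
    bins = (0, 50, np.inf)
    rows = [
        make_vector(["a", "b"], ["+", "+"], ["0-50"], "p1", "histone"),
        make_vector(["a", "b"], ["+", "-"], ["0-50"], "p2", "histone"),
        make_vector(["b", "a"], ["+", "+"], ["50-inf"], "p3", "histone"),
        make_vector(["b", "a"], ["-", "+"], ["50-inf"], "n1", "background"),
        make_vector(["b", "b"], ["-", "-"], ["0-50"], "n2", "background"),
        make_vector(["a", "b"], ["-", "+"], ["50-inf"], "n3", "background"),
    ]
    return FeatureTable(rows, ["a", "b"], 2, bins)


class TestFitCompleteData:
    def test_closed_form_smoothed_frequencies(self):
        """One EM pass equals (count + alpha) / (total + alpha*K) by hand."""
        table = toy_complete_table()
        model = fit(pg.build_structure(2), table, alpha=1.0)
        # class prior: 3+3 rows -> (3+1)/(6+2) each
        assert model.class_prior == pytest.approx([0.5, 0.5])
        # M1 | histone: a,a,b -> counts (2,1) -> (3/5, 2/5)
        assert model.cpts["M1"][0] == pytest.approx([3 / 5, 2 / 5])
        # M2 | histone, M1=a: rows p1,p2 have M2=b -> (0+1, 2+1)/(2+2)
        assert model.cpts["M2"][0][0] == pytest.approx([1 / 4, 3 / 4])
        # S1 | background, M1=b: rows n1,n2 both '-' -> (0+1, 2+1)/(2+2)
        assert model.cpts["S1"][1][1] == pytest.approx([1 / 4, 3 / 4])
        # L2_1 | histone, M2=b: rows p1,p2 -> both bin 0-50
        assert model.cpts["L2_1"][0][1] == pytest.approx([3 / 4, 1 / 4])

    def test_complete_data_converges_immediately(self):
        model = fit(pg.build_structure(2), toy_complete_table())
        assert model.n_em_iter <= 3

    def test_alpha_limit_concentrates_on_observed(self):
        rows = [make_vector(["a", "b"], ["+", "+"], ["0-50"], "p", "histone"),
                make_vector(["b", "a"], ["-", "-"], ["50-inf"], "n",
                            "background")]
        table = FeatureTable(rows, ["a", "b"], 2, (0, 50, np.inf))
        model = fit(pg.build_structure(2), table, alpha=1e-8)
        assert model.cpts["M1"][0][0] == pytest.approx(1.0, abs=1e-6)
        assert model.cpts["S1"][1][1][1] == pytest.approx(1.0, abs=1e-6)

    def test_missing_class_raises(self):
        rows = [make_vector(["a", "b"], ["+", "+"], ["0-50"], "p", "histone")]
        table = FeatureTable(rows, ["a", "b"], 2, (0, 50, np.inf))
        with pytest.raises(ParameterError):
            fit(pg.build_structure(2), table)


class TestEMWithMissing:
    def objective_trace(self, structure, table, alpha=1.0, iters=12):
        """Observed-data log-likelihood + Dirichlet penalty per EM step."""
        trace = []
        for i in range(1, iters + 1):
            model = fit(structure, table, alpha=alpha, em_max_iter=i,
                        em_tol=0.0)
            spacer_states = bin_labels(table.spacer_bins)
            y, M, S, L = _encode_rows(table.rows, table.motif_alphabet,
                                      spacer_states,
                                      class_states=CLASS_STATES)
            ll = _class_logliks(model, M, S, L)
            obj = float(ll[np.arange(len(y)), y].sum()
                        + np.log(model.class_prior[y]).sum()
                        + _log_prior_penalty(model))
            trace.append(obj)
        return trace

    def test_objective_non_decreasing_with_masked_slots(self):
        true = random_model(0, n_positions=4, K=3, B=3, conc=2.0)
        table = sample(true, 120, seed=1, p_missing=0.3)
        trace = self.objective_trace(true.structure, table)
        diffs = np.diff(trace)
        assert np.all(diffs > -1e-8)

    def test_em_reaches_tolerance(self):
        true = random_model(2, n_positions=4, K=3, B=3, conc=2.0)
        table = sample(true, 150, seed=3, p_missing=0.3)
        model = fit(true.structure, table, em_tol=1e-6, em_max_iter=200)
        assert model.n_em_iter < 200

    def test_missing_as_state_is_complete_data_fit(self):
        true = random_model(4, n_positions=3, K=3, B=2, conc=2.0)
        table = sample(true, 80, seed=5, p_missing=0.4)
        model = fit(true.structure, table, missing_as_state=True)
        assert model.n_em_iter <= 3
        assert model.cpts["M1"].shape[-1] == 4  # explicit absent state


class TestPosterior:
    def test_matches_exhaustive_enumeration(self):
        """Chain inference equals full-joint summation on small models."""
        for seed in range(40):
            p = 2 + seed % 2
            model = random_model(seed, n_positions=p, K=3, B=2)
            v = random_vector(seed + 1000, model, p_missing=0.4)
            ours = pg.posterior(model, v)
            oracle = enumerate_posterior(model, v)
            assert np.isclose(np.log(ours), np.log(oracle), atol=1e-9)

    def test_identical_cpts_give_half(self):
        model = random_model(7, n_positions=3, K=3, B=2)
        for k, v in model.cpts.items():
            if k == "class":
                model.cpts[k] = np.array([0.5, 0.5])
            else:
                v[1] = v[0]
        for seed in range(5):
            vec = random_vector(seed, model)
            assert pg.posterior(model, vec) == pytest.approx(0.5)

    def test_all_missing_vector_returns_prior(self):
        model = random_model(8, n_positions=3, K=3, B=2)
        p = model.structure.n_positions
        v = make_vector([MISSING] * p, [MISSING] * p, [MISSING] * (p - 1))
        prior_h = model.class_prior[0]
        assert pg.posterior(model, v) == pytest.approx(prior_h, abs=1e-12)

    def test_normalization(self):
        model = random_model(9, n_positions=3, K=3, B=2)
        for seed in range(20):
            v = random_vector(seed, model)
            p = pg.posterior(model, v)
            assert 0.0 <= p <= 1.0

    def test_unseen_state_names_the_node(self, fitted_model):
        p = fitted_model.structure.n_positions
        v = make_vector(["nosuch"] + [MISSING] * (p - 1),
                        ["+"] + [MISSING] * (p - 1), [MISSING] * (p - 1))
        with pytest.raises(ParameterError, match="M1"):
            pg.posterior(fitted_model, v)


class TestClassify:
    def test_tie_goes_to_background(self):
        model = random_model(7, n_positions=3, K=3, B=2)
        for k, v in model.cpts.items():
            if k == "class":
                model.cpts[k] = np.array([0.5, 0.5])
            else:
                v[1] = v[0]
        call, post = pg.classify(model, random_vector(0, model), cut=0.5)
        assert post == pytest.approx(0.5)
        assert call == "background"

    def test_zero_cut_calls_everything_histone(self):
        model = random_model(11, n_positions=3, K=3, B=2)
        for seed in range(5):
            call, _ = pg.classify(model, random_vector(seed, model), cut=0.0)
            assert call == "histone"


class TestNaiveBayesOracle:
    def test_matches_sklearn_categorical_nb_on_complete_data(self):
        """Naive structure + complete data = textbook naive Bayes."""
        from sklearn.naive_bayes import CategoricalNB

        true = random_model(13, n_positions=3, K=3, B=2, naive=True,
                            conc=2.0)
        table = sample(true, 400, seed=14)
        # balanced subset so the (smoothed vs empirical) priors coincide
        hist = [r for r in table.rows if r.class_label == "histone"][:100]
        bg = [r for r in table.rows if r.class_label == "background"][:100]
        table = FeatureTable(hist + bg, table.motif_alphabet, 3,
                             table.spacer_bins)
        model = fit(pg.build_structure(3, naive=True), table, alpha=1.0)
        ours = pg.predict_proba(model, table.rows)

        spacer_states = bin_labels(table.spacer_bins)
        y, M, S, L = _encode_rows(table.rows, table.motif_alphabet,
                                  spacer_states, class_states=CLASS_STATES)
        X = np.concatenate([M, S, L], axis=1)
        clf = CategoricalNB(alpha=1.0,
                            min_categories=[3] * 3 + [2] * 3 + [2] * 2)
        clf.fit(X, y)
        theirs = clf.predict_proba(X)[:, 0]
        assert np.allclose(ours, theirs, atol=1e-9)


class TestParameterRecovery:
    def test_augmented_cpts_recovered(self):
        """2000 complete rows pin augmented CPTs to ~0.1 max error."""
        true = random_model(21, n_positions=4, K=3, B=3, conc=6.0)
        table = sample(true, 2000, seed=22)
        fitted = fit(true.structure, table)
        err = max(np.abs(fitted.cpts[k] - true.cpts[k]).max()
                  for k in true.cpts)
        assert err < 0.1


class TestSerialization:
    def test_json_round_trip(self, fitted_model, tmp_path):
        path = tmp_path / "model.json"
        fitted_model.to_json(path)
        back = BNModel.from_json(path)
        assert back.motif_states == fitted_model.motif_states
        assert back.structure == fitted_model.structure
        for k in fitted_model.cpts:
            assert np.allclose(back.cpts[k], fitted_model.cpts[k])
        v = sample(fitted_model, 5, seed=1).rows
        assert np.allclose(pg.predict_proba(back, v),
                           pg.predict_proba(fitted_model, v))


class TestSample:
    def test_deterministic(self):
        model = random_model(31, n_positions=3, K=3, B=2)
        t1 = sample(model, 20, seed=9)
        t2 = sample(model, 20, seed=9)
        assert t1.to_frame().equals(t2.to_frame())

    def test_masking_respects_slot_coupling(self):
        model = random_model(32, n_positions=4, K=3, B=2)
        table = sample(model, 100, seed=10, p_missing=0.4)
        for r in table.rows:
            for i in range(4):
                assert (r.M[i] == MISSING) == (r.S[i] == MISSING)
            for i in range(3):
                if r.M[i] == MISSING or r.M[i + 1] == MISSING:
                    assert r.L[i] == MISSING
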