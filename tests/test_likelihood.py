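import numpy as np
import pytest
from hypothesis import given, strategies as st

import upwellsurv as u
from upwellsurv.likelihood import drop_missing_covariate, resolve_structure
from conftest import all_post_release_histories, enumerate_history_prob


class TestChiRecursion:
    def test_hand_recursion(self):
        chi = u.chi_recursion(np.full(2, 0.8), np.full(2, 0.5))
        assert np.allclose(chi, [0.44, 0.6, 1.0])

    def test_certain_detection_and_survival(self):
        chi = u.chi_recursion(np.ones(4), np.ones(4))
        assert np.allclose(chi[:-1], 0.0) and chi[-1] == 1.0

    def test_dead_animals_never_seen(self):
        chi = u.chi_recursion(np.zeros(4), np.full(4, 0.3))
        assert np.allclose(chi, 1.0)

    def test_domain_error(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            u.chi_recursion(np.array([1.2]), np.array([0.5]))


class TestHistoryLoglik:
    phi = np.full(2, 0.8)
    p = np.full(2, 0.5)

    @pytest.mark.parametrize(
        "y,f,p,expected",
        [
            ([1, 0, 1], 1, [0.5, 0.5], 0.16),
            ([1, 0, 0], 1, [0.5, 0.5], 0.44),
            ([1, 0, 1], 1, [0.0, 0.5], 0.32),  # p2 pinned at 0 (no search)
        ],
    )
    def test_worked_probabilities(self, y, f, p, expected):
        ll = u.history_loglik(np.array(y), f, self.phi, np.array(p))
        assert np.isclose(np.exp(ll), expected, atol=1e-12)

    def test_release_at_final_occasion_contributes_nothing(self):
        ll = u.history_loglik(np.array([0, 0, 1]), 3, self.phi, self.p)
        assert ll == 0.0

    def test_all_zero_history_rejected(self):
        with pytest.raises(ValueError, match="no detection"):
            u.history_loglik(np.zeros(3, dtype=int), 1, self.phi, self.p)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        T = 6
        for _ in range(50):
            phi = rng.uniform(0.05, 0.98, T - 1)
            p = rng.uniform(0.05, 0.95, T - 1)
            if rng.uniform() < 0.5:
                p[rng.integers(0, T - 1)] = 0.0  # masked month
            f = int(rng.integers(1, T))
            for y in all_post_release_histories(T, f):
                if (y[f:] * (p[f - 1 :] == 0)).any():
                    continue  # impossible under the mask
                ll = u.history_loglik(y, f, phi, p)
                assert np.isclose(
                    np.exp(ll), enumerate_history_prob(y, f, phi, p),
                    rtol=0, atol=1e-12,
                )

    @given(
        phi=st.lists(st.floats(0.05, 0.95), min_size=3, max_size=3),
        p=st.lists(st.floats(0.05, 0.95), min_size=3, max_size=3),
        f=st.integers(1, 3),
    )
    def test_post_release_histories_normalize(self, phi, p, f):
        phi, p = np.array(phi), np.array(p)
        total = sum(
            np.exp(u.history_loglik(y, f, phi, p))
            for y in all_post_release_histories(4, f)
        )
        assert np.isclose(total, 1.0, atol=1e-10)

    def test_widening_gap_between_detections_never_raises_probability(self):
        """Moving the second of two detections later (inserting extra
        non-detection months) multiplies the likelihood by phi(1-p) <= 1."""
        phi = np.full(5, 0.9)
        p = np.full(5, 0.4)
        histories = [
            [1, 1, 0, 0, 0, 0], [1, 0, 1, 0, 0, 0],
            [1, 0, 0, 1, 0, 0], [1, 0, 0, 0, 1, 0],
        ]
        lls = [u.history_loglik(np.array(y), 1, phi, p) for y in histories]
        assert all(a >= b for a, b in zip(lls, lls[1:]))


class TestDatasetLoglik:
    def make(self, y, first, searched=None, covariates=None):
        import pandas as pd

        y = np.asarray(y)
        searched = [True] * y.shape[1] if searched is None else searched
        tags = [f"i{k}" for k in range(y.shape[0])]
        cov = None
        if covariates is not None:
            cov = pd.DataFrame(covariates, index=tags)
        return u.EncounterHistories(
            y=y, first=first, tag_ids=tags, site="talcaruca",
            species="chiton_granosus", searched=searched,
            covariates=cov if cov is not None else pd.DataFrame(index=tags),
        )

    def test_independence_doubles_loglik(self):
        h1 = self.make([[1, 0, 1]], [1])
        h2 = self.make([[1, 0, 1], [1, 0, 1]], [1, 1])
        spec = u.CJSModelSpec("phi_dot", np.zeros(3, bool))
        state = u.ParameterState(phi=0.8, p=np.array([0.5, 0.5]))
        assert np.isclose(
            u.dataset_loglik(h2, spec, state),
            2 * u.dataset_loglik(h1, spec, state),
        )

    def test_permutation_invariance(self, sim300):
        spec = u.CJSModelSpec("phi_dot", ~sim300.searched)
        p = np.where(sim300.searched[1:], 0.4, 0.0)
        state = u.ParameterState(phi=0.9, p=p)
        base = u.dataset_loglik(sim300, spec, state)
        rng = np.random.default_rng(0)
        perm = rng.permutation(sim300.n_individuals)
        shuffled = self.make(
            sim300.y[perm], sim300.first[perm], searched=sim300.searched
        )
        assert np.isclose(u.dataset_loglik(shuffled, spec, state), base, atol=1e-9)

    def test_masked_months_contribute_nothing(self):
        """A masked occasion behaves exactly like an occasion that does not
        exist: the likelihood equals the enumeration oracle with p=0 there."""
        h = self.make([[1, 0, 0, 1]], [1], searched=[True, False, True, True])
        spec = u.CJSModelSpec("phi_dot", ~np.array([True, False, True, True]))
        state = u.ParameterState(phi=0.85, p=np.array([0.0, 0.3, 0.6]))
        ll = u.dataset_loglik(h, spec, state)
        oracle = enumerate_history_prob(
            np.array([1, 0, 0, 1]), 1, np.full(3, 0.85), np.array([0.0, 0.3, 0.6])
        )
        assert np.isclose(np.exp(ll), oracle, atol=1e-14)

    def test_nonzero_masked_p_rejected(self):
        h = self.make([[1, 0, 1]], [1], searched=[True, False, True])
        spec = u.CJSModelSpec("phi_dot", ~np.array([True, False, True]))
        state = u.ParameterState(phi=0.8, p=np.array([0.2, 0.5]))
        with pytest.raises(ValueError, match="exactly 0"):
            u.dataset_loglik(h, spec, state)

    def test_covariate_structure_matches_manual(self):
        from scipy.special import expit

        lengths = [18.0, 25.0, 31.0]
        h = self.make(
            [[1, 1, 0], [1, 0, 1], [1, 1, 1]], [1, 1, 1],
            covariates={"length_mm": lengths},
        )
        spec = u.CJSModelSpec("phi_length", np.zeros(3, bool))
        state = u.ParameterState(phi=(0.5, 0.8), p=np.array([0.5, 0.5]))
        x = np.array(lengths)
        xs = (x - x.mean()) / x.std(ddof=1)
        manual = sum(
            u.history_loglik(h.y[i], 1, np.full(2, expit(0.5 + 0.8 * xs[i])),
                             np.array([0.5, 0.5]))
            for i in range(3)
        )
        assert np.isclose(u.dataset_loglik(h, spec, state), manual, atol=1e-10)

    def test_missing_covariate_drop(self):
        h = self.make(
            [[1, 1, 0], [1, 0, 1]], [1, 1],
            covariates={"length_mm": [18.0, np.nan]},
        )
        sub, n_drop = drop_missing_covariate(h, "length_mm")
        assert n_drop == 1 and sub.n_individuals == 1


class TestMarrayEquivalence:
    @pytest.mark.parametrize("structure", ["phi_dot", "phi_time"])
    def test_exact_equivalence_random_parameters(self, sim300, structure):
        ma = u.m_array(sim300)
        spec = u.CJSModelSpec(structure, ~sim300.searched)
        rng = np.random.default_rng(7)
        T = sim300.n_occasions
        for _ in range(20):
            if structure == "phi_dot":
                phi = float(rng.uniform(0.3, 0.98))
                phi_vec = np.full(T - 1, phi)
            else:
                phi_vec = rng.uniform(0.3, 0.98, T - 1)
                phi = phi_vec
            p = np.where(sim300.searched[1:], rng.uniform(0.05, 0.95, T - 1), 0.0)
            state = u.ParameterState(phi=phi, p=p)
            assert np.isclose(
                u.marray_loglik(ma, phi_vec, p),
                u.dataset_loglik(sim300, spec, state),
                rtol=0, atol=1e-10,
            )

    def test_single_history_identity(self):
        h = u.EncounterHistories(
            y=[[1, 0, 1]], first=[1], tag_ids=["a"], site="talcaruca",
            species="chiton_granosus", searched=[True] * 3,
        )
        ma = u.m_array(h)
        phi, p = np.full(2, 0.8), np.full(2, 0.5)
        assert np.isclose(
            u.marray_loglik(ma, phi, p),
            u.history_loglik(np.array([1, 0, 1]), 1, phi, p),
            atol=1e-14,
        )

    def test_empty_recaptures_gives_log_chi(self):
        h = u.EncounterHistories(
            y=[[1, 0, 0]], first=[1], tag_ids=["a"], site="talcaruca",
            species="chiton_granosus", searched=[True] * 3,
        )
        ma = u.m_array(h)
        phi, p = np.full(2, 0.8), np.full(2, 0.5)
        chi = u.chi_recursion(phi, p)
        assert np.isclose(u.marray_loglik(ma, phi, p), np.log(chi[0]), atol=1e-14)


def test_structure_aliases_resolve():
    assert resolve_structure(".") == "phi_dot"
    assert resolve_structure("Po") == "phi_site"
    assert resolve_structure("t") == "phi_time"
    assert resolve_structure("L") == "phi_length"
    assert resolve_structure("F") == "phi_perf"
    with pytest.raises(ValueError, match="unknown survival structure"):
        resolve_structure("x")


def test_spec_rejects_covariate_on_time_structure():
    with pytest.raises(ValueError, match="only valid"):
        u.CJSModelSpec("phi_dot", np.zeros(3, bool), covariate_name="length_mm")
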