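"""HMM construction and the no-repeat Viterbi decoder.

The decoder is checked three ways: against a brute-force enumeration of
all simple state paths (upper bound), against an independently coded
plain-loop reference of the same greedy-commit recurrence (exact
equality), and — for two-observation sequences, where the commit mechanism
cannot act — against hmmlearn's standard Viterbi.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import norm

import cryotrace as ct
from cryotrace.ca_extraction import CaAtom, CaAtomSet
from cryotrace.constants import AA_ALPHABET, AA_INDEX, CA_CA_MEAN, \
    CA_CA_SIGMA, background_frequencies
from cryotrace.hmm_alignment import InfeasibleAlignmentError, build_hmm


def _atoms_from(coords, aa_probs=None, ca_probs=None) -> CaAtomSet:
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if aa_probs is None:
        aa_probs = np.full((n, 20), 1.0 / 20.0)
    if ca_probs is None:
        ca_probs = np.full(n, 0.9)
    return CaAtomSet(atoms=[
        CaAtom(coord=c, ca_prob=float(p), aa_probs=np.asarray(a))
        for c, p, a in zip(coords, ca_probs, aa_probs)])


class TestDistanceAndDensity:
    def test_three_four_five_triangle(self):
        assert ct.pairwise_distance([0, 0, 0], [3, 4, 0]) == 5.0
        assert ct.pairwise_distance([0, 0, 0], [0, 0, 0]) == 0.0

    def test_symmetry(self, rng):
        for _ in range(10):
            p, q = rng.normal(size=(2, 3))
            assert ct.pairwise_distance(p, q) == \
                pytest.approx(ct.pairwise_distance(q, p))

    def test_peak_value_matches_scaled_normal_pdf(self):
        """At the mean, the density equals a normal pdf with sd = 10*sigma;
        scipy.stats.norm is the independent oracle."""
        got = ct.gaussian_transition_density(CA_CA_MEAN)
        expected = norm.pdf(CA_CA_MEAN, loc=CA_CA_MEAN,
                            scale=10 * CA_CA_SIGMA)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.1082, abs=1e-4)

    def test_symmetric_and_decreasing_in_distance(self):
        f = ct.gaussian_transition_density
        for d in (0.1, 0.5, 2.0):
            assert f(CA_CA_MEAN + d) == pytest.approx(f(CA_CA_MEAN - d))
        xs = CA_CA_MEAN + np.linspace(0, 5, 40)
        assert np.all(np.diff(f(xs)) < 0)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            ct.gaussian_transition_density(3.8, sigma=0.0)
        with pytest.raises(ValueError):
            ct.gaussian_transition_density(3.8, lambda_scale=-1.0)


class TestTransitionMatrix:
    def test_two_states_always_swap(self):
        lg = ct.build_transition(np.array([[0, 0, 0], [123.0, 0, 0]]))
        np.testing.assert_allclose(np.exp(lg), [[0, 1], [1, 0]], atol=1e-12)

    def test_three_collinear_atoms(self):
        """From an end atom the adjacent neighbor takes essentially all the
        probability; the far one keeps ~5e-25 (direct density ratio)."""
        coords = np.array([[0, 0, 0], [CA_CA_MEAN, 0, 0],
                           [2 * CA_CA_MEAN, 0, 0]])
        gamma = np.exp(ct.build_transition(coords))
        s = 10 * CA_CA_SIGMA
        f_near = norm.pdf(CA_CA_MEAN, CA_CA_MEAN, s)
        f_far = norm.pdf(2 * CA_CA_MEAN, CA_CA_MEAN, s)
        assert gamma[0, 1] == pytest.approx(f_near / (f_near + f_far))
        assert gamma[0, 2] == pytest.approx(5.0e-25, rel=0.02)

    def test_rows_stochastic_for_random_geometry(self, rng):
        coords = rng.uniform(0, 30, size=(12, 3))
        lg = ct.build_transition(coords)
        np.testing.assert_allclose(np.exp(lg).sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.isneginf(np.diag(lg)))

    def test_far_apart_states_still_normalize(self):
        """Distances so large every density underflows linearly must still
        yield a finite stochastic row via log-space normalization."""
        coords = np.array([[0, 0, 0], [1000.0, 0, 0], [2000.0, 0, 0]])
        lg = ct.build_transition(coords)
        assert np.isfinite(lg[~np.isneginf(lg)]).all()
        np.testing.assert_allclose(np.exp(lg).sum(axis=1), 1.0, atol=1e-9)


class TestEmissionAndInitial:
    def test_uniform_times_uniform_is_uniform(self):
        ld = ct.build_emission(np.full((3, 20), 0.05), np.full(20, 0.05))
        np.testing.assert_allclose(np.exp(ld), 0.05, atol=1e-12)

    def test_one_hot_prediction_dominates(self):
        a = np.zeros((1, 20))
        a[0, AA_INDEX["A"]] = 1.0
        ld = ct.build_emission(a, background_frequencies())
        assert np.exp(ld)[0, AA_INDEX["A"]] == pytest.approx(1.0)

    def test_prediction_equal_to_background_is_fixed_point(self):
        b = background_frequencies()
        ld = ct.build_emission(np.tile(b, (2, 1)), b)
        np.testing.assert_allclose(np.exp(ld), np.tile(b, (2, 1)),
                                   atol=1e-12)

    def test_initial_from_emission_column(self):
        ld = np.log(np.tile(np.array([[0.1, 0.3, 0.6]]).T, (1, 20)))
        lpi = ct.build_initial(ld, "A")
        np.testing.assert_allclose(np.exp(lpi), [0.1, 0.3, 0.6], atol=1e-9)

    def test_identical_rows_give_uniform_initial(self):
        ld = np.log(np.full((4, 20), 0.05))
        np.testing.assert_allclose(np.exp(ct.build_initial(ld, "W")), 0.25)

    def test_initial_sums_to_one_for_random_emission(self, rng):
        a = rng.dirichlet(np.ones(20), size=9)
        ld = ct.build_emission(a, background_frequencies())
        for sym in "ACDW":
            assert np.exp(ct.build_initial(ld, sym)).sum() == \
                pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# decoder oracles
# ---------------------------------------------------------------------------

def _reference_decoder(log_pi, log_gamma, log_delta, obs):
    """Plain-loop reference of the greedy-commit recurrence with
    backpointer traceback and collision repair (independent coding)."""
    k = len(log_pi)
    t_len = len(obs)
    t1 = [[-np.inf] * t_len for _ in range(k)]
    t2 = [[0] * t_len for _ in range(k)]
    for i in range(k):
        t1[i][0] = log_pi[i] + log_delta[i][obs[0]]
    visited: set[int] = set()
    for j in range(1, t_len):
        for i in range(k):
            if i in visited:
                continue
            best, arg = -np.inf, 0
            for kk in range(k):
                s = t1[kk][j - 1] + log_gamma[kk][i]
                if s > best:
                    best, arg = s, kk
            t1[i][j] = best + log_delta[i][obs[j]]
            t2[i][j] = arg
        for i in visited:
            t1[i][j] = -np.inf
        z, zbest = None, -np.inf
        for i in range(k):
            if i not in visited and t1[i][j] > zbest:
                z, zbest = i, t1[i][j]
        visited.add(z)
    # traceback with repair
    end, ebest = 0, -np.inf
    for i in range(k):
        if t1[i][t_len - 1] > ebest:
            end, ebest = i, t1[i][t_len - 1]
    path = [end]
    used = {end}
    for j in range(t_len - 1, 0, -1):
        prev = t2[path[-1]][j]
        if prev in used:
            best, arg = -np.inf, None
            for kk in range(k):
                if kk in used:
                    continue
                s = t1[kk][j - 1] + log_gamma[kk][path[-1]]
                if s >= best or arg is None:
                    if s > best or arg is None:
                        best, arg = s, kk
            prev = arg
        used.add(prev)
        path.append(prev)
    return path[::-1]


def _path_logprob(log_pi, log_gamma, log_delta, obs, path):
    lp = log_pi[path[0]] + log_delta[path[0]][obs[0]]
    for j in range(1, len(obs)):
        lp += log_gamma[path[j - 1]][path[j]] + log_delta[path[j]][obs[j]]
    return lp


def _best_simple_path(log_pi, log_gamma, log_delta, obs, k):
    best = -np.inf
    for perm in itertools.permutations(range(k), len(obs)):
        best = max(best, _path_logprob(log_pi, log_gamma, log_delta, obs,
                                       list(perm)))
    return best


def _random_instance(rng, k, t_len):
    coords = rng.uniform(0, 12, size=(k, 3))
    aa = rng.dirichlet(np.ones(20), size=k)
    atoms = _atoms_from(coords, aa_probs=aa)
    hmm = build_hmm(atoms)
    seq = "".join(rng.choice(list(AA_ALPHABET), size=t_len))
    return hmm, seq


class TestModifiedViterbi:
    def test_single_state_single_observation(self):
        hmm = build_hmm(_atoms_from([[0, 0, 0]]))
        res = ct.modified_viterbi(hmm, "A")
        assert list(res.path) == [0]

    def test_single_observation_picks_argmax_of_pi_times_delta(self):
        # equal emissions, initial distribution decides
        aa = np.full((2, 20), 1.0 / 20.0)
        atoms = _atoms_from([[0, 0, 0], [4, 0, 0]], aa_probs=aa)
        hmm = build_hmm(atoms)
        # bias state 2 through its emission of the observed symbol
        hmm.log_delta[1, AA_INDEX["A"]] = np.log(0.8)
        res = ct.modified_viterbi(hmm, "A")
        assert list(res.path) == [1]

    def test_oracle_equivalence_on_random_instances(self, rng):
        """No repeats, bounded by the enumeration optimum, identical to the
        independent reference recurrence (200 seeded instances)."""
        for trial in range(200):
            k = int(rng.integers(2, 8))
            t_len = int(rng.integers(1, min(k, 4) + 1))
            hmm, seq = _random_instance(rng, k, t_len)
            res = ct.modified_viterbi(hmm, seq)
            assert len(set(res.path.tolist())) == t_len
            obs = [AA_INDEX[c] for c in seq]
            log_pi = ct.build_initial(hmm.log_delta, seq[0])
            lg, ld = hmm.log_gamma, hmm.log_delta
            lg = lg - np.logaddexp.reduce(lg, axis=1, keepdims=True)
            lp = _path_logprob(log_pi, lg, ld, obs, list(res.path))
            assert lp == pytest.approx(res.log_prob, abs=1e-9)
            assert lp <= _best_simple_path(log_pi, lg, ld, obs, k) + 1e-9
            if t_len > 1:
                ref = _reference_decoder(log_pi.tolist(), lg.tolist(),
                                         ld.tolist(), obs)
                assert list(res.path) == ref

    def test_two_observation_decode_matches_hmmlearn(self, rng):
        """With two observations the commit mechanism cannot influence the
        result, so the decode must equal standard Viterbi (hmmlearn)."""
        from hmmlearn.hmm import CategoricalHMM
        for _ in range(20):
            hmm, seq = _random_instance(rng, 5, 2)
            res = ct.modified_viterbi(hmm, seq)
            m = CategoricalHMM(n_components=5)
            m.startprob_ = np.exp(ct.build_initial(hmm.log_delta, seq[0]))
            m.transmat_ = hmm.gamma
            m.emissionprob_ = hmm.delta
            obs = np.array([[AA_INDEX[c]] for c in seq])
            _, ref_path = m.decode(obs, algorithm="viterbi")
            assert list(res.path) == list(ref_path)

    def test_infeasible_when_fewer_states_than_residues(self):
        hmm = build_hmm(_atoms_from([[0, 0, 0], [4, 0, 0]]))
        with pytest.raises(InfeasibleAlignmentError, match="threshold"):
            ct.modified_viterbi(hmm, "AAA")

    def test_flat_degenerate_input_returns_valid_path(self):
        """With flat transitions and uniform emissions any simple path is
        equi-probable; a valid non-repeating path must still come back."""
        coords = np.arange(15).reshape(5, 3) * 100.0
        atoms = _atoms_from(coords)
        hmm = build_hmm(atoms, lambda_scale=1e9)
        res = ct.modified_viterbi(hmm, "AAAA")
        assert len(set(res.path.tolist())) == 4


class TestAlignAllChains:
    def _trace_hmm(self, seed, n=12):
        protein = ct.generate_protein(1, n, seed=seed)
        seq, coords = protein.chains[0]
        aa = np.full((n, 20), 0.1 / 20.0)
        for i, c in enumerate(seq):
            aa[i, AA_INDEX[c]] += 0.9
        order = np.random.default_rng(seed).permutation(n)
        atoms = _atoms_from(coords[order], aa_probs=aa[order])
        return protein, atoms, order

    def test_near_deterministic_trace_recovered_in_order(self):
        protein, atoms, order = self._trace_hmm(seed=2)
        hmm = build_hmm(atoms)
        chains = protein.to_sequences()
        res = ct.align_all_chains(hmm, chains)[0]
        recovered = [order[s] for s in res.path]
        assert recovered == list(range(len(order)))

    def test_two_chains_use_all_states_exactly_once(self, rng):
        coords = rng.uniform(0, 25, size=(8, 3))
        atoms = _atoms_from(coords)
        hmm = build_hmm(atoms)
        chains = ct.ChainSequenceSet(chains=[("A", "AGV"), ("B", "MKVLY")])
        results = ct.align_all_chains(hmm, chains)
        union = np.concatenate([r.path for r in results])
        assert len(np.unique(union)) == 8

    def test_alignment_is_deterministic(self, rng):
        coords = rng.uniform(0, 25, size=(10, 3))
        atoms = _atoms_from(coords)
        chains = ct.ChainSequenceSet(chains=[("A", "AGVK"), ("B", "MKW")])
        p1 = [r.path for r in ct.align_all_chains(build_hmm(atoms), chains)]
        p2 = [r.path for r in ct.align_all_chains(build_hmm(atoms), chains)]
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a, b)

    def test_total_residues_exceeding_states_is_infeasible(self, rng):
        atoms = _atoms_from(rng.uniform(0, 10, size=(4, 3)))
        chains = ct.ChainSequenceSet(chains=[("A", "AGV"), ("B", "MK")])
        with pytest.raises(InfeasibleAlignmentError):
            ct.align_all_chains(build_hmm(atoms), chains)

    def test_stochastic_invariants_survive_state_removal(self, rng):
        """Rows of gamma/delta and Pi stay stochastic after chains remove
        states and the model is renormalized over the survivors."""
        coords = rng.uniform(0, 30, size=(14, 3))
        atoms = _atoms_from(coords,
                            aa_probs=rng.dirichlet(np.ones(20), size=14))
        hmm = build_hmm(atoms)
        chains = ct.ChainSequenceSet(chains=[("A", "AGVKL"), ("B", "MKW")])
        results = ct.align_all_chains(hmm, chains)
        removed = np.concatenate([r.path for r in results])
        survivors = np.setdiff1d(np.arange(14), removed)
        from scipy.special import logsumexp
        lg = hmm.log_gamma[np.ix_(survivors, survivors)]
        lg = lg - logsumexp(lg, axis=1, keepdims=True)
        np.testing.assert_allclose(np.exp(lg).sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(np.exp(hmm.log_delta).sum(axis=1), 1.0,
                                   atol=1e-9)
        lpi = ct.build_initial(hmm.log_delta, "A", survivors)
        assert np.exp(lpi).sum() == pytest.approx(1.0, abs=1e-9)

    def test_synthetic_parameter_recovery(self):
        """A 30-residue chain with 0.9-one-hot emissions is recovered at
        >= 95% of positions and assignments (20 replicates)."""
        ok_pos = 0
        total = 0
        for seed in range(20):
            protein, atoms, order = self._trace_hmm(seed=seed, n=30)
            hmm = build_hmm(atoms)
            res = ct.align_all_chains(hmm, protein.to_sequences())[0]
            recovered = order[res.path]
            ok_pos += int((recovered == np.arange(30)).sum())
            total += 30
        assert ok_pos / total >= 0.95


class TestPathsToStructure:
    def test_residues_follow_path_order(self, rng):
        coords = np.array([[0, 0, 0], [4, 0, 0], [8, 0, 0]], dtype=float)
        atoms = _atoms_from(coords)
        res = ct.AlignmentResult(chain_id="A", sequence="AGV",
                                 path=np.array([2, 0, 1]),
                                 emission_probs=np.array([0.5, 0.5, 0.5]),
                                 log_prob=-1.0)
        chains = ct.ChainSequenceSet(chains=[("A", "AGV")])
        model = ct.paths_to_structure([res], atoms, chains)
        got = model.coordinates()
        np.testing.assert_allclose(got, coords[[2, 0, 1]])
        assert [r.aa for r in model.all_residues()] == ["A", "G", "V"]

    def test_residue_count_matches_sequence(self, two_chain_protein):
        p = two_chain_protein
        b = ct.rasterize(p)
        preds = ct.simulate_predictions(b, correct_prob=1.0)
        atoms = ct.extract_ca_atoms(preds, b.grid)
        hmm = build_hmm(atoms)
        chains = p.to_sequences()
        model = ct.paths_to_structure(
            ct.align_all_chains(hmm, chains), atoms, chains)
        assert model.n_residues == chains.total_residues
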