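"""Block HMM core: forward/Viterbi vs enumeration, EM, discriminative ascent."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

import gazehmm as gz
from gazehmm import (
    CLASSES,
    BlockHMMParams,
    ObservationEvent,
    ObservationSequence,
    StateSpec,
    baum_welch,
    classify,
    conditional_log_likelihood,
    discriminative_train,
    fit_generative,
    log_forward,
    sample_sequence,
    viterbi,
)
from gazehmm.hmm import ValidationError, _cll_and_grad, _Unconstrained, SequenceBatch

from conftest import make_emission, make_params


# --- independent brute-force oracle ----------------------------------------


def emission_logpdf(ev: ObservationEvent, em, include_aoi=False) -> float:
    lp = norm.logpdf(ev.log_fd, em.mu_fd, em.sigma_fd)
    if include_aoi:
        lp += math.log(em.p_aoi[ev.aoi - 1])
    if ev.sd is not None:
        lp += norm.logpdf(ev.log_sl, em.mu_sl, em.sigma_sl)
        lp += math.log(em.p_sd[ev.sd - 1])
    return float(lp)


def enumerate_logmass(seq, params, include_aoi=False):
    """Total and per-class log mass by explicit summation over all paths."""
    n = params.n_states
    T = len(seq)
    per_class = {c: -np.inf for c in CLASSES}
    total = -np.inf
    for path in itertools.product(range(n), repeat=T):
        if params.pi[path[0]] <= 0:
            continue
        lp = math.log(params.pi[path[0]])
        ok = True
        for t in range(1, T):
            a = params.A[path[t - 1], path[t]]
            if a <= 0:
                ok = False
                break
            lp += math.log(a)
        if not ok:
            continue
        for t in range(T):
            lp += emission_logpdf(seq.events[t], params.emissions[path[t]], include_aoi)
        total = np.logaddexp(total, lp)
        cls = params.class_of_state[path[-1]]
        per_class[cls] = np.logaddexp(per_class[cls], lp)
    return total, per_class


def random_block_params(rng, n_lfrr=2, n_rflr=2):
    n = n_lfrr + n_rflr
    pi = rng.dirichlet(np.ones(n))
    A = np.zeros((n, n))
    for lo, hi in ((0, n_lfrr), (n_lfrr, n)):
        for i in range(lo, hi):
            A[i, lo:hi] = rng.dirichlet(np.ones(hi - lo))
    ems = [
        make_emission(
            mu_fd=rng.normal(5, 1), sigma_fd=rng.uniform(0.3, 1.0),
            mu_sl=rng.normal(4, 1), sigma_sl=rng.uniform(0.3, 1.0),
            p_aoi=rng.dirichlet(np.ones(4)), p_sd=rng.dirichlet(np.ones(4)),
        )
        for _ in range(n)
    ]
    p = make_params(pi, A, ems, ("LFRR",) * n_lfrr + ("RFLR",) * n_rflr)
    p.validate()
    return p


def random_seq(rng, params, T, cls="LFRR"):
    return sample_sequence(params, cls, T, rng)


# --- forward ----------------------------------------------------------------


@pytest.mark.parametrize("n_lfrr,n_rflr", [(1, 1), (2, 2), (1, 3)])
@pytest.mark.parametrize("T", [1, 2, 3, 5])
def test_forward_matches_path_enumeration(n_lfrr, n_rflr, T, rng):
    params = random_block_params(rng, n_lfrr, n_rflr)
    seq = random_seq(rng, params, T, cls="RFLR")
    ll, mass = log_forward(seq, params)
    bll, bmass = enumerate_logmass(seq, params)
    assert ll == pytest.approx(bll, rel=1e-10)
    for c in CLASSES:
        assert mass[c] == pytest.approx(bmass[c], rel=1e-10)


def test_forward_single_state_single_event_closed_form(rng):
    params = random_block_params(rng, 1, 1)
    seq = random_seq(rng, params, 1, cls="LFRR")
    ll, _ = log_forward(seq, params)
    expected = np.logaddexp(
        math.log(params.pi[0]) + emission_logpdf(seq.events[0], params.emissions[0]),
        math.log(params.pi[1]) + emission_logpdf(seq.events[0], params.emissions[1]),
    )
    assert ll == pytest.approx(expected, rel=1e-12)


def test_forward_no_underflow_for_very_long_sequences(toy_params, rng):
    seq = sample_sequence(toy_params, "LFRR", 10_000, rng)
    ll, mass = log_forward(seq, toy_params)
    assert np.isfinite(ll)
    assert ll < 0


def test_classify_invariant_to_joint_pi_rescaling(toy_params, rng):
    seq = sample_sequence(toy_params, "LFRR", 6, rng)
    raw = np.array([0.3, 0.2, 0.4, 0.1])
    a = toy_params.copy()
    a.pi = raw / raw.sum()
    b = toy_params.copy()
    b.pi = (7.0 * raw) / (7.0 * raw).sum()
    pa, pb = classify(seq, a), classify(seq, b)
    assert pa.p_lfrr == pytest.approx(pb.p_lfrr, rel=1e-12)
    assert pa.p_lfrr + pa.p_rflr == pytest.approx(1.0, abs=1e-9)


# --- viterbi ----------------------------------------------------------------


def test_viterbi_matches_argmax_enumeration(rng):
    for _ in range(5):
        params = random_block_params(rng, 2, 2)
        seq = random_seq(rng, params, 4, cls="LFRR")
        path, lp = viterbi(seq, params)
        best_lp, best_path = -np.inf, None
        n, T = params.n_states, len(seq)
        for cand in itertools.product(range(n), repeat=T):
            if params.pi[cand[0]] <= 0:
                continue
            p = math.log(params.pi[cand[0]])
            ok = True
            for t in range(1, T):
                if params.A[cand[t - 1], cand[t]] <= 0:
                    ok = False
                    break
                p += math.log(params.A[cand[t - 1], cand[t]])
            if not ok:
                continue
            for t in range(T):
                p += emission_logpdf(seq.events[t], params.emissions[cand[t]])
            if p > best_lp:
                best_lp, best_path = p, cand
        assert lp == pytest.approx(best_lp, rel=1e-10)
        assert tuple(path) == best_path


def test_viterbi_recovers_deterministic_chain(rng):
    ems = [make_emission(mu_fd=2.0, sigma_fd=0.1), make_emission(mu_fd=9.0, sigma_fd=0.1),
           make_emission(), make_emission()]
    A = [[0.01, 0.99, 0, 0], [0.01, 0.99, 0, 0], [0, 0, 1, 0], [0, 0, 0.5, 0.5]]
    params = make_params([0.98, 0.01, 0.005, 0.005], A, ems,
                         ("LFRR", "LFRR", "RFLR", "RFLR"))
    events = [ObservationEvent(log_fd=m, aoi=1, log_sl=4.0, sd=1) for m in (2.0, 9.0)]
    events.append(ObservationEvent(log_fd=9.0, aoi=1))
    seq = ObservationSequence("s", "LFRR", "t", events)
    path, lp = viterbi(seq, params)
    assert path == [0, 1, 1]
    ll, _ = log_forward(seq, params)
    assert lp <= ll + 1e-12


def test_viterbi_tie_breaks_to_lowest_state_index():
    # two identical states: every path has the same probability
    ems = [make_emission(), make_emission(), make_emission(), make_emission()]
    A = [[0.5, 0.5, 0, 0], [0.5, 0.5, 0, 0], [0, 0, 0.5, 0.5], [0, 0, 0.5, 0.5]]
    params = make_params([0.25] * 4, A, ems, ("LFRR", "LFRR", "RFLR", "RFLR"))
    seq = ObservationSequence("s", "LFRR", "t", [
        ObservationEvent(log_fd=5.0, aoi=1, log_sl=4.0, sd=1),
        ObservationEvent(log_fd=5.0, aoi=1),
    ])
    path, _ = viterbi(seq, params)
    assert path == [0, 0]


def test_viterbi_logprob_never_exceeds_forward(rng):
    for _ in range(5):
        params = random_block_params(rng, 2, 1)
        seq = random_seq(rng, params, 6, cls="LFRR")
        _, lp = viterbi(seq, params)
        ll, _ = log_forward(seq, params)
        assert lp <= ll + 1e-12


# --- validation -------------------------------------------------------------


def test_validation_rejects_bad_params(toy_params):
    bad = toy_params.copy()
    bad.pi = np.array([0.5, 0.5, 0.5, 0.5])
    with pytest.raises(ValidationError):
        bad.validate()
    bad2 = toy_params.copy()
    bad2.A[0, 2] = 0.1  # cross-block mass
    with pytest.raises(ValidationError):
        bad2.validate()


def test_params_json_round_trip_is_exact(toy_params, tmp_path):
    import gazehmm.io as gio

    path = tmp_path / "params.json"
    gio.write_params(toy_params, path)
    back = gio.read_params(path)
    assert np.array_equal(back.pi, toy_params.pi)
    assert np.array_equal(back.A, toy_params.A)
    for a, b in zip(back.emissions, toy_params.emissions):
        assert a.mu_fd == b.mu_fd and a.sigma_fd == b.sigma_fd
        assert np.array_equal(a.p_sd, b.p_sd)


# --- Baum-Welch -------------------------------------------------------------


def _labelled_corpus(params, n_per_class, rng, mean_len=12):
    seqs = []
    for cls in CLASSES:
        for _ in range(n_per_class):
            T = max(1, int(rng.poisson(mean_len)))
            seqs.append(sample_sequence(params, cls, T, rng))
    return seqs


def test_single_state_mle_is_sample_mean(toy_params, rng):
    seqs = _labelled_corpus(toy_params, 40, rng)
    init = random_block_params(rng, 1, 1)
    res = baum_welch(seqs, init, max_iter=5)
    for cls, state in (("LFRR", 0), ("RFLR", 1)):
        logs = np.concatenate([s.log_fd for s in seqs if s.strategy == cls])
        assert res.params.emissions[state].mu_fd == pytest.approx(logs.mean(), abs=1e-9)
        assert res.params.emissions[state].sigma_fd == pytest.approx(
            logs.std(), abs=1e-9)


def test_baum_welch_loglik_monotone(toy_params, rng):
    seqs = _labelled_corpus(toy_params, 30, rng)
    init = random_block_params(rng, 2, 2)
    res = baum_welch(seqs, init, max_iter=40)
    diffs = np.diff(res.history)
    assert np.all(diffs > -1e-8)


def test_baum_welch_handles_length_one_sequences(toy_params, rng):
    seqs = _labelled_corpus(toy_params, 10, rng)
    seqs.append(sample_sequence(toy_params, "LFRR", 1, rng))
    res = baum_welch(seqs, random_block_params(rng, 2, 2), max_iter=10)
    res.params.validate()


def test_parameter_recovery_two_state_blocks(rng):
    """Fitting data from a well-separated model recovers its SD rows."""
    truth = random_block_params(np.random.default_rng(5), 2, 2)
    # sharpen separation so the small corpus identifies the states
    for i, em in enumerate(truth.emissions):
        em.p_sd = np.roll(np.array([0.85, 0.05, 0.05, 0.05]), i)
        em.mu_fd = 4.0 + 1.5 * (i % 2)
        em.sigma_fd = 0.4
    seqs = _labelled_corpus(truth, 250, np.random.default_rng(6), mean_len=15)
    res = fit_generative(seqs, StateSpec(2, 2), restarts=4, seed=0,
                         max_iter=60, polish_max_iter=200)
    for cls in CLASSES:
        idx = res.params.states_of(cls)
        tidx = truth.states_of(cls)
        # match by dominant SD category
        for ti in tidx:
            best = min(idx, key=lambda j: np.abs(
                res.params.emissions[j].p_sd - truth.emissions[ti].p_sd).sum())
            assert np.abs(
                res.params.emissions[best].p_sd - truth.emissions[ti].p_sd
            ).max() < 0.05


# --- conditional likelihood and discriminative training ---------------------


def _mirror_params(block_emissions, A_block, pi_block):
    """Params with identical LFRR and RFLR blocks."""
    k = len(block_emissions)
    n = 2 * k
    A = np.zeros((n, n))
    A[:k, :k] = A_block
    A[k:, k:] = A_block
    pi = np.concatenate([pi_block, pi_block]) / 2.0
    ems = block_emissions + [
        make_emission(e.mu_fd, e.sigma_fd, e.mu_sl, e.sigma_sl, e.p_aoi.copy(),
                      e.p_sd.copy())
        for e in block_emissions
    ]
    return make_params(pi, A, ems, ("LFRR",) * k + ("RFLR",) * k)


def test_cll_symmetric_blocks_is_n_log_half(rng):
    ems = [make_emission(mu_fd=4.5), make_emission(mu_fd=5.5)]
    params = _mirror_params(ems, np.array([[0.7, 0.3], [0.4, 0.6]]),
                            np.array([0.6, 0.4]))
    seqs = _labelled_corpus(params, 10, rng, mean_len=6)
    cll = conditional_log_likelihood(seqs, params)
    assert cll == pytest.approx(len(seqs) * math.log(0.5), rel=1e-9)


def test_cll_single_state_blocks_matches_hand_bayes(rng):
    ems = [make_emission(mu_fd=4.0, sigma_fd=0.5), make_emission(mu_fd=6.0, sigma_fd=0.5)]
    params = make_params([0.5, 0.5], [[1.0, 0.0], [0.0, 1.0]], ems, ("LFRR", "RFLR"))
    ev = ObservationEvent(log_fd=4.4, aoi=1)
    seq = ObservationSequence("s", "LFRR", "t", [ev])
    num = 0.5 * norm.pdf(4.4, 4.0, 0.5)
    den = num + 0.5 * norm.pdf(4.4, 6.0, 0.5)
    assert conditional_log_likelihood([seq], params) == pytest.approx(
        math.log(num / den), rel=1e-10)
    post = classify(seq, params)
    assert post.p_lfrr == pytest.approx(num / den, rel=1e-10)


def test_cll_well_separated_emissions_approaches_zero(rng):
    ems = [make_emission(mu_fd=2.0, sigma_fd=0.1), make_emission(mu_fd=9.0, sigma_fd=0.1)]
    params = make_params([0.5, 0.5], np.eye(2), ems, ("LFRR", "RFLR"))
    seqs = [
        ObservationSequence("s", "LFRR", "t", [ObservationEvent(log_fd=2.0, aoi=1)]),
        ObservationSequence("s", "RFLR", "t", [ObservationEvent(log_fd=9.0, aoi=1)]),
    ]
    cll = conditional_log_likelihood(seqs, params)
    assert -1e-6 < cll <= 0.0


@pytest.mark.parametrize("include_aoi", [False, True])
def test_discriminative_gradient_matches_finite_differences(rng, include_aoi):
    params = random_block_params(rng, 2, 1)
    seqs = _labelled_corpus(params, 3, rng, mean_len=4)
    batches = {c: SequenceBatch([s for s in seqs if s.strategy == c]) for c in CLASSES}
    u = _Unconstrained.from_params(params)
    cll, grad = _cll_and_grad(batches, u, include_aoi)
    gvec = grad.vector()
    v0 = u.vector()
    rng2 = np.random.default_rng(0)
    idx = rng2.choice(len(v0), size=25, replace=False)
    h = 1e-5
    for i in idx:
        vp, vm = v0.copy(), v0.copy()
        vp[i] += h
        vm[i] -= h
        cp, _ = _cll_and_grad(batches, u.with_vector(vp), include_aoi)
        cm, _ = _cll_and_grad(batches, u.with_vector(vm), include_aoi)
        fd = (cp - cm) / (2 * h)
        if abs(fd) < 1e-10 and abs(gvec[i]) < 1e-10:
            continue
        assert gvec[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


def test_discriminative_objective_monotone_and_fixed_point(rng):
    params = random_block_params(rng, 2, 2)
    seqs = _labelled_corpus(params, 25, rng, mean_len=8)
    gen = baum_welch(seqs, params, max_iter=30)
    res = discriminative_train(seqs, gen.params, max_iter=40)
    assert np.all(np.diff(res.history) >= -1e-9)
    # on separable data an optimal init is a fixed point
    ems = [make_emission(mu_fd=2.0, sigma_fd=0.1), make_emission(mu_fd=9.0, sigma_fd=0.1)]
    sep = make_params([0.5, 0.5], np.eye(2), ems, ("LFRR", "RFLR"))
    sep_seqs = [
        ObservationSequence("s", "LFRR", "t", [ObservationEvent(log_fd=2.0, aoi=1)]),
        ObservationSequence("s", "RFLR", "t", [ObservationEvent(log_fd=9.0, aoi=1)]),
    ]
    res2 = discriminative_train(sep_seqs, sep, max_iter=10)
    assert res2.final_objective == pytest.approx(res2.history[0], abs=1e-6)


def test_discriminative_refinement_does_not_hurt_heldout_accuracy():
    """Paired seeded comparison: refined model >= generative fit on held-out data."""
    cfg = gz.GeneratorConfig(n_per_class=120, seed=0)
    corpus = gz.simulate_corpus(cfg)
    gen = fit_generative(corpus.train, StateSpec(3, 3), restarts=3, seed=0,
                         max_iter=60, polish_max_iter=150)
    disc = discriminative_train(corpus.train, gen.params, max_iter=60)
    actual = [s.strategy for s in corpus.test]
    acc_gen = np.mean([p == a for p, a in zip(
        gz.classify_batch(corpus.test, gen.params)[0], actual)])
    acc_disc = np.mean([p == a for p, a in zip(
        gz.classify_batch(corpus.test, disc.params)[0], actual)])
    assert acc_disc >= acc_gen


# --- classification ----------------------------------------------------------


def test_classify_symmetric_blocks_gives_half(rng):
    ems = [make_emission(mu_fd=4.5), make_emission(mu_fd=5.5)]
    params = _mirror_params(ems, np.array([[0.7, 0.3], [0.4, 0.6]]),
                            np.array([0.6, 0.4]))
    seq = sample_sequence(params, "LFRR", 5, rng)
    post = classify(seq, params)
    assert post.p_lfrr == pytest.approx(0.5, abs=1e-9)
    assert post.predicted == "LFRR"  # tie goes to LFRR


def test_classify_all_pi_mass_in_one_block(rng):
    params = random_block_params(rng, 2, 2)
    params.pi = np.array([0.6, 0.4, 0.0, 0.0])
    seq = random_seq(rng, params, 4, cls="LFRR")
    post = classify(seq, params)
    assert post.p_lfrr == pytest.approx(1.0)


def test_classify_matches_enumeration_bayes(rng):
    params = random_block_params(rng, 1, 1)
    seq = random_seq(rng, params, 3, cls="RFLR")
    post = classify(seq, params)
    _, bmass = enumerate_logmass(seq, params)
    expected = 1.0 / (1.0 + math.exp(bmass["RFLR"] - bmass["LFRR"]))
    assert post.p_lfrr == pytest.approx(expected, rel=1e-9)


# --- sampling ----------------------------------------------------------------


def test_sample_length_one_has_no_saccade(toy_params, rng):
    seq = sample_sequence(toy_params, "LFRR", 1, rng)
    assert len(seq) == 1
    assert seq.events[0].sd is None


def test_sample_sd_frequencies_converge_to_emission_row(rng):
    p_sd = np.array([0.89, 0.04, 0.05, 0.02])
    ems = [make_emission(p_sd=p_sd), make_emission()]
    params = make_params([0.5, 0.5], np.eye(2), ems, ("LFRR", "RFLR"))
    seq = sample_sequence(params, "LFRR", 100_001, rng)
    freqs = np.bincount(seq.sd, minlength=5)[1:] / (len(seq) - 1)
    assert np.abs(freqs - p_sd).max() < 0.01


def test_sampling_is_deterministic_given_seed(toy_params):
    a = sample_sequence(toy_params, "RFLR", 50, np.random.default_rng(99))
    b = sample_sequence(toy_params, "RFLR", 50, np.random.default_rng(99))
    assert a.events == b.events
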