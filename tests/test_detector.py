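import numpy as np
import pytest

from stepmatch import (
    DetectorConfig,
    Recording,
    Template,
    TemplateLibrary,
    detect_steps,
    evaluate_detection,
    greedy_select,
    reject_low_amplitude,
    simulate_recording,
    SimConfig,
)
from stepmatch.correlation import Candidate


def naive_greedy(candidates, template_lengths, nx, lam):
    """Reference implementation: re-sort and re-scan the full list each
    iteration, testing overlap against every accepted interval."""
    remaining = list(candidates)
    accepted = []
    forbidden = set()
    while remaining:
        remaining.sort(key=lambda c: (-c.score, c.t, c.p_index, c.k))
        best = remaining.pop(0)
        if best.score < lam:
            break
        if len(forbidden) == nx:
            break
        np_c = template_lengths[best.p_index]
        interval = set(range(best.t, best.t + np_c))
        if best.t + np_c > nx or interval & forbidden:
            continue
        forbidden |= interval
        accepted.append((best.t, best.t + np_c, best.p_index, best.k, best.score))
    return sorted(accepted)


def random_candidates(rng, n, nx, n_templates, lengths):
    out = []
    for _ in range(n):
        p = int(rng.integers(0, n_templates))
        t = int(rng.integers(0, nx - lengths[p] + 1))
        out.append(
            Candidate(k=int(rng.integers(0, 3)), p_index=p, t=t,
                      score=float(rng.uniform(-1, 1)))
        )
    return out


class TestGreedySelect:
    def test_single_candidate_above_lambda(self):
        steps = greedy_select(
            [Candidate(k=1, p_index=0, t=10, score=0.9)], [20], nx=100, lam=0.6
        )
        assert [(s.start, s.end) for s in steps] == [(10, 30)]
        assert steps[0].score == 0.9

    def test_overlapping_lower_score_discarded(self):
        cands = [
            Candidate(k=0, p_index=0, t=10, score=0.9),
            Candidate(k=0, p_index=0, t=15, score=0.8),
        ]
        steps = greedy_select(cands, [20], nx=100, lam=0.6)
        assert [(s.start, s.end) for s in steps] == [(10, 30)]

    def test_abutting_intervals_both_accepted(self):
        cands = [
            Candidate(k=0, p_index=0, t=10, score=0.9),
            Candidate(k=0, p_index=0, t=30, score=0.8),
        ]
        steps = greedy_select(cands, [20], nx=100, lam=0.6)
        assert [(s.start, s.end) for s in steps] == [(10, 30), (30, 50)]

    def test_stop_below_lambda(self):
        cands = [
            Candidate(k=0, p_index=0, t=10, score=0.9),
            Candidate(k=0, p_index=0, t=50, score=0.5),
        ]
        steps = greedy_select(cands, [20], nx=100, lam=0.6)
        assert len(steps) == 1

    def test_empty_input(self):
        assert greedy_select([], [20], nx=100, lam=0.6) == []

    def test_deterministic_tie_break(self):
        cands = [
            Candidate(k=2, p_index=1, t=5, score=0.8),
            Candidate(k=0, p_index=0, t=5, score=0.8),
            Candidate(k=0, p_index=0, t=3, score=0.8),
        ]
        steps = greedy_select(cands, [10, 10], nx=100, lam=0.0)
        # earliest lag wins, then lowest template index
        assert (steps[0].start, steps[0].template_index) == (3, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_rescan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lengths = [20, 35, 50]
        cands = random_candidates(rng, 50, 500, 3, lengths)
        fast = greedy_select(cands, lengths, nx=500, lam=0.3)
        ref = naive_greedy(cands, lengths, nx=500, lam=0.3)
        assert [(s.start, s.end, s.template_index, s.component, s.score)
                for s in fast] == ref

    def test_disjointness_and_threshold_invariants(self):
        rng = np.random.default_rng(99)
        lengths = [15, 25]
        cands = random_candidates(rng, 200, 400, 2, lengths)
        steps = greedy_select(cands, lengths, nx=400, lam=0.4)
        for a, b in zip(steps, steps[1:]):
            assert a.end <= b.start
        assert all(s.score >= 0.4 for s in steps)

    def test_monotone_in_lambda(self):
        rng = np.random.default_rng(7)
        lengths = [20]
        cands = random_candidates(rng, 100, 300, 1, lengths)
        lo = greedy_select(cands, lengths, nx=300, lam=0.3)
        hi = greedy_select(cands, lengths, nx=300, lam=0.7)
        lo_set = {(s.start, s.end) for s in lo}
        assert all((s.start, s.end) in lo_set for s in hi)


class TestAmplitudeGate:
    @pytest.fixture
    def setup(self, rng):
        tpl = Template(rng.normal(size=(3, 30)))
        lib = TemplateLibrary([tpl])
        return tpl, lib

    def _step(self):
        from stepmatch import StepInterval

        return StepInterval(10, 40, kind="detected", template_index=0,
                            component=1, score=0.9)

    def test_zero_segment_discarded(self, setup):
        tpl, lib = setup
        rec = Recording(np.zeros((3, 100)) + 1.0)
        assert reject_low_amplitude([self._step()], rec, lib, mu=0.1) == []

    def test_exact_copy_kept(self, setup):
        tpl, lib = setup
        samples = np.zeros((3, 100))
        samples[:, 10:40] = tpl.samples
        rec = Recording(samples)
        assert len(reject_low_amplitude([self._step()], rec, lib, mu=0.1)) == 1

    @pytest.mark.parametrize("gain,kept", [(0.05, False), (0.2, True)])
    def test_sigma_scales_with_gain(self, setup, gain, kept):
        tpl, lib = setup
        samples = np.zeros((3, 100))
        samples[:, 10:40] = gain * tpl.samples
        rec = Recording(samples)
        out = reject_low_amplitude([self._step()], rec, lib, mu=0.1)
        assert (len(out) == 1) == kept

    def test_monotone_in_mu(self, setup, rng):
        tpl, lib = setup
        rec = Recording(rng.normal(size=(3, 100)) * 0.08)
        from stepmatch import StepInterval

        steps = [
            StepInterval(i, i + 30, kind="detected", template_index=0,
                         component=k, score=0.9)
            for i, k in [(0, 0), (35, 1), (70, 2)]
        ]
        small = reject_low_amplitude(steps, rec, lib, mu=0.02)
        large = reject_low_amplitude(steps, rec, lib, mu=0.2)
        assert set((s.start, s.end) for s in large) <= set(
            (s.start, s.end) for s in small
        )


class TestDetectSteps:
    def test_planted_copies_recovered_exactly(self, rng):
        tpl = Template(rng.normal(size=(3, 40)))
        lib = TemplateLibrary([tpl])
        samples = np.zeros((3, 5 * 140 + 100))
        plants = [100 + i * 140 for i in range(5)]
        for pos in plants:
            samples[:, pos : pos + 40] = tpl.samples
        rec = Recording(samples)
        steps = detect_steps(rec, lib, DetectorConfig())
        assert [s.start for s in steps] == plants
        assert all(s.score == pytest.approx(1.0, abs=1e-9) for s in steps)

    def test_zero_signal_no_steps(self, library10):
        rec = Recording(np.zeros((3, 2000)))
        assert detect_steps(rec, library10) == []

    def test_noisy_planted_steps_recovered(self, library10):
        cfg = SimConfig(n_steps=5, noise_sigma=0.05, seed=11)
        rec, truth = simulate_recording(cfg, library10)
        steps = detect_steps(rec, library10)
        report = evaluate_detection(steps, truth.steps)
        assert report.recall == 1.0
        assert all(abs(d) <= 10 for d in report.delta_start)

    def test_deterministic(self, library10):
        rec, _ = simulate_recording(SimConfig(n_steps=5, seed=3), library10)
        a = detect_steps(rec, library10)
        b = detect_steps(rec, library10)
        assert a == b
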