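import numpy as np
import pytest
from scipy import stats

from enhancerkit.evolution import (
    Objective,
    branched_search,
    evolve_near_enhancer,
    greedy_evolve,
    random_drift,
    repress_with_sites,
)
from enhancerkit.fixtures import implanted_positive_fixture, near_enhancer_fixture
from enhancerkit.mutagenesis import saturation_mutagenesis, saturation_scores
from enhancerkit.oracle import GcContentOracle, fly_surrogate, score_sequences
from enhancerkit.seqcore import (
    ALPHABET,
    Sequence,
    ValidationError,
    decode,
    default_profile,
    encode,
    generate_random_sequences,
)


def brute_force_best(seq, oracle, objective, names):
    """Independent exhaustive search over all feasible single substitutions."""
    codes = encode(seq.residues)
    base = {
        n: score_sequences(oracle, [seq], n)[0] for n in names
    }
    best = None
    for p in range(len(codes)):
        for b in range(4):
            if b == codes[p]:
                continue
            v = codes.copy()
            v[p] = b
            mut = Sequence(id="v", residues=decode(v))
            scores = {n: score_sequences(oracle, [mut], n)[0] for n in names}
            d_t = scores[objective.target_class] - base[objective.target_class]
            if objective.mode == "maximize":
                feasible, key = d_t > 0, d_t
            elif objective.mode == "augment":
                feasible = d_t > 0 and all(
                    scores[c] >= f for c, f in objective.keep_floors.items()
                )
                key = d_t
            elif objective.mode == "prune":
                d_off = sum(scores[c] - base[c] for c in objective.off_target_classes)
                feasible = d_off < 0 and scores[objective.target_class] >= objective.target_floor
                key = -d_off
            else:  # repress
                feasible = d_t < 0 and not any(
                    a <= p < e for a, e in objective.protected_intervals
                )
                key = -d_t
            if feasible and (best is None or key > best[0]):
                best = (key, p, b)
    return None if best is None else (best[1], best[2])


class TestGreedyEvolve:
    def test_constant_oracle_stops_immediately(self, constant_oracle, short_random):
        trace = greedy_evolve(short_random[0], constant_oracle, "flat", n_steps=5)
        assert len(trace) == 0
        assert trace.stop_reason == "no_feasible_mutation"

    @pytest.mark.parametrize(
        "objective",
        [
            Objective(mode="maximize", target_class="KC"),
            Objective(mode="augment", target_class="KC", keep_floors={"T_neuron": 0.0}),
            Objective(
                mode="prune", target_class="T_neuron",
                off_target_classes=("KC",), target_floor=0.0,
            ),
            Objective(mode="repress", target_class="KC", protected_intervals=((0, 5),)),
        ],
        ids=["maximize", "augment", "prune", "repress"],
    )
    def test_single_step_equals_brute_force(self, fly, objective):
        seq = near_enhancer_fixture(1, seed=55, length=60, oracle=fly)[0]
        names = list(objective.classes_needed)
        expected = brute_force_best(seq, fly, objective, names)
        trace = greedy_evolve(seq, fly, objective, n_steps=1)
        got = (
            None
            if len(trace) == 0
            else (trace.steps[0].position, ALPHABET.index(trace.steps[0].alt))
        )
        assert got == expected

    def test_maximize_traces_strictly_increase(self, fly, profile500):
        for seq in generate_random_sequences(profile500, 3, seed=66):
            trace = greedy_evolve(seq, fly, "KC", n_steps=8)
            scores = trace.target_scores("KC")
            assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_snapshots_differ_at_exactly_one_position(self, fly):
        seq = near_enhancer_fixture(1, seed=57, length=80, oracle=fly)[0]
        trace = greedy_evolve(seq, fly, "KC", n_steps=4)
        snaps = trace.snapshots()
        for a, b in zip(snaps, snaps[1:]):
            diff = sum(x != y for x, y in zip(a.residues, b.residues))
            assert diff == 1

    def test_augment_never_breaks_keep_floor(self, fly):
        # a sequence with both codes present: augment KC while keeping T_neuron
        from enhancerkit.oracle import T_NEURON_SITES

        base = near_enhancer_fixture(1, seed=58, length=200, oracle=fly)[0]
        codes = encode(base.residues)
        for i, site in enumerate(T_NEURON_SITES.values()):
            codes[i * 40 : i * 40 + len(site)] = encode(site)
        seq = Sequence(id="dual", residues=decode(codes))
        floor = score_sequences(fly, [seq], "T_neuron")[0] - 0.05
        obj = Objective(mode="augment", target_class="KC", keep_floors={"T_neuron": floor})
        trace = greedy_evolve(seq, fly, obj, n_steps=6)
        for step in trace.steps:
            assert step.scores["T_neuron"] >= floor

    def test_class_mismatch_rejected(self, fly, short_random):
        with pytest.raises(ValidationError):
            greedy_evolve(short_random[0], fly, "MEL", n_steps=1)


class TestBranchedSearch:
    def test_small_run_matches_exhaustive_recursion(self, fly):
        seq = generate_random_sequences(default_profile(20), 1, seed=70)[0]

        def recurse(codes, depth):
            if depth == 0:
                return [([], [])]
            base = fly.score_encoded(codes[None, :], ["KC"])[0, 0]
            cands = []
            for p in range(len(codes)):
                for b in range(4):
                    if b != codes[p]:
                        v = codes.copy()
                        v[p] = b
                        s = fly.score_encoded(v[None, :], ["KC"])[0, 0]
                        cands.append((-(s - base), p, b, s))
            cands.sort(key=lambda t: (t[0], t[1], t[2]))
            out = []
            for _, p, b, s in cands[:2]:
                v = codes.copy()
                v[p] = b
                for muts, scores in recurse(v, depth - 1):
                    out.append(([(p, ALPHABET[b])] + muts, [s] + scores))
            return out

        expected = recurse(encode(seq.residues), 3)
        got = branched_search(seq, fly, "KC", k=2, depth=3)
        assert len(got) == 8
        for i, (emuts, escores) in enumerate(expected):
            muts, scores = got.path(i)
            assert muts == emuts
            assert np.allclose(scores, escores)

    def test_k1_reduces_to_greedy(self):
        gc = GcContentOracle()
        seq = generate_random_sequences(default_profile(25), 1, seed=71)[0]
        trace = greedy_evolve(seq, gc, "GC", n_steps=4)
        paths = branched_search(seq, gc, "GC", k=1, depth=4)
        muts, _ = paths.path(0)
        assert muts == [(s.position, s.alt) for s in trace.steps]

    def test_path_count_is_k_to_the_depth(self):
        gc = GcContentOracle()
        seq = generate_random_sequences(default_profile(15), 1, seed=72)[0]
        paths = branched_search(seq, gc, "GC", k=3, depth=4)
        assert len(paths) == 3**4
        assert paths.leaf_scores.shape == (81,)

    def test_k_larger_than_candidates_rejected(self, fly):
        seq = Sequence(id="s", residues="ACGT")
        with pytest.raises(ValidationError):
            branched_search(seq, fly, "KC", k=13, depth=1)


class TestNearEnhancerWrappers:
    def test_fixture_crosses_half_within_six_steps(self, fly):
        seq = near_enhancer_fixture(2, seed=80, oracle=fly)[0]
        start = score_sequences(fly, [seq], "KC")[0]
        assert start < 0.5
        trace, rescue = evolve_near_enhancer(seq, fly, "KC")
        assert max(trace.target_scores("KC")) > 0.5
        assert rescue is None

    def test_budget_and_rescue_contract(self, fly, profile500):
        seq = generate_random_sequences(profile500, 1, seed=81)[0]
        trace, rescue = evolve_near_enhancer(seq, fly, "KC", n_steps=6, rescue_steps=5)
        assert len(trace) <= 6
        if rescue is not None:
            assert len(rescue) <= 5
            joined = trace.target_scores("KC") + rescue.target_scores("KC")[1:]
            assert all(b >= a for a, b in zip(joined, joined[1:]))

    def test_infeasible_start_stops_immediately(self, constant_oracle, short_random):
        trace, rescue = evolve_near_enhancer(short_random[0], constant_oracle, "flat")
        assert trace.stop_reason == "no_feasible_mutation" and len(trace) == 0


class TestRepression:
    def test_whole_sequence_protected_gives_empty_trace(self, fly, short_random):
        seq = short_random[0]
        trace = repress_with_sites(seq, fly, "KC", [(0, len(seq))], n_steps=3)
        assert len(trace) == 0
        assert trace.stop_reason == "no_feasible_mutation"

    def test_single_step_is_restricted_argmin(self, fly):
        seq = near_enhancer_fixture(1, seed=82, length=60, oracle=fly)[0]
        protected = [(0, 20)]
        dm = saturation_mutagenesis(seq, fly, "KC")
        deltas = dm.deltas.copy()
        deltas[0:20, :] = np.inf
        ref = encode(seq.residues)
        deltas[np.arange(len(ref)), ref] = np.inf
        flat_best = int(np.where(deltas.ravel() == deltas.min())[0][0])
        trace = repress_with_sites(seq, fly, "KC", protected, n_steps=1)
        assert (trace.steps[0].position, ALPHABET.index(trace.steps[0].alt)) == (
            flat_best // 4,
            flat_best % 4,
        )

    def test_designed_enhancer_switched_off(self, fly):
        seqs, placements = implanted_positive_fixture(1, seed=83, oracle=fly)
        protected = [(p.start, p.end) for p in placements[0]]
        trace = repress_with_sites(seqs[0], fly, "KC", protected, n_steps=6)
        scores = trace.target_scores("KC")
        assert scores[-1] < 0.1
        assert all(b <= a for a, b in zip(scores, scores[1:]))
        for step in trace.steps:
            assert not any(a <= step.position < e for a, e in protected)


class TestRandomDrift:
    def test_reproducible_and_correct_length(self, fly, short_random):
        t1 = random_drift(short_random[0], fly, n_steps=10, seed=5)
        t2 = random_drift(short_random[0], fly, n_steps=10, seed=5)
        assert [s.position for s in t1.steps] == [s.position for s in t2.steps]
        assert len(t1) == 10

    def test_drift_leaves_score_distribution_unchanged(self, fly, profile500):
        """15 random mutations should not systematically move surrogate scores."""
        starts = generate_random_sequences(profile500, 40, seed=90)
        before = score_sequences(fly, starts, "KC")
        after = np.array(
            [
                random_drift(s, fly, n_steps=15, seed=91 + i).target_scores("KC")[-1]
                for i, s in enumerate(starts)
            ]
        )
        stat = stats.wilcoxon(before, after)
        assert stat.pvalue > 0.01
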