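"""Dual-code design: augment a second cell-type code, then prune it away.

Starts from a sequence carrying the synthetic T-neuron code, adds the KC code
while keeping the T-neuron score above a floor (augment), then removes the
T-neuron code from the resulting dual-code enhancer while keeping KC high
(prune).
"""

from enhancerkit import Sequence
from enhancerkit.evolution import Objective, greedy_evolve
from enhancerkit.implant import iterative_implant
from enhancerkit.oracle import T_NEURON_SITES, fly_surrogate, score_sequences
from enhancerkit.seqcore import default_profile, generate_random_sequences

oracle = fly_surrogate()
start = generate_random_sequences(default_profile(500), n=1, seed=22)[0]
t_code, _, _ = iterative_implant(
    start, list(T_NEURON_SITES.items()), oracle, "T_neuron"
)
scores = oracle.score_batch([t_code])[0]
by = dict(zip(oracle.class_names, scores))
print(f"start:    KC={by['KC']:.3f}  T_neuron={by['T_neuron']:.3f}")

floor = by["T_neuron"] - 0.05
augment = Objective(mode="augment", target_class="KC", keep_floors={"T_neuron": floor})
trace = greedy_evolve(t_code, oracle, augment, n_steps=15)
dual = trace.final
s = dict(zip(oracle.class_names, oracle.score_batch([dual])[0]))
print(f"augmented ({len(trace)} mutations): KC={s['KC']:.3f}  T_neuron={s['T_neuron']:.3f}")

prune = Objective(
    mode="prune", target_class="KC", off_target_classes=("T_neuron",), target_floor=0.5
)
trace2 = greedy_evolve(dual, oracle, prune, n_steps=15)
s2 = dict(zip(oracle.class_names, oracle.score_batch([trace2.final])[0]))
print(f"pruned    ({len(trace2)} mutations): KC={s2['KC']:.3f}  T_neuron={s2['T_neuron']:.3f}")
print(
    "Augment raises the KC score without letting T_neuron drop below its "
    "floor; prune destroys T-neuron sites while KC stays above 0.5 — two "
    "intertwined codes edited independently."
)
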