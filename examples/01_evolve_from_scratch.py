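"""Greedy in silico evolution of a random sequence into a Kenyon-cell enhancer.

Starts from a GC-profile-matched 500 bp random sequence and repeatedly applies
the single substitution with the highest positive delta score under the
packaged fly surrogate, printing the score trajectory.
"""

from enhancerkit import default_profile, generate_random_sequences, greedy_evolve
from enhancerkit.oracle import fly_surrogate

oracle = fly_surrogate()
start = generate_random_sequences(default_profile(500), n=1, seed=20)[0]
trace = greedy_evolve(start, oracle, "KC", n_steps=15)

print("step  position  ref->alt  KC score")
print(f"   0         -        -  {trace.start_scores['KC']:.4f}")
for i, step in enumerate(trace.steps, 1):
    print(f"{i:4d}  {step.position:8d}  {step.ref}->{step.alt}      {step.scores['KC']:.4f}")
print(f"stopped: {trace.stop_reason} after {len(trace)} mutations")
print(
    "Each mutation is the best of all 1,500 single substitutions; the score "
    "climbs from near 0 (random DNA) towards 1 (confident KC enhancer call)."
)
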