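"""Find near-enhancers in a toy genome: high predicted score, low accessibility.

Builds a three-contig toy genome with two planted KC-positive loci (one
accessible, one not), scores 500 bp windows at 50 bp stride, attaches mean
bedGraph accessibility, and filters for near-enhancer candidates.
"""

import numpy as np

from enhancerkit.fixtures import toy_genome_fixture
from enhancerkit.genomescan import mean_signal_per_window, near_enhancer_filter, scan_genome
from enhancerkit.oracle import fly_surrogate

oracle = fly_surrogate()
toy = toy_genome_fixture(seed=25)
scored, skipped = scan_genome(toy.contigs, oracle, "KC", width=500, stride=50)
signal = {
    c: (
        np.array([r[0] for r in rows]),
        np.array([r[1] for r in rows]),
        np.array([r[2] for r in rows]),
    )
    for c, rows in toy.signal.items()
}
means = mean_signal_per_window(scored, signal)
candidates = near_enhancer_filter(scored, means, score_min=0.3, collapse=True)

print(f"{len(scored)} windows scored ({skipped} skipped)")
print("near-enhancer candidates (score > 0.3, accessibility <= 25th percentile):")
for c in candidates:
    print(f"  {c.chrom}:{c.start}-{c.end}  score={c.score:.3f}  signal={c.mean_signal:.2f}")
print("planted inaccessible locus:", toy.planted_low_signal)
print("planted accessible locus (correctly excluded):", toy.planted_high_signal)
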