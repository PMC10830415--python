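# enhancerkit

Oracle-guided design of cell-type-specific synthetic enhancers.

Enhancers are DNA sequences that switch genes on in specific cell types by
docking particular combinations of transcription factors.  Given a scoring
*oracle* — any model mapping a fixed-length DNA sequence to per-cell-type
activity scores in [0, 1] — this package designs enhancer sequences from
scratch and dissects what makes them work:

* **in silico saturation mutagenesis** — score all 3L single-nucleotide
  substitutions (1,500 for a 500 bp sequence) to obtain a delta-score
  landscape;
* **greedy and branched sequence evolution** — iteratively apply the best
  mutation (or keep the top-k per step) towards a target cell type, with
  *dual-code* objectives that add a second cell-type code while keeping the
  first (augment) or strip one code from a multi-type enhancer (prune), and
  a repression mode that switches an enhancer off by creating repressor
  sites outside protected activator intervals;
* **motif implantation** — write a binding site into every possible
  position, keep the oracle's best placement, iterate over ordered site
  combinations, and analyse the resulting syntax (inter-site spacing,
  orientation, flank preference, minimal enhancers, background robustness);
* **motif annotation** — PWM scanning with overlapping-hit merging and
  empirical significance thresholds (mean + s.d. of best hits over random
  sequences), plus per-step motif censuses along design trajectories;
* **genome scanning** — score sliding windows (500 bp / 50 bp stride) and
  filter *near-enhancers*: high predicted score, low measured
  accessibility, convertible into functional enhancers with few mutations;
* **a WGAN-GP sequence generator** — the full generator/critic architecture
  (64,000-unit dense layer, five residual convolution blocks, width-1
  output convolution with softmax; 10 critic updates per generator update,
  gradient penalty λ=10, Adam 1e-4/0.5/0.9) on a self-contained NumPy
  autodiff engine with double backprop.

Everything runs against a packaged **surrogate oracle** built from
published binding-site sequences (fly Kenyon-cell activators Ey, Mef2,
Onecut, Sr and the CAATTA repressor class; human melanoma activators SOX10,
MITF, TFAP2): a weighted sum of thresholded log-odds motif hits through a
logistic link.  It is calibrated so random 500 bp sequences score ≈0 and
fully implanted, repressor-free designs score ≈1, and its additivity makes
exact per-nucleotide attribution available alongside model-agnostic
in-silico-mutagenesis attribution.  Trained deep learning models can be
plugged in through the same one-method contract.  See `docs/methods.md`
for the model, parameters and their rationale.

## Worked example

```python
from enhancerkit import default_profile, generate_random_sequences, greedy_evolve
from enhancerkit.oracle import fly_surrogate

oracle = fly_surrogate()
start = generate_random_sequences(default_profile(500), n=1, seed=20)[0]
trace = greedy_evolve(start, oracle, "KC", n_steps=15)
for step, score in enumerate(trace.target_scores("KC")):
    print(step, round(score, 4))
```

prints the Kenyon-cell score trajectory of one design run:

```
0 0.0001
1 0.002
2 0.0737
3 0.6
4 0.8669
5 0.9659
6 0.9919
7 0.9981
8 0.9996
```

Step 0 is random DNA (score ≈ 0, i.e. no predicted KC activity); each
subsequent line is the score after applying the single best of the 1,500
possible point mutations.  Early steps destroy chance repressor sites and
complete activator sites, driving the score to a confident call within a
handful of mutations; the run stops when no mutation increases the score
further.  The scripts in `examples/` walk through each capability the same
way (implantation and minimal enhancers, dual-code design, trace censuses,
genome scanning, GAN smoke training, attribution).

A thin command-line interface mirrors the library for shell use:

```bash
enhancerkit fixtures toy_genome --seed 1 --out-dir fx
enhancerkit scan-genome fx/toy_genome.fa --signal fx/toy_genome.bedgraph --out-dir scan
enhancerkit evolve my_starts.fa --class KC --steps 15 --seed 1 --out-dir runs
```

Every command writes a JSON manifest (versions, parameters, seeds, inputs,
outputs) sufficient to re-run deterministic stages bit-identically, and all
commands can be driven from a TOML file via `enhancerkit run --config`.

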