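# sitefree

Design DNA sequences that contain **no binding sites** for a chosen set of
DNA-binding proteins.

Synthetic regulatory constructs — reporter fusions, enhancer rearrangements,
spacers between functional elements — need "neutral" DNA, but random
sequence (and popular fillers such as phage DNA) is riddled with
transcription-factor binding sites that can confound the experiment.
`sitefree` removes every occurrence of user-specified motifs from a sequence
by Monte Carlo mutation, while holding GC content at a target value and
keeping designated functional blocks byte-identical.

## The method

Motifs to remove are given either as exact site strings (IUPAC codes
allowed) or as frequency matrices. Matrices are converted to log-odds
position weight matrices (PWMs), `w(b, j) = ln(p_bj / q_b)`, under an i.i.d.
background with `q_A = q_T = (1 − gc)/2`, `q_C = q_G = gc/2`. A window is
called a site when its score reaches a threshold calibrated from a user
p-value: the exact distribution of the score of a random background L-mer is
computed by dynamic programming (column-wise convolution on an integer score
grid), and the threshold is the smallest score `t` with `P(score ≥ t) ≤ p`.
Both strands are scanned; every window/strand match counts as one site.

Each Monte Carlo iteration mutates one random nucleotide inside every
detected site (the replacement base is drawn from the GC-parameterized
background, so composition stays on target), rescans, and accepts the
mutated sequence with probability

```
Pa = exp(N_old − N_new) / (1 + exp(N_old − N_new))
```

where `N` is the number of binding sites. The rule is a logistic in the
change of site count: moves that remove sites are favoured but not certain,
and moves that add sites are possible — that stochasticity is what lets the
search escape local minima where a deterministic descent gets stuck. The
loop stops when no sites remain, or when the best site count seen has not
improved for 100 iterations (the stall rule), in which case the best
sequence is returned. Optionally the acceptance blends in logistic terms for
the change in mean site affinity and in repeat content,
`Pa = λ1·σ(ΔN) + λ2·σ(ΔA) + λ3·σ(ΔR)` with `λ1 + λ2 + λ3 = 1`.

Three modes: **random** (de-novo design of a site-free sequence of arbitrary
length), **refine** (remove sites from a given sequence), and **spacer**
(link protected functional blocks with site-free spacers, mutating spacer
positions only). Two composite recipes build on these: hierarchical removal
(one motif library at a time, most important last) and merge-and-refine
(concatenate independently designed pieces, then clean the junctions).

## Worked example

```python
import numpy as np
import sitefree as sf
from sitefree.synthetic import toy_pwm

bg = sf.make_background(0.5)
library = sf.MotifLibrary.build(
    [toy_pwm(8, 0.8, np.random.default_rng(99), motif_id="soft8")],
    [sf.ExactSiteSet("sites", ("GAATTC", "CAGGTA", "TTAACC"))],
    bg=bg, pvalue=0.01,
)
result = sf.design_from_scratch(1000, library, sf.OptimizerConfig(seed=2, gc=0.5))
```

prints (via `examples/01_denovo_design.py`):

```
initial sites : 15
final sites   : 0
iterations    : 13
converged     : True
output GC     : 0.507
```

The random 1 kb draw contained 15 sites (both strands, exact patterns plus
PWM windows above the p = 0.01 threshold); 13 accepted/rejected mutation
rounds later the design has none, and its GC content sits at the 0.5 target.
The `examples/` directory has one short script per capability (de-novo
design, spacer design, threshold calibration, hierarchical removal and
merge-and-refine).

The same runs from a shell:

```
sitefree random --length 1000 --gc 0.5 --sites toy.sites --pvalue 0.01 \
    --seed 2 --out design.fa --report design.bed
```

Outputs: FASTA design, BED6 residual-hit report (+ sidecar TSV with raw
log-odds scores), per-iteration TSV trajectory, and a JSON summary carrying
the seed and full configuration so any run can be reproduced bit-exactly.
Exit status 3 (distinct from usage errors, 2) flags a run that stalled with
residual sites.

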