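# Methods

## Model and procedure

The package optimizes a DNA string of fixed length under a single objective:
the number `N` of binding-site occurrences for a user-supplied motif
library. Nothing is inserted or deleted; every move is a point substitution,
so output length always equals input length and protected coordinates can be
guaranteed byte-identical.

**Background model.** Bases are i.i.d. with `P(A) = P(T) = (1 − gc)/2` and
`P(C) = P(G) = gc/2`. The single parameter `gc` (fraction in [0, 1], default
0.5) serves three roles: the log-odds denominator of PWMs, the null model of
the p-value calibration, and the proposal distribution of replacement bases.
Using one distribution for all three keeps the design's stationary
composition at the target GC — relevant because GC content influences
nucleosome positioning and users typically want it held constant. The
default of 0.5 is a neutral choice; matching a genome's intergenic
composition is the user's call via `--gc`.

**PWMs and thresholds.** A 4×L frequency matrix becomes a log-odds PWM with
background-proportional pseudocounts:
`p = (count + s·q_b) / (total + s)`, `w = ln(p / q_b)`, pseudocount scale
`s = 1.0` by default (the convention of classical PWM-scanning tools;
user-overridable). Natural log is used throughout; since thresholds are
calibrated from a p-value, results are invariant to the log base. The score
of a random background L-mer is discretized to an integer grid
(`round(w × resolution)`, resolution 1000, i.e. per-column rounding error
≤ 5×10⁻⁴) and its exact distribution is built by convolving the 4-atom
column distributions — O(L × score-range), never 4^L enumeration. The
threshold for p-value `p` is the smallest grid score `t` with
`P(score ≥ t) ≤ p`; windows scoring ≥ t are sites. A `p` below the
probability of the best word is reported as unreachable, naming the
attainable minimum. Note one boundary consequence of this (tail ≤ p)
semantics: the tail at the minimum score is exactly 1, so even `p`
arbitrarily close to 1 excludes the worst-scoring words; the alternative
(tail ≥ p) semantics would over-call at small p, which is the case that
matters. Default p is 0.003; 0.001–0.01 is the practical range — smaller p
means fewer, stronger calls and an easier optimization.

**Scanning.** Exact patterns (IUPAC allowed) are matched with overlapping
occurrences on both strands; minus-strand hits are forward windows equal to
the reverse complement of a pattern, reported in forward coordinates. PWM
windows are scored vectorized on the forward strand and, for the minus
strand, against the reverse-complement PWM (`w'(b, j) = w(comp b, L−1−j)`),
which satisfies `score'(x) = score(revcomp x)` exactly. Every window/strand
match counts as one hit: overlapping hits are not merged, and a palindromic
site counts once per strand. This double-count convention is a deliberate
choice — it makes `N` a simple monotone objective — and users should read
reported counts accordingly.

**Monte Carlo loop.** Per iteration: scan; if `N = 0`, stop; otherwise, for
each hit in coordinate order, draw one position uniformly among the hit's
mutable positions and replace it with a background draw (a draw equal to the
current base is a lawful null move); rescan; accept the candidate with
probability `Pa = σ(N_old − N_new)` where `σ` is the logistic, comparing one
uniform draw against `Pa`; a rejection restores the previous sequence
exactly. All hits are mutated simultaneously against one scan per iteration.
Improving moves are not auto-accepted — the logistic is applied literally,
so `Pa < 1` even when `N` drops — and worsening moves pass with probability
`σ(−ΔN) > 0`, which is what lets the search cross barriers in `N`.

**Stopping.** The run ends at `N = 0`, or when the *best* `N` seen has not
strictly improved for `stall_limit` iterations (default 100), returning the
best sequence (not the current one). A hard cap `max_iterations` (default
100 000) bounds pathological inputs; hitting it returns the best sequence
flagged unconverged. A stalled result is a legitimate outcome (exit status 3
from the CLI), not an error.

**Extended acceptance.** Optionally
`Pa = λ1·σ(ΔN) + λ2·σ(ΔA) + λ3·σ(ΔR)`, weights non-negative and summing
to 1 (default (1, 0, 0), reducing exactly to the site-count rule). The
auxiliary statistics have no canonical definition, so the package fixes
documented ones: `A` is the mean log-odds score over PWM hits (0 when there
are none) and `R` is the number of distinct k-mers occurring at least twice
(k = `repeat_kmer`, default 10). Both are extensions to steer repetitiveness
and residual affinity; the repeat count is reported, never repaired.

**Masks and spacer mode.** A design is an ordered alternation of protected
blocks and spacer lengths; the mutability mask is true exactly on spacer
positions. Hits with no mutable position are excluded from the objective and
from the report of retained hits — they are unremovable by construction, and
counting them would make `N = 0` unreachable and let the stall rule dominate.
They are still surfaced separately (`protected_hits`) for information.

**Reproducibility.** One seeded RNG stream drives a run with a fixed draw
order: (initial sequence or spacers, if any) then per iteration, for each
hit in coordinate order a position draw and a base draw, then one acceptance
draw. A fixed seed gives a bit-identical result; varying the seed reproduces
the method's intended "different solution every time" behaviour.

## Parameters at a glance

| parameter | default | meaning |
|---|---|---|
| `gc` | 0.5 | target GC fraction; background, calibration and proposal model |
| `pvalue` | 0.003 | site-call tail probability per PWM |
| `pseudocount_scale` | 1.0 | background-proportional pseudocount mass per column |
| `resolution` | 1000 | score-grid discretization (log-odds × 1000) |
| `stall_limit` | 100 | iterations without best-N improvement before giving up |
| `max_iterations` | 100 000 | hard safety cap |
| `weights` | (1, 0, 0) | λ blend of site-count / affinity / repeat terms |
| `repeat_kmer` | 10 | k of the repeat statistic R |
| `both_strands` | true | scan both strands (forward-only flag exists) |

## Synthetic data

`sitefree.synthetic` generates everything the tests (and users' dry runs)
need with zero downloads: `toy_pwm` interpolates uniform → consensus-only
frequency matrices (lengths 6–8 keep exhaustive 4^L cross-checks fast);
`plant_sites` writes known site strings into random background;
`exact_library_patterns` draws distinct random site strings; emitters write
the standard motif/sites file formats so CLI-level tests consume real files.

These fixtures emulate the *structure* of real inputs — motif widths,
degeneracy, site density — but not real motif content: columns are
exchangeable, there is no correlation between adjacent positions, and real
TF collections are far more redundant (overlapping, near-duplicate motifs).
Passing tests therefore demonstrate the correctness of the calibration,
scanning and optimization machinery and the convergence behaviour at
realistic site densities; they do not certify convergence speed for large
curated motif collections, where dozens of PWMs can make `N = 0`
unattainable and the stall exit is the expected outcome (the test suite
exercises that regime with a scaled-down 20-PWM, 1 kb run).

## Numerical choices and degenerate inputs

* Logistic via `scipy.special.expit` — stable for arbitrarily large |ΔN|.
* Score comparisons use `score ≥ threshold − 1e−9` to absorb float jitter;
  the calibration itself is exact on the integer grid.
* The score-grid array widens as needed during convolution; it cannot wrap.
* `gc = 0` or `1` is legal for sequence generation and exact-site work, but
  PWM conversion rejects it (log-odds undefined at zero-probability bases).
* Empty motif library: every workflow is a pure identity/concatenation,
  converged, zero iterations. Zero-length spacers and already-site-free
  inputs likewise short-circuit.
* Ambiguity codes in input sequences are an error unless the caller opts
  into seeded randomization (each code resolved by a background draw
  restricted to its allowed bases).
* An exact pattern whose only sequence-matching positions are protected
  (e.g. an all-N tail over a too-short spacer) can make a junction
  unbreakable; the result is an unconverged report, not an exception.

## Problem sizes used in the checks

The test suite and examples run at deliberately modest scale, chosen so the
exhaustive oracles stay exact and fast: motif lengths ≤ 8 (enumeration
oracles ≤ 4^8 words), design lengths 300 bp–10 kb, 20–50 seeds per
stochastic claim, and a 20-PWM 1 kb smoke run for the many-motif regime.
The method itself has no such limits; sequences up to tens of kb are the
intended working range (genome-scale scanning indexes are out of scope).

## Known limitations

* Zeroth-order background only; no dinucleotide or higher-order null models.
* No motif discovery, matrix trimming, or information-content filtering.
* The double-count convention inflates `N` relative to merged-occurrence
  counting; compare counts across tools with care.
* No annealing schedule or population search; the single-chain logistic rule
  is the method, chosen over deterministic descent (local minima) and
  genetic algorithms (slow, repetitive outputs).
* No synthesis-oriented post-processing (restriction-site screening,
  homopolymer capping); constrained designs can be repetitive, and the
  repeat statistic only reports this.
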