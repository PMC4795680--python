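"""Monte Carlo binding-site removal.

One iteration: identify every binding site, mutate one random nucleotide
inside each site (drawing the replacement base from the GC-parameterized
background), rescan, and accept the mutated sequence with the logistic
probability

    Pa = exp(N_old - N_new) / (1 + exp(N_old - N_new)),

where N counts binding sites. A rejected proposal restores the previous
sequence exactly. Improving moves are not auto-accepted: the logistic is
applied literally, so even a site-removing mutation can be rejected. The loop
stops once no sites remain, or when the best site count seen has not strictly
improved for ``stall_limit`` iterations (default 100), in which case the best
sequence is returned.

The acceptance rule optionally blends in two more logistic terms, weighted by
``(lambda1, lambda2, lambda3)`` summing to 1: one in the change of mean site
affinity A (mean PWM hit score), one in the change of repeat content R
(distinct k-mers occurring at least twice, k=10 by default). With weights
(1, 0, 0) it reduces exactly to the site-count rule.

Reproducibility: a single seeded RNG stream drives the run, with a fixed draw
order — for each hit in coordinate order, one position draw then one base
draw; then one acceptance draw per iteration. A fixed seed therefore gives a
bit-identical result.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from sitefree.motifs import BASES, Background, MotifLibrary, make_background
from sitefree.scan import ScanReport, SiteHit, scan_all


class EngineError(ValueError):
    """Invalid optimizer parameters."""


@dataclass(frozen=True)
class ExtendedWeights:
    """Weights of the site-count, affinity and repeat acceptance terms."""

    lambda1: float = 1.0
    lambda2: float = 0.0
    lambda3: float = 0.0

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lambda3"):
            if getattr(self, name) < 0:
                raise EngineError(f"{name} must be non-negative")
        total = self.lambda1 + self.lambda2 + self.lambda3
        if abs(total - 1.0) > 1e-9:
            raise EngineError(
                f"lambda1 + lambda2 + lambda3 must equal 1, got {total!r}"
            )

    @property
    def site_count_only(self) -> bool:
        return self.lambda2 == 0.0 and self.lambda3 == 0.0


@dataclass(frozen=True)
class OptimizerConfig:
    """Tunable parameters of the removal loop."""

    gc: float = 0.5
    stall_limit: int = 100
    max_iterations: int = 100_000
    seed: Optional[int] = None
    weights: ExtendedWeights = field(default_factory=ExtendedWeights)
    repeat_kmer: int = 10
    both_strands: bool = True

    def __post_init__(self):
        if self.stall_limit < 1:
            raise EngineError("stall_limit must be >= 1")
        if self.max_iterations < 0:
            raise EngineError("max_iterations must be >= 0")
        if not 0.0 <= self.gc <= 1.0:
            raise EngineError("gc must be in [0, 1]")
        if self.repeat_kmer < 2:
            raise EngineError("repeat_kmer must be >= 2")


@dataclass
class TrajectoryPoint:
    """State after one iteration: current N, proposal fate, Pa used."""

    iteration: int
    n: int
    accepted: bool
    pa: float


@dataclass
class OptimizationResult:
    """Outcome of one optimization run."""

    sequence: str
    residual: ScanReport
    converged: bool
    iterations: int
    trajectory: list[TrajectoryPoint]
    seed: Optional[int]
    initial_n: int
    protected_hits: list[SiteHit] = field(default_factory=list)

    @property
    def final_n(self) -> int:
        return self.residual.N


def acceptance_probability(n_old: float, n_new: float) -> float:
    """Logistic acceptance probability in the site-count change.

    Strictly increasing in ``n_old - n_new``; 0.5 when the count is
    unchanged. Numerically stable for large count differences.
    """
    return float(expit(n_old - n_new))


def extended_acceptance(
    n_old: float,
    n_new: float,
    a_old: float,
    a_new: float,
    r_old: float,
    r_new: float,
    w: ExtendedWeights,
) -> float:
    """Convex combination of logistic terms in site count, affinity, repeats.

    Equals :func:`acceptance_probability` exactly when ``w = (1, 0, 0)``.
    """
    return float(
        w.lambda1 * expit(n_old - n_new)
        + w.lambda2 * expit(a_old - a_new)
        + w.lambda3 * expit(r_old - r_new)
    )


def count_repeats(seq: str, k: int = 10) -> int:
    """Number of distinct forward-strand k-mers occurring at least twice."""
    if k < 2:
        raise EngineError("k must be >= 2")
    if len(seq) < k:
        return 0
    counts = Counter(seq[i : i + k] for i in range(len(seq) - k + 1))
    return sum(1 for c in counts.values() if c >= 2)


def propose_mutation(
    seq: str,
    hits: Sequence[SiteHit],
    mask: np.ndarray,
    bg: Background,
    rng: np.random.Generator,
) -> str:
    """Mutate one random maskable nucleotide inside each hit.

    For each hit (coordinate order), one uniformly chosen position among the
    hit's mask-allowed positions is replaced by a base drawn from the
    background distribution. The draw may equal the current base (a lawful
    null move — this keeps the sampler's stationary composition at the target
    GC). Positions shared by several hits may be drawn more than once; the
    last draw wins. Positions outside the mask never change.
    """
    if not hits:
        raise EngineError("propose_mutation requires at least one hit")
    chars = list(seq)
    probs = bg.probs
    for hit in sorted(hits):
        positions = [p for p in range(hit.start, hit.end) if mask[p]]
        if not positions:
            raise RuntimeError(
                f"hit {hit} has no mutable position; scan_all should have "
                "filtered it out"
            )
        pos = positions[int(rng.integers(len(positions)))]
        base = BASES[int(rng.choice(4, p=probs))]
        chars[pos] = base
    return "".join(chars)


def optimize(
    seq: str,
    library: MotifLibrary,
    mask: Optional[np.ndarray] = None,
    config: Optional[OptimizerConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> OptimizationResult:
    """Run the removal loop until no sites remain or the search stalls.

    The stall counter resets only when the best-so-far site count strictly
    improves; on stall the best sequence seen (not the current one) is
    returned. ``rng`` overrides ``config.seed`` when given, so callers can
    thread one RNG stream through sequence generation and optimization.
    """
    config = config or OptimizerConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if mask is None:
        mask = np.ones(len(seq), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != len(seq):
            raise EngineError("mask length must equal sequence length")
    bg = make_background(config.gc)
    w = config.weights
    k = config.repeat_kmer

    def scan(s: str) -> ScanReport:
        return scan_all(s, library, mask=mask, both_strands=config.both_strands)

    cur_seq = seq
    cur = scan(cur_seq)
    initial_n = cur.N
    cur_repeats = count_repeats(cur_seq, k) if not w.site_count_only else 0

    best_seq, best_n = cur_seq, cur.N
    stall = 0
    iterations = 0
    trajectory: list[TrajectoryPoint] = []

    while cur.N > 0 and iterations < config.max_iterations:
        iterations += 1
        candidate = propose_mutation(cur_seq, cur.hits, mask, bg, rng)
        cand = scan(candidate)
        if w.site_count_only:
            pa = acceptance_probability(cur.N, cand.N)
            cand_repeats = 0
        else:
            cand_repeats = count_repeats(candidate, k)
            pa = extended_acceptance(
                cur.N, cand.N,
                cur.mean_affinity, cand.mean_affinity,
                cur_repeats, cand_repeats,
                w,
            )
        accepted = bool(rng.random() < pa)
        if accepted:
            cur_seq, cur, cur_repeats = candidate, cand, cand_repeats
        trajectory.append(
            TrajectoryPoint(iteration=iterations, n=cur.N, accepted=accepted, pa=pa)
        )
        if cur.N < best_n:
            best_seq, best_n = cur_seq, cur.N
            stall = 0
        else:
            stall += 1
        if stall >= config.stall_limit:
            break

    residual = scan(best_seq)
    return OptimizationResult(
        sequence=best_seq,
        residual=residual,
        converged=residual.N == 0,
        iterations=iterations,
        trajectory=trajectory,
        seed=config.seed,
        initial_n=initial_n,
    )
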