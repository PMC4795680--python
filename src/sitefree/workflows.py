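"""User-facing design modes.

Three basic modes — de-novo random design, refinement of a given sequence,
and site-free spacer design between protected blocks — plus two composite
recipes: hierarchical removal (one motif library at a time, least important
first, so the most important sites are cleaned last and stay clean) and
merge-and-refine (concatenate independently designed pieces, then refine the
whole to remove junction-spanning sites).

All modes mutate in place and never insert or delete: output length always
equals input/spec length, and in spacer mode the protected blocks are
byte-identical in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from sitefree.engine import (
    EngineError,
    OptimizationResult,
    OptimizerConfig,
    optimize,
)
from sitefree.motifs import BASES, MotifLibrary, make_background
from sitefree.scan import ScanError, encode, scan_all


@dataclass(frozen=True)
class ProtectedBlock:
    """A functional sequence that must remain untouched."""

    name: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        encode(seq)  # validate alphabet
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Spacer:
    """A designed filler segment of fixed length (mutable positions)."""

    length: int

    def __post_init__(self):
        if self.length < 0:
            raise EngineError(f"spacer length must be >= 0, got {self.length}")

    def __len__(self) -> int:
        return self.length


Element = Union[ProtectedBlock, Spacer]


@dataclass(frozen=True)
class DesignSpec:
    """Ordered alternation of protected blocks and spacer lengths."""

    elements: tuple[Element, ...]

    def __post_init__(self):
        if not self.elements:
            raise EngineError("design spec needs at least one element")
        object.__setattr__(self, "elements", tuple(self.elements))

    @property
    def total_length(self) -> int:
        return sum(len(e) for e in self.elements)

    def mask(self) -> np.ndarray:
        """Boolean mutability mask: True exactly on spacer positions."""
        out = np.zeros(self.total_length, dtype=bool)
        pos = 0
        for e in self.elements:
            if isinstance(e, Spacer):
                out[pos : pos + len(e)] = True
            pos += len(e)
        return out

    def block_slices(self) -> list[tuple[str, slice]]:
        """Name and coordinate slice of every protected block, in order."""
        out = []
        pos = 0
        for e in self.elements:
            if isinstance(e, ProtectedBlock):
                out.append((e.name, slice(pos, pos + len(e))))
            pos += len(e)
        return out

    def initial_sequence(self, gc: float, rng: np.random.Generator) -> str:
        """Concatenation with spacers filled by random background draws."""
        parts = []
        for e in self.elements:
            if isinstance(e, ProtectedBlock):
                parts.append(e.sequence)
            else:
                parts.append(random_sequence(len(e), gc, rng))
        return "".join(parts)


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """i.i.d. random DNA with P(A)=P(T)=(1-gc)/2, P(C)=P(G)=gc/2."""
    if length < 0:
        raise EngineError("length must be >= 0")
    if length == 0:
        return ""
    probs = make_background(gc).probs
    draws = rng.choice(4, size=length, p=probs)
    return "".join(BASES[i] for i in draws)


def design_from_scratch(
    length: int,
    library: MotifLibrary,
    config: Optional[OptimizerConfig] = None,
) -> OptimizationResult:
    """Make a random binding-site-free sequence of the requested length.

    The initial sequence is drawn from the GC-parameterized background, then
    every position is mutable during optimization.
    """
    config = config or OptimizerConfig()
    rng = np.random.default_rng(config.seed)
    seq = random_sequence(length, config.gc, rng)
    return optimize(seq, library, mask=None, config=config, rng=rng)


def refine_sequence(
    seq: str,
    library: MotifLibrary,
    config: Optional[OptimizerConfig] = None,
) -> OptimizationResult:
    """Remove the library's sites from a given sequence.

    All positions are mutable, but only positions inside a detected site are
    ever drawn, so sequence outside hit footprints is untouched.
    """
    config = config or OptimizerConfig()
    seq = seq.upper()
    encode(seq)  # validate alphabet before any work
    rng = np.random.default_rng(config.seed)
    return optimize(seq, library, mask=None, config=config, rng=rng)


def design_spacers(
    spec: DesignSpec,
    library: MotifLibrary,
    config: Optional[OptimizerConfig] = None,
) -> OptimizationResult:
    """Link protected blocks with site-free spacers.

    Spacers are initialized randomly at the target GC and only spacer
    positions mutate. Hits lying entirely inside protected blocks are
    unremovable by construction; they are excluded from the objective and
    reported separately in ``protected_hits`` (informational only). A spacer
    too short to break an unavoidable junction motif yields an unconverged
    result with a residual-hit report, not an exception.
    """
    config = config or OptimizerConfig()
    rng = np.random.default_rng(config.seed)
    seq = spec.initial_sequence(config.gc, rng)
    mask = spec.mask()
    result = optimize(seq, library, mask=mask, config=config, rng=rng)
    full = scan_all(result.sequence, library, both_strands=config.both_strands)
    retained = set(result.residual.hits)
    result.protected_hits = [h for h in full.hits if h not in retained]
    return result


@dataclass
class HierarchicalResult:
    """Outcome of sequential removal, one library per pass."""

    sequence: str
    passes: list[OptimizationResult]
    residual_by_library: dict[str, list]

    @property
    def converged(self) -> bool:
        """True when the final (highest-priority) pass reached zero sites."""
        return self.passes[-1].converged


def hierarchical_removal(
    seq: str,
    ordered_libraries: Sequence[tuple[str, MotifLibrary]],
    config: Optional[OptimizerConfig] = None,
) -> HierarchicalResult:
    """Remove one binding-site type at a time, least important first.

    Removing one type can create sites of another; running the
    most-important library last guarantees its sites are clean in the final
    sequence (when that pass converges), while earlier types may reappear and
    are reported per library.
    """
    if not ordered_libraries:
        raise EngineError("hierarchical removal needs at least one library")
    config = config or OptimizerConfig()
    rng = np.random.default_rng(config.seed)
    current = seq.upper()
    encode(current)
    passes: list[OptimizationResult] = []
    for _, library in ordered_libraries:
        result = optimize(current, library, mask=None, config=config, rng=rng)
        passes.append(result)
        current = result.sequence
    residual_by_library = {
        name: scan_all(current, library, both_strands=config.both_strands).hits
        for name, library in ordered_libraries
    }
    return HierarchicalResult(
        sequence=current, passes=passes, residual_by_library=residual_by_library
    )


def merge_and_refine(
    pieces: Sequence[str],
    library: MotifLibrary,
    config: Optional[OptimizerConfig] = None,
) -> OptimizationResult:
    """Concatenate independently designed pieces and refine the whole.

    Refinement removes sites created at the junctions; every position is
    mutable (unlike spacer mode) and piece order is preserved up to point
    mutations.
    """
    if not pieces:
        raise EngineError("merge_and_refine needs at least one piece")
    return refine_sequence("".join(pieces), library, config)


def parse_design_file(
    path: str | Path,
    sequences: Optional[Mapping[str, str]] = None,
) -> DesignSpec:
    """Read a design file describing the block/spacer construct.

    One element per line, in construct order; ``#`` starts a comment:

    * ``sequence <NAME> <ACGT...>`` — a protected block given inline;
    * ``sequence <NAME> @<fasta_id>`` — a protected block resolved against
      the ``sequences`` mapping (typically read from a FASTA file);
    * ``spacer <LENGTH_BP>`` — a spacer of that many mutable bases.
    """
    path = Path(path)
    elements: list[Element] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        kind = parts[0].lower()
        if kind == "spacer":
            if len(parts) != 2:
                raise EngineError(f"{path}:{lineno}: expected 'spacer <LENGTH_BP>'")
            try:
                length = int(parts[1])
            except ValueError:
                raise EngineError(f"{path}:{lineno}: bad spacer length {parts[1]!r}")
            elements.append(Spacer(length))
        elif kind == "sequence":
            if len(parts) != 3:
                raise EngineError(
                    f"{path}:{lineno}: expected 'sequence <NAME> <ACGT...|@fasta_id>'"
                )
            name, body = parts[1], parts[2]
            if body.startswith("@"):
                key = body[1:]
                if sequences is None or key not in sequences:
                    raise EngineError(
                        f"{path}:{lineno}: sequence id {key!r} not found in the "
                        "provided FASTA"
                    )
                body = sequences[key]
            try:
                elements.append(ProtectedBlock(name=name, sequence=body))
            except ScanError as exc:
                raise EngineError(f"{path}:{lineno}: {exc}")
        else:
            raise EngineError(
                f"{path}:{lineno}: unknown element {kind!r} (use 'sequence' or 'spacer')"
            )
    return DesignSpec(elements=tuple(elements))
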