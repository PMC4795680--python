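"""Motif models: backgrounds, PWMs, exact-site sets, and p-value calibration.

A motif is either an exact-site set (IUPAC patterns matched literally) or a
position weight matrix (PWM). Frequency matrices are converted to log-odds
PWMs under an i.i.d. background parameterized by GC content, and a score
threshold is calibrated from a user p-value by exact dynamic programming over
the background score distribution — the classical PATSER calibration, done
here by column-wise convolution rather than word enumeration.

Conventions (they matter because thresholds are unit-dependent):

* log-odds use the natural logarithm, ``w = ln(p / b)``;
* pseudocounts are background-proportional, ``count + scale * b_base`` with
  a default scale of 1.0;
* the p-value of a threshold ``t`` is the probability that a random
  background L-mer scores ``>= t``.

The p-value calibration itself is unit-invariant: the same p gives the same
set of called words whatever log base is used.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC nucleotide ambiguity codes mapped to the concrete bases they allow.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT_TABLE = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class MotifError(ValueError):
    """Invalid motif parameters or malformed motif input."""


class UnreachablePValueError(MotifError):
    """Requested p-value is below the smallest attainable tail probability."""

    def __init__(self, requested: float, attainable: float):
        self.requested = requested
        self.attainable = attainable
        super().__init__(
            f"p-value {requested:g} is unreachable: even the maximum score has "
            f"tail probability {attainable:.3g}; use p >= {attainable:.3g}"
        )


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes allowed)."""
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def expand_iupac(pattern: str) -> list[str]:
    """All concrete A/C/G/T strings matched by an IUPAC pattern."""
    words = [""]
    for ch in pattern.upper():
        try:
            choices = IUPAC_CODES[ch]
        except KeyError:
            raise MotifError(f"character {ch!r} is not an IUPAC nucleotide code")
        words = [w + c for w in words for c in choices]
    return words


@dataclass(frozen=True)
class Background:
    """i.i.d. base model with P(A)=P(T)=(1-gc)/2 and P(C)=P(G)=gc/2."""

    gc: float

    def __post_init__(self):
        if not 0.0 <= self.gc <= 1.0:
            raise MotifError(f"gc must be in [0, 1], got {self.gc}")

    @property
    def probs(self) -> np.ndarray:
        """Per-base probabilities in A, C, G, T order."""
        at = (1.0 - self.gc) / 2.0
        cg = self.gc / 2.0
        return np.array([at, cg, cg, at])


def make_background(gc: float) -> Background:
    """Background base distribution for a target GC fraction."""
    return Background(gc)


@dataclass(frozen=True)
class FrequencyMatrix:
    """4 x L table of per-position base counts (rows A, C, G, T)."""

    motif_id: str
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise MotifError(
                f"{self.motif_id}: counts must be a 4 x L array with L >= 1, "
                f"got shape {counts.shape}"
            )
        if (counts < 0).any():
            raise MotifError(f"{self.motif_id}: negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class PWM:
    """Log-odds position weight matrix, ``weights[base, pos] = ln(p/b)``."""

    motif_id: str
    weights: np.ndarray

    def __post_init__(self):
        weights = np.asarray(self.weights, dtype=float)
        if weights.ndim != 2 or weights.shape[0] != 4 or weights.shape[1] < 1:
            raise MotifError(f"{self.motif_id}: weights must be 4 x L, L >= 1")
        if not np.isfinite(weights).all():
            raise MotifError(f"{self.motif_id}: non-finite log-odds weights")
        object.__setattr__(self, "weights", weights)

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        """PWM scoring the opposite strand: score'(w) = score(revcomp(w))."""
        comp = [BASE_INDEX[c] for c in "TGCA"]
        return PWM(self.motif_id, self.weights[comp, :][:, ::-1])

    def score_word(self, word: str) -> float:
        """Sum of column weights for a concrete word of matching length."""
        if len(word) != self.length:
            raise MotifError(f"word length {len(word)} != motif length {self.length}")
        idx = [BASE_INDEX[c] for c in word.upper()]
        return float(self.weights[idx, np.arange(self.length)].sum())


def frequency_to_pwm(
    freq: FrequencyMatrix, bg: Background, pseudocount_scale: float = 1.0
) -> PWM:
    """Convert a count matrix to a log-odds PWM under a background model.

    Per column, ``p_base = (count + scale * b_base) / (total + scale)`` and
    ``weight = ln(p_base / b_base)``. A positive scale guarantees finite
    weights whenever the background itself is non-degenerate at that base;
    zero-background bases (gc of exactly 0 or 1) are rejected because their
    log-odds is undefined.
    """
    if pseudocount_scale < 0:
        raise MotifError("pseudocount_scale must be >= 0")
    b = bg.probs
    counts = freq.counts
    totals = counts.sum(axis=0) + pseudocount_scale
    if (totals <= 0).any():
        raise MotifError(
            f"{freq.motif_id}: column with zero total and zero pseudocount"
        )
    p = (counts + pseudocount_scale * b[:, None]) / totals[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        weights = np.log(p / b[:, None])
    if not np.isfinite(weights).all():
        raise MotifError(
            f"{freq.motif_id}: degenerate matrix (zero probability cell); "
            "use a positive pseudocount_scale and a background with 0 < gc < 1"
        )
    return PWM(freq.motif_id, weights)


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact distribution of the PWM score of a random background L-mer.

    Scores are discretized to an integer grid (``round(score * resolution)``)
    and the distribution is the full convolution over motif columns, so tail
    probabilities are exact up to discretization.
    """

    resolution: int
    min_score: int          # integer grid value of the smallest score
    probs: np.ndarray       # probs[i] = P(score grid == min_score + i)

    @property
    def scores(self) -> np.ndarray:
        """Integer grid scores, ascending."""
        return self.min_score + np.arange(len(self.probs))

    @property
    def tail(self) -> np.ndarray:
        """tail[i] = P(score grid >= scores[i])."""
        return self.probs[::-1].cumsum()[::-1]

    def tail_at(self, score: float) -> float:
        """P(discretized score >= round(score * resolution))."""
        grid = int(round(score * self.resolution))
        i = grid - self.min_score
        if i <= 0:
            return 1.0
        if i >= len(self.probs):
            return 0.0
        return float(self.tail[i])


def score_distribution(pwm: PWM, bg: Background, resolution: int = 1000) -> ScoreDistribution:
    """Exact background score distribution by column-wise convolution.

    Runs in O(L * score-range) independent of 4**L: each column contributes a
    4-atom distribution which is convolved into the running distribution.
    """
    if resolution < 1:
        raise MotifError("resolution must be >= 1")
    grid = np.rint(pwm.weights * resolution).astype(np.int64)
    b = bg.probs
    probs = np.array([1.0])
    lo = 0
    for j in range(pwm.length):
        col = grid[:, j]
        cmin = int(col.min())
        cmax = int(col.max())
        new = np.zeros(len(probs) + (cmax - cmin), dtype=float)
        for base in range(4):
            if b[base] == 0.0:
                continue
            off = int(col[base]) - cmin
            new[off : off + len(probs)] += b[base] * probs
        probs = new
        lo += cmin
    return ScoreDistribution(resolution=resolution, min_score=lo, probs=probs)


def threshold_for_pvalue(dist: ScoreDistribution, p: float) -> float:
    """Smallest score t (in log-odds units) with P(score >= t) <= p.

    Site calls are windows scoring ``>= t``. Raises
    :class:`UnreachablePValueError` when even the maximum attainable score
    has a tail probability above ``p``.
    """
    if not 0.0 < p < 1.0:
        raise MotifError(f"p must be in (0, 1), got {p}")
    tail = dist.tail
    ok = tail <= p
    if not ok.any():
        raise UnreachablePValueError(p, float(tail[-1]))
    i = int(np.argmax(ok))
    return float(dist.scores[i]) / dist.resolution


@dataclass(frozen=True)
class ExactSiteSet:
    """A named set of exact-site IUPAC patterns to remove."""

    motif_id: str
    patterns: tuple[str, ...]

    def __post_init__(self):
        pats = tuple(p.upper() for p in self.patterns)
        for p in pats:
            if len(p) < 1:
                raise MotifError(f"{self.motif_id}: empty site pattern")
            for ch in p:
                if ch not in IUPAC_CODES:
                    raise MotifError(
                        f"{self.motif_id}: {ch!r} is not an IUPAC nucleotide code"
                    )
        object.__setattr__(self, "patterns", pats)


@dataclass(frozen=True)
class CalibratedPWM:
    """A PWM paired with its calibrated score threshold and the p-value used."""

    pwm: PWM
    threshold: float
    pvalue: float

    def __post_init__(self):
        if self.threshold > self.pwm.max_score + 1e-9:
            raise MotifError(
                f"{self.pwm.motif_id}: threshold {self.threshold:g} exceeds "
                f"maximum attainable score {self.pwm.max_score:g}"
            )


@dataclass(frozen=True)
class MotifLibrary:
    """Everything to remove: exact-site sets plus calibrated PWMs."""

    exact_sets: tuple[ExactSiteSet, ...] = ()
    pwms: tuple[CalibratedPWM, ...] = ()

    def __post_init__(self):
        ids = [s.motif_id for s in self.exact_sets] + [c.pwm.motif_id for c in self.pwms]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise MotifError(f"duplicate motif ids in library: {sorted(dupes)}")
        object.__setattr__(self, "exact_sets", tuple(self.exact_sets))
        object.__setattr__(self, "pwms", tuple(self.pwms))

    @property
    def motif_ids(self) -> list[str]:
        return [s.motif_id for s in self.exact_sets] + [c.pwm.motif_id for c in self.pwms]

    def __len__(self) -> int:
        return len(self.exact_sets) + len(self.pwms)

    @staticmethod
    def build(
        matrices: Iterable[FrequencyMatrix] = (),
        site_sets: Iterable[ExactSiteSet] = (),
        *,
        bg: Background,
        pvalue: float = 0.003,
        pseudocount_scale: float = 1.0,
        resolution: int = 1000,
    ) -> "MotifLibrary":
        """Assemble a library, converting and calibrating every matrix."""
        calibrated = []
        for freq in matrices:
            pwm = frequency_to_pwm(freq, bg, pseudocount_scale)
            dist = score_distribution(pwm, bg, resolution)
            t = threshold_for_pvalue(dist, pvalue)
            calibrated.append(CalibratedPWM(pwm=pwm, threshold=t, pvalue=pvalue))
        return MotifLibrary(exact_sets=tuple(site_sets), pwms=tuple(calibrated))


# ---------------------------------------------------------------------------
# motif file parsing


_NUMERIC_ROW = re.compile(r"^[\d.eE+\-\s\[\]]+$")


def _strip_comment(line: str) -> str:
    return line.split("#", 1)[0].rstrip()


def _parse_count_row(raw: str, lineno: int, motif_id: str) -> tuple[str | None, list[float]]:
    """Parse one matrix row, returning (optional base label, counts)."""
    text = raw.strip()
    label = None
    m = re.match(r"^([ACGTacgt])[\s:|]", text)
    if m:
        label = m.group(1).upper()
        text = text[m.end():]
    text = text.replace("[", " ").replace("]", " ")
    try:
        values = [float(tok) for tok in text.split()]
    except ValueError:
        raise MotifError(f"line {lineno}: cannot parse matrix row: {raw.strip()!r}")
    if any(v < 0 for v in values):
        raise MotifError(f"line {lineno}: negative count in motif {motif_id!r}")
    return label, values


def _rows_to_matrix(
    motif_id: str, rows: list[tuple[int, str | None, list[float]]]
) -> FrequencyMatrix:
    if len(rows) != 4:
        lineno = rows[0][0] if rows else 0
        raise MotifError(
            f"line {lineno}: motif {motif_id!r} has {len(rows)} rows, expected 4"
        )
    lengths = {len(vals) for _, _, vals in rows}
    if len(lengths) != 1:
        raise MotifError(
            f"line {rows[0][0]}: motif {motif_id!r} rows have unequal lengths"
        )
    labels = [lab for _, lab, _ in rows]
    counts = np.array([vals for _, _, vals in rows], dtype=float)
    if all(lab is not None for lab in labels):
        if sorted(labels) != list("ACGT"):
            raise MotifError(
                f"line {rows[0][0]}: motif {motif_id!r} row labels {labels} "
                "are not a permutation of A, C, G, T"
            )
        order = [labels.index(b) for b in "ACGT"]
        counts = counts[order]
    elif any(lab is not None for lab in labels):
        raise MotifError(
            f"line {rows[0][0]}: motif {motif_id!r} mixes labeled and "
            "unlabeled rows"
        )
    # unlabeled rows are taken in A, C, G, T order by convention
    return FrequencyMatrix(motif_id=motif_id, counts=counts)


def parse_motif_file(
    path: str | Path,
) -> tuple[list[FrequencyMatrix], list[ExactSiteSet]]:
    """Parse a motif file, auto-detecting its dialect.

    Three dialects are recognized:

    a. JASPAR-style: ``>id`` header followed by 4 count rows, optionally
       labeled A/C/G/T and optionally bracketed;
    b. headerless 4-row whitespace table (rows in A, C, G, T order), one
       matrix per file;
    c. exact-sites list: one IUPAC site per line, optionally ``id<TAB>site``;
       ``#`` comments allowed everywhere.

    Returns the frequency matrices and exact-site sets found (one of the two
    lists is always empty — a file holds matrices or sites, not both).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    content = [
        (i + 1, _strip_comment(line))
        for i, line in enumerate(lines)
        if _strip_comment(line).strip()
    ]
    if not content:
        raise MotifError(f"{path}: no motif content found")

    if any(text.lstrip().startswith(">") for _, text in content):
        return _parse_jaspar(content), []

    def is_numeric(text: str) -> bool:
        probe = re.sub(r"^[ACGTacgt][\s:|]", "", text.strip())
        probe = probe.replace("[", " ").replace("]", " ").strip()
        return bool(probe) and bool(_NUMERIC_ROW.match(probe))

    if all(is_numeric(text) for _, text in content):
        rows = [
            (lineno, *_parse_count_row(text, lineno, path.stem))
            for lineno, text in content
        ]
        # a transposed (positions-as-rows) 4-column table is accepted only
        # when unambiguous, i.e. the row count is not 4
        if len(rows) != 4 and all(len(vals) == 4 for _, _, vals in rows):
            counts = np.array([vals for _, _, vals in rows], dtype=float).T
            if (counts < 0).any():
                raise MotifError(f"{path}: negative counts")
            return [FrequencyMatrix(motif_id=path.stem, counts=counts)], []
        return [_rows_to_matrix(path.stem, rows)], []

    return [], _parse_sites(content, path.stem)


def _parse_jaspar(content: list[tuple[int, str]]) -> list[FrequencyMatrix]:
    matrices: list[FrequencyMatrix] = []
    motif_id: str | None = None
    rows: list[tuple[int, str | None, list[float]]] = []

    def flush():
        nonlocal rows
        if motif_id is not None:
            matrices.append(_rows_to_matrix(motif_id, rows))
        rows = []

    for lineno, text in content:
        stripped = text.strip()
        if stripped.startswith(">"):
            flush()
            motif_id = stripped[1:].split()[0] if stripped[1:].split() else stripped[1:]
            if not motif_id:
                raise MotifError(f"line {lineno}: empty motif header")
        else:
            if motif_id is None:
                raise MotifError(f"line {lineno}: matrix row before any '>' header")
            label, values = _parse_count_row(text, lineno, motif_id)
            rows.append((lineno, label, values))
    flush()
    ids = [m.motif_id for m in matrices]
    if len(set(ids)) != len(ids):
        raise MotifError(f"duplicate motif ids in file: {ids}")
    return matrices


def _parse_sites(content: list[tuple[int, str]], default_id: str) -> list[ExactSiteSet]:
    grouped: dict[str, list[str]] = {}
    for lineno, text in content:
        parts = text.strip().split("\t")
        if len(parts) == 2:
            motif_id, site = parts[0].strip(), parts[1].strip()
        elif len(parts) == 1:
            motif_id, site = default_id, parts[0].strip()
        else:
            raise MotifError(f"line {lineno}: expected 'site' or 'id<TAB>site'")
        for ch in site.upper():
            if ch not in IUPAC_CODES:
                raise MotifError(
                    f"line {lineno}: {ch!r} is not an IUPAC nucleotide code"
                )
        grouped.setdefault(motif_id, []).append(site.upper())
    return [
        ExactSiteSet(motif_id=mid, patterns=tuple(sites))
        for mid, sites in grouped.items()
    ]
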