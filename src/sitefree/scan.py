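"""Binding-site detection on both strands.

Every window/strand match counts as one hit: overlapping hits are all
reported, and a palindromic pattern yields one hit per strand at the same
interval. This double-count convention keeps the optimizer's objective N a
simple monotone sum; it is documented so users can interpret N.

Coordinates are always 0-based half-open on the forward strand, whichever
strand the hit is on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from sitefree.motifs import (
    BASE_INDEX,
    IUPAC_CODES,
    CalibratedPWM,
    ExactSiteSet,
    MotifLibrary,
    PWM,
    revcomp,
)


class ScanError(ValueError):
    """Invalid scanner input (e.g. non-ACGT bases)."""


@dataclass(frozen=True, order=True)
class SiteHit:
    """One detected binding site, forward-strand coordinates."""

    start: int
    end: int
    strand: str
    motif_id: str
    score: Optional[float] = None

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ScanError(f"bad hit interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ScanError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class ScanReport:
    """All hits in a sequence plus the summaries the optimizer consumes."""

    hits: list[SiteHit] = field(default_factory=list)

    @property
    def N(self) -> int:
        """Total hit count (the optimization objective)."""
        return len(self.hits)

    @property
    def mean_affinity(self) -> float:
        """Mean log-odds score over PWM hits; 0.0 when there are none."""
        scores = [h.score for h in self.hits if h.score is not None]
        return float(np.mean(scores)) if scores else 0.0


def encode(seq: str) -> np.ndarray:
    """Map an A/C/G/T string to an integer index array."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for base, i in BASE_INDEX.items():
        lut[ord(base)] = i
    idx = lut[arr]
    if (idx == 255).any():
        bad = seq[int(np.argmax(idx == 255))]
        raise ScanError(f"non-ACGT base {bad!r} in sequence")
    return idx.astype(np.intp)


def _iupac_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping and self-overlapping occurrences all match
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else "[" + IUPAC_CODES[c] + "]"
        for c in pattern.upper()
    )
    return re.compile(f"(?=({body}))")


def scan_exact(
    seq: str, sites: ExactSiteSet, both_strands: bool = True
) -> list[SiteHit]:
    """All occurrences of an exact-site set, forward coordinates.

    A minus-strand hit is a forward window equal to the reverse complement of
    a pattern. Overlapping occurrences are all reported.
    """
    encode(seq)  # validates the alphabet
    hits: list[SiteHit] = []
    for pattern in sites.patterns:
        for strand, pat in (("+", pattern), ("-", revcomp(pattern))):
            if not both_strands and strand == "-":
                continue
            for m in _iupac_regex(pat).finditer(seq):
                hits.append(
                    SiteHit(
                        start=m.start(),
                        end=m.start() + len(pat),
                        strand=strand,
                        motif_id=sites.motif_id,
                    )
                )
    return sorted(hits)


def _window_scores(idx: np.ndarray, pwm: PWM) -> np.ndarray:
    L = pwm.length
    if len(idx) < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    return pwm.weights[windows, np.arange(L)].sum(axis=1)


def scan_pwm(
    seq: str, pwm: PWM, threshold: float, both_strands: bool = True
) -> list[SiteHit]:
    """All windows scoring at or above the threshold, on either strand.

    The minus-strand score of a window is the forward score of its reverse
    complement, computed by scoring with the reverse-complement PWM.
    """
    idx = encode(seq)
    L = pwm.length
    hits: list[SiteHit] = []
    # tiny epsilon guards against float jitter in "score >= threshold"
    eps = 1e-9
    fwd = _window_scores(idx, pwm)
    for i in np.flatnonzero(fwd >= threshold - eps):
        hits.append(SiteHit(int(i), int(i) + L, "+", pwm.motif_id, float(fwd[i])))
    if both_strands:
        rev = _window_scores(idx, pwm.reverse_complement())
        for i in np.flatnonzero(rev >= threshold - eps):
            hits.append(SiteHit(int(i), int(i) + L, "-", pwm.motif_id, float(rev[i])))
    return sorted(hits)


def scan_all(
    seq: str,
    library: MotifLibrary,
    mask: Optional[np.ndarray] = None,
    both_strands: bool = True,
) -> ScanReport:
    """Union of all exact and PWM hits, optionally restricted by a mask.

    ``mask`` is a boolean array over sequence positions marking mutable
    coordinates. When given, hits with no position inside the mask are
    excluded from the report entirely — they are unremovable by construction,
    so counting them would make a zero objective unreachable.
    """
    hits: list[SiteHit] = []
    for sites in library.exact_sets:
        hits.extend(scan_exact(seq, sites, both_strands))
    for cal in library.pwms:
        hits.extend(scan_pwm(seq, cal.pwm, cal.threshold, both_strands))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != len(seq):
            raise ScanError(
                f"mask length {len(mask)} != sequence length {len(seq)}"
            )
        cum = np.concatenate([[0], np.cumsum(mask)])
        hits = [h for h in hits if cum[h.end] - cum[h.start] > 0]
    return ScanReport(hits=sorted(hits))
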