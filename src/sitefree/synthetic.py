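"""Deterministic generators of toy motifs and planted-site sequences.

Everything here is a pure function of its RNG, so the whole test surface —
and any user experiment — runs with zero downloads. Toy motif lengths
default to 6-8 bp so exhaustive 4**L cross-checks stay fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from sitefree.motifs import BASES, ExactSiteSet, FrequencyMatrix
from sitefree.scan import SiteHit
from sitefree.workflows import random_sequence


def toy_pwm(
    length: int,
    sharpness: float,
    rng: np.random.Generator,
    motif_id: str = "toy",
    total: float = 100.0,
) -> FrequencyMatrix:
    """Random frequency matrix interpolating uniform -> single-base columns.

    ``sharpness`` 0 gives a zero-information matrix (all columns uniform);
    1 gives a consensus-only matrix where exactly one word attains the
    maximum score. The consensus word is drawn from the RNG.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= sharpness <= 1.0:
        raise ValueError("sharpness must be in [0, 1]")
    consensus = rng.integers(4, size=length)
    counts = np.full((4, length), (1.0 - sharpness) * total / 4.0)
    counts[consensus, np.arange(length)] += sharpness * total
    return FrequencyMatrix(motif_id=motif_id, counts=counts)


def exact_library_patterns(
    n: int, length: int, rng: np.random.Generator
) -> list[str]:
    """n distinct random concrete site strings of a given length."""
    seen: set[str] = set()
    while len(seen) < n:
        word = "".join(BASES[i] for i in rng.integers(4, size=length))
        seen.add(word)
    return sorted(seen)


@dataclass(frozen=True)
class PlantedSequence:
    """A background sequence with known sites written at known positions."""

    sequence: str
    planted: tuple[SiteHit, ...]


def plant_sites(
    background_len: int,
    sites: Sequence[str],
    positions: Sequence[int],
    gc: float,
    rng: np.random.Generator,
) -> PlantedSequence:
    """Write the given site strings into a random background.

    Later plants overwrite earlier ones where they overlap. Re-scanning the
    result finds at least the planted hits; spontaneous background hits may
    add more.
    """
    if len(sites) != len(positions):
        raise ValueError("sites and positions must have equal length")
    chars = list(random_sequence(background_len, gc, rng))
    planted = []
    for site, pos in zip(sites, positions):
        if pos < 0 or pos + len(site) > background_len:
            raise ValueError(
                f"plant [{pos}, {pos + len(site)}) outside sequence of "
                f"length {background_len}"
            )
        chars[pos : pos + len(site)] = list(site.upper())
        planted.append(
            SiteHit(start=pos, end=pos + len(site), strand="+", motif_id=site.upper())
        )
    return PlantedSequence(sequence="".join(chars), planted=tuple(planted))


def write_sites_file(path: str | Path, patterns: Sequence[str]) -> None:
    """Emit an exact-sites file (one IUPAC pattern per line)."""
    Path(path).write_text("".join(f"{p}\n" for p in patterns))


def write_matrix_file(path: str | Path, matrices: Sequence[FrequencyMatrix]) -> None:
    """Emit a JASPAR-style motif file with labeled, bracketed count rows."""
    lines = []
    for m in matrices:
        lines.append(f">{m.motif_id}")
        for base, row in zip(BASES, m.counts):
            body = " ".join(f"{v:g}" for v in row)
            lines.append(f"{base} [ {body} ]")
    Path(path).write_text("\n".join(lines) + "\n")
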