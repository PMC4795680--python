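"""Standard-format I/O: FASTA, BED6 hit reports, trajectory TSV, JSON summary."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from sitefree.engine import TrajectoryPoint
from sitefree.motifs import Background, IUPAC_CODES, BASES, MotifLibrary
from sitefree.scan import SiteHit


class IOError_(ValueError):
    """Malformed sequence input."""


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) records; sequences uppercased.

    Duplicate record ids and empty files are rejected; character validation
    is deferred to the consumer (ambiguity codes may be legal, see
    :func:`resolve_ambiguous`).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise IOError_(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise IOError_(f"{path}: duplicate record ids {sorted(dupes)}")
    return [(r.id, str(r.seq).upper()) for r in records]


def write_fasta(path: str | Path, records: Sequence[tuple[str, str]]) -> None:
    """Write records with 60-column line wrapping (round-trip stable)."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def resolve_ambiguous(seq: str, bg: Background, rng: np.random.Generator) -> str:
    """Replace IUPAC ambiguity codes by background draws over the allowed bases.

    Each ambiguous position is drawn from the background distribution
    restricted (and renormalized) to the bases the code permits; reproducible
    given the RNG state.
    """
    out = []
    probs = bg.probs
    for ch in seq.upper():
        if ch in "ACGT":
            out.append(ch)
            continue
        if ch not in IUPAC_CODES:
            raise IOError_(f"character {ch!r} is not an IUPAC nucleotide code")
        allowed = [BASES.index(b) for b in IUPAC_CODES[ch]]
        p = probs[allowed]
        total = p.sum()
        if total == 0:
            p = np.full(len(allowed), 1.0 / len(allowed))
        else:
            p = p / total
        out.append(BASES[allowed[int(rng.choice(len(allowed), p=p))]])
    return "".join(out)


def _bed_score(hit: SiteHit, library: Optional[MotifLibrary]) -> int:
    """BED score column: exact hits 1000; PWM hits rescaled threshold..max."""
    if hit.score is None:
        return 1000
    if library is not None:
        for cal in library.pwms:
            if cal.pwm.motif_id == hit.motif_id:
                span = cal.pwm.max_score - cal.threshold
                if span <= 0:
                    return 1000
                frac = (hit.score - cal.threshold) / span
                return int(round(1000 * min(1.0, max(0.0, frac))))
    return int(min(1000, max(0, round(hit.score * 100))))


def write_hit_report(
    path: str | Path,
    record_name: str,
    hits: Sequence[SiteHit],
    library: Optional[MotifLibrary] = None,
) -> None:
    """BED6 hit table plus a sidecar TSV with raw log-odds scores.

    The sidecar is written next to ``path`` with a ``.scores.tsv`` suffix.
    """
    path = Path(path)
    with path.open("w") as bed:
        for h in sorted(hits):
            bed.write(
                f"{record_name}\t{h.start}\t{h.end}\t{h.motif_id}\t"
                f"{_bed_score(h, library)}\t{h.strand}\n"
            )
    sidecar = path.with_suffix(path.suffix + ".scores.tsv")
    with sidecar.open("w") as tsv:
        tsv.write("record\tstart\tend\tmotif_id\tstrand\traw_score\n")
        for h in sorted(hits):
            score = "" if h.score is None else f"{h.score:.6f}"
            tsv.write(
                f"{record_name}\t{h.start}\t{h.end}\t{h.motif_id}\t{h.strand}\t{score}\n"
            )


def write_trajectory(path: str | Path, trajectory: Sequence[TrajectoryPoint]) -> None:
    """Per-iteration TSV: iteration, N, accepted (0/1), Pa."""
    with Path(path).open("w") as tsv:
        tsv.write("iteration\tN\taccepted\tPa\n")
        for pt in trajectory:
            tsv.write(f"{pt.iteration}\t{pt.n}\t{int(pt.accepted)}\t{pt.pa:.6f}\n")


def write_summary(path: str | Path, summary: dict) -> None:
    """JSON run summary; holds seed + full config echo for reproducibility."""
    with Path(path).open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
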