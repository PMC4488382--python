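"""Tripeptide-motif screening of predicted proteomes.

The screen that anchors the whole analysis: find proteins carrying a short
peptide (FYY by default, the coelenterazine precursor tripeptide), either
anywhere in the sequence or, more stringently, as the C-terminal suffix of
the mature protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .seqio import PROTEIN_ALPHABET, Proteome, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = ["MotifSpec", "MotifHit", "ScreenSummary", "scan_sequence", "scan_proteome"]


@dataclass(frozen=True)
class MotifSpec:
    """A short exact peptide pattern with a positional mode.

    'X' in the pattern is a wildcard matching any residue; an 'X' in the
    *target* sequence never matches a concrete pattern residue
    (unknown residues are treated conservatively).
    """

    pattern: str
    mode: str = "any"  # any | c_terminal | n_terminal

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError("motif pattern must have length >= 2")
        bad = set(self.pattern.upper()) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"invalid motif residues {sorted(bad)}")
        if self.mode not in ("any", "c_terminal", "n_terminal"):
            raise ValueError(f"unknown motif mode {self.mode!r}")


@dataclass(frozen=True)
class MotifHit:
    record_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    mode_matched: str


@dataclass
class ScreenSummary:
    n_records: int
    n_records_with_hit: int
    hits: list[MotifHit] = field(default_factory=list)


def _matches_at(seq: str, pattern: str, pos: int) -> bool:
    for k, p in enumerate(pattern):
        c = seq[pos + k]
        if p == "X":
            continue
        if c != p:  # 'X' in the target never matches a concrete residue
            return False
    return True


def scan_sequence(record: SequenceRecord, spec: MotifSpec) -> list[MotifHit]:
    """All motif occurrences in one protein, left to right.

    mode='any' reports every (possibly overlapping) occurrence;
    mode='c_terminal' / 'n_terminal' report at most one hit, requiring the
    pattern to be the suffix/prefix of the sequence (a single trailing '*'
    stop symbol is already stripped at record construction). Matching is
    case-insensitive. Records with internal stop symbols never reach this
    point (the record alphabet forbids them).
    """
    if record.moltype != "protein":
        raise ValueError(
            f"motif scan requires a protein record (got {record.moltype!r} "
            f"for {record.id!r}); translate first"
        )
    seq = record.seq.upper()
    pattern = spec.pattern.upper()
    m = len(pattern)
    if len(seq) < m:
        return []
    if spec.mode == "c_terminal":
        start = len(seq) - m
        if _matches_at(seq, pattern, start):
            return [MotifHit(record.id, start, len(seq), "c_terminal")]
        return []
    if spec.mode == "n_terminal":
        if _matches_at(seq, pattern, 0):
            return [MotifHit(record.id, 0, m, "n_terminal")]
        return []
    hits = []
    for pos in range(len(seq) - m + 1):
        if _matches_at(seq, pattern, pos):
            hits.append(MotifHit(record.id, pos, pos + m, "any"))
    return hits


def scan_proteome(proteome: Proteome, spec: MotifSpec) -> ScreenSummary:
    """Screen every record of a proteome; counts records, not occurrences.

    ``n_records_with_hit`` counts records with at least one hit, matching
    the convention of reporting gene products rather than motif copies.
    Records are processed in id order so output is deterministic.
    """
    if len(proteome) == 0:
        raise ValueError(f"proteome for {proteome.species!r} is empty")
    all_hits: list[MotifHit] = []
    n_with = 0
    for rec in sorted(proteome.records, key=lambda r: r.id):
        hits = scan_sequence(rec, spec)
        if hits:
            n_with += 1
            all_hits.extend(hits)
    return ScreenSummary(
        n_records=len(proteome), n_records_with_hit=n_with, hits=all_hits
    )
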