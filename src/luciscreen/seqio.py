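"""Sequence containers and readers/writers for the external file formats.

Everything downstream of this module works on four small containers:

* :class:`SequenceRecord` — one named protein or DNA sequence;
* :class:`Proteome` — the per-species collection of predicted proteins;
* :class:`MultipleAlignment` — a gapped sequence matrix with column homology;
* :class:`IdentityMatrix` — symmetric pairwise percent identities with an
  explicit gap convention;
* :class:`PhenotypeTable` — species → luminous yes/no.

FASTA parsing is delegated to :mod:`Bio.SeqIO` and Clustal parsing to
:mod:`Bio.AlignIO`; the identity-matrix TSV dialect mirrors the printed
lower-triangular tables ('=' on the diagonal, '-' in the mirrored triangle)
and is handled here directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")
GAP = "-"

__all__ = [
    "SequenceRecord",
    "Proteome",
    "MultipleAlignment",
    "IdentityMatrix",
    "PhenotypeTable",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_identity_matrix",
    "write_identity_matrix",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_position_table",
]


@dataclass
class SequenceRecord:
    """A named biological sequence.

    Parameters
    ----------
    id : str
        Unique label, e.g. ``ML199826a``. The token before the first
        whitespace of a FASTA header.
    seq : str
        Residue string. Protein sequences may end in a single ``*`` stop
        symbol which is stripped on construction and recorded in
        :attr:`had_stop`.
    moltype : {"protein", "dna"}
    species : str
        Free species tag; empty until the record joins a Proteome.
    description : str
        Remainder of the FASTA header after the id token.
    """

    id: str
    seq: str
    moltype: str = "protein"
    species: str = ""
    description: str = ""
    had_stop: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.moltype not in ("protein", "dna"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        if self.moltype == "protein" and self.seq.endswith("*"):
            self.seq = self.seq[:-1]
            self.had_stop = True
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        alphabet = PROTEIN_ALPHABET if self.moltype == "protein" else DNA_ALPHABET
        bad = set(self.seq.upper()) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters {sorted(bad)} "
                f"outside the {self.moltype} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Proteome:
    """Ordered collection of same-species protein records."""

    species: str
    records: list[SequenceRecord] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r} in proteome")
            seen.add(rec.id)
            rec.species = self.species

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)


@dataclass
class MultipleAlignment:
    """Gapped sequence matrix; rows are (id, gapped string) pairs."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            detail = ", ".join(f"{i}:{len(s)}" for i, s in self.rows)
            raise ValueError(f"ragged alignment rows ({detail})")
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, row_id: str) -> str:
        for i, s in self.rows:
            if i == row_id:
                return s
        raise KeyError(row_id)

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    def drop_all_gap_columns(self) -> "MultipleAlignment":
        keep = [
            c
            for c in range(self.n_columns)
            if any(s[c] != GAP for _, s in self.rows)
        ]
        return MultipleAlignment(
            [(i, "".join(s[c] for c in keep)) for i, s in self.rows]
        )

    def column(self, c: int) -> str:
        return "".join(s[c] for _, s in self.rows)


@dataclass
class IdentityMatrix:
    """Symmetric pairwise percent-identity matrix.

    ``convention`` records which denominator produced the values:
    ``ignore_gaps`` (identities / columns where both rows have residues) or
    ``include_gaps`` (identities / columns where at least one row has a
    residue). The diagonal is a self marker, not a value, and is stored as
    100 for convenience but excluded from all summaries.
    """

    labels: list[str]
    values: np.ndarray
    convention: str = "ignore_gaps"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("identity matrix must be symmetric")
        off = self.values[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 100):
            raise ValueError("identities must lie in [0, 100]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def pairwise_values(self) -> np.ndarray:
        """The n(n-1)/2 distinct off-diagonal values, row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class PhenotypeTable:
    """Species → luminous flag (True = luminous)."""

    flags: dict[str, bool]

    def __post_init__(self) -> None:
        if not self.flags:
            raise ValueError("phenotype table is empty")

    def luminous(self, species: str) -> bool:
        return self.flags[species]

    @property
    def species(self) -> list[str]:
        return list(self.flags)


# ---------------------------------------------------------------------------
# FASTA

def _guess_moltype(seq: str) -> str:
    return "dna" if set(seq.upper()) <= DNA_ALPHABET else "protein"


def read_fasta(path: str | Path, moltype: str = "auto") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    The header token before the first whitespace becomes the id; the
    remainder is kept as the description. ``moltype='auto'`` classifies each
    sequence as DNA when it uses only ACGTN, protein otherwise.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        seq = str(bio.seq).replace(" ", "")
        if not seq:
            raise ValueError(f"empty sequence under header {bio.id!r} in {path}")
        if bio.id in seen:
            raise ValueError(f"duplicate sequence id {bio.id!r} in {path}")
        seen.add(bio.id)
        mt = _guess_moltype(seq.rstrip("*")) if moltype == "auto" else moltype
        desc = bio.description[len(bio.id):].strip()
        records.append(SequenceRecord(id=bio.id, seq=seq, moltype=mt, description=desc))
    if not records:
        logger.warning("FASTA file %s contained no records", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Alignments

def read_alignment(path: str | Path, format: str = "aligned_fasta") -> MultipleAlignment:
    """Read a pre-computed MSA from aligned FASTA or Clustal.

    '.' gap characters are normalized to '-'. Clustal consensus lines are
    ignored by the parser. Ragged aligned-FASTA rows raise with the
    offending ids and lengths.
    """
    if format == "clustal":
        aln = AlignIO.read(str(path), "clustal")
        rows = [(r.id, str(r.seq).replace(".", GAP)) for r in aln]
        return MultipleAlignment(rows)
    if format != "aligned_fasta":
        raise ValueError(f"unknown alignment format {format!r}")
    recs = SeqIO.parse(str(path), "fasta")
    rows = [(r.id, str(r.seq).replace(".", GAP)) for r in recs]
    if not rows:
        raise ValueError(f"no alignment rows in {path}")
    return MultipleAlignment(rows)


def write_alignment(msa: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in msa.rows:
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# Identity matrices (printed-table TSV dialect)

def read_identity_matrix(path: str | Path, convention: str = "ignore_gaps") -> IdentityMatrix:
    """Read a TSV identity matrix in the printed-table dialect.

    Layout: header row of labels; each data row starts with its label;
    '=' marks the diagonal and '-' marks cells mirrored from the other
    triangle. Both lower-triangular and full-symmetric layouts are accepted;
    a full matrix whose two triangles disagree is an error, as is any
    missing pairwise cell.
    """
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    header = lines[0].split("\t")
    labels = [h for h in header[1:] if h]
    n = len(labels)
    vals = np.full((n, n), np.nan)
    np.fill_diagonal(vals, 100.0)
    if len(lines) - 1 != n:
        raise ValueError(f"expected {n} data rows, found {len(lines) - 1}")
    for i, ln in enumerate(lines[1:]):
        cells = ln.split("\t")
        if cells[0] != labels[i]:
            raise ValueError(
                f"row label {cells[0]!r} does not match header label {labels[i]!r}"
            )
        for j, cell in enumerate(cells[1 : n + 1]):
            cell = cell.strip()
            if cell in ("=", ""):
                continue
            if cell == "-":
                continue
            v = float(cell)
            if not np.isnan(vals[i, j]) and i != j and not np.isclose(vals[i, j], v):
                raise ValueError(
                    f"asymmetric matrix: ({labels[i]}, {labels[j]}) "
                    f"{v} vs {vals[i, j]}"
                )
            vals[i, j] = v
            if np.isnan(vals[j, i]):
                vals[j, i] = v
            elif i != j and not np.isclose(vals[j, i], v):
                raise ValueError(
                    f"asymmetric matrix: ({labels[i]}, {labels[j]}) "
                    f"{v} vs {vals[j, i]}"
                )
    missing = [
        (labels[i], labels[j])
        for i in range(n)
        for j in range(i + 1, n)
        if np.isnan(vals[i, j])
    ]
    if missing:
        raise ValueError(f"missing pairwise cells: {missing[:5]}")
    return IdentityMatrix(labels=labels, values=vals, convention=convention)


def write_identity_matrix(m: IdentityMatrix, path: str | Path) -> None:
    """Write the lower-triangular TSV dialect read by read_identity_matrix."""
    with open(path, "w") as fh:
        fh.write("\t".join([""] + m.labels) + "\n")
        for i, lab in enumerate(m.labels):
            cells = []
            for j in range(m.n):
                if j < i:
                    cells.append(_fmt(m.values[i, j]))
                elif j == i:
                    cells.append("=")
                else:
                    cells.append("-")
            fh.write("\t".join([lab] + cells) + "\n")


def _fmt(v: float) -> str:
    return f"{int(v)}" if float(v).is_integer() else f"{v:.2f}"


# ---------------------------------------------------------------------------
# Phenotype and position tables

def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    """TSV with columns species / luminous (Y|N, case-insensitive).

    A header row whose first cell is 'species' is skipped.
    """
    flags: dict[str, bool] = {}
    for ln in open(path):
        ln = ln.strip()
        if not ln:
            continue
        sp, flag = ln.split("\t")[:2]
        if sp.lower() == "species":
            continue
        if sp in flags:
            raise ValueError(f"species {sp!r} listed twice in phenotype table")
        fl = flag.strip().upper()
        if fl in ("Y", "YES", "1", "TRUE"):
            flags[sp] = True
        elif fl in ("N", "NO", "0", "FALSE"):
            flags[sp] = False
        else:
            raise ValueError(f"unparseable luminous flag {flag!r} for {sp!r}")
    return PhenotypeTable(flags)


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tluminous\n")
        for sp, fl in table.flags.items():
            fh.write(f"{sp}\t{'Y' if fl else 'N'}\n")


def read_position_table(path: str | Path) -> dict[str, list[tuple[int, str, str]]]:
    """Read catalytic-residue positions keyed by reference id.

    TSV columns: ref_id, position (1-based on the ungapped reference),
    expected residue, label.
    """
    out: dict[str, list[tuple[int, str, str]]] = {}
    for ln in open(path):
        ln = ln.strip()
        if not ln or ln.lower().startswith("ref_id"):
            continue
        ref, pos, res, label = ln.split("\t")[:4]
        out.setdefault(ref, []).append((int(pos), res.upper(), label))
    return out
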