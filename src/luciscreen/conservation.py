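"""Consensus rendering and catalytic-residue conservation mapping.

Non-heme Fe(II) oxidases of the IPNS/DAOCS superfamily coordinate their
iron through a 2-His-1-carboxylate facial triad and bind the 2-oxoglutarate
(or substrate carboxylate) through an R-x-S pair. In the reference protein
ML199826a those residues sit at H245/D247/H301 and R310-S312. This module
maps such 1-based reference positions through a family alignment and
reports, member by member, whether the triad and the RXS pair are intact.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import GAP, MultipleAlignment

__all__ = [
    "ResiduePositionSet",
    "ConservationReport",
    "consensus_line",
    "map_reference_positions",
    "check_family_conservation",
    "CLUSTAL_STRONG_GROUPS",
]

# ClustalX "strong" similarity groups used for the '.' consensus symbol
CLUSTAL_STRONG_GROUPS = [
    frozenset(g)
    for g in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
]

TRIAD_LABELS = ("iron_his1", "iron_asp", "iron_his2")
RXS_LABELS = ("rxs_arg", "rxs_ser")


@dataclass
class ResiduePositionSet:
    """1-based residue positions on an ungapped reference sequence."""

    ref_id: str
    positions: list[tuple[int, str, str]]  # (index, expected residue, label)

    def __post_init__(self) -> None:
        for idx, res, _ in self.positions:
            if idx < 1:
                raise ValueError(f"positions are 1-based; got {idx}")
            if res.upper() not in "ACDEFGHIKLMNPQRSTVWY":
                raise ValueError(f"invalid expected residue {res!r}")


@dataclass
class ConservationReport:
    ref_id: str
    columns: list[int]  # alignment column per mapped position
    labels: list[str]
    expected: list[str]
    observed: dict[str, list[str]]  # per member: residue at each column
    triad_intact: dict[str, bool]
    rxs_intact: dict[str, bool]
    partial: dict[str, bool]  # leading/trailing gap run covers a column


def consensus_line(msa: MultipleAlignment) -> str:
    """Clustal-style consensus: '*' where a column is one residue in every
    row (no gaps), '.' where all residues fall into one strong similarity
    group (gaps disqualify), ' ' otherwise."""
    out = []
    for c in range(msa.n_columns):
        col = msa.column(c).upper()
        if GAP in col:
            out.append(" ")
            continue
        residues = set(col)
        if len(residues) == 1:
            out.append("*")
        elif any(residues <= g for g in CLUSTAL_STRONG_GROUPS):
            out.append(".")
        else:
            out.append(" ")
    return "".join(out)


def _ref_columns(ref_row: str, positions: list[int]) -> list[int]:
    """Map 1-based ungapped residue indices to alignment columns."""
    cols = {}
    count = 0
    for c, ch in enumerate(ref_row):
        if ch != GAP:
            count += 1
            cols[count] = c
    out = []
    for p in positions:
        if p not in cols:
            raise ValueError(
                f"position {p} beyond ungapped reference length {count}"
            )
        out.append(cols[p])
    return out


def map_reference_positions(msa: MultipleAlignment, pset: ResiduePositionSet) -> ConservationReport:
    """Report every member's residue at each reference-anchored column.

    triad_intact requires H, D, H at the three iron-binding columns;
    rxs_intact requires R at the arginine column and S at the serine column
    (the middle position is unconstrained by definition). Members whose
    leading/trailing gap run covers a mapped column are marked partial.
    """
    if pset.ref_id not in msa.ids:
        raise ValueError(f"reference {pset.ref_id!r} not in alignment")
    ref_row = msa.row(pset.ref_id)
    cols = _ref_columns(ref_row, [p for p, _, _ in pset.positions])
    labels = [lab for _, _, lab in pset.positions]
    expected = [res.upper() for _, res, _ in pset.positions]

    observed: dict[str, list[str]] = {}
    triad: dict[str, bool] = {}
    rxs: dict[str, bool] = {}
    partial: dict[str, bool] = {}
    by_label = dict(zip(labels, cols))
    for rid, row in msa.rows:
        obs = [row[c].upper() for c in cols]
        observed[rid] = obs
        first = len(row) - len(row.lstrip(GAP))
        last = len(row.rstrip(GAP))  # exclusive end of residue span
        partial[rid] = any(c < first or c >= last for c in cols)
        got = dict(zip(labels, obs))
        if all(l in by_label for l in TRIAD_LABELS):
            triad[rid] = (
                got["iron_his1"] == "H"
                and got["iron_asp"] == "D"
                and got["iron_his2"] == "H"
            )
        if all(l in by_label for l in RXS_LABELS):
            rxs[rid] = got["rxs_arg"] == "R" and got["rxs_ser"] == "S"
    return ConservationReport(
        ref_id=pset.ref_id,
        columns=cols,
        labels=labels,
        expected=expected,
        observed=observed,
        triad_intact=triad,
        rxs_intact=rxs,
        partial=partial,
    )


def check_family_conservation(report: ConservationReport) -> dict:
    """Fractions of (non-partial) members with intact triad / RXS.

    Partial sequences are excluded from the denominators and listed; if
    every member is partial there is nothing to summarize and that is an
    error rather than a 0/0."""
    full = [rid for rid, isp in report.partial.items() if not isp]
    if not full:
        raise ValueError("all sequences are partial at the mapped columns")
    out = {
        "n_full": len(full),
        "partial_members": sorted(r for r, p in report.partial.items() if p),
    }
    if report.triad_intact:
        out["fraction_triad_intact"] = sum(
            report.triad_intact[r] for r in full
        ) / len(full)
    if report.rxs_intact:
        out["fraction_rxs_intact"] = sum(report.rxs_intact[r] for r in full) / len(full)
    return out
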