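"""Codon-level selection analysis: Nei-Gojobori (1986) dN/dS.

The counting estimator works directly on a codon alignment:

* every codon position contributes a synonymous-site fraction — of the
  three possible nucleotide changes at that position, the fraction that
  preserve the encoded amino acid, with changes to stop codons removed
  from both numerator and denominator;
* differences between two codons differing at k positions are averaged
  over all k! mutational orderings, skipping pathways that pass through a
  stop codon;
* proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits with
  the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).

omega = dN/dS < 1 indicates purifying selection. A proportion >= 3/4 is
saturated (the correction is undefined) and is flagged rather than
silently numeric; dS = 0 likewise flags the ratio as undefined, rendered
as 0 in table output to match the reporting convention for inadequate
comparisons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .seqio import MultipleAlignment, SequenceRecord

__all__ = ["CodonAlignment", "DnDsResult", "back_translate", "ng86_pair", "dnds_table"]

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
NUCS = "ACGT"
STOPS = frozenset(_TABLE.stop_codons)
CODONS = [a + b + c for a in NUCS for b in NUCS for c in NUCS]
SENSE_CODONS = [c for c in CODONS if c not in STOPS]
AA = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}
CODON_GAP = "---"


@dataclass
class CodonAlignment:
    """Rows of gapped codon strings; gaps are whole-codon '---'."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("codon alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1 or next(iter(lengths)) % 3:
            raise ValueError("codon rows must share a length divisible by 3")
        for rid, s in self.rows:
            for k in range(0, len(s), 3):
                codon = s[k : k + 3].upper()
                if codon in STOPS:
                    raise ValueError(f"internal stop codon in {rid!r} at codon {k // 3}")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0][1]) // 3

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, rid: str) -> str:
        for i, s in self.rows:
            if i == rid:
                return s
        raise KeyError(rid)


@dataclass
class DnDsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # nan when saturated
    dN: float
    omega: float  # nan when undefined (dS == 0 or saturation)
    n_codons: int
    flags: dict = field(default_factory=dict)

    @property
    def omega_display(self) -> float:
        """Ratio rendered with undefined values as 0 (table convention for
        comparisons the model could not evaluate)."""
        return 0.0 if math.isnan(self.omega) else self.omega


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Synonymous-site count of one codon (sum of per-position fractions)."""
    total = 0.0
    aa = AA[codon]
    for pos in range(3):
        syn = valid = 0
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOPS:
                continue  # mutations to stops excluded from both counts
            valid += 1
            if AA[alt] == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


@lru_cache(maxsize=None)
def _pair_diffs(c1: str, c2: str) -> tuple[float, float, bool]:
    """(Sd, Nd, used_fallback) between two sense codons, averaging over all
    orderings of the differing positions; pathways through stops are
    skipped. If every pathway hits a stop, positions are counted by direct
    single-site comparison and the fallback flag is set."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0, False
    path_scores = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if AA[cur] == AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            path_scores.append((sd, nd))
    if path_scores:
        sd = sum(s for s, _ in path_scores) / len(path_scores)
        nd = sum(n for _, n in path_scores) / len(path_scores)
        return sd, nd, False
    # all pathways pass through stops: count sites one at a time
    sd = nd = 0.0
    for pos in diff:
        alt = c1[:pos] + c2[pos] + c1[pos + 1 :]
        if alt not in STOPS and AA[alt] == AA[c1]:
            sd += 1
        else:
            nd += 1
    return sd, nd, True


def _jc(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pair(row_a: str, row_b: str) -> DnDsResult:
    """NG86 estimate for one pair of (possibly gapped) codon rows.

    Codon columns where either row is gapped or contains an ambiguous base
    are excluded. Symmetric in its arguments.
    """
    a, b = row_a.upper(), row_b.upper()
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("codon rows must share a length divisible by 3")
    cod_a, cod_b = [], []
    for k in range(0, len(a), 3):
        ca, cb = a[k : k + 3], b[k : k + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if ca in STOPS or cb in STOPS:
            raise ValueError(f"stop codon in compared column {k // 3}")
        cod_a.append(ca)
        cod_b.append(cb)
    L = len(cod_a)
    if L == 0:
        raise ValueError("no comparable codons between the two rows")

    S = 0.5 * (sum(_syn_sites(c) for c in cod_a) + sum(_syn_sites(c) for c in cod_b))
    N = 3.0 * L - S
    Sd = Nd = 0.0
    flags: dict[str, bool] = {}
    for ca, cb in zip(cod_a, cod_b):
        sd, nd, fb = _pair_diffs(ca, cb)
        Sd += sd
        Nd += nd
        if fb:
            flags["stop_pathway_fallback"] = True
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dN = _jc(pS), _jc(pN)
    if Sd == 0 and Nd == 0:
        flags["identical"] = True
    if math.isnan(dS):
        flags["saturated_dS"] = True
    if math.isnan(dN):
        flags["saturated_dN"] = True
    if dS == 0:
        flags["dS_zero"] = True
    omega = float("nan")
    if not math.isnan(dS) and not math.isnan(dN) and dS > 0:
        omega = dN / dS
    return DnDsResult(S, N, Sd, Nd, pS, pN, dS, dN, omega, L, flags)


def back_translate(protein_msa: MultipleAlignment, cds_records: list[SequenceRecord]) -> CodonAlignment:
    """Expand a protein alignment to codons using each row's source CDS.

    Each protein row must have a CDS whose standard-code translation
    (trailing stop allowed) equals the ungapped protein; 'X' residues match
    any codon. Gaps become '---'; a trailing stop codon is dropped.
    """
    cds_by_id = {r.id: r for r in cds_records}
    rows = []
    for rid, prow in protein_msa.rows:
        if rid not in cds_by_id:
            raise ValueError(f"no CDS provided for {rid!r}")
        cds = cds_by_id[rid].seq.upper()
        prot = prow.replace("-", "").upper()
        if len(cds) == 3 * len(prot) + 3 and cds[-3:] in STOPS:
            cds = cds[:-3]
        if len(cds) != 3 * len(prot):
            raise ValueError(
                f"CDS length for {rid!r} is {len(cds_by_id[rid].seq)}, "
                f"expected 3x{len(prot)} (+ optional stop)"
            )
        trans = str(Seq(cds).translate())
        for k, (p, t) in enumerate(zip(prot, trans)):
            if p != t and p != "X":
                raise ValueError(
                    f"translation mismatch for {rid!r} at residue {k}: "
                    f"protein {p!r} vs CDS {t!r}"
                )
        out, i = [], 0
        for ch in prow:
            if ch == "-":
                out.append(CODON_GAP)
            else:
                out.append(cds[3 * i : 3 * i + 3])
                i += 1
        rows.append((rid, "".join(out)))
    return CodonAlignment(rows)


def dnds_table(aln: CodonAlignment, reference_ids: list[str]) -> pd.DataFrame:
    """One NG86 row per (reference, other) pair, mirroring the layout of a
    per-gene substitution-rate table. Undefined dN/dS values are rendered 0
    in the omega column; machine-readable flags are preserved alongside.
    Per-cell failures are recorded, not raised."""
    ids = aln.ids
    unknown = set(reference_ids) - set(ids)
    if unknown:
        raise ValueError(f"reference ids not in alignment: {sorted(unknown)}")
    rows = []
    for ref in reference_ids:
        for other in ids:
            if other == ref:
                continue
            rec = {"reference": ref, "other": other}
            try:
                r = ng86_pair(aln.row(ref), aln.row(other))
                rec.update(
                    S=r.S, N=r.N, Sd=r.Sd, Nd=r.Nd,
                    dS=0.0 if math.isnan(r.dS) else r.dS,
                    dN=0.0 if math.isnan(r.dN) else r.dN,
                    omega=r.omega_display,
                    flags=";".join(sorted(r.flags)) or "",
                )
            except ValueError as err:
                rec.update(S=float("nan"), N=float("nan"), Sd=float("nan"),
                           Nd=float("nan"), dS=float("nan"), dN=float("nan"),
                           omega=float("nan"), flags=f"error:{err}")
            rows.append(rec)
    return pd.DataFrame(rows)
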