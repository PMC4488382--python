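"""Synthetic-data generation: species trees, codon evolution, and a full
synthetic screening study.

The generator reproduces the statistical structure the analysis assumes:

* a Yule species tree over ~20 luminous and 2 non-luminous taxa, scaled to
  unit root-to-tip depth (branch lengths are then expected substitutions
  per codon);
* one highly conserved candidate gene family evolving under strong
  purifying selection (omega = 0.1 by default) whose proteins end in a
  fixed tripeptide motif and carry a locked 2-His-1-carboxylate triad and
  RXS pair, present only in luminous species;
* two more divergent paralog families (omega = 0.3 and 0.5) present in all
  species;
* decoy proteins carrying the motif internally in every species, so an
  anywhere-in-sequence screen fires everywhere but a C-terminal screen
  fires only in luminous species.

Codon evolution is an exact Gillespie simulation per codon: the rate of a
single-nucleotide codon change is kappa^[transition] * omega^[nonsynonymous]
* pi(target nucleotide), changes to stop codons are forbidden, and rates
are normalized so branch lengths are expected substitutions per codon
at the family's own omega. Every substitution event is logged, which makes
the simulation usable as an oracle: between a leaf and the root, NG86
counting can miss events only through multiple hits at one codon.

Per-branch random streams are split from the master seed keyed by the CRC32
of the sorted leaf labels below the branch, so adding taxa elsewhere in the
tree does not perturb existing lineages. Non-candidate families and decoys
carry a pinned non-aromatic final residue, so no sequence outside the
candidate family can ever end in the motif, whatever the seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .phylo import newick_string
from .seqio import (
    PhenotypeTable,
    Proteome,
    SequenceRecord,
    write_fasta,
    write_phenotype_table,
)
from .selection import AA, NUCS, SENSE_CODONS, STOPS

__all__ = [
    "EvolutionParams",
    "StudyConfig",
    "SyntheticTruth",
    "simulate_tree",
    "evolve_codons",
    "generate_study",
    "load_study_proteomes",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class EvolutionParams:
    """Codon substitution parameters.

    codon_frequencies: 'uniform', 'f3x4' (positional nucleotide frequencies
    estimated from the root CDS), or an explicit (3, 4) array of positional
    frequencies in ACGT order. invariant_sites are 0-based codon positions
    that never substitute (locked catalytic residues).
    """

    omega: float = 0.1
    kappa: float = 2.0
    codon_frequencies: object = "f3x4"
    invariant_sites: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        self.invariant_sites = frozenset(self.invariant_sites)


@dataclass
class SubstitutionEvent:
    branch: str  # key of the child-side node
    codon_index: int
    position: int  # 0..2 within the codon
    from_codon: str
    to_codon: str
    synonymous: bool


@dataclass
class EvolveResult:
    leaf_cds: dict[str, str]
    events: list["SubstitutionEvent"]

    def branch_counts(self) -> dict[str, tuple[int, int]]:
        """Per-branch (synonymous, nonsynonymous) event counts."""
        out: dict[str, tuple[int, int]] = {}
        for ev in self.events:
            s, n = out.get(ev.branch, (0, 0))
            out[ev.branch] = (s + ev.synonymous, n + (not ev.synonymous))
        return out


def simulate_tree(
    n_taxa: int,
    seed: int,
    model: str = "yule",
    labels: list[str] | None = None,
) -> dendropy.Tree:
    """Yule (pure-birth, rate 1) ultrametric tree rescaled to unit depth.

    Deterministic under seed; binary with ``n_taxa`` leaves, all at
    root-to-tip depth exactly 1. Leaves are labeled sp01, sp02, ... in
    preorder unless ``labels`` is given.
    """
    if model != "yule":
        raise ValueError(f"unknown tree model {model!r}")
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)

    class _N:
        __slots__ = ("birth", "children")

        def __init__(self, birth: float):
            self.birth = birth
            self.children: list["_N"] = []

    root = _N(0.0)
    active = [root]
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(k)))
        node.children = [_N(t), _N(t)]
        active.extend(node.children)
    t_end = t + rng.exponential(1.0 / n_taxa)

    if labels is None:
        labels = [f"sp{i + 1:02d}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ValueError("label count must equal n_taxa")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    t_first = root.children[0].birth  # no stem: the seed node is the first split
    scale = t_end - t_first
    counter = [0]

    def build(n: _N, dn: dendropy.Node) -> None:
        for ch in n.children:
            cdn = dendropy.Node()
            dn.add_child(cdn)
            end = ch.children[0].birth if ch.children else t_end
            cdn.edge.length = (end - ch.birth) / scale
            if ch.children:
                build(ch, cdn)
            else:
                cdn.taxon = taxa.get_taxon(labels[counter[0]])
                counter[0] += 1

    build(root, tree.seed_node)
    tree.is_rooted = True
    return tree


def _branch_key(node: dendropy.Node) -> str:
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    return f"{zlib.crc32('|'.join(leaves).encode()):08x}"


def _positional_frequencies(params: EvolutionParams, root_cds: str) -> np.ndarray:
    if isinstance(params.codon_frequencies, str):
        if params.codon_frequencies == "uniform":
            return np.full((3, 4), 0.25)
        if params.codon_frequencies == "f3x4":
            pi = np.zeros((3, 4))
            for k in range(0, len(root_cds), 3):
                for p in range(3):
                    pi[p, NUCS.index(root_cds[k + p])] += 1.0
            pi += 0.5  # pseudocount: unseen nucleotides stay reachable
            return pi / pi.sum(axis=1, keepdims=True)
        raise ValueError(f"unknown frequency model {params.codon_frequencies!r}")
    pi = np.asarray(params.codon_frequencies, dtype=float)
    if pi.shape != (3, 4) or not np.allclose(pi.sum(axis=1), 1.0):
        raise ValueError("explicit frequencies must be (3,4) rows summing to 1")
    return pi


def _rate_table(params: EvolutionParams, pi: np.ndarray) -> dict:
    """Per sense codon: (targets, rates, positions, synonymy, total rate)."""
    table = {}
    for codon in SENSE_CODONS:
        targets, rates, poss, syns = [], [], [], []
        for pos in range(3):
            for nt in NUCS:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if alt in STOPS:
                    continue
                r = pi[pos, NUCS.index(nt)]
                if (codon[pos], nt) in _TRANSITIONS:
                    r *= params.kappa
                syn = AA[alt] == AA[codon]
                if not syn:
                    r *= params.omega
                targets.append(alt)
                rates.append(r)
                poss.append(pos)
                syns.append(syn)
        rate_arr = np.array(rates)
        table[codon] = (targets, rate_arr, poss, syns, rate_arr.sum())
    return table


def evolve_codons(
    tree: dendropy.Tree,
    root_cds: str,
    params: EvolutionParams,
    seed: int,
) -> EvolveResult:
    """Evolve a root CDS along every branch of ``tree`` (exact Gillespie).

    Branch lengths are expected substitutions per codon under these
    parameters (rates are normalized by the mean total rate over the root
    codons, invariant sites excluded). Returns the leaf sequences and the
    exact substitution log; sequences stay gap- and stop-free by
    construction, so leaves are also the true alignment.
    """
    root_cds = root_cds.upper()
    if len(root_cds) % 3:
        raise ValueError("root CDS length must be divisible by 3")
    codons = [root_cds[k : k + 3] for k in range(0, len(root_cds), 3)]
    for i, c in enumerate(codons):
        if c in STOPS:
            raise ValueError(f"root CDS contains a stop codon at codon {i}")

    pi = _positional_frequencies(params, root_cds)
    table = _rate_table(params, pi)
    mutable = [i for i in range(len(codons)) if i not in params.invariant_sites]
    rho = float(np.mean([table[codons[i]][4] for i in mutable])) if mutable else 1.0
    if rho <= 0:
        rho = 1.0

    events: list[SubstitutionEvent] = []
    leaf_cds: dict[str, str] = {}

    def walk(node: dendropy.Node, seq: list[str]) -> None:
        for child in node.child_nodes():
            cseq = list(seq)
            bl = child.edge.length or 0.0
            key = _branch_key(child)
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(int(key, 16),))
            )
            if bl > 0:
                for ci in mutable:
                    t = 0.0
                    while True:
                        targets, rates, poss, syns, total = table[cseq[ci]]
                        if total <= 0:
                            break
                        t += rng.exponential(rho / total)
                        if t >= bl:
                            break
                        j = int(rng.choice(len(rates), p=rates / total))
                        events.append(
                            SubstitutionEvent(
                                branch=key,
                                codon_index=ci,
                                position=poss[j],
                                from_codon=cseq[ci],
                                to_codon=targets[j],
                                synonymous=syns[j],
                            )
                        )
                        cseq[ci] = targets[j]
            if child.is_leaf():
                leaf_cds[child.taxon.label] = "".join(cseq)
            else:
                walk(child, cseq)

    walk(tree.seed_node, codons)
    return EvolveResult(leaf_cds=leaf_cds, events=events)


# ---------------------------------------------------------------------------
# Whole-study generation

@dataclass
class StudyConfig:
    n_luminous: int = 20
    n_nonluminous: int = 2
    n_codons: int = 330
    candidate_omega: float = 0.1
    paralog_omegas: tuple[float, float] = (0.3, 0.5)
    kappa: float = 2.0
    motif: str = "FYY"
    n_decoys: int = 5
    decoy_codons: int = 200
    # 1-based residue anchors for the catalytic positions (triad + RXS + Y),
    # mirroring the reference numbering style H245/D247/H301, R310-S312, Y221
    anchors: dict = field(
        default_factory=lambda: {
            221: ("Y", "acv_tyr"),
            245: ("H", "iron_his1"),
            247: ("D", "iron_asp"),
            301: ("H", "iron_his2"),
            310: ("R", "rxs_arg"),
            312: ("S", "rxs_ser"),
        }
    )

    def __post_init__(self) -> None:
        if self.n_luminous < 1:
            raise ValueError("need at least one luminous species")
        if self.n_nonluminous < 1:
            raise ValueError("need at least one non-luminous species")
        if max(self.anchors) > self.n_codons - len(self.motif):
            raise ValueError("anchors collide with the motif suffix or exceed length")

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Flat ``key = value`` config file; unknown keys error."""
        kwargs: dict = {}
        for ln in open(path):
            ln = ln.split("#")[0].strip()
            if not ln:
                continue
            key, val = (x.strip() for x in ln.split("=", 1))
            if key in ("n_luminous", "n_nonluminous", "n_codons", "n_decoys", "decoy_codons"):
                kwargs[key] = int(val)
            elif key in ("candidate_omega", "kappa"):
                kwargs[key] = float(val)
            elif key == "paralog_omegas":
                kwargs[key] = tuple(float(x) for x in val.split(","))
            elif key == "motif":
                kwargs[key] = val
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)


@dataclass
class SyntheticTruth:
    """Ground-truth manifest sufficient to recompute expected values.

    Families are keyed by name; each entry records the omega used, whether
    the family carries the motif suffix, planted member ids, the per-branch
    substitution counts from the event log, and the root CDS. Planted
    sequences are gapless, so the homology map is the identity on codon
    positions.
    """

    tree_newick: str
    phenotypes: dict[str, bool]
    families: dict
    locked_positions: list
    reference_ids: dict
    n_codons: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


_AA_CODONS: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _AA_CODONS.setdefault(AA[_c], []).append(_c)


def _random_cds(rng: np.random.Generator, n_codons: int, plant: dict[int, str]) -> str:
    """Random CDS; ``plant[i]`` pins the amino acid at 0-based codon i."""
    aas = sorted(_AA_CODONS)
    out = []
    for i in range(n_codons):
        aa = plant.get(i) or aas[int(rng.integers(len(aas)))]
        syn = _AA_CODONS[aa]
        out.append(syn[int(rng.integers(len(syn)))])
    return "".join(out)


def _translate(cds: str) -> str:
    return "".join(AA[cds[k : k + 3]] for k in range(0, len(cds), 3))


def _pick_nonluminous(tree: dendropy.Tree, n: int) -> list[str]:
    """Prefer a cherry (sister leaf pair), emulating a non-luminous sister
    clade; fall back to the last n leaves in preorder."""
    if n == 2:
        for node in tree.postorder_node_iter():
            kids = node.child_nodes()
            if len(kids) == 2 and all(k.is_leaf() for k in kids):
                return sorted(k.taxon.label for k in kids)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    return leaves[-n:]


def generate_study(config: StudyConfig, seed: int, out_dir: str | Path) -> SyntheticTruth:
    """Write a complete synthetic study to ``out_dir``.

    Outputs per species: <sp>.proteome.fasta, <sp>.cds.fasta; plus
    phenotypes.tsv, positions.tsv, species_tree.nwk, truth.json.
    Byte-identical for a fixed (config, seed). The candidate family is
    emitted only for luminous species; paralogs and decoys end in a pinned
    leucine so only candidate proteins can carry the motif as a suffix.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_taxa = config.n_luminous + config.n_nonluminous
    tree = simulate_tree(n_taxa, seed=seed)
    species = [lf.taxon.label for lf in tree.leaf_node_iter()]
    nonlum = set(_pick_nonluminous(tree, config.n_nonluminous))
    phen = {sp: sp not in nonlum for sp in species}

    anchor_plant = {pos - 1: aa for pos, (aa, _) in config.anchors.items()}
    locked = frozenset(p - 1 for p in config.anchors)
    motif_plant = {
        config.n_codons - len(config.motif) + k: aa
        for k, aa in enumerate(config.motif)
    }
    motif_sites = frozenset(motif_plant)
    last = config.n_codons - 1

    fam_specs = {
        "FYY": (config.candidate_omega, True),
        "2OGFe1": (config.paralog_omegas[0], False),
        "2OGFe2": (config.paralog_omegas[1], False),
    }
    families: dict = {}
    proteomes: dict[str, list[SequenceRecord]] = {sp: [] for sp in species}
    cds_out: dict[str, list[SequenceRecord]] = {sp: [] for sp in species}
    truth_refs: dict[str, str] = {}

    for fam_idx, (fam, (omega, has_motif)) in enumerate(fam_specs.items()):
        froot_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(1000 + fam_idx,))
        )
        fam_plant = dict(anchor_plant)
        if has_motif:
            fam_plant.update(motif_plant)
            invariant = locked | motif_sites
        else:
            fam_plant[last] = "L"  # pinned: paralogs can never end in the motif
            invariant = locked | {last}
        root = _random_cds(froot_rng, config.n_codons, fam_plant)
        params = EvolutionParams(
            omega=omega, kappa=config.kappa, invariant_sites=invariant
        )
        res = evolve_codons(tree, root, params, seed=seed * 10 + fam_idx)
        members = []
        for sp in species:
            if has_motif and not phen[sp]:
                continue  # candidate family exists only in luminous species
            gid = f"{sp}_{fam}1"
            cds = res.leaf_cds[sp]
            proteomes[sp].append(
                SequenceRecord(id=gid, seq=_translate(cds), moltype="protein")
            )
            cds_out[sp].append(SequenceRecord(id=gid, seq=cds, moltype="dna"))
            members.append(gid)
        families[fam] = {
            "omega": omega,
            "motif_suffix": has_motif,
            "members": members,
            "branch_counts": {k: list(v) for k, v in res.branch_counts().items()},
            "root_cds": root,
        }
        truth_refs[fam] = members[0]

    # decoys: motif strictly internal, pinned terminal leucine, every species
    for sp_idx, sp in enumerate(species):
        drng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(2000 + sp_idx,))
        )
        for d in range(config.n_decoys):
            pos = int(drng.integers(1, config.decoy_codons - len(config.motif) - 1))
            plant_d = {pos + k: aa for k, aa in enumerate(config.motif)}
            plant_d[config.decoy_codons - 1] = "L"
            cds = _random_cds(drng, config.decoy_codons, plant_d)
            gid = f"{sp}_dec{d + 1}"
            proteomes[sp].append(
                SequenceRecord(id=gid, seq=_translate(cds), moltype="protein")
            )
            cds_out[sp].append(SequenceRecord(id=gid, seq=cds, moltype="dna"))

    for sp in species:
        write_fasta(proteomes[sp], out / f"{sp}.proteome.fasta")
        write_fasta(cds_out[sp], out / f"{sp}.cds.fasta")
    write_phenotype_table(PhenotypeTable(phen), out / "phenotypes.tsv")
    with open(out / "positions.tsv", "w") as fh:
        fh.write("ref_id\tposition\tresidue\tlabel\n")
        for fam, ref in truth_refs.items():
            for pos, (aa, label) in sorted(config.anchors.items()):
                fh.write(f"{ref}\t{pos}\t{aa}\t{label}\n")
    with open(out / "species_tree.nwk", "w") as fh:
        fh.write(newick_string(tree) + "\n")

    truth = SyntheticTruth(
        tree_newick=newick_string(tree),
        phenotypes=phen,
        families=families,
        locked_positions=[
            [pos, aa, label] for pos, (aa, label) in sorted(config.anchors.items())
        ],
        reference_ids=truth_refs,
        n_codons=config.n_codons,
    )
    truth.to_json(out / "truth.json")
    return truth


def load_study_proteomes(study_dir: str | Path) -> dict[str, Proteome]:
    """Read back the per-species proteomes of a generated study."""
    from .seqio import read_fasta

    out = {}
    for f in sorted(Path(study_dir).glob("*.proteome.fasta")):
        sp = f.name.split(".")[0]
        out[sp] = Proteome(species=sp, records=read_fasta(f, moltype="protein"))
    return out
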