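"""Flat-file reaction–enzyme–organism database.

The store is a directory of plain-text files:

  reactions.tsv   id, substrates, products, ec, xrefs
                  (sides are ';'-joined SMILES with optional '*n' coefficients)
  molecules.tsv   molecule_id, smiles, name      (display names)
  sequences.fasta headers 'accession|taxon_id|evidence|description'
  links.tsv       reaction_id, accession
  taxonomy.nwk    Newick tree; labels 'taxon_id|name'
  consensus.tsv   reaction_id, direction in {forward, reverse}   (optional)

Loading validates referential integrity (links point at real reactions and
sequences, every sequence's taxon is in the tree) and builds the indices
used by the similarity screen: id/accession lookup and an EC-prefix index.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import Phylo, SeqIO

from .errors import DatabaseError, ValidationError
from .reactions import (
    FORWARD,
    REVERSE,
    UNKNOWN,
    Molecule,
    Reaction,
    ReactionSide,
    canonical_smiles,
)
from .similarity import RxnSimilarity, reaction_similarity

log = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
MIN_SEQ_LEN = 20

MANDATORY_FILES = ("reactions.tsv", "molecules.tsv", "sequences.fasta", "links.tsv", "taxonomy.nwk")


@dataclass(frozen=True)
class SequenceRecord:
    accession: str
    sequence: str
    description: str
    taxon_id: str
    evidence: int  # UniProt-style 1 (protein level) .. 5 (uncertain)

    def __post_init__(self):
        if len(self.sequence) < MIN_SEQ_LEN:
            raise ValidationError(
                f"{self.accession}: sequence shorter than {MIN_SEQ_LEN} residues"
            )
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValidationError(f"{self.accession}: illegal residues {sorted(bad)}")
        if self.evidence not in (1, 2, 3, 4, 5):
            raise ValidationError(f"{self.accession}: evidence must be 1..5")


class TaxonomyTree:
    """Rooted tree over organisms; the host-distance oracle.

    Distance between two taxa is the path length through their lowest
    common ancestor: summed branch lengths when every edge on the tree
    carries one, edge count otherwise.
    """

    def __init__(self, clades, parent, names):
        self._clades = clades  # taxon_id -> Bio.Phylo clade
        self._parent = parent  # clade -> parent clade (root absent)
        self._names = names  # taxon_id -> display name

    @classmethod
    def from_newick(cls, text: str) -> "TaxonomyTree":
        tree = Phylo.read(io.StringIO(text), "newick")
        clades: dict[str, object] = {}
        parent: dict[object, object] = {}
        names: dict[str, str] = {}
        for clade in tree.find_clades():
            for child in clade.clades:
                parent[child] = clade
            if clade.name:
                tid, _, name = clade.name.partition("|")
                if tid in clades:
                    raise ValidationError(f"duplicate taxon id {tid!r} in taxonomy")
                clades[tid] = clade
                names[tid] = name or tid
        if not clades:
            raise ValidationError("taxonomy tree has no labelled nodes")
        obj = cls(clades, parent, names)
        obj._use_lengths = all(
            c.branch_length is not None for c in parent  # every non-root edge
        )
        return obj

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._clades

    def taxa(self) -> list[str]:
        return sorted(self._clades)

    def name_of(self, taxon_id: str) -> str:
        return self._names[taxon_id]

    def _path_to_root(self, clade) -> list:
        path = [clade]
        while clade in self._parent:
            clade = self._parent[clade]
            path.append(clade)
        return path

    def distance(self, a: str, b: str) -> float:
        """LCA path length between two taxa (>= 0; 0 iff same taxon)."""
        for t in (a, b):
            if t not in self._clades:
                raise ValidationError(f"unknown taxon {t!r}")
        if a == b:
            return 0.0
        pa = self._path_to_root(self._clades[a])
        pb = self._path_to_root(self._clades[b])
        ancestors = set(pb)
        lca_idx = next(i for i, c in enumerate(pa) if c in ancestors)
        lca = pa[lca_idx]
        edges = pa[:lca_idx] + pb[: pb.index(lca)]
        if self._use_lengths:
            return float(sum(c.branch_length for c in edges))
        return float(len(edges))


@dataclass
class ScoreColumn:
    weight: float
    orientation: str  # "higher_better" | "lower_better"


@dataclass
class EnzymeDatabase:
    reactions: dict[str, Reaction]
    sequences: dict[str, SequenceRecord]
    links: dict[str, tuple[str, ...]]  # reaction_id -> accessions
    taxonomy: TaxonomyTree
    consensus: dict[str, str]
    molecule_names: dict[str, str] = field(default_factory=dict)  # smiles -> name
    _ec_index: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        for rid, r in self.reactions.items():
            for ec in r.ec_numbers:
                fields = ec.split(".")
                for k in range(1, len(fields) + 1):
                    self._ec_index.setdefault(".".join(fields[:k]), set()).add(rid)

    def reactions_sorted(self) -> list[Reaction]:
        return [self.reactions[k] for k in sorted(self.reactions)]

    def reactions_by_ec_prefix(self, prefix: str) -> list[Reaction]:
        clean = ".".join(f for f in prefix.split(".") if f != "-")
        ids = self._ec_index.get(clean, set())
        return [self.reactions[i] for i in sorted(ids)]

    def summary(self) -> dict[str, int]:
        return {
            "reactions": len(self.reactions),
            "sequences": len(self.sequences),
            "links": sum(len(v) for v in self.links.values()),
            "taxa": len(self.taxonomy.taxa()),
            "consensus_entries": len(self.consensus),
        }


def _parse_side(cell: str, names: dict[str, str]) -> ReactionSide:
    members = []
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        smiles, _, coeff = token.partition("*")
        can = canonical_smiles(smiles)
        members.append((Molecule(can, name=names.get(can)), int(coeff) if coeff else 1))
    if not members:
        raise ValidationError(f"empty reaction side cell {cell!r}")
    return ReactionSide(tuple(members))


def _read_tsv(path: Path, n_min: int) -> list[list[str]]:
    rows = []
    for ln, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) < n_min:
            raise DatabaseError(f"{path.name}:{ln}: expected >= {n_min} columns")
        rows.append(cells)
    return rows


def load_database(path) -> EnzymeDatabase:
    """Load and validate a database directory (see module docstring)."""
    root = Path(path)
    for fname in MANDATORY_FILES:
        if not (root / fname).exists():
            raise DatabaseError(f"missing mandatory database file {fname!r} in {root}")

    names: dict[str, str] = {}
    for cells in _read_tsv(root / "molecules.tsv", 2):
        smiles = canonical_smiles(cells[1])
        if len(cells) > 2 and cells[2]:
            names[smiles] = cells[2]

    consensus: dict[str, str] = {}
    cpath = root / "consensus.tsv"
    if cpath.exists():
        for cells in _read_tsv(cpath, 2):
            if cells[1] not in (FORWARD, REVERSE):
                raise DatabaseError(f"consensus.tsv: bad direction {cells[1]!r}")
            consensus[cells[0]] = cells[1]
    else:
        log.warning("consensus.tsv absent: all preferred directions unknown")

    reactions: dict[str, Reaction] = {}
    for cells in _read_tsv(root / "reactions.tsv", 3):
        rid = cells[0]
        ec = tuple(x for x in (cells[3].split(";") if len(cells) > 3 and cells[3] else []) if x)
        xr = tuple(x for x in (cells[4].split(";") if len(cells) > 4 and cells[4] else []) if x)
        reactions[rid] = Reaction(
            id=rid,
            substrates=_parse_side(cells[1], names),
            products=_parse_side(cells[2], names),
            ec_numbers=ec,
            xrefs=xr,
            preferred_direction=consensus.get(rid, UNKNOWN),
        )

    dangling_consensus = [rid for rid in consensus if rid not in reactions]
    if dangling_consensus:
        raise DatabaseError(
            f"consensus.tsv references unknown reactions: {dangling_consensus[:10]}"
        )

    taxonomy = TaxonomyTree.from_newick((root / "taxonomy.nwk").read_text(encoding="utf-8"))

    sequences: dict[str, SequenceRecord] = {}
    for rec in SeqIO.parse(str(root / "sequences.fasta"), "fasta"):
        parts = rec.description.split("|")
        if len(parts) < 2:
            raise DatabaseError(
                f"sequences.fasta: header {rec.description!r} is not "
                "'accession|taxon_id|evidence|description'"
            )
        accession, taxon = parts[0], parts[1]
        evidence = int(parts[2]) if len(parts) > 2 and parts[2] else 4
        descr = parts[3] if len(parts) > 3 else ""
        if taxon not in taxonomy:
            raise DatabaseError(f"sequence {accession}: taxon {taxon!r} absent from taxonomy")
        sequences[accession] = SequenceRecord(
            accession=accession,
            sequence=str(rec.seq).upper(),
            description=descr,
            taxon_id=taxon,
            evidence=evidence,
        )

    links: dict[str, list[str]] = {}
    offenders = []
    for cells in _read_tsv(root / "links.tsv", 2):
        rid, acc = cells[0], cells[1]
        if rid not in reactions or acc not in sequences:
            offenders.append((rid, acc))
            continue
        links.setdefault(rid, []).append(acc)
    if offenders:
        raise DatabaseError(f"links.tsv has dangling endpoints (first 10): {offenders[:10]}")

    return EnzymeDatabase(
        reactions=reactions,
        sequences=sequences,
        links={k: tuple(sorted(set(v))) for k, v in links.items()},
        taxonomy=taxonomy,
        consensus=consensus,
        molecule_names=names,
    )


def rank_database_reactions(
    q: Reaction,
    db: EnzymeDatabase,
    mode: str = "both",
    mask: frozenset[str] = frozenset(),
    nbits: int = 1024,
    radius: int = 2,
) -> list[tuple[Reaction, RxnSimilarity]]:
    """Score every database reaction against the query and sort by
    similarity descending (ties by reaction id ascending)."""
    scored = [
        (r, reaction_similarity(q, r, mode=mode, mask=mask, nbits=nbits, radius=radius))
        for r in db.reactions_sorted()
    ]
    scored.sort(key=lambda t: (-t[1].score, t[0].id))
    return scored
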