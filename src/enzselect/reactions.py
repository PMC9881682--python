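"""Reaction model: parse query reactions from every supported input form.

A query reaction may arrive as a reaction SMILES string (``s1.s2>>p1.p2``),
a SMIRKS/SMARTS reaction rule, an MDL ``.rxn`` file (V2000), or an EC
number / external reaction identifier resolved against the loaded database.
All forms converge on one :class:`Reaction` value whose participants carry
canonical SMILES, so that downstream fingerprinting and similarity scoring
never see input-format differences.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional

from rdkit import Chem, RDLogger

from .errors import NotFoundError, ReactionFormatError, ReactionParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .database import EnzymeDatabase

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

FORWARD = "forward"
REVERSE = "reverse"
UNKNOWN = "unknown"

_EC_RE = re.compile(r"^\d+(\.(\d+|-)){0,3}$")


def canonical_smiles(text: str) -> str:
    """Canonical SMILES via RDKit; idempotent by construction."""
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ReactionParseError(f"unparsable SMILES component: {text!r}")
    return Chem.MolToSmiles(mol)


def canonical_smarts(text: str) -> str:
    qmol = Chem.MolFromSmarts(text)
    if qmol is None:
        raise ReactionParseError(f"invalid SMARTS pattern: {text!r}")
    return Chem.MolToSmarts(qmol)


@dataclass(frozen=True)
class Molecule:
    """One chemical participant.

    ``smiles`` holds a canonical SMILES for concrete structures, or a
    canonical SMARTS when the participant came from a reaction rule that
    cannot be read as a concrete structure.  Molecules compare (and hash)
    by that canonical string alone.
    """

    smiles: str
    name: Optional[str] = None
    is_pattern: bool = False

    def __post_init__(self):
        if not self.smiles:
            raise ValidationError("molecule requires a non-empty structure string")

    def __eq__(self, other):
        if not isinstance(other, Molecule):
            return NotImplemented
        return self.smiles == other.smiles

    def __hash__(self):
        return hash(self.smiles)


@dataclass(frozen=True)
class ReactionSide:
    """Ordered (Molecule, stoichiometric coefficient) pairs; coefficients >= 1."""

    members: tuple[tuple[Molecule, int], ...]

    def __post_init__(self):
        if not self.members:
            raise ValidationError("a reaction side must contain at least one molecule")
        if any(c < 1 for _, c in self.members):
            raise ValidationError("stoichiometric coefficients must be >= 1")

    @classmethod
    def from_molecules(cls, mols: Iterable[Molecule]) -> "ReactionSide":
        """Merge repeated identical canonical structures into coefficients."""
        order: list[Molecule] = []
        counts: dict[str, int] = {}
        for m in mols:
            if m.smiles in counts:
                counts[m.smiles] += 1
            else:
                counts[m.smiles] = 1
                order.append(m)
        return cls(tuple((m, counts[m.smiles]) for m in order))

    def expanded(self) -> list[Molecule]:
        """Each molecule repeated by its coefficient."""
        return [m for m, c in self.members for _ in range(c)]

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.members)


@dataclass(frozen=True)
class Reaction:
    id: str
    substrates: ReactionSide
    products: ReactionSide
    ec_numbers: tuple[str, ...] = ()
    xrefs: tuple[str, ...] = ()
    preferred_direction: str = UNKNOWN

    def __post_init__(self):
        if self.preferred_direction not in (FORWARD, REVERSE, UNKNOWN):
            raise ValidationError(f"bad direction {self.preferred_direction!r}")
        for ec in self.ec_numbers:
            if not _EC_RE.match(ec):
                raise ValidationError(f"malformed EC number {ec!r}")

    def reversed(self) -> "Reaction":
        return Reaction(
            id=self.id,
            substrates=self.products,
            products=self.substrates,
            ec_numbers=self.ec_numbers,
            xrefs=self.xrefs,
            preferred_direction=self.preferred_direction,
        )


@dataclass
class QuerySpec:
    """A fully-resolved query: reaction + host + ranking options."""

    reaction: Reaction
    host_taxon: str
    direction_mode: str = "both"  # "both" | "preferred_only"
    weights: Optional[dict] = None
    top_n: int = 50
    do_msa: bool = True

    def __post_init__(self):
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        if self.direction_mode not in ("both", "preferred_only"):
            raise ValidationError(f"bad direction mode {self.direction_mode!r}")


def _split_parts(text: str, what: str) -> tuple[str, str]:
    """Split a reaction string on '>' into substrate/product parts.

    Accepts the two-part 'a>>b' and three-part 'a>agents>b' conventions;
    agents are parsed for validity elsewhere but otherwise discarded.
    """
    parts = text.split(">")
    if len(parts) != 3:
        raise ReactionParseError(
            f"{what} must contain one '>>' (or 'a>agents>b') separator: {text!r}"
        )
    left, agents, right = parts
    if agents.strip():
        log.warning("%s agents %r are ignored", what, agents)
    if not left.strip():
        raise ValidationError(f"empty substrate side in {what}: {text!r}")
    if not right.strip():
        raise ValidationError(f"empty product side in {what}: {text!r}")
    return left.strip(), right.strip()


def parse_reaction_smiles(text: str, rxn_id: str = "query") -> Reaction:
    """Parse a reaction SMILES string into a :class:`Reaction`.

    Dot-separated components become molecules with coefficient 1; repeats
    of the same canonical structure on one side merge into a coefficient.
    """
    left, right = _split_parts(text, "reaction SMILES")
    sides = []
    for part in (left, right):
        mols = [Molecule(canonical_smiles(c)) for c in part.split(".") if c]
        if not mols:
            raise ValidationError(f"empty reaction side in {text!r}")
        sides.append(ReactionSide.from_molecules(mols))
    return Reaction(id=rxn_id, substrates=sides[0], products=sides[1])


def _pattern_molecule(component: str) -> Molecule:
    """A rule component: concrete if it reads as strict SMILES, else SMARTS."""
    mol = Chem.MolFromSmiles(component)
    if mol is not None:
        return Molecule(Chem.MolToSmiles(mol), is_pattern=True)
    return Molecule(canonical_smarts(component), is_pattern=True)


def parse_smirks_rule(text: str, rxn_id: str = "query") -> Reaction:
    """Parse a SMARTS/SMIRKS reaction rule.

    Components that happen to be valid concrete SMILES (no query atoms)
    canonicalize as SMILES so a pattern-free rule behaves exactly like the
    equivalent reaction SMILES downstream; true patterns keep a canonical
    SMARTS and are fingerprinted with a reserved wildcard atom invariant.
    """
    left, right = _split_parts(text, "reaction rule")
    sides = []
    for part in (left, right):
        mols = [_pattern_molecule(c) for c in part.split(".") if c]
        if not mols:
            raise ValidationError(f"empty side in rule {text!r}")
        sides.append(ReactionSide.from_molecules(mols))
    return Reaction(id=rxn_id, substrates=sides[0], products=sides[1])


def parse_rxn_file(content: str, rxn_id: str = "query") -> Reaction:
    """Parse MDL .rxn text (V2000 molfiles only)."""
    if not content.startswith("$RXN"):
        raise ReactionFormatError("not an MDL .rxn file: missing $RXN header")
    lines = content.splitlines()
    if len(lines) < 5:
        raise ReactionFormatError("truncated .rxn: missing counts line")
    counts = lines[4]
    try:
        n_react = int(counts[0:3])
        n_prod = int(counts[3:6])
    except ValueError:
        try:
            n_react, n_prod = (int(x) for x in counts.split()[:2])
        except Exception as exc:
            raise ReactionFormatError(f"unreadable counts line {counts!r}") from exc
    blocks = content.split("$MOL")[1:]
    if len(blocks) != n_react + n_prod:
        raise ReactionFormatError(
            f"counts line declares {n_react}+{n_prod} molecules "
            f"but {len(blocks)} $MOL blocks found"
        )
    mols: list[Molecule] = []
    for i, block in enumerate(blocks):
        # drop the remainder of the $MOL line only: the molfile's title
        # line is frequently empty and must be preserved
        text = block.split("\n", 1)[1] if "\n" in block else block
        mol_lines = text.splitlines()
        if len(mol_lines) > 3 and "V3000" in mol_lines[3]:
            raise ReactionFormatError(f"molfile block {i + 1} is V3000; only V2000 supported")
        mol = Chem.MolFromMolBlock(text)
        if mol is None:
            raise ReactionParseError(f"unparsable molfile block {i + 1}")
        mols.append(Molecule(Chem.MolToSmiles(mol)))
    substrates = ReactionSide.from_molecules(mols[:n_react])
    products = ReactionSide.from_molecules(mols[n_react:])
    return Reaction(id=rxn_id, substrates=substrates, products=products)


def write_rxn(rxn: Reaction) -> str:
    """Serialize a concrete Reaction back to MDL .rxn text (V2000)."""
    sub = rxn.substrates.expanded()
    prod = rxn.products.expanded()
    out = ["$RXN", rxn.id, "  enzselect", "", f"{len(sub):3d}{len(prod):3d}"]
    for m in sub + prod:
        mol = Chem.MolFromSmiles(m.smiles)
        if mol is None:
            raise ValidationError(f"cannot write pattern molecule {m.smiles!r} to .rxn")
        out.append("$MOL")
        out.append(Chem.MolToMolBlock(mol).rstrip("\n"))
    return "\n".join(out) + "\n"


def ec_matches(stored_ec: str, query_ec: str) -> bool:
    """Prefix match on dotted EC fields; '-' acts as a wildcard field."""
    q = [f for f in query_ec.split(".") if f != "-"]
    s = stored_ec.split(".")
    if len(q) > len(s):
        return False
    return all(sf == qf or sf == "-" for sf, qf in zip(s, q))


def resolve_id_query(key: str, db: "EnzymeDatabase") -> list[Reaction]:
    """Resolve an EC number or external/database reaction id to stored reactions.

    EC numbers match by prefix (EC '1.1.1' matches '1.1.1.1'); other keys
    must hit a reaction id or xref exactly.  Returns one Reaction per match;
    the caller runs one similarity query per returned reaction.
    """
    if _EC_RE.match(key):
        hits = [r for r in db.reactions_sorted() if any(ec_matches(e, key) for e in r.ec_numbers)]
        if not hits:
            prefixes = sorted({e.rsplit(".", 1)[0] for r in db.reactions_sorted() for e in r.ec_numbers})
            raise NotFoundError(
                f"no reaction with EC matching {key!r}; EC prefixes present: "
                + ", ".join(prefixes[:10])
            )
        return hits
    if key in db.reactions:
        return [db.reactions[key]]
    hits = [r for r in db.reactions_sorted() if key in r.xrefs]
    if not hits:
        raise NotFoundError(f"no reaction with id or xref {key!r}")
    return hits
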