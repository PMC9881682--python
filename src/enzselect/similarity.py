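"""Fingerprints and reaction similarity.

Molecules are encoded as circular (Morgan) substructure fingerprints —
hashed atom environments of radius 0..r folded into a fixed-length bit
vector — and compared with the Tanimoto coefficient |A∩B| / |A∪B|.  A
reaction-versus-reaction score aggregates per-compound Tanimoto values by
a greedy one-to-one assignment on each side, normalized by the larger
side, and averages the substrate-side and product-side scores; direction
handling either takes the better of forward/reverse or respects the
database reaction's curated preferred direction.

Stereochemistry is deliberately ignored: the screen is structural, and
reaction rules mined from retrosynthesis tools rarely carry stereo.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .errors import ReactionParseError, ValidationError
from .reactions import FORWARD, REVERSE, UNKNOWN, Molecule, Reaction, ReactionSide

DEFAULT_NBITS = 1024
DEFAULT_RADIUS = 2

# reserved Morgan atom invariant for wildcard / query atoms in SMARTS rules
WILDCARD_INVARIANT = 119


@dataclass(frozen=True)
class Fingerprint:
    bits: frozenset[int]
    nbits: int = DEFAULT_NBITS
    radius: int = DEFAULT_RADIUS

    def __post_init__(self):
        if not self.bits:
            raise ValidationError("empty fingerprint: molecule produced no substructure bits")


@dataclass(frozen=True)
class RxnSimilarity:
    """Aggregate reaction similarity plus the per-compound assignment."""

    score: float
    matched_direction: str  # forward | reverse
    per_pair: tuple[tuple[str, str, float], ...]  # (query smiles, db smiles, tanimoto)


@lru_cache(maxsize=8)
def _generator(radius: int, nbits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)


@lru_cache(maxsize=100_000)
def _fingerprint_cached(smiles: str, is_pattern: bool, nbits: int, radius: int) -> Fingerprint:
    gen = _generator(radius, nbits)
    mol = Chem.MolFromSmiles(smiles)
    if mol is not None:
        Chem.RemoveStereochemistry(mol)
        bv = gen.GetFingerprint(mol)
    elif is_pattern:
        qmol = Chem.MolFromSmarts(smiles)
        if qmol is None:
            raise ReactionParseError(f"cannot fingerprint pattern {smiles!r}")
        qmol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(qmol)
        invariants = [
            a.GetAtomicNum() if a.GetAtomicNum() > 0 else WILDCARD_INVARIANT
            for a in qmol.GetAtoms()
        ]
        bv = gen.GetFingerprint(qmol, customAtomInvariants=invariants)
    else:
        raise ReactionParseError(f"cannot fingerprint molecule {smiles!r}")
    return Fingerprint(frozenset(bv.GetOnBits()), nbits=nbits, radius=radius)


def fingerprint_molecule(
    m: Molecule, nbits: int = DEFAULT_NBITS, radius: int = DEFAULT_RADIUS
) -> Fingerprint:
    """Morgan fingerprint of a molecule (stereo-agnostic, deterministic).

    Pattern molecules (SMARTS from reaction rules) are fingerprinted with
    a reserved atom-invariant code for wildcard atoms, so rules yield
    stable, comparable fingerprints.
    """
    return _fingerprint_cached(m.smiles, m.is_pattern, nbits, radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A∩B| / |A∪B| over the on-bit sets; symmetric, in [0, 1]."""
    if a.nbits != b.nbits or a.radius != b.radius:
        raise ValidationError(
            f"fingerprint mismatch: {a.nbits}b/r{a.radius} vs {b.nbits}b/r{b.radius}"
        )
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


def _apply_mask(side: ReactionSide, mask: frozenset[str]) -> list[Molecule]:
    """Drop currency compounds unless that would empty the side."""
    expanded = side.expanded()
    kept = [m for m in expanded if m.smiles not in mask]
    return kept if kept else expanded


def greedy_assignment(matrix: list[list[float]]) -> list[tuple[int, int, float]]:
    """Greedy maximum assignment: repeatedly take the global maximum entry,
    removing its row and column.  Ties break on the lowest (row, col) pair,
    so the output is deterministic."""
    if not matrix or not matrix[0]:
        return []
    free_rows = set(range(len(matrix)))
    free_cols = set(range(len(matrix[0])))
    pairs: list[tuple[int, int, float]] = []
    while free_rows and free_cols:
        best = max(
            ((matrix[i][j], -i, -j) for i in free_rows for j in free_cols),
        )
        val, i, j = best[0], -best[1], -best[2]
        pairs.append((i, j, val))
        free_rows.discard(i)
        free_cols.discard(j)
    return pairs


def side_similarity(
    q: ReactionSide,
    d: ReactionSide,
    mask: frozenset[str] = frozenset(),
    nbits: int = DEFAULT_NBITS,
    radius: int = DEFAULT_RADIUS,
    _pairs_out: Optional[list] = None,
) -> float:
    """Aggregate one-side similarity in [0, 1].

    Currency compounds are removed first (unless a side would become
    empty); remaining compounds are matched greedily one-to-one on the
    pairwise Tanimoto matrix and the matched values are summed and divided
    by the size of the larger side, so unmatched compounds count as 0.
    """
    qm = _apply_mask(q, mask)
    dm = _apply_mask(d, mask)
    fq = [fingerprint_molecule(m, nbits, radius) for m in qm]
    fd = [fingerprint_molecule(m, nbits, radius) for m in dm]
    matrix = [[tanimoto(a, b) for b in fd] for a in fq]
    pairs = greedy_assignment(matrix)
    if _pairs_out is not None:
        _pairs_out.extend((qm[i].smiles, dm[j].smiles, v) for i, j, v in pairs)
    return sum(v for _, _, v in pairs) / max(len(qm), len(dm))


def reaction_similarity(
    q: Reaction,
    d: Reaction,
    mode: str = "both",
    mask: frozenset[str] = frozenset(),
    nbits: int = DEFAULT_NBITS,
    radius: int = DEFAULT_RADIUS,
) -> RxnSimilarity:
    """Reaction-vs-reaction similarity with direction handling.

    forward = mean of substrate-vs-substrate and product-vs-product side
    scores; reverse swaps the database reaction's sides.  mode='both'
    returns the larger (ties -> forward); mode='preferred_only' evaluates
    only the database reaction's curated direction, falling back to 'both'
    when that direction is unknown.
    """
    if mode not in ("both", "preferred_only"):
        raise ValidationError(f"bad direction mode {mode!r}")

    def directed(swap: bool) -> tuple[float, tuple]:
        d_sub, d_prod = (d.products, d.substrates) if swap else (d.substrates, d.products)
        pairs: list = []
        s1 = side_similarity(q.substrates, d_sub, mask, nbits, radius, pairs)
        s2 = side_similarity(q.products, d_prod, mask, nbits, radius, pairs)
        return (s1 + s2) / 2.0, tuple(pairs)

    if mode == "preferred_only" and d.preferred_direction != UNKNOWN:
        swap = d.preferred_direction == REVERSE
        score, pairs = directed(swap)
        return RxnSimilarity(score, REVERSE if swap else FORWARD, pairs)

    fwd, fwd_pairs = directed(False)
    rev, rev_pairs = directed(True)
    if rev > fwd:
        return RxnSimilarity(rev, REVERSE, rev_pairs)
    return RxnSimilarity(fwd, FORWARD, fwd_pairs)


def load_currency_mask(path) -> frozenset[str]:
    """Read a currency-compound mask file: one SMILES per line, '#' comments.
    SMILES are canonicalized so masking matches database participants."""
    from .reactions import canonical_smiles

    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(canonical_smiles(line))
    return frozenset(out)
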