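"""Internal progressive multiple sequence alignment and conservation.

The candidate table can carry a per-sequence conservation score computed
from a multiple alignment of the collected candidates.  The aligner is a
self-contained progressive scheme — global pairwise alignment with affine
gaps (Needleman–Wunsch/Gotoh), a 3-mer-distance UPGMA guide tree, and
profile–profile merges under the same scoring — so no external alignment
program is needed.  A plug-in hook (pass your own ``aligned rows``) allows
an external aligner in production.

Gap cost convention: a gap of length L costs ``gap_open + (L-1)*gap_extend``.
Traceback ties resolve diagonal > up > left, and UPGMA ties resolve by
lexicographic accession, so outputs are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._tables import blosum62
from .errors import ValidationError

log = logging.getLogger(__name__)

GAP_OPEN = 10.0
GAP_EXTEND = 0.5

_ALPHA = "ARNDCQEGHILKMFPSTWYVX"
_AIDX = {a: i for i, a in enumerate(_ALPHA)}
_NEG = -1e30


def _subst_matrix() -> np.ndarray:
    table = blosum62()
    n = len(_ALPHA)
    m = np.zeros((n, n))
    for i, a in enumerate(_ALPHA):
        for j, b in enumerate(_ALPHA):
            m[i, j] = table[(a, b)]
    return m


_B = _subst_matrix()


@dataclass(frozen=True)
class Alignment:
    """Gapped rows keyed by accession; all rows have length ncols."""

    rows: dict[str, str]
    ncols: int

    def __post_init__(self):
        for acc, row in self.rows.items():
            if len(row) != self.ncols:
                raise ValidationError(f"row {acc} has length {len(row)} != {self.ncols}")

    def degapped(self, acc: str) -> str:
        return self.rows[acc].replace("-", "")

    def to_fasta(self) -> str:
        return "".join(f">{acc}\n{row}\n" for acc, row in self.rows.items())

    def to_clustal(self) -> str:
        out = ["CLUSTAL format alignment (enzselect)", ""]
        width = 60
        pad = max(len(a) for a in self.rows) + 2
        for start in range(0, self.ncols, width):
            for acc, row in self.rows.items():
                out.append(f"{acc:<{pad}}{row[start:start + width]}")
            out.append("")
        return "\n".join(out) + "\n"


def _check_seq(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValidationError("cannot align an empty sequence")
    for i, ch in enumerate(seq):
        if ch not in _AIDX:
            raise ValidationError(f"unknown residue {ch!r} at position {i + 1}")
    return seq


def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    """ncols x |alphabet| residue counts (gaps excluded)."""
    ncols = len(rows[0])
    counts = np.zeros((ncols, len(_ALPHA)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != "-":
                counts[j, _AIDX[ch]] += 1
    return counts


def _gotoh(score: np.ndarray, gap_open: float, gap_extend: float):
    """Affine-gap global DP on a precomputed column-score matrix.

    Returns the optimal score and the traceback as a list of moves
    ('D' diagonal, 'U' up = gap in the second profile, 'L' left).
    """
    n, m = score.shape
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in second profile (consume rows)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in first profile (consume cols)
    # pointers: which source matrix (0=M, 1=Ix, 2=Iy)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + (j - 1) * gap_extend)
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], Ix[i - 1], Iy[i - 1]
        Mi, Xi, Yi = M[i], Ix[i], Iy[i]
        si = score[i - 1]
        for j in range(1, m + 1):
            # M: diagonal from the best of the three (ties M > Ix > Iy)
            d0, d1, d2 = Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]
            if d0 >= d1 and d0 >= d2:
                Mi[j], pM[i, j] = d0 + si[j - 1], 0
            elif d1 >= d2:
                Mi[j], pM[i, j] = d1 + si[j - 1], 1
            else:
                Mi[j], pM[i, j] = d2 + si[j - 1], 2
            # Ix: consume a row (gap in second profile)
            o0, o1, o2 = Mi1[j] - gap_open, Xi1[j] - gap_extend, Yi1[j] - gap_open
            if o0 >= o1 and o0 >= o2:
                Xi[j], pX[i, j] = o0, 0
            elif o1 >= o2:
                Xi[j], pX[i, j] = o1, 1
            else:
                Xi[j], pX[i, j] = o2, 2
            # Iy: consume a column (gap in first profile)
            l0, l1, l2 = Mi[j - 1] - gap_open, Xi[j - 1] - gap_open, Yi[j - 1] - gap_extend
            if l0 >= l1 and l0 >= l2:
                Yi[j], pY[i, j] = l0, 0
            elif l1 >= l2:
                Yi[j], pY[i, j] = l1, 1
            else:
                Yi[j], pY[i, j] = l2, 2
    fM, fX, fY = M[n, m], Ix[n, m], Iy[n, m]
    if fM >= fX and fM >= fY:
        state, best = 0, fM
    elif fX >= fY:
        state, best = 1, fX
    else:
        state, best = 2, fY
    moves: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            moves.append("D")
            state = int(pM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            moves.append("U")
            state = int(pX[i, j])
            i -= 1
        else:
            moves.append("L")
            state = int(pY[i, j])
            j -= 1
    moves.reverse()
    return float(best), moves


def pairwise_align(
    a: str,
    b: str,
    substitution: str = "BLOSUM62",
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> tuple[float, tuple[str, str]]:
    """Optimal global alignment of two sequences with affine gaps.

    Returns the optimal score and one optimal aligned pair (deterministic
    traceback: diagonal > up > left).
    """
    if substitution != "BLOSUM62":
        raise ValidationError(f"unknown substitution matrix {substitution!r}")
    a, b = _check_seq(a), _check_seq(b)
    ia = np.array([_AIDX[c] for c in a])
    ib = np.array([_AIDX[c] for c in b])
    score = _B[np.ix_(ia, ib)]
    best, moves = _gotoh(score, gap_open, gap_extend)
    ga, gb = [], []
    pa = pb = 0
    for mv in moves:
        if mv == "D":
            ga.append(a[pa]); gb.append(b[pb]); pa += 1; pb += 1
        elif mv == "U":
            ga.append(a[pa]); gb.append("-"); pa += 1
        else:
            ga.append("-"); gb.append(b[pb]); pb += 1
    return best, ("".join(ga), "".join(gb))


def _align_profiles(rows1: dict[str, str], rows2: dict[str, str],
                    gap_open: float, gap_extend: float) -> dict[str, str]:
    r1 = list(rows1.values())
    r2 = list(rows2.values())
    c1 = _profile_counts(r1)
    c2 = _profile_counts(r2)
    # average substitution score over cross pairs; gap pairs contribute 0
    score = (c1 @ _B @ c2.T) / (len(r1) * len(r2))
    _, moves = _gotoh(score, gap_open, gap_extend)
    out: dict[str, str] = {}
    for acc, row in rows1.items():
        p = 0
        s = []
        for mv in moves:
            if mv in ("D", "U"):
                s.append(row[p]); p += 1
            else:
                s.append("-")
        out[acc] = "".join(s)
    for acc, row in rows2.items():
        p = 0
        s = []
        for mv in moves:
            if mv in ("D", "L"):
                s.append(row[p]); p += 1
            else:
                s.append("-")
        out[acc] = "".join(s)
    return out


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _upgma_order(names: list[str], dist: dict[tuple[str, str], float]) -> list[tuple]:
    """UPGMA merge list over leaf names; ties break on the lexicographically
    smallest representative accession of each cluster."""
    clusters: dict[str, tuple[str, ...]] = {n: (n,) for n in names}
    d = dict(dist)
    merges = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for x in range(len(keys)):
            for y in range(x + 1, len(keys)):
                key = (keys[x], keys[y])
                cand = (d[key], keys[x], keys[y])
                if best is None or cand < best:
                    best = cand
        _, a, b = best
        merges.append((a, b))
        na, nb = len(clusters[a]), len(clusters[b])
        merged = tuple(sorted(clusters[a] + clusters[b]))
        rep = merged[0]
        del clusters[a], clusters[b]
        for other in list(clusters):
            lo_a, hi_a = sorted((other, a))
            lo_b, hi_b = sorted((other, b))
            dv = (na * d.pop((lo_a, hi_a)) + nb * d.pop((lo_b, hi_b))) / (na + nb)
            d[tuple(sorted((other, rep)))] = dv
        clusters[rep] = merged
    return merges


def build_msa(
    seqs: Iterable,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> Alignment:
    """Progressive multiple alignment of sequence records.

    Accepts SequenceRecord-like objects (``.accession``/``.sequence``) or
    (accession, sequence) pairs.  Sequences are processed in accession
    order, so the result is independent of input order.
    """
    items: list[tuple[str, str]] = []
    for s in seqs:
        if hasattr(s, "accession"):
            items.append((s.accession, _check_seq(s.sequence)))
        else:
            acc, seq = s
            items.append((acc, _check_seq(seq)))
    if not items:
        raise ValidationError("build_msa requires at least one sequence")
    if len({a for a, _ in items}) != len(items):
        raise ValidationError("duplicate accessions in MSA input")
    items.sort(key=lambda t: t[0])
    if len(items) == 1:
        log.warning("single sequence: returning a trivial one-row alignment")
        acc, seq = items[0]
        return Alignment(rows={acc: seq}, ncols=len(seq))

    by_acc = dict(items)
    names = [a for a, _ in items]
    dist = {
        (names[i], names[j]): _kmer_distance(by_acc[names[i]], by_acc[names[j]])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }
    profiles: dict[str, dict[str, str]] = {a: {a: by_acc[a]} for a in names}
    for a, b in _upgma_order(names, dist):
        merged = _align_profiles(profiles.pop(a), profiles.pop(b), gap_open, gap_extend)
        rep = min(merged)
        profiles[rep] = merged
    final = profiles.popitem()[1]
    rows = {a: final[a] for a in sorted(final)}
    ncols = len(next(iter(rows.values())))
    al = Alignment(rows=rows, ncols=ncols)
    for acc in rows:
        if al.degapped(acc) != by_acc[acc]:
            raise AssertionError(f"alignment row {acc} does not degap to its input")
    return al


def conservation_scores(al: Alignment) -> dict[str, float]:
    """Per-sequence conservation in [0, 1].

    Column conservation is the frequency of the modal non-gap residue
    among non-gap entries; columns that are majority-gap (> 50% gaps)
    score 0.  A sequence's score is the mean column conservation over the
    columns where it has a residue.
    """
    if not al.rows:
        raise ValidationError("empty alignment")
    accs = list(al.rows)
    nrows = len(accs)
    col_scores = []
    for j in range(al.ncols):
        column = [al.rows[a][j] for a in accs]
        residues = [c for c in column if c != "-"]
        if len(residues) * 2 < nrows:
            col_scores.append(0.0)
        else:
            top = max(residues.count(c) for c in set(residues))
            col_scores.append(top / len(residues))
    out = {}
    for a in accs:
        cols = [col_scores[j] for j in range(al.ncols) if al.rows[a][j] != "-"]
        out[a] = sum(cols) / len(cols) if cols else 0.0
    return out


def sum_of_pairs(rows: dict[str, str]) -> float:
    """Substitution-only sum-of-pairs score (gap pairs contribute 0)."""
    accs = list(rows)
    total = 0.0
    table = blosum62()
    for x in range(len(accs)):
        for y in range(x + 1, len(accs)):
            for a, b in zip(rows[accs[x]], rows[accs[y]]):
                if a != "-" and b != "-":
                    total += table[(a, b)]
    return total
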