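"""Per-sequence annotations: host distance and physicochemical properties.

Candidate enzymes are annotated with the taxonomy-tree distance from their
source organism to the intended host chassis, and with standard sequence
physicochemistry: average molecular weight, isoelectric point (bisection on
the Henderson–Hasselbalch net charge with the classic EMBOSS pKa set),
grand average of hydropathy (GRAVY, Kyte–Doolittle), hydropathy-window
transmembrane segments, and a heuristic solubility proxy.

All residue tables are frozen TSV data files shipped with the package so
the numbers are reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from ._tables import STANDARD_AA, kyte_doolittle, pka_table, residue_masses
from .database import TaxonomyTree
from .errors import ValidationError

log = logging.getLogger(__name__)

TM_WINDOW = 19
TM_THRESHOLD = 1.6
TM_MIN_LEN = 15


@dataclass(frozen=True)
class SequenceProperties:
    length: int
    mol_weight: float  # Daltons, average masses
    pI: float  # pH units
    gravy: float  # mean Kyte-Doolittle hydropathy
    tm_segments: tuple[tuple[int, int], ...]  # 1-based inclusive intervals
    solubility_score: float  # heuristic, in (0, 1), higher = more soluble

    def __post_init__(self):
        if self.length <= 0 or self.mol_weight <= 0:
            raise ValidationError("empty sequence has no properties")
        if not 0 < self.pI < 14:
            raise ValidationError(f"pI {self.pI} outside (0, 14)")


def taxonomic_distance(tree: TaxonomyTree, a: str, b: str) -> float:
    """Path length between two taxa through their lowest common ancestor.

    Summed branch lengths when the tree carries them on every edge, edge
    count otherwise.  A metric on the tree's labelled taxa.
    """
    return tree.distance(a, b)


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValidationError("empty sequence")
    for i, ch in enumerate(seq):
        if ch not in STANDARD_AA and ch != "X":
            raise ValidationError(f"illegal residue {ch!r} at position {i + 1}")
    return seq


def molecular_weight(seq: str) -> float:
    """Average molecular mass of the free peptide: residue masses plus one
    water.  X (unknown residue) is skipped."""
    seq = _check_sequence(seq)
    masses = residue_masses()
    return sum(masses[a] for a in seq if a != "X") + masses["H2O"]


def net_charge(seq: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge at a given pH, including termini."""
    seq = _check_sequence(seq)
    pka = pka_table()
    counts = {g: 0 for g in pka}
    counts["Nterm"] = counts["Cterm"] = 1
    for a in seq:
        if a in counts:
            counts[a] += 1
    charge = 0.0
    for group, n in counts.items():
        if n == 0:
            continue
        pk, sign = pka[group]
        if sign > 0:
            charge += n / (1.0 + 10.0 ** (ph - pk))
        else:
            charge -= n / (1.0 + 10.0 ** (pk - ph))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-3) -> float:
    """pH at which the net charge vanishes, found by bisection on (0, 14).

    Net charge is strictly decreasing in pH, so bisection converges; the
    loop stops when |charge| < tol."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        c = net_charge(seq, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value, X skipped."""
    seq = _check_sequence(seq)
    kd = kyte_doolittle()
    vals = [kd[a] for a in seq if a != "X"]
    if not vals:
        raise ValidationError("sequence contains no standard residues")
    return sum(vals) / len(vals)


def predict_tm_segments(
    seq: str, window: int = TM_WINDOW, threshold: float = TM_THRESHOLD
) -> tuple[tuple[int, int], ...]:
    """Hydropathy-window transmembrane segment prediction.

    Sliding Kyte–Doolittle window means; maximal runs of consecutive
    window centers above the threshold are expanded to the full window
    extent, merged when overlapping, and segments shorter than
    ``TM_MIN_LEN`` residues are discarded.  X residues score 0.
    Returns 1-based inclusive (start, end) intervals.
    """
    seq = _check_sequence(seq)
    if window % 2 == 0:
        raise ValidationError("window must be odd")
    if len(seq) < window:
        log.warning("sequence shorter than window %d: no TM prediction", window)
        return ()
    kd = kyte_doolittle()
    vals = [kd.get(a, 0.0) for a in seq]
    half = window // 2
    n = len(seq)
    means = []
    s = sum(vals[:window])
    means.append(s / window)
    for c in range(half + 1, n - half):
        s += vals[c + half] - vals[c - half - 1]
        means.append(s / window)
    # centers run from `half` to `n - half - 1` (0-based)
    above = [c for c, m in zip(range(half, n - half), means) if m > threshold]
    raw: list[list[int]] = []
    for c in above:
        if raw and c == raw[-1][1] + 1:
            raw[-1][1] = c
        else:
            raw.append([c, c])
    segments: list[list[int]] = []
    for c0, c1 in raw:
        start = max(0, c0 - half)
        end = min(n - 1, c1 + half)
        if segments and start <= segments[-1][1] + 1:
            segments[-1][1] = max(segments[-1][1], end)
        else:
            segments.append([start, end])
    return tuple(
        (s + 1, e + 1) for s, e in segments if (e - s + 1) >= TM_MIN_LEN
    )


def solubility_score(seq: str) -> float:
    """Heuristic solubility proxy in (0, 1): a logistic transform of the
    hydropathy adjusted by the absolute fractional net charge at pH 7.

        score = 1 / (1 + exp(gravy - 2*|net charge at pH 7| / length))

    Hydrophilic, charged sequences score high.  This is a documented
    heuristic, not a trained predictor; swap in another callable via
    :func:`physicochemical`'s ``solubility`` hook for production use.
    """
    seq = _check_sequence(seq)
    g = gravy(seq)
    q = abs(net_charge(seq, 7.0)) / len(seq)
    return 1.0 / (1.0 + math.exp(g - 2.0 * q))


def physicochemical(seq: str, solubility=solubility_score) -> SequenceProperties:
    """All physicochemical annotations for one amino-acid sequence."""
    seq = _check_sequence(seq)
    return SequenceProperties(
        length=len(seq),
        mol_weight=molecular_weight(seq),
        pI=isoelectric_point(seq),
        gravy=gravy(seq),
        tm_segments=predict_tm_segments(seq),
        solubility_score=solubility(seq),
    )
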