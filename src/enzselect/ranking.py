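"""Candidate collection, weighted composite scoring, and CSV output.

The selection walks database reactions in order of decreasing similarity
to the query and collects the sequences linked to each reaction — never
splitting one reaction's sequence set — until the requested number of
distinct candidates is reached.  Each candidate row then carries the
similarity of the reaction through which it was first collected, host
distance, evidence, physicochemistry and (optionally) conservation, and a
user-weighted composite score over min–max-normalized columns.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from typing import Optional

from .annotations import SequenceProperties
from .database import EnzymeDatabase, ScoreColumn
from .errors import ConfigError
from .reactions import UNKNOWN, Reaction
from .similarity import RxnSimilarity

log = logging.getLogger(__name__)

# orientation of every scoreable column; evidence level 1 is the strongest,
# so smaller is better, as for host distance
COLUMN_ORIENTATION = {
    "rxn_similarity": "higher_better",
    "tax_distance": "lower_better",
    "evidence": "lower_better",
    "conservation": "higher_better",
    "solubility": "higher_better",
    "gravy": "lower_better",
    "n_tm_segments": "lower_better",
}

DEFAULT_WEIGHTS = {
    "rxn_similarity": 1.0,
    "tax_distance": 1.0,
    "evidence": 1.0,
    "conservation": 1.0,
}

CSV_COLUMNS = [
    "accession", "description", "organism", "taxon_id", "reaction_id",
    "similarity", "direction", "consensus_agreement", "evidence",
    "tax_distance", "conservation", "length", "mol_weight", "pI", "gravy",
    "n_tm_segments", "solubility", "combined_score",
]


@dataclass
class CandidateRow:
    accession: str
    description: str
    organism: str
    taxon_id: str
    reaction_id: str
    rxn_similarity: float
    matched_direction: str
    consensus_flag: Optional[bool]  # None when the db reaction has no consensus
    evidence: int
    tax_distance: Optional[float] = None
    conservation: Optional[float] = None
    properties: Optional[SequenceProperties] = None
    combined_score: Optional[float] = None

    def column(self, name: str) -> Optional[float]:
        if name == "rxn_similarity":
            return self.rxn_similarity
        if name == "tax_distance":
            return self.tax_distance
        if name == "evidence":
            return float(self.evidence)
        if name == "conservation":
            return self.conservation
        if self.properties is None:
            return None
        if name == "solubility":
            return self.properties.solubility_score
        if name == "gravy":
            return self.properties.gravy
        if name == "n_tm_segments":
            return float(len(self.properties.tm_segments))
        raise ConfigError(f"unknown score column {name!r}")


def make_score_config(weights: Optional[dict] = None) -> dict[str, ScoreColumn]:
    """Build a per-column ScoreConfig from a name->weight mapping."""
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    cfg = {}
    for name, weight in w.items():
        if name not in COLUMN_ORIENTATION:
            raise ConfigError(
                f"unknown score column {name!r}; valid: {sorted(COLUMN_ORIENTATION)}"
            )
        if weight < 0 or weight != weight:
            raise ConfigError(f"weight for {name!r} must be finite and >= 0")
        cfg[name] = ScoreColumn(weight=float(weight), orientation=COLUMN_ORIENTATION[name])
    if not any(c.weight > 0 for c in cfg.values()):
        raise ConfigError("at least one score weight must be positive")
    return cfg


def collect_candidates(
    ranked: list[tuple[Reaction, RxnSimilarity]],
    db: EnzymeDatabase,
    top_n: int = 50,
) -> list[CandidateRow]:
    """Traverse reactions by decreasing similarity, collecting each linked
    sequence not yet seen, and stop only at a reaction boundary once at
    least top_n distinct accessions are held (a reaction's sequence set is
    never split).  Each row keeps the similarity of the reaction through
    which the sequence was first collected."""
    rows: list[CandidateRow] = []
    seen: set[str] = set()
    for reaction, sim in ranked:
        for acc in db.links.get(reaction.id, ()):
            if acc in seen:
                continue
            seen.add(acc)
            rec = db.sequences[acc]
            flag = None
            if reaction.preferred_direction != UNKNOWN:
                flag = sim.matched_direction == reaction.preferred_direction
            rows.append(
                CandidateRow(
                    accession=acc,
                    description=rec.description,
                    organism=db.taxonomy.name_of(rec.taxon_id),
                    taxon_id=rec.taxon_id,
                    reaction_id=reaction.id,
                    rxn_similarity=sim.score,
                    matched_direction=sim.matched_direction,
                    consensus_flag=flag,
                    evidence=rec.evidence,
                )
            )
        if len(rows) >= top_n:
            break
    if not rows:
        log.warning("no sequences reachable from the ranked reaction list")
    return rows


def merge_candidates(tables: list[list[CandidateRow]]) -> list[CandidateRow]:
    """Merge candidate tables from fanned-out sub-queries, keeping for each
    accession the row with the best similarity (ties: first table wins)."""
    best: dict[str, CandidateRow] = {}
    for table in tables:
        for row in table:
            cur = best.get(row.accession)
            if cur is None or row.rxn_similarity > cur.rxn_similarity:
                best[row.accession] = row
    return sorted(best.values(), key=lambda r: (-r.rxn_similarity, r.accession))


def combined_score(
    rows: list[CandidateRow], cfg: Optional[dict[str, ScoreColumn]] = None
) -> list[CandidateRow]:
    """Weighted composite in [0, 1] over min–max-normalized columns.

    lower_better columns are flipped (1 - normalized); a column that is
    constant across the table normalizes to 0.5 for every row; a column
    absent from every row (e.g. conservation without an MSA) is dropped
    from the weighting.
    """
    if cfg is None:
        cfg = make_score_config()
    if not rows:
        return rows
    active = {n: c for n, c in cfg.items() if c.weight > 0}
    norm: dict[str, dict[str, float]] = {}
    for name, col in list(active.items()):
        values = {r.accession: r.column(name) for r in rows}
        present = {k: v for k, v in values.items() if v is not None}
        if not present:
            log.info("score column %s absent from all rows; weight dropped", name)
            del active[name]
            continue
        vmin, vmax = min(present.values()), max(present.values())
        scaled = {}
        for acc, v in present.items():
            x = 0.5 if vmax == vmin else (v - vmin) / (vmax - vmin)
            scaled[acc] = 1.0 - x if col.orientation == "lower_better" else x
        norm[name] = scaled
    if not active:
        raise ConfigError("no score column with positive weight has any values")
    total_w = sum(c.weight for c in active.values())
    out = []
    for r in rows:
        num = sum(
            c.weight * norm[name].get(r.accession, 0.5)
            for name, c in active.items()
        )
        out.append(replace(r, combined_score=num / total_w))
    return out


def sort_rows(rows: list[CandidateRow]) -> list[CandidateRow]:
    return sorted(
        rows,
        key=lambda r: (
            -(r.combined_score if r.combined_score is not None else 0.0),
            -r.rxn_similarity,
            r.accession,
        ),
    )


def _fmt(v, spec: str) -> str:
    return "" if v is None else format(v, spec)


def row_to_record(r: CandidateRow) -> dict[str, str]:
    p = r.properties
    return {
        "accession": r.accession,
        "description": r.description,
        "organism": r.organism,
        "taxon_id": r.taxon_id,
        "reaction_id": r.reaction_id,
        "similarity": _fmt(r.rxn_similarity, ".6f"),
        "direction": r.matched_direction,
        "consensus_agreement": "" if r.consensus_flag is None else ("yes" if r.consensus_flag else "no"),
        "evidence": str(r.evidence),
        "tax_distance": _fmt(r.tax_distance, "g"),
        "conservation": _fmt(r.conservation, ".6f"),
        "length": "" if p is None else str(p.length),
        "mol_weight": "" if p is None else _fmt(p.mol_weight, ".2f"),
        "pI": "" if p is None else _fmt(p.pI, ".2f"),
        "gravy": "" if p is None else _fmt(p.gravy, ".4f"),
        "n_tm_segments": "" if p is None else str(len(p.tm_segments)),
        "solubility": "" if p is None else _fmt(p.solubility_score, ".6f"),
        "combined_score": _fmt(r.combined_score, ".6f"),
    }


def rank_and_write(rows: list[CandidateRow], out) -> list[CandidateRow]:
    """Sort rows (composite desc, similarity desc, accession asc) and write
    the frozen-column CSV; returns the sorted rows."""
    ordered = sort_rows(rows)
    with open(out, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for r in ordered:
            writer.writerow(row_to_record(r))
    return ordered
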