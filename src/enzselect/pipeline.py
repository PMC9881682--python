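"""End-to-end query execution: parse → screen → collect → annotate → score.

This is the composition layer behind both the CLI and the REST service.
An EC-number or external-id query can resolve to several stored reactions;
such queries fan out into one similarity screen per resolved reaction and
the candidate tables are merged by best similarity before scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .annotations import physicochemical
from .config import SimilarityOptions
from .database import EnzymeDatabase, rank_database_reactions
from .errors import ValidationError
from .msa import Alignment, build_msa, conservation_scores
from .ranking import (
    CandidateRow,
    collect_candidates,
    combined_score,
    make_score_config,
    merge_candidates,
    sort_rows,
)
from .reactions import (
    Reaction,
    parse_reaction_smiles,
    parse_rxn_file,
    parse_smirks_rule,
    resolve_id_query,
)

log = logging.getLogger(__name__)

QUERY_FORMS = ("smiles", "smirks", "rxn", "ec", "xref")


@dataclass
class QueryRequest:
    """One enzyme-selection query.  Exactly one query form must be set;
    ``rxn`` holds the text content of an MDL .rxn file."""

    host: str
    smiles: Optional[str] = None
    smirks: Optional[str] = None
    rxn: Optional[str] = None
    ec: Optional[str] = None
    xref: Optional[str] = None
    direction: str = "both"  # "both" | "preferred"
    targets: int = 50
    weights: Optional[dict] = None
    msa: bool = True

    def __post_init__(self):
        forms = [f for f in QUERY_FORMS if getattr(self, f)]
        if len(forms) != 1:
            raise ValidationError(
                f"exactly one query form required, got {forms or 'none'}"
            )
        if self.targets < 1:
            raise ValidationError("targets must be >= 1")
        if self.direction not in ("both", "preferred"):
            raise ValidationError(f"direction must be 'both' or 'preferred', got {self.direction!r}")


@dataclass
class QueryResult:
    rows: list[CandidateRow]
    alignment: Optional[Alignment] = None


def resolve_request_reactions(req: QueryRequest, db: EnzymeDatabase) -> list[Reaction]:
    if req.smiles:
        return [parse_reaction_smiles(req.smiles)]
    if req.smirks:
        return [parse_smirks_rule(req.smirks)]
    if req.rxn:
        return [parse_rxn_file(req.rxn)]
    return resolve_id_query(req.ec or req.xref, db)


def run_query(
    req: QueryRequest,
    db: EnzymeDatabase,
    options: Optional[SimilarityOptions] = None,
) -> QueryResult:
    """Execute a query end to end and return scored, sorted candidates."""
    opts = options or SimilarityOptions()
    if req.host not in db.taxonomy:
        raise ValidationError(f"host taxon {req.host!r} absent from the taxonomy tree")
    mode = "preferred_only" if req.direction == "preferred" else "both"

    queries = resolve_request_reactions(req, db)
    tables = []
    for q in queries:
        ranked = rank_database_reactions(
            q, db, mode=mode, mask=opts.mask, nbits=opts.nbits, radius=opts.radius
        )
        tables.append(collect_candidates(ranked, db, top_n=req.targets))
    rows = merge_candidates(tables)

    for i, row in enumerate(rows):
        rec = db.sequences[row.accession]
        rows[i].tax_distance = db.taxonomy.distance(req.host, rec.taxon_id)
        rows[i].properties = physicochemical(rec.sequence)

    alignment = None
    if req.msa and len(rows) >= 2:
        alignment = build_msa(db.sequences[r.accession] for r in rows)
        cons = conservation_scores(alignment)
        for i, row in enumerate(rows):
            rows[i].conservation = cons[row.accession]
    elif req.msa:
        log.warning("fewer than 2 candidates: skipping MSA/conservation")

    cfg = make_score_config(req.weights)
    rows = combined_score(rows, cfg)
    return QueryResult(rows=sort_rows(rows), alignment=alignment)
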