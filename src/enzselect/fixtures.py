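"""Deterministic synthetic fixture databases.

Generates a complete on-disk database (reactions, molecules, sequences,
links, taxonomy, consensus) from a seed, so every part of the package is
testable offline.  Molecules come from a curated pool of small-metabolite
SMILES; reactions are random pool combinations with coefficients in {1,2};
sequence families are mutants of random 120-residue parents; the taxonomy
is a random binary tree with unit branch lengths.

Every fixture also plants the four-step pinocembrin pathway (PAL, 4CL,
CHS, CHI) with hand-assigned sequences as the worked example, with
*Escherichia coli* (taxon 562) present as the intended host.  CoA
thioesters use a methanethiol surrogate (CS / CSC(=O)R) so the compounds
stay small and stable; the sequences are generated, not real enzymes — no
biological claim attaches to fixtures.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path

from .errors import FixtureError
from .reactions import canonical_smiles

AA = "ACDEFGHIKLMNPQRSTVWY"

# Curated small-metabolite pool (name, SMILES); canonicalized on use.
COMPOUND_POOL = [
    ("ethanol", "CCO"),
    ("acetaldehyde", "CC=O"),
    ("acetate", "CC(=O)O"),
    ("pyruvate", "CC(=O)C(=O)O"),
    ("L-lactate", "C[C@H](O)C(=O)O"),
    ("glycerol", "OCC(O)CO"),
    ("succinate", "OC(=O)CCC(=O)O"),
    ("fumarate", "OC(=O)/C=C/C(=O)O"),
    ("L-malate", "OC(=O)C[C@H](O)C(=O)O"),
    ("citrate", "OC(=O)CC(O)(CC(=O)O)C(=O)O"),
    ("oxaloacetate", "OC(=O)CC(=O)C(=O)O"),
    ("2-oxoglutarate", "OC(=O)CCC(=O)C(=O)O"),
    ("D-glucose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"),
    ("glycine", "NCC(=O)O"),
    ("L-alanine", "C[C@H](N)C(=O)O"),
    ("L-serine", "N[C@@H](CO)C(=O)O"),
    ("L-aspartate", "N[C@@H](CC(=O)O)C(=O)O"),
    ("L-glutamate", "N[C@@H](CCC(=O)O)C(=O)O"),
    ("benzoate", "OC(=O)c1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("catechol", "Oc1ccccc1O"),
    ("L-tyrosine", "N[C@@H](Cc1ccc(O)cc1)C(=O)O"),
    ("L-tryptophan", "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O"),
    ("urea", "NC(N)=O"),
    ("formate", "OC=O"),
    ("methanol", "CO"),
    ("ethanolamine", "NCCO"),
    ("putrescine", "NCCCCN"),
    ("shikimate", "O[C@@H]1CC(=C[C@H](O)[C@H]1O)C(=O)O"),
    ("4-hydroxybenzoate", "OC(=O)c1ccc(O)cc1"),
]

# Pinocembrin pathway compounds (CoA as methanethiol surrogate).
L_PHENYLALANINE = "N[C@@H](Cc1ccccc1)C(=O)O"
TRANS_CINNAMATE = "OC(=O)/C=C/c1ccccc1"
AMMONIA = "N"
WATER = "O"
CO2 = "O=C=O"
COA_SURROGATE = "CS"
CINNAMOYL_SUR = "CSC(=O)/C=C/c1ccccc1"
MALONYL_SUR = "CSC(=O)CC(=O)O"
PINOCEMBRIN_CHALCONE = "O=C(/C=C/c1ccccc1)c1c(O)cc(O)cc1O"
PINOCEMBRIN = "O=C1C[C@H](c2ccccc2)Oc2cc(O)cc(O)c12"

PAL_SMILES = f"{L_PHENYLALANINE}>>{TRANS_CINNAMATE}.{AMMONIA}"
HOST_TAXON = "562"  # Escherichia coli

PATHWAY = [
    # (reaction id, substrates, products, EC, xref)
    ("RX_PAL", [(L_PHENYLALANINE, 1)], [(TRANS_CINNAMATE, 1), (AMMONIA, 1)],
     "4.3.1.24", "MNXR-PAL"),
    ("RX_4CL", [(TRANS_CINNAMATE, 1), (COA_SURROGATE, 1)],
     [(CINNAMOYL_SUR, 1), (WATER, 1)], "6.2.1.12", "MNXR-4CL"),
    ("RX_CHS", [(CINNAMOYL_SUR, 1), (MALONYL_SUR, 3)],
     [(PINOCEMBRIN_CHALCONE, 1), (COA_SURROGATE, 4), (CO2, 3)], "2.3.1.74", "MNXR-CHS"),
    ("RX_CHI", [(PINOCEMBRIN_CHALCONE, 1)], [(PINOCEMBRIN, 1)], "5.5.1.6", "MNXR-CHI"),
    # serine ammonia-lyase: a second 4.3.1.x entry so EC-prefix queries fan out
    ("RX_SAL", [("N[C@@H](CO)C(=O)O", 1)], [("CC(=O)C(=O)O", 1), (AMMONIA, 1)],
     "4.3.1.17", "MNXR-SAL"),
]

PATHWAY_NAMES = {
    L_PHENYLALANINE: "L-phenylalanine",
    TRANS_CINNAMATE: "trans-cinnamate",
    AMMONIA: "ammonia",
    WATER: "water",
    CO2: "carbon dioxide",
    COA_SURROGATE: "CoA-surrogate(methanethiol)",
    CINNAMOYL_SUR: "cinnamoyl-CoA-surrogate",
    MALONYL_SUR: "malonyl-CoA-surrogate",
    PINOCEMBRIN_CHALCONE: "pinocembrin chalcone",
    PINOCEMBRIN: "pinocembrin",
}

# conservative bound on distinct random reactions the 30-compound pool yields
MAX_REACTIONS = 2000

# hand-assigned worked-example family: strong evidence, host-proximal taxa
PAL_ACCESSIONS = ("PAL_HOST01", "PAL_PLANT01", "PAL_PLANT02", "PAL_YEAST01")
PAL_EVIDENCE = (1, 1, 2, 2)


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 7
    n_reactions: int = 40  # total, including the 5 planted reactions
    n_seqs_per_reaction: int = 6
    n_taxa: int = 32
    mutation_rate: float = 0.1

    def __post_init__(self):
        if min(self.n_reactions, self.n_seqs_per_reaction, self.n_taxa) < 1:
            raise FixtureError("all fixture counts must be >= 1")
        if not 0.0 <= self.mutation_rate <= 0.5:
            raise FixtureError("mutation_rate must be in [0, 0.5]")
        if self.n_reactions < len(PATHWAY):
            raise FixtureError(f"n_reactions must be >= {len(PATHWAY)} (planted pathway)")
        if self.n_reactions > MAX_REACTIONS:
            raise FixtureError(
                f"compound pool supports at most {MAX_REACTIONS} distinct reactions"
            )
        if self.n_taxa < 2:
            raise FixtureError("need at least 2 taxa")


def random_sequence(rng: random.Random, length: int = 120) -> str:
    return "M" + "".join(rng.choice(AA) for _ in range(length - 1))


def mutate(rng: random.Random, parent: str, rate: float) -> str:
    out = []
    for a in parent:
        if rng.random() < rate:
            out.append(rng.choice([x for x in AA if x != a]))
        else:
            out.append(a)
    return "".join(out)


def _random_taxonomy(rng: random.Random, n_taxa: int) -> tuple[str, list[str]]:
    """Random binary tree over n_taxa leaves, unit branch lengths.
    Taxon 562 (Escherichia coli) is always a leaf."""
    taxa = [HOST_TAXON] + [f"T{i:03d}" for i in range(1, n_taxa)]
    labels = {HOST_TAXON: f"{HOST_TAXON}|Escherichia_coli"}
    for t in taxa[1:]:
        labels[t] = f"{t}|Organism_{t}"
    nodes = [f"{labels[t]}:1" for t in taxa]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append(f"({a},{b}):1")
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    return newick, taxa


def _side_cell(members: list[tuple[str, int]]) -> str:
    return ";".join(s if c == 1 else f"{s}*{c}" for s, c in members)


def generate_fixture(spec: FixtureSpec, out) -> dict:
    """Write a fixture database directory; returns a manifest of what was
    planted.  Byte-identical output for identical specs."""
    rng = random.Random(spec.seed)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    pool = [(name, canonical_smiles(s)) for name, s in COMPOUND_POOL]
    names = {s: n for n, s in pool}
    for s, n in PATHWAY_NAMES.items():
        names[canonical_smiles(s)] = n

    # --- reactions ---------------------------------------------------------
    reactions: list[tuple[str, list, list, str, str]] = []
    signatures: set = set()
    for rid, subs, prods, ec, xref in PATHWAY:
        subs = [(canonical_smiles(s), c) for s, c in subs]
        prods = [(canonical_smiles(s), c) for s, c in prods]
        reactions.append((rid, subs, prods, ec, xref))
        signatures.add((frozenset(subs), frozenset(prods)))

    attempts = 0
    while len(reactions) < spec.n_reactions:
        attempts += 1
        if attempts > 200 * spec.n_reactions:
            raise FixtureError(
                f"compound pool exhausted: cannot assemble {spec.n_reactions} distinct reactions"
            )
        k_s, k_p = rng.randint(1, 2), rng.randint(1, 2)
        chosen = rng.sample(pool, k_s + k_p)
        subs = [(s, rng.randint(1, 2)) for _, s in chosen[:k_s]]
        prods = [(s, rng.randint(1, 2)) for _, s in chosen[k_s:]]
        sig = (frozenset(subs), frozenset(prods))
        if sig in signatures:
            continue
        signatures.add(sig)
        idx = len(reactions) - len(PATHWAY) + 1
        rid = f"R{idx:04d}"
        ec = f"{rng.randint(1, 6)}.{rng.randint(1, 9)}.{rng.randint(1, 9)}.{rng.randint(1, 99)}"
        reactions.append((rid, subs, prods, ec, f"XR-{rid}"))

    # --- taxonomy -----------------------------------------------------------
    newick, taxa = _random_taxonomy(rng, spec.n_taxa)

    # --- sequences and links ------------------------------------------------
    sequences: list[tuple[str, str, int, str, str]] = []  # acc, taxon, evidence, descr, seq
    links: list[tuple[str, str]] = []

    pal_parent = random_sequence(rng)
    pal_taxa = [HOST_TAXON] + [taxa[1 + (i % (len(taxa) - 1))] for i in range(3)]
    for acc, ev, taxon in zip(PAL_ACCESSIONS, PAL_EVIDENCE, pal_taxa):
        seq = mutate(rng, pal_parent, 0.05)
        sequences.append((acc, taxon, ev, f"phenylalanine ammonia-lyase family member {acc}", seq))
        links.append(("RX_PAL", acc))

    counter = 1
    for rid, *_ in reactions:
        if rid == "RX_PAL":
            continue
        parent = random_sequence(rng)
        for _ in range(spec.n_seqs_per_reaction):
            acc = f"Q{counter:05d}"
            counter += 1
            seq = mutate(rng, parent, spec.mutation_rate)
            taxon = rng.choice(taxa)
            ev = rng.randint(1, 5)
            sequences.append((acc, taxon, ev, f"synthetic enzyme family {rid}", seq))
            links.append((rid, acc))

    # --- consensus ----------------------------------------------------------
    consensus: list[tuple[str, str]] = [(rid, "forward") for rid, *_ in PATHWAY]
    for rid, *_ in reactions[len(PATHWAY):]:
        if rng.random() < 0.7:
            consensus.append((rid, rng.choice(["forward", "reverse"])))

    # --- write --------------------------------------------------------------
    def write(name: str, text: str):
        (out / name).write_text(text, encoding="utf-8", newline="\n")

    all_smiles = sorted({s for _, subs, prods, _, _ in reactions for s, _ in subs + prods})
    write(
        "molecules.tsv",
        "".join(f"M{i + 1:04d}\t{s}\t{names.get(s, '')}\n" for i, s in enumerate(all_smiles)),
    )
    write(
        "reactions.tsv",
        "".join(
            f"{rid}\t{_side_cell(subs)}\t{_side_cell(prods)}\t{ec}\t{xref}\n"
            for rid, subs, prods, ec, xref in sorted(reactions)
        ),
    )
    write(
        "sequences.fasta",
        "".join(
            f">{acc}|{taxon}|{ev}|{descr}\n{seq}\n"
            for acc, taxon, ev, descr, seq in sorted(sequences)
        ),
    )
    write("links.tsv", "".join(f"{rid}\t{acc}\n" for rid, acc in sorted(links)))
    write("taxonomy.nwk", newick + "\n")
    write("consensus.tsv", "".join(f"{rid}\t{d}\n" for rid, d in sorted(consensus)))

    manifest = {
        "seed": spec.seed,
        "n_reactions": len(reactions),
        "n_sequences": len(sequences),
        "n_links": len(links),
        "n_taxa": len(taxa),
        "mutation_rate": spec.mutation_rate,
        "host_taxon": HOST_TAXON,
        "pal_reaction_id": "RX_PAL",
        "pal_query_smiles": PAL_SMILES,
        "pal_accessions": list(PAL_ACCESSIONS),
    }
    write("manifest.json", json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
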