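# enzselect

Enzyme sequence selection for metabolic pathway design.

When a synthetic-biology pathway is designed — by hand or by a
retrosynthesis tool emitting reaction SMARTS rules — each reaction step
still needs an enzyme, and the best candidate is rarely the first database
hit: it should catalyse a *similar* transformation, come from an organism
close to the intended host chassis, be well annotated, sit in a conserved
family, and be expressible (soluble, not membrane-bound). `enzselect`
ranks candidate enzyme sequences from a local reaction–enzyme–organism
database on exactly those criteria. Target reactions do not need to exist
in the database, so the tool also works for non-natural transformations.

## Method

A query reaction (reaction SMILES, SMARTS/SMIRKS rule, MDL `.rxn` file, or
an EC number / reaction id resolved against the database) is screened
against every database reaction:

- each compound is encoded as a circular Morgan fingerprint (radius 2,
  1024 bits, stereo-agnostic) and compared by the Tanimoto coefficient
  T(A,B) = |A∩B| / |A∪B|;
- per side, compounds are matched one-to-one by a greedy maximum
  assignment on the pairwise Tanimoto matrix; the side score is the sum of
  matched values divided by the size of the larger side (optionally after
  masking currency metabolites such as water, ATP and NAD(H));
- the reaction score is the mean of the substrate-side and product-side
  scores, taken either as the better of the forward/reverse orientations
  or restricted to the database reaction's curated consensus direction.

Walking reactions by decreasing similarity, the linked sequences are
collected (never splitting one reaction's sequence set) until the requested
number of candidates is reached. Each candidate is annotated with the
taxonomy-tree distance to the host chassis, its UniProt-style evidence
level (1 = protein level … 5 = uncertain), physicochemical properties
(average MW, pI by Henderson–Hasselbalch bisection, Kyte–Doolittle GRAVY,
hydropathy-window transmembrane segments, a heuristic solubility proxy),
and a conservation score from an internal progressive multiple alignment
(Gotoh affine-gap pairwise alignment, 3-mer UPGMA guide tree, BLOSUM62).
The final ranking is a weighted average of min–max-normalized columns
(default: equal weights on reaction similarity, host distance, evidence,
conservation), written as a CSV table.

## Worked example

The synthetic fixture database plants the four-step pinocembrin pathway
(PAL, 4CL, CHS, CHI) with *Escherichia coli* (taxon 562) as host. Querying
the PAL step — deamination of L-phenylalanine to trans-cinnamate and
ammonia — retrieves the planted reaction and its sequences:

```bash
enzselect make-fixture --out demo --seed 7
enzselect query \
    --smiles "N[C@@H](Cc1ccccc1)C(=O)O>>OC(=O)/C=C/c1ccccc1.N" \
    --db demo --host 562 --targets 10 --out hits.csv
```

prints `10 candidate sequences written to hits.csv`; the top of the table:

| accession | organism | reaction | similarity | consensus | evidence | tax_distance | conservation | combined |
|---|---|---|---|---|---|---|---|---|
| PAL_HOST01 | Escherichia_coli | RX_PAL | 1.000000 | yes | 1 | 0 | 0.423333 | 0.750000 |
| PAL_PLANT01 | Organism_T001 | RX_PAL | 1.000000 | yes | 1 | 13 | 0.423333 | 0.500000 |
| Q00020 | Organism_T009 | RX_SAL | 0.503205 | yes | 1 | 13 | 0.684444 | 0.500000 |

The host's own PAL homolog leads: perfect reaction similarity (1.0), zero
host distance, protein-level evidence. The serine ammonia-lyase sequences
(RX_SAL) appear at similarity ≈ 0.50 because the two deaminations share an
amino-acid substrate pattern and an ammonia product. Re-weighting
(`--weights rxn_similarity=1,evidence=0.5`) reorders but never changes the
candidate set.

The same query is served over HTTP (`enzselect serve --db demo --port
8000`; `POST /query` with the request as JSON, `GET /health` for database
counts) and returns identical row content.

## Database layout

A database directory holds plain-text files: `reactions.tsv` (id,
substrate SMILES `;`-joined with `*n` coefficients, product SMILES, EC
`;`-joined, xrefs), `molecules.tsv` (id, SMILES, name), `sequences.fasta`
(headers `accession|taxon_id|evidence|description`), `links.tsv`
(reaction_id, accession), `taxonomy.nwk` (Newick, labels
`taxon_id|name`), and optional `consensus.tsv` (reaction_id,
forward/reverse). `enzselect make-fixture` writes a complete synthetic
example of the layout.
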