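"""Loaders for the frozen residue-property and substitution-matrix tables."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def _data_text(name: str) -> str:
    return resources.files("enzselect.data").joinpath(name).read_text(encoding="utf-8")


def _rows(name: str):
    for line in _data_text(name).splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            yield line.split("\t")


@lru_cache(maxsize=None)
def kyte_doolittle() -> dict[str, float]:
    return {r[0]: float(r[1]) for r in _rows("kyte_doolittle.tsv")}


@lru_cache(maxsize=None)
def residue_masses() -> dict[str, float]:
    return {r[0]: float(r[1]) for r in _rows("residue_masses.tsv")}


@lru_cache(maxsize=None)
def pka_table() -> dict[str, tuple[float, int]]:
    """group -> (pKa, charge sign of the ionized/protonated species)."""
    return {r[0]: (float(r[1]), int(r[2])) for r in _rows("pka.tsv")}


@lru_cache(maxsize=None)
def blosum62() -> dict[tuple[str, str], float]:
    lines = list(_rows("blosum62.tsv"))
    header = lines[0]
    # header row starts with an empty cell
    cols = header[1:] if header[0] == "" else header
    table: dict[tuple[str, str], float] = {}
    for row in lines[1:]:
        a = row[0]
        for b, v in zip(cols, row[1:]):
            table[(a, b)] = float(v)
    return table
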