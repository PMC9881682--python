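"""Similarity configuration: fingerprint parameters and currency mask.

A TOML config file may set::

    [fingerprint]
    nbits = 1024
    radius = 2

    [similarity]
    currency_mask_file = "currency_smiles.txt"

CLI flags override config-file values.  The currency mask defaults to
empty; a sample mask of ubiquitous cofactors ships with the package
(``enzselect/data/currency_smiles.txt``).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .similarity import DEFAULT_NBITS, DEFAULT_RADIUS, load_currency_mask


@dataclass(frozen=True)
class SimilarityOptions:
    nbits: int = DEFAULT_NBITS
    radius: int = DEFAULT_RADIUS
    mask: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.nbits < 8 or self.radius < 0:
            raise ConfigError("fingerprint.nbits must be >= 8 and radius >= 0")


def load_config(path) -> SimilarityOptions:
    """Read a TOML config file into SimilarityOptions."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    fp = data.get("fingerprint", {})
    sim = data.get("similarity", {})
    mask: frozenset[str] = frozenset()
    mask_file = sim.get("currency_mask_file")
    if mask_file:
        mask_path = Path(mask_file)
        if not mask_path.is_absolute():
            mask_path = Path(path).parent / mask_path
        mask = load_currency_mask(mask_path)
    return SimilarityOptions(
        nbits=int(fp.get("nbits", DEFAULT_NBITS)),
        radius=int(fp.get("radius", DEFAULT_RADIUS)),
        mask=mask,
    )
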