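"""Variable metadata: the data dictionary every stage shares.

A catalog is an ordered list of :class:`VariableMetadata`.  Domain tags
(biological / behavioral / psychosocial / socioeconomic / administrative)
drive the incremental-domain evaluation and the semantic audit; the
``modifiable`` flag is the actionability contract the scenario critic
enforces — administrative bookkeeping variables and downstream proxies
(e.g. a prescription-medication checklist) are never legitimate what-if
perturbation targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterable

DOMAINS = ("biological", "behavioral", "psychosocial", "socioeconomic", "administrative")
SIGNAL_DOMAINS = ("biological", "behavioral", "psychosocial", "socioeconomic")
DTYPES = ("continuous", "ordinal", "binary", "categorical")
WAVES = ("W2", "W3", "both")


class CatalogError(ValueError):
    """Invalid variable metadata or catalog."""


@dataclass(frozen=True)
class VariableMetadata:
    """One variable's entry in the data dictionary."""

    name: str
    label: str
    domain: str
    dtype: str
    scale_min: float | None = None
    scale_max: float | None = None
    wave: str = "both"
    modifiable: bool = False

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise CatalogError(f"{self.name}: unknown domain {self.domain!r}")
        if self.dtype not in DTYPES:
            raise CatalogError(f"{self.name}: unknown dtype {self.dtype!r}")
        if self.wave not in WAVES:
            raise CatalogError(f"{self.name}: unknown wave {self.wave!r}")
        if self.dtype == "ordinal":
            if self.scale_min is None or self.scale_max is None:
                raise CatalogError(f"{self.name}: ordinal variable needs scale_min/scale_max")
            if not self.scale_min < self.scale_max:
                raise CatalogError(f"{self.name}: scale_min must be < scale_max")
        if self.domain == "administrative" and self.modifiable:
            raise CatalogError(f"{self.name}: administrative variables are not modifiable")


def validate_catalog(catalog: Iterable[VariableMetadata]) -> list[VariableMetadata]:
    """Check name uniqueness; return the catalog as a list."""
    cat = list(catalog)
    seen: set[str] = set()
    for v in cat:
        if v.name in seen:
            raise CatalogError(f"duplicate variable name {v.name!r} in catalog")
        seen.add(v.name)
    return cat


def catalog_by_name(catalog: Iterable[VariableMetadata]) -> dict[str, VariableMetadata]:
    return {v.name: v for v in validate_catalog(catalog)}


def write_catalog(catalog: Iterable[VariableMetadata], path: str | Path) -> None:
    """Serialize a catalog as a JSON array (the data-dictionary file)."""
    Path(path).write_text(json.dumps([asdict(v) for v in catalog], indent=1))


def read_catalog(path: str | Path) -> list[VariableMetadata]:
    raw = json.loads(Path(path).read_text())
    return validate_catalog(VariableMetadata(**entry) for entry in raw)
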