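"""Species trait tables for floristic quality assessment.

Every downstream metric counts over the attributes stored here: nativity,
lifespan, growth form, genus, and the coefficient of conservatism (C-value).
The C-value is an expert-assigned integer on 0-10 expressing a native
species' fidelity to undisturbed habitat; introduced species carry none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

__all__ = [
    "Nativity",
    "Lifespan",
    "GrowthForm",
    "SpeciesTrait",
    "TraitTable",
    "TraitValidationError",
    "canonical_name",
    "load_trait_table",
    "write_trait_table",
]

TRAIT_COLUMNS = ["name", "genus", "nativity", "lifespan", "growth_form", "c_value"]


class Nativity(str, Enum):
    NATIVE = "native"
    INTRODUCED = "introduced"


class Lifespan(str, Enum):
    ANNUAL = "annual"
    BIENNIAL = "biennial"
    PERENNIAL = "perennial"


class GrowthForm(str, Enum):
    """Growth-form vocabulary; ``grass_like`` covers sedges and rushes."""

    GRASS = "grass"
    GRASS_LIKE = "grass_like"
    FORB = "forb"
    SHRUB = "shrub"
    OTHER = "other"


class TraitValidationError(ValueError):
    """A trait row (or the table as a whole) violates an invariant."""


def canonical_name(name: str) -> str:
    """Canonicalize a scientific name.

    Trims, collapses internal whitespace, capitalizes the genus token and
    lowercases subsequent epithets.  Hybrid markers ("×" or "x" standing
    alone) are preserved as "×".
    """
    tokens = name.strip().split()
    if not tokens:
        return ""
    out = [tokens[0].capitalize()]
    for tok in tokens[1:]:
        if tok in ("×", "x", "X"):
            out.append("×")
        else:
            out.append(tok.lower())
    return " ".join(out)


@dataclass(frozen=True)
class SpeciesTrait:
    """Trait record for one species.

    ``c_value`` may be ``None`` (absent); when present it must be an integer
    in [0, 10] and the species must be native — introduced species are never
    assigned a coefficient of conservatism.
    """

    name: str
    genus: str
    nativity: Nativity
    lifespan: Lifespan
    growth_form: GrowthForm
    c_value: Optional[int] = None

    def __post_init__(self) -> None:
        canon = canonical_name(self.name)
        if canon != self.name:
            object.__setattr__(self, "name", canon)
        expected_genus = self.name.split()[0] if self.name else ""
        if self.genus != expected_genus:
            if canonical_name(self.genus) == expected_genus:
                object.__setattr__(self, "genus", expected_genus)
            else:
                raise TraitValidationError(
                    f"{self.name!r}: genus {self.genus!r} is not the first "
                    f"token of the binomial ({expected_genus!r})"
                )
        if self.c_value is not None:
            if not (0 <= int(self.c_value) <= 10):
                raise TraitValidationError(
                    f"{self.name!r}: c_value {self.c_value} outside [0, 10]"
                )
            if self.nativity is not Nativity.NATIVE:
                raise TraitValidationError(
                    f"{self.name!r}: introduced species cannot carry a C-value"
                )

    @property
    def is_native(self) -> bool:
        return self.nativity is Nativity.NATIVE

    @property
    def is_native_perennial(self) -> bool:
        return self.is_native and self.lifespan is Lifespan.PERENNIAL

    @property
    def is_annual_biennial_or_introduced(self) -> bool:
        """Union membership for the disturbance-composition metric."""
        return (
            self.lifespan in (Lifespan.ANNUAL, Lifespan.BIENNIAL)
            or self.nativity is Nativity.INTRODUCED
        )

    @property
    def is_native_grass_or_grasslike(self) -> bool:
        return self.is_native and self.growth_form in (
            GrowthForm.GRASS,
            GrowthForm.GRASS_LIKE,
        )


@dataclass
class TraitTable:
    """Mapping from canonical species name to its trait record.

    Lookup is case- and whitespace-insensitive after canonicalization.
    Unknown species are a typed not-found outcome (``lookup`` returns
    ``None``) so callers can apply the unknown-species policy: counted in
    total-richness denominators, excluded from every native/C-value metric.
    """

    entries: dict[str, SpeciesTrait] = field(default_factory=dict)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return canonical_name(name) in self.entries

    def add(self, trait: SpeciesTrait) -> None:
        if trait.name in self.entries:
            raise TraitValidationError(f"duplicate canonical name {trait.name!r}")
        self.entries[trait.name] = trait

    def lookup(self, name: str) -> Optional[SpeciesTrait]:
        """Return the trait record for ``name``, or ``None`` if unknown."""
        return self.entries.get(canonical_name(name))

    def species(self) -> list[str]:
        return sorted(self.entries)

    def natives_with_c(self, names: Iterable[str]) -> list[SpeciesTrait]:
        """Trait records among ``names`` that are native and carry a C-value."""
        out = []
        for n in names:
            t = self.lookup(n)
            if t is not None and t.is_native and t.c_value is not None:
                out.append(t)
        return out


def _parse_c_value(raw: object) -> Optional[int]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip()
    if s == "":
        return None
    try:
        v = float(s)
    except ValueError as exc:
        raise TraitValidationError(f"c_value {raw!r} is not numeric") from exc
    if v != int(v):
        raise TraitValidationError(f"c_value {raw!r} is not an integer")
    return int(v)


def load_trait_table(
    path: Union[str, Path], sep: Optional[str] = None, provenance: str = ""
) -> TraitTable:
    """Load a delimited trait table (comma default, tab accepted).

    Header must name ``name,genus,nativity,lifespan,growth_form,c_value``;
    enum columns are matched case-insensitively and an empty string means an
    absent C-value.  Rows violating an invariant raise
    :class:`TraitValidationError` with the offending row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep=sep, engine="python" if sep is None else "c", dtype=str,
        keep_default_na=False,
    )
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise TraitValidationError(f"{path}: missing columns {missing}")
    table = TraitTable(provenance=provenance or str(path))
    seen_rows: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = row 1
        try:
            trait = SpeciesTrait(
                name=str(row.name),
                genus=canonical_name(str(row.genus)),
                nativity=Nativity(str(row.nativity).strip().lower()),
                lifespan=Lifespan(str(row.lifespan).strip().lower()),
                growth_form=GrowthForm(str(row.growth_form).strip().lower()),
                c_value=_parse_c_value(row.c_value),
            )
        except (ValueError, TraitValidationError) as exc:
            raise TraitValidationError(f"{path}, row {i}: {exc}") from exc
        if trait.name in table.entries:
            raise TraitValidationError(
                f"{path}: duplicate canonical name {trait.name!r} "
                f"(rows {seen_rows[trait.name]} and {i})"
            )
        seen_rows[trait.name] = i
        table.add(trait)
    return table


def write_trait_table(table: TraitTable, path: Union[str, Path]) -> None:
    """Write a trait table in the canonical delimited schema (round-trips)."""
    rows = [
        {
            "name": t.name,
            "genus": t.genus,
            "nativity": t.nativity.value,
            "lifespan": t.lifespan.value,
            "growth_form": t.growth_form.value,
            "c_value": "" if t.c_value is None else t.c_value,
        }
        for t in (table.entries[k] for k in table.species())
    ]
    pd.DataFrame(rows, columns=TRAIT_COLUMNS).to_csv(path, index=False)


def warn_unknown(names: Iterable[str], table: TraitTable) -> set[str]:
    """Warn once for species absent from the trait table; return the set."""
    unknown = {n for n in names if table.lookup(n) is None}
    if unknown:
        warnings.warn(
            f"{len(unknown)} species not in trait table (counted in total "
            f"richness only): {sorted(unknown)[:5]}...",
            stacklevel=2,
        )
    return unknown
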