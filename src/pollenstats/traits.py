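"""Domain types and I/O for pollen trait tables, taxonomies and pedigrees.

The package works on three plain-text inputs:

* a *trait table* — long-format replicated measurements, one row per
  taxon x replicate x trait, for the seven measured pollen indicators:
  polar-axis length ``P`` (um), equatorial diameter ``E`` (um), the
  diameter at the plane halfway between equator and pole ``Eprime``
  (um), equatorial-view area ``S`` (um^2), ridge width ``RW`` (um),
  furrow width ``FW`` (um) and perforation density ``PD`` (count/um^2);
  plus a per-taxon aberrant-pollen rate ``AP`` in [0, 1];
* a *taxonomy* — taxon id, display name, rank (species/cultivar) and,
  for species, an ordinal section 1-5 running from the most ancient to
  the most derived infrageneric section;
* a *pedigree* — breeding routes ``parent1 x parent2 -> progeny`` in
  which a parent slot may be ``unknown`` (unnamed) or a named species
  that was never measured (flagged ``untested`` downstream).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Measured traits, in canonical order.
TRAITS: tuple[str, ...] = ("P", "E", "Eprime", "S", "RW", "FW", "PD")

#: Derived dimensionless ratio traits.
RATIO_TRAITS: tuple[str, ...] = ("P_over_E", "P_over_Eprime", "Eprime_over_E")

#: Expected number of replicate measurements per taxon per trait.
DEFAULT_REPLICATES = 30

UNKNOWN = "unknown"
UNTESTED = "untested"
_MISSING_PARENT_TOKENS = {UNKNOWN, UNTESTED}


class Rank(str, enum.Enum):
    SPECIES = "species"
    CULTIVAR = "cultivar"


class FormatError(ValueError):
    """A file does not have the expected columns or dialect."""


class ValidationError(ValueError):
    """Data violate a domain invariant."""


@dataclass(frozen=True)
class TaxonRecord:
    """Identity of one taxon: id, display name, rank and optional section.

    ``section`` is an ordinal 1-5 (ancient -> derived); it is only
    meaningful for species and must be ``None`` for cultivars.
    """

    taxon_id: str
    name: str
    rank: Rank
    section: int | None = None

    def __post_init__(self) -> None:
        if self.section is not None:
            if self.rank is not Rank.SPECIES:
                raise ValidationError(
                    f"taxon {self.taxon_id!r}: section set on a non-species"
                )
            if not 1 <= int(self.section) <= 5:
                raise ValidationError(
                    f"taxon {self.taxon_id!r}: section must be in 1..5"
                )


@dataclass(frozen=True)
class BreedingRoute:
    """One cross ``parent1 x parent2 -> progeny``.

    Parent slots hold a taxon name, ``"unknown"`` (parent unnamed) or
    ``"untested"`` (explicitly marked as never measured).
    """

    progeny: str
    parent1: str
    parent2: str
    source: str = ""

    @property
    def named_parents(self) -> tuple[str, ...]:
        return tuple(
            p for p in (self.parent1, self.parent2)
            if p.lower() not in _MISSING_PARENT_TOKENS
        )


@dataclass
class Pedigree:
    """A set of breeding routes; progeny ids unique, no ancestry cycles."""

    entries: list[BreedingRoute] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.progeny in seen:
                raise ValidationError(f"duplicate progeny row {e.progeny!r}")
            seen.add(e.progeny)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents_of = {e.progeny: set(e.named_parents) for e in self.entries}
        WHITE, GREY, BLACK = 0, 1, 2
        colour: dict[str, int] = {}

        def visit(node: str) -> None:
            colour[node] = GREY
            for p in parents_of.get(node, ()):  # walk towards ancestors
                c = colour.get(p, WHITE)
                if c == GREY:
                    raise ValidationError(f"pedigree cycle through {p!r}")
                if c == WHITE:
                    visit(p)
            colour[node] = BLACK

        for n in parents_of:
            if colour.get(n, WHITE) == WHITE:
                visit(n)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


class TraitTable:
    """Replicated trait measurements plus per-taxon aberrant rates.

    Parameters
    ----------
    data
        Long-format frame with columns ``taxon_id, replicate, trait,
        value``. Missing trait cells are simply absent rows.
    aberrant_rate
        Optional mapping/Series taxon_id -> aberrant pollen rate in
        [0, 1] (a population fraction over all counted grains, stored
        per taxon rather than per replicate).
    """

    COLUMNS = ("taxon_id", "replicate", "trait", "value")

    def __init__(
        self,
        data: pd.DataFrame,
        aberrant_rate: Mapping[str, float] | pd.Series | None = None,
        expected_replicates: int = DEFAULT_REPLICATES,
    ) -> None:
        missing = set(self.COLUMNS) - set(data.columns)
        if missing:
            raise FormatError(f"trait table missing columns {sorted(missing)}")
        self.data = data.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if aberrant_rate is None:
            self.aberrant_rate = pd.Series(dtype=float, name="AP")
        else:
            self.aberrant_rate = pd.Series(aberrant_rate, dtype=float, name="AP")
        self.expected_replicates = expected_replicates
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        df = self.data
        bad_trait = ~df["trait"].isin(TRAITS)
        if bad_trait.any():
            names = sorted(df.loc[bad_trait, "trait"].unique())
            raise ValidationError(f"unknown trait(s) {names}")
        values = df["value"].to_numpy(dtype=float)
        finite = np.isfinite(values)
        if not finite.all():
            row = int(np.flatnonzero(~finite)[0])
            raise ValidationError(f"non-finite value at row {row}")
        if (values < 0).any():
            row = int(np.flatnonzero(values < 0)[0])
            t = df.iloc[row]
            raise ValidationError(
                f"negative value at row {row} "
                f"(taxon {t['taxon_id']!r}, trait {t['trait']!r})"
            )
        counts = df.groupby(["taxon_id", "trait"], sort=False)["replicate"].count()
        too_few = counts[counts < 2]
        if len(too_few):
            key = too_few.index[0]
            raise ValidationError(
                f"taxon {key[0]!r} has {int(too_few.iloc[0])} replicate(s) "
                f"for trait {key[1]!r}; at least 2 required"
            )
        ragged = counts[counts != self.expected_replicates]
        if len(ragged):
            logger.warning(
                "%d taxon/trait cells deviate from the expected %d replicates",
                len(ragged), self.expected_replicates,
            )
        ap = self.aberrant_rate.to_numpy(dtype=float)
        if len(ap) and ((ap < 0) | (ap > 1)).any():
            raise ValidationError("aberrant rate outside [0, 1]")

    # -- views ---------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return list(dict.fromkeys(self.data["taxon_id"]))

    def traits_present(self) -> list[str]:
        present = set(self.data["trait"])
        return [t for t in TRAITS if t in present]

    def values_for(self, taxon_id: str, trait: str) -> np.ndarray:
        m = (self.data["taxon_id"] == taxon_id) & (self.data["trait"] == trait)
        return self.data.loc[m, "value"].to_numpy(dtype=float)

    def taxon_means(self) -> pd.DataFrame:
        """Per-taxon trait means, wide: index taxon_id, one column per trait."""
        wide = self.data.pivot_table(
            index="taxon_id", columns="trait", values="value", aggfunc="mean"
        )
        wide = wide.reindex(index=self.taxa)
        wide = wide.reindex(columns=[t for t in TRAITS if t in wide.columns])
        wide.columns.name = None
        return wide

    def replicate_counts(self) -> pd.Series:
        return self.data.groupby(["taxon_id", "trait"], sort=False)["replicate"].count()


# -- derived ratios ----------------------------------------------------


def compute_derived_ratios(
    table: TraitTable, convention: str = "ratio_of_means"
) -> pd.DataFrame:
    """Per-taxon shape ratios P/E, P/E' and E'/E.

    ``ratio_of_means`` divides per-taxon trait means; ``mean_of_ratios``
    pairs replicates by replicate id, divides within each replicate and
    averages. With constant replicates the two conventions coincide.
    The chosen convention is recorded in ``result.attrs["convention"]``.
    """
    if convention not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError(f"unknown convention {convention!r}")
    need = ("P", "E", "Eprime")
    means = table.taxon_means()
    for t in need:
        if t not in means.columns:
            raise ValidationError(f"trait {t!r} required for derived ratios")
    sub = means[list(need)].dropna()
    zero = sub.index[(sub["E"] == 0) | (sub["Eprime"] == 0)]
    if len(zero):
        raise ValidationError(
            f"zero mean E or Eprime for taxon {zero[0]!r}; ratio undefined"
        )
    if convention == "ratio_of_means":
        out = pd.DataFrame(
            {
                "P_over_E": sub["P"] / sub["E"],
                "P_over_Eprime": sub["P"] / sub["Eprime"],
                "Eprime_over_E": sub["Eprime"] / sub["E"],
            }
        )
    else:
        wide = table.data[table.data["trait"].isin(need)].pivot_table(
            index=["taxon_id", "replicate"], columns="trait", values="value"
        ).dropna()
        if (wide[["E", "Eprime"]] == 0).any().any():
            raise ValidationError("zero replicate E or Eprime; ratio undefined")
        per_rep = pd.DataFrame(
            {
                "P_over_E": wide["P"] / wide["E"],
                "P_over_Eprime": wide["P"] / wide["Eprime"],
                "Eprime_over_E": wide["Eprime"] / wide["E"],
            }
        )
        out = per_rep.groupby(level="taxon_id", sort=False).mean()
        out = out.reindex(index=sub.index)
    out.index.name = "taxon_id"
    out.attrs["convention"] = convention
    return out


# -- readers / writers -------------------------------------------------


def _sep(dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    raise ValueError(f"unknown dialect {dialect!r}")


def read_trait_table(path: str | Path, dialect: str = "csv") -> TraitTable:
    """Read a long-format trait table; an optional ``AP`` column (or a
    companion ``<stem>.ap.csv`` file with columns taxon_id, AP) supplies
    aberrant rates."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect))
    required = {"taxon_id", "replicate", "trait", "value"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path.name}: expected columns {sorted(required)}, "
            f"got {sorted(df.columns)}"
        )
    ap: pd.Series | None = None
    if "AP" in df.columns:
        ap = df.groupby("taxon_id", sort=False)["AP"].first()
        df = df.drop(columns=["AP"])
    else:
        companion = path.with_suffix(".ap" + path.suffix)
        if companion.exists():
            apdf = pd.read_csv(companion, sep=_sep(dialect))
            ap = apdf.set_index("taxon_id")["AP"]
    table = TraitTable(df, aberrant_rate=ap)
    n = table.replicate_counts()
    logger.info(
        "read %d taxa, %d traits, replicate counts %d..%d",
        len(table.taxa), len(table.traits_present()),
        int(n.min()), int(n.max()),
    )
    return table


def write_trait_table(table: TraitTable, path: str | Path, dialect: str = "csv") -> None:
    path = Path(path)
    df = table.data.copy()
    if len(table.aberrant_rate):
        df["AP"] = df["taxon_id"].map(table.aberrant_rate)
    df.to_csv(path, sep=_sep(dialect), index=False)


_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4, "V": 5}


def _parse_section(raw) -> int | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None
    s = str(raw).strip()
    if s.upper() in _ROMAN:
        return _ROMAN[s.upper()]
    return int(float(s))  # CSV readers may deliver '4' as 4.0


def read_taxonomy(path: str | Path, dialect: str = "csv") -> list[TaxonRecord]:
    df = pd.read_csv(Path(path), sep=_sep(dialect), dtype={"taxon_id": str})
    required = {"taxon_id", "name", "rank"}
    if not required <= set(df.columns):
        raise FormatError(f"taxonomy must have columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            TaxonRecord(
                taxon_id=str(row["taxon_id"]),
                name=str(row["name"]),
                rank=Rank(str(row["rank"]).strip().lower()),
                section=_parse_section(row.get("section")),
            )
        )
    ids = [r.taxon_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate taxon_id in taxonomy")
    return records


def write_taxonomy(records: Iterable[TaxonRecord], path: str | Path,
                   dialect: str = "csv") -> None:
    df = pd.DataFrame(
        [
            {
                "taxon_id": r.taxon_id,
                "name": r.name,
                "rank": r.rank.value,
                "section": "" if r.section is None else r.section,
            }
            for r in records
        ]
    )
    df.to_csv(Path(path), sep=_sep(dialect), index=False)


def _norm_parent(raw) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return UNKNOWN
    s = str(raw).strip()
    if s == "" or s.lower() in _MISSING_PARENT_TOKENS:
        return s.lower() if s else UNKNOWN
    return s


def read_pedigree(path: str | Path, dialect: str = "csv") -> Pedigree:
    """Read breeding routes; 'unknown'/'untested' parent tokens are
    recognised case-insensitively and preserved as distinct states."""
    df = pd.read_csv(Path(path), sep=_sep(dialect))
    required = {"progeny", "parent1", "parent2"}
    if not required <= set(df.columns):
        raise FormatError(f"pedigree must have columns {sorted(required)}")
    entries = [
        BreedingRoute(
            progeny=str(row["progeny"]).strip(),
            parent1=_norm_parent(row["parent1"]),
            parent2=_norm_parent(row["parent2"]),
            source=str(row.get("source", "") or ""),
        )
        for _, row in df.iterrows()
    ]
    if not entries:
        logger.warning("empty pedigree: downstream percentages undefined")
    return Pedigree(entries)


def write_pedigree(pedigree: Pedigree, path: str | Path, dialect: str = "csv") -> None:
    df = pd.DataFrame(
        [
            {"progeny": e.progeny, "parent1": e.parent1,
             "parent2": e.parent2, "source": e.source}
            for e in pedigree
        ],
        columns=["progeny", "parent1", "parent2", "source"],
    )
    df.to_csv(Path(path), sep=_sep(dialect), index=False)
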