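"""Domain types, CSV I/O, name canonicalization and count summaries.

The analysis works on three tabular objects shared by every downstream
stage:

* a :class:`TaxonTable` — one row per seed-plant taxon, carrying its
  lineage, the set of economic-use categories recorded for it (if any),
  whether it has naturalized anywhere, and in how many regions;
* a :class:`RegionSet` — regional naturalized floras with latitude and
  island metadata;
* a phylogeny (see :mod:`econatur.phylo`).

Economic uses follow the 12 main categories of the World Economic Plants
(WEP) catalogue.  Four further WEP categories describe harmful rather
than economic attributes (harmful organism hosts, vertebrate poisons,
weeds, CITES-listed) and are rejected at load time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "USE_CATEGORIES",
    "EXCLUDED_CATEGORIES",
    "CONTINENTS",
    "CONTINENT_NAMES",
    "ValidationError",
    "NameParseError",
    "Taxon",
    "TaxonTable",
    "Region",
    "RegionSet",
    "CountsSummary",
    "canonicalize_name",
    "load_taxon_table",
    "write_taxon_table",
    "load_region_set",
    "write_region_set",
    "summarize_counts",
]

#: The 12 main economic-use categories (closed set).
USE_CATEGORIES: tuple[str, ...] = (
    "animal_food",
    "bee_plants",
    "environmental",
    "food_additives",
    "fuels",
    "gene_sources",
    "human_food",
    "invertebrate_food",
    "materials",
    "medicines",
    "nonvertebrate_poisons",
    "social",
)

#: WEP categories that describe harmful/regulatory attributes, not
#: economic uses; any row carrying one of these is rejected.
EXCLUDED_CATEGORIES: tuple[str, ...] = (
    "harmful_organism_hosts",
    "vertebrate_poisons",
    "weeds",
    "cites",
)

#: Nine-symbol internal alphabet for TDWG level-1 continents.
CONTINENTS: tuple[str, ...] = (
    "AFR", "TAS", "TRA", "AUS", "EUR", "NAM", "SAM", "PAC", "ANT",
)

#: Mapping of the internal codes to TDWG level-1 names.
CONTINENT_NAMES: dict[str, str] = {
    "AFR": "Africa",
    "TAS": "Temperate Asia",
    "TRA": "Tropical Asia",
    "AUS": "Australasia",
    "EUR": "Europe",
    "NAM": "Northern America",
    "SAM": "Southern America",
    "PAC": "Pacific Islands",
    "ANT": "Antarctic",
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class NameParseError(ValueError):
    """Raised when a taxon name cannot be canonicalized."""


# ---------------------------------------------------------------------------
# name canonicalization
# ---------------------------------------------------------------------------

_RANK_MARKERS = {
    "ssp": "subsp.",
    "ssp.": "subsp.",
    "subsp": "subsp.",
    "subsp.": "subsp.",
    "subspecies": "subsp.",
    "var": "var.",
    "var.": "var.",
    "variety": "var.",
    "v.": "var.",
    "f.": "f.",
    "fo.": "f.",
    "forma": "f.",
}

# epithets are purely alphabetic (any case); authority tokens carry
# dots, parentheses or commas and never match
_WORD_RE = re.compile(r"^[A-Za-z][A-Za-z\-]*$")


def canonicalize_name(raw_name: str) -> str:
    """Reduce a raw taxon-name string to a canonical binomial/trinomial.

    Authority strings, hybrid signs and redundant whitespace are
    stripped; infraspecific rank markers are normalized to
    ``subsp.``/``var.``/``f.``.  The function is idempotent.

    This is a lightweight stand-in for full nomenclatural
    standardization against a reference checklist, which is outside the
    scope of this package.
    """
    if raw_name is None:
        raise NameParseError("empty name")
    s = raw_name.replace("×", " ").replace("✕", " ").strip()
    tokens = s.split()
    # drop standalone hybrid markers written as a bare 'x'
    tokens = [t for t in tokens if t.lower() not in {"x", "×"}]
    if not tokens or not any(any(c.isalpha() for c in t) for t in tokens):
        raise NameParseError(f"cannot parse taxon name: {raw_name!r}")

    genus = tokens[0]
    if not any(c.isalpha() for c in genus):
        raise NameParseError(f"cannot parse taxon name: {raw_name!r}")
    parts = [genus[0].upper() + genus[1:].lower()]

    rest = tokens[1:]
    epithet = None
    if rest and _WORD_RE.match(rest[0]) and not rest[0][0].isupper():
        epithet = rest[0].lower()
        rest = rest[1:]
    elif rest and rest[0].isupper() and _WORD_RE.match(rest[0]):
        # fully upper-case epithet (shouty input), not an authority
        epithet = rest[0].lower()
        rest = rest[1:]
    if epithet:
        parts.append(epithet)
        # scan the remainder (authorities interleaved) for a rank marker
        i = 0
        while i < len(rest):
            marker = _RANK_MARKERS.get(rest[i].lower())
            if marker is not None:
                for j in range(i + 1, len(rest)):
                    if _WORD_RE.match(rest[j]) and not rest[j][0].isupper():
                        parts.append(marker)
                        parts.append(rest[j].lower())
                        break
                break
            i += 1
    return " ".join(parts)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Taxon:
    """One seed-plant taxon (species, subspecies or variety)."""

    taxon_id: str
    name: str
    genus: str
    family: str
    uses: frozenset = frozenset()
    native_continents: frozenset = frozenset()
    naturalized: bool = False
    n_regions: int = 0
    cultivation_only: bool = False

    @property
    def n_uses(self) -> int:
        """Number of distinct main economic-use categories."""
        return len(self.uses)

    @property
    def economic(self) -> bool:
        return len(self.uses) > 0

    def validate(self) -> None:
        for code in self.uses:
            if code in EXCLUDED_CATEGORIES:
                raise ValidationError(
                    f"taxon {self.taxon_id!r}: category {code!r} is one of the "
                    "four excluded WEP categories (not an economic use)"
                )
            if code not in USE_CATEGORIES:
                raise ValidationError(
                    f"taxon {self.taxon_id!r}: unknown use category {code!r}"
                )
        for cont in self.native_continents:
            if cont not in CONTINENTS:
                raise ValidationError(
                    f"taxon {self.taxon_id!r}: unknown continent code {cont!r}"
                )
        if self.naturalized != (self.n_regions > 0):
            raise ValidationError(
                f"taxon {self.taxon_id!r}: naturalized flag inconsistent with "
                f"n_regions={self.n_regions}"
            )
        if self.cultivation_only and self.native_continents:
            raise ValidationError(
                f"taxon {self.taxon_id!r}: cultivation-only taxa must have an "
                "empty native-continent set"
            )


@dataclass
class TaxonTable:
    """A flora: list of taxa plus free-text provenance metadata."""

    rows: list
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def validate(self) -> None:
        seen: set[str] = set()
        genus_family: dict[str, str] = {}
        for t in self.rows:
            if t.taxon_id in seen:
                raise ValidationError(f"duplicate taxon_id {t.taxon_id!r}")
            seen.add(t.taxon_id)
            t.validate()
            fam = genus_family.setdefault(t.genus, t.family)
            if fam != t.family:
                raise ValidationError(
                    f"genus {t.genus!r} mapped to two families "
                    f"({fam!r}, {t.family!r})"
                )

    # -- convenience views ---------------------------------------------------

    def ids(self) -> set[str]:
        return {t.taxon_id for t in self.rows}

    def by_id(self) -> dict[str, Taxon]:
        return {t.taxon_id: t for t in self.rows}

    def economic(self) -> list:
        return [t for t in self.rows if t.economic]

    def naturalized(self) -> list:
        return [t for t in self.rows if t.naturalized]

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for t in self.rows:
            recs.append(
                {
                    "taxon_id": t.taxon_id,
                    "name": t.name,
                    "genus": t.genus,
                    "family": t.family,
                    "uses": ";".join(sorted(t.uses)),
                    "native_continents": ";".join(sorted(t.native_continents)),
                    "naturalized": int(t.naturalized),
                    "n_regions": int(t.n_regions),
                    "cultivation_only": int(t.cultivation_only),
                }
            )
        cols = [
            "taxon_id", "name", "genus", "family", "uses",
            "native_continents", "naturalized", "n_regions",
            "cultivation_only",
        ]
        return pd.DataFrame.from_records(recs, columns=cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "TaxonTable":
        rows = []
        for rec in df.to_dict("records"):
            uses = frozenset(_split_set(rec.get("uses")))
            conts = frozenset(_split_set(rec.get("native_continents")))
            rows.append(
                Taxon(
                    taxon_id=str(rec["taxon_id"]),
                    name=str(rec["name"]),
                    genus=str(rec["genus"]),
                    family=str(rec["family"]),
                    uses=uses,
                    native_continents=conts,
                    naturalized=bool(int(rec["naturalized"])),
                    n_regions=int(rec["n_regions"]),
                    cultivation_only=bool(int(rec.get("cultivation_only", 0))),
                )
            )
        return cls(rows=rows, provenance=provenance)


def _split_set(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    s = str(value).strip()
    if not s:
        return []
    return [p for p in s.split(";") if p]


@dataclass(frozen=True)
class Region:
    """A regional naturalized flora (country or subnational unit)."""

    region_id: str
    latitude: float
    island: bool
    taxa: frozenset = frozenset()
    continent: str | None = None

    def validate(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"region {self.region_id!r}: latitude {self.latitude} out of range"
            )
        if self.continent is not None and self.continent not in CONTINENTS:
            raise ValidationError(
                f"region {self.region_id!r}: unknown continent {self.continent!r}"
            )


@dataclass
class RegionSet:
    regions: list

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def validate(self) -> None:
        seen: set[str] = set()
        for r in self.regions:
            if r.region_id in seen:
                raise ValidationError(f"duplicate region_id {r.region_id!r}")
            seen.add(r.region_id)
            r.validate()

    def region_counts(self) -> dict[str, int]:
        """Number of regions containing each taxon."""
        counts: dict[str, int] = {}
        for r in self.regions:
            for tid in r.taxa:
                counts[tid] = counts.get(tid, 0) + 1
        return counts

    def check_consistent(self, table: TaxonTable) -> None:
        """Assert the per-taxon region counts match ``table.n_regions``."""
        counts = self.region_counts()
        for t in table:
            if counts.get(t.taxon_id, 0) != t.n_regions:
                raise ValidationError(
                    f"taxon {t.taxon_id!r}: n_regions={t.n_regions} but appears "
                    f"in {counts.get(t.taxon_id, 0)} regions"
                )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def load_taxon_table(path) -> TaxonTable:
    """Read ``taxa.csv`` (see the package README for the column schema)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {
        "taxon_id", "name", "genus", "family", "uses",
        "native_continents", "naturalized", "n_regions",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"taxa csv missing columns: {sorted(missing)}")
    return TaxonTable.from_dataframe(df, provenance=f"loaded from {path}")


def write_taxon_table(table: TaxonTable, path) -> None:
    df = table.to_dataframe()
    df.to_csv(path, index=False, lineterminator="\n")


def load_region_set(regions_path, membership_path) -> RegionSet:
    rdf = pd.read_csv(regions_path, dtype=str, keep_default_na=False)
    mdf = pd.read_csv(membership_path, dtype=str, keep_default_na=False)
    members: dict[str, set[str]] = {}
    for rec in mdf.to_dict("records"):
        members.setdefault(str(rec["region_id"]), set()).add(str(rec["taxon_id"]))
    regions = []
    for rec in rdf.to_dict("records"):
        cont = str(rec.get("continent", "")).strip() or None
        regions.append(
            Region(
                region_id=str(rec["region_id"]),
                latitude=float(rec["latitude"]),
                island=bool(int(rec["island"])),
                taxa=frozenset(members.get(str(rec["region_id"]), set())),
                continent=cont,
            )
        )
    return RegionSet(regions=regions)


def write_region_set(rs: RegionSet, regions_path, membership_path) -> None:
    rrecs = [
        {
            "region_id": r.region_id,
            "latitude": repr(float(r.latitude)),
            "island": int(r.island),
            "continent": r.continent or "",
        }
        for r in rs.regions
    ]
    pd.DataFrame.from_records(
        rrecs, columns=["region_id", "latitude", "island", "continent"]
    ).to_csv(regions_path, index=False, lineterminator="\n")
    mrecs = []
    for r in rs.regions:
        for tid in sorted(r.taxa):
            mrecs.append({"region_id": r.region_id, "taxon_id": tid})
    pd.DataFrame.from_records(
        mrecs, columns=["region_id", "taxon_id"]
    ).to_csv(membership_path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# count summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoryCount:
    n: int
    n_naturalized: int

    @property
    def prop_naturalized(self) -> float:
        return self.n_naturalized / self.n if self.n else float("nan")


@dataclass(frozen=True)
class CountsSummary:
    """Headline counts of a flora and its per-category breakdown."""

    n_total: int
    n_econ: int
    n_naturalized: int
    n_econ_naturalized: int
    per_category: dict

    @property
    def prop_naturalized(self) -> float:
        """Share of the whole flora that is naturalized."""
        return self.n_naturalized / self.n_total if self.n_total else float("nan")

    @property
    def prop_econ_naturalized(self) -> float:
        """Share of economic taxa that are naturalized."""
        return self.n_econ_naturalized / self.n_econ if self.n_econ else float("nan")

    @property
    def prop_naturalized_econ(self) -> float:
        """Share of naturalized taxa that have an economic use."""
        return (
            self.n_econ_naturalized / self.n_naturalized
            if self.n_naturalized
            else float("nan")
        )

    @property
    def prop_nonecon_naturalized(self) -> float:
        """Share of non-economic taxa that are naturalized."""
        denom = self.n_total - self.n_econ
        if denom == 0:
            return float("nan")
        return (self.n_naturalized - self.n_econ_naturalized) / denom

    @property
    def econ_vs_nonecon_ratio(self) -> float:
        """How many times likelier naturalization is for economic taxa."""
        q = self.prop_nonecon_naturalized
        return self.prop_econ_naturalized / q if q else float("inf")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_econ": self.n_econ,
            "n_naturalized": self.n_naturalized,
            "n_econ_naturalized": self.n_econ_naturalized,
            "per_category": {
                c: {"n": cc.n, "n_naturalized": cc.n_naturalized}
                for c, cc in self.per_category.items()
            },
        }


def summarize_counts(table: TaxonTable) -> CountsSummary:
    """Tabulate the headline overlap counts and per-category counts."""
    n_total = len(table)
    n_econ = 0
    n_nat = 0
    n_econ_nat = 0
    per = {c: [0, 0] for c in USE_CATEGORIES}
    for t in table:
        if t.economic:
            n_econ += 1
        if t.naturalized:
            n_nat += 1
            if t.economic:
                n_econ_nat += 1
        for c in t.uses:
            per[c][0] += 1
            if t.naturalized:
                per[c][1] += 1
    return CountsSummary(
        n_total=n_total,
        n_econ=n_econ,
        n_naturalized=n_nat,
        n_econ_naturalized=n_econ_nat,
        per_category={c: CategoryCount(n, k) for c, (n, k) in per.items()},
    )
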