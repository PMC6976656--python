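"""Cluster-level survey data: records, validation, and regional count tables.

The package's canonical exchange format is a plain CSV of survey clusters,
one row per cluster, with columns::

    cluster_id,region_id,stratum,lon,lat,year,n_examined,n_lifetime,n_untreated

``n_examined`` counts women of childbearing age (15-49) interviewed at the
cluster, ``n_lifetime`` those ever reporting vaginal-fistula symptoms, and
``n_untreated`` those reporting symptoms with no treatment.  Coordinates are
WGS84 decimal degrees.  A small regional count table from two national
household surveys (2005 and 2016) ships with the package as a worked-example
fixture.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

Outcome = Literal["lifetime", "untreated"]

STRATA = ("urban", "rural")

CSV_COLUMNS = [
    "cluster_id",
    "region_id",
    "stratum",
    "lon",
    "lat",
    "year",
    "n_examined",
    "n_lifetime",
    "n_untreated",
]

# Regions are stored under one canonical spelling; survey tables vary.
REGION_SYNONYMS = {
    "Amara": "Amhara",
    "Beneshangul Gumuz": "Benishangul Gumuz",
    "Benishangul-Gumuz": "Benishangul Gumuz",
    "SNNPR": "SNNP",
}


class SchemaError(ValueError):
    """A required CSV column is missing."""


class ValidationError(ValueError):
    """A row violates a count or coordinate invariant."""


@dataclass(frozen=True)
class ClusterRecord:
    """One survey cluster: location, design stratum, and outcome counts.

    Invariants: ``0 <= n_untreated <= n_lifetime <= n_examined``,
    ``n_examined >= 1``, finite coordinates.
    """

    cluster_id: str
    region_id: str
    stratum: str
    lon: float
    lat: float
    year: int
    n_examined: int
    n_lifetime: int
    n_untreated: int

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValidationError(
                f"cluster {self.cluster_id}: stratum must be one of {STRATA}, "
                f"got {self.stratum!r}"
            )
        if self.n_examined < 1:
            raise ValidationError(
                f"cluster {self.cluster_id}: n_examined must be >= 1"
            )
        if not (0 <= self.n_untreated <= self.n_lifetime <= self.n_examined):
            raise ValidationError(
                f"cluster {self.cluster_id}: counts must satisfy "
                f"0 <= n_untreated <= n_lifetime <= n_examined, got "
                f"({self.n_untreated}, {self.n_lifetime}, {self.n_examined})"
            )
        if not (_finite(self.lon) and _finite(self.lat)):
            raise ValidationError(
                f"cluster {self.cluster_id}: non-finite coordinates"
            )

    def count(self, outcome: Outcome) -> int:
        """Outcome count for the requested definition."""
        if outcome == "lifetime":
            return self.n_lifetime
        if outcome == "untreated":
            return self.n_untreated
        raise ValueError(f"unknown outcome {outcome!r}")


@dataclass(frozen=True)
class RegionCountRow:
    """One region's interviewed/symptomatic/untreated counts for both survey years."""

    region: str
    interviewed_2005: int
    symptoms_2005: int
    untreated_2005: int
    interviewed_2016: int
    symptoms_2016: int
    untreated_2016: int

    def __post_init__(self) -> None:
        for year in (2005, 2016):
            n = getattr(self, f"interviewed_{year}")
            s = getattr(self, f"symptoms_{year}")
            u = getattr(self, f"untreated_{year}")
            if not (0 <= u <= s <= n):
                raise ValidationError(
                    f"region {self.region}, {year}: untreated <= symptoms <= "
                    f"interviewed violated ({u}, {s}, {n})"
                )


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def load_clusters(path: str | Path, outcome: Outcome = "lifetime") -> list[ClusterRecord]:
    """Read and validate a cluster CSV.

    ``outcome`` declares which count downstream model fitting will use; both
    count columns are required and validated regardless.  Rows with
    ``n_examined == 0`` are rejected.
    """
    if outcome not in ("lifetime", "untreated"):
        raise ValueError(f"unknown outcome {outcome!r}")
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    ClusterRecord(
                        cluster_id=row["cluster_id"],
                        region_id=row["region_id"],
                        stratum=row["stratum"],
                        lon=float(row["lon"]),
                        lat=float(row["lat"]),
                        year=int(row["year"]),
                        n_examined=int(row["n_examined"]),
                        n_lifetime=int(row["n_lifetime"]),
                        n_untreated=int(row["n_untreated"]),
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path} line {lineno}: {exc}") from exc
    return records


def write_clusters(records: Iterable[ClusterRecord], path: str | Path) -> None:
    """Write records in the canonical cluster-CSV dialect (lossless round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for rec in records:
            d = asdict(rec)
            d["lon"] = repr(rec.lon)
            d["lat"] = repr(rec.lat)
            writer.writerow(d)


def table1_fixture() -> list[RegionCountRow]:
    """The packaged 11-region count table for the 2005 and 2016 surveys."""
    text = (
        resources.files("burdenmap")
        .joinpath("data/table1_region_counts.csv")
        .read_text()
    )
    rows = []
    for row in csv.DictReader(text.splitlines()):
        region = REGION_SYNONYMS.get(row["region"], row["region"])
        rows.append(
            RegionCountRow(
                region=region,
                **{k: int(v) for k, v in row.items() if k != "region"},
            )
        )
    return rows


def crude_prevalence(
    records: list[ClusterRecord], per: float = 1.0, outcome: Outcome = "lifetime"
) -> float:
    """Pooled crude prevalence: sum(counts)/sum(n_examined) scaled by ``per``."""
    if not records:
        raise ValueError("crude_prevalence needs at least one record")
    cases = sum(r.count(outcome) for r in records)
    denom = sum(r.n_examined for r in records)
    return cases / denom * per
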