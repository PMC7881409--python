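"""Domain types and file I/O for province-level disease-mapping data.

The central objects are :class:`ProvinceRecord` (one area × sex stratum of
observed and internally-standardized expected case counts, with optional
area-level covariates), :class:`AdjacencyStructure` (the symmetric
neighbour graph that carries spatial correlation in CAR models) and
:class:`StudyDataset` (records + adjacency + provenance).

Two fixtures ship with the package: the 2005–2008 Iranian colorectal-cancer
counts for 30 provinces × 2 sexes, and a neighbour graph for the pre-2010
provincial division (Tehran includes present-day Alborz).
"""

from __future__ import annotations

import csv
import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female", "both")


class DataFormatError(ValueError):
    """Malformed input file (missing column, unparseable line)."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


def slugify(name: str) -> str:
    """Canonical area identifier: lower-case ASCII, underscores.

    Handles the spelling variants seen in published tables, e.g.
    ``"E- Azerbaijan"`` → ``"east_azerbaijan"``.
    """
    s = unicodedata.normalize("NFKD", name).encode("ascii", "ignore").decode()
    s = s.strip().lower()
    s = re.sub(r"[^a-z0-9]+", "_", s).strip("_")
    return _NAME_ALIASES.get(s, s)


_NAME_ALIASES = {
    "e_azerbaijan": "east_azerbaijan",
    "w_azerbaijan": "west_azerbaijan",
    "east_azarbaijan": "east_azerbaijan",
    "west_azarbaijan": "west_azerbaijan",
    "s_khorasan": "south_khorasan",
    "r_khorasan": "razavi_khorasan",
    "n_khorasan": "north_khorasan",
    "khorasan_razavi": "razavi_khorasan",
    "isfahan": "esfahan",
    "kurdistan": "kordistan",
    "sistan_and_baluchestan": "sistan",
    "sistan_baluchestan": "sistan",
    "chaharmahal_and_bakhtiari": "chaharmahal",
    "kohgiluyeh_and_boyer_ahmad": "kohgiluyeh",
}


@dataclass(frozen=True)
class ProvinceRecord:
    """Observed/expected counts for one area × sex stratum.

    ``expected`` comes from internal standardization; ``uer`` (unemployment
    rate, percent) and ``mhi`` (mean household income, 10^6 Rials) are
    optional area-level covariates.
    """

    area_id: str
    sex: str
    observed: int
    expected: float
    uer: Optional[float] = None
    mhi: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.area_id:
            raise ValidationError("area_id must be non-empty")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.observed < 0:
            raise ValidationError(
                f"observed count must be >= 0 in area {self.area_id!r}"
            )

    @property
    def sir(self) -> float:
        if self.expected <= 0:
            raise ValidationError(
                f"expected must be > 0 to form an SIR (area {self.area_id!r})"
            )
        return self.observed / self.expected


@dataclass
class AdjacencyStructure:
    """Symmetric neighbour graph over areas (who borders whom)."""

    areas: list[str]
    edges: set[frozenset]
    connected: bool = field(init=False)

    def __post_init__(self) -> None:
        seen = set(self.areas)
        if len(seen) != len(self.areas):
            raise ValidationError("duplicate area ids in adjacency")
        for e in self.edges:
            if len(e) != 2:
                raise ValidationError(f"self-loop or malformed edge: {set(e)}")
            for a in e:
                if a not in seen:
                    raise ValidationError(f"edge endpoint {a!r} not in area list")
        g = self.graph()
        self.connected = len(self.areas) > 0 and nx.is_connected(g)
        isolated = [a for a in self.areas if g.degree(a) == 0]
        if isolated:
            logger.warning("isolated areas in adjacency: %s", isolated)

    @classmethod
    def from_pairs(
        cls, areas: Sequence[str], pairs: Iterable[tuple[str, str]]
    ) -> "AdjacencyStructure":
        edges = set()
        for a, b in pairs:
            if a == b:
                raise ValidationError(f"self-loop on area {a!r}")
            edges.add(frozenset((a, b)))
        return cls(areas=list(areas), edges=edges)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.areas)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph())

    def neighbour_counts(self) -> dict[str, int]:
        g = self.graph()
        return {a: g.degree(a) for a in self.areas}

    def neighbours(self, area: str) -> list[str]:
        g = self.graph()
        return sorted(g.neighbors(area))

    def edge_index_arrays(self):
        """(i, j) integer index arrays over ``areas`` order, one row per edge."""
        import numpy as np

        idx = {a: k for k, a in enumerate(self.areas)}
        ii, jj = [], []
        for e in sorted(tuple(sorted(e)) for e in self.edges):
            ii.append(idx[e[0]])
            jj.append(idx[e[1]])
        return np.asarray(ii, dtype=int), np.asarray(jj, dtype=int)


@dataclass
class StudyDataset:
    """Records plus adjacency; the unit of analysis for every model."""

    records: list[ProvinceRecord]
    adjacency: Optional[AdjacencyStructure] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sex in {r.sex for r in self.records}:
            ids = [r.area_id for r in self.records if r.sex == sex]
            if len(ids) != len(set(ids)):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise ValidationError(f"duplicate area_id for sex {sex!r}: {dup}")
        if self.adjacency is not None and self.records:
            area_set = set(self.adjacency.areas)
            for sex in {r.sex for r in self.records}:
                rec_ids = {r.area_id for r in self.records if r.sex == sex}
                if rec_ids != area_set:
                    missing = sorted(area_set - rec_ids)
                    extra = sorted(rec_ids - area_set)
                    raise ValidationError(
                        f"record/adjacency area mismatch for sex {sex!r}: "
                        f"missing {missing}, extra {extra}"
                    )

    def sexes(self) -> list[str]:
        return sorted({r.sex for r in self.records})

    def for_sex(self, sex: str) -> list[ProvinceRecord]:
        """Records for one sex; ``"both"`` pools counts per area.

        Pooling adds observed and expected across sexes before any ratio is
        taken (standard practice for combining strata).
        """
        if sex != "both" or any(r.sex == "both" for r in self.records):
            recs = [r for r in self.records if r.sex == sex]
            if not recs:
                raise ValidationError(f"no records for sex {sex!r}")
            return recs
        pooled: dict[str, dict] = {}
        order: list[str] = []
        for r in self.records:
            if r.area_id not in pooled:
                pooled[r.area_id] = {"observed": 0, "expected": 0.0,
                                     "uer": r.uer, "mhi": r.mhi}
                order.append(r.area_id)
            pooled[r.area_id]["observed"] += r.observed
            pooled[r.area_id]["expected"] += r.expected
        return [
            ProvinceRecord(area_id=a, sex="both", **pooled[a]) for a in order
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "area": r.area_id,
                    "sex": r.sex,
                    "observed": r.observed,
                    "expected": r.expected,
                    "uer": r.uer,
                    "mhi": r.mhi,
                }
                for r in self.records
            ]
        )


# ---------------------------------------------------------------------------
# CSV I/O

_MANDATORY = ("area", "sex", "observed", "expected")


def read_counts_csv(
    path, adjacency: Optional[AdjacencyStructure] = None
) -> StudyDataset:
    """Read a counts CSV with columns area, sex, observed, expected[, uer, mhi].

    Numbers are parsed exactly as printed; blanks in optional columns stay
    missing (never coerced to zero). Raises :class:`DataFormatError` for a
    missing mandatory column and :class:`ValidationError` for a negative
    observed or non-positive expected value, naming the offending row.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DataFormatError(f"{path}: empty file, no header")
        header = [h.strip().lower() for h in reader.fieldnames]
        for col in _MANDATORY:
            if col not in header:
                raise DataFormatError(f"{path}: missing mandatory column {col!r}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            row = {k.strip().lower(): (v.strip() if v else "") for k, v in row.items()}
            try:
                observed = int(row["observed"])
                expected = float(row["expected"])
            except ValueError as exc:
                raise DataFormatError(f"{path} line {lineno}: {exc}") from exc
            if observed < 0:
                raise ValidationError(
                    f"{path} line {lineno}: negative observed count {observed}"
                )
            if expected <= 0:
                raise ValidationError(
                    f"{path} line {lineno}: expected must be > 0, got {expected}"
                )
            records.append(
                ProvinceRecord(
                    area_id=slugify(row["area"]),
                    sex=row["sex"].lower(),
                    observed=observed,
                    expected=expected,
                    uer=float(row["uer"]) if row.get("uer") else None,
                    mhi=float(row["mhi"]) if row.get("mhi") else None,
                )
            )
    if not records:
        logger.warning("%s: header only, empty dataset", path)
    return StudyDataset(
        records=records, adjacency=adjacency, metadata={"source": str(path)}
    )


def write_counts_csv(dataset: StudyDataset, path) -> None:
    """Write records back to CSV; numeric fields round-trip as decimal text."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        has_cov = any(r.uer is not None or r.mhi is not None for r in dataset.records)
        cols = list(_MANDATORY) + (["uer", "mhi"] if has_cov else [])
        w = csv.writer(fh)
        w.writerow(cols)
        for r in dataset.records:
            row = [r.area_id, r.sex, repr(r.observed), _decimal(r.expected)]
            if has_cov:
                row += [
                    "" if r.uer is None else _decimal(r.uer),
                    "" if r.mhi is None else _decimal(r.mhi),
                ]
            w.writerow(row)


def _decimal(x: float) -> str:
    return repr(x)


# ---------------------------------------------------------------------------
# Adjacency I/O


def read_adjacency(path, areas: Optional[Sequence[str]] = None) -> AdjacencyStructure:
    """Read adjacency from an edge-list text file or a GeoJSON polygon file.

    Edge-list format: one ``areaA<TAB>areaB`` (or whitespace-separated) pair
    per line; ``#`` starts a comment. GeoJSON: a FeatureCollection of
    polygons with an ``"area"`` property; two areas are adjacent when their
    boundaries share positive length (rook adjacency).

    If ``areas`` is given (a dataset is already loaded), unknown names are a
    :class:`ValidationError`; otherwise the area list is inferred from the
    file itself.
    """
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        return _adjacency_from_geojson(path, areas)
    pairs = []
    names: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise DataFormatError(
                    f"{path} line {lineno}: expected two area names, got {line!r}"
                )
            a, b = slugify(parts[0]), slugify(parts[1])
            if a == b:
                raise ValidationError(f"{path} line {lineno}: self-loop on {a!r}")
            for x in (a, b):
                if x not in names:
                    names.append(x)
            pairs.append((a, b))
    if areas is not None:
        known = {slugify(a) for a in areas}
        unknown = sorted({n for n in names if n not in known})
        if unknown:
            raise ValidationError(f"{path}: unknown area names {unknown}")
        names = [slugify(a) for a in areas]
    return AdjacencyStructure.from_pairs(names, pairs)


def _adjacency_from_geojson(path, areas) -> AdjacencyStructure:
    from shapely.geometry import shape

    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    feats = gj.get("features", [])
    geoms, names = [], []
    for k, f in enumerate(feats):
        props = f.get("properties") or {}
        if "area" not in props:
            raise DataFormatError(f"{path}: feature {k} lacks an 'area' property")
        names.append(slugify(str(props["area"])))
        geoms.append(shape(f["geometry"]))
    if areas is not None:
        known = {slugify(a) for a in areas}
        unknown = sorted(set(names) - known)
        if unknown:
            raise ValidationError(f"{path}: unknown area names {unknown}")
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            inter = geoms[i].boundary.intersection(geoms[j].boundary)
            if inter.length > 0:
                pairs.append((names[i], names[j]))
    return AdjacencyStructure.from_pairs(names, pairs)


def write_adjacency(adj: AdjacencyStructure, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in sorted(tuple(sorted(e)) for e in adj.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")


# ---------------------------------------------------------------------------
# Packaged fixtures


def _dataset_path(name: str) -> Path:
    return Path(resources.files("spatrisk.datasets") / name)


def load_table1_fixture(adjacency: bool = True) -> StudyDataset:
    """The 2005–2008 Iranian colorectal-cancer counts, 30 provinces × 2 sexes.

    Transcribed verbatim from the published observed/expected table,
    including rows that look anomalous relative to their neighbours (no
    corrections are applied). Per-sex observed totals: 12,155 male and
    9,388 female (21,543 overall).
    """
    ds = read_counts_csv(
        _dataset_path("table1.csv"),
        adjacency=load_iran_adjacency_fixture() if adjacency else None,
    )
    ds.metadata["source"] = "packaged fixture: Iran CRC 2005-2008 counts"
    return ds


def load_iran_adjacency_fixture() -> AdjacencyStructure:
    """Neighbour graph for Iran's 30 pre-2010 provinces (symmetric, connected)."""
    return read_adjacency(_dataset_path("iran_adjacency.txt"))
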