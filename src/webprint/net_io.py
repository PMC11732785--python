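"""Reading and writing food webs, metadata, and pipeline outputs.

Food webs travel as two-column edge lists (resource, consumer) or as labeled
0/1 adjacency matrices with row = resource and column = consumer.  Metadata is
a six-column CSV.  All pipeline outputs (orbit tables, distance matrices,
cohort summaries) are plain CSV/JSON so every number in a report can be
recomputed from the emitted files alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("webprint")

ECOSYSTEMS = ("aquatic", "aquatic_and_terrestrial", "terrestrial")
AQUATIC_SUBTYPES = ("lake", "marine", "river", "stream", "spring")

METADATA_COLUMNS = (
    "web_id",
    "publication_id",
    "publication_year",
    "ecosystem",
    "aquatic_subtype",
    "ecopath",
)


@dataclass
class FoodWeb:
    """One food web: a labeled graph plus an identifier.

    Raw webs are directed (edge = resource -> consumer); processed webs are
    simple undirected graphs.  Node labels are opaque strings, compared
    case-sensitively after trimming surrounding whitespace.
    """

    web_id: str
    graph: nx.Graph | nx.DiGraph

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> set[tuple[str, str]]:
        if self.directed:
            return set(self.graph.edges)
        return {tuple(sorted(e)) for e in self.graph.edges}


@dataclass(frozen=True)
class WebMetadata:
    """Per-web annotations: source publication, year, ecosystem class."""

    web_id: str
    publication_id: str
    publication_year: int
    ecosystem: str
    aquatic_subtype: str | None = None
    ecopath: bool = False

    def __post_init__(self) -> None:
        if self.ecosystem not in ECOSYSTEMS:
            raise ValueError(
                f"web {self.web_id!r}: unknown ecosystem {self.ecosystem!r}; "
                f"must be one of {ECOSYSTEMS}"
            )
        if self.aquatic_subtype is not None:
            if self.ecosystem != "aquatic":
                raise ValueError(
                    f"web {self.web_id!r}: aquatic_subtype given for "
                    f"non-aquatic ecosystem {self.ecosystem!r}"
                )
            if self.aquatic_subtype not in AQUATIC_SUBTYPES:
                raise ValueError(
                    f"web {self.web_id!r}: unknown aquatic_subtype "
                    f"{self.aquatic_subtype!r}; must be one of {AQUATIC_SUBTYPES}"
                )
        if self.ecopath and self.ecosystem != "aquatic":
            raise ValueError(
                f"web {self.web_id!r}: ecopath=true requires ecosystem=aquatic"
            )


def _clean_label(raw: object) -> str:
    return str(raw).strip()


def read_edgelist(
    path: str | Path,
    delimiter: str | None = None,
    header: bool = False,
    web_id: str | None = None,
) -> FoodWeb:
    """Read a two-column (resource, consumer) edge list into a raw directed web.

    Duplicate rows collapse to a single directed edge; the number of discarded
    duplicates is logged.  ``delimiter=None`` sniffs comma vs tab from the
    first line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if header and lines:
        lines = lines[1:]
    if not lines:
        raise ValueError(f"{path}: no edges")
    if delimiter is None:
        delimiter = "\t" if "\t" in lines[0] else ","
    g = nx.DiGraph()
    duplicates = 0
    for i, line in enumerate(lines, start=2 if header else 1):
        parts = [p for p in line.split(delimiter)]
        if len(parts) < 2:
            raise ValueError(f"{path}: row {i} has fewer than 2 fields: {line!r}")
        u, v = _clean_label(parts[0]), _clean_label(parts[1])
        if not u or not v:
            raise ValueError(f"{path}: row {i} has an empty label: {line!r}")
        if g.has_edge(u, v):
            duplicates += 1
        else:
            g.add_edge(u, v)
    if duplicates:
        logger.info("%s: discarded %d duplicate edge rows", path.name, duplicates)
    return FoodWeb(web_id=web_id or path.stem, graph=g)


def read_adjacency(path: str | Path, web_id: str | None = None) -> FoodWeb:
    """Read a labeled square 0/1 adjacency matrix (row=resource, col=consumer).

    Numeric entries > 0 are coerced to 1 with a logged warning; negative
    entries are rejected.  Self-loops in the raw matrix are retained (they are
    removed later by preprocessing).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"adjacency matrix not found: {path}")
    df = pd.read_csv(path, index_col=0)
    df.index = [_clean_label(x) for x in df.index]
    df.columns = [_clean_label(x) for x in df.columns]
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: not square ({df.shape[0]}x{df.shape[1]})")
    if set(df.index) != set(df.columns):
        raise ValueError(f"{path}: row and column label sets differ")
    df = df.loc[:, df.index]  # align column order to row order
    values = df.to_numpy(dtype=float)
    if np.any(values < 0) or np.any(~np.isfinite(values)):
        raise ValueError(f"{path}: entries must be nonnegative finite numbers")
    nonbinary = np.sum((values > 0) & (values != 1))
    if nonbinary:
        logger.warning(
            "%s: %d entries > 0 coerced to 1 (binary structure only)",
            path.name,
            int(nonbinary),
        )
    g = nx.DiGraph()
    labels = list(df.index)
    g.add_nodes_from(labels)
    rows, cols = np.nonzero(values > 0)
    for r, c in zip(rows, cols):
        g.add_edge(labels[r], labels[c])
    return FoodWeb(web_id=web_id or path.stem, graph=g)


def _parse_bool(x: object) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f", "", "nan"):
        return False
    raise ValueError(f"cannot interpret {x!r} as a boolean")


def read_metadata(path: str | Path) -> list[WebMetadata]:
    """Read and validate the per-web metadata table (CSV, six named columns)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    records: list[WebMetadata] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        wid = _clean_label(row["web_id"])
        if wid in seen:
            raise ValueError(f"{path}: duplicate web id {wid!r}")
        seen.add(wid)
        subtype = _clean_label(row["aquatic_subtype"]) or None
        records.append(
            WebMetadata(
                web_id=wid,
                publication_id=_clean_label(row["publication_id"]),
                publication_year=int(row["publication_year"]),
                ecosystem=_clean_label(row["ecosystem"]),
                aquatic_subtype=subtype,
                ecopath=_parse_bool(row["ecopath"]),
            )
        )
    return records


def metadata_frame(records: Iterable[WebMetadata]) -> pd.DataFrame:
    """Metadata records as a DataFrame indexed by web_id."""
    df = pd.DataFrame(
        [
            {
                "web_id": m.web_id,
                "publication_id": m.publication_id,
                "publication_year": m.publication_year,
                "ecosystem": m.ecosystem,
                "aquatic_subtype": m.aquatic_subtype or "",
                "ecopath": m.ecopath,
            }
            for m in records
        ]
    )
    return df.set_index("web_id", drop=False)


def write_edgelist(web: FoodWeb, path: str | Path, delimiter: str = ",") -> None:
    """Write a web as a two-column edge list (deterministic sorted order)."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(web.edges()):
            fh.write(f"{u}{delimiter}{v}\n")


def write_metadata(records: Iterable[WebMetadata], path: str | Path) -> None:
    metadata_frame(records).to_csv(path, index=False)


def write_matrix_csv(
    labels: Sequence[str], values: np.ndarray, path: str | Path, fmt: str = "%.10g"
) -> None:
    """Write a labeled square matrix (e.g. a distance matrix) as CSV."""
    df = pd.DataFrame(np.asarray(values), index=list(labels), columns=list(labels))
    df.to_csv(path, float_format=fmt)


def read_matrix_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return [str(c) for c in df.columns], df.to_numpy(dtype=float)


def write_json_report(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
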