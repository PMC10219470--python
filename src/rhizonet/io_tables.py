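"""Tabular and graph I/O plus taxonomic aggregation.

In-memory conventions
---------------------
* **Count table** — :class:`pandas.DataFrame`, rows = samples, columns =
  OTUs (or aggregated taxa), integer dtype, all entries >= 0.
* **Taxonomy map** — :class:`pandas.DataFrame` indexed by OTU id with one
  column per rank (``kingdom`` ... ``genus``); unresolved ranks hold the
  literal string ``"unclassified"``.
* **Sample frame** — :class:`pandas.DataFrame` indexed by sample id with a
  ``group`` column (two condition labels), a ``site`` column pairing the
  two conditions, and one column per soil variable
  (pH, TC, TN, TP, AN, NN, AP).

All on-disk tables are UTF-8 TSV with a header row.  Networks are
:class:`networkx.Graph` objects written as GraphML or CSV edge lists.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

RANKS: tuple[str, ...] = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_LETTERS: dict[str, str] = dict(zip(RANKS, "kpcofg"))
UNCLASSIFIED = "unclassified"

SOIL_VARIABLES: tuple[str, ...] = ("pH", "TC", "TN", "TP", "AN", "NN", "AP")


class TableFormatError(ValueError):
    """Raised when an on-disk table violates the format contract."""


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def validate_count_table(table: pd.DataFrame, min_samples: int = 1, min_otus: int = 1) -> pd.DataFrame:
    """Validate a samples x OTUs count table, returning it with int64 dtype.

    Checks for duplicate identifiers, negative or non-integer cells, and
    minimum dimensions.  Error messages name the offending cell.
    """
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate sample ids: {dupes}")
    if table.columns.has_duplicates:
        dupes = table.columns[table.columns.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate OTU ids: {dupes}")
    if table.shape[0] < min_samples or table.shape[1] < min_otus:
        raise TableFormatError(
            f"table is {table.shape[0]} samples x {table.shape[1]} OTUs; "
            f"need at least {min_samples} x {min_otus}"
        )
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        coerced = pd.DataFrame(table).apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & table.notna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise TableFormatError(
                f"non-numeric count at sample {table.index[r]!r}, OTU {table.columns[c]!r}: "
                f"{table.iat[r, c]!r}"
            )
        values = coerced.to_numpy()
        table = coerced
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise TableFormatError(f"missing count at sample {table.index[r]!r}, OTU {table.columns[c]!r}")
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise TableFormatError(
            f"negative count at sample {table.index[r]!r}, OTU {table.columns[c]!r}: {values[r, c]}"
        )
    if not np.allclose(values, np.round(values)):
        r, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise TableFormatError(
            f"non-integer count at sample {table.index[r]!r}, OTU {table.columns[c]!r}: {values[r, c]}"
        )
    out = table.astype(np.int64)
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    return out


def read_count_table(path: str | Path, orientation: str = "otu_rows") -> pd.DataFrame:
    """Read a TSV count table and return it oriented samples x OTUs.

    Parameters
    ----------
    path
        Tab-delimited file with a header row of identifiers.
    orientation
        ``"otu_rows"`` (default; rows are OTUs, the common QIIME export) or
        ``"sample_rows"``.  No auto-detection is attempted.
    """
    if orientation not in ("otu_rows", "sample_rows"):
        raise ValueError(f"orientation must be 'otu_rows' or 'sample_rows', got {orientation!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.isna().any() or raw.isna().any().any():
        raise TableFormatError(f"{path}: ragged or incomplete rows")
    table = raw.T if orientation == "otu_rows" else raw
    table = validate_count_table(table)
    table.index.name = "sample_id"
    table.columns.name = None
    return table


def write_count_table(table: pd.DataFrame, path: str | Path, orientation: str = "otu_rows") -> None:
    """Write a samples x OTUs count table as TSV (default: OTUs as rows)."""
    out = table.T if orientation == "otu_rows" else table
    label = "otu_id" if orientation == "otu_rows" else "sample_id"
    out.to_csv(path, sep="\t", index_label=label)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse one QIIME-style rank-prefixed lineage string.

    ``"k__Fungi;p__Ascomycota"`` maps to kingdom Fungi, phylum Ascomycota,
    with all deeper ranks recorded as unclassified.  Empty names after the
    prefix are treated as unclassified.
    """
    out = {rank: UNCLASSIFIED for rank in RANKS}
    letter_to_rank = {v: k for k, v in RANK_LETTERS.items()}
    for token in str(lineage).split(";"):
        token = token.strip()
        if not token:
            continue
        if len(token) >= 3 and token[1:3] == "__" and token[0] in letter_to_rank:
            name = token[3:].strip()
            if name and name.lower() != UNCLASSIFIED:
                out[letter_to_rank[token[0]]] = name
    return out


def format_lineage(row: pd.Series) -> str:
    """Inverse of :func:`parse_lineage` for a taxonomy-map row."""
    parts = []
    for rank in RANKS:
        name = row[rank]
        parts.append(f"{RANK_LETTERS[rank]}__{'' if name == UNCLASSIFIED else name}")
    return ";".join(parts)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a two-column TSV (otu_id, lineage) into a taxonomy map."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[1] < 1:
        raise TableFormatError(f"{path}: expected otu_id and lineage columns")
    if raw.index.has_duplicates:
        raise TableFormatError(f"{path}: duplicate OTU ids in taxonomy")
    lineages = raw.iloc[:, 0]
    records = {otu: parse_lineage(lin) for otu, lin in lineages.items()}
    tax = pd.DataFrame.from_dict(records, orient="index", columns=list(RANKS))
    tax.index = tax.index.astype(str)
    tax.index.name = "otu_id"
    return tax


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    lineages = tax.apply(format_lineage, axis=1)
    lineages.rename("lineage").to_csv(path, sep="\t", index_label="otu_id")


def complete_taxonomy(tax: pd.DataFrame, otu_ids) -> pd.DataFrame:
    """Ensure every OTU has a lineage row; missing OTUs become all-unclassified."""
    missing = [o for o in otu_ids if o not in tax.index]
    if not missing:
        return tax
    filler = pd.DataFrame(UNCLASSIFIED, index=pd.Index(missing, name=tax.index.name), columns=list(RANKS))
    return pd.concat([tax, filler])


def taxon_label(row: pd.Series, rank: str) -> str:
    """Aggregation label of one OTU at ``rank``.

    A classified OTU contributes its plain name.  An OTU unclassified at the
    rank contributes a composite built from its deepest classified ancestor,
    ``<rankletter>_unclassified_<deepestletter>__<name>`` — e.g. an OTU
    resolved to order Tremellales but not family aggregates into
    ``f_unclassified_o__Tremellales``.  With no classified ancestor at all
    the label is ``<rankletter>__unclassified``.
    """
    name = row[rank]
    if name != UNCLASSIFIED:
        return name
    letter = RANK_LETTERS[rank]
    for ancestor in reversed(RANKS[: RANKS.index(rank)]):
        if row[ancestor] != UNCLASSIFIED:
            return f"{letter}_unclassified_{RANK_LETTERS[ancestor]}__{row[ancestor]}"
    return f"{letter}__{UNCLASSIFIED}"


def aggregate_to_rank(table: pd.DataFrame, tax: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Sum OTU counts into taxon columns at the requested rank.

    Column sums are conserved: the grand total of the output equals that of
    the input for every rank.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    tax = complete_taxonomy(tax, table.columns)
    labels = {otu: taxon_label(tax.loc[otu], rank) for otu in table.columns}
    agg = table.T.groupby(table.columns.map(labels)).sum().T
    agg.index.name = table.index.name
    agg.columns.name = rank
    return agg


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def validate_sample_frame(meta: pd.DataFrame, table: pd.DataFrame | None = None,
                          require_soil: bool = True) -> pd.DataFrame:
    """Check group labels, pairing and soil values of a sample frame."""
    if "group" not in meta.columns:
        raise TableFormatError("sample frame must have a 'group' column")
    groups = meta["group"].unique()
    if len(groups) != 2:
        raise TableFormatError(f"expected exactly two group labels, found {sorted(map(str, groups))}")
    if table is not None:
        missing = [s for s in table.index if s not in meta.index]
        if missing:
            raise TableFormatError(f"samples without metadata rows: {missing}")
    soil_cols = [c for c in SOIL_VARIABLES if c in meta.columns]
    if require_soil and soil_cols:
        soil = meta[soil_cols].apply(pd.to_numeric, errors="coerce")
        if not np.isfinite(soil.to_numpy(float)).all():
            bad = soil.columns[soil.isna().any() | ~np.isfinite(soil).all()].tolist()
            raise TableFormatError(f"non-finite soil values in columns {bad}")
        meta = meta.copy()
        meta[soil_cols] = soil
    return meta


def read_sample_frame(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return validate_sample_frame(meta)


def write_sample_frame(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def soil_matrix(meta: pd.DataFrame) -> pd.DataFrame:
    """Extract the numeric soil-variable block of a sample frame."""
    cols = [c for c in SOIL_VARIABLES if c in meta.columns]
    if not cols:
        raise TableFormatError("sample frame carries no soil variable columns")
    return meta[cols].astype(float)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a co-occurrence network as GraphML or a CSV edge list.

    Node attributes (abundance, phylum, module) and edge attributes
    (rho, weight=|rho|, sign, p) are preserved; GraphML round-trips to an
    isomorphic graph with identical attributes.
    """
    if format not in ("graphml", "csv"):
        raise ValueError(f"format must be 'graphml' or 'csv', got {format!r}")
    if net.number_of_nodes() == 0:
        warnings.warn(f"writing empty network to {path}", stacklevel=2)
    if format == "graphml":
        nx.write_graphml(net, path)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "rho", "weight", "sign", "p"])
        for u, v, d in net.edges(data=True):
            writer.writerow([u, v, d.get("rho", ""), d.get("weight", ""),
                             d.get("sign", ""), d.get("p", "")])


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    if format == "graphml":
        return nx.read_graphml(path)
    net = nx.Graph()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            net.add_edge(row["source"], row["target"],
                         rho=float(row["rho"]), weight=float(row["weight"]),
                         sign=row["sign"], p=float(row["p"]))
    return net
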