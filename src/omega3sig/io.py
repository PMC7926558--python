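"""Domain containers and readers/writers for the pipeline's tabular artifacts.

Canonical on-disk matrix format is TSV (first column ``gene_id``, header row
of sample ids); MatrixMarket triplets are supported read-only with
``<stem>.rows.txt`` / ``<stem>.cols.txt`` sidecars. Gene-set collections use
the standard GMT format.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("omega3sig")

BIOTYPES = ("protein_coding", "lncRNA", "other")
SPECIES = ("human", "mouse")
CONDITIONS = ("vehicle", "DHA", "EPA", "OA")

__all__ = [
    "GeneTable",
    "CountMatrix",
    "DesignTable",
    "GeneSetCollection",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_table",
    "write_gene_table",
    "read_design_table",
    "write_design_table",
    "read_gmt",
    "write_gmt",
    "FLOAT_FORMAT",
]

# single float format everywhere so reruns are byte-identical
FLOAT_FORMAT = "%.10g"


class FormatError(ValueError):
    """Malformed input artifact."""


@dataclasses.dataclass(frozen=True)
class GeneTable:
    """Per-gene annotation: unique id, biotype and species of origin.

    The biotype governs the biotype-specific CPM and fold-change thresholds;
    the species prefix matters only for the exosome origin-partitioning stage.
    """

    table: pd.DataFrame  # index: gene_id; columns: biotype, species

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_id(s): {dups[:5]}")
        bad = set(t["biotype"].unique()) - set(BIOTYPES)
        if bad:
            raise ValueError(f"unknown biotype(s): {sorted(bad)}")
        bad = set(t["species"].unique()) - set(SPECIES)
        if bad:
            raise ValueError(f"unknown species: {sorted(bad)}")

    @classmethod
    def from_records(
        cls,
        gene_ids: Sequence[str],
        biotypes: Sequence[str] | str = "protein_coding",
        species: Sequence[str] | str = "human",
    ) -> "GeneTable":
        n = len(gene_ids)
        if isinstance(biotypes, str):
            biotypes = [biotypes] * n
        if isinstance(species, str):
            species = [species] * n
        df = pd.DataFrame(
            {"biotype": list(biotypes), "species": list(species)},
            index=pd.Index(gene_ids, name="gene_id"),
        )
        return cls(df)

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def biotype_of(self, gene_ids: Sequence[str]) -> pd.Series:
        return self.table.loc[list(gene_ids), "biotype"]

    def subset(self, gene_ids: Sequence[str]) -> "GeneTable":
        return GeneTable(self.table.loc[list(gene_ids)])

    def genes_of_biotype(self, biotype: str) -> list[str]:
        return self.table.index[self.table["biotype"] == biotype].tolist()

    def genes_of_species(self, species: str) -> list[str]:
        return self.table.index[self.table["species"] == species].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclasses.dataclass(frozen=True)
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts.

    ``library_size`` defaults to the column sums and may be overridden when a
    sample's true sequencing depth differs from its post-filter column sum.
    """

    counts: pd.DataFrame  # index: gene_id; columns: sample_id; integer
    library_size: pd.Series = None  # per-sample, > 0

    def __post_init__(self) -> None:
        c = self.counts
        if not np.issubdtype(c.values.dtype, np.integer):
            if not np.allclose(c.values, np.round(c.values)):
                raise FormatError("counts must be integers")
            object.__setattr__(self, "counts", c.astype(np.int64))
            c = self.counts
        if (c.values < 0).any():
            raise FormatError("counts must be non-negative")
        if self.library_size is None:
            object.__setattr__(self, "library_size", c.sum(axis=0))
        ls = self.library_size
        if not ls.index.equals(c.columns):
            raise ValueError("library_size index must match sample columns")
        if (ls <= 0).any():
            bad = ls.index[ls <= 0].tolist()
            raise ValueError(f"non-positive library size for sample(s): {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.library_size)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)], self.library_size[list(sample_ids)]
        )


@dataclasses.dataclass(frozen=True)
class DesignTable:
    """Sample-to-treatment assignment for the hepatocyte experiment."""

    table: pd.DataFrame  # columns: sample_id, condition, donor_id, replicate

    REQUIRED = ("sample_id", "condition", "donor_id", "replicate")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing column(s): {sorted(missing)}")
        bad = set(self.table["condition"].unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition(s): {sorted(bad)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design table")

    def samples_of(self, condition: str) -> list[str]:
        t = self.table
        return t.loc[t["condition"] == condition, "sample_id"].tolist()

    def check_against(self, counts: CountMatrix) -> None:
        missing = set(self.table["sample_id"]) - set(counts.sample_ids)
        if missing:
            raise ValueError(f"design samples absent from count matrix: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.table)


@dataclasses.dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT-style) with an optional enrichment universe."""

    sets: Mapping[str, list[str]]
    descriptions: Mapping[str, str] = dataclasses.field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers


def _read_mtx(path: Path) -> pd.DataFrame:
    stem = path.with_suffix("")
    rows = Path(f"{stem}.rows.txt")
    cols = Path(f"{stem}.cols.txt")
    for sidecar in (rows, cols):
        if not sidecar.exists():
            raise FormatError(f"MTX sidecar missing: {sidecar}")
    m = scipy.io.mmread(path)
    if scipy.sparse.issparse(m):
        m = m.toarray()
    gene_ids = rows.read_text().split()
    sample_ids = cols.read_text().split()
    if m.shape != (len(gene_ids), len(sample_ids)):
        raise FormatError(
            f"MTX dimensions {m.shape} do not match sidecars "
            f"({len(gene_ids)} rows, {len(sample_ids)} cols)"
        )
    return pd.DataFrame(m, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)


def read_count_matrix(path: str | Path, gene_table: GeneTable) -> CountMatrix:
    """Read a count matrix (TSV or MTX), restricted to annotated genes.

    Cells must be non-negative integers; a violation raises ``FormatError``
    naming the offending row and column. Genes absent from ``gene_table`` are
    dropped with one logged warning giving the dropped count.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        df = _read_mtx(path)
    else:
        if path.stat().st_size == 0:
            raise FormatError(f"empty count matrix file: {path}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "gene_id"
        if df.shape[1] == 0:
            raise FormatError(f"count matrix has no sample columns: {path}")
    values = df.to_numpy()
    numeric = pd.to_numeric(pd.Series(values.ravel()), errors="coerce").to_numpy()
    bad = ~np.isfinite(numeric) | (numeric < 0) | (numeric != np.round(numeric))
    if bad.any():
        i = int(np.argmax(bad))
        r, c = divmod(i, df.shape[1])
        raise FormatError(
            f"non-integer or negative count at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {values.ravel()[i]!r}"
        )
    known = df.index.isin(gene_table.gene_ids)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.warning(
            "dropping %d gene(s) absent from the gene table (e.g. %s)",
            n_dropped,
            df.index[~known][0],
        )
        df = df.loc[known]
    return CountMatrix(df.astype(np.int64))


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t")


def read_gene_table(path: str | Path) -> GeneTable:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return GeneTable(df[["biotype", "species"]])


def write_gene_table(gt: GeneTable, path: str | Path) -> None:
    gt.table.to_csv(path, sep="\t")


def read_design_table(path: str | Path) -> DesignTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    return DesignTable(df)


def write_design_table(dt: DesignTable, path: str | Path) -> None:
    dt.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: ``set_name TAB description TAB member...``.

    Duplicate members within a set are removed (first occurrence kept);
    duplicate set names, or lines with fewer than three fields, are errors.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(m for m in members if m))
            if not deduped:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")
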