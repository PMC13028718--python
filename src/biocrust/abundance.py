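"""Count tables, metadata and taxonomy: containers, readers and resampling.

The central object is :class:`AbundanceTable`, an integer samples x ASVs
count matrix with authoritative string identifiers. Everything downstream
(diversity, networks, the neutral model) consumes this type. Rarefaction is
uniform subsampling without replacement (multivariate hypergeometric), the
standard normalisation for amplicon count tables before diversity and
co-occurrence analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "Taxonomy",
    "read_abundance_table",
    "read_metadata",
    "read_taxonomy",
    "rarefy",
    "goods_coverage",
    "top_n_asvs",
]


@dataclass
class AbundanceTable:
    """Samples x ASVs integer count matrix with identifier bookkeeping.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row.
    asv_ids : list of str
        Unique ASV identifiers, one per column.
    counts : ndarray of int, shape (n_samples, n_asvs)
        Non-negative read counts.
    """

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.asv_ids = [str(a) for a in self.asv_ids]
        n, m = self.counts.shape
        if n < 1 or m < 1:
            raise ValueError("table needs at least one sample and one ASV")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match counts rows")
        if len(self.asv_ids) != m:
            raise ValueError("asv_ids length does not match counts columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.asv_ids)) != m:
            raise ValueError("duplicate ASV identifiers")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    # -- basic views -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def asv_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised counts (each sample sums to 1)."""
        sums = self.sample_sums().astype(float)
        if (sums == 0).any():
            raise ValueError("sample with zero total reads")
        return self.counts / sums[:, None]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def subset_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceTable(list(sample_ids), list(self.asv_ids), self.counts[idx])

    def subset_asvs(self, asv_ids: list[str]) -> "AbundanceTable":
        pos = {a: j for j, a in enumerate(self.asv_ids)}
        idx = [pos[a] for a in asv_ids]
        return AbundanceTable(list(self.sample_ids), list(asv_ids), self.counts[:, idx])

    def drop_empty_asvs(self) -> "AbundanceTable":
        keep = self.asv_sums() > 0
        ids = [a for a, k in zip(self.asv_ids, keep) if k]
        return AbundanceTable(list(self.sample_ids), ids, self.counts[:, keep])

    def write_tsv(self, path, orientation: str = "samples-in-rows") -> None:
        df = self.to_dataframe()
        if orientation == "asvs-in-rows":
            df = df.T
        elif orientation != "samples-in-rows":
            raise ValueError(f"unknown orientation {orientation!r}")
        df.to_csv(path, sep="\t", index_label="id")


@dataclass
class SampleMetadata:
    """Sample -> treatment group map with replicate numbers."""

    table: pd.DataFrame  # columns: sample_id, group, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        if "replicate" not in self.table.columns:
            self.table = self.table.assign(
                replicate=self.table.groupby("group").cumcount() + 1
            )

    def groups_for(self, sample_ids: list[str]) -> np.ndarray:
        lookup = dict(zip(self.table["sample_id"], self.table["group"]))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")
        return np.array([lookup[s] for s in sample_ids])

    def samples_in_group(self, group: str) -> list[str]:
        sel = self.table["group"] == group
        return list(self.table.loc[sel, "sample_id"])

    @property
    def group_names(self) -> list[str]:
        return list(pd.unique(self.table["group"]))


RANK_ORDER = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]


@dataclass
class Taxonomy:
    """ASV -> lineage map. Ranks beyond what the annotation gives are absent."""

    ranks: pd.DataFrame = field(default_factory=pd.DataFrame)  # index asv_id

    def __post_init__(self) -> None:
        if self.ranks.index.duplicated().any():
            raise ValueError("duplicate asv_id in taxonomy")
        unknown = [c for c in self.ranks.columns if c not in RANK_ORDER]
        if unknown:
            raise ValueError(f"unknown rank names: {unknown}")

    def rank_of(self, asv_id: str, rank: str) -> str | None:
        if asv_id in self.ranks.index and rank in self.ranks.columns:
            val = self.ranks.loc[asv_id, rank]
            return None if pd.isna(val) else str(val)
        return None


# ---------------------------------------------------------------------------
# readers


def read_abundance_table(path, orientation: str = "samples-in-rows") -> AbundanceTable:
    """Read a TSV count table, normalised to samples x ASVs.

    The first column holds row identifiers, the header row column
    identifiers. `orientation` says which axis carries samples in the file.
    """
    if orientation not in ("samples-in-rows", "asvs-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {raw!r} at row {df.index[i]!r}, "
                    f"column {col!r} in {path}"
                ) from None
            if val < 0:
                raise ValueError(
                    f"negative count {val} at row {df.index[i]!r}, column {col!r}"
                )
            counts[i, j] = val
    if orientation == "asvs-in-rows":
        return AbundanceTable(list(df.columns), list(df.index), counts.T)
    return AbundanceTable(list(df.index), list(df.columns), counts)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    return SampleMetadata(df)


def read_taxonomy(path) -> Taxonomy:
    """Read taxonomy TSV: either one column per rank, or a semicolon-joined
    `lineage` column (kingdom;phylum;...)."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("asv_id")
    if "lineage" in df.columns:
        parts = df["lineage"].str.split(";", expand=True)
        parts.columns = RANK_ORDER[: parts.shape[1]]
        df = parts.apply(lambda c: c.str.strip())
    return Taxonomy(df)


# ---------------------------------------------------------------------------
# resampling and filtering


def rarefy(table: AbundanceTable, depth: int, seed: int | None = None) -> AbundanceTable:
    """Subsample every sample to exactly `depth` reads without replacement.

    Samples with fewer than `depth` total reads are dropped with a warning.
    Deterministic given `seed` (multivariate hypergeometric draw per sample).
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums >= depth
    if not keep.any():
        raise ValueError("no sample reaches the rarefaction depth")
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped[:5]}",
            stacklevel=2,
        )
    rows = []
    for i in np.flatnonzero(keep):
        rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
    ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return AbundanceTable(ids, list(table.asv_ids), np.array(rows, dtype=np.int64))


def goods_coverage(table: AbundanceTable) -> np.ndarray:
    """Good's coverage per sample: 1 - singletons / total reads."""
    sums = table.sample_sums()
    if (sums == 0).any():
        raise ValueError("empty sample: coverage undefined")
    singletons = (table.counts == 1).sum(axis=1)
    return 1.0 - singletons / sums


def top_n_asvs(table: AbundanceTable, n: int) -> AbundanceTable:
    """Keep the n most abundant ASVs by total count.

    Ties broken by ASV identifier ascending so the selection is
    deterministic. If the table has fewer than n ASVs all are kept.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    totals = table.asv_sums()
    order = sorted(range(table.n_asvs), key=lambda j: (-totals[j], table.asv_ids[j]))
    chosen = sorted(order[:n])  # preserve original column order
    ids = [table.asv_ids[j] for j in chosen]
    return AbundanceTable(list(table.sample_ids), ids, table.counts[:, chosen])
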