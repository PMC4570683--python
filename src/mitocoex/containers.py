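"""In-memory containers shared across the pipeline.

The pipeline moves three kinds of data around: a gene × sample expression
matrix with a normalization state, the factorial sample design (cell line ×
treatment × replicate), and named gene sets with functional roles (OXPHOS
complex subunits, assembly factors, mitochondrial annotation, ...).  All
three are thin wrappers over pandas objects so they interoperate with the
usual DataFrame tooling while enforcing the invariants the analysis relies
on (unique identifiers, known normalization state, mutually exclusive
analysis groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: valid normalization states, in pipeline order
STATES = ("raw", "log", "centered")

NUCLEAR = "nuclear"
MITOCHONDRIAL = "mitochondrial"


class CatalogError(ValueError):
    """Raised when a gene-set catalog violates an analysis requirement."""


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values with a normalization state.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per sample id.  In the
        ``raw`` state values are RPKM (non-negative); after log transform
        and median centering they are dimensionless ratios around 1.0.
    state
        One of ``raw``, ``log``, ``centered``.
    origin
        Per-gene flag, ``nuclear`` or ``mitochondrial``.  Defaults to all
        nuclear.
    """

    data: pd.DataFrame
    state: str = "raw"
    origin: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.origin is None:
            self.origin = pd.Series(NUCLEAR, index=self.data.index)
        else:
            self.origin = self.origin.reindex(self.data.index)
            if self.origin.isna().any():
                missing = self.origin.index[self.origin.isna()].tolist()
                raise ValueError(f"origin missing for genes: {missing[:5]}")
            bad = set(self.origin.unique()) - {NUCLEAR, MITOCHONDRIAL}
            if bad:
                raise ValueError(f"unknown origin labels: {sorted(bad)}")
        if self.state == "raw" and (self.data.to_numpy() < 0).any():
            raise ValueError("raw RPKM values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Row subset preserving the requested order; genes must exist."""
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.data.loc[genes].copy(), self.state, self.origin.loc[genes].copy()
        )

    def nuclear(self) -> "ExpressionMatrix":
        keep = self.origin[self.origin == NUCLEAR].index
        return self.subset_genes(keep)

    def mitochondrial(self) -> "ExpressionMatrix":
        keep = self.origin[self.origin == MITOCHONDRIAL].index
        return self.subset_genes(keep)

    def with_data(self, data: pd.DataFrame, state: str) -> "ExpressionMatrix":
        """New matrix with replaced values/state, origin realigned to rows."""
        return ExpressionMatrix(data, state, self.origin.reindex(data.index))


@dataclass
class SampleDesign:
    """Per-sample metadata for the factorial design.

    ``table`` has columns sample_id, cell_line, genotype, treatment,
    replicate; genotype is ``control`` or ``patient``.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "cell_line", "genotype", "treatment", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids matching all column=value conditions."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            mask &= self.table[col] == val
        return list(self.table.loc[mask, "sample_id"])


@dataclass
class GeneSetCatalog:
    """Named gene sets (GMT-style) with optional per-set role labels.

    Roles distinguish the bait set from the mutually exclusive analysis
    groups (complex I–V subunits, assembly factors, mitochondrial, other).
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                self.sets[name] = list(dict.fromkeys(members))

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> set[str]:
        return set(self.sets[name])

    def validate_exclusive(self, names: list[str] | None = None) -> None:
        """Require the listed groups (default: all) to be pairwise disjoint."""
        names = list(names) if names is not None else self.names
        seen: dict[str, str] = {}
        for name in names:
            for gene in self.sets[name]:
                if gene in seen:
                    raise CatalogError(
                        f"gene {gene!r} occurs in groups {seen[gene]!r} and {name!r}; "
                        "analysis groups must be mutually exclusive"
                    )
                seen[gene] = name
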