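"""Core in-memory containers for the pipeline.

The root object is :class:`OtuTable`, an integer sample × OTU count matrix.
Row-normalised abundances live in :class:`RelAbundanceTable`; per-sample host
annotations in :class:`SampleMetadata`; lineage strings in :class:`TaxonomyMap`.
Distance matrices use :class:`skbio.DistanceMatrix` directly and phylogenies use
:class:`skbio.TreeNode` — there is no point wrapping either.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "RelAbundanceTable",
    "SampleMetadata",
    "TaxonomyMap",
    "DIET_GROUPS",
    "FEEDING_HABITS",
    "TAXONOMIC_RANKS",
]

#: The seven diet-type groups used throughout the analysis and the generator.
DIET_GROUPS = ("fruits", "corn-soy", "grains", "foliage", "flesh", "fish", "omnivore")

#: The six broad feeding-habit categories.
FEEDING_HABITS = (
    "herbivore",
    "frugivore",
    "granivore",
    "carnivore",
    "piscivore",
    "omnivore",
)

#: Canonical seven-rank lineage order.
TAXONOMIC_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


def _check_ids(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(ids) == 0:
        raise ValueError(f"need at least one {what}")
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


@dataclass
class OtuTable:
    """Validated integer count matrix, samples as rows, OTUs as columns.

    Parameters
    ----------
    data
        DataFrame with sample ids as the index and OTU ids as the columns.
        Entries must be nonnegative integers.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        samples = _check_ids(self.data.index, "sample")
        otus = _check_ids(self.data.columns, "OTU")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            fvals = np.asarray(values, dtype=float)
            if not np.all(np.isfinite(fvals)):
                raise ValueError("count table contains non-finite values")
            if not np.all(fvals == np.round(fvals)):
                r, c = np.argwhere(fvals != np.round(fvals))[0]
                raise ValueError(
                    f"non-integer count at sample {samples[r]!r}, OTU {otus[c]!r}: "
                    f"{fvals[r, c]!r} (pass counts through an explicit rounding step "
                    "if this is intended)"
                )
            values = fvals.astype(np.int64)
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at sample {samples[r]!r}, OTU {otus[c]!r}: {values[r, c]}"
            )
        self.data = pd.DataFrame(
            values.astype(np.int64), index=pd.Index(samples), columns=pd.Index(otus)
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, OtuTable) and self.data.equals(other.data)


@dataclass
class RelAbundanceTable:
    """Row-normalised abundance matrix; every row sums to 1 within 1e-9.

    A column subset produced by abundance filtering keeps whole-community
    fractions (rows then sum to < 1); such subsets are built with
    ``unit_rows=False``.
    """

    data: pd.DataFrame
    unit_rows: bool = True

    _ROW_SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        samples = _check_ids(self.data.index, "sample")
        otus = _check_ids(self.data.columns, "OTU")
        values = np.asarray(self.data.to_numpy(), dtype=float)
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("relative abundances must be finite and nonnegative")
        sums = values.sum(axis=1)
        limit = self._ROW_SUM_TOL if self.unit_rows else 1.0 + self._ROW_SUM_TOL
        bad = np.where(np.abs(sums - 1.0) > self._ROW_SUM_TOL)[0] if self.unit_rows else np.where(sums > limit)[0]
        if bad.size:
            raise ValueError(
                f"sample {samples[bad[0]]!r} abundances sum to {sums[bad[0]]!r}"
                + (", not 1" if self.unit_rows else " > 1")
            )
        self.data = pd.DataFrame(values, index=pd.Index(samples), columns=pd.Index(otus))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def fractions(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]


@dataclass
class SampleMetadata:
    """Per-sample host annotations: species, feeding habit and diet-type group."""

    data: pd.DataFrame  # index: sample id; columns: host_species, feeding_habit, diet_group

    REQUIRED = ("host_species", "feeding_habit", "diet_group")

    def __post_init__(self) -> None:
        _check_ids(self.data.index, "sample")
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(
                f"metadata missing required column(s) {missing}; found {list(self.data.columns)}"
            )
        for col, levels in (("feeding_habit", FEEDING_HABITS), ("diet_group", DIET_GROUPS)):
            unknown = sorted(set(self.data[col].astype(str)) - set(levels))
            if unknown:
                warnings.warn(
                    f"unknown {col} level(s) {unknown}; retained as their own levels",
                    stacklevel=2,
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def diet_groups(self, sample_ids=None) -> pd.Series:
        s = self.data["diet_group"].astype(str)
        return s if sample_ids is None else s.loc[list(sample_ids)]

    def host_species(self, sample_ids=None) -> pd.Series:
        s = self.data["host_species"].astype(str)
        return s if sample_ids is None else s.loc[list(sample_ids)]

    def require_samples(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")


@dataclass
class TaxonomyMap:
    """OTU id → ordered lineage; unknown ranks are explicit empty strings."""

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for otu, lineage in self.lineages.items():
            lineage = tuple(str(x) for x in lineage)
            if len(lineage) > len(TAXONOMIC_RANKS):
                raise ValueError(
                    f"lineage for {otu!r} has {len(lineage)} ranks; "
                    f"at most {len(TAXONOMIC_RANKS)} allowed"
                )
            # pad truncated lineages so unknown ranks stay explicit
            clean[str(otu)] = lineage + ("",) * (len(TAXONOMIC_RANKS) - len(lineage))
        self.lineages = clean

    def rank(self, otu_id: str, rank: str) -> str:
        return self.lineages[otu_id][TAXONOMIC_RANKS.index(rank)]

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)
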