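"""Rarefaction, relative-abundance conversion and abundance/prevalence filters.

Counts are rarefied by a single seeded subsampling draw without replacement
(the multivariate hypergeometric), the common practice for equalising
sequencing effort before diversity analysis. Samples whose library is smaller
than the target depth are dropped, not padded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import OtuTable, RelAbundanceTable

__all__ = [
    "rarefy",
    "to_relative",
    "filter_low_abundance",
    "prevalence_summary",
    "PrevalenceSummary",
]

logger = logging.getLogger(__name__)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample's counts without replacement to a common depth.

    Each retained row is one uniform draw of ``depth`` reads from the sample's
    read multiset, so its rarefied counts follow the multivariate
    hypergeometric distribution and sum exactly to ``depth``. Samples with
    fewer than ``depth`` total counts are dropped (logged). Deterministic for
    a given ``seed``.
    """
    depth = int(depth)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_totals()
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if len(keep) == 0:
        raise ValueError(f"no samples retained: every sample total is below depth {depth}")
    if dropped:
        logger.info("rarefy: dropped %d sample(s) below depth %d: %s", len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    out = np.zeros((len(keep), table.n_otus), dtype=np.int64)
    counts = table.data.loc[keep].to_numpy()
    for i in range(len(keep)):
        row = counts[i]
        total = int(row.sum())
        if total == depth:
            out[i] = row
            continue
        # draw `depth` read positions uniformly without replacement from the
        # expanded multiset, then count which OTU each position belongs to
        positions = rng.choice(total, size=depth, replace=False)
        edges = np.cumsum(row)
        otu_of_pos = np.searchsorted(edges, positions, side="right")
        out[i] = np.bincount(otu_of_pos, minlength=table.n_otus)
    return OtuTable(pd.DataFrame(out, index=list(keep), columns=table.otu_ids))


def to_relative(table: OtuTable) -> RelAbundanceTable:
    """Divide each sample's counts by its total."""
    totals = table.counts.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValueError(f"sample {table.sample_ids[zero[0]]!r} has zero total count")
    frac = table.counts / totals[:, None]
    return RelAbundanceTable(pd.DataFrame(frac, index=table.sample_ids, columns=table.otu_ids))


def filter_low_abundance(
    rel: RelAbundanceTable,
    threshold: float = 1e-4,
    *,
    criterion: str = "mean",
) -> tuple[RelAbundanceTable, list[str]]:
    """Drop rare OTUs before network construction.

    An OTU is retained iff its mean (default) or max relative abundance across
    samples is at least ``threshold`` (default 0.01%). Returns the filtered
    table (column order preserved) and the list of removed OTU ids. The
    surviving columns are NOT renormalised: completeness/abundance statistics
    downstream are defined on whole-community fractions.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    if criterion == "mean":
        score = rel.fractions.mean(axis=0)
    elif criterion == "max":
        score = rel.fractions.max(axis=0)
    else:
        raise ValueError(f"criterion must be 'mean' or 'max', got {criterion!r}")
    keep_mask = score >= threshold if threshold > 0 else np.ones(rel.n_otus, bool)
    if not keep_mask.any():
        raise ValueError(f"all OTUs fall below the {criterion} abundance threshold {threshold}")
    removed = [o for o, k in zip(rel.otu_ids, keep_mask) if not k]
    filtered = RelAbundanceTable(rel.data.loc[:, keep_mask], unit_rows=False)
    return filtered, removed


@dataclass
class PrevalenceSummary:
    """Per-OTU prevalence (fraction of samples with a nonzero count)."""

    prevalence: pd.Series  # indexed by OTU id, values in [0, 1]

    def fraction_below(self, cutoff: float) -> float:
        """Share of OTUs whose prevalence is strictly below ``cutoff``."""
        return float((self.prevalence < cutoff).mean())


def prevalence_summary(table: OtuTable) -> PrevalenceSummary:
    prev = (table.counts > 0).mean(axis=0)
    return PrevalenceSummary(pd.Series(prev, index=table.otu_ids))
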