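"""Samples x taxa count table joined to sample metadata."""

from __future__ import annotations

import numpy as np
import pandas as pd

POOLS = (300, 400)
COMPARTMENTS = ("water", "sediment", "coral")

METADATA_COLUMNS = ("pool", "compartment", "species",
                    "latitude", "longitude", "depth")


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check controlled vocabularies and coordinate ranges; returns the
    frame with canonical dtypes."""
    md = metadata.copy()
    if md.index.has_duplicates:
        dupes = sorted(md.index[md.index.duplicated()].unique())
        raise ValueError(f"duplicated sample ids in metadata: {dupes}")
    for col in ("pool", "compartment"):
        if col not in md.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    md["pool"] = md["pool"].astype(int)
    bad_pool = sorted(set(md["pool"]) - set(POOLS))
    if bad_pool:
        raise ValueError(f"unknown pool values {bad_pool}; expected {POOLS}")
    bad_comp = sorted(set(md["compartment"]) - set(COMPARTMENTS))
    if bad_comp:
        raise ValueError(
            f"unknown compartment values {bad_comp}; expected {COMPARTMENTS}")
    for col in ("species", "latitude", "longitude", "depth"):
        if col not in md.columns:
            md[col] = np.nan
    for col in ("latitude", "longitude", "depth"):
        md[col] = pd.to_numeric(md[col], errors="coerce")
    if (md["latitude"].abs() > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (md["longitude"].abs() > 180).any():
        raise ValueError("longitude outside [-180, 180]")
    return md


class CountTable:
    """Integer read counts per (sample, taxon) plus per-sample metadata.

    ``counts`` is a samples x taxa DataFrame; ``metadata`` is indexed by
    sample id and carries pool, compartment, species, and coordinates.
    Sample sets of the two frames must coincide.
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame):
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise ValueError("duplicated sample ids or taxon names")
        metadata = validate_metadata(metadata)
        missing = sorted(set(counts.index) - set(metadata.index))
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        extra = sorted(set(metadata.index) - set(counts.index))
        if extra:
            raise ValueError(f"metadata samples absent from counts: {extra}")
        self.counts = counts.astype(int)
        self.metadata = metadata.loc[counts.index]

    # -- basic accessors ---------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        """Per-sample read totals."""
        return self.counts.sum(axis=1)

    def __repr__(self) -> str:
        return (f"CountTable({len(self.samples)} samples x "
                f"{len(self.taxa)} taxa)")

    # -- manipulation ------------------------------------------------------

    def subset(self, **criteria) -> "CountTable":
        """Subset samples by metadata equality, e.g.
        ``table.subset(compartment="water", pool=300)``."""
        mask = pd.Series(True, index=self.metadata.index)
        for col, value in criteria.items():
            mask &= self.metadata[col] == value
        idx = self.metadata.index[mask]
        return CountTable(self.counts.loc[idx], self.metadata.loc[idx])

    def drop_empty_samples(self) -> "CountTable":
        keep = self.totals() > 0
        return CountTable(self.counts.loc[keep], self.metadata.loc[keep])

    def drop_empty_taxa(self) -> "CountTable":
        keep = self.counts.sum(axis=0) > 0
        return CountTable(self.counts.loc[:, keep], self.metadata)
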