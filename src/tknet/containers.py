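"""Core tabular containers shared across the pipeline.

The central object is :class:`AbundanceTable`, a features × samples matrix
(OTU counts, gene expression, lipid or metabolite intensities) carrying
per-sample metadata (experiment, group, compartment, timepoint) and an
optional per-sample DNA quantity used for normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("experiment", "group", "compartment", "timepoint")


@dataclass
class AbundanceTable:
    """Features × samples abundance matrix with sample metadata.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are features (OTUs, genes, lipids, metabolites), columns are
        sample ids. Values must be non-negative (counts or normalized
        intensities).
    metadata : pandas.DataFrame, optional
        Indexed by sample id; typically carries ``experiment``, ``group``,
        ``compartment`` and ``timepoint``.
    dna_quantity : pandas.Series, optional
        Per-sample DNA quantity (ng), used by DNA-quantity scaling.
    provenance : list of str
        Human-readable log of the operations applied so far.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None
    dna_quantity: pd.Series | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        if self.data.shape[0] == 0:
            raise ValueError("abundance table has no features")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (np.asarray(self.data.values, dtype=float) < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.metadata is not None:
            missing = set(self.data.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)}")
            if self.metadata.index.duplicated().any():
                raise ValueError("duplicate sample ids in metadata")
        if self.dna_quantity is not None:
            missing = set(self.data.columns) - set(self.dna_quantity.index)
            if missing:
                raise ValueError(f"samples missing DNA quantity: {sorted(missing)}")

    # -- convenience accessors -------------------------------------------
    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy_with(self, data: pd.DataFrame, note: str | None = None) -> "AbundanceTable":
        """Return a new table with replaced values, metadata carried over."""
        meta = None if self.metadata is None else self.metadata.loc[list(data.columns)]
        dna = None
        if self.dna_quantity is not None:
            dna = self.dna_quantity.loc[list(data.columns)]
        prov = list(self.provenance) + ([note] if note else [])
        return AbundanceTable(data=data, metadata=meta, dna_quantity=dna, provenance=prov)

    def select_samples(self, mask_or_ids) -> "AbundanceTable":
        """Subset to samples, by boolean metadata mask or explicit id list."""
        if isinstance(mask_or_ids, pd.Series):
            ids = list(mask_or_ids.index[mask_or_ids])
        else:
            ids = list(mask_or_ids)
        return self.copy_with(self.data[ids])

    def samples_in(self, **conditions) -> "AbundanceTable":
        """Subset to samples whose metadata matches all keyword conditions.

        ``table.samples_in(group="WD", compartment="stool4")``
        """
        if self.metadata is None:
            raise ValueError("no metadata attached")
        mask = pd.Series(True, index=self.metadata.index)
        for key, value in conditions.items():
            mask &= self.metadata[key] == value
        ids = [s for s in self.data.columns if mask.get(s, False)]
        return self.copy_with(self.data[ids])

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, path, metadata_path=None) -> None:
        """Write values as TSV (leading feature-id column) and metadata as CSV."""
        path = Path(path)
        out = self.data.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")
        if metadata_path is not None and self.metadata is not None:
            meta = self.metadata.copy()
            meta.index.name = "sample_id"
            meta.to_csv(metadata_path)

    @classmethod
    def from_tsv(cls, path, metadata_path=None, dna_path=None) -> "AbundanceTable":
        data = pd.read_csv(path, sep="\t", index_col=0)
        metadata = None
        if metadata_path is not None:
            metadata = pd.read_csv(metadata_path, index_col=0)
        dna = None
        if dna_path is not None:
            dna = pd.read_csv(dna_path, index_col=0).iloc[:, 0]
        return cls(data=data, metadata=metadata, dna_quantity=dna)
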