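"""Parcel atlas container.

A :class:`ParcelAtlas` holds the per-parcel metadata every stage of the
pipeline keys on: an integer parcel id, the hemisphere, a functional-network
label, the association/sensory class of that network, and a 3-D centroid used
to build the inter-parcel distance matrix for spatially informed nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

#: CAB-NP-style network labels, split into higher-order (association) and
#: primary (sensory) classes.  The first eight are association networks,
#: the last four sensory, mirroring the 12-network whole-brain parcellation.
ASSOCIATION_NETWORKS = ("DMN", "FPN", "LAN", "OAN", "VMM", "PMM", "CON", "DAN")
SENSORY_NETWORKS = ("AUD", "VIS1", "SOM", "VIS2")

ATLAS_COLUMNS = ["parcel_id", "hemisphere", "network", "klass", "x", "y", "z"]


@dataclass(frozen=True)
class ParcelAtlas:
    """Immutable table of parcel identities, labels and centroids."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ATLAS_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        pid = t["parcel_id"].to_numpy()
        if len(np.unique(pid)) != len(pid):
            raise ValueError("parcel_ids must be unique")
        if not np.array_equal(np.sort(pid), np.arange(1, len(pid) + 1)):
            raise ValueError("parcel_ids must be contiguous from 1")
        if not set(t["hemisphere"]) <= {"L", "R"}:
            raise ValueError("hemisphere must be 'L' or 'R'")
        if not ({"L", "R"} <= set(t["hemisphere"])):
            raise ValueError("both hemispheres must be non-empty")
        if not set(t["klass"]) <= {"association", "sensory"}:
            raise ValueError("klass must be 'association' or 'sensory'")
        if not np.isfinite(t[["x", "y", "z"]].to_numpy()).all():
            raise ValueError("centroids must be finite")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def parcel_ids(self) -> np.ndarray:
        return self.table["parcel_id"].to_numpy()

    @property
    def networks(self) -> np.ndarray:
        return self.table["network"].to_numpy()

    @property
    def klass(self) -> np.ndarray:
        return self.table["klass"].to_numpy()

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(float)

    @property
    def is_association(self) -> np.ndarray:
        return self.klass == "association"

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix between parcel centroids."""
        return squareform(pdist(self.centroids))

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.table[ATLAS_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "ParcelAtlas":
        return cls(pd.read_csv(path, sep="\t", float_precision="round_trip"))
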