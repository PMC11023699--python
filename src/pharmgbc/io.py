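"""Plain-text (TSV) readers and writers for every pipeline input/output.

Formats:
  atlas        parcel_id, hemisphere, network, klass, x, y, z
  time series  frames × parcels, header = parcel ids
  motion       frame, FD, RMS
  behavior     subject × item
  gene map     parcel_id, value, differential_stability
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .connectivity import ParcelTimeSeries
from .genemap import GeneExpressionMap


def write_timeseries(ts: ParcelTimeSeries, data_path, motion_path=None) -> None:
    cols = [str(i + 1) for i in range(ts.n_parcels)]
    pd.DataFrame(ts.data, columns=cols).to_csv(
        data_path, sep="\t", index=False, float_format="%.17g"
    )
    if motion_path is not None:
        pd.DataFrame(
            {"frame": np.arange(ts.n_frames), "FD": ts.fd, "RMS": ts.rms}
        ).to_csv(motion_path, sep="\t", index=False, float_format="%.17g")


def read_timeseries(data_path, motion_path, tr: float) -> ParcelTimeSeries:
    data = pd.read_csv(data_path, sep="\t", float_precision="round_trip").to_numpy(float)
    motion = pd.read_csv(motion_path, sep="\t", float_precision="round_trip")
    return ParcelTimeSeries(
        data=data, tr=tr, fd=motion["FD"].to_numpy(float), rms=motion["RMS"].to_numpy(float)
    )


def write_maps(maps: np.ndarray, path, atlas: ParcelAtlas | None = None) -> None:
    """Subjects × parcels matrix (e.g. Δ-GBC maps), header = parcel ids."""
    maps = np.atleast_2d(np.asarray(maps, float))
    cols = (
        [str(i) for i in atlas.parcel_ids]
        if atlas is not None
        else [str(i + 1) for i in range(maps.shape[1])]
    )
    pd.DataFrame(maps, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_maps(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", float_precision="round_trip").to_numpy(float)


def write_behavior(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="subject", float_format="%.17g")


def read_behavior(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject", float_precision="round_trip")


def write_gene_map(gm: GeneExpressionMap, path) -> None:
    pd.DataFrame(
        {
            "parcel_id": np.arange(1, len(gm.values) + 1),
            "value": gm.values,
            "differential_stability": gm.differential_stability,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_map(path, gene: str | None = None) -> GeneExpressionMap:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return GeneExpressionMap(
        gene=gene or Path(path).stem,
        values=df["value"].to_numpy(float),
        differential_stability=float(df["differential_stability"].iloc[0]),
    )
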