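"""Fixed-resolution tissue score tracks.

A :class:`TrackSet` presents per-tissue genome tracks binned at a fixed
step (25 bp by default) behind one interface, whether they come from
in-memory arrays, fixed-step bedGraph files, or bigWig files.  The model
queries ``values(chrom, bins)`` and receives a (n_bins, d_tissues) matrix
with NaN outside track bounds.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrackSet", "read_bedgraph_track", "write_bed_scores"]


def read_bedgraph_track(path, bin_size: int = 25) -> dict[str, np.ndarray]:
    """Read a fixed-step bedGraph (0-based half-open, constant step) into
    per-chromosome bin arrays."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if ((df["end"] - df["start"]) != bin_size).any():
        raise ValueError(f"{path}: intervals are not fixed {bin_size} bp steps")
    if (df["start"] % bin_size).any():
        raise ValueError(f"{path}: intervals are not aligned to the {bin_size} bp grid")
    out = {}
    for chrom, sub in df.groupby("chrom"):
        bins = (sub["start"] // bin_size).to_numpy()
        arr = np.full(int(bins.max()) + 1, np.nan)
        arr[bins] = sub["value"].to_numpy(dtype=float)
        out[str(chrom)] = arr
    return out


class TrackSet:
    """Per-tissue binned score tracks with a uniform lookup interface."""

    def __init__(self, tissue_arrays: dict[str, dict[str, np.ndarray]], bin_size: int = 25):
        self.bin_size = bin_size
        self.tissue_ids = list(tissue_arrays)
        self._arrays = tissue_arrays

    @classmethod
    def from_arrays(cls, tissue_arrays, bin_size: int = 25) -> "TrackSet":
        return cls(tissue_arrays, bin_size=bin_size)

    @classmethod
    def from_bedgraph_dir(cls, directory, bin_size: int = 25, suffix: str = ".bedgraph") -> "TrackSet":
        """One track per ``<tissue><suffix>`` file in ``directory``."""
        directory = Path(directory)
        arrays = {}
        for path in sorted(directory.glob(f"*{suffix}")):
            arrays[path.name[: -len(suffix)]] = read_bedgraph_track(path, bin_size=bin_size)
        if not arrays:
            raise FileNotFoundError(f"no *{suffix} tracks under {directory}")
        return cls(arrays, bin_size=bin_size)

    @classmethod
    def from_bigwig_dir(cls, directory, bin_size: int = 25, suffix: str = ".bw") -> "TrackSet":
        import pyBigWig  # optional dependency

        directory = Path(directory)
        arrays = {}
        for path in sorted(directory.glob(f"*{suffix}")):
            bw = pyBigWig.open(str(path))
            per_chrom = {}
            for chrom, length in bw.chroms().items():
                n_bins = length // bin_size
                vals = np.asarray(
                    bw.stats(chrom, 0, n_bins * bin_size, nBins=n_bins), dtype=float
                )
                per_chrom[str(chrom).removeprefix("chr")] = vals
            bw.close()
            arrays[path.name[: -len(suffix)]] = per_chrom
        if not arrays:
            raise FileNotFoundError(f"no *{suffix} tracks under {directory}")
        return cls(arrays, bin_size=bin_size)

    def values(self, chrom: str, bins) -> np.ndarray:
        """(len(bins), d) matrix of per-tissue bin values; NaN out of bounds."""
        bins = np.asarray(bins, dtype=int)
        out = np.full((bins.size, len(self.tissue_ids)), np.nan)
        for j, tissue in enumerate(self.tissue_ids):
            arr = self._arrays[tissue].get(str(chrom))
            if arr is None:
                continue
            ok = (bins >= 0) & (bins < arr.size)
            out[ok, j] = arr[bins[ok]]
        return out


def write_bed_scores(scored: pd.DataFrame, path, bin_size: int = 25, name: str = "score") -> None:
    """Export per-position scores as BED (0-based half-open, bin-aligned)."""
    df = scored.dropna(subset=["score"]).copy()
    start = df["bin"].astype(int) * bin_size
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": start,
            "end": start + bin_size,
            name: df["score"],
        }
    ).drop_duplicates(subset=["chrom", "start"])
    out.to_csv(path, sep="\t", header=False, index=False)
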