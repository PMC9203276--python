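"""Aggregation of scaled tracks over bins, regions, promoters and chromosomes.

All intervals are 0-based half-open.  Region means are exact length-weighted
per-basepair means computed from the track's bin values (bins are constant
within), so a region covering the whole genome reproduces the global mean.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .scaling import ScaledTrack


def make_bins(chrom_sizes: dict[str, int], width: int = 10_000) -> pd.DataFrame:
    """Tile the genome into fixed-width bins (last bin truncated)."""
    if width <= 0:
        raise ConfigurationError(f"bin width must be > 0, got {width}")
    rows = []
    for chrom, length in chrom_sizes.items():
        starts = np.arange(0, length, width)
        for s in starts:
            e = min(s + width, length)
            rows.append((chrom, int(s), int(e), f"{chrom}:{s}-{e}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])


def promoter_windows(
    tss_set: pd.DataFrame, flank_up: int = 1_000, flank_down: int = 1_000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Strand-aware promoter windows around each TSS, clipped to bounds.

    On the + strand the window is [TSS - flank_up, TSS + flank_down); on the
    - strand it is mirrored.
    """
    if flank_up < 0 or flank_down < 0:
        raise ConfigurationError("flanks must be >= 0")
    plus = tss_set["strand"].to_numpy() == "+"
    pos = tss_set["pos"].to_numpy(np.int64)
    start = np.where(plus, pos - flank_up, pos - flank_down)
    end = np.where(plus, pos + flank_down, pos + flank_up)
    start = np.maximum(start, 0)
    if chrom_sizes is not None:
        lens = tss_set["chrom"].map(chrom_sizes).to_numpy(np.int64)
        end = np.minimum(end, lens)
    return pd.DataFrame(
        {
            "chrom": tss_set["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "id": tss_set["gene_id"].to_numpy(),
        }
    )


def _prefix_integrals(track: ScaledTrack) -> dict[str, np.ndarray]:
    """Per-chromosome cumulative integral of coverage at bin boundaries."""
    out = {}
    for c, v in track.values.items():
        out[c] = np.concatenate([[0.0], np.cumsum(v * track.bin_widths(c))])
    return out


def summarize_regions(track: ScaledTrack, regions: pd.DataFrame) -> pd.DataFrame:
    """Exact length-weighted mean RPGC per region.

    Returns a frame with region id, width, and ``mean``; raises listing
    offenders when regions fall outside chromosome bounds.
    """
    bad = []
    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        if chrom not in track.chrom_sizes or start < 0 or end > track.chrom_sizes[chrom] or end <= start:
            bad.append(f"{chrom}:{start}-{end}")
    if bad:
        raise DataError("regions out of bounds: " + ", ".join(bad[:10]))
    prefix = _prefix_integrals(track)
    res = track.resolution

    means = np.empty(len(regions), dtype=float)
    for i, (chrom, start, end) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"])
    ):
        p = prefix[chrom]
        v = track.values[chrom]

        def F(x):
            b = min(x // res, len(v) - 1)
            return p[b] + v[b] * (x - b * res)

        means[i] = (F(int(end)) - F(int(start))) / (end - start)
    out = regions[["id", "chrom", "start", "end"]].copy()
    out["width"] = regions["end"] - regions["start"]
    out["mean"] = means
    return out


def genome_median(track: ScaledTrack, width: int | None = None) -> float:
    """Width-weighted median of the track's bin values.

    With ``width`` the track is first rebinned to that bin size; a coarser
    median (e.g. 1 kb) stays informative at sequencing depths where most
    native-resolution bins are empty.
    """
    if width is not None and width != track.resolution:
        rebinned = summarize_regions(track, make_bins(track.chrom_sizes, width))
        vals = rebinned["mean"].to_numpy(float)
        widths = rebinned["width"].to_numpy(float)
        order = np.argsort(vals)
        cw = np.cumsum(widths[order])
        return float(vals[order][np.searchsorted(cw, cw[-1] / 2.0)])
    vals = np.concatenate([track.values[c] for c in track.values])
    widths = np.concatenate([track.bin_widths(c) for c in track.values])
    order = np.argsort(vals)
    cw = np.cumsum(widths[order])
    return float(vals[order][np.searchsorted(cw, cw[-1] / 2.0)])


def chromosome_stats(track: ScaledTrack, x_chrom: str):
    """Per-chromosome density, integrated signal and share of the total.

    Returns ``(table, ratios)`` where ratios holds the X:autosome density
    ratio (autosome density is length-weighted) and the X share of total
    signal.  Shares sum to 1.
    """
    if x_chrom not in track.chrom_sizes:
        raise ConfigurationError(f"unknown chromosome {x_chrom!r}")
    rows = []
    for c in track.chrom_sizes:
        w = track.bin_widths(c)
        integ = float(np.dot(track.values[c], w))
        rows.append(
            {
                "chrom": c,
                "length": track.chrom_sizes[c],
                "density": integ / track.chrom_sizes[c],
                "integrated": integ,
            }
        )
    table = pd.DataFrame(rows).set_index("chrom")
    total = table["integrated"].sum()
    table["share"] = table["integrated"] / total
    autosomes = table.index != x_chrom
    auto_density = (
        table.loc[autosomes, "integrated"].sum()
        / table.loc[autosomes, "length"].sum()
    )
    x_density = float(table.loc[x_chrom, "density"])
    ratios = {
        "x_over_autosome_density": (
            x_density / auto_density if auto_density > 0 else float("inf")
        ),
        "x_share": float(table.loc[x_chrom, "share"]),
    }
    return table, ratios


def per_chromosome_fc_summary(diff: pd.DataFrame, tss_set: pd.DataFrame) -> pd.DataFrame:
    """Median finite log2 fold change per chromosome.

    ``diff`` must be indexed by gene id with a ``log2fc`` column; genes are
    mapped to chromosomes through ``tss_set``.  Chromosomes without genes
    are omitted with a warning.
    """
    chrom_of = tss_set.set_index("gene_id")["chrom"]
    merged = diff.join(chrom_of, how="inner")
    merged = merged[np.isfinite(merged["log2fc"])]
    rows = []
    for chrom in tss_set["chrom"].unique():
        sub = merged[merged["chrom"] == chrom]
        if sub.empty:
            warnings.warn(f"no genes with finite log2fc on {chrom}; omitted")
            continue
        rows.append(
            {
                "chrom": chrom,
                "median_log2fc": float(sub["log2fc"].median()),
                "n_genes": len(sub),
            }
        )
    return pd.DataFrame(rows).set_index("chrom")
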