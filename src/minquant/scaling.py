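"""Input-normalized read counts (INRC) and quantitative RPGC track scaling.

In a multiplexed (MINUTE-style) experiment all barcoded samples are pooled
before immunoprecipitation, so each sample's share of sequenced reads is
proportional to epitope abundance, up to unevenness in barcode
representation.  Dividing unique ChIP reads by the matched input reads for
the same barcode (INRC = #mapped[ChIP] / #mapped[Input]) removes that
unevenness, and the ratio of a sample's INRC to the reference condition's
INRC (untreated naive, pooled replicates) is its global level.

Tracks are expressed in reads-per-genome-coverage (RPGC): the reference is
scaled so its genome-wide mean coverage is exactly 1, and every other sample
is scaled so its mean equals its global level.  For human data the hg38
effective genome size 3,095,978,588 bp is the conventional constant; for
synthetic genomes the sum of chromosome lengths is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

#: effective hg38 genome size used for 1x RPGC normalization of human data
HG38_GENOME_SIZE = 3_095_978_588

POOLED = "pooled"


def compute_inrc(chip_unique: float, input_unique: float, sample: str = "?") -> float:
    """Input-normalized read count: unique ChIP reads / matched input reads."""
    if input_unique <= 0:
        raise DataError(f"non-positive input read count for sample {sample}")
    return chip_unique / input_unique


def inrc_table(
    chip_counts: pd.Series, input_counts: pd.Series, design: pd.DataFrame
) -> pd.DataFrame:
    """Assemble the per-sample INRC table.

    ``chip_counts`` and ``input_counts`` are unique read counts indexed by
    sample id; ``design`` maps sample id to (mark, condition, replicate).
    """
    rows = []
    for sid, row in design.iterrows():
        chip = int(chip_counts[sid])
        inp = int(input_counts[row.get("input_sample", sid)])
        rows.append(
            {
                "sample_id": sid,
                "mark": row["mark"],
                "condition": row["condition"],
                "replicate": row["replicate"],
                "chip_unique": chip,
                "input_unique": inp,
                "inrc": compute_inrc(chip, inp, sample=str(sid)),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class ScaleFactors:
    """Per-sample RPGC scale factors anchored to a reference condition."""

    table: pd.DataFrame  # per sample: inrc, global_level, factor
    reference_condition: str
    genome_size: int
    fragment_length: int

    def factor(self, sample_id: str) -> float:
        return float(self.table.loc[sample_id, "factor"])

    def global_level(self, sample_id: str) -> float:
        return float(self.table.loc[sample_id, "global_level"])


def compute_scale_factors(
    inrc: pd.DataFrame,
    reference_condition: str,
    genome_size: int,
    fragment_length: int = 150,
) -> ScaleFactors:
    """Reference-anchored global levels and per-sample track factors.

    The reference INRC is computed from the reference condition's pooled
    replicates (summed ChIP and input counts) within each mark.  Each
    sample's global level is inrc_sample / inrc_reference (exactly 1 for
    the pooled reference itself), and its track factor is chosen so that
    the scaled genome-wide mean coverage equals the global level:
    factor = global_level * genome_size / (unique_reads * fragment_length).
    Pooled per-condition rows (replicate = ``pooled``) are appended.
    """
    out = []
    for mark, sub in inrc.groupby("mark", sort=False):
        ref = sub[sub["condition"] == reference_condition]
        if ref.empty:
            raise ConfigurationError(
                f"reference condition {reference_condition!r} missing for mark {mark}"
            )
        ref_inrc = compute_inrc(
            ref["chip_unique"].sum(), ref["input_unique"].sum(), sample=f"{mark} reference"
        )
        pooled = (
            sub.groupby("condition", sort=False)[["chip_unique", "input_unique"]]
            .sum()
            .reset_index()
        )
        pooled["replicate"] = POOLED
        pooled["mark"] = mark
        pooled["inrc"] = pooled["chip_unique"] / pooled["input_unique"]
        pooled["sample_id"] = [
            f"{mark}_{c}_pooled" for c in pooled["condition"]
        ]
        pooled = pooled.set_index("sample_id")
        both = pd.concat([sub, pooled[sub.columns]])
        both["global_level"] = both["inrc"] / ref_inrc
        both["factor"] = (
            both["global_level"] * genome_size / (both["chip_unique"] * fragment_length)
        )
        out.append(both)
    table = pd.concat(out)
    return ScaleFactors(
        table=table,
        reference_condition=reference_condition,
        genome_size=int(genome_size),
        fragment_length=int(fragment_length),
    )


@dataclass
class ScaledTrack:
    """Binned coverage in RPGC units for one sample.

    ``values[chrom]`` holds the mean per-basepair coverage of each bin at
    ``resolution`` bp (the last bin of a chromosome may be shorter).
    """

    values: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]
    resolution: int
    sample_id: str = ""
    factor: float = 1.0

    def bin_widths(self, chrom: str) -> np.ndarray:
        n = len(self.values[chrom])
        w = np.full(n, self.resolution, dtype=float)
        w[-1] = self.chrom_sizes[chrom] - (n - 1) * self.resolution
        return w

    def global_mean(self) -> float:
        total = sum(
            float(np.dot(self.values[c], self.bin_widths(c))) for c in self.values
        )
        return total / sum(self.chrom_sizes.values())

    def integral(self) -> float:
        """Total basepair-weighted signal, sum(bin value x bin width)."""
        return sum(
            float(np.dot(self.values[c], self.bin_widths(c))) for c in self.values
        )

    def scaled(self, a: float) -> "ScaledTrack":
        return ScaledTrack(
            {c: v * a for c, v in self.values.items()},
            dict(self.chrom_sizes),
            self.resolution,
            self.sample_id,
            self.factor * a,
        )

    def add(self, other: "ScaledTrack") -> "ScaledTrack":
        if self.chrom_sizes != other.chrom_sizes or self.resolution != other.resolution:
            raise DataError("tracks are not on the same grid")
        return ScaledTrack(
            {c: self.values[c] + other.values[c] for c in self.values},
            dict(self.chrom_sizes),
            self.resolution,
            self.sample_id,
            self.factor,
        )


def build_scaled_track(
    reads: pd.DataFrame,
    chrom_sizes: dict[str, int],
    factor: float,
    resolution: int = 50,
    fragment_length: int = 150,
    sample_id: str = "",
) -> ScaledTrack:
    """Coverage track from deduplicated reads, scaled to RPGC units.

    Each read is extended to a fixed ``fragment_length`` from its 5' end
    toward 3'; per-bin values are mean per-basepair coverage times
    ``factor``, so the genome integral equals
    factor * reads * fragment_length when all fragments fit within their
    chromosome.
    """
    values: dict[str, np.ndarray] = {}
    per_bp: dict[str, np.ndarray] = {
        c: np.zeros(length + 1, dtype=np.float64) for c, length in chrom_sizes.items()
    }
    chroms = reads["chrom"].to_numpy()
    pos = reads["pos"].to_numpy(np.int64)
    strands = reads["strand"].to_numpy()
    starts = np.where(strands == "+", pos, pos - fragment_length + 1)
    ends = starts + fragment_length
    for c, length in chrom_sizes.items():
        m = chroms == c
        if not np.any(m):
            continue
        s = starts[m]
        e = ends[m]
        if (pos[m] < 0).any() or (pos[m] >= length).any():
            bad = np.flatnonzero((pos[m] < 0) | (pos[m] >= length))
            raise DataError(
                f"{len(bad)} reads beyond bounds of {c} (length {length})"
            )
        np.add.at(per_bp[c], np.clip(s, 0, length), 1.0)
        np.add.at(per_bp[c], np.clip(e, 0, length), -1.0)
    for c, length in chrom_sizes.items():
        cov = np.cumsum(per_bp[c][:-1]) * factor
        n = math.ceil(length / resolution)
        pad = n * resolution - length
        if pad:
            cov = np.concatenate([cov, np.zeros(pad)])
        binned = cov.reshape(n, resolution).sum(axis=1)
        widths = np.full(n, resolution, dtype=float)
        if pad:
            widths[-1] = resolution - pad
        values[c] = binned / widths
    return ScaledTrack(
        values=values,
        chrom_sizes=dict(chrom_sizes),
        resolution=resolution,
        sample_id=sample_id,
        factor=factor,
    )
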