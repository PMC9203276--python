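"""Plain-text format plumbing: TSV, BED, bedGraph, FASTQ, YAML.

All genomic intervals are 0-based half-open.  Numeric TSV output uses a
fixed %.6g format so repeated runs are byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .scaling import ScaledTrack

FLOAT_FORMAT = "%.6g"
FASTQ_STUFFER = "AGCTAGCTTAGGACCTAGGTCCTAAGCTAGCTAGGA"  # fixed read-1 filler


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_bed(regions: pd.DataFrame, path, name_col: str | None = "id") -> None:
    """Write (chrom, start, end[, name(, strand)]) as BED."""
    cols = [regions["chrom"], regions["start"], regions["end"]]
    if name_col and name_col in regions:
        cols.append(regions[name_col])
        if "strand" in regions:
            cols.append(pd.Series("0", index=regions.index))
            cols.append(regions["strand"])
    out = pd.concat(cols, axis=1)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED into (chrom, start, end[, id[, score, strand]])."""
    names = ["chrom", "start", "end", "id", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except Exception as e:  # noqa: BLE001 - rewrap with file context
        raise DataError(f"cannot parse BED file {path}: {e}") from e
    df.columns = names[: df.shape[1]]
    for i, (s, e) in enumerate(zip(df["start"], df["end"])):
        try:
            if int(e) <= int(s):
                raise ValueError
        except (TypeError, ValueError):
            raise DataError(f"{path}: invalid interval at line {i + 1}") from None
    return df


def write_tss_bed(tss_set: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": tss_set["chrom"],
            "start": tss_set["pos"],
            "end": tss_set["pos"] + 1,
            "id": tss_set["gene_id"],
            "score": 0,
            "strand": tss_set["strand"],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_tss_bed(path) -> pd.DataFrame:
    bed = read_bed(path)
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "pos": bed["start"],
            "strand": bed.get("strand", "+"),
            "gene_id": bed.get("id", bed.index.astype(str)),
        }
    )


def write_bedgraph(track: ScaledTrack, path) -> None:
    """4-column bedGraph at the track's bin resolution."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            length = track.chrom_sizes[chrom]
            res = track.resolution
            for i, v in enumerate(vals):
                start = i * res
                fh.write(
                    f"{chrom}\t{start}\t{min(start + res, length)}\t{FLOAT_FORMAT % v}\n"
                )


def read_bedgraph(path, chrom_sizes: dict[str, int], resolution: int) -> ScaledTrack:
    df = read_bed(path)
    df.columns = ["chrom", "start", "end", "value"][: df.shape[1]]
    values = {}
    for chrom, length in chrom_sizes.items():
        n = math.ceil(length / resolution)
        arr = np.zeros(n)
        sub = df[df["chrom"] == chrom]
        idx = sub["start"].to_numpy(np.int64) // resolution
        arr[idx] = sub["value"].to_numpy(float)
        values[chrom] = arr
    return ScaledTrack(values, dict(chrom_sizes), resolution)


def write_fastq(reads: pd.DataFrame, path, stuffer: str = FASTQ_STUFFER) -> None:
    """Read-1 FASTQ whose first 14 nt are the UMI + barcode tag."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, (umi, bc) in enumerate(zip(reads["umi"], reads["barcode"])):
            seq = umi + bc + stuffer
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq_tags(path, umi_length: int = 6, barcode_length: int = 8) -> pd.DataFrame:
    """Parse UMI/barcode from the first nucleotides of each FASTQ record."""
    umis, bcs = [], []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                seq = line.strip()
                if len(seq) < umi_length + barcode_length:
                    raise DataError(f"{path}: read shorter than tag at line {i + 1}")
                umis.append(seq[:umi_length])
                bcs.append(seq[umi_length : umi_length + barcode_length])
    return pd.DataFrame({"umi": umis, "barcode": bcs})


def write_yaml(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)
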