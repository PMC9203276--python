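"""Barcode demultiplexing and UMI-sensitive duplicate marking.

Pooled reads carry a 6 nt UMI followed by an 8 nt sample barcode at the
start of read 1.  A read is assigned to a sample when exactly one design
barcode lies within the mismatch tolerance (default 1); the barcode set is
required to have minimum pairwise Hamming distance >= 2*max_mismatch + 1,
which makes assignment unambiguous by construction.

Reads are duplicates when they map to the same location — identical
(sample, chrom, 0-based 5' position of read 1, strand) — and their UMIs lie
within Hamming distance 1 of each other.  UMIs at one location are clustered
by connected components of the 1-mismatch graph; the number of unique
molecules is the number of components, and one representative read per
component (highest UMI multiplicity, ties broken by lexicographically
smallest UMI) is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .simdata import strings_to_codes

UNASSIGNED = "UNASSIGNED"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise DataError(f"length mismatch: {a!r} vs {b!r}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeLayout:
    """Tag layout of read 1: UMI then sample barcode.

    ``barcodes`` is an ordered list of distinct 8-mers; ``sample_ids`` (if
    given) maps them positionally to sample identifiers.
    """

    barcodes: list[str]
    sample_ids: list[str] | None = None
    umi_length: int = 6
    barcode_length: int = 8
    max_mismatch: int = 1

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.barcodes:
            raise ConfigurationError("empty barcode list")
        for b in self.barcodes:
            if len(b) != self.barcode_length:
                raise ConfigurationError(
                    f"barcode {b!r} is not {self.barcode_length} nt"
                )
            if set(b) - set("ACGT"):
                raise ConfigurationError(f"barcode {b!r} has non-ACGT characters")
        if self.sample_ids is not None and len(self.sample_ids) != len(self.barcodes):
            raise ConfigurationError("sample_ids and barcodes differ in length")
        min_dist = 2 * self.max_mismatch + 1
        for a, b in combinations(self.barcodes, 2):
            d = hamming(a, b)
            if d < min_dist:
                raise ConfigurationError(
                    f"barcodes {a} and {b} at Hamming distance {d} < {min_dist}; "
                    "assignment would be ambiguous"
                )

    def sample_of(self, barcode: str) -> str:
        if self.sample_ids is None:
            return barcode
        return self.sample_ids[self.barcodes.index(barcode)]


def generate_barcodes(n: int, length: int = 8, min_dist: int = 3, seed: int = 0) -> list[str]:
    """Random barcode set with minimum pairwise Hamming distance.

    Greedy rejection sampling; raises if the requested set cannot be found
    in a reasonable number of draws.
    """
    rng = np.random.default_rng(seed)
    kept: list[str] = []
    bases = "ACGT"
    for _ in range(200_000):
        cand = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        if all(hamming(cand, k) >= min_dist for k in kept):
            kept.append(cand)
            if len(kept) == n:
                return kept
    raise ConfigurationError(
        f"could not generate {n} barcodes of length {length} at distance {min_dist}"
    )


def demultiplex(reads: pd.DataFrame, layout: BarcodeLayout):
    """Assign pooled reads to samples by barcode within the mismatch tolerance.

    Returns ``(assigned, tallies)``: a copy of ``reads`` with a
    ``sample_id`` column (``UNASSIGNED`` where no design barcode is within
    ``max_mismatch``), and a per-sample tally Series whose values sum to the
    input read count.
    """
    layout.validate()
    obs = strings_to_codes(reads["barcode"].to_numpy(), layout.barcode_length)
    design = strings_to_codes(layout.barcodes, layout.barcode_length)
    n = len(obs)
    best = np.full(n, -1, dtype=np.int32)
    chunk = 200_000
    for s in range(0, n, chunk):
        d = (obs[s : s + chunk, None, :] != design[None, :, :]).sum(axis=2)
        ok = d.min(axis=1) <= layout.max_mismatch
        # the distance invariant guarantees at most one barcode within range
        best[s : s + chunk][ok] = d.argmin(axis=1)[ok]
    samples = np.array(
        [layout.sample_of(b) for b in layout.barcodes] + [UNASSIGNED], dtype=object
    )
    assigned = reads.copy()
    assigned["sample_id"] = samples[best]
    tallies = (
        assigned["sample_id"].value_counts().reindex(samples, fill_value=0)
    )
    tallies.index.name = "sample_id"
    tallies.name = "reads"
    return assigned, tallies


@dataclass
class DedupResult:
    """Per-read duplicate flags plus per-sample accounting."""

    is_duplicate: pd.Series  # aligned to the input read index
    unique_counts: pd.Series  # per sample_id
    duplicate_counts: pd.Series

    @property
    def stats(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"unique": self.unique_counts, "duplicates": self.duplicate_counts}
        )
        df["total"] = df["unique"] + df["duplicates"]
        return df


def _cluster_umis(umis: list[str], max_mismatch: int):
    """Connected components of the <=max_mismatch Hamming graph.

    Returns (components, representative per component) where each component
    is a list of distinct UMIs and the representative is the UMI with the
    highest multiplicity (ties: lexicographically smallest).
    """
    mult: dict[str, int] = {}
    for u in umis:
        mult[u] = mult.get(u, 0) + 1
    distinct = sorted(mult)
    parent = {u: u for u in distinct}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for a, b in combinations(distinct, 2):
        if hamming(a, b) <= max_mismatch:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    comps: dict[str, list[str]] = {}
    for u in distinct:
        comps.setdefault(find(u), []).append(u)
    out = []
    for members in comps.values():
        rep = min(members, key=lambda u: (-mult[u], u))
        out.append((members, rep))
    return out


def mark_duplicates(reads: pd.DataFrame, umi_mismatch: int = 1) -> DedupResult:
    """Flag PCR duplicates among assigned reads.

    ``reads`` must carry ``sample_id``, ``umi``, ``chrom``, ``pos`` and
    ``strand`` columns; reads with ``sample_id == UNASSIGNED`` are ignored
    (never flagged, never counted).  Within every (sample, chrom, pos,
    strand) group, UMIs within Hamming distance ``umi_mismatch`` are merged
    into one molecule; all reads but the component representative are
    flagged duplicate.  Unique + duplicate counts equal the assigned total
    per sample, and the result is invariant to input read order.
    """
    umi_len = reads["umi"].str.len()
    if len(reads) and umi_len.nunique() != 1:
        raise DataError("inconsistent UMI lengths in input reads")

    assigned_mask = (reads["sample_id"] != UNASSIGNED).to_numpy()
    idx_assigned = np.flatnonzero(assigned_mask)
    sub = reads.iloc[idx_assigned]

    sample_codes, sample_levels = pd.factorize(sub["sample_id"], sort=True)
    chrom_codes, _ = pd.factorize(sub["chrom"], sort=True)
    strand_codes, _ = pd.factorize(sub["strand"], sort=True)
    pos = sub["pos"].to_numpy(np.int64)
    umi_arr = sub["umi"].to_numpy()
    umi_codes, _ = pd.factorize(sub["umi"], sort=True)

    order = np.lexsort((umi_codes, strand_codes, pos, chrom_codes, sample_codes))
    key = np.stack(
        [sample_codes[order], chrom_codes[order], pos[order], strand_codes[order]]
    )
    new_group = np.ones(len(order), dtype=bool)
    if len(order) > 1:
        new_group[1:] = (np.diff(key, axis=1) != 0).any(axis=0)
    bounds = np.flatnonzero(new_group).tolist() + [len(order)]

    dup = np.zeros(len(reads), dtype=bool)
    unique_per_sample = np.zeros(len(sample_levels), dtype=np.int64)
    for gi in range(len(bounds) - 1):
        s, e = bounds[gi], bounds[gi + 1]
        sample = key[0, s]
        if e - s == 1:
            unique_per_sample[sample] += 1
            continue
        rows = order[s:e]
        umis = [umi_arr[r] for r in rows]
        if len(set(umis)) == 1:
            unique_per_sample[sample] += 1
            keep_local = 0
            for j, r in enumerate(rows):
                if j != keep_local:
                    dup[idx_assigned[r]] = True
            continue
        comps = _cluster_umis(umis, umi_mismatch)
        unique_per_sample[sample] += len(comps)
        for members, rep in comps:
            kept = False
            member_set = set(members)
            for r in rows:
                u = umi_arr[r]
                if u not in member_set:
                    continue
                if not kept and u == rep:
                    kept = True
                else:
                    dup[idx_assigned[r]] = True

    is_dup = pd.Series(dup, index=reads.index, name="is_duplicate")
    totals = (
        pd.Series(sample_codes)
        .value_counts()
        .reindex(range(len(sample_levels)), fill_value=0)
        .to_numpy()
    )
    uniq = pd.Series(unique_per_sample, index=sample_levels, name="unique")
    dups = pd.Series(totals - unique_per_sample, index=sample_levels, name="duplicates")
    uniq.index.name = dups.index.name = "sample_id"
    return DedupResult(is_dup, uniq, dups)
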