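"""Seeded synthetic data emulating a multiplexed quantitative ChIP-seq study.

The generator produces a small genome (4 autosomes + chrX, 2 Mb total) with a
known histone-modification landscape for three marks (H3K27me3, H3K4me3,
H2Aub) across four conditions (naive/primed x untreated/EZH2i), pooled
tagged-read libraries (6 nt UMI + 8 nt sample barcode read prefix, PCR
duplicates, substitution errors), and NB-distributed expression count
matrices with promoter-class-linked effects.  Every quantity downstream
modules estimate (global levels, X-chromosome enrichment, promoter classes,
transcriptional responses) is planted here as ground truth, so the entire
pipeline is testable without external data.

Default effect sizes emulate the magnitudes of the modelled study: the
diffuse (non-promoter) H3K27me3 background is 3.3-fold higher in naive than
primed (H2Aub 2.1-fold) while promoter signal is planted at absolute,
class-defined heights, so common-bivalent promoters carry equal scaled
signal in both states; EZH2i leaves 3% (naive) / 8% (primed) of H3K27me3;
naive X-chromosome H3K27me3 density is 2-fold over autosomes; H2Aub retains
85% at derepressed promoters after treatment.  True global factors are the
emergent landscape-mass ratios relative to untreated naive and are recorded
in the model.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

CLASS_LABELS = (
    "primed_bivalent",
    "naive_bivalent",
    "common_bivalent",
    "k4_only",
    "k4_negative",
)

#: chromatin-state labels used in the synthetic state map, with their
#: genome fractions (exact quotas per chromosome, shuffled within).
STATE_FRACTIONS = {
    "polycomb": 0.2,
    "active": 0.2,
    "heterochromatin": 0.2,
    "quiescent": 0.4,
}

# per-mark multiplicative background modifiers by chromatin state
STATE_MODIFIERS = {
    "H3K27me3": {"polycomb": 2.0, "active": 0.5},
    "H3K4me3": {"active": 1.5, "heterochromatin": 0.5},
    "H2Aub": {"polycomb": 1.5},
}

# chromosome lengths chosen so promoter quotas (100 per class, 500 total)
# are exactly proportional to length: 125/100/100/100/75 promoters.
DEFAULT_CHROM_SIZES = {
    "chr1": 500_000,
    "chr2": 400_000,
    "chr3": 400_000,
    "chr4": 400_000,
    "chrX": 300_000,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Probabilities must lie in [0, 1], fold parameters must be positive and
    at least two replicates are required.  ``global_levels`` may override
    the derived per-(mark, condition) true global levels, e.g. to simulate
    an arbitrary grid of factors.
    """

    seed: int = 0
    depth: int = 100_000
    dup_rate: float = 0.15
    tag_error_rate: float = 0.01
    conditions: Sequence[str] = (
        "naive_untreated",
        "naive_ezh2i",
        "primed_untreated",
        "primed_ezh2i",
    )
    replicates: int = 3
    marks: Sequence[str] = ("H3K27me3", "H3K4me3", "H2Aub")
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_SIZES)
    )
    x_chrom: str = "chrX"
    state_segment: int = 10_000
    density_bin: int = 200
    n_promoters: int = 500
    promoter_flank: int = 1_000
    fragment_length: int = 150
    # effect sizes (fold over background unless noted)
    k27_promoter_fold: float = 8.0
    k27_state_bias: float = 4.0  # enriched-state / other-state K27 at differential promoters
    k4_promoter_fold: float = 8.0
    h2aub_promoter_fold: float = 3.0
    h2aub_state_bias: float = 2.0
    x_boost: float = 2.0  # naive H3K27me3 chrX density over autosomes
    naive_over_primed_k27: float = 3.3
    naive_over_primed_h2aub: float = 2.1
    ezh2i_residual_naive: float = 0.03
    ezh2i_residual_primed: float = 0.08
    h2aub_derepressed_retention: float = 0.85
    rep_sigma: float = 0.02  # lognormal biological replicate noise on level
    barcode_sigma: float = 0.10  # lognormal barcode-representation unevenness
    global_levels: Mapping[str, Mapping[str, float]] | None = None
    # expression
    expr_mean_range: tuple[float, float] = (20.0, 500.0)
    expr_dispersion_range: tuple[float, float] = (0.01, 0.15)
    repression_log2: float = 1.0
    derepression_log2: float = 1.0
    # fraction of K27-devoid (k4_only / k4_negative) genes upregulated on
    # treatment anyway — secondary activation downstream of derepressed
    # regulators, so not every upregulated gene is K27-marked
    offtarget_derepression_fraction: float = 0.5

    def validate(self) -> None:
        for name in ("dup_rate", "tag_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "k27_promoter_fold",
            "k27_state_bias",
            "k4_promoter_fold",
            "h2aub_promoter_fold",
            "h2aub_state_bias",
            "x_boost",
            "naive_over_primed_k27",
            "naive_over_primed_h2aub",
            "ezh2i_residual_naive",
            "ezh2i_residual_primed",
            "h2aub_derepressed_retention",
        ):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigurationError(f"{name} must be > 0, got {v}")
        if not 0.0 <= self.offtarget_derepression_fraction <= 1.0:
            raise ConfigurationError(
                "offtarget_derepression_fraction must be in [0, 1], got "
                f"{self.offtarget_derepression_fraction}"
            )
        if self.replicates < 2:
            raise ConfigurationError(
                f"replicates must be >= 2, got {self.replicates}"
            )
        if self.depth <= 0:
            raise ConfigurationError(f"depth must be > 0, got {self.depth}")
        lo, hi = self.expr_dispersion_range
        if lo <= 0 or hi <= 0:
            raise ConfigurationError(
                f"expr_dispersion_range must be positive, got {self.expr_dispersion_range}"
            )
        if self.x_chrom not in self.chrom_sizes:
            raise ConfigurationError(
                f"x_chrom {self.x_chrom!r} not in chrom_sizes"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_rep{r}"
            for cond in self.conditions
            for r in range(1, self.replicates + 1)
        ]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chrom_sizes"] = dict(self.chrom_sizes)
        return d


@dataclass
class GenomeModel:
    """Simulation ground truth: genome, annotations, landscape and levels.

    ``density`` maps (mark, condition) to per-chromosome relative-enrichment
    profiles at ``density_bin`` resolution with genome-wide mean exactly 1;
    the global level is carried only by ``global_factor`` (relative to the
    naive untreated reference).
    """

    chrom_sizes: dict[str, int]
    tss_set: pd.DataFrame  # chrom, pos, strand, gene_id
    state_map: pd.DataFrame  # chrom, start, end, state
    x_chrom: str
    promoter_truth: dict[str, str]
    density: dict[tuple[str, str], dict[str, np.ndarray]]
    global_factor: dict[tuple[str, str], float]
    density_bin: int

    @property
    def genome_size(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def density_mean(self, mark: str, condition: str, chroms=None) -> float:
        """Length-weighted mean density over the given chromosomes."""
        prof = self.density[(mark, condition)]
        chroms = list(prof) if chroms is None else list(chroms)
        total = sum(
            float(np.sum(prof[c] * self._bin_widths(c))) for c in chroms
        )
        length = sum(self.chrom_sizes[c] for c in chroms)
        return total / length

    def _bin_widths(self, chrom: str) -> np.ndarray:
        n = len(self.density[next(iter(self.density))][chrom])
        w = np.full(n, self.density_bin, dtype=float)
        w[-1] = self.chrom_sizes[chrom] - (n - 1) * self.density_bin
        return w


def _parse_condition(cond: str) -> tuple[str | None, bool]:
    state = (
        "naive"
        if cond.startswith("naive")
        else "primed" if cond.startswith("primed") else None
    )
    return state, "ezh2i" in cond


def _class_heights(config: SimulationConfig, mark: str, state: str) -> dict[str, float]:
    """Absolute promoter heights (units of the reference background level).

    Common-bivalent promoters carry the same absolute signal in both states;
    the global naive/primed difference is diffuse (background-level), which
    is what makes the five classes distinguishable on quantitatively scaled
    tracks.
    """
    if mark == "H3K27me3":
        hi, lo = config.k27_promoter_fold, config.k27_promoter_fold / config.k27_state_bias
        if state == "naive":
            return {"naive_bivalent": hi, "common_bivalent": hi, "primed_bivalent": lo}
        return {"primed_bivalent": hi, "common_bivalent": hi, "naive_bivalent": lo}
    if mark == "H3K4me3":
        f = config.k4_promoter_fold
        return {c: f for c in CLASS_LABELS if c != "k4_negative"}
    if mark == "H2Aub":
        hi, lo = config.h2aub_promoter_fold, config.h2aub_promoter_fold / config.h2aub_state_bias
        if state == "naive":
            return {"naive_bivalent": hi, "common_bivalent": hi, "primed_bivalent": lo}
        return {"primed_bivalent": hi, "common_bivalent": hi, "naive_bivalent": lo}
    return {}


def _background_level(config: SimulationConfig, mark: str, state: str | None) -> float:
    """Diffuse (non-promoter) signal level relative to the naive background."""
    if state != "primed":
        return 1.0
    if mark == "H3K27me3":
        return 1.0 / config.naive_over_primed_k27
    if mark == "H2Aub":
        return 1.0 / config.naive_over_primed_h2aub
    return 1.0


def _derepressed_classes(state: str) -> tuple[str, ...]:
    if state == "naive":
        return ("naive_bivalent", "common_bivalent")
    return ("primed_bivalent", "common_bivalent")


def simulate_landscape(config: SimulationConfig) -> GenomeModel:
    """Build the synthetic genome, annotations and true modification landscape.

    Promoters (and chromatin-state quotas) are stratified by chromosome in
    exact proportion to length, so chromosome-scale ratios such as the
    X:autosome H3K27me3 density are governed by ``x_boost`` rather than by
    placement sampling noise.  Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = dict(config.chrom_sizes)
    genome_size = sum(sizes.values())
    dbin = config.density_bin

    # --- chromatin states: exact per-chromosome quotas, shuffled ---
    state_rows = []
    for chrom, length in sizes.items():
        n_seg = math.ceil(length / config.state_segment)
        labels: list[str] = []
        for lab, frac in STATE_FRACTIONS.items():
            labels.extend([lab] * int(round(frac * n_seg)))
        while len(labels) < n_seg:
            labels.append("quiescent")
        labels = labels[:n_seg]
        rng.shuffle(labels)
        for i, lab in enumerate(labels):
            start = i * config.state_segment
            state_rows.append(
                (chrom, start, min(start + config.state_segment, length), lab)
            )
    state_map = pd.DataFrame(state_rows, columns=["chrom", "start", "end", "state"])

    # --- promoters: evenly spaced slots, per-chromosome class quotas ---
    if config.n_promoters % len(CLASS_LABELS):
        raise ConfigurationError(
            "n_promoters must be divisible by the number of classes (5)"
        )
    tss_rows = []
    promoter_truth: dict[str, str] = {}
    gene_i = 0
    for chrom, length in sizes.items():
        n_prom = int(round(config.n_promoters * length / genome_size))
        per_class = n_prom // len(CLASS_LABELS)
        if per_class * len(CLASS_LABELS) != n_prom:
            raise ConfigurationError(
                f"promoter quota on {chrom} ({n_prom}) not divisible by 5; "
                "adjust chrom_sizes or n_promoters"
            )
        spacing = length // n_prom
        jitter_max = max((spacing // 2 - config.promoter_flank) // dbin, 0)
        classes = [c for c in CLASS_LABELS for _ in range(per_class)]
        rng.shuffle(classes)
        for i, cls in enumerate(classes):
            jitter = int(rng.integers(-jitter_max, jitter_max + 1)) * dbin
            pos = i * spacing + spacing // 2 + jitter
            pos = (pos // dbin) * dbin  # snap to density bins
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"g{gene_i:04d}"
            gene_i += 1
            tss_rows.append((chrom, pos, strand, gene_id))
            promoter_truth[gene_id] = cls
    tss_set = pd.DataFrame(tss_rows, columns=["chrom", "pos", "strand", "gene_id"])

    # --- densities ---
    n_bins = {c: math.ceil(length / dbin) for c, length in sizes.items()}
    widths = {
        c: np.concatenate(
            [
                np.full(n_bins[c] - 1, dbin, dtype=float),
                [sizes[c] - (n_bins[c] - 1) * dbin],
            ]
        )
        for c in sizes
    }

    def state_background(mark: str) -> dict[str, np.ndarray]:
        mods = STATE_MODIFIERS.get(mark, {})
        prof = {c: np.ones(n_bins[c]) for c in sizes}
        for chrom, start, end, lab in state_map.itertuples(index=False):
            m = mods.get(lab, 1.0)
            if m != 1.0:
                prof[chrom][start // dbin : math.ceil(end / dbin)] *= m
        return prof

    def window_bins(chrom, pos):
        lo = max(pos - config.promoter_flank, 0) // dbin
        hi = math.ceil(min(pos + config.promoter_flank, sizes[chrom]) / dbin)
        return lo, hi

    def raw_mean(prof) -> float:
        return sum(float(np.sum(prof[c] * widths[c])) for c in sizes) / genome_size

    def build_profile(mark, state, bg_level):
        """Absolute landscape: diffuse background at bg_level, promoter
        windows overwritten at absolute class heights, X boost on top."""
        prof = state_background(mark)
        for c in prof:
            prof[c] *= bg_level
        if state is not None:
            heights = _class_heights(config, mark, state)
            for chrom, pos, _strand, gene_id in tss_set.itertuples(index=False):
                h = heights.get(promoter_truth[gene_id])
                if h is not None:
                    lo, hi = window_bins(chrom, pos)
                    prof[chrom][lo:hi] = h
            if mark == "H3K27me3" and state == "naive":
                prof[config.x_chrom] = prof[config.x_chrom] * config.x_boost
        return prof

    override = config.global_levels or {}
    density: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    global_factor: dict[tuple[str, str], float] = {}
    ref_cond = (
        "naive_untreated"
        if "naive_untreated" in config.conditions
        else config.conditions[0]
    )

    for mark in config.marks:
        raw_profiles: dict[str, dict[str, np.ndarray]] = {}
        cache: dict = {}
        for cond in config.conditions:
            state, treated = _parse_condition(cond)
            ov = override.get(mark, {}).get(cond)
            if ov is not None:
                key = ("unit", state)
                if key not in cache:
                    cache[key] = build_profile(mark, state, 1.0)
                prof = {c: a * ov for c, a in cache[key].items()}
            else:
                key = ("bg", state)
                if key not in cache:
                    cache[key] = build_profile(
                        mark, state, _background_level(config, mark, state)
                    )
                prof = cache[key]
                if treated and state is not None:
                    if mark == "H3K27me3":
                        residual = (
                            config.ezh2i_residual_primed
                            if state == "primed"
                            else config.ezh2i_residual_naive
                        )
                        prof = {c: a * residual for c, a in prof.items()}
                    elif mark == "H2Aub":
                        prof = {c: a.copy() for c, a in prof.items()}
                        targets = _derepressed_classes(state)
                        for chrom, pos, _s, gid in tss_set.itertuples(index=False):
                            if promoter_truth[gid] in targets:
                                lo, hi = window_bins(chrom, pos)
                                prof[chrom][lo:hi] *= config.h2aub_derepressed_retention
            raw_profiles[cond] = prof
        ref_mass = raw_mean(raw_profiles[ref_cond])
        for cond in config.conditions:
            m = raw_mean(raw_profiles[cond])
            density[(mark, cond)] = {c: raw_profiles[cond][c] / m for c in sizes}
            global_factor[(mark, cond)] = m / ref_mass

    return GenomeModel(
        chrom_sizes=sizes,
        tss_set=tss_set,
        state_map=state_map,
        x_chrom=config.x_chrom,
        promoter_truth=promoter_truth,
        density=density,
        global_factor=global_factor,
        density_bin=dbin,
    )


def _codes_to_str(codes: np.ndarray) -> np.ndarray:
    """(n, k) array of base codes 0..3 -> length-k ACGT strings."""
    k = codes.shape[1]
    by = _BASES[codes].reshape(-1, k).copy()
    return np.char.decode(by.view(f"S{k}").ravel(), "ascii")


def strings_to_codes(strings, k: int) -> np.ndarray:
    """Array-like of length-k ACGT strings -> (n, k) uint8 base codes."""
    arr = np.asarray(strings, dtype=f"U{k}")
    u = arr.view(np.uint32).reshape(len(arr), k)
    codes = np.full(u.shape, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[u == b] = i
    return codes


def _apply_tag_errors(codes: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate <= 0:
        return codes
    mask = rng.random(codes.shape) < rate
    shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
    out = codes.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def _sample_positions(model, mark, cond, n, fragment_length, rng, uniform=False):
    """Sample n fragment 5' read positions proportional to density."""
    sizes = model.chrom_sizes
    chroms = list(sizes)
    dbin = model.density_bin
    if uniform:
        weights = [
            np.full(math.ceil(sizes[c] / dbin), 1.0) for c in chroms
        ]
    else:
        prof = model.density[(mark, cond)]
        weights = [prof[c] for c in chroms]
    bw = []
    for c, w in zip(chroms, weights):
        widths = np.full(len(w), dbin, dtype=float)
        widths[-1] = sizes[c] - (len(w) - 1) * dbin
        bw.append(w * widths)
    flat = np.concatenate(bw)
    offsets = np.cumsum([0] + [len(b) for b in bw])
    idx = rng.choice(len(flat), size=n, p=flat / flat.sum())
    chrom_idx = np.searchsorted(offsets, idx, side="right") - 1
    local_bin = idx - offsets[chrom_idx]
    starts = local_bin * dbin + rng.integers(0, dbin, size=n)
    lens = np.array([sizes[c] for c in chroms])[chrom_idx]
    starts = np.minimum(starts, lens - fragment_length)  # fragments fit
    strands = rng.integers(0, 2, size=n)
    pos = np.where(strands == 0, starts, starts + fragment_length - 1)
    chrom_names = np.array(chroms, dtype=object)[chrom_idx]
    return chrom_names, pos.astype(np.int64), np.where(strands == 0, "+", "-")


def simulate_pool(model: GenomeModel, config: SimulationConfig, layout):
    """Emit pooled tagged reads per mark pool and one input pool.

    Returns ``(pools, truth)``: both are dicts keyed by pool name (each mark
    plus ``"input"``).  ``pools[name]`` is a DataFrame of observed reads
    (umi, barcode, chrom, pos, strand) in shuffled pool order;
    ``truth[name]`` is the row-aligned truth table (sample_id, condition,
    replicate, is_duplicate).

    Read counts per sample follow Poisson(depth x global level x barcode
    representation x replicate noise); the same barcode-representation
    draw is shared between a sample's ChIP and input reads, which is the
    unevenness the INRC correction exists to remove.
    """
    config.validate()
    sample_ids = config.sample_ids
    if len(layout.barcodes) < len(sample_ids):
        raise ConfigurationError(
            f"{len(layout.barcodes)} barcodes for {len(sample_ids)} samples"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    barcode_of = {s: b for b, s in zip(layout.barcodes, sample_ids)}
    bc_codes = {
        s: strings_to_codes([b], layout.barcode_length)[0]
        for s, b in barcode_of.items()
    }
    # barcode (pool-loading) unevenness, shared by ChIP and input
    wobble = {s: rng.lognormal(0.0, config.barcode_sigma) for s in sample_ids}

    pools: dict[str, pd.DataFrame] = {}
    truth: dict[str, pd.DataFrame] = {}
    for pool_name in list(config.marks) + ["input"]:
        parts, truth_parts = [], []
        for cond in config.conditions:
            for r in range(1, config.replicates + 1):
                sid = f"{cond}_rep{r}"
                if pool_name == "input":
                    lam = config.depth * wobble[sid]
                else:
                    bio = rng.lognormal(0.0, config.rep_sigma)
                    lam = (
                        config.depth
                        * model.global_factor[(pool_name, cond)]
                        * wobble[sid]
                        * bio
                    )
                n = int(rng.poisson(lam))
                if n == 0:
                    continue
                dup = rng.random(n) < config.dup_rate
                dup[0] = False
                n_new = int((~dup).sum())
                chrom, pos, strand = _sample_positions(
                    model,
                    pool_name,
                    cond,
                    n_new,
                    config.fragment_length,
                    rng,
                    uniform=(pool_name == "input"),
                )
                umis = rng.integers(0, 4, size=(n_new, layout.umi_length), dtype=np.uint8)
                n_dup = n - n_new
                src = rng.integers(0, n_new, size=n_dup)
                order = np.empty(n, dtype=np.int64)
                order[~dup] = np.arange(n_new)
                order[dup] = src
                tag = np.concatenate(
                    [umis[order], np.tile(bc_codes[sid], (n, 1))], axis=1
                )
                tag = _apply_tag_errors(tag, config.tag_error_rate, rng)
                parts.append(
                    pd.DataFrame(
                        {
                            "umi": _codes_to_str(tag[:, : layout.umi_length]),
                            "barcode": _codes_to_str(tag[:, layout.umi_length :]),
                            "chrom": chrom[order],
                            "pos": pos[order],
                            "strand": np.asarray(strand, dtype=object)[order],
                        }
                    )
                )
                truth_parts.append(
                    pd.DataFrame(
                        {
                            "sample_id": sid,
                            "condition": cond,
                            "replicate": r,
                            "is_duplicate": dup,
                        }
                    )
                )
        reads = pd.concat(parts, ignore_index=True)
        tt = pd.concat(truth_parts, ignore_index=True)
        perm = rng.permutation(len(reads))
        pools[pool_name] = reads.iloc[perm].reset_index(drop=True)
        truth[pool_name] = tt.iloc[perm].reset_index(drop=True)
    return pools, truth


def expression_effects(config: SimulationConfig) -> dict[str, dict[str, float]]:
    """True log2 expression effects by promoter class and condition."""
    rep, der = config.repression_log2, config.derepression_log2
    eff = {c: {cond: 0.0 for cond in config.conditions} for c in CLASS_LABELS}
    for cond in config.conditions:
        state, treated = _parse_condition(cond)
        if state is None:
            continue
        biv = "naive_bivalent" if state == "naive" else "primed_bivalent"
        eff[biv][cond] = -rep + (der if treated else 0.0)
        eff["common_bivalent"][cond] = -rep + (der if treated else 0.0)
    return eff


def simulate_expression(model: GenomeModel, config: SimulationConfig):
    """NB count matrix (gene x sample) with class-linked expression effects.

    Returns ``(counts, truth)``: counts indexed by gene_id with one column
    per sample; truth holds per-gene base mean, dispersion, class and the
    applied log2 effect per condition.
    """
    config.validate()
    if not model.promoter_truth:
        raise ConfigurationError("model has no promoter truth")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = list(model.tss_set["gene_id"])
    lo, hi = config.expr_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))
    disp = rng.uniform(*config.expr_dispersion_range, size=len(genes))
    eff = expression_effects(config)
    cls = np.array([model.promoter_truth[g] for g in genes])

    # secondary (K27-independent) responders among k4_only / k4_negative
    devoid = np.isin(cls, ["k4_only", "k4_negative"])
    offtarget = {}
    for cond in config.conditions:
        _state, treated = _parse_condition(cond)
        offtarget[cond] = (
            devoid
            & treated
            & (rng.random(len(genes)) < config.offtarget_derepression_fraction)
        )

    cols = {}
    truth_eff = {}
    for cond in config.conditions:
        e = np.array([eff[c][cond] for c in cls])
        e = e + np.where(offtarget[cond], config.derepression_log2, 0.0)
        mu = base * 2.0**e
        truth_eff[f"log2_effect_{cond}"] = e
        for r in range(1, config.replicates + 1):
            n_param = 1.0 / disp
            p_param = n_param / (n_param + mu)
            cols[f"{cond}_rep{r}"] = rng.negative_binomial(n_param, p_param)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    truth = pd.DataFrame(
        {"base_mean": base, "dispersion": disp, "promoter_class": cls, **truth_eff},
        index=counts.index,
    )
    return counts, truth


def simulate_intensity_table(
    seed: int,
    n_control: int = 165,
    n_treated: Mapping[str, int] = None,
    positive_fraction: Mapping[str, float] = None,
    control_mean: float = 100.0,
) -> pd.DataFrame:
    """Per-nucleus immunofluorescence intensity table for gating demos.

    Emulates an imaging experiment in which a minority of inhibitor-treated
    nuclei acquire a marker (GATA3) while H3K27me3 intensity drops; control
    nuclei scatter log-normally around ``control_mean``.
    """
    n_treated = dict(n_treated or {"ezh2i": 235, "eedi": 270})
    positive_fraction = dict(positive_fraction or {"ezh2i": 0.119, "eedi": 0.026})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows = []
    for sample, n in [("untreated", n_control)] + list(n_treated.items()):
        gata3 = control_mean * rng.lognormal(0.0, 0.25, size=n)
        k27 = 200.0 * rng.lognormal(0.0, 0.2, size=n)
        if sample != "untreated":
            pos = rng.random(n) < positive_fraction.get(sample, 0.0)
            gata3[pos] *= 4.0
            k27 *= 0.15
        for i in range(n):
            rows.append((f"{sample}_{i:04d}", sample, sample == "untreated", gata3[i], k27[i]))
    return pd.DataFrame(
        rows, columns=["object_id", "sample", "is_control", "GATA3", "H3K27me3"]
    )


def simulate_pseudotime_table(
    seed: int,
    n_control: int = 500,
    n_treated: int = 500,
    control_q95: float = 5.949,
    activated_fraction: float = 0.4,
) -> pd.DataFrame:
    """Per-cell pseudotime/branch table for trajectory-gating demos.

    Control (untreated) pseudotimes are rescaled so their empirical 95%
    quantile equals ``control_q95``; a fraction of treated cells is pushed
    beyond it and assigned a post-bifurcation branch label.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    ctrl = rng.gamma(2.0, 1.0, size=n_control)
    ctrl *= control_q95 / np.quantile(ctrl, 0.95)
    treated = rng.gamma(2.0, 1.0, size=n_treated) * control_q95 / 4.7
    act = rng.random(n_treated) < activated_fraction
    treated[act] = control_q95 * (1.1 + rng.gamma(2.0, 0.6, size=int(act.sum())))
    branches_act = rng.choice(
        ["trophectoderm", "mesoderm", "pre_bifurcation"], size=int(act.sum()), p=[0.5, 0.3, 0.2]
    )
    rows = []
    for i, t in enumerate(ctrl):
        rows.append((f"ctrl_{i:04d}", float(t), "untreated", "pre_bifurcation"))
    j = 0
    for i, t in enumerate(treated):
        br = branches_act[j] if act[i] else "pre_bifurcation"
        if act[i]:
            j += 1
        rows.append((f"ezh2i_{i:04d}", float(t), "ezh2i", br))
    return pd.DataFrame(rows, columns=["cell_id", "pseudotime", "treatment", "branch"])
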