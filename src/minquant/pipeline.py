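"""End-to-end orchestration: simulate -> demux -> dedup -> scale -> quantify
-> diff -> classify -> gate -> report.

``run_pipeline`` executes every stage on the synthetic study design and
writes stable, byte-reproducible TSV/BED/bedGraph outputs plus a manifest
into a run directory; the returned :class:`PipelineResult` also exposes the
in-memory products for programmatic use.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bivalency import (
    DerepressionResult,
    call_k4_positive,
    class_switch_table,
    classify_promoters,
    derepression_analysis,
    h2aub_change_at_derepressed,
)
from .demux import BarcodeLayout, demultiplex, generate_barcodes, mark_duplicates
from .diffstats import nb_wald_test
from .errors import ConfigurationError
from .gating import gate_ground_state, gate_marker_positive, split_activated
from .io import (
    write_bed,
    write_bedgraph,
    write_tss_bed,
    write_tsv,
    write_yaml,
)
from .landscape import (
    chromosome_stats,
    genome_median,
    make_bins,
    per_chromosome_fc_summary,
    promoter_windows,
    summarize_regions,
)
from .scaling import ScaleFactors, build_scaled_track, compute_scale_factors
from .simdata import (
    GenomeModel,
    SimulationConfig,
    simulate_expression,
    simulate_intensity_table,
    simulate_landscape,
    simulate_pool,
    simulate_pseudotime_table,
)


@dataclass
class PipelineConfig:
    """All tunables of a full synthetic run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    reference_condition: str = "naive_untreated"
    resolution: int = 50
    bin_width: int = 10_000
    flank_up: int = 1_000
    flank_down: int = 1_000
    k4_min_fold: float = 2.0
    k27_min_fold: float = 2.0
    chip_alpha: float = 0.05
    chip_fc: float = 1.5
    rna_alpha: float = 0.05
    rna_fc: float = 2.0
    intensity_factor: float = 1.5
    pseudotime_q: float = 0.95
    write_tracks: bool = True

    def validate(self) -> None:
        self.sim.validate()
        if self.reference_condition not in self.sim.conditions:
            raise ConfigurationError(
                f"reference condition {self.reference_condition!r} not in design"
            )
        for name in ("chip_alpha", "rna_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        if not 0 < self.pseudotime_q < 1:
            raise ConfigurationError("pseudotime_q must be in (0, 1)")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "sim"}
        d["sim"] = self.sim.to_dict()
        return d


@dataclass
class PipelineResult:
    outdir: Path
    model: GenomeModel
    config: PipelineConfig
    demux_stats: pd.DataFrame
    dedup_stats: pd.DataFrame
    factors: ScaleFactors
    tracks: dict  # (mark, condition) pooled ScaledTrack
    promoter_means: dict  # (mark, condition) -> per-gene pooled mean Series
    diffs: dict  # name -> DataFrame
    classes: pd.DataFrame
    class_accuracy: float
    switch_table: pd.DataFrame
    derepression: DerepressionResult
    h2aub_at_derepressed: pd.DataFrame
    chrom_stats: dict
    gate_percent_positive: pd.Series
    gate_threshold: float
    ground_fractions: pd.Series
    elc_counts: pd.Series


def _pseudo_counts(mean_by_rep: pd.DataFrame, width: int, fragment_length: int) -> pd.DataFrame:
    """Integer pseudo-counts from scaled means: round(mean * width / fraglen)."""
    return (mean_by_rep * width / fragment_length).round().astype(int)


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    config.validate()
    sim = config.sim
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fraglen = sim.fragment_length

    # --- simulate ---
    model = simulate_landscape(sim)
    sample_ids = sim.sample_ids
    layout = BarcodeLayout(
        barcodes=generate_barcodes(len(sample_ids), seed=sim.seed),
        sample_ids=sample_ids,
    )
    pools, truth = simulate_pool(model, sim, layout)
    counts_rna, expr_truth = simulate_expression(model, sim)

    write_yaml({"pipeline": config.to_dict()}, out / "config.yaml")
    write_tss_bed(model.tss_set, out / "genome" / "tss.bed")
    states = model.state_map.rename(columns={"state": "id"})
    write_bed(states, out / "genome" / "states.bed")
    write_tsv(
        pd.Series(model.chrom_sizes, name="length").rename_axis("chrom").to_frame(),
        out / "genome" / "chrom_sizes.tsv",
    )
    write_tsv(
        pd.Series(model.promoter_truth, name="true_class")
        .rename_axis("gene_id")
        .to_frame(),
        out / "genome" / "truth_promoter_classes.tsv",
    )
    gf = pd.DataFrame(
        [(m, c, v) for (m, c), v in model.global_factor.items()],
        columns=["mark", "condition", "global_factor"],
    )
    write_tsv(gf, out / "genome" / "truth_global_factors.tsv", index=False)
    write_tsv(counts_rna, out / "rna" / "counts.tsv")

    # --- demux + dedup ---
    demux_rows, dedup_rows = [], []
    unique_reads: dict[tuple[str, str, int], pd.DataFrame] = {}
    unique_counts: dict[str, pd.Series] = {}
    for pool_name, reads in pools.items():
        assigned, tallies = demultiplex(reads, layout)
        res = mark_duplicates(assigned)
        unique_counts[pool_name] = res.unique_counts
        keep = assigned[
            (~res.is_duplicate) & (assigned["sample_id"] != "UNASSIGNED")
        ]
        for sid, sub in keep.groupby("sample_id", sort=False):
            cond, rep = sid.rsplit("_rep", 1)
            unique_reads[(pool_name, cond, int(rep))] = sub
        for sid in sample_ids:
            demux_rows.append(
                {"pool": pool_name, "sample_id": sid, "assigned": int(tallies.get(sid, 0))}
            )
        demux_rows.append(
            {"pool": pool_name, "sample_id": "UNASSIGNED",
             "assigned": int(tallies.get("UNASSIGNED", 0))}
        )
        st = res.stats
        st.insert(0, "pool", pool_name)
        dedup_rows.append(st.reset_index())
    demux_stats = pd.DataFrame(demux_rows)
    dedup_stats = pd.concat(dedup_rows, ignore_index=True)
    write_tsv(demux_stats, out / "demux" / "demux_stats.tsv", index=False)
    write_tsv(dedup_stats, out / "demux" / "dedup_stats.tsv", index=False)

    # --- INRC + scale factors ---
    inrc_rows = []
    for mark in sim.marks:
        for cond in sim.conditions:
            for r in range(1, sim.replicates + 1):
                sid = f"{cond}_rep{r}"
                inrc_rows.append(
                    {
                        "sample_id": f"{mark}_{sid}",
                        "mark": mark,
                        "condition": cond,
                        "replicate": r,
                        "chip_unique": int(unique_counts[mark].get(sid, 0)),
                        "input_unique": int(unique_counts["input"].get(sid, 0)),
                    }
                )
    inrc = pd.DataFrame(inrc_rows).set_index("sample_id")
    inrc["inrc"] = inrc["chip_unique"] / inrc["input_unique"]
    factors = compute_scale_factors(
        inrc, config.reference_condition, model.genome_size, fraglen
    )
    write_tsv(factors.table, out / "scale" / "scale_factors.tsv")

    # --- scaled tracks (pooled per condition; per-replicate kept in memory) ---
    tracks: dict[tuple[str, str], object] = {}
    rep_tracks: dict[tuple[str, str, int], object] = {}
    for mark in sim.marks:
        for cond in sim.conditions:
            pooled_reads = pd.concat(
                [unique_reads[(mark, cond, r)] for r in range(1, sim.replicates + 1)],
                ignore_index=True,
            )
            f = factors.factor(f"{mark}_{cond}_pooled")
            tracks[(mark, cond)] = build_scaled_track(
                pooled_reads, model.chrom_sizes, f, config.resolution, fraglen,
                sample_id=f"{mark}_{cond}_pooled",
            )
            if config.write_tracks:
                write_bedgraph(
                    tracks[(mark, cond)], out / "tracks" / f"{mark}_{cond}.bedgraph"
                )
            for r in range(1, sim.replicates + 1):
                rep_tracks[(mark, cond, r)] = build_scaled_track(
                    unique_reads[(mark, cond, r)],
                    model.chrom_sizes,
                    factors.factor(f"{mark}_{cond}_rep{r}"),
                    config.resolution,
                    fraglen,
                    sample_id=f"{mark}_{cond}_rep{r}",
                )

    # --- landscape quantification ---
    bins = make_bins(model.chrom_sizes, config.bin_width)
    windows = promoter_windows(
        model.tss_set, config.flank_up, config.flank_down, model.chrom_sizes
    )
    win_width = int((windows["end"] - windows["start"]).iloc[0])

    bin_table = bins[["id", "chrom", "start", "end"]].copy()
    promoter_means: dict[tuple[str, str], pd.Series] = {}
    state_rows = []
    chrom_stats_all: dict[tuple[str, str], tuple] = {}
    prom_table = windows[["id"]].copy().set_index("id")
    for (mark, cond), track in tracks.items():
        bin_table[f"{mark}_{cond}"] = summarize_regions(track, bins)["mean"].to_numpy()
        pm = summarize_regions(track, windows).set_index("id")["mean"]
        promoter_means[(mark, cond)] = pm
        prom_table[f"{mark}_{cond}"] = pm
        smeans = summarize_regions(track, states)
        smeans["signal"] = smeans["mean"] * smeans["width"]
        agg = smeans.groupby("id").apply(
            lambda g: g["signal"].sum() / g["width"].sum(), include_groups=False
        )
        for lab, v in agg.items():
            state_rows.append({"mark": mark, "condition": cond, "state": lab, "mean_rpgc": v})
        chrom_stats_all[(mark, cond)] = chromosome_stats(track, model.x_chrom)
    write_tsv(bin_table, out / "quant" / f"bins_{config.bin_width}.tsv", index=False)
    write_tsv(prom_table, out / "quant" / "promoter_means.tsv")
    write_tsv(pd.DataFrame(state_rows), out / "quant" / "state_means.tsv", index=False)
    chrom_rows = []
    for (mark, cond), (tab, ratios) in chrom_stats_all.items():
        t = tab.reset_index()
        t.insert(0, "condition", cond)
        t.insert(0, "mark", mark)
        chrom_rows.append(t)
    write_tsv(pd.concat(chrom_rows, ignore_index=True),
              out / "quant" / "chromosome_stats.tsv", index=False)

    # --- differential tests on promoter pseudo-counts ---
    def promoter_diff(mark, cond_a, cond_b):
        cols = {}
        for cond in (cond_a, cond_b):
            for r in range(1, sim.replicates + 1):
                pm = summarize_regions(rep_tracks[(mark, cond, r)], windows).set_index("id")["mean"]
                cols[f"{cond}_rep{r}"] = pm
        mat = _pseudo_counts(pd.DataFrame(cols), win_width, fraglen)
        conditions = {c: c.rsplit("_rep", 1)[0] for c in mat.columns}
        return nb_wald_test(mat, conditions, cond_a, cond_b)

    diffs = {
        # oriented naive over primed
        "k27_promoters": promoter_diff("H3K27me3", "primed_untreated", "naive_untreated"),
        "k4_promoters": promoter_diff("H3K4me3", "primed_untreated", "naive_untreated"),
        # treated over untreated
        "h2aub_naive_ezh2i": promoter_diff("H2Aub", "naive_untreated", "naive_ezh2i"),
    }
    rna_conditions = {c: c.rsplit("_rep", 1)[0] for c in counts_rna.columns}
    diffs["rna_naive_ezh2i"] = nb_wald_test(
        counts_rna, rna_conditions, "naive_untreated", "naive_ezh2i", shrink_log2fc=True
    )
    diffs["rna_primed_ezh2i"] = nb_wald_test(
        counts_rna, rna_conditions, "primed_untreated", "primed_ezh2i", shrink_log2fc=True
    )
    for name, d in diffs.items():
        write_tsv(d, out / "diff" / f"{name}.tsv")

    # --- bivalency classification ---
    # positivity anchors on a 1-kb rebinned genome median, which stays
    # informative at depths where most native 50-bp bins are empty
    k4_pos, k27_pos = {}, {}
    for state, cond in (("naive", "naive_untreated"), ("primed", "primed_untreated")):
        k4_pos[state] = call_k4_positive(
            promoter_means[("H3K4me3", cond)],
            genome_median(tracks[("H3K4me3", cond)], width=1_000),
            config.k4_min_fold,
        )
        k27_pos[state] = call_k4_positive(
            promoter_means[("H3K27me3", cond)],
            genome_median(tracks[("H3K27me3", cond)], width=1_000),
            config.k27_min_fold,
        )
    classes = classify_promoters(
        k4_pos, k27_pos, diffs["k27_promoters"], config.chip_alpha, config.chip_fc
    )
    truth_cls = pd.Series(model.promoter_truth).reindex(classes.index)
    class_accuracy = float((classes["promoter_class"] == truth_cls).mean())
    classes["true_class"] = truth_cls
    write_tsv(classes, out / "classes" / "promoter_classes.tsv")

    switch = class_switch_table(
        diffs["k4_promoters"],
        diffs["k27_promoters"],
        promoters=classes.index[classes["promoter_class"] != "k4_negative"],
        alpha=config.chip_alpha,
        fc_threshold=config.chip_fc,
    )
    write_tsv(switch, out / "classes" / "switch_table.tsv")

    derep = derepression_analysis(
        diffs["rna_naive_ezh2i"],
        classes,
        k27_pos["naive"],
        alpha=config.rna_alpha,
        fc_threshold=config.rna_fc,
    )
    resp = pd.DataFrame([r.__dict__ for r in derep.class_responses]).set_index("label")
    write_tsv(resp, out / "classes" / "class_response_naive_ezh2i.tsv")
    (out / "classes" / "derepressed_naive_ezh2i.txt").write_text(
        "\n".join(sorted(derep.derepressed)) + "\n"
    )
    bivalent = set(
        classes.index[classes["promoter_class"].isin(["naive_bivalent", "common_bivalent"])]
    )
    devoid = set(
        classes.index[~classes["k27_naive_pos"] & ~classes["k27_primed_pos"]]
    )
    h2aub_tab = h2aub_change_at_derepressed(
        diffs["h2aub_naive_ezh2i"],
        derep.derepressed,
        {"bivalent": bivalent, "k27_devoid": devoid},
    )
    write_tsv(h2aub_tab, out / "classes" / "h2aub_at_derepressed.tsv")

    fc_by_chrom = per_chromosome_fc_summary(diffs["rna_naive_ezh2i"], model.tss_set)
    write_tsv(fc_by_chrom, out / "quant" / "rna_fc_by_chromosome.tsv")

    # --- gating ---
    intensities = simulate_intensity_table(sim.seed)
    positive, percent, thr_i = gate_marker_positive(
        intensities, "GATA3", config.intensity_factor
    )
    gate_tab = intensities.copy()
    gate_tab["GATA3_positive"] = positive
    write_tsv(gate_tab, out / "gate" / "intensity_gate.tsv", index=False)
    ptime = simulate_pseudotime_table(sim.seed)
    thr_p, labels, ground_frac = gate_ground_state(
        ptime, "untreated", config.pseudotime_q
    )
    ptime = ptime.copy()
    ptime["state"] = labels
    ptime["elc_class"] = split_activated(ptime, thr_p)
    write_tsv(ptime, out / "gate" / "pseudotime_gate.tsv", index=False)
    elc_counts = ptime["elc_class"].value_counts()

    # --- manifest ---
    manifest = {
        "version": __version__,
        "seed": sim.seed,
        "config_sha256": hashlib.sha256(
            repr(sorted(config.to_dict().items())).encode()
        ).hexdigest(),
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        ),
    }
    write_yaml(manifest, out / "manifest.yaml")

    return PipelineResult(
        outdir=out,
        model=model,
        config=config,
        demux_stats=demux_stats,
        dedup_stats=dedup_stats,
        factors=factors,
        tracks=tracks,
        promoter_means=promoter_means,
        diffs=diffs,
        classes=classes,
        class_accuracy=class_accuracy,
        switch_table=switch,
        derepression=derep,
        h2aub_at_derepressed=h2aub_tab,
        chrom_stats=chrom_stats_all,
        gate_percent_positive=percent,
        gate_threshold=thr_i,
        ground_fractions=ground_frac,
        elc_counts=elc_counts,
    )


def report_summary(run_dir) -> pd.DataFrame:
    """Cross-checked single-table summary of a completed run directory.

    Collects global levels, class counts, switch-table counts, class
    responses and gate fractions from the stage outputs; missing stages are
    reported as explicit gaps rather than errors.
    """
    run = Path(run_dir)
    rows = []

    def add(section, key, value):
        rows.append({"section": section, "key": key, "value": value})

    f = run / "scale" / "scale_factors.tsv"
    if f.exists():
        sf = pd.read_csv(f, sep="\t", index_col=0)
        pooled = sf[sf["replicate"] == "pooled"]
        for sid, r in pooled.iterrows():
            add("global_level", sid, r["global_level"])
    else:
        add("global_level", "MISSING", float("nan"))
    f = run / "classes" / "promoter_classes.tsv"
    if f.exists():
        cls = pd.read_csv(f, sep="\t", index_col=0)
        for lab, n in cls["promoter_class"].value_counts().items():
            add("class_count", lab, int(n))
        add("class_count", "total", len(cls))
    else:
        add("class_count", "MISSING", float("nan"))
    f = run / "classes" / "switch_table.tsv"
    if f.exists():
        sw = pd.read_csv(f, sep="\t", index_col=0)
        for k4 in sw.index:
            for k27 in sw.columns:
                add("switch", f"k4_{k4}|k27_{k27}", int(sw.loc[k4, k27]))
    f = run / "classes" / "class_response_naive_ezh2i.tsv"
    if f.exists():
        resp = pd.read_csv(f, sep="\t", index_col=0)
        for lab, r in resp.iterrows():
            add("response_median_log2fc", lab, r["median_log2fc"])
    f = run / "gate" / "pseudotime_gate.tsv"
    if f.exists():
        pt = pd.read_csv(f, sep="\t")
        for treat, frac in (pt["state"] == "ground").groupby(pt["treatment"]).mean().items():
            add("ground_fraction", treat, frac)
    f = run / "gate" / "intensity_gate.tsv"
    if f.exists():
        it = pd.read_csv(f, sep="\t")
        for s, frac in it.groupby("sample")["GATA3_positive"].mean().items():
            add("percent_gata3_positive", s, 100.0 * frac)
    summary = pd.DataFrame(rows)
    write_tsv(summary, run / "report" / "summary.tsv", index=False)
    return summary
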