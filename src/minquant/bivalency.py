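"""Five-class bivalent-promoter annotation and expression-response integration.

Every promoter is assigned to exactly one of five classes from its
H3K4me3/H3K27me3 status in the naive and primed states:

* ``k4_negative`` — H3K4me3-negative in both states (regardless of K27);
* ``primed_bivalent`` — K4-positive, K27 significantly higher in primed
  (padj < 0.05 and fold change > 1.5) and K27-positive in primed;
* ``naive_bivalent`` — the mirror image;
* ``common_bivalent`` — K27-positive in both states with no significant
  state difference;
* ``k4_only`` — everything else (K4-positive, K27-devoid or inconclusive).

Mark positivity uses a promoter-mean >= min_fold x genome-median rule
(default 2x), exposed as configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffstats import ClassResponse, call_significant, class_response
from .errors import ConfigurationError
from .simdata import CLASS_LABELS


def call_k4_positive(
    promoter_means: pd.Series, genome_median: float, min_fold: float = 2.0
) -> pd.Series:
    """Positive iff promoter mean RPGC >= min_fold x genome median."""
    if genome_median <= 0:
        raise ConfigurationError(
            f"degenerate track: genome median {genome_median} <= 0"
        )
    return promoter_means >= min_fold * genome_median


def classify_promoters(
    k4_pos: dict[str, pd.Series],
    k27_pos: dict[str, pd.Series],
    k27_diff: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    naive: str = "naive",
    primed: str = "primed",
) -> pd.DataFrame:
    """Assign each promoter to one of the five bivalency classes.

    ``k4_pos``/``k27_pos`` map state name to per-gene positivity booleans;
    ``k27_diff`` is the promoter H3K27me3 differential table with ``log2fc``
    oriented naive over primed.  Genes lacking a differential row are
    omitted with a warning.  The assignment is a partition: swapping the
    two state labels swaps the primed/naive bivalent classes exactly and
    leaves the others unchanged.
    """
    genes = k4_pos[naive].index
    missing = [g for g in genes if g not in k27_diff.index]
    if missing:
        warnings.warn(f"{len(missing)} promoters lack a differential row; omitted")
        genes = genes[~genes.isin(missing)]
    thr = np.log2(fc_threshold)
    sub = k27_diff.loc[genes]
    sig_naive = (sub["padj"] < alpha) & (sub["log2fc"] > thr)
    sig_primed = (sub["padj"] < alpha) & (sub["log2fc"] < -thr)

    k4n = k4_pos[naive].loc[genes]
    k4p = k4_pos[primed].loc[genes]
    k27n = k27_pos[naive].loc[genes]
    k27p = k27_pos[primed].loc[genes]

    cls = pd.Series("k4_only", index=genes, name="promoter_class")
    cls[k27n & k27p] = "common_bivalent"
    cls[sig_primed & k27p] = "primed_bivalent"
    cls[sig_naive & k27n] = "naive_bivalent"
    cls[~k4n & ~k4p] = "k4_negative"
    out = pd.DataFrame(
        {
            "k4_naive_pos": k4n,
            "k4_primed_pos": k4p,
            "k27_naive_pos": k27n,
            "k27_primed_pos": k27p,
            "k27_log2fc": sub["log2fc"],
            "k27_padj": sub["padj"],
            "promoter_class": cls,
        }
    )
    out.index.name = "gene_id"
    return out


def class_switch_table(
    k4_diff: pd.DataFrame,
    k27_diff: pd.DataFrame,
    promoters=None,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Cross-tabulate K4 x K27 gain/loss/stable calls between states.

    Both differential tables are oriented the same way (naive over primed);
    ``up`` means gained in the naive state.  Cell counts sum to the number
    of promoters considered.
    """
    genes = k4_diff.index.intersection(k27_diff.index)
    if promoters is not None:
        genes = genes.intersection(pd.Index(promoters))

    def status(diff):
        up, down = call_significant(diff.loc[genes], alpha, fc_threshold)
        s = pd.Series("stable", index=genes)
        s[s.index.isin(up)] = "up"
        s[s.index.isin(down)] = "down"
        return s

    k4s, k27s = status(k4_diff), status(k27_diff)
    order = ["up", "stable", "down"]
    tab = (
        pd.crosstab(k4s, k27s)
        .reindex(index=order, columns=order, fill_value=0)
    )
    tab.index.name = "k4"
    tab.columns.name = "k27"
    return tab


@dataclass
class DerepressionResult:
    derepressed: set
    downregulated: set
    class_responses: list[ClassResponse]
    frac_derepressed_k27_marked: float


def derepression_analysis(
    rna_diff: pd.DataFrame,
    classes: pd.DataFrame,
    k27_promoter_pos: pd.Series,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
) -> DerepressionResult:
    """Expression response to PRC2 inhibition, stratified by promoter class.

    ``rna_diff`` is the EZH2i-vs-untreated differential expression table;
    derepressed genes are the significant-up set at FDR < alpha and fold
    change > ``fc_threshold`` (the |log2FC| > 1 volcano rule).  Per-class
    Wilcoxon/Cohen's d compare each class's log2FC distribution against all
    genes; the K27-marked fraction is computed over derepressed genes with
    a positivity flag.
    """
    up, down = call_significant(rna_diff, alpha, fc_threshold)
    lfc = rna_diff["log2fc"].dropna()
    responses = []
    for label in CLASS_LABELS:
        members = classes.index[classes["promoter_class"] == label]
        members = [g for g in members if g in lfc.index]
        if not members:
            warnings.warn(f"class {label} empty; response omitted")
            continue
        responses.append(class_response(lfc, members, label=label))
    flagged = [g for g in up if g in k27_promoter_pos.index]
    frac = (
        float(k27_promoter_pos.loc[flagged].mean()) if flagged else float("nan")
    )
    return DerepressionResult(
        derepressed=up,
        downregulated=down,
        class_responses=responses,
        frac_derepressed_k27_marked=frac,
    )


def h2aub_change_at_derepressed(
    h2aub_diff: pd.DataFrame,
    derepressed,
    strata: dict[str, set],
) -> pd.DataFrame:
    """H2Aub promoter fold-change summaries at derepressed genes, by stratum.

    Fold changes are linear (2**log2fc); the table reports n, median and
    quartiles plus the median percent loss.  Empty strata are omitted with
    a warning.
    """
    if not len(derepressed):
        raise ConfigurationError("derepressed gene set is empty")
    dep = pd.Index(sorted(derepressed))
    rows = []
    for name, members in strata.items():
        genes = dep.intersection(pd.Index(sorted(members)))
        genes = genes.intersection(h2aub_diff.index)
        if genes.empty:
            warnings.warn(f"stratum {name} empty at derepressed genes; omitted")
            continue
        fold = 2.0 ** h2aub_diff.loc[genes, "log2fc"].to_numpy(float)
        rows.append(
            {
                "stratum": name,
                "n": len(fold),
                "q25_fold": float(np.quantile(fold, 0.25)),
                "median_fold": float(np.median(fold)),
                "q75_fold": float(np.quantile(fold, 0.75)),
                "median_loss_pct": float((1.0 - np.median(fold)) * 100.0),
            }
        )
    return pd.DataFrame(rows).set_index("stratum")
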