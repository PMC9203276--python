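"""Single-cell gating rules: intensity positivity and pseudotime thresholds.

Two control-anchored rules:

* marker positivity — an object is positive when its mean intensity is
  strictly above ``factor`` x the mean intensity of the matching control
  objects (default 1.5x, the GATA3 rule);
* ground-state gating — cells with pseudotime strictly below the q-quantile
  (default 0.95, linear interpolation) of the control distribution are
  "ground"; the rest are "activated", optionally split by branch label into
  activated / trophectoderm-activated / mesoderm-activated subsets.

Both gates are deterministic, order-independent and scale-invariant (for
the intensity gate, jointly rescaling a sample and its control changes no
call).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError

GROUND = "ground"
ACTIVATED = "activated"

DEFAULT_BRANCH_MAP = {
    "pre_bifurcation": "aELC",
    "trophectoderm": "TaELC",
    "mesoderm": "MaELC",
}


def gate_marker_positive(
    table: pd.DataFrame, channel: str, factor: float = 1.5
):
    """Control-anchored intensity gate.

    ``table`` needs the intensity ``channel``, a ``sample`` column and an
    ``is_control`` boolean column.  Returns ``(positive, percent, threshold)``:
    per-object booleans (strictly above threshold), percent positive per
    sample, and the threshold factor x mean(control intensities).
    """
    if channel not in table.columns:
        raise ConfigurationError(f"channel {channel!r} not in table")
    controls = table.loc[table["is_control"], channel]
    if controls.empty:
        raise ConfigurationError("no control objects present")
    threshold = factor * float(controls.mean())
    positive = table[channel] > threshold
    percent = positive.groupby(table["sample"]).mean() * 100.0
    percent.name = f"percent_{channel}_positive"
    return positive.rename(f"{channel}_positive"), percent, threshold


def gate_ground_state(
    table: pd.DataFrame, control_label: str, q: float = 0.95
):
    """Control-quantile pseudotime gate.

    The threshold is the q-quantile (linear interpolation between order
    statistics) of the control cells' pseudotimes; cells strictly below it
    are labelled ``ground``, others ``activated``.  Returns
    ``(threshold, labels, fractions)`` with per-treatment ground fractions.
    """
    if not 0.0 < q < 1.0:
        raise ConfigurationError(f"q must be in (0, 1), got {q}")
    ctrl = table.loc[table["treatment"] == control_label, "pseudotime"]
    if ctrl.empty:
        raise ConfigurationError(f"no cells with control label {control_label!r}")
    threshold = float(np.quantile(ctrl.to_numpy(float), q))
    labels = pd.Series(
        np.where(table["pseudotime"] < threshold, GROUND, ACTIVATED),
        index=table.index,
        name="state",
    )
    fractions = (labels == GROUND).groupby(table["treatment"]).mean()
    fractions.name = "ground_fraction"
    return threshold, labels, fractions


def split_activated(
    table: pd.DataFrame,
    threshold: float,
    branch_map: dict[str, str] | None = None,
) -> pd.Series:
    """Split cells into ground / activated subsets by branch label.

    Cells below the pseudotime threshold are ``gELC``; cells above are
    mapped through ``branch_map`` (default: pre_bifurcation -> aELC,
    trophectoderm -> TaELC, mesoderm -> MaELC); activated cells with a
    missing or unknown branch are flagged ``unclassified``.
    """
    branch_map = DEFAULT_BRANCH_MAP if branch_map is None else branch_map
    labels = np.where(
        table["pseudotime"] < threshold,
        "gELC",
        table["branch"].map(branch_map).fillna("unclassified").to_numpy(object),
    )
    return pd.Series(labels, index=table.index, name="elc_class")
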