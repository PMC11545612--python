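"""Paired cell-line differential profiling under chronic exposure.

Each isogenic pair (parental cells vs the chronically exposed subline) yields
a per-miRNA expression ratio; ratios are thresholded into up / down / none
calls and the ordered pair of calls across two cell lines places each miRNA
into one of eight joint-dysregulation regions arranged on a 3x3 grid with
the concordant-null centre removed:

             line 2: down   none    up
  line 1 up        R8      R1      R2
  line 1 none      R7    CENTER    R3
  line 1 down      R6      R5      R4

R2 / R6 are the concordant up / down regions; R4 and R8 are discordant.
Derived sets: up in at least one line = R1+R2+R3, down in at least one
line = R5+R6+R7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, geometric_mean

DEFAULT_THRESHOLD = 1.2
CENTER = "CENTER"

#: region label keyed by (call in line 1, call in line 2)
REGION_GRID: dict[tuple[str, str], str] = {
    ("up", "none"): "R1",
    ("up", "up"): "R2",
    ("none", "up"): "R3",
    ("down", "up"): "R4",
    ("down", "none"): "R5",
    ("down", "down"): "R6",
    ("none", "down"): "R7",
    ("up", "down"): "R8",
    ("none", "none"): CENTER,
}

UP_REGIONS = ("R1", "R2", "R3")
DOWN_REGIONS = ("R5", "R6", "R7")
DISCORDANT_REGIONS = ("R4", "R8")


def normalize_matrix(
    m: ExpressionMatrix, epsilon_scale: float = 1e-6
) -> ExpressionMatrix:
    """Equalize per-sample median log-intensity across samples.

    Each sample's intensities are rescaled so that its median log-intensity
    equals the across-sample mean of the median log-intensities; this removes
    per-chip scale factors while leaving within-sample ratios untouched.
    Zero intensities are floored at ``epsilon_scale`` times the global
    median before taking logs to avoid infinities.
    """
    vals = m.values.to_numpy(dtype=float)
    if (vals.sum(axis=0) == 0).any():
        dead = m.samples[vals.sum(axis=0) == 0].tolist()
        raise ValueError(f"all-zero sample(s): {dead}")
    global_median = np.median(vals[vals > 0])
    floor = epsilon_scale * global_median
    vals = np.maximum(vals, floor)
    log_medians = np.median(np.log(vals), axis=0)
    correction = np.exp(log_medians.mean() - log_medians)
    out = m.values.copy()
    out.loc[:, :] = vals * correction
    meta = dict(m.meta, normalized=True, scale_corrections=dict(zip(m.samples, correction)))
    return ExpressionMatrix(out, m.annotations.copy(), meta)


def group_ratio(
    m: ExpressionMatrix,
    cell_line: str,
    numerator_condition: str = "exposed",
    denominator_condition: str = "parental",
) -> pd.Series:
    """Per-miRNA ratio of group geometric means for one cell line.

    Singleton groups are allowed (the screening arrays ran one chip per
    condition); the ratio then reduces to a direct division.
    """
    num = m.samples_where(cell_line=cell_line, condition=numerator_condition)
    den = m.samples_where(cell_line=cell_line, condition=denominator_condition)
    for cond, group in ((numerator_condition, num), (denominator_condition, den)):
        if not group:
            raise ValueError(f"no samples for cell line {cell_line!r}, condition {cond!r}")
    num_gm = geometric_mean(m.values[num].to_numpy(), axis=1)
    den_gm = geometric_mean(m.values[den].to_numpy(), axis=1)
    return pd.Series(num_gm / den_gm, index=m.features, name=cell_line)


def classify_dysregulation(r: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Call a ratio up / down / none at an inclusive fold threshold."""
    if threshold <= 1:
        raise ValueError("dysregulation threshold must exceed 1")
    if r >= threshold:
        return "up"
    if r <= 1.0 / threshold:
        return "down"
    return "none"


def assign_region(call_line1: str, call_line2: str) -> str:
    """Map an ordered pair of per-line calls to its joint region label."""
    key = (call_line1, call_line2)
    if key not in REGION_GRID:
        raise ValueError(f"calls must be in {{up, down, none}}, got {key}")
    return REGION_GRID[key]


@dataclass
class AnePanel:
    """Joint dysregulation panel across two (or more) isogenic pairs."""

    table: pd.DataFrame  # per-miRNA: fc_<line>, call_<line>, region
    lines: list[str]
    threshold: float
    singleton_groups: bool = False
    meta: dict = field(default_factory=dict)

    def _region_set(self, regions) -> set[str]:
        mask = self.table["region"].isin(regions)
        return set(self.table.index[mask])

    @property
    def up_any(self) -> set[str]:
        return self._region_set(UP_REGIONS)

    @property
    def down_any(self) -> set[str]:
        return self._region_set(DOWN_REGIONS)

    @property
    def common_up(self) -> set[str]:
        return self._region_set(["R2"])

    @property
    def common_down(self) -> set[str]:
        return self._region_set(["R6"])

    @property
    def discordant(self) -> set[str]:
        return self._region_set(DISCORDANT_REGIONS)

    @property
    def center(self) -> set[str]:
        return self._region_set([CENTER])

    def region_counts(self) -> pd.Series:
        return self.table["region"].value_counts()

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="mirna")


def build_ane_panel(
    m: ExpressionMatrix,
    lines: list[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    normalize: bool = True,
) -> AnePanel:
    """Build the joint exposure panel from a paired cell-line experiment.

    Region assignment uses the first two cell lines (sorted order if not
    given); additional lines contribute fold-change columns only.
    """
    if lines is None:
        lines = sorted(m.annotations["cell_line"].unique())
    if len(lines) < 2:
        raise ValueError("need at least two cell lines with both conditions")
    if normalize:
        m = normalize_matrix(m)
    fcs = {line: group_ratio(m, line) for line in lines}
    calls = {
        line: fc.map(lambda r: classify_dysregulation(r, threshold))
        for line, fc in fcs.items()
    }
    table = pd.DataFrame(index=m.features)
    for line in lines:
        table[f"fc_{line}"] = fcs[line]
        table[f"call_{line}"] = calls[line]
    l1, l2 = lines[:2]
    table["region"] = [
        assign_region(a, b) for a, b in zip(table[f"call_{l1}"], table[f"call_{l2}"])
    ]
    singleton = any(
        len(m.samples_where(cell_line=line, condition=cond)) == 1
        for line in lines
        for cond in ("parental", "exposed")
    )
    return AnePanel(table, list(lines), threshold, singleton_groups=singleton)
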