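"""Per-organoid area statistics and group-level growth testing.

Segmented masks are decomposed into connected components (8-connectivity by
default, so adhering organoids merge into one object, matching how a 2-D
segmentation sees them); components below ``min_area`` pixels are dropped
as speckle.  Areas are pooled per (group, day) cell into a long-form table,
summarised by violin plots with quartile lines, and compared between a
control and each treatment group with a two-sample t-test per day (Welch by
default, organoids as the sampling unit).  Areas are in pixels unless a
micrometre-per-pixel calibration is supplied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import label as sk_label, regionprops

__all__ = [
    "OrganoidRecord", "DayTestResult", "label_components", "build_area_table",
    "area_table_from_series", "day_ttest", "violin_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrganoidRecord:
    image_id: str
    component_id: int
    area: float
    centroid: tuple[float, float]     # (row, col)


@dataclass(frozen=True)
class DayTestResult:
    day: int
    group_a: str
    group_b: str
    t: float
    p: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    variant: str                      # "welch" | "student"
    flagged: bool = False


def label_components(mask: np.ndarray, *, connectivity: int = 2,
                     min_area: int = 30, image_id: str = "",
                     um_per_px: float | None = None) -> list[OrganoidRecord]:
    """Connected foreground components of a binary mask as area records.

    ``connectivity`` follows scikit-image: 1 = 4-neighbourhood,
    2 = 8-neighbourhood.  Components smaller than ``min_area`` pixels are
    dropped (and counted in the module log).
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary {0, 1}")
    labels = sk_label(mask, connectivity=connectivity)
    records, dropped = [], 0
    scale = (um_per_px ** 2) if um_per_px else 1.0
    for rp in regionprops(labels):
        if rp.area < min_area:
            dropped += 1
            continue
        records.append(OrganoidRecord(
            image_id=image_id, component_id=int(rp.label),
            area=float(rp.area * scale), centroid=tuple(map(float, rp.centroid))))
    if dropped:
        log.info("dropped %d components below min_area=%d in %s",
                 dropped, min_area, image_id or "<mask>")
    return records


def build_area_table(masks_by_cell: dict, *, connectivity: int = 2,
                     min_area: int = 30,
                     um_per_px: float | None = None) -> pd.DataFrame:
    """Long-form area table from ``{(group, day): [(image_id, mask), ...]}``.

    Image ids must be unique across the whole table; empty cells are
    excluded with a warning.
    """
    rows, seen = [], set()
    for (group, day), items in masks_by_cell.items():
        if not items:
            warnings.warn(f"empty cell ({group}, day {day}) excluded",
                          stacklevel=2)
            continue
        for image_id, mask in items:
            if image_id in seen:
                raise ValueError(f"duplicate image id {image_id!r}")
            seen.add(image_id)
            for rec in label_components(mask, connectivity=connectivity,
                                        min_area=min_area, image_id=image_id,
                                        um_per_px=um_per_px):
                rows.append({"group": group, "day": int(day),
                             "image_id": image_id,
                             "organoid_id": rec.component_id,
                             "area": rec.area})
    return pd.DataFrame(rows, columns=["group", "day", "image_id",
                                       "organoid_id", "area"])


def area_table_from_series(series_by_group: dict, **kwargs) -> pd.DataFrame:
    """Area table straight from ``synthetic.make_growth_series`` outputs:
    ``{group: [(day, image, truth), ...]}`` using the ground-truth masks."""
    cells: dict = {}
    for group, series in series_by_group.items():
        counters: dict[int, int] = {}
        for day, _, truth in series:
            i = counters.get(day, 0)
            counters[day] = i + 1
            cells.setdefault((group, day), []).append(
                (f"{group}_d{day}_{i}", truth.mask))
    return build_area_table(cells, **kwargs)


def day_ttest(table: pd.DataFrame, group_a: str, group_b: str, day: int,
              *, welch: bool = True) -> DayTestResult:
    """Two-sided two-sample t-test on per-organoid areas for one day."""
    a = table.query("group == @group_a and day == @day")["area"].to_numpy()
    b = table.query("group == @group_b and day == @day")["area"].to_numpy()
    variant = "welch" if welch else "student"
    if len(a) < 2 or len(b) < 2 or (np.var(a) == 0 and np.var(b) == 0):
        return DayTestResult(day, group_a, group_b, np.nan, np.nan,
                             float(np.median(a)) if len(a) else np.nan,
                             float(np.median(b)) if len(b) else np.nan,
                             len(a), len(b), variant, flagged=True)
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return DayTestResult(day, group_a, group_b, float(t), float(p),
                         float(np.median(a)), float(np.median(b)),
                         len(a), len(b), variant)


def violin_report(table: pd.DataFrame, out_path) -> pd.DataFrame:
    """Violin plot (one violin per group x day, quartile lines) plus a
    summary CSV carrying exactly the plotted statistics.

    Returns the summary; the figure goes to ``out_path`` and the CSV next
    to it with suffix ``_summary.csv``.
    """
    if table.empty:
        raise ValueError("area table is empty")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    groups = sorted(table["group"].unique(), key=lambda g: (g != "CTR", g))
    days = sorted(table["day"].unique())
    fig, ax = plt.subplots(figsize=(2 + 2 * len(days), 4))
    sns.violinplot(data=table, x="day", y="area", hue="group", order=days,
                   hue_order=groups, inner="quartile", cut=0, ax=ax)
    ax.set_xlabel("culture day")
    ax.set_ylabel("organoid area (px)")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    summary = (table.groupby(["group", "day"])["area"]
               .agg(n="count", median="median",
                    q1=lambda s: s.quantile(0.25),
                    q3=lambda s: s.quantile(0.75))
               .reset_index())
    summary = summary.sort_values(
        ["group", "day"],
        key=lambda col: col.map(lambda g: (g != "CTR", g))
        if col.name == "group" else col).reset_index(drop=True)
    summary.to_csv(out_path.with_name(out_path.stem + "_summary.csv"),
                   index=False)
    return summary
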