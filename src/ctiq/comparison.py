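"""Summary statistics over a table of image-quality metrics.

A metric table is a pandas DataFrame indexed by (dose mGy, algorithm,
level) whose columns are the per-condition scalar metrics: noise magnitude,
1-D NPS peak, f_av, f50 per insert, and d' per simulated lesion. Pairwise
contrasts between algorithms, levels or doses are expressed as percent
differences, 100 * (b - a) / a, and summarised as mean +/- sample standard
deviation (n - 1) across the matched conditions. Only descriptive
statistics are produced: one measurement exists per condition, so no
inferential analysis is meaningful here.

A transcription of the reference measurement tables of the emulated study
(noise metrics, f50 values and d' values for two deep-learning
reconstructions at three strength levels and three dose levels) ships with
the package and can be loaded with :func:`load_reference_tables`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "INDEX_COLS",
    "METRIC_COLS",
    "ComparisonStat",
    "load_reference_tables",
    "make_metric_table",
    "percent_diff",
    "summarize_contrast",
    "reference_summary_statistics",
    "render_tables",
]

logger = logging.getLogger(__name__)

INDEX_COLS = ["dose_mgy", "algorithm", "level"]
METRIC_COLS = [
    "noise_magnitude",
    "nps1d_peak",
    "f_av",
    "f50_solid_water",
    "f50_iodine",
    "dprime_low_contrast",
    "dprime_high_contrast",
]


@dataclass
class ComparisonStat:
    """Mean +/- sample SD of percent differences over matched conditions."""

    contrast_description: str
    values: np.ndarray  # per-condition percent differences
    mean: float
    sd: float  # n-1 convention

    def __str__(self) -> str:
        return f"{self.contrast_description}: {self.mean:+.1f} ± {self.sd:.1f}%"


def percent_diff(a: float, b: float) -> float:
    """Percent difference of b relative to baseline a: 100 * (b - a) / a."""
    if a == 0:
        raise ZeroDivisionError("percent difference undefined for a zero baseline")
    return 100.0 * (b - a) / a


def make_metric_table(rows: list[Mapping[str, object]]) -> pd.DataFrame:
    """Assemble per-condition metric records into an indexed metric table."""
    df = pd.DataFrame(rows)
    missing = [c for c in INDEX_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"metric records lack index fields {missing}")
    df = df.set_index(INDEX_COLS).sort_index()
    if df.index.has_duplicates:
        raise ValueError("duplicate (dose, algorithm, level) keys in metric table")
    return df


def load_reference_tables() -> pd.DataFrame:
    """Load the packaged transcription of the reference measurement tables."""
    frames = []
    for name in ("table1_noise.csv", "table2_f50.csv", "table3_dprime.csv"):
        with resources.files("ctiq.data").joinpath(name).open() as fh:
            frames.append(pd.read_csv(fh).set_index(INDEX_COLS))
    return pd.concat(frames, axis=1).sort_index()


def summarize_contrast(
    table: pd.DataFrame,
    metric: str,
    group_a: Mapping[str, object],
    group_b: Mapping[str, object],
    description: str | None = None,
) -> ComparisonStat:
    """Element-wise percent differences of metric between two condition groups.

    ``group_a``/``group_b`` select rows by fixing some of the index levels
    (e.g. ``{"algorithm": "AiCE", "level": 2}``); the remaining free levels
    must match one-to-one between the two groups — the per-condition percent
    differences are taken over those matched conditions, with group_a as
    the baseline.
    """
    if metric not in table.columns:
        raise KeyError(f"metric {metric!r} not in table")

    def _select(sel: Mapping[str, object]) -> pd.Series:
        sub = table
        for key, value in sel.items():
            sub = sub.xs(value, level=key, drop_level=True)
        return sub[metric]

    a = _select(group_a)
    b = _select(group_b)
    if not a.index.equals(b.index):
        raise ValueError("selectors resolve to mismatched condition sets")
    vals = np.array([percent_diff(x, y) for x, y in zip(a.to_numpy(), b.to_numpy())])
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    desc = description or f"{metric}: {dict(group_b)} vs {dict(group_a)}"
    return ComparisonStat(contrast_description=desc, values=vals, mean=mean, sd=sd)


def reference_summary_statistics(
    table: pd.DataFrame | None = None,
    algorithms: tuple[str, str] = ("AiCE", "PIQE"),
) -> dict[str, ComparisonStat]:
    """The noise-table contrasts quoted as mean +/- SD in the reference study.

    ``algorithms`` names the (normal-resolution baseline, super-resolution)
    pair as labelled in the table. Returns the contrasts that regenerate
    exactly from the printed table cells, plus the level-1-to-2 contrast of
    the super-resolution algorithm, which is rounding-limited (the printed
    mean differs in the last decimal from what the rounded cells give).
    """
    if table is None:
        table = load_reference_tables()
    nr, sr = algorithms
    stats = {
        "nps1d_peak_sr_vs_nr": summarize_contrast(
            table, "nps1d_peak", {"algorithm": nr}, {"algorithm": sr},
            f"NPS1D peak, {sr} vs {nr}, all dose/level pairs",
        ),
        "noise_magnitude_level2_sr_vs_nr": summarize_contrast(
            table, "noise_magnitude",
            {"algorithm": nr, "level": 2}, {"algorithm": sr, "level": 2},
            f"noise magnitude, {sr} vs {nr}, level-2",
        ),
        "noise_magnitude_level3_sr_vs_nr": summarize_contrast(
            table, "noise_magnitude",
            {"algorithm": nr, "level": 3}, {"algorithm": sr, "level": 3},
            f"noise magnitude, {sr} vs {nr}, level-3",
        ),
        "noise_magnitude_nr_l1_to_l2": summarize_contrast(
            table, "noise_magnitude",
            {"algorithm": nr, "level": 1}, {"algorithm": nr, "level": 2},
            f"noise magnitude, {nr} level-1 to level-2",
        ),
        "noise_magnitude_nr_l2_to_l3": summarize_contrast(
            table, "noise_magnitude",
            {"algorithm": nr, "level": 2}, {"algorithm": nr, "level": 3},
            f"noise magnitude, {nr} level-2 to level-3",
        ),
        "noise_magnitude_sr_l2_to_l3": summarize_contrast(
            table, "noise_magnitude",
            {"algorithm": sr, "level": 2}, {"algorithm": sr, "level": 3},
            f"noise magnitude, {sr} level-2 to level-3",
        ),
        # rounding-limited: regenerates as -44.5 from the rounded cells
        "noise_magnitude_sr_l1_to_l2": summarize_contrast(
            table, "noise_magnitude",
            {"algorithm": sr, "level": 1}, {"algorithm": sr, "level": 2},
            f"noise magnitude, {sr} level-1 to level-2 (rounding-limited)",
        ),
    }
    return stats


_TABLE_LAYOUTS = {
    # filename -> (columns, decimals)
    "table_noise.csv": (["nps1d_peak", "noise_magnitude", "f_av"], {"nps1d_peak": 1, "noise_magnitude": 1, "f_av": 2}),
    "table_f50.csv": (["f50_solid_water", "f50_iodine"], {"f50_solid_water": 2, "f50_iodine": 2}),
    "table_dprime.csv": (["dprime_low_contrast", "dprime_high_contrast"], {"dprime_low_contrast": 1, "dprime_high_contrast": 1}),
}


def render_tables(table: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write the metric table as three CSVs (noise metrics, f50, d').

    Layout mirrors the reference study's tables: one row per dose level,
    one column per algorithm x level combination, fixed decimal formatting
    per metric. Missing cells are rendered empty and logged.
    """
    if len(table) == 0:
        raise ValueError("no rows in metric table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doses = sorted(table.index.get_level_values("dose_mgy").unique())
    combos = sorted(
        {(alg, lvl) for _, alg, lvl in table.index},
        key=lambda al: (al[0], al[1]),
    )
    written = []
    for fname, (metrics, decimals) in _TABLE_LAYOUTS.items():
        present = [m for m in metrics if m in table.columns]
        if not present:
            continue
        rows = []
        for metric in present:
            for dose in doses:
                row: dict[str, object] = {"metric": metric, "dose_mgy": dose}
                for alg, lvl in combos:
                    key = (dose, alg, lvl)
                    col = f"{alg} level-{lvl}"
                    if key in table.index and pd.notna(table.loc[key, metric]):
                        row[col] = f"{table.loc[key, metric]:.{decimals[metric]}f}"
                    else:
                        logger.warning("missing cell %s for %s", key, metric)
                        row[col] = ""
                rows.append(row)
        path = out_dir / fname
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
    return written
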