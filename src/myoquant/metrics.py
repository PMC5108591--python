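"""Assay quantities derived from per-cell tables.

All operations here are pure functions of a tidy per-cell table (one
row per segmented or ground-truth cell, with an ``n_nuclei`` column
and boolean ``marker_<name>`` columns):

* **Fusion index** — the number of nuclei inside MyHC-positive cells
  containing ≥ 2 nuclei, divided by the total number of nuclei in the
  field of view.  Raw counts are retained so the index can feed
  binomial models downstream.
* **Myotube size classes** — small (2–4 nuclei), medium (5–9), large
  (10–24), very large (≥ 25); inclusive, exhaustive, non-overlapping.
* **Marker fractions** — positive / total cell counts for a marker,
  optionally gated on a second marker (e.g. EdU⁺ among GFP⁺ cells).
* **Engraftment summaries** — totals per muscle, averages per section
  and the along-length profile for donor-nucleus counts from serial
  cryosections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

SIZE_CLASS_NAMES = ("small", "medium", "large", "very_large")
SIZE_CLASS_BOUNDS = {"small": (2, 4), "medium": (5, 9), "large": (10, 24),
                     "very_large": (25, None)}


@dataclass
class FusionIndex:
    numerator: int          # nuclei in MyHC+ cells with >= 2 nuclei
    denominator: int        # all nuclei in the field of view
    ratio: float

    def as_counts(self) -> tuple[int, int]:
        return self.numerator, self.denominator


@dataclass
class MarkerFraction:
    marker: str
    gate: str | None
    positive: int
    total: int
    ratio: float


@dataclass
class AssaySummary:
    """Per-frame derived quantities."""

    frame_id: str
    fusion_index: FusionIndex | None
    size_class_counts: dict[str, int]
    size_class_proportions: dict[str, float]
    marker_fractions: dict[str, MarkerFraction]
    condition: str | None = None
    dose: float | None = None
    group: str | None = None


def _marker_col(df: pd.DataFrame, name: str) -> pd.Series:
    col = f"marker_{name}" if f"marker_{name}" in df.columns else name
    if col not in df.columns:
        raise ValidationError(f"table has no marker column for {name!r}")
    return df[col].astype(bool)


def fusion_index(
    cells: pd.DataFrame,
    myhc_marker: str = "myhc",
    gate_marker: str | None = None,
    total_nuclei: int | None = None,
) -> FusionIndex:
    """Fusion index of one field of view.

    Numerator: nuclei in cells positive for ``myhc_marker``, holding
    ≥ 2 nuclei and, if ``gate_marker`` is given, positive for the gate
    as well (e.g. the eGFP⁺/MyHC⁺ variant used for transduced cells).
    Denominator: all nuclei in the field — pass ``total_nuclei`` to
    include nuclei not assigned to any cell, otherwise the table's
    nucleus total is used.
    """
    if "n_nuclei" not in cells.columns:
        raise ValidationError("cell table lacks an n_nuclei column")
    denom = int(total_nuclei) if total_nuclei is not None else int(cells["n_nuclei"].sum())
    if denom < 1:
        raise ValidationError(
            f"zero total nuclei in frame "
            f"{cells['frame_id'].iat[0] if 'frame_id' in cells and len(cells) else '?'}"
        )
    sel = _marker_col(cells, myhc_marker) & (cells["n_nuclei"] >= 2)
    if gate_marker is not None:
        sel &= _marker_col(cells, gate_marker)
    num = int(cells.loc[sel, "n_nuclei"].sum())
    if num > denom:
        raise ValidationError("fusion numerator exceeds the nucleus total")
    return FusionIndex(numerator=num, denominator=denom, ratio=num / denom)


def classify_myotube_size(n_nuclei: int) -> str:
    """Size class of a myotube: 2–4 small, 5–9 medium, 10–24 large, ≥25 very_large."""
    n = int(n_nuclei)
    if n < 2:
        raise ValidationError(f"a myotube has >= 2 nuclei (got {n})")
    if n <= 4:
        return "small"
    if n <= 9:
        return "medium"
    if n <= 24:
        return "large"
    return "very_large"


def size_class_histogram(cells: pd.DataFrame) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and proportions of myotubes (≥ 2 nuclei) per size class."""
    tubes = cells.loc[cells["n_nuclei"] >= 2, "n_nuclei"]
    counts = {name: 0 for name in SIZE_CLASS_NAMES}
    for n in tubes:
        counts[classify_myotube_size(n)] += 1
    total = sum(counts.values())
    props = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return counts, props


def marker_fraction(
    cells: pd.DataFrame, marker: str, gate: str | None = None
) -> MarkerFraction:
    """Fraction of cells positive for ``marker`` among gate-positive cells.

    Without a gate the denominator is all cells.  An empty gate set
    yields a missing-value fraction with a warning.
    """
    pos = _marker_col(cells, marker)
    if gate is not None:
        in_gate = _marker_col(cells, gate)
    else:
        in_gate = pd.Series(True, index=cells.index)
    n = int(in_gate.sum())
    if n == 0:
        warnings.warn(f"empty gate set for marker {marker!r} gated on {gate!r}")
        return MarkerFraction(marker, gate, 0, 0, float("nan"))
    k = int((pos & in_gate).sum())
    return MarkerFraction(marker, gate, k, n, k / n)


def summarise_assay(
    cells: pd.DataFrame,
    myhc_marker: str = "myhc",
    fusion_gate: str | None = None,
    markers: list[str] | None = None,
    total_nuclei: int | None = None,
) -> AssaySummary:
    """Bundle the per-frame assay quantities for one cell table."""
    meta = {
        k: (cells[k].iat[0] if k in cells.columns and len(cells) else None)
        for k in ("frame_id", "condition", "dose", "group")
    }
    fi = None
    has_myhc = f"marker_{myhc_marker}" in cells.columns or myhc_marker in cells.columns
    if len(cells) and has_myhc:
        fi = fusion_index(cells, myhc_marker, fusion_gate, total_nuclei)
    counts, props = size_class_histogram(cells) if len(cells) else (
        {n: 0 for n in SIZE_CLASS_NAMES}, {n: 0.0 for n in SIZE_CLASS_NAMES})
    fractions = {}
    for m in markers or []:
        fractions[m] = marker_fraction(cells, m)
    return AssaySummary(
        frame_id=str(meta["frame_id"] or ""), fusion_index=fi,
        size_class_counts=counts, size_class_proportions=props,
        marker_fractions=fractions, condition=meta["condition"],
        dose=meta["dose"], group=meta["group"],
    )


# ---------------------------------------------------------------------------
# engraftment

_ENGRAFT_COLS = (
    "mouse", "section", "position",
    "laminac_in_fibre", "laminac_interstitial",
    "spectrin_fibres", "spectrin_fibres_with_laminac",
)


@dataclass
class EngraftmentSummary:
    """Donor-cell engraftment counts across serial muscle sections.

    Donor nuclei are human LAMIN A/C⁺; donor-derived myofibres are
    human SPECTRIN⁺.  Totals are per muscle (all sections combined),
    means are per section, and the profile is the mean per ordered
    section position across mice.
    """

    per_mouse: pd.DataFrame          # totals per mouse
    per_section_mean: pd.DataFrame   # mean per section, per mouse
    profile: pd.DataFrame            # mean per position across mice
    sections: pd.DataFrame = field(repr=False, default=None)


def engraftment_summary(sections: pd.DataFrame) -> EngraftmentSummary:
    """Summarise per-section engraftment counts.

    ``sections`` needs the columns ``mouse``, ``section``, ``position``
    (ordered index or µm along the muscle), ``laminac_in_fibre``,
    ``laminac_interstitial``, ``spectrin_fibres`` and
    ``spectrin_fibres_with_laminac``.
    """
    missing = [c for c in _ENGRAFT_COLS if c not in sections.columns]
    if missing:
        raise ValidationError(f"section table missing columns: {missing}")
    df = sections.copy()
    bad = df["spectrin_fibres_with_laminac"] > df["spectrin_fibres"]
    if bad.any():
        raise ValidationError(
            "spectrin_fibres_with_laminac exceeds spectrin_fibres in "
            f"{int(bad.sum())} section(s)"
        )
    df["laminac_total"] = df["laminac_in_fibre"] + df["laminac_interstitial"]
    count_cols = [
        "laminac_total", "laminac_in_fibre", "laminac_interstitial",
        "spectrin_fibres", "spectrin_fibres_with_laminac",
    ]
    per_mouse = df.groupby("mouse", as_index=False)[count_cols].sum()
    per_mouse["in_fibre_fraction"] = np.where(
        per_mouse["laminac_total"] > 0,
        per_mouse["laminac_in_fibre"] / per_mouse["laminac_total"], np.nan,
    )
    per_section = df.groupby("mouse", as_index=False)[count_cols].mean()
    profile = df.groupby("position", as_index=False)[count_cols].mean()
    return EngraftmentSummary(
        per_mouse=per_mouse, per_section_mean=per_section,
        profile=profile, sections=df,
    )
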