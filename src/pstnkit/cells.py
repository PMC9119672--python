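"""Cell-count quantification with Abercrombie correction.

Per-section counts of marker-class cells (e.g. Tac1-only, Crh-only,
co-expressing) are pooled within each animal before forming percentages
(ratio of sums, robust to sparse sections), and profile counts are
corrected for double counting across adjacent sections with
Abercrombie's factor T / (T + h), where T is the section thickness and
h the mean particle (nuclear) height along the cutting axis. Group
dispersion is reported across animals, never across sections.

Input tables are long-format with columns
``animal_id, section_id, bregma_mm, class, count``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbercrombieParams",
    "CoexpressionSummary",
    "FosSummary",
    "validate_cell_counts",
    "abercrombie_correct",
    "coexpression_summary",
    "fos_coexpression",
]

#: Section thickness used in the reference protocol, micrometres.
DEFAULT_THICKNESS_UM = 30.0
#: Sections per animal expected by the reference protocol.
EXPECTED_SECTIONS = 18

REQUIRED_COLUMNS = ("animal_id", "section_id", "class", "count")


@dataclass
class AbercrombieParams:
    """Parameters of the double-counting correction N = n * T / (T + h).

    ``h_um`` (mean particle height) is preparation-specific and must be
    measured by the user; there is no universal default.
    """

    T_um: float = DEFAULT_THICKNESS_UM
    h_um: float = 0.0

    def __post_init__(self) -> None:
        if self.T_um <= 0:
            raise ValueError("section thickness T_um must be positive")
        if self.h_um < 0:
            raise ValueError("particle height h_um must be non-negative")

    @property
    def factor(self) -> float:
        """Correction factor T / (T + h), in (0, 1]."""
        return self.T_um / (self.T_um + self.h_um)


@dataclass
class CoexpressionSummary:
    """Per-animal percentages, group mean +/- SD, and corrected counts."""

    per_animal: pd.DataFrame  # animals x percentage columns
    group: pd.DataFrame  # mean / sd / n per percentage column
    corrected_counts: pd.DataFrame  # animals x class, Abercrombie-corrected
    excluded_animals: list[str] = field(default_factory=list)


@dataclass
class FosSummary:
    """Per-animal Fos co-activation percentages and corrected counts."""

    per_animal: pd.DataFrame
    group: pd.DataFrame  # mean / sem / n
    excluded_animals: list[str] = field(default_factory=list)


def validate_cell_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format count table and warn on protocol deviations."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table is missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("empty count table")
    counts = pd.to_numeric(table["count"], errors="raise")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be integers")
    n_sections = table.groupby("animal_id")["section_id"].nunique()
    off_protocol = n_sections[n_sections != EXPECTED_SECTIONS]
    if len(off_protocol) > 0:
        warnings.warn(
            f"animals with != {EXPECTED_SECTIONS} sections: "
            f"{dict(off_protocol)}",
            stacklevel=2,
        )
    return table


def abercrombie_correct(n, params: AbercrombieParams):
    """Correct raw profile counts for double counting: N = n * T / (T + h)."""
    arr = np.asarray(n, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    corrected = arr * params.factor
    if np.ndim(n) == 0:
        return float(corrected)
    return corrected


def _animal_class_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Sum counts over sections within each animal (animals x classes)."""
    totals = (
        table.groupby(["animal_id", "class"])["count"].sum().unstack(fill_value=0)
    )
    return totals.sort_index()


def _group_stats(per_animal: pd.DataFrame, dispersion: str) -> pd.DataFrame:
    rows = {}
    n = len(per_animal)
    for col in per_animal.columns:
        vals = per_animal[col].to_numpy(dtype=float)
        mean = float(np.mean(vals)) if n else math.nan
        sd = float(np.std(vals, ddof=1)) if n > 1 else math.nan
        row = {"mean": mean, "n": n}
        if dispersion == "sd":
            row["sd"] = sd
        else:
            row["sem"] = sd / math.sqrt(n) if n > 1 else math.nan
        rows[col] = row
    return pd.DataFrame(rows).T


def coexpression_summary(
    table: pd.DataFrame,
    markers: tuple[str, str] = ("tac1", "crh"),
    denominator: list[str] | None = None,
    params: AbercrombieParams | None = None,
) -> CoexpressionSummary:
    """Marker co-expression percentages from exclusive class counts.

    Expects the exclusive classes ``{m1}_only``, ``{m2}_only`` and
    ``both``. For each animal, sections are summed first and
    percentages are ratios of those sums against the denominator
    (default: all labeled cells). Both reporting conventions are
    returned: exclusive percentages (``pct_{m}_only``, ``pct_both``,
    summing to 100 of the labeled denominator) and inclusive marker
    totals (``pct_{m}``, counting co-expressing cells towards each
    marker). Group dispersion is the SD across animals. Corrected
    counts apply Abercrombie's factor (identity if ``params`` is None);
    percentages are unaffected because a class-independent factor
    cancels.
    """
    validate_cell_counts(table)
    m1, m2 = markers
    classes = [f"{m1}_only", f"{m2}_only", "both"]
    totals = _animal_class_totals(table)
    for cls in classes:
        if cls not in totals.columns:
            totals[cls] = 0
    totals = totals[classes]
    if denominator is None:
        denominator = classes
    unknown = [c for c in denominator if c not in totals.columns]
    if unknown:
        raise ValueError(f"denominator classes not present: {unknown}")

    den = totals[denominator].sum(axis=1)
    zero = den == 0
    excluded = list(totals.index[zero])
    if excluded:
        warnings.warn(
            f"animals with zero denominator excluded: {excluded}", stacklevel=2
        )
    kept = totals[~zero]
    den = den[~zero]
    if len(kept) == 0:
        raise ValueError("no animal has a non-zero denominator")

    per_animal = pd.DataFrame(index=kept.index)
    for cls in classes:
        per_animal[f"pct_{cls}"] = 100.0 * kept[cls] / den
    per_animal[f"pct_{m1}"] = 100.0 * (kept[f"{m1}_only"] + kept["both"]) / den
    per_animal[f"pct_{m2}"] = 100.0 * (kept[f"{m2}_only"] + kept["both"]) / den

    factor = params.factor if params is not None else 1.0
    corrected = kept[classes] * factor

    group = _group_stats(per_animal, dispersion="sd")
    return CoexpressionSummary(
        per_animal=per_animal,
        group=group,
        corrected_counts=corrected,
        excluded_animals=excluded,
    )


def fos_coexpression(
    table: pd.DataFrame,
    markers: tuple[str, ...] = ("tac1", "crh"),
    params: AbercrombieParams | None = None,
) -> FosSummary:
    """Percentage and corrected number of marker cells co-expressing Fos.

    Expects classes ``{m}_fos_pos`` and ``{m}_fos_neg`` for each
    marker. Per animal, the percentage is 100 * Fos+ / (Fos+ + Fos-)
    over section-summed counts, and the absolute count is the
    Abercrombie-corrected Fos+ sum. Group values are mean +/- SEM
    across animals. Animals with no cells for a marker are excluded
    with a warning. The percentage is invariant to a class-independent
    correction factor.
    """
    validate_cell_counts(table)
    totals = _animal_class_totals(table)
    factor = params.factor if params is not None else 1.0

    per_animal = pd.DataFrame(index=totals.index)
    excluded: set[str] = set()
    for m in markers:
        pos_col, neg_col = f"{m}_fos_pos", f"{m}_fos_neg"
        for col in (pos_col, neg_col):
            if col not in totals.columns:
                totals[col] = 0
        marker_total = totals[pos_col] + totals[neg_col]
        zero = marker_total == 0
        excluded.update(totals.index[zero])
        pct = 100.0 * totals[pos_col] / marker_total.where(~zero)
        per_animal[f"pct_fos_{m}"] = pct
        per_animal[f"n_fos_{m}_corrected"] = totals[pos_col] * factor
    if excluded:
        warnings.warn(
            f"animals with zero marker total excluded: {sorted(excluded)}",
            stacklevel=2,
        )
        per_animal = per_animal.drop(index=sorted(excluded))
    if len(per_animal) == 0:
        raise ValueError("no animal has marker-positive cells")
    group = _group_stats(per_animal, dispersion="sem")
    return FosSummary(
        per_animal=per_animal, group=group, excluded_animals=sorted(excluded)
    )
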