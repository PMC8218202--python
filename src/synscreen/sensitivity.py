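"""Combination sensitivity scoring: CSS and the S score.

CSS (combination sensitivity score) asks how much inhibition the
combination delivers overall, on the same normalized log10-AUC scale as
the single-agent RI so the two are directly comparable.  For each drug in
turn, the partner is fixed at (the tested dose nearest) its IC50, a
log-logistic curve is fitted to the combination responses along the
remaining axis, and that curve's RI over the axis's positive range is one
CSS component; CSS is the mean of the two components.

The S score is CSS minus the single-agent RI — by default the larger of
the two drugs' RIs, i.e. how much the combination beats the best
monotherapy on the sensitivity scale.  S = 0 is additive, S > 0 synergy,
S < 0 antagonism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import (
    InvalidInputError,
    MonotherapyCurve,
    compute_ri,
    fit_curve,
)
from .synergy import SYNERGY_MODELS, DoseResponseMatrix, SynergyResult

__all__ = [
    "SensitivityResult",
    "css_slice",
    "compute_css_s",
    "ss_points",
    "score_distributions",
    "summary_table",
]

S_VARIANTS = ("max", "mean", "sum")


@dataclass
class SensitivityResult:
    """Per-block sensitivity summary: RIs, IC50s, CSS components, CSS, S."""

    block_id: str
    ri_row: float
    ri_col: float
    ic50_row: float
    ic50_col: float
    css_row_slice: float
    css_col_slice: float
    css: float
    s: float
    s_variant: str = "max"
    degenerate_slices: int = 0


def _nearest_dose_index(doses: np.ndarray, target: float) -> int:
    """Index of the tested dose nearest ``target`` on the log10 scale.

    Ties break toward the lower concentration, keeping slice selection
    reproducible without interpolating unmeasured wells.
    """
    pos = doses[doses > 0]
    if pos.size == 0:
        raise InvalidInputError("no positive doses on the fixed axis")
    target = min(max(target, pos[0]), pos[-1])
    d = np.abs(np.log10(pos) - math.log10(target))
    best = np.nonzero(d <= d.min() + 1e-12)[0][0]
    # map back into the full axis (which may include the zero dose)
    return int(np.nonzero(doses == pos[best])[0][0])


def css_slice(
    matrix: DoseResponseMatrix,
    fixed_axis: str,
    partner_ic50: float,
) -> tuple[float, bool]:
    """One CSS component: normalized log10-AUC of a combination slice.

    ``fixed_axis="row"`` fixes drug_row at the tested dose nearest
    ``partner_ic50`` and integrates the fitted response along the column
    axis (and symmetrically for ``"col"``).  Returns ``(value, degenerate)``
    where ``degenerate`` marks flat/unfittable slices whose mean response
    is returned instead of a fitted RI.
    """
    if fixed_axis not in ("row", "col"):
        raise InvalidInputError("fixed_axis must be 'row' or 'col'")
    if fixed_axis == "row":
        idx = _nearest_dose_index(matrix.conc_r, partner_ic50)
        doses, resp = matrix.conc_c, matrix.response[idx, :]
    else:
        idx = _nearest_dose_index(matrix.conc_c, partner_ic50)
        doses, resp = matrix.conc_r, matrix.response[:, idx]

    pos = doses > 0
    ok = pos & np.isfinite(resp)
    x, y = doses[ok], resp[ok]
    if np.unique(x).size < 2:
        raise InvalidInputError(
            f"CSS slice needs >=2 positive doses in block {matrix.block_id}"
        )
    try:
        curve = fit_curve(x, y, unit=matrix.unit, block_id=matrix.block_id)
    except InvalidInputError:
        return float(np.mean(y)), True
    if curve.flat:
        return float(np.mean(y)), True
    return compute_ri(curve, float(x.min()), float(x.max())), False


def compute_css_s(
    matrix: DoseResponseMatrix,
    *,
    s_variant: str = "max",
) -> SensitivityResult:
    """CSS and S for one block.

    Fits both monotherapies, forms the two CSS slice components with each
    partner fixed at its relative IC50, averages them into CSS, and sets
    S = CSS - RI_single where RI_single is max (default), mean or sum of
    the two monotherapy RIs depending on ``s_variant``.
    """
    if s_variant not in S_VARIANTS:
        raise InvalidInputError(f"s_variant must be one of {S_VARIANTS}")
    curve_r, curve_c = matrix.fit_monotherapies()
    ri_row, ri_col = compute_ri(curve_r), compute_ri(curve_c)

    # partner fixed at its IC50: the col-varying slice fixes drug_row
    val_row_fixed, deg1 = css_slice(matrix, "row", curve_r.m)
    val_col_fixed, deg2 = css_slice(matrix, "col", curve_c.m)
    css = 0.5 * (val_row_fixed + val_col_fixed)

    if s_variant == "max":
        ri_single = max(ri_row, ri_col)
    elif s_variant == "mean":
        ri_single = 0.5 * (ri_row + ri_col)
    else:
        ri_single = ri_row + ri_col
    return SensitivityResult(
        block_id=matrix.block_id,
        ri_row=ri_row, ri_col=ri_col,
        ic50_row=curve_r.m, ic50_col=curve_c.m,
        css_row_slice=val_row_fixed, css_col_slice=val_col_fixed,
        css=css, s=css - ri_single, s_variant=s_variant,
        degenerate_slices=int(deg1) + int(deg2),
    )


def ss_points(
    results: Sequence[tuple[SensitivityResult, SynergyResult]],
    *,
    synergy_metric: str = "s",
) -> list[dict]:
    """Coordinates for the synergy-sensitivity (SS) scatter plot.

    One point per block: x = the chosen synergy metric (the S score by
    default, or any of the four model means), y = CSS.  Input order is
    preserved; labels carry block and cell-line identity.
    """
    if not results:
        raise InvalidInputError("ss_points needs at least one scored block")
    if synergy_metric != "s" and synergy_metric not in SYNERGY_MODELS:
        raise InvalidInputError(
            f"synergy_metric must be 's' or one of {SYNERGY_MODELS}"
        )
    points = []
    for sens, syn in results:
        x = sens.s if synergy_metric == "s" else syn.mean[synergy_metric]
        points.append({
            "synergy": float(x), "css": float(sens.css),
            "block_id": sens.block_id, "cell_line": syn.cell_line,
        })
    return points


def ss_points_json(points: list[dict]) -> str:
    return json.dumps({"metric_x": "synergy", "metric_y": "css",
                       "points": points})


def score_distributions(
    grouped: Mapping[str, Iterable[float]],
    *,
    bins: int = 20,
) -> pd.DataFrame:
    """Distribution summaries of a score, keyed by drug or cell line.

    Per key: n, mean, median, quartiles, min, max and histogram bin counts.
    Keys with no finite values are dropped with a warning.
    """
    import warnings

    rows = []
    for key, values in grouped.items():
        v = np.asarray(list(values), dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            warnings.warn(f"score_distributions: key {key!r} has no finite "
                          "values; dropped", stacklevel=2)
            continue
        counts, edges = np.histogram(v, bins=bins)
        rows.append({
            "key": key, "n": int(v.size),
            "mean": float(v.mean()), "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)), "q3": float(np.percentile(v, 75)),
            "min": float(v.min()), "max": float(v.max()),
            "hist_counts": counts.tolist(), "hist_edges": edges.tolist(),
        })
    return pd.DataFrame(rows)


def summary_table(
    results: Sequence[tuple[SensitivityResult, SynergyResult]],
) -> pd.DataFrame:
    """One row per block: IC50s, RI pair, CSS, S and the four synergy means."""
    rows = []
    for sens, syn in results:
        row = syn.summary_row()
        row.update({
            "ic50_row": sens.ic50_row, "ic50_col": sens.ic50_col,
            "ri_row": sens.ri_row, "ri_col": sens.ri_col,
            "css": sens.css, "s": sens.s,
        })
        rows.append(row)
    return pd.DataFrame(rows)
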