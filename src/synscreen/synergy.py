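"""Synergy scoring of two-drug checkerboard matrices.

A combination block is a factorial dose grid: row axis = drug_row doses,
column axis = drug_col doses, each axis including the zero dose, with a
percent-inhibition response per well.  Row 0 / column 0 therefore hold the
two monotherapies and the (0, 0) corner is the untreated control.

Four non-interaction reference models are implemented:

* Bliss  — probabilistic independence, expected fraction f1 + f2 - f1*f2;
* HSA    — highest single agent, expected effect max(y1, y2);
* Loewe  — dose additivity: the combination behaves like a drug combined
  with itself, solving x1/X1(y) + x2/X2(y) = 1 for the expected effect y;
* ZIP    — departure from the Bliss product of potency-shifted log-logistic
  fits along matrix rows and columns.

The per-dose synergy score (delta) is observed minus expected, in
percentage points; the block summary is the mean delta over interior
(both doses positive) cells.  Statistical significance of per-dose scores
is deliberately not computed: typical screens lack replicates, so no
well-level error model is identifiable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dose_response import (
    InvalidInputError,
    MonotherapyCurve,
    fit_curve,
    predict_response,
)

__all__ = [
    "DoseResponseMatrix",
    "SynergyResult",
    "bliss_expected",
    "hsa_expected",
    "loewe_expected",
    "zip_delta",
    "score_block",
    "landscape",
    "SYNERGY_MODELS",
]

SYNERGY_MODELS = ("bliss", "loewe", "hsa", "zip")

LOEWE_Y_TOL = 1e-10
LOEWE_EDGE_EPS = 1e-9
CONTROL_TOL = 1.0  # pp tolerance on the untreated-control well


@dataclass
class DoseResponseMatrix:
    """One checkerboard block: dose axes (including 0) and response grid."""

    conc_r: np.ndarray          # drug_row doses, sorted ascending, starts at 0
    conc_c: np.ndarray          # drug_col doses
    response: np.ndarray        # shape (len(conc_r), len(conc_c)), NaN = missing
    drug_row: str = "drug_row"
    drug_col: str = "drug_col"
    cell_line: str = "cell"
    block_id: str = "block"
    unit: str = "uM"
    replicate_counts: np.ndarray | None = None
    control_missing: bool = False

    def __post_init__(self) -> None:
        self.conc_r = np.asarray(self.conc_r, dtype=float)
        self.conc_c = np.asarray(self.conc_c, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != (self.conc_r.size, self.conc_c.size):
            raise InvalidInputError(
                f"response grid shape {self.response.shape} does not match "
                f"axes ({self.conc_r.size}, {self.conc_c.size}) in block {self.block_id}"
            )
        for name, axis in (("conc_r", self.conc_r), ("conc_c", self.conc_c)):
            if np.any(np.diff(axis) <= 0):
                raise InvalidInputError(
                    f"{name} must be strictly increasing in block {self.block_id}"
                )
            if np.any(axis < 0):
                raise InvalidInputError(f"negative dose on {name}")

    @property
    def has_zero_row(self) -> bool:
        return self.conc_r[0] == 0.0

    @property
    def has_zero_col(self) -> bool:
        return self.conc_c[0] == 0.0

    def monotherapy(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(doses, responses) of one drug alone, taken from the zero row/column."""
        if which == "row":
            if not self.has_zero_col:
                raise InvalidInputError(
                    f"no zero column: monotherapy of {self.drug_row} unavailable"
                )
            return self.conc_r[1:] if self.has_zero_row else self.conc_r, \
                self.response[1:, 0] if self.has_zero_row else self.response[:, 0]
        if which == "col":
            if not self.has_zero_row:
                raise InvalidInputError(
                    f"no zero row: monotherapy of {self.drug_col} unavailable"
                )
            return self.conc_c[1:] if self.has_zero_col else self.conc_c, \
                self.response[0, 1:] if self.has_zero_col else self.response[0, :]
        raise ValueError("which must be 'row' or 'col'")

    def fit_monotherapies(self) -> tuple[MonotherapyCurve, MonotherapyCurve]:
        xr, yr = self.monotherapy("row")
        xc, yc = self.monotherapy("col")
        okr, okc = np.isfinite(yr), np.isfinite(yc)
        curve_r = fit_curve(xr[okr], yr[okr], unit=self.unit, block_id=self.block_id)
        curve_c = fit_curve(xc[okc], yc[okc], unit=self.unit, block_id=self.block_id)
        return curve_r, curve_c

    def interior(self) -> np.ndarray:
        """Sub-grid where both doses are positive."""
        r0 = 1 if self.has_zero_row else 0
        c0 = 1 if self.has_zero_col else 0
        return self.response[r0:, c0:]

    def transposed(self) -> "DoseResponseMatrix":
        return DoseResponseMatrix(
            conc_r=self.conc_c.copy(), conc_c=self.conc_r.copy(),
            response=self.response.T.copy(),
            drug_row=self.drug_col, drug_col=self.drug_row,
            cell_line=self.cell_line, block_id=self.block_id, unit=self.unit,
        )


@dataclass
class SynergyResult:
    """Per-dose delta grids, summary means and upsampled landscapes."""

    block_id: str
    drug_row: str
    drug_col: str
    cell_line: str
    conc_r: np.ndarray          # positive doses only (interior axes)
    conc_c: np.ndarray
    delta: dict[str, np.ndarray] = field(default_factory=dict)
    mean: dict[str, float] = field(default_factory=dict)
    landscapes: dict[str, np.ndarray] = field(default_factory=dict)
    loewe_capped: np.ndarray | None = None
    completeness: float = 1.0

    def summary_row(self) -> dict:
        row = {
            "block_id": self.block_id, "drug_row": self.drug_row,
            "drug_col": self.drug_col, "cell_line": self.cell_line,
        }
        row.update({f"synergy_{k}": self.mean.get(k, float("nan"))
                    for k in SYNERGY_MODELS})
        return row

    def to_json(self, model: str) -> str:
        """One model's delta grid + summary as a JSON document."""
        return json.dumps({
            "block_id": self.block_id,
            "model": model,
            "drug_row": self.drug_row,
            "drug_col": self.drug_col,
            "cell_line": self.cell_line,
            "conc_r": self.conc_r.tolist(),
            "conc_c": self.conc_c.tolist(),
            "delta": [[None if not np.isfinite(v) else v for v in row]
                      for row in self.delta[model]],
            "summary": self.mean[model],
        })


def bliss_expected(f1: float, f2: float) -> float:
    """Bliss independence: expected combined fraction f1 + f2 - f1*f2.

    Monotherapy fractions are clamped to [0, 1] before combining so the
    probabilistic semantics hold even for noisy inputs.
    """
    if not (np.isfinite(f1) and np.isfinite(f2)):
        raise InvalidInputError("non-finite Bliss input")
    a = min(max(f1, 0.0), 1.0)
    b = min(max(f2, 0.0), 1.0)
    return a + b - a * b


def hsa_expected(y1: float, y2: float) -> float:
    """Highest single agent: the better monotherapy effect."""
    if not (np.isfinite(y1) and np.isfinite(y2)):
        raise InvalidInputError("non-finite HSA input")
    return max(y1, y2)


def _inverse_dose(curve: MonotherapyCurve, y: float) -> float:
    """Dose X(y) at which the curve attains effect y (interior of range)."""
    ratio = (y - curve.d_min) / (curve.d_max - y)
    return curve.m * ratio ** (1.0 / curve.lam)


def loewe_expected(
    curve1: MonotherapyCurve,
    curve2: MonotherapyCurve,
    x1: float,
    x2: float,
) -> tuple[float, bool]:
    """Loewe-additive expected effect at doses (x1, x2).

    Solves x1/X1(y) + x2/X2(y) = 1 for y by bisection over the shared
    attainable effect interval; the left side is strictly decreasing in y
    for monotone increasing curves, so the root is unique.  Returns
    (effect, capped): ``capped`` is True when no root exists inside the
    interval and the nearer boundary is returned instead.
    """
    if x1 < 0 or x2 < 0:
        raise InvalidInputError("negative dose")
    if x1 == 0 and x2 == 0:
        raise InvalidInputError("Loewe expectation needs at least one positive dose")
    if x2 == 0:
        return float(predict_response(curve1, x1)), False
    if x1 == 0:
        return float(predict_response(curve2, x2)), False
    if curve1.flat or curve2.flat:
        raise InvalidInputError("Loewe expectation needs non-flat curves")

    lo = max(min(curve1.d_min, curve1.d_max), min(curve2.d_min, curve2.d_max))
    hi = min(max(curve1.d_min, curve1.d_max), max(curve2.d_min, curve2.d_max))
    if not lo < hi:  # non-overlapping attainable ranges
        return (lo if abs(lo) < abs(hi) else hi), True

    span = hi - lo
    a, b = lo + LOEWE_EDGE_EPS * span, hi - LOEWE_EDGE_EPS * span

    def g(y: float) -> float:
        return x1 / _inverse_dose(curve1, y) + x2 / _inverse_dose(curve2, y) - 1.0

    ga, gb = g(a), g(b)
    if ga < 0:      # even the weakest shared effect over-accounts the doses
        return a, True
    if gb > 0:      # doses exceed what the shared range can express
        return b, True
    while b - a > LOEWE_Y_TOL:
        mid = 0.5 * (a + b)
        if g(mid) > 0:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b), False


def zip_delta(
    matrix: DoseResponseMatrix,
    curve_r: MonotherapyCurve,
    curve_c: MonotherapyCurve,
) -> np.ndarray:
    """ZIP per-dose delta grid over the interior cells, in percentage points.

    For each interior cell (x1, x2) the observed surface is smoothed by two
    potency-shift fits: a log-logistic along the row (drug_col varying) with
    the zero-dose asymptote pinned to the fitted monotherapy effect y_r(x1),
    and symmetrically along the column pinned to y_c(x2).  The cell's fitted
    effect is the mean of the two directional fits (each as a fraction);
    delta is that mean minus the Bliss product of the monotherapy fractions.
    Slices with fewer than two finite interior cells are skipped and the
    cell falls back to the remaining direction; cells with neither are NaN.
    """
    r0 = 1 if matrix.has_zero_row else 0
    c0 = 1 if matrix.has_zero_col else 0
    rows = matrix.conc_r[r0:]
    cols = matrix.conc_c[c0:]
    if rows.size == 0 or cols.size == 0:
        raise InvalidInputError(f"block {matrix.block_id} has no interior cells")
    obs = matrix.response[r0:, c0:]

    y_r = np.atleast_1d(predict_response(curve_r, rows))   # effect of drug_row alone
    y_c = np.atleast_1d(predict_response(curve_c, cols))

    fit_along_row = np.full(obs.shape, np.nan)   # row i: response vs cols
    fit_along_col = np.full(obs.shape, np.nan)

    for i, x1 in enumerate(rows):
        ok = np.isfinite(obs[i, :])
        if np.unique(cols[ok]).size < 2:
            continue
        try:
            slice_curve = fit_curve(cols[ok], obs[i, ok], unit=matrix.unit,
                                    block_id=matrix.block_id, pin_d_min=float(y_r[i]))
        except InvalidInputError:
            continue
        fit_along_row[i, :] = np.atleast_1d(predict_response(slice_curve, cols))
    for j, x2 in enumerate(cols):
        ok = np.isfinite(obs[:, j])
        if np.unique(rows[ok]).size < 2:
            continue
        try:
            slice_curve = fit_curve(rows[ok], obs[ok, j], unit=matrix.unit,
                                    block_id=matrix.block_id, pin_d_min=float(y_c[j]))
        except InvalidInputError:
            continue
        fit_along_col[:, j] = np.atleast_1d(predict_response(slice_curve, rows))

    with np.errstate(invalid="ignore"):
        fitted = np.nanmean(np.stack([fit_along_row, fit_along_col]), axis=0)
    fitted[~np.isfinite(obs)] = np.nan   # no observation -> no score

    f1 = np.clip(y_r / 100.0, 0.0, 1.0)[:, None]
    f2 = np.clip(y_c / 100.0, 0.0, 1.0)[None, :]
    expected = (f1 + f2 - f1 * f2) * 100.0
    return fitted - expected


def score_block(
    matrix: DoseResponseMatrix,
    *,
    models: Sequence[str] = SYNERGY_MODELS,
    expected_from: str = "fitted",
    upsample: int = 10,
) -> SynergyResult:
    """Score one block under the requested reference models.

    Monotherapy curves are fitted from the zero row/column; expected
    effects are evaluated from the fitted curves at the matrix doses
    (``expected_from="observed"`` uses the raw monotherapy wells instead).
    Delta grids cover the interior cells; each summary is the mean over
    finite interior cells.
    """
    curve_r, curve_c = matrix.fit_monotherapies()
    r0 = 1 if matrix.has_zero_row else 0
    c0 = 1 if matrix.has_zero_col else 0
    rows, cols = matrix.conc_r[r0:], matrix.conc_c[c0:]
    obs = matrix.response[r0:, c0:]

    if expected_from == "fitted":
        y_r = np.atleast_1d(predict_response(curve_r, rows))
        y_c = np.atleast_1d(predict_response(curve_c, cols))
    elif expected_from == "observed":
        xr, yr = matrix.monotherapy("row")
        xc, yc = matrix.monotherapy("col")
        y_r = np.interp(rows, xr, yr)
        y_c = np.interp(cols, xc, yc)
    else:
        raise ValueError("expected_from must be 'fitted' or 'observed'")

    result = SynergyResult(
        block_id=matrix.block_id, drug_row=matrix.drug_row,
        drug_col=matrix.drug_col, cell_line=matrix.cell_line,
        conc_r=rows.copy(), conc_c=cols.copy(),
    )
    result.completeness = float(np.mean(np.isfinite(obs))) if obs.size else 0.0

    for model in models:
        if model == "bliss":
            f1 = np.clip(y_r / 100.0, 0.0, 1.0)[:, None]
            f2 = np.clip(y_c / 100.0, 0.0, 1.0)[None, :]
            expected = (f1 + f2 - f1 * f2) * 100.0
            delta = obs - expected
        elif model == "hsa":
            expected = np.maximum(y_r[:, None], y_c[None, :])
            delta = obs - expected
        elif model == "loewe":
            expected = np.full(obs.shape, np.nan)
            capped = np.zeros(obs.shape, dtype=bool)
            for i, x1 in enumerate(rows):
                for j, x2 in enumerate(cols):
                    if not np.isfinite(obs[i, j]):
                        continue
                    try:
                        expected[i, j], capped[i, j] = loewe_expected(
                            curve_r, curve_c, float(x1), float(x2))
                    except InvalidInputError:
                        expected[i, j] = np.nan
            delta = obs - expected
            result.loewe_capped = capped
        elif model == "zip":
            delta = zip_delta(matrix, curve_r, curve_c)
        else:
            raise ValueError(f"unknown synergy model: {model}")
        delta = np.where(np.isfinite(obs), delta, np.nan)
        result.delta[model] = delta
        finite = delta[np.isfinite(delta)]
        result.mean[model] = float(finite.mean()) if finite.size else float("nan")
        if np.isfinite(delta).sum() >= 4 and rows.size >= 2 and cols.size >= 2:
            result.landscapes[model] = landscape(delta, rows, cols,
                                                 factor=upsample)[0]
    return result


def landscape(
    delta: np.ndarray,
    conc_r: np.ndarray,
    conc_c: np.ndarray,
    *,
    factor: int = 10,
) -> tuple[np.ndarray, tuple[int, int], tuple[int, int]]:
    """Upsampled synergy surface over the log10-dose plane.

    Bilinear interpolation of the delta grid on log10 dose coordinates,
    ``factor`` x per axis; also returns the (row, col) indices of the most
    synergistic (argmax) and most antagonistic (argmin) raw cells.
    """
    delta = np.asarray(delta, dtype=float)
    if not np.isfinite(delta).any():
        raise InvalidInputError("landscape needs at least one finite delta cell")
    if delta.shape[0] < 2 or delta.shape[1] < 2:
        raise InvalidInputError("landscape needs at least a 2x2 grid")
    tr = np.log10(np.asarray(conc_r, dtype=float))
    tc = np.log10(np.asarray(conc_c, dtype=float))

    def _subdivide(t: np.ndarray) -> np.ndarray:
        # factor sub-steps per interval; original nodes land exactly on the
        # dense axis at indices i * factor
        parts = [np.linspace(t[i], t[i + 1], factor + 1)[:-1]
                 for i in range(t.size - 1)]
        return np.concatenate(parts + [t[-1:]])

    dense_r = _subdivide(tr)
    dense_c = _subdivide(tc)
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator((tr, tc), delta, method="linear",
                                     bounds_error=False, fill_value=None)
    grid_r, grid_c = np.meshgrid(dense_r, dense_c, indexing="ij")
    dense = interp(np.stack([grid_r.ravel(), grid_c.ravel()], axis=1))
    dense = dense.reshape(grid_r.shape)
    imax = np.unravel_index(np.nanargmax(delta), delta.shape)
    imin = np.unravel_index(np.nanargmin(delta), delta.shape)
    return dense, (int(imax[0]), int(imax[1])), (int(imin[0]), int(imin[1]))
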