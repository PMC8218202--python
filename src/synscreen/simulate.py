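"""Synthetic screens with known ground truth.

Every scorer in this package is exercised against simulated checkerboard
blocks: two log-logistic monotherapy curves define the zero row/column,
the interior is filled from a chosen non-interaction model (Bliss/ZIP
product, HSA max, or the Loewe sham where one drug is combined with
itself) plus an optional constant synergy offset, and i.i.d. Gaussian
noise on the percent-inhibition scale emulates well-to-well variability.
The untreated control is 0 by normalization.  Plate artefacts
(edge effects, spatial drift) and heteroscedastic noise are deliberately
not modelled.

Randomness everywhere comes from :func:`numpy.random.default_rng` seeded
through the spec, so identical seeds give identical screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dose_response import InvalidInputError, MonotherapyCurve, predict_response
from .qc import ScreenRecord
from .synergy import DoseResponseMatrix

__all__ = [
    "CurveParams",
    "SimSpec",
    "SimulatedScreen",
    "simulate_block",
    "simulate_monotherapy",
    "simulate_screen",
    "INTERACTIONS",
]

INTERACTIONS = ("bliss_null", "hsa_null", "loewe_sham", "zip_null", "offset")

N_FINGERPRINT_BITS = 166   # MACCS key length


@dataclass(frozen=True)
class CurveParams:
    """True monotherapy parameters of one simulated drug."""

    d_min: float = 0.0
    d_max: float = 100.0
    m: float = 1.0
    lam: float = 1.0

    def curve(self, c_lo: float, c_hi: float, unit: str = "uM") -> MonotherapyCurve:
        return MonotherapyCurve(d_min=self.d_min, d_max=self.d_max,
                                m=self.m, lam=self.lam,
                                c_lo=c_lo, c_hi=c_hi, unit=unit)


@dataclass(frozen=True)
class SimSpec:
    """Recipe for one simulated checkerboard block.

    Dose grids are log-spaced over [c_lo, c_hi] (positive doses; the zero
    dose is added automatically).  ``interaction`` names the generating
    model; ``offset`` adds a constant synergy (pp) to every interior cell
    ("offset" alone means Bliss null + offset).  ``noise_sd`` applies to
    interior wells, ``mono_noise_sd`` to the monotherapy wells.
    """

    drug1: CurveParams = CurveParams(m=1.0, lam=1.2)
    drug2: CurveParams = CurveParams(m=5.0, lam=0.8)
    n_doses1: int = 5
    n_doses2: int = 5
    c_lo1: float = 0.01
    c_hi1: float = 100.0
    c_lo2: float = 0.05
    c_hi2: float = 500.0
    interaction: str = "bliss_null"
    offset: float = 0.0
    noise_sd: float = 0.0
    mono_noise_sd: float = 0.0
    seed: int = 0
    unit: str = "uM"
    block_id: str = "sim-block"
    drug_row: str = "drugA"
    drug_col: str = "drugB"
    cell_line: str = "CL-1"

    def doses(self) -> tuple[np.ndarray, np.ndarray]:
        d1 = np.logspace(np.log10(self.c_lo1), np.log10(self.c_hi1), self.n_doses1)
        d2 = np.logspace(np.log10(self.c_lo2), np.log10(self.c_hi2), self.n_doses2)
        return d1, d2


def _interaction_surface(spec: SimSpec, d1: np.ndarray, d2: np.ndarray,
                         y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    """Noiseless expected interior grid under the spec's interaction model."""
    if spec.interaction in ("bliss_null", "zip_null", "offset"):
        # the Bliss product of log-logistic monotherapies is also the ZIP
        # null: each slice is again log-logistic with a shifted baseline
        f1 = np.clip(y1 / 100.0, 0.0, 1.0)[:, None]
        f2 = np.clip(y2 / 100.0, 0.0, 1.0)[None, :]
        base = (f1 + f2 - f1 * f2) * 100.0
    elif spec.interaction == "hsa_null":
        base = np.maximum(y1[:, None], y2[None, :])
    elif spec.interaction == "loewe_sham":
        # one drug combined with itself: requires both axes on one curve
        curve = spec.drug1.curve(min(spec.c_lo1, spec.c_lo2),
                                 max(spec.c_hi1, spec.c_hi2), spec.unit)
        total = d1[:, None] + d2[None, :]
        base = np.asarray(predict_response(curve, total))
    else:
        raise InvalidInputError(
            f"unknown interaction model {spec.interaction!r}; "
            f"expected one of {INTERACTIONS}")
    return base + spec.offset


def simulate_block(
    spec: SimSpec,
    rng: np.random.Generator | None = None,
) -> tuple[DoseResponseMatrix, dict]:
    """Generate one checkerboard block and its ground truth.

    Returns the matrix (axes including the zero dose, control = 0) and a
    ground-truth record holding the noiseless expected grid and the true
    curve parameters.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    d1, d2 = spec.doses()
    curve1 = spec.drug1.curve(d1[0], d1[-1], spec.unit)
    if spec.interaction == "loewe_sham":
        curve2 = spec.drug1.curve(d2[0], d2[-1], spec.unit)
    else:
        curve2 = spec.drug2.curve(d2[0], d2[-1], spec.unit)
    y1 = np.atleast_1d(predict_response(curve1, d1))
    y2 = np.atleast_1d(predict_response(curve2, d2))
    interior = _interaction_surface(spec, d1, d2, y1, y2)

    n_r, n_c = d1.size + 1, d2.size + 1
    grid = np.zeros((n_r, n_c))
    grid[1:, 0] = y1
    grid[0, 1:] = y2
    grid[1:, 1:] = interior
    truth_grid = grid.copy()

    if spec.mono_noise_sd > 0:
        grid[1:, 0] += rng.normal(0.0, spec.mono_noise_sd, d1.size)
        grid[0, 1:] += rng.normal(0.0, spec.mono_noise_sd, d2.size)
    if spec.noise_sd > 0:
        grid[1:, 1:] += rng.normal(0.0, spec.noise_sd, interior.shape)

    matrix = DoseResponseMatrix(
        conc_r=np.concatenate([[0.0], d1]),
        conc_c=np.concatenate([[0.0], d2]),
        response=grid,
        drug_row=spec.drug_row, drug_col=spec.drug_col,
        cell_line=spec.cell_line, block_id=spec.block_id, unit=spec.unit,
    )
    truth = {
        "spec": spec,
        "noiseless": truth_grid,
        "curve_row": curve1,
        "curve_col": curve2,
        "offset": spec.offset,
        "interaction": spec.interaction,
    }
    return matrix, truth


def simulate_monotherapy(
    params: CurveParams,
    doses: Sequence[float],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noisy single-agent responses at the given doses."""
    doses = np.asarray(doses, dtype=float)
    curve = params.curve(doses[doses > 0].min(), doses.max())
    y = np.atleast_1d(predict_response(curve, doses))
    return y + rng.normal(0.0, noise_sd, y.shape)


@dataclass
class SimulatedScreen:
    """A whole synthetic study: wells plus feature side-tables."""

    records: list[ScreenRecord]
    fingerprints: pd.DataFrame     # drugs x 166 bits
    expression: pd.DataFrame       # cell lines x genes
    ground_truth: list[dict]

    def to_frame(self) -> pd.DataFrame:
        from .qc import records_to_frame

        return records_to_frame(self.records)


def _default_spec_generator(rng: np.random.Generator,
                            drugs: Sequence[str],
                            cells: Sequence[str],
                            drug_potency: dict[str, CurveParams],
                            cell_shift: dict[str, float],
                            noise_sd: float) -> Callable[[int], SimSpec]:
    """Blocks drawn from a drug panel with per-cell potency shifts.

    A drug's curve in a given cell line is its panel curve with the
    inflection dose scaled by the cell's sensitivity factor — the
    deterministic drug/cell structure a predictor is expected to learn.
    """

    def gen(i: int) -> SimSpec:
        a, b = rng.choice(len(drugs), size=2, replace=False)
        da, db = drugs[a], drugs[b]
        cell = cells[rng.integers(len(cells))]
        shift = cell_shift[cell]
        p1 = drug_potency[da]
        p2 = drug_potency[db]
        p1 = replace(p1, m=p1.m * shift)
        p2 = replace(p2, m=p2.m * shift)
        return SimSpec(
            drug1=p1, drug2=p2,
            c_lo1=p1.m / 30, c_hi1=p1.m * 30,
            c_lo2=p2.m / 30, c_hi2=p2.m * 30,
            interaction="bliss_null", noise_sd=noise_sd,
            block_id=f"B{i:05d}", drug_row=da, drug_col=db,
            cell_line=cell, seed=int(rng.integers(2 ** 31)),
        )

    return gen


def simulate_screen(
    n_blocks: int,
    spec_generator: Callable[[int], SimSpec] | None = None,
    seed: int = 0,
    *,
    n_drugs: int = 12,
    n_cells: int = 8,
    n_genes: int = 200,
    noise_sd: float = 5.0,
) -> SimulatedScreen:
    """Generate a long-format screen with feature side-tables.

    Drugs come from a synthetic compound list with random 166-bit
    fingerprint vectors; cell lines from a synthetic panel with a random
    expression matrix.  Each block is a full checkerboard (axes including
    zero) whose wells become :class:`ScreenRecord` rows.
    """
    if n_blocks < 1:
        raise InvalidInputError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    drugs = [f"D{i:03d}" for i in range(n_drugs)]
    cells = [f"CL{i:03d}" for i in range(n_cells)]
    genes = [f"G{i:04d}" for i in range(n_genes)]

    fingerprints = pd.DataFrame(
        rng.integers(0, 2, size=(n_drugs, N_FINGERPRINT_BITS)),
        index=drugs, columns=[f"maccs_{k}" for k in range(N_FINGERPRINT_BITS)],
    )
    expression = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n_cells, n_genes)) * rng.uniform(
            0.2, 2.0, size=(1, n_genes)),
        index=cells, columns=genes,
    )

    drug_potency = {
        d: CurveParams(d_min=0.0,
                       d_max=float(rng.uniform(60, 100)),
                       m=float(10 ** rng.uniform(-1.5, 1.5)),
                       lam=float(rng.uniform(0.7, 2.0)))
        for d in drugs
    }
    cell_shift = {c: float(10 ** rng.uniform(-0.5, 0.5)) for c in cells}

    if spec_generator is None:
        spec_generator = _default_spec_generator(
            rng, drugs, cells, drug_potency, cell_shift, noise_sd)

    records: list[ScreenRecord] = []
    truths: list[dict] = []
    for i in range(n_blocks):
        spec = spec_generator(i)
        matrix, truth = simulate_block(spec)
        truths.append(truth)
        for ri, cr in enumerate(matrix.conc_r):
            for ci, cc in enumerate(matrix.conc_c):
                records.append(ScreenRecord(
                    block_id=matrix.block_id,
                    drug_row=matrix.drug_row, drug_col=matrix.drug_col,
                    conc_r=float(cr), conc_c=float(cc),
                    response=float(matrix.response[ri, ci]),
                    cell_line=matrix.cell_line, unit=matrix.unit,
                    study_id="SIM",
                ))
    return SimulatedScreen(records=records, fingerprints=fingerprints,
                           expression=expression, ground_truth=truths)
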