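"""Baseline machine-learning prediction of dose-level response and synergy.

A gradient-boosted decision-tree regressor (LightGBM) is trained per
target — percent inhibition, and optionally the per-dose synergy deltas
of each reference model — from features combining:

* drug and cell-line identities as categorical features;
* the two concentrations as both numeric and categorical features;
* 166-bit MACCS structural fingerprints per drug;
* expression values of the most variant genes (top 5% by variance across
  the cell panel by default).

Only the four hyperparameters that matter most for boosted trees are
exposed: number of trees, maximum depth, learning rate and L2 leaf
regularization; everything else stays at backend defaults.  Prediction
for a new drug pair fills a 10x10 equally spaced dose grid within
user-given maximal concentrations.

The module also ranks candidate expression biomarkers by correlating each
gene with a per-cell sensitivity score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import InvalidInputError
from .qc import ScreenRecord, assemble_blocks
from .synergy import SYNERGY_MODELS, score_block

__all__ = [
    "FEATURE_LAYOUT_VERSION",
    "select_variant_genes",
    "build_features",
    "train_model",
    "ModelBundle",
    "train_bundle",
    "predict_grid",
    "rank_biomarkers",
    "fingerprints_from_smiles",
]

FEATURE_LAYOUT_VERSION = "1"
N_FINGERPRINT_BITS = 166

DEFAULT_HYPERPARAMS = {
    "n_trees": 500,
    "max_depth": 6,
    "learning_rate": 0.1,
    "l2_leaf_reg": 3.0,
}

GRID_SIZE = 10


class LookupFeatureError(InvalidInputError):
    """A drug or cell-line identifier has no feature-store entry."""


def select_variant_genes(expr: pd.DataFrame, top_frac: float = 0.05) -> list[str]:
    """Most variant genes across the cell panel.

    Genes are ranked by variance across cell lines (descending, ties
    broken by gene identifier); the top ``ceil(top_frac * n_genes)`` are
    returned.  An all-constant matrix yields an empty list with a warning.
    """
    if expr.shape[0] < 2:
        raise InvalidInputError("need >= 2 cell lines to rank gene variance")
    var = expr.var(axis=0, ddof=1)
    if (var == 0).all():
        warnings.warn("all genes constant; no variant genes selected",
                      stacklevel=2)
        return []
    k = math.ceil(top_frac * expr.shape[1])
    order = sorted(expr.columns, key=lambda g: (-var[g], g))
    return order[:k]


def _canonical_order(drug_row: str, drug_col: str, conc_r: float,
                     conc_c: float) -> tuple[str, str, float, float]:
    """Lexicographic drug-slot ordering so (A,B) and (B,A) share one row."""
    if drug_col < drug_row:
        return drug_col, drug_row, conc_c, conc_r
    return drug_row, drug_col, conc_r, conc_c


def build_features(
    records: Sequence[ScreenRecord],
    fingerprints: pd.DataFrame,
    expr: pd.DataFrame,
    genes: Sequence[str],
    *,
    targets: Sequence[str] = ("inhibition",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the feature matrix and target table from well records.

    One row per well, with the inhibition target; when synergy model names
    are included in ``targets`` the blocks are scored and each interior
    well additionally carries that model's per-dose delta (monotherapy
    wells get NaN there).  Unknown drug or cell identifiers raise
    :class:`LookupFeatureError` naming the identifier.
    """
    synergy_targets = [t for t in targets if t in SYNERGY_MODELS]
    deltas: dict[str, dict[str, np.ndarray]] = {}
    axes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if synergy_targets:
        for block in assemble_blocks(records):
            res = score_block(block, models=synergy_targets)
            deltas[block.block_id] = res.delta
            axes[block.block_id] = (res.conc_r, res.conc_c)

    fp_cols = list(fingerprints.columns)
    rows = []
    for r in records:
        for drug in (r.drug_row, r.drug_col):
            if drug and drug not in fingerprints.index:
                raise LookupFeatureError(f"no fingerprint for drug {drug!r}")
        if r.cell_line not in expr.index:
            raise LookupFeatureError(f"no expression for cell line {r.cell_line!r}")
        da, db, ca, cb = _canonical_order(r.drug_row, r.drug_col,
                                          r.conc_r, r.conc_c)
        row = {
            "drug_a": da, "drug_b": db, "cell": r.cell_line,
            "conc_a": ca, "conc_b": cb,
            "conc_a_cat": f"{ca:.6g}", "conc_b_cat": f"{cb:.6g}",
        }
        fpa = fingerprints.loc[da] if da else pd.Series(0, index=fp_cols)
        fpb = fingerprints.loc[db] if db else pd.Series(0, index=fp_cols)
        row.update({f"fpa_{c}": int(v) for c, v in fpa.items()})
        row.update({f"fpb_{c}": int(v) for c, v in fpb.items()})
        row.update({f"ex_{g}": float(expr.at[r.cell_line, g]) for g in genes})

        y = {"inhibition": r.response}
        for model in synergy_targets:
            val = np.nan
            if r.conc_r > 0 and r.conc_c > 0 and r.block_id in deltas:
                cr, cc = axes[r.block_id]
                i = np.nonzero(np.isclose(cr, r.conc_r))[0]
                j = np.nonzero(np.isclose(cc, r.conc_c))[0]
                if i.size and j.size:
                    val = deltas[r.block_id][model][i[0], j[0]]
            y[model] = val
        rows.append((row, y))

    X = pd.DataFrame([r for r, _ in rows])
    Y = pd.DataFrame([y for _, y in rows])
    for col in ("drug_a", "drug_b", "cell", "conc_a_cat", "conc_b_cat"):
        X[col] = X[col].astype("category")
    return X, Y


def train_model(
    X: pd.DataFrame,
    y: Sequence[float],
    hyperparams: Mapping[str, float] | None = None,
    *,
    seed: int = 0,
):
    """Fit one gradient-boosted tree regressor to one target column."""
    import lightgbm as lgb

    y = np.asarray(y, dtype=float)
    if len(X) != y.size:
        raise InvalidInputError("feature/target length mismatch")
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    model = lgb.LGBMRegressor(
        n_estimators=int(hp["n_trees"]),
        max_depth=int(hp["max_depth"]),
        learning_rate=float(hp["learning_rate"]),
        reg_lambda=float(hp["l2_leaf_reg"]),
        random_state=seed,
        deterministic=True,
        n_jobs=1,
        verbose=-1,
    )
    model.fit(X, y)
    return model


@dataclass
class ModelBundle:
    """Trained per-target models plus the feature store needed to predict."""

    models: dict
    feature_columns: list[str]
    fingerprints: pd.DataFrame
    expression: pd.DataFrame
    genes: list[str]
    layout_version: str = FEATURE_LAYOUT_VERSION
    hyperparams: dict = field(default_factory=lambda: dict(DEFAULT_HYPERPARAMS))

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        import joblib

        bundle = joblib.load(path)
        if bundle.layout_version != FEATURE_LAYOUT_VERSION:
            raise InvalidInputError(
                f"model bundle layout {bundle.layout_version} != "
                f"current {FEATURE_LAYOUT_VERSION}")
        return bundle


def train_bundle(
    records: Sequence[ScreenRecord],
    fingerprints: pd.DataFrame,
    expr: pd.DataFrame,
    *,
    targets: Sequence[str] = ("inhibition",),
    top_frac: float = 0.05,
    hyperparams: Mapping[str, float] | None = None,
    seed: int = 0,
) -> ModelBundle:
    """Feature assembly + per-target training in one step."""
    genes = select_variant_genes(expr, top_frac)
    X, Y = build_features(records, fingerprints, expr, genes, targets=targets)
    models = {}
    for t in targets:
        ok = np.isfinite(Y[t].to_numpy())
        models[t] = train_model(X[ok], Y.loc[ok, t], hyperparams, seed=seed)
    return ModelBundle(models=models, feature_columns=list(X.columns),
                       fingerprints=fingerprints, expression=expr,
                       genes=list(genes),
                       hyperparams=dict(hyperparams or DEFAULT_HYPERPARAMS))


def dose_grid(max_conc: float, *, spacing: str = "linear") -> np.ndarray:
    """10 equally spaced doses in (0, max]: max/10, 2*max/10, ..., max.

    ``spacing="log"`` gives 10 log-spaced doses over [max/1000, max].
    """
    if max_conc <= 0:
        raise InvalidInputError("maximal concentration must be positive")
    if spacing == "linear":
        return np.linspace(max_conc / GRID_SIZE, max_conc, GRID_SIZE)
    if spacing == "log":
        return np.logspace(np.log10(max_conc) - 3, np.log10(max_conc), GRID_SIZE)
    raise InvalidInputError("spacing must be 'linear' or 'log'")


def predict_grid(
    bundle: ModelBundle,
    drug_a: str,
    drug_b: str,
    max_conc_a: float,
    max_conc_b: float,
    cell: str,
    *,
    spacing: str = "linear",
) -> dict[str, np.ndarray]:
    """Predict 10x10 dose grids for every trained target.

    Grid cell [i, j] corresponds to (dose_a[i], dose_b[j]); dose axes are
    returned under ``"doses_a"`` / ``"doses_b"``.
    """
    for drug in (drug_a, drug_b):
        if drug not in bundle.fingerprints.index:
            raise LookupFeatureError(f"no fingerprint for drug {drug!r}")
    if cell not in bundle.expression.index:
        raise LookupFeatureError(f"no expression for cell line {cell!r}")

    doses_a = dose_grid(max_conc_a, spacing=spacing)
    doses_b = dose_grid(max_conc_b, spacing=spacing)
    records = [
        ScreenRecord(block_id="grid", drug_row=drug_a, drug_col=drug_b,
                     conc_r=float(xa), conc_c=float(xb), response=0.0,
                     cell_line=cell)
        for xa in doses_a for xb in doses_b
    ]
    X, _ = build_features(records, bundle.fingerprints, bundle.expression,
                          bundle.genes)
    X = X[bundle.feature_columns]
    out: dict[str, np.ndarray] = {"doses_a": doses_a, "doses_b": doses_b}
    for target, model in bundle.models.items():
        pred = np.asarray(model.predict(X), dtype=float)
        out[target] = pred.reshape(GRID_SIZE, GRID_SIZE)
    return out


def rank_biomarkers(
    expr: pd.DataFrame,
    sensitivity: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Rank genes by correlation of expression with drug sensitivity.

    ``sensitivity`` maps cell lines to a per-cell sensitivity score (e.g.
    CSS of one combination across a panel).  Each gene's Pearson r with
    the score is computed over the overlapping cell lines; genes are
    ranked by |r| descending.  Zero-variance genes are excluded with a
    flag column rather than silently dropped.
    """
    sens = pd.Series(sensitivity, dtype=float)
    cells = [c for c in expr.index if c in sens.index]
    if len(cells) < 3:
        raise InvalidInputError(
            f"need >= 3 overlapping cell lines, got {len(cells)}")
    E = expr.loc[cells].to_numpy(dtype=float)
    s = sens.loc[cells].to_numpy(dtype=float)

    Ec = E - E.mean(axis=0)
    sc = s - s.mean()
    denom_g = np.sqrt((Ec ** 2).sum(axis=0))
    denom_s = float(np.sqrt((sc ** 2).sum()))
    zero_var = denom_g == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ec * sc[:, None]).sum(axis=0) / (denom_g * denom_s)
    r[zero_var] = np.nan

    table = pd.DataFrame({
        "gene": expr.columns,
        "r": r,
        "n": len(cells),
        "zero_variance": zero_var,
    })
    table = table.sort_values(
        by=["zero_variance", "r"], ascending=[True, True],
        key=lambda col: -col.abs() if col.name == "r" else col,
    ).reset_index(drop=True)
    table["rank"] = np.where(table["zero_variance"], np.nan,
                             np.arange(1, len(table) + 1, dtype=float))
    return table


def fingerprints_from_smiles(smiles: Mapping[str, str]) -> pd.DataFrame:
    """166-bit MACCS keys computed from SMILES structures (needs RDKit)."""
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    rows = {}
    for drug, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise InvalidInputError(f"unparseable SMILES for drug {drug!r}")
        bv = MACCSkeys.GenMACCSKeys(mol)   # 167 bits; bit 0 is unused
        rows[drug] = [int(bv.GetBit(k)) for k in range(1, 167)]
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"maccs_{k}" for k in range(N_FINGERPRINT_BITS)])
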