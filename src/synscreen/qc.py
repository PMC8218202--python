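"""Screen-table ingestion, quality control and harmonization.

The interchange format is a long-format delimited table, one row per well:

    block_id, drug_row, drug_col, conc_r, conc_c, conc_unit, inhibition,
    cell_line_name, study_id, replicate

Monotherapy wells are a subset of a combination experiment where the other
drug is absent (its concentration is 0 or its identifier is empty).  QC
flags wells whose percent inhibition falls strictly outside the plausible
window (|inhibition| > 200 by default); flagged wells are excluded from
scoring but kept in exports with a quality column.  A study-level gate
compares recomputed synergy scores against the scores reported by the
original publication and admits the study only when the correlation
exceeds 0.6.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import InvalidInputError
from .sensitivity import SensitivityResult, compute_css_s
from .synergy import DoseResponseMatrix, SynergyResult, score_block

__all__ = [
    "ScreenRecord",
    "QCReport",
    "read_screen_table",
    "write_screen_table",
    "records_to_frame",
    "frame_to_records",
    "flag_out_of_range",
    "study_gate",
    "assemble_blocks",
    "harmonize_study",
]

CANONICAL_COLUMNS = [
    "block_id", "drug_row", "drug_col", "conc_r", "conc_c", "conc_unit",
    "inhibition", "cell_line_name", "study_id", "replicate",
]
REQUIRED_COLUMNS = ["block_id", "drug_row", "conc_r", "conc_c", "inhibition"]

# case-insensitive header synonyms accepted on input
DEFAULT_ALIASES = {
    "block": "block_id", "blockid": "block_id",
    "drug1": "drug_row", "drug2": "drug_col",
    "conc1": "conc_r", "conc2": "conc_c",
    "conc_row": "conc_r", "conc_col": "conc_c",
    "unit": "conc_unit", "concentration_unit": "conc_unit",
    "response": "inhibition", "percent_inhibition": "inhibition",
    "cell_line": "cell_line_name", "cell": "cell_line_name",
    "study": "study_id", "rep": "replicate",
}
UNIT_SYNONYMS = {
    "um": "uM", "µm": "uM", "μm": "uM",
    "nm": "nM", "mm": "mM", "m": "M", "pm": "pM",
}

RESPONSE_LO = -200.0
RESPONSE_HI = 200.0
STUDY_GATE_R = 0.6

NULL_DRUG = ""   # drug_col for monotherapy rows of the row drug


class SchemaError(InvalidInputError):
    """Input table does not match the expected schema."""


class HarmonizationError(InvalidInputError):
    """Records within one block are mutually inconsistent."""


@dataclass(frozen=True)
class ScreenRecord:
    """One well of a screen: block, drugs, doses, response, provenance."""

    block_id: str
    drug_row: str
    drug_col: str
    conc_r: float
    conc_c: float
    response: float
    cell_line: str = "cell"
    unit: str = "uM"
    study_id: str = ""
    replicate: int | None = None

    @property
    def is_monotherapy(self) -> bool:
        return (self.conc_r == 0.0 or self.conc_c == 0.0
                or self.drug_col == NULL_DRUG or self.drug_row == NULL_DRUG)


@dataclass
class QCReport:
    """Outcome of quality control over one screen table."""

    n_records: int
    n_flagged_range: int
    flagged_ids: list[int]
    completeness: dict[str, float] = field(default_factory=dict)
    study_gate: dict | None = None
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "n_records": self.n_records,
            "n_flagged_range": self.n_flagged_range,
            "flagged_ids": self.flagged_ids,
            "completeness": self.completeness,
            "study_gate": self.study_gate,
            "warnings": self.warnings,
        })


def normalize_unit(unit: str) -> str:
    u = str(unit).strip()
    return UNIT_SYNONYMS.get(u.lower(), u)


def _canonicalize_columns(columns: Iterable[str],
                          aliases: dict[str, str] | None) -> dict[str, str]:
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update({k.lower(): v for k, v in aliases.items()})
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        mapping[col] = table.get(key, key)
    return mapping


def read_screen_table(
    path,
    *,
    sep: str | None = None,
    aliases: dict[str, str] | None = None,
) -> list[ScreenRecord]:
    """Read a long-format screen table into typed records.

    Accepts comma- (default) or tab-delimited text; header names are
    matched case-insensitively with configurable aliases.  Unit strings
    are normalized (uM/µM/nM...).  Row order is preserved.
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    df = df.rename(columns=_canonicalize_columns(df.columns, aliases))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")
    return frame_to_records(df)


def frame_to_records(df: pd.DataFrame) -> list[ScreenRecord]:
    records = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            conc_r = float(d["conc_r"])
            conc_c = float(d.get("conc_c", 0.0))
            response = float(d["inhibition"])
        except (TypeError, ValueError) as exc:
            raise InvalidInputError(
                f"unparseable number at line {line_no}: {exc}") from None
        rep = d.get("replicate")
        rep = None if rep is None or (isinstance(rep, float) and math.isnan(rep)) \
            else int(rep)
        drug_col = d.get("drug_col", NULL_DRUG)
        if drug_col is None or (isinstance(drug_col, float) and math.isnan(drug_col)):
            drug_col = NULL_DRUG
        records.append(ScreenRecord(
            block_id=str(d["block_id"]),
            drug_row=str(d["drug_row"]),
            drug_col=str(drug_col),
            conc_r=conc_r, conc_c=conc_c, response=response,
            cell_line=str(d.get("cell_line_name", "cell")),
            unit=normalize_unit(d.get("conc_unit", "uM")),
            study_id=str(d.get("study_id", "")),
            replicate=rep,
        ))
    return records


def records_to_frame(records: Sequence[ScreenRecord],
                     quality: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.DataFrame([{
        "block_id": r.block_id, "drug_row": r.drug_row, "drug_col": r.drug_col,
        "conc_r": r.conc_r, "conc_c": r.conc_c, "conc_unit": r.unit,
        "inhibition": r.response, "cell_line_name": r.cell_line,
        "study_id": r.study_id,
        "replicate": "" if r.replicate is None else r.replicate,
    } for r in records])
    if quality is not None:
        df["quality"] = list(quality)
    return df


def write_screen_table(records: Sequence[ScreenRecord], path, *,
                       sep: str = ",",
                       quality: Sequence[str] | None = None) -> None:
    # %.17g keeps write->read an identity on float doses/responses
    records_to_frame(records, quality).to_csv(path, sep=sep, index=False,
                                              float_format="%.17g")


def flag_out_of_range(
    records: Sequence[ScreenRecord],
    lo: float = RESPONSE_LO,
    hi: float = RESPONSE_HI,
) -> QCReport:
    """Flag wells with implausible percent inhibition.

    A well is flagged when its response is strictly below ``lo`` or
    strictly above ``hi`` (the bounds themselves pass).  Flagged wells are
    excluded from scoring downstream but retained in exports.
    """
    flagged = [i for i, r in enumerate(records)
               if not np.isfinite(r.response) or r.response < lo or r.response > hi]
    return QCReport(
        n_records=len(records),
        n_flagged_range=len(flagged),
        flagged_ids=flagged,
    )


def study_gate(
    recomputed: Sequence[float],
    reported: Sequence[float],
    *,
    threshold: float = STUDY_GATE_R,
    method: str = "pearson",
) -> tuple[float, bool]:
    """Study-inclusion gate on recomputed-vs-reported synergy agreement.

    Returns (correlation, included) with included = r > threshold
    (strictly).  Fewer than 3 pairs or zero variance makes the gate
    undecidable: r is NaN and the study is not included.
    """
    a = np.asarray(recomputed, dtype=float)
    b = np.asarray(reported, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("recomputed/reported length mismatch")
    if a.size < 3 or not (np.isfinite(a).all() and np.isfinite(b).all()) \
            or a.std() == 0 or b.std() == 0:
        return float("nan"), False
    if method == "pearson":
        r = float(stats.pearsonr(a, b).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(a, b).statistic)
    else:
        raise InvalidInputError("method must be 'pearson' or 'spearman'")
    return r, r > threshold


def assemble_blocks(records: Sequence[ScreenRecord]) -> list[DoseResponseMatrix]:
    """Pivot well-level records into checkerboard matrices, one per block.

    Concentration axes are the sorted unique doses seen in the block
    (including 0 when present); replicate wells are averaged with the
    count recorded; absent wells stay missing.  Blocks are returned in
    order of first appearance.
    """
    order: list[str] = []
    groups: dict[str, list[ScreenRecord]] = {}
    for r in records:
        if r.block_id not in groups:
            groups[r.block_id] = []
            order.append(r.block_id)
        groups[r.block_id].append(r)

    blocks = []
    for block_id in order:
        recs = groups[block_id]
        drugs_row = {r.drug_row for r in recs if r.drug_row != NULL_DRUG}
        drugs_col = {r.drug_col for r in recs if r.drug_col != NULL_DRUG}
        if len(drugs_row) > 1 or len(drugs_col) > 1:
            raise HarmonizationError(
                f"block {block_id} mixes drugs: rows {sorted(drugs_row)}, "
                f"cols {sorted(drugs_col)}")
        units = {r.unit for r in recs}
        if len(units) > 1:
            raise HarmonizationError(
                f"block {block_id} mixes concentration units: {sorted(units)}")
        cells = {r.cell_line for r in recs}
        if len(cells) > 1:
            raise HarmonizationError(
                f"block {block_id} mixes cell lines: {sorted(cells)}")

        conc_r = np.unique([r.conc_r for r in recs])
        conc_c = np.unique([r.conc_c for r in recs])
        grid_sum = np.zeros((conc_r.size, conc_c.size))
        grid_n = np.zeros((conc_r.size, conc_c.size), dtype=int)
        ir = {v: i for i, v in enumerate(conc_r)}
        ic = {v: i for i, v in enumerate(conc_c)}
        seen_unreplicated = set()
        for r in recs:
            i, j = ir[r.conc_r], ic[r.conc_c]
            if r.replicate is None:
                if (i, j) in seen_unreplicated:
                    warnings.warn(
                        f"block {block_id}: duplicate well at "
                        f"({r.conc_r}, {r.conc_c}) without replicate ids; "
                        "averaging", stacklevel=2)
                seen_unreplicated.add((i, j))
            grid_sum[i, j] += r.response
            grid_n[i, j] += 1
        with np.errstate(invalid="ignore"):
            grid = np.where(grid_n > 0, grid_sum / np.maximum(grid_n, 1), np.nan)
        control_missing = bool(
            conc_r[0] == 0 and conc_c[0] == 0 and grid_n[0, 0] == 0)
        blocks.append(DoseResponseMatrix(
            conc_r=conc_r, conc_c=conc_c, response=grid,
            drug_row=next(iter(drugs_row), NULL_DRUG),
            drug_col=next(iter(drugs_col), NULL_DRUG),
            cell_line=next(iter(cells)), block_id=block_id,
            unit=next(iter(units)),
            replicate_counts=grid_n, control_missing=control_missing,
        ))
    return blocks


def harmonize_study(
    records: Sequence[ScreenRecord],
    reported_scores: dict[str, float] | None = None,
    *,
    gate_model: str = "zip",
    s_variant: str = "max",
) -> tuple[list[DoseResponseMatrix], QCReport,
           list[tuple[SensitivityResult, SynergyResult]]]:
    """Full curation pass over one study.

    Runs range QC, assembles blocks from unflagged wells, scores every
    assemblable block for sensitivity (CSS/S) and synergy (four models),
    and — when the study's originally reported scores are supplied as a
    ``{block_id: score}`` mapping — applies the correlation gate on the
    chosen recomputed synergy mean.  Per-block failures are collected in
    the report rather than aborting the study.
    """
    report = flag_out_of_range(records)
    flagged = set(report.flagged_ids)
    clean = [r for i, r in enumerate(records) if i not in flagged]
    blocks = assemble_blocks(clean)
    for b in blocks:
        report.completeness[b.block_id] = float(
            np.mean(np.isfinite(b.response)))

    results: list[tuple[SensitivityResult, SynergyResult]] = []
    for b in blocks:
        try:
            syn = score_block(b)
            sens = compute_css_s(b, s_variant=s_variant)
        except InvalidInputError as exc:
            report.warnings.append(f"block {b.block_id} not scored: {exc}")
            continue
        results.append((sens, syn))

    if reported_scores is not None:
        pairs = [(syn.mean[gate_model], reported_scores[sens.block_id])
                 for sens, syn in results
                 if sens.block_id in reported_scores
                 and np.isfinite(syn.mean[gate_model])]
        if pairs:
            rec, rep = zip(*pairs)
            r, included = study_gate(rec, rep)
        else:
            r, included = float("nan"), False
        report.study_gate = {"pearson_r": r, "included": included,
                             "model": gate_model, "n": len(pairs)}
    return blocks, report, results
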