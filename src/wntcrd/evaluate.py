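"""Model evaluation: RMSE, per-complex comparison tables, range agreement.

The evaluation table mirrors how experimental comparisons are usually
reported for this data: one row per complex with experimental and
predicted binding energy, their absolute difference, both dissociation
constants, both ordinal affinity ranges, and a flag marking complexes
whose experimental and predicted Kd fall in different ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .models import AffinityPrediction
from .search import AffinityMeasurement
from .thermo import AffinityRange, classify_affinity, range_distance

__all__ = [
    "EvaluationRow",
    "RangeAgreementSummary",
    "rmse",
    "evaluation_table",
    "evaluation_frame",
    "compare_models",
]


@dataclass(frozen=True)
class EvaluationRow:
    """One complex's experimental-vs-predicted comparison."""

    complex_id: str
    dg_exp: float
    dg_pred: float
    abs_diff: float
    kd_exp_nm: float
    kd_pred_nm: float
    exp_range: AffinityRange
    pred_range: AffinityRange
    set_label: str
    range_mismatch: bool


@dataclass(frozen=True)
class RangeAgreementSummary:
    """Three-way split of ordinal range distances between two prediction sets."""

    n_compared: int
    fraction_same: float
    fraction_adjacent: float
    fraction_far: float

    def to_dict(self) -> dict:
        return {
            "n_compared": self.n_compared,
            "fraction_same": self.fraction_same,
            "fraction_adjacent": self.fraction_adjacent,
            "fraction_far": self.fraction_far,
        }


def rmse(predicted: Sequence[float], experimental: Sequence[float]) -> float:
    """Root-mean-square error between paired binding energies (kcal/mol)."""
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(experimental, dtype=float)
    if p.shape != e.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {e.shape}")
    if p.size == 0:
        raise ValueError("cannot compute RMSE of empty vectors")
    return float(np.sqrt(np.mean((p - e) ** 2)))


def evaluation_table(
    predictions: Sequence[AffinityPrediction],
    measurements: Sequence[AffinityMeasurement],
) -> list[EvaluationRow]:
    """Per-complex comparison rows, one per prediction, in prediction order.

    Experimental dG is derived from the measured Kd; the mismatch flag is
    set when experimental and predicted Kd occur in different affinity
    ranges.
    """
    by_id = {m.complex_id: m for m in measurements}
    unmatched = [p.complex_id for p in predictions if p.complex_id not in by_id]
    if unmatched:
        raise KeyError(f"predictions without measurements: {unmatched}")
    rows = []
    for pred in predictions:
        m = by_id[pred.complex_id]
        dg_exp = m.dg_exp
        exp_range = classify_affinity(m.kd_nm)
        rows.append(
            EvaluationRow(
                complex_id=pred.complex_id,
                dg_exp=dg_exp,
                dg_pred=pred.dg_kcal_mol,
                abs_diff=abs(dg_exp - pred.dg_kcal_mol),
                kd_exp_nm=m.kd_nm,
                kd_pred_nm=pred.kd_nm,
                exp_range=exp_range,
                pred_range=pred.range_class,
                set_label=m.set_label,
                range_mismatch=exp_range != pred.range_class,
            )
        )
    return rows


def evaluation_frame(rows: Sequence[EvaluationRow]) -> pd.DataFrame:
    """Evaluation rows as a DataFrame with range symbols as strings."""
    return pd.DataFrame(
        {
            "complex": [r.complex_id for r in rows],
            "dG_exp": [r.dg_exp for r in rows],
            "dG_pred": [r.dg_pred for r in rows],
            "abs_diff": [r.abs_diff for r in rows],
            "Kd_exp_nM": [r.kd_exp_nm for r in rows],
            "Kd_pred_nM": [r.kd_pred_nm for r in rows],
            "exp_range": [r.exp_range.symbol for r in rows],
            "pred_range": [r.pred_range.symbol for r in rows],
            "set": [r.set_label for r in rows],
            "range_mismatch": [r.range_mismatch for r in rows],
        }
    )


def compare_models(
    predictions_a: Sequence[AffinityPrediction],
    predictions_b: Sequence[AffinityPrediction],
) -> RangeAgreementSummary:
    """Fraction of complexes predicted in the same / adjacent / farther
    affinity range by two models over the same complexes."""
    a_by_id = {p.complex_id: p for p in predictions_a}
    b_by_id = {p.complex_id: p for p in predictions_b}
    if set(a_by_id) != set(b_by_id):
        only_a = sorted(set(a_by_id) - set(b_by_id))
        only_b = sorted(set(b_by_id) - set(a_by_id))
        raise KeyError(
            f"prediction sets cover different complexes (only in A: {only_a}, "
            f"only in B: {only_b})"
        )
    if not a_by_id:
        raise ValueError("no complexes to compare")
    distances = [
        range_distance(a_by_id[cid].range_class, b_by_id[cid].range_class)
        for cid in a_by_id
    ]
    n = len(distances)
    same = sum(d == 0 for d in distances)
    adjacent = sum(d == 1 for d in distances)
    far = n - same - adjacent
    return RangeAgreementSummary(
        n_compared=n,
        fraction_same=same / n,
        fraction_adjacent=adjacent / n,
        fraction_far=far / n,
    )
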