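"""Exhaustive sign-constrained search for k-descriptor linear models.

The model-building procedure: enumerate every k-descriptor subset with a
fixed class composition (by default exactly one lipid-protein term among
four descriptors), fit ordinary least squares of experimental binding
energy on the training complexes, keep only candidates whose
lipid-protein contribution is favourable (non-positive) on the training
set, and rank the survivors by RMSE on the fixed training/test split.

Everything is deterministic: enumeration order and all tie-breaks are
lexicographic in descriptor names, and the train/test split is taken
verbatim from the measurement table, never re-randomised.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .models import (
    LIPID_PROTEIN,
    PROTEIN_PROTEIN,
    AffinityPrediction,
    DescriptorMatrix,
    LinearAffinityModel,
    ModelTerm,
    lipid_contribution,
    predict_matrix,
)
from .thermo import delta_g_from_kd

__all__ = [
    "AffinityMeasurement",
    "ModelSearchConfig",
    "CandidateEvaluation",
    "SearchResult",
    "enumerate_subsets",
    "fit_least_squares",
    "check_lipid_favourable",
    "count_within_experimental_error",
    "search",
]

TRAINING = "training"
TEST = "test"


@dataclass(frozen=True)
class AffinityMeasurement:
    """An experimental dissociation constant with train/test assignment."""

    complex_id: str
    kd_nm: float
    kd_err_nm: float | None = None
    set_label: str = TRAINING

    def __post_init__(self) -> None:
        if not self.kd_nm > 0:
            raise ValueError(
                f"Kd must be strictly positive, got {self.kd_nm} for {self.complex_id!r}"
            )
        if self.kd_err_nm is not None and self.kd_err_nm < 0:
            raise ValueError(f"Kd error range must be >= 0 for {self.complex_id!r}")
        if self.set_label not in (TRAINING, TEST):
            raise ValueError(
                f"set label must be {TRAINING!r} or {TEST!r}, got {self.set_label!r}"
            )

    @property
    def dg_exp(self) -> float:
        return delta_g_from_kd(self.kd_nm)


@dataclass(frozen=True)
class ModelSearchConfig:
    """Knobs of the model search.

    k: descriptors per model; n_lipid: required lipid-class count;
    sign_mode: "per-sample" requires a non-positive lipid contribution for
    every training complex, "mean" only for the training mean;
    ranking: "mean_rmse" sorts by (RMSE_train + RMSE_test)/2 then
    RMSE_test then descriptor names, "rmse_train"/"rmse_test" by the
    respective single RMSE; max_models truncates the ranked list;
    condition_threshold skips subsets whose design is numerically
    ill-conditioned rather than letting unstable fits poison the ranking.
    """

    k: int = 4
    n_lipid: int = 1
    sign_mode: Literal["per-sample", "mean"] = "per-sample"
    ranking: Literal["mean_rmse", "rmse_train", "rmse_test"] = "mean_rmse"
    max_models: int | None = None
    condition_threshold: float = 1e8

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 <= self.n_lipid <= self.k:
            raise ValueError("required lipid count must be between 0 and k")
        if self.sign_mode not in ("per-sample", "mean"):
            raise ValueError(f"unknown sign mode {self.sign_mode!r}")
        if self.ranking not in ("mean_rmse", "rmse_train", "rmse_test"):
            raise ValueError(f"unknown ranking key {self.ranking!r}")


@dataclass(frozen=True)
class CandidateEvaluation:
    """One fitted, constraint-checked candidate with its split metrics."""

    model: LinearAffinityModel
    rmse_train: float
    rmse_test: float
    in_exp_train: int
    in_exp_test: int
    feasible: bool

    @property
    def mean_rmse(self) -> float:
        return 0.5 * (self.rmse_train + self.rmse_test)


@dataclass
class SearchResult:
    """Ranked feasible candidates plus enumeration diagnostics."""

    candidates: list[CandidateEvaluation]
    n_enumerated: int
    n_fitted: int
    n_rejected_constraint: int
    n_skipped_collinear: int
    config: ModelSearchConfig = field(default_factory=ModelSearchConfig)

    @property
    def best(self) -> CandidateEvaluation | None:
        return self.candidates[0] if self.candidates else None

    def to_dict(self) -> dict:
        return {
            "config": {
                "k": self.config.k,
                "n_lipid": self.config.n_lipid,
                "sign_mode": self.config.sign_mode,
                "ranking": self.config.ranking,
                "max_models": self.config.max_models,
                "condition_threshold": self.config.condition_threshold,
            },
            "diagnostics": {
                "n_enumerated": self.n_enumerated,
                "n_fitted": self.n_fitted,
                "n_rejected_constraint": self.n_rejected_constraint,
                "n_skipped_collinear": self.n_skipped_collinear,
            },
            "candidates": [
                {
                    "model": c.model.to_dict(),
                    "rmse_train": c.rmse_train,
                    "rmse_test": c.rmse_test,
                    "in_exp_train": c.in_exp_train,
                    "in_exp_test": c.in_exp_test,
                }
                for c in self.candidates
            ],
        }


def enumerate_subsets(
    classes: dict[str, str], k: int, n_lipid: int
) -> list[tuple[str, ...]]:
    """All k-descriptor subsets with exactly ``n_lipid`` lipid-class names.

    Deterministic: each subset is sorted and subsets are emitted in
    lexicographic order.  Raises if the pool cannot satisfy the
    composition.
    """
    protein = sorted(n for n, c in classes.items() if c == PROTEIN_PROTEIN)
    lipid = sorted(n for n, c in classes.items() if c == LIPID_PROTEIN)
    n_protein = k - n_lipid
    if len(lipid) < n_lipid or len(protein) < n_protein:
        raise ValueError(
            f"cannot form subsets of {n_protein} protein-protein + {n_lipid} "
            f"lipid-protein descriptors from pools of {len(protein)} and {len(lipid)}"
        )
    subsets = [
        tuple(sorted(p + l))
        for p in itertools.combinations(protein, n_protein)
        for l in itertools.combinations(lipid, n_lipid)
    ]
    subsets.sort()
    return subsets


def fit_least_squares(
    design: np.ndarray, targets: np.ndarray
) -> tuple[np.ndarray, float]:
    """Ordinary least squares with an intercept.

    ``design`` is (n_samples, n_descriptors); returns the coefficient
    vector and the intercept minimising the squared training residuals.
    """
    design = np.asarray(design, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if design.ndim != 2 or design.shape[0] != targets.shape[0]:
        raise ValueError("design and target shapes do not match")
    x = np.column_stack([design, np.ones(design.shape[0])])
    beta, *_ = np.linalg.lstsq(x, targets, rcond=None)
    return beta[:-1], float(beta[-1])


def check_lipid_favourable(
    model: LinearAffinityModel,
    records: Sequence,
    mode: Literal["per-sample", "mean"] = "per-sample",
) -> bool:
    """Whether the model's lipid-protein contribution is favourable.

    Favourable means the lipid-class terms lower (or leave unchanged) the
    predicted binding energy: contribution <= 0 for every training record
    (``per-sample``) or on average (``mean``).
    """
    contributions = [lipid_contribution(model, r) for r in records]
    if not contributions:
        return True
    if mode == "per-sample":
        return all(c <= 0.0 for c in contributions)
    if mode == "mean":
        return float(np.mean(contributions)) <= 0.0
    raise ValueError(f"unknown sign mode {mode!r}")


def count_within_experimental_error(
    predictions: Sequence[AffinityPrediction],
    measurements: Sequence[AffinityMeasurement],
) -> int:
    """Complexes whose predicted dG falls inside the experimental error band.

    The band is the dG image of [Kd - err, Kd + err]; dG is increasing in
    Kd, so the interval maps monotonically.  A measurement without an
    error range cannot contain any prediction and counts as not-within.
    """
    by_id = {m.complex_id: m for m in measurements}
    count = 0
    for pred in predictions:
        if pred.complex_id not in by_id:
            raise KeyError(f"no measurement for complex {pred.complex_id!r}")
        m = by_id[pred.complex_id]
        if m.kd_err_nm is None:
            continue
        lo_kd = m.kd_nm - m.kd_err_nm
        hi_kd = m.kd_nm + m.kd_err_nm
        lo_dg = delta_g_from_kd(lo_kd) if lo_kd > 0 else -np.inf
        hi_dg = delta_g_from_kd(hi_kd)
        if lo_dg <= pred.dg_kcal_mol <= hi_dg:
            count += 1
    return count


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def search(
    matrix: DescriptorMatrix,
    measurements: Sequence[AffinityMeasurement],
    config: ModelSearchConfig | None = None,
) -> SearchResult:
    """Run the exhaustive constrained model search.

    Fits every admissible descriptor subset on the training complexes,
    rejects candidates with an unfavourable lipid-protein contribution,
    evaluates RMSE and within-error counts on both sets, and returns the
    feasible candidates ranked by the configured key.  Deterministic for
    fixed inputs.
    """
    config = config or ModelSearchConfig()
    by_id = {m.complex_id: m for m in measurements}
    missing = [cid for cid in matrix.complex_ids if cid not in by_id]
    if missing:
        raise KeyError(f"complexes without measurements: {missing}")

    train_ids = [c for c in matrix.complex_ids if by_id[c].set_label == TRAINING]
    test_ids = [c for c in matrix.complex_ids if by_id[c].set_label == TEST]
    if not train_ids:
        raise ValueError("training set is empty")

    data = matrix.data
    dg_train = np.array([by_id[c].dg_exp for c in train_ids])
    dg_test = np.array([by_id[c].dg_exp for c in test_ids])
    train_meas = [by_id[c] for c in train_ids]
    test_meas = [by_id[c] for c in test_ids]
    train_records = [
        r for r in matrix.records() if r.complex_id in set(train_ids)
    ]
    test_records = [r for r in matrix.records() if r.complex_id in set(test_ids)]

    subsets = enumerate_subsets(matrix.classes, config.k, config.n_lipid)

    n_fitted = 0
    n_rejected = 0
    n_collinear = 0
    feasible: list[CandidateEvaluation] = []
    for subset in subsets:
        x_train = data.loc[train_ids, list(subset)].to_numpy(dtype=float)
        design = np.column_stack([x_train, np.ones(len(train_ids))])
        if np.linalg.cond(design) > config.condition_threshold:
            n_collinear += 1
            continue
        coefs, intercept = fit_least_squares(x_train, dg_train)
        n_fitted += 1
        model = LinearAffinityModel(
            name="+".join(subset),
            terms=tuple(
                ModelTerm(name, float(c), matrix.classes[name])
                for name, c in zip(subset, coefs)
            ),
            intercept=intercept,
        )
        if model.lipid_terms() and not check_lipid_favourable(
            model, train_records, config.sign_mode
        ):
            n_rejected += 1
            continue
        preds_train = predict_matrix(model, train_records)
        preds_test = predict_matrix(model, test_records)
        pred_dg_train = np.array([p.dg_kcal_mol for p in preds_train])
        pred_dg_test = np.array([p.dg_kcal_mol for p in preds_test])
        feasible.append(
            CandidateEvaluation(
                model=model,
                rmse_train=_rmse(pred_dg_train, dg_train),
                rmse_test=_rmse(pred_dg_test, dg_test) if test_ids else float("nan"),
                in_exp_train=count_within_experimental_error(preds_train, train_meas),
                in_exp_test=count_within_experimental_error(preds_test, test_meas),
                feasible=True,
            )
        )

    key_funcs = {
        "mean_rmse": lambda c: (c.mean_rmse, c.rmse_test, c.model.descriptor_names),
        "rmse_train": lambda c: (c.rmse_train, c.rmse_test, c.model.descriptor_names),
        "rmse_test": lambda c: (c.rmse_test, c.rmse_train, c.model.descriptor_names),
    }
    feasible.sort(key=key_funcs[config.ranking])
    if config.max_models is not None:
        feasible = feasible[: config.max_models]

    return SearchResult(
        candidates=feasible,
        n_enumerated=len(subsets),
        n_fitted=n_fitted,
        n_rejected_constraint=n_rejected,
        n_skipped_collinear=n_collinear,
        config=config,
    )
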