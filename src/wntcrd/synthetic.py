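"""Synthetic descriptor matrices with a planted linear affinity model.

Interface-descriptor values from structure-based scoring pipelines are
not redistributable, so the package ships a generator that reproduces
their statistical shape instead: protein-protein columns are zero-centred
with per-column scales spanning about three orders of magnitude (the
scale heterogeneity implied by published coefficient magnitudes), and
lipid-protein columns are strictly positive, emulating a binding-site
desolvation energy.  Binding energies come from a planted sparse linear
model plus Gaussian noise, so the full search pipeline can be exercised
and its recovery behaviour measured.

The packaged experimental fixture — the 23 mouse Wnt--Fzd CRD complexes
with measured Kd, set assignments and published model-1 predictions — is
exposed through :func:`fixture_table2`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import (
    LIPID_PROTEIN,
    PROTEIN_PROTEIN,
    AffinityPrediction,
    DescriptorMatrix,
    LinearAffinityModel,
    ModelTerm,
    predict_dg,
)
from .search import AffinityMeasurement
from .thermo import kd_from_delta_g

__all__ = [
    "SyntheticSpec",
    "default_planted_model",
    "generate_descriptor_matrix",
    "generate_measurements",
    "fixture_table2",
    "fixture_frame",
]

_FIXTURE = "wnt_fzd_affinity_table.csv"


def default_planted_model() -> LinearAffinityModel:
    """Planted model with published-magnitude coefficients.

    Three protein-protein terms and one lipid-protein term whose negative
    coefficient against a strictly positive descriptor guarantees a
    favourable lipid contribution.
    """
    return LinearAffinityModel(
        name="planted",
        terms=(
            ModelTerm("pp_001", 0.06715, PROTEIN_PROTEIN),
            ModelTerm("pp_002", 0.001913, PROTEIN_PROTEIN),
            ModelTerm("pp_003", -0.01128, PROTEIN_PROTEIN),
            ModelTerm("lp_001", -0.3072, LIPID_PROTEIN),
        ),
        intercept=-6.2941,
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one synthetic study.

    n_train/n_test mirror the experimental 15/8 split; m_protein/m_lipid
    give the descriptor pool per class; noise_sd (kcal/mol) is Gaussian
    noise on the true binding energy; kd_err_fraction sets each
    measurement's error range as a fraction of its Kd.
    """

    n_train: int = 15
    n_test: int = 8
    m_protein: int = 100
    m_lipid: int = 4
    planted_model: LinearAffinityModel = field(default_factory=default_planted_model)
    noise_sd: float = 0.3
    kd_err_fraction: float = 0.2
    protein_scale_range: tuple[float, float] = (1.0, 1e3)
    lipid_mean: float = 20.0
    lipid_cv: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 0:
            raise ValueError("complex counts must be positive")
        if self.m_protein < 1 or self.m_lipid < 1:
            raise ValueError("descriptor counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.kd_err_fraction < 0:
            raise ValueError("Kd error fraction must be >= 0")
        lo, hi = self.protein_scale_range
        if not 0 < lo <= hi:
            raise ValueError("protein scale range must satisfy 0 < lo <= hi")

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_test


def _descriptor_names(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    width = max(3, len(str(max(spec.m_protein, spec.m_lipid))))
    protein = [f"pp_{i + 1:0{width}d}" for i in range(spec.m_protein)]
    lipid = [f"lp_{i + 1:0{width}d}" for i in range(spec.m_lipid)]
    return protein, lipid


def generate_descriptor_matrix(spec: SyntheticSpec) -> DescriptorMatrix:
    """Draw a complexes x descriptors matrix per the spec.

    Protein-protein columns ~ Normal(0, sigma) with sigma log-uniform over
    ``protein_scale_range``; columns named by the planted model instead
    get sigma = 1/|coefficient| so each planted term contributes about
    1 kcal/mol of spread regardless of coefficient magnitude.
    Lipid-protein columns are log-normal with the configured mean and
    coefficient of variation, hence strictly positive.  Identical spec and
    seed give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    protein_names, lipid_names = _descriptor_names(spec)
    planted_coef = {t.descriptor: t.coefficient for t in spec.planted_model.terms}
    missing = [
        n for n in spec.planted_model.descriptor_names
        if n not in protein_names + lipid_names
    ]
    if missing:
        raise ValueError(f"planted model names descriptors outside the pool: {missing}")

    n = spec.n_total
    lo, hi = spec.protein_scale_range
    columns: dict[str, np.ndarray] = {}
    for name in protein_names:
        sigma = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        if name in planted_coef and planted_coef[name] != 0:
            sigma = 1.0 / abs(planted_coef[name])
        columns[name] = rng.normal(0.0, sigma, size=n)
    # log-normal parameterised by mean and CV: mean = exp(mu + s^2/2)
    s = float(np.sqrt(np.log1p(spec.lipid_cv**2)))
    mu = float(np.log(spec.lipid_mean)) - s**2 / 2.0
    for name in lipid_names:
        columns[name] = rng.lognormal(mu, s, size=n)

    ids = [f"complex_{i + 1:03d}" for i in range(n)]
    frame = pd.DataFrame(columns, index=ids)
    classes = {n: PROTEIN_PROTEIN for n in protein_names}
    classes.update({n: LIPID_PROTEIN for n in lipid_names})
    return DescriptorMatrix(data=frame, classes=classes)


def generate_measurements(
    matrix: DescriptorMatrix, spec: SyntheticSpec
) -> tuple[list[AffinityMeasurement], np.ndarray]:
    """Measurements from the planted model plus noise; also the true dG.

    dG_true is the planted model applied to each row; observed dG adds
    Gaussian noise with sd ``noise_sd``; Kd inverts the observed dG and
    the error range is ``kd_err_fraction`` of Kd.  The first ``n_train``
    rows are labelled training, the rest test.  Noise uses a seed offset
    from the matrix seed so matrix and measurements are independent draws.
    """
    records = matrix.records()
    missing = [
        n for n in spec.planted_model.descriptor_names
        if n not in matrix.descriptor_names
    ]
    if missing:
        raise ValueError(f"planted model descriptors absent from matrix: {missing}")
    dg_true = np.array([predict_dg(spec.planted_model, r) for r in records])
    rng = np.random.default_rng(spec.seed + 1_000_003)
    dg_obs = dg_true + rng.normal(0.0, spec.noise_sd, size=len(records))
    measurements = []
    for i, (rec, dg) in enumerate(zip(records, dg_obs)):
        kd = kd_from_delta_g(float(dg))
        measurements.append(
            AffinityMeasurement(
                complex_id=rec.complex_id,
                kd_nm=kd,
                kd_err_nm=kd * spec.kd_err_fraction,
                set_label="training" if i < spec.n_train else "test",
            )
        )
    return measurements, dg_true


def fixture_frame() -> pd.DataFrame:
    """The packaged experimental comparison table, cells as printed.

    23 mouse Wnt--Fzd CRD complexes with experimental and model-1
    predicted binding energies (kcal/mol, 2 dp), dissociation constants
    (nM, 1 dp), range symbols and train/test assignment.
    """
    ref = importlib.resources.files("wntcrd.data").joinpath(_FIXTURE)
    with ref.open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle)


def fixture_table2() -> tuple[list[AffinityMeasurement], list[AffinityPrediction]]:
    """Packaged measurements and published model-1 predictions.

    Measurements carry the printed experimental Kd and set labels (no
    error ranges are published); predictions are built from the printed
    predicted binding energies, with Kd and range derived by the package's
    own thermodynamics.
    """
    frame = fixture_frame()
    measurements = [
        AffinityMeasurement(
            complex_id=row["complex"],
            kd_nm=float(row["kd_exp_nM"]),
            kd_err_nm=None,
            set_label=row["set"],
        )
        for _, row in frame.iterrows()
    ]
    predictions = [
        AffinityPrediction(complex_id=row["complex"], dg_kcal_mol=float(row["dg_pred"]))
        for _, row in frame.iterrows()
    ]
    return measurements, predictions
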