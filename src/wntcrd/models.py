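"""Linear binding-energy models over named interface descriptors.

A model is an intercept plus a weighted sum of descriptor values, where
each descriptor carries a class label: ``protein-protein`` (docking /
statistical-potential scores of the protein interface) or
``lipid-protein`` (an MM-GB/SA term capturing the Wnt palmitoleate--CRD
contribution).  The four published Wnt--Fzd CRD models are built in with
their printed coefficients.

Descriptor names are opaque exact-match strings, normalised only for
surrounding whitespace: the column headers of the originating scoring
pipeline are the vocabulary, and fuzzy matching risks wrong-column bugs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .thermo import AffinityRange, classify_affinity, kd_from_delta_g

__all__ = [
    "PROTEIN_PROTEIN",
    "LIPID_PROTEIN",
    "ModelTerm",
    "LinearAffinityModel",
    "DescriptorRecord",
    "AffinityPrediction",
    "DescriptorMatrix",
    "MissingDescriptorError",
    "builtin_models",
    "predict_dg",
    "lipid_contribution",
    "protein_contribution",
    "predict_matrix",
]

PROTEIN_PROTEIN = "protein-protein"
LIPID_PROTEIN = "lipid-protein"
_CLASSES = (PROTEIN_PROTEIN, LIPID_PROTEIN)


class MissingDescriptorError(KeyError):
    """A record lacks a descriptor the model requires."""

    def __init__(self, descriptor: str, complex_id: str | None = None):
        self.descriptor = descriptor
        self.complex_id = complex_id
        where = f" for complex {complex_id!r}" if complex_id else ""
        super().__init__(f"missing descriptor {descriptor!r}{where}")

    def __str__(self) -> str:
        return self.args[0]


@dataclass(frozen=True)
class ModelTerm:
    """One descriptor term: name, coefficient (kcal/mol per unit), class."""

    descriptor: str
    coefficient: float
    descriptor_class: str = PROTEIN_PROTEIN

    def __post_init__(self) -> None:
        object.__setattr__(self, "descriptor", self.descriptor.strip())
        if not self.descriptor:
            raise ValueError("descriptor name must be non-empty")
        if self.descriptor_class not in _CLASSES:
            raise ValueError(
                f"descriptor class must be one of {_CLASSES}, got {self.descriptor_class!r}"
            )


@dataclass(frozen=True)
class LinearAffinityModel:
    """Named linear model: dG = intercept + sum(coefficient * descriptor)."""

    name: str
    terms: tuple[ModelTerm, ...]
    intercept: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if not self.terms:
            raise ValueError("a model needs at least one term")
        names = [t.descriptor for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate descriptor names in model {self.name!r}")

    @property
    def descriptor_names(self) -> tuple[str, ...]:
        return tuple(t.descriptor for t in self.terms)

    @property
    def descriptor_classes(self) -> dict[str, str]:
        return {t.descriptor: t.descriptor_class for t in self.terms}

    def lipid_terms(self) -> tuple[ModelTerm, ...]:
        return tuple(t for t in self.terms if t.descriptor_class == LIPID_PROTEIN)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intercept": self.intercept,
            "terms": [
                {
                    "descriptor": t.descriptor,
                    "coefficient": t.coefficient,
                    "class": t.descriptor_class,
                }
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "LinearAffinityModel":
        terms = tuple(
            ModelTerm(t["descriptor"], float(t["coefficient"]), t.get("class", PROTEIN_PROTEIN))
            for t in doc["terms"]
        )
        return cls(name=str(doc["name"]), terms=terms, intercept=float(doc["intercept"]))

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "LinearAffinityModel":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class DescriptorRecord:
    """Descriptor values for one protein complex."""

    complex_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        import math

        for name, v in self.values.items():
            if not name.strip():
                raise ValueError(f"empty descriptor name in record {self.complex_id!r}")
            if not math.isfinite(v):
                raise ValueError(
                    f"non-finite value for {name!r} in record {self.complex_id!r}: {v}"
                )


@dataclass(frozen=True)
class AffinityPrediction:
    """Predicted binding energy, Kd and range class for one complex."""

    complex_id: str
    dg_kcal_mol: float
    kd_nm: float = field(default=None)  # type: ignore[assignment]
    range_class: AffinityRange = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kd_nm is None:
            object.__setattr__(self, "kd_nm", kd_from_delta_g(self.dg_kcal_mol))
        if self.range_class is None:
            object.__setattr__(self, "range_class", classify_affinity(self.kd_nm))


def _model_value(model: LinearAffinityModel, record: DescriptorRecord, term: ModelTerm) -> float:
    try:
        return record.values[term.descriptor]
    except KeyError:
        raise MissingDescriptorError(term.descriptor, record.complex_id) from None


def predict_dg(model: LinearAffinityModel, record: DescriptorRecord) -> float:
    """Binding free energy (kcal/mol) predicted by ``model`` for ``record``.

    Raises :class:`MissingDescriptorError` naming the first descriptor the
    record lacks.
    """
    total = model.intercept
    for term in model.terms:
        total += term.coefficient * _model_value(model, record, term)
    return total


def lipid_contribution(model: LinearAffinityModel, record: DescriptorRecord) -> float:
    """Sum of the lipid-protein terms only (kcal/mol).

    Negative values are favourable.  A model without a lipid-class term is
    an error: the question does not apply to it.
    """
    lipid = model.lipid_terms()
    if not lipid:
        raise ValueError(f"model {model.name!r} has no lipid-protein term")
    return sum(t.coefficient * _model_value(model, record, t) for t in lipid)


def protein_contribution(model: LinearAffinityModel, record: DescriptorRecord) -> float:
    """Sum of the protein-protein terms only (kcal/mol)."""
    return sum(
        t.coefficient * _model_value(model, record, t)
        for t in model.terms
        if t.descriptor_class == PROTEIN_PROTEIN
    )


def predict_matrix(
    model: LinearAffinityModel, records: Sequence[DescriptorRecord] | Iterable[DescriptorRecord]
) -> list[AffinityPrediction]:
    """One :class:`AffinityPrediction` per record, preserving input order."""
    return [
        AffinityPrediction(complex_id=r.complex_id, dg_kcal_mol=predict_dg(model, r))
        for r in records
    ]


@dataclass
class DescriptorMatrix:
    """Complexes x named numeric descriptors, with a class label per column.

    ``data`` is a DataFrame indexed by complex id with one numeric column
    per descriptor; ``classes`` maps each descriptor name to
    ``protein-protein`` or ``lipid-protein``.  Class labels live here
    rather than in the data file because descriptor provenance (docking
    score vs MM-GB/SA term), not the table itself, determines the class.
    """

    data: "pandas.DataFrame"  # noqa: F821 - imported lazily
    classes: dict[str, str]

    def __post_init__(self) -> None:
        self.classes = {k.strip(): v for k, v in self.classes.items()}
        missing = [c for c in self.data.columns if c not in self.classes]
        if missing:
            raise ValueError(f"descriptor columns without a class label: {missing}")
        bad = {k: v for k, v in self.classes.items() if v not in _CLASSES}
        if bad:
            raise ValueError(f"invalid descriptor class labels: {bad}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate complex ids: {dupes}")

    @property
    def complex_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def descriptor_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def names_by_class(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {PROTEIN_PROTEIN: [], LIPID_PROTEIN: []}
        for name in self.descriptor_names:
            out[self.classes[name]].append(name)
        return out

    def records(self) -> list[DescriptorRecord]:
        return [
            DescriptorRecord(complex_id=str(idx), values=row.to_dict())
            for idx, row in self.data.iterrows()
        ]

    @classmethod
    def from_records(
        cls, records: Sequence[DescriptorRecord], classes: Mapping[str, str]
    ) -> "DescriptorMatrix":
        import pandas as pd

        frame = pd.DataFrame(
            [dict(r.values) for r in records],
            index=[r.complex_id for r in records],
        )
        return cls(data=frame, classes=dict(classes))


def builtin_models() -> dict[str, LinearAffinityModel]:
    """The four published Wnt--Fzd CRD binding-energy models.

    ``previous`` is the earlier atomic-potential model whose lipid term
    (the MM-GB/SA van der Waals component) usually contributes
    unfavourably; ``model1``..``model3`` are the residue-potential models
    in which the MM-GB/SA binding-site desolvation term (almost always
    positive) carries a negative coefficient, forcing a favourable
    lipid-protein contribution.  Coefficients are the printed decimals.
    """
    pp, lp = PROTEIN_PROTEIN, LIPID_PROTEIN
    models = [
        LinearAffinityModel(
            name="previous",
            terms=(
                ModelTerm("AP_calRW", 0.0038165, pp),
                ModelTerm("MMGBSA dG Bind vdW", -0.22506, lp),
                ModelTerm("HBOND2", -0.24626, pp),
                ModelTerm("FIREDOCK_AB", -0.049875, pp),
            ),
            intercept=-3.3475,
        ),
        LinearAffinityModel(
            name="model1",
            terms=(
                ModelTerm("CP_TSC", 0.06715, pp),
                ModelTerm("CP_ELOCAL_CB", 0.001913, pp),
                ModelTerm("CP_ELOCAL_MIN", -0.01128, pp),
                ModelTerm("MMGBSA dG Bind Solv GB", -0.3072, lp),
            ),
            intercept=-6.2941,
        ),
        LinearAffinityModel(
            name="model2",
            terms=(
                ModelTerm("CP_ELOCAL_CB", 0.002936, pp),
                ModelTerm("CP_ELOCAL_MIN", -0.01811, pp),
                ModelTerm("CP_ZLOCAL_CB", -0.6022, pp),
                ModelTerm("MMGBSA dG Bind Solv GB", -0.2115, lp),
            ),
            intercept=-7.2704,
        ),
        LinearAffinityModel(
            name="model3",
            terms=(
                ModelTerm("CP_TSC", 0.0840, pp),
                ModelTerm("INSIDE", 0.2258, pp),
                ModelTerm("FA_PP", -0.06487, pp),
                ModelTerm("MMGBSA dG Bind Solv GB", -0.4274, lp),
            ),
            intercept=-4.6833,
        ),
    ]
    return {m.name: m for m in models}
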