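"""Core domain types shared across the pipeline.

All tabular data ride on pandas objects; these thin wrappers add the unit
bookkeeping and invariants the pipeline relies on (unique identifiers,
non-negative counts, aligned shapes).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Unit",
    "ExpressionMatrix",
    "ClinicalTable",
    "FixedSignature",
    "SignatureModel",
    "StandardizationParams",
    "EvalReport",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class Unit(str, enum.Enum):
    """Scale of the values held by an :class:`ExpressionMatrix`."""

    counts = "counts"
    tpm = "tpm"
    log2tpm1 = "log2tpm1"
    standardized = "standardized"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a unit tag.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    """

    values: pd.DataFrame
    unit: Unit = Unit.counts

    def __post_init__(self) -> None:
        if not isinstance(self.unit, Unit):
            self.unit = Unit(self.unit)
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate gene ids: {dups}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dups}")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValidationError(f"missing values in samples: {bad}")
        if self.unit is Unit.counts and (self.values.to_numpy() < 0).any():
            raise ValidationError("counts must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.unit)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.values[list(samples)], self.unit)


RECIST_CODES = ("CR", "PR", "SD", "PD")
RESPONDER_CODES = frozenset({"CR", "PR"})


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations.

    ``table`` is indexed by sample id with at least a binary ``response``
    column (1 = responder, i.e. RECIST CR/PR).  Optional columns: ``recist``,
    ``os_time`` (months), ``os_event`` (1 = death observed), plus arbitrary
    numeric covariates (e.g. TMB).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dups = sorted(set(t.index[t.index.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dups}")
        if "recist" in t.columns:
            vals = t["recist"].dropna()
            bad = sorted(set(vals) - set(RECIST_CODES))
            if bad:
                raise ValidationError(f"invalid RECIST codes: {bad}")
            derived = vals.isin(RESPONDER_CODES).astype(int)
            if "response" in t.columns:
                given = t.loc[vals.index, "response"].astype(int)
                if not (given == derived).all():
                    off = given.index[given != derived].tolist()
                    raise ValidationError(
                        f"response inconsistent with RECIST for samples: {off}"
                    )
            else:
                t = t.copy()
                t["response"] = np.nan
                t.loc[vals.index, "response"] = derived
                self.table = t
        if "response" not in self.table.columns:
            raise ValidationError("clinical table needs 'recist' or 'response'")
        resp = self.table["response"].dropna()
        if not resp.isin([0, 1]).all():
            raise ValidationError("response must be binary 0/1")
        if "os_time" in self.table.columns:
            ost = self.table["os_time"].dropna()
            if (ost < 0).any():
                raise ValidationError("os_time must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def response(self) -> pd.Series:
        return self.table["response"].astype(int)

    @property
    def has_survival(self) -> bool:
        return {"os_time", "os_event"} <= set(self.table.columns)

    def subset(self, samples: Sequence[str]) -> "ClinicalTable":
        missing = [s for s in samples if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples absent from clinical table: {missing}")
        return ClinicalTable(self.table.loc[list(samples)])


@dataclass
class FixedSignature:
    """A named, published gene list used as a fixed predictor."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} has no genes")
        seen: dict[str, None] = {}
        dropped = []
        for g in self.genes:
            if g in seen:
                dropped.append(g)
            else:
                seen[g] = None
        if dropped:
            import warnings

            warnings.warn(
                f"signature {self.name!r}: dropped duplicate genes {dropped}",
                stacklevel=2,
            )
            self.genes = list(seen)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class StandardizationParams:
    """Per-gene means/SDs frozen from a cohort, for scoring new samples."""

    gene_ids: list[str]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.gene_ids) == len(self.means) == len(self.sds)):
            raise ValidationError("standardization params misaligned")
        if (self.sds <= 0).any():
            raise ValidationError("standardization SDs must be > 0")


@dataclass
class SignatureModel:
    """A fitted penalized-logit predictor over an ordered gene list.

    ``train_means``/``train_sds`` freeze the training cohort's per-gene
    moments so single new samples can be scored without a full test cohort.
    """

    genes: list[str]
    weights: np.ndarray
    intercept: float
    penalty: str  # "l2" | "l1"
    lam: float
    train_means: np.ndarray
    train_sds: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.train_means = np.asarray(self.train_means, dtype=float)
        self.train_sds = np.asarray(self.train_sds, dtype=float)
        n = len(self.genes)
        if not (len(self.weights) == len(self.train_means) == len(self.train_sds) == n):
            raise ValidationError("model fields misaligned with gene list")
        if self.penalty not in ("l2", "l1"):
            raise ValidationError(f"unknown penalty {self.penalty!r}")
        if self.lam < 0:
            raise ValidationError("lambda must be >= 0")
        if (self.train_sds <= 0).any():
            raise ValidationError("train_sds must be > 0")


@dataclass
class EvalReport:
    """Threshold-based classification metrics plus ranking AUC."""

    auc: float
    accuracy: float
    f1: float
    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float
    n_samples: int
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tp + self.tn + self.fp + self.fn != self.n_samples:
            raise ValidationError("confusion counts do not sum to n_samples")

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "threshold": self.threshold,
            "n_samples": self.n_samples,
            "notes": list(self.notes),
        }
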