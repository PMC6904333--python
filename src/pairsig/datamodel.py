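"""Core data containers for the gene-pair prognostic-signature pipeline.

All containers are thin, validated wrappers around numpy arrays with
explicit identifier lists, so that every downstream operation can be
exact about sample/gene alignment.  Gene identifiers are opaque strings
(no alias resolution is attempted).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairsigError",
    "ParseError",
    "SchemaError",
    "DomainError",
    "ExpressionMatrix",
    "SurvivalData",
    "ClinicalTable",
    "SignatureModel",
    "RiskScore",
]


class PairsigError(ValueError):
    """Base class for pipeline errors."""


class ParseError(PairsigError):
    """A delimited input file could not be parsed."""


class SchemaError(PairsigError):
    """A structured file is missing or mangling a required field."""


class DomainError(PairsigError):
    """A value lies outside its declared domain."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DomainError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix.

    Parameters
    ----------
    gene_ids : unique gene identifiers (rows).
    sample_ids : unique sample identifiers (columns).
    values : 2-d float array, shape ``(len(gene_ids), len(sample_ids))``.
        Must be finite, and non-negative unless ``log_scale`` is set.
    units : free-text abundance unit label (e.g. "FPKM", "RPM").
    log_scale : whether values are already log2-transformed.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    units: str = "arbitrary"
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DomainError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.values.size == 0:
            raise DomainError("empty expression matrix")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("expression values must be finite")
        if not self.log_scale and np.any(self.values < 0):
            raise DomainError("negative abundance in a non-log matrix")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._index[gene_id]]
        except KeyError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def sample_profile(self, sample_id: str) -> dict[str, float]:
        """Single-sample gene -> value mapping."""
        j = self.sample_ids.index(sample_id)
        return {g: float(v) for g, v in zip(self.gene_ids, self.values[:, j])}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, units: str = "arbitrary",
                   log_scale: bool = False) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float),
                   units=units, log_scale=log_scale)


@dataclass
class SurvivalData:
    """Right-censored survival outcomes for one endpoint.

    ``time`` is in months; ``event`` is 1 for an observed event (death or
    progression), 0 for censoring.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    endpoint_label: str = "OS"

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != self.time.shape:
            raise DomainError("time/event length does not match sample ids")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            raise DomainError("survival times must be finite and >= 0")
        ev = np.unique(self.event)
        if not np.all(np.isin(ev, [0, 1])):
            raise DomainError(f"event indicator must be 0/1, got {ev}")
        self.event = self.event.astype(int)
        if self.endpoint_label not in ("OS", "EFS"):
            raise DomainError("endpoint_label must be 'OS' or 'EFS'")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, mask: np.ndarray) -> "SurvivalData":
        mask = np.asarray(mask)
        ids = [s for s, m in zip(self.sample_ids, mask) if m]
        return SurvivalData(ids, self.time[mask], self.event[mask], self.endpoint_label)

    def align(self, sample_ids: Sequence[str]) -> "SurvivalData":
        """Reorder/subset to the given sample ids (all must be present)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise DomainError(f"samples without survival data: {missing[:5]}")
        idx = np.array([pos[s] for s in sample_ids])
        return SurvivalData(list(sample_ids), self.time[idx], self.event[idx],
                            self.endpoint_label)


#: categorical domains of the clinical covariates
CLINICAL_FACTORS = ("sex", "age_ge_18m", "mycn_amplified", "stage4")


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates plus survival outcomes.

    Dichotomizations follow the usual neuroblastoma conventions: age at
    diagnosis >= 18 months vs < 18 months, INSS stage 4 vs stages
    1/2/3/4S, MYCN amplified vs not.  Missing values are retained as NaN
    and dropped listwise only by operations that use the field.
    """

    data: pd.DataFrame  # index = sample ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise DomainError("duplicate sample ids in clinical table")
        self.data = self.data.copy()
        for col in CLINICAL_FACTORS:
            if col not in self.data.columns:
                self.data[col] = np.nan
            vals = self.data[col].dropna().unique()
            bad = [v for v in vals if v not in (0, 1, 0.0, 1.0)]
            if bad:
                raise DomainError(f"{col} outside {{0,1,missing}}: {bad[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def __len__(self) -> int:
        return len(self.data)

    def survival(self, endpoint: str = "OS") -> SurvivalData:
        """Extract the (time, event) pair for one endpoint, dropping samples
        where either is missing."""
        pre = endpoint.lower()
        tcol, ecol = f"{pre}_time", f"{pre}_event"
        if tcol not in self.data.columns or ecol not in self.data.columns:
            raise SchemaError(f"clinical table has no {endpoint} columns "
                              f"({tcol}, {ecol})")
        sub = self.data[[tcol, ecol]].dropna()
        return SurvivalData(list(sub.index.astype(str)), sub[tcol].to_numpy(),
                            sub[ecol].to_numpy().astype(int), endpoint)

    def factor(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise DomainError(f"unknown clinical factor {name!r}")
        return self.data[name]


@dataclass
class SignatureModel:
    """A fitted gene-pair signature: ordered pairs, Cox coefficients and a
    risk-score cutoff.

    Scoring honours the stored ``(gene1, gene2)`` order of each pair: the
    pair indicator is 1 when gene1's abundance is strictly below gene2's
    within the sample.  The coefficients are order-dependent.
    """

    pairs: list[tuple[str, str]]
    coefficients: np.ndarray
    cutoff: float | None = None
    cutoff_method: str = "roc"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = [(str(a), str(b)) for a, b in self.pairs]
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.pairs) != len(self.coefficients):
            raise DomainError("pairs and coefficients differ in length")
        if len(set(self.pairs)) != len(self.pairs):
            raise DomainError("duplicate pairs in signature")
        for a, b in self.pairs:
            if a == b:
                raise DomainError(f"pair with identical members: {a!r}")
        if self.coefficients.size and not np.all(np.isfinite(self.coefficients)):
            raise DomainError("non-finite coefficient")
        if self.cutoff_method not in ("roc", "median"):
            raise DomainError("cutoff_method must be 'roc' or 'median'")
        if len(self.pairs) == 0:
            warnings.warn("signature model with zero pairs", stacklevel=2)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in self.pairs:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    def with_cutoff(self, cutoff: float, method: str = "roc") -> "SignatureModel":
        return replace(self, cutoff=float(cutoff), cutoff_method=method)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class RiskScore:
    """Per-sample risk score (RPI or RCPI) with an optional high/low call.

    ``group`` is "high" iff ``score > cutoff`` (ties fall to "low");
    "unassigned" before stratification.
    """

    sample_ids: list[str]
    score: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.sample_ids),):
            raise DomainError("score length does not match sample ids")
        if not np.all(np.isfinite(self.score)):
            raise DomainError("risk scores must be finite")
        if self.group is None:
            self.group = np.full(len(self.sample_ids), "unassigned", dtype=object)
        else:
            self.group = np.asarray(self.group, dtype=object)
            bad = set(self.group) - {"high", "low", "unassigned"}
            if bad:
                raise DomainError(f"invalid group labels: {bad}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.score, "group": self.group},
                            index=self.sample_ids)
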