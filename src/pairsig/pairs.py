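"""Within-sample gene-pair indicator features.

The pair score is 1 when the first gene's abundance is strictly below
the second's in the same sample, else 0 (ties score 0).  Because only
the within-sample order of two genes enters, the features are exactly
invariant under any strictly increasing per-sample transform — the
property that lets a signature trained on FPKM data score an RPM
profile, one sample at a time, with no normalization.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import DomainError, ExpressionMatrix

__all__ = ["PairMatrix", "pair_score", "build_pair_matrix", "filter_constant_pairs"]


@dataclass
class PairMatrix:
    """Binary pairs x samples indicator matrix in canonical orientation
    (gene1 < gene2 lexicographically)."""

    pair_ids: list[tuple[str, str]]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.pair_ids = [(str(a), str(b)) for a, b in self.pair_ids]
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.pair_ids), len(self.sample_ids)):
            raise DomainError("pair matrix shape mismatch")
        if self.values.size and not np.all((self.values == 0) | (self.values == 1)):
            raise DomainError("pair matrix must be binary")
        seen = set(self.pair_ids)
        if len(seen) != len(self.pair_ids):
            raise DomainError("duplicate pairs")
        if any((b, a) in seen for a, b in self.pair_ids if (b, a) != (a, b)):
            raise DomainError("a pair and its reverse are both present")
        self._index = {p: i for i, p in enumerate(self.pair_ids)}

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def row(self, pair: tuple[str, str]) -> np.ndarray:
        return self.values[self._index[pair]]

    def subset(self, pairs: Sequence[tuple[str, str]]) -> "PairMatrix":
        idx = [self._index[tuple(p)] for p in pairs]
        return PairMatrix([self.pair_ids[i] for i in idx], self.sample_ids,
                          self.values[idx])

    def subset_samples(self, sample_ids: Sequence[str]) -> "PairMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise DomainError(f"samples absent from pair matrix: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return PairMatrix(self.pair_ids, list(sample_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        index = [f"{a}|{b}" for a, b in self.pair_ids]
        return pd.DataFrame(self.values, index=index, columns=self.sample_ids)


def pair_score(e1: float, e2: float) -> int:
    """1 if e1 < e2 else 0 (ties -> 0)."""
    if not (np.isfinite(e1) and np.isfinite(e2)):
        raise DomainError("pair_score requires finite inputs")
    return int(e1 < e2)


def build_pair_matrix(expr: ExpressionMatrix, candidate_genes: Sequence[str]
                      ) -> PairMatrix:
    """Indicator matrix over all C(k, 2) unordered candidate pairs.

    Pairs are oriented lexicographically by gene id; entry (g1, g2), s is
    ``pair_score(expr[g1, s], expr[g2, s])``.
    """
    candidates = sorted(dict.fromkeys(str(g) for g in candidate_genes))
    missing = [g for g in candidates if g not in expr]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:10]}")
    if len(candidates) < 2:
        raise DomainError("need >= 2 candidate genes")
    sub = np.stack([expr.row(g) for g in candidates])
    i1, i2 = np.triu_indices(len(candidates), k=1)
    values = (sub[i1] < sub[i2]).astype(np.uint8)
    pair_ids = [(candidates[a], candidates[b]) for a, b in zip(i1, i2)]
    return PairMatrix(pair_ids, list(expr.sample_ids), values)


def filter_constant_pairs(pair_matrices: Sequence[PairMatrix]
                          ) -> list[tuple[str, str]]:
    """Pairs that are non-constant (contain both 0 and 1) in *every*
    supplied dataset; a pair constant in any one dataset is removed."""
    if not pair_matrices:
        raise DomainError("no pair matrices supplied")
    ref = pair_matrices[0].pair_ids
    for pm in pair_matrices[1:]:
        if pm.pair_ids != ref:
            raise DomainError("pair matrices do not share pair_ids")
    keep = np.ones(len(ref), dtype=bool)
    for pm in pair_matrices:
        keep &= pm.values.min(axis=1) < pm.values.max(axis=1)
    result = [p for p, k in zip(ref, keep) if k]
    if not result:
        warnings.warn("all pairs are constant in at least one dataset", stacklevel=2)
    return result
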