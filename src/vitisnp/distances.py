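"""Kimura 2-parameter distances with ambiguity-aware pairwise deletion.

K2P corrects separately for transitions (A<->G, C<->T; proportion P) and
transversions (proportion Q):

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

The model is defined on fixed bases, so any site where either sequence
carries a non-ACGT symbol (gap, N, or a heterozygous IUB code) is deleted
pairwise before counting.  When a log argument is non-positive, or no sites
survive deletion, the distance is *undefined* and flagged as such -- it is
never silently reported as 0, and tree construction refuses matrices that
contain undefined entries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import CODE4_LUT, seq_to_bytes
from .errors import UndefinedDistanceError, VitisnpError
from .io import AccessionMeta

__all__ = [
    "K2PResult",
    "DistanceMatrix",
    "k2p_distance",
    "k2p_matrix",
    "group_distance_summary",
]


@dataclass(frozen=True)
class K2PResult:
    n_sites_used: int
    P: float
    Q: float
    d: Optional[float]  # None when undefined

    @property
    def defined(self) -> bool:
        return self.d is not None


def _k2p_from_counts(n_used: int, ts: int, tv: int) -> K2PResult:
    if n_used == 0:
        return K2PResult(0, 0.0, 0.0, None)
    P = ts / n_used
    Q = tv / n_used
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        return K2PResult(n_used, P, Q, None)
    d = -0.5 * math.log(a1) - 0.25 * math.log(a2)
    return K2PResult(n_used, P, Q, d)


def k2p_distance(seq_a: str, seq_b: str) -> K2PResult:
    """K2P distance between two aligned IUB strings (pairwise deletion)."""
    if len(seq_a) != len(seq_b):
        raise VitisnpError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a = CODE4_LUT[seq_to_bytes(seq_a)]
    b = CODE4_LUT[seq_to_bytes(seq_b)]
    valid = (a != 255) & (b != 255)
    a, b = a[valid], b[valid]
    diff = a != b
    # A=0, C=1, G=2, T=3: transitions connect codes of equal parity
    ts = int((diff & ((a & 1) == (b & 1))).sum())
    tv = int((diff & ((a & 1) != (b & 1))).sum())
    return _k2p_from_counts(int(valid.sum()), ts, tv)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a fixed label order.

    Undefined pairs are stored as NaN and listed in ``undefined_pairs``.
    """

    labels: list[str]
    values: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise VitisnpError("distance matrix shape does not match labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.values).any())

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _codes_matrix(sequences: Mapping[str, str], labels: Sequence[str]) -> np.ndarray:
    lengths = {len(sequences[a]) for a in labels}
    if len(lengths) != 1:
        raise VitisnpError(f"aligned sequences have differing lengths: {sorted(lengths)}")
    return np.vstack([CODE4_LUT[seq_to_bytes(sequences[a])] for a in labels])


def k2p_matrix(
    sequences: Mapping[str, str], labels: Optional[Sequence[str]] = None
) -> DistanceMatrix:
    """All-pairs K2P distances over a set of aligned sequences."""
    labs = list(labels) if labels is not None else list(sequences)
    codes = _codes_matrix(sequences, labs)
    return k2p_matrix_from_codes(codes, labs)


def k2p_matrix_from_codes(codes: np.ndarray, labels: Sequence[str]) -> DistanceMatrix:
    """K2P matrix from a pre-encoded (n, L) base-code array (internal fast path,
    reused by the bootstrap so columns can be resampled without re-encoding)."""
    n = codes.shape[0]
    values = np.zeros((n, n), dtype=float)
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        ai = codes[i]
        for j in range(i + 1, n):
            bj = codes[j]
            valid = (ai != 255) & (bj != 255)
            a, b = ai[valid], bj[valid]
            diff = a != b
            ts = int((diff & ((a & 1) == (b & 1))).sum())
            tv = int(diff.sum()) - ts
            res = _k2p_from_counts(int(valid.sum()), ts, tv)
            if res.defined:
                values[i, j] = values[j, i] = res.d
            else:
                values[i, j] = values[j, i] = np.nan
                undefined.append((labels[i], labels[j]))
    return DistanceMatrix(list(labels), values, undefined)


def group_distance_summary(
    matrix: DistanceMatrix, meta: Sequence[AccessionMeta]
) -> pd.DataFrame:
    """Mean and SD of pairwise distances within and between subgroups.

    Within-group rows need >= 2 members; undefined (NaN) pairs are excluded
    from the averages and counted in ``n_undefined``.  The SD is the sample
    standard deviation (0 when only one pair contributes).
    """
    by_id = {m.accession_id: m for m in meta}
    subgroup = [by_id[a].subgroup for a in matrix.labels]
    groups = sorted(set(subgroup))
    members = {g: [i for i, s in enumerate(subgroup) if s == g] for g in groups}
    rows = []
    for gi, ga in enumerate(groups):
        for gb in groups[gi:]:
            if ga == gb:
                idx = members[ga]
                pairs = list(itertools.combinations(idx, 2))
            else:
                pairs = [(i, j) for i in members[ga] for j in members[gb]]
            if not pairs:
                continue
            vals = np.array([matrix.values[i, j] for i, j in pairs])
            ok = vals[~np.isnan(vals)]
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "kind": "within" if ga == gb else "between",
                    "n_pairs": len(ok),
                    "n_undefined": int(np.isnan(vals).sum()),
                    "mean": float(ok.mean()) if ok.size else np.nan,
                    "sd": float(ok.std(ddof=1)) if ok.size > 1 else (0.0 if ok.size == 1 else np.nan),
                }
            )
    return pd.DataFrame(rows)


def require_defined(matrix: DistanceMatrix) -> None:
    """Raise if any pairwise distance is undefined (NaN)."""
    if matrix.has_undefined:
        raise UndefinedDistanceError(
            f"{len(matrix.undefined_pairs)} undefined pairwise distance(s), "
            f"e.g. {matrix.undefined_pairs[:3]}"
        )
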