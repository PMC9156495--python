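"""Jaccard-Tanimoto similarity of binary presence vectors, with a
margin-preserving permutation test.

``J = |u AND v| / |u OR v|``; a pair of all-zero vectors compares equal
(J = 1) so empty scopes never abort a whole-network run.

The p-value holds ``u`` fixed and applies B independent uniform random
permutations to the entries of ``v`` (preserving its margin).  Because J
depends on the permuted ``v`` only through the intersection count, the
permuted statistics are computed from hypergeometric draws of that count.
The two-sided p measures distance from the permutation mean:

    p = (1 + #{ |J_b - mean(J_perm)| >= |J_obs - mean(J_perm)| }) / (B + 1)

one-sided variants use the corresponding tail.  p is never reported below
1/(B+1) nor as 0.  Degenerate inputs (all-zero or all-one vectors, where
permutation cannot change anything) are flagged uninformative with p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["JaccardParams", "JaccardResult", "jaccard", "jaccard_test"]

ALTERNATIVES = ("two_sided", "less_similar", "more_similar")


@dataclass(frozen=True)
class JaccardParams:
    """Configuration of the permutation test."""

    B_permutations: int = 10000
    seed: int | None = None
    alternative: str = "two_sided"

    def __post_init__(self) -> None:
        if self.B_permutations < 100:
            raise ValueError("B_permutations must be >= 100 for any reported p")
        if self.alternative not in ALTERNATIVES:
            raise ValueError(
                f"alternative must be one of {ALTERNATIVES}, got {self.alternative!r}"
            )


@dataclass(frozen=True)
class JaccardResult:
    J: float
    p: float
    n_intersection: int
    n_union: int
    params: JaccardParams
    uninformative: bool = False


def _as_binary(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a 1-d vector of length >= 1")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} entries must be 0 or 1")
    return arr.astype(np.int64)


def jaccard(u, v) -> tuple[float, int, int]:
    """Jaccard-Tanimoto coefficient of two equal-length binary vectors.

    Returns ``(J, n_intersection, n_union)``; an all-zero pair yields
    ``(1.0, 0, 0)``.
    """
    ua = _as_binary(u, "u")
    va = _as_binary(v, "v")
    if ua.shape != va.shape:
        raise ValueError(f"length mismatch: {ua.size} vs {va.size}")
    inter = int(np.sum(ua & va))
    union = int(np.sum(ua | va))
    if union == 0:
        return 1.0, 0, 0
    return inter / union, inter, union


def _tail_count(j_perm: np.ndarray, j_obs: float, alternative: str) -> int:
    if alternative == "less_similar":
        return int(np.sum(j_perm <= j_obs))
    if alternative == "more_similar":
        return int(np.sum(j_perm >= j_obs))
    center = float(j_perm.mean())
    return int(np.sum(np.abs(j_perm - center) >= abs(j_obs - center)))


def jaccard_test(u, v, params: JaccardParams) -> JaccardResult:
    """Permutation test of the similarity between two binary vectors.

    ``u`` is held fixed; ``v`` is randomly rearranged ``B_permutations``
    times.  Reproducible for a given ``params.seed``.
    """
    if params.seed is None:
        raise ValueError("params.seed must be set for a permutation test")
    ua = _as_binary(u, "u")
    va = _as_binary(v, "v")
    if ua.shape != va.shape:
        raise ValueError(f"length mismatch: {ua.size} vs {va.size}")
    j_obs, inter, union = jaccard(ua, va)
    n = ua.size
    a = int(ua.sum())
    b = int(va.sum())
    if a in (0, n) or b in (0, n):
        return JaccardResult(
            J=j_obs, p=1.0, n_intersection=inter, n_union=union, params=params,
            uninformative=True,
        )
    rng = np.random.default_rng(params.seed)
    # permuting v uniformly => intersection count is hypergeometric(n, a, b)
    k = rng.hypergeometric(ngood=a, nbad=n - a, nsample=b, size=params.B_permutations)
    j_perm = k / (a + b - k)
    B = params.B_permutations
    p = (1 + _tail_count(j_perm, j_obs, params.alternative)) / (B + 1)
    return JaccardResult(
        J=j_obs, p=p, n_intersection=inter, n_union=union, params=params,
    )
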