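"""Clayton-copula machinery and Kendall's tau.

The cell-cell dependence score used throughout the package is Kendall's tau,
read through its copula representation: for a bivariate copula C,

    tau = 4 * E[C(U, V)] - 1,

and for the Clayton family with generator phi(x) = (x^-theta - 1)/theta this
integral has the closed form theta / (theta + 2).  The empirical tau-b
estimator (concordant minus discordant pairs, tie-corrected) is the
data-driven counterpart; both routes live here so each can check the other.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ClaytonParams:
    """Clayton dependence parameter theta in [-1, inf), theta != 0.

    The theta -> 0 limit is the independence copula; pass ``theta=0`` to get
    that limit explicitly where an operation supports it.
    """

    theta: float

    def __post_init__(self) -> None:
        if self.theta < -1:
            raise ValueError(f"theta must be >= -1, got {self.theta}")


def pseudo_observations(x: np.ndarray) -> np.ndarray:
    """Rank-transform a sample to (0, 1): r_i / (n + 1), average ranks for ties."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if np.all(x == x[0]):
        warnings.warn("constant vector: pseudo-observations set to 0.5", stacklevel=2)
        return np.full(x.size, 0.5)
    return stats.rankdata(x, method="average") / (x.size + 1)


def clayton_generator(x: float | np.ndarray, p: ClaytonParams) -> float | np.ndarray:
    """Generator phi(x) = (x^-theta - 1)/theta on (0, 1]; phi(1) = 0.

    Strictly decreasing for every admissible theta; the theta -> 0 limit is
    -log(x) (treated as ``theta == 0``).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(x > 1):
        raise ValueError("generator domain is (0, 1]")
    if p.theta == 0:
        out = -np.log(x)
    else:
        out = (x ** (-p.theta) - 1.0) / p.theta
    return out if out.ndim else float(out)


def clayton_cdf(
    u: float | np.ndarray, v: float | np.ndarray, p: ClaytonParams
) -> float | np.ndarray:
    """Clayton copula C(u, v) = max(u^-theta + v^-theta - 1, 0)^(-1/theta).

    The max(., 0) clamp is the generator pseudo-inverse, needed for theta < 0
    where mass is pushed off the lower corner.  theta == 0 returns u*v.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u < 0) or np.any(u > 1) or np.any(v < 0) or np.any(v > 1):
        raise ValueError("copula arguments must lie in [0, 1]")
    if p.theta == 0:
        out = u * v
        return out if out.ndim else float(out)
    with np.errstate(divide="ignore", invalid="ignore"):
        base = u ** (-p.theta) + v ** (-p.theta) - 1.0
        out = np.where(base > 0, np.maximum(base, np.finfo(float).tiny) ** (-1.0 / p.theta), 0.0)
    # boundaries: C(u, 0) = 0, C(u, 1) = u (exact, avoids 0**negative)
    out = np.where((u == 0) | (v == 0), 0.0, out)
    out = np.where(v == 1, u, out)
    out = np.where(u == 1, np.where(v == 1, 1.0, np.where(v == 0, 0.0, v)), out)
    return out if out.ndim else float(out)


def sample_clayton(
    n: int, p: ClaytonParams, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw n pairs from the Clayton copula by conditional inversion.

    Uses the closed-form inverse of the conditional CDF C(v | u); valid on the
    whole admissible range theta in [-1, inf) \\ {0} (theta == 0 draws
    independent uniforms).  Returns an (n, 2) array in (0, 1).
    """
    rng = np.random.default_rng(rng)
    u = rng.uniform(size=n)
    t = rng.uniform(size=n)
    th = p.theta
    if th == 0:
        return np.column_stack([u, t])
    # invert dC/du = u^(-th-1) (u^-th + v^-th - 1)^(-1/th - 1) = t
    base = (t ** (-th / (th + 1.0)) - 1.0) * u ** (-th) + 1.0
    base = np.maximum(base, np.finfo(float).tiny)
    v = base ** (-1.0 / th)
    return np.column_stack([u, np.clip(v, np.finfo(float).tiny, 1.0)])


def _tie_term(sorted_vals: np.ndarray) -> int:
    """Sum of t*(t-1)/2 over tie groups of a sorted array."""
    total = 0
    i = 0
    n = len(sorted_vals)
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        t = j - i
        total += t * (t - 1) // 2
        i = j
    return total


def _merge_count(y: list) -> tuple[list, int]:
    """Merge sort counting inversions (exchanges) in y."""
    n = len(y)
    if n <= 1:
        return y, 0
    mid = n // 2
    left, a = _merge_count(y[:mid])
    right, b = _merge_count(y[mid:])
    merged = []
    swaps = a + b
    i = j = 0
    while i < len(left) and j < len(right):
        if right[j] < left[i]:
            merged.append(right[j])
            j += 1
            swaps += len(left) - i
        else:
            merged.append(left[i])
            i += 1
    merged.extend(left[i:])
    merged.extend(right[j:])
    return merged, swaps


def kendall_tau(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall tau-b via Knight's O(n log n) merge-sort algorithm.

    Exchanges (discordant pairs) are counted by merge-sorting y after a stable
    sort on (x, y); the numerator and the tie corrections are exact integers,
    so the result agrees bit-for-bit with direct O(n^2) pair enumeration.
    Returns 0 (with a warning) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    order = np.lexsort((y, x))
    xs, ys = x[order], y[order]
    n0 = n * (n - 1) // 2
    n1 = _tie_term(xs)
    # joint ties: runs of identical (x, y)
    joint = 0
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i] and ys[j] == ys[i]:
            j += 1
        t = j - i
        joint += t * (t - 1) // 2
        i = j
    _, swaps = _merge_count(list(ys))
    # swaps counted over x-sorted y include exchanges inside x-tie groups that
    # are not discordant; the stable (x, y) sort makes those zero except for
    # genuinely unordered y within tied x, which must be removed.
    within = 0
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        if j - i > 1:
            _, s = _merge_count(list(ys[i:j]))
            within += s
        i = j
    swaps -= within
    n2 = _tie_term(np.sort(ys))
    num = n0 - n1 - n2 + joint - 2 * swaps
    d1 = n0 - n1
    d2 = n0 - n2
    if d1 == 0 or d2 == 0:
        warnings.warn("constant vector: Kendall tau undefined, returning 0", stacklevel=2)
        return 0.0
    return num / np.sqrt(d1 * d2)


def kendall_tau_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Reference tau-b by enumerating all n(n-1)/2 pairs (O(n^2) oracle)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    prod = dx[iu] * dy[iu]
    conc = int(np.sum(prod > 0))
    disc = int(np.sum(prod < 0))
    tx = int(np.sum(dx[iu] == 0))
    ty = int(np.sum(dy[iu] == 0))
    joint = int(np.sum((dx[iu] == 0) & (dy[iu] == 0)))
    n0 = n * (n - 1) // 2
    num = n0 - tx - ty + joint - 2 * disc
    assert num == conc - disc
    d1, d2 = n0 - tx, n0 - ty
    if d1 == 0 or d2 == 0:
        warnings.warn("constant vector: Kendall tau undefined, returning 0", stacklevel=2)
        return 0.0
    return num / np.sqrt(d1 * d2)


def tau_from_theta(p: ClaytonParams) -> float:
    """Kendall tau implied by a Clayton copula: theta / (theta + 2).

    This is the closed form of 4*E[C(U,V)] - 1 for the Clayton family; the
    test suite checks it against numerical evaluation of that integral.
    """
    if p.theta <= -1:
        raise ValueError("tau_from_theta requires theta > -1")
    return p.theta / (p.theta + 2.0)


def theta_from_tau(tau: float) -> ClaytonParams:
    """Invert tau = theta/(theta+2); defined for tau in (-1, 1)."""
    if not -1 < tau < 1:
        raise ValueError("tau must lie in (-1, 1)")
    return ClaytonParams(2.0 * tau / (1.0 - tau))
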