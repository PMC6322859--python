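"""Shared statistical primitives.

All cluster permutation tests in this package use the same exchangeability
unit: the participant. Swapping the within/between condition labels within
a participant is equivalent to flipping the sign of that participant's
within-minus-between difference, so the permutation machinery operates on
per-participant difference arrays and seeded sign-flip indicators.

The permutation p-value convention is ``(b + 1) / (n_perm + 1)`` where
``b`` counts null draws at least as extreme as the observed statistic;
with 1000 permutations the smallest attainable p is therefore ~0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "PermutationPlan",
    "paired_t",
    "rm_anova_2x2",
    "permutation_null",
    "perm_p_value",
    "sign_flips",
    "percentile",
]


@dataclass(frozen=True)
class PermutationPlan:
    """Sign-flip permutation scheme over participants."""

    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def sign_flips(plan: PermutationPlan, n_participants: int) -> np.ndarray:
    """(n_perm, n_participants) array of +/-1 flip indicators, seeded."""
    rng = np.random.default_rng(plan.seed)
    return rng.integers(0, 2, size=(plan.n_perm, n_participants)) * 2 - 1


def perm_p_value(null: np.ndarray, observed: float) -> float:
    """(b + 1) / (n + 1) with b = #{null >= observed}."""
    null = np.asarray(null, dtype=float)
    b = int(np.sum(null >= observed))
    return (b + 1) / (null.size + 1)


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float, bool]:
    """Classical two-sided paired t-test.

    Returns ``(t, df, p, degenerate)``. A zero-variance difference is
    flagged degenerate; its t is ``0`` when all differences are zero and
    signed infinity otherwise (p 1.0 / 0.0 respectively).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t expects two equal-length 1-D arrays")
    n = a.size
    if n < 2:
        raise ValueError("paired_t needs >= 2 participants")
    d = a - b
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d[0] == 0.0:
            return 0.0, df, 1.0, True
        return float(np.sign(d[0]) * np.inf), df, 0.0, True
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p, False


def rm_anova_2x2(cells: np.ndarray) -> dict[str, dict[str, float]]:
    """Two-factor fully within-subject ANOVA on a 2 x 2 cell design.

    ``cells`` has shape ``(n_participants, 2, 2)`` (factor A x factor B).
    With one degree of freedom per factor, each effect reduces to a paired
    t-test on a per-participant contrast score; F = t^2 with df (1, n-1).
    Returns ``{"A": {...}, "B": {...}, "AxB": {...}}`` with F, df1, df2, p
    and partial eta squared.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3 or cells.shape[1:] != (2, 2):
        raise ValueError("cells must be (n_participants, 2, 2)")
    if np.any(~np.isfinite(cells)):
        raise ValueError("missing cells")
    n = cells.shape[0]
    if n < 2:
        raise ValueError("need >= 2 participants")
    contrasts = {
        "A": cells[:, 0, :].mean(axis=1) - cells[:, 1, :].mean(axis=1),
        "B": cells[:, :, 0].mean(axis=1) - cells[:, :, 1].mean(axis=1),
        "AxB": (cells[:, 0, 0] - cells[:, 0, 1]) - (cells[:, 1, 0] - cells[:, 1, 1]),
    }
    out: dict[str, dict[str, float]] = {}
    for name, d in contrasts.items():
        ss_effect = n * d.mean() ** 2
        ss_error = np.sum((d - d.mean()) ** 2) / (n - 1)  # MS_error for the contrast
        if ss_error == 0.0:
            f = 0.0 if ss_effect == 0.0 else np.inf
        else:
            f = float(ss_effect / ss_error)
        p = float(stats.f.sf(f, 1, n - 1)) if np.isfinite(f) else 0.0
        eta = float(f / (f + (n - 1))) if np.isfinite(f) else 1.0
        out[name] = dict(F=f, df1=1.0, df2=float(n - 1), p=p, partial_eta_sq=eta)
    return out


def permutation_null(
    differences: np.ndarray,
    statistic: Callable[[np.ndarray], float],
    plan: PermutationPlan,
) -> tuple[np.ndarray, float, float]:
    """Max-statistic sign-flip permutation null.

    ``differences`` is an array whose first axis indexes participants (any
    trailing shape); ``statistic`` maps such an array to a scalar (e.g. the
    largest cluster mass). For each permutation the per-participant
    differences are sign-flipped and the statistic recomputed.

    Returns ``(null, observed, p)`` with ``p = (b+1)/(n_perm+1)``.
    """
    differences = np.asarray(differences, dtype=float)
    observed = float(statistic(differences))
    flips = sign_flips(plan, differences.shape[0])
    extra = (1,) * (differences.ndim - 1)
    null = np.empty(plan.n_perm)
    for k in range(plan.n_perm):
        null[k] = statistic(differences * flips[k].reshape(-1, *extra))
    return null, observed, perm_p_value(null, observed)


def percentile(values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile (the convention used for cluster
    thresholds; fixed so thresholds are reproducible)."""
    return float(np.percentile(np.asarray(values, dtype=float), q, method="linear"))
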