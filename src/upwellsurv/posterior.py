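"""Derived posterior quantities: annual survival, population comparisons,
covariate-slope summaries, and time-varying survival series.

These operate on vectors of posterior draws.  Draws from independently
fitted population models are paired by (chain, iteration) index — the fits
are independent, so any exhaustive pairing estimator converges to the same
value; index pairing is deterministic and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ComparisonResult",
    "annual_survival",
    "fold_difference",
    "prob_difference",
    "slope_summary",
    "survival_series",
]


def annual_survival(monthly_draws: np.ndarray) -> np.ndarray:
    """Annual apparent survival draws from monthly ones: phi^12.

    Twelve months per year regardless of calendar gaps — the model is
    parameterized on a monthly grid.
    """
    phi = np.asarray(monthly_draws, dtype=float)
    if ((phi < 0) | (phi > 1)).any() or not np.isfinite(phi).all():
        raise ValueError("monthly survival draws must lie in [0, 1]")
    return phi ** 12


def fold_difference(a: float, b: float) -> float:
    """How many times larger ``a`` is than ``b`` (a/b)."""
    if b == 0:
        raise ZeroDivisionError("fold difference undefined for b = 0")
    return a / b


@dataclass
class ComparisonResult:
    """Posterior comparison of a parameter between two populations.

    ``prob_greater`` is the posterior probability that population A's value
    exceeds population B's (strict inequality; ties count as not greater).
    """

    label_a: str
    label_b: str
    prob_greater: float
    diff_mean: float
    diff_cri: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "prob_greater": self.prob_greater,
            "diff_mean": self.diff_mean,
            "diff_cri_low": self.diff_cri[0],
            "diff_cri_high": self.diff_cri[1],
        }


def prob_difference(
    draws_a: np.ndarray,
    draws_b: np.ndarray,
    label_a: str = "A",
    label_b: str = "B",
) -> ComparisonResult:
    """Bayesian probability that A > B, with summaries of A - B.

    Draw vectors must have equal length and are paired by index.
    """
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("draw vectors must be 1-D and of equal length")
    diff = a - b
    lo, hi = np.quantile(diff, [0.025, 0.975])
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        prob_greater=float(np.mean(a > b)),
        diff_mean=float(diff.mean()),
        diff_cri=(float(lo), float(hi)),
    )


def slope_summary(beta_draws: np.ndarray) -> dict:
    """Posterior summary of a logit-scale covariate slope.

    ``crosses_zero`` is True when the central 95% credible interval
    contains 0 — the study's criterion for an unsupported covariate effect.
    """
    b = np.asarray(beta_draws, dtype=float)
    if b.size == 0:
        raise ValueError("empty draws")
    lo, hi = np.quantile(b, [0.025, 0.975])
    return {
        "mean": float(b.mean()),
        "q2.5": float(lo),
        "q97.5": float(hi),
        "crosses_zero": bool(lo < 0 < hi),
    }


def survival_series(
    phi_draws: np.ndarray, searched: np.ndarray, month_labels: list[str] | None = None
) -> pd.DataFrame:
    """Per-interval posterior summary of a time-varying survival fit.

    Parameters
    ----------
    phi_draws
        (draws, T-1) matrix of monthly survival draws.
    searched
        Length-T boolean effort mask of the fitted population.

    Intervals where survival is confounded with detection are flagged
    ``confounded``: the survival of interval t is separately identifiable
    only when occasion t+1 was searched and some searched occasion lies
    beyond it (the terminal searched interval only informs the product
    phi * p).
    """
    draws = np.asarray(phi_draws, dtype=float)
    searched = np.asarray(searched, dtype=bool)
    T = searched.shape[0]
    if draws.ndim != 2 or draws.shape[1] != T - 1:
        raise ValueError(f"phi draws must be (draws, {T - 1})")
    searched_occ = np.flatnonzero(searched) + 1  # 1-based
    last_search = searched_occ.max()
    rows = []
    for t in range(1, T):  # interval t: occasion t -> t+1
        col = draws[:, t - 1]
        lo, hi = np.quantile(col, [0.025, 0.975])
        confounded = (not searched[t]) or (t + 1 >= last_search)
        rows.append(
            {
                "interval": t,
                "from_month": month_labels[t - 1] if month_labels else t,
                "mean": col.mean(),
                "q2.5": lo,
                "q97.5": hi,
                "confounded": confounded,
            }
        )
    return pd.DataFrame(rows)
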