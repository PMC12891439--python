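"""Marginalized Cormack-Jolly-Seber likelihood.

The CJS model conditions on first capture and tracks a latent alive state
with per-interval apparent survival phi_t and per-occasion detection p_t.
Instead of data-augmenting the alive state, the likelihood marginalizes it
with the chi recursion

    chi_T = 1,   chi_t = (1 - phi_t) + phi_t (1 - p_{t+1}) chi_{t+1},

the probability of never being seen after occasion t given alive at t.
The probability of a history with first capture f and last detection l is

    prod_{t=f}^{l-1} phi_t p_{t+1}^{y_{t+1}} (1 - p_{t+1})^{1 - y_{t+1}} * chi_l .

Months without a field search carry detection pinned at exactly 0; those
occasions contribute factors of 1 and their p is never a free parameter.

Five survival structures are supported: constant (phi_dot), site-dependent
(phi_site), fully time-varying (phi_time), and logit-linear in body length
(phi_length) or standard metabolic rate (phi_perf).  Detection is always
fully time-varying, following the irregular search calendar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .histories import EncounterHistories, MArray

__all__ = [
    "SURVIVAL_STRUCTURES",
    "STRUCTURE_ALIASES",
    "CJSModelSpec",
    "ParameterState",
    "chi_recursion",
    "history_loglik",
    "dataset_loglik",
    "marray_loglik",
]

SURVIVAL_STRUCTURES = ("phi_dot", "phi_site", "phi_time", "phi_length", "phi_perf")

# classical CMR notation for the same structures
STRUCTURE_ALIASES = {
    ".": "phi_dot",
    "dot": "phi_dot",
    "po": "phi_site",
    "t": "phi_time",
    "l": "phi_length",
    "f": "phi_perf",
}

_COVARIATE_FOR = {"phi_length": "length_mm", "phi_perf": "smr_mgO2_per_h_per_g"}


def resolve_structure(name: str) -> str:
    key = str(name).lower()
    key = STRUCTURE_ALIASES.get(key, key)
    if key not in SURVIVAL_STRUCTURES:
        raise ValueError(
            f"unknown survival structure {name!r}; valid: "
            f"{SURVIVAL_STRUCTURES} or aliases {tuple(STRUCTURE_ALIASES)}"
        )
    return key


@dataclass
class CJSModelSpec:
    """Which survival structure is fitted, and the detection mask.

    ``fixed_zero_mask`` is a length-T boolean vector, True where detection
    is pinned to 0 (no search); entry 1 is unused (no detection parameter
    exists for the first occasion).  ``covariate_name`` is required for the
    covariate structures and must be absent otherwise.
    """

    survival_structure: str
    fixed_zero_mask: np.ndarray
    covariate_name: str | None = None
    standardize_covariate: bool = True

    def __post_init__(self) -> None:
        self.survival_structure = resolve_structure(self.survival_structure)
        self.fixed_zero_mask = np.asarray(self.fixed_zero_mask, dtype=bool)
        expected = _COVARIATE_FOR.get(self.survival_structure)
        if expected is not None:
            if self.covariate_name is None:
                self.covariate_name = expected
        elif self.covariate_name is not None:
            raise ValueError(
                f"covariate_name is only valid for phi_length/phi_perf, "
                f"not {self.survival_structure}"
            )

    @property
    def n_occasions(self) -> int:
        return self.fixed_zero_mask.shape[0]


@dataclass
class ParameterState:
    """Current values of survival/detection parameters for one likelihood eval.

    ``phi`` is a scalar (phi_dot), a dict site -> scalar (phi_site), a
    length T-1 vector (phi_time), or the pair (alpha, beta) on the logit
    scale (covariate structures).  ``p`` maps occasions 2..T to detection
    probabilities (length T-1, storage index t-2); masked entries must be
    exactly 0.
    """

    phi: object
    p: np.ndarray | dict = field(default_factory=dict)


def _check_prob(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if ((x < 0) | (x > 1)).any() or not np.isfinite(x).all():
        raise ValueError(f"{name} must lie in [0, 1]")
    return x


def chi_recursion(phi_vec: np.ndarray, p_vec: np.ndarray) -> np.ndarray:
    """Probability of never being seen after each occasion, given alive there.

    ``phi_vec`` has length T-1 (intervals t -> t+1); ``p_vec`` has length
    T-1 and holds detection at occasions 2..T.  Returns chi of length T.
    Both arguments may carry a leading individual axis (..., T-1).
    """
    phi_vec = _check_prob(phi_vec, "phi")
    p_vec = _check_prob(p_vec, "p")
    Tm1 = phi_vec.shape[-1]
    if p_vec.shape[-1] != Tm1:
        raise ValueError("phi and p must both have length T-1")
    shape = np.broadcast_shapes(phi_vec.shape[:-1], p_vec.shape[:-1])
    chi = np.ones(shape + (Tm1 + 1,), dtype=float)
    for t in range(Tm1 - 1, -1, -1):
        chi[..., t] = (1.0 - phi_vec[..., t]) + phi_vec[..., t] * (
            1.0 - p_vec[..., t]
        ) * chi[..., t + 1]
    return chi


def history_loglik(
    y_i: np.ndarray, f_i: int, phi_vec: np.ndarray, p_vec: np.ndarray
) -> float:
    """Log-probability of one encounter history, conditioning on release at f.

    ``y_i`` is the 0/1 history (length T), ``f_i`` the 1-based first-capture
    occasion.  ``p_vec`` must hold zeros wherever the effort mask demands.
    """
    y_i = np.asarray(y_i, dtype=int)
    T = y_i.shape[0]
    if not y_i.any():
        raise ValueError("history has no detection")
    if y_i[f_i - 1] != 1 or y_i[: f_i - 1].any():
        raise ValueError("first capture index inconsistent with history")
    chi = chi_recursion(phi_vec, p_vec)
    last = int(np.flatnonzero(y_i)[-1]) + 1  # 1-based
    ll = 0.0
    with np.errstate(divide="ignore"):
        for t in range(f_i, last):  # 1-based intervals f..l-1
            pt = p_vec[t - 1]  # detection at occasion t+1
            ll += np.log(phi_vec[t - 1])
            ll += np.log(pt) if y_i[t] else np.log1p(-pt)
    ll += np.log(chi[last - 1])
    return float(ll)


def _expand_phi(
    spec: CJSModelSpec, state: ParameterState, histories: EncounterHistories
) -> np.ndarray:
    """Per-individual, per-interval survival matrix (n, T-1)."""
    n, T = histories.y.shape
    s = spec.survival_structure
    if s == "phi_dot" or s == "phi_site":
        phi = state.phi
        if isinstance(phi, dict):
            phi = phi[histories.site]
        return np.full((n, T - 1), float(phi))
    if s == "phi_time":
        vec = np.asarray(state.phi, dtype=float)
        if vec.shape != (T - 1,):
            raise ValueError(f"phi_time needs length {T - 1}, got {vec.shape}")
        return np.broadcast_to(vec, (n, T - 1)).copy()
    # covariate structures: logit(phi_i) = alpha + beta * x_i
    alpha, beta = state.phi
    x = covariate_values(histories, spec)
    from scipy.special import expit

    phi_i = expit(alpha + beta * x)
    return np.repeat(phi_i[:, None], T - 1, axis=1)


def covariate_values(
    histories: EncounterHistories, spec: CJSModelSpec
) -> np.ndarray:
    """Standardized covariate vector for a covariate survival structure.

    Individuals with missing covariate must have been dropped beforehand
    (see :func:`drop_missing_covariate`).
    """
    name = spec.covariate_name
    if name is None:
        raise ValueError("spec has no covariate")
    x = histories.covariates[name].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError(
            f"{int(np.isnan(x).sum())} individuals missing {name}; "
            "drop them before fitting (drop_missing_covariate)"
        )
    if spec.standardize_covariate:
        sd = x.std(ddof=1) if len(x) > 1 else 1.0
        x = (x - x.mean()) / (sd if sd > 0 else 1.0)
    return x


def drop_missing_covariate(
    histories: EncounterHistories, covariate_name: str
) -> tuple[EncounterHistories, int]:
    """Remove individuals lacking the covariate; returns (subset, n_dropped)."""
    x = histories.covariates[covariate_name].to_numpy(dtype=float)
    keep = ~np.isnan(x)
    n_drop = int((~keep).sum())
    if keep.all():
        return histories, 0
    if not keep.any():
        raise ValueError(f"no individual has covariate {covariate_name}")
    tags = [t for t, k in zip(histories.tag_ids, keep) if k]
    sub = EncounterHistories(
        y=histories.y[keep], first=histories.first[keep], tag_ids=tags,
        site=histories.site, species=histories.species,
        searched=histories.searched, covariates=histories.covariates.loc[tags],
    )
    return sub, n_drop


def _p_for(
    spec: CJSModelSpec, state: ParameterState, histories: EncounterHistories
) -> np.ndarray:
    p = state.p
    if isinstance(p, dict):
        p = p[histories.site]
    p = _check_prob(p, "p")
    T = histories.n_occasions
    if p.shape != (T - 1,):
        raise ValueError(f"p needs length {T - 1}, got {p.shape}")
    mask = spec.fixed_zero_mask[1:] if spec.fixed_zero_mask.shape[0] == T else spec.fixed_zero_mask
    if (p[mask] != 0).any():
        raise ValueError("masked detection entries must be exactly 0")
    return p


def dataset_loglik(
    histories: EncounterHistories | list[EncounterHistories],
    spec: CJSModelSpec,
    state: ParameterState,
) -> float:
    """Sum of history log-likelihoods over all individuals (vectorized).

    For phi_site, pass a list of per-site history sets; ``state.phi`` and
    ``state.p`` are then dicts keyed by site.
    """
    if isinstance(histories, (list, tuple)):
        return float(sum(dataset_loglik(h, spec, state) for h in histories))
    y = histories.y
    n, T = y.shape
    first = histories.first
    phi_mat = _check_prob(_expand_phi(spec, state, histories), "phi")
    p_vec = _p_for(spec, state, histories)
    chi = chi_recursion(phi_mat, np.broadcast_to(p_vec, (n, T - 1)))  # (n, T)
    last0 = T - 1 - np.argmax(y[:, ::-1], axis=1)  # 0-based last detection
    with np.errstate(divide="ignore"):
        logphi = np.log(phi_mat)  # (n, T-1)
        log1mp = np.where(p_vec < 1.0, np.log1p(-p_vec), -np.inf)  # (T-1,)
        logp = np.where(p_vec > 0.0, np.log(p_vec), -np.inf)
    # interval t (0-based, occasions t+1 -> t+2) is active when
    # first-1 <= t <= last0-1
    tidx = np.arange(T - 1)
    active = (tidx[None, :] >= (first - 1)[:, None]) & (tidx[None, :] < last0[:, None])
    det = y[:, 1:].astype(bool)  # detection at occasion t+2
    contrib = logphi + np.where(det, logp[None, :], log1mp[None, :])
    ll = np.where(active, contrib, 0.0).sum(axis=1)
    with np.errstate(divide="ignore"):
        ll = ll + np.log(chi[np.arange(n), last0])
    total = ll.sum()
    return float(total) if np.isfinite(total) else float("-inf")


_GRID_CACHE: dict[int, tuple] = {}


def _marray_grids(Tm1: int) -> tuple:
    """Static (release, recapture) index grids for the m-array cells."""
    if Tm1 not in _GRID_CACHE:
        i = np.arange(Tm1)[:, None]         # release occasion i+1, row i
        j = np.arange(1, Tm1 + 1)[None, :]  # recapture occasion j+1, column j-1
        _GRID_CACHE[Tm1] = (i, j, j > i)
    return _GRID_CACHE[Tm1]


def marray_loglik(
    marray: MArray, phi_vec: np.ndarray, p_vec: np.ndarray
) -> float:
    """Multinomial m-array log-likelihood (constant term dropped: the count
    data enter as sum of counts x log cell probabilities, which matches
    :func:`dataset_loglik` exactly for time-structured models).

    ``phi_vec`` and ``p_vec`` have length T-1 (intervals; detection at
    occasions 2..T).
    """
    phi_vec = _check_prob(np.asarray(phi_vec, dtype=float), "phi")
    p_vec = _check_prob(np.asarray(p_vec, dtype=float), "p")
    Tm1 = marray.released.shape[0]
    if phi_vec.shape != (Tm1,) or p_vec.shape != (Tm1,):
        raise ValueError("phi and p must have length T-1")
    phis = phi_vec.tolist()
    ps = p_vec.tolist()
    chi = [1.0] * (Tm1 + 1)
    for t in range(Tm1 - 1, -1, -1):
        chi[t] = (1.0 - phis[t]) + phis[t] * (1.0 - ps[t]) * chi[t + 1]
    with np.errstate(divide="ignore"):
        logphi = np.log(phi_vec)
        log1mp = np.where(p_vec < 1.0, np.log1p(-p_vec), -np.inf)
        logp = np.where(p_vec > 0.0, np.log(p_vec), -np.inf)
        logchi = np.log(np.asarray(chi[:-1]))
    # cumulative sums over intervals for cell log-probabilities:
    # P[i, j] = sum_{t=i..j-1} log phi_t + sum_{t=i+1..j-1} log(1-p_t) + log p_j
    # (1-based occasions; release i in 1..T-1, recapture j in i+1..T)
    cphi = np.concatenate([[0.0], np.cumsum(logphi)])       # cphi[k] = sum first k
    c1mp = np.concatenate([[0.0], np.cumsum(log1mp)])
    i, j, valid = _marray_grids(Tm1)
    with np.errstate(invalid="ignore"):
        cell = (cphi[j] - cphi[i]) + (c1mp[j - 1] - c1mp[i]) + logp[j - 1]
    m = marray.recaptured
    if (m[~valid]).any():
        raise ValueError("recapture cannot precede release")
    sel = valid & (m > 0)
    ll = float((m[sel] * cell[sel]).sum())
    ns = marray.never_seen
    ll += float((ns[ns > 0] * logchi[ns > 0]).sum())
    return ll if np.isfinite(ll) else float("-inf")
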