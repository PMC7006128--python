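"""Tri-allelic recursive selection model on ancestry-haplotype frequencies.

Each of the K ancestry components is treated as an allelic state of a single
locus; the favored ancestry haplotype carries a multiplicative (genic,
haploid-equivalent) fitness advantage 1 + s per generation, and the remaining
ancestries are selectively equivalent:

    p' = p (1 + s) / w_bar,    q_j' = q_j / w_bar,    w_bar = 1 + s p,

where p is the favored frequency.  The relative odds of the favored ancestry
against the rest grow geometrically, p_t / (1 - p_t) = (1+s)^t p_0 / (1-p_0),
which the numeric trajectories must reproduce and which makes the map from s
to terminal frequency (and hence to an enrichment z-score) strictly monotone.

Expressing the terminal frequency on the scan's z scale,
z = (p_t - mu_anc) / sigma_anc, lets an observed gene-level enrichment be
inverted into the selection coefficient that would produce it in t
generations of post-admixture selection.  Because all of the observed
deviation is attributed to selection at that locus, the inferred s is an
upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SelectionModelState",
    "SelectionFitResult",
    "step",
    "trajectory",
    "z_from_s",
    "infer_s",
    "fit_populations",
]

UPPER_BOUND_NOTE = (
    "s_hat attributes the entire observed ancestry deviation to selection at "
    "this locus over t generations; it is therefore an upper-bound estimate."
)


@dataclass(frozen=True)
class SelectionModelState:
    freqs: tuple[float, ...]
    favored: int
    s: float
    t: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.freqs, dtype=float)
        if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must be a probability vector")
        if not 0 <= self.favored < fr.size:
            raise ValueError("favored index outside frequency vector")
        if self.s < -1.0:
            raise ValueError("selection coefficient below -1")
        object.__setattr__(self, "freqs", tuple(float(x) for x in fr))


@dataclass(frozen=True)
class SelectionFitResult:
    populations: tuple[str, ...]
    s_hat: dict[str, float]
    z_obs: dict[str, float]
    t: int
    s_mean: float
    note: str = UPPER_BOUND_NOTE


def step(state: SelectionModelState) -> SelectionModelState:
    """One generation of genic selection on the favored ancestry."""
    p = np.asarray(state.freqs, dtype=float)
    w_bar = 1.0 + state.s * p[state.favored]
    if w_bar <= 0.0:
        raise ValueError("mean fitness non-positive")
    new = p / w_bar
    new[state.favored] = p[state.favored] * (1.0 + state.s) / w_bar
    return SelectionModelState(tuple(new), state.favored, state.s, state.t + 1)


def trajectory(
    p0,
    favored: int,
    s: float,
    t: int,
    mu_anc: float | None = None,
    sigma_anc: float | None = None,
) -> pd.DataFrame:
    """Iterate the recursion for t generations; one row per generation 0..t.

    Columns: generation, one frequency column per ancestry index, and (when
    mu_anc/sigma_anc are given) the favored ancestry's z value.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    state = SelectionModelState(tuple(np.asarray(p0, dtype=float)), favored, s)
    rows = []
    for _ in range(t + 1):
        row = {"generation": state.t}
        for i, f in enumerate(state.freqs):
            row[f"p{i}"] = f
        if mu_anc is not None and sigma_anc is not None:
            row["z"] = (state.freqs[favored] - mu_anc) / sigma_anc
        rows.append(row)
        state = step(state)
    return pd.DataFrame(rows)


def _terminal_freq(p0: float, s: float, t: int) -> float:
    p = p0
    for _ in range(t):
        p = p * (1.0 + s) / (1.0 + s * p)
    return p


def z_from_s(
    s: float,
    t: int,
    mu_anc: float,
    sigma_anc: float,
    p0: float | None = None,
) -> float:
    """Terminal enrichment z after t generations of selection at strength s.

    The trajectory starts from the genome-wide background frequency
    (p0 = mu_anc unless overridden) and the terminal favored frequency is
    standardized with the scan's (mu_anc, sigma_anc).  Strictly increasing
    in s for p0 in (0, 1).
    """
    if sigma_anc <= 0:
        raise ValueError("sigma_anc must be positive")
    if p0 is None:
        p0 = mu_anc
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    return (_terminal_freq(p0, s, t) - mu_anc) / sigma_anc


def infer_s(
    z_obs: float,
    t: int,
    mu_anc: float,
    sigma_anc: float,
    p0: float | None = None,
    tol: float = 1e-8,
    s_bounds: tuple[float, float] = (0.0, 1.0),
) -> float:
    """Invert the monotone map s -> z by root bracketing.

    Raises when z_obs falls outside the achievable range
    [z(s_bounds[0]), z(s_bounds[1])].
    """
    lo, hi = s_bounds
    z_lo = z_from_s(lo, t, mu_anc, sigma_anc, p0)
    z_hi = z_from_s(hi, t, mu_anc, sigma_anc, p0)
    if not z_lo <= z_obs <= z_hi:
        raise ValueError(
            f"z_obs = {z_obs:.4g} outside achievable range "
            f"[{z_lo:.4g}, {z_hi:.4g}] for s in [{lo}, {hi}], t = {t}"
        )
    if z_obs == z_lo:
        return lo
    if z_obs == z_hi:
        return hi
    return float(brentq(
        lambda s: z_from_s(s, t, mu_anc, sigma_anc, p0) - z_obs,
        lo, hi, xtol=tol,
    ))


def fit_populations(
    z_obs: dict[str, float],
    mu_anc: dict[str, float],
    sigma_anc: dict[str, float],
    t: int = 20,
    p0: dict[str, float] | None = None,
    s_bounds: tuple[float, float] = (0.0, 1.0),
) -> SelectionFitResult:
    """Infer s per population from observed enrichment z and average them."""
    if not z_obs:
        raise ValueError("need at least one population")
    s_hat = {}
    for pop, z in z_obs.items():
        s_hat[pop] = infer_s(
            z, t, mu_anc[pop], sigma_anc[pop],
            p0=None if p0 is None else p0.get(pop),
            s_bounds=s_bounds,
        )
    return SelectionFitResult(
        populations=tuple(z_obs),
        s_hat=s_hat,
        z_obs=dict(z_obs),
        t=t,
        s_mean=float(np.mean(list(s_hat.values()))),
    )
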