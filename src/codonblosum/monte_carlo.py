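"""Monte Carlo neutral replicates and one-sided empirical p-values.

Each replicate draws N events i.i.d. from Categorical(p_1..p_J) over the
neutral table and records the replicate mean BLOSUM score mu_s and radical
fraction r_s. The primary tests ask whether the observed cohort is *more
radical* than neutral:

    p_mean = (1/M) sum_s 1{mu_s <= mu_obs}
    p_rad  = (1/M) sum_s 1{r_s >= r_obs}

Ties count as extreme (non-strict inequalities), so the plain empirical
fraction can report exactly 0; an add-one correction (1+count)/(M+1) is
available behind a flag for callers who want a strictly positive estimate.
Both opposite tails are always reported: a cohort under purifying-style
selection (conservative shift) shows up in the opposite tail, and silently
flipping the tail would turn a one-sided test into an unacknowledged
two-sided one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neutral_model import NeutralEventTable

#: Default terminal replicate count for convergence checks.
DEFAULT_M = 7600

#: Default convergence grid, ending at DEFAULT_M.
DEFAULT_M_GRID = (100, 250, 500, 1000, 2000, 4000, DEFAULT_M)


@dataclass(frozen=True)
class ReplicateSet:
    """Summaries (mu_s, r_s) of M neutral replicates of cohort size N."""

    M: int
    N: int
    seed: int
    mean_scores: np.ndarray
    radical_fractions: np.ndarray


@dataclass(frozen=True)
class NeutralTest:
    """One-sided empirical p-values with Monte Carlo standard errors.

    ``p_mean``/``p_rad`` test the radical direction; the ``_opposite``
    fields are the reversed-inequality tails. On any tie
    ``p + opposite >= 1``.
    """

    p_mean: float
    p_rad: float
    p_mean_opposite: float
    p_rad_opposite: float
    mc_se: dict[str, float]
    M: int


def _mc_se(p: float, M: int) -> float:
    return math.sqrt(p * (1.0 - p) / M)


def simulate(table: NeutralEventTable, N: int, M: int, seed: int) -> ReplicateSet:
    """Draw M neutral replicates of N events each; reproducible under seed."""
    if N < 1 or M < 1:
        raise ValueError(f"N and M must be >= 1 (got N={N}, M={M})")
    rng = np.random.default_rng(seed)
    scores = table.scores
    radical = table.radical_flags.astype(float)
    draws = rng.choice(table.J, size=(M, N), p=table.probs)
    return ReplicateSet(
        M=M,
        N=N,
        seed=seed,
        mean_scores=scores[draws].mean(axis=1),
        radical_fractions=radical[draws].mean(axis=1),
    )


def p_values(
    reps: ReplicateSet,
    mu_obs: float,
    r_obs: float,
    add_one: bool = False,
) -> NeutralTest:
    """One-sided empirical p-values against the replicate null.

    ``add_one=True`` applies the (1 + count) / (M + 1) correction to every
    tail, guaranteeing p > 0.
    """
    mu = reps.mean_scores
    r = reps.radical_fractions
    M = reps.M

    def frac(count: int) -> float:
        if add_one:
            return (1 + count) / (M + 1)
        return count / M

    p_mean = frac(int((mu <= mu_obs).sum()))
    p_rad = frac(int((r >= r_obs).sum()))
    p_mean_opp = frac(int((mu >= mu_obs).sum()))
    p_rad_opp = frac(int((r <= r_obs).sum()))
    se = {
        "p_mean": _mc_se(p_mean, M),
        "p_rad": _mc_se(p_rad, M),
        "p_mean_opposite": _mc_se(p_mean_opp, M),
        "p_rad_opposite": _mc_se(p_rad_opp, M),
    }
    return NeutralTest(
        p_mean=p_mean,
        p_rad=p_rad,
        p_mean_opposite=p_mean_opp,
        p_rad_opposite=p_rad_opp,
        mc_se=se,
        M=M,
    )


def convergence_check(
    table: NeutralEventTable,
    N: int,
    mu_obs: float,
    r_obs: float,
    seed: int,
    M_grid: tuple[int, ...] = DEFAULT_M_GRID,
) -> pd.DataFrame:
    """Re-estimate the p-values across an increasing replicate-count grid.

    Each grid point uses an independent seed stream. A grid point is flagged
    non-converged when either p estimate moves by more than 3 pooled Monte
    Carlo standard errors from the previous point. Returns a DataFrame with
    columns M, p_mean, p_rad, their SEs, and the flag.
    """
    grid = tuple(int(m) for m in M_grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("M_grid must be strictly increasing")
    ss = np.random.SeedSequence(seed)
    rows = []
    prev: NeutralTest | None = None
    for m, child in zip(grid, ss.spawn(len(grid))):
        reps = simulate(table, N=N, M=m, seed=child.generate_state(1)[0] % (2**31))
        test = p_values(reps, mu_obs, r_obs)
        flagged = False
        if prev is not None:
            for attr in ("p_mean", "p_rad"):
                delta = abs(getattr(test, attr) - getattr(prev, attr))
                pooled = math.hypot(test.mc_se[attr], prev.mc_se[attr])
                if pooled > 0 and delta > 3 * pooled:
                    flagged = True
        rows.append(
            {
                "M": m,
                "p_mean": test.p_mean,
                "p_rad": test.p_rad,
                "se_p_mean": test.mc_se["p_mean"],
                "se_p_rad": test.mc_se["p_rad"],
                "non_converged": flagged,
            }
        )
        prev = test
    return pd.DataFrame(rows)


def calibration_pvalues(
    table: NeutralEventTable,
    n_trials: int,
    N: int,
    M: int,
    seed: int,
) -> np.ndarray:
    """Null self-test: draw observed cohorts from the neutral table itself
    and return the p_rad of each trial.

    Under the null the p-values are (super-)uniform on the lattice induced
    by N and M; used for calibration checks.
    """
    rng = np.random.default_rng(seed)
    radical = table.radical_flags.astype(float)
    p = table.probs
    out = np.empty(n_trials)
    for t in range(n_trials):
        obs = radical[rng.choice(table.J, size=N, p=p)].mean()
        reps = radical[rng.choice(table.J, size=(M, N), p=p)].mean(axis=1)
        out[t] = float((reps >= obs).mean())
    return out
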