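"""Elo-rating engine and hierarchy statistics for round-robin tournaments.

A group of animals competes in round robins of pairwise contests (tube tests);
ratings are updated sequentially with the classical Elo rule and summarized by

- per-round-robin ordinal ranks (:func:`ordinal_ranks`),
- hierarchy *stability*: the fraction of animals whose rank is unchanged
  between consecutive round robins, moving-averaged (:func:`hierarchy_stability`),
- pairwise *consistency*: a capped run-length counter of repeated same-winner
  outcomes within a pair, reset on reversals (:func:`pairwise_consistency`),
- *delta Elo*: per-animal rating change between round robins (:func:`delta_elo`)
  and its rank-dependent standard deviation (:func:`rank_variance`),
- the *defensive index* A/(A+B) of dyadic defensive-behavior durations,
- a random-outcome null ensemble for observed-vs-chance comparison
  (:func:`null_ensemble`).

:class:`HierarchyAnalysis` wraps the chain in a model/fit/results idiom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hierkit import synthio

logger = logging.getLogger(__name__)

__all__ = [
    "EloState",
    "elo_update",
    "elo_trajectories",
    "ordinal_ranks",
    "rank_table",
    "hierarchy_stability",
    "pairwise_consistency",
    "mean_consistency",
    "delta_elo",
    "rank_variance",
    "defensive_index",
    "null_ensemble",
    "HierarchyAnalysis",
    "HierarchyResults",
]

DEFAULT_K = 100.0
DEFAULT_START = 1000.0


def _validate_log(log: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("round_robin", "contest_idx", "animal_a", "animal_b", "winner") if c not in log.columns]
    if missing:
        raise ValueError(f"contest log missing columns: {missing}")
    if log["group_id"].nunique() > 1 if "group_id" in log.columns else False:
        raise ValueError("log contains multiple groups; analyze one group at a time")
    log = log.sort_values("contest_idx", kind="mergesort").reset_index(drop=True)
    bad = log[(log["winner"] != log["animal_a"]) & (log["winner"] != log["animal_b"])]
    if len(bad):
        raise ValueError(f"winner not a contest participant (or draw) at contest_idx {bad['contest_idx'].tolist()[:5]}")
    return log


# ---------------------------------------------------------------------------
# Elo
# ---------------------------------------------------------------------------


def elo_update(r_winner: float, r_loser: float, k: float = DEFAULT_K) -> tuple[float, float]:
    """One Elo update: winner gains, loser loses ``k * (1 - E_winner)`` points.

    ``E_winner = 1 / (1 + 10**((r_loser - r_winner) / 400))`` is the winner's
    expected score; the update is exactly zero-sum.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if not (math.isfinite(r_winner) and math.isfinite(r_loser)):
        raise ValueError("ratings must be finite")
    expected = 1.0 / (1.0 + 10.0 ** ((r_loser - r_winner) / 400.0))
    delta = k * (1.0 - expected)
    return r_winner + delta, r_loser - delta


@dataclass
class EloState:
    """Rating trajectories for one group.

    ``history`` is an ``(n_contests + 1, n_animals)`` array of ratings, row 0
    being the common start rating; ``rr_end_row`` maps a round-robin index to
    the history row holding ratings at the end of that round robin.
    """

    animals: list[str]
    k: float
    start: float
    history: np.ndarray
    rr_end_row: dict[int, int]
    round_robins: list[int]

    @property
    def ratings(self) -> dict[str, float]:
        return dict(zip(self.animals, self.history[-1]))

    def ratings_at(self, round_robin: int) -> dict[str, float]:
        if round_robin not in self.rr_end_row:
            raise ValueError(f"round robin {round_robin} not in log")
        return dict(zip(self.animals, self.history[self.rr_end_row[round_robin]]))


def elo_trajectories(log: pd.DataFrame, k: float = DEFAULT_K, start: float = DEFAULT_START) -> EloState:
    """Sequentially apply :func:`elo_update` over a time-ordered contest log.

    The total of all ratings is conserved at ``n_animals * start`` after every
    contest (zero-sum invariant).
    """
    log = _validate_log(log)
    animals = sorted(set(log["animal_a"]) | set(log["animal_b"]))
    col = {a: i for i, a in enumerate(animals)}
    history = np.empty((len(log) + 1, len(animals)))
    history[0] = start
    ratings = np.full(len(animals), float(start))
    rr_end_row: dict[int, int] = {}
    for row_i, row in enumerate(log.itertuples(index=False), start=1):
        winner = row.winner
        loser = row.animal_b if winner == row.animal_a else row.animal_a
        if winner not in col or loser not in col:
            raise ValueError(f"unknown animal in contest {row.contest_idx}")
        rw, rl = elo_update(ratings[col[winner]], ratings[col[loser]], k)
        ratings[col[winner]], ratings[col[loser]] = rw, rl
        history[row_i] = ratings
        rr_end_row[int(row.round_robin)] = row_i
    return EloState(
        animals=animals,
        k=k,
        start=start,
        history=history,
        rr_end_row=rr_end_row,
        round_robins=sorted(rr_end_row),
    )


def ordinal_ranks(state: EloState, at_round_robin: int) -> dict[str, int]:
    """Ordinal ranks (1 = highest rating) at the end of a round robin.

    Ties are broken by the rating at the end of the previous round robin
    (higher prior rating ranks better), then by animal identifier.
    """
    current = state.ratings_at(at_round_robin)
    earlier = [r for r in state.round_robins if r < at_round_robin]
    prior = state.ratings_at(earlier[-1]) if earlier else {a: state.start for a in state.animals}
    ordered = sorted(state.animals, key=lambda a: (-current[a], -prior[a], a))
    return {a: i + 1 for i, a in enumerate(ordered)}


def rank_table(state: EloState) -> pd.DataFrame:
    """Round robins x animals table of ordinal ranks."""
    rows = {rr: ordinal_ranks(state, rr) for rr in state.round_robins}
    return pd.DataFrame.from_dict(rows, orient="index")[state.animals]


# ---------------------------------------------------------------------------
# stability & consistency
# ---------------------------------------------------------------------------


def hierarchy_stability(ranks: pd.DataFrame, window: int = 2) -> pd.Series:
    """Moving-averaged fraction of animals with unchanged rank per transition.

    For each consecutive pair of round robins the raw stability is the number
    of animals whose ordinal rank did not change divided by the group size
    (1 = no rank changes, 0 = every animal changed).  The reported series is
    the trailing moving average of the raw values over ``window`` transitions,
    indexed by the round robin ending each transition.  A single round robin
    yields an empty series.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if ranks.shape[0] < 2:
        return pd.Series(dtype=float, name="stability")
    raw = (ranks.to_numpy()[1:] == ranks.to_numpy()[:-1]).mean(axis=1)
    smooth = pd.Series(raw).rolling(window, min_periods=1).mean().to_numpy()
    return pd.Series(smooth, index=ranks.index[1:], name="stability")


def pairwise_consistency(log: pd.DataFrame, cap: int | None = None) -> pd.DataFrame:
    """Capped run-length consistency per pair per contest.

    For each unordered pair, a counter starts at 0 on the pair's first
    contest, increments (capped at ``cap``) when the outcome repeats the
    pair's previous outcome, and resets to 0 when it reverses.  Consistency is
    ``counter / cap``, so values share a [0, 1] scale across group sizes.
    ``cap`` defaults to 4 for quartets, 3 for trios, else the group size.

    Returns a tidy frame ``(pair, contest_idx, round_robin, consistency)``;
    pairs with fewer than two contests are skipped (logged).
    """
    log = _validate_log(log)
    animals = sorted(set(log["animal_a"]) | set(log["animal_b"]))
    if cap is None:
        cap = {4: 4, 3: 3}.get(len(animals), len(animals))
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rows = []
    pair_key = log.apply(lambda r: tuple(sorted((r["animal_a"], r["animal_b"]))), axis=1)
    for pair, grp in log.groupby(pair_key, sort=True):
        if len(grp) < 2:
            logger.warning("pair %s has fewer than 2 contests; consistency undefined, skipped", pair)
            continue
        counter, prev = 0, None
        for row in grp.itertuples(index=False):
            if prev is None:
                counter = 0
            elif row.winner == prev:
                counter = min(cap, counter + 1)
            else:
                counter = 0
            prev = row.winner
            rows.append(
                {
                    "pair": "|".join(pair),
                    "contest_idx": row.contest_idx,
                    "round_robin": row.round_robin,
                    "consistency": counter / cap,
                }
            )
    return pd.DataFrame(rows, columns=["pair", "contest_idx", "round_robin", "consistency"])


def mean_consistency(log: pd.DataFrame, cap: int | None = None) -> float:
    """Group-level consistency: mean over pairs of per-contest consistency."""
    df = pairwise_consistency(log, cap=cap)
    if df.empty:
        return float("nan")
    return float(df.groupby("pair")["consistency"].mean().mean())


# ---------------------------------------------------------------------------
# delta Elo and rank variance
# ---------------------------------------------------------------------------


def delta_elo(state: EloState) -> pd.DataFrame:
    """Per-animal rating change between consecutive round robins.

    Row ``t`` holds ``rating_end(t) - rating_end(t-1)``; by the zero-sum
    property each row sums to 0.  Requires at least two round robins.
    """
    rrs = state.round_robins
    rows = {}
    for prev, cur in zip(rrs[:-1], rrs[1:]):
        before = state.history[state.rr_end_row[prev]]
        after = state.history[state.rr_end_row[cur]]
        rows[cur] = dict(zip(state.animals, after - before))
    return pd.DataFrame.from_dict(rows, orient="index")[state.animals]


def rank_variance(delta: pd.DataFrame, final_ranks: dict[str, int]) -> tuple[pd.Series, float]:
    """Sample SD of delta Elo pooled within each final rank.

    Returns ``(sd_per_rank, mean_sd)`` where the mean is across ranks (the
    reference line for rank-dependent variance plots).  Ranks pooling fewer
    than two observations get NaN (flagged via log).
    """
    by_rank: dict[int, list[float]] = {}
    for animal, rank in final_ranks.items():
        if animal in delta.columns:
            by_rank.setdefault(rank, []).extend(delta[animal].tolist())
    sds = {}
    for rank in sorted(by_rank):
        vals = np.asarray(by_rank[rank], dtype=float)
        if len(vals) < 2:
            logger.warning("rank %d has <2 delta-Elo observations; SD undefined", rank)
            sds[rank] = float("nan")
        else:
            sds[rank] = float(np.std(vals, ddof=1))
    series = pd.Series(sds, name="delta_elo_sd")
    valid = series.dropna()
    return series, float(valid.mean()) if len(valid) else float("nan")


def defensive_index(dur_a: float, dur_b: float) -> float:
    """Share of total dyadic defensive duration attributed to animal A.

    ``A / (A + B)``; both durations zero is undefined and returns NaN (not 0).
    """
    if dur_a < 0 or dur_b < 0:
        raise ValueError("durations must be non-negative")
    total = dur_a + dur_b
    if total == 0:
        logger.warning("both defensive durations zero; index undefined")
        return float("nan")
    return dur_a / total


# ---------------------------------------------------------------------------
# random-outcome null
# ---------------------------------------------------------------------------


def null_ensemble(
    log: pd.DataFrame,
    n_reps: int = 1000,
    seed: int = 0,
    window: int = 2,
    cap: int | None = None,
    k: float = DEFAULT_K,
    start: float = DEFAULT_START,
) -> pd.DataFrame:
    """Stability/consistency distribution under random contest outcomes.

    Each replicate keeps the observed schedule but draws every winner by fair
    coin flip, then recomputes mean hierarchy stability and group consistency.
    Returns one row per replicate (``rep``, ``stability_mean``,
    ``consistency_mean``); empirical quantiles of these columns provide the
    observed-vs-null comparison (model fitting is delegated to standard
    statistical routines).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        null_log = synthio.simulate_random_log(log, seed=int(rng.integers(2**31)))
        state = elo_trajectories(null_log, k=k, start=start)
        stab = hierarchy_stability(rank_table(state), window=window)
        rows.append(
            {
                "rep": rep,
                "stability_mean": float(stab.mean()) if len(stab) else float("nan"),
                "consistency_mean": mean_consistency(null_log, cap=cap),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------


class HierarchyAnalysis:
    """Hierarchy analysis of one group's contest log, statsmodels-style.

    >>> model = HierarchyAnalysis(log, k=100, start=1000)
    >>> res = model.fit(null_reps=1000, seed=7)
    >>> print(res.summary())
    """

    def __init__(self, log: pd.DataFrame, k: float = DEFAULT_K, start: float = DEFAULT_START,
                 window: int = 2, cap: int | None = None):
        self.log = _validate_log(log)
        self.k = k
        self.start = start
        self.window = window
        self.cap = cap

    def fit(self, null_reps: int = 0, seed: int = 0) -> "HierarchyResults":
        state = elo_trajectories(self.log, k=self.k, start=self.start)
        ranks = rank_table(state)
        stability = hierarchy_stability(ranks, window=self.window)
        consistency = pairwise_consistency(self.log, cap=self.cap)
        delta = delta_elo(state)
        final = ordinal_ranks(state, state.round_robins[-1])
        sd_per_rank, mean_sd = rank_variance(delta, final) if len(delta) else (pd.Series(dtype=float), float("nan"))
        null = null_ensemble(self.log, n_reps=null_reps, seed=seed, window=self.window, cap=self.cap,
                             k=self.k, start=self.start) if null_reps else None
        return HierarchyResults(
            state=state, ranks=ranks, stability=stability, consistency=consistency,
            delta=delta, final_ranks=final, sd_per_rank=sd_per_rank, mean_sd=mean_sd, null=null,
        )


@dataclass
class HierarchyResults:
    """Fitted hierarchy statistics for one group."""

    state: EloState
    ranks: pd.DataFrame
    stability: pd.Series
    consistency: pd.DataFrame
    delta: pd.DataFrame
    final_ranks: dict[str, int]
    sd_per_rank: pd.Series
    mean_sd: float
    null: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        """Per-animal table: final rating, final rank, mean delta Elo."""
        mean_delta = self.delta.mean() if len(self.delta) else pd.Series(dtype=float)
        return pd.DataFrame(
            {
                "final_elo": pd.Series(self.state.ratings),
                "final_rank": pd.Series(self.final_ranks),
                "mean_delta_elo": mean_delta,
            }
        ).sort_values("final_rank")

    def null_quantiles(self, q=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        if self.null is None:
            raise ValueError("fit with null_reps > 0 to obtain a null ensemble")
        return self.null[["stability_mean", "consistency_mean"]].quantile(list(q))

    def plot_trajectories(self, ax=None):
        """Elo rating trajectories per animal (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, animal in enumerate(self.state.animals):
            ax.plot(self.state.history[:, i], label=animal)
        ax.set_xlabel("contest")
        ax.set_ylabel("Elo rating")
        ax.legend()
        return ax
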