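"""Day-of-year phenotypes from repeated ordinal phenology scores.

Spring budbreak is scored 0-6 (0 dormant bud ... 3 emergence of green
leaves ... 6 fully unfolded leaves) and autumn leaf senescence 0-8 (0
uniformly green ... 7 = 50% leaf abscission ... 8 = >=90% abscission) on a
handful of assessment dates per season.  The phenotype used in the genetic
analysis is the day of year (DoY) at which a tree reaches the critical score
(3 for budbreak, 7 for senescence): the first date on which the critical
score is recorded exactly, otherwise the linear interpolation between the
first pair of adjacent dates whose scores bracket it.  Trees that never
reach or bracket the critical score are missing.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: trait -> critical score (budbreak: emergence of green leaves;
#: senescence: 50% leaf abscission)
CRITICAL_SCORES: Dict[str, int] = {"budbreak": 3, "senescence": 7}

#: trait -> inclusive ordinal score range
SCORE_RANGES: Dict[str, Tuple[int, int]] = {"budbreak": (0, 6), "senescence": (0, 8)}


class MalformedTrajectoryError(ValueError):
    """Observation dates are not strictly increasing."""


class ScoreRangeError(ValueError):
    """A score lies outside the trait's ordinal scale."""


def doy_at_critical(
    observations: Sequence[Tuple[float, float]],
    critical_score: float,
    score_range: Optional[Tuple[int, int]] = None,
) -> Optional[float]:
    """DoY at which a score trajectory reaches ``critical_score``.

    Parameters
    ----------
    observations:
        Ordered ``(doy, score)`` pairs for one tree, strictly increasing in
        ``doy``.
    critical_score:
        The critical stage defining the event.
    score_range:
        Optional inclusive ``(lo, hi)`` validation range for scores.

    Returns
    -------
    The DoY of the first exact record of the critical score; else the linear
    interpolation within the first adjacent pair bracketing it
    (``s1 < critical < s2``); else ``None`` (event not observed).  The
    interpolated value is kept fractional; rounding belongs to reporting.
    """
    if len(observations) == 0:
        raise MalformedTrajectoryError("empty trajectory")
    doys = np.asarray([o[0] for o in observations], dtype=float)
    scores = np.asarray([o[1] for o in observations], dtype=float)
    if np.any(np.diff(doys) <= 0):
        raise MalformedTrajectoryError("observation DoYs must be strictly increasing")
    if score_range is not None:
        lo, hi = score_range
        if np.any(scores < lo) or np.any(scores > hi):
            raise ScoreRangeError(f"score outside scale [{lo}, {hi}]")
    exact = np.nonzero(scores == critical_score)[0]
    if exact.size:
        # earliest exact record of the critical score wins
        return float(doys[exact[0]])
    for k in range(len(doys) - 1):
        s1, s2 = scores[k], scores[k + 1]
        if s1 < critical_score < s2:
            # first bracketing pair in time; with two points linear
            # regression reduces to interpolation
            d1, d2 = doys[k], doys[k + 1]
            return float(d1 + (critical_score - s1) * (d2 - d1) / (s2 - s1))
    return None


def score_table_to_doy(
    scores: pd.DataFrame,
    trait: str,
    critical_score: Optional[float] = None,
    date_columns: Optional[Sequence[str]] = None,
    validate: bool = True,
) -> pd.Series:
    """Per-tree DoY for one trait from a wide score table.

    ``scores`` has one row per tree and one column per assessment date; date
    columns are named ``d<DoY>`` (e.g. ``d102``) unless given explicitly.
    Missing scores (NaN) are skipped.  Returns a float Series indexed like
    ``scores`` with NaN where the event was not observed.
    """
    if critical_score is None:
        critical_score = CRITICAL_SCORES[trait]
    if date_columns is None:
        date_columns = [c for c in scores.columns if c.startswith("d") and c[1:].isdigit()]
        date_columns = sorted(date_columns, key=lambda c: int(c[1:]))
    doys = np.array([int(c[1:]) if c.startswith("d") else int(c) for c in date_columns])
    rng = SCORE_RANGES.get(trait) if validate else None
    out = np.full(len(scores), np.nan)
    vals = scores[list(date_columns)].to_numpy(dtype=float)
    for r in range(len(scores)):
        mask = ~np.isnan(vals[r])
        if not mask.any():
            continue
        res = doy_at_critical(list(zip(doys[mask], vals[r][mask])), critical_score, rng)
        if res is not None:
            out[r] = res
    return pd.Series(out, index=scores.index, name=f"{trait}_doy")


def trial_doy_table(
    score_table: pd.DataFrame,
    critical_scores: Optional[Mapping[str, float]] = None,
    trial_col: str = "trial",
    tree_col: str = "tree",
    trait_col: str = "trait",
    known_trials: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-tree DoY table from a long score table.

    ``score_table`` has one row per tree x trait with columns ``trial``,
    ``tree``, ``trait`` plus wide date columns (``d<DoY>``) of repeated
    scores, as produced by the S1-dialect reader or the simulator.  Returns
    a tidy frame ``trial, tree, trait, doy`` (``doy`` NaN when the event was
    not observed).
    """
    critical_scores = dict(CRITICAL_SCORES, **(critical_scores or {}))
    if known_trials is not None:
        unknown = set(score_table[trial_col].astype(str)) - {str(t) for t in known_trials}
        if unknown:
            raise KeyError(f"unknown trial code(s): {sorted(unknown)}")
    pieces = []
    for trait, sub in score_table.groupby(trait_col, sort=False):
        if trait not in critical_scores:
            raise KeyError(f"no critical score defined for trait {trait!r}")
        doy = score_table_to_doy(sub, trait, critical_scores[trait])
        pieces.append(
            pd.DataFrame(
                {
                    trial_col: sub[trial_col].to_numpy(),
                    tree_col: sub[tree_col].to_numpy(),
                    trait_col: trait,
                    "doy": doy.to_numpy(),
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)


def trial_mean_doy(doy_table: pd.DataFrame, trial_col: str = "trial") -> pd.DataFrame:
    """Trial x trait mean DoY over non-missing trees, rounded for reporting.

    Returns columns ``trial, trait, n, mean_doy`` with ``mean_doy`` rounded
    to the nearest integer day (fractional per-tree values are averaged
    first; rounding happens only here).
    """
    rows = []
    for (trial, trait), sub in doy_table.groupby([trial_col, "trait"], sort=True):
        ok = sub["doy"].dropna()
        rows.append(
            {
                trial_col: trial,
                "trait": trait,
                "n": int(len(ok)),
                "mean_doy": int(round(ok.mean())) if len(ok) else np.nan,
            }
        )
    return pd.DataFrame(rows)
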