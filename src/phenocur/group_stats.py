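"""Group comparison protocol: plant-level aggregation and Welch t-tests.

The unit of biological replication is the plant, never the time point.  Each
per-time phenotype series is first collapsed to one scalar per plant (the
temporal mean, ignoring missing values), and control vs. drought groups of
these plant-level aggregates are compared with Welch's two-sample t-test:

    t  = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b)
    df = (s2_a/n_a + s2_b/n_b)^2
         / [ (s2_a/n_a)^2/(n_a-1) + (s2_b/n_b)^2/(n_b-1) ]   (Welch-Satterthwaite)

with sample variances and a two-sided p-value from the Student-t tail.  No
multiple-testing correction is applied; the number of tests run is reported
so users can apply their own.

Time-resolved summaries (mean with t-based 95% confidence band per time
point) support diagnostic trajectory plots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_model import PhenocurError

logger = logging.getLogger("phenocur")


class DegenerateGroupsError(PhenocurError):
    """Both groups have zero variance and different means; t is infinite."""


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    df: float
    p_two_sided: float
    n_a: int
    n_b: int


def plant_level_aggregate(values: Iterable[float]) -> float:
    """Temporal mean of one plant's phenotype series, skipping missing values.

    Missing values (NaN, e.g. Dispersion+ at time points with a single
    change component) are excluded from both numerator and denominator.
    Returns NaN when every value is missing; callers exclude such plants.
    """
    arr = np.asarray([math.nan if v is None else float(v) for v in values])
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        logger.warning("all values missing; plant excluded from aggregation")
        return math.nan
    return float(finite.mean())


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch's two-sample t-test (unequal variances), two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two plants")
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(t_stat=0.0, df=float(a.size + b.size - 2),
                               p_two_sided=1.0, n_a=a.size, n_b=b.size)
        raise DegenerateGroupsError("zero variance in both groups with unequal means")
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t_stat=float(t), df=float(df), p_two_sided=float(p),
                       n_a=int(a.size), n_b=int(b.size))


def summarize_mean_ci(
    groups_by_time: dict[int, Sequence[float]], level: float = 0.95
) -> pd.DataFrame:
    """Per-time mean and t-based confidence half-width across replicates.

    Time points with a single replicate report the mean only (no interval);
    the half-width is t_{1-(1-level)/2, n-1} * s / sqrt(n).
    """
    rows = []
    for t in sorted(groups_by_time):
        vals = np.asarray(groups_by_time[t], dtype=float)
        vals = vals[np.isfinite(vals)]
        n = vals.size
        if n == 0:
            continue
        mean = float(vals.mean())
        if n >= 2:
            half = float(stats.t.ppf(0.5 + level / 2, n - 1)
                         * vals.std(ddof=1) / math.sqrt(n))
        else:
            half = math.nan
        rows.append({"t": t, "mean": mean, "ci_half_width": half, "n": n})
    return pd.DataFrame(rows, columns=["t", "mean", "ci_half_width", "n"])


def compare_treatments(
    table: pd.DataFrame,
    phenotypes: Sequence[str],
    group_col: str = "treatment",
    groups: tuple[str, str] = ("control", "drought"),
    within: Optional[str] = "species",
) -> pd.DataFrame:
    """Welch comparisons of plant-level aggregates, one row per phenotype.

    ``table`` is a tidy per-time phenotype table with ``plant_id`` and
    ``group_col`` columns (the output of the phenotype modules).  Each
    phenotype is aggregated to the plant level first; plants whose series is
    entirely missing are excluded with a warning.
    """
    strata = sorted(table[within].unique()) if within else [None]
    rows = []
    for stratum in strata:
        sub = table if stratum is None else table[table[within] == stratum]
        for phen in phenotypes:
            per_plant = (
                sub.groupby(["plant_id", group_col])[phen]
                .apply(lambda s: plant_level_aggregate(s.tolist()))
                .reset_index()
            )
            per_plant = per_plant[np.isfinite(per_plant[phen])]
            ga = per_plant.loc[per_plant[group_col] == groups[0], phen].to_numpy()
            gb = per_plant.loc[per_plant[group_col] == groups[1], phen].to_numpy()
            row = {"within": stratum, "phenotype": phen,
                   "group_a": groups[0], "group_b": groups[1],
                   "n_a": ga.size, "n_b": gb.size}
            if ga.size < 2 or gb.size < 2:
                logger.warning("%s/%s: fewer than 2 plants per group, test skipped",
                               stratum, phen)
                row.update({"t": math.nan, "df": math.nan, "p": math.nan})
            else:
                try:
                    res = welch_t(ga, gb)
                    row.update({"t": res.t_stat, "df": res.df, "p": res.p_two_sided})
                except DegenerateGroupsError:
                    logger.warning("%s/%s: degenerate groups, test skipped",
                                   stratum, phen)
                    row.update({"t": math.nan, "df": math.nan, "p": math.nan})
            rows.append(row)
    out = pd.DataFrame(rows, columns=["within", "phenotype", "group_a", "group_b",
                                      "n_a", "n_b", "t", "df", "p"])
    logger.info("ran %d Welch tests (no multiplicity correction applied)",
                int(np.isfinite(out["t"]).sum()))
    return out
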