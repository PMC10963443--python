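"""Multi-group comparison machinery.

Normality screening (Shapiro-Wilk), Kruskal-Wallis omnibus test, all-pairs
Nemenyi post hoc with the Tukey (studentized-range) reference distribution,
compact letter displays, paired t-tests, and the vegetation-type summary
table (pooled daily MDT/DRT with significance letters).

The Nemenyi statistic for groups i, j with pooled average ranks R_i, R_j is

    q_ij = |R_i - R_j| / sqrt( N(N+1)/12 * (1/n_i + 1/n_j) )

referred to the studentized-range distribution with k groups and infinite
degrees of freedom via  p_ij = P( q_{k,inf} >= q_ij * sqrt(2) ).  A
chi-square variant (q_ij^2 against chi2 with k-1 df) is available behind a
flag. Ranks are midranks (average ranks on ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError

DEFAULT_ALPHA = 0.001  # the summary table's significance level for letters


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test; used to route parametric vs rank-based
    comparisons. Requires 3 <= n <= 5000 and non-constant data."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValidationError(f"shapiro_wilk: n={x.size} outside [3, 5000]")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("shapiro_wilk: constant input")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H; p from chi-square with k-1 df."""
    if len(groups) < 2:
        raise ValidationError("kruskal_wallis: need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValidationError(f"kruskal_wallis: group {i} has n < 2")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        # all observations tied: H = 0 by convention (tie correction -> 0/0)
        return 0.0, len(arrays) - 1, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), len(arrays) - 1, float(p)


@dataclass
class PosthocResult:
    labels: list
    h: float
    df: int
    p_omnibus: float
    mean_ranks: np.ndarray
    statistic: pd.DataFrame   # pairwise q matrix
    p_matrix: pd.DataFrame    # symmetric, diagonal NaN
    alpha: float = DEFAULT_ALPHA

    @property
    def letters(self) -> dict:
        return compact_letters(self.p_matrix, alpha=self.alpha)


def nemenyi_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    method: str = "tukey",
    alpha: float = DEFAULT_ALPHA,
) -> PosthocResult:
    """All-pairs Nemenyi post hoc test on pooled midranks."""
    if method not in ("tukey", "chisq"):
        raise ValidationError(f"nemenyi_posthoc: unknown method {method!r}")
    h, df, p_omni = kruskal_wallis(groups)
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(k)]
    sizes = np.array([g.size for g in arrays])
    N = int(sizes.sum())
    ranks = stats.rankdata(np.concatenate(arrays))
    mean_ranks = np.array(
        [ranks[s - n : s].mean() for s, n in zip(np.cumsum(sizes), sizes)]
    )
    q = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(N * (N + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            qij = abs(mean_ranks[i] - mean_ranks[j]) / se
            if method == "tukey":
                pij = float(stats.studentized_range.sf(qij * np.sqrt(2.0), k, np.inf))
            else:
                pij = float(stats.chi2.sf(qij**2, k - 1))
            q[i, j] = q[j, i] = qij
            p[i, j] = p[j, i] = min(1.0, pij)
    return PosthocResult(
        labels=labels,
        h=h,
        df=df,
        p_omnibus=p_omni,
        mean_ranks=mean_ranks,
        statistic=pd.DataFrame(q, index=labels, columns=labels),
        p_matrix=pd.DataFrame(p, index=labels, columns=labels),
        alpha=alpha,
    )


def compact_letters(p_matrix: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> dict:
    """Compact letter display by insert-and-absorb.

    Contract: two groups share at least one letter iff their pairwise p-value
    is >= alpha (i.e. iff they are *not* significantly different). Letters
    are assigned a, b, c, ... in group order; redundant letter sets are
    absorbed.
    """
    labels = list(p_matrix.index)
    k = len(labels)
    P = p_matrix.to_numpy()
    if P.shape != (k, k):
        raise ValidationError("compact_letters: p matrix must be square")
    if not np.allclose(P, P.T, equal_nan=True):
        raise ValidationError("compact_letters: p matrix must be symmetric")

    # letter sets as sets of group indices; start with one all-inclusive set
    sets: list[set] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if P[i, j] < alpha:  # significant pair: i and j must not share
                new_sets = []
                for s in sets:
                    if i in s and j in s:
                        new_sets.append(s - {i})
                        new_sets.append(s - {j})
                    else:
                        new_sets.append(s)
                # absorb: drop sets contained in another
                sets = [
                    s
                    for a, s in enumerate(new_sets)
                    if s
                    and not any(
                        b != a and s < t or (s == t and b < a)
                        for b, t in enumerate(new_sets)
                    )
                ]
    # order letter sets by their first (lowest-index) member for stable output
    sets.sort(key=lambda s: min(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {}
    for gi, lab in enumerate(labels):
        chars = [alphabet[si % 26] for si, s in enumerate(sets) if gi in s]
        out[lab] = "".join(chars)
    return out


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    n: int


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Classical two-sided paired t-test on day-matched differences.

    All-zero differences are the defined degenerate case (t=0, p=1);
    constant non-zero differences have no finite t and raise
    :class:`DegenerateDataError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("paired_t_test: unequal lengths")
    if x.size < 3:
        raise ValidationError("paired_t_test: need >= 3 pairs")
    d = y - x
    n = d.size
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0, n=n)
        raise DegenerateDataError(
            "paired_t_test: zero-variance non-zero differences"
        )
    t, p = stats.ttest_rel(y, x)
    return PairedTResult(
        t=float(t), df=n - 1, p=float(p), mean_diff=float(d.mean()), n=n
    )


def table1_analogue(
    daily_by_site: dict,
    vegetation_by_site: dict,
    alpha: float = DEFAULT_ALPHA,
    unit: str = "days",
) -> pd.DataFrame:
    """Vegetation-type comparison of MDT and DRT with significance letters.

    For each vegetation type, daily values are pooled across that type's
    (stand) sites; for each window (365 d / warmest quarter / coldest
    quarter, MDT; warmest quarter, DRT) the groups are compared with
    Kruskal-Wallis + Nemenyi and annotated with compact letters at ``alpha``.

    ``unit='days'`` pools daily values (days as replicates — the default,
    with the pseudo-replication caveat documented); ``unit='sites'`` uses one
    per-site mean per site.

    ``daily_by_site`` maps site_id -> daily_summaries frame;
    ``vegetation_by_site`` maps site_id -> vegetation label (include only the
    sites that should enter, i.e. stands).
    """
    from .aggregate import CQ_MONTHS, WQ_MONTHS, quarter_mask

    if unit not in ("days", "sites"):
        raise ValidationError(f"table1_analogue: unknown unit {unit!r}")

    veg_order = []
    for sid in daily_by_site:
        v = vegetation_by_site.get(sid)
        if v is not None and v not in veg_order:
            veg_order.append(str(v))

    def pooled(metric: str, months) -> dict:
        vals: dict[str, list] = {v: [] for v in veg_order}
        for sid, daily in daily_by_site.items():
            v = vegetation_by_site.get(sid)
            if v is None:
                continue
            idx = pd.DatetimeIndex(daily.index)
            mask = (
                quarter_mask(idx, months) if months is not None else np.ones(len(idx), bool)
            )
            series = daily[metric].to_numpy()[mask]
            if unit == "sites":
                if series.size:
                    vals[str(v)].append(float(series.mean()))
            else:
                vals[str(v)].extend(series.tolist())
        return vals

    blocks = {
        "mdt_365d": ("t_mean", None),
        "mdt_wq": ("t_mean", WQ_MONTHS),
        "mdt_cq": ("t_mean", CQ_MONTHS),
        "drt_wq": ("drt", WQ_MONTHS),
    }
    out = pd.DataFrame(index=pd.Index(veg_order, name="vegetation"))
    for name, (metric, months) in blocks.items():
        vals = pooled(metric, months)
        present = [v for v in veg_order if len(vals[v]) >= 2]
        groups = [np.asarray(vals[v]) for v in present]
        out[f"{name}_mean"] = [
            float(np.mean(vals[v])) if vals[v] else np.nan for v in veg_order
        ]
        out[f"{name}_sd"] = [
            float(np.std(vals[v], ddof=1)) if len(vals[v]) > 1 else np.nan
            for v in veg_order
        ]
        if len(present) >= 2:
            res = nemenyi_posthoc(groups, labels=present, alpha=alpha)
            letters = res.letters
        elif len(present) == 1:
            letters = {present[0]: "a"}
        else:
            letters = {}
        out[f"{name}_letters"] = [letters.get(v, "") for v in veg_order]
    return out
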