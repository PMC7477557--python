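"""Statistical battery for the binned joint series.

* :func:`stepwise_lm` — stepwise linear regression with main effects and
  pairwise interactions, selected by partial-F p-values (enter at
  p < 0.05, remove at p > 0.10, hierarchy enforced), mirroring the
  behaviour of MATLAB-style stepwise model building.
* :func:`anova_oneway` / :func:`tukey_hsd` — one-way ANOVA and the
  Tukey–Kramer honestly-significant-difference table (studentized-range
  distribution, valid for unequal group sizes).
* :func:`ks_two_sample` — two-sample Kolmogorov–Smirnov test (asymptotic
  p; the translocation-time samples this is used on are huge).
* :func:`mad_outliers` — scaled-MAD outlier flags.
* :func:`adjusted_r2` — the usual small-sample adjustment of R².
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "RegressionResult",
    "ANOVAResult",
    "TukeyResult",
    "KSResult",
    "stepwise_lm",
    "anova_oneway",
    "tukey_hsd",
    "ks_two_sample",
    "mad_outliers",
    "adjusted_r2",
]


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1)."""
    if n <= k + 1:
        raise InputError(f"need n > k + 1 observations (n={n}, k={k})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# stepwise linear regression


@dataclass
class RegressionResult:
    """Selected terms, coefficients and fit summary of a stepwise fit."""

    terms: list[str]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    r2: float
    adj_r2: float
    n_obs: int
    history: list[str] = field(default_factory=list)


def _term_column(term: str, data: dict[str, np.ndarray]) -> np.ndarray:
    if ":" in term:
        a, b = term.split(":")
        return data[a] * data[b]
    return data[term]


def _fit(y: np.ndarray, X: np.ndarray):
    """OLS via lstsq; returns (beta, sse, rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), rank


def _partial_f_p(sse_small: float, sse_big: float, df_big: int,
                 df_num: int = 1) -> float:
    """p-value of the partial F test for a ``df_num``-column change."""
    if df_big <= 0:
        return 1.0
    if sse_big <= 0:
        return 0.0 if sse_small > sse_big else 1.0
    f = (sse_small - sse_big) / df_num / (sse_big / df_big)
    return float(sps.f.sf(max(f, 0.0), df_num, df_big))


def stepwise_lm(
    response: np.ndarray | pd.Series,
    candidates: dict[str, np.ndarray] | pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_degree: int = 2,
) -> RegressionResult:
    """Bidirectional stepwise OLS from an intercept-only start.

    Candidate terms are the named main effects plus (if ``max_degree >= 2``)
    all pairwise interaction products. At each step the candidate with the
    smallest partial-F p-value below ``p_enter`` is added (an interaction
    only once both parents are in); then any included term with partial-F
    p above ``p_remove`` is removed (a main effect is locked while one of
    its interactions is included). Missing values are dropped listwise.
    The search stops when no move is possible or a model state repeats.
    """
    if isinstance(candidates, pd.DataFrame):
        data = {str(c): candidates[c].to_numpy(float) for c in candidates.columns}
    else:
        data = {k: np.asarray(v, float) for k, v in candidates.items()}
    y = np.asarray(response, float)
    if any(len(v) != len(y) for v in data.values()):
        raise InputError("response and candidates must have equal length")

    mask = np.isfinite(y)
    for v in data.values():
        mask &= np.isfinite(v)
    y = y[mask]
    data = {k: v[mask] for k, v in data.items()}
    n = len(y)

    names = list(data)
    mains = names
    inters = (
        [f"{a}:{b}" for a, b in itertools.combinations(names, 2)]
        if max_degree >= 2
        else []
    )
    all_terms = mains + inters
    if n < len(all_terms) + 2:
        raise InputError(f"need more than {len(all_terms) + 2} complete observations, have {n}")
    for name in names:
        if np.ptp(data[name]) == 0:
            raise InputError(f"candidate {name!r} is constant (singular design)")

    def design(terms: list[str]) -> np.ndarray:
        cols = [np.ones(n)] + [_term_column(t, data) for t in terms]
        return np.column_stack(cols)

    def addition_for(t: str, terms: list[str]) -> list[str]:
        """Columns an addition of ``t`` brings in: itself plus any missing
        parent main effects (the model stays hierarchical)."""
        new = [t]
        if ":" in t:
            new = [p for p in t.split(":") if p not in terms] + new
        return new

    def eligible_to_add(terms: list[str]) -> list[str]:
        return [t for t in all_terms if t not in terms]

    def eligible_to_remove(terms: list[str]) -> list[str]:
        locked = set()
        for t in terms:
            if ":" in t:
                locked.update(t.split(":"))
        return [t for t in terms if ":" in t or t not in locked]

    terms: list[str] = []
    history: list[str] = []
    seen = {tuple(terms)}
    _, sse_cur, _ = _fit(y, design(terms))

    while True:
        moved = False
        # forward step
        best = None  # (p, added columns, sse)
        for t in eligible_to_add(terms):
            added = addition_for(t, terms)
            X = design(terms + added)
            _, sse, rank = _fit(y, X)
            if rank < X.shape[1]:
                continue  # collinear with current model; skip
            df_new = n - (len(terms) + len(added) + 1)
            p = _partial_f_p(sse_cur, sse, df_new, df_num=len(added))
            if p < p_enter and (best is None or p < best[0]):
                best = (p, added, sse)
        if best is not None:
            terms = terms + best[1]
            sse_cur = best[2]
            history.append(f"+{'+'.join(best[1])} (p={best[0]:.3g})")
            moved = True

        # backward step(s)
        while True:
            worst_p, worst_t, worst_sse = None, None, None
            df_cur = n - (len(terms) + 1)
            for t in eligible_to_remove(terms):
                reduced = [u for u in terms if u != t]
                _, sse_red, _ = _fit(y, design(reduced))
                p = _partial_f_p(sse_red, sse_cur, df_cur)
                if p > p_remove and (worst_p is None or p > worst_p):
                    worst_p, worst_t = p, t
                    worst_sse = sse_red
            if worst_t is None:
                break
            terms = [u for u in terms if u != worst_t]
            sse_cur = worst_sse
            history.append(f"-{worst_t} (p={worst_p:.3g})")
            moved = True

        state = tuple(sorted(terms))
        if not moved or state in seen:
            break
        seen.add(state)

    X = design(terms)
    beta, sse, rank = _fit(y, X)
    if rank < X.shape[1]:
        raise InputError("final design is singular")
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    k = len(terms)
    adj = adjusted_r2(r2, n, k) if n > k + 1 else float("nan")
    df_res = n - k - 1
    mse = sse / df_res if df_res > 0 else np.nan
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * mse, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2 * sps.t.sf(np.abs(tstat), df_res)
    labels = ["(intercept)"] + terms
    return RegressionResult(
        terms=terms,
        coefficients=dict(zip(labels, beta.tolist())),
        p_values=dict(zip(labels, pvals.tolist())),
        r2=r2,
        adj_r2=adj,
        n_obs=n,
        history=history,
    )


# ---------------------------------------------------------------------------
# ANOVA / Tukey


@dataclass
class ANOVAResult:
    labels: list[str]
    means: dict[str, float]
    ns: dict[str, int]
    f: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float


@dataclass
class TukeyResult:
    comparisons: pd.DataFrame  # group_a, group_b, diff, p_adj, significant
    alpha: float


def _check_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    clean = {str(k): np.asarray(v, float) for k, v in groups.items()}
    clean = {k: v[np.isfinite(v)] for k, v in clean.items()}
    if len(clean) < 2:
        raise InputError("need at least 2 groups")
    if any(len(v) == 0 for v in clean.values()):
        raise InputError("every group needs at least 1 value")
    total = sum(len(v) for v in clean.values())
    if total <= len(clean):
        raise InputError("total observations must exceed number of groups")
    return clean


def anova_oneway(groups: dict[str, np.ndarray]) -> ANOVAResult:
    """Classic one-way fixed-effects ANOVA (between/within decomposition)."""
    clean = _check_groups(groups)
    values = np.concatenate(list(clean.values()))
    grand = values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in clean.values())
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in clean.values())
    k = len(clean)
    n = len(values)
    df_b, df_w = k - 1, n - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = float("inf") if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        f = ms_b / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    return ANOVAResult(
        labels=list(clean),
        means={k_: float(v.mean()) for k_, v in clean.items()},
        ns={k_: len(v) for k_, v in clean.items()},
        f=float(f),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        ms_within=float(ms_w),
    )


def tukey_hsd(groups: dict[str, np.ndarray], alpha: float = 0.05) -> TukeyResult:
    """Tukey–Kramer all-pairs comparison after a one-way ANOVA.

    For groups a, b the studentized statistic is
    ``q = |mean_a - mean_b| / sqrt(MSW/2 * (1/n_a + 1/n_b))`` and the
    adjusted p comes from the studentized-range distribution with k groups
    and the ANOVA residual df — conservative under unequal sample sizes.
    """
    res = anova_oneway(groups)
    clean = _check_groups(groups)
    k = len(clean)
    rows = []
    for a, b in itertools.combinations(clean, 2):
        diff = res.means[a] - res.means[b]
        if res.ms_within == 0:
            p = 0.0 if diff != 0 else 1.0
        else:
            se = np.sqrt(res.ms_within / 2 * (1 / res.ns[a] + 1 / res.ns[b]))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, res.df_within))
        rows.append(
            {"group_a": a, "group_b": b, "diff": diff,
             "p_adj": min(max(p, 0.0), 1.0), "significant": p < alpha}
        )
    return TukeyResult(comparisons=pd.DataFrame(rows), alpha=alpha)


# ---------------------------------------------------------------------------
# KS / MAD


@dataclass
class KSResult:
    d: float
    p_value: float
    n_x: int
    n_y: int


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> KSResult:
    """Two-sided two-sample KS test, asymptotic p-value.

    D is the supremum of |ECDF_x - ECDF_y|; symmetric in its inputs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be nonempty")
    res = sps.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return KSResult(d=float(res.statistic), p_value=float(res.pvalue),
                    n_x=len(x), n_y=len(y))


#: consistency factor making MAD estimate the SD for normal data
MAD_SCALE = 1.4826


def mad_outliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Flag values whose scaled-MAD distance from the median exceeds ``k``.

    Distance is ``|x - median| / (1.4826 * MAD)`` with
    ``MAD = median(|x - median|)``. When MAD is 0 (over half the values
    identical) any value differing from the median is flagged.
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise InputError("need at least 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x != med
    return np.abs(x - med) / (MAD_SCALE * mad) > k
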