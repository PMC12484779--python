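"""The study's statistical battery.

Spearman correlations (optionally partial, rank-residual based) with
Benjamini-Hochberg FDR correction; percentile-bootstrap mediation with
standardized OLS paths; paired and one-sample t tests with Cohen's d;
Kruskal-Wallis with the epsilon-squared effect size eps2 = H/(n-1); and
the Dwass-Steel-Critchlow-Fligner (DSCF) pairwise post hoc test on the
studentized-range scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MediationResult",
    "GroupComparison",
    "spearman_fdr",
    "mediate",
    "paired_t",
    "one_sample_t",
    "kruskal_wallis_eps2",
    "epsilon_squared_from_h",
    "cohens_d_from_t",
    "dscf_posthoc",
]


@dataclass
class MediationResult:
    a: float
    b: float
    direct: float  # c'
    indirect: float  # a*b
    total: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    indirect_boot: np.ndarray = field(repr=False, default=None)


@dataclass
class GroupComparison:
    test: str
    statistic: float
    df: float | None
    p: float
    effect_size: float | None = None
    effect_name: str | None = None
    n: int | None = None
    pairwise: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# correlations


def _rank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def _partial_spearman(x: np.ndarray, y: np.ndarray, Z: np.ndarray) -> tuple[float, float]:
    """Spearman partial correlation via rank-regression residuals."""
    rx, ry = _rank(x), _rank(y)
    RZ = np.column_stack([np.ones(len(x))] + [_rank(Z[:, j]) for j in range(Z.shape[1])])
    bx, *_ = np.linalg.lstsq(RZ, rx, rcond=None)
    by, *_ = np.linalg.lstsq(RZ, ry, rcond=None)
    ex, ey = rx - RZ @ bx, ry - RZ @ by
    r, _ = sps.pearsonr(ex, ey)
    n, g = len(x), Z.shape[1]
    df = n - 2 - g
    t = r * np.sqrt(df / max(1e-300, 1 - r**2))
    p = 2 * sps.t.sf(abs(t), df)
    return float(r), float(p)


def spearman_fdr(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman rho per pair with BH-adjusted p over the declared family.

    Ties get average ranks.  With covariates, the partial correlation of
    rank-regression residuals is used.  The FDR family is exactly the
    list of pairs passed in.
    """
    rows = []
    for xcol, ycol in pairs:
        sub = table[[xcol, ycol] + (covariates or [])].dropna()
        if len(sub) < 4:
            raise ValueError(f"pair ({xcol}, {ycol}): need >= 4 complete rows")
        x, y = sub[xcol].to_numpy(float), sub[ycol].to_numpy(float)
        for name, v in ((xcol, x), (ycol, y)):
            if np.ptp(v) == 0:
                raise ValueError(f"constant column {name!r}")
        if covariates:
            rho, p = _partial_spearman(x, y, sub[covariates].to_numpy(float))
        else:
            rho, p = sps.spearmanr(x, y)
        rows.append({"x": xcol, "y": ycol, "rho": float(rho), "p": float(p), "n": len(sub)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# mediation


def _paths_from_moments(Sxx, Sxm, Sxy, Smm, Smy):
    """Closed-form OLS paths from centered cross-moments.

    a from m~x; (b, c') from y~x+m; total from y~x.  The OLS identity
    total = c' + a*b holds exactly.
    """
    det = Sxx * Smm - Sxm**2
    a = Sxm / Sxx
    b = (Sxx * Smy - Sxm * Sxy) / det
    cprime = (Smm * Sxy - Sxm * Smy) / det
    total = Sxy / Sxx
    return a, b, cprime, total


def mediate(
    x,
    m,
    y,
    n_boot: int = 1000,
    seed: int = 0,
    standardize: bool = True,
) -> MediationResult:
    """Simple mediation with a percentile bootstrap CI on the indirect effect.

    Paths are OLS: a from m~x, (b, c') from y~x+m; indirect = a*b; the
    95% CI is the 2.5th/97.5th percentile of the indirect effect over
    ``n_boot`` case-resampled replicates.  With ``standardize`` (the
    default) x, m, y are z-scored first so the paths are standardized
    betas and total = direct + indirect on the standardized scale.
    """
    x, m, y = (np.asarray(v, dtype=float) for v in (x, m, y))
    n = len(x)
    if not (len(m) == len(y) == n):
        raise ValueError("x, m, y must have equal length")
    if n < 10:
        raise ValueError("need n >= 10")
    D = np.column_stack([x, m, y])
    if standardize:
        D = (D - D.mean(axis=0)) / D.std(axis=0, ddof=1)

    # point estimates from centered cross-moments (identical to lstsq fits)
    C = D - D.mean(axis=0)
    Sxx = C[:, 0] @ C[:, 0]
    Sxm = C[:, 0] @ C[:, 1]
    Sxy = C[:, 0] @ C[:, 2]
    Smm = C[:, 1] @ C[:, 1]
    Smy = C[:, 1] @ C[:, 2]
    if abs(Sxm**2 - Sxx * Smm) < 1e-12 * Sxx * Smm:
        raise ValueError("x and m are collinear; mediation paths undefined")
    a, b, cprime, total = _paths_from_moments(Sxx, Sxm, Sxy, Smm, Smy)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    chunk = max(1, min(n_boot, 200_000 // max(n, 1)))
    done = 0
    while done < n_boot:
        B = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(B, n))
        block = D[idx]  # (B, n, 3)
        c = block - block.mean(axis=1, keepdims=True)
        bSxx = np.einsum("bi,bi->b", c[..., 0], c[..., 0])
        bSxm = np.einsum("bi,bi->b", c[..., 0], c[..., 1])
        bSxy = np.einsum("bi,bi->b", c[..., 0], c[..., 2])
        bSmm = np.einsum("bi,bi->b", c[..., 1], c[..., 1])
        bSmy = np.einsum("bi,bi->b", c[..., 1], c[..., 2])
        ba, bb, _, _ = _paths_from_moments(bSxx, bSxm, bSxy, bSmm, bSmy)
        boots[done : done + B] = ba * bb
        done += B
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    return MediationResult(
        a=float(a),
        b=float(b),
        direct=float(cprime),
        indirect=float(a * b),
        total=float(total),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        seed=seed,
        indirect_boot=boots,
    )


# ---------------------------------------------------------------------------
# t tests


def paired_t(a, b) -> GroupComparison:
    """Paired t test with Cohen's d = mean(diff)/sd(diff) = t/sqrt(n)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) != len(b):
        raise ValueError("paired vectors must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    d = diff.mean() / sd
    return GroupComparison(
        test="paired_t", statistic=float(t), df=n - 1, p=float(p),
        effect_size=float(d), effect_name="cohen_d", n=n,
    )


def one_sample_t(a, mu: float = 0.0, alternative: str = "two-sided") -> GroupComparison:
    """One-sample t test against mu; df = n - 1."""
    a = np.asarray(a, float)
    n = len(a)
    if n < 3:
        raise ValueError("need n >= 3")
    if a.std(ddof=1) == 0:
        raise ValueError("zero variance")
    res = sps.ttest_1samp(a, popmean=mu, alternative=alternative)
    d = (a.mean() - mu) / a.std(ddof=1)
    return GroupComparison(
        test="one_sample_t", statistic=float(res.statistic), df=n - 1,
        p=float(res.pvalue), effect_size=float(d), effect_name="cohen_d", n=n,
    )


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired/one-sample Cohen's d recovered from a printed t and n."""
    return t / np.sqrt(n)


# ---------------------------------------------------------------------------
# Kruskal-Wallis and DSCF


def epsilon_squared_from_h(H: float, n: int) -> float:
    """Rank epsilon-squared effect size: eps2 = H*(n+1)/(n^2-1) = H/(n-1)."""
    return H / (n - 1)


def kruskal_wallis_eps2(groups: list[np.ndarray]) -> GroupComparison:
    """Kruskal-Wallis H (tie-corrected) with eps2 = H/(n-1).

    If every pooled value is identical the tie-correction convention
    gives H = 0 (p = 1) rather than an error.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    n = sum(len(g) for g in groups)
    if n < len(groups) + 1:
        raise ValueError("too few observations")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return GroupComparison(
            test="kruskal_wallis", statistic=0.0, df=len(groups) - 1, p=1.0,
            effect_size=0.0, effect_name="epsilon_sq", n=n,
        )
    H, p = sps.kruskal(*groups)
    return GroupComparison(
        test="kruskal_wallis", statistic=float(H), df=len(groups) - 1, p=float(p),
        effect_size=float(epsilon_squared_from_h(H, n)), effect_name="epsilon_sq", n=n,
    )


def dscf_posthoc(groups: list[np.ndarray], names: list[str] | None = None) -> pd.DataFrame:
    """Dwass-Steel-Critchlow-Fligner all-pairs post hoc test.

    For each pair of groups, the Wilcoxon rank-sum statistic on the
    pair's pooled (average-rank, tie-corrected) ranks is standardized
    and scaled by sqrt(2); the p value refers |q| to the studentized
    range distribution with g groups and infinite df (the large-sample
    approximation used by common implementations).
    """
    groups = [np.asarray(g, float) for g in groups]
    g = len(groups)
    if g < 3:
        raise ValueError("need >= 3 groups")
    if any(len(x) < 2 for x in groups):
        raise ValueError("every group needs >= 2 observations")
    if names is None:
        names = [f"g{i + 1}" for i in range(g)]
    rows = []
    for i, j in combinations(range(g), 2):
        xi, xj = groups[i], groups[j]
        ni, nj = len(xi), len(xj)
        pooled = np.concatenate([xi, xj])
        ranks = sps.rankdata(pooled, method="average")
        W = ranks[ni:].sum()  # rank sum of group j
        nn = ni + nj
        mean = nj * (nn + 1) / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / ((nn) * (nn - 1))
        var = ni * nj / 12.0 * ((nn + 1) - tie_term)
        if var <= 0:
            q, p = 0.0, 1.0
        else:
            q = np.sqrt(2.0) * (W - mean) / np.sqrt(var)
            p = float(sps.studentized_range.sf(abs(q), g, np.inf))
        rows.append({"group_a": names[i], "group_b": names[j], "W": float(W), "q": float(q), "p": p})
    return pd.DataFrame(rows)
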