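"""Moderated differential expression via the randomized variance model.

With only a handful of replicates per condition, per-gene residual variances
are too noisy for an ordinary ANOVA F-test.  The randomized variance model
assumes each gene's residual precision 1/sigma^2 is drawn from a
Gamma(shape a, scale b) prior shared across genes.  Under that prior the
residual mean square s^2 of a gene with m within-group degrees of freedom
satisfies

    s^2 * a * b  ~  F(m, 2a),

so (a, b) can be fitted by maximizing the marginal likelihood of the
observed s^2 values.  The moderated variance

    sigma_tilde^2 = (m * s^2 + 2/b) / (m + 2a)

shrinks each gene's variance toward the prior, and the moderated statistic
F_mod = MS_between / sigma_tilde^2 is referred to F(k-1, m+2a): the prior
effectively adds 2a denominator degrees of freedom.

The module also provides the small-sample one-way ANOVA with Fisher's LSD
post-hoc test used for phenotype tables (growth, photosynthesis, hormones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

S2_FLOOR = 1e-12


class RVMBoundaryError(RuntimeError):
    """The marginal likelihood is maximized on the boundary (a -> infinity)."""


@dataclass(frozen=True)
class RVMPrior:
    """Fitted gamma prior on residual precision.

    ``a`` and ``b`` are the shape and scale of the precision prior (prior
    mean precision = a*b); ``m`` is the common per-gene residual degrees of
    freedom; ``loglik`` is the marginal log-likelihood at the optimum.
    """

    a: float
    b: float
    m: int
    loglik: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.m >= 1):
            raise ValueError("require a > 0, b > 0, m >= 1")

    @property
    def extra_df(self) -> float:
        """Denominator degrees of freedom added by the prior (= 2a)."""
        return 2.0 * self.a


def _group_stats(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, int]:
    """Per-condition means, residual mean squares, between-group mean squares
    and residual df, all on the log2 scale."""
    log = matrix.log2()
    conds = matrix.condition_order
    groups = [log[matrix.samples_of(c)].to_numpy(dtype=float) for c in conds]
    ns = np.array([g.shape[1] for g in groups])
    means = np.column_stack([g.mean(axis=1) for g in groups])
    ssw = sum(((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for g in groups)
    m = int(ns.sum() - len(conds))
    s2 = ssw / m
    grand = (means * ns).sum(axis=1) / ns.sum()
    msb = ((ns * (means - grand[:, None]) ** 2).sum(axis=1)) / (len(conds) - 1)
    mean_table = pd.DataFrame(means, index=log.index, columns=[f"mean_{c}" for c in conds])
    return mean_table, s2, msb, m


def rvm_marginal_loglik(s2: np.ndarray, a: float, b: float, m: int) -> float:
    """Summed log marginal density of residual mean squares under the prior.

    The marginal law of s^2 is that of X/(a*b) with X ~ F(m, 2a); the
    density therefore carries a Jacobian factor a*b.
    """
    ab = a * b
    return float(np.sum(stats.f.logpdf(s2 * ab, m, 2.0 * a) + np.log(ab)))


def fit_rvm_prior(matrix: ExpressionMatrix, tol: float = 1e-8) -> RVMPrior:
    """Fit the precision prior (a, b) by marginal maximum likelihood.

    Optimization runs on (log a, log b) from a moment-based start so
    positivity is structural; Nelder-Mead with a tight function tolerance
    keeps the fit deterministic.  Raises :class:`RVMBoundaryError` when the
    s^2 values have (numerically) no spread, in which case the likelihood
    pushes a to infinity.
    """
    _, s2, _, m = _group_stats(matrix)
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 < S2_FLOOR):
        warnings.warn(
            f"{int((s2 < S2_FLOOR).sum())} residual variance(s) below "
            f"{S2_FLOOR:g}; floored", RuntimeWarning, stacklevel=2,
        )
        s2 = np.maximum(s2, S2_FLOOR)
    mean_s2 = s2.mean()
    # CV of s2 under the prior shrinks as a grows; no spread => boundary
    if np.std(s2) / mean_s2 < 1e-6:
        raise RVMBoundaryError(
            "prior degenerate (a -> infinity): residual variances have no spread"
        )

    def neg(params: np.ndarray) -> float:
        a, b = np.exp(params)
        ll = rvm_marginal_loglik(s2, a, b, m)
        return -ll if np.isfinite(ll) else np.inf

    # moment start: E[s2] = 1/(b (a-1)) for a > 1; try several shapes
    starts = []
    for a0 in (1.5, 3.0, 8.0, 30.0):
        b0 = 1.0 / (mean_s2 * max(a0 - 1.0, 0.5))
        starts.append(np.log([a0, b0]))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": tol, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    if a > 1e6:
        raise RVMBoundaryError("prior degenerate (a -> infinity) at optimum")
    return RVMPrior(a=float(a), b=float(b), m=m, loglik=float(-best.fun))


def rvm_f_test(matrix: ExpressionMatrix, prior: RVMPrior) -> pd.DataFrame:
    """Moderated F-test of equal condition means for every probe.

    Returns one row per probe: per-condition log2 means, s2, the moderated
    variance s2_tilde, F_mod, its degrees of freedom (k-1, m+2a), the
    upper-tail p and the Benjamini-Hochberg q.
    """
    mean_table, s2, msb, m = _group_stats(matrix)
    s2 = np.maximum(s2, S2_FLOOR)
    k = matrix.n_conditions
    a, b = prior.a, prior.b
    s2_tilde = (m * s2 + 2.0 / b) / (m + 2.0 * a)
    f_mod = msb / s2_tilde
    df1, df2 = k - 1, m + 2.0 * a
    p = stats.f.sf(f_mod, df1, df2)
    out = mean_table.copy()
    out["s2"] = s2
    out["s2_tilde"] = s2_tilde
    out["F_mod"] = f_mod
    out["df1"] = df1
    out["df2"] = df2
    out["p"] = p
    out["q"] = bh_fdr(p)
    out.index.name = "probe"
    return out


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(
    results: pd.DataFrame, p_max: float = 0.05, q_max: float = 0.05
) -> list[str]:
    """Probes passing the conjunctive threshold p < p_max and q < q_max."""
    mask = (results["p"] < p_max) & (results["q"] < q_max)
    return list(results.index[mask])


# ---------------------------------------------------------------------------
# one-way ANOVA + Fisher's LSD (phenotype tables)
# ---------------------------------------------------------------------------


@dataclass
class AnovaLsdResult:
    f: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    group_means: list[float]
    pairwise: pd.DataFrame  # i, j, mean_diff, lsd, significant
    letters: list[str]


def one_way_anova_lsd(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> AnovaLsdResult:
    """Classic one-way ANOVA with Fisher's least-significant-difference test.

    Two group means differ when |mean_i - mean_j| exceeds
    LSD = t(1 - alpha/2, df_within) * sqrt(MSW * (1/n_i + 1/n_j)).
    Groups sharing a letter in the compact letter display are not
    significantly different (the convention of bar-chart annotations).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs at least 2 values")
    k = len(arrs)
    ns = np.array([a.size for a in arrs])
    means = np.array([a.mean() for a in arrs])
    grand = np.concatenate(arrs).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    dfb, dfw = k - 1, int(ns.sum() - k)
    msb, msw = ssb / dfb, ssw / dfw
    if msw == 0.0:
        f_stat = 0.0 if msb == 0.0 else np.inf
    else:
        f_stat = msb / msw
    p = float(stats.f.sf(f_stat, dfb, dfw)) if np.isfinite(f_stat) else 0.0
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, dfw)
    rows = []
    differ: set[tuple[int, int]] = set()
    for i, j in combinations(range(k), 2):
        lsd = tcrit * np.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j]))
        diff = abs(means[i] - means[j])
        sig = bool(diff > lsd)
        if sig:
            differ.add((i, j))
        rows.append({"i": i, "j": j, "mean_diff": diff, "lsd": lsd, "significant": sig})
    letters = _compact_letter_display(means, differ)
    return AnovaLsdResult(
        f=float(f_stat), p=p, df_between=dfb, df_within=dfw, ms_within=msw,
        group_means=list(means), pairwise=pd.DataFrame(rows), letters=letters,
    )


def _compact_letter_display(means: np.ndarray, differ: set[tuple[int, int]]) -> list[str]:
    """Assign letters so that two groups share a letter iff they are not
    significantly different; letters ordered by descending group mean."""
    import networkx as nx

    k = len(means)
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if (i, j) not in differ:
                g.add_edge(i, j)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: -max(means[i] for i in c))
    labels = [""] * k
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, clique in zip(alphabet, cliques):
        for i in clique:
            labels[i] += letter
    return ["".join(sorted(s)) for s in labels]
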