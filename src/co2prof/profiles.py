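"""Series-test-of-cluster profile assignment for short ordered series.

Each differentially expressed gene is summarized as a log2-ratio vector
anchored at the reference condition (v[0] = 0) and assigned to the model
profile — an integer shape vector such as (0, 1, 0) — with which it has the
highest Pearson correlation.  The null for "how many genes would land on
this profile by chance" permutes the condition positions of every gene's
vector (all 3! = 6 orderings for three conditions, identity included),
re-anchors, re-assigns, and averages the per-profile counts; profile
significance is the upper binomial tail P(X >= assigned) with
X ~ Binomial(total, expected/total), accumulated in log space so that
p-values far below float underflow remain meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .io_formats import ExpressionMatrix


@dataclass(frozen=True)
class ModelProfile:
    """Integer expression-shape vector anchored at 0 at the reference."""

    id: int
    shape: tuple[int, ...]
    max_step: int = 2

    def __post_init__(self) -> None:
        if len(self.shape) < 2:
            raise ValueError("profile needs at least 2 conditions")
        if self.shape[0] != 0:
            raise ValueError(f"profile {self.id}: shape must start at 0")
        if all(s == 0 for s in self.shape):
            raise ValueError(f"profile {self.id}: shape must not be constant")
        if any(abs(s) > 3 for s in self.shape):
            raise ValueError(f"profile {self.id}: entries must lie in [-3, 3]")
        steps = [abs(b - a) for a, b in zip(self.shape, self.shape[1:])]
        if any(s > self.max_step for s in steps):
            raise ValueError(
                f"profile {self.id}: step exceeds max_step={self.max_step}"
            )


# The 16 shipped model profiles for a three-condition series.  Profile 15 is
# (0, 0, 1): the mirror of profile 14, so that the set contains no duplicate
# shapes and covers both late-response directions.
_DEFAULT_SHAPES: dict[int, tuple[int, ...]] = {
    1: (0, 1, 2),
    2: (0, 2, 3),
    3: (0, 1, 1),
    4: (0, -1, -2),
    5: (0, 2, 1),
    6: (0, -1, 0),
    7: (0, -2, -3),
    8: (0, -2, -1),
    9: (0, -1, -3),
    10: (0, -1, 1),
    11: (0, 1, 3),
    12: (0, 1, 0),
    13: (0, -1, -1),
    14: (0, 0, -1),
    15: (0, 0, 1),
    16: (0, 1, -1),
}


def default_profiles(n_conditions: int = 3) -> list[ModelProfile]:
    """The 16 shipped three-condition model profiles.

    Other series lengths have no shipped default; supply a profile table via
    :func:`read_profile_table`.
    """
    if n_conditions != 3:
        raise ValueError(
            "default profiles are defined for 3 conditions; "
            "load a profile table for other lengths"
        )
    return [ModelProfile(id=i, shape=s) for i, s in sorted(_DEFAULT_SHAPES.items())]


def read_profile_table(path: str | Path) -> list[ModelProfile]:
    """Read profiles from a TSV with columns ``id`` and comma-separated
    ``shape`` (e.g. ``12<TAB>0,1,0``)."""
    table = pd.read_csv(path, sep="\t", dtype={"id": int, "shape": str})
    out = []
    for _, row in table.iterrows():
        shape = tuple(int(x) for x in str(row["shape"]).split(","))
        out.append(ModelProfile(id=int(row["id"]), shape=shape))
    return out


def write_profile_table(profiles: Sequence[ModelProfile], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [p.id for p in profiles],
            "shape": [",".join(str(x) for x in p.shape) for p in profiles],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ratio vectors and assignment
# ---------------------------------------------------------------------------


def log2_ratio_vectors(
    matrix: ExpressionMatrix, genes: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-gene log2 ratios of condition means against the reference.

    v[t] = mean log2 signal at condition t minus mean log2 signal at the
    reference (first) condition, so v[0] = 0 identically.
    """
    if genes is None:
        genes = matrix.probe_ids
    genes = list(genes)
    unknown = [g for g in genes if g not in matrix.signals.index]
    if unknown:
        raise KeyError(f"genes not in matrix: {unknown[:5]}")
    log = matrix.log2().loc[genes]
    cond_means = pd.DataFrame(
        {c: log[matrix.samples_of(c)].mean(axis=1) for c in matrix.condition_order}
    )
    ref = matrix.condition_order[0]
    return cond_means.sub(cond_means[ref], axis=0)


def _corr_matrix(vectors: np.ndarray, shapes: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``vectors`` with each profile shape;
    rows with zero variance yield NaN columns."""
    v = vectors - vectors.mean(axis=1, keepdims=True)
    s = shapes - shapes.mean(axis=1, keepdims=True)
    vn = np.linalg.norm(v, axis=1)
    sn = np.linalg.norm(s, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (v @ s.T) / np.outer(vn, sn)
    c[vn == 0.0, :] = np.nan
    return c


def assign_profiles(
    vectors: pd.DataFrame,
    profiles: Sequence[ModelProfile],
    min_corr: float | None = None,
) -> tuple[pd.Series, list[str]]:
    """Assign each ratio vector to the best-correlated model profile.

    Returns (gene -> profile id, unassigned genes).  Flat (zero-variance)
    vectors are unassigned; correlation ties break toward the lowest profile
    id.  ``min_corr`` optionally excludes genes whose best correlation falls
    below a floor (off by default: only flat vectors are excluded).
    """
    if not profiles:
        raise ValueError("empty profile set")
    profiles = sorted(profiles, key=lambda p: p.id)
    shapes = np.array([p.shape for p in profiles], dtype=float)
    ids = np.array([p.id for p in profiles])
    v = vectors.to_numpy(dtype=float)
    corr = _corr_matrix(v, shapes)
    flat = np.isnan(corr).all(axis=1)
    best = np.zeros(len(vectors), dtype=int)
    ok = ~flat
    if ok.any():
        # argmax returns the first (= lowest-id) profile on exact ties
        best[ok] = np.argmax(corr[ok], axis=1)
    assigned_mask = ok.copy()
    if min_corr is not None and ok.any():
        best_corr = corr[np.arange(len(vectors)), np.where(ok, best, 0)]
        assigned_mask &= best_corr >= min_corr
    assignment = pd.Series(
        ids[best[assigned_mask]], index=vectors.index[assigned_mask], name="profile"
    )
    unassigned = list(vectors.index[~assigned_mask])
    return assignment, unassigned


def _counts(assignment: pd.Series, ids: Sequence[int]) -> pd.Series:
    counts = assignment.value_counts()
    return pd.Series([int(counts.get(i, 0)) for i in ids], index=list(ids))


def expected_counts(
    vectors: pd.DataFrame,
    profiles: Sequence[ModelProfile],
    min_corr: float | None = None,
) -> pd.Series:
    """Permutation-expected number of genes per profile.

    Every permutation pi of the condition positions (all n! orderings,
    identity included) is applied to every gene's vector; the permuted
    vector is re-anchored by subtracting its new first element, re-assigned,
    and counted.  The expectation is the mean count over permutations — for
    three conditions every expected count is therefore a multiple of 1/6,
    and the expected counts sum exactly to the number of assigned genes
    (flatness is permutation-invariant).
    """
    ids = [p.id for p in sorted(profiles, key=lambda p: p.id)]
    v = vectors.to_numpy(dtype=float)
    n_cond = v.shape[1]
    perms = list(permutations(range(n_cond)))
    total = pd.Series(0.0, index=ids)
    for perm in perms:
        pv = v[:, list(perm)]
        pv = pv - pv[:, [0]]
        pdf = pd.DataFrame(pv, index=vectors.index)
        assignment, _ = assign_profiles(pdf, profiles, min_corr=min_corr)
        total = total.add(_counts(assignment, ids), fill_value=0.0)
    return total / len(perms)


# ---------------------------------------------------------------------------
# profile significance
# ---------------------------------------------------------------------------


def profile_significance(assigned: int, expected: float, total: int) -> float:
    """Upper binomial tail P(X >= assigned), X ~ Binomial(total, expected/total).

    The tail is accumulated as logsumexp of binomial log-pmf terms, so the
    computation stays stable for p-values well below 1e-300 (the returned
    float may still underflow to 0 for such extremes; use
    :func:`profile_log10_significance` to keep the magnitude).
    """
    return float(np.exp(_log_tail(assigned, expected, total)))


def profile_log10_significance(assigned: int, expected: float, total: int) -> float:
    """log10 of the upper binomial tail (exact even when the tail underflows)."""
    return float(_log_tail(assigned, expected, total) / np.log(10.0))


def _log_tail(assigned: int, expected: float, total: int) -> float:
    if not (0 <= assigned <= total):
        raise ValueError("require 0 <= assigned <= total")
    if not (0.0 <= expected <= total):
        raise ValueError("require 0 <= expected <= total")
    if assigned == 0:
        return 0.0  # log(1)
    if expected == 0.0:
        warnings.warn(
            "expected count 0 with assigned > 0: p = 0 by convention",
            RuntimeWarning, stacklevel=3,
        )
        return -np.inf
    p0 = expected / total
    ks = np.arange(assigned, total + 1)
    return float(logsumexp(stats.binom.logpmf(ks, total, p0)))


@dataclass
class ProfileStats:
    """Per-profile assignment summary: observed count, permutation
    expectation and binomial tail p-value."""

    table: pd.DataFrame  # profile, shape, assigned, expected, p


def profile_stats(
    vectors: pd.DataFrame,
    profiles: Sequence[ModelProfile],
    min_corr: float | None = None,
) -> ProfileStats:
    """Assign, compute permutation expectations, and score every profile."""
    profiles = sorted(profiles, key=lambda p: p.id)
    assignment, unassigned = assign_profiles(vectors, profiles, min_corr=min_corr)
    ids = [p.id for p in profiles]
    assigned = _counts(assignment, ids)
    expected = expected_counts(vectors, profiles, min_corr=min_corr)
    total = len(vectors)
    pvals = [
        profile_significance(int(assigned[i]), float(expected[i]), total) for i in ids
    ]
    table = pd.DataFrame(
        {
            "profile": ids,
            "shape": [",".join(str(x) for x in p.shape) for p in profiles],
            "assigned": [int(assigned[i]) for i in ids],
            "expected": [float(expected[i]) for i in ids],
            "p": pvals,
        }
    )
    return ProfileStats(table=table)


def significant_profiles(stats_: ProfileStats, alpha: float = 0.05) -> list[int]:
    """Profile ids with p < alpha, ordered by ascending p (ties by id)."""
    t = stats_.table
    sig = t[t["p"] < alpha].sort_values(["p", "profile"], kind="mergesort")
    return [int(x) for x in sig["profile"]]
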