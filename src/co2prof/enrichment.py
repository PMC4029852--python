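"""Gene-set over-representation by the hypergeometric upper tail.

For a study set of n genes drawn from a background of N, a category with K
background members and k study hits is scored by p = P(X >= k) with
X ~ Hypergeometric(N, K, n), plus the enrichment ratio

    Re = (k / n) / (K / N),

the study hit rate relative to the background rate.  The pipeline's
screening convention is raw p < 0.05 for pathway namespaces and the
stricter dual filter p < 0.05 and Re > 5 for GO biological process terms;
Benjamini-Hochberg correction is available behind a flag.  The EASE variant
(score on k-1 hits, the conservative convention of DAVID) is off by
default; the enrichment ratio always uses the unmodified counts.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotationSet
from .rvm import bh_fdr


def hypergeom_enrichment(
    study: Iterable[str],
    background: Iterable[str],
    annotations: AnnotationSet,
    ease: bool = False,
) -> pd.DataFrame:
    """Score every annotation category with at least one study hit.

    Category gene sets are intersected with the background before counting.
    Returns a table with columns namespace, category, description, k, n, K,
    N, p, re.
    """
    study_set = set(study)
    bg = set(background)
    if not study_set:
        raise ValueError("empty study set")
    if not bg:
        raise ValueError("empty background")
    offenders = study_set - bg
    if offenders:
        raise ValueError(
            f"study genes absent from background: {sorted(offenders)[:5]}"
        )
    n = len(study_set)
    N = len(bg)
    rows = []
    for cid, (desc, genes) in annotations.categories.items():
        cat = genes & bg
        K = len(cat)
        if K == 0:
            continue
        k = len(cat & study_set)
        if k == 0:
            continue
        k_eff = k - 1 if ease else k
        p = float(stats.hypergeom.sf(k_eff - 1, N, K, n))
        re = (k / n) / (K / N)
        rows.append(
            {
                "namespace": annotations.namespace,
                "category": cid,
                "description": desc,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": min(p, 1.0),
                "re": re,
            }
        )
    return pd.DataFrame(
        rows, columns=["namespace", "category", "description", "k", "n", "K", "N", "p", "re"]
    )


def filter_enriched(
    results: pd.DataFrame,
    p_max: float = 0.05,
    re_min: float = 0.0,
    adjust: bool = False,
) -> pd.DataFrame:
    """Keep categories with p < p_max and Re > re_min, sorted by ascending p.

    Adds a ``neg_log10_p`` column for bar-chart style reporting.  With
    ``adjust`` on, the threshold applies to Benjamini-Hochberg adjusted
    p-values (added as column ``q``).
    """
    if results.empty:
        out = results.copy()
        out["neg_log10_p"] = pd.Series(dtype=float)
        return out
    out = results.copy()
    crit = out["p"].to_numpy(dtype=float)
    if adjust:
        out["q"] = bh_fdr(crit)
        crit = out["q"].to_numpy(dtype=float)
    keep = (crit < p_max) & (out["re"].to_numpy(dtype=float) > re_min)
    out = out.loc[keep].sort_values(["p", "category"], kind="mergesort")
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    return out.reset_index(drop=True)
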