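"""Relative quantification by the 2^-ddCt method and platform concordance.

Per biological replicate, technical replicate Ct values are averaged first;
dCt = Ct(target) - Ct(reference gene) removes loading differences, and
ddCt = dCt(condition) - mean dCt(control condition) anchors each gene at
the control.  The fold change 2^-ddCt assumes perfect doubling per cycle
(amplification efficiency 2); it is invariant to any constant shift of a
replicate block's Ct values.  Concordance with the array is the Pearson
correlation between array log2 fold changes and log2 qPCR folds over
matched (gene, condition) pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import QpcrPlate
from .network import correlation_pvalue


def ddct_fold_change(plate: QpcrPlate, control_condition: str) -> pd.DataFrame:
    """Per (gene, condition) 2^-ddCt fold changes vs the control condition.

    Returns columns gene, condition, fold (mean over biological replicates),
    spread (SD of per-replicate folds) and n_bio.  The reference gene's fold
    is 1 in every condition by construction of ddCt.
    """
    wells = plate.wells
    if control_condition not in set(wells["condition"]):
        raise ValueError(f"control condition {control_condition!r} not in plate")
    # technical replicates averaged first
    ct = (
        wells.groupby(["gene", "condition", "bio_rep"])["ct"].mean().rename("ct")
    )
    ref = ct.xs(plate.reference_gene, level="gene").rename("ref_ct")
    dct = (ct.reset_index().merge(ref.reset_index(), on=["condition", "bio_rep"], how="left"))
    if dct["ref_ct"].isna().any():
        bad = dct.loc[dct["ref_ct"].isna()].iloc[0]
        raise ValueError(
            f"reference gene missing from block (condition={bad['condition']!r}, "
            f"bio_rep={bad['bio_rep']})"
        )
    dct["dct"] = dct["ct"] - dct["ref_ct"]
    control_mean = (
        dct[dct["condition"] == control_condition].groupby("gene")["dct"].mean()
    )
    dct = dct.merge(control_mean.rename("control_dct"), on="gene", how="left")
    dct["fold"] = 2.0 ** (-(dct["dct"] - dct["control_dct"]))
    out = (
        dct.groupby(["gene", "condition"])["fold"]
        .agg(fold="mean", spread=lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
             n_bio="count")
        .reset_index()
    )
    return out


def platform_concordance(
    array_log2fc: pd.Series, qpcr_folds: pd.DataFrame
) -> tuple[float, float, int]:
    """Pearson correlation between array and qPCR fold changes.

    ``array_log2fc`` is indexed by (gene, condition) and holds log2 fold
    changes vs the control condition; qPCR folds are log2-transformed before
    correlating.  Returns (r, two-sided p, number of matched pairs); fewer
    than 3 matched pairs is an error.
    """
    q = qpcr_folds.set_index(["gene", "condition"])["fold"]
    common = array_log2fc.index.intersection(q.index)
    n = len(common)
    if n < 3:
        raise ValueError(f"need >= 3 matched (gene, condition) pairs, got {n}")
    x = array_log2fc.loc[common].to_numpy(dtype=float)
    y = np.log2(q.loc[common].to_numpy(dtype=float))
    r = float(np.corrcoef(x, y)[0, 1])
    p = correlation_pvalue(r, n)
    return r, p, n
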