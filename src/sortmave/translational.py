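"""Antibody activatability of loss-of-signalling variants.

Anti-receptor monoclonal antibodies (83-7, 83-14) can stimulate signalling by
receptors whose insulin response is severely impaired.  To nominate variants
for antibody-based therapy the analysis first selects *robust
loss-of-insulin-signalling* variants: scored in all five insulin-signalling
replicates, with median replicate score in the lowest 80 % of the observed
loss-of-function range (the span from the most negative median up to 0), and
scored in all replicates of both antibody-signalling assays.  For each such
variant the "selective sensitivity score" is the antibody-stimulated
signalling score minus the insulin-stimulated signalling score; a variant
with selective sensitivity strictly above +0.204 for an antibody is flagged
activatable by it, and the two-antibody scatter is divided into quadrants at
that threshold.
"""

from __future__ import annotations

from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SENSITIVITY_THRESHOLD",
    "select_robust_lof",
    "selective_sensitivity",
    "sensitivity_table",
    "classify_quadrants",
]

#: Threshold on the selective sensitivity score above which a loss-of-insulin-
#: signalling variant is called antibody-activatable (strict inequality).
SENSITIVITY_THRESHOLD = 0.204

QUADRANTS = ("both-activatable", "83-7-only", "83-14-only", "neither")


def _ratio_columns(table: pd.DataFrame) -> list[str]:
    return sorted(c for c in table.columns if c.startswith("ratio_rep"))


def select_robust_lof(
    insulin_sig: pd.DataFrame,
    antibody_sigs: Mapping[str, pd.DataFrame] = None,
    required_reps: int = 5,
    range_fraction: float = 0.8,
    method: Literal["span", "quantile"] = "span",
) -> pd.Index:
    """Variants with robust loss of insulin signalling.

    ``insulin_sig`` must carry per-replicate ``ratio_rep*`` columns.  A
    variant qualifies when (a) it has a score in all ``required_reps`` insulin
    replicates, (b) its median replicate log2 score lies in the lowest
    ``range_fraction`` of the observed loss-of-function range — with
    ``method="span"`` the subinterval of [min_median, 0) nearest the minimum
    covering that fraction of its span, i.e. median <= (1 - fraction) * min;
    with ``method="quantile"`` the lowest ``range_fraction`` quantile of the
    negative medians — and (c) it is scored in every replicate of each table
    in ``antibody_sigs``.

    Raises ``ValueError`` if no variant has a negative median (empty LoF
    range).  Returns the selected variant ids as an Index.
    """
    rep_cols = _ratio_columns(insulin_sig)
    if len(rep_cols) < required_reps:
        raise ValueError(
            f"insulin signalling table has {len(rep_cols)} replicates, "
            f"{required_reps} required"
        )
    t = insulin_sig.set_index("variant")
    complete = t[rep_cols].notna().sum(axis=1) >= required_reps
    medians = np.log2(t[rep_cols]).median(axis=1, skipna=True)
    neg = medians[complete & (medians < 0)]
    if neg.empty:
        raise ValueError("no negative median scores: empty loss-of-function range")
    if method == "span":
        cutoff = (1.0 - range_fraction) * neg.min()
        selected = neg[neg <= cutoff].index
    elif method == "quantile":
        cutoff = neg.quantile(range_fraction)
        selected = neg[neg <= cutoff].index
    else:
        raise ValueError(f"unknown method {method!r}")
    if antibody_sigs:
        for label, table in antibody_sigs.items():
            ab_cols = _ratio_columns(table)
            ab = table.set_index("variant")
            full = ab.index[ab[ab_cols].notna().all(axis=1)]
            selected = selected.intersection(full)
    return selected


def selective_sensitivity(ab_score: float, insulin_score: float) -> float:
    """Antibody-stimulated minus insulin-stimulated signalling score."""
    if pd.isna(ab_score) or pd.isna(insulin_score):
        raise ValueError("both scores must be present")
    return float(ab_score) - float(insulin_score)


def sensitivity_table(
    insulin_sig: pd.DataFrame,
    antibody_sigs: Mapping[str, pd.DataFrame],
    robust_lof: pd.Index,
    threshold: float = SENSITIVITY_THRESHOLD,
) -> pd.DataFrame:
    """Per-variant selective sensitivity scores and activatability flags.

    Restricted to the ``robust_lof`` variant set; one ``sensitivity_<mAb>``
    and ``activatable_<mAb>`` column pair per antibody (label keys of
    ``antibody_sigs``, e.g. ``83-7``).
    """
    ins = insulin_sig.set_index("variant").loc[robust_lof]
    out = pd.DataFrame(index=robust_lof)
    for col in ("position", "wt_aa", "alt_aa"):
        if col in ins.columns:
            out[col] = ins[col]
    out["insulin_score"] = ins["score"]
    for label, table in antibody_sigs.items():
        ab = table.set_index("variant")["score"].reindex(robust_lof)
        out[f"score_{label}"] = ab
        out[f"sensitivity_{label}"] = ab - out["insulin_score"]
        out[f"activatable_{label}"] = out[f"sensitivity_{label}"] > threshold
    out.index.name = "variant"
    return out.reset_index()


def classify_quadrants(
    sens: pd.DataFrame,
    mabs: tuple[str, str] = ("83-7", "83-14"),
    threshold: float = SENSITIVITY_THRESHOLD,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Quadrant labels of the two-antibody sensitivity scatter + proportions.

    A variant is activatable by a mAb iff its selective sensitivity is
    strictly greater than ``threshold`` (a score exactly at the threshold is
    not activatable).  Returns the labelled table (rows missing either
    sensitivity score are dropped) and the per-quadrant proportions, which
    sum to 1.
    """
    a, b = (f"sensitivity_{m}" for m in mabs)
    out = sens.dropna(subset=[a, b]).copy()
    act_a = out[a] > threshold
    act_b = out[b] > threshold
    label = np.select(
        [act_a & act_b, act_a & ~act_b, ~act_a & act_b],
        ["both-activatable", f"{mabs[0]}-only", f"{mabs[1]}-only"],
        default="neither",
    )
    out["quadrant"] = label
    quadrants = ("both-activatable", f"{mabs[0]}-only", f"{mabs[1]}-only", "neither")
    if len(out):
        proportions = {q: float((out["quadrant"] == q).mean()) for q in quadrants}
    else:
        proportions = {q: 0.0 for q in quadrants}
    return out, proportions
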