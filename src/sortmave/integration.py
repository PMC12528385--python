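"""Cross-assay integration of variant score tables.

Surface expression is not assayed directly: it is read out as binding of two
anti-receptor monoclonal antibodies (83-7 and 83-14) with distinct epitopes.
Away from the epitopes the two readouts agree and their mean is taken as the
"expression score"; at a residue inside one antibody's epitope, mutating the
residue perturbs that antibody's binding independently of surface abundance,
so the score from the *other* antibody is used instead.  The set of discordant
epitope residues is supplied as configuration (an epitope map), with a helper
to flag candidate outliers from the two-antibody scatter for users without a
curated list.

Also here: per-position summaries, the position x substitution effect matrix
used for heatmaps, loss/gain-of-function calling, and the MaveDB-style score
file writer (three-letter ``p.`` protein HGVS).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.SeqUtils import seq3

from .library_design import AMINO_ACIDS, STOP, SYNONYMOUS, Region

__all__ = [
    "ANTIBODIES",
    "merge_expression_score",
    "flag_epitope_outliers",
    "position_summaries",
    "build_effect_matrix",
    "effect_matrix_to_table",
    "call_function_class",
    "DEFAULT_LOF_CUTOFF",
    "hgvs_pro",
    "write_mavedb_scores",
]

ANTIBODIES = ("83-7", "83-14")

#: Default loss-of-function cutoff: half of wild-type function on the log2
#: scale.  Curated-variant-derived cutoffs can be supplied instead.
DEFAULT_LOF_CUTOFF = math.log2(0.5)


def _check_epitopes(epitope_exceptions: Iterable[tuple[int, str]]) -> dict[int, str]:
    by_pos: dict[int, str] = {}
    for pos, antibody in epitope_exceptions:
        if antibody not in ANTIBODIES:
            raise ValueError(f"unknown antibody {antibody!r}")
        if pos in by_pos and by_pos[pos] != antibody:
            raise ValueError(
                f"residue {pos} listed as epitope for both antibodies"
            )
        by_pos[pos] = antibody
    return by_pos


def merge_expression_score(
    bind_83_7: pd.DataFrame,
    bind_83_14: pd.DataFrame,
    epitope_exceptions: Iterable[tuple[int, str]] = (),
) -> pd.DataFrame:
    """Merge the two antibody-binding tables into an expression score table.

    ``epitope_exceptions`` lists ``(position, antibody)`` pairs meaning the
    position belongs to that antibody's epitope; variants there take the score
    of the other antibody alone.  Elsewhere the expression score is the mean
    of the two antibody scores, falling back to whichever is present when one
    is missing.  The merged ``fdr`` is the epitope-chosen antibody's FDR at
    exception residues and the (conservative) maximum of the available FDRs
    otherwise.
    """
    epitopes = _check_epitopes(epitope_exceptions)
    a = bind_83_7.set_index("variant")
    b = bind_83_14.set_index("variant")
    idx = a.index.union(b.index)

    s7 = a["score"].reindex(idx)
    s14 = b["score"].reindex(idx)
    f7 = a["fdr"].reindex(idx) if "fdr" in a.columns else pd.Series(np.nan, index=idx)
    f14 = b["fdr"].reindex(idx) if "fdr" in b.columns else pd.Series(np.nan, index=idx)

    anno_cols = [c for c in ("position", "wt_aa", "alt_aa") if c in a.columns]
    anno = a[anno_cols].combine_first(b[anno_cols]).reindex(idx)

    score = pd.concat([s7, s14], axis=1).mean(axis=1, skipna=True)
    fdr = pd.concat([f7, f14], axis=1).max(axis=1, skipna=True)
    source = pd.Series("mean", index=idx)
    only7 = s14.isna() & s7.notna()
    only14 = s7.isna() & s14.notna()
    source[only7] = "83-7"
    source[only14] = "83-14"
    score[only7] = s7[only7]
    score[only14] = s14[only14]

    pos = anno["position"]
    in_7 = pos.map(lambda p: epitopes.get(int(p)) == "83-7" if pd.notna(p) else False)
    in_14 = pos.map(lambda p: epitopes.get(int(p)) == "83-14" if pd.notna(p) else False)
    # epitope of 83-7 mutated -> trust 83-14 (and vice versa)
    use14 = in_7 & s14.notna()
    use7 = in_14 & s7.notna()
    score[use14], fdr[use14], source[use14] = s14[use14], f14[use14], "83-14"
    score[use7], fdr[use7], source[use7] = s7[use7], f7[use7], "83-7"

    out = anno.copy()
    out["score"] = score
    out["fdr"] = fdr
    out["source"] = source
    return out.dropna(subset=["score"]).reset_index()


def flag_epitope_outliers(
    bind_83_7: pd.DataFrame, bind_83_14: pd.DataFrame, threshold: float = 1.0
) -> pd.DataFrame:
    """Candidate epitope residues from the 83-7 vs 83-14 per-position scatter.

    Positions whose median scores in the two antibody assays differ by more
    than ``threshold`` (residual from the identity line) are flagged, with the
    lower-scoring antibody recorded as the putative epitope owner.
    """
    m7 = position_summaries(bind_83_7).set_index("position")["median_score"]
    m14 = position_summaries(bind_83_14).set_index("position")["median_score"]
    both = pd.concat({"83-7": m7, "83-14": m14}, axis=1).dropna()
    resid = both["83-7"] - both["83-14"]
    flagged = both.loc[resid.abs() > threshold].copy()
    flagged["residual"] = resid[flagged.index]
    flagged["antibody"] = np.where(flagged["residual"] < 0, "83-7", "83-14")
    return flagged.reset_index()


def position_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Median score and scored-variant count per residue position."""
    scored = table.dropna(subset=["score"])
    grouped = scored.groupby("position")["score"].agg(["median", "size"])
    return grouped.rename(
        columns={"median": "median_score", "size": "n_variants"}
    ).reset_index()


def build_effect_matrix(
    table: pd.DataFrame, region: Region, wt_sequence: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Position x substitution score matrix for heatmap-style display.

    Rows are the 20 amino acids plus stop; columns are region positions.
    Returns ``(scores, wt_mask)`` with unscored cells NaN and wt_mask True at
    the wild-type residue of each column.  Raises if a variant's recorded
    wild-type residue disagrees with ``wt_sequence``.
    """
    if len(wt_sequence) != len(region):
        raise ValueError("wt_sequence length must equal region length")
    rows = list(AMINO_ACIDS) + [STOP]
    cols = list(region.positions)
    scores = pd.DataFrame(np.nan, index=rows, columns=cols)
    wt_by_pos = dict(zip(cols, wt_sequence))
    for _, rec in table.dropna(subset=["score"]).iterrows():
        pos, alt = int(rec["position"]), rec["alt_aa"]
        if pos not in wt_by_pos or alt == SYNONYMOUS:
            continue
        if rec["wt_aa"] != wt_by_pos[pos]:
            raise ValueError(
                f"wild-type mismatch at {pos}: map says {rec['wt_aa']}, "
                f"sequence says {wt_by_pos[pos]}"
            )
        scores.loc[alt, pos] = rec["score"]
    wt_mask = pd.DataFrame(False, index=rows, columns=cols)
    for pos, wt in wt_by_pos.items():
        wt_mask.loc[wt, pos] = True
    return scores, wt_mask


def effect_matrix_to_table(scores: pd.DataFrame, wt_sequence: str) -> pd.DataFrame:
    """Inverse of :func:`build_effect_matrix` (round-trip preserving)."""
    wt_by_pos = dict(zip(scores.columns, wt_sequence))
    records = []
    for pos in scores.columns:
        for alt in scores.index:
            val = scores.loc[alt, pos]
            if pd.notna(val):
                records.append(
                    {"variant": f"{wt_by_pos[pos]}{pos}{alt}",
                     "position": pos, "wt_aa": wt_by_pos[pos],
                     "alt_aa": alt, "score": float(val)}
                )
    return pd.DataFrame(records)


def call_function_class(
    score: float,
    fdr: float,
    lof_cutoff: float = DEFAULT_LOF_CUTOFF,
    fdr_cutoff: float = 0.05,
) -> str:
    """Classify one variant as LoF / GoF / WT-like / low-confidence.

    Confident calls require ``fdr < fdr_cutoff``; an extreme score without FDR
    support is low-confidence rather than WT-like.
    """
    if fdr < fdr_cutoff:
        if score <= lof_cutoff:
            return "LoF"
        if score > 0:
            return "GoF"
        return "WT-like"
    if score <= lof_cutoff or score >= -lof_cutoff:
        return "low-confidence"
    return "WT-like"


def hgvs_pro(wt_aa: str, position: int, alt_aa: str) -> str:
    """Three-letter protein HGVS, e.g. ``p.Cys35Lys``, ``p.Trp516Ter``."""
    wt3 = seq3(wt_aa)
    if alt_aa == STOP:
        alt3 = "Ter"
    elif alt_aa == SYNONYMOUS or alt_aa == wt_aa:
        alt3 = "="
    else:
        alt3 = seq3(alt_aa)
    return f"p.{wt3}{position}{alt3}"


def write_mavedb_scores(table: pd.DataFrame, path) -> None:
    """Write a MaveDB-style score CSV (hgvs_pro, score, fdr, replicate ratios)."""
    rows = table.dropna(subset=["position"]).copy()
    rows = rows[rows["wt_aa"] != SYNONYMOUS]
    rows["hgvs_pro"] = [
        hgvs_pro(w, int(p), a)
        for w, p, a in zip(rows["wt_aa"], rows["position"], rows["alt_aa"])
    ]
    rep_cols = sorted(c for c in rows.columns if c.startswith("ratio_rep"))
    cols = ["hgvs_pro", "score"] + (["fdr"] if "fdr" in rows.columns else []) + rep_cols
    rows[cols].to_csv(path, index=False)
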