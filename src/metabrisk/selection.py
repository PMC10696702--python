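"""Replicated biomarker selection and chemical super-class over-representation.

A feature is *selected* when its VIP score exceeds the threshold (1.0 by
convention) in BOTH independent case-control sets — replication across sets
is the guard against set-specific artefacts.  Fold change is the ratio of
case to control mean abundance on the raw (relative-abundance) scale, per
set.

``superclass_enrichment`` asks whether the selected metabolites concentrate
in predefined chemical super-classes: a one-sided hypergeometric
over-representation test per class against a background universe of
identified metabolites, Benjamini-Hochberg adjusted across classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def fold_change(abundance: pd.DataFrame, groups: pd.Series,
                case_label: str = "case") -> pd.Series:
    """Per-feature case/control ratio of mean raw abundance."""
    is_case = (groups == case_label).to_numpy()
    case_mean = abundance.iloc[is_case].mean(axis=0)
    control_mean = abundance.iloc[~is_case].mean(axis=0)
    return case_mean / control_mean


def replicated_selection(vips1: pd.Series, vips2: pd.Series,
                         threshold: float = 1.0,
                         fold_change1: pd.Series | None = None,
                         fold_change2: pd.Series | None = None) -> pd.DataFrame:
    """Features with VIP above ``threshold`` in both sets.

    ``vips1`` and ``vips2`` must cover the same feature universe.  Returns a
    per-feature frame with both VIPs, optional per-set fold changes and the
    ``selected`` flag.
    """
    u1, u2 = set(vips1.index), set(vips2.index)
    if u1 != u2:
        diff = sorted(u1.symmetric_difference(u2))[:10]
        raise ValueError(f"feature universes differ between sets, e.g. {diff}")
    vips2 = vips2.reindex(vips1.index)
    out = pd.DataFrame({"vip_set1": vips1, "vip_set2": vips2})
    out["selected"] = (out["vip_set1"] > threshold) & (out["vip_set2"] > threshold)
    if fold_change1 is not None:
        out["fold_change_set1"] = fold_change1.reindex(out.index)
    if fold_change2 is not None:
        out["fold_change_set2"] = fold_change2.reindex(out.index)
    return out


def superclass_enrichment(selected, annotation: pd.Series,
                          background) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per chemical super-class.

    Parameters
    ----------
    selected : iterable of selected feature ids
    annotation : Series mapping feature id -> super-class (NaN = unannotated)
    background : iterable of feature ids forming the universe

    Returns one row per class present in the background: hits, class size,
    selection size, hypergeometric p and BH q, sorted by p.
    """
    background = list(background)
    selected = set(selected)
    if not selected.issubset(background):
        raise ValueError("every selected feature must be in the background")
    if not selected:
        return pd.DataFrame(columns=["super_class", "hits", "class_size",
                                     "selection_size", "p_value", "fdr_q"])
    ann = annotation.reindex(background)
    classes = ann.dropna().unique()
    N = len(background)
    n_sel = len(selected)
    rows = []
    for cls in classes:
        members = set(ann.index[ann == cls])
        K = len(members)
        hits = len(selected & members)
        # P(X >= hits) for X ~ Hypergeom(N, K, n_sel)
        p = float(hypergeom.sf(hits - 1, N, K, n_sel))
        rows.append({"super_class": cls, "hits": hits, "class_size": K,
                     "selection_size": n_sel, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["fdr_q"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
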