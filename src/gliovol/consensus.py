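"""Rating scales, inter-rater agreement and the progression endpoint.

Every follow-up scan is rated on a nominal 0–5 scale:

====  ==========================================
0     initial diagnosis
1     immediate postoperative MRI
2     disease regression
3     stable disease
4     uncertain disease progression (e.g. possible pseudo-progression)
5     disease progression
====  ==========================================

The radiologic consensus (RC) is what two readers agree on;
the multidisciplinary consensus (MC) refines it hierarchically using, in
order of priority, histopathology, the CNS tumor-board decision, and RC.
MC is then dichotomized into the binary progression endpoint used by the
mixed-effects model; categories 0 and 1 are excluded from modelling
(no meaningful preceding comparison / postoperative cavity artefacts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VALID_CATEGORIES",
    "McSource",
    "cohens_kappa",
    "resolve_mc",
    "dichotomize",
    "label_change_table",
]

VALID_CATEGORIES = frozenset(range(6))


@dataclass(frozen=True)
class McSource:
    """Label sources for one scan, in decreasing priority order."""

    rc: int
    histology: int | None = None
    board: int | None = None


def _check_categories(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size and not np.isin(arr, list(VALID_CATEGORIES)).all():
        raise ValueError("ratings must be integer categories 0-5")
    return arr


def cohens_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa for two aligned nominal rating vectors.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement ``p_o`` and
    chance agreement ``p_e`` from the raters' marginal category
    frequencies.  When both raters are constant and identical (``p_e = 1``)
    agreement is perfect and kappa is defined as 1.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rating vectors must be 1D and of equal length")
    if a.size == 0:
        raise ValueError("rating vectors are empty")
    p_o = float(np.mean(a == b))
    cats = np.union1d(a, b)
    fa = np.array([np.mean(a == c) for c in cats])
    fb = np.array([np.mean(b == c) for c in cats])
    p_e = float(fa @ fb)
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def resolve_mc(source: McSource) -> tuple[int, int]:
    """Hierarchical multidisciplinary consensus.

    Returns ``(category, tier)`` where tier 1 = histopathology,
    2 = tumor board, 3 = radiologic consensus.
    """
    for tier, label in ((1, source.histology), (2, source.board)):
        if label is not None and not (isinstance(label, float) and np.isnan(label)):
            cat = int(label)
            if cat not in VALID_CATEGORIES:
                raise ValueError(f"invalid category {cat}")
            return cat, tier
    cat = int(source.rc)
    if cat not in VALID_CATEGORIES:
        raise ValueError(f"invalid category {cat}")
    return cat, 3


def dichotomize(rating: int, progression_categories=(5,)) -> float:
    """Binary progression endpoint from a 0–5 category.

    Categories 0 (initial) and 1 (immediate postoperative) are excluded
    from modelling — returned as NaN.  Categories in
    ``progression_categories`` map to 1.0, the rest of 2–5 to 0.0.  The
    default counts only definite progression (5); pass ``(4, 5)`` to also
    count uncertain progression.
    """
    cat = int(rating)
    if cat not in VALID_CATEGORIES:
        raise ValueError(f"rating {cat} outside the 0-5 scale")
    if cat in (0, 1):
        return float("nan")
    return 1.0 if cat in progression_categories else 0.0


def label_change_table(
    changes: pd.DataFrame, progression_categories=(5,)
) -> pd.DataFrame:
    """Attach MC category, provenance tier and the binary endpoint.

    Expects the change table to carry ``rating`` (RC) and optionally
    ``histology``/``board`` columns; adds ``mc``, ``mc_tier`` and
    ``label`` (NaN = excluded) columns.
    """
    out = changes.copy()
    mcs, tiers, labels = [], [], []
    for _, row in out.iterrows():
        histo = row.get("histology", None)
        board = row.get("board", None)
        histo = None if histo is None or (isinstance(histo, float) and np.isnan(histo)) else int(histo)
        board = None if board is None or (isinstance(board, float) and np.isnan(board)) else int(board)
        mc, tier = resolve_mc(McSource(rc=int(row["rating"]), histology=histo, board=board))
        mcs.append(mc)
        tiers.append(tier)
        labels.append(dichotomize(mc, progression_categories))
    out["mc"] = mcs
    out["mc_tier"] = tiers
    out["label"] = labels
    return out
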