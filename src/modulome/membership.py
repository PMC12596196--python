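"""Gene membership: from continuous gene weights to discrete iModulons.

Each robust component's gene-weight vector is mostly near-zero
background with a few large-magnitude outliers — the member genes. The
threshold separating the two is found with the D'Agostino K² normality
statistic: genes are stripped off in order of decreasing |weight| until
the remaining weights no longer reject normality (K² below a cutoff).
The stripped genes are the iModulon members and the threshold is the
largest |weight| left in the background.

The K² cutoff can be fixed (default 550) or optimized against a known
TRN by maximizing the mean best-match F1 between thresholded member
sets and curated regulons over a cutoff grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_K2_CUTOFF = 550.0
DEFAULT_CUTOFF_GRID = tuple(range(100, 2001, 50))
MIN_K2_LENGTH = 20

CATEGORIES = (
    "PULs",
    "Uncharacterized",
    "ECF-σ",
    "Metabolism",
    "Structural components",
    "Functional",
    "Stress",
    "Single gene",
)


@dataclass
class ThresholdResult:
    threshold: float
    members: frozenset
    degenerate: bool = False  # cutoff never reached: every gene removed
    empty: bool = False  # background already normal-ish: no members


@dataclass
class IModulon:
    """One robust component with discrete gene membership."""

    component_id: str
    weights: pd.Series
    threshold: float
    members: frozenset
    category: str | None = None
    enrichment: object | None = None

    def __post_init__(self) -> None:
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")


def dagostino_k2(values) -> float:
    """D'Agostino K² omnibus statistic (z_skew² + z_kurt²).

    Large values indicate departure from normality — here, the presence
    of outlier gene weights. Requires at least 20 observations and a
    non-constant vector.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < MIN_K2_LENGTH:
        raise ValueError(f"need at least {MIN_K2_LENGTH} values for the K² statistic")
    if np.all(arr == arr[0]):
        raise ValueError("constant vector has no defined K² statistic")
    stat, _ = stats.normaltest(arr)
    return float(stat)


def threshold_component(weights: pd.Series, k2_cutoff: float = DEFAULT_K2_CUTOFF) -> ThresholdResult:
    """Iterative outlier stripping under the K² statistic.

    Repeatedly removes the gene(s) with the largest absolute weight
    (ties removed together, making the result order-independent) and
    recomputes K² on the remainder, until K² falls below ``k2_cutoff``.
    The removed genes are the members; the threshold is the largest
    |weight| among the remaining background genes. Membership is
    invariant to a global sign flip of the weight vector.

    An exactly-constant remainder (e.g. an exactly sparse ground-truth
    vector whose background is all zeros) counts as K² = 0. If fewer
    than 20 genes remain before the cutoff is reached, the component is
    flagged degenerate.
    """
    if not isinstance(weights, pd.Series):
        weights = pd.Series(np.asarray(weights, dtype=float))
    # rank by |weight|, but test normality of the signed remainder
    signed = weights.iloc[np.argsort(-weights.abs().to_numpy(), kind="stable")]
    removed: list = []
    remaining = signed
    while True:
        if len(remaining) < MIN_K2_LENGTH:
            logger.warning("degenerate component: K² cutoff never reached")
            return ThresholdResult(threshold=0.0, members=frozenset(weights.index), degenerate=True)
        vals = remaining.to_numpy()
        k2 = 0.0 if np.all(vals == vals[0]) else dagostino_k2(vals)
        if k2 < k2_cutoff:
            threshold = float(abs(remaining.iloc[0]))
            return ThresholdResult(
                threshold=threshold,
                members=frozenset(removed),
                empty=not removed,
            )
        top = abs(remaining.iloc[0])
        tied = remaining.index[remaining.abs() == top]
        removed.extend(tied)
        remaining = remaining.drop(tied)


def members_f1(members: set, regulon: set) -> float:
    """F1 between a thresholded member set and a regulon."""
    overlap = len(set(members) & set(regulon))
    if overlap == 0:
        return 0.0
    precision = overlap / len(members)
    recall = overlap / len(regulon)
    return 2 * precision * recall / (precision + recall)


def optimize_cutoff(
    M: pd.DataFrame,
    trn,
    grid=DEFAULT_CUTOFF_GRID,
    default: float = DEFAULT_K2_CUTOFF,
) -> float:
    """Pick the K² cutoff maximizing mean best-match F1 against a TRN.

    For each grid value, every component of M is thresholded and scored
    by its best F1 against any single regulon; the cutoff with the
    highest mean score wins, ties resolved toward the lowest cutoff.
    With an empty TRN the default cutoff is returned with a warning.
    """
    if trn is None or not len(trn.regulons):
        logger.warning("empty TRN: optimize_cutoff falls back to default %.0f", default)
        return float(default)
    if not len(grid):
        raise ValueError("empty cutoff grid")
    regulons = trn.regulons
    best_cutoff, best_score = None, -1.0
    for cutoff in sorted(grid):
        scores = []
        for cid in M.columns:
            res = threshold_component(M[cid], cutoff)
            if res.degenerate or not res.members:
                scores.append(0.0)
                continue
            scores.append(max(members_f1(res.members, reg) for reg in regulons.values()))
        score = float(np.mean(scores)) if scores else 0.0
        if score > best_score + 1e-12:
            best_cutoff, best_score = float(cutoff), score
    logger.info("optimized K² cutoff = %.0f (mean best F1 = %.3f)", best_cutoff, best_score)
    return best_cutoff


def build_imodulons(
    decomp,
    k2_cutoff: float = DEFAULT_K2_CUTOFF,
    categories: dict | None = None,
) -> list[IModulon]:
    """Threshold every component of a robust decomposition.

    ``categories`` is an optional curation mapping component_id →
    category label (category assignment is manual curation, not
    algorithmic).
    """
    imodulons = []
    for cid in decomp.component_ids:
        res = threshold_component(decomp.M[cid], k2_cutoff)
        category = (categories or {}).get(cid)
        if category is None and len(res.members) == 1:
            category = "Single gene"
        imodulons.append(
            IModulon(
                component_id=cid,
                weights=decomp.M[cid],
                threshold=res.threshold,
                members=res.members,
                category=category,
            )
        )
    return imodulons


def write_imodulons(imodulons: list[IModulon], path) -> None:
    """Serialize iModulons to a JSON array."""
    payload = []
    for im in imodulons:
        entry = {
            "component_id": im.component_id,
            "threshold": im.threshold,
            "members": sorted(im.members),
            "category": im.category,
        }
        if im.enrichment is not None:
            e = im.enrichment
            entry["enrichment"] = {
                "regulator": e.regulator,
                "p_value": e.p_value,
                "q_value": e.q_value,
                "imodulon_recall": e.imodulon_recall,
                "regulon_recall": e.regulon_recall,
                "quadrant": e.quadrant,
                "is_regulatory": e.is_regulatory,
            }
        payload.append(entry)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
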