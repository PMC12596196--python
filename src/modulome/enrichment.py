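"""Regulon enrichment of iModulons against a known TRN.

Each iModulon's member set is scored against every curated regulon with
a one-sided Fisher's exact (hypergeometric over-representation) test;
p-values are Benjamini–Hochberg adjusted across all
(component, regulator) pairs. Components whose best enrichment clears
the regulatory FDR threshold (default 1e-4) are flagged "regulatory".
The overlap geometry is summarized by two recalls —

    iModulon recall  = |members ∩ regulon| / |members|
    regulon  recall  = |members ∩ regulon| / |regulon|

— which jointly classify components into four groups at a 0.7 cut:
well-matched, regulon subset, unknown-containing, and closest match.
Finally, member genes under an enriched regulator that are absent from
the curated TRN count as novel regulator–target predictions (TRN
expansion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_REGULATORY_FDR = 1e-4
DEFAULT_TERM_FDR = 1e-2
DEFAULT_QUADRANT_CUT = 0.7

QUADRANTS = ("well-matched", "regulon subset", "unknown-containing", "closest match")


@dataclass
class TRN:
    """Regulator → target-gene associations with free-text evidence."""

    associations: pd.DataFrame  # columns: regulator, target, evidence
    gene_universe: frozenset

    def __post_init__(self) -> None:
        needed = {"regulator", "target"}
        if not needed.issubset(self.associations.columns):
            raise ValueError("TRN table needs 'regulator' and 'target' columns")
        if "evidence" not in self.associations.columns:
            self.associations = self.associations.assign(evidence="")
        pairs = self.associations[["regulator", "target"]]
        if pairs.duplicated().any():
            raise ValueError("duplicate (regulator, target) pair in TRN")
        outside = set(self.associations["target"]) - set(self.gene_universe)
        if outside:
            raise ValueError(f"TRN targets outside gene universe: {sorted(outside)[:5]}")

    @classmethod
    def from_csv(cls, path, gene_universe) -> "TRN":
        table = pd.read_csv(path)
        return cls(associations=table, gene_universe=frozenset(gene_universe))

    def to_csv(self, path) -> None:
        self.associations.to_csv(path, index=False)

    @cached_property
    def regulons(self) -> dict[str, frozenset]:
        return {
            reg: frozenset(grp["target"])
            for reg, grp in self.associations.groupby("regulator")
        }

    @cached_property
    def pairs(self) -> frozenset:
        return frozenset(zip(self.associations["regulator"], self.associations["target"]))

    def __len__(self) -> int:
        return len(self.associations)


@dataclass
class EnrichmentResult:
    component_id: str
    regulator: str
    p_value: float
    q_value: float
    imodulon_recall: float
    regulon_recall: float
    quadrant: str
    is_regulatory: bool
    overlap: int = 0


def fisher_enrichment(members: set, regulon: set, universe_size: int) -> float:
    """One-sided over-representation p-value P(overlap ≥ observed).

    Equivalent to Fisher's exact test (greater) on the 2×2 membership
    table; computed as the hypergeometric survival function.
    """
    members, regulon = set(members), set(regulon)
    if not members:
        raise ValueError("empty member set")
    if universe_size < len(members | regulon):
        raise ValueError("universe smaller than the union of the two sets")
    overlap = len(members & regulon)
    # P(X >= overlap) with X ~ Hypergeom(N=universe, K=|regulon|, n=|members|)
    p = stats.hypergeom.sf(overlap - 1, universe_size, len(regulon), len(members))
    return float(min(1.0, p))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def compute_recalls(members: set, regulon: set) -> tuple[float, float]:
    """(iModulon recall, regulon recall) of a member set vs a regulon."""
    members, regulon = set(members), set(regulon)
    if not members or not regulon:
        raise ValueError("empty input set")
    overlap = len(members & regulon)
    return overlap / len(members), overlap / len(regulon)


def classify_quadrant(imodulon_recall: float, regulon_recall: float,
                      cut: float = DEFAULT_QUADRANT_CUT) -> str:
    """Four-group classification on the (ir, rr) plane, boundary inclusive."""
    for r in (imodulon_recall, regulon_recall):
        if not 0.0 <= r <= 1.0:
            raise ValueError("recalls must lie in [0, 1]")
    if imodulon_recall >= cut and regulon_recall >= cut:
        return "well-matched"
    if imodulon_recall >= cut:
        return "regulon subset"
    if regulon_recall >= cut:
        return "unknown-containing"
    return "closest match"


def enrich_all(
    imodulons,
    trn: TRN,
    regulatory_fdr: float = DEFAULT_REGULATORY_FDR,
    quadrant_cut: float = DEFAULT_QUADRANT_CUT,
) -> list[EnrichmentResult]:
    """Best single-regulator enrichment for every non-empty iModulon.

    Tests every (component, regulator) pair, BH-adjusts the pooled
    p-values, and reports for each component the regulator with the
    lowest q-value (ties broken toward the larger overlap, then the
    lexicographically smaller regulator id).
    """
    if not len(trn.regulons):
        raise ValueError("empty TRN")
    universe = len(trn.gene_universe)
    rows = []
    for im in imodulons:
        if not im.members:
            continue
        for reg, regulon in trn.regulons.items():
            p = fisher_enrichment(im.members, regulon, universe)
            overlap = len(set(im.members) & regulon)
            rows.append((im.component_id, reg, p, overlap, frozenset(im.members), regulon))
    if not rows:
        return []
    q = fdr_adjust([r[2] for r in rows])
    by_component: dict[str, tuple] = {}
    for (cid, reg, p, overlap, members, regulon), qv in zip(rows, q):
        key = (qv, -overlap, reg)
        if cid not in by_component or key < by_component[cid][0]:
            by_component[cid] = (key, reg, p, qv, overlap, members, regulon)
    results = []
    for cid, (_, reg, p, qv, overlap, members, regulon) in by_component.items():
        ir, rr = compute_recalls(members, regulon)
        results.append(
            EnrichmentResult(
                component_id=cid,
                regulator=reg,
                p_value=float(p),
                q_value=float(qv),
                imodulon_recall=ir,
                regulon_recall=rr,
                quadrant=classify_quadrant(ir, rr, quadrant_cut),
                is_regulatory=bool(qv < regulatory_fdr),
                overlap=overlap,
            )
        )
    results.sort(key=lambda r: r.component_id)
    return results


def count_trn_expansion(results, imodulons, trn: TRN) -> tuple[int, int, float]:
    """TRN-expansion accounting over a declared component set.

    For every enrichment result, each (enriched regulator, member gene)
    pair is counted once; pairs absent from the curated TRN are novel
    predictions. The expanded TRN size is |known associations| + novel,
    and the expansion fraction is novel / |known associations|.
    """
    members_of = {im.component_id: set(im.members) for im in imodulons}
    predicted = set()
    for res in results:
        for gene in members_of.get(res.component_id, ()):
            predicted.add((res.regulator, gene))
    novel = {pair for pair in predicted if pair not in trn.pairs}
    total = len(trn) + len(novel)
    fraction = len(novel) / len(trn) if len(trn) else float("nan")
    return total, len(novel), fraction


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "component_id": r.component_id,
                "regulator": r.regulator,
                "p": r.p_value,
                "q": r.q_value,
                "imodulon_recall": r.imodulon_recall,
                "regulon_recall": r.regulon_recall,
                "quadrant": r.quadrant,
                "is_regulatory": r.is_regulatory,
            }
            for r in results
        ]
    )


def write_enrichment(results, path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
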