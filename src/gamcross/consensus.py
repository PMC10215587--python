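"""Consensus over multiple haplotype-phasing scenarios.

A phasing algorithm run under different window parameters can assign
the same SNP to different parental origins in different runs.  This
module measures pairwise agreement ("similitude") between scenario
outputs and retains, per (sow, SNP) position, the modal ordered
(paternal allele, maternal allele) assignment when it reaches a vote
threshold (default 7 of 9 scenarios).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .simulate import MISSING, PhasedGametes

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseScenarioSet",
    "pairwise_similitude",
    "similitude_matrix",
    "consensus_phase",
]


@dataclass
class PhaseScenarioSet:
    """Phase assignments of several scenarios over a shared index.

    ``paternal`` and ``maternal`` have shape
    (n_scenarios, n_sows, n_snp) with alleles 0/1 and MISSING for
    unassigned positions.
    """

    scenario_ids: list[str]
    paternal: np.ndarray
    maternal: np.ndarray
    sow_ids: list[str]
    cross: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_scenarios(self) -> int:
        return self.paternal.shape[0]

    def validate(self) -> None:
        if self.paternal.shape != self.maternal.shape:
            raise ValueError("paternal/maternal tensors must be conformable")
        ok = np.isin(self.paternal, (0, 1, MISSING)) & np.isin(
            self.maternal, (0, 1, MISSING)
        )
        if not ok.all():
            raise ValueError("assignments must be alleles 0/1 or unassigned")

    def _codes(self) -> np.ndarray:
        """Ordered-assignment code per (scenario, sow, SNP): 0..3, -1 unassigned."""
        assigned = (self.paternal != MISSING) & (self.maternal != MISSING)
        return np.where(assigned, self.paternal * 2 + self.maternal, -1)


def pairwise_similitude(scen: PhaseScenarioSet, a: int, b: int) -> float:
    """Agreement between two scenarios' ordered assignments.

    The fraction, over positions assigned in both scenarios, where the
    ordered (paternal, maternal) allele pair is identical.  A pure
    origin swap is invisible at homozygous positions.
    """
    codes = scen._codes()
    both = (codes[a] >= 0) & (codes[b] >= 0)
    n = both.sum()
    if n == 0:
        raise ValueError("no positions jointly assigned in both scenarios")
    return float((codes[a][both] == codes[b][both]).mean())


def similitude_matrix(scen: PhaseScenarioSet) -> tuple[np.ndarray, float]:
    """All pairwise similitudes plus their off-diagonal mean."""
    S = scen.n_scenarios
    if S < 2:
        raise ValueError("need at least two scenarios")
    M = np.eye(S)
    for a in range(S):
        for b in range(a + 1, S):
            M[a, b] = M[b, a] = pairwise_similitude(scen, a, b)
    mean = M[~np.eye(S, dtype=bool)].mean()
    return M, float(mean)


def consensus_phase(
    scen: PhaseScenarioSet, min_agree: int = 7
) -> tuple[PhasedGametes, dict]:
    """Retain per-position modal assignments supported by >= min_agree votes.

    For each (sow, SNP), the modal ordered (paternal, maternal)
    assignment is kept iff its multiplicity over scenarios reaches
    ``min_agree``; otherwise the position becomes unassigned.  Ties for
    the mode at exactly the threshold are dropped and logged.

    Returns consensus gametes and a report with the position-level
    retention fraction and, per SNP, the fraction of sows retained
    (plus the fraction of SNPs retained in every sow).
    """
    if not 1 <= min_agree <= scen.n_scenarios:
        raise ValueError(
            f"min_agree must lie in [1, {scen.n_scenarios}], got {min_agree}"
        )
    codes = scen._codes()  # (S, n, m)
    counts = np.stack([(codes == c).sum(axis=0) for c in range(4)])  # (4, n, m)
    top = counts.max(axis=0)
    modal = counts.argmax(axis=0)
    tie = (counts == top[None]).sum(axis=0) > 1
    keep = (top >= min_agree) & ~tie
    n_tied = int((tie & (top >= min_agree)).sum())
    if n_tied:
        logger.warning("dropped %d positions with tied modal assignment", n_tied)

    pat = np.where(keep, modal // 2, MISSING).astype(np.int8)
    mat = np.where(keep, modal % 2, MISSING).astype(np.int8)
    consensus = PhasedGametes(
        sow_ids=list(scen.sow_ids),
        cross=scen.cross.copy(),
        paternal=pat,
        maternal=mat,
    )
    report = {
        "retention": float(keep.mean()),
        "per_snp_retention": keep.mean(axis=0),
        "snp_retention_all_sows": float(keep.all(axis=0).mean()),
        "min_agree": min_agree,
        "n_tied_dropped": n_tied,
    }
    return consensus, report
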