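"""SNP quality-control cascade for the merged genotype panel.

Filters are applied sequentially — call rate, monomorphic, minor allele
frequency in population E, then in population R — and every SNP is
attributed to the first filter it fails, so the per-reason counts
partition the input panel exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import MISSING

__all__ = ["QcReport", "compute_call_rate", "compute_maf", "filter_snps"]


@dataclass
class QcReport:
    """Per-reason exclusion counts and per-SNP fates of one QC run."""

    n_input_snps: int
    n_removed_call_rate: int
    n_removed_monomorphic: int
    n_removed_maf_popE: int
    n_removed_maf_popR: int
    n_retained: int
    fates: np.ndarray = field(repr=False)  # per-SNP label
    call_rate_min: float = 0.90
    maf_min: float = 0.05

    def __post_init__(self):
        total = (
            self.n_removed_call_rate
            + self.n_removed_monomorphic
            + self.n_removed_maf_popE
            + self.n_removed_maf_popR
            + self.n_retained
        )
        if total != self.n_input_snps:
            raise ValueError("QC fates do not partition the input SNP set")

    def to_dict(self) -> dict:
        return {
            "n_input_snps": self.n_input_snps,
            "n_removed_call_rate": self.n_removed_call_rate,
            "n_removed_monomorphic": self.n_removed_monomorphic,
            "n_removed_maf_popE": self.n_removed_maf_popE,
            "n_removed_maf_popR": self.n_removed_maf_popR,
            "n_retained": self.n_retained,
            "call_rate_min": self.call_rate_min,
            "maf_min": self.maf_min,
        }


def compute_call_rate(genotypes: np.ndarray) -> np.ndarray:
    """Fraction of non-missing calls per SNP over all genotyped individuals."""
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.size == 0:
        raise ValueError("genotype matrix must be non-empty 2-D")
    return (g != MISSING).mean(axis=0)


def compute_maf(
    genotypes: np.ndarray, population_labels: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-SNP minor allele frequency within each population.

    MAF = min(f, 1-f) with f the A2 frequency among non-missing calls of
    that population; NaN where a population has no calls at a SNP.
    """
    g = np.asarray(genotypes, float)
    labels = np.asarray(population_labels)
    if len(labels) != g.shape[0]:
        raise ValueError("population labels must cover all individuals")
    out = {}
    for pop in dict.fromkeys(labels.tolist()):
        sub = g[labels == pop]
        ok = sub != MISSING
        n_alleles = 2 * ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(ok, sub, 0).sum(axis=0) / np.where(n_alleles > 0, n_alleles, np.nan)
        out[pop] = np.minimum(f, 1 - f)
    return out


def filter_snps(
    genotypes: np.ndarray,
    population_labels: np.ndarray,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    pop_E: str = "E",
    pop_R: str = "R",
) -> tuple[np.ndarray, QcReport]:
    """Apply the sequential SNP filter cascade.

    ``population_labels`` names each row's panel; rows labelled other
    than ``pop_E``/``pop_R`` (e.g. crossbreds) count toward call rate
    and pooled monomorphism but not the per-population MAF filters.
    Returns the retained SNP indices and a report; each SNP receives
    exactly one fate (the first filter it fails, in the order call rate,
    monomorphic, MAF in E, MAF in R).
    """
    if not (0 < call_rate_min < 1 and 0 < maf_min < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    g = np.asarray(genotypes)
    labels = np.asarray(population_labels)
    n_snp = g.shape[1]
    fates = np.full(n_snp, "retained", dtype=object)

    call = compute_call_rate(g)
    fates[call < call_rate_min] = "call_rate"

    pooled = compute_maf(g, np.full(g.shape[0], "pooled"))["pooled"]
    mono = np.nan_to_num(pooled, nan=0.0) == 0.0
    fates[(fates == "retained") & mono] = "monomorphic"

    maf = compute_maf(g, labels)
    for pop, fate in ((pop_E, "maf_popE"), (pop_R, "maf_popR")):
        if pop not in maf:
            raise ValueError(f"no individuals labelled {pop!r}")
        fail = np.isnan(maf[pop]) | (maf[pop] < maf_min)
        fates[(fates == "retained") & fail] = fate

    retained = np.flatnonzero(fates == "retained")
    report = QcReport(
        n_input_snps=n_snp,
        n_removed_call_rate=int((fates == "call_rate").sum()),
        n_removed_monomorphic=int((fates == "monomorphic").sum()),
        n_removed_maf_popE=int((fates == "maf_popE").sum()),
        n_removed_maf_popR=int((fates == "maf_popR").sum()),
        n_retained=len(retained),
        fates=fates,
        call_rate_min=call_rate_min,
        maf_min=maf_min,
    )
    return retained, report
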