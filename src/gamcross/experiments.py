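"""Canned validation experiments built from the package's own stages.

These are the study-shaped simulation experiments used to audit the
gametic-relationship construction against pedigree expectations and to
measure parameter recovery of the Gibbs model; tests and the
reproduction script call them with fixed seeds.
"""

from __future__ import annotations

import numpy as np

from .gibbs import McmcConfig, build_design, run_chain
from .grm import build_centered_matrix, build_gametic_matrix
from .simulate import CrossDesign, TraitParameters, TrueParameters, simulate_dataset

__all__ = [
    "half_sib_relationship_audit",
    "fullsib_sire_relationship_audit",
    "correlation_recovery",
    "table4_parameters",
]


def _gamete_from(hap_pair: np.ndarray, rng) -> np.ndarray:
    n_snp = hap_pair.shape[1]
    return hap_pair[rng.integers(0, 2, n_snp), np.arange(n_snp)]


def half_sib_relationship_audit(
    n_pairs: int = 200, n_snp: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Mean gametic relationship of paternal gametes sharing a sire.

    For each replicate pair, one sire (haplotypes Bernoulli(q), q
    uniform on [0.05, 0.5]) transmits two gametes by per-locus uniform
    picks; the relationship is read off G = MM'/sum q(1-q) built with
    the true q.  Pedigree expectation: 0.50.  Returns (mean, MC
    standard error).
    """
    rng = np.random.default_rng(seed)
    q = rng.uniform(0.05, 0.5, n_snp)
    vals = np.empty(n_pairs)
    for k in range(n_pairs):
        sire = (rng.random((2, n_snp)) < q).astype(np.int8)
        g = np.vstack([_gamete_from(sire, rng), _gamete_from(sire, rng)])
        G = build_gametic_matrix(build_centered_matrix(g, q), q).values
        vals[k] = G[0, 1]
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_pairs))


def fullsib_sire_relationship_audit(
    n_pairs: int = 200, n_snp: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Mean paternal-gamete relationship when the sires are full sibs.

    A grandparental couple produces two full-sib sires; each sire
    transmits one gamete to its offspring.  Pedigree expectation: 0.25.
    """
    rng = np.random.default_rng(seed)
    q = rng.uniform(0.05, 0.5, n_snp)
    vals = np.empty(n_pairs)
    for k in range(n_pairs):
        grandsire = (rng.random((2, n_snp)) < q).astype(np.int8)
        granddam = (rng.random((2, n_snp)) < q).astype(np.int8)
        gam = []
        for _ in range(2):
            sire = np.vstack(
                [_gamete_from(grandsire, rng), _gamete_from(granddam, rng)]
            )
            gam.append(_gamete_from(sire, rng))
        G = build_gametic_matrix(build_centered_matrix(np.vstack(gam), q), q).values
        vals[k] = G[0, 1]
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_pairs))


def table4_parameters(r_E: float = 0.5, r_R: float = 0.5) -> TrueParameters:
    """Litter-size-scale generating parameters with chosen gametic correlations."""
    cE = r_E * np.sqrt(0.206 * 0.197)
    cR = r_R * np.sqrt(0.224 * 0.163)
    tp = TraitParameters(
        V_E=np.array([[0.206, cE], [cE, 0.197]]),
        V_R=np.array([[0.224, cR], [cR, 0.163]]),
    )
    return TrueParameters(tnb=tp, nba=tp)


def correlation_recovery(
    r_true: float,
    seed: int,
    n_sows: int = 60,
    n_snp: int = 500,
    n_iter: int = 50_000,
    burn_in: int = 10_000,
    residual_er: float = 4.296,
    residual_re: float = 4.795,
    n_founders: int = 10,
) -> dict:
    """Simulate a reduced reciprocal cross with gametic correlation
    ``r_true`` in both origins and fit it, returning posterior means.

    The founder sire and dam pools coincide, so E-origin gametes of ER
    sows are half sibs of E-origin gametes of RE sows — the relatedness
    that carries the information about sigma_pm.
    """
    params = table4_parameters(r_true, r_true)
    params.tnb.sigma2_e_er = params.nba.sigma2_e_er = residual_er
    params.tnb.sigma2_e_re = params.nba.sigma2_e_re = residual_re
    design = CrossDesign(
        n_sires_E=n_founders,
        n_dams_E=n_founders,
        n_sires_R=n_founders,
        n_dams_R=n_founders,
        n_er_sows=n_sows,
        n_re_sows=n_sows,
    )
    data = simulate_dataset(
        n_founders_E=n_founders,
        n_founders_R=n_founders,
        n_snp=n_snp,
        design=design,
        params=params,
        seed=seed,
    )
    md = build_design(
        data["phenotypes"], data["grm"]["E"].index, data["grm"]["R"].index
    )
    samples = run_chain(
        md,
        data["grm"]["E"],
        data["grm"]["R"],
        McmcConfig(n_iter=n_iter, burn_in=burn_in, thin=10, seed=seed + 7919),
    )
    means = samples.draws.mean(numeric_only=True)
    return {
        "r_pmE": float(means["r_pmE"]),
        "r_pmR": float(means["r_pmR"]),
        "r_pm_mean": float((means["r_pmE"] + means["r_pmR"]) / 2),
        "samples": samples,
    }
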