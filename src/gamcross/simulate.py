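"""Synthetic reciprocal-cross data generator.

Emulates the data structure of a two-variety pig crossbreeding scheme:
two purebred founder populations (labelled E and R) with distinct allele
frequencies, F1 crossbred sows produced in both mating directions
(ER: sire E x dam R; RE: sire R x dam E), phased gametes with known
parental origin, gametic effects drawn from a bivariate
(paternal-role, maternal-role) covariance per origin population, and
repeated litter-size records per sow.

Allele coding: haplotypes carry 0 (A1) or 1 (A2); genotypes are A2
dosages in {0, 1, 2}; -1 marks a missing / unassigned call everywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "FounderPopulation",
    "CrossDesign",
    "TraitParameters",
    "TrueParameters",
    "PhasedGametes",
    "GameticEffects",
    "simulate_founders",
    "simulate_cross",
    "simulate_gametic_effects",
    "simulate_phenotypes",
    "corrupt_genotypes",
    "make_phasing_scenarios",
    "simulate_dataset",
]


@dataclass
class FounderPopulation:
    """A purebred founder panel with fully phased haplotypes.

    ``haplotypes`` has shape (n_individuals, 2, n_snp); ``q`` is the
    generating A2 allele-frequency vector (strictly inside (0, 1) for
    segregating loci).
    """

    label: str
    ids: list[str]
    haplotypes: np.ndarray
    q: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snp(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def genotypes(self) -> np.ndarray:
        """A2-dosage matrix (n_individuals x n_snp)."""
        return self.haplotypes.sum(axis=1)

    def validate(self) -> None:
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_snp)")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        if np.any((self.q <= 0) | (self.q >= 1)):
            raise ValueError("generating frequencies must lie strictly in (0,1)")


@dataclass
class CrossDesign:
    """Mating design for the reciprocal cross.

    Default counts mirror the motivating study: 38 E boars and 139 R
    dams producing 203 ER sows; 38 R boars and 92 E dams producing 125
    RE sows.  When ``share_parent_pools`` is true the sire and dam pools
    drawn from one founder population overlap (both start at the first
    founder), so E-origin gametes in ER sows are related to E-origin
    gametes in RE sows through shared purebred parents — the relatedness
    route that makes the paternal-maternal gametic correlation
    estimable from a reciprocal cross.
    """

    n_sires_E: int = 38
    n_dams_R: int = 139
    n_sires_R: int = 38
    n_dams_E: int = 92
    n_er_sows: int = 203
    n_re_sows: int = 125
    records_min: int = 3
    records_max: int = 8
    n_hys: int = 34
    n_parity: int = 5
    share_parent_pools: bool = True


@dataclass
class TraitParameters:
    """Generating parameters for one trait (e.g. TNB or NBA).

    Variance magnitudes default to the litter-size scale of the
    motivating study: gametic variances ~0.2, permanent sow-environment
    variances 0.14/0.36, residual variances 4.3/4.8, phenotype means
    near 8.8 piglets.  The paternal-maternal gametic covariances default
    to half the geometric mean of the variances (correlation 0.5).
    """

    V_E: np.ndarray = field(
        default_factory=lambda: np.array([[0.206, 0.1007], [0.1007, 0.197]])
    )
    V_R: np.ndarray = field(
        default_factory=lambda: np.array([[0.224, 0.0955], [0.0955, 0.163]])
    )
    sigma2_s_er: float = 0.144
    sigma2_s_re: float = 0.357
    sigma2_e_er: float = 4.296
    sigma2_e_re: float = 4.795
    mean_er: float = 8.78
    mean_re: float = 8.85
    parity_sd: float = 0.3
    hys_sd: float = 0.3

    def validate(self) -> None:
        for V in (self.V_E, self.V_R):
            V = np.asarray(V, float)
            if V.shape != (2, 2) or abs(V[0, 1] - V[1, 0]) > 1e-12:
                raise ValueError("V must be symmetric 2x2")
            if np.linalg.eigvalsh(V)[0] < -1e-10:
                raise ValueError("V must be positive semi-definite")
        for v in (self.sigma2_s_er, self.sigma2_s_re, self.sigma2_e_er, self.sigma2_e_re):
            if v < 0:
                raise ValueError("variances must be non-negative")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["V_E"] = np.asarray(self.V_E).tolist()
        d["V_R"] = np.asarray(self.V_R).tolist()
        return d


@dataclass
class TrueParameters:
    """Per-trait generating parameters plus fixed-effect level values."""

    tnb: TraitParameters = field(default_factory=TraitParameters)
    nba: TraitParameters = field(default_factory=TraitParameters)


@dataclass
class PhasedGametes:
    """Phased, origin-labelled gametes of the crossbred sows.

    ``paternal`` / ``maternal`` are (n_sows x n_snp) haploid allele
    matrices (0/1, MISSING for unassigned).  Origin labels follow the
    cross: ER sows carry an E paternal and an R maternal gamete, RE sows
    the reverse.
    """

    sow_ids: list[str]
    cross: np.ndarray  # "ER"/"RE" per sow
    paternal: np.ndarray
    maternal: np.ndarray

    @property
    def n_sows(self) -> int:
        return len(self.sow_ids)

    @property
    def n_snp(self) -> int:
        return self.paternal.shape[1]

    def origin_of(self, role: str) -> np.ndarray:
        """Founder origin ('E'/'R') of each sow's gamete in ``role``."""
        er = self.cross == "ER"
        if role == "paternal":
            return np.where(er, "E", "R")
        if role == "maternal":
            return np.where(er, "R", "E")
        raise ValueError(f"unknown role {role!r}")


@dataclass
class GameticEffects:
    """Latent bivariate (paternal-role, maternal-role) gametic values.

    ``U_E`` / ``U_R`` are (n_gametes x 2) arrays over the origin's
    gamete index (all ER-sow gametes of the origin first, then RE-sow
    gametes), column 0 = paternal role, column 1 = maternal role.
    """

    U_E: np.ndarray
    U_R: np.ndarray


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_founders(
    n_E: int,
    n_R: int,
    n_snp: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed=None,
) -> tuple[FounderPopulation, FounderPopulation]:
    """Simulate two unlinked founder panels with distinct frequencies.

    Per population, the A2 frequency of each locus is drawn uniformly on
    [maf_low, maf_high]; haplotypes are then locus-independent
    Bernoulli(q) draws (no linkage disequilibrium).
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError(f"require 0 < maf_low <= maf_high <= 0.5, got [{maf_low}, {maf_high}]")
    if n_E <= 0 or n_R <= 0 or n_snp <= 0:
        raise ValueError("population and SNP counts must be positive")
    rng = _rng(seed)
    pops = []
    for label, n in (("E", n_E), ("R", n_R)):
        q = rng.uniform(maf_low, maf_high, size=n_snp)
        haps = (rng.random((n, 2, n_snp)) < q).astype(np.int8)
        ids = [f"{label}{i + 1:04d}" for i in range(n)]
        pops.append(FounderPopulation(label=label, ids=ids, haplotypes=haps, q=q))
    return pops[0], pops[1]


def _transmit(haplotypes: np.ndarray, parent_idx: np.ndarray, rng) -> np.ndarray:
    """Per-locus uniform pick between the parent's two haplotypes."""
    n_snp = haplotypes.shape[2]
    pick = rng.integers(0, 2, size=(len(parent_idx), n_snp))
    parent = haplotypes[parent_idx]  # (n, 2, n_snp)
    return np.take_along_axis(parent, pick[:, None, :], axis=1)[:, 0, :].astype(np.int8)


def simulate_cross(
    founders_E: FounderPopulation,
    founders_R: FounderPopulation,
    design: CrossDesign,
    seed=None,
) -> tuple[PhasedGametes, pd.DataFrame]:
    """Mate the founder panels and phase the resulting F1 sows.

    Each crossbred sow receives one gamete from a randomly assigned sire
    and one from a randomly assigned dam, every locus an independent
    uniform pick between the parent's two haplotypes (free
    recombination).  Returns the phased gametes and a pedigree table
    (id, sire, dam, group).
    """
    rng = _rng(seed)
    for pop, n_s, n_d in (
        (founders_E, design.n_sires_E, design.n_dams_E),
        (founders_R, design.n_sires_R, design.n_dams_R),
    ):
        need = max(n_s, n_d) if design.share_parent_pools else n_s + n_d
        if need > pop.n_individuals:
            raise ValueError(
                f"population {pop.label} has {pop.n_individuals} founders, "
                f"design needs {need}"
            )
    if founders_E.n_snp != founders_R.n_snp:
        raise ValueError("founder panels must share the SNP index")

    def pools(pop, n_s, n_d):
        if design.share_parent_pools:
            return np.arange(n_s), np.arange(n_d)
        return np.arange(n_s), np.arange(n_s, n_s + n_d)

    sires_E, dams_E = pools(founders_E, design.n_sires_E, design.n_dams_E)
    sires_R, dams_R = pools(founders_R, design.n_sires_R, design.n_dams_R)

    rows = []
    pat_blocks, mat_blocks, crosses, sow_ids = [], [], [], []
    for cross, n_sows, sire_pool, sire_pop, dam_pool, dam_pop in (
        ("ER", design.n_er_sows, sires_E, founders_E, dams_R, founders_R),
        ("RE", design.n_re_sows, sires_R, founders_R, dams_E, founders_E),
    ):
        sire_idx = rng.choice(sire_pool, size=n_sows, replace=True)
        dam_idx = rng.choice(dam_pool, size=n_sows, replace=True)
        pat_blocks.append(_transmit(sire_pop.haplotypes, sire_idx, rng))
        mat_blocks.append(_transmit(dam_pop.haplotypes, dam_idx, rng))
        for k in range(n_sows):
            sid = f"{cross}{k + 1:04d}"
            sow_ids.append(sid)
            rows.append(
                {
                    "id": sid,
                    "sire": sire_pop.ids[sire_idx[k]],
                    "dam": dam_pop.ids[dam_idx[k]],
                    "group": cross,
                }
            )
        crosses.extend([cross] * n_sows)

    gametes = PhasedGametes(
        sow_ids=sow_ids,
        cross=np.array(crosses),
        paternal=np.vstack(pat_blocks),
        maternal=np.vstack(mat_blocks),
    )
    return gametes, pd.DataFrame(rows)


def simulate_gametic_effects(
    G_E: np.ndarray,
    G_R: np.ndarray,
    V_E: np.ndarray,
    V_R: np.ndarray,
    jitter: float = 1e-8,
    seed=None,
) -> GameticEffects:
    """Draw latent gametic values from N(0, V (x) G) per origin.

    The Kronecker covariance means Var(p) = sigma2_p*G,
    Var(m) = sigma2_m*G and Cov(p, m) = sigma_pm*G over each origin's
    gamete index; every gamete carries both a paternal-role and a
    maternal-role value even though only the role matching its sow's
    cross ever reaches a phenotype.
    """
    rng = _rng(seed)
    out = []
    for G, V in ((G_E, V_E), (G_R, V_R)):
        G = np.asarray(G, float)
        V = np.asarray(V, float)
        if G.shape[0] != G.shape[1] or not np.allclose(G, G.T, atol=1e-8):
            raise ValueError("G must be symmetric square")
        n = G.shape[0]
        try:
            L_G = np.linalg.cholesky(G + jitter * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"G not positive definite at jitter {jitter:g}; "
                "increase jitter"
            ) from exc
        # 2x2 PSD factor tolerant of singular V (e.g. correlation one)
        w, Q = np.linalg.eigh(V)
        if w.min() < -1e-10:
            raise ValueError("V must be positive semi-definite")
        L_V = Q @ np.diag(np.sqrt(np.clip(w, 0, None)))
        Z = rng.standard_normal((n, 2))
        out.append(L_G @ Z @ L_V.T)
    return GameticEffects(U_E=out[0], U_R=out[1])


def gamete_index(gametes: PhasedGametes, origin: str) -> pd.DataFrame:
    """Index map of one origin's gametes: ER-sow gametes first, then RE.

    Columns: sow_id, role, cross.  For origin E the ER rows are paternal
    gametes and the RE rows maternal; for origin R the reverse.
    """
    if origin not in ("E", "R"):
        raise ValueError("origin must be 'E' or 'R'")
    rows = []
    for cross in ("ER", "RE"):
        role = (
            "paternal"
            if (cross == "ER") == (origin == "E")
            else "maternal"
        )
        for i in np.flatnonzero(gametes.cross == cross):
            rows.append({"sow_id": gametes.sow_ids[i], "role": role, "cross": cross})
    return pd.DataFrame(rows)


def simulate_phenotypes(
    gametes: PhasedGametes,
    effects: dict[str, GameticEffects],
    params: TrueParameters,
    design: CrossDesign,
    seed=None,
) -> tuple[pd.DataFrame, dict]:
    """Generate repeated litter records for every crossbred sow.

    Each record is mean + parity effect + herd-year-season effect +
    permanent sow effect + paternal gametic effect + maternal gametic
    effect + residual, with cross-specific permanent-environment and
    residual variances.  Records per sow are uniform on
    [records_min, records_max]; the record's parity is its sequence
    number capped at the top level.  TNB and NBA are generated from the
    same structure with their own parameters and effects.

    Returns the phenotype table and a truth dict (fixed-effect level
    values and generating parameters) for recovery tests.
    """
    rng = _rng(seed)
    traits = {"tnb": params.tnb, "nba": params.nba}
    for tp in traits.values():
        tp.validate()
    for trait in traits:
        if trait not in effects:
            raise ValueError(f"missing gametic effects for trait {trait!r}")

    idx_E = gamete_index(gametes, "E")
    idx_R = gamete_index(gametes, "R")
    pos_E = {sid: k for k, sid in enumerate(idx_E["sow_id"])}
    pos_R = {sid: k for k, sid in enumerate(idx_R["sow_id"])}

    n_rec = rng.integers(design.records_min, design.records_max + 1, size=gametes.n_sows)
    truth: dict = {"fixed_effects": {}, "parameters": {}}
    level_values = {}
    for trait, tp in traits.items():
        level_values[trait] = {
            "parity": np.concatenate([[0.0], rng.normal(0, tp.parity_sd, design.n_parity - 1)]),
            "hys": np.concatenate([[0.0], rng.normal(0, tp.hys_sd, design.n_hys - 1)]),
        }
        truth["fixed_effects"][trait] = {
            k: v.tolist() for k, v in level_values[trait].items()
        }
        truth["parameters"][trait] = tp.as_dict()

    perm = {
        trait: {
            sid: rng.normal(
                0.0,
                np.sqrt(tp.sigma2_s_er if gametes.cross[i] == "ER" else tp.sigma2_s_re),
            )
            for i, sid in enumerate(gametes.sow_ids)
        }
        for trait, tp in traits.items()
    }

    rows = []
    for i, sid in enumerate(gametes.sow_ids):
        cross = gametes.cross[i]
        for k in range(n_rec[i]):
            parity = min(k + 1, design.n_parity)
            hys = int(rng.integers(0, design.n_hys))
            rec = {"sow_id": sid, "cross": cross, "parity": parity, "hys": hys + 1}
            for trait, tp in traits.items():
                eff = effects[trait]
                if cross == "ER":
                    gam = eff.U_E[pos_E[sid], 0] + eff.U_R[pos_R[sid], 1]
                    mu, s2e = tp.mean_er, tp.sigma2_e_er
                else:
                    gam = eff.U_R[pos_R[sid], 0] + eff.U_E[pos_E[sid], 1]
                    mu, s2e = tp.mean_re, tp.sigma2_e_re
                rec[trait] = (
                    mu
                    + level_values[trait]["parity"][parity - 1]
                    + level_values[trait]["hys"][hys]
                    + perm[trait][sid]
                    + gam
                    + rng.normal(0.0, np.sqrt(s2e))
                )
            rows.append(rec)
    return pd.DataFrame(rows), truth


def corrupt_genotypes(
    genotypes: np.ndarray,
    missing_rate: float = 0.0,
    monomorph_fraction: float = 0.0,
    rare_fraction: float = 0.0,
    low_call_fraction: float = 0.0,
    call_rate_threshold: float = 0.90,
    maf_threshold: float = 0.05,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Plant QC failures into a genotype matrix.

    Disjoint SNP subsets are forced monomorphic, to a minor allele
    frequency just below ``maf_threshold``, or below the call-rate
    threshold; background missingness is then applied Bernoulli per call
    outside the designated subsets.  Returns the corrupted matrix and a
    per-SNP fate label array ('ok', 'monomorphic', 'rare', 'low_call')
    — the ground truth the QC stage should recover.
    """
    for r in (missing_rate, monomorph_fraction, rare_fraction, low_call_fraction):
        if not 0 <= r <= 1:
            raise ValueError("rates must lie in [0, 1]")
    rng = _rng(seed)
    g = np.array(genotypes, dtype=np.int8, copy=True)
    n_ind, n_snp = g.shape
    n_mono = int(round(monomorph_fraction * n_snp))
    n_rare = int(round(rare_fraction * n_snp))
    n_low = int(round(low_call_fraction * n_snp))
    if n_mono + n_rare + n_low > n_snp:
        raise ValueError("designated corruption subsets overlap: fractions sum above 1")
    order = rng.permutation(n_snp)
    mono = order[:n_mono]
    rare = order[n_mono : n_mono + n_rare]
    low = order[n_mono + n_rare : n_mono + n_rare + n_low]
    fate = np.full(n_snp, "ok", dtype=object)

    g[:, mono] = 0
    fate[mono] = "monomorphic"
    # just-below-threshold MAF: one heterozygote if that stays rare
    n_carriers = max(1, int(np.ceil((maf_threshold * 2 * n_ind - 1) / 2)) - 1)
    n_carriers = min(n_carriers, n_ind)
    if n_carriers / (2 * n_ind) >= maf_threshold:
        n_carriers = max(0, int(np.floor(maf_threshold * 2 * n_ind)) - 1)
    for j in rare:
        g[:, j] = 0
        carriers = rng.choice(n_ind, size=max(n_carriers, 1), replace=False)
        g[carriers, j] = 1
        if max(n_carriers, 1) / (2 * n_ind) >= maf_threshold:
            g[:, j] = 0  # cannot plant a polymorphic rare SNP this small
            fate[j] = "monomorphic"
            continue
        fate[j] = "rare"
    fate[low] = "low_call"
    # largest non-missing count strictly below the call-rate threshold
    t = round(call_rate_threshold * n_ind, 9)
    n_miss = n_ind - (int(np.ceil(t - 1e-9)) - 1)
    n_miss = min(max(n_miss, 1), n_ind)
    for j in low:
        g[rng.choice(n_ind, size=n_miss, replace=False), j] = MISSING

    if missing_rate > 0:
        designated = np.zeros(n_snp, bool)
        designated[np.concatenate([mono, rare, low])] = True
        mask = (rng.random(g.shape) < missing_rate) & ~designated[None, :]
        g[mask] = MISSING
    return g, fate


def make_phasing_scenarios(
    truth: PhasedGametes,
    n_scenarios: int,
    flip_rates,
    seed=None,
):
    """Derive multi-scenario phase outputs by randomly swapping origins.

    Scenario ``s`` equals the true phase with each (sow, SNP) paternal/
    maternal assignment independently swapped with probability
    ``flip_rates[s]`` — emulating the disagreement between runs of a
    phasing algorithm under different window parameters.  A swap is only
    visible at heterozygous positions.
    """
    from .consensus import PhaseScenarioSet

    flip_rates = np.asarray(flip_rates, float)
    if len(flip_rates) != n_scenarios:
        raise ValueError(
            f"expected {n_scenarios} flip rates, got {len(flip_rates)}"
        )
    if np.any((flip_rates < 0) | (flip_rates > 0.5)):
        raise ValueError("flip rates must lie in [0, 0.5]")
    rng = _rng(seed)
    pat = np.repeat(truth.paternal[None], n_scenarios, axis=0).copy()
    mat = np.repeat(truth.maternal[None], n_scenarios, axis=0).copy()
    for s in range(n_scenarios):
        flip = rng.random(truth.paternal.shape) < flip_rates[s]
        p = pat[s].copy()
        pat[s][flip] = mat[s][flip]
        mat[s][flip] = p[flip]
    return PhaseScenarioSet(
        scenario_ids=[f"S{s + 1}" for s in range(n_scenarios)],
        paternal=pat,
        maternal=mat,
        sow_ids=list(truth.sow_ids),
        cross=truth.cross.copy(),
    )


def simulate_dataset(
    n_founders_E: int = 120,
    n_founders_R: int = 160,
    n_snp: int = 800,
    design: CrossDesign | None = None,
    params: TrueParameters | None = None,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    jitter: float = 1e-6,
    seed=None,
):
    """End-to-end synthetic study: founders, cross, effects, phenotypes.

    Returns a dict with founders, phased gametes, pedigree, per-origin
    gametic relationship matrices built from the true frequencies,
    effects, the phenotype table and the truth record.
    """
    from .grm import build_centered_matrix, build_gametic_matrix, origin_gametes

    rng = _rng(seed)
    design = design or CrossDesign()
    params = params or TrueParameters()
    fE, fR = simulate_founders(n_founders_E, n_founders_R, n_snp, maf_low, maf_high, rng)
    gametes, pedigree = simulate_cross(fE, fR, design, rng)
    grms = {}
    for origin, q in (("E", fE.q), ("R", fR.q)):
        hap, idx = origin_gametes(gametes, origin)
        M = build_centered_matrix(hap, q)
        grms[origin] = build_gametic_matrix(M, q, index=idx)
    effects = {
        trait: simulate_gametic_effects(
            grms["E"].values, grms["R"].values, tp.V_E, tp.V_R, jitter, rng
        )
        for trait, tp in (("tnb", params.tnb), ("nba", params.nba))
    }
    phenotypes, truth = simulate_phenotypes(gametes, effects, params, design, rng)
    truth["design"] = dataclasses.asdict(design)
    return {
        "founders": (fE, fR),
        "gametes": gametes,
        "pedigree": pedigree,
        "grm": grms,
        "effects": effects,
        "phenotypes": phenotypes,
        "truth": truth,
    }
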