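"""Bivariate reciprocal-cross gametic model fitted by Gibbs sampling.

The model for one litter-size trait splits the records by cross
direction (ER: sire from population E, dam from R; RE the reverse):

    y_ER = X_ER b_ER + B_ER s_ER + Z_ER p_E + W_ER m_R + e_ER
    y_RE = X_RE b_RE + B_RE s_RE + Z_RE p_R + W_RE m_E + e_RE

with fixed effects b (parity, herd-year-season, plus a per-cross mean),
permanent sow-environment effects s ~ N(0, sigma2_s per cross), and
per-origin gametic effects with prior (p_O; m_O) ~ N(0, V_O (x) G_O):
every gamete of origin O carries a latent paternal-role and
maternal-role value, correlated through the 2x2 covariance V_O and
related across gametes through the gametic relationship matrix G_O.
Only the role matching the gamete's cross is connected to data; the
paternal-maternal correlation r_pm = sigma_pm / sqrt(sigma2_p
sigma2_m) is identified through relatives shared between the ER and RE
sides.  All (co)variance priors are flat.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .grm import GameticRelationshipMatrix, factorize_with_jitter

__all__ = [
    "ModelDesign",
    "McmcConfig",
    "McmcSamples",
    "build_design",
    "sample_scalar_variance",
    "sample_gametic_covariance",
    "derive_correlation",
    "run_chain",
    "PARAM_NAMES",
]

PARAM_NAMES = [
    "sigma2_s_ER",
    "sigma2_s_RE",
    "sigma2_pE",
    "sigma2_mE",
    "sigma_pmE",
    "r_pmE",
    "sigma2_pR",
    "sigma2_mR",
    "sigma_pmR",
    "r_pmR",
    "sigma2_e_ER",
    "sigma2_e_RE",
]


class ConsistencyError(ValueError):
    """Raised when phenotypes and gamete maps disagree."""


@dataclass
class ModelDesign:
    """Flattened design for one trait's sampler run.

    Scalar location effects (per-cross mean, parity, herd-year-season,
    permanent sow environment) live in one concatenated bank addressed
    by a CSR record map; the gametic effects are addressed per origin by
    gamete-to-record CSR maps plus each gamete's data-connected role
    (0 = paternal, 1 = maternal).
    """

    y: np.ndarray
    cross_code: np.ndarray  # 0 = ER, 1 = RE per record
    # scalar bank
    n_levels: int
    free: np.ndarray
    bank_levels_of_record: np.ndarray  # (4, n_rec) level id per factor
    segments: dict  # name -> (offset, n_levels)
    sow_cross: np.ndarray  # cross code per sow level
    # gametic maps, per origin
    gam_indptr: dict
    gam_recs: dict
    active_role: dict
    rec_gamete: dict  # origin -> (n_rec,) gamete index of each record
    rec_role: dict  # origin -> (n_rec,) role that gamete plays in the record
    sow_ids: list = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        levels = self.bank_levels_of_record.ravel()
        recs = np.tile(np.arange(self.n_records), self.bank_levels_of_record.shape[0])
        order = np.argsort(levels, kind="stable")
        counts = np.bincount(levels, minlength=self.n_levels)
        indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        return indptr, recs[order].astype(np.int64)

    def fixed_effect_rank_ok(self) -> bool:
        """Check the constrained fixed-effect design is full column rank."""
        cols = []
        n = self.n_records
        for name in ("mean", "parity", "hys"):
            off, k = self.segments[name]
            for lev in range(k):
                if not self.free[off + lev]:
                    continue
                col = np.zeros(n)
                col[self.bank_levels_of_record[_FACTOR_ROW[name]] == off + lev] = 1.0
                cols.append(col)
        X = np.column_stack(cols)
        return np.linalg.matrix_rank(X) == X.shape[1]


_FACTOR_ROW = {"mean": 0, "parity": 1, "hys": 2, "sow": 3}


@dataclass
class McmcConfig:
    """Chain length and numerical settings.

    The reference analysis in the motivating study ran 10M iterations
    with a 1M burn-in; package defaults are scaled down for desk-size
    synthetic data and configurable upward.
    """

    n_iter: int = 200_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    jitter: float = 1e-8
    sweep_order: str = "fixed"  # or "random"
    scalar_dof_offset: int = -2
    wishart_dof_offset: int = -3
    recompute_every: int = 500

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.sweep_order not in ("fixed", "random"):
            raise ValueError("sweep_order must be 'fixed' or 'random'")


@dataclass
class McmcSamples:
    """Stored post-burn-in draws, one column per (co)variance parameter."""

    draws: pd.DataFrame  # columns: iteration + PARAM_NAMES
    config: McmcConfig
    meta: dict = field(default_factory=dict)

    def to_tidy(self) -> pd.DataFrame:
        return self.draws.melt(
            id_vars="iteration", var_name="parameter", value_name="value"
        )

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, config: McmcConfig | None = None):
        wide = tidy.pivot(index="iteration", columns="parameter", values="value")
        wide = wide.reset_index()
        wide.columns.name = None
        return cls(draws=wide, config=config or McmcConfig(n_iter=2, burn_in=0))


def build_design(
    phenotypes: pd.DataFrame,
    index_E: pd.DataFrame,
    index_R: pd.DataFrame,
    trait: str = "tnb",
    n_parity: int = 5,
) -> ModelDesign:
    """Assemble the sampler design for one trait.

    ``index_E`` / ``index_R`` are the gamete index maps of the two
    relationship matrices (columns sow_id, role, cross).  Parities at or
    above ``n_parity`` are pooled into the top level; the first parity
    and first herd-year-season level of each cross are constrained to
    zero (a per-cross mean absorbs the reference cell).
    """
    required = {"sow_id", "cross", "parity", "hys", trait}
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
    ph = phenotypes.reset_index(drop=True)
    if not set(ph["cross"]) <= {"ER", "RE"}:
        raise ValueError("cross labels must be 'ER' or 'RE'")

    pos = {}
    for origin, idx in (("E", index_E), ("R", index_R)):
        pos[origin] = {
            (r["sow_id"], r["role"]): i for i, r in idx.reset_index(drop=True).iterrows()
        }
    sows = list(dict.fromkeys(ph["sow_id"]))
    orphans = []
    for sid, cr in zip(ph["sow_id"], ph["cross"]):
        pat_origin = "E" if cr == "ER" else "R"
        mat_origin = "R" if cr == "ER" else "E"
        if (sid, "paternal") not in pos[pat_origin] or (sid, "maternal") not in pos[mat_origin]:
            orphans.append(sid)
    if orphans:
        raise ConsistencyError(
            f"sows with phenotypes but no gametes: {sorted(set(orphans))[:20]}"
        )

    n_rec = len(ph)
    y = ph[trait].to_numpy(float)
    cross_code = (ph["cross"] == "RE").to_numpy().astype(np.int64)
    parity = np.minimum(ph["parity"].to_numpy(int), n_parity)
    if parity.min() < 1:
        raise ValueError("parity must be coded from 1")

    # scalar bank: per-cross mean, per-cross parity, per-cross hys, sow
    segments = {}
    bank_rows = np.zeros((4, n_rec), dtype=np.int64)
    free_parts, prior_parts = [], []
    off = 0

    segments["mean"] = (off, 2)
    bank_rows[0] = off + cross_code
    free_parts.append(np.ones(2, bool))
    off += 2

    segments["parity"] = (off, 2 * n_parity)
    bank_rows[1] = off + cross_code * n_parity + (parity - 1)
    fp = np.ones(2 * n_parity, bool)
    fp[[0, n_parity]] = False  # first parity of each cross
    free_parts.append(fp)
    off += 2 * n_parity

    hys_codes = np.zeros(n_rec, dtype=np.int64)
    hys_free = []
    n_hys_total = 0
    for code, cr in enumerate(("ER", "RE")):
        m = cross_code == code
        codes, uniq = pd.factorize(ph.loc[m, "hys"], sort=True)
        hys_codes[m] = n_hys_total + codes
        fh = np.ones(len(uniq), bool)
        if len(uniq):
            fh[0] = False  # first level of each cross constrained
        hys_free.append(fh)
        n_hys_total += len(uniq)
    segments["hys"] = (off, n_hys_total)
    bank_rows[2] = off + hys_codes
    free_parts.append(np.concatenate(hys_free) if hys_free else np.zeros(0, bool))
    off += n_hys_total

    sow_of = {s: i for i, s in enumerate(sows)}
    segments["sow"] = (off, len(sows))
    bank_rows[3] = off + np.array([sow_of[s] for s in ph["sow_id"]])
    free_parts.append(np.ones(len(sows), bool))
    sow_cross = np.array(
        [int(ph.loc[ph["sow_id"] == s, "cross"].iloc[0] == "RE") for s in sows],
        dtype=np.int64,
    )
    off += len(sows)

    free = np.concatenate(free_parts)
    # levels with no records cannot be updated
    counts = np.bincount(bank_rows.ravel(), minlength=off)
    free &= counts > 0

    gam_indptr, gam_recs, active_role = {}, {}, {}
    rec_gamete, rec_role = {}, {}
    for origin, idx in (("E", index_E), ("R", index_R)):
        idx = idx.reset_index(drop=True)
        n_g = len(idx)
        role0 = (idx["role"] == "paternal").to_numpy()
        active_role[origin] = np.where(role0, 0, 1).astype(np.int64)
        g_of_rec = np.empty(n_rec, dtype=np.int64)
        r_of_rec = np.empty(n_rec, dtype=np.int64)
        for t in range(n_rec):
            sid, cr = ph.at[t, "sow_id"], ph.at[t, "cross"]
            if (cr == "ER") == (origin == "E"):
                g_of_rec[t] = pos[origin][(sid, "paternal")]
                r_of_rec[t] = 0
            else:
                g_of_rec[t] = pos[origin][(sid, "maternal")]
                r_of_rec[t] = 1
        rec_gamete[origin] = g_of_rec
        rec_role[origin] = r_of_rec
        indptr, recs = _kernels.build_csr(g_of_rec, n_g)
        gam_indptr[origin] = indptr
        gam_recs[origin] = recs

    return ModelDesign(
        y=y,
        cross_code=cross_code,
        n_levels=off,
        free=free,
        bank_levels_of_record=bank_rows,
        segments=segments,
        sow_cross=sow_cross,
        gam_indptr=gam_indptr,
        gam_recs=gam_recs,
        active_role=active_role,
        rec_gamete=rec_gamete,
        rec_role=rec_role,
        sow_ids=sows,
    )


def sample_scalar_variance(
    x: np.ndarray, rng: np.random.Generator, dof_offset: int = -2
) -> float:
    """Draw a variance from its flat-prior full conditional.

    With a flat prior on sigma2, the conditional given the effect (or
    residual) vector x is scaled inverse-chi-square with scale sum(x^2)
    and df = n + dof_offset (default n - 2).
    """
    x = np.asarray(x, float)
    n = x.size
    if n == 0:
        raise ValueError("empty effect vector")
    ss = float(x @ x)
    df = n + dof_offset
    if ss <= 0.0:
        warnings.warn("degenerate variance draw: zero sum of squares", stacklevel=2)
        ss = 1e-30
    if df <= 0:
        warnings.warn(f"non-positive degrees of freedom ({df}); using 1", stacklevel=2)
        df = 1
    return ss / rng.chisquare(df)


def sample_gametic_covariance(
    U: np.ndarray,
    Ginv: np.ndarray,
    rng: np.random.Generator,
    dof_offset: int = -3,
) -> np.ndarray:
    """Draw the 2x2 gametic covariance from its full conditional.

    Under a flat prior on V, the conditional given the stacked gametic
    values U (n x 2) is inverse-Wishart with scale S_u = U' G^-1 U and
    df = n + dof_offset (default n - 3, the flat-on-V convention).
    """
    U = np.asarray(U, float)
    n = U.shape[0]
    S = U.T @ Ginv @ U
    S = 0.5 * (S + S.T)
    if np.trace(S) <= 1e-20:
        warnings.warn("degenerate covariance draw: zero scale matrix", stacklevel=2)
        S = S + 1e-20 * np.eye(2)
    if np.linalg.det(S) <= 0:
        S = S + 1e-12 * np.trace(S) * np.eye(2)
    df = n + dof_offset
    if df < 2:
        raise ValueError(f"too few gametes ({n}) for the inverse-Wishart draw")
    V = stats.invwishart.rvs(df=df, scale=S, random_state=rng)
    return 0.5 * (V + V.T)


def derive_correlation(V: np.ndarray) -> float:
    """Paternal-maternal gametic correlation sigma_pm / sqrt(s2_p s2_m)."""
    V = np.asarray(V, float)
    if V[0, 0] <= 0 or V[1, 1] <= 0:
        warnings.warn("zero gametic variance: correlation undefined", stacklevel=2)
        return np.nan
    return float(V[0, 1] / np.sqrt(V[0, 0] * V[1, 1]))


class _Chain:
    """Mutable state of one Gibbs run (location sweep + variance draws)."""

    def __init__(self, design, G_E, G_R, config):
        self.d = design
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.Ginv = {}
        for origin, G in (("E", G_E), ("R", G_R)):
            handle = factorize_with_jitter(G, config.jitter)
            self.Ginv[origin] = np.ascontiguousarray(handle.inverse())
        self.indptr, self.recs = design.csr()

        y = design.y
        vy = max(float(np.var(y)), 1e-6)
        self.vals = np.zeros(design.n_levels)
        self.U = {o: np.zeros((self.Ginv[o].shape[0], 2)) for o in ("E", "R")}
        self.V = {o: np.eye(2) * 0.05 * vy for o in ("E", "R")}
        self.sigma2_s = np.array([0.1 * vy, 0.1 * vy])  # per cross
        self.sigma2_e = np.array([0.5 * vy, 0.5 * vy])
        self.prior_prec = np.zeros(design.n_levels)
        self._refresh_prior_prec()
        self.Vinv = {o: np.linalg.inv(self.V[o]) for o in ("E", "R")}
        self.Q = {
            o: self.Ginv[o] @ self.U[o] @ self.Vinv[o] for o in ("E", "R")
        }
        self.e = y.copy()
        self.recompute_residuals()

    def _refresh_prior_prec(self):
        off, n_sow = self.d.segments["sow"]
        self.prior_prec[off : off + n_sow] = 1.0 / self.sigma2_s[self.d.sow_cross]

    def recompute_residuals(self):
        d = self.d
        pred = self.vals[d.bank_levels_of_record].sum(axis=0)
        for o in ("E", "R"):
            pred += self.U[o][d.rec_gamete[o], d.rec_role[o]]
        self.e[:] = d.y - pred

    def location_sweep(self):
        d = self.d
        w = 1.0 / self.sigma2_e[d.cross_code]
        order = ["scalar", "E", "R"]
        if self.cfg.sweep_order == "random":
            order = [order[i] for i in self.rng.permutation(3)]
        for step in order:
            if step == "scalar":
                z = self.rng.standard_normal(d.n_levels)
                _kernels.sweep_scalar(
                    self.e, w, self.vals, d.free, self.prior_prec,
                    self.indptr, self.recs, z,
                )
            else:
                o = step
                z = self.rng.standard_normal(2 * self.U[o].shape[0])
                _kernels.sweep_gametic(
                    self.e, w, self.U[o], self.Ginv[o], self.Q[o], self.Vinv[o],
                    d.active_role[o], d.gam_indptr[o], d.gam_recs[o], z,
                )

    def variance_draws(self):
        d, cfg, rng = self.d, self.cfg, self.rng
        for o in ("E", "R"):
            self.V[o] = sample_gametic_covariance(
                self.U[o], self.Ginv[o], rng, cfg.wishart_dof_offset
            )
            self.Vinv[o] = np.linalg.inv(self.V[o])
            self.Q[o] = self.Ginv[o] @ self.U[o] @ self.Vinv[o]
        off, n_sow = d.segments["sow"]
        sow_vals = self.vals[off : off + n_sow]
        for code in (0, 1):
            self.sigma2_s[code] = sample_scalar_variance(
                sow_vals[d.sow_cross == code], rng, cfg.scalar_dof_offset
            )
            self.sigma2_e[code] = sample_scalar_variance(
                self.e[d.cross_code == code], rng, cfg.scalar_dof_offset
            )
        self._refresh_prior_prec()

    def state_row(self, iteration: int) -> dict:
        VE, VR = self.V["E"], self.V["R"]
        return {
            "iteration": iteration,
            "sigma2_s_ER": self.sigma2_s[0],
            "sigma2_s_RE": self.sigma2_s[1],
            "sigma2_pE": VE[0, 0],
            "sigma2_mE": VE[1, 1],
            "sigma_pmE": VE[0, 1],
            "r_pmE": derive_correlation(VE),
            "sigma2_pR": VR[0, 0],
            "sigma2_mR": VR[1, 1],
            "sigma_pmR": VR[0, 1],
            "r_pmR": derive_correlation(VR),
            "sigma2_e_ER": self.sigma2_e[0],
            "sigma2_e_RE": self.sigma2_e[1],
        }


def run_chain(
    design: ModelDesign,
    G_E: GameticRelationshipMatrix | np.ndarray,
    G_R: GameticRelationshipMatrix | np.ndarray,
    config: McmcConfig | None = None,
) -> McmcSamples:
    """Run the Gibbs sampler and return thinned post-burn-in draws.

    Update sweep per iteration: all location effects (single-site),
    then V_E, V_R, the permanent-environment variances and the residual
    variances from their flat-prior conditionals.  The derived
    correlations r_pmE, r_pmR are stored per kept iteration.
    Deterministic for a fixed config (single seeded generator).
    """
    config = config or McmcConfig()
    GE = G_E.values if isinstance(G_E, GameticRelationshipMatrix) else np.asarray(G_E, float)
    GR = G_R.values if isinstance(G_R, GameticRelationshipMatrix) else np.asarray(G_R, float)
    chain = _Chain(design, GE, GR, config)
    rows = []
    for it in range(config.n_iter):
        chain.location_sweep()
        chain.variance_draws()
        if not np.all(np.isfinite(chain.sigma2_e)) or chain.sigma2_e.max() > 1e12:
            raise RuntimeError(f"chain diverged at iteration {it}: {chain.sigma2_e}")
        if (it + 1) % config.recompute_every == 0:
            chain.recompute_residuals()
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            rows.append(chain.state_row(it))
    draws = pd.DataFrame(rows)
    meta = {"n_records": design.n_records, "config": dataclasses.asdict(config)}
    return McmcSamples(draws=draws, config=config, meta=meta)
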