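"""Gametic relationship matrices from phased, origin-labelled gametes.

For each founder origin, the haploid allele vectors of all its gametes
(across both crosses) are centered by the origin population's A2
frequencies, M[i, j] = x_ij - q_j with x in {0, 1}, and the gametic
relationship matrix is G = M M' / sum_j q_j (1 - q_j).  With the true
frequencies this scaling gives unit expected diagonal for gametes drawn
from the origin population; gametes transmitted by a shared parent show
relationships near 0.5 and gametes whose parents are full sibs near
0.25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .simulate import MISSING, PhasedGametes, gamete_index

__all__ = [
    "GameticRelationshipMatrix",
    "estimate_frequencies",
    "origin_gametes",
    "build_centered_matrix",
    "build_gametic_matrix",
    "relationship_histogram",
    "factorize_with_jitter",
    "CholeskyHandle",
]

#: off-diagonal bin edges used in relationship audits
DEFAULT_BIN_EDGES = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50)


@dataclass
class GameticRelationshipMatrix:
    """Symmetric relationship matrix over one origin's gametes.

    ``index`` maps rows to (sow_id, role, cross), ER-sow gametes first
    then RE-sow gametes so the cross-cross block is contiguous;
    ``denominator`` is sum_j q_j (1 - q_j).
    """

    values: np.ndarray
    index: pd.DataFrame
    denominator: float
    origin: str = ""

    @property
    def n_gametes(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("G must be symmetric")
        if np.any(np.diag(self.values) <= 0):
            raise ValueError("G diagonal must be positive")


def estimate_frequencies(
    genotypes: np.ndarray, floor: float = 0.01
) -> np.ndarray:
    """A2 allele frequency per SNP from a purebred genotype panel.

    Computed over non-missing calls and clipped to [floor, 1 - floor]
    so downstream denominators q(1-q) stay bounded away from zero.
    """
    g = np.asarray(genotypes, float)
    ok = g != MISSING
    n_alleles = 2 * ok.sum(axis=0)
    bad = np.flatnonzero(n_alleles == 0)
    if bad.size:
        raise ValueError(f"SNPs with all calls missing: {bad.tolist()[:20]}")
    q = np.where(ok, g, 0).sum(axis=0) / n_alleles
    return np.clip(q, floor, 1 - floor)


def origin_gametes(
    gametes: PhasedGametes, origin: str
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack one origin's haploid vectors with their index map.

    ER-sow gametes come first, then RE-sow gametes, matching the row
    order of the relationship matrix built from them.
    """
    idx = gamete_index(gametes, origin)
    pos = {sid: i for i, sid in enumerate(gametes.sow_ids)}
    rows = []
    for _, r in idx.iterrows():
        source = gametes.paternal if r["role"] == "paternal" else gametes.maternal
        rows.append(source[pos[r["sow_id"]]])
    return np.array(rows, dtype=np.int8), idx


def build_centered_matrix(haploid: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Center haploid allele vectors by the origin frequencies.

    Entries are 1 - q for an A2 allele and -q for A1; unassigned
    positions are imputed at the centered mean 0.
    """
    h = np.asarray(haploid)
    q = np.asarray(q, float)
    if h.shape[1] != q.shape[0]:
        raise ValueError("haploid matrix and frequency vector disagree on SNP count")
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("frequencies must lie strictly in (0, 1); clip first")
    M = h.astype(float) - q[None, :]
    M[h == MISSING] = 0.0
    return M


def build_gametic_matrix(
    M: np.ndarray, q: np.ndarray, index: pd.DataFrame | None = None, origin: str = ""
) -> GameticRelationshipMatrix:
    """G = M M' / sum_j q_j (1 - q_j) over the centered gamete matrix."""
    M = np.asarray(M, float)
    if M.size == 0:
        raise ValueError("empty centered matrix")
    denom = float(np.sum(q * (1 - q)))
    if denom <= 0:
        raise ZeroDivisionError("zero scaling denominator: all frequencies at 0/1")
    G = (M @ M.T) / denom
    if index is None:
        index = pd.DataFrame(
            {"sow_id": [f"g{i}" for i in range(M.shape[0])], "role": "", "cross": ""}
        )
    return GameticRelationshipMatrix(values=G, index=index, denominator=denom, origin=origin)


def relationship_histogram(
    grm: GameticRelationshipMatrix | np.ndarray,
    bin_edges=DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Audit the off-diagonal relationship distribution.

    Counts ordered off-diagonal pairs (both triangles, total n(n-1))
    into bins (-inf, e1), [e1, e2), ..., [ek, inf); percentages sum
    to 100.
    """
    G = grm.values if isinstance(grm, GameticRelationshipMatrix) else np.asarray(grm)
    n = G.shape[0]
    off = G[~np.eye(n, dtype=bool)]
    edges = np.concatenate([[-np.inf], np.asarray(bin_edges, float), [np.inf]])
    counts, _ = np.histogram(off, bins=edges)
    labels = (
        [f"<{bin_edges[0]:g}"]
        + [f"{a:g}-{b:g}" for a, b in zip(bin_edges[:-1], bin_edges[1:])]
        + [f">{bin_edges[-1]:g}"]
    )
    return pd.DataFrame(
        {
            "bin": labels,
            "count": counts,
            "percent": 100 * counts / max(off.size, 1),
        }
    )


@dataclass
class CholeskyHandle:
    """Factorization of G + jitter*I supporting solves and log-determinant."""

    factor: tuple = field(repr=False)
    jitter: float = 0.0

    def solve(self, b: np.ndarray) -> np.ndarray:
        return linalg.cho_solve(self.factor, b)

    def logdet(self) -> float:
        c = self.factor[0]
        return 2.0 * float(np.sum(np.log(np.diag(c))))

    def inverse(self) -> np.ndarray:
        n = self.factor[0].shape[0]
        return self.solve(np.eye(n))


def factorize_with_jitter(
    G: GameticRelationshipMatrix | np.ndarray,
    jitter: float = 0.0,
    jitter_cap: float = 1e-2,
) -> CholeskyHandle:
    """Cholesky-factorize G, escalating diagonal jitter on failure.

    Genomic G matrices are often numerically singular (duplicate or
    near-duplicate gametes).  If factorization fails, jitter is raised
    in x10 steps (from 1e-10 when starting at 0) up to ``jitter_cap``.
    """
    A = G.values if isinstance(G, GameticRelationshipMatrix) else np.asarray(G, float)
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    j = jitter
    while True:
        try:
            factor = linalg.cho_factor(A + j * np.eye(A.shape[0]), lower=True)
            if j > jitter:
                warnings.warn(
                    f"relationship matrix needed jitter {j:g} to factorize",
                    stacklevel=2,
                )
            return CholeskyHandle(factor=factor, jitter=j)
        except linalg.LinAlgError:
            j = 1e-10 if j == 0 else j * 10
            if j > jitter_cap:
                raise np.linalg.LinAlgError(
                    f"factorization failed up to jitter cap {jitter_cap:g}"
                ) from None
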