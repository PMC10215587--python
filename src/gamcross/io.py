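"""Readers and writers for the pipeline's plain-text formats.

Conventions: alleles are coded 1/2 in files (0 = missing/unassigned)
and 0/1 internally; genotypes are A2 dosages {0,1,2} with -1 missing;
SNP and individual indices are 0-based internally and 1-based in files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import MISSING, PhasedGametes

logger = logging.getLogger(__name__)

__all__ = [
    "read_plink",
    "write_plink",
    "read_haplotypes",
    "write_haplotypes",
    "read_phenotypes",
    "write_grm",
    "read_grm",
    "load_config",
]


class ParseError(ValueError):
    pass


def write_plink(path_prefix, genotypes: np.ndarray, ids=None, snp_names=None) -> None:
    """Write a genotype dosage matrix as PLINK .ped/.map (alleles 1/2)."""
    g = np.asarray(genotypes)
    n_ind, n_snp = g.shape
    ids = ids or [f"ind{i + 1}" for i in range(n_ind)]
    snp_names = snp_names or [f"snp{j + 1}" for j in range(n_snp)]
    prefix = Path(path_prefix)
    with open(prefix.with_suffix(".map"), "w") as f:
        for j, name in enumerate(snp_names):
            f.write(f"1\t{name}\t0\t{j + 1}\n")
    # dosage d -> allele pair: 0 -> 1 1, 1 -> 1 2, 2 -> 2 2, missing -> 0 0
    pair = {0: "1 1", 1: "1 2", 2: "2 2", MISSING: "0 0"}
    with open(prefix.with_suffix(".ped"), "w") as f:
        for i, iid in enumerate(ids):
            alleles = " ".join(pair[int(d)] for d in g[i])
            f.write(f"FAM {iid} 0 0 0 -9 {alleles}\n")


def read_plink(ped_path, map_path) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Read PLINK .ped/.map into an A2-dosage matrix.

    Returns (genotypes, individual ids, SNP metadata table).  Allele
    codes must be 1/2 with 0 for missing; any 0 in a pair marks the
    call missing.
    """
    snps = []
    with open(map_path) as f:
        for ln, line in enumerate(f, 1):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{map_path}:{ln}: expected 4 columns")
            snps.append({"chrom": parts[0], "snp": parts[1], "pos": parts[3]})
    snp_meta = pd.DataFrame(snps)
    n_snp = len(snp_meta)
    rows, ids = [], []
    with open(ped_path) as f:
        for ln, line in enumerate(f, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_snp:
                raise ParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snp} columns, got {len(parts)}"
                )
            ids.append(parts[1])
            alleles = np.array(parts[6:], dtype=np.int8).reshape(n_snp, 2)
            if not np.isin(alleles, (0, 1, 2)).all():
                raise ParseError(f"{ped_path}:{ln}: allele codes must be 0/1/2")
            dose = (alleles == 2).sum(axis=1).astype(np.int8)
            dose[(alleles == 0).any(axis=1)] = MISSING
            rows.append(dose)
    if not rows:
        raise ParseError(f"{ped_path}: empty file")
    return np.array(rows), ids, snp_meta


def write_haplotypes(path, gametes: PhasedGametes, snp_names=None) -> None:
    """Write phased gametes as TSV: sow_id, role, origin, one column per SNP.

    Alleles are 1/2, unassigned positions 0.
    """
    n_snp = gametes.n_snp
    snp_names = snp_names or [f"snp{j + 1}" for j in range(n_snp)]
    origin = {r: gametes.origin_of(r) for r in ("paternal", "maternal")}
    with open(path, "w") as f:
        f.write("sow_id\trole\torigin\t" + "\t".join(snp_names) + "\n")
        for i, sid in enumerate(gametes.sow_ids):
            for role, hap in (("paternal", gametes.paternal), ("maternal", gametes.maternal)):
                coded = np.where(hap[i] == MISSING, 0, hap[i] + 1)
                f.write(
                    f"{sid}\t{role}\t{origin[role][i]}\t"
                    + "\t".join(map(str, coded))
                    + "\n"
                )


def read_haplotypes(path) -> PhasedGametes:
    """Read the phased-haplotype TSV dialect back into PhasedGametes."""
    df = pd.read_csv(path, sep="\t")
    snp_cols = [c for c in df.columns if c not in ("sow_id", "role", "origin")]
    sow_ids = list(dict.fromkeys(df["sow_id"]))
    n, m = len(sow_ids), len(snp_cols)
    pat = np.full((n, m), MISSING, dtype=np.int8)
    mat = np.full((n, m), MISSING, dtype=np.int8)
    cross = np.empty(n, dtype=object)
    pos = {s: i for i, s in enumerate(sow_ids)}
    for _, row in df.iterrows():
        i = pos[row["sow_id"]]
        alleles = row[snp_cols].to_numpy(int)
        hap = np.where(alleles == 0, MISSING, alleles - 1).astype(np.int8)
        if row["role"] == "paternal":
            pat[i] = hap
            cross[i] = "ER" if row["origin"] == "E" else "RE"
        else:
            mat[i] = hap
    return PhasedGametes(
        sow_ids=sow_ids, cross=cross.astype(str), paternal=pat, maternal=mat
    )


def read_phenotypes(path, permissive: bool = False) -> pd.DataFrame:
    """Read and validate the repeated-records phenotype CSV.

    Requires columns sow_id, cross (ER/RE), parity, hys, tnb, nba.
    Parity is recoded to the 5-level scheme (fifth and later parities
    pooled).  Bad rows raise (or are dropped under ``permissive``, with
    a row-level report logged); a per-cross summary in the style
    "N (NS)  mean +/- sd" is logged.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ParseError(f"{path}: empty phenotype file")
    required = {"sow_id", "cross", "parity", "hys", "tnb", "nba"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad = []
    for t, row in df.iterrows():
        problems = []
        if row["cross"] not in ("ER", "RE"):
            problems.append(f"unknown cross {row['cross']!r}")
        for trait in ("tnb", "nba"):
            if not np.isfinite(pd.to_numeric(row[trait], errors="coerce")):
                problems.append(f"non-numeric {trait}")
        if problems:
            bad.append((t, "; ".join(problems)))
    if bad:
        report = "; ".join(f"row {t}: {msg}" for t, msg in bad[:10])
        if not permissive:
            raise ParseError(f"{path}: {len(bad)} bad rows ({report})")
        logger.warning("%s: dropping %d bad rows (%s)", path, len(bad), report)
        df = df.drop(index=[t for t, _ in bad]).reset_index(drop=True)
    df["parity"] = np.minimum(df["parity"].astype(int), 5)
    for cross, sub in df.groupby("cross"):
        logger.info(
            "%s: N (NS) = %d (%d); TNB %.2f +/- %.2f; NBA %.2f +/- %.2f",
            cross, len(sub), sub["sow_id"].nunique(),
            sub["tnb"].mean(), sub["tnb"].std(),
            sub["nba"].mean(), sub["nba"].std(),
        )
    return df


def phenotype_summary(df: pd.DataFrame) -> dict:
    """Per-cross record counts and trait moments, keyed like a data-summary table."""
    out = {}
    for cross, sub in df.groupby("cross"):
        out[cross] = {
            "N": int(len(sub)),
            "NS": int(sub["sow_id"].nunique()),
            "tnb_mean": float(sub["tnb"].mean()),
            "tnb_sd": float(sub["tnb"].std()),
            "nba_mean": float(sub["nba"].mean()),
            "nba_sd": float(sub["nba"].std()),
        }
    return out


def write_grm(path, grm) -> None:
    """Write a gametic relationship matrix as TSV + sidecar index map."""
    path = Path(path)
    np.savetxt(path, grm.values, delimiter="\t")
    grm.index.to_csv(path.with_suffix(".index.csv"), index=False)
    meta = {"denominator": grm.denominator, "origin": grm.origin}
    path.with_suffix(".meta.json").write_text(json.dumps(meta))


def read_grm(path):
    from .grm import GameticRelationshipMatrix

    path = Path(path)
    values = np.loadtxt(path, delimiter="\t")
    index = pd.read_csv(path.with_suffix(".index.csv"))
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return GameticRelationshipMatrix(
        values=values, index=index, denominator=meta["denominator"], origin=meta["origin"]
    )


def load_config(path) -> dict:
    """Load a YAML or JSON pipeline configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        return yaml.safe_load(text)
    return json.loads(text)
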