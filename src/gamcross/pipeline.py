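"""End-to-end pipeline: QC -> consensus -> frequencies -> G -> fit -> summary.

Each stage writes its outputs plus a manifest entry (parameters, output
checksums); with ``resume`` enabled a stage whose outputs already exist
is skipped and its outputs are re-read, so a broken run restarts
downstream of its last good stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import io as gio
from .consensus import consensus_phase
from .gibbs import McmcConfig, build_design, run_chain
from .grm import build_centered_matrix, build_gametic_matrix, estimate_frequencies, origin_gametes
from .qc import filter_snps
from .simulate import MISSING, gamete_index

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_done(outputs: list[Path]) -> bool:
    return all(p.exists() for p in outputs)


def run_pipeline(config: dict, resume: bool = False) -> dict:
    """Execute the full analysis described by ``config``.

    Required config keys: out_dir, seed, inputs {ped_E, map_E, ped_R,
    map_R, scenarios (list of haplotype TSVs), phenotypes}; optional
    sections qc, consensus, grm, mcmc, trait.  Returns the manifest.
    """
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    trait = config.get("trait", "tnb")
    manifest: dict = {"seed": seed, "trait": trait, "stages": {}, "config": config}

    def finish(stage: str, outputs: list[Path], params: dict):
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {str(p): _sha256(p) for p in outputs},
        }
        logger.info("stage %s done", stage)

    try:
        inputs = config["inputs"]
        # --- QC over the pooled purebred panels ---------------------------
        qc_cfg = config.get("qc", {})
        qc_out = out / "qc_report.json"
        retained_out = out / "retained_snps.txt"
        geno_E, _, snp_meta = gio.read_plink(inputs["ped_E"], inputs["map_E"])
        geno_R, _, _ = gio.read_plink(inputs["ped_R"], inputs["map_R"])
        genotypes = np.vstack([geno_E, geno_R])
        labels = np.array(["E"] * len(geno_E) + ["R"] * len(geno_R))
        if resume and _stage_done([qc_out, retained_out]):
            retained = np.loadtxt(retained_out, dtype=int, ndmin=1)
        else:
            retained, report = filter_snps(
                genotypes,
                labels,
                call_rate_min=qc_cfg.get("call_rate_min", 0.90),
                maf_min=qc_cfg.get("maf_min", 0.05),
            )
            qc_out.write_text(json.dumps(report.to_dict(), indent=1))
            np.savetxt(retained_out, retained, fmt="%d")
            finish("qc", [qc_out, retained_out], qc_cfg)

        # --- phase consensus ----------------------------------------------
        cons_cfg = config.get("consensus", {})
        min_agree = cons_cfg.get("min_agree", 7)
        cons_out = out / "consensus_haplotypes.tsv"
        cons_rep = out / "consensus_report.json"
        if resume and _stage_done([cons_out, cons_rep]):
            consensus = gio.read_haplotypes(cons_out)
        else:
            from .consensus import PhaseScenarioSet, similitude_matrix

            sets = [gio.read_haplotypes(p) for p in inputs["scenarios"]]
            scen = PhaseScenarioSet(
                scenario_ids=[f"S{i + 1}" for i in range(len(sets))],
                paternal=np.stack([s.paternal for s in sets]),
                maternal=np.stack([s.maternal for s in sets]),
                sow_ids=sets[0].sow_ids,
                cross=sets[0].cross,
            )
            consensus, report = consensus_phase(scen, min_agree=min_agree)
            M, mean_sim = similitude_matrix(scen)
            gio.write_haplotypes(cons_out, consensus)
            cons_rep.write_text(
                json.dumps(
                    {
                        "similitude_matrix": M.tolist(),
                        "mean_similitude": mean_sim,
                        "retention": report["retention"],
                        "snp_retention_all_sows": report["snp_retention_all_sows"],
                        "min_agree": min_agree,
                    },
                    indent=1,
                )
            )
            finish("consensus", [cons_out, cons_rep], {"min_agree": min_agree})

        # --- allele frequencies and gametic matrices ----------------------
        grm_cfg = config.get("grm", {})
        floor = grm_cfg.get("freq_floor", 0.01)
        jitter = grm_cfg.get("jitter", 1e-8)
        grms = {}
        for origin, panel in (("E", geno_E), ("R", geno_R)):
            g_out = out / f"grm_{origin}.tsv"
            if resume and _stage_done([g_out]):
                grms[origin] = gio.read_grm(g_out)
                continue
            q = estimate_frequencies(panel[:, retained], floor=floor)
            hap, idx = origin_gametes(consensus, origin)
            M = build_centered_matrix(hap[:, retained], q)
            grms[origin] = build_gametic_matrix(M, q, index=idx, origin=origin)
            gio.write_grm(g_out, grms[origin])
            finish(f"grm_{origin}", [g_out], {"freq_floor": floor})

        # --- model fit -----------------------------------------------------
        mc = config.get("mcmc", {})
        mcfg = McmcConfig(
            n_iter=mc.get("n_iter", 20000),
            burn_in=mc.get("burn_in", 4000),
            thin=mc.get("thin", 10),
            seed=seed,
            jitter=jitter,
        )
        samples_out = out / f"samples_{trait}.csv"
        phenotypes = gio.read_phenotypes(inputs["phenotypes"])
        if resume and _stage_done([samples_out]):
            import pandas as pd

            from .gibbs import McmcSamples

            samples = McmcSamples.from_tidy(pd.read_csv(samples_out), mcfg)
        else:
            design = build_design(
                phenotypes, grms["E"].index, grms["R"].index, trait=trait
            )
            samples = run_chain(design, grms["E"], grms["R"], mcfg)
            samples.to_tidy().to_csv(samples_out, index=False)
            finish(f"fit_{trait}", [samples_out], samples.meta["config"])

        # --- summary -------------------------------------------------------
        from .summary import summarize

        summary_out = out / f"summary_{trait}.json"
        summ = summarize(samples)
        summary_out.write_text(summ.reset_index().to_json(orient="records", indent=1))
        finish(f"summary_{trait}", [summary_out], {})
    except Exception as exc:
        done = list(manifest["stages"])
        raise RuntimeError(
            f"pipeline failed after stages {done}: {exc}"
        ) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
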