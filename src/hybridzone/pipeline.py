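"""End-to-end orchestration of the hybrid-zone analysis stages.

The pipeline runs QC -> hybrid index -> transect -> cline -> tension zone
(optionally triangle and niche arms) from a single configuration mapping,
writing per-stage tables and a combined JSON summary.

A first-class "table1 mode" covers the common situation where only the
published locality-level summaries exist (no individual genotypes):
individual-level stages are skipped with explicit notices, and cline
fitting runs on allele counts reconstructed from the locality hybrid index
(k_i = round(HI_i * 2 N_i), n_i = 2 N_i; mtDNA: k_i = freq_i * N_mt_i,
n_i = N_mt_i as haploid counts).
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import individual_hybrid_index, locality_hybrid_index, triangle_batch
from .cline import ClineData, ClineFit, best_fit, model_select
from .data_model_io import (
    GenotypePanel,
    LocalityFrame,
    load_table1_fixture,
    read_genotype_table,
    read_locality_table,
)
from .marker_qc import hwe_table, screen_hwe
from .tension_zone import dispersal_pipeline, neutral_width, sigma_from_ld
from .transect import IsolineTransect, build_transect

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "stages": ["qc", "hybrid_index", "transect", "cline", "tension"],
    "table1_mode": False,
    "alpha": 0.05,
    "min_sig_pops": 2,
    "transect_resolution_deg": 0.01,
    "isoline_level": 0.5,
    "mcmc_chains": 3,
    "mcmc_steps": 20000,
    "n_starts": 12,
    "recombination_rate": 0.5,
    "contact_age_years": 12000.0,
    "generation_time_years": 5.0,
    "output_dir": "hybridzone_out",
}


def load_config(path: str | Path) -> dict[str, Any]:
    cfg = dict(DEFAULTS)
    cfg.update(yaml.safe_load(Path(path).read_text()) or {})
    return cfg


def table1_allele_counts(
    localities: LocalityFrame, transect: IsolineTransect, kind: str = "hi"
) -> ClineData:
    """Reconstruct per-locality allele counts from published summaries.

    ``kind='hi'``: diploid counts from the hybrid index and KASP sample
    size. ``kind='mtdna'``: haploid haplotype counts.
    """
    f = localities.frame
    dist = transect.as_dict()
    x = np.array([dist[str(c)] for c in f["code"].astype(str)])
    if kind == "hi":
        n = 2.0 * f["n_kasp"].to_numpy(float)
        k = np.round(f["hybrid_index"].to_numpy(float) * n)
    elif kind == "mtdna":
        n = f["n_mtdna"].to_numpy(float)
        k = np.round(f["mtdna_freq"].to_numpy(float) * n)
    else:
        raise ValueError("kind must be 'hi' or 'mtdna'")
    keep = n >= 1
    return ClineData(x[keep], k[keep], n[keep])


def _fit_summary(fit: ClineFit) -> dict[str, Any]:
    return {
        "tail_variant": fit.model.tail_variant,
        "scaling_variant": fit.model.scaling_variant,
        "center_km": fit.model.c,
        "width_km": fit.model.w,
        "pmin": fit.model.pmin,
        "pmax": fit.model.pmax,
        "logL": fit.logL,
        "AICc": fit.aicc,
        "delta_AICc": fit.delta_aicc,
        "support": {k: list(v) for k, v in fit.support.items()},
        "converged": fit.converged,
    }


def run_pipeline(config: dict[str, Any], localities: LocalityFrame | None = None,
                 panel: GenotypePanel | None = None) -> dict[str, Any]:
    """Execute the enabled stages in order and return the summary mapping.

    Inputs may be passed directly (programmatic use) or named by path in
    the config (``genotypes``, ``localities``; ``localities: table1`` loads
    the packaged fixture). The summary plus per-stage tables are written to
    ``output_dir``; the config is echoed verbatim alongside them.
    """
    cfg = dict(DEFAULTS)
    cfg.update(config)
    stages = list(cfg["stages"])
    if not stages:
        raise ValueError("nothing to do: no stages enabled")
    # validate stage dependencies before touching the filesystem
    if "cline" in stages and "transect" not in stages:
        raise ValueError("cline stage requires the transect stage")
    if "tension" in stages and "cline" not in stages:
        raise ValueError("tension stage requires the cline stage")
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    if localities is None and cfg.get("localities"):
        localities = (
            load_table1_fixture()
            if cfg["localities"] == "table1"
            else read_locality_table(cfg["localities"])
        )
    if panel is None and cfg.get("genotypes"):
        panel = read_genotype_table(cfg["genotypes"])

    table1_mode = bool(cfg["table1_mode"]) or panel is None
    summary: dict[str, Any] = {
        "version": __version__,
        "seed": cfg["seed"],
        "table1_mode": table1_mode,
        "timings_s": {},
        "notices": [],
    }
    needs_panel = {"qc", "triangle", "tension"}
    for stage in stages:
        if stage in needs_panel and table1_mode and stage != "tension":
            summary["notices"].append(
                f"stage {stage!r} skipped: requires individual genotypes"
            )
    if "cline" in stages and localities is None:
        raise ValueError("cline stage enabled but no locality table given")

    t0 = time.perf_counter()
    if "qc" in stages and not table1_mode:
        decisions = screen_hwe(panel, cfg["alpha"], cfg["min_sig_pops"])
        pd.DataFrame([vars(d) for d in decisions]).to_csv(
            out_dir / "qc_decisions.csv", index=False
        )
        pd.DataFrame([vars(r) for r in hwe_table(panel)]).to_csv(
            out_dir / "hwe_table.csv", index=False
        )
        excluded = [d.marker_id for d in decisions if d.excluded]
        if excluded:
            panel = panel.drop_markers(excluded)
        summary["qc"] = {"excluded_markers": excluded}
        summary["timings_s"]["qc"] = time.perf_counter() - t0

    if "hybrid_index" in stages and not table1_mode:
        t0 = time.perf_counter()
        his = [individual_hybrid_index(panel, i) for i in panel.individual_ids]
        pd.DataFrame([vars(h) for h in his]).to_csv(
            out_dir / "individual_hybrid_index.csv", index=False
        )
        loc_his = {
            code: locality_hybrid_index(panel, code).value
            for code in panel.localities()
        }
        summary["hybrid_index"] = {"locality_hi": loc_his}
        summary["timings_s"]["hybrid_index"] = time.perf_counter() - t0

    transect = None
    if "transect" in stages:
        t0 = time.perf_counter()
        natural = localities.natural_range()
        transect = build_transect(
            natural, cfg["transect_resolution_deg"], cfg["isoline_level"]
        )
        pd.DataFrame(
            {"code": transect.codes, "distance_km": transect.distances_km}
        ).to_csv(out_dir / "transect.csv", index=False)
        summary["transect"] = {
            "n_localities": len(transect.codes),
            "isoline_vertices": len(transect.isoline),
        }
        summary["timings_s"]["transect"] = time.perf_counter() - t0

    hi_best = None
    if "cline" in stages:
        if transect is None:
            raise ValueError("cline stage requires the transect stage")
        t0 = time.perf_counter()
        natural = localities.natural_range()
        summary["cline"] = {}
        for kind in ("hi", "mtdna"):
            data = table1_allele_counts(natural, transect, kind)
            fits = model_select(
                data, seed=cfg["seed"], mcmc_chains=cfg["mcmc_chains"],
                mcmc_steps=cfg["mcmc_steps"], n_starts=cfg["n_starts"],
            )
            pd.DataFrame([_fit_summary(f) for f in fits]).to_csv(
                out_dir / f"cline_fits_{kind}.csv", index=False
            )
            chosen = best_fit(fits)
            if kind == "hi":
                hi_best = chosen
            summary["cline"][kind] = _fit_summary(chosen)
        summary["timings_s"]["cline"] = time.perf_counter() - t0

    if "tension" in stages:
        t0 = time.perf_counter()
        if table1_mode or panel is None:
            if hi_best is None:
                raise ValueError("tension stage requires the cline stage")
            summary["notices"].append(
                "tension stage in table1 mode: D'/sigma need individual "
                "genotypes; reporting the neutral-width chain at configured sigma"
            )
            sigma = cfg.get("sigma_km_per_gen")
            T = cfg["contact_age_years"] / cfg["generation_time_years"]
            tension: dict[str, Any] = {"T_generations": T}
            if sigma:
                tension.update(
                    sigma_km_per_gen=sigma,
                    w_neutral_km=neutral_width(sigma, T),
                    generations_to_cross=hi_best.model.w / sigma,
                )
            summary["tension"] = tension
        else:
            est = dispersal_pipeline(
                panel, transect, hi_best,
                r=cfg["recombination_rate"],
                contact_age_years=cfg["contact_age_years"],
                generation_time_years=cfg["generation_time_years"],
            )
            summary["tension"] = {
                "d_prime": est.d_prime,
                "sigma_km_per_gen": est.sigma_km_per_gen,
                "w_neutral_km": est.w_neutral_km,
                "s_star": est.s_star,
                "generations_to_cross": est.generations_to_cross,
                "inputs": est.inputs,
            }
        summary["timings_s"]["tension"] = time.perf_counter() - t0

    if "triangle" in stages and not table1_mode:
        t0 = time.perf_counter()
        estimates, corner = triangle_batch(panel)
        pd.DataFrame([vars(e) for e in estimates]).to_csv(
            out_dir / "triangle.csv", index=False
        )
        summary["triangle"] = corner
        summary["timings_s"]["triangle"] = time.perf_counter() - t0

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
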