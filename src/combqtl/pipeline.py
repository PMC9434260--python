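"""End-to-end seeded run: simulate -> morphometrics -> scan -> escan -> coloc.

Every stage derives its RNG stream from the single run seed, writes its
outputs under the run directory, and is summarized in a JSON manifest
sufficient to re-run the analysis bit-identically.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coloc import (find_overlaps, map_ci_to_physical,
                    overlap_enrichment_from_sets, trait_expression_correlation)
from .eqtl import eqtl_table, scan_expression
from .io import (CrossFileDialect, write_chrom_sizes, write_cross_csv,
                 write_expression_csv, write_outlines_csv, write_regions_bed)
from .morphometrics import (EFACoefficients, align_outlines, efa_decompose,
                            interpolate_outline, shape_pca)
from .qtl import find_qtl_peaks, genotype_probabilities
from .simulate import (ExpressionSpec, QTLSpec, SimConfig, noise_sd_for_pve,
                       simulate_ail_genotypes, simulate_expression_matrix,
                       simulate_map, simulate_outline_population,
                       simulate_quantitative_trait, to_cross)

DEFAULT_CONFIG = {
    "seed": 0,
    "sim": {},                       # SimConfig overrides
    "qtl": [                         # planted trait QTL
        {"trait_name": "area", "chromosome": "3", "position": 110.0,
         "additive_effect": 1.0, "dominance_effect": 0.2},
    ],
    "target_pve": 0.10,
    "covariate_effects": {"sex": 0.5, "batch": 0.3, "weight": 0.002, "family": 0.2},
    "shape": {"chromosome": "2", "position": 60.0, "effect": 0.06,
              "coeff_noise_sd": 0.01, "n_points": 300},
    "expression": {"n_null_probes": 30, "n_cis": 5, "n_trans": 5,
                   "effect_sd_ratio": 3.0, "noise_sd": 0.5, "batch_effect_sd": 0.3},
    "n_perm": 1000,
    "harmonics": 8,
    "outline_points": 300,
    "covariates": ["sex", "batch", "family", "weight"],
    "enrichment_iterations": 2000,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _comb_mean_coeffs(n_harmonics: int = 8) -> EFACoefficients:
    """A smooth comb-like blob: a 2:1 ellipse with mild upper-edge bumps."""
    a = np.zeros(n_harmonics); b = np.zeros(n_harmonics)
    c = np.zeros(n_harmonics); d = np.zeros(n_harmonics)
    a[0], d[0] = 2.0, 1.0
    if n_harmonics >= 3:
        c[2] = 0.12
    if n_harmonics >= 5:
        c[4] = 0.05
    return EFACoefficients(a, b, c, d)


def run_pipeline(config: dict | None = None, outdir="run", seed: int | None = None) -> Path:
    """Run the whole analysis on synthetic data; returns the run directory."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = seed
    if cfg.get("seed") is None:
        raise ValueError("config must provide a seed")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    root = np.random.default_rng(cfg["seed"])
    stage_seeds = {name: int(s) for name, s in zip(
        ["breed", "trait", "shape", "expr", "scan", "escan", "coloc"],
        root.integers(0, 2**31 - 1, size=7))}
    manifest = {"version": __version__, "seed": cfg["seed"],
                "stage_seeds": stage_seeds, "config": {k: v for k, v in cfg.items()},
                "stages": {}}

    def _stage(name):
        manifest["stages"][name] = {"t": round(time.time() - t0, 2)}

    # --- simulate ---------------------------------------------------------
    sim_cfg = SimConfig(**{**cfg["sim"], "seed": stage_seeds["breed"]})
    gmap = simulate_map(sim_cfg)
    geno = simulate_ail_genotypes(gmap, sim_cfg)
    qtls = [QTLSpec(**q) for q in cfg["qtl"]]
    rng_t = np.random.default_rng(stage_seeds["trait"])
    pilot = simulate_quantitative_trait(geno, gmap, qtls, cfg["covariate_effects"],
                                        noise_sd=1.0, rng=np.random.default_rng(stage_seeds["trait"]))
    sds = {}
    for trait in pilot.genetic_values.columns:
        g = pilot.genetic_values[trait].to_numpy()
        sds[trait] = noise_sd_for_pve(g, cfg["target_pve"]) if np.var(g) > 0 else 1.0
    table = simulate_quantitative_trait(geno, gmap, qtls, cfg["covariate_effects"],
                                        noise_sd=float(np.mean(list(sds.values()))),
                                        rng=rng_t)
    cross = to_cross(geno, table)

    shape = cfg["shape"]
    mean_coeffs = _comb_mean_coeffs(cfg["harmonics"])
    effect = np.zeros(4 * cfg["harmonics"])
    effect[0] = shape["effect"]                     # stretch along x per W dose
    shape_qtl = QTLSpec(chromosome=shape["chromosome"], position=shape["position"],
                        additive_effect=1.0, trait_name="outline")
    outlines = simulate_outline_population(
        geno, shape_qtl, mean_coeffs, effect, noise_sd=shape["coeff_noise_sd"],
        n_points=shape["n_points"], rng=np.random.default_rng(stage_seeds["shape"]))

    ex = cfg["expression"]
    rng_e = np.random.default_rng(stage_seeds["expr"])
    chroms = [str(c) for c in gmap.chromosomes]
    positions = {}
    n_probes = ex["n_null_probes"] + ex["n_cis"] + ex["n_trans"]
    for i in range(n_probes):
        ch = chroms[int(rng_e.integers(len(chroms)))]
        positions[f"probe{i + 1}"] = (ch, float(rng_e.uniform(0, gmap.chrom_length(ch))))
    cis_ids = tuple(f"probe{i + 1}" for i in range(ex["n_cis"]))
    trans_pairs = []
    for i in range(ex["n_cis"], ex["n_cis"] + ex["n_trans"]):
        pid = f"probe{i + 1}"
        pch, pcm = positions[pid]
        others = [c for c in chroms if c != pch] or chroms
        rch = others[int(rng_e.integers(len(others)))]
        trans_pairs.append((pid, rch, float(rng_e.uniform(0, gmap.chrom_length(rch))),
                            ex["effect_sd_ratio"] * ex["noise_sd"]))
    espec = ExpressionSpec(probe_positions=positions, cis_probes=cis_ids,
                           cis_effect_size=ex["effect_sd_ratio"] * ex["noise_sd"],
                           trans_pairs=tuple(trans_pairs),
                           batch_effect_sd=ex["batch_effect_sd"], noise_sd=ex["noise_sd"])
    sim_expr = simulate_expression_matrix(geno, gmap, espec, rng=rng_e)

    dialect = CrossFileDialect(
        phenotype_columns=tuple(table.phenotypes.columns),
        covariate_columns=tuple(table.covariates.columns))
    write_cross_csv(cross, outdir / "cross.csv", dialect)
    write_outlines_csv(outlines, outdir / "outlines.csv", ids=list(cross.individual_ids))
    write_expression_csv(sim_expr.values, outdir / "expression.csv")
    sim_expr.annotation.to_csv(outdir / "probe_annotation.csv", index=False)
    _stage("simulate")

    # --- morphometrics ----------------------------------------------------
    interp = [interpolate_outline(o, cfg["outline_points"]) for o in outlines]
    aligned = align_outlines(interp)
    coeffs = [efa_decompose(o, cfg["harmonics"]) for o in aligned.outlines]
    mat = np.stack([c.flatten() for c in coeffs])
    pca = shape_pca(mat)
    pc = pd.DataFrame(pca.scores[:, :2], columns=["PC1", "PC2"],
                      index=cross.individual_ids)
    cross.phenotypes = cross.phenotypes.join(pc)
    pc.to_csv(outdir / "shape_pca_scores.csv")
    pd.DataFrame(mat, index=cross.individual_ids).to_csv(outdir / "efa_coefficients.csv")
    _stage("morphometrics")

    # --- QTL scans --------------------------------------------------------
    probs = genotype_probabilities(cross)
    rng_s = np.random.default_rng(stage_seeds["scan"])
    all_peaks = []
    for trait in cross.phenotypes.columns:
        peaks = find_qtl_peaks(cross, trait, cfg["covariates"],
                               n_perm=cfg["n_perm"], rng=rng_s, probs=probs)
        all_peaks.extend(peaks)
    peaks_df = pd.DataFrame([p.as_row() for p in all_peaks])
    peaks_df.to_csv(outdir / "qtl_peaks.csv", index=False)
    _stage("qtl_scan")

    # --- eQTL scan --------------------------------------------------------
    ecross = to_cross(geno, table)
    ecross.covariates = ecross.covariates.assign(
        batch=pd.Categorical(sim_expr.batch.to_numpy()))
    records = scan_expression(ecross, sim_expr.values, ("batch",),
                              annotation=sim_expr.annotation,
                              n_perm=cfg["n_perm"],
                              rng=np.random.default_rng(stage_seeds["escan"]),
                              probs=probs)
    eqtl_df = eqtl_table(records)
    eqtl_df.to_csv(outdir / "eqtl_records.csv", index=False)
    _stage("eqtl_scan")

    # --- colocalization ---------------------------------------------------
    qtl_iv = [map_ci_to_physical(p.chrom, p.ci_start, p.ci_end, gmap, label=f"{p.trait}")
              for p in all_peaks]
    eqtl_iv = [map_ci_to_physical(r.chrom, r.ci_start, r.ci_end, gmap, label=r.probe)
               for r in records]
    genome = {str(c): gmap.chrom_length(str(c)) * sim_cfg.bp_per_cm
              for c in gmap.chromosomes}
    write_regions_bed(qtl_iv, outdir / "qtl_ci.bed")
    write_regions_bed(eqtl_iv, outdir / "eqtl_ci.bed")
    write_chrom_sizes(genome, outdir / "chrom.sizes")
    pairs = find_overlaps(qtl_iv, eqtl_iv)
    coloc_rows = []
    rngc = np.random.default_rng(stage_seeds["coloc"])
    for i, j in pairs:
        p, r = all_peaks[i], records[j]
        if p.trait in cross.phenotypes.columns:
            corr = trait_expression_correlation(
                sim_expr.values.loc[r.probe, list(cross.individual_ids)].to_numpy(),
                cross.phenotypes[p.trait].to_numpy(), probe=r.probe, trait=p.trait)
            coloc_rows.append({"trait": p.trait, "probe": r.probe, "class": r.klass,
                               "r": corr.r, "pvalue": corr.pvalue, "n": corr.n,
                               "significant": corr.significant})
    pd.DataFrame(coloc_rows, columns=["trait", "probe", "class", "r", "pvalue",
                                      "n", "significant"]
                 ).to_csv(outdir / "overlap_correlations.csv", index=False)
    enrich = None
    if qtl_iv and eqtl_iv:
        enrich = overlap_enrichment_from_sets(
            qtl_iv, eqtl_iv, genome, iterations=cfg["enrichment_iterations"], rng=rngc)
        with open(outdir / "enrichment.json", "w") as fh:
            json.dump({"observed": enrich.observed, "pvalue": enrich.pvalue,
                       "parameters": enrich.parameters}, fh, indent=2)
    _stage("colocalization")

    manifest["n_qtl_peaks"] = len(all_peaks)
    manifest["n_eqtl"] = len(records)
    manifest["n_overlaps"] = len(pairs)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
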