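"""Run the whole seeded analysis: simulate -> morpho -> scan -> coloc.

One seed drives every stage; the manifest under the run directory is
sufficient to re-run bit-identically.
"""

import json

import pandas as pd

from combqtl import run_pipeline

out = run_pipeline({"n_perm": 500, "enrichment_iterations": 2000},
                   outdir="scratch/example_run", seed=3)
manifest = json.loads((out / "manifest.json").read_text())
peaks = pd.read_csv(out / "qtl_peaks.csv")
eqtl = pd.read_csv(out / "eqtl_records.csv")

print(f"run directory: {out}")
print(f"{manifest['n_qtl_peaks']} QTL peaks, {manifest['n_eqtl']} eQTL, "
      f"{manifest['n_overlaps']} CI overlaps")
if len(peaks):
    cols = ["trait", "marker", "chrom", "pos", "lod", "pvalue", "tier"]
    print(peaks[cols].to_string(index=False))
if len(eqtl):
    n_cis = int((eqtl["class"] == "cis").sum())
    print(f"eQTL classes: {n_cis} cis, {len(eqtl) - n_cis} trans")
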