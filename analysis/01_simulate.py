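#!/usr/bin/env python
"""Simulate the dye-swap experiment that the rest of the analysis consumes.

Generates the study-scale design — 2000 genes (300 planted with 4-fold
effects across the interaction taxonomy, 100 genes with redundant probes),
four competitive comparisons, two pools each hybridized in both dye
orientations — and writes the per-hybridization intensity tables, the
manifest, the probe annotation and the ground-truth table.
"""

import argparse
from pathlib import Path

import tfsarray as ta
from tfsarray import io as aio

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/simulated"))
parser.add_argument("--seed", type=int, default=42)
args = parser.parse_args()

design = ta.default_design(n_genes=2000, n_planted=300, seed=args.seed)
sim = ta.simulate_experiment(design)

args.out.mkdir(parents=True, exist_ok=True)
files = {}
for comp, tables in sim.hybridizations.items():
    names = []
    for i, hyb in enumerate(tables, start=1):
        name = f"comparison{comp}_hyb{i}.tsv"
        aio.write_hybridization(hyb, args.out / name)
        names.append(name)
    files[comp] = names
aio.write_manifest(files, args.out / "manifest.yaml")
aio.write_probe_annotation(sim.annotation, args.out / "probe_annotation.tsv")
ta.write_truth(sim.truth, args.out / "truth.tsv")

n_hyb = sum(len(v) for v in files.values())
n_planted = (sim.truth["tfs"] != "0.0000").sum()
print(f"simulated {n_hyb} hybridizations over 4 comparisons "
      f"({len(sim.annotation)} probes, {design.n_genes} genes, "
      f"{n_planted} planted non-null) -> {args.out}")
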