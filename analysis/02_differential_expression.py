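#!/usr/bin/env python
"""Per-comparison differential expression from the simulated hybridizations.

Excludes flagged features, LOWESS-normalizes each array, combines the four
replicates of each comparison by error-weighted averaging, and writes the
per-probe fold-changes and p-values.  Prints the counts of probes meeting
the combined significance threshold (|fold| > 2, p < 0.005) per comparison.
"""

import argparse
from pathlib import Path

import tfsarray as ta
from tfsarray import io as aio
from tfsarray.normalize import ErrorModelParams, combine_replicates, lowess_normalize
from tfsarray.pipeline import _wide_results
from tfsarray.tfs import COMPARISON_LABELS, Thresholds, call_significance_array

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/simulated"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

em = ErrorModelParams()
th = Thresholds()
files = aio.read_manifest(args.data / "manifest.yaml")
results = {}
for comp in sorted(files):
    hybs = [aio.read_hybridization(f) for f in files[comp]]
    normalized = [lowess_normalize(h, params=em) for h in hybs]
    results[comp] = combine_replicates(normalized, em)
    calls = call_significance_array(
        results[comp]["fold"].to_numpy(), results[comp]["p"].to_numpy(), th
    )
    up, down = int((calls == 1).sum()), int((calls == 2).sum())
    print(f"comparison {comp} ({COMPARISON_LABELS[comp]}): "
          f"{len(results[comp])} probes, {up} up / {down} down at "
          f"|fold|>{th.fold_min:g}, p<{th.p_max:g}")

args.out.mkdir(parents=True, exist_ok=True)
wide = _wide_results(results)
wide.to_csv(args.out / "comparison_results.tsv", sep="\t", index=False)
print(f"wrote {args.out / 'comparison_results.tsv'} ({len(wide)} probes)")
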