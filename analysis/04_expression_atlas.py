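#!/usr/bin/env python
"""Tissue-atlas expression analyses.

Median-of-ratios library-size correction, presence calls for the immune gene
set, immune vs non-immune abundance comparison per tissue, co-expression
clustering of ohnolog-pair genes and per-pair profile classification, scored
against the simulator's divergent-profile truth.
"""

import json
from pathlib import Path

from ohnokit import pipeline
from ohnokit.atlas import profile_recovery
from ohnokit.config import SimConfig

ROOT = Path(__file__).resolve().parents[1]
SEED = 1

bundle = pipeline.simulate_bundle(SimConfig(seed=SEED))
pairs = pipeline.run_ohnolog_calling(bundle)
results = pipeline.run_atlas(bundle, pairs, seed=SEED)

results["immune_vs_rest"].round(4).to_csv(ROOT / "results" / "04_immune_vs_rest.tsv", sep="\t")
results["pair_labels"].to_csv(ROOT / "results" / "04_pair_profiles.tsv", sep="\t", index=False)

recovery = profile_recovery(results["pair_labels"], bundle.truth.true_divergent_pairs,
                            bundle.truth.pair_by_ancestor)
summary = {
    "presence": results["presence_summary"],
    "pair_profiles": results["pair_summary"],
    "divergent_profile_recovery": {k: round(v, 3) for k, v in recovery.items()},
    "n_tissues_immune_significant": int((results["immune_vs_rest"]["p_adjusted"] < 0.05).sum()),
}
(ROOT / "results" / "04_atlas_summary.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
print("Pairs simulated with a shared tissue program cluster together; pairs given "
      "divergent programs split across clusters. The immune set shows no abundance "
      "shift here because the generator assigns immune labels independently of "
      "expression level.")
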