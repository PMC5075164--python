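#!/usr/bin/env python
"""Per-tree model selection and ancestral reconstruction for every focal
trait of the simulated study: on each tree, prune tips without data, fit
ER/SYM/ARD, choose a model by AIC (simpler preferred on ties), run 100
stochastic maps, and record per-clade crown/stem most-likely states and
the fitted rates.

Reads scratch/study/ (from 01_simulate_study.py); writes per-trait
record files to scratch/records/ and a model-preference summary to
results/02_model_preference.tsv.

    python analysis/02_reconstruct.py
"""

import time
from pathlib import Path

import pandas as pd
import yaml

from mkasr import aggregate, pipeline, traits, treeio

ROOT = Path(__file__).resolve().parent.parent


def main():
    study_dir = ROOT / "scratch" / "study"
    cfg = yaml.safe_load((study_dir / "config.yaml").read_text())
    sample = treeio.read_tree_sample(cfg["trees"])
    defs = pipeline.load_trait_definitions(cfg["trait_definitions"])
    matrix = traits.read_trait_table(cfg["trait_table"], defs)
    clades = pipeline.load_clades(cfg["clades"])
    by_species = traits.collapse_to_species(matrix, "strict")
    config = aggregate.AnalysisConfig(seed=cfg["analysis"]["seed"])

    rec_dir = ROOT / "scratch" / "records"
    rec_dir.mkdir(parents=True, exist_ok=True)
    pref_rows = []
    for trait_name in cfg["traits"]:
        t0 = time.time()
        tips, prune = traits.tip_states_for_trait(
            by_species, trait_name, sample[0].tip_labels
        )
        records = aggregate.reconstruct_over_sample(
            sample, tips, clades, config, trait_name=trait_name
        )
        (rec_dir / f"{trait_name}.json").write_text(aggregate.records_to_json(records))
        rt = aggregate.rate_table(records)
        for row in rt.model_fractions.itertuples():
            pref_rows.append(
                {
                    "trait": trait_name,
                    "model": row.model,
                    "fraction_of_trees": round(row.fraction, 4),
                    "n_scored_species": len(tips.states),
                    "n_pruned_tips": len(prune),
                }
            )
        print(
            f"{trait_name}: {len(records)} trees in {time.time() - t0:.1f}s, "
            f"models {dict(zip(rt.model_fractions.model, rt.model_fractions.fraction))}"
        )

    pref = pd.DataFrame(pref_rows)
    out = ROOT / "results" / "02_model_preference.tsv"
    out.parent.mkdir(exist_ok=True)
    pref.to_csv(out, sep="\t", index=False)
    print(f"\nmodel preference table -> {out}")


if __name__ == "__main__":
    main()
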