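#!/usr/bin/env python
"""Cross-tree clade summary: for every trait and named clade, the
proportion of trees whose most-likely crown/stem state is each state
(values > 0.90 flagged bold, the confidence rule), plus stem-branch
change calls (strong-change / no-change / equivocal).

Reads scratch/records/; writes results/03_clade_summary.tsv and
results/03_branch_calls.tsv.

    python analysis/03_clade_summary.py
"""

from pathlib import Path

import pandas as pd
import yaml

from mkasr import aggregate, pipeline

ROOT = Path(__file__).resolve().parent.parent


def main():
    cfg = yaml.safe_load((ROOT / "scratch" / "study" / "config.yaml").read_text())
    defs = {d.name: d for d in pipeline.load_trait_definitions(cfg["trait_definitions"])}
    config = aggregate.AnalysisConfig(seed=cfg["analysis"]["seed"])

    tables, call_rows = [], []
    for rec_file in sorted((ROOT / "scratch" / "records").glob("*.json")):
        records = aggregate.records_from_json(rec_file.read_text())
        trait = records[0].trait
        names = dict(enumerate(defs[trait].states))
        table = aggregate.clade_state_proportions(records, state_names=names)
        tables.append(aggregate.render_clade_table(table, config))
        for c in aggregate.confidence_and_branch_calls(table, config):
            call_rows.append(vars(c))

    out = ROOT / "results"
    summary = pd.concat(tables, ignore_index=True)
    summary.to_csv(out / "03_clade_summary.tsv", sep="\t", index=False)
    calls = pd.DataFrame(call_rows)
    calls.to_csv(out / "03_branch_calls.tsv", sep="\t", index=False)

    strong = calls[calls.call == "strong-change"]
    print(f"clade summary: {len(summary)} rows, {int(summary.bold.sum())} bold (>0.90)")
    print(f"branch calls: {calls.call.value_counts().to_dict()}")
    if len(strong):
        print("strong state changes:")
        print(
            strong[["trait", "clade", "stem_state", "crown_state"]].to_string(index=False)
        )


if __name__ == "__main__":
    main()
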