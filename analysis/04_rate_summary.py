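#!/usr/bin/env python
"""Rate summaries across the tree sample: per trait, chosen model and
directional transition (0 to 1, 0 to 2, ..., 2 to 1), the average and
(min - max) of the maximum-likelihood rate over the trees preferring
that model.  Rates are in expected changes per unit branch length
(per million years at the study scale).

Reads scratch/records/; writes results/04_rate_summary.tsv.

    python analysis/04_rate_summary.py
"""

from pathlib import Path

import pandas as pd

from mkasr import aggregate

ROOT = Path(__file__).resolve().parent.parent


def main():
    frames = []
    for rec_file in sorted((ROOT / "scratch" / "records").glob("*.json")):
        records = aggregate.records_from_json(rec_file.read_text())
        rt = aggregate.rate_table(records)
        merged = rt.rates.merge(
            rt.model_fractions, on=["trait", "model"], how="left"
        )
        frames.append(merged)
    table = pd.concat(frames, ignore_index=True)
    table["formatted"] = [
        f"{r.average:.3f} ({r['min']:.3f} - {r['max']:.3f})"
        for _, r in table.iterrows()
    ]
    out = ROOT / "results" / "04_rate_summary.tsv"
    table.to_csv(out, sep="\t", index=False)
    print(table[["trait", "model", "fraction", "transition", "formatted"]].to_string(index=False))
    print(f"\n-> {out}")


if __name__ == "__main__":
    main()
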