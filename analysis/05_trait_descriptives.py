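#!/usr/bin/env python
"""Descriptive statistics of the trait matrix, reported the way anatomy
surveys print them: per-trait state counts with explicit denominators
("x out of n taxa (p %)", unscored taxa excluded per trait) and
mean/range summaries of continuous traits.

Reads scratch/study/; writes results/05_trait_descriptives.tsv.

    python analysis/05_trait_descriptives.py
"""

from pathlib import Path

import pandas as pd
import yaml

from mkasr import pipeline, traits

ROOT = Path(__file__).resolve().parent.parent


def main():
    cfg = yaml.safe_load((ROOT / "scratch" / "study" / "config.yaml").read_text())
    defs = pipeline.load_trait_definitions(cfg["trait_definitions"])
    matrix = traits.read_trait_table(cfg["trait_table"], defs)
    sp = traits.collapse_to_species(matrix, "strict")

    rows = []
    for d in defs:
        if d.kind == "discrete" and not d.name.startswith("filler"):
            freq = traits.state_frequencies(sp, d.name)
            for _, r in freq.iterrows():
                rows.append(
                    {
                        "trait": d.name,
                        "state": r.state,
                        "count": int(r["count"]),
                        "denominator": int(r.denominator),
                        "percent": r.percent,
                    }
                )
                print(
                    f"{d.name}/{r.state}: {r['count']} out of {r.denominator} "
                    f"taxa ({r.percent} %)"
                )
    cont = [d for d in defs if d.kind == "continuous"][:4]
    for d in cont:
        s = traits.continuous_summary(sp, d.name)
        rows.append(
            {
                "trait": d.name,
                "state": f"mean={s['mean']:.1f} range={s['min']:.1f}-{s['max']:.1f} {s['units']}",
                "count": s["n"],
                "denominator": s["n"],
                "percent": float("nan"),
            }
        )
    out = ROOT / "results" / "05_trait_descriptives.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"\n-> {out}")


if __name__ == "__main__":
    main()
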