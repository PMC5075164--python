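"""Config-driven end-to-end run: trees + trait table -> summary tables.

A run reads a posterior tree sample, a trait table with definitions, and
named clade definitions; collapses accessions to species; and for every
requested discrete trait fits ER/SYM/ARD per tree, reconstructs states,
and writes the clade summary, branch calls and rate summary tables plus
a manifest recording config, seeds and input digests.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import aggregate, traits, treeio

__all__ = [
    "load_config",
    "load_trait_definitions",
    "load_clades",
    "run_pipeline",
    "write_table",
]

_TOP_KEYS = {
    "trees",
    "tree_schema",
    "burnin",
    "thin",
    "trait_table",
    "trait_table_sep",
    "trait_definitions",
    "clades",
    "traits",
    "collapse_rule",
    "analysis",
    "out_dir",
    "format",
}
_ANALYSIS_KEYS = {
    "confidence_threshold",
    "tie_margin",
    "n_draws",
    "root_prior_mode",
    "non_monophyly_policy",
    "state_source",
    "n_restarts",
    "seed",
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    unknown = set(cfg.get("analysis") or {}) - _ANALYSIS_KEYS
    if unknown:
        raise ConfigError(f"unknown analysis keys: {sorted(unknown)}")
    for key in ("trees", "trait_table", "trait_definitions", "clades"):
        if key not in cfg:
            raise ConfigError(f"config is missing required key {key!r}")
    return cfg


def load_trait_definitions(path: str | Path) -> list[traits.TraitDefinition]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    defs = []
    for item in raw:
        defs.append(
            traits.TraitDefinition(
                name=item["name"],
                kind=item["kind"],
                states=tuple(item.get("states") or ()),
                units=item.get("units", ""),
            )
        )
    return defs


def load_clades(path: str | Path) -> list[treeio.CladeDefinition]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        treeio.CladeDefinition(name=name, members=frozenset(members))
        for name, members in raw.items()
    ]


def _digest(path: str | Path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def write_table(df: pd.DataFrame, path: Path, header_lines: list[str], sep: str = "\t"):
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)


def run_pipeline(
    config: str | Path | dict,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> Path:
    """Run the full workflow described by a config file.

    Returns the output directory.  Outputs: clade_summary.tsv,
    branch_calls.tsv, rate_summary.tsv, model_fractions.tsv,
    trait_frequencies.tsv and manifest.json.  Fully deterministic for a
    fixed config + seed.
    """
    t_start = time.time()
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
        cfg_path = str(config)
    else:
        cfg = dict(config)
        cfg_path = "<dict>"
    out = Path(out_dir or cfg.get("out_dir") or "mkasr_out")
    out.mkdir(parents=True, exist_ok=True)
    sep = "\t" if cfg.get("format", "tsv") == "tsv" else ","

    analysis_cfg = dict(cfg.get("analysis") or {})
    if seed is not None:
        analysis_cfg["seed"] = seed
    config_obj = aggregate.AnalysisConfig(**analysis_cfg)

    manifest = {
        "config_path": cfg_path,
        "config": cfg,
        "analysis": asdict(config_obj),
        "stage": "start",
        "inputs": {},
        "timings": {},
        "outputs": [],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    try:
        tree_paths = cfg["trees"]
        if isinstance(tree_paths, str):
            tree_paths = [tree_paths]
        for p in tree_paths + [cfg["trait_table"], cfg["trait_definitions"], cfg["clades"]]:
            if not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
            manifest["inputs"][str(p)] = _digest(p)

        manifest["stage"] = "read"
        sample = treeio.read_tree_sample(
            tree_paths,
            schema=cfg.get("tree_schema", "newick"),
            burnin=float(cfg.get("burnin", 0.0)),
            thin=int(cfg.get("thin", 1)),
        )
        defs = load_trait_definitions(cfg["trait_definitions"])
        matrix = traits.read_trait_table(
            cfg["trait_table"], defs, sep=cfg.get("trait_table_sep", ",")
        )
        clades = load_clades(cfg["clades"])
        by_species = traits.collapse_to_species(
            matrix, rule=cfg.get("collapse_rule", "strict")
        )
        focal = cfg.get("traits") or [
            d.name for d in defs if d.kind == "discrete"
        ]

        header = [
            f"mkasr run seed={config_obj.seed}",
            f"config={cfg_path}",
            f"trees={tree_paths} burnin={cfg.get('burnin', 0.0)} n={len(sample)}",
        ]

        summaries, calls_rows, rate_frames, frac_frames, freq_frames = [], [], [], [], []
        for trait_name in focal:
            t0 = time.time()
            manifest["stage"] = f"reconstruct:{trait_name}"
            tips, _prune = traits.tip_states_for_trait(
                by_species, trait_name, sample.trees[0].tip_labels
            )
            records = aggregate.reconstruct_over_sample(
                sample, tips, clades, config_obj, trait_name=trait_name
            )
            table = aggregate.clade_state_proportions(
                records, state_names=tips.state_names
            )
            summaries.append(aggregate.render_clade_table(table, config_obj))
            for call in aggregate.confidence_and_branch_calls(table, config_obj):
                calls_rows.append(vars(call))
            rt = aggregate.rate_table(records)
            rate_frames.append(rt.rates)
            frac_frames.append(rt.model_fractions)
            freq = traits.state_frequencies(by_species, trait_name)
            freq.insert(0, "trait", trait_name)
            freq_frames.append(freq)
            manifest["timings"][trait_name] = round(time.time() - t0, 3)

        manifest["stage"] = "write"
        outputs = {
            "clade_summary.tsv": pd.concat(summaries, ignore_index=True),
            "branch_calls.tsv": pd.DataFrame(calls_rows),
            "rate_summary.tsv": pd.concat(rate_frames, ignore_index=True),
            "model_fractions.tsv": pd.concat(frac_frames, ignore_index=True),
            "trait_frequencies.tsv": pd.concat(freq_frames, ignore_index=True),
        }
        for name, df in outputs.items():
            path = out / name
            write_table(df, path, header, sep=sep)
            manifest["outputs"].append(str(path))
        manifest["stage"] = "done"
        manifest["timings"]["total"] = round(time.time() - t_start, 3)
    finally:
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return out
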