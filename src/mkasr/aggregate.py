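"""Cross-tree aggregation of per-tree model fits and reconstructions.

The workflow mirrors comparative studies that reconstruct a discrete
character independently on every tree of a posterior sample and then
summarise: for each tree, prune tips without data, fit ER/SYM/ARD, pick
a model by AIC (simpler preferred on ties), map the character, and read
off the most likely state at each named clade's crown and stem nodes.
Across trees this yields

* a clade summary table: per (trait, clade, crown/stem, state) the
  proportion of trees whose most likely state is that state;
* confidence calls: a state is confidently inferred when its proportion
  is strictly greater than the threshold (default 0.90);
* branch calls: a state change on a stem branch is "strong" when stem
  and crown are both confidently reconstructed in differing states;
* a rate summary: per (trait, chosen model, directional transition) the
  average and (min - max) of the MLE rate across trees, plus the
  fraction of trees preferring each model.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import asr, mk, treeio

__all__ = [
    "AnalysisConfig",
    "TreeRecord",
    "BranchCall",
    "RateSummaryTable",
    "reconstruct_over_sample",
    "clade_state_proportions",
    "confidence_and_branch_calls",
    "rate_table",
    "render_clade_table",
    "round_half_up",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the aggregation pipeline (defaults = reporting rules
    used throughout: >90% confidence, strict AIC minimum with simpler
    models preferred on exact ties, 100 mapping draws per tree)."""

    confidence_threshold: float = 0.90
    tie_margin: float = 0.0
    n_draws: int = 100
    root_prior_mode: str = "uniform"
    non_monophyly_policy: str = "include-with-flag"  # or "exclude"
    state_source: str = "simmap"  # or "marginal"
    n_restarts: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.confidence_threshold < 1:
            raise ValueError("confidence threshold must be in (0, 1)")
        if self.non_monophyly_policy not in ("include-with-flag", "exclude"):
            raise ValueError(f"unknown policy {self.non_monophyly_policy!r}")
        if self.state_source not in ("simmap", "marginal"):
            raise ValueError(f"unknown state source {self.state_source!r}")


@dataclass
class CladeNodeStates:
    crown_state: int | None
    stem_state: int | None
    monophyletic: bool | None
    n_members_present: int
    missing: bool = False  # clade absent from this tree (after pruning)


@dataclass
class TreeRecord:
    """Per-tree result for one trait: chosen model, rates, clade states."""

    trait: str
    tree_index: int
    model: str
    rates: dict[str, float]
    logL: float
    aic: float
    converged: bool
    aic_table: dict[str, float]
    clades: dict[str, CladeNodeStates] = field(default_factory=dict)


@dataclass(frozen=True)
class BranchCall:
    trait: str
    clade: str
    stem_state: int | None
    stem_proportion: float | None
    stem_confident: bool
    crown_state: int | None
    crown_proportion: float | None
    crown_confident: bool
    call: str  # strong-change | no-change | equivocal


def reconstruct_over_sample(
    sample: treeio.TreeSample,
    tips: mk.TipStates,
    clades: list[treeio.CladeDefinition],
    config: AnalysisConfig = AnalysisConfig(),
    trait_name: str = "trait",
) -> list[TreeRecord]:
    """Model selection + reconstruction on every tree of the sample.

    Deterministic given ``config.seed`` (each tree gets an independent
    child seed).  Clades absent from a tree contribute a record marked
    missing rather than being silently dropped.
    """
    scored = set(tips.observed_labels())
    records: list[TreeRecord] = []
    seeds = np.random.SeedSequence(config.seed).spawn(len(sample))
    for i, tree in enumerate(sample):
        keep = scored & set(tree.tip_labels)
        if len(keep) < 2:
            raise treeio.TreeError(
                f"tree {i}: fewer than 2 tips scored for {trait_name!r}"
            )
        pruned = treeio.relabel_and_prune(tree, keep=keep)
        chosen, fits = mk.select_model(
            pruned,
            tips,
            tie_margin=config.tie_margin,
            root_prior_mode=config.root_prior_mode,
            n_restarts=config.n_restarts,
        )
        q = chosen.q
        if config.state_source == "simmap":
            rng = np.random.default_rng(seeds[i])
            _, marg = asr.simmap(
                pruned,
                tips,
                q,
                n_draws=config.n_draws,
                rng=rng,
                root_prior=chosen.root_prior,
                include_histories=False,
            )
        else:
            marg = asr.marginal_asr(pruned, tips, q, root_prior=chosen.root_prior)
        clade_states: dict[str, CladeNodeStates] = {}
        for cd in clades:
            present = cd.members & set(pruned.tip_labels)
            if not present:
                clade_states[cd.name] = CladeNodeStates(
                    None, None, None, 0, missing=True
                )
                continue
            cn = treeio.clade_nodes(pruned, cd)
            if config.non_monophyly_policy == "exclude" and not cn.monophyletic:
                clade_states[cd.name] = CladeNodeStates(
                    None, None, False, cn.n_members_present, missing=True
                )
                continue
            crown_state = asr.most_likely_state(marg, cn.crown)
            stem_state = (
                asr.most_likely_state(marg, cn.stem) if cn.stem is not None else None
            )
            clade_states[cd.name] = CladeNodeStates(
                crown_state=crown_state,
                stem_state=stem_state,
                monophyletic=cn.monophyletic,
                n_members_present=cn.n_members_present,
            )
        records.append(
            TreeRecord(
                trait=trait_name,
                tree_index=i,
                model=chosen.model_class.value,
                rates=mk.rates_by_transition(q),
                logL=chosen.logL,
                aic=chosen.aic,
                converged=chosen.converged,
                aic_table={f.model_class.value: f.aic for f in fits},
                clades=clade_states,
            )
        )
    return records


def clade_state_proportions(
    records: list[TreeRecord],
    state_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Table-style summary: proportion of trees per most-likely state.

    One row per (trait, clade, node_kind, state); the denominator
    ``n_trees`` counts trees where the node exists (stem rows lose trees
    whose crown is the root), and ``n_nonmono`` counts trees where the
    clade was not monophyletic.
    """
    if not records:
        raise ValueError("no records")
    rows = []
    clade_names = list(records[0].clades)
    all_states = sorted(
        {
            s
            for r in records
            for cs in r.clades.values()
            for s in (cs.crown_state, cs.stem_state)
            if s is not None
        }
    )
    if state_names:
        all_states = sorted(set(all_states) | set(state_names))
    trait = records[0].trait
    for clade in clade_names:
        nonmono = sum(
            1
            for r in records
            if r.clades[clade].monophyletic is False and not r.clades[clade].missing
        )
        for kind in ("crown", "stem"):
            vals = [
                getattr(r.clades[clade], f"{kind}_state")
                for r in records
                if not r.clades[clade].missing
            ]
            vals = [v for v in vals if v is not None]
            denom = len(vals)
            for s in all_states:
                prop = (sum(1 for v in vals if v == s) / denom) if denom else np.nan
                rows.append(
                    {
                        "trait": trait,
                        "clade": clade,
                        "node_kind": kind,
                        "state": s,
                        "state_name": (state_names or {}).get(s, str(s)),
                        "proportion": prop,
                        "n_trees": denom,
                        "n_nonmono": nonmono,
                    }
                )
    return pd.DataFrame(rows)


def confidence_and_branch_calls(
    table: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[BranchCall]:
    """Confidence (> threshold, strictly) and stem-branch change calls."""
    calls: list[BranchCall] = []
    thr = config.confidence_threshold
    for (trait, clade), grp in table.groupby(["trait", "clade"], sort=False):
        info = {}
        for kind in ("crown", "stem"):
            sub = grp[grp.node_kind == kind].dropna(subset=["proportion"])
            if len(sub) == 0 or sub.n_trees.max() == 0:
                info[kind] = (None, None, False)
                continue
            top = sub.loc[sub.proportion.idxmax()]
            info[kind] = (
                int(top.state),
                float(top.proportion),
                bool(top.proportion > thr),
            )
        (cs, cp, cc), (ss, sp, sc) = info["crown"], info["stem"]
        if cc and sc and cs != ss:
            call = "strong-change"
        elif cc and sc and cs == ss:
            call = "no-change"
        else:
            call = "equivocal"
        calls.append(
            BranchCall(
                trait=trait,
                clade=clade,
                stem_state=ss,
                stem_proportion=sp,
                stem_confident=sc,
                crown_state=cs,
                crown_proportion=cp,
                crown_confident=cc,
                call=call,
            )
        )
    return calls


@dataclass
class RateSummaryTable:
    """Average and (min - max) MLE rates per model and directional
    transition, plus the fraction of trees preferring each model."""

    rates: pd.DataFrame  # trait, model, transition, average, min, max, n_trees
    model_fractions: pd.DataFrame  # trait, model, fraction


def rate_table(records: list[TreeRecord]) -> RateSummaryTable:
    if not records:
        raise ValueError("no records")
    trait = records[0].trait
    by_model: dict[str, list[TreeRecord]] = {}
    for r in records:
        by_model.setdefault(r.model, []).append(r)
    rate_rows = []
    labels = list(records[0].rates)  # canonical "i to j" order
    for model, recs in sorted(by_model.items()):
        for lab in labels:
            vals = np.array([r.rates[lab] for r in recs])
            rate_rows.append(
                {
                    "trait": trait,
                    "model": model,
                    "transition": lab,
                    "average": float(vals.mean()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "n_trees": len(recs),
                }
            )
    frac_rows = [
        {"trait": trait, "model": m, "fraction": len(recs) / len(records)}
        for m, recs in sorted(by_model.items())
    ]
    return RateSummaryTable(
        rates=pd.DataFrame(rate_rows),
        model_fractions=pd.DataFrame(frac_rows),
    )


# ---------------------------------------------------------------------------
# record (de)serialisation for multi-step analyses


def records_to_json(records: list[TreeRecord]) -> str:
    import json

    return json.dumps(
        [
            {
                **{k: v for k, v in vars(r).items() if k != "clades"},
                "clades": {c: vars(s) for c, s in r.clades.items()},
            }
            for r in records
        ]
    )


def records_from_json(text: str) -> list[TreeRecord]:
    import json

    out = []
    for d in json.loads(text):
        clades = {c: CladeNodeStates(**s) for c, s in d.pop("clades").items()}
        out.append(TreeRecord(**d, clades=clades))
    return out


# ---------------------------------------------------------------------------
# rendering


def round_half_up(x: float, places: int = 2) -> float:
    """Round half away from zero (so 0.005 -> 0.01), as printed tables do."""
    if not np.isfinite(x):
        return x
    q = decimal.Decimal(10) ** -places
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def render_clade_table(
    table: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Rendered copy: proportions to 2 decimals plus a bold (>threshold) flag."""
    out = table.copy()
    out["rendered"] = [
        "" if not np.isfinite(p) else f"{round_half_up(p, 2):.2f}"
        for p in out.proportion
    ]
    out["bold"] = out.proportion > config.confidence_threshold
    return out
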