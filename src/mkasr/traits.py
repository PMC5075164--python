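"""Accession x trait matrices and descriptive summaries.

The study design this package serves scores ~150 living accessions of
~110 species for a mix of discrete (qualitative) and continuous
(quantitative) leaf-anatomy traits, with missing values wherever a trait
could not be scored for a taxon.  Summaries therefore always report the
per-trait denominator (rows actually scored) alongside counts and
percentages.

Discrete values are stored as pandas nullable integers (state codes into
a per-trait state dictionary); continuous values as floats with NaN for
missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .mk import MISSING, TipStates

__all__ = [
    "TraitDefinition",
    "TraitMatrix",
    "TraitError",
    "read_trait_table",
    "write_trait_table",
    "collapse_to_species",
    "state_frequencies",
    "continuous_summary",
    "fraction_summary",
    "tip_states_for_trait",
]

log = logging.getLogger(__name__)


class TraitError(ValueError):
    pass


@dataclass(frozen=True)
class TraitDefinition:
    """Name, kind and (for discrete traits) the ordered state names."""

    name: str
    kind: str  # "discrete" | "continuous"
    states: tuple[str, ...] = ()
    units: str = ""

    def __post_init__(self):
        if self.kind not in ("discrete", "continuous"):
            raise TraitError(f"trait {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "discrete" and len(self.states) < 2:
            raise TraitError(f"discrete trait {self.name!r} needs >= 2 states")
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def k(self) -> int:
        return len(self.states)


@dataclass
class TraitMatrix:
    """Rows = accessions (or species after collapsing), columns = traits."""

    data: pd.DataFrame
    species: pd.Series  # accession -> species name
    definitions: dict[str, TraitDefinition]
    level: str = "accession"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dups = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise TraitError(f"duplicate accession ids: {dups}")
        missing_cols = [c for c in self.data.columns if c not in self.definitions]
        if missing_cols:
            raise TraitError(f"columns without a trait definition: {missing_cols}")

    def definition(self, trait: str) -> TraitDefinition:
        try:
            return self.definitions[trait]
        except KeyError:
            raise TraitError(f"unknown trait {trait!r}") from None

    @property
    def n_rows(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# reading / writing


def read_trait_table(
    path: str,
    definitions: Sequence[TraitDefinition],
    id_column: str = "accession",
    species_column: str = "species",
    sep: str = ",",
) -> TraitMatrix:
    """Read a CSV/TSV trait table, validating every value.

    Discrete cells must hold a state name from the trait's definition (or
    be empty = missing); continuous cells must parse as finite numbers.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (id_column, species_column):
        if col not in raw.columns:
            raise TraitError(f"required column {col!r} missing from {path}")
    defs = {d.name: d for d in definitions}
    ids = raw[id_column]
    if ids.duplicated().any():
        raise TraitError(f"duplicate accession ids: {sorted(ids[ids.duplicated()])}")
    out: dict[str, pd.Series] = {}
    for name, d in defs.items():
        if name not in raw.columns:
            raise TraitError(f"trait column {name!r} missing from {path}")
        col = raw[name].str.strip()
        if d.kind == "discrete":
            codes = pd.array([pd.NA] * len(col), dtype="Int64")
            lookup = {s: i for i, s in enumerate(d.states)}
            for row, val in enumerate(col):
                if val == "":
                    continue
                if val not in lookup:
                    raise TraitError(
                        f"row {row} ({ids.iloc[row]!r}), column {name!r}: "
                        f"unknown state {val!r} (expected one of {list(d.states)})"
                    )
                codes[row] = lookup[val]
            out[name] = pd.Series(codes, index=ids.values)
        else:
            vals = pd.to_numeric(col.replace("", np.nan), errors="coerce")
            bad = col[(col != "") & vals.isna().values]
            if len(bad):
                raise TraitError(
                    f"non-numeric value {bad.iloc[0]!r} in continuous column {name!r}"
                )
            if np.any(np.isinf(vals.dropna().values)):
                raise TraitError(f"non-finite value in continuous column {name!r}")
            out[name] = pd.Series(vals.values, index=ids.values)
    data = pd.DataFrame(out, index=ids.values)
    species = pd.Series(raw[species_column].values, index=ids.values)
    return TraitMatrix(
        data=data,
        species=species,
        definitions=defs,
        provenance={"path": str(path)},
    )


def write_trait_table(matrix: TraitMatrix, path: str, sep: str = ",") -> None:
    """Write the matrix back to CSV/TSV with state names (round-trips)."""
    out = pd.DataFrame(index=matrix.data.index)
    out["accession"] = matrix.data.index
    out["species"] = matrix.species.values
    for name, d in matrix.definitions.items():
        col = matrix.data[name]
        if d.kind == "discrete":
            out[name] = [
                "" if pd.isna(v) else d.states[int(v)] for v in col
            ]
        else:
            out[name] = ["" if pd.isna(v) else repr(float(v)) for v in col]
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# species collapsing


def collapse_to_species(matrix: TraitMatrix, rule: str = "strict") -> TraitMatrix:
    """Collapse accession rows to one row per species.

    Rules: ``first-scored`` takes the first non-missing accession value;
    ``majority`` takes the modal value (ties -> missing); ``strict`` makes
    any conflicting accession values missing and logs the conflict.  The
    default is strict: discrete leaf-anatomy traits are expected to be
    constant within species, so conflicts indicate data problems and must
    surface rather than be averaged away.
    """
    if rule not in ("first-scored", "majority", "strict"):
        raise TraitError(f"unknown collapse rule {rule!r}")
    species_order = list(dict.fromkeys(matrix.species.values))
    rows: dict[str, dict] = {sp: {} for sp in species_order}
    for name, d in matrix.definitions.items():
        col = matrix.data[name]
        for sp in species_order:
            accs = matrix.species.index[matrix.species.values == sp]
            vals = [col.loc[a] for a in accs if not pd.isna(col.loc[a])]
            if not vals:
                rows[sp][name] = pd.NA if d.kind == "discrete" else np.nan
                continue
            if d.kind == "continuous":
                # continuous: mean of scored accessions under every rule
                rows[sp][name] = (
                    float(vals[0]) if rule == "first-scored" else float(np.mean(vals))
                )
                continue
            uniq = sorted({int(v) for v in vals})
            if rule == "first-scored":
                rows[sp][name] = int(vals[0])
            elif len(uniq) == 1:
                rows[sp][name] = uniq[0]
            elif rule == "strict":
                log.warning(
                    "species %s: conflicting values %s for trait %s -> missing",
                    sp, uniq, name,
                )
                rows[sp][name] = pd.NA
            else:  # majority
                counts = pd.Series([int(v) for v in vals]).value_counts()
                top = counts[counts == counts.max()]
                rows[sp][name] = int(top.index[0]) if len(top) == 1 else pd.NA
    data = pd.DataFrame.from_dict(rows, orient="index")
    for name, d in matrix.definitions.items():
        if d.kind == "discrete":
            data[name] = data[name].astype("Int64")
        else:
            data[name] = data[name].astype(float)
    data = data[list(matrix.definitions)]
    return TraitMatrix(
        data=data,
        species=pd.Series(data.index, index=data.index),
        definitions=matrix.definitions,
        level="species",
        provenance={**matrix.provenance, "collapse_rule": rule},
    )


# ---------------------------------------------------------------------------
# summaries


def state_frequencies(matrix: TraitMatrix, trait: str) -> pd.DataFrame:
    """Per-state count, denominator and percent for a discrete trait.

    The denominator is the number of rows actually scored for the trait,
    matching the reporting style "70 out of 110 taxa (63.6 %)".
    """
    d = matrix.definition(trait)
    if d.kind != "discrete":
        raise TraitError(f"trait {trait!r} is not discrete")
    col = matrix.data[trait].dropna()
    denom = len(col)
    recs = []
    for code, name in enumerate(d.states):
        n = int((col == code).sum())
        pct = round(100.0 * n / denom, 1) if denom else float("nan")
        recs.append({"state": name, "count": n, "denominator": denom, "percent": pct})
    return pd.DataFrame(recs)


def continuous_summary(
    matrix: TraitMatrix,
    trait: str,
    subset: Callable[[pd.Series], pd.Series] | None = None,
) -> dict:
    """Mean / min / max / n of a continuous trait, optionally on a subset.

    ``subset`` receives the full data frame row-wise as a boolean mask
    builder: it is called with ``matrix.data`` and must return a boolean
    Series (e.g. ``lambda df: df["mesophyll"] == 0`` for bifacial taxa).
    """
    d = matrix.definition(trait)
    if d.kind != "continuous":
        raise TraitError(f"trait {trait!r} is not continuous")
    col = matrix.data[trait]
    if subset is not None:
        mask = subset(matrix.data).fillna(False).astype(bool)
        col = col[mask.values]
    col = col.dropna()
    if len(col) == 0:
        raise TraitError(f"empty subset for trait {trait!r}")
    return {
        "mean": float(col.mean()),
        "min": float(col.min()),
        "max": float(col.max()),
        "n": int(len(col)),
        "units": d.units,
    }


def fraction_summary(
    matrix: TraitMatrix,
    numerator: str,
    complement: str,
    subset: Callable[[pd.DataFrame], pd.Series] | None = None,
) -> dict:
    """Mean per-taxon fraction numerator/(numerator+complement) as a percent.

    Used for e.g. the palisade fraction of total mesophyll thickness.
    """
    a = matrix.data[numerator].astype(float)
    b = matrix.data[complement].astype(float)
    mask = a.notna() & b.notna() & ((a + b) > 0)
    if subset is not None:
        mask &= subset(matrix.data).fillna(False).astype(bool)
    if not mask.any():
        raise TraitError("empty subset for fraction summary")
    frac = (a[mask] / (a[mask] + b[mask])).mean()
    return {"percent": round(100.0 * float(frac), 1), "n": int(mask.sum())}


# ---------------------------------------------------------------------------
# bridge to the ASR pipeline


def tip_states_for_trait(
    matrix: TraitMatrix,
    trait: str,
    tree_tips: Iterable[str],
) -> tuple[TipStates, list[str]]:
    """Tip-state vector for a tree, plus the list of tips to prune.

    Tips scored for the trait get their state code; tips present on the
    tree but missing the trait are returned in the prune list (the
    pipeline removes tree tips without data rather than integrating over
    them).
    """
    d = matrix.definition(trait)
    if d.kind != "discrete":
        raise TraitError(f"trait {trait!r} is not discrete")
    tree_tips = list(tree_tips)
    col = matrix.data[trait]
    states: dict[str, int] = {}
    prune: list[str] = []
    overlap = 0
    for lab in tree_tips:
        if lab in col.index:
            overlap += 1
            v = col.loc[lab]
            if pd.isna(v):
                prune.append(lab)
            else:
                states[lab] = int(v)
        else:
            prune.append(lab)
    if overlap == 0:
        raise TraitError("no overlap between trait matrix rows and tree tips")
    if not states:
        raise TraitError(f"no tree tip is scored for trait {trait!r}")
    tips = TipStates(
        k=d.k,
        states=states,
        state_names={i: s for i, s in enumerate(d.states)},
    )
    return tips, prune
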