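"""Synthetic study generator: trees, posterior-like tree samples,
Mk-evolved characters with known ancestral truth, and trait matrices.

The generator emulates the shape of a dated-phylogeny comparative study:
a base ultrametric tree of ~110 species with a crown age of 56 time
units, a posterior-like sample of 300 trees obtained by perturbing the
base tree (random NNI moves plus mean-preserving lognormal branch-length
noise), discrete characters evolved forward under known Q matrices with
optional clade scenarios that force a derived state at a clade's crown,
and an accession x trait matrix (149 accessions over the species, 35
discrete + 24 continuous traits) with injected missing values.

Because the characters are simulated with full internal-node truth, every
pipeline stage can be checked against known answers without any external
data.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .mk import QMatrix, TipStates, build_q
from .traits import TraitDefinition, TraitMatrix
from .treeio import CladeDefinition, PhyloTree, TreeSample, clade_nodes

__all__ = [
    "GeneratorSpec",
    "CladeScenario",
    "SimulatedCharacter",
    "StudyData",
    "simulate_yule_tree",
    "perturb_tree_sample",
    "simulate_mk_tips",
    "simulate_trait_matrix",
    "select_clades",
    "study_characters",
    "make_study",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Study-scale defaults: ~110 species, crown age 56 time units, a
    300-tree posterior-like sample, mild topological (2 NNI moves/tree)
    and branch-length (CV 0.1) perturbation, and ~10% missing data."""

    n_tips: int = 110
    root_age: float = 56.0
    sample_size: int = 300
    nni_moves: int = 2
    blen_cv: float = 0.1
    n_accessions: int = 149
    n_discrete: int = 35
    n_continuous: int = 24
    missing_rate: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2 or self.sample_size < 1:
            raise ValueError("n_tips >= 2 and sample_size >= 1 required")
        if self.nni_moves < 0 or self.blen_cv < 0 or not 0 <= self.missing_rate < 1:
            raise ValueError("invalid perturbation/missing settings")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass(frozen=True)
class CladeScenario:
    """Force ``derived_state`` at a clade's crown node; within the clade
    the character evolves from that state with rates scaled by
    ``rate_scale`` (0 freezes the clade)."""

    clade: CladeDefinition
    derived_state: int
    rate_scale: float = 1.0


@dataclass
class SimulatedCharacter:
    """Forward-simulated character with full internal-node truth."""

    tips: TipStates
    node_states: np.ndarray  # true state at every node of the base tree
    changes_per_branch: np.ndarray  # realised change counts per branch
    definition: TraitDefinition | None = None
    q: QMatrix | None = None
    scenarios: tuple[CladeScenario, ...] = ()


# ---------------------------------------------------------------------------
# trees


def simulate_yule_tree(
    n_tips: int, root_age: float = 56.0, seed: int | np.random.Generator = 0
) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_tips`` leaves, rescaled so every
    tip is exactly ``root_age`` from the root (ultrametric)."""
    rng = np.random.default_rng(seed)
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    t0 = [0.0, 0.0, 0.0]  # branch start time per node
    t1: list[float | None] = [0.0, None, None]  # branch end (event) time
    kids: list[list[int]] = [[1, 2], [], []]
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        v = active.pop(int(rng.integers(len(active))))
        t1[v] = t
        for _ in range(2):
            c = len(t0)
            kids[v].append(c)
            t0.append(t)
            t1.append(None)
            kids.append([])
        active.extend(kids[v])
    t_end = t + rng.exponential(1.0 / len(active))
    for v in active:
        t1[v] = t_end
    scale = root_age / t_end

    parent, blen, label = [], [], []
    index: dict[int, int] = {}
    ntip = 0
    stack = [(0, -1)]
    while stack:
        v, p = stack.pop()
        my = len(parent)
        index[v] = my
        parent.append(-1 if p == -1 else index[p])
        blen.append(0.0 if p == -1 else (t1[v] - t0[v]) * scale)
        if kids[v]:
            label.append(None)
        else:
            ntip += 1
            label.append(f"t{ntip:03d}")
        for c in reversed(kids[v]):
            stack.append((c, v))
    return PhyloTree(np.array(parent), np.array(blen), label)


def _one_nni(parent: np.ndarray, children: list[list[int]], rng) -> bool:
    """One random NNI move in place.  Returns False on a star tree."""
    internal = [v for v in range(1, len(parent)) if children[v]]
    if not internal:
        return False
    v = int(internal[int(rng.integers(len(internal)))])
    u = int(parent[v])
    sibs = [c for c in children[u] if c != v]
    x = int(children[v][int(rng.integers(len(children[v])))])
    y = int(sibs[int(rng.integers(len(sibs)))])
    children[v].remove(x)
    children[u].remove(y)
    children[v].append(y)
    children[u].append(x)
    parent[x] = u
    parent[y] = v
    return True


def perturb_tree_sample(
    base: PhyloTree,
    spec: GeneratorSpec,
    seed: int | np.random.Generator | None = None,
) -> TreeSample:
    """A posterior-like sample: ``sample_size`` copies of the base tree,
    each with ``nni_moves`` random NNI rearrangements and mean-preserving
    lognormal branch-length noise (CV ``blen_cv``), rescaled so the
    deepest tip sits at ``root_age``.  The tip set never changes."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sigma = float(np.sqrt(np.log1p(spec.blen_cv**2)))
    trees = []
    for _ in range(spec.sample_size):
        parent = base.parent.copy()
        blen = base.blen.copy()
        children = [list(c) for c in base.children]
        for _ in range(spec.nni_moves):
            if not _one_nni(parent, children, rng):
                warnings.warn("NNI impossible on a star tree; noise only")
                break
        if spec.blen_cv > 0:
            mult = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(blen))
            blen[1:] *= mult[1:]
        tree = PhyloTree(parent, blen, base.label)
        depth = tree.depths().max()
        if depth > 0 and spec.root_age > 0:
            blen2 = tree.blen * (spec.root_age / depth)
            tree = PhyloTree(parent, blen2, base.label)
        trees.append(tree)
    return TreeSample(
        trees,
        provenance={
            "generator": "nni+lognormal-noise",
            "spec": asdict(spec),
            "spec_digest": spec.digest(),
        },
    )


# ---------------------------------------------------------------------------
# characters


def simulate_mk_tips(
    tree: PhyloTree,
    q: QMatrix,
    root_state: int | None = None,
    root_prior: np.ndarray | None = None,
    clade_scenarios: tuple[CladeScenario, ...] | list[CladeScenario] = (),
    seed: int | np.random.Generator = 0,
) -> SimulatedCharacter:
    """Evolve a k-state character root -> tips by exponential waiting
    times, returning observed tip states plus the true node states and
    per-branch change counts.

    Clade scenarios override the state at the clade's crown node (so the
    forced change falls on the stem branch) and scale Q inside the clade.
    """
    rng = np.random.default_rng(seed)
    k = q.k
    if root_state is None:
        pr = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)
        root_state = int(rng.choice(k, p=pr / pr.sum()))
    scenarios = tuple(clade_scenarios)
    forced: dict[int, int] = {}
    scale = np.ones(tree.n_nodes)
    for sc in scenarios:
        cn = clade_nodes(tree, sc.clade)
        forced[cn.crown] = sc.derived_state
        stack = [cn.crown]
        while stack:
            v = stack.pop()
            scale[v] = sc.rate_scale
            stack.extend(tree.children[v])

    states = np.empty(tree.n_nodes, dtype=np.int64)
    changes = np.zeros(tree.n_nodes, dtype=np.int64)
    states[0] = forced.get(0, root_state)
    for v in tree.postorder()[::-1]:  # preorder
        if v == 0:
            continue
        if v in forced:
            states[v] = forced[v]
            continue
        s = int(states[int(tree.parent[v])])
        t_rem = float(tree.blen[v]) * float(scale[v])
        nch = 0
        while True:
            out_rate = -q.matrix[s, s]
            if out_rate <= 0:
                break
            w = rng.exponential(1.0 / out_rate)
            if w >= t_rem:
                break
            t_rem -= w
            probs = q.matrix[s].copy()
            probs[s] = 0.0
            probs /= probs.sum()
            s = int(rng.choice(k, p=probs))
            nch += 1
        states[v] = s
        changes[v] = nch
    tip_states = {tree.label[v]: int(states[v]) for v in tree.tip_indices}
    tips = TipStates(k=k, states=tip_states)
    return SimulatedCharacter(
        tips=tips,
        node_states=states,
        changes_per_branch=changes,
        q=q,
        scenarios=scenarios,
    )


# ---------------------------------------------------------------------------
# clades and the packaged study scenario


def select_clades(
    tree: PhyloTree,
    n_clades: int = 8,
    size_range: tuple[int, int] = (4, 30),
) -> list[CladeDefinition]:
    """Pick disjoint named clades (subtrees) of moderate size from a tree,
    largest first, numbered clade01, clade02, ... deterministically."""
    sizes = {}
    for v in tree.postorder():
        sizes[v] = 1 if tree.is_tip(v) else sum(sizes[c] for c in tree.children[v])
    cands = sorted(
        (v for v in sizes if size_range[0] <= sizes[v] <= size_range[1] and v != 0),
        key=lambda v: (-sizes[v], v),
    )
    chosen: list[int] = []
    covered: set[int] = set()
    for v in cands:
        if v in covered:
            continue
        chain = set()
        u = v
        while u != -1:
            chain.add(u)
            u = int(tree.parent[u])
        if chain & set(chosen):
            continue
        # skip if v contains an already chosen clade
        stack, contains = [v], False
        while stack:
            w = stack.pop()
            if w in set(chosen):
                contains = True
                break
            stack.extend(tree.children[w])
        if contains:
            continue
        chosen.append(v)
        if len(chosen) >= n_clades:
            break
    return [
        CladeDefinition(name=f"clade{i + 1:02d}", members=frozenset(tree.subtree_tips(v)))
        for i, v in enumerate(chosen)
    ]


_STUDY_TRAITS: list[tuple[str, tuple[str, ...], str, tuple[float, ...], int]] = [
    # (name, states, model, rates, root_state) — rates per unit branch length
    # the focal marker trait is a clean synapomorphy: derived state forced
    # on the focal clade, no background change (its empirical counterpart
    # is confined to a single subclade in the real data)
    ("ad_cell_type", ("irregular", "swollen"), "ER", (0.0,), 0),
    ("ab_cell_type", ("irregular", "swollen", "semi_swollen"), "ER", (0.004,), 2),
    ("stomatal_position", ("hypostomatic", "epistomatic", "amphistomatic"), "ER", (0.004,), 0),
    ("mesophyll", ("bifacial", "isobilateral", "homogenous"), "SYM", (0.050, 0.004, 0.008), 0),
    ("vascular_sheath", ("absent", "present"), "ER", (0.117,), 0),
    # asymmetric binary: conduplicate -> flat four times faster than the
    # reverse, rates low enough that both states persist among the tips
    ("leaflet_type", ("flat", "conduplicate"), "ARD", (0.005, 0.02), 1),
]


def study_characters(
    tree: PhyloTree,
    clades: list[CladeDefinition],
    seed: int | np.random.Generator = 0,
) -> dict[str, SimulatedCharacter]:
    """The packaged six-trait scenario: slowly evolving characters with a
    derived state forced onto the first (focal) clade for the first
    character, fast characters (vascular sheath) that stay equivocal, and
    an asymmetric binary character.  Mirrors the mix of confident and
    equivocal rows a real clade-summary table shows."""
    rng = np.random.default_rng(seed)
    focal = clades[0]
    out: dict[str, SimulatedCharacter] = {}
    for name, states, model, rates, root in _STUDY_TRAITS:
        q = build_q(model, len(states), rates)
        scenarios: tuple[CladeScenario, ...] = ()
        if name == "ad_cell_type":
            scenarios = (CladeScenario(clade=focal, derived_state=1, rate_scale=0.0),)
        if name == "stomatal_position" and len(clades) > 1:
            scenarios = (CladeScenario(clade=clades[1], derived_state=1),)
        sim = simulate_mk_tips(
            tree,
            q,
            root_state=root,
            clade_scenarios=scenarios,
            seed=rng,
        )
        sim.definition = TraitDefinition(name=name, kind="discrete", states=states)
        sim.tips.state_names = {i: s for i, s in enumerate(states)}
        out[name] = sim
    return out


# ---------------------------------------------------------------------------
# trait matrix


def simulate_trait_matrix(
    spec: GeneratorSpec,
    tree: PhyloTree,
    characters: dict[str, SimulatedCharacter],
    seed: int | np.random.Generator | None = None,
) -> TraitMatrix:
    """Accession x trait matrix shaped like a real anatomy supplement.

    Accessions duplicate a random subset of species (to reach
    ``n_accessions`` rows over ``n_tips`` species) with within-species
    concordant discrete values.  Filler discrete traits are iid draws;
    continuous traits are lognormal, half of them with state-linked mean
    shifts tied to the first simulated character.  Missing values are
    injected completely at random at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    species = tree.tip_labels
    n_extra = max(0, spec.n_accessions - len(species))
    extra = list(rng.choice(species, size=n_extra, replace=True))
    owners = species + extra
    acc_ids = [f"MO{i + 1:04d}" for i in range(len(owners))]

    defs: dict[str, TraitDefinition] = {}
    cols: dict[str, list] = {}
    for name, sim in characters.items():
        d = sim.definition or TraitDefinition(
            name=name,
            kind="discrete",
            states=tuple(sim.tips.state_names[i] for i in range(sim.tips.k)),
        )
        defs[name] = d
        cols[name] = [sim.tips.states.get(sp) for sp in owners]
    n_filler = max(0, spec.n_discrete - len(characters))
    for j in range(n_filler):
        name = f"filler_discrete_{j + 1:02d}"
        k = 2 + (j % 2)
        defs[name] = TraitDefinition(
            name=name, kind="discrete", states=tuple(f"s{i}" for i in range(k))
        )
        per_species = {sp: int(rng.integers(k)) for sp in species}
        cols[name] = [per_species[sp] for sp in owners]
    anchor = next(iter(characters)) if characters else None
    for j in range(spec.n_continuous):
        name = f"cont_{j + 1:02d}"
        defs[name] = TraitDefinition(name=name, kind="continuous", units="um")
        mu = np.log(30.0 + 10.0 * j)
        base = {sp: rng.lognormal(mean=mu, sigma=0.4) for sp in species}
        if anchor is not None and j % 2 == 0:
            st = characters[anchor].tips.states
            base = {sp: v * (1.5 ** st.get(sp, 0)) for sp, v in base.items()}
        noise = rng.lognormal(mean=0.0, sigma=0.05, size=len(owners))
        cols[name] = [base[sp] * noise[i] for i, sp in enumerate(owners)]

    data = {}
    for name, d in defs.items():
        if d.kind == "discrete":
            data[name] = pd.array(cols[name], dtype="Int64")
        else:
            data[name] = np.asarray(cols[name], dtype=float)
    df = pd.DataFrame(data, index=acc_ids)

    if spec.missing_rate > 0:
        mask = rng.random(df.shape) < spec.missing_rate
        for ci, name in enumerate(df.columns):
            col = df[name].copy()
            col[mask[:, ci]] = pd.NA if defs[name].kind == "discrete" else np.nan
            df[name] = col

    return TraitMatrix(
        data=df,
        species=pd.Series(owners, index=acc_ids),
        definitions=defs,
        provenance={"spec": asdict(spec), "spec_digest": spec.digest()},
    )


# ---------------------------------------------------------------------------
# the whole bundle


@dataclass
class StudyData:
    """Everything the pipeline needs, with generating truth attached."""

    spec: GeneratorSpec
    base_tree: PhyloTree
    sample: TreeSample
    clades: list[CladeDefinition]
    characters: dict[str, SimulatedCharacter]
    matrix: TraitMatrix


def make_study(spec: GeneratorSpec = GeneratorSpec()) -> StudyData:
    """Generate the full synthetic study deterministically from
    ``spec.seed``: base tree, perturbed tree sample, named clades, six
    focal characters with truth, and the accession-level trait matrix."""
    ss = np.random.SeedSequence(spec.seed).spawn(4)
    base = simulate_yule_tree(spec.n_tips, spec.root_age, seed=np.random.default_rng(ss[0]))
    clades = select_clades(base, n_clades=8, size_range=(4, max(6, spec.n_tips // 4)))
    # focal clade first: mid-sized with the longest stem branch, so a
    # forced state change on its stem is identifiable (a change on a very
    # short stem is intrinsically equivocal); remaining clades by size
    def stem_length(c: CladeDefinition) -> float:
        return float(base.blen[clade_nodes(base, c).crown])

    clades.sort(key=lambda c: (-stem_length(c), c.name))
    clades = [clades[0]] + sorted(
        clades[1:], key=lambda c: (-len(c.members), min(c.members))
    )
    clades = [
        CladeDefinition(name=f"clade{i + 1:02d}", members=c.members)
        for i, c in enumerate(clades)
    ]
    chars = study_characters(base, clades, seed=np.random.default_rng(ss[1]))
    sample = perturb_tree_sample(base, spec, seed=np.random.default_rng(ss[2]))
    matrix = simulate_trait_matrix(spec, base, chars, seed=np.random.default_rng(ss[3]))
    return StudyData(
        spec=spec,
        base_tree=base,
        sample=sample,
        clades=clades,
        characters=chars,
        matrix=matrix,
    )
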