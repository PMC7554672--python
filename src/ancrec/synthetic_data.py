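"""Synthetic inputs with recorded ground truth for every pipeline stage.

Three generators mirror the three data streams the pipeline consumes:

* gene-family occurrence matrices evolved on a tree under known
  gain/loss/duplication rates, with the true copy number at every ancestral
  node and the realized per-branch events recorded;
* stem alignments evolved under the branch-specific T92 model, where each
  branch's equilibrium GC tracks an optimal growth temperature that drifts
  by Brownian motion along the tree through a known linear calibration;
* pairwise hit tables with planted family structure that thresholded
  single-linkage clustering must recover.

Everything is deterministic given its seed.  The OGT trait evolves by
Brownian motion because that is the model under which independent
contrasts are exact, so calibration diagnostics computed on these data are
meaningful.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .phylo_core import Node, Tree, write_newick, parse_newick
from .famclust import FamilySet
from .genefam_bd import BDRates, bd_stationary
from .thermometer import StemAlignment, t92_stationary, t92_transition_probs, _LETTER

__all__ = [
    "SimTruth",
    "PlantedFamilies",
    "simulate_tree",
    "simulate_family_evolution",
    "simulate_bd_endpoints",
    "simulate_thermometer_dataset",
    "make_planted_families",
    "simulate_hit_table",
    "write_hit_table",
    "write_lengths_table",
    "write_seq2genome_table",
    "write_ogt_table",
    "write_alignment_fasta",
]


@dataclass
class SimTruth:
    """Recorded ground truth of a simulation (self-consistent by construction)."""

    tree_newick: str
    seed: int
    family_rates: dict | None = None  # family -> {gain, dup, loss}
    node_counts: dict | None = None  # node id (str) -> {family: count}
    branch_events: list | None = None  # rows: family, parent, child, event flags
    theta_by_node: dict | None = None  # node id (str) -> equilibrium GC
    ogt_by_node: dict | None = None  # node id (str) -> degC
    ancestral_gc: dict | None = None  # node id (str) -> realized stem GC %
    calibration: dict | None = None  # {"slope": a, "intercept": b}

    def to_json(self, path=None, indent: int | None = 1) -> str:
        text = json.dumps(asdict(self), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SimTruth":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(**data)


# -- trees ---------------------------------------------------------------------


def simulate_tree(
    n_tips: int,
    seed: int = 0,
    model: str = "Yule",
    scale: float = 0.3,
    rate_variation: float = 0.0,
    min_tip_depth: float | None = None,
) -> Tree:
    """Random rooted binary tree with positive branch lengths.

    Yule (pure-birth) process: lineages split at equal rate; the tree is
    rescaled so the mean root-to-tip path length equals ``scale``
    (substitutions/site; default 0.3, a deep-but-resolvable prokaryotic
    core-gene scale).  ``rate_variation`` > 0 multiplies each branch by an
    independent lognormal factor with that log-sd (mean 1), breaking the
    clock the way evolutionary rates vary across prokaryotic lineages;
    slowly evolving lineages then retain short root-to-tip paths, which is
    what makes deep ancestral composition recoverable in real data sets.
    ``min_tip_depth`` shortens the branches on the path to the shallowest
    tip so that its root-to-tip length equals the given value — an explicit
    slowly-evolving basal lineage, the analogue of the deeply branching
    relict taxa that anchor ancestral-composition inference in real
    calibration sets.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if model != "Yule":
        raise ValueError(f"unknown tree model {model!r}")
    rng = np.random.default_rng(seed)
    nodes: list[Node] = [Node(0)]
    pending: dict[int, float] = {}

    def spawn(parent: int) -> int:
        node = Node(len(nodes), parent=parent)
        nodes.append(node)
        nodes[parent].children.append(node.id)
        pending[node.id] = 0.0
        return node.id

    active = [spawn(0), spawn(0)]
    while len(active) < n_tips:
        dt = rng.exponential(1.0 / len(active))
        for nid in active:
            pending[nid] += dt
        k = int(rng.integers(len(active)))
        split = active.pop(k)
        nodes[split].branch_length = pending.pop(split)
        active.extend([spawn(split), spawn(split)])
    dt = rng.exponential(1.0 / len(active))
    for i, nid in enumerate(active):
        nodes[nid].branch_length = pending.pop(nid) + dt
        nodes[nid].label = f"T{i + 1:03d}"
    tree = Tree(nodes, 0)
    if rate_variation > 0:
        for n in tree.nodes:
            if n.branch_length is not None:
                n.branch_length *= float(
                    rng.lognormal(-0.5 * rate_variation**2, rate_variation)
                )
    depths = [tree.root_to_node_length(l) for l in tree.leaves()]
    factor = scale / float(np.mean(depths))
    for n in tree.nodes:
        if n.branch_length is not None:
            n.branch_length *= factor
    if min_tip_depth is not None:
        # one relict lineage per root subtree: ancestral composition is only
        # identifiable when short root-to-tip paths exist on both sides of
        # the root (a single one can be absorbed by its own branch theta)
        for child in tree.nodes[tree.root].children:
            sub_leaves = [
                l for l in tree.leaves() if child in _path_to_root(tree, l) or l == child
            ]
            depths = {l: tree.root_to_node_length(l) for l in sub_leaves}
            shallow = min(depths, key=depths.get)
            if depths[shallow] > min_tip_depth:
                f = min_tip_depth / depths[shallow]
                nid = shallow
                while tree.nodes[nid].parent is not None:
                    tree.nodes[nid].branch_length *= f
                    nid = tree.nodes[nid].parent
    return tree


def _path_to_root(tree: Tree, nid: int) -> set[int]:
    out = set()
    while tree.nodes[nid].parent is not None:
        nid = tree.nodes[nid].parent
        out.add(nid)
    return out


# -- gene-family evolution ------------------------------------------------------


def _evolve_branch(n0: int, t: float, g: float, lam: float, mu: float, rng) -> int:
    """Exact Gillespie simulation of the (uncapped) jump process."""
    n, elapsed = n0, 0.0
    while True:
        up = g + n * lam
        down = n * mu
        total = up + down
        if total <= 0:
            return n
        elapsed += rng.exponential(1.0 / total)
        if elapsed > t:
            return n
        n = n + 1 if rng.random() < up / total else n - 1


def simulate_bd_endpoints(
    rates: BDRates, t: float, n_paths: int, start_state: int, seed: int = 0
) -> np.ndarray:
    """End states of n_paths exact jump-chain simulations of the truncated
    gain-loss-duplication process run for time t (Monte-Carlo oracle for the
    transition kernel)."""
    rng = np.random.default_rng(seed)
    states = np.full(n_paths, int(start_state), dtype=np.int64)
    remaining = np.full(n_paths, float(t))
    active = np.ones(n_paths, dtype=bool)
    while active.any():
        up = np.where(states < rates.cmax, rates.gain + states * rates.dup, 0.0)
        down = states * rates.loss
        total = up + down
        frozen = total <= 0
        active &= ~frozen
        total_safe = np.where(total > 0, total, 1.0)
        dt = rng.exponential(1.0, n_paths) / total_safe
        u = rng.random(n_paths)
        step = active & (remaining - dt > 0)
        remaining = remaining - np.where(active, dt, 0.0)
        active &= remaining > 0
        go_up = u < up / total_safe
        states[step & go_up] += 1
        states[step & ~go_up] -= 1
    return states


def _classify(parent: int, child: int) -> dict[str, bool]:
    return {
        "gain": parent == 0 and child >= 1,
        "loss": parent >= 1 and child == 0,
        "expand": child > parent >= 1,
        "contract": parent > child >= 1,
    }


def simulate_family_evolution(
    tree: Tree,
    n_families: int,
    rates: BDRates | Callable[[np.random.Generator], BDRates] | None = None,
    root_prior: str | np.ndarray = "stationary",
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Evolve copy numbers for ``n_families`` down the tree.

    ``rates`` is either one BDRates applied to every family, or a callable
    drawing per-family rates from a prior; the default prior draws
    gain ~ Gamma(2, 0.5), loss ~ Gamma(2, 0.5), dup = 0 — a regime where
    typical families are present in an informative fraction of tips.
    Returns the leaves x families occurrence matrix and the recorded truth.
    """
    rng = np.random.default_rng(seed)
    if rates is None:
        def rates(r):
            return BDRates(float(r.gamma(2, 0.5)), 0.0, float(r.gamma(2, 0.5)))
    draw = rates if callable(rates) else (lambda r: rates)
    post = list(tree.postorder())
    pre = list(tree.preorder())
    fam_ids = [f"FAM{i + 1:06d}" for i in range(n_families)]
    node_counts: dict[int, dict[str, int]] = {n: {} for n in post}
    fam_rates: dict[str, dict] = {}
    events: list[dict] = []
    for fam in fam_ids:
        fr = draw(rng)
        fam_rates[fam] = {"gain": fr.gain, "dup": fr.dup, "loss": fr.loss}
        prior = (
            bd_stationary(fr) if isinstance(root_prior, str) and root_prior == "stationary"
            else np.asarray(root_prior, dtype=float)
        )
        root_state = int(rng.choice(len(prior), p=prior / prior.sum()))
        node_counts[tree.root][fam] = root_state
        for nid in pre:
            if nid == tree.root:
                continue
            parent_state = node_counts[tree.nodes[nid].parent][fam]
            t = tree.nodes[nid].branch_length or 0.0
            child_state = _evolve_branch(parent_state, t, fr.gain, fr.dup, fr.loss, rng)
            node_counts[nid][fam] = child_state
            ev = _classify(parent_state, child_state)
            if any(ev.values()):
                events.append(
                    {"family": fam, "parent": tree.nodes[nid].parent, "child": nid, **ev}
                )
    leaves = tree.leaf_labels()
    leaf_id = {tree.nodes[l].label: l for l in tree.leaves()}
    matrix = pd.DataFrame(
        {fam: [node_counts[leaf_id[lab]][fam] for lab in leaves] for fam in fam_ids},
        index=pd.Index(leaves, name="genome"),
    )
    matrix.columns.name = "family"
    truth = SimTruth(
        tree_newick=write_newick(tree),
        seed=seed,
        family_rates=fam_rates,
        node_counts={str(n): node_counts[n] for n in post},
        branch_events=events,
    )
    return matrix, truth


# -- thermometer data -----------------------------------------------------------


def simulate_thermometer_dataset(
    tree: Tree,
    calibration: tuple[float, float] = (2.0, -60.0),
    ogt_root: float = 75.0,
    ogt_bm_variance: float = 800.0,
    n_sites: int = 1000,
    kappa: float = 2.0,
    seed: int = 0,
) -> tuple[StemAlignment, dict[str, float], SimTruth]:
    """Stem alignment whose per-branch equilibrium GC tracks a drifting OGT.

    An OGT is assigned to every node by Brownian motion along branches
    (variance ``ogt_bm_variance`` per unit branch length — with the default
    tree scale this spreads tip OGTs over several tens of degC, like a real
    thermophile-to-mesophile calibration set).  The branch ending at node v
    evolves under T92 with theta_v = clamp(((OGT_v - b) / a) / 100, 0.01,
    0.99) where (a, b) is the true calibration.  All columns are stem
    columns.  Returns (alignment, tip OGT table, truth).
    """
    a, b = calibration
    if a == 0:
        raise ValueError("calibration slope must be nonzero")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    ogt: dict[int, float] = {tree.root: float(ogt_root)}
    for nid in tree.preorder():
        if nid == tree.root:
            continue
        t = tree.nodes[nid].branch_length or 0.0
        parent = tree.nodes[nid].parent
        ogt[nid] = float(ogt[parent] + rng.normal(0.0, math.sqrt(ogt_bm_variance * t)))

    def theta_of(nid: int) -> float:
        return float(np.clip(((ogt[nid] - b) / a) / 100.0, 0.01, 0.99))

    theta = {nid: theta_of(nid) for nid in ogt}
    seqs: dict[int, np.ndarray] = {}
    pi_root = t92_stationary(theta[tree.root])
    seqs[tree.root] = rng.choice(4, size=n_sites, p=pi_root).astype(np.int8)
    for nid in tree.preorder():
        if nid == tree.root:
            continue
        t = tree.nodes[nid].branch_length or 0.0
        P = t92_transition_probs(np.array([theta[nid]]), kappa, np.array([t]))[0]
        probs = P[seqs[tree.nodes[nid].parent]]
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n_sites)
        seqs[nid] = (u[:, None] > cum).sum(axis=1).astype(np.int8)

    labels = tree.leaf_labels()
    leaf_id = {tree.nodes[l].label: l for l in tree.leaves()}
    sequences = ["".join(_LETTER[seqs[leaf_id[lab]]]) for lab in labels]
    aln = StemAlignment(labels, sequences, np.ones(n_sites, dtype=bool))
    tip_ogt = {lab: ogt[leaf_id[lab]] for lab in labels}
    gc_true = {
        str(nid): 100.0 * float(((seqs[nid] == 1) | (seqs[nid] == 2)).mean())
        for nid in seqs
    }
    truth = SimTruth(
        tree_newick=write_newick(tree),
        seed=seed,
        theta_by_node={str(n): theta[n] for n in theta},
        ogt_by_node={str(n): ogt[n] for n in ogt},
        ancestral_gc=gc_true,
        calibration={"slope": a, "intercept": b},
    )
    return aln, tip_ogt, truth


# -- planted protein families and hit tables -------------------------------------


@dataclass
class PlantedFamilies:
    famset: FamilySet
    seq2genome: dict[str, str]
    lengths: dict[str, int]


def make_planted_families(
    n_genomes: int = 8,
    n_families: int = 10,
    max_copies: int = 3,
    presence_prob: float = 0.8,
    seed: int = 0,
) -> PlantedFamilies:
    """Plant a family partition across genomes with 1..max_copies per genome."""
    rng = np.random.default_rng(seed)
    genomes = [f"G{i + 1:02d}" for i in range(n_genomes)]
    families: dict[str, set[str]] = {}
    seq2genome: dict[str, str] = {}
    lengths: dict[str, int] = {}
    for f in range(n_families):
        fid = f"FAM{f + 1:06d}"
        base_len = int(rng.integers(120, 450))
        members: set[str] = set()
        for g in genomes:
            if rng.random() > presence_prob and members:
                continue
            for k in range(int(rng.integers(1, max_copies + 1))):
                sid = f"{g}|{fid}_{k + 1}"
                members.add(sid)
                seq2genome[sid] = g
                lengths[sid] = int(base_len * rng.uniform(0.92, 1.08))
        if not members:  # force non-empty families
            sid = f"{genomes[0]}|{fid}_1"
            members.add(sid)
            seq2genome[sid] = genomes[0]
            lengths[sid] = base_len
        families[fid] = members
    membership = {s: fid for fid, mem in families.items() for s in mem}
    return PlantedFamilies(FamilySet(families, membership), seq2genome, lengths)


def simulate_hit_table(
    planted: PlantedFamilies, noise: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Pairwise hits whose thresholded single-linkage closure is the planted
    partition.

    Within-family hits pass every screen (identity >= 40, coverage >= 0.8 of
    the longer partner, E <= 1e-5) and connect each family through a random
    spanning path plus extra random pairs.  ``noise`` adds spurious
    cross-family rows with identity below 35% (they must not survive the
    filter).  Self-hits are always included.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    lengths = planted.lengths

    def add_hit(q, s, pident, evalue):
        aln_len = math.ceil(0.85 * max(lengths[q], lengths[s]))
        rows.append((q, s, round(pident, 1), aln_len, evalue))

    for fid in sorted(planted.famset.families):
        members = sorted(planted.famset.families[fid])
        for m in members:
            rows.append((m, m, 100.0, lengths[m], 0.0))
        order = list(members)
        rng.shuffle(order)
        for q, s in zip(order, order[1:]):
            add_hit(q, s, 40 + 50 * rng.random(), 10.0 ** -(5 + 25 * rng.random()))
        n_extra = int(rng.integers(0, max(1, len(members))))
        for _ in range(n_extra):
            q, s = rng.choice(members, size=2, replace=False)
            add_hit(q, s, 40 + 50 * rng.random(), 10.0 ** -(5 + 25 * rng.random()))
    if noise > 0:
        universe = sorted(planted.famset.membership)
        n_noise = int(rng.poisson(noise * max(1, len(rows))))
        for _ in range(n_noise):
            q, s = rng.choice(universe, size=2, replace=False)
            add_hit(q, s, 10 + 24.9 * rng.random(), 10.0 ** -(1 + 5 * rng.random()))
    return pd.DataFrame(rows, columns=["query", "subject", "pident", "length", "evalue"])


# -- writers (exact formats the consuming modules read) ---------------------------


def write_hit_table(hits: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in hits.itertuples(index=False):
            fh.write(
                f"{row.query}\t{row.subject}\t{row.pident:.1f}\t{int(row.length)}\t{row.evalue:.3e}\n"
            )


def write_lengths_table(lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(lengths):
            fh.write(f"{sid}\t{lengths[sid]}\n")


def write_seq2genome_table(seq2genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(seq2genome):
            fh.write(f"{sid}\t{seq2genome[sid]}\n")


def write_ogt_table(ogt: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("label\togt_degC\n")
        for lab in sorted(ogt):
            fh.write(f"{lab}\t{ogt[lab]:.4f}\n")


def write_alignment_fasta(aln: StemAlignment, path) -> None:
    with open(path, "w") as fh:
        for lab, seq in zip(aln.labels, aln.sequences):
            fh.write(f">{lab}\n{seq}\n")
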