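"""The 16S rRNA "molecular thermometer" track.

Stem (double-stranded) regions of the small-subunit rRNA keep a G+C content
that tracks the organism's optimal growth temperature (OGT), because G:C
pairs stabilise helices at high temperature.  The track has three parts:

1. a *calibration*: ordinary least squares of OGT on stem GC% across extant
   taxa, with a phylogenetic-independent-contrasts (PIC) corrected
   correlation as a diagnostic;
2. a *nonhomogeneous substitution model*: Tamura (1992) exchange rates with
   a branch-specific equilibrium GC fraction theta_b, a global
   transition/transversion ratio kappa and a free root GC, fitted by maximum
   likelihood on the stem columns with branch lengths fixed;
3. *ancestral reconstruction*: joint posterior samples of ancestral stem
   sequences ("replicates"), converted to OGT estimates per internal node
   through the calibration line, with a percentile confidence interval over
   replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .phylo_core import Tree, prune_to_taxa

__all__ = [
    "StemAlignment",
    "NonHomT92Model",
    "AncestralReplicateSet",
    "ThermometerCalibration",
    "OgtEstimate",
    "FitConfig",
    "read_fasta_alignment",
    "read_stem_annotations",
    "read_ogt_table",
    "build_stem_mask",
    "stem_gc",
    "calibrate_thermometer",
    "pic_contrasts",
    "pic_correlation",
    "t92_generator",
    "t92_stationary",
    "transition_matrix",
    "t92_transition_probs",
    "pruning_loglik",
    "fit_nonhom_t92",
    "sample_ancestral_replicates",
    "predict_ancestral_ogt",
    "run_thermometer_track",
]

# state order everywhere: A, C, G, T
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_LETTER = np.array(["A", "C", "G", "T"])


def encode_sequence(seq: str) -> np.ndarray:
    """Encode to int8; gaps, N and other ambiguity codes become -1 (missing)."""
    return np.array([_CODE.get(c, -1) for c in seq.upper()], dtype=np.int8)


@dataclass
class StemAlignment:
    """Gapped nucleotide alignment plus a boolean stem-column mask."""

    labels: list[str]
    sequences: list[str]
    stem_mask: np.ndarray | None = None

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxa labels in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment, lengths {sorted(lengths)}")
        if self.stem_mask is not None:
            self.stem_mask = np.asarray(self.stem_mask, dtype=bool)
            if self.stem_mask.size != self.length:
                raise ValueError("stem mask length != alignment length")
            if not self.stem_mask.any():
                raise ValueError("empty stem mask")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def encoded(self) -> np.ndarray:
        """(n_taxa, L) int8 matrix; -1 = missing."""
        return np.stack([encode_sequence(s) for s in self.sequences])

    def sequence(self, label: str) -> str:
        return self.sequences[self.labels.index(label)]


def read_fasta_alignment(path) -> StemAlignment:
    from Bio import SeqIO

    labels, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not labels:
        raise ValueError(f"no sequences in {path}")
    return StemAlignment(labels, seqs)


def read_stem_annotations(path) -> dict[str, set[int]]:
    """TSV: label <tab> comma-separated 1-based ungapped stem positions."""
    out: dict[str, set[int]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            out[parts[0]] = {int(p) for p in parts[1].split(",") if p}
    return out


def read_ogt_table(path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("label\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            out[parts[0]] = float(parts[1])
    return out


# -- stem mask and GC ----------------------------------------------------------


def build_stem_mask(
    alignment: StemAlignment,
    stem_positions: Mapping[str, set[int]],
    *,
    consensus_fraction: float = 1.0,
) -> np.ndarray:
    """Consensus stem mask over alignment columns.

    ``stem_positions`` holds, per annotated taxon, the 1-based positions of
    stem residues in its *ungapped* sequence.  A column is a stem column iff
    at least ``consensus_fraction`` of the annotated sequences that have a
    residue (non-gap) in the column place a stem residue there.  The default
    1.0 is a strict consensus.
    """
    if not 0 < consensus_fraction <= 1:
        raise ValueError("consensus_fraction must be in (0, 1]")
    L = alignment.length
    votes = np.zeros(L, dtype=int)
    voters = np.zeros(L, dtype=int)
    for label, positions in stem_positions.items():
        if label not in alignment.labels:
            raise KeyError(f"annotated taxon {label!r} not in alignment")
        seq = alignment.sequence(label)
        ungapped_len = sum(1 for c in seq if c != "-")
        beyond = [p for p in positions if p < 1 or p > ungapped_len]
        if beyond:
            raise ValueError(
                f"stem annotation for {label!r} references position(s) {beyond} "
                f"beyond its ungapped length {ungapped_len}"
            )
        pos = 0
        for col, c in enumerate(seq):
            if c == "-":
                continue
            pos += 1
            voters[col] += 1
            if pos in positions:
                votes[col] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(voters > 0, votes / np.maximum(voters, 1), 0.0)
    mask = (voters > 0) & (frac >= consensus_fraction)
    if not mask.any():
        raise ValueError("empty stem mask: no column reaches the consensus fraction")
    return mask


def stem_gc(sequence: str | np.ndarray, mask: np.ndarray) -> float:
    """GC percentage over masked columns; gaps/N excluded from both counts."""
    enc = encode_sequence(sequence) if isinstance(sequence, str) else sequence
    mask = np.asarray(mask, dtype=bool)
    if enc.size != mask.size:
        raise ValueError("sequence length != mask length")
    sub = enc[mask]
    counted = sub >= 0
    n = int(counted.sum())
    if n == 0:
        raise ValueError("no counted bases under the stem mask")
    gc = int(((sub == 1) | (sub == 2)).sum())
    return 100.0 * gc / n


# -- calibration ---------------------------------------------------------------


@dataclass
class ThermometerCalibration:
    """OLS of OGT (degC) on stem GC (%): OGT = slope * GC + intercept."""

    slope: float
    intercept: float
    r_pearson: float
    r_pic: float
    r2_adjusted: float
    n_taxa: int
    # OLS diagnostics used to propagate prediction uncertainty into the
    # ancestral-OGT confidence intervals; zero residual variance (the
    # default for hand-built calibrations) disables that propagation.
    sigma2_resid: float = 0.0
    x_mean: float = 0.0
    s_xx: float = np.inf

    def predict(self, gc_percent):
        return self.slope * np.asarray(gc_percent, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope_degC_per_gc_point": self.slope,
            "intercept_degC": self.intercept,
            "r_pearson": self.r_pearson,
            "r_pic": self.r_pic,
            "r2_adjusted": self.r2_adjusted,
            "n_taxa": self.n_taxa,
        }


def pic_contrasts(tree: Tree, values: Mapping[str, float]) -> np.ndarray:
    """Felsenstein's standardized independent contrasts for one trait.

    Polytomies are folded pairwise in child order (each fold contributes one
    contrast, connected by zero-length internal branches), which reduces to
    the classical algorithm on binary trees.
    """
    leaves = set(tree.leaf_labels())
    missing = leaves - set(values)
    if missing:
        raise KeyError(f"trait missing for leaves: {sorted(missing)}")
    if len(leaves) < 3:
        raise ValueError("need >= 3 leaves for independent contrasts")

    # per node: (trait value, accumulated variance) passed rootward
    state: dict[int, tuple[float, float]] = {}
    contrasts: list[float] = []
    for nid in tree.postorder():
        node = tree.nodes[nid]
        bl = node.branch_length or 0.0
        if node.is_leaf:
            state[nid] = (float(values[node.label]), bl)
            continue
        x1, v1 = state[node.children[0]]
        for c in node.children[1:]:
            x2, v2 = state[c]
            contrasts.append((x1 - x2) / np.sqrt(v1 + v2))
            x1 = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
            v1 = v1 * v2 / (v1 + v2)
        state[nid] = (x1, v1 + bl)
    return np.asarray(contrasts)


def pic_correlation(
    tree: Tree, x: Mapping[str, float], y: Mapping[str, float]
) -> float:
    """Correlation of independent contrasts (through the origin)."""
    keep = sorted(set(tree.leaf_labels()) & set(x) & set(y))
    sub = tree if set(keep) == set(tree.leaf_labels()) else prune_to_taxa(tree, keep)
    ux = pic_contrasts(sub, x)
    uy = pic_contrasts(sub, y)
    if len(ux) < 2:
        raise ValueError("insufficient contrasts (need >= 2)")
    sx, sy = np.sum(ux**2), np.sum(uy**2)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in contrasts")
    return float(np.sum(ux * uy) / np.sqrt(sx * sy))


def calibrate_thermometer(
    tree: Tree, gc: Mapping[str, float], ogt: Mapping[str, float]
) -> ThermometerCalibration:
    """Fit OGT = slope * stemGC% + intercept by OLS over shared taxa."""
    taxa = sorted(set(gc) & set(ogt) & set(tree.leaf_labels()))
    if len(taxa) < 3:
        raise ValueError(f"need >= 3 taxa with GC, OGT and tree placement, got {len(taxa)}")
    gx = np.array([gc[t] for t in taxa], dtype=float)
    gy = np.array([ogt[t] for t in taxa], dtype=float)
    if np.ptp(gx) == 0:
        raise ValueError("degenerate fit: all GC values identical")
    n = len(taxa)
    if np.ptp(gy) == 0:
        # flat response: slope 0, correlation undefined
        return ThermometerCalibration(0.0, float(gy[0]), np.nan, np.nan, np.nan, n)
    res = stats.linregress(gx, gy)
    r2_adj = 1 - (1 - res.rvalue**2) * (n - 1) / (n - 2)
    try:
        r_pic = pic_correlation(tree, dict(zip(taxa, gx)), dict(zip(taxa, gy)))
    except ValueError:
        r_pic = np.nan
    resid = gy - (res.slope * gx + res.intercept)
    sigma2 = float(np.sum(resid**2) / (n - 2))
    return ThermometerCalibration(
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        r_pic,
        float(r2_adj),
        n,
        sigma2_resid=sigma2,
        x_mean=float(gx.mean()),
        s_xx=float(np.sum((gx - gx.mean()) ** 2)),
    )


# -- Tamura-92 substitution model ----------------------------------------------


def t92_stationary(theta: float) -> np.ndarray:
    """Stationary distribution (A, C, G, T) at equilibrium GC fraction theta."""
    return np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])


def t92_generator(theta: float, kappa: float) -> np.ndarray:
    """T92 rate matrix, scaled to one expected substitution per unit time
    at its own stationary distribution.

    Transitions (A<->G, C<->T) run at kappa times the transversion rate;
    target frequencies are f_C = f_G = theta/2, f_A = f_T = (1-theta)/2.
    """
    if not 0 < theta < 1:
        raise ValueError(f"theta must be in (0,1), got {theta}")
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    pi = t92_stationary(theta)
    Q = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transition = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))
            Q[i, j] = (kappa if transition else 1.0) * pi[j]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(pi @ np.diag(Q))  # expected rate at stationarity
    return Q / mu


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) for a valid generator; rows sum to 1."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    return linalg.expm(np.asarray(Q, dtype=float) * t)


def t92_transition_probs(
    thetas: np.ndarray, kappa: float, ts: np.ndarray
) -> np.ndarray:
    """Batched T92 transition matrices, shape (n, 4, 4).

    Uses the reversibility of T92: Q = D^-1 S D with S symmetric and
    D = diag(sqrt(pi)), solved by a batched symmetric eigendecomposition.
    Each branch's generator is normalised to one expected substitution per
    unit time at its own stationary distribution (so t keeps its
    substitutions/site meaning).
    """
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    ts = np.atleast_1d(np.asarray(ts, dtype=float))
    n = thetas.size
    pi = np.empty((n, 4))
    pi[:, 0] = pi[:, 3] = (1 - thetas) / 2
    pi[:, 1] = pi[:, 2] = thetas / 2
    C = np.ones((4, 4))
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
        C[i, j] = kappa
    # off-diagonal Q_ij = C_ij * pi_j / mu
    mu = 0.5 + kappa * thetas * (1 - thetas)
    Q = C[None, :, :] * pi[:, None, :] / mu[:, None, None]
    diag = np.einsum("nij->ni", Q) - np.einsum("nii->ni", Q)
    Q[:, np.arange(4), np.arange(4)] = -diag
    sq = np.sqrt(pi)
    S = Q * sq[:, :, None] / sq[:, None, :]
    S = 0.5 * (S + np.transpose(S, (0, 2, 1)))  # kill rounding asymmetry
    w, U = np.linalg.eigh(S)
    ew = np.exp(w * ts[:, None])
    P = np.einsum("nik,nk,njk->nij", U, ew, U) * (sq[:, None, :] / sq[:, :, None])
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    P[ts == 0] = np.eye(4)  # exact identity, not identity +- rounding
    return P


# -- pruning likelihood ---------------------------------------------------------


@dataclass
class NonHomT92Model:
    """Nonhomogeneous T92: global kappa, free root GC, per-branch theta."""

    kappa: float
    theta_root: float
    theta_b: dict[int, float]  # keyed by child node id
    loglik: float = np.nan
    converged: bool = True

    def __post_init__(self):
        if not 0 < self.theta_root < 1 or self.kappa <= 0:
            raise ValueError("model parameters out of bounds")
        for nid, th in self.theta_b.items():
            if not 0 < th < 1:
                raise ValueError(f"theta out of bounds on node {nid}: {th}")


class _PruningEngine:
    """Shared machinery: column patterns, postorder schedule, partials."""

    def __init__(self, tree: Tree, aln: StemAlignment, *, use_mask: bool = True):
        labels = set(aln.labels)
        leaves = set(tree.leaf_labels())
        if labels != leaves:
            raise ValueError(
                f"tree/alignment label mismatch: only-in-tree={sorted(leaves - labels)} "
                f"only-in-alignment={sorted(labels - leaves)}"
            )
        self.tree = tree
        enc = aln.encoded()
        if use_mask and aln.stem_mask is not None:
            enc = enc[:, aln.stem_mask]
        self.columns = enc  # (n_taxa, L) in alignment row order
        self.row_of = {lab: i for i, lab in enumerate(aln.labels)}
        self.post = list(tree.postorder())
        self.nonroot = [n for n in self.post if tree.nodes[n].parent is not None]
        self.branch_index = {nid: k for k, nid in enumerate(self.nonroot)}
        self.ts = np.array(
            [tree.nodes[n].branch_length or 0.0 for n in self.nonroot]
        )
        # pattern compression for likelihood evaluation
        cols = self.columns.T  # (L, n_taxa)
        uniq, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = uniq.T  # (n_taxa, n_patterns)
        self.pattern_counts = counts.astype(float)
        self.pattern_inverse = inverse
        self.n_sites = cols.shape[0]
        self._leaf_cache: dict[bool, dict[int, np.ndarray]] = {}
        # per-node rescaling guards against underflow; with <= 64 leaves the
        # smallest partial stays far above the float64 floor, so skip it
        self.scale_partials = tree.n_leaves() > 64

    def _leaf_partial(self, nid: int, data: np.ndarray, per_site: bool) -> np.ndarray:
        cache = self._leaf_cache.setdefault(per_site, {})
        if nid not in cache:
            states = data[self.row_of[self.tree.nodes[nid].label]]
            out = np.zeros((states.size, 4))
            obs = states >= 0
            out[obs, states[obs]] = 1.0
            out[~obs, :] = 1.0  # missing: partial likelihood 1 for all states
            cache[nid] = out
        return cache[nid]

    def inside(
        self, P: np.ndarray, *, per_site: bool = False
    ) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray], np.ndarray]:
        """Upward pass.  Returns (partials, messages, logscale).

        ``partials[n]`` is the scaled conditional likelihood of data below n;
        ``messages[c]`` is P_c @ partial_c seen from the parent side.
        """
        data = self.columns if per_site else self.patterns
        npat = data.shape[1]
        partials: dict[int, np.ndarray] = {}
        messages: dict[int, np.ndarray] = {}
        logscale = np.zeros(npat)
        for nid in self.post:
            node = self.tree.nodes[nid]
            if node.is_leaf:
                part = self._leaf_partial(nid, data, per_site)
            else:
                part = messages[node.children[0]].copy()
                for c in node.children[1:]:
                    part *= messages[c]
                if self.scale_partials:
                    s = part.max(axis=1)
                    safe = np.where(s > 0, s, 1.0)
                    part /= safe[:, None]
                    logscale += np.log(safe)
            partials[nid] = part
            if node.parent is not None:
                messages[nid] = part @ P[self.branch_index[nid]].T
        return partials, messages, logscale


def _model_arrays(engine: _PruningEngine, model: NonHomT92Model):
    thetas = np.array([model.theta_b[n] for n in engine.nonroot])
    P = t92_transition_probs(thetas, model.kappa, engine.ts)
    return thetas, P


def pruning_loglik(
    tree: Tree, aln: StemAlignment, model: NonHomT92Model, *, use_mask: bool = True
) -> float:
    """Log-likelihood of the stem columns under the nonhomogeneous model.

    Gaps and N are missing data.  Sites impossible under the model
    contribute -inf.
    """
    engine = _PruningEngine(tree, aln, use_mask=use_mask)
    _, P = _model_arrays(engine, model)
    return _loglik_from_engine(engine, P, model.theta_root)


def _loglik_from_engine(
    engine: _PruningEngine, P: np.ndarray, theta_root: float
) -> float:
    partials, _, logscale = engine.inside(P)
    root_part = partials[engine.tree.root]
    site_lik = root_part @ t92_stationary(theta_root)
    with np.errstate(divide="ignore"):
        per_pattern = np.log(site_lik) + logscale
    return float(np.dot(engine.pattern_counts, per_pattern))


@dataclass
class FitConfig:
    multi_start: int = 3
    seed: int = 0
    maxiter: int = 300
    ftol: float = 1e-8
    kappa_bounds: tuple[float, float] = (0.05, 100.0)
    theta_bounds: tuple[float, float] = (0.01, 0.99)
    kappa_init: float = 2.0


def _tip_gc_fractions(engine: _PruningEngine) -> dict[int, float]:
    """Mean descendant tip GC fraction per node (fit initializer)."""
    out: dict[int, float] = {}
    tree = engine.tree
    for nid in engine.post:
        node = tree.nodes[nid]
        if node.is_leaf:
            states = engine.columns[engine.row_of[node.label]]
            obs = states >= 0
            out[nid] = (
                float(((states == 1) | (states == 2))[obs].mean()) if obs.any() else 0.5
            )
        else:
            out[nid] = float(np.mean([out[c] for c in node.children]))
    return out


def fit_nonhom_t92(
    tree: Tree, aln: StemAlignment, config: FitConfig | None = None
) -> NonHomT92Model:
    """ML fit of (kappa, theta_root, theta_b per branch); branch lengths fixed.

    Bounded L-BFGS-B with multi-start; theta_b initialised at the mean
    descendant tip GC fraction, further starts jittered from the config seed.
    """
    config = config or FitConfig()
    engine = _PruningEngine(tree, aln)
    nonroot = engine.nonroot
    m = len(nonroot)
    lo_t, hi_t = config.theta_bounds
    bounds = [config.kappa_bounds, (lo_t, hi_t)] + [(lo_t, hi_t)] * m

    def objective(x: np.ndarray) -> float:
        kappa, theta_root = x[0], x[1]
        P = t92_transition_probs(x[2:], kappa, engine.ts)
        ll = _loglik_from_engine(engine, P, theta_root)
        return np.inf if not np.isfinite(ll) else -ll

    gc = _tip_gc_fractions(engine)
    base = np.empty(2 + m)
    base[0] = config.kappa_init
    base[1] = np.clip(gc[tree.root], lo_t, hi_t)
    base[2:] = np.clip([gc[n] for n in nonroot], lo_t, hi_t)

    rng = np.random.default_rng(config.seed)
    best = None
    converged = False
    for start in range(max(1, config.multi_start)):
        x0 = base.copy()
        if start > 0:
            x0[0] = float(np.clip(x0[0] * np.exp(rng.normal(0, 0.5)), *config.kappa_bounds))
            x0[1:] = np.clip(x0[1:] + rng.normal(0, 0.08, size=m + 1), lo_t, hi_t)
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.maxiter, "ftol": config.ftol},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    x = best.x
    return NonHomT92Model(
        kappa=float(x[0]),
        theta_root=float(x[1]),
        theta_b={n: float(v) for n, v in zip(nonroot, x[2:])},
        loglik=-float(best.fun),
        converged=converged,
    )


# -- ancestral sampling ----------------------------------------------------------


@dataclass
class AncestralReplicateSet:
    """Joint posterior samples of ancestral stem sequences.

    ``sequences[node_id]`` is an (R, L) int8 array of sampled states; the
    exact per-site marginal posteriors are in ``marginals[node_id]`` (L, 4).
    """

    node_ids: list[int]
    R: int
    seed: int
    sequences: dict[int, np.ndarray] = field(repr=False)
    marginals: dict[int, np.ndarray] = field(repr=False)

    @property
    def length(self) -> int:
        return next(iter(self.sequences.values())).shape[1]


def _sample_categorical(rng, probs: np.ndarray, shape_prefix) -> np.ndarray:
    """Sample state indices; ties broken by cumulative order A<C<G<T."""
    cum = np.cumsum(probs, axis=-1)
    cum = cum / cum[..., -1:]
    u = rng.random(shape_prefix)
    return (u[..., None] > cum).sum(axis=-1).astype(np.int8)


def sample_ancestral_replicates(
    tree: Tree,
    aln: StemAlignment,
    model: NonHomT92Model,
    R: int = 100,
    seed: int = 0,
    *,
    use_mask: bool = True,
) -> AncestralReplicateSet:
    """Draw R joint samples of ancestral states at every internal node.

    The root is drawn from its exact marginal posterior, then children are
    drawn conditionally down the tree (site-independent), so cross-node
    correlation in GC is preserved within a replicate.  Exact marginal
    posteriors (inside-outside) are returned alongside.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    engine = _PruningEngine(tree, aln, use_mask=use_mask)
    _, P = _model_arrays(engine, model)
    partials, messages, _ = engine.inside(P, per_site=True)
    L = engine.n_sites
    pi_root = t92_stationary(model.theta_root)

    # outside pass for exact marginals
    outside: dict[int, np.ndarray] = {tree.root: np.tile(pi_root, (L, 1))}
    marginals: dict[int, np.ndarray] = {}
    internal_order = [n for n in tree.preorder() if not tree.nodes[n].is_leaf]
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.is_leaf:
            continue
        post = outside[nid] * partials[nid]
        post = post / post.sum(axis=1, keepdims=True)
        marginals[nid] = post
        for c in node.children:
            if tree.nodes[c].is_leaf:
                continue
            a = outside[nid].copy()
            for s in node.children:
                if s != c:
                    a *= messages[s]
            out_c = a @ P[engine.branch_index[c]]
            norm = out_c.sum(axis=1, keepdims=True)
            outside[c] = out_c / np.where(norm > 0, norm, 1.0)

    rng = np.random.default_rng(seed)
    sequences: dict[int, np.ndarray] = {}
    root_probs = pi_root[None, :] * partials[tree.root]
    sequences[tree.root] = _sample_categorical(
        rng, np.broadcast_to(root_probs, (R, L, 4)), (R, L)
    )
    for nid in internal_order:
        for c in tree.nodes[nid].children:
            if tree.nodes[c].is_leaf:
                continue
            parent_states = sequences[nid]  # (R, L)
            Pc = P[engine.branch_index[c]]
            probs = Pc[parent_states] * partials[c][None, :, :]
            sequences[c] = _sample_categorical(rng, probs, (R, L))
    internal_ids = [n for n in internal_order]
    return AncestralReplicateSet(
        node_ids=internal_ids,
        R=R,
        seed=seed,
        sequences={n: sequences[n] for n in internal_ids},
        marginals={n: marginals[n] for n in internal_ids},
    )


@dataclass
class OgtEstimate:
    node_id: int
    label: str | None
    point: float
    ci_low: float
    ci_high: float
    replicate_ogts: np.ndarray = field(repr=False)


def predict_ancestral_ogt(
    replicates: AncestralReplicateSet,
    calibration: ThermometerCalibration,
    tree: Tree | None = None,
    seed: int = 0,
) -> list[OgtEstimate]:
    """Thermometer applied to each sampled ancestral sequence.

    Per internal node: OGT_r = a_r * stemGC(replicate r) + b_r, where
    (a_r, b_r) is drawn from the OLS coefficient sampling distribution and a
    residual draw N(0, sigma_resid) is added, so the replicate spread
    carries both ancestral-sequence and calibration-prediction uncertainty
    (the regression maps GC to OGT only up to its residual scatter).  The
    point estimate is the replicate mean and the CI the 2.5/97.5 percentile
    interval.  A calibration with zero recorded residual variance (any
    hand-built one) reduces to the plain plug-in prediction.
    """
    rng = np.random.default_rng(seed)
    R = replicates.R
    s2, xm, sxx, n = (
        calibration.sigma2_resid,
        calibration.x_mean,
        calibration.s_xx,
        calibration.n_taxa,
    )
    if s2 > 0 and np.isfinite(sxx) and sxx > 0:
        var_a = s2 / sxx
        var_b = s2 * (1.0 / n + xm**2 / sxx)
        cov_ab = -s2 * xm / sxx
        cov = np.array([[var_a, cov_ab], [cov_ab, var_b]])
        draws = rng.multivariate_normal(
            [calibration.slope, calibration.intercept], cov, size=R
        )
        a_r, b_r = draws[:, 0], draws[:, 1]
        resid_sd = math.sqrt(s2)
    else:
        a_r = np.full(R, calibration.slope)
        b_r = np.full(R, calibration.intercept)
        resid_sd = 0.0
    out = []
    for nid in replicates.node_ids:
        seqs = replicates.sequences[nid]  # (R, L), always concrete states
        gc = 100.0 * ((seqs == 1) | (seqs == 2)).mean(axis=1)
        ogts = a_r * gc + b_r
        if resid_sd > 0:
            ogts = ogts + rng.normal(0.0, resid_sd, size=R)
        lo, hi = np.percentile(ogts, [2.5, 97.5])
        label = tree.nodes[nid].label if tree is not None else None
        out.append(OgtEstimate(nid, label, float(ogts.mean()), float(lo), float(hi), ogts))
    return out


# -- end-to-end track ------------------------------------------------------------


def run_thermometer_track(
    tree: Tree,
    aln: StemAlignment,
    ogt: Mapping[str, float],
    *,
    R: int = 100,
    seed: int = 0,
    fit_config: FitConfig | None = None,
):
    """Calibrate, fit the nonhomogeneous model, sample ancestors, predict OGTs.

    The tree is pruned to the taxa present in the alignment (taxa without a
    16S sequence drop out of this track); calibration uses the subset that
    also has an OGT.  Returns (pruned tree, calibration, model, replicates,
    estimates, dropped taxa).
    """
    with_16s = sorted(set(tree.leaf_labels()) & set(aln.labels))
    dropped = sorted(set(tree.leaf_labels()) - set(with_16s))
    if len(with_16s) < 3:
        raise ValueError("fewer than 3 taxa with 16S sequences")
    sub = (
        tree.copy()
        if not dropped
        else prune_to_taxa(tree, with_16s)
    )
    keep_rows = [aln.labels.index(t) for t in with_16s]
    aln_sub = StemAlignment(
        [aln.labels[i] for i in keep_rows],
        [aln.sequences[i] for i in keep_rows],
        aln.stem_mask,
    )
    mask = (
        aln_sub.stem_mask
        if aln_sub.stem_mask is not None
        else np.ones(aln_sub.length, dtype=bool)
    )
    gc = {lab: stem_gc(seq, mask) for lab, seq in zip(aln_sub.labels, aln_sub.sequences)}
    calibration = calibrate_thermometer(sub, gc, ogt)
    model = fit_nonhom_t92(sub, aln_sub, fit_config)
    replicates = sample_ancestral_replicates(sub, aln_sub, model, R=R, seed=seed)
    estimates = predict_ancestral_ogt(replicates, calibration, sub)
    return sub, calibration, model, replicates, estimates, dropped
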