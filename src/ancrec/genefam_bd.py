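"""Gene-family gain-loss-duplication inference on a rooted species tree.

Each protein family evolves its copy number along the tree as an independent
continuous-time birth-death chain on {0..C_max}: innovation 0->1 at rate g
(gain), per-copy duplication at rate lam, per-copy loss at rate mu.  Per
family the three rates are fitted by maximum likelihood from the extant
occurrence matrix; an inside-outside pass then gives the exact posterior
copy-number distribution at every ancestral node and the exact joint
parent-child posterior on every branch, from which gains, losses,
expansions and contractions are called at a posterior threshold (default
0.5, strict).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo_core import Tree

__all__ = [
    "BDRates",
    "BDFitConfig",
    "bd_generator",
    "bd_stationary",
    "bd_transition_probs",
    "family_loglik",
    "fit_rates",
    "fit_global_rates",
    "node_posteriors",
    "call_events",
    "ancestral_content",
    "gain_rates",
    "compare_gain_rates",
    "gains_vs_substitutions",
]


@dataclass(frozen=True)
class BDRates:
    """Per-family rates (per unit branch length, substitutions/site)."""

    gain: float  # innovation 0 -> 1
    dup: float  # per-copy duplication
    loss: float  # per-copy loss
    cmax: int = 10  # truncation cap of the tracked copy-number space

    def __post_init__(self):
        if min(self.gain, self.dup, self.loss) < 0:
            raise ValueError("rates must be >= 0")
        if self.cmax < 2:
            raise ValueError("cmax must be >= 2")


def bd_generator(rates: BDRates) -> np.ndarray:
    """(C+1)x(C+1) rate matrix: up n->n+1 at g + n*lam, down n->n-1 at n*mu.

    The top state C_max has no up-transition (truncation).
    """
    C = rates.cmax
    Q = np.zeros((C + 1, C + 1))
    n = np.arange(C + 1)
    up = rates.gain + n[:-1] * rates.dup
    down = n[1:] * rates.loss
    Q[n[:-1], n[:-1] + 1] = up
    Q[n[1:], n[1:] - 1] = down
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def bd_stationary(rates: BDRates) -> np.ndarray:
    """Stationary distribution of the truncated chain (detailed balance).

    With g = 0 state 0 is absorbing and the stationary law is a point mass
    at 0; with mu = 0 all mass piles at the cap.
    """
    C = rates.cmax
    if rates.gain == 0:
        out = np.zeros(C + 1)
        out[0] = 1.0
        return out
    if rates.loss == 0:
        out = np.zeros(C + 1)
        out[-1] = 1.0
        return out
    logw = np.zeros(C + 1)
    for n in range(C):
        logw[n + 1] = logw[n] + math.log(rates.gain + n * rates.dup) - math.log(
            (n + 1) * rates.loss
        )
    w = np.exp(logw - logw.max())
    return w / w.sum()


def bd_transition_probs(rates: BDRates, ts: np.ndarray) -> np.ndarray:
    """Batched exp(Q t) over branch lengths ts, shape (len(ts), C+1, C+1).

    The birth-death chain is reversible, so Q is symmetrised by the square
    root of its detailed-balance weights and solved with one symmetric
    eigendecomposition shared by all branches; degenerate corners (g=0 or
    mu=0) fall back to scipy's expm.
    """
    ts = np.atleast_1d(np.asarray(ts, dtype=float))
    Q = bd_generator(rates)
    if rates.gain <= 0 or rates.loss <= 0:
        return np.stack([linalg.expm(Q * t) for t in ts])
    C = rates.cmax
    logw = np.zeros(C + 1)
    for n in range(C):
        logw[n + 1] = logw[n] + math.log(rates.gain + n * rates.dup) - math.log(
            (n + 1) * rates.loss
        )
    half = 0.5 * (logw - logw.max())
    d = np.exp(half)  # sqrt of unnormalised stationary weights
    S = Q * d[:, None] / d[None, :]
    S = 0.5 * (S + S.T)
    w, U = np.linalg.eigh(S)
    ew = np.exp(np.clip(w[None, :] * ts[:, None], -700, 50))
    P = np.einsum("ik,tk,jk->tij", U, ew, U) * (d[None, :] / d[:, None])
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    P[ts == 0] = np.eye(C + 1)
    return P


# -- pruning -------------------------------------------------------------------


class _BDEngine:
    """Postorder schedule shared across families for one tree."""

    def __init__(self, tree: Tree):
        self.tree = tree
        self.post = list(tree.postorder())
        self.pre = list(tree.preorder())
        self.nonroot = [n for n in self.post if tree.nodes[n].parent is not None]
        self.branch_index = {nid: k for k, nid in enumerate(self.nonroot)}
        self.ts = np.array([tree.nodes[n].branch_length or 0.0 for n in self.nonroot])
        self.leaf_label = {
            n: tree.nodes[n].label for n in self.post if tree.nodes[n].is_leaf
        }

    def leaf_partial(self, count: int, cmax: int) -> np.ndarray:
        v = np.zeros(cmax + 1)
        v[min(int(count), cmax)] = 1.0
        return v

    def inside(self, counts: Mapping[str, int], P: np.ndarray, cmax: int):
        partials: dict[int, np.ndarray] = {}
        messages: dict[int, np.ndarray] = {}
        logscale = 0.0
        for nid in self.post:
            node = self.tree.nodes[nid]
            if node.is_leaf:
                part = self.leaf_partial(counts[node.label], cmax)
            else:
                part = np.ones(cmax + 1)
                for c in node.children:
                    part = part * messages[c]
                s = part.max()
                if s > 0:
                    part = part / s
                    logscale += math.log(s)
            partials[nid] = part
            if node.parent is not None:
                messages[nid] = P[self.branch_index[nid]] @ part
        return partials, messages, logscale


def _root_prior_vector(root_prior, rates: BDRates) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior == "stationary":
            return bd_stationary(rates)
        if root_prior == "uniform":
            return np.full(rates.cmax + 1, 1.0 / (rates.cmax + 1))
        raise ValueError(f"unknown root prior {root_prior!r}")
    v = np.asarray(root_prior, dtype=float)
    if v.size != rates.cmax + 1 or abs(v.sum() - 1) > 1e-9 or (v < 0).any():
        raise ValueError("root prior must be a distribution over 0..cmax")
    return v


def _check_counts(tree: Tree, counts: Mapping[str, int]) -> None:
    missing = set(tree.leaf_labels()) - set(counts)
    if missing:
        raise KeyError(f"counts missing for leaves: {sorted(missing)}")


def family_loglik(
    tree: Tree,
    counts: Mapping[str, int],
    rates: BDRates,
    root_prior="stationary",
    *,
    engine: "_BDEngine | None" = None,
    P: np.ndarray | None = None,
) -> float:
    """Log-likelihood of one family's leaf copy numbers."""
    _check_counts(tree, counts)
    engine = engine or _BDEngine(tree)
    if P is None:
        P = bd_transition_probs(rates, engine.ts)
    prior = _root_prior_vector(root_prior, rates)
    partials, _, logscale = engine.inside(counts, P, rates.cmax)
    lik = float(prior @ partials[tree.root])
    return -np.inf if lik <= 0 else math.log(lik) + logscale


# -- rate fitting ---------------------------------------------------------------


@dataclass
class BDFitConfig:
    cmax: int = 10
    multi_start: int = 2
    seed: int = 0
    maxiter: int = 200
    rate_bounds: tuple[float, float] = (1e-6, 50.0)
    fit_duplication: bool = True  # if False, lam is pinned to 0
    root_prior: str = "stationary"
    # partial pooling across families: per-family log-rates are shrunk
    # toward the pooled (all-families) ML by curvature-weighted
    # empirical-Bayes shrinkage.  With few genomes per-family ML is
    # information-starved; sharing strength across families is the
    # standard remedy (rate variation across families around shared
    # hyper-rates).
    empirical_bayes: bool = False


def _fit_one_family(
    engine: _BDEngine, counts: Mapping[str, int], config: BDFitConfig, rng
) -> dict:
    lo, hi = np.log(config.rate_bounds[0]), np.log(config.rate_bounds[1])
    ndim = 3 if config.fit_duplication else 2

    def unpack(x):
        if config.fit_duplication:
            g, lam, mu = np.exp(x)
        else:
            (g, mu), lam = np.exp(x), 0.0
        return BDRates(float(g), float(lam), float(mu), config.cmax)

    def objective(x):
        rates = unpack(x)
        ll = family_loglik(
            engine.tree, counts, rates, config.root_prior, engine=engine
        )
        return np.inf if not np.isfinite(ll) else -ll

    occ = np.mean([1.0 if counts[l] > 0 else 0.0 for l in engine.leaf_label.values()])
    depth = max(float(engine.ts.sum()), 1e-6)
    g0 = np.clip(-np.log(max(1 - occ, 0.05)) * engine.tree.n_leaves() / depth, 0.05, 5.0)
    base = np.log(np.array([g0, 0.2, 1.0]) if ndim == 3 else np.array([g0, 1.0]))

    best = None
    converged = False
    for start in range(max(1, config.multi_start)):
        x0 = base + (rng.normal(0, 0.7, size=ndim) if start else 0.0)
        x0 = np.clip(x0, lo, hi)
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * ndim,
            options={"maxiter": config.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    rates = unpack(best.x)
    # full Hessian of -loglik in log-rate space; the marginal variances come
    # from the inverse (log g and log mu are strongly correlated: the ratio
    # is well determined by tip occupancy, the magnitude much less so)
    h = 0.15
    f0 = best.fun
    H = np.zeros((ndim, ndim))
    def at(dx):
        return objective(best.x + dx)
    for k in range(ndim):
        e = np.zeros(ndim); e[k] = h
        H[k, k] = (at(e) - 2 * f0 + at(-e)) / h**2
    for k in range(ndim):
        for l in range(k + 1, ndim):
            ek = np.zeros(ndim); ek[k] = h
            el = np.zeros(ndim); el[l] = h
            H[k, l] = H[l, k] = (
                at(ek + el) - at(ek - el) - at(-ek + el) + at(-ek - el)
            ) / (4 * h**2)
    try:
        cov = np.linalg.inv(H)
        se2 = [float(cov[k, k]) for k in range(ndim)]
        if min(se2) <= 0 or not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        se2 = [100.0] * ndim
    names = ["gain", "dup", "loss"] if config.fit_duplication else ["gain", "loss"]
    out = {
        "gain": rates.gain,
        "dup": rates.dup,
        "loss": rates.loss,
        "loglik": -float(best.fun),
        "converged": converged,
    }
    for name, v in zip(names, se2):
        out[f"se2_log_{name}"] = min(max(v, 1e-6), 100.0)
    return out


def fit_global_rates(
    tree: Tree, matrix: pd.DataFrame, config: BDFitConfig | None = None
) -> dict:
    """Shared (g, lam, mu) maximising the summed log-likelihood of all
    families — the pooled estimate that anchors empirical-Bayes shrinkage."""
    config = config or BDFitConfig()
    leaves = tree.leaf_labels()
    sub = matrix.loc[leaves]
    profiles: dict[tuple, int] = {}
    for fam in sub.columns:
        key = tuple(int(v) for v in sub[fam])
        profiles[key] = profiles.get(key, 0) + 1
    engine = _BDEngine(tree)
    lo, hi = np.log(config.rate_bounds[0]), np.log(config.rate_bounds[1])
    ndim = 3 if config.fit_duplication else 2

    def unpack(x):
        if config.fit_duplication:
            g, lam, mu = np.exp(x)
        else:
            (g, mu), lam = np.exp(x), 0.0
        return BDRates(float(g), float(lam), float(mu), config.cmax)

    def objective(x):
        rates = unpack(x)
        P = bd_transition_probs(rates, engine.ts)
        prior = _root_prior_vector(config.root_prior, rates)
        total = 0.0
        for key, mult in profiles.items():
            counts = dict(zip(leaves, key))
            partials, _, logscale = engine.inside(counts, P, rates.cmax)
            lik = float(prior @ partials[tree.root])
            if lik <= 0:
                return np.inf
            total += mult * (math.log(lik) + logscale)
        return -total

    x0 = np.log([0.5, 0.2, 1.0]) if ndim == 3 else np.log([0.5, 1.0])
    res = optimize.minimize(
        objective, x0, method="L-BFGS-B", bounds=[(lo, hi)] * ndim,
        options={"maxiter": config.maxiter},
    )
    rates = unpack(res.x)
    return {
        "gain": rates.gain,
        "dup": rates.dup,
        "loss": rates.loss,
        "loglik": -float(res.fun),
        "converged": bool(res.success),
    }


def _shrink_log_rates(rates_df: pd.DataFrame, pooled: dict, names) -> pd.DataFrame:
    """Curvature-weighted shrinkage of per-family log-rates toward the
    pooled ML (James-Stein on the log scale; the across-family variance
    tau^2 is estimated by moments and floors at zero)."""
    out = rates_df.copy()
    for name in names:
        x = np.log(np.maximum(out[name].to_numpy(), 1e-12))
        se2 = out[f"se2_log_{name}"].to_numpy()
        m = math.log(max(pooled[name], 1e-12))
        tau2 = max(0.0, float(np.var(x - m)) - float(np.mean(se2)))
        w = tau2 / (tau2 + se2)
        out[name] = np.exp(m + w * (x - m))
    return out


def fit_rates(
    tree: Tree, matrix: pd.DataFrame, config: BDFitConfig | None = None
) -> pd.DataFrame:
    """Per-family ML rates from a genomes x families occurrence matrix.

    Families observed in zero genomes are rejected.  Identical leaf-count
    profiles share one fit (the likelihood only sees the profile).  Returns
    a DataFrame indexed by family with columns gain/dup/loss/loglik/converged.
    """
    config = config or BDFitConfig()
    leaves = tree.leaf_labels()
    missing = set(leaves) - set(matrix.index)
    if missing:
        raise KeyError(f"tree leaves missing from matrix: {sorted(missing)}")
    sub = matrix.loc[leaves]
    empty = sub.columns[(sub.sum(axis=0) == 0)]
    if len(empty):
        raise ValueError(
            f"families observed in zero genomes: {list(empty[:5])}"
            + ("..." if len(empty) > 5 else "")
        )
    rng = np.random.default_rng(config.seed)
    engine = _BDEngine(tree)
    cache: dict[tuple, dict] = {}
    rows = []
    for fam in sub.columns:
        profile = tuple(int(v) for v in sub[fam])
        if profile not in cache:
            counts = dict(zip(leaves, profile))
            cache[profile] = _fit_one_family(engine, counts, config, rng)
        rows.append({"family": fam, **cache[profile]})
    out = pd.DataFrame(rows).set_index("family")
    if config.empirical_bayes:
        pooled = fit_global_rates(tree, matrix, config)
        names = ["gain", "dup", "loss"] if config.fit_duplication else ["gain", "loss"]
        out = _shrink_log_rates(out, pooled, names)
    return out


# -- posteriors and event calls --------------------------------------------------


def _inside_outside(
    tree: Tree,
    counts: Mapping[str, int],
    rates: BDRates,
    root_prior,
    engine: _BDEngine | None = None,
):
    engine = engine or _BDEngine(tree)
    P = bd_transition_probs(rates, engine.ts)
    prior = _root_prior_vector(root_prior, rates)
    partials, messages, _ = engine.inside(counts, P, rates.cmax)
    outside: dict[int, np.ndarray] = {tree.root: prior.copy()}
    for nid in engine.pre:
        node = tree.nodes[nid]
        for c in node.children:
            a = outside[nid].copy()
            for s in node.children:
                if s != c:
                    a *= messages[s]
            v = a @ P[engine.branch_index[c]]
            tot = v.sum()
            outside[c] = v / tot if tot > 0 else v
    return engine, P, partials, messages, outside


def node_posteriors(
    tree: Tree,
    counts: Mapping[str, int],
    rates: BDRates,
    root_prior="stationary",
) -> dict[int, np.ndarray]:
    """Exact marginal posterior over copy number 0..cmax at every node.

    Leaf posteriors are point masses at the (possibly truncated) observed
    count.
    """
    _check_counts(tree, counts)
    engine, P, partials, messages, outside = _inside_outside(
        tree, counts, rates, root_prior
    )
    out: dict[int, np.ndarray] = {}
    for nid in engine.post:
        v = outside[nid] * partials[nid]
        tot = v.sum()
        if tot <= 0:
            raise ValueError("data impossible under the model (zero likelihood)")
        out[nid] = v / tot
    return out


_EVENT_COLS = ["P_gain", "P_loss", "P_expand", "P_contract"]


def call_events(
    tree: Tree,
    counts: Mapping[str, int],
    rates: BDRates,
    root_prior="stationary",
    tau: float = 0.5,
    family: str | None = None,
) -> pd.DataFrame:
    """Per-branch event probabilities from exact joint parent-child posteriors.

    Events: gain parent=0 & child>=1; loss parent>=1 & child=0; expansion
    child>parent>=1; contraction parent>child>=1.  A call requires the
    probability to be strictly above tau.
    """
    _check_counts(tree, counts)
    engine, P, partials, messages, outside = _inside_outside(
        tree, counts, rates, root_prior
    )
    C = rates.cmax
    i_idx = np.arange(C + 1)[:, None]
    j_idx = np.arange(C + 1)[None, :]
    masks = {
        "P_gain": (i_idx == 0) & (j_idx >= 1),
        "P_loss": (i_idx >= 1) & (j_idx == 0),
        "P_expand": (j_idx > i_idx) & (i_idx >= 1),
        "P_contract": (i_idx > j_idx) & (j_idx >= 1),
    }
    rows = []
    for c in engine.nonroot:
        p = tree.nodes[c].parent
        a = outside[p].copy()
        for s in tree.nodes[p].children:
            if s != c:
                a *= messages[s]
        joint = a[:, None] * P[engine.branch_index[c]] * partials[c][None, :]
        tot = joint.sum()
        if tot <= 0:
            raise ValueError("data impossible under the model (zero likelihood)")
        joint /= tot
        row = {
            "family": family,
            "parent": p,
            "child": c,
            "child_is_leaf": tree.nodes[c].is_leaf,
            "branch_length": tree.nodes[c].branch_length or 0.0,
        }
        for name, m in masks.items():
            row[name] = float(joint[m].sum())
        for name in _EVENT_COLS:
            row["call" + name[1:]] = row[name] > tau
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AncestralGenome:
    node_id: int
    present: set[str]
    multicopy: set[str]


def ancestral_content(
    posteriors: Mapping[str, Mapping[int, np.ndarray]], tau: float = 0.5
) -> dict[int, AncestralGenome]:
    """Presence / multicopy calls per node at threshold tau (strict >).

    ``posteriors`` maps family -> {node id -> copy-number posterior}.
    Present iff P(n>=1) > tau; multicopy iff P(n>=2) > tau.
    """
    nodes: set[int] = set()
    for fam_post in posteriors.values():
        nodes.update(fam_post)
    out = {}
    for nid in sorted(nodes):
        present, multi = set(), set()
        for fam, fam_post in posteriors.items():
            v = fam_post[nid]
            if float(v[1:].sum()) > tau:
                present.add(fam)
                if float(v[2:].sum()) > tau:
                    multi.add(fam)
        out[nid] = AncestralGenome(nid, present, multi)
    return out


# -- gain-rate statistics ---------------------------------------------------------


def gain_rates(events: pd.DataFrame, tree: Tree) -> pd.DataFrame:
    """Called gains per branch divided by branch length (substitutions/site).

    Branches are classed ancestral (internal child) vs terminal (leaf
    child); zero-length branches get rate NaN and are flagged, not dropped.
    """
    grouped = (
        events.groupby("child")
        .agg(
            n_gains=("call_gain", "sum"),
            branch_length=("branch_length", "first"),
            child_is_leaf=("child_is_leaf", "first"),
        )
        .reset_index()
    )
    grouped["branch_class"] = np.where(
        grouped["child_is_leaf"], "terminal", "ancestral"
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        grouped["gain_rate"] = np.where(
            grouped["branch_length"] > 0,
            grouped["n_gains"] / grouped["branch_length"],
            np.nan,
        )
    grouped["rate_defined"] = grouped["branch_length"] > 0
    return grouped


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """Exact rank-sum p by enumeration of all group-A label assignments."""
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)  # midranks handle ties
    n_a = len(a)
    obs = float(ranks[:n_a].sum())
    sums = np.array(
        [ranks[list(idx)].sum() for idx in itertools.combinations(range(len(combined)), n_a)]
    )
    eps = 1e-9
    if alternative == "less":
        return float(np.mean(sums <= obs + eps))
    if alternative == "greater":
        return float(np.mean(sums >= obs - eps))
    mean = sums.mean()
    return float(np.mean(np.abs(sums - mean) >= abs(obs - mean) - eps))


def compare_gain_rates(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: str = "rank-sum",
    alternative: str = "two-sided",
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Compare two groups of per-branch gain rates.

    ``rank-sum`` (independent groups, the primary method) uses exact
    enumeration when n_A + n_B <= exact_max_n, else the normal approximation
    with tie correction.  ``signed-rank`` treats the groups as paired.
    Returns (statistic, p-value).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if method == "signed-rank":
        if len(a) != len(b):
            raise ValueError("signed-rank requires paired groups of equal size")
        res = stats.wilcoxon(a, b, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    if method != "rank-sum":
        raise ValueError(f"unknown method {method!r}")
    ranks = stats.rankdata(np.concatenate([a, b]))
    statistic = float(ranks[: len(a)].sum())
    if len(a) + len(b) <= exact_max_n:
        return statistic, _exact_rank_sum_p(a, b, alternative)
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return statistic, float(res.pvalue)


def gains_vs_substitutions(
    events: pd.DataFrame, tree: Tree, content: Mapping[int, AncestralGenome]
) -> dict:
    """Per ancestral branch: proportion of gains vs branch length.

    x = branch length (substitutions/site); y = called gains on the branch
    divided by the number of families present at the child node.  Returns
    Pearson r, adjusted R^2 and the OLS line.
    """
    rates = gain_rates(events, tree)
    anc = rates[~rates["child_is_leaf"]]
    if len(anc) < 3:
        raise ValueError("need >= 3 ancestral branches")
    xs, ys = [], []
    for _, row in anc.iterrows():
        child = int(row["child"])
        n_present = len(content[child].present) if child in content else 0
        if n_present == 0:
            continue
        xs.append(float(row["branch_length"]))
        ys.append(float(row["n_gains"]) / n_present)
    xs, ys = np.asarray(xs), np.asarray(ys)
    if len(xs) < 3:
        raise ValueError("need >= 3 ancestral branches with nonempty child content")
    if np.ptp(ys) == 0 or np.ptp(xs) == 0:
        return {
            "n": len(xs),
            "r_pearson": np.nan,
            "slope": 0.0,
            "intercept": float(ys.mean()) if len(ys) else np.nan,
            "r2_adjusted": np.nan,
            "degenerate": True,
        }
    res = stats.linregress(xs, ys)
    r2_adj = 1 - (1 - res.rvalue**2) * (len(xs) - 1) / (len(xs) - 2)
    return {
        "n": len(xs),
        "r_pearson": float(res.rvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2_adjusted": float(r2_adj),
        "degenerate": False,
    }
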