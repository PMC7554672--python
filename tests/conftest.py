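import itertools
import math

import numpy as np
import pytest

from ancrec.phylo_core import Tree, parse_newick
from ancrec.thermometer import (
    NonHomT92Model,
    StemAlignment,
    t92_generator,
    t92_stationary,
)
from scipy.linalg import expm


@pytest.fixture
def four_leaf_tree() -> Tree:
    return parse_newick("((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.6);")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def enumeration_loglik_t92(tree: Tree, aln: StemAlignment, model: NonHomT92Model):
    """Brute-force likelihood: sum over all internal-state assignments."""
    enc = aln.encoded()
    row = {lab: i for i, lab in enumerate(aln.labels)}
    internals = [n.id for n in tree.nodes if not n.is_leaf]
    P = {
        n.id: expm(t92_generator(model.theta_b[n.id], model.kappa) * n.branch_length)
        for n in tree.nodes
        if n.parent is not None
    }
    pi = t92_stationary(model.theta_root)
    total = 0.0
    for site in range(enc.shape[1]):
        site_lik = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            amap = dict(zip(internals, assign))
            p = pi[amap[tree.root]]
            for n in tree.nodes:
                if n.parent is None:
                    continue
                if n.is_leaf:
                    obs = enc[row[n.label], site]
                    p *= 1.0 if obs < 0 else P[n.id][amap[n.parent], obs]
                else:
                    p *= P[n.id][amap[n.parent], amap[n.id]]
            site_lik += p
        total += math.log(site_lik)
    return total


def enumeration_bd(tree: Tree, counts, Q: np.ndarray, prior: np.ndarray):
    """Brute-force joint distribution over internal copy-number states.

    Returns (loglik, {internal node id: marginal posterior vector},
    {(parent, child): joint posterior matrix}) by full enumeration.
    """
    C = Q.shape[0] - 1
    internals = [n.id for n in tree.nodes if not n.is_leaf]
    P = {
        n.id: expm(Q * (n.branch_length or 0.0))
        for n in tree.nodes
        if n.parent is not None
    }
    marg = {nid: np.zeros(C + 1) for nid in internals}
    joints = {
        (n.parent, n.id): np.zeros((C + 1, C + 1))
        for n in tree.nodes
        if n.parent is not None
    }
    total = 0.0
    for assign in itertools.product(range(C + 1), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        p = prior[amap[tree.root]]
        state = dict(amap)
        for n in tree.nodes:
            if n.parent is None:
                continue
            if n.is_leaf:
                state[n.id] = min(counts[n.label], C)
            p *= P[n.id][state[n.parent], state[n.id]]
        total += p
        for nid in internals:
            marg[nid][amap[nid]] += p
        for n in tree.nodes:
            if n.parent is not None:
                joints[(n.parent, n.id)][state[n.parent], state[n.id]] += p
    for nid in internals:
        marg[nid] /= total
    for key in joints:
        joints[key] /= total
    return math.log(total), marg, joints
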