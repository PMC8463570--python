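"""Permutation nulls: curveball matrix randomization and host-tree shuffles.

The clade-size null holds the symbiont tree fixed and permutes the
incidence matrix under a fixed-margins binary null (the curveball
algorithm), so that every permuted matrix keeps each ASV's occurrence
count and each sample's richness. Re-running classification and the
clade scan on permuted matrices calibrates how large a host-restricted
clade can get by chance.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .host_restriction import classify_all, find_maximal_clades
from .model import (HOST_RESTRICTED, AnalysisConfig, CladeSizeNull, HostTree,
                    IncidenceMatrix, SampleTable, SymbiontTree, add_one_p)


def curveball_permute(matrix: IncidenceMatrix, n_trials: int,
                      rng: np.random.Generator) -> IncidenceMatrix:
    """Randomize a binary matrix preserving all row and column sums.

    Each curveball trade picks two random rows and reallocates the columns
    in the symmetric difference of their presence sets at random, keeping
    each row's count. Margins are conserved exactly by construction.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    values = matrix.values()
    n_rows = values.shape[0]
    if n_rows < 2:
        return matrix.with_values(values.copy())
    rows = [set(np.flatnonzero(values[i]).tolist()) for i in range(n_rows)]
    for _ in range(n_trials):
        i = int(rng.integers(n_rows))
        j = int(rng.integers(n_rows - 1))
        if j >= i:
            j += 1
        only_i = rows[i] - rows[j]
        only_j = rows[j] - rows[i]
        diff = np.array(sorted(only_i | only_j), dtype=np.int64)
        if diff.size == 0:
            continue
        take = rng.permutation(diff)
        new_i = set(take[:len(only_i)].tolist())
        rows[i] = (rows[i] - only_i) | new_i
        rows[j] = (rows[j] - only_j) | (set(diff.tolist()) - new_i)
    out = np.zeros_like(values)
    for i, cols in enumerate(rows):
        out[i, sorted(cols)] = 1
    return matrix.with_values(out)


def default_n_trials(matrix: IncidenceMatrix) -> int:
    """Standard mixing heuristic: five trades per matrix row."""
    return 5 * matrix.shape[0]


def clade_size_null(tree: SymbiontTree, incidence: IncidenceMatrix,
                    samples: SampleTable, config: AnalysisConfig,
                    rng: np.random.Generator,
                    n_trials: int | None = None) -> CladeSizeNull:
    """Calibrate host-restricted clade sizes against the curveball null.

    For each of ``config.n_permutations`` permuted matrices the full
    classification + clade scan is re-run on the fixed tree; the summary
    kept per permutation is the largest host-restricted clade size (0 when
    none is found) and the number of accepted host-restricted clades.
    Each observed clade size s receives the add-one empirical p
    (1 + #{permutation max >= s}) / (1 + n_permutations).
    """
    if n_trials is None:
        n_trials = default_n_trials(incidence)
    observed = [c for c in find_maximal_clades(
        tree, classify_all(incidence, samples), incidence, samples, config)
        if c.category == HOST_RESTRICTED]
    observed_sizes = tuple(sorted({len(c.member_asvs) for c in observed}))

    n_perm = config.n_permutations
    perm_max = np.zeros(n_perm, dtype=np.int64)
    perm_count = np.zeros(n_perm, dtype=np.int64)
    for k in range(n_perm):
        permuted = curveball_permute(incidence, n_trials, rng)
        clades = [c for c in find_maximal_clades(
            tree, classify_all(permuted, samples), permuted, samples, config)
            if c.category == HOST_RESTRICTED]
        perm_count[k] = len(clades)
        perm_max[k] = max((len(c.member_asvs) for c in clades), default=0)

    empirical_p = {s: add_one_p(perm_max, s, "ge") for s in observed_sizes}
    return CladeSizeNull(
        n_permutations=n_perm, perm_max_size=perm_max,
        perm_n_clades=perm_count, observed_sizes=observed_sizes,
        empirical_p=empirical_p)


def _reparse(host: HostTree) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=host.as_newick(), schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    for node in tree.preorder_internal_node_iter():
        node.support = None
    return tree


def randomize_host_tree(host: HostTree, mode: str = "shuffle",
                        rng: np.random.Generator | None = None) -> HostTree:
    """Random host phylogeny for the co-speciation control.

    mode='shuffle' (default) keeps topology and branch lengths and permutes
    the tip labels uniformly over non-identity permutations, preserving
    the multiset of patristic distances. mode='yule' draws a fresh
    pure-birth topology over the same labels, rescaled to the original
    root age (ultrametric by construction).
    """
    rng = np.random.default_rng() if rng is None else rng
    labels = sorted(host.tip_labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 tips to randomize a host tree")
    if mode == "shuffle":
        perm = rng.permutation(n)
        while np.array_equal(perm, np.arange(n)):
            perm = rng.permutation(n)
        mapping = {labels[i]: labels[perm[i]] for i in range(n)}
        tree = _reparse(host)
        for leaf in tree.leaf_node_iter():
            leaf.taxon.label = mapping[leaf.taxon.label]
        return HostTree(tree)
    if mode == "yule":
        return _yule_tree(labels, host.root_age, rng)
    raise ValueError(f"unknown mode {mode!r}")


def _yule_tree(labels: list[str], root_age: float,
               rng: np.random.Generator) -> HostTree:
    """Pure-birth (rate 1) tree over the labels, rescaled to root_age."""
    taxa = dendropy.TaxonNamespace(labels)
    n = len(labels)
    root = dendropy.Node()
    root.birth = 0.0
    active = [root]
    t = 0.0
    # first split at the root (time 0), then exponential waits per lineage
    while len(active) < n:
        k = len(active)
        if k > 1:
            t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(k)))
        node.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            child.birth = t
            node.add_child(child)
            active.append(child)
    t += rng.exponential(1.0 / n)
    total = t
    scale = root_age / total
    order = rng.permutation(n)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    for idx, leaf in zip(order, tree.leaf_node_iter()):
        leaf.taxon = taxa[int(idx)]
        leaf.edge.length = (total - leaf.birth) * scale
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is not None:
            node.edge.length = (node.split_time - node.birth) * scale
        node.support = None
    return HostTree(tree)
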