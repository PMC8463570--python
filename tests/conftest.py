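"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pandas as pd
import pytest

import cophylorestrict as cp
from cophylorestrict.model import (HOST_RESTRICTED, MIXED_HOST,
                                   UNIQUE_TO_CAPTIVE)


def make_samples(rows):
    """rows: (sample_id, species, lifestyle, site, enclosure) tuples."""
    df = pd.DataFrame(
        [(r[0], r[1], r[2], r[3], r[4], "test") for r in rows],
        columns=list(cp.SampleTable.COLUMNS))
    return cp.SampleTable(df)


def make_incidence(asv_rows: dict, sample_ids):
    """asv_rows: asv_id -> iterable of 0/1 aligned with sample_ids."""
    return cp.IncidenceMatrix(
        pd.DataFrame.from_dict(asv_rows, orient="index",
                               columns=list(sample_ids)))


@pytest.fixture
def wild_samples():
    """Two wild samples per ape species plus two humans and two captives."""
    rows = []
    for sp in ("bonobo", "chimpanzee", "gorilla", "orangutan"):
        rows += [(f"w_{sp}_1", sp, "wild", None, None),
                 (f"w_{sp}_2", sp, "wild", None, None)]
    rows += [("h_1", "human", "industrialized", None, None),
             ("h_2", "human", "non_industrialized", None, None),
             ("c_gor_1", "gorilla", "captive", "zoo_a", "zoo_a_gorilla"),
             ("c_ora_1", "orangutan", "captive", "zoo_a", "zoo_a_orangutan")]
    return make_samples(rows)


# ---------------------------------------------------------------------------
# Brute-force oracle for the maximal-clade scan: enumerate every internal
# node, evaluate the pass predicate directly, and keep only accepted nodes
# with no accepted proper ancestor (explicit maximality filtering).
# ---------------------------------------------------------------------------

def brute_force_clades(tree, classifications, incidence, samples, config):
    values = incidence.values().astype(bool)
    row_of = {a: i for i, a in enumerate(incidence.asv_ids)}

    def n_individuals(members):
        return int(values[[row_of[m] for m in members]].any(axis=0).sum())

    def passes(node, consumed, category):
        members = sorted(l.taxon.label for l in node.leaf_iter()
                         if l.taxon.label not in consumed)
        if len(members) < 2:
            return None
        sup = getattr(node, "support", None) or 0.0
        if not sup > config.min_support:
            return None
        cls = [classifications[m] for m in members]
        if category == HOST_RESTRICTED:
            if not all(c.category == HOST_RESTRICTED for c in cls):
                return None
            if len({c.restricted_host for c in cls}) != 1:
                return None
        else:
            pooled = set().union(*(c.wild_profile for c in cls))
            if category == MIXED_HOST and len(pooled) < 2:
                return None
            if category == UNIQUE_TO_CAPTIVE and len(pooled) != 0:
                return None
        if n_individuals(members) < config.min_individuals:
            return None
        return frozenset(members)

    consumed: set = set()
    out = []
    for category in (HOST_RESTRICTED, MIXED_HOST, UNIQUE_TO_CAPTIVE):
        hits = {}
        for node in tree.tree.preorder_node_iter():
            res = passes(node, consumed, category)
            if res is not None:
                hits[id(node)] = (node, res)
        # maximality: drop nodes with an accepted proper ancestor
        keep = []
        for nid, (node, members) in hits.items():
            anc = node.parent_node
            dominated = False
            while anc is not None:
                if id(anc) in hits:
                    dominated = True
                    break
                anc = anc.parent_node
            if not dominated:
                keep.append((members, category))
        for members, _ in keep:
            consumed |= members
        out.extend(keep)
    return {(cat, members) for members, cat in out}


def random_classified_instance(rng, max_tips=32):
    """Random tree + incidence + metadata for oracle comparison."""
    n_tips = int(rng.integers(4, max_tips + 1))
    labels = [f"t{i}" for i in range(n_tips)]
    # random topology by sequential joining, random supports, random lengths
    import dendropy
    nodes = [dendropy.Node() for _ in labels]
    for node, lbl in zip(nodes, labels):
        node.label = lbl
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        p = dendropy.Node()
        p.add_child(a)
        p.add_child(b)
        a.edge.length = float(rng.uniform(0.1, 1))
        b.edge.length = float(rng.uniform(0.1, 1))
        # some nodes unlabeled (support absent -> treated as 0)
        p.support = float(rng.uniform(0, 100)) if rng.random() < 0.8 else None
        nodes.append(p)
    tree = dendropy.Tree()
    tree.seed_node = nodes[0]
    ns = dendropy.TaxonNamespace()
    for leaf in tree.leaf_node_iter():
        leaf.taxon = ns.new_taxon(leaf.label)
        leaf.label = None
    tree.taxon_namespace = ns
    symb = cp.SymbiontTree(tree)

    sample_rows = []
    for sp in ("bonobo", "chimpanzee", "gorilla", "orangutan"):
        for k in range(3):
            sample_rows.append((f"w_{sp}_{k}", sp, "wild", None, None))
    for k in range(3):
        sample_rows.append((f"h_{k}", "human", "industrialized", None, None))
    for k in range(3):
        sample_rows.append(
            (f"c_{k}", "chimpanzee", "captive", "zoo", "zoo_chimp"))
    samples = make_samples(sample_rows)
    n_samples = len(samples.sample_ids)
    mat = (rng.random((n_tips, n_samples)) < 0.35).astype(int)
    mat[mat.sum(axis=1) == 0, rng.integers(n_samples)] = 1
    incidence = make_incidence(
        {lbl: mat[i] for i, lbl in enumerate(labels)}, samples.sample_ids)
    config = cp.AnalysisConfig(
        min_support=float(rng.choice([0, 30, 50, 70])),
        min_individuals=int(rng.integers(1, 5)))
    return symb, incidence, samples, config
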