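"""Synthetic data with planted structure for every pipeline stage.

The generator emulates a wild/captive great-ape ASV survey: a dated host
phylogeny over the four wild ape species plus humans, a symbiont (ASV)
phylogeny containing host-restricted radiations, a binary incidence
matrix with per-ASV prevalence structure, and sample metadata with zoo
sites and enclosures. Four scenarios plant different generative regimes:

* ``codiversification`` — the symbiont backbone mirrors the host
  topology; each host tip subtends a within-host radiation.
* ``host_switch`` — host-restricted radiations attached at random
  backbone positions, with host labels drawn independently of position
  (restricted but topologically discordant with the hosts).
* ``filtering`` — hosts assigned to tips i.i.d.; no clade structure.
* ``captive_mixing`` — as codiversification, plus captive groups whose
  individuals acquire human-generated ASVs with probability rho and
  retain conspecific wild ASVs with probability pi * (1 - rho).

Bootstrap supports are simulated (the pipeline consumes supports; it does
not estimate trees): radiation nodes draw from the high-support range,
backbone/noise nodes from the full range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .model import (APE_SPECIES, HostTree, IncidenceMatrix, SampleTable,
                    SymbiontTree, ValidationError)

SCENARIOS = ("codiversification", "host_switch", "filtering", "captive_mixing")
HOSTS = APE_SPECIES + ("human",)


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator parameters; defaults are the study conditions the
    pipeline is calibrated against.

    Divergence times are Myr before present on the fixed hominid topology
    (orangutan,(gorilla,(human,(chimpanzee,bonobo)))).
    """

    scenario: str = "codiversification"
    t_chimp_bonobo: float = 1.8
    t_human: float = 6.4
    t_gorilla: float = 8.6
    t_orangutan: float = 15.2
    n_individuals_per_group: int = 20
    n_clades_per_host: int = 3
    asvs_per_clade: int = 4
    within_host_prevalence: float = 0.6    # pi
    cross_colonization_rate: float = 0.0   # epsilon
    captive_human_acquisition: float = 0.8  # rho
    support_high: tuple[float, float] = (80.0, 100.0)
    support_noise: tuple[float, float] = (0.0, 100.0)
    n_captive_sites: int = 2
    rng_seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if not (0 < self.t_chimp_bonobo < self.t_human
                < self.t_gorilla < self.t_orangutan):
            raise ValidationError(
                "divergence times must nest: chimp-bonobo < human < "
                "gorilla < orangutan, all positive")
        if not (0 < self.within_host_prevalence <= 1):
            raise ValidationError("within_host_prevalence must be in (0, 1]")
        if not (0 <= self.cross_colonization_rate < 1):
            raise ValidationError("cross_colonization_rate must be in [0, 1)")
        if not (0 <= self.captive_human_acquisition <= 1):
            raise ValidationError("captive_human_acquisition must be in [0, 1]")
        if self.n_individuals_per_group < 1:
            raise ValidationError("need >= 1 individual per group")
        if self.n_clades_per_host < 1 or self.asvs_per_clade < 1:
            raise ValidationError("need >= 1 clade per host and ASV per clade")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def simulate_host_tree(config: ScenarioConfig) -> HostTree:
    """Fixed hominid topology with the configured divergence times."""
    t_cb = config.t_chimp_bonobo
    t_h, t_g, t_o = config.t_human, config.t_gorilla, config.t_orangutan
    newick = (
        f"((((chimpanzee:{t_cb},bonobo:{t_cb}):{t_h - t_cb},"
        f"human:{t_h}):{t_g - t_h},gorilla:{t_g}):{t_o - t_g},"
        f"orangutan:{t_o});"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)
    for node in tree.preorder_internal_node_iter():
        node.support = None
    return HostTree(tree)


def _leaf(label: str) -> dendropy.Node:
    node = dendropy.Node()
    node.label = label  # taxon attached when the tree is finalised
    return node


def _random_subtree(children: list[dendropy.Node], rng: np.random.Generator,
                    depth_scale: float) -> dendropy.Node:
    """Join subtrees pairwise in random order into a binary ultrametric-ish
    subtree; branch lengths accumulate on the depth_scale."""
    nodes = list(children)
    heights = [getattr(n, "_height", 0.0) for n in nodes]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        hb = heights.pop(j)
        ha = heights.pop(i)
        h = max(ha, hb) + float(rng.uniform(0.2, 1.0)) * depth_scale
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = h - ha
        b.edge.length = h - hb
        parent._height = h
        nodes.append(parent)
        heights.append(h)
    return nodes[0]


def _radiation(host: str, clade_idx: int, config: ScenarioConfig,
               rng: np.random.Generator) -> tuple[dendropy.Node, list[str]]:
    labels = [f"{host}_c{clade_idx}_a{a}"
              for a in range(config.asvs_per_clade)]
    leaves = [_leaf(lbl) for lbl in labels]
    for leaf in leaves:
        leaf._height = 0.0
    root = _random_subtree(leaves, rng, depth_scale=0.05) \
        if len(leaves) > 1 else leaves[0]
    return root, labels


def _assign_supports(tree: dendropy.Tree, high_nodes: set[int],
                     config: ScenarioConfig, rng: np.random.Generator) -> None:
    lo_h, hi_h = config.support_high
    lo_n, hi_n = config.support_noise
    for node in tree.preorder_internal_node_iter():
        if id(node) in high_nodes:
            node.support = float(rng.uniform(lo_h, hi_h))
        else:
            node.support = float(rng.uniform(lo_n, hi_n))


def _finalise(root: dendropy.Node) -> dendropy.Tree:
    tree = dendropy.Tree()
    tree.seed_node = root
    ns = dendropy.TaxonNamespace()
    for leaf in tree.leaf_node_iter():
        leaf.taxon = ns.new_taxon(leaf.label)
        leaf.label = None
    tree.taxon_namespace = ns
    return tree


def _mirror_host_backbone(config: ScenarioConfig, copy_idx: int,
                          rng: np.random.Generator,
                          rate: float = 0.1
                          ) -> tuple[dendropy.Node, dict[str, str], set[int]]:
    """One symbiont backbone copy mirroring the host topology; each host
    tip subtends a within-host radiation. Returns (root, asv->host map,
    ids of radiation-internal nodes)."""
    host_map: dict[str, str] = {}
    high: set[int] = set()

    def rad(host: str) -> tuple[dendropy.Node, float]:
        root, labels = _radiation(host, copy_idx, config, rng)
        for lbl in labels:
            host_map[lbl] = host
        for node in _internal_nodes(root):
            high.add(id(node))
        return root, getattr(root, "_height", 0.0)

    def join(a, ha, b, hb, t):
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = t - ha
        b.edge.length = t - hb
        return parent, t

    scale = rate
    c, hc = rad("chimpanzee")
    b, hb = rad("bonobo")
    cb, hcb = join(c, hc, b, hb, config.t_chimp_bonobo * scale + max(hc, hb))
    h, hh = rad("human")
    chb, hchb = join(cb, hcb, h, hh, config.t_human * scale + max(hcb, hh))
    g, hg = rad("gorilla")
    cg, hcg = join(chb, hchb, g, hg, config.t_gorilla * scale + max(hchb, hg))
    o, ho = rad("orangutan")
    root, hroot = join(cg, hcg, o, ho,
                       config.t_orangutan * scale + max(hcg, ho))
    root._height = hroot
    return root, host_map, high


def _internal_nodes(root: dendropy.Node):
    stack = [root]
    while stack:
        node = stack.pop()
        kids = node.child_nodes()
        if kids:
            yield node
            stack.extend(kids)


def simulate_symbiont_tree(config: ScenarioConfig,
                           rng: np.random.Generator
                           ) -> tuple[SymbiontTree, dict[str, str]]:
    """Symbiont phylogeny plus the true generating host of every ASV."""
    if config.scenario in ("codiversification", "captive_mixing"):
        copies = []
        host_map: dict[str, str] = {}
        high: set[int] = set()
        for k in range(config.n_clades_per_host):
            root_k, map_k, high_k = _mirror_host_backbone(config, k, rng)
            copies.append(root_k)
            host_map.update(map_k)
            high |= high_k
        for c in copies:
            if not hasattr(c, "_height"):
                c._height = 0.0
        root = copies[0] if len(copies) == 1 \
            else _random_subtree(copies, rng, depth_scale=3.0)
        # the whole mirrored backbone is planted structure: radiation roots
        # must out-support the threshold, so mark radiation internals high
        tree = _finalise(root)
        _assign_supports(tree, high, config, rng)
        return SymbiontTree(tree), host_map

    if config.scenario == "host_switch":
        hosts = [h for h in HOSTS for _ in range(config.n_clades_per_host)]
        rng.shuffle(hosts)
        host_map = {}
        high: set[int] = set()
        rads = []
        for k, host in enumerate(hosts):
            r, labels = _radiation(host, k, config, rng)
            for lbl in labels:
                host_map[lbl] = host
            for node in _internal_nodes(r):
                high.add(id(node))
            if not hasattr(r, "_height"):
                r._height = 0.0
            rads.append(r)
        root = rads[0] if len(rads) == 1 \
            else _random_subtree(rads, rng, depth_scale=1.0)
        tree = _finalise(root)
        _assign_supports(tree, high, config, rng)
        return SymbiontTree(tree), host_map

    # filtering: hosts i.i.d. over tips, no clade structure
    n_tips = len(HOSTS) * config.n_clades_per_host * config.asvs_per_clade
    labels = [f"asv{k:04d}" for k in range(n_tips)]
    host_map = {lbl: HOSTS[int(rng.integers(len(HOSTS)))] for lbl in labels}
    leaves = [_leaf(lbl) for lbl in labels]
    for leaf in leaves:
        leaf._height = 0.0
    root = _random_subtree(leaves, rng, depth_scale=0.3)
    tree = _finalise(root)
    _assign_supports(tree, set(), config, rng)
    return SymbiontTree(tree), host_map


def _sample_frame(config: ScenarioConfig) -> pd.DataFrame:
    rows = []
    n = config.n_individuals_per_group
    for species in APE_SPECIES:
        for k in range(n):
            rows.append((f"wild_{species}_{k}", species, "wild",
                         f"range_{species}", None, "synthetic"))
    for k in range(n):
        lifestyle = "industrialized" if k % 2 == 0 else "non_industrialized"
        rows.append((f"human_{k}", "human", lifestyle, None, None,
                     "synthetic"))
    if config.scenario == "captive_mixing":
        sites = [f"zoo_{chr(ord('a') + s)}" for s in range(config.n_captive_sites)]
        for species in APE_SPECIES:
            for k in range(n):
                site = sites[k % len(sites)]
                rows.append((f"captive_{species}_{k}", species, "captive",
                             site, f"{site}_{species}", "synthetic"))
    return pd.DataFrame(rows, columns=list(SampleTable.COLUMNS))


def simulate_incidence(host_map: dict[str, str], config: ScenarioConfig,
                       rng: np.random.Generator
                       ) -> tuple[IncidenceMatrix, SampleTable, list[str]]:
    """Draw the binary ASV x sample matrix from the scenario's rates.

    Each ASV is present in each individual of its generating host group
    with probability pi, and in individuals of other wild-ape groups with
    probability epsilon. Captive individuals (captive_mixing only) carry
    human-generated ASVs with probability rho and conspecific wild ASVs
    with probability pi * (1 - rho). All-zero ASVs are dropped with a
    warning (kept i.i.d.-interpretable rather than redrawn); the dropped
    ids are returned so callers can prune the symbiont tree.
    """
    samples = SampleTable(_sample_frame(config))
    meta = samples.df
    asvs = sorted(host_map)
    pi = config.within_host_prevalence
    eps = config.cross_colonization_rate
    rho = config.captive_human_acquisition

    prob = np.zeros((len(asvs), len(meta)))
    species = meta["host_species"].to_numpy()
    lifestyle = meta["lifestyle"].to_numpy()
    is_human = species == "human"
    is_wild = lifestyle == "wild"
    is_captive = lifestyle == "captive"
    for i, asv in enumerate(asvs):
        h = host_map[asv]
        if h == "human":
            prob[i, is_human] = pi
            prob[i, is_wild] = eps
            prob[i, is_captive] = rho
        else:
            prob[i, is_wild & (species == h)] = pi
            prob[i, is_wild & (species != h)] = eps
            prob[i, is_captive & (species == h)] = pi * (1 - rho)
    draws = (rng.random(prob.shape) < prob).astype(np.int8)
    df = pd.DataFrame(draws, index=asvs, columns=meta.index)
    dropped = [a for a in df.index[df.sum(axis=1) == 0]]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} ASV(s) with no occurrences: "
            + ", ".join(dropped[:5]), stacklevel=2)
        df = df.drop(index=dropped)
    return IncidenceMatrix(df), samples, dropped


@dataclass
class ScenarioData:
    """Bundle returned by :func:`simulate_scenario`."""

    config: ScenarioConfig
    host_tree: HostTree
    symbiont_tree: SymbiontTree
    incidence: IncidenceMatrix
    samples: SampleTable
    true_host_map: dict[str, str]
    dropped_asvs: list[str] = field(default_factory=list)

    def planted_clades(self) -> dict[str, set[str]]:
        """Radiation id -> surviving member ASVs (>= 2 members only)."""
        out: dict[str, set[str]] = {}
        present = set(self.incidence.asv_ids)
        for asv, host in self.true_host_map.items():
            if asv not in present or "_c" not in asv:
                continue
            rad_id = asv.rsplit("_a", 1)[0]
            out.setdefault(rad_id, set()).add(asv)
        return {k: v for k, v in out.items() if len(v) >= 2}


def simulate_scenario(config: ScenarioConfig,
                      rng: np.random.Generator | None = None) -> ScenarioData:
    """Generate a full scenario: trees, incidence, metadata, and truth.

    ASVs dropped for having no occurrences are pruned from the symbiont
    tree so that tree tips and incidence rows coincide.
    """
    rng = config.rng() if rng is None else rng
    host_tree = simulate_host_tree(config)
    symbiont_tree, host_map = simulate_symbiont_tree(config, rng)
    incidence, samples, dropped = simulate_incidence(host_map, config, rng)
    if dropped:
        keep = [t for t in symbiont_tree.tip_labels if t not in set(dropped)]
        symbiont_tree.tree.retain_taxa_with_labels(keep)
        symbiont_tree = SymbiontTree(symbiont_tree.tree)
    return ScenarioData(config=config, host_tree=host_tree,
                        symbiont_tree=symbiont_tree, incidence=incidence,
                        samples=samples, true_host_map=host_map,
                        dropped_asvs=dropped)
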