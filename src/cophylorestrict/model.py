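"""Shared domain types for the host-restriction / co-phylogeny pipeline.

The pipeline operates on four kinds of objects: a symbiont (ASV) phylogeny
with bootstrap supports, an ultrametric host phylogeny in units of Myr, a
binary ASV x sample incidence matrix, and a per-sample metadata table.
Each type validates its own invariants at construction so downstream
stages can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

HOST_SPECIES = ("bonobo", "chimpanzee", "gorilla", "orangutan", "human")
APE_SPECIES = ("bonobo", "chimpanzee", "gorilla", "orangutan")
LIFESTYLES = ("wild", "captive", "industrialized", "non_industrialized")
HUMAN_LIFESTYLES = ("industrialized", "non_industrialized")

#: categories assigned to ASVs and clades
HOST_RESTRICTED = "host_restricted"
MIXED_HOST = "mixed_host"
UNIQUE_TO_CAPTIVE = "unique_to_captive"
CATEGORIES = (HOST_RESTRICTED, MIXED_HOST, UNIQUE_TO_CAPTIVE)


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


class _Tree:
    """Thin wrapper over a rooted dendropy tree with labelled tips.

    Internal nodes carry a ``support`` attribute (float in [0, 100] or
    ``None`` when the input newick had no label on that node).
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.tree.is_rooted = True
        self._validate()

    def _validate(self) -> None:
        labels = self.tip_labels
        _require(all(lbl for lbl in labels), "empty tip label")
        _require(len(labels) == len(set(labels)),
                 "duplicate tip labels: "
                 + ", ".join(sorted({l for l in labels if labels.count(l) > 1})))
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None:
                _require(edge.length >= 0, f"negative branch length {edge.length}")
        for node in self.tree.preorder_internal_node_iter():
            sup = getattr(node, "support", None)
            if sup is not None:
                _require(0 <= sup <= 100, f"support {sup} outside [0, 100]")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def patristic_matrix(self) -> pd.DataFrame:
        """Tip-to-tip path-length distances as a labelled symmetric matrix."""
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = sorted(self.tree.taxon_namespace, key=lambda t: t.label)
        labels = [t.label for t in taxa]
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        return pd.DataFrame(d, index=labels, columns=labels)

    def as_newick(self) -> str:
        """Newick string with supports written back as internal-node labels."""
        for node in self.tree.preorder_internal_node_iter():
            sup = getattr(node, "support", None)
            node.label = None if sup is None else format(sup, "g")
        s = self.tree.as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=True, real_value_format_specifier=".10g",
        )
        return s.strip() + "\n"

    def clone(self):
        return type(self)(self.tree.clone(depth=1))


class SymbiontTree(_Tree):
    """Rooted symbiont (ASV) phylogeny with bootstrap supports on internal nodes."""


class HostTree(_Tree):
    """Ultrametric host phylogeny with branch lengths in Myr."""

    ULTRAMETRIC_TOL = 1e-6

    def _validate(self) -> None:
        super()._validate()
        depths = self.tip_depths()
        span = max(depths.values()) - min(depths.values())
        tol = self.ULTRAMETRIC_TOL * max(1.0, max(depths.values()))
        _require(span <= tol,
                 f"host tree is not ultrametric (root-to-tip spread {span:g})")

    def tip_depths(self) -> dict[str, float]:
        self.tree.calc_node_root_distances(return_leaf_distances_only=True)
        return {leaf.taxon.label: leaf.root_distance
                for leaf in self.tree.leaf_node_iter()}

    @property
    def root_age(self) -> float:
        return max(self.tip_depths().values())


class IncidenceMatrix:
    """Binary ASV x sample presence matrix.

    Wraps a pandas DataFrame (rows = ASV ids, columns = sample ids, entries
    0/1). Rows of all zeros are rejected: an ASV with no occurrence carries
    no information and breaks prevalence denominators downstream.
    """

    def __init__(self, df: pd.DataFrame):
        _require(df.index.is_unique, "duplicate ASV ids")
        _require(df.columns.is_unique, "duplicate sample ids")
        values = df.to_numpy()
        _require(np.isin(values, (0, 1)).all(), "incidence entries must be 0/1")
        zero_rows = df.index[values.sum(axis=1) == 0]
        _require(len(zero_rows) == 0,
                 "all-zero incidence row(s): " + ", ".join(map(str, zero_rows[:5])))
        self.df = df.astype(np.int8)
        self.df.index.name = "asv_id"
        self.df.columns.name = None

    @property
    def asv_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def presence(self, asv_id: str) -> pd.Series:
        if asv_id not in self.df.index:
            raise KeyError(f"unknown ASV id: {asv_id}")
        return self.df.loc[asv_id] > 0

    def with_values(self, values: np.ndarray) -> "IncidenceMatrix":
        """Same labels, new 0/1 entries (used by the permutation null)."""
        return IncidenceMatrix(
            pd.DataFrame(values, index=self.df.index, columns=self.df.columns))

    def asv_sets(self) -> dict[str, frozenset[str]]:
        """Per-sample set of ASVs present (for Sorenson sharing)."""
        arr = self.df.to_numpy().astype(bool)
        asvs = np.asarray(self.df.index)
        return {s: frozenset(asvs[arr[:, j]])
                for j, s in enumerate(self.df.columns)}


class SampleTable:
    """Per-sample metadata: host species, lifestyle, site, enclosure, study."""

    COLUMNS = ("sample_id", "host_species", "lifestyle", "site", "enclosure", "study")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        _require(not missing, f"missing metadata columns: {missing}")
        df = df[list(self.COLUMNS)].copy()
        for col in ("site", "enclosure"):
            df[col] = df[col].replace({"NA": None, "": None, np.nan: None})
        _require(df["sample_id"].is_unique, "duplicate sample ids")
        bad_sp = df.loc[~df["host_species"].isin(HOST_SPECIES)]
        _require(bad_sp.empty,
                 "unknown host_species in rows: " + _rows(bad_sp))
        bad_ls = df.loc[~df["lifestyle"].isin(LIFESTYLES)]
        _require(bad_ls.empty, "unknown lifestyle in rows: " + _rows(bad_ls))
        humans = df["host_species"] == "human"
        bad_hl = df.loc[humans & ~df["lifestyle"].isin(HUMAN_LIFESTYLES)]
        _require(bad_hl.empty,
                 "human samples must be industrialized/non_industrialized: "
                 + _rows(bad_hl))
        bad_al = df.loc[~humans & ~df["lifestyle"].isin(("wild", "captive"))]
        _require(bad_al.empty,
                 "ape samples must be wild/captive: " + _rows(bad_al))
        captive_nosite = df.loc[(df["lifestyle"] == "captive") & df["site"].isna()]
        _require(captive_nosite.empty,
                 "captive samples must carry a site: " + _rows(captive_nosite))
        # enclosure ids must be nested within a single site
        encl = df.dropna(subset=["enclosure"])
        sites_per_encl = encl.groupby("enclosure")["site"].nunique(dropna=False)
        _require((sites_per_encl <= 1).all(),
                 "enclosure spans multiple sites: "
                 + ", ".join(sites_per_encl.index[sites_per_encl > 1]))
        self.df = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def covers(self, sample_ids: Iterable[str]) -> bool:
        return set(sample_ids) <= set(self.df.index)

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        return SampleTable(self.df.loc[list(sample_ids)].reset_index(drop=True))

    def group_key(self, by_site: bool = False) -> pd.Series:
        """host_species x lifestyle group label per sample.

        With ``by_site=True`` captive groups are further split by zoo site.
        """
        df = self.df
        key = df["lifestyle"] + "_" + df["host_species"]
        if by_site:
            captive = df["lifestyle"] == "captive"
            key = key.where(~captive, key + "@" + df["site"].astype(str))
        return key


def _rows(df: pd.DataFrame) -> str:
    return ", ".join(map(str, df["sample_id"].head(5)))


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds for clade detection and permutation testing.

    min_support
        bootstrap support a clade's node must *exceed* (0-100 scale).
    min_individuals
        minimum number of distinct samples containing >=1 member ASV.
    prevalence_threshold
        fraction of a sample group's individuals a clade must *exceed*
        to count as prominent.
    n_permutations
        permutations for every empirical null in the pipeline.
    """

    min_support: float = 50.0
    min_individuals: int = 5
    prevalence_threshold: float = 0.25
    n_permutations: int = 999
    rng_seed: int = 0

    def __post_init__(self):
        _require(self.n_permutations >= 1, "n_permutations must be >= 1")
        _require(self.min_individuals >= 1, "min_individuals must be >= 1")
        _require(0 < self.prevalence_threshold <= 1,
                 "prevalence_threshold must be in (0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass(frozen=True)
class AsvClassification:
    """Host-source designation of one ASV.

    ``wild_profile`` is the set of designation-relevant host groups (each
    wild ape species, plus humans of either lifestyle) whose samples
    contain the ASV; captive occurrences never contribute.
    """

    asv_id: str
    category: str
    restricted_host: Optional[str]
    wild_profile: frozenset[str]

    def __post_init__(self):
        _require(self.category in CATEGORIES, f"bad category {self.category}")
        _require((self.restricted_host is not None)
                 == (self.category == HOST_RESTRICTED),
                 "restricted_host must be set iff host_restricted")
        _require((len(self.wild_profile) == 0)
                 == (self.category == UNIQUE_TO_CAPTIVE),
                 "wild_profile empty iff unique_to_captive")


@dataclass
class CladeRecord:
    """A maximal well-supported monophyletic clade of same-category ASVs."""

    clade_id: str
    node: object  # dendropy node the members descend from
    member_asvs: tuple[str, ...]
    category: str
    host_species: Optional[str]
    support: float
    n_individuals: int
    prevalence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        _require(len(self.member_asvs) >= 2, "a clade needs >=2 member ASVs")
        _require(all(0 <= v <= 1 for v in self.prevalence.values()),
                 "prevalence values must lie in [0, 1]")


@dataclass
class CladeSizeNull:
    """Permutation null for host-restricted clade sizes.

    ``perm_max_size[k]`` / ``perm_n_clades[k]`` summarise permutation k;
    ``empirical_p`` maps each observed clade size s to the add-one upper
    tail (1 + #{perm max >= s}) / (1 + n_permutations).
    """

    n_permutations: int
    perm_max_size: np.ndarray
    perm_n_clades: np.ndarray
    observed_sizes: tuple[int, ...]
    empirical_p: dict[int, float]

    def __post_init__(self):
        _require(len(self.perm_max_size) == self.n_permutations,
                 "summary length != n_permutations")
        _require(all(0 < p <= 1 for p in self.empirical_p.values()),
                 "empirical p outside (0, 1]")


@dataclass
class CospeciationResult:
    """Outcome of one co-phylogenetic congruence test.

    ``direction`` records which tail counts as congruence: 'ge' for
    Hommola r and ParaFitGlobal (large = congruent), 'le' for the PACo
    Procrustes residual m2 (small = congruent). ``degenerate`` flags
    zero-variance instances where the statistic is undefined; p is then 1.
    """

    test: str
    statistic: float
    null_values: np.ndarray
    p: float
    direction: str
    degenerate: bool = False

    def __post_init__(self):
        _require(self.test in ("hommola", "parafit", "paco"), self.test)
        _require(self.direction in ("ge", "le"), self.direction)
        _require(0 < self.p <= 1, f"p={self.p} outside (0, 1]")
        if not self.degenerate:
            _require(np.isfinite(self.statistic), "non-finite statistic")


def add_one_p(null_values: np.ndarray, observed: float, direction: str) -> float:
    """Add-one empirical p: (1 + #{null as-or-more extreme}) / (1 + N)."""
    null_values = np.asarray(null_values, dtype=float)
    if direction == "ge":
        k = int(np.sum(null_values >= observed))
    elif direction == "le":
        k = int(np.sum(null_values <= observed))
    else:  # pragma: no cover
        raise ValueError(direction)
    return (1 + k) / (1 + len(null_values))
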