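"""Host-source classification of ASVs and maximal-clade extraction.

An ASV's designation considers only occurrences in *wild* apes and in
humans (either lifestyle): captive animals can swap strains in shared
enclosures, so their occurrences never alter the designation. ASVs seen
in exactly one designation-relevant host group are host-restricted to it;
in two or more, mixed-host; in none (captive-only), unique-to-captive.

Clades are extracted from the symbiont phylogeny by a greedy top-down
scan in three sequential passes (host-restricted, then mixed-host on the
leftover tips, then unique-to-captive), accepting the largest possible
monophyletic groups whose bootstrap support exceeds ``min_support`` and
that occur in at least ``min_individuals`` distinct samples. Accepting a
node consumes its tips: descendants are never revisited and later passes
only see unconsumed tips, so the returned clades are pairwise disjoint.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import (HOST_RESTRICTED, MIXED_HOST, UNIQUE_TO_CAPTIVE,
                    AnalysisConfig, AsvClassification, CladeRecord,
                    IncidenceMatrix, SampleTable, SymbiontTree)

_PASS_PREFIX = {HOST_RESTRICTED: "HR", MIXED_HOST: "MH", UNIQUE_TO_CAPTIVE: "UC"}


def _designation_groups(samples: SampleTable) -> pd.Series:
    """Designation-relevant group per sample: wild-ape species or 'human';
    None for captive apes."""
    df = samples.df
    group = pd.Series([None] * len(df), index=df.index, dtype=object)
    group[df["host_species"] == "human"] = "human"
    wild = (df["lifestyle"] == "wild") & (df["host_species"] != "human")
    group[wild] = df.loc[wild, "host_species"]
    return group


def classify_all(incidence: IncidenceMatrix,
                 samples: SampleTable) -> dict[str, AsvClassification]:
    """Classify every ASV in the incidence matrix (vectorised)."""
    if not samples.covers(incidence.sample_ids):
        missing = set(incidence.sample_ids) - set(samples.sample_ids)
        raise KeyError(f"samples missing from metadata: {sorted(missing)[:5]}")
    groups = _designation_groups(samples).reindex(incidence.sample_ids)
    values = incidence.values().astype(bool)
    out: dict[str, AsvClassification] = {}
    group_labels = sorted({g for g in groups if g is not None})
    masks = {g: (groups == g).to_numpy() for g in group_labels}
    present = {g: values[:, m].any(axis=1) for g, m in masks.items()}
    for i, asv in enumerate(incidence.asv_ids):
        profile = frozenset(g for g in group_labels if present[g][i])
        if len(profile) == 1:
            cat, host = HOST_RESTRICTED, next(iter(profile))
        elif profile:
            cat, host = MIXED_HOST, None
        else:
            cat, host = UNIQUE_TO_CAPTIVE, None
        out[asv] = AsvClassification(asv, cat, host, profile)
    return out


def classify_asv(asv_id: str, incidence: IncidenceMatrix,
                 samples: SampleTable) -> AsvClassification:
    """Classify one ASV by its host-source pattern.

    Raises KeyError for an ASV absent from the incidence matrix.
    """
    if asv_id not in incidence.df.index:
        raise KeyError(f"unknown ASV id: {asv_id}")
    groups = _designation_groups(samples).reindex(incidence.sample_ids)
    row = incidence.presence(asv_id).to_numpy()
    profile = frozenset(g for g in set(groups.dropna())
                        if row[(groups == g).to_numpy()].any())
    if len(profile) == 1:
        return AsvClassification(asv_id, HOST_RESTRICTED, next(iter(profile)),
                                 profile)
    if profile:
        return AsvClassification(asv_id, MIXED_HOST, None, profile)
    return AsvClassification(asv_id, UNIQUE_TO_CAPTIVE, None, profile)


def _category_ok(members: list[AsvClassification], category: str):
    """(ok, host) for the candidate member set under the given pass."""
    if category == HOST_RESTRICTED:
        hosts = {m.restricted_host for m in members}
        if len(hosts) == 1 and all(m.category == HOST_RESTRICTED for m in members):
            return True, next(iter(hosts))
        return False, None
    pooled = frozenset().union(*(m.wild_profile for m in members))
    if category == MIXED_HOST:
        return len(pooled) >= 2, None
    return len(pooled) == 0, None  # unique_to_captive


def find_maximal_clades(tree: SymbiontTree,
                        classifications: Mapping[str, AsvClassification],
                        incidence: IncidenceMatrix,
                        samples: SampleTable,
                        config: AnalysisConfig) -> list[CladeRecord]:
    """Extract maximal supported monophyletic clades in three passes.

    Pass order: host-restricted, mixed-host, unique-to-captive. A node is
    accepted when its (unconsumed) tips satisfy the pass's category rule,
    its bootstrap support strictly exceeds ``config.min_support`` (missing
    support counts as 0), and its members occur in at least
    ``config.min_individuals`` distinct samples. Acceptance is greedy
    top-down: an accepted ancestor suppresses all its descendants, which
    yields the largest possible clades.
    """
    tips = tree.tip_labels
    missing = [t for t in tips if t not in classifications]
    if missing:
        raise KeyError(f"tips without classification: {missing[:5]}")
    row_of = {a: i for i, a in enumerate(incidence.asv_ids)}
    missing_rows = [t for t in tips if t not in row_of]
    if missing_rows:
        raise KeyError(f"tips absent from incidence: {missing_rows[:5]}")
    values = incidence.values().astype(bool)

    consumed: set[str] = set()
    accepted: list[tuple[str, CladeRecord]] = []

    def n_individuals(members: list[str]) -> int:
        rows = [row_of[m] for m in members]
        return int(values[rows].any(axis=0).sum())

    for category in (HOST_RESTRICTED, MIXED_HOST, UNIQUE_TO_CAPTIVE):
        newly: list[CladeRecord] = []
        stack = [tree.tree.seed_node]
        while stack:
            node = stack.pop()
            members = sorted(
                leaf.taxon.label for leaf in node.leaf_iter()
                if leaf.taxon.label not in consumed)
            if len(members) < 2:
                continue  # leaves/singletons cannot carry bootstrap support
            support = getattr(node, "support", None)
            support = 0.0 if support is None else float(support)
            ok, host = _category_ok([classifications[m] for m in members],
                                    category)
            n_ind = n_individuals(members) if ok else 0
            if ok and support > config.min_support \
                    and n_ind >= config.min_individuals:
                newly.append(CladeRecord(
                    clade_id="", node=node, member_asvs=tuple(members),
                    category=category, host_species=host, support=support,
                    n_individuals=n_ind))
            else:
                stack.extend(node.child_nodes())
        for rec in newly:
            consumed.update(rec.member_asvs)
        accepted.extend((category, rec) for rec in newly)

    # deterministic ids: order within each pass by member tuple
    result: list[CladeRecord] = []
    for category in (HOST_RESTRICTED, MIXED_HOST, UNIQUE_TO_CAPTIVE):
        recs = sorted((r for c, r in accepted if c == category),
                      key=lambda r: r.member_asvs)
        for k, rec in enumerate(recs, start=1):
            rec.clade_id = f"{_PASS_PREFIX[category]}{k:04d}"
            rec.prevalence = _member_prevalence(
                list(rec.member_asvs), incidence, samples)
            result.append(rec)
    return result


def _member_prevalence(members: list[str], incidence: IncidenceMatrix,
                       samples: SampleTable, by_site: bool = False
                       ) -> dict[str, float]:
    row_of = {a: i for i, a in enumerate(incidence.asv_ids)}
    values = incidence.values().astype(bool)
    rows = [row_of[m] for m in members]
    present = pd.Series(values[rows].any(axis=0), index=incidence.sample_ids)
    key = samples.group_key(by_site=by_site).reindex(incidence.sample_ids)
    out: dict[str, float] = {}
    for group, idx in present.groupby(key).groups.items():
        n = len(idx)
        if n == 0:
            continue  # empty group: prevalence undefined, omitted
        out[str(group)] = float(present.loc[idx].sum() / n)
    return out


def clade_prevalence(clade: CladeRecord, incidence: IncidenceMatrix,
                     samples: SampleTable, by_site: bool = False
                     ) -> dict[str, float]:
    """Fraction of each sample group's individuals harbouring the clade.

    A clade is present in a sample when >=1 member ASV is present (union
    over members). Groups are host_species x lifestyle; ``by_site=True``
    further splits captive groups by zoo site.
    """
    missing = [m for m in clade.member_asvs if m not in incidence.df.index]
    if missing:
        raise KeyError(f"clade members absent from incidence: {missing}")
    return _member_prevalence(list(clade.member_asvs), incidence, samples,
                              by_site=by_site)


def prominent_clades(clades: Sequence[CladeRecord],
                     config: AnalysisConfig) -> list[CladeRecord]:
    """Clades whose prevalence strictly exceeds the threshold in >=1 group."""
    thr = config.prevalence_threshold
    return [c for c in clades if any(v > thr for v in c.prevalence.values())]
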