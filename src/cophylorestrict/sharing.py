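"""Pairwise Sørenson ASV-sharing between individuals, with permutation tests.

Sharing between two samples is the Sørenson index 2|A∩B|/(|A|+|B|) over
their ASV presence sets. Pairs of captive individuals are stratified by
their relationship — same enclosure, same zoo site but different
enclosure, same species at different sites, or different species at
different sites — and group differences are assessed with a two-sided
permutation t-test that permutes *sample-level* identities (never the
non-independent pair rows), with Bonferroni correction across the family
of comparisons reported together.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import IncidenceMatrix, SampleTable

SAME_ENCLOSURE = "same_enclosure"
SAME_SITE = "same_site_diff_enclosure"
SAME_SPECIES = "same_species_diff_site"
DIFF_SPECIES = "diff_species_diff_site"
RELATIONSHIPS = (SAME_ENCLOSURE, SAME_SITE, SAME_SPECIES, DIFF_SPECIES)


def sorenson(set_a: frozenset | set, set_b: frozenset | set) -> float:
    """Sørenson similarity 2|A∩B| / (|A| + |B|). Undefined when both empty."""
    total = len(set_a) + len(set_b)
    if total == 0:
        raise ValueError("Sorenson undefined for two empty sets")
    return 2 * len(set_a & set_b) / total


def _relationship(sp_a, sp_b, site_a, site_b, enc_a, enc_b) -> str:
    same_site = site_a is not None and site_a == site_b
    if same_site:
        if enc_a is not None and enc_a == enc_b:
            return SAME_ENCLOSURE
        return SAME_SITE
    return SAME_SPECIES if sp_a == sp_b else DIFF_SPECIES


def pairwise_sharing(incidence: IncidenceMatrix, samples: SampleTable,
                     scope: str = "captive") -> pd.DataFrame:
    """Sørenson sharing for all unordered in-scope sample pairs.

    scope='captive' (the reported comparison) restricts to captive apes;
    scope='all' uses every sample with incidence data. Columns:
    sample_a, sample_b, sorenson, relationship.
    """
    if scope not in ("captive", "all"):
        raise ValueError(f"scope must be 'captive' or 'all', got {scope!r}")
    meta = samples.df.loc[[s for s in incidence.sample_ids]]
    if scope == "captive":
        meta = meta[meta["lifestyle"] == "captive"]
        if meta["site"].isna().any():
            raise ValueError("captive sample without site")
    ids = list(meta.index)
    if len(ids) < 2:
        raise ValueError("need >= 2 samples in scope")
    sets = incidence.asv_sets()
    sp = meta["host_species"]
    site = meta["site"]
    enc = meta["enclosure"]
    rows = []
    for a, b in itertools.combinations(ids, 2):
        rows.append({
            "sample_a": a, "sample_b": b,
            "sorenson": sorenson(sets[a], sets[b]),
            "relationship": _relationship(
                sp[a], sp[b],
                None if pd.isna(site[a]) else site[a],
                None if pd.isna(site[b]) else site[b],
                None if pd.isna(enc[a]) else enc[a],
                None if pd.isna(enc[b]) else enc[b]),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    n_a: int
    n_b: int


def _t_stat(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled two-sample t; 0 when the pooled variance vanishes."""
    na, nb = len(x), len(y)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) \
        / (na + nb - 2)
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    diff = x.mean() - y.mean()
    if denom == 0:
        # zero pooled variance: identical groups -> 0, separated -> +-inf
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / denom)


def permutation_t_test(values, group_labels, n_perm: int,
                       rng: np.random.Generator) -> TTestResult:
    """Two-sided permutation t-test over two groups of values.

    The null permutes the group labels over the values; p is add-one
    two-sided: (1 + #{|t_null| >= |t_obs|}) / (1 + n_perm). For pair-level
    sharing data use :func:`sharing_permutation_tests`, which permutes
    sample identities instead of the non-independent pair rows.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(uniq)}")
    mask = labels == uniq[0]
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each group needs >= 2 values")
    t_obs = _t_stat(values[mask], values[~mask])
    count = 0
    for _ in range(n_perm):
        pm = rng.permutation(mask)
        if abs(_t_stat(values[pm], values[~pm])) >= abs(t_obs):
            count += 1
    return TTestResult(t=t_obs, p=(1 + count) / (1 + n_perm),
                       n_a=int(mask.sum()), n_b=int((~mask).sum()))


DEFAULT_COMPARISONS = (
    (SAME_ENCLOSURE, SAME_SITE),
    (SAME_ENCLOSURE, SAME_SPECIES),
    (SAME_ENCLOSURE, DIFF_SPECIES),
    (SAME_SITE, DIFF_SPECIES),
    (SAME_SPECIES, DIFF_SPECIES),
)

#: comparisons whose permutation unit is restricted to within-site label
#: swaps (enclosure effects; both groups live inside sites)
_WITHIN_SITE = {(SAME_ENCLOSURE, SAME_SITE)}


def sharing_permutation_tests(pairs: pd.DataFrame, samples: SampleTable,
                              n_perm: int, rng: np.random.Generator,
                              comparisons=DEFAULT_COMPARISONS) -> pd.DataFrame:
    """Permutation t-tests between relationship groups of sharing values.

    The permutation unit is the sample, not the pair: each permutation
    shuffles the metadata tuples (species, site, enclosure) across
    samples — within each site for the enclosure comparison, across the
    whole scope otherwise — and pair relationships are recomputed before
    the t statistic. Bonferroni correction is applied across the family.
    """
    ids = sorted(set(pairs["sample_a"]) | set(pairs["sample_b"]))
    idx = {s: i for i, s in enumerate(ids)}
    ia = pairs["sample_a"].map(idx).to_numpy()
    ib = pairs["sample_b"].map(idx).to_numpy()
    vals = pairs["sorenson"].to_numpy(dtype=float)
    meta = samples.df.loc[ids]
    sp = pd.factorize(meta["host_species"])[0]
    # a null site never matches anything: give it a per-sample sentinel
    site_raw = meta["site"].where(meta["site"].notna(),
                                  "\0none_" + pd.Series(ids, index=meta.index))
    site = pd.factorize(site_raw)[0]
    enc_raw = meta["enclosure"].where(meta["enclosure"].notna(),
                                      "\0none_" + pd.Series(ids, index=meta.index))
    enc = pd.factorize(enc_raw)[0]

    def relationships(order: np.ndarray) -> np.ndarray:
        s_a, s_b = sp[order[ia]], sp[order[ib]]
        t_a, t_b = site[order[ia]], site[order[ib]]
        e_a, e_b = enc[order[ia]], enc[order[ib]]
        same_site = t_a == t_b
        same_enc = same_site & (e_a == e_b)
        out = np.where(same_enc, 0,
                       np.where(same_site, 1, np.where(s_a == s_b, 2, 3)))
        return out

    rel_code = {r: c for c, r in enumerate(RELATIONSHIPS)}
    identity = np.arange(len(ids))
    obs_rel = relationships(identity)
    rows = []
    for group_a, group_b in comparisons:
        ca, cb = rel_code[group_a], rel_code[group_b]
        xa = vals[obs_rel == ca]
        xb = vals[obs_rel == cb]
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(
                f"fewer than 2 pairs in {group_a!r} or {group_b!r}")
        t_obs = _t_stat(xa, xb)
        within_site = (group_a, group_b) in _WITHIN_SITE
        count = 0
        for _ in range(n_perm):
            if within_site:
                order = identity.copy()
                for s_code in np.unique(site):
                    members = np.flatnonzero(site == s_code)
                    order[members] = members[rng.permutation(len(members))]
            else:
                order = rng.permutation(len(ids))
            rel = relationships(order)
            ya = vals[rel == ca]
            yb = vals[rel == cb]
            if len(ya) < 2 or len(yb) < 2:
                continue  # degenerate permutation never exceeds
            if abs(_t_stat(ya, yb)) >= abs(t_obs):
                count += 1
        p_raw = (1 + count) / (1 + n_perm)
        rows.append({"group_a": group_a, "group_b": group_b,
                     "t": t_obs, "n_a": len(xa), "n_b": len(xb),
                     "p_raw": p_raw,
                     "p_bonferroni": min(1.0, p_raw * len(comparisons))})
    return pd.DataFrame(rows)
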