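"""Distance-based co-phylogenetic congruence tests.

Three classical tests are implemented over a host distance matrix, a
symbiont distance matrix, and a binary association matrix linking them:

* Hommola correlation test — Pearson correlation r between host and
  symbiont patristic distances over all unordered pairs of association
  links; the null permutes host and symbiont identities independently.
* ParaFit — global statistic = sum of squared entries of the
  fourth-corner matrix D = C' A B, where B and C are principal
  coordinates of the host and symbiont distance matrices; the null
  permutes associations within each symbiont row.
* PACo — Procrustes superimposition of the link-expanded symbiont
  configuration onto the host configuration; the statistic is the
  residual sum of squares m2 (small = congruent); the null re-draws
  which host each link touches.

All empirical p-values use the add-one rule (1 + k) / (1 + N), so the
attainable floor at 999 permutations is 0.001.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg

from .model import (AnalysisConfig, CospeciationResult, HostTree,
                    SymbiontTree, add_one_p)
from .null_models import randomize_host_tree

__all__ = [
    "AssociationMatrix", "association_from_incidence", "patristic_matrix",
    "pcoa", "procrustes_m2", "hommola_test", "parafit_global", "paco_test",
    "host_randomization_battery",
]


class AssociationMatrix:
    """Binary symbiont x host association matrix.

    Entry (p, h) = 1 when symbiont p was observed in host species h.
    Every symbiont must have at least one association.
    """

    def __init__(self, df: pd.DataFrame):
        if not df.index.is_unique or not df.columns.is_unique:
            raise ValueError("association labels must be unique")
        values = df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("association entries must be 0/1")
        empty = df.index[values.sum(axis=1) == 0]
        if len(empty):
            raise ValueError(
                "symbiont(s) with no host association: "
                + ", ".join(map(str, empty[:5])))
        self.df = df.astype(np.int8)

    @property
    def symbionts(self) -> list[str]:
        return list(self.df.index)

    @property
    def hosts(self) -> list[str]:
        return list(self.df.columns)


def association_from_incidence(incidence, samples,
                               hosts=None) -> AssociationMatrix:
    """Associate each ASV with every designation-relevant host group it
    occupies (wild apes by species, humans of either lifestyle).

    ASVs seen only in captive animals carry no designation-relevant
    association and are dropped.
    """
    from .host_restriction import classify_all
    cls = classify_all(incidence, samples)
    if hosts is None:
        hosts = sorted({g for c in cls.values() for g in c.wild_profile})
    rows = {a: [1 if h in c.wild_profile else 0 for h in hosts]
            for a, c in cls.items() if c.wild_profile}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(hosts))
    return AssociationMatrix(df.sort_index())


def patristic_matrix(tree) -> pd.DataFrame:
    """Sum of branch lengths along the path between every pair of tips."""
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("tree has a missing branch length")
    return tree.patristic_matrix()


def _center(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D2 @ J


def cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making D + c (off-diagonal) Euclidean."""
    n = D.shape[0]
    d1 = _center(D ** 2)
    d2 = _center(D)
    block = np.block([
        [np.zeros((n, n)), 2 * d1],
        [-np.eye(n), -4 * d2],
    ])
    eigvals = np.linalg.eigvals(block)
    return float(np.max(eigvals.real))


def pcoa(dist: pd.DataFrame | np.ndarray, correction: str = "none",
         eps: float = 1e-8) -> pd.DataFrame:
    """Principal-coordinates embedding of a distance matrix.

    Axes with eigenvalue <= eps * largest are dropped; with
    correction='cailliez' the additive constant is applied to off-diagonal
    distances first, removing negative eigenvalues.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        labels = list(range(D.shape[0]))
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if correction == "cailliez":
        c = cailliez_constant(D)
        if c > 0:
            D = D + c
            np.fill_diagonal(D, 0.0)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    B = _center(D ** 2)
    eigvals, eigvecs = scipy.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > eps * max(eigvals.max(), 1e-300)
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    return pd.DataFrame(coords, index=labels)


def min_eigenvalue_ratio(dist: pd.DataFrame | np.ndarray) -> float:
    """min eigenvalue / max eigenvalue of the Gower-centred matrix."""
    D = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    eigvals = scipy.linalg.eigvalsh(_center(D ** 2))
    return float(eigvals.min() / max(eigvals.max(), 1e-300))


def _auto_pcoa(dist, threshold: float = -1e-8) -> pd.DataFrame:
    """PCoA with the Cailliez correction applied automatically when the
    smallest eigenvalue dips below -1e-8 x the largest."""
    correction = "cailliez" if min_eigenvalue_ratio(dist) < threshold else "none"
    return pcoa(dist, correction=correction)


def _aligned(hostD: pd.DataFrame, symbiontD: pd.DataFrame,
             assoc: AssociationMatrix):
    """Reorder/validate the three inputs onto shared label orders."""
    missing_h = set(assoc.hosts) - set(hostD.index)
    if missing_h:
        raise ValueError(f"association hosts absent from host tree: {missing_h}")
    missing_s = set(assoc.symbionts) - set(symbiontD.index)
    if missing_s:
        raise ValueError(
            f"association symbionts absent from symbiont tree: "
            f"{sorted(missing_s)[:5]}")
    hosts = list(assoc.hosts)
    symbionts = list(assoc.symbionts)
    HD = hostD.loc[hosts, hosts].to_numpy(dtype=float)
    SD = symbiontD.loc[symbionts, symbionts].to_numpy(dtype=float)
    A = assoc.df.to_numpy()
    return HD, SD, A


def hommola_test(hostD: pd.DataFrame, symbiontD: pd.DataFrame,
                 assoc: AssociationMatrix, n_perm: int,
                 rng: np.random.Generator) -> CospeciationResult:
    """Hommola correlation test of host-symbiont codiversification.

    Builds, over every unordered pair of association links, the vectors of
    symbiont and host patristic distances and correlates them; the null
    relabels hosts and symbionts independently.
    """
    HD, SD, A = _aligned(hostD, symbiontD, assoc)
    si, hi = np.nonzero(A)
    L = len(si)
    if L < 3:
        raise ValueError("need >= 3 association links")
    I, J = np.triu_indices(L, 1)
    sI, sJ, hI, hJ = si[I], si[J], hi[I], hi[J]
    sd = SD[sI, sJ]
    hd = HD[hI, hJ]

    def corr(x, y):
        xs = x - x.mean()
        ys = y - y.mean()
        denom = np.sqrt((xs ** 2).sum() * (ys ** 2).sum())
        if denom == 0:
            return None
        return float((xs * ys).sum() / denom)

    r_obs = corr(sd, hd)
    if r_obs is None:
        return CospeciationResult("hommola", float("nan"),
                                  np.empty(0), 1.0, "ge", degenerate=True)
    n_h, n_s = HD.shape[0], SD.shape[0]
    null = np.empty(n_perm)
    for k in range(n_perm):
        ps = rng.permutation(n_s)
        ph = rng.permutation(n_h)
        r = corr(SD[ps[sI], ps[sJ]], HD[ph[hI], ph[hJ]])
        null[k] = -np.inf if r is None else r
    p = add_one_p(null, r_obs, "ge")
    return CospeciationResult("hommola", r_obs, null, p, "ge")


def parafit_global(hostD: pd.DataFrame, symbiontD: pd.DataFrame,
                   assoc: AssociationMatrix, n_perm: int,
                   rng: np.random.Generator) -> CospeciationResult:
    """ParaFit global test of host-symbiont congruence.

    D = C' A B with B, C the principal coordinates of the host and
    symbiont distance matrices; ParaFitGlobal = sum of squared entries.
    The null permutes each symbiont's associations across hosts.
    """
    HD, SD, A = _aligned(hostD, symbiontD, assoc)
    if HD.shape[0] < 2 or SD.shape[0] < 2:
        raise ValueError("need >= 2 hosts and >= 2 symbionts")
    B = _auto_pcoa(pd.DataFrame(HD)).to_numpy()
    C = _auto_pcoa(pd.DataFrame(SD)).to_numpy()

    def stat(Amat):
        D = C.T @ Amat @ B
        return float((D ** 2).sum())

    obs = stat(A.astype(float))
    n_s, n_h = A.shape
    null = np.empty(n_perm)
    for k in range(n_perm):
        # independent permutation within each row
        keys = rng.random((n_s, n_h)).argsort(axis=1)
        Aperm = np.take_along_axis(A, keys, axis=1)
        null[k] = stat(Aperm.astype(float))
    p = add_one_p(null, obs, "ge")
    return CospeciationResult("parafit", obs, null, p, "ge")


def procrustes_m2(X: np.ndarray, Y: np.ndarray) -> float:
    """Residual sum of squares after optimal superimposition of Y onto X.

    Both configurations are centred and scaled to unit sum of squares, so
    the residual is invariant to translation, rotation, and global scaling
    of either input; the value lies in [0, 1]. Column counts are equalised
    by zero-padding the narrower configuration.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    k = max(X.shape[1], Y.shape[1])
    if X.shape[1] < k:
        X = np.hstack([X, np.zeros((X.shape[0], k - X.shape[1]))])
    if Y.shape[1] < k:
        Y = np.hstack([Y, np.zeros((Y.shape[0], k - Y.shape[1]))])
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    nx = np.sqrt((Xc ** 2).sum())
    ny = np.sqrt((Yc ** 2).sum())
    if nx == 0 or ny == 0:
        raise ValueError("degenerate configuration (all points identical)")
    Xc /= nx
    Yc /= ny
    s = scipy.linalg.svd(Xc.T @ Yc, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def paco_test(hostD: pd.DataFrame, symbiontD: pd.DataFrame,
              assoc: AssociationMatrix, n_perm: int,
              rng: np.random.Generator) -> CospeciationResult:
    """PACo Procrustes test: superimpose the link-expanded symbiont
    configuration onto the host configuration.

    m2 is the Procrustes residual (small = congruent); the null re-draws
    which host each link touches, preserving the link count.
    """
    HD, SD, A = _aligned(hostD, symbiontD, assoc)
    if HD.shape[0] < 2 or SD.shape[0] < 2:
        raise ValueError("need >= 2 hosts and >= 2 symbionts")
    X = _auto_pcoa(pd.DataFrame(HD)).to_numpy()
    Y = _auto_pcoa(pd.DataFrame(SD)).to_numpy()
    si, hi = np.nonzero(A)
    Ylinks = Y[si]
    try:
        obs = procrustes_m2(X[hi], Ylinks)
    except ValueError:
        return CospeciationResult("paco", float("nan"), np.empty(0), 1.0,
                                  "le", degenerate=True)
    # the symbiont side is fixed across permutations: standardize it once
    # (zero-padding to equal widths does not change X'Y or the norms, so
    # this matches procrustes_m2 exactly)
    Yc = Ylinks - Ylinks.mean(axis=0)
    ny = np.sqrt((Yc ** 2).sum())
    Yn = Yc / ny
    null = np.empty(n_perm)
    for k in range(n_perm):
        Xl = X[hi[rng.permutation(len(hi))]]
        Xc = Xl - Xl.mean(axis=0)
        nx = np.sqrt((Xc ** 2).sum())
        if nx == 0:
            null[k] = np.inf
            continue
        s = scipy.linalg.svd((Xc / nx).T @ Yn, compute_uv=False)
        null[k] = max(0.0, 1.0 - s.sum() ** 2)
    p = add_one_p(null, obs, "le")
    return CospeciationResult("paco", obs, null, p, "le")


def host_randomization_battery(host_tree: HostTree,
                               symbiont_tree: SymbiontTree,
                               assoc: AssociationMatrix,
                               config: AnalysisConfig,
                               rng: np.random.Generator,
                               randomize_mode: str = "shuffle") -> pd.DataFrame:
    """Run all three tests with the true and a randomized host phylogeny.

    Returns a six-row table (test x host_phylogeny) of statistics and
    add-one p-values. A test that stays significant under the randomized
    host cannot be discriminating co-diversification from host-restricted
    diversification.
    """
    symD = patristic_matrix(symbiont_tree)
    random_host = randomize_host_tree(host_tree, mode=randomize_mode, rng=rng)
    rows = []
    for host_label, tree in (("true", host_tree), ("randomized", random_host)):
        hd = patristic_matrix(tree)
        for name, fn in (("hommola", hommola_test),
                         ("parafit", parafit_global),
                         ("paco", paco_test)):
            res = fn(hd, symD, assoc, config.n_permutations, rng)
            rows.append({
                "test": name, "host_phylogeny": host_label,
                "statistic": res.statistic, "p": res.p,
                "direction": res.direction, "degenerate": res.degenerate,
            })
    return pd.DataFrame(rows)
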