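"""CAF subtype harmonization across samples and robust marker discovery.

Clusters found independently in each discovery sample are matched by
canonical correlation analysis between cluster profiles. A profile is the
normalized-expression submatrix with rows = common variable features and
columns = the cluster's cells, so the two views share their observations
(the genes) and CCA finds maximally correlated linear combinations of cells.
Cross-sample cluster pairs are ranked by the correlation of their first
canonical variate pair; ties are broken by comparing successive canonical
correlations until a difference appears, and pairs are assembled greedily
(highest correlation first, transitively across samples, never joining two
clusters of the same sample).

Robust markers of a matched subtype are genes appearing in the top-N
lowest-p differentially expressed genes in every sample with a consistent
average log2 fold-change sign.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from caflineage.errors import DataError

log = logging.getLogger(__name__)

TIE_TOL = 1e-9


def _view_cov(F: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Covariance between the cell-variables of two feature x cell views."""
    n = F.shape[0]
    Fc = F - F.mean(axis=0, keepdims=True)
    Gc = G - G.mean(axis=0, keepdims=True)
    return Fc.T @ Gc / (n - 1)


def _inv_sqrt(S: np.ndarray, eps: float) -> np.ndarray:
    S = S + eps * np.eye(S.shape[0])
    w, V = np.linalg.eigh(S)
    tol = S.shape[0] * np.finfo(float).eps * max(w.max(), 1.0)
    if w.min() <= tol:
        raise DataError(
            "rank-deficient within-view covariance; use ridge eps > 0"
        )
    return V @ np.diag(1.0 / np.sqrt(w)) @ V.T


def canonical_correlations(
    X: np.ndarray, Y: np.ndarray, n_components: int | None = None, eps: float = 1e-3
) -> np.ndarray:
    """Canonical correlations between two feature x cell profile views.

    ``X`` and ``Y`` are (n_features, cells) arrays over the same ordered
    features. Returns the non-increasing vector of canonical correlations in
    [0, 1], computed by SVD of the whitened cross-covariance with ridge
    regularization ``eps`` on each within-view covariance.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise DataError("profiles must share the same ordered feature rows")
    if X.shape[1] < 2 or Y.shape[1] < 2:
        raise DataError("each profile needs at least 2 cells")
    max_comp = min(X.shape[1], Y.shape[1], X.shape[0])
    k = max_comp if n_components is None else n_components
    if k > max_comp:
        raise DataError(f"n_components > {max_comp} not identifiable")
    Sxx = _view_cov(X, X)
    Syy = _view_cov(Y, Y)
    Sxy = _view_cov(X, Y)
    M = _inv_sqrt(Sxx, eps) @ Sxy @ _inv_sqrt(Syy, eps)
    svals = np.linalg.svd(M, compute_uv=False)
    return np.clip(svals[:k], 0.0, 1.0)


def _cmp_cc(a: np.ndarray, b: np.ndarray, tol: float = TIE_TOL) -> tuple[int, int]:
    """Lexicographic comparison of correlation vectors with tie tolerance.

    Returns (sign, depth): sign>0 if a>b decided at canonical depth ``depth``
    (1-based); (0, len) if indistinguishable throughout.
    """
    m = min(len(a), len(b))
    for i in range(m):
        d = a[i] - b[i]
        if abs(d) >= tol:
            return (1 if d > 0 else -1), i + 1
    return 0, m


@dataclass
class CorrespondenceMap:
    """Cross-sample subtype assignment with its canonical-correlation audit."""

    assignment: pd.DataFrame  # sample, cluster, subtype, cc1, cc2, tie_depth
    pairs: pd.DataFrame  # every scored cross-sample pair with its cc vector
    eps: float
    merged: list[list[tuple[str, int]]] = field(default_factory=list)

    def subtype_of(self, sample: str, cluster: int) -> str:
        sel = self.assignment[
            (self.assignment["sample"] == sample)
            & (self.assignment["cluster"] == cluster)
        ]
        return str(sel["subtype"].iloc[0])


class _UnionFind:
    def __init__(self, keys):
        self.parent = {k: k for k in keys}

    def find(self, k):
        while self.parent[k] != k:
            self.parent[k] = self.parent[self.parent[k]]
            k = self.parent[k]
        return k

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def match_clusters(
    profiles: dict[str, dict[int, np.ndarray]],
    n_components: int = 5,
    eps: float = 1e-3,
) -> CorrespondenceMap:
    """Assemble per-sample CAF clusters into shared subtypes.

    ``profiles[sample][cluster]`` is the (features x cells) normalized profile
    of one cluster, all over the same ordered common variable features.
    """
    samples = list(profiles)
    if len(samples) < 2:
        raise DataError("need clusters from at least two samples to match")
    keys = [(s, c) for s in samples for c in profiles[s]]
    if any(len(profiles[s]) == 0 for s in samples):
        raise DataError("every sample must contribute at least one cluster")

    pair_rows = []
    pair_cc: dict[tuple, np.ndarray] = {}
    for i, sa in enumerate(samples):
        for sb in samples[i + 1 :]:
            for ca, Xa in profiles[sa].items():
                for cb, Xb in profiles[sb].items():
                    k = min(n_components, Xa.shape[1], Xb.shape[1], Xa.shape[0])
                    cc = canonical_correlations(Xa, Xb, n_components=k, eps=eps)
                    key = (sa, ca, sb, cb)
                    pair_cc[key] = cc
                    pair_rows.append(
                        {
                            "sample_a": sa,
                            "cluster_a": ca,
                            "sample_b": sb,
                            "cluster_b": cb,
                            **{f"cc{j + 1}": cc[j] for j in range(len(cc))},
                        }
                    )

    order = sorted(
        pair_cc,
        key=functools.cmp_to_key(
            lambda p, q: -_cmp_cc(pair_cc[p], pair_cc[q])[0]
        ),
    )

    uf = _UnionFind(keys)
    members: dict = {k: {k} for k in keys}
    accepted: dict[tuple, tuple[np.ndarray, int]] = {}
    for idx, key in enumerate(order):
        sa, ca, sb, cb = key
        ra, rb = uf.find((sa, ca)), uf.find((sb, cb))
        if ra == rb:
            continue
        ga, gb = members[ra], members[rb]
        samples_a = {s for s, _ in ga}
        samples_b = {s for s, _ in gb}
        if samples_a & samples_b:
            continue  # would place two clusters of one sample in one subtype
        uf.union(ra, rb)
        root = uf.find(ra)
        members[root] = ga | gb
        # tie depth: canonical depth needed to beat the next-ranked competitor
        depth = 1
        if idx + 1 < len(order):
            sign, d = _cmp_cc(pair_cc[key], pair_cc[order[idx + 1]])
            depth = d if sign != 0 else d
        accepted[key] = (pair_cc[key], depth)

    groups: dict = {}
    for k in keys:
        groups.setdefault(uf.find(k), []).append(k)
    ordered_groups = sorted(
        groups.values(), key=lambda g: (-len(g), sorted(g)[0])
    )
    rows = []
    for gi, group in enumerate(ordered_groups):
        name = f"ST{gi}"
        if len(group) == 1:
            log.info("unmatched cluster %s assigned singleton subtype %s",
                     group[0], name)
        for sample, cluster in sorted(group):
            best_cc, depth = None, 1
            for key, (cc, d) in accepted.items():
                if (key[0], key[1]) == (sample, cluster) or (key[2], key[3]) == (
                    sample,
                    cluster,
                ):
                    if best_cc is None or cc[0] > best_cc[0]:
                        best_cc, depth = cc, d
            rows.append(
                {
                    "sample": sample,
                    "cluster": cluster,
                    "subtype": name,
                    "cc1": np.nan if best_cc is None else best_cc[0],
                    "cc2": np.nan
                    if best_cc is None or len(best_cc) < 2
                    else best_cc[1],
                    "tie_depth": depth,
                }
            )
    assignment = pd.DataFrame(rows)
    return CorrespondenceMap(
        assignment=assignment,
        pairs=pd.DataFrame(pair_rows),
        eps=eps,
        merged=[sorted(g) for g in ordered_groups],
    )


def name_subtype_by_marker(
    cmap: CorrespondenceMap,
    cluster_marker_means: dict[tuple[str, int], float],
    marker: str,
    min_ratio: float = 2.0,
) -> CorrespondenceMap:
    """Rename the subtype with clearly the highest marker expression.

    The subtype whose member clusters have the highest average marker mean is
    renamed to ``<marker>+`` when that mean is at least ``min_ratio`` times
    the next subtype's; otherwise the map is returned unchanged.
    """
    means = (
        cmap.assignment.assign(
            m=[
                cluster_marker_means.get((r.sample, r.cluster), np.nan)
                for r in cmap.assignment.itertuples()
            ]
        )
        .groupby("subtype")["m"]
        .mean()
        .sort_values(ascending=False)
    )
    if len(means) >= 2 and means.iloc[0] < min_ratio * max(means.iloc[1], 1e-12):
        return cmap
    top = means.index[0]
    cmap.assignment["subtype"] = cmap.assignment["subtype"].replace(
        {top: f"{marker}+"}
    )
    return cmap


def _dense(values) -> np.ndarray:
    return np.asarray(values.todense()) if sp.issparse(values) else np.asarray(values)


def wilcoxon_de(
    nm: np.ndarray | sp.spmatrix,
    genes: pd.Index | list[str],
    group_a: np.ndarray,
    group_b: np.ndarray,
    min_positive_fraction: float = 0.1,
    pseudocount: float = 1e-9,
) -> pd.DataFrame:
    """Two-sided rank-sum DE per gene on normalized values.

    ``nm`` is cells x genes; ``group_a``/``group_b`` are row indices. Genes
    detected in fewer than ``min_positive_fraction`` of cells in both groups
    are skipped. avg log2FC = log2((mean expm1 a + ps) / (mean expm1 b + ps)).
    Exact p-values for small groups (combined n <= 20, no ties), the
    tie-corrected normal approximation otherwise. Adds BH-adjusted p.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise DataError("both groups need at least 3 cells")
    A = _dense(nm[group_a])
    B = _dense(nm[group_b])
    frac_a = (A > 0).mean(axis=0)
    frac_b = (B > 0).mean(axis=0)
    keep = (frac_a >= min_positive_fraction) | (frac_b >= min_positive_fraction)
    genes = pd.Index(genes)[keep]
    A, B = A[:, keep], B[:, keep]
    frac_a, frac_b = frac_a[keep], frac_b[keep]
    n_a, n_b = A.shape[0], B.shape[0]
    n = n_a + n_b

    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    pvals = np.ones(A.shape[1])
    if n <= 20:
        for j in range(A.shape[1]):
            a, b = A[:, j], B[:, j]
            if np.all(a == a[0]) and np.all(b == a[0]):
                pvals[j] = 1.0
                continue
            ties = len(np.unique(np.concatenate([a, b]))) < n
            res = stats.mannwhitneyu(
                a, b, alternative="two-sided",
                method="asymptotic" if ties else "exact",
            )
            pvals[j] = res.pvalue
    else:
        Z = np.vstack([A, B])
        ranks = stats.rankdata(Z, axis=0)
        U = ranks[:n_a].sum(axis=0) - n_a * (n_a + 1) / 2
        mu = n_a * n_b / 2.0
        # tie correction per gene
        tie_term = np.zeros(Z.shape[1])
        for j in range(Z.shape[1]):
            _, cnt = np.unique(Z[:, j], return_counts=True)
            tie_term[j] = np.sum(cnt**3 - cnt)
        sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        degenerate = sigma2 <= 0
        sigma = np.sqrt(np.where(degenerate, 1.0, sigma2))
        z = (np.abs(U - mu) - 0.5) / sigma
        z = np.maximum(z, 0.0)
        pvals = 2 * stats.norm.sf(z)
        pvals = np.clip(pvals, 0.0, 1.0)
        pvals[degenerate] = 1.0

    out = pd.DataFrame(
        {
            "p": pvals,
            "log2fc": log2fc,
            "frac_a": frac_a,
            "frac_b": frac_b,
        },
        index=genes,
    )
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("p")


def robust_markers(
    de_tables: dict[str, pd.DataFrame], top_n: int = 75
) -> pd.DataFrame:
    """Cross-sample robust markers of one subtype.

    Intersect each sample's ``top_n`` lowest-p genes and drop genes whose
    average log2FC sign varies across samples. Returns a table indexed by
    gene with per-sample p/log2FC, mean_p, mean_log2fc and sign_consistent.
    """
    if len(de_tables) < 2:
        raise DataError("need DE tables from at least two samples")
    tops = {
        s: t.nsmallest(top_n, "p") for s, t in de_tables.items()
    }
    common: set[str] | None = None
    for t in tops.values():
        common = set(t.index) if common is None else common & set(t.index)
    if not common:
        log.info("robust_markers: empty top-%d intersection", top_n)
    rows = []
    for g in sorted(common or set()):
        ps = [tops[s].loc[g, "p"] for s in de_tables]
        fcs = [tops[s].loc[g, "log2fc"] for s in de_tables]
        consistent = all(f > 0 for f in fcs) or all(f < 0 for f in fcs)
        rows.append(
            {
                "gene": g,
                "mean_p": float(np.mean(ps)),
                "mean_log2fc": float(np.mean(fcs)),
                "sign_consistent": consistent,
                **{f"p_{s}": p for s, p in zip(de_tables, ps)},
                **{f"log2fc_{s}": f for s, f in zip(de_tables, fcs)},
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene", "mean_p", "mean_log2fc", "sign_consistent"]
        + [f"p_{s}" for s in de_tables]
        + [f"log2fc_{s}" for s in de_tables],
    )
    df = df[df["sign_consistent"]].set_index("gene")
    return df.sort_values("mean_p")
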