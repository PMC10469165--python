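"""Ligand-receptor cross-talk scoring and the cross-sample aggregation rules.

The per-pair scoring law is deliberately simple: the interaction score of
(ligand, receptor) from a sender group to a receiver group is the product of
the sender-group mean of the back-transformed ligand expression and the
receiver-group mean of the back-transformed receptor expression. Significance
comes from a permutation test randomly relabeling group membership within the
sender/receiver cell pool (add-one corrected tail probability). The
aggregation layer — per-sample BH selection, overlap with CAFs, cross-sample
intersection of interaction identities, and the paired signed-rank comparison
of interaction frequencies between two subtypes — is the reusable analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from caflineage.errors import DataError
from caflineage.subtypes import _dense

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LRInteraction:
    ligand: str
    receptor: str
    sender: str
    receiver: str
    score: float
    p: float
    sample: str = ""

    @property
    def identity(self) -> tuple[str, str, str, str]:
        return (self.ligand, self.receptor, self.sender, self.receiver)


def lr_score(
    nm: np.ndarray | sp.spmatrix,
    genes: pd.Index | list[str],
    ligand: str,
    receptor: str,
    sender_cells: np.ndarray,
    receiver_cells: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    sender: str = "sender",
    receiver: str = "receiver",
    sample: str = "",
) -> LRInteraction:
    """Score one ligand-receptor pair between a sender and a receiver group.

    score = mean(expm1 ligand | senders) * mean(expm1 receptor | receivers);
    p is the add-one-corrected fraction of group-relabeling permutations with
    a score >= the observed one.
    """
    genes = pd.Index(genes)
    for g in (ligand, receptor):
        if g not in set(genes):
            raise DataError(f"gene {g!r} not in matrix")
    if len(sender_cells) < 10 or len(receiver_cells) < 10:
        raise DataError("sender and receiver groups need >= 10 cells")
    X = _dense(nm)
    lig = np.expm1(X[:, genes.get_loc(ligand)])
    rec = np.expm1(X[:, genes.get_loc(receptor)])
    s_idx = np.asarray(sender_cells)
    r_idx = np.asarray(receiver_cells)
    obs = lig[s_idx].mean() * rec[r_idx].mean()
    if obs == 0.0:
        return LRInteraction(ligand, receptor, sender, receiver, 0.0, 1.0, sample)

    rng = np.random.default_rng(seed)
    pool = np.concatenate([s_idx, r_idx])
    n_s = len(s_idx)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        stat = lig[perm[:n_s]].mean() * rec[perm[n_s:]].mean()
        if stat >= obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return LRInteraction(ligand, receptor, sender, receiver, float(obs), float(p), sample)


def _permuted_group_means(
    values: np.ndarray, pool: np.ndarray, n_first: int, n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Means of ``values`` columns over permuted splits of ``pool``.

    values: cells x genes; returns (n_perm x genes) means for the first
    n_first cells of each permutation and for the rest.
    """
    first = np.empty((n_perm, values.shape[1]))
    second = np.empty((n_perm, values.shape[1]))
    for i in range(n_perm):
        perm = rng.permutation(pool)
        first[i] = values[perm[:n_first]].mean(axis=0)
        second[i] = values[perm[n_first:]].mean(axis=0)
    return first, second


def sample_interactions(
    nm: np.ndarray | sp.spmatrix,
    genes: pd.Index | list[str],
    groups: pd.Series,
    lr_table: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    min_group_size: int = 10,
    sample: str = "",
) -> pd.DataFrame:
    """Score every (pair, sender group, receiver group) combination.

    ``groups`` maps each cell (row of ``nm``) to its interaction group
    (cancer clusters, T cells, myeloid, endothelial, CAF subtypes, ...).
    Missing LR genes are skipped with a log entry. Significant interactions
    are those with BH-adjusted q <= alpha within the sample; the returned
    table carries score, p and q for every scored combination plus a
    ``significant`` flag.
    """
    genes = pd.Index(genes)
    groups = pd.Series(groups)
    X = np.expm1(_dense(nm))
    counts = groups.value_counts()
    labels = sorted(
        (g for g, cnt in counts.items() if cnt >= min_group_size),
        key=lambda g: (-counts[g], str(g)),
    )
    idx_of = {g: np.flatnonzero((groups == g).to_numpy()) for g in labels}
    pairs = []
    for lig, rec in lr_table[["ligand", "receptor"]].itertuples(index=False):
        if lig not in set(genes) or rec not in set(genes):
            log.info("skipping LR pair (%s, %s): gene missing", lig, rec)
            continue
        pairs.append((lig, rec))
    if not pairs:
        raise DataError("no scoreable ligand-receptor pairs")
    lig_cols = genes.get_indexer([p[0] for p in pairs])
    rec_cols = genes.get_indexer([p[1] for p in pairs])

    rng = np.random.default_rng(seed)
    rows = []
    for sg in labels:
        for rg in labels:
            if sg == rg:
                continue
            s_idx, r_idx = idx_of[sg], idx_of[rg]
            pool = np.concatenate([s_idx, r_idx])
            vals = X[pool]
            lig_obs = X[s_idx][:, lig_cols].mean(axis=0)
            rec_obs = X[r_idx][:, rec_cols].mean(axis=0)
            obs = lig_obs * rec_obs
            local = np.arange(len(pool))
            pf, ps = _permuted_group_means(
                vals[:, np.concatenate([lig_cols, rec_cols])],
                local, len(s_idx), n_perm, rng,
            )
            k = len(pairs)
            perm_scores = pf[:, :k] * ps[:, k:]
            count = (perm_scores >= obs[None, :]).sum(axis=0)
            p = np.where(obs > 0, (count + 1) / (n_perm + 1), 1.0)
            for j, (lig, rec) in enumerate(pairs):
                rows.append(
                    {
                        "sample": sample,
                        "ligand": lig,
                        "receptor": rec,
                        "sender": sg,
                        "receiver": rg,
                        "score": obs[j],
                        "p": p[j],
                    }
                )
    out = pd.DataFrame(rows)
    # BH within each sender->receiver communication family: a permutation p
    # has a floor of 1/(n_perm+1), so adjusting across every family at once
    # could never declare any interaction significant; the family of ligand-
    # receptor pairs per channel is the conventional adjustment unit.
    out["q"] = (
        out.groupby(["sender", "receiver"])["p"]
        .transform(lambda p: multipletests(p.to_numpy(), method="fdr_bh")[1])
    )
    out["significant"] = out["q"] <= alpha
    return out


def significant_set(interactions: pd.DataFrame) -> set[tuple[str, str, str, str]]:
    sig = interactions[interactions["significant"]]
    return {
        (r.ligand, r.receptor, r.sender, r.receiver) for r in sig.itertuples()
    }


def common_interactions(
    per_sample: dict[str, pd.DataFrame],
    caf_prefix: str = "CAF",
) -> set[tuple[str, str, str, str]]:
    """Interactions involving CAFs found in every sample.

    Within each sample, collect the significant interactions where sender or
    receiver is a CAF group; then intersect interaction identities (ligand,
    receptor, sender, receiver) across samples.
    """
    if len(per_sample) < 2:
        raise DataError("need interaction sets from at least two samples")
    sets = []
    for sample, tab in per_sample.items():
        ids = {
            i
            for i in significant_set(tab)
            if i[2].startswith(caf_prefix) or i[3].startswith(caf_prefix)
        }
        sets.append(ids)
    common = sets[0]
    for s in sets[1:]:
        common &= s
    return common


def interaction_counts(
    interactions: pd.DataFrame, group: str
) -> tuple[int, int]:
    """(incoming, outgoing) significant interaction counts for a group."""
    sig = interactions[interactions["significant"]]
    incoming = int((sig["receiver"] == group).sum())
    outgoing = int((sig["sender"] == group).sum())
    return incoming, outgoing


def interaction_frequency_compare(
    counts_a: np.ndarray, counts_b: np.ndarray, alternative: str = "greater"
) -> dict:
    """Paired signed-rank comparison of per-sample interaction frequencies.

    ``counts_a`` and ``counts_b`` are paired per-sample counts for the two
    subtypes. Uses the exact Wilcoxon signed-rank distribution for few pairs
    (scipy's exact mode), reporting direction, statistic and p. All-zero
    differences give p = 1.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise DataError("need equal-length paired count vectors (>= 2 pairs)")
    d = a - b
    if np.all(d == 0):
        return {"statistic": 0.0, "p": 1.0, "direction": "equal", "n": int(a.size)}
    nz = d[d != 0]  # zero differences dropped, classic signed-rank convention
    r = stats.rankdata(np.abs(nz))
    w_plus = float(r[nz > 0].sum())
    n = nz.size
    if n <= 15:
        # exact null: enumerate all 2^n sign assignments of the ranks
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        w_all = signs @ r
        p_ge = float(np.mean(w_all >= w_plus))
        p_le = float(np.mean(w_all <= w_plus))
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        res = stats.wilcoxon(nz, alternative=alternative, method="approx")
        p = float(res.pvalue)
    direction = "a_greater" if np.median(d) > 0 else (
        "b_greater" if np.median(d) < 0 else "mixed"
    )
    return {
        "statistic": w_plus,
        "p": float(p),
        "direction": direction,
        "n": int(a.size),
    }
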