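"""Community-ecology statistics.

Rarefaction (subsampling without replacement), alpha diversity, Bray-Curtis
dissimilarity, non-metric multidimensional scaling, ANOSIM, SIMPER
decomposition, and weighted UniFrac. All statistics operate on the package's
samples x features :class:`~ribotide.containers.CountTable` and on
:class:`skbio.DistanceMatrix` objects.

ANOSIM follows Clarke's rank formulation

    R = (rbar_between - rbar_within) / (M / 2),   M = n (n - 1) / 2,

with mid-ranks for ties and a label-permutation p-value with the +1
correction. SIMPER decomposes the mean between-group Bray-Curtis
dissimilarity into additive per-feature contributions; the contributions sum
exactly to the mean between-group dissimilarity.

Weighted UniFrac weights each branch by the absolute difference in the
fraction of each sample's counts descending through it; the normalized
variant (the default) divides by the branch-length-weighted sum of the two
profiles, giving values in [0, 1] that are comparable across sequencing
depths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.stats import rankdata
from sklearn.manifold import MDS

from .containers import CountTable, as_group_series
from .errors import ValidationError
from .io import spawn_rng

logger = logging.getLogger("ribotide")


# ---------------------------------------------------------------------------
# Rarefaction and alpha diversity
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning; if no
    sample reaches the depth this is an error. Each retained sample's counts
    follow a multivariate hypergeometric draw, so every row of the result
    sums to exactly ``depth``.
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    totals = table.sample_totals()
    keep = totals.index[totals >= depth].tolist()
    dropped = totals.index[totals < depth].tolist()
    if not keep:
        raise ValidationError(
            f"rarefaction depth {depth} exceeds every sample total "
            f"(max {int(totals.max()) if len(totals) else 0})"
        )
    if dropped:
        logger.warning("rarefy: dropping samples below depth %d: %s", depth, dropped)
    rng = spawn_rng(seed, "rarefy")
    out = np.empty((len(keep), table.shape[1]), dtype=np.int64)
    for i, sid in enumerate(keep):
        row = table.df.loc[sid].to_numpy()
        out[i] = rng.multivariate_hypergeometric(row, depth)
    logger.info("rarefy: %d samples rarefied to depth %d (%d dropped)",
                len(keep), depth, len(dropped))
    return CountTable.from_arrays(keep, table.feature_ids, out)


def rarefaction_curve(
    table: CountTable,
    depths: list[int],
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean observed richness per sample at each rarefaction depth.

    Returns a depths x samples DataFrame of the mean (over replicates) number
    of features observed in a without-replacement subsample. Depths beyond a
    sample's total yield NaN for that sample.
    """
    if sorted(depths) != list(depths):
        raise ValidationError("depths must be increasing")
    rng = spawn_rng(seed, "rarefaction_curve")
    totals = table.sample_totals()
    result = pd.DataFrame(index=pd.Index(depths, name="depth"),
                          columns=table.sample_ids, dtype=float)
    for sid in table.sample_ids:
        row = table.df.loc[sid].to_numpy()
        total = int(totals[sid])
        for depth in depths:
            if depth > total:
                continue
            richness = [
                int((rng.multivariate_hypergeometric(row, depth) > 0).sum())
                for _ in range(replicates)
            ]
            result.loc[depth, sid] = float(np.mean(richness))
    return result


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Observed richness and Shannon index (natural log) per sample.

    All-zero samples get richness 0, Shannon 0, and ``undefined=True``.
    """
    values = table.values
    richness = (values > 0).sum(axis=1)
    totals = values.sum(axis=1)
    shannon = np.zeros(len(totals))
    undefined = totals == 0
    for i in np.nonzero(~undefined)[0]:
        p = values[i][values[i] > 0] / totals[i]
        shannon[i] = float(-(p * np.log(p)).sum())
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon, "undefined": undefined},
        index=table.sample_ids,
    )


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(table: CountTable) -> skbio.DistanceMatrix:
    """BC(j,k) = sum_i |y_ij - y_ik| / sum_i (y_ij + y_ik)."""
    values = table.values.astype(float)
    totals = values.sum(axis=1)
    if (totals == 0).any():
        empty = [table.sample_ids[i] for i in np.nonzero(totals == 0)[0]]
        raise ValidationError(f"Bray-Curtis undefined for all-zero samples: {empty}")
    n = len(values)
    dm = np.zeros((n, n))
    for j in range(n):
        diff = np.abs(values[j] - values[j + 1 :]).sum(axis=1)
        dm[j, j + 1 :] = diff / (totals[j] + totals[j + 1 :])
    dm += dm.T
    return skbio.DistanceMatrix(dm, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# Non-metric MDS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NmdsResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float  # Kruskal stress-1 of the best restart


def _pcoa_init(dm: np.ndarray, k: int) -> np.ndarray:
    """Classical (principal-coordinates) embedding used as one nMDS start."""
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return coords


def nmds(
    dm: skbio.DistanceMatrix,
    k: int = 2,
    n_restarts: int = 8,
    seed: int = 0,
    max_iter: int = 300,
) -> NmdsResult:
    """Kruskal non-metric MDS of a dissimilarity matrix.

    SMACOF with isotonic (monotone) regression of configuration distances on
    dissimilarity ranks, run from a principal-coordinates start plus
    ``n_restarts`` random starts; the configuration with the lowest Kruskal
    stress-1 is returned. Deterministic for a fixed seed.
    """
    n = len(dm.ids)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k >= n:
        raise ValidationError(f"k = {k} must be smaller than the number of samples {n}")
    data = dm.data
    rng = spawn_rng(seed, "nmds")
    inits = [_pcoa_init(data, k)]
    inits += [rng.normal(size=(n, k)) for _ in range(n_restarts)]
    best_coords, best_stress = None, np.inf
    for init in inits:
        model = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            n_init=1,
            init="random",  # overridden by the explicit init below
            max_iter=max_iter,
            normalized_stress=True,
            random_state=0,
        )
        coords = model.fit_transform(data, init=init)
        if model.stress_ < best_stress:
            best_stress, best_coords = float(model.stress_), coords
    cols = [f"MDS{i + 1}" for i in range(k)]
    return NmdsResult(pd.DataFrame(best_coords, index=list(dm.ids), columns=cols),
                      best_stress)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray, m: int) -> float:
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    dm: skbio.DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Clarke's analysis of similarities with a permutation p-value.

    Requires at least two groups, each with at least two samples. The
    p-value is (1 + #{permuted R >= observed R}) / (1 + n_permutations).
    """
    groups = as_group_series(groups)
    ids = list(dm.ids)
    missing = [s for s in ids if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without group labels: {missing}")
    labels = groups.loc[ids].to_numpy()
    uniq, sizes = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (sizes < 2).any():
        raise ValidationError("ANOSIM needs >= 2 groups each with >= 2 samples")

    n = len(ids)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm.data[iu])  # mid-ranks for ties
    m = n * (n - 1) // 2
    codes = pd.factorize(labels)[0]
    within = codes[iu[0]] == codes[iu[1]]
    r_obs = _anosim_r(ranks, within, m)

    rng = spawn_rng(seed, "anosim")
    # vectorized permutation null: P x M within-masks, means via matmul
    perms = np.argsort(rng.random((n_permutations, n)), axis=1)
    permuted = codes[perms]  # (P, n)
    masks = permuted[:, iu[0]] == permuted[:, iu[1]]  # (P, M)
    n_within = masks.sum(axis=1)
    sum_within = masks @ ranks
    rw = sum_within / n_within
    rb = (ranks.sum() - sum_within) / (m - n_within)
    r_perm = (rb - rw) / (m / 2.0)
    p = (1 + int((r_perm >= r_obs - 1e-12).sum())) / (1 + n_permutations)
    return AnosimResult(R=r_obs, p_value=p, n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

def simper(
    table: CountTable,
    groups,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-feature decomposition of mean between-group Bray-Curtis.

    For each between-group pair (j, k) the feature contribution is
    |y_ij - y_ik| / sum_m (y_mj + y_mk); averaging over pairs gives additive
    contributions whose sum is exactly the mean between-group dissimilarity.
    Returns a DataFrame (feature_id, mean_contribution, contribution_pct,
    cumulative_pct) sorted by contribution.
    """
    if group_a == group_b:
        raise ValidationError("SIMPER requires two distinct groups")
    groups = as_group_series(groups)
    a_ids = [s for s in table.sample_ids if groups.get(s) == group_a]
    b_ids = [s for s in table.sample_ids if groups.get(s) == group_b]
    if not a_ids or not b_ids:
        raise ValidationError(f"empty group: {group_a!r} or {group_b!r}")
    a = table.df.loc[a_ids].to_numpy(float)
    b = table.df.loc[b_ids].to_numpy(float)
    contrib = np.zeros(table.shape[1])
    n_pairs = 0
    for row_a in a:
        denom = row_a.sum() + b.sum(axis=1)  # per b-sample
        if (denom == 0).any():
            raise ValidationError("SIMPER undefined when a sample pair has zero total")
        contrib += (np.abs(row_a - b) / denom[:, None]).sum(axis=0)
        n_pairs += len(b)
    contrib /= n_pairs
    total = contrib.sum()
    pct = 100 * contrib / total if total > 0 else np.zeros_like(contrib)
    out = pd.DataFrame(
        {"feature_id": table.feature_ids, "mean_contribution": contrib,
         "contribution_pct": pct}
    ).sort_values(["mean_contribution", "feature_id"], ascending=[False, True])
    out["cumulative_pct"] = out["contribution_pct"].cumsum()
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Weighted UniFrac
# ---------------------------------------------------------------------------

def _branch_proportions(table: CountTable, tree: skbio.TreeNode) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch descending count proportions for every sample.

    Returns (lengths, props) where props[s, b] is the fraction of sample s's
    total counts descending through branch b (one branch per non-root node).
    """
    tips = {t.name for t in tree.tips()}
    present = table.df.columns[(table.values > 0).any(axis=0)]
    missing = [f for f in present if f not in tips]
    if missing:
        raise ValidationError(f"features with counts absent from tree: {missing}")
    totals = table.sample_totals().to_numpy(float)
    if (totals == 0).any():
        empty = [table.sample_ids[i] for i in np.nonzero(totals == 0)[0]]
        raise ValidationError(f"weighted UniFrac undefined for all-zero samples: {empty}")
    n = table.shape[0]
    col = {f: i for i, f in enumerate(table.feature_ids)}
    sums: dict[int, np.ndarray] = {}
    lengths, props = [], []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = (table.values[:, col[node.name]].astype(float)
                   if node.name in col else np.zeros(n))
        else:
            vec = np.zeros(n)
            for child in node.children:
                vec = vec + sums[id(child)]
        sums[id(node)] = vec
        if not node.is_root():
            lengths.append(float(node.length or 0.0))
            props.append(vec / totals)
    return np.asarray(lengths), np.asarray(props).T  # (B,), (n, B)


def weighted_unifrac(
    table: CountTable,
    tree: skbio.TreeNode,
    normalized: bool = True,
) -> skbio.DistanceMatrix:
    """Weighted UniFrac between all sample pairs.

    raw(j,k) = sum_b l_b |p_j(b) - p_k(b)|; the normalized variant divides by
    sum_b l_b (p_j(b) + p_k(b)), bounding values in [0, 1]. Every feature
    with nonzero counts must be a tree leaf.
    """
    lengths, props = _branch_proportions(table, tree)
    n = table.shape[0]
    dm = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            num = float((lengths * np.abs(props[j] - props[k])).sum())
            if normalized:
                den = float((lengths * (props[j] + props[k])).sum())
                dm[j, k] = num / den if den > 0 else 0.0
            else:
                dm[j, k] = num
    dm += dm.T
    return skbio.DistanceMatrix(dm, ids=table.sample_ids)
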