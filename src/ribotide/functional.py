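"""Metatranscriptome functional-count analysis.

Reads-per-million and median-of-ratios normalization, KO -> pathway
aggregation, lowest-common-ancestor taxon assignment, a subsample-resampling
differential-abundance test between two libraries, and viral-quotient
scoring/filtering of phage orthologous groups (POGs).

The differential test draws ``resample_n`` pairs of multinomial subsamples of
``resample_size`` hits from each library's empirical proportions and records
the per-feature count difference each round; a matching null distribution is
built by drawing both subsamples from the pooled proportions. A feature is
significant when its central ``resample_conf`` observed interval is disjoint
from the null interval.

The viral quotient VQ = v / (v + h) measures how exclusively a POG occurs in
phage genomes, where v and h are per-genome-normalized hit rates to viral and
prokaryotic references (prophage regions excluded from h).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ValidationError
from .io import spawn_rng

logger = logging.getLogger("ribotide")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_rpm(counts: pd.DataFrame, total_reads: pd.Series) -> pd.DataFrame:
    """Reads-per-million: count / total_reads x 1e6, per sample (rows)."""
    totals = total_reads.loc[counts.index].astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValidationError(f"non-positive total_reads for samples: {bad}")
    sums = counts.sum(axis=1)
    if (sums > totals).any():
        bad = sums.index[sums > totals].tolist()
        raise ValidationError(f"assigned counts exceed total reads for: {bad}")
    return counts.div(totals, axis=0) * 1e6


def size_factor_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size factors followed by a log2(x + 1) transform.

    A variance-stabilizing stand-in for count-depth normalization: the size
    factor of a sample is the median, over features nonzero in every sample,
    of count / geometric-mean(count across samples); normalized values are
    count / size_factor, then log2(x + 1). Samples are rows.
    """
    if counts.shape[0] < 2:
        raise ValidationError("size-factor normalization needs >= 2 samples")
    values = counts.to_numpy(float)
    everywhere = (values > 0).all(axis=0)
    if not everywhere.any():
        raise ValidationError(
            "no feature is nonzero in all samples; filter features first"
        )
    ref = values[:, everywhere]
    log_geo_mean = np.log(ref).mean(axis=0)
    factors = np.exp(np.median(np.log(ref) - log_geo_mean, axis=1))
    normed = np.log2(values / factors[:, None] + 1.0)
    sf = pd.Series(factors, index=counts.index, name="size_factor")
    return pd.DataFrame(normed, index=counts.index, columns=counts.columns), sf


def aggregate_pathways(
    normalized: pd.DataFrame, ko_to_pathways: dict[str, list[str]]
) -> pd.DataFrame:
    """Average per-KO normalized values into pathway summaries (samples x pathways).

    A KO belonging to several pathways contributes to each; pathways with no
    KO present in the table are omitted.
    """
    if not ko_to_pathways:
        raise ValidationError("empty KO -> pathway map")
    members: dict[str, list[str]] = {}
    for ko, pathways in ko_to_pathways.items():
        if ko not in normalized.columns:
            continue
        for pw in pathways:
            members.setdefault(pw, []).append(ko)
    out = {pw: normalized[kos].mean(axis=1) for pw, kos in sorted(members.items())}
    return pd.DataFrame(out, index=normalized.index)


# ---------------------------------------------------------------------------
# Lowest common ancestor
# ---------------------------------------------------------------------------

class TaxonomyTree:
    """Rooted taxonomy with parent pointers; supports LCA queries."""

    def __init__(self, parents: dict[str, str | None]):
        roots = [n for n, p in parents.items() if p is None]
        if len(roots) != 1:
            raise ValidationError(f"taxonomy must have exactly one root, got {roots}")
        self.root = roots[0]
        self.parents = dict(parents)
        for node, parent in parents.items():
            if parent is not None and parent not in parents:
                raise ValidationError(f"node {node!r} has unknown parent {parent!r}")
        # cycle check via path-to-root walk
        for node in parents:
            seen = set()
            cur: str | None = node
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"cycle in taxonomy at {cur!r}")
                seen.add(cur)
                cur = self.parents[cur]

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str]]) -> "TaxonomyTree":
        """Build from (child, parent) pairs; the one parent never appearing
        as a child becomes the root."""
        parents: dict[str, str | None] = {c: p for c, p in edges}
        for _, p in edges:
            parents.setdefault(p, None)
        return cls(parents)

    def path_to_root(self, node: str) -> list[str]:
        if node not in self.parents:
            raise ValidationError(f"unknown taxon id {node!r}")
        path = [node]
        while self.parents[path[-1]] is not None:
            path.append(self.parents[path[-1]])
        return path

    def lca(self, nodes: list[str]) -> str:
        paths = [self.path_to_root(n)[::-1] for n in nodes]
        lca = self.root
        for level in zip(*paths):
            if len(set(level)) == 1:
                lca = level[0]
            else:
                break
        return lca


def lca_assign(
    hits: dict[str, list[tuple[str, float]]],
    tree: TaxonomyTree,
    score_margin: float = 0.1,
) -> dict[str, str | None]:
    """Assign each read to the LCA of its near-best hits.

    Hits scoring >= (1 - score_margin) x the read's best score are retained;
    the read is placed at the LCA of their taxa. Reads with no hits map to
    None (unassigned).
    """
    if not 0 <= score_margin <= 1:
        raise ValidationError("score_margin must lie in [0, 1]")
    assignments: dict[str, str | None] = {}
    for read_id, read_hits in hits.items():
        if not read_hits:
            assignments[read_id] = None
            continue
        best = max(score for _, score in read_hits)
        taxa = [t for t, score in read_hits if score >= (1 - score_margin) * best]
        assignments[read_id] = tree.lca(taxa)
    return assignments


# ---------------------------------------------------------------------------
# Resampling differential test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffTestResult:
    feature_id: str
    observed_difference: float  # median per-subsample difference (A - B)
    observed_interval: tuple[float, float]
    null_interval: tuple[float, float]
    significant: bool
    direction: str  # 'A>B' | 'B>A' | '='


def resampling_difference_test(
    count_a: pd.Series,
    count_b: pd.Series,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    rule: str = "disjoint",
) -> list[DiffTestResult]:
    """Subsample-resampling differential abundance between two libraries.

    Draws ``cfg.resample_n`` rounds of multinomial subsamples of
    ``cfg.resample_size`` hits from A's and B's empirical proportions
    (observed distribution) and from the pooled proportions (null
    distribution). Significance rules: ``disjoint`` (default) calls a
    feature when its central ``resample_conf`` observed and null intervals
    do not overlap; ``median_outside`` when the median observed difference
    falls outside the null interval.
    """
    cfg = cfg or PipelineConfig()
    if rule not in ("disjoint", "median_outside"):
        raise ValidationError(f"unknown significance rule {rule!r}")
    features = count_a.index.union(count_b.index, sort=False)
    a = count_a.reindex(features, fill_value=0).to_numpy(float)
    b = count_b.reindex(features, fill_value=0).to_numpy(float)
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("negative counts")
    if a.sum() < cfg.resample_size or b.sum() < cfg.resample_size:
        raise ValidationError(
            f"resample_size {cfg.resample_size} exceeds a library total "
            f"({int(a.sum())}, {int(b.sum())})"
        )
    pa, pb = a / a.sum(), b / b.sum()
    pooled = (a + b) / (a + b).sum()
    rng = spawn_rng(seed, "difftest")

    def draws(p: np.ndarray) -> np.ndarray:
        return rng.multinomial(cfg.resample_size, p, size=cfg.resample_n)

    obs_diff = draws(pa) - draws(pb)  # (n_rounds, F)
    null_diff = draws(pooled) - draws(pooled)
    alpha = 1.0 - cfg.resample_conf
    qs = [alpha / 2, 1 - alpha / 2]
    obs_lo, obs_hi = np.quantile(obs_diff, qs, axis=0)
    null_lo, null_hi = np.quantile(null_diff, qs, axis=0)
    med = np.median(obs_diff, axis=0)
    if rule == "disjoint":
        sig = (obs_lo > null_hi) | (obs_hi < null_lo)
    else:
        sig = (med > null_hi) | (med < null_lo)

    results = []
    for i, fid in enumerate(features):
        direction = "A>B" if med[i] > 0 else ("B>A" if med[i] < 0 else "=")
        results.append(
            DiffTestResult(
                feature_id=str(fid),
                observed_difference=float(med[i]),
                observed_interval=(float(obs_lo[i]), float(obs_hi[i])),
                null_interval=(float(null_lo[i]), float(null_hi[i])),
                significant=bool(sig[i]),
                direction=direction,
            )
        )
    logger.info(
        "difftest: %d features, %d significant at conf %.2f (%s rule)",
        len(features), int(sig.sum()), cfg.resample_conf, rule,
    )
    return results


def difftest_to_frame(results: list[DiffTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "observed_difference": [r.observed_difference for r in results],
            "obs_lo": [r.observed_interval[0] for r in results],
            "obs_hi": [r.observed_interval[1] for r in results],
            "null_lo": [r.null_interval[0] for r in results],
            "null_hi": [r.null_interval[1] for r in results],
            "significant": [r.significant for r in results],
            "direction": [r.direction for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Viral quotient
# ---------------------------------------------------------------------------

def viral_quotient(v: float, h: float) -> float:
    """VQ = v / (v + h); 1 means phage-exclusive, 0 means never in phage.

    v and h are hit rates normalized per reference genome (viral and
    prokaryotic respectively, prophage hits excluded from h); the quotient is
    invariant to a common scaling of both.
    """
    if v < 0 or h < 0:
        raise ValidationError("v and h must be non-negative")
    if v == 0 and h == 0:
        raise ValidationError("viral quotient undefined for v = h = 0")
    return v / (v + h)


@dataclass(frozen=True)
class PogRecord:
    pog_id: str
    v: float
    h: float
    total_counts: int
    vq: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "vq", viral_quotient(self.v, self.h))


def filter_pogs(
    records: list[PogRecord], cfg: PipelineConfig | None = None
) -> list[PogRecord]:
    """Keep POGs with total_counts >= vq_min_counts (inclusive) and
    vq strictly greater than vq_min."""
    cfg = cfg or PipelineConfig()
    kept = [
        r for r in records
        if r.total_counts >= cfg.vq_min_counts and r.vq > cfg.vq_min
    ]
    logger.info(
        "vq filter: %d of %d POGs retained (counts >= %d, VQ > %.2f)",
        len(kept), len(records), cfg.vq_min_counts, cfg.vq_min,
    )
    return kept
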