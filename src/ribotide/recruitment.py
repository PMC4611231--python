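"""Competitive fragment recruitment of reads to a reference genome panel.

A seed-and-extend mapper: exact k-mer seeds against an index of both strands
of every genome, ungapped extension over the full read placement with
match +1 / mismatch -2, and local trimming to the best-scoring segment.
Per read, the single best hit across all genomes is retained, with a total
deterministic tie order (score, then identity, then genome id, then strand,
then position). Substitution-only alignment: the error model upstream plants
no indels, and a gap-free mapper admits an exhaustive alignment oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SequenceRead, revcomp
from .errors import ValidationError

logger = logging.getLogger("ribotide")

MATCH_SCORE = 1.0
MISMATCH_SCORE = -2.0

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class RecruitmentHit:
    read_id: str
    genome_id: str
    position: int  # 0-based start on the forward strand of the genome
    strand: str
    score: float
    identity: float  # matches / aligned columns
    aligned_length: int


@dataclass
class RecruitmentSummary:
    genome_ids: list[str]
    read_counts: dict[str, int]
    proportions: dict[str, float]
    coverage: dict[str, np.ndarray]
    covered_fraction: dict[str, float]
    mean_identity: dict[str, float]
    n_assigned: int


def _encode(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    out.fill(4)
    for base, code in _BASE_CODE.items():
        out[raw == ord(base)] = code
    return out


def _kmer_codes(encoded: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer; -1 where the window contains a non-ACGT base."""
    n = len(encoded) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    e = encoded.astype(np.int64)
    for j in range(k):
        codes = codes * 4 + np.minimum(e[j : j + n], 3)
        valid &= e[j : j + n] < 4
    codes[~valid] = -1
    return codes


class GenomeIndex:
    """Exact k-mer index over both strands of a genome panel."""

    def __init__(self, panel: dict[str, str], k: int = 15):
        if k < 8:
            raise ValidationError("k must be >= 8")
        if not panel:
            raise ValidationError("empty genome panel")
        self.k = k
        self.genome_ids = sorted(panel)
        self.forward = {g: _encode(panel[g]) for g in self.genome_ids}
        self.reverse = {g: _encode(revcomp(panel[g])) for g in self.genome_ids}
        self.lengths = {g: len(panel[g]) for g in self.genome_ids}
        self._index: dict[int, list[tuple[int, int, int]]] = {}
        for gi, g in enumerate(self.genome_ids):
            for si, enc in ((0, self.forward[g]), (1, self.reverse[g])):
                for pos, code in enumerate(_kmer_codes(enc, k)):
                    if code >= 0:
                        self._index.setdefault(int(code), []).append((gi, si, pos))

    def lookup(self, code: int) -> list[tuple[int, int, int]]:
        return self._index.get(code, ())


def _best_segment(eq: np.ndarray) -> tuple[float, int, int]:
    """Best-scoring contiguous segment of a match/mismatch column vector.

    Returns (score, start, end) of the maximum-sum segment under
    match +1 / mismatch -2 (the gapless Smith-Waterman optimum on this
    diagonal). Ties resolve to the leftmost, shortest segment.
    """
    col = np.where(eq, MATCH_SCORE, MISMATCH_SCORE)
    c = np.concatenate([[0.0], np.cumsum(col)])
    run_min = np.minimum.accumulate(c[:-1])
    gains = c[1:] - run_min
    end = int(np.argmax(gains))  # leftmost best end
    score = float(gains[end])
    start = int(np.argmin(c[: end + 1]))
    return score, start, end + 1


def recruit(
    reads,
    panel: dict[str, str] | GenomeIndex,
    k: int = 15,
    min_identity: float = 0.7,
    min_score: float = 40.0,
    seed_stride: int = 1,
) -> list[RecruitmentHit]:
    """Map each read to its single best genome hit.

    ``panel`` may be a prebuilt :class:`GenomeIndex` (reusable across read
    sets). Reads shorter than k are skipped and counted. Candidate diagonals
    are those sharing at least one exact k-mer with the read (sampled every
    ``seed_stride`` positions); each is scored by gapless extension with
    local trimming, then filtered by ``min_identity`` and ``min_score``.
    """
    index = panel if isinstance(panel, GenomeIndex) else GenomeIndex(panel, k)
    k = index.k
    strands = {0: index.forward, 1: index.reverse}
    hits: list[RecruitmentHit] = []
    n_reads = n_short = n_unmapped = 0
    for read in reads:
        bases = read.bases if isinstance(read, SequenceRead) else read[1]
        read_id = read.read_id if isinstance(read, SequenceRead) else read[0]
        n_reads += 1
        if len(bases) < k:
            n_short += 1
            continue
        enc = _encode(bases)
        codes = _kmer_codes(enc, k)
        diagonals: set[tuple[int, int, int]] = set()
        for rp in range(0, len(codes), seed_stride):
            code = codes[rp]
            if code < 0:
                continue
            for gi, si, pos in index.lookup(int(code)):
                diagonals.add((gi, si, pos - rp))
        best: tuple | None = None  # sort key + hit payload
        for gi, si, diag in diagonals:
            g = index.genome_ids[gi]
            gseq = strands[si][g]
            glen = index.lengths[g]
            r0 = max(0, -diag)
            g0 = max(0, diag)
            length = min(len(enc) - r0, glen - g0)
            if length < k:
                continue
            eq = enc[r0 : r0 + length] == gseq[g0 : g0 + length]
            eq &= enc[r0 : r0 + length] < 4
            score, s0, s1 = _best_segment(eq)
            seg_len = s1 - s0
            if seg_len == 0:
                continue
            identity = float(eq[s0:s1].sum()) / seg_len
            if score < min_score or identity < min_identity:
                continue
            if si == 0:
                fwd_pos = g0 + s0
            else:
                fwd_pos = glen - (g0 + s0 + seg_len)
            strand = "+" if si == 0 else "-"
            key = (-score, -identity, g, strand != "+", fwd_pos)
            if best is None or key < best[0]:
                best = (key, RecruitmentHit(read_id, g, fwd_pos, strand,
                                            score, identity, seg_len))
        if best is None:
            n_unmapped += 1
        else:
            hits.append(best[1])
    logger.info(
        "recruit: %d reads, %d hits, %d unmapped, %d shorter than k=%d",
        n_reads, len(hits), n_unmapped, n_short, k,
    )
    return hits


def summarize_recruitment(
    hits: list[RecruitmentHit], panel: dict[str, str]
) -> RecruitmentSummary:
    """Per-genome counts, proportions, coverage, and identity summaries.

    Coverage increments each hit's aligned interval (clipped to genome ends);
    covered fraction is the share of positions with depth >= 1; mean identity
    is weighted by aligned length.
    """
    genome_ids = sorted(panel)
    unknown = {h.genome_id for h in hits} - set(genome_ids)
    if unknown:
        raise ValidationError(f"hits reference genomes outside panel: {sorted(unknown)}")
    coverage = {g: np.zeros(len(panel[g]), dtype=np.int64) for g in genome_ids}
    counts = {g: 0 for g in genome_ids}
    id_weight = {g: 0.0 for g in genome_ids}
    len_weight = {g: 0 for g in genome_ids}
    for h in hits:
        cov = coverage[h.genome_id]
        start = max(0, h.position)
        end = min(len(cov), h.position + h.aligned_length)
        cov[start:end] += 1
        counts[h.genome_id] += 1
        id_weight[h.genome_id] += h.identity * h.aligned_length
        len_weight[h.genome_id] += h.aligned_length
    n_assigned = len(hits)
    if n_assigned == 0:
        logger.warning("recruitment summary: no assigned reads")
    proportions = {
        g: (counts[g] / n_assigned if n_assigned else 0.0) for g in genome_ids
    }
    covered = {g: float((coverage[g] > 0).mean()) for g in genome_ids}
    mean_identity = {
        g: (id_weight[g] / len_weight[g] if len_weight[g] else 0.0)
        for g in genome_ids
    }
    return RecruitmentSummary(
        genome_ids=genome_ids,
        read_counts=counts,
        proportions=proportions,
        coverage=coverage,
        covered_fraction=covered,
        mean_identity=mean_identity,
        n_assigned=n_assigned,
    )


def compare_conditions(
    summary_a: RecruitmentSummary, summary_b: RecruitmentSummary
) -> pd.DataFrame:
    """Per-genome proportion shift between two conditions, sorted by |delta|."""
    if summary_a.genome_ids != summary_b.genome_ids:
        raise ValidationError("recruitment summaries cover different panels")
    rows = [
        {
            "genome_id": g,
            "proportion_a": summary_a.proportions[g],
            "proportion_b": summary_b.proportions[g],
            "delta": summary_a.proportions[g] - summary_b.proportions[g],
        }
        for g in summary_a.genome_ids
    ]
    df = pd.DataFrame(rows)
    df["abs_delta"] = df["delta"].abs()
    df = df.sort_values(["abs_delta", "genome_id"], ascending=[False, True])
    return df.drop(columns="abs_delta").reset_index(drop=True)


def hits_to_frame(hits: list[RecruitmentHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [h.read_id for h in hits],
            "genome_id": [h.genome_id for h in hits],
            "position": [h.position for h in hits],
            "strand": [h.strand for h in hits],
            "score": [h.score for h in hits],
            "identity": [h.identity for h in hits],
            "aligned_length": [h.aligned_length for h in hits],
        }
    )
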