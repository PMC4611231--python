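"""Amplicon read processing: quality filtering, PSSM-based V4 ribotag
extraction, and greedy de-novo OTU clustering.

The QC rule follows the standard amplicon protocol: truncate each read at the
first position with Phred below the truncation threshold (default Q20), then
retain it only if the truncated read is longer than 75 bp, carries fewer than
3 low-quality (Q<20) bases, and contains no N.

Ribotag extraction scans both strands of every read with a log-odds
position-specific scoring matrix (PSSM) trained on an alignment of the
conserved flank 5' of the 16S V4 hyper-variable region, and reports the 33 nt
immediately downstream of the best match as the read's taxon fingerprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .config import PipelineConfig
from .containers import CountTable, SequenceRead, revcomp
from .errors import ValidationError

logger = logging.getLogger("ribotide")

LOWQ_PHRED = 20  # a "low quality" base is Q < 20, same notion as truncation

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcResult:
    """Outcome of qc_filter: the kept (possibly truncated) read, or a reason."""

    read: SequenceRead | None
    reason: str | None  # None | too_short | too_many_lowq | contains_N

    @property
    def kept(self) -> bool:
        return self.read is not None


def qc_filter(read: SequenceRead, cfg: PipelineConfig | None = None) -> QcResult:
    """Truncate at the first sub-threshold base and apply retention rules.

    Rejection reasons are checked in order: ``too_short`` (truncated length
    not greater than ``qc_min_length``), ``too_many_lowq`` (>= ``qc_max_lowq``
    bases with Q < 20 in the retained portion), ``contains_N``.
    """
    cfg = cfg or PipelineConfig()
    quals = np.asarray(read.quals)
    below = np.nonzero(quals < cfg.qc_trunc_phred)[0]
    end = int(below[0]) if below.size else len(read)
    bases = read.bases[:end]
    kept_quals = quals[:end]
    if len(bases) <= cfg.qc_min_length:
        return QcResult(None, "too_short")
    if int((kept_quals < LOWQ_PHRED).sum()) >= cfg.qc_max_lowq:
        return QcResult(None, "too_many_lowq")
    if "N" in bases:
        return QcResult(None, "contains_N")
    return QcResult(SequenceRead(read.read_id, bases, tuple(int(q) for q in kept_quals)), None)


def qc_filter_reads(
    reads: Iterable[SequenceRead], cfg: PipelineConfig | None = None
) -> tuple[list[SequenceRead], dict[str, int]]:
    """Filter a read stream; returns kept reads and per-reason counts."""
    cfg = cfg or PipelineConfig()
    kept: list[SequenceRead] = []
    stats = {"input": 0, "kept": 0, "too_short": 0, "too_many_lowq": 0, "contains_N": 0}
    for read in reads:
        stats["input"] += 1
        res = qc_filter(read, cfg)
        if res.kept:
            kept.append(res.read)
            stats["kept"] += 1
        else:
            stats[res.reason] += 1
    logger.info(
        "qc: %d reads in, %d kept (%d too_short, %d too_many_lowq, %d contains_N)",
        stats["input"], stats["kept"], stats["too_short"],
        stats["too_many_lowq"], stats["contains_N"],
    )
    return kept, stats


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pssm:
    """Log-odds position-specific scoring matrix over A,C,G,T.

    ``scores[i, b]`` is log2 of the pseudocount-smoothed position-specific
    base probability over the background probability. ``max_score`` is the
    sum of per-column maxima; the scanning threshold may be given either as
    an absolute score or as a fraction of ``max_score``.
    """

    scores: np.ndarray  # (width, 4)
    background: np.ndarray  # (4,)
    pseudocount: float

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    def threshold(self, frac: float | None = None, absolute: float | None = None) -> float:
        if absolute is not None:
            if absolute > self.max_score:
                raise ValidationError(
                    f"threshold {absolute} exceeds max achievable score "
                    f"{self.max_score:.3f}"
                )
            return float(absolute)
        frac = 0.8 if frac is None else frac
        return frac * self.max_score

    def score_sequence(self, seq: str) -> float:
        """Score one window of exactly ``width`` bases (N scores as background)."""
        if len(seq) != self.width:
            raise ValidationError(f"window length {len(seq)} != PSSM width {self.width}")
        total = 0.0
        for i, b in enumerate(seq):
            idx = _BASE_INDEX.get(b)
            if idx is not None:
                total += self.scores[i, idx]
        return total


def build_pssm(
    aligned_sequences: Sequence[str],
    background: Sequence[float] | None = None,
    pseudocount: float = 1.0,
) -> Pssm:
    """Build a log-odds PSSM from an ungapped alignment of flank sequences.

    score_i(b) = log2( ((n_i(b) + pseudocount * bg_b) / (N + pseudocount)) / bg_b )
    """
    if not aligned_sequences:
        raise ValidationError("need at least one training sequence")
    width = len(aligned_sequences[0])
    if any(len(s) != width for s in aligned_sequences):
        raise ValidationError("training sequences must all have equal length")
    if any(set(s) - set("ACGT") for s in aligned_sequences):
        raise ValidationError("training sequences must be gap-free DNA over ACGT")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
        raise ValidationError("background must be 4 positive frequencies summing to 1")
    n = len(aligned_sequences)
    counts = np.zeros((width, 4))
    for seq in aligned_sequences:
        for i, b in enumerate(seq):
            counts[i, _BASE_INDEX[b]] += 1
    probs = (counts + pseudocount * bg) / (n + pseudocount)
    return Pssm(scores=np.log2(probs / bg), background=bg, pseudocount=pseudocount)


def load_builtin_flank_alignment() -> list[str]:
    """Packaged synthetic alignment of the conserved flank 5' of the V4 region.

    A synthetic stand-in built from degenerate variants of the conserved
    515F-region motif GTGYCAGCMGCCGCGGTAA bordering V4; it reproduces the
    scanning mechanism, not any published scoring matrix.
    """
    text = resources.files("ribotide.data").joinpath("synthetic_v4_flank.fasta").read_text()
    seqs = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith(">"):
            seqs.append(line)
    return seqs


def default_pssm() -> Pssm:
    return build_pssm(load_builtin_flank_alignment())


# ---------------------------------------------------------------------------
# Tag extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TagHit:
    read_id: str
    strand: str  # '+' or '-'
    match_start: int  # 0-based offset of the PSSM match on the scanned orientation
    score: float
    tag: str


def _encode(seq: str) -> np.ndarray:
    # A,C,G,T -> 0..3; N -> 4 (scores as 0 via padded matrix column)
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


def _window_scores(encoded: np.ndarray, padded_scores: np.ndarray, width: int) -> np.ndarray:
    """Scores of every width-window of an encoded sequence (vectorized)."""
    n_win = len(encoded) - width + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, width)
    return padded_scores[np.arange(width), windows].sum(axis=1)


def scan_read(
    read: SequenceRead, pssm: Pssm, threshold: float, tag_length: int = 33
) -> TagHit | None:
    """Best PSSM match on either strand with a full tag downstream.

    Both the read and its reverse complement are scanned; only windows with
    at least ``tag_length`` bases remaining downstream are eligible. The
    highest-scoring window at or above ``threshold`` wins; ties prefer the
    leftmost window on the '+' strand. One tag per read.
    """
    width = pssm.width
    padded = np.hstack([pssm.scores, np.zeros((width, 1))])
    best: TagHit | None = None
    for strand, seq in (("+", read.bases), ("-", revcomp(read.bases))):
        if len(seq) < width + tag_length:
            continue
        scores = _window_scores(_encode(seq), padded, width)
        # only windows leaving room for a full tag downstream
        scores = scores[: len(seq) - width - tag_length + 1]
        if scores.size == 0:
            continue
        i = int(np.argmax(scores))  # argmax takes the leftmost maximum
        s = float(scores[i])
        if s < threshold:
            continue
        hit = TagHit(read.read_id, strand, i, s, seq[i + width : i + width + tag_length])
        if best is None or s > best.score:
            best = hit
    return best


def extract_tags(
    reads: Iterable[SequenceRead],
    pssm: Pssm | None = None,
    cfg: PipelineConfig | None = None,
    sample_ids: dict[str, str] | str | None = None,
    threshold: float | None = None,
) -> tuple[list[TagHit], CountTable]:
    """Extract V4 ribotags from a read stream.

    ``sample_ids`` maps read_id -> sample (or names a single sample for the
    whole stream; default "sample"). Returns the per-read hits and a
    samples x tags count table. No-hit reads are counted and logged.
    """
    pssm = pssm or default_pssm()
    cfg = cfg or PipelineConfig()
    thr = pssm.threshold(frac=cfg.pssm_threshold_frac, absolute=threshold)
    single = sample_ids if isinstance(sample_ids, str) else None
    mapping = sample_ids if isinstance(sample_ids, dict) else None

    hits: list[TagHit] = []
    counts: dict[str, dict[str, int]] = {}
    n_reads = n_nohit = 0
    for read in reads:
        n_reads += 1
        hit = scan_read(read, pssm, thr, cfg.tag_length)
        if hit is None:
            n_nohit += 1
            continue
        hits.append(hit)
        sample = mapping.get(read.read_id, "sample") if mapping else (single or "sample")
        counts.setdefault(sample, {})[hit.tag] = (
            counts.setdefault(sample, {}).get(hit.tag, 0) + 1
        )
    logger.info(
        "ribotag: %d reads scanned, %d tags reported, %d without a match "
        "(threshold %.2f of max %.2f)",
        n_reads, len(hits), n_nohit, thr, pssm.max_score,
    )
    df = pd.DataFrame(counts).T.fillna(0).astype(np.int64)
    df = df.sort_index().sort_index(axis=1)
    return hits, CountTable(df)


def normalize_tag_frequencies(table: CountTable) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample relative frequency over tag-bearing reads.

    Samples with zero tag-bearing reads are excluded and returned as flagged.
    """
    totals = table.sample_totals()
    flagged = totals.index[totals == 0].tolist()
    if flagged:
        logger.warning("tag normalization: excluding zero-tag samples %s", flagged)
    keep = table.df.loc[totals > 0]
    freqs = keep.div(keep.sum(axis=1), axis=0)
    return freqs, flagged


# ---------------------------------------------------------------------------
# Greedy OTU clustering
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matches / alignment columns.

    Needleman-Wunsch with match=1, mismatch=0, gap=-1; identity is the
    number of identical columns divided by total alignment columns.
    """
    aligner = aligner or _make_aligner()
    aln = next(iter(aligner.align(a, b)))
    c = aln.counts()
    return c.identities / (c.gaps + c.identities + c.mismatches)


def cluster_otus(
    sequences: dict[str, str],
    abundances: dict[str, int] | None = None,
    identity: float = 0.97,
) -> tuple[dict[str, str], dict[str, str]]:
    """Greedy centroid clustering of sequences into OTUs.

    Sequences are processed in decreasing abundance (ties broken by
    lexicographic id); each joins the first centroid with pairwise identity
    >= threshold, else founds a new OTU. Returns (sequence_id -> otu_id,
    otu_id -> centroid sequence).
    """
    if not sequences:
        raise ValidationError("no sequences to cluster")
    if not 0 < identity <= 1:
        raise ValidationError("identity must lie in (0, 1]")
    abundances = abundances or {}
    order = sorted(sequences, key=lambda sid: (-abundances.get(sid, 1), sid))
    aligner = _make_aligner()

    centroid_order: list[str] = []  # otu ids in founding order
    centroids: dict[str, str] = {}
    assignment: dict[str, str] = {}
    for sid in order:
        seq = sequences[sid]
        placed = False
        for otu_id in centroid_order:
            if pairwise_identity(seq, centroids[otu_id], aligner) >= identity:
                assignment[sid] = otu_id
                placed = True
                break
        if not placed:
            otu_id = f"OTU_{len(centroid_order) + 1:05d}"
            centroid_order.append(otu_id)
            centroids[otu_id] = seq
            assignment[sid] = otu_id
    logger.info(
        "cluster: %d sequences -> %d OTUs at %.0f%% identity",
        len(sequences), len(centroids), identity * 100,
    )
    return assignment, centroids
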