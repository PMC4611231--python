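"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: multi-station OTU
count tables with water-mass group structure, amplicon-style reads carrying a
conserved flank motif followed by a 33-nt variable tag, two-condition
functional count libraries with planted fold-changes, and small genome panels
with controlled divergence plus transcript reads sampled from them.

All generators are seed-deterministic. Defaults emulate the study design:
five water-mass groups (SO, MSO, BB, SAI, SAO) of surface-ocean stations,
several-fold dominant-taxon shifts between water masses, per-sample depths
comfortably above the 6871-read rarefaction depth, and overdispersed
(Dirichlet-multinomial) OTU counts as seen in real amplicon data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountTable, SequenceRead, revcomp
from .errors import ValidationError
from .io import spawn_rng

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
}

WATER_MASS_GROUPS = ("SO", "MSO", "BB", "SAI", "SAO")


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _apply_substitutions(
    codes: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    if error_rate <= 0:
        return codes
    mask = rng.random(codes.shape) < error_rate
    shift = rng.integers(1, 4, size=codes.shape, dtype=np.int8)
    out = codes.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


# ---------------------------------------------------------------------------
# Community (OTU table) simulation
# ---------------------------------------------------------------------------

@dataclass
class CommunitySimSpec:
    """Design of a multi-group community count table.

    ``group_effects[g, i]`` multiplies feature i's base abundance in group g;
    ``dispersion`` is the Dirichlet-multinomial overdispersion (0 degenerates
    to a plain multinomial; positive values draw each sample's composition
    from Dirichlet(base / dispersion)).
    """

    n_groups: int = 5
    samples_per_group: int = 5
    n_features: int = 200
    base_abundance: np.ndarray | None = None  # normalized internally
    group_effects: np.ndarray | None = None  # (n_groups, n_features)
    dispersion: float = 0.002
    depth_range: tuple[int, int] = (7000, 15000)
    group_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.samples_per_group < 1 or self.n_features < 1:
            raise ValidationError("group, sample, and feature counts must be >= 1")
        if self.depth_range[0] < 1 or self.depth_range[0] > self.depth_range[1]:
            raise ValidationError("invalid depth_range")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")


def default_watermass_spec(seed: int = 0, **overrides) -> CommunitySimSpec:
    """Five discrete water-mass communities with strong indicator-taxon blocks.

    Each group gets a dedicated 10% block of features boosted 8-fold,
    emulating the several-fold dominant-taxon shifts between oceanic water
    masses; base abundances are lognormal (sigma 1.5), the realistic
    uneven-community regime.
    """
    spec = CommunitySimSpec(seed=seed, group_names=WATER_MASS_GROUPS, **overrides)
    rng = spawn_rng(seed, "watermass_spec")
    base = rng.lognormal(mean=0.0, sigma=1.5, size=spec.n_features)
    effects = np.ones((spec.n_groups, spec.n_features))
    block = max(1, spec.n_features // 10)
    for g in range(spec.n_groups):
        start = (g * block) % spec.n_features
        effects[g, start : start + block] = 8.0
    spec.base_abundance = base
    spec.group_effects = effects
    return spec


def simulate_otu_table(
    spec: CommunitySimSpec,
) -> tuple[CountTable, pd.Series, np.ndarray]:
    """Draw a samples x features count table with planted group effects.

    Returns (table, group labels, effects matrix actually applied). Counts
    per sample are multinomial (dispersion 0) or Dirichlet-multinomial over
    base_abundance x group_effects, with depth uniform in depth_range.
    """
    rng = spawn_rng(spec.seed, "otu_table")
    base = (
        np.asarray(spec.base_abundance, float)
        if spec.base_abundance is not None
        else rng.lognormal(0.0, 1.5, size=spec.n_features)
    )
    if base.shape != (spec.n_features,) or (base < 0).any():
        raise ValidationError("base_abundance must be non-negative with n_features entries")
    if base.sum() == 0:
        raise ValidationError("base_abundance sums to zero")
    effects = (
        np.asarray(spec.group_effects, float)
        if spec.group_effects is not None
        else np.ones((spec.n_groups, spec.n_features))
    )
    if effects.shape != (spec.n_groups, spec.n_features) or (effects < 0).any():
        raise ValidationError("group_effects must be (n_groups, n_features) and >= 0")
    names = spec.group_names or tuple(f"G{g + 1}" for g in range(spec.n_groups))
    if len(names) != spec.n_groups:
        raise ValidationError("group_names length must equal n_groups")

    rows, sample_ids, labels = [], [], {}
    for g, gname in enumerate(names):
        p = base * effects[g]
        if p.sum() == 0:
            raise ValidationError(f"group {gname!r} has an all-zero abundance profile")
        p = p / p.sum()
        for s in range(spec.samples_per_group):
            depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
            if spec.dispersion > 0:
                alpha = np.clip(p / spec.dispersion, 1e-9, None)
                draw_p = rng.dirichlet(alpha)
            else:
                draw_p = p
            rows.append(rng.multinomial(depth, draw_p))
            sid = f"{gname}{s + 1:02d}"
            sample_ids.append(sid)
            labels[sid] = gname
    features = [f"OTU_{i + 1:04d}" for i in range(spec.n_features)]
    table = CountTable.from_arrays(sample_ids, features, np.asarray(rows))
    return table, pd.Series(labels, name="group"), effects


# ---------------------------------------------------------------------------
# Tagged amplicon-read simulation
# ---------------------------------------------------------------------------

@dataclass
class TagSimSpec:
    """Design of a ribotag read set.

    ``flank_motif`` may contain IUPAC degeneracy codes, resolved per read;
    non-decoy reads carry the motif followed by a pool tag at a random
    offset, then per-base substitution errors; ``revcomp_fraction`` of reads
    are emitted reverse-complemented; decoys are pure random sequence.
    """

    tag_pool: list[str] = field(default_factory=list)
    tag_freqs: np.ndarray | None = None  # uniform when None
    flank_motif: str = "GTGYCAGCMGCCGCGGTAA"
    n_reads: int = 10000
    read_length: int = 150
    error_rate: float = 0.01
    decoy_fraction: float = 0.2
    revcomp_fraction: float = 0.5
    base_quality: int = 37
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.flank_motif) < 10:
            raise ValidationError("flank_motif must be at least 10 nt")
        if any(b not in _IUPAC for b in self.flank_motif):
            raise ValidationError("flank_motif contains unsupported characters")
        for frac in (self.error_rate, self.decoy_fraction, self.revcomp_fraction):
            if not 0 <= frac <= 1:
                raise ValidationError("fractions must lie in [0, 1]")


def random_tag_pool(n_tags: int, tag_length: int = 33, seed: int = 0) -> list[str]:
    rng = spawn_rng(seed, "tag_pool")
    return [_decode(_random_codes(rng, tag_length)) for _ in range(n_tags)]


def simulate_tagged_reads(
    spec: TagSimSpec,
) -> tuple[list[SequenceRead], pd.DataFrame]:
    """Generate ribotag-bearing reads plus a per-read truth table.

    Truth columns: read_id, is_decoy, pool_tag (the clean pool sequence),
    realized_tag (the planted tag after substitution errors; what a perfect
    extractor recovers), strand, motif_offset (on the emitted orientation
    before reverse complementing).
    """
    if not spec.tag_pool:
        raise ValidationError("tag_pool is empty")
    tag_len = len(spec.tag_pool[0])
    if any(len(t) != tag_len for t in spec.tag_pool):
        raise ValidationError("all pool tags must share one length")
    motif_len = len(spec.flank_motif)
    if spec.read_length < motif_len + tag_len:
        raise ValidationError("read_length must cover motif + tag")
    freqs = (
        np.full(len(spec.tag_pool), 1.0 / len(spec.tag_pool))
        if spec.tag_freqs is None
        else np.asarray(spec.tag_freqs, float)
    )
    if freqs.shape != (len(spec.tag_pool),) or not np.isclose(freqs.sum(), 1.0):
        raise ValidationError("tag_freqs must match tag_pool and sum to 1")

    rng = spawn_rng(spec.seed, "tagged_reads")
    tag_codes = [_encode_str(t) for t in spec.tag_pool]
    motif_options = [np.array([_BASE_CODE_STR.index(c) for c in _IUPAC[b]], dtype=np.int8)
                     for b in spec.flank_motif]
    max_offset = spec.read_length - motif_len - tag_len

    n = spec.n_reads
    is_decoy = rng.random(n) < spec.decoy_fraction
    do_rc = rng.random(n) < spec.revcomp_fraction
    tag_idx = rng.choice(len(spec.tag_pool), size=n, p=freqs)
    offsets = rng.integers(0, max_offset + 1, size=n)
    # one vectorized draw per structure, then row-wise planting
    codes_mat = rng.integers(0, 4, size=(n, spec.read_length), dtype=np.int8)
    motif_mat = np.empty((n, motif_len), dtype=np.int8)
    for j, opts in enumerate(motif_options):
        motif_mat[:, j] = opts[rng.integers(0, len(opts), size=n)]
    for i in range(n):
        if not is_decoy[i]:
            off = int(offsets[i])
            codes_mat[i, off : off + motif_len] = motif_mat[i]
            codes_mat[i, off + motif_len : off + motif_len + tag_len] = tag_codes[tag_idx[i]]
    codes_mat = _apply_substitutions(codes_mat, spec.error_rate, rng)

    reads: list[SequenceRead] = []
    truth_rows = []
    quals = tuple([spec.base_quality] * spec.read_length)
    for i in range(n):
        codes = codes_mat[i]
        rid = f"read_{i + 1:06d}"
        if is_decoy[i]:
            if do_rc[i]:
                codes = (3 - codes)[::-1]
            reads.append(SequenceRead(rid, _decode(codes), quals))
            truth_rows.append((rid, True, "", "", "+", -1))
            continue
        off = int(offsets[i])
        realized = _decode(codes[off + motif_len : off + motif_len + tag_len])
        strand = "+"
        if do_rc[i]:
            codes = (3 - codes)[::-1]
            strand = "-"
        reads.append(SequenceRead(rid, _decode(codes), quals))
        truth_rows.append((rid, False, spec.tag_pool[tag_idx[i]], realized, strand, off))
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "is_decoy", "pool_tag", "realized_tag", "strand",
                 "motif_offset"],
    )
    return reads, truth


_BASE_CODE_STR = "ACGT"


def _encode_str(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE_STR.index(c) for c in seq], dtype=np.int8)
    except ValueError as exc:
        raise ValidationError(f"non-ACGT base in sequence {seq!r}") from exc


# ---------------------------------------------------------------------------
# QC fixture reads
# ---------------------------------------------------------------------------

def simulate_qc_reads(
    n_reads: int = 200, read_length: int = 120, seed: int = 0
) -> list[SequenceRead]:
    """Reads with designed quality/base patterns exercising every QC branch.

    Mixes clean high-quality reads, reads with an early or late sub-Q20
    position (moving the truncation point around the 75-bp retention
    boundary), reads containing N, and boundary-length reads.
    """
    rng = spawn_rng(seed, "qc_reads")
    reads = []
    for i in range(n_reads):
        kind = i % 5
        length = read_length
        codes = _random_codes(rng, length)
        quals = np.full(length, 38)
        if kind == 1:  # low-quality base at a random position (may truncate short)
            pos = int(rng.integers(0, length))
            quals[pos] = int(rng.integers(0, 20))
        elif kind == 2:  # N somewhere in the retained portion
            codes_str = list(_decode(codes))
            codes_str[int(rng.integers(0, min(80, length)))] = "N"
            return_read = SequenceRead(f"qc_{i + 1:04d}", "".join(codes_str),
                                       tuple(int(q) for q in quals))
            reads.append(return_read)
            continue
        elif kind == 3:  # boundary lengths around the >75 bp rule
            length = int(rng.choice([74, 75, 76, 77]))
            codes = codes[:length]
            quals = quals[:length]
        elif kind == 4:  # quality dip near the boundary region
            pos = int(rng.integers(60, 90))
            quals[pos] = 10
        reads.append(
            SequenceRead(f"qc_{i + 1:04d}", _decode(codes), tuple(int(q) for q in quals))
        )
    return reads


# ---------------------------------------------------------------------------
# Two-condition functional libraries
# ---------------------------------------------------------------------------

def simulate_feature_libraries(
    n_features: int,
    planted: dict[str, float] | None = None,
    library_sizes: tuple[int, int] = (1_000_000, 1_000_000),
    seed: int = 0,
    base_proportions: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Two multinomial count libraries with planted fold-changes in B.

    ``planted`` maps feature ids (``F0001``-style) to multiplicative
    fold-changes applied to B's proportions (renormalized). Returns a
    2 x n_features DataFrame indexed 'A', 'B' and the planted truth map.
    """
    if library_sizes[0] < 1 or library_sizes[1] < 1:
        raise ValidationError("library sizes must be >= 1")
    features = [f"F{i + 1:04d}" for i in range(n_features)]
    planted = dict(planted or {})
    unknown = set(planted) - set(features)
    if unknown:
        raise ValidationError(f"planted features outside range: {sorted(unknown)}")
    if any(f <= 0 for f in planted.values()):
        raise ValidationError("fold-changes must be positive")
    rng = spawn_rng(seed, "feature_libraries")
    base = (
        rng.lognormal(0.0, 1.0, size=n_features)
        if base_proportions is None
        else np.asarray(base_proportions, float)
    )
    if base.shape != (n_features,) or (base < 0).any() or base.sum() == 0:
        raise ValidationError("invalid base_proportions")
    pa = base / base.sum()
    fold = np.ones(n_features)
    for fid, fc in planted.items():
        fold[features.index(fid)] = fc
    pb = pa * fold
    pb = pb / pb.sum()
    counts = np.vstack(
        [rng.multinomial(library_sizes[0], pa), rng.multinomial(library_sizes[1], pb)]
    )
    df = pd.DataFrame(counts, index=["A", "B"], columns=features)
    return df, planted


# ---------------------------------------------------------------------------
# Genome panels and transcript reads
# ---------------------------------------------------------------------------

def simulate_genome_panel(
    n_genomes: int,
    length: int,
    divergence: float | np.ndarray = 0.03,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Genomes mutated from a common random ancestor.

    A scalar ``divergence`` is the per-genome substitution rate away from the
    ancestor (so two genomes are pairwise separated by roughly twice that).
    A full matrix gives target *pairwise* divergences, decomposed into
    per-genome rates r_i with r_i + r_j ~= D_ij (least squares); an
    infeasible matrix (some r_i < 0) is an error. Returns the panel and the
    achieved pairwise divergence matrix.
    """
    if n_genomes < 1 or length < 1:
        raise ValidationError("n_genomes and length must be >= 1")
    if np.isscalar(divergence):
        if not 0 <= float(divergence) <= 0.5:
            raise ValidationError("divergence must lie in [0, 0.5]")
        rates = np.full(n_genomes, float(divergence))
    else:
        d = np.asarray(divergence, float)
        if d.shape != (n_genomes, n_genomes):
            raise ValidationError("divergence matrix shape mismatch")
        if (d < 0).any() or (d > 0.5).any():
            raise ValidationError("divergence entries must lie in [0, 0.5]")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValidationError("divergence matrix must be symmetric with zero diagonal")
        iu = np.triu_indices(n_genomes, k=1)
        rows = np.zeros((len(iu[0]), n_genomes))
        rows[np.arange(len(iu[0])), iu[0]] = 1
        rows[np.arange(len(iu[0])), iu[1]] = 1
        rates, *_ = np.linalg.lstsq(rows, d[iu], rcond=None)
        if (rates < -1e-9).any():
            raise ValidationError("unattainable divergence triangle (negative rate)")
        rates = np.clip(rates, 0, 0.5)
    rng = spawn_rng(seed, "genome_panel")
    ancestor = _random_codes(rng, length)
    panel: dict[str, str] = {}
    genomes = []
    for i in range(n_genomes):
        g = _apply_substitutions(ancestor, rates[i], rng)
        genomes.append(g)
        panel[f"G{i + 1:02d}"] = _decode(g)
    names = list(panel)
    achieved = np.zeros((n_genomes, n_genomes))
    for i in range(n_genomes):
        for j in range(i + 1, n_genomes):
            achieved[i, j] = achieved[j, i] = float((genomes[i] != genomes[j]).mean())
    return panel, pd.DataFrame(achieved, index=names, columns=names)


def simulate_transcript_reads(
    panel: dict[str, str],
    weights: dict[str, float] | None = None,
    n_reads: int = 10000,
    read_length: int = 100,
    error_rate: float = 0.005,
    seed: int = 0,
) -> tuple[list[SequenceRead], pd.DataFrame]:
    """Sample reads from a genome mixture with truth labels.

    Truth columns: read_id, genome_id, position (forward-strand 0-based),
    strand. Positions are uniform over valid starts; half the reads are
    emitted reverse-complemented.
    """
    if not panel:
        raise ValidationError("empty panel")
    names = sorted(panel)
    w = (
        np.full(len(names), 1.0 / len(names))
        if weights is None
        else np.array([float(weights.get(g, 0.0)) for g in names])
    )
    if (w < 0).any() or not np.isclose(w.sum(), 1.0):
        raise ValidationError("mixture weights must be non-negative and sum to 1")
    for g in names:
        if len(panel[g]) < read_length:
            raise ValidationError(f"genome {g!r} shorter than read_length")
    rng = spawn_rng(seed, "transcript_reads")
    encoded = {g: _encode_str(panel[g]) for g in names}
    choice = rng.choice(len(names), size=n_reads, p=w)
    do_rc = rng.random(n_reads) < 0.5
    reads, rows = [], []
    quals = tuple([37] * read_length)
    for i in range(n_reads):
        g = names[choice[i]]
        pos = int(rng.integers(0, len(panel[g]) - read_length + 1))
        codes = encoded[g][pos : pos + read_length]
        codes = _apply_substitutions(codes, error_rate, rng)
        strand = "+"
        if do_rc[i]:
            codes = (3 - codes)[::-1]
            strand = "-"
        rid = f"tx_{i + 1:06d}"
        reads.append(SequenceRead(rid, _decode(codes), quals))
        rows.append((rid, g, pos, strand))
    truth = pd.DataFrame(rows, columns=["read_id", "genome_id", "position", "strand"])
    return reads, truth
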