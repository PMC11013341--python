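"""Synthetic paired-amplicon pools with known ribotype composition.

Generates the ground truth the rest of the pipeline is tested against:
families of near-identical ribotype sequences, hybrid pools that mix two
parents' ribotypes at stated proportions, and seeded paired-end reads with
Phred-scored substitution errors.  The defaults emulate the statistical
structure of published Alopecurinae rDNA pools: ~450-nt amplicons covered
by overlapping 2x300 reads, pools of a few thousand to a few tens of
thousands of read pairs, a handful of high-frequency ribotypes per sample
(main-ribotype fractions roughly 20-56%) over a tail of minor variants.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .reads import QualityRead, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

DEFAULT_AMPLICON_LENGTH = 450
DEFAULT_READ_LENGTH = 300


@dataclass(frozen=True)
class RibotypeSeq:
    """A named ribotype sequence (A/C/G/T only)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("ribotype sequence must be non-empty")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"ribotype {self.id!r}: alphabet restricted to ACGT")


@dataclass(frozen=True)
class ErrorModel:
    """Phred-profile model for simulated reads.

    ``mean_quality`` is the Phred score at cycle 0 and ``quality_decay`` the
    per-cycle decline, giving the familiar tapering quality profile of
    Illumina reads.  Substitution-only: indels are not simulated, so exact
    dereplication and Hamming-distance semantics stay exact.
    """

    mean_quality: float = 33.0
    quality_decay: float = 0.0
    substitution_only: bool = True

    def __post_init__(self):
        if not 2 <= self.mean_quality <= 41:
            raise ValueError("mean_quality must be in [2, 41]")
        if self.quality_decay < 0:
            raise ValueError("quality_decay must be >= 0")
        if not self.substitution_only:
            raise NotImplementedError("indel error mode is not implemented")

    def profile(self, read_length: int) -> np.ndarray:
        q = self.mean_quality - self.quality_decay * np.arange(read_length)
        return np.clip(np.rint(q), 2, 41).astype(np.uint8)


@dataclass(frozen=True)
class PoolSpec:
    """Ground truth for one (possibly hybrid) sample's rDNA pool."""

    sample_id: str
    members: tuple  # ((RibotypeSeq, true_proportion), ...)
    n_read_pairs: int = 5000
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        members = tuple((m, float(p)) for m, p in self.members)
        object.__setattr__(self, "members", members)
        if not members:
            raise ValueError("a pool needs at least one member")
        total = sum(p for _, p in members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1 (got {total})")
        if any(p < 0 or p > 1 for _, p in members):
            raise ValueError("proportions must lie in [0, 1]")
        ids = [m.id for m, _ in members]
        seqs = [m.sequence for m, _ in members]
        if len(set(ids)) != len(ids) or len(set(seqs)) != len(seqs):
            raise ValueError("member ids and sequences must be unique")
        if self.n_read_pairs < 1:
            raise ValueError("n_read_pairs must be >= 1")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")

    def default_error_model(self) -> ErrorModel:
        """Phred profile consistent with the injected substitution rate."""
        if self.error_rate <= 0:
            return ErrorModel(mean_quality=38.0)
        q = -10.0 * np.log10(self.error_rate)
        return ErrorModel(mean_quality=float(np.clip(q, 2, 41)))


def make_ribotype_family(
    base_length: int,
    n_variants: int,
    steps_apart: Sequence[int],
    seed: int,
    id_prefix: str = "rt",
) -> List[RibotypeSeq]:
    """A chain of ribotype variants at exact mutational distances.

    Variant ``i+1`` differs from variant ``i`` by exactly ``steps_apart[i]``
    substitutions.  Every step mutates positions untouched by earlier steps,
    so the Hamming distance between any two family members equals the sum of
    the intervening step counts — the family doubles as an exact distance
    oracle.  Emulates within-species ribotype sets, where variants differ by
    a few substitutions.
    """
    if len(steps_apart) != n_variants - 1:
        raise ValueError("steps_apart must have n_variants - 1 entries")
    if any(s < 1 or s > base_length // 10 for s in steps_apart):
        raise ValueError("each step count must be in [1, base_length/10]")
    if sum(steps_apart) > base_length:
        raise ValueError("step counts exceed available positions")
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, size=base_length)
    variants = [base.copy()]
    free = list(rng.permutation(base_length))
    for steps in steps_apart:
        nxt = variants[-1].copy()
        for _ in range(steps):
            pos = free.pop()
            nxt[pos] = (nxt[pos] + rng.integers(1, 4)) % 4
        variants.append(nxt)
    return [
        RibotypeSeq(f"{id_prefix}{i + 1}", _BASES[v].tobytes().decode("ascii"))
        for i, v in enumerate(variants)
    ]


def make_hybrid_spec(
    parent_a: PoolSpec,
    parent_b: PoolSpec,
    weight_a: float,
    sample_id: str,
    n_read_pairs: Optional[int] = None,
    error_rate: Optional[float] = None,
    seed: Optional[int] = None,
) -> PoolSpec:
    """Mix two parental pools into a hybrid ground truth.

    The member set is the union of both parents' ribotypes; each proportion
    is the parent proportion scaled by its weight (``weight_a`` for parent
    A, ``1 - weight_a`` for B).  Ribotypes whose sequences are identical in
    both parents are merged into one member with the summed weighted
    proportion — as in a real allopolyploid, where shared parental variants
    are indistinguishable in the pool.
    """
    if not 0.0 < weight_a < 1.0:
        raise ValueError("weight_a must be strictly between 0 and 1")
    merged: dict = {}
    order: list = []
    for spec, w in ((parent_a, weight_a), (parent_b, 1.0 - weight_a)):
        for member, p in spec.members:
            key = member.sequence
            if key in merged:
                merged[key] = (merged[key][0], merged[key][1] + w * p)
            else:
                merged[key] = (member, w * p)
                order.append(key)
    total = sum(p for _, p in merged.values())
    members = tuple((merged[k][0], merged[k][1] / total) for k in order)
    return PoolSpec(
        sample_id=sample_id,
        members=members,
        n_read_pairs=parent_a.n_read_pairs if n_read_pairs is None else n_read_pairs,
        error_rate=parent_a.error_rate if error_rate is None else error_rate,
        seed=(parent_a.seed + 1_000_003) % (2**31) if seed is None else seed,
    )


@dataclass(frozen=True)
class SimulatedPool:
    """Output of :func:`simulate_read_pairs`: paired reads + truth table."""

    forward: tuple  # QualityRead, 5' ends of the amplicons
    reverse: tuple  # QualityRead, in sequencing orientation (revcomp of 3' ends)
    truth: tuple  # (read_id, member_id, n_errors) per pair


def simulate_read_pairs(
    spec: PoolSpec,
    read_length: int = DEFAULT_READ_LENGTH,
    overlap: int = 20,
    model: Optional[ErrorModel] = None,
) -> SimulatedPool:
    """Draw seeded paired reads from a pool's ribotype composition.

    Each pair's source member is drawn from a multinomial over the true
    proportions.  The forward read is the amplicon's 5' prefix and the
    reverse read the reverse complement of its 3' suffix, so every pair
    overlaps by at least ``overlap`` bases and merging can reconstruct the
    amplicon.  Substitution errors are injected per base at
    ``spec.error_rate``; quality strings follow the error model's Phred
    profile.  Fully deterministic in ``spec.seed``.
    """
    if overlap < 20:
        raise ValueError("overlap must be >= 20")
    for member, _ in spec.members:
        if 2 * read_length - overlap < len(member.sequence):
            raise ValueError(
                f"amplicon {member.id!r} ({len(member.sequence)} nt) cannot be covered "
                f"by 2x{read_length} reads with >= {overlap} nt overlap"
            )
    model = model or spec.default_error_model()
    ss = np.random.SeedSequence(spec.seed)
    rng_assign, rng_err_f, rng_err_r = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )
    props = np.array([p for _, p in spec.members])
    counts = rng_assign.multinomial(spec.n_read_pairs, props)
    source = np.repeat(np.arange(len(spec.members)), counts)
    source = source[rng_assign.permutation(spec.n_read_pairs)]

    fwd_reads: list = []
    rev_reads: list = []
    truth: list = []
    width = len(str(spec.n_read_pairs))
    for i, m_idx in enumerate(source):
        member = spec.members[m_idx][0]
        amplicon = member.sequence
        rl = min(read_length, len(amplicon))
        f_codes = _BASE_INDEX[_encode_u8(amplicon[:rl])].astype(np.int64)
        r_codes = _BASE_INDEX[_encode_u8(reverse_complement(amplicon[-rl:]))].astype(np.int64)
        nf = _inject(f_codes, spec.error_rate, rng_err_f)
        nr = _inject(r_codes, spec.error_rate, rng_err_r)
        prof = model.profile(rl)
        rid = f"{spec.sample_id}_read{i + 1:0{width}d}"
        fwd_reads.append(QualityRead(rid, _BASES[f_codes].tobytes().decode(), prof))
        rev_reads.append(QualityRead(rid, _BASES[r_codes].tobytes().decode(), prof))
        truth.append((rid, member.id, nf + nr))
    return SimulatedPool(tuple(fwd_reads), tuple(rev_reads), tuple(truth))


def _encode_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _inject(codes: np.ndarray, rate: float, rng: np.random.Generator) -> int:
    """In-place substitution errors; returns the number injected."""
    if rate <= 0:
        return 0
    mask = rng.random(codes.size) < rate
    n = int(mask.sum())
    if n:
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n)) % 4
    return n


# ---------------------------------------------------------------------------
# serialisation


def write_fastq(reads: Sequence[QualityRead], path: Union[str, Path]) -> None:
    """Write reads as Sanger/Illumina 1.8+ FASTQ (Phred+33); .gz by suffix."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            qual = (r.quals + 33).tobytes().decode("ascii")
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def write_truth_table(pool: SimulatedPool, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmember_id\tn_errors\n")
        for rid, mid, ne in pool.truth:
            fh.write(f"{rid}\t{mid}\t{ne}\n")


def spec_to_yaml(spec: PoolSpec, path: Union[str, Path]) -> None:
    doc = {
        "sample_id": spec.sample_id,
        "n_read_pairs": spec.n_read_pairs,
        "error_rate": spec.error_rate,
        "seed": spec.seed,
        "members": [
            {"id": m.id, "sequence": m.sequence, "proportion": p}
            for m, p in spec.members
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path: Union[str, Path]) -> PoolSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    members = tuple(
        (RibotypeSeq(m["id"], m["sequence"]), float(m["proportion"]))
        for m in doc["members"]
    )
    return PoolSpec(
        sample_id=doc["sample_id"],
        members=members,
        n_read_pairs=int(doc.get("n_read_pairs", 5000)),
        error_rate=float(doc.get("error_rate", 0.001)),
        seed=int(doc.get("seed", 0)),
    )


def write_pool(pool: SimulatedPool, spec: PoolSpec, out_dir: Union[str, Path],
               gzip_fastq: bool = False) -> dict:
    """Write _R1/_R2 FASTQ, truth TSV and the spec YAML into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gzip_fastq else ".fastq"
    paths = {
        "r1": out / f"{spec.sample_id}_R1{ext}",
        "r2": out / f"{spec.sample_id}_R2{ext}",
        "truth": out / f"{spec.sample_id}_truth.tsv",
        "spec": out / f"{spec.sample_id}_spec.yaml",
    }
    write_fastq(pool.forward, paths["r1"])
    write_fastq(pool.reverse, paths["r2"])
    write_truth_table(pool, paths["truth"])
    spec_to_yaml(spec, paths["spec"])
    return {k: str(v) for k, v in paths.items()}
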