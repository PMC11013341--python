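"""Major/minor ribotype classification and integer-percentage pooling.

A sample's "rDNA pool" is its dereplicated ribotype table.  A ribotype is
*major* when its read count clears a depth-dependent cutoff: pools of at
least 10,000 reads require strictly more than 1,000 reads, shallower pools
require at least 100 reads.  Percentages are reported as integers
(round half up), matching how published ribotype summaries print them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Optional, Union

import pandas as pd

MAJOR = "major"
MINOR = "minor"


@dataclass(frozen=True)
class Ribotype:
    """One unique amplicon sequence in a sample, with its abundance.

    ``sequence`` may be ``None`` for pools reconstructed from published
    count tables where only labels and counts are available.
    """

    sequence: Optional[str] = None
    count: int = 0
    label: str = ""
    percent: Optional[int] = None
    status: Optional[str] = None

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.status not in (None, MAJOR, MINOR):
            raise ValueError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class SamplePool:
    """One sample's ribotype table plus its total processed read count.

    For pipeline-produced pools the ribotype counts sum to ``total_reads``.
    Pools loaded from published summaries may list major ribotypes only, in
    which case the listed counts sum to less than the pool total.
    """

    sample_id: str
    species: str = ""
    total_reads: int = 0
    ribotypes: tuple = ()
    processing_log: Optional[dict] = None

    def __post_init__(self):
        object.__setattr__(self, "ribotypes", tuple(self.ribotypes))
        if self.total_reads < 0:
            raise ValueError("total_reads must be >= 0")

    @property
    def majors(self) -> tuple:
        return tuple(r for r in self.ribotypes if r.status == MAJOR)


@dataclass(frozen=True)
class ThresholdRule:
    """Depth-dependent major-ribotype cutoff."""

    large_pool_min_total: int = 10_000
    large_pool_major_min: int = 1_001  # "more than 1000 reads", read strictly
    small_pool_major_min: int = 100  # "100 or more reads", read inclusively

    def __post_init__(self):
        if min(
            self.large_pool_min_total,
            self.large_pool_major_min,
            self.small_pool_major_min,
        ) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.large_pool_major_min <= self.small_pool_major_min:
            raise ValueError("large-pool cutoff must exceed small-pool cutoff")


def major_cutoff(total_reads: int, rule: ThresholdRule = ThresholdRule()) -> int:
    """Minimum read count for major status in a pool of ``total_reads``."""
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    if total_reads >= rule.large_pool_min_total:
        return rule.large_pool_major_min
    return rule.small_pool_major_min


def integer_percent(count: int, total: int) -> int:
    """Integer percentage of ``count`` in ``total``, rounded half up.

    Computed in exact integer arithmetic: floor((200*count + total) / (2*total)).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must satisfy 0 <= count <= total")
    return (200 * count + total) // (2 * total)


def _sort_key(r: Ribotype):
    # count desc; ties broken lexicographically by sequence so tables are
    # byte-stable; label as a fallback for sequence-free pools
    return (-r.count, r.sequence if r.sequence is not None else "", r.label)


def classify(pool: SamplePool, rule: ThresholdRule = ThresholdRule()) -> SamplePool:
    """Fill percent and major/minor status for every ribotype.

    Ribotypes are sorted by count descending (majors therefore precede
    minors), percent is the round-half-up integer share of ``total_reads``,
    and status compares the count to :func:`major_cutoff`.  Counts and
    sequences are never altered; the operation is idempotent.
    """
    cutoff = major_cutoff(pool.total_reads, rule)
    out = []
    for r in sorted(pool.ribotypes, key=_sort_key):
        pct = integer_percent(r.count, pool.total_reads) if pool.total_reads else 0
        status = MAJOR if r.count >= cutoff else MINOR
        out.append(replace(r, percent=pct, status=status))
    return replace(pool, ribotypes=tuple(out))


def label_ribotypes(pool: SamplePool, prefix: str) -> SamplePool:
    """Assign ``prefix``+rank labels (Ae1, Ae2, ...) in count order."""
    if not prefix:
        raise ValueError("prefix must be non-empty")
    out = [
        replace(r, label=f"{prefix}{i}")
        for i, r in enumerate(sorted(pool.ribotypes, key=_sort_key), start=1)
    ]
    return replace(pool, ribotypes=tuple(out))


def pool_table(pool: SamplePool) -> pd.DataFrame:
    """Ribotype table as a DataFrame (one row per ribotype)."""
    return pd.DataFrame(
        {
            "sample_id": pool.sample_id,
            "species": pool.species,
            "total_reads": pool.total_reads,
            "label": [r.label for r in pool.ribotypes],
            "sequence": [r.sequence for r in pool.ribotypes],
            "count": [r.count for r in pool.ribotypes],
            "percent": [r.percent for r in pool.ribotypes],
            "status": [r.status for r in pool.ribotypes],
        }
    )


def summary_table(pools: Iterable[SamplePool], majors_only: bool = True) -> pd.DataFrame:
    """Stacked per-sample summary shaped like a published ribotype table.

    One row per (sample, ribotype) with species, pool total, label, count
    and integer percent; by default only major ribotypes are listed.
    """
    frames = []
    for pool in pools:
        df = pool_table(pool)
        if majors_only:
            df = df[df["status"] == MAJOR]
        frames.append(df.drop(columns=["sequence"]))
    if not frames:
        return pd.DataFrame(
            columns=["sample_id", "species", "total_reads", "label", "count", "percent", "status"]
        )
    return pd.concat(frames, ignore_index=True)


def write_pool_tsv(pool: SamplePool, path: Union[str, Path]) -> None:
    pool_table(pool).to_csv(path, sep="\t", index=False)


def read_pool_tsv(path: Union[str, Path]) -> SamplePool:
    df = pd.read_csv(path, sep="\t", dtype={"label": str}, keep_default_na=False)
    if df.empty:
        raise ValueError(f"empty ribotype table: {path}")
    ribotypes = [
        Ribotype(
            sequence=(row["sequence"] or None) if "sequence" in df.columns else None,
            count=int(row["count"]),
            label=str(row.get("label", "") or ""),
            percent=int(row["percent"]) if str(row.get("percent", "")) not in ("", "nan") else None,
            status=(row.get("status") or None) if "status" in df.columns else None,
        )
        for _, row in df.iterrows()
    ]
    return SamplePool(
        sample_id=str(df["sample_id"].iloc[0]),
        species=str(df["species"].iloc[0]) if "species" in df.columns else "",
        total_reads=int(df["total_reads"].iloc[0]),
        ribotypes=ribotypes,
    )


def write_pool_fasta(pool: SamplePool, path: Union[str, Path]) -> None:
    """Write ribotypes as FASTA with usearch/vsearch ``;size=N`` annotations."""
    with open(path, "w") as fh:
        for i, r in enumerate(pool.ribotypes, start=1):
            if r.sequence is None:
                raise ValueError("cannot write FASTA for a sequence-free pool")
            name = r.label or f"{pool.sample_id}_ribotype{i}"
            fh.write(f">{name};size={r.count}\n{r.sequence}\n")


def read_pool_fasta(
    path: Union[str, Path], sample_id: str, species: str = ""
) -> SamplePool:
    """Read an abundance-annotated FASTA back into an (unclassified) pool."""
    from Bio import SeqIO

    ribotypes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.description.split()[0]
        label, size = name, 1
        for part in name.split(";"):
            if part.startswith("size="):
                size = int(part[5:])
            elif part:
                label = part
        ribotypes.append(Ribotype(sequence=str(rec.seq).upper(), count=size, label=label))
    total = sum(r.count for r in ribotypes)
    return SamplePool(sample_id=sample_id, species=species, total_reads=total, ribotypes=ribotypes)
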