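"""Shared-ribotype detection and hybrid parentage scoring.

An allopolyploid or recent hybrid carries rDNA ribotypes inherited from
both parental species.  "Shared" here means full-length exact sequence
identity between samples — near-identical variants are related through the
parsimony network, not through sharing.  A hybrid's parentage is read from
its *major* ribotypes: each one either matches a ribotype of parent A, of
parent B, of both, or of neither (a candidate post-hybridization
derivative).  Minor-fraction sharing between species is reported
separately as a possible signature of past introgression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Union

import pandas as pd

from .pooling import MAJOR, MINOR, SamplePool

FROM_A = "from_a"
FROM_B = "from_b"
FROM_BOTH = "from_both"
HYBRID_SPECIFIC = "hybrid_specific"

BOTH_PARENTS = "both_parents_detected"
ONE_PARENT = "one_parent_only"
NEITHER = "neither"


class Cell(NamedTuple):
    label: str
    count: int
    percent: Optional[int]
    status: Optional[str]


@dataclass(frozen=True)
class SharedRibotype:
    shared_id: str
    sequence: str
    cells: dict  # sample_id -> Cell

    @property
    def samples(self) -> tuple:
        return tuple(sorted(self.cells))

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.cells.values())


@dataclass(frozen=True)
class SharingMatrix:
    """Exact-identity ribotype grid: shared ids x samples."""

    entries: tuple  # SharedRibotype, ordered by total count then sequence
    samples: tuple

    def by_sequence(self, sequence: str) -> Optional[SharedRibotype]:
        return self._seq_index.get(sequence)

    @property
    def _seq_index(self) -> dict:
        return {e.sequence: e for e in self.entries}

    def sample_entries(self, sample_id: str) -> list:
        if sample_id not in self.samples:
            raise KeyError(f"unknown sample {sample_id!r}")
        return [e for e in self.entries if sample_id in e.cells]

    def to_wide(self) -> pd.DataFrame:
        """Wide TSV-ready view: one row per shared id, one column block per sample."""
        rows = []
        for e in self.entries:
            row: dict = {"shared_id": e.shared_id, "n_samples": len(e.cells)}
            for s in self.samples:
                c = e.cells.get(s)
                row[f"{s}.count"] = c.count if c else 0
                row[f"{s}.percent"] = c.percent if c else None
                row[f"{s}.status"] = c.status if c else None
            row["sequence"] = e.sequence
            rows.append(row)
        return pd.DataFrame(rows)

    def to_long(self) -> pd.DataFrame:
        rows = [
            {
                "shared_id": e.shared_id,
                "sample_id": s,
                "label": c.label,
                "count": c.count,
                "percent": c.percent,
                "status": c.status,
            }
            for e in self.entries
            for s, c in sorted(e.cells.items())
        ]
        return pd.DataFrame(rows)


def sharing_matrix(pools: Sequence[SamplePool]) -> SharingMatrix:
    """Group ribotypes across samples by exact sequence identity.

    Each unique sequence gets one stable shared id (ordered by summed read
    count, then sequence), with per-sample count/percent/status preserved —
    so "major in one sample, minor in another" relationships stay
    queryable.  Pools must be classified and carry sequences.
    """
    sample_ids = []
    groups: Dict[str, dict] = {}
    for pool in pools:
        if pool.sample_id in sample_ids:
            raise ValueError(f"duplicate sample id {pool.sample_id!r}")
        sample_ids.append(pool.sample_id)
        for r in pool.ribotypes:
            if r.sequence is None:
                raise ValueError(
                    f"pool {pool.sample_id!r} has sequence-free ribotypes"
                )
            if r.status is None:
                raise ValueError(f"pool {pool.sample_id!r} is not classified")
            groups.setdefault(r.sequence, {})[pool.sample_id] = Cell(
                r.label, r.count, r.percent, r.status
            )
    ordered = sorted(
        groups.items(),
        key=lambda kv: (-sum(c.count for c in kv[1].values()), kv[0]),
    )
    entries = tuple(
        SharedRibotype(shared_id=f"R{i + 1}", sequence=seq, cells=cells)
        for i, (seq, cells) in enumerate(ordered)
    )
    return SharingMatrix(entries=entries, samples=tuple(sample_ids))


@dataclass(frozen=True)
class ParentageReport:
    """Which of a hybrid's major ribotypes trace to which candidate parent."""

    hybrid_id: str
    parent_a_id: str
    parent_b_id: str
    assignments: tuple  # ((shared_id, label, count, percent, origin), ...)
    verdict: str
    subnetworks: Optional[dict] = None  # (sample, label) -> subnetwork id, if given

    def to_dict(self) -> dict:
        return {
            "hybrid": self.hybrid_id,
            "parent_a": self.parent_a_id,
            "parent_b": self.parent_b_id,
            "verdict": self.verdict,
            "major_ribotypes": [
                {
                    "shared_id": sid,
                    "label": label,
                    "count": count,
                    "percent": percent,
                    "origin": origin,
                    **(
                        {"subnetwork": self.subnetworks.get((self.hybrid_id, label))}
                        if self.subnetworks
                        else {}
                    ),
                }
                for sid, label, count, percent, origin in self.assignments
            ],
        }

    def to_text(self) -> str:
        lines = [
            f"Hybrid {self.hybrid_id} vs parents "
            f"{self.parent_a_id} / {self.parent_b_id}: {self.verdict}"
        ]
        for sid, label, count, percent, origin in self.assignments:
            lines.append(
                f"  {sid} {label or '-'}: {count} reads"
                + (f" ({percent}%)" if percent is not None else "")
                + f" -> {origin}"
            )
        return "\n".join(lines)


def parentage_support(
    matrix: SharingMatrix,
    hybrid: str,
    parent_a: str,
    parent_b: str,
    subnetworks: Optional[dict] = None,
) -> ParentageReport:
    """Score a putative hybrid against one candidate parent pair.

    Every major ribotype of the hybrid is assigned by exact identity to
    the parents' ribotypes (parental status is ignored: a hybrid major may
    match a parental minor).  The verdict is ``both_parents_detected``
    when at least one major traces to each side; a hybrid with no majors
    yields ``neither`` but the report is still emitted.
    """
    for s in (hybrid, parent_a, parent_b):
        if s not in matrix.samples:
            raise KeyError(f"sample {s!r} not in sharing matrix")
    assignments = []
    a_seen = b_seen = False
    for entry in matrix.sample_entries(hybrid):
        cell = entry.cells[hybrid]
        if cell.status != MAJOR:
            continue
        in_a = parent_a in entry.cells
        in_b = parent_b in entry.cells
        if in_a and in_b:
            origin = FROM_BOTH
            a_seen = b_seen = True
        elif in_a:
            origin = FROM_A
            a_seen = True
        elif in_b:
            origin = FROM_B
            b_seen = True
        else:
            origin = HYBRID_SPECIFIC
        assignments.append(
            (entry.shared_id, cell.label, cell.count, cell.percent, origin)
        )
    if a_seen and b_seen:
        verdict = BOTH_PARENTS
    elif a_seen or b_seen:
        verdict = ONE_PARENT
    else:
        verdict = NEITHER
    return ParentageReport(
        hybrid_id=hybrid,
        parent_a_id=parent_a,
        parent_b_id=parent_b,
        assignments=tuple(assignments),
        verdict=verdict,
        subnetworks=subnetworks,
    )


def introgression_scan(
    matrix: SharingMatrix, focal: str, donor: str
) -> List[dict]:
    """Ribotypes major in one sample but only minor in the other.

    A ribotype that dominates one species' pool yet persists as a minor
    fraction of another's is the read-count signature of past
    introgression.  Both directions are reported; interpretation (how many
    reads constitute evidence) is left to the user.
    """
    if focal == donor:
        raise ValueError("focal and donor must be distinct samples")
    for s in (focal, donor):
        if s not in matrix.samples:
            raise KeyError(f"sample {s!r} not in sharing matrix")
    hits = []
    for entry in matrix.entries:
        cf, cd = entry.cells.get(focal), entry.cells.get(donor)
        if cf is None or cd is None:
            continue
        if {cf.status, cd.status} == {MAJOR, MINOR}:
            major_side = focal if cf.status == MAJOR else donor
            hits.append(
                {
                    "shared_id": entry.shared_id,
                    "major_in": major_side,
                    "minor_in": donor if major_side == focal else focal,
                    f"{focal}.count": cf.count,
                    f"{focal}.percent": cf.percent,
                    f"{donor}.count": cd.count,
                    f"{donor}.percent": cd.percent,
                }
            )
    return hits


def write_report_json(report: ParentageReport, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
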