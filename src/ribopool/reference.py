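"""Published Alopecurinae rDNA pool summary bundled as reference data.

The packaged table lists, for 21 sequenced samples of *Alopecurus* and
*Limnas*, each pool's total processed read count and the read counts and
printed integer percentages of its major ribotypes.  Ribotype sequences are
not included (they live in public archives); the table supports the
count-level operations — integer percentages, major/minor thresholds — and
serves as the numeric surface the pipeline's pooling rules are checked
against.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List

import pandas as pd

from .pooling import (
    MAJOR,
    Ribotype,
    SamplePool,
    ThresholdRule,
    classify,
    integer_percent,
    major_cutoff,
)

_DATA = "alopecurinae_ribotypes.tsv"


def load_reference_table() -> pd.DataFrame:
    """The published per-sample major-ribotype counts, one row per ribotype."""
    with resources.files("ribopool.data").joinpath(_DATA).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"sample_id": str, "label": str})


def load_reference_pools() -> Dict[str, SamplePool]:
    """Reference samples as (unclassified) count-only pools, keyed by sample id.

    Only the published major ribotypes are listed, so each pool's listed
    counts sum to less than its total read count (the minor tail is not
    itemised in the source table).
    """
    df = load_reference_table()
    pools: Dict[str, SamplePool] = {}
    for sample_id, grp in df.groupby("sample_id", sort=False):
        pools[str(sample_id)] = SamplePool(
            sample_id=str(sample_id),
            species=str(grp["species"].iloc[0]),
            total_reads=int(grp["total_reads"].iloc[0]),
            ribotypes=[
                Ribotype(sequence=None, count=int(r["count"]), label=str(r["label"]))
                for _, r in grp.iterrows()
            ],
        )
    return pools


def consistency_report(rule: ThresholdRule = ThresholdRule()) -> pd.DataFrame:
    """Recompute percentages and major status; flag rows that disagree.

    ``percent_ok`` compares round-half-up of count/total with the printed
    percent; ``status_ok`` checks that a row printed among the majors
    actually clears the depth-dependent cutoff.  A handful of published
    rows fail one of the checks (e.g. an 80-read ribotype listed as major
    in a 1,704-read pool); they are reported, not silently corrected.
    """
    df = load_reference_table().copy()
    df["computed_percent"] = [
        integer_percent(c, t) for c, t in zip(df["count"], df["total_reads"])
    ]
    df["percent_ok"] = df["computed_percent"] == df["percent"]
    df["cutoff"] = [major_cutoff(t, rule) for t in df["total_reads"]]
    df["status_ok"] = df["count"] >= df["cutoff"]
    return df


def classified_reference_pools(
    rule: ThresholdRule = ThresholdRule(),
) -> Dict[str, SamplePool]:
    """Reference pools with percent and major/minor status filled in."""
    return {sid: classify(pool, rule) for sid, pool in load_reference_pools().items()}
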