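"""Bundled worked-example data.

``load_capture_stats`` returns the published per-sample target-capture
sequencing statistics of the Aloe custom-panel experiment the toolkit's
summary functions are modelled on: quality-filtered and mapped read counts,
assembled target length, loci recovered and percent target length recovered,
for 23 *Aloe* samples, one close relative and three subfamily outgroups.

The printed on-target percentages are carried verbatim in the
``pct_on_target_printed`` column; ``evaluate.pct_on_target`` recomputes them
from the counts (two printed rows are internally inconsistent with their own
counts; the recomputed value is authoritative here).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluate import SampleCaptureStats, pct_on_target


def load_capture_stats() -> pd.DataFrame:
    """The bundled per-sample capture statistics table."""
    with resources.files("cladecap.data").joinpath(
        "alooideae_capture_stats.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def stats_from_table(df: pd.DataFrame) -> list[SampleCaptureStats]:
    """Convert table rows into SampleCaptureStats, recomputing the on-target
    percentage from the read counts."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SampleCaptureStats(
                sample=row.sample,
                reads_after_trimming=int(row.reads_after_trimming),
                reads_mapped=int(row.reads_mapped),
                pct_on_target=pct_on_target(
                    int(row.reads_mapped), int(row.reads_after_trimming)
                ),
                total_assembled_target_len=int(row.total_assembled_target_len),
                loci_with_sequence=int(row.loci_with_sequence),
                pct_target_recovered=float(row.pct_target_recovered),
            )
        )
    return out
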