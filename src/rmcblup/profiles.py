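"""Reference-free tag profiling of rumen metagenome sequencing reads.

A "tag" is the first 65 bases of a quality/adapter-trimmed read starting at
the restriction cut site; identical tags are taken to mark the same
microbial genome fragment, so a sample's profile is simply the multiset of
its tags. No reference database is involved: tag identity is exact string
match.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

DEFAULT_TAG_LENGTH = 65
DEFAULT_MIN_READ_LENGTH = 40
DEFAULT_MIN_SAMPLE_READS = 100_000
DEFAULT_PRESENCE_THRESHOLD = 0.25


@dataclass
class TagCountMatrix:
    """Samples x tags integer count matrix.

    ``total_reads`` is the per-sample read total captured at extraction
    time (before any tag filtering) and is the quantity sample QC acts on;
    after tag filtering the row sums of ``counts`` may be smaller.
    """

    counts: pd.DataFrame
    total_reads: pd.Series = field(default=None)

    def __post_init__(self):
        if self.total_reads is None:
            self.total_reads = self.counts.sum(axis=1)
        self.total_reads = self.total_reads.reindex(self.counts.index)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("tag counts must be non-negative")
        if self.counts.columns.duplicated().any():
            raise ValueError("tag ids must be unique")

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def tag_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class ExtractionReport:
    n_records: int = 0
    n_below_min_length: int = 0
    n_short_of_tag: int = 0  # >= min_read_length but < tag_length
    n_tagged: int = 0

    @property
    def total_reads(self) -> int:
        """Reads surviving trimming QC (>= min length), tagged or not."""
        return self.n_short_of_tag + self.n_tagged


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def extract_tags(reads_path: str | Path,
                 tag_length: int = DEFAULT_TAG_LENGTH,
                 min_read_length: int = DEFAULT_MIN_READ_LENGTH,
                 ) -> tuple[Counter, ExtractionReport]:
    """Count tags (first ``tag_length`` bases) in one sample's FASTQ file.

    Reads shorter than ``min_read_length`` are dropped outright. Reads at
    least ``min_read_length`` but shorter than ``tag_length`` cannot yield
    a tag; they are skipped from counting but retained in the report's
    ``total_reads``, since sample QC is defined on reads surviving
    trimming, not on tag-eligible reads.
    """
    reads_path = Path(reads_path)
    counts: Counter = Counter()
    report = ExtractionReport()
    with _open_maybe_gzip(reads_path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                report.n_records += 1
                seq = str(rec.seq)
                if len(seq) < min_read_length:
                    report.n_below_min_length += 1
                    continue
                if len(seq) < tag_length:
                    report.n_short_of_tag += 1
                    continue
                counts[seq[:tag_length]] += 1
                report.n_tagged += 1
        except ValueError as err:
            raise ValueError(
                f"unreadable FASTQ record in {reads_path} "
                f"after record {report.n_records}: {err}"
            ) from err
    return counts, report


def tag_matrix_from_counts(per_sample: dict[str, Counter],
                           total_reads: dict[str, int] | None = None,
                           ) -> TagCountMatrix:
    """Assemble per-sample tag counters into a TagCountMatrix.

    ``total_reads`` defaults to the per-sample sum of tag counts (exact
    when every surviving read was tag-eligible)."""
    df = pd.DataFrame.from_dict(per_sample, orient="index").fillna(0).astype(int)
    df = df.sort_index(axis=1)
    tot = None
    if total_reads is not None:
        tot = pd.Series(total_reads).reindex(df.index)
    return TagCountMatrix(counts=df, total_reads=tot)


def extract_tag_matrix(paths: dict[str, str | Path],
                       tag_length: int = DEFAULT_TAG_LENGTH,
                       min_read_length: int = DEFAULT_MIN_READ_LENGTH,
                       ) -> tuple[TagCountMatrix, pd.DataFrame]:
    """Run extract_tags over {sample_id: fastq_path} and assemble the matrix."""
    counters, totals, rows = {}, {}, []
    for sample, path in paths.items():
        c, rep = extract_tags(path, tag_length, min_read_length)
        counters[sample] = c
        totals[sample] = rep.total_reads
        rows.append({"sample_id": sample, **rep.__dict__,
                     "total_reads": rep.total_reads})
    tcm = tag_matrix_from_counts(counters, totals)
    return tcm, pd.DataFrame(rows).set_index("sample_id")


def sample_qc(tcm: TagCountMatrix,
              min_reads: int = DEFAULT_MIN_SAMPLE_READS,
              ) -> tuple[TagCountMatrix, pd.DataFrame]:
    """Discard samples with fewer than ``min_reads`` total reads (strict <).

    Returns the filtered matrix and a report table (sample_id,
    total_reads, status)."""
    keep = tcm.total_reads >= min_reads
    report = pd.DataFrame(
        {
            "total_reads": tcm.total_reads,
            "status": ["retained" if k else "discarded" for k in keep],
        }
    )
    if not keep.any():
        raise ValueError(
            f"all {len(keep)} samples fall below the {min_reads}-read QC "
            "threshold"
        )
    kept = TagCountMatrix(counts=tcm.counts.loc[keep],
                          total_reads=tcm.total_reads.loc[keep])
    return kept, report


def filter_tags(tcm: TagCountMatrix,
                reference_samples=None,
                presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
                ) -> TagCountMatrix:
    """Retain tags present (>= 1 read) in at least ``presence_threshold``
    of the reference samples.

    For forward prediction the reference set is the training samples, so a
    validation sample may end up with all-zero retained columns; for
    cross-validation the reference set is all samples. The comparison is
    inclusive ("at least 25%").
    """
    if reference_samples is None:
        reference_samples = tcm.sample_ids
    reference_samples = pd.Index(reference_samples)
    if len(reference_samples) == 0:
        raise ValueError("reference sample set is empty")
    missing = reference_samples.difference(tcm.sample_ids)
    if len(missing):
        raise ValueError(f"reference samples not in matrix: {list(missing)[:5]}")
    presence = (tcm.counts.loc[reference_samples] >= 1).mean(axis=0)
    keep = presence >= presence_threshold
    return TagCountMatrix(counts=tcm.counts.loc[:, keep],
                          total_reads=tcm.total_reads)
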