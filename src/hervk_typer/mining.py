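"""Read recovery and the n/T matching statistic.

Reads mapped over the catalogued HERV-K intervals are extracted, reduced to
canonical k-mers, and matched exactly (hash lookup) against the
locus-unique reference. Per locus, ``n`` counts the reference *entries*
with at least one exact query match -- never raw hits -- so n <= T and the
ratio n/T lies in [0, 1] by construction: 1 means the individual carries
the reference allele, 0 that the element is absent, and intermediate
values point at solo LTRs or unreported alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pysam

from .reference import KmerReference, canonical

__all__ = [
    "MinedRead",
    "LocusProfile",
    "SampleProfile",
    "MiningError",
    "mine_reads",
    "kmerize_reads",
    "profile_sample",
    "estimate_depth",
]


class MiningError(ValueError):
    """Raised on invalid mining inputs."""


class MinedRead(NamedTuple):
    name: str
    mate: int           # 1 or 2 (0 for unpaired)
    sequence: str
    chrom: str
    pos: int


@dataclass
class LocusProfile:
    """Per-locus recovery record for one sample."""

    locus_id: str
    n: int
    T: int
    recovered_entry_ids: frozenset[int] = frozenset()

    @property
    def ratio(self) -> float | None:
        """n/T, or None (undefined) for loci with an empty reference set."""
        if self.T == 0:
            return None
        return self.n / self.T


@dataclass
class SampleProfile:
    """All per-locus n/T records for one sample, with sequencing depth."""

    sample_id: str
    depth: float
    records: dict[str, LocusProfile] = field(default_factory=dict)

    def ratio(self, locus_id: str) -> float | None:
        return self.records[locus_id].ratio


def _mate_index(read: pysam.AlignedSegment) -> int:
    if read.is_paired:
        return 1 if read.is_read1 else 2
    return 0


def mine_reads(
    alignment_file: str | Path,
    intervals: list[tuple[str, int, int]],
) -> list[MinedRead]:
    """Extract aligned reads overlapping any HERV-K interval.

    Keeps primary and supplementary alignments overlapping an interval by
    at least one base; unmapped, secondary and duplicate-marked records are
    dropped. Deduplicated by (read name, mate), so a read counted through
    one interval or one alignment record is never counted again.
    """
    if not intervals:
        raise MiningError("no intervals supplied")
    path = str(alignment_file)
    try:
        bam = pysam.AlignmentFile(path, "rb")
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot open alignment file {path}: {exc}") from exc
    if not bam.has_index():
        bam.close()
        raise IOError(f"alignment file {path} is not indexed")
    seen: set[tuple[str, int]] = set()
    out: list[MinedRead] = []
    with bam:
        for chrom, start, end in intervals:
            if chrom not in bam.references:
                continue
            for read in bam.fetch(chrom, start, end):
                if read.is_unmapped or read.is_secondary or read.is_duplicate:
                    continue
                key = (read.query_name, _mate_index(read))
                if key in seen:
                    continue
                seen.add(key)
                seq = read.query_sequence
                if not seq:
                    continue
                out.append(
                    MinedRead(
                        name=read.query_name,
                        mate=_mate_index(read),
                        sequence=seq,
                        chrom=read.reference_name,
                        pos=read.reference_start,
                    )
                )
    return out


def kmerize_reads(sequences: Iterable[str], k: int) -> set[str]:
    """Distinct canonical k-mers over a collection of read sequences.

    Reads shorter than k contribute nothing; windows containing non-ACGT
    symbols are dropped.
    """
    kmers: set[str] = set()
    for seq in sequences:
        seq = seq.upper()
        length = len(seq)
        if length < k:
            continue
        last_bad = -1
        for i, base in enumerate(seq):
            if base not in "ACGT":
                last_bad = i
            start = i - k + 1
            if start >= 0 and last_bad < start:
                kmers.add(canonical(seq[start : start + k]))
    return kmers


def profile_sample(
    reads: Iterable[str | MinedRead],
    reference: KmerReference,
    sample_id: str = "sample",
    depth: float = 1.0,
) -> SampleProfile:
    """Match a sample's reads against the reference and report n/T per locus.

    Each reference entry counts toward n at most once, whichever merged
    variant matched and however many reads carried it. Loci sharing a
    reporting group are pooled into a single record under the group
    representative.
    """
    sequences = (r.sequence if isinstance(r, MinedRead) else r for r in reads)
    query = kmerize_reads(sequences, reference.k)
    hits: dict[str, set[int]] = {}
    for kmer in query:
        entry_id = reference.entries.get(kmer)
        if entry_id is not None:
            locus = reference.entry_records[entry_id].locus_id
            hits.setdefault(locus, set()).add(entry_id)
    profile = SampleProfile(sample_id=sample_id, depth=depth)
    for rep in reference.representative_loci:
        recovered = frozenset(hits.get(rep, set()))
        profile.records[rep] = LocusProfile(
            locus_id=rep,
            n=len(recovered),
            T=reference.T_per_locus[rep],
            recovered_entry_ids=recovered,
        )
    return profile


def estimate_depth(
    metadata_depth: float | None = None,
    alignment_file: str | Path | None = None,
    control_intervals: list[tuple[str, int, int]] | None = None,
) -> float:
    """Mean sequencing depth for a sample.

    A metadata-supplied value (e.g. the cohort's published mean depth) is
    returned verbatim; otherwise mean per-base coverage is computed over
    the control intervals of an indexed alignment.
    """
    if metadata_depth is not None:
        return float(metadata_depth)
    if alignment_file is None or not control_intervals:
        raise MiningError(
            "supply either a metadata depth or an alignment plus control intervals"
        )
    total, bases = 0, 0
    with pysam.AlignmentFile(str(alignment_file), "rb") as bam:
        for chrom, start, end in control_intervals:
            if chrom not in bam.references:
                bases += end - start
                continue
            cov = bam.count_coverage(chrom, start, end, quality_threshold=0)
            total += sum(sum(track) for track in cov)
            bases += end - start
    depth = total / bases if bases else 0.0
    if depth == 0.0:
        warnings.warn("degenerate depth estimate: no coverage over control intervals")
    return depth
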