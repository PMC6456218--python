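"""Cluster-to-state genotype calling.

Clusters of (n/T, log depth) points are converted into biological states
per sample x locus. Classification is cluster-level, never per-sample: the
mixture model groups individuals with a common underlying state, and the
pooled k-mer evidence of each cluster is re-localised on the reference
allele to decide what that state is.

States:

- ``provirus_reference``: the cluster recovers (nearly) the full unique
  k-mer set; at low sequencing depth the full set is not reachable, so the
  required ratio relaxes along a depth curve.
- ``solo_LTR``: recovered entries localise (almost) exclusively inside the
  LTR intervals -- the signature of LTR-LTR recombination that excised the
  viral genes.
- ``provirus_allele``: coding-region k-mers are present but the set is
  incomplete, pointing at an allele absent from the catalog.
- ``absent``: (nearly) nothing recovered; the site is unoccupied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mining import SampleProfile
from .reference import KmerReference

__all__ = [
    "STATES",
    "PROVIRUS_STATES",
    "CallingThresholds",
    "ClusterEvidence",
    "GenotypeMatrix",
    "CallingError",
    "summarize_cluster_evidence",
    "classify_cluster",
    "call_genotypes",
    "burden",
]

STATES = ("provirus_reference", "provirus_allele", "solo_LTR", "absent")
PROVIRUS_STATES = ("provirus_reference", "provirus_allele")


class CallingError(ValueError):
    """Raised on inconsistent calling inputs or configuration."""


@dataclass(frozen=True)
class CallingThresholds:
    """Cluster classification bands.

    ``high_ratio`` applies at depth >= ``full_band_depth``; below that the
    reference band relaxes linearly down to ``min_reference_ratio`` (at low
    depth the reference cluster sits well below 1 even for true reference
    alleles). ``low_ratio`` bounds the absent state and ``ltr_purity`` the
    fraction of LTR-localised entries required to call a solo LTR.
    """

    high_ratio: float = 0.95
    low_ratio: float = 0.05
    ltr_purity: float = 0.90
    full_band_depth: float = 20.0
    relaxation: float = 0.30
    min_reference_ratio: float = 0.60

    def validate(self) -> None:
        for name in ("high_ratio", "low_ratio", "ltr_purity"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise CallingError(f"threshold {name}={value} outside [0, 1]")
        if self.low_ratio >= self.high_ratio:
            raise CallingError("low_ratio must be below high_ratio")

    def effective_high(self, depth: float | None) -> float:
        """Reference band lower edge at a given mean depth."""
        if depth is None or depth >= self.full_band_depth:
            return self.high_ratio
        relaxed = self.high_ratio - self.relaxation * (
            (self.full_band_depth - depth) / self.full_band_depth
        )
        return max(self.min_reference_ratio, relaxed)


@dataclass
class ClusterEvidence:
    """Pooled k-mer localisation evidence for one cluster at one locus."""

    locus_id: str
    cluster_id: int
    mean_ratio: float
    member_sample_ids: list[str]
    fraction_ltr: float
    fraction_internal: float
    coverage_gaps: list[tuple[int, int]]
    mean_depth: float | None = None
    n_recovered_entries: int = 0
    low_confidence: bool = False


def summarize_cluster_evidence(
    member_profiles: list[SampleProfile],
    locus_id: str,
    reference: KmerReference,
    cluster_id: int = 0,
) -> ClusterEvidence:
    """Pool recovered entries across cluster members and localise them.

    ``fraction_ltr`` is the fraction of pooled recovered entries flagged as
    LTR-contained; coverage gaps are maximal runs of unrecovered anchor
    positions on the reference allele.
    """
    if not member_profiles:
        raise CallingError("cluster has no members")
    if locus_id not in reference.coverage_map:
        raise CallingError(f"locus {locus_id} missing from coverage map")
    pooled: set[int] = set()
    ratios = []
    depths = []
    for prof in member_profiles:
        rec = prof.records[locus_id]
        pooled.update(rec.recovered_entry_ids)
        if rec.ratio is not None:
            ratios.append(rec.ratio)
        depths.append(prof.depth)
    n_ltr = sum(1 for eid in pooled if reference.entry_records[eid].in_ltr)
    total = len(pooled)
    frac_ltr = n_ltr / total if total else 0.0
    frac_internal = 1.0 - frac_ltr if total else 0.0

    # coverage gaps: maximal runs of unrecovered anchors, in anchor order
    gaps: list[tuple[int, int]] = []
    run_start = None
    prev_anchor = None
    anchor_hit = {
        e.anchor: (e.entry_id in pooled)
        for e in reference.entry_records
        if e.locus_id == locus_id
    }
    for anchor in sorted(anchor_hit):
        if not anchor_hit[anchor]:
            if run_start is None:
                run_start = anchor
            prev_anchor = anchor
        else:
            if run_start is not None:
                gaps.append((run_start, prev_anchor))
                run_start = None
    if run_start is not None:
        gaps.append((run_start, prev_anchor))

    T = reference.T_per_locus[locus_id]
    return ClusterEvidence(
        locus_id=locus_id,
        cluster_id=cluster_id,
        mean_ratio=float(np.mean(ratios)) if ratios else 0.0,
        member_sample_ids=[p.sample_id for p in member_profiles],
        fraction_ltr=frac_ltr,
        fraction_internal=frac_internal,
        coverage_gaps=gaps,
        mean_depth=float(np.mean(depths)) if depths else None,
        n_recovered_entries=total,
        low_confidence=bool(T and total / T < 0.3 and frac_ltr < 0.9),
    )


def classify_cluster(
    evidence: ClusterEvidence,
    thresholds: CallingThresholds = CallingThresholds(),
) -> str:
    """Assign a biological state to a cluster from its pooled evidence."""
    thresholds.validate()
    high = thresholds.effective_high(evidence.mean_depth)
    if evidence.mean_ratio >= high:
        return "provirus_reference"
    if evidence.mean_ratio <= thresholds.low_ratio:
        return "absent"
    if evidence.fraction_ltr >= thresholds.ltr_purity:
        return "solo_LTR"
    return "provirus_allele"


@dataclass
class GenotypeMatrix:
    """Per sample x locus categorical states with cluster provenance."""

    states: pd.DataFrame                  # index samples, columns loci, str states
    cluster_labels: pd.DataFrame | None = None
    ratios: pd.DataFrame | None = None
    cluster_states: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.states.values.ravel()) - set(STATES)
        if bad:
            raise CallingError(f"unknown states {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.states.index)

    @property
    def loci(self) -> list[str]:
        return list(self.states.columns)

    def occupancy(self) -> pd.DataFrame:
        """True where the site carries anything (provirus or solo LTR)."""
        return self.states != "absent"

    def presence(self) -> pd.DataFrame:
        """True where a provirus (reference or allele) is present."""
        return self.states.isin(PROVIRUS_STATES)

    def to_tsv(self, path) -> None:
        self.states.to_csv(path, sep="\t", index_label="sample_id")


def call_genotypes(
    cluster_labels: pd.DataFrame,
    cluster_states: dict[str, dict[int, str]],
    ratios: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Propagate per-cluster states to every member sample.

    ``cluster_labels``: sample x locus integer cluster ids;
    ``cluster_states``: per locus, cluster id -> state.
    """
    states = pd.DataFrame(index=cluster_labels.index, columns=cluster_labels.columns,
                          dtype=object)
    for locus in cluster_labels.columns:
        if locus not in cluster_states:
            raise CallingError(f"no cluster states for locus {locus}")
        mapping = cluster_states[locus]
        col = cluster_labels[locus]
        if col.isna().any():
            raise CallingError(f"unlabeled samples at locus {locus}")
        unknown = set(col.unique()) - set(mapping)
        if unknown:
            raise CallingError(f"locus {locus}: clusters {unknown} have no state")
        states[locus] = col.map(mapping)
    return GenotypeMatrix(
        states=states,
        cluster_labels=cluster_labels,
        ratios=ratios,
        cluster_states=cluster_states,
    )


def burden(genotypes: GenotypeMatrix, polymorphic_loci: list[str]) -> pd.Series:
    """Per-sample count of provirus states over the designated loci."""
    unknown = set(polymorphic_loci) - set(genotypes.loci)
    if unknown:
        raise CallingError(f"unknown loci in polymorphic set: {sorted(unknown)}")
    sub = genotypes.states[list(polymorphic_loci)]
    counts = sub.isin(PROVIRUS_STATES).sum(axis=1)
    counts.name = "burden"
    return counts
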