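"""Locus-unique k-mer reference construction.

The detection statistic rests on a reference set T per locus: the k-mers
(default k = 50) that occur at exactly one HERV-K locus across every
catalogued allele. Because HERV-K loci share high sequence identity, most
k-mers occur at several loci and are discarded; what survives is a sparse
set of locus-diagnostic positions. Within a locus, k-mers from different
alleles that anchor at the same position on the primary allele and differ
by at most 2 substitutions (allelic SNPs) are merged into a single entry so
that T counts positions, not allelic variants.

All matching is done in canonical orientation: a k-mer and its reverse
complement are represented by the lexicographically smaller of the two, so
reads from either strand hit the same table entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .catalog import LocusCatalog

__all__ = [
    "KmerEntry",
    "KmerReference",
    "ReferenceError",
    "enumerate_kmers",
    "canonical",
    "reverse_complement",
    "hamming",
    "build_unique_reference",
    "annotate_reference_coverage",
    "save_reference",
    "load_reference",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FORMAT_VERSION = 1


class ReferenceError(ValueError):
    """Raised on invalid reference-construction inputs."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def enumerate_kmers(sequence: str, k: int) -> list[tuple[int, str]]:
    """All (position, k-mer) windows of ``sequence``.

    Windows containing any non-ACGT symbol are dropped; positions are
    0-based start coordinates. Returns an empty list when k exceeds the
    sequence length.
    """
    if k <= 0:
        raise ReferenceError(f"k must be positive, got {k}")
    sequence = sequence.upper()
    out = []
    # track the most recent disallowed symbol so N-containing windows are
    # skipped without rescanning each window
    last_bad = -1
    for i, base in enumerate(sequence):
        if base not in "ACGT":
            last_bad = i
        start = i - k + 1
        if start >= 0 and last_bad < start:
            out.append((start, sequence[start : start + k]))
    return out


@dataclass
class KmerEntry:
    """One locus-diagnostic position with its merged allelic variants.

    ``variants`` holds k-mer strings in allele orientation; members are
    pairwise within Hamming distance 2 (allelic SNPs at the same
    location). ``anchor`` is the entry's position on the locus's primary
    allele. ``in_ltr`` is True when the window lies entirely inside an
    annotated LTR interval (so an LTR-only haplotype carries it). Lookup
    happens through the canonical form of each variant.
    """

    entry_id: int
    locus_id: str
    anchor: int
    variants: set[str] = field(default_factory=set)
    in_ltr: bool = False


@dataclass
class KmerReference:
    """Lookup table from canonical k-mer to entry, with per-locus totals.

    ``T_per_locus`` maps every catalog locus to its entry count; loci that
    cannot be distinguished (identical sequences) share a
    ``reporting_group`` and only the group representative carries entries,
    the rest report T = 0.
    """

    k: int
    entries: dict[str, int]              # canonical k-mer -> entry_id
    entry_records: list[KmerEntry]       # entry_id indexes this list
    T_per_locus: dict[str, int]
    reporting_groups: dict[str, str]     # locus_id -> representative locus_id
    coverage_map: dict[str, list[tuple[int, bool]]] = field(default_factory=dict)

    @property
    def representative_loci(self) -> list[str]:
        """Loci that carry entries (one per reporting group), catalog order."""
        seen, out = set(), []
        for locus_id, rep in self.reporting_groups.items():
            if rep not in seen:
                seen.add(rep)
                out.append(rep)
        return out

    def entries_for_locus(self, locus_id: str) -> list[KmerEntry]:
        rep = self.reporting_groups.get(locus_id, locus_id)
        return [e for e in self.entry_records if e.locus_id == rep]

    def t_ltr(self, locus_id: str) -> int:
        return sum(e.in_ltr for e in self.entries_for_locus(locus_id))

    def t_internal(self, locus_id: str) -> int:
        rep = self.reporting_groups.get(locus_id, locus_id)
        return self.T_per_locus[rep] - self.t_ltr(rep)


def _identity_groups(catalog: LocusCatalog) -> dict[str, str]:
    """Map each locus to its reporting-group representative.

    Loci are grouped when byte-identical in their sorted allele sequences
    (indistinguishable by any k-mer) or when the catalog declares a shared
    reporting_group. Representative = first member in catalog order.
    """
    key_to_rep: dict[object, str] = {}
    rep_of: dict[str, str] = {}
    for locus in catalog:
        keys: list[object] = [tuple(sorted(a.sequence for a in locus.alleles))]
        if locus.reporting_group is not None:
            keys.append(("declared", locus.reporting_group))
        rep = None
        for key in keys:
            if key in key_to_rep:
                rep = rep_of[key_to_rep[key]]
                break
        if rep is None:
            rep = locus.locus_id
        for key in keys:
            key_to_rep.setdefault(key, rep)
        rep_of[locus.locus_id] = rep
    return rep_of


def build_unique_reference(catalog: LocusCatalog, k: int = 50) -> KmerReference:
    """Construct the locus-unique k-mer reference from a catalog.

    Selection proceeds in canonical-orientation space:

    1. every k-mer of every allele is labelled with the loci (reporting
       groups) it occurs in; k-mers seen at two or more groups are excluded;
    2. surviving k-mers of one locus that project to the same anchor on the
       primary allele and sit within Hamming distance 2 of each other are
       merged into a single entry;
    3. loci with identical sequences share one reporting group: entries are
       built once for the representative, the others report T = 0.
    """
    if k <= 0:
        raise ReferenceError(f"k must be positive, got {k}")
    catalog.validate()

    rep_of = _identity_groups(catalog)

    # label each canonical k-mer with the reporting groups containing it
    group_count: dict[str, set[str]] = {}
    per_locus_kmers: dict[str, list[tuple[str, int, str]]] = {}
    for locus in catalog:
        rep = rep_of[locus.locus_id]
        if rep != locus.locus_id:
            # identical to representative: contributes the same k-mers
            continue
        rows = []
        primary = locus.primary_allele
        ordered = [primary] + [a for a in locus.alleles if a is not primary]
        for allele in ordered:
            for pos, kmer in enumerate_kmers(allele.sequence, k):
                canon = canonical(kmer)
                group_count.setdefault(canon, set()).add(rep)
                rows.append((pos + allele.offset, kmer, canon))
        per_locus_kmers[rep] = rows

    banned = {kmer for kmer, groups in group_count.items() if len(groups) > 1}

    entries: dict[str, int] = {}
    entry_records: list[KmerEntry] = []
    T_per_locus: dict[str, int] = {locus.locus_id: 0 for locus in catalog}

    for locus in catalog:
        rep = rep_of[locus.locus_id]
        if rep != locus.locus_id:
            continue
        by_anchor: dict[int, list[int]] = {}
        for anchor, fwd, canon in per_locus_kmers[rep]:
            if canon in banned:
                continue
            if canon in entries:
                continue  # same k-mer string, already an entry (repeat or shared)
            # merge on Hamming distance in allele orientation: "the same
            # location" compares like-oriented windows, while uniqueness
            # and lookup stay canonical
            target = None
            for eid in by_anchor.get(anchor, []):
                rec = entry_records[eid]
                if all(hamming(fwd, v) <= 2 for v in rec.variants):
                    target = eid
                    break
            if target is None:
                target = len(entry_records)
                entry_records.append(
                    KmerEntry(entry_id=target, locus_id=rep, anchor=anchor)
                )
                by_anchor.setdefault(anchor, []).append(target)
            entry_records[target].variants.add(fwd)
            entries[canon] = target
        T_per_locus[rep] = sum(1 for e in entry_records if e.locus_id == rep)

    reference = KmerReference(
        k=k,
        entries=entries,
        entry_records=entry_records,
        T_per_locus=T_per_locus,
        reporting_groups=rep_of,
    )
    annotate_reference_coverage(reference, catalog)
    return reference


def annotate_reference_coverage(
    reference: KmerReference, catalog: LocusCatalog
) -> dict[str, list[tuple[int, bool]]]:
    """Flag entries inside LTRs and build per-locus anchor coverage maps.

    An entry is ``in_ltr`` when its window [anchor, anchor + k) lies
    entirely within an annotated LTR interval of the locus's primary
    allele; such entries are exactly the ones an LTR-only (solo) haplotype
    can produce. Returns ``{locus: sorted [(anchor, in_ltr), ...]}``.
    """
    known = set(catalog.locus_ids)
    missing = set(reference.T_per_locus) - known
    if missing:
        raise ReferenceError(f"loci absent from catalog: {sorted(missing)}")
    k = reference.k
    coverage: dict[str, list[tuple[int, bool]]] = {}
    for locus in catalog:
        rep = reference.reporting_groups.get(locus.locus_id, locus.locus_id)
        if rep != locus.locus_id or rep in coverage:
            continue
        ltrs = locus.primary_allele.ltr_intervals
        rows = []
        for entry in reference.entry_records:
            if entry.locus_id != rep:
                continue
            inside = any(
                s <= entry.anchor and entry.anchor + k <= e for s, e in ltrs
            )
            entry.in_ltr = inside
            rows.append((entry.anchor, inside))
        coverage[rep] = sorted(rows)
    reference.coverage_map = coverage
    return coverage


def save_reference(reference: KmerReference, path: str | Path) -> None:
    """Write the reference as a versioned, self-describing JSON archive."""
    payload = {
        "format": "hervk-typer-kmer-reference",
        "version": FORMAT_VERSION,
        "k": reference.k,
        "T_per_locus": reference.T_per_locus,
        "reporting_groups": reference.reporting_groups,
        "entries": [
            {
                "entry_id": e.entry_id,
                "locus_id": e.locus_id,
                "anchor": e.anchor,
                "variants": sorted(e.variants),
                "in_ltr": e.in_ltr,
            }
            for e in reference.entry_records
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_reference(path: str | Path) -> KmerReference:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "hervk-typer-kmer-reference":
        raise ReferenceError(f"{path}: not a k-mer reference archive")
    records = [
        KmerEntry(
            entry_id=e["entry_id"],
            locus_id=e["locus_id"],
            anchor=e["anchor"],
            variants=set(e["variants"]),
            in_ltr=e["in_ltr"],
        )
        for e in payload["entries"]
    ]
    entries = {canonical(v): rec.entry_id for rec in records for v in rec.variants}
    ref = KmerReference(
        k=payload["k"],
        entries=entries,
        entry_records=records,
        T_per_locus=payload["T_per_locus"],
        reporting_groups=payload["reporting_groups"],
    )
    coverage: dict[str, list[tuple[int, bool]]] = {}
    for rec in records:
        coverage.setdefault(rec.locus_id, []).append((rec.anchor, rec.in_ltr))
    ref.coverage_map = {loc: sorted(rows) for loc, rows in coverage.items()}
    return ref


def write_reference_summary(reference: KmerReference, path: str | Path) -> None:
    """Human-readable per-locus TSV of T, T_LTR, T_internal."""
    with open(path, "w") as handle:
        handle.write("locus_id\treporting_group\tT\tT_LTR\tT_internal\n")
        for locus_id, T in reference.T_per_locus.items():
            rep = reference.reporting_groups.get(locus_id, locus_id)
            if locus_id == rep:
                handle.write(
                    f"{locus_id}\t{rep}\t{T}\t{reference.t_ltr(locus_id)}\t"
                    f"{reference.t_internal(locus_id)}\n"
                )
            else:
                handle.write(f"{locus_id}\t{rep}\t0\t0\t0\n")
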