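"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's construction code paths: they
enumerate every window, tabulate locus membership in plain dictionaries
and apply the merge/containment rules directly.
"""

from __future__ import annotations

import itertools

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def canon(kmer: str) -> str:
    r = rc(kmer)
    return kmer if kmer <= r else r


def windows(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if all(b in "ACGT" for b in w):
            yield i, w


def brute_force_reference(catalog, k):
    """Enumerate / filter / merge by hand.

    Returns {locus_id: {"T": int, "entries": [(anchor, frozenset variants,
    in_ltr)], "rep": representative}} mirroring the uniqueness, merge and
    LTR-containment semantics.
    """
    # identity grouping: equal sorted allele-sequence tuples share a group
    reps = {}
    keys = {}
    for locus in catalog:
        key = "|".join(sorted(a.sequence for a in locus.alleles))
        if key in keys:
            reps[locus.locus_id] = keys[key]
        else:
            keys[key] = locus.locus_id
            reps[locus.locus_id] = locus.locus_id

    # canonical k-mer -> set of groups observing it
    membership = {}
    for locus in catalog:
        rep = reps[locus.locus_id]
        for allele in locus.alleles:
            for _, w in windows(allele.sequence, k):
                membership.setdefault(canon(w), set()).add(rep)
    banned = {km for km, groups in membership.items() if len(groups) > 1}

    result = {}
    for locus in catalog:
        rep = reps[locus.locus_id]
        if rep != locus.locus_id:
            result[locus.locus_id] = {"T": 0, "entries": [], "rep": rep}
            continue
        primary = locus.primary_allele
        ordered = [primary] + [a for a in locus.alleles if a is not primary]
        entries = []  # (anchor, set of forward-orientation variants)
        seen = set()  # canonical strings already placed
        for allele in ordered:
            for pos, w in windows(allele.sequence, k):
                c = canon(w)
                if c in banned or c in seen:
                    continue
                anchor = pos + allele.offset
                target = None
                for idx, (a, variants) in enumerate(entries):
                    if a == anchor and all(
                        sum(x != y for x, y in zip(w, v)) <= 2 for v in variants
                    ):
                        target = idx
                        break
                if target is None:
                    entries.append((anchor, {w}))
                else:
                    entries[target][1].add(w)
                seen.add(c)
        ltrs = primary.ltr_intervals
        rows = [
            (
                anchor,
                frozenset(variants),
                any(s <= anchor and anchor + k <= e for s, e in ltrs),
            )
            for anchor, variants in entries
        ]
        result[locus.locus_id] = {"T": len(rows), "entries": rows, "rep": rep}
    return result


def brute_force_itemsets(presence, min_support, max_size=None):
    """Supports of every non-empty locus subset, filtered by threshold."""
    items = list(presence.columns)
    X = presence.to_numpy(dtype=bool)
    n = X.shape[0]
    if max_size is None:
        max_size = len(items)
    out = {}
    for m in range(1, max_size + 1):
        for combo in itertools.combinations(range(len(items)), m):
            support = X[:, list(combo)].all(axis=1).sum() / n
            if support >= min_support:
                out[frozenset(items[i] for i in combo)] = support
    return out


def step_up_bh(p_values):
    """Benjamini-Hochberg step-up adjustment from its textbook definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p_values[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted
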