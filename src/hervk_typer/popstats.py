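"""Population-level analysis of polymorphic provirus genotypes.

Prevalence tables per population and super-population, pairwise
super-population proportion tests with Benjamini-Hochberg correction,
Fisher LDA projections of per-sample HERV-K profiles, Apriori mining of
co-occurring proviruses, and the JSON payload consumed by the interactive
co-occurrence map.

Prevalence of a locus in a population is the fraction of its individuals
carrying a provirus there; a catalogued-allele call (``provirus_allele``)
counts as provirus present, a solo LTR does not.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .calling import PROVIRUS_STATES, GenotypeMatrix

__all__ = [
    "PrevalenceTable",
    "ComparisonResult",
    "CooccurrenceResult",
    "StatsError",
    "prevalence",
    "compare_proportions",
    "compare_populations",
    "comparison_families",
    "bh_adjust",
    "apriori_cooccurrence",
    "lda_project",
    "burden_histogram",
    "burden_categories",
    "export_viz_json",
]


class StatsError(ValueError):
    """Raised on invalid population-statistics inputs."""


REQUIRED_METADATA = ("sample_id", "population", "super_population")


def _check_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_METADATA) - set(metadata.columns)
    if missing:
        raise StatsError(f"metadata missing columns {sorted(missing)}")
    return metadata.set_index("sample_id") if metadata.index.name != "sample_id" else metadata


@dataclass
class PrevalenceTable:
    """Per locus x group state counts and fractions.

    ``table`` is tidy with columns: level (population / super_population /
    all), group, locus_id, n, provirus, solo_LTR, absent, and the
    corresponding *_frac columns. Fractions per row sum to 1.
    """

    table: pd.DataFrame

    def fraction(self, locus_id: str, group: str, state: str = "provirus") -> float:
        rows = self.table[(self.table.locus_id == locus_id) & (self.table.group == group)]
        if rows.empty:
            raise KeyError((locus_id, group))
        return float(rows.iloc[0][f"{state}_frac"])

    def wide(self, level: str = "super_population", state: str = "provirus") -> pd.DataFrame:
        """Loci x groups matrix of state fractions (Table-1-style layout)."""
        sub = self.table[self.table.level == level]
        return sub.pivot(index="locus_id", columns="group", values=f"{state}_frac")


def prevalence(genotypes: GenotypeMatrix, metadata: pd.DataFrame) -> PrevalenceTable:
    """Tabulate provirus / solo LTR / absent fractions per population.

    Samples without metadata are listed in a warning and excluded.
    """
    meta = _check_metadata(metadata)
    samples = genotypes.states.index
    unknown = [s for s in samples if s not in meta.index]
    if unknown:
        warnings.warn(f"samples without metadata excluded: {unknown}")
    keep = [s for s in samples if s in meta.index]
    states = genotypes.states.loc[keep]
    meta = meta.loc[keep]

    groupings = [
        ("population", meta["population"]),
        ("super_population", meta["super_population"]),
        ("all", pd.Series("ALL", index=meta.index)),
    ]
    rows = []
    for level, labels in groupings:
        for group, members in states.groupby(labels):
            n = len(members)
            for locus in states.columns:
                col = members[locus]
                prov = int(col.isin(PROVIRUS_STATES).sum())
                solo = int((col == "solo_LTR").sum())
                absent = n - prov - solo
                rows.append(
                    {
                        "level": level,
                        "group": group,
                        "locus_id": locus,
                        "n": n,
                        "provirus": prov,
                        "solo_LTR": solo,
                        "absent": absent,
                        "provirus_frac": prov / n,
                        "solo_LTR_frac": solo / n,
                        "absent_frac": absent / n,
                    }
                )
    return PrevalenceTable(table=pd.DataFrame(rows))


def compare_proportions(
    successes_a: int, n_a: int, successes_b: int, n_b: int
) -> float:
    """Two-sample test of equal proportions (chi-square, Yates-corrected).

    Mirrors the default behaviour of R's ``prop.test`` on a 2x2 table.
    Degenerate tables where the pooled proportion is 0 or 1 return p = 1
    with a warning.
    """
    for successes, n in ((successes_a, n_a), (successes_b, n_b)):
        if n <= 0:
            raise StatsError("group size must be positive")
        if not 0 <= successes <= n:
            raise StatsError("successes must lie in [0, n]")
    table = np.array(
        [[successes_a, n_a - successes_a], [successes_b, n_b - successes_b]]
    )
    if table[:, 0].sum() in (0, n_a + n_b):
        warnings.warn("degenerate proportion comparison: pooled proportion is 0 or 1")
        return 1.0
    _, p, _, _ = chi2_contingency(table, correction=True)
    return float(p)


def comparison_families(groups: list[str]) -> list[tuple[str, str]]:
    """The one-to-one comparison families: all unordered group pairs."""
    return list(itertools.combinations(sorted(groups), 2))


@dataclass
class ComparisonResult:
    """Pairwise proportion tests within one comparison problem.

    One BH family per (problem, population pair), matching how the
    multiple-comparison correction is organised.
    """

    table: pd.DataFrame  # family, group_a, group_b, item, p_raw, p_adj, significant


def compare_populations(
    prevalence_table: PrevalenceTable,
    level: str = "super_population",
    state: str = "provirus",
    alpha: float = 0.05,
    problem: str = "prevalence",
) -> ComparisonResult:
    """All pairwise group comparisons of per-locus state proportions.

    Raw p-values come from ``compare_proportions``; BH adjustment is
    applied within each family (one family per group pair).
    """
    sub = prevalence_table.table[prevalence_table.table.level == level]
    groups = sorted(sub.group.unique())
    rows = []
    for ga, gb in comparison_families(groups):
        for locus in sub.locus_id.unique():
            a = sub[(sub.group == ga) & (sub.locus_id == locus)].iloc[0]
            b = sub[(sub.group == gb) & (sub.locus_id == locus)].iloc[0]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = compare_proportions(a[state], a["n"], b[state], b["n"])
            rows.append(
                {
                    "family": f"{problem}:{ga}-{gb}",
                    "group_a": ga,
                    "group_b": gb,
                    "item": locus,
                    "p_raw": p,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    for family, idx in table.groupby("family").groups.items():
        table.loc[idx, "p_adj"] = bh_adjust(table.loc[idx, "p_raw"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return ComparisonResult(table=table)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CooccurrenceResult:
    """Frequent provirus itemsets with exact supports.

    ``itemsets`` maps a frozenset of locus ids to its overall support (the
    fraction of individuals carrying a provirus at *every* member locus).
    Support is anti-monotone under set inclusion, which is what lets the
    level-wise search prune candidates.
    """

    itemsets: dict[frozenset, float]
    min_support: float
    n_samples: int
    candidate_counts: dict[int, int] = field(default_factory=dict)
    per_population: dict[frozenset, dict[str, float]] = field(default_factory=dict)

    def of_size(self, m: int) -> dict[frozenset, float]:
        return {s: v for s, v in self.itemsets.items() if len(s) == m}


def apriori_cooccurrence(
    presence: pd.DataFrame,
    min_support: float,
    max_size: int | None = None,
    metadata: pd.DataFrame | None = None,
) -> CooccurrenceResult:
    """Level-wise Apriori search for co-occurring proviruses.

    ``presence`` is a samples x loci boolean matrix (provirus present).
    Candidates of size m+1 are generated by self-joining frequent sets of
    size m on their first m-1 items and pruned when any m-subset is
    infrequent; supports are computed exactly, so the result equals a
    brute-force enumeration of all 2^p - 1 itemsets above threshold.
    """
    if presence.shape[0] == 0 or presence.shape[1] == 0:
        raise StatsError("empty presence matrix")
    if not 0.0 <= min_support <= 1.0:
        raise StatsError("min_support must lie in [0, 1]")
    X = presence.to_numpy(dtype=bool)
    items = list(presence.columns)
    n = X.shape[0]
    if max_size is None:
        max_size = len(items)

    def support(cols: tuple[int, ...]) -> float:
        return float(X[:, list(cols)].all(axis=1).sum()) / n

    itemsets: dict[frozenset, float] = {}
    candidate_counts: dict[int, int] = {}
    frequent: list[tuple[int, ...]] = []
    candidates = [(i,) for i in range(len(items))]
    m = 1
    while candidates and m <= max_size:
        candidate_counts[m] = len(candidates)
        frequent = []
        for cols in candidates:
            s = support(cols)
            if s >= min_support:
                frequent.append(cols)
                itemsets[frozenset(items[i] for i in cols)] = s
        # self-join frequent m-sets sharing their first m-1 items
        freq_set = set(frequent)
        nxt = []
        for a, b in itertools.combinations(sorted(frequent), 2):
            if a[:-1] == b[:-1]:
                cand = a + (b[-1],)
                if all(
                    tuple(x for x in cand if x != drop) in freq_set for drop in cand
                ):
                    nxt.append(cand)
        candidates = nxt
        m += 1

    per_population: dict[frozenset, dict[str, float]] = {}
    if metadata is not None:
        meta = _check_metadata(metadata)
        pops = meta.loc[[s for s in presence.index if s in meta.index], "population"]
        for itemset in itemsets:
            cols = [items.index(i) for i in itemset]
            carrier = presence.iloc[:, cols].all(axis=1)
            per_population[itemset] = {
                pop: float(carrier.loc[members.index].mean())
                for pop, members in pops.groupby(pops)
            }
    return CooccurrenceResult(
        itemsets=itemsets,
        min_support=min_support,
        n_samples=n,
        candidate_counts=candidate_counts,
        per_population=per_population,
    )


def lda_project(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_components: int = 2,
):
    """Fisher LDA projection of per-sample HERV-K features.

    Features may be raw n/T columns or one-hot state encodings. Returns
    ``(projection, scalings, separation)``: the projection onto the top
    discriminant axes, the discriminant directions (feature loadings), and
    a per-class-pair separation score (squared Mahalanobis distance between
    class means under the pooled within-class covariance of the projected
    space, ridge-regularised when singular).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StatsError("need at least two classes")
    if counts.min() < 2:
        raise StatsError("each class needs at least two samples")
    n_components = min(n_components, len(classes) - 1, X.shape[1])
    lda = LinearDiscriminantAnalysis(n_components=n_components, solver="svd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear one-hot features are expected
        Z = lda.fit_transform(X, y)
    scalings = lda.scalings_[:, :n_components]

    # pooled within-class covariance in the projected space
    d = Z.shape[1]
    Sw = np.zeros((d, d))
    for c in classes:
        zc = Z[y == c]
        Sw += (zc - zc.mean(axis=0)).T @ (zc - zc.mean(axis=0))
    Sw /= max(len(y) - len(classes), 1)
    eps = 1e-9 * max(np.trace(Sw) / d, 1.0)
    if np.linalg.cond(Sw) > 1e12:
        warnings.warn("singular within-class scatter; ridge-regularised")
    Sw_inv = np.linalg.inv(Sw + eps * np.eye(d))

    separation: dict[tuple, float] = {}
    for ca, cb in itertools.combinations(classes, 2):
        diff = Z[y == ca].mean(axis=0) - Z[y == cb].mean(axis=0)
        separation[(ca, cb)] = float(diff @ Sw_inv @ diff)

    projection = pd.DataFrame(
        Z,
        index=features.index if hasattr(features, "index") else None,
        columns=[f"LD{i + 1}" for i in range(Z.shape[1])],
    )
    return projection, scalings, separation


def burden_categories(n_loci: int) -> list[int]:
    """Possible per-individual provirus counts: 0..n_loci inclusive."""
    return list(range(n_loci + 1))


def burden_histogram(burdens: pd.Series, metadata: pd.DataFrame, n_loci: int) -> pd.DataFrame:
    """Counts of individuals per burden category per super-population."""
    meta = _check_metadata(metadata)
    cats = burden_categories(n_loci)
    groups = meta.loc[burdens.index, "super_population"]
    out = pd.DataFrame(0, index=cats, columns=sorted(groups.unique()))
    for group, members in burdens.groupby(groups):
        counts = members.value_counts()
        for cat in cats:
            out.loc[cat, group] = int(counts.get(cat, 0))
    out.index.name = "burden"
    return out


def export_viz_json(
    genotypes: GenotypeMatrix,
    selection: list[str],
    loci_info: pd.DataFrame,
    metadata: pd.DataFrame,
    display_coordinates: pd.DataFrame | None = None,
    path=None,
) -> dict:
    """Build the co-occurrence visualisation payload.

    Schema: ``loci`` (id, label, chrom, start, end), ``populations`` (id,
    super-population, size, optional display coordinates), ``matrix``
    (samples x selected loci, 0/1 provirus presence) and per-population
    co-occurrence prevalence of the selected set.
    """
    if not selection:
        raise StatsError("empty locus selection")
    missing = set(selection) - set(genotypes.loci)
    if missing:
        raise StatsError(f"selected loci absent from genotypes: {sorted(missing)}")
    meta = _check_metadata(metadata)
    presence = genotypes.presence()[list(selection)]
    keep = [s for s in presence.index if s in meta.index]
    presence = presence.loc[keep]
    pops = meta.loc[keep]

    coords = {}
    if display_coordinates is not None:
        coords = {
            row["population"]: (float(row["lon"]), float(row["lat"]))
            for _, row in display_coordinates.iterrows()
        }

    loci_payload = []
    for locus in selection:
        info = loci_info[loci_info.locus_id == locus]
        if info.empty:
            raise StatsError(f"locus {locus} missing from loci_info")
        row = info.iloc[0]
        loci_payload.append(
            {
                "id": locus,
                "label": f"{row.chrom}:{int(row.start) + 1}-{int(row.end)}",
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
            }
        )

    carrier = presence.all(axis=1)
    populations_payload = []
    for pop, members in pops.groupby("population"):
        entry = {
            "id": pop,
            "super_population": members["super_population"].iloc[0],
            "size": int(len(members)),
            "cooccurrence_prevalence": float(carrier.loc[members.index].mean()),
        }
        if pop in coords:
            entry["lon"], entry["lat"] = coords[pop]
        populations_payload.append(entry)

    payload = {
        "loci": loci_payload,
        "populations": populations_payload,
        "samples": list(presence.index),
        "matrix": presence.astype(int).to_numpy().tolist(),
    }
    if path is not None:
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1)
    return payload
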