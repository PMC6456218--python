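"""Synthetic HERV-K cohorts for end-to-end validation.

The simulator emulates the structure the genotyper is built for: a family
of ~9.5 kb proviruses at distinct genomic loci sharing high (>80%)
sequence identity, each flanked by a duplicated ~1 kb LTR, embedded in
unique host flanks. Per-locus diploid states (provirus / solo LTR /
absent) are drawn at population-specific haplotype frequencies; solo-LTR
haplotypes are single-LTR recombinants, exactly what LTR-LTR homologous
recombination leaves behind. Short reads are sampled per haplotype at a
configurable depth and per-base substitution error rate, with read names
encoding their source for ground-truth checks.

Read starts are stratified-uniform: the start range is cut into one
equal-width stratum per read and a start drawn uniformly within each. At
high depth the strata are narrower than a k-mer window, so every window is
covered and recovery saturates exactly; at low depth coverage gaps
reappear, reproducing the dispersion that motivates the mixture model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import Allele, Locus, LocusCatalog

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "SimulationError",
    "simulate_catalog",
    "simulate_cohort",
    "simulate_reads",
    "sample_read_layout",
    "haplotype_sequence",
    "reads_for_sample",
    "write_cohort",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# diploid haplotype state codes
PROVIRUS, SOLO, ABSENT = 0, 1, 2
STATE_NAMES = {PROVIRUS: "provirus", SOLO: "solo_LTR", ABSENT: "absent"}


class SimulationError(ValueError):
    """Raised on invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated cohort.

    ``divergence`` is the per-site substitution probability applied
    independently per locus to a shared ancestral provirus (0.08 keeps
    pairwise identity just above the >80% the locus family exhibits).
    ``prevalences`` holds per-population x per-locus haplotype frequencies
    of (provirus, solo LTR, absent); when None a population-structured set
    is generated from the seed. ``depth`` is total diploid depth (x-fold),
    split evenly between haplotypes.
    """

    n_loci: int = 10
    n_samples: int = 500
    n_populations: int = 2
    provirus_length: int = 9500
    ltr_length: int = 968
    flank_length: int = 300
    divergence: float = 0.08
    allele_polymorphism: float = 0.0
    read_length: int = 100
    depth: float = 7.0
    error_rate: float = 0.01
    prevalences: tuple | None = None   # (n_populations, n_loci, 3), rows sum to 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.n_loci, self.n_samples, self.n_populations) <= 0:
            raise SimulationError("counts must be positive")
        if not 0.0 <= self.divergence <= 0.2:
            raise SimulationError("divergence must lie in [0, 0.2]")
        if self.divergence == 0.0 and self.n_loci > 1:
            warnings.warn("divergence 0 with multiple loci: loci are indistinguishable")
        if self.ltr_length < 0 or self.ltr_length * 2 >= self.provirus_length:
            raise SimulationError("LTRs must fit inside the provirus")
        if self.read_length <= 0 or self.depth < 0 or not 0 <= self.error_rate < 1:
            raise SimulationError("invalid read parameters")
        if self.prevalences is not None:
            arr = np.asarray(self.prevalences, dtype=float)
            if arr.shape != (self.n_populations, self.n_loci, 3):
                raise SimulationError(
                    f"prevalences shape {arr.shape} != "
                    f"({self.n_populations}, {self.n_loci}, 3)"
                )
            if not np.allclose(arr.sum(axis=2), 1.0):
                raise SimulationError("prevalence rows must sum to 1")

    @property
    def population_names(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_populations)]


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    if rate > 0:
        mask = rng.random(len(seq)) < rate
        out[mask] = (out[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return out


def codes_to_str(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def str_to_codes(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def simulate_catalog(config: SimulationConfig) -> tuple[LocusCatalog, dict[str, dict]]:
    """Generate the locus catalog and per-locus host context.

    One ancestral provirus (internal region plus one LTR) is drawn at
    random; each locus receives an independently mutated copy with its LTR
    duplicated at both ends, embedded in a unique host flank. Returns the
    catalog and per-locus context: flank sequences (as code arrays), the
    locus's solo-LTR sequence, and genome placement on chromosome "sim1".
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    internal_len = config.provirus_length - 2 * config.ltr_length
    anc_ltr = _random_seq(rng, config.ltr_length)
    anc_internal = _random_seq(rng, internal_len)

    loci: list[Locus] = []
    context: dict[str, dict] = {}
    cursor = 0
    gap = 200
    for i in range(config.n_loci):
        ltr = _mutate(rng, anc_ltr, config.divergence)
        internal = _mutate(rng, anc_internal, config.divergence)
        provirus = np.concatenate([ltr, internal, ltr])
        flank_l = _random_seq(rng, config.flank_length)
        flank_r = _random_seq(rng, config.flank_length)
        # host flanks are unrelated DNA: keep both insertion junctions
        # informative by forbidding a coincidental base match between the
        # flank side of an LTR and the internal sequence adjoining the same
        # LTR inside the provirus (otherwise a solo haplotype's host-LTR
        # junctions would mimic the provirus's internal-LTR junction k-mers)
        if config.flank_length > 0 and len(internal) > 0:
            if flank_r[0] == internal[0]:
                flank_r[0] = (internal[0] + rng.integers(1, 4)) % 4
            if flank_l[-1] == internal[-1]:
                flank_l[-1] = (internal[-1] + rng.integers(1, 4)) % 4

        start = cursor + config.flank_length
        end = start + len(provirus)
        locus_id = f"sim1:{start}-{end}"
        ltr_ivals = (
            [(0, config.ltr_length), (len(provirus) - config.ltr_length, len(provirus))]
            if config.ltr_length > 0
            else []
        )
        alleles = [
            Allele(
                allele_id=f"{locus_id}|a1",
                sequence=codes_to_str(provirus),
                ltr_intervals=ltr_ivals,
                primary=True,
            )
        ]
        if config.allele_polymorphism > 0:
            alt = _mutate(rng, provirus, config.allele_polymorphism)
            alleles.append(
                Allele(
                    allele_id=f"{locus_id}|a2",
                    sequence=codes_to_str(alt),
                    ltr_intervals=ltr_ivals,
                )
            )
        loci.append(
            Locus(
                locus_id=locus_id,
                chrom="sim1",
                start=start,
                end=end,
                alleles=alleles,
            )
        )
        context[locus_id] = {
            "flank_left": flank_l,
            "flank_right": flank_r,
            "ltr": ltr,
            "region_start": cursor,
        }
        cursor = end + config.flank_length + gap
    context["__genome_length__"] = cursor
    return LocusCatalog(loci=loci), context


def default_prevalences(config: SimulationConfig) -> np.ndarray:
    """Population-structured haplotype frequencies when none are given.

    Each locus gets a baseline provirus frequency; populations deviate
    from it independently, giving the between-population contrasts the
    population layer is meant to detect. Solo-LTR mass is a minority share
    of the non-provirus remainder (solo conversion is the rarer event).
    """
    rng = np.random.default_rng([config.seed, 3])
    base = rng.uniform(0.15, 0.9, size=config.n_loci)
    out = np.empty((config.n_populations, config.n_loci, 3))
    for p in range(config.n_populations):
        f = np.clip(base + rng.uniform(-0.2, 0.2, size=config.n_loci), 0.02, 0.98)
        solo = rng.uniform(0.05, 0.3, size=config.n_loci) * (1 - f)
        if config.ltr_length == 0:
            solo[:] = 0.0
        out[p, :, 0] = f
        out[p, :, 1] = solo
        out[p, :, 2] = 1.0 - f - solo
    return out


@dataclass
class CohortTruth:
    """Ground-truth diploid states and the parameters that generated them."""

    sample_ids: list[str]
    populations: list[str]
    hap_states: np.ndarray        # (n_samples, n_loci, 2) codes
    locus_ids: list[str]
    prevalences: np.ndarray       # (n_populations, n_loci, 3)
    config: SimulationConfig

    def observed_states(self) -> pd.DataFrame:
        """Collapsed per-individual state: provirus if either haplotype
        carries one, else solo LTR if either does, else absent."""
        n, L, _ = self.hap_states.shape
        out = np.full((n, L), "absent", dtype=object)
        any_solo = (self.hap_states == SOLO).any(axis=2)
        any_prov = (self.hap_states == PROVIRUS).any(axis=2)
        out[any_solo] = "solo_LTR"
        out[any_prov] = "provirus"
        return pd.DataFrame(out, index=self.sample_ids, columns=self.locus_ids)

    def provirus_presence(self) -> pd.DataFrame:
        return self.observed_states() == "provirus"

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "population": self.populations,
                "super_population": self.populations,
                "mean_depth": self.config.depth,
            }
        )


def simulate_cohort(catalog: LocusCatalog, config: SimulationConfig) -> CohortTruth:
    """Draw population-structured diploid states for every sample x locus."""
    config.validate()
    if len(catalog) != config.n_loci:
        raise SimulationError("catalog size does not match config.n_loci")
    if config.prevalences is not None:
        prev = np.asarray(config.prevalences, dtype=float)
    else:
        prev = default_prevalences(config)
    if config.ltr_length == 0 and (prev[:, :, 1] > 0).any():
        warnings.warn("ltr_length 0: solo-LTR states disabled, mass moved to absent")
        prev = prev.copy()
        prev[:, :, 2] += prev[:, :, 1]
        prev[:, :, 1] = 0.0

    rng = np.random.default_rng([config.seed, 1])
    pops = config.population_names
    populations = [pops[i % len(pops)] for i in range(config.n_samples)]
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    hap_states = np.empty((config.n_samples, config.n_loci, 2), dtype=np.int8)
    for i, pop in enumerate(populations):
        p = pops.index(pop)
        for l in range(config.n_loci):
            hap_states[i, l] = rng.choice(3, size=2, p=prev[p, l])
    return CohortTruth(
        sample_ids=sample_ids,
        populations=populations,
        hap_states=hap_states,
        locus_ids=catalog.locus_ids,
        prevalences=prev,
        config=config,
    )


def haplotype_sequence(
    locus: Locus, context: dict, state: int, allele_index: int = 0
) -> np.ndarray:
    """Code array of a haplotype region: flank + (provirus|LTR|nothing) + flank."""
    ctx = context[locus.locus_id]
    if state == PROVIRUS:
        core = str_to_codes(locus.alleles[allele_index].sequence)
    elif state == SOLO:
        core = ctx["ltr"]
    else:
        core = np.empty(0, dtype=np.uint8)
    return np.concatenate([ctx["flank_left"], core, ctx["flank_right"]])


def _hap_rng(config: SimulationConfig, sample: int, locus: int, hap: int):
    return np.random.default_rng([config.seed, 2, sample, locus, hap])


def sample_read_layout(
    rng: np.random.Generator,
    region_len: int,
    config: SimulationConfig,
    depth: float,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Stratified-uniform read starts plus a per-base error mask.

    Returns ``(starts, error_mask)`` with starts sorted ascending and
    error_mask of shape (n_reads, read_length), or None when the error
    rate is zero. This is the single source of read randomness: the
    literal FASTQ path and the streaming profiling path consume identical
    layouts, which is what makes them exactly equivalent.
    """
    read_len = config.read_length
    if region_len < read_len:
        raise SimulationError(
            f"read_length {read_len} exceeds haplotype region length {region_len}"
        )
    n_reads = int(round(depth * region_len / read_len))
    if n_reads == 0:
        return np.empty(0, dtype=np.int64), None
    span = region_len - read_len
    edges = np.linspace(0.0, span + 1.0, n_reads + 1)
    u = rng.random(n_reads)
    starts = np.minimum(
        np.floor(edges[:-1] + u * np.diff(edges)).astype(np.int64), span
    )
    mask = None
    if config.error_rate > 0:
        mask = rng.random((n_reads, read_len)) < config.error_rate
    return starts, mask


def _apply_errors(
    rng: np.random.Generator, reads: np.ndarray, mask: np.ndarray | None
) -> np.ndarray:
    if mask is not None and mask.any():
        idx = np.nonzero(mask)
        reads[idx] = (reads[idx] + rng.integers(1, 4, size=len(idx[0]))) % 4
    return reads


def reads_for_sample(
    truth: CohortTruth,
    catalog: LocusCatalog,
    context: dict,
    sample_index: int,
) -> list[tuple[str, str, str, int]]:
    """All reads of one sample as (name, sequence, chrom, genome_pos).

    Read names encode sample, locus, haplotype and start so that mining
    results can be checked against ground truth by name.
    """
    config = truth.config
    out = []
    for l, locus in enumerate(catalog):
        ctx = context[locus.locus_id]
        for hap in (0, 1):
            state = int(truth.hap_states[sample_index, l, hap])
            rng = _hap_rng(config, sample_index, l, hap)
            allele_index = 0
            if state == PROVIRUS and len(locus.alleles) > 1:
                allele_index = int(rng.integers(0, len(locus.alleles)))
            hap_seq = haplotype_sequence(locus, context, state, allele_index)
            if len(hap_seq) < config.read_length:
                continue
            starts, mask = sample_read_layout(
                rng, len(hap_seq), config, config.depth / 2.0
            )
            if len(starts) == 0:
                continue
            reads = hap_seq[starts[:, None] + np.arange(config.read_length)]
            reads = _apply_errors(rng, reads, mask)
            for r, start in enumerate(starts):
                name = f"S{sample_index:04d}:L{l}:H{hap}:R{r}:{start}"
                out.append(
                    (
                        name,
                        codes_to_str(reads[r]),
                        locus.chrom,
                        ctx["region_start"] + int(start),
                    )
                )
    return out


def simulate_reads(
    truth: CohortTruth,
    catalog: LocusCatalog,
    context: dict,
    out_dir: str | Path,
    write_bam: bool = False,
) -> dict[str, Path]:
    """Write per-sample FASTQ (plus optional pre-mapped BAM) and metadata.

    The optional BAM places each read at its true genome position on the
    simulated chromosome so the read miner can run without an external
    aligner.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    qual = "I" * truth.config.read_length

    bam_records = []
    for i, sample in enumerate(truth.sample_ids):
        fq = out_dir / f"{sample}.fastq"
        with open(fq, "w") as handle:
            for name, seq, chrom, pos in reads_for_sample(truth, catalog, context, i):
                handle.write(f"@{name}\n{seq}\n+\n{qual[: len(seq)]}\n")
                if write_bam:
                    bam_records.append((name, seq, chrom, pos))
        paths[sample] = fq

    if write_bam:
        import pysam

        genome_len = context["__genome_length__"]
        header = {"HD": {"VN": "1.6", "SO": "unknown"},
                  "SQ": [{"SN": "sim1", "LN": int(genome_len)}]}
        unsorted = out_dir / "cohort.unsorted.bam"
        with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
            for name, seq, chrom, pos in bam_records:
                rec = pysam.AlignedSegment(bam.header)
                rec.query_name = name
                rec.query_sequence = seq
                rec.reference_id = 0
                rec.reference_start = pos
                rec.mapping_quality = 60
                rec.cigartuples = [(0, len(seq))]
                rec.query_qualities = pysam.qualitystring_to_array(qual[: len(seq)])
                bam.write(rec)
        sorted_bam = out_dir / "cohort.bam"
        pysam.sort("-o", str(sorted_bam), str(unsorted))
        pysam.index(str(sorted_bam))
        unsorted.unlink()
        paths["bam"] = sorted_bam

    meta_path = out_dir / "metadata.tsv"
    truth.metadata().to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = meta_path
    truth_path = out_dir / "truth.tsv"
    truth.observed_states().to_csv(truth_path, sep="\t", index_label="sample_id")
    paths["truth"] = truth_path
    return paths


def write_cohort(config: SimulationConfig, out_dir: str | Path, write_bam: bool = False):
    """Convenience wrapper: catalog + cohort + reads + companion files."""
    from .catalog import write_bed, write_catalog

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog, context = simulate_catalog(config)
    truth = simulate_cohort(catalog, config)
    write_catalog(catalog, out_dir / "alleles.fasta", out_dir / "loci.tsv")
    write_bed(catalog, out_dir / "loci.bed")
    paths = simulate_reads(truth, catalog, context, out_dir, write_bam=write_bam)
    paths["fasta"] = out_dir / "alleles.fasta"
    paths["locus_table"] = out_dir / "loci.tsv"
    paths["bed"] = out_dir / "loci.bed"
    return catalog, context, truth, paths
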