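import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helpers

from hervk_typer.catalog import Allele, Locus, LocusCatalog
from hervk_typer.reference import build_unique_reference
from hervk_typer.simulate import SimulationConfig, simulate_catalog, simulate_cohort


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def make_locus(locus_id, sequence, chrom="chr1", start=1000, ltr_intervals=None,
               extra_alleles=None):
    alleles = [
        Allele(
            allele_id=f"{locus_id}|a1",
            sequence=sequence,
            ltr_intervals=ltr_intervals or [],
            primary=True,
        )
    ]
    for i, (seq, ivals) in enumerate(extra_alleles or []):
        alleles.append(
            Allele(allele_id=f"{locus_id}|a{i + 2}", sequence=seq,
                   ltr_intervals=ivals)
        )
    return Locus(
        locus_id=locus_id,
        chrom=chrom,
        start=start,
        end=start + len(sequence),
        alleles=alleles,
    )


def random_toy_catalog(rng: np.random.Generator, k: int):
    """Small random catalog exercising sharing, multi-allele SNPs and LTRs."""
    n_loci = int(rng.integers(2, 6))
    loci = []
    sequences = []
    for i in range(n_loci):
        length = int(rng.integers(max(4 * k, 150), 600))
        seq = random_dna(rng, length)
        # sometimes copy a chunk from an earlier locus to force shared k-mers
        if sequences and rng.random() < 0.6:
            src = sequences[int(rng.integers(0, len(sequences)))]
            chunk = int(rng.integers(k, min(len(src), 3 * k)))
            s0 = int(rng.integers(0, len(src) - chunk + 1))
            d0 = int(rng.integers(0, length - chunk + 1))
            seq = seq[:d0] + src[s0 : s0 + chunk] + seq[d0 + chunk :]
        sequences.append(seq)
        ltr = []
        if rng.random() < 0.5:
            w = int(rng.integers(k, 2 * k))
            ltr = [(0, w), (length - w, length)]
        extra = []
        if rng.random() < 0.5:
            n_snp = int(rng.integers(1, 4))
            alt = list(seq)
            for _ in range(n_snp):
                p = int(rng.integers(0, length))
                alt[p] = "ACGT"[(("ACGT".index(alt[p])) + 1) % 4]
            extra.append(("".join(alt), ltr))
        loci.append(
            make_locus(f"toy{i}", seq, start=1000 + 5000 * i,
                       ltr_intervals=ltr, extra_alleles=extra)
        )
    return LocusCatalog(loci=loci)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated cohort shared across tests (depth 30, error-free)."""
    config = SimulationConfig(
        n_loci=3, n_samples=60, n_populations=2, depth=30.0, error_rate=0.0,
        provirus_length=3000, ltr_length=400, flank_length=200, seed=7,
    )
    catalog, context = simulate_catalog(config)
    truth = simulate_cohort(catalog, config)
    reference = build_unique_reference(catalog, k=50)
    return config, catalog, context, truth, reference
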