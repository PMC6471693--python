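"""Synthetic planted-haplotype instance generator.

Plants a pair of complementary haplotypes over randomly placed SNPs,
samples single-end reads of fixed length uniformly over the implicit
genome, flips covered alleles with a per-base error probability, and
assigns each entry a phred-scaled confidence weight.  The number of
reads follows ``ceil(cov * len(genome) / len(read))`` with
``len(genome) = f_snps * n_snps``.

Two built-in profiles mirror long-read platforms: ``roche454`` (600 bp
reads, low error) and ``pacbio`` (5000 bp reads, high error).  The error
rates are config-exposed stand-ins chosen from the platforms' published
characteristics, not fitted values.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .core import MISSING, FragmentMatrix, Haplotype, InvalidInputError
from .io_wif import write_truth, write_wif

#: profile name -> (read_len, error_rate)
PROFILES = {
    "roche454": (600, 0.01),
    "pacbio": (5000, 0.13),
}

_ZERO_ERROR_PHRED = 60  # weight used when the error rate is exactly 0


@dataclass(frozen=True)
class SimConfig:
    """Instance-generation parameters (genome length = f_snps * n_snps)."""

    n_snps: int
    f_snps: int = 100
    cov: float = 30.0
    read_len: int = 600
    error_rate: float = 0.01
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_snps < 2:
            raise InvalidInputError("n_snps must be >= 2")
        if self.f_snps < 1:
            raise InvalidInputError("f_snps must be >= 1")
        if self.cov < 1:
            raise InvalidInputError("cov must be >= 1")
        if self.read_len < 1:
            raise InvalidInputError("read_len must be >= 1")
        if not 0.0 <= self.error_rate < 0.5:
            raise InvalidInputError("error_rate must lie in [0, 0.5)")
        if self.read_len < self.f_snps:
            warnings.warn(
                "read_len < f_snps: reads will rarely span two SNPs", stacklevel=2
            )

    @classmethod
    def from_profile(cls, profile: str, **kwargs) -> "SimConfig":
        read_len, error_rate = PROFILES[profile]
        kwargs.setdefault("read_len", read_len)
        kwargs.setdefault("error_rate", error_rate)
        return cls(**kwargs)

    @property
    def genome_length(self) -> int:
        return self.f_snps * self.n_snps


def generate_truth(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, Haplotype, Haplotype]:
    """Sample distinct 1-based SNP positions (mean spacing exactly f_snps)
    and a complementary heterozygous haplotype pair.

    The i-th SNP lands uniformly inside the i-th f_snps-wide window, so
    spacing is random with every inter-SNP gap below 2*f_snps.  Unbounded
    (e.g. exponential) gap tails would create stretches no read can span,
    which real marker panels avoid and which would make whole regions
    unphasable regardless of coverage.
    """
    offsets = rng.integers(1, config.f_snps + 1, size=config.n_snps)
    positions = (
        np.arange(config.n_snps, dtype=np.int64) * config.f_snps + offsets
    )
    h1 = rng.integers(0, 2, size=config.n_snps, dtype=np.int8)
    return positions, Haplotype(h1), Haplotype(1 - h1)


def num_reads(config: SimConfig) -> int:
    """ceil(cov * genome_length / read_len)."""
    return math.ceil(config.cov * config.genome_length / config.read_len)


def simulate_reads(
    positions: np.ndarray,
    h1: Haplotype,
    h2: Haplotype,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[FragmentMatrix, dict]:
    """Sample reads over the planted pair.

    Read starts are uniform with overhang at both genome ends (clipped),
    keeping expected coverage flat across SNPs.  Reads covering no SNP are
    resampled so the matrix has exactly :func:`num_reads` rows.  Entry
    weights are ``round(-10*log10(e'))`` with ``e'`` the error rate
    jittered by +-20% per entry.
    """
    n = positions.size
    total = num_reads(config)
    genome_len = config.genome_length
    haps = np.vstack([h1.alleles, h2.alleles])

    entries = np.full((total, n), MISSING, dtype=np.int8)
    weights = np.zeros((total, n), dtype=np.float64)
    sources = np.empty(total, dtype=np.int8)
    n_flips = 0
    n_entries = 0

    lo = 2 - config.read_len  # allow left/right overhang, clip to [1, genome_len]
    for i in range(total):
        while True:
            start = int(rng.integers(lo, genome_len + 1))
            first = int(np.searchsorted(positions, start))
            last = int(np.searchsorted(positions, start + config.read_len - 1, "right"))
            if last > first:
                break
        src = int(rng.integers(0, 2))
        sources[i] = src + 1
        alleles = haps[src, first:last].copy()
        if config.error_rate > 0.0:
            flips = rng.random(last - first) < config.error_rate
            alleles ^= flips.astype(np.int8)
            n_flips += int(flips.sum())
            jitter = 1.0 + rng.uniform(-0.2, 0.2, size=last - first)
            phred = np.rint(-10.0 * np.log10(config.error_rate * jitter))
        else:
            phred = np.full(last - first, _ZERO_ERROR_PHRED, dtype=np.float64)
        n_entries += last - first
        entries[i, first:last] = alleles
        weights[i, first:last] = np.maximum(phred, 1.0)

    matrix = FragmentMatrix(
        entries, weights, positions, [f"read_{i}" for i in range(total)]
    )
    provenance = {
        "config": dataclasses.asdict(config),
        "n_reads": total,
        "n_columns_covered": matrix.n,
        "n_entries": n_entries,
        "n_flipped_alleles": n_flips,
        "planted_sources": sources.tolist(),
    }
    return matrix, provenance


def simulate_matrix(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[FragmentMatrix, np.ndarray, Haplotype, Haplotype, dict]:
    """In-memory bundle: (matrix, positions, h1, h2, provenance)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions, h1, h2 = generate_truth(config, rng)
    matrix, provenance = simulate_reads(positions, h1, h2, config, rng)
    return matrix, positions, h1, h2, provenance


def simulate_instance(config: SimConfig, out_prefix: str | Path) -> dict:
    """Write ``<prefix>.wif``, ``<prefix>.truth.txt`` and
    ``<prefix>.provenance.json``; fully reproducible from ``config.seed``."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    matrix, positions, h1, h2, provenance = simulate_matrix(config)

    wif_path = out_prefix.with_suffix(".wif")
    truth_path = Path(str(out_prefix) + ".truth.txt")
    prov_path = Path(str(out_prefix) + ".provenance.json")
    with open(wif_path, "w") as fh:
        write_wif(matrix, fh)
    with open(truth_path, "w") as fh:
        write_truth(positions, h1, h2, fh)
    provenance["files"] = {"wif": str(wif_path), "truth": str(truth_path)}
    with open(prov_path, "w") as fh:
        json.dump(provenance, fh, indent=2)
    return provenance
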