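"""Coalescent simulation of haplotype samples under a piecewise demography.

This module generates all synthetic data used by the package: tree sequences
(the ancestral recombination graph in succinct form) for a sample of
haplotypes evolving under a configurable epoch model of diploid population
size, a random pairing of haplotypes into diploid individuals, and a
down-sampling of sequence variants to an array-like marker panel.

The default demographic model is a European-style history with a recent
explosive expansion: a constant ancestral size of 12,500 diploids before
17,000 generations ago, 24,500 between 3500 and 17,000 generations ago,
7700 between 368 and 3500 generations ago, and exponential growth at 0.017
per generation from 368 generations ago to a present-day size of four
million diploids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import msprime
import numpy as np
import tskit

from .genmap import DEFAULT_MAP, GeneticMap

__all__ = [
    "Epoch",
    "DemographicModel",
    "SimulationConfig",
    "SimulatedRegion",
    "ArrayDataset",
    "simulate_region",
    "pair_into_diploids",
    "downsample_to_array",
    "write_vcf",
]


@dataclass(frozen=True)
class Epoch:
    """One backwards-in-time epoch of the demographic model.

    ``start_time`` is the epoch's onset in generations before the present,
    ``size`` the diploid population size at that onset, and ``growth_rate``
    the forward-time exponential growth rate that applies within the epoch
    (so, looking backwards, the size shrinks as exp(-growth_rate * dt)).
    """

    start_time: float
    size: float
    growth_rate: float = 0.0


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-exponential single-population demography.

    Epoch start times must increase strictly from zero and all sizes must be
    positive.  The first epoch describes the present.
    """

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("at least one epoch is required")
        epochs = tuple(
            e if isinstance(e, Epoch) else Epoch(*e) for e in self.epochs
        )
        object.__setattr__(self, "epochs", epochs)
        times = [e.start_time for e in epochs]
        if times[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(e.size <= 0 for e in epochs):
            raise ValueError("all population sizes must be positive")

    @property
    def present_size(self) -> float:
        return self.epochs[0].size

    @classmethod
    def default_european(cls) -> "DemographicModel":
        """European-style history with recent explosive growth.

        Growth at 0.017/generation back to 368 generations ago (present size
        4e6 diploids, 7700 at 368), then constant sizes of 7700 on
        [368, 3500), 24,500 on [3500, 17,000) and 12,500 earlier.
        """
        return cls(
            epochs=(
                Epoch(0.0, 4_000_000.0, 0.017),
                Epoch(368.0, 7_700.0, 0.0),
                Epoch(3_500.0, 24_500.0, 0.0),
                Epoch(17_000.0, 12_500.0, 0.0),
            )
        )

    def size_at(self, time: float) -> float:
        """Diploid population size ``time`` generations before the present."""
        if time < 0:
            raise ValueError("time must be >= 0")
        epoch = self.epochs[0]
        for e in self.epochs[1:]:
            if time < e.start_time:
                break
            epoch = e
        return epoch.size * np.exp(-epoch.growth_rate * (time - epoch.start_time))

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        first = self.epochs[0]
        dem.add_population(
            name="pop", initial_size=first.size, growth_rate=first.growth_rate
        )
        for e in self.epochs[1:]:
            dem.add_population_parameters_change(
                time=e.start_time,
                initial_size=e.size,
                growth_rate=e.growth_rate,
                population="pop",
            )
        return dem


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated region.

    Defaults describe the study conditions: a 20 Mb region of 2000
    haplotypes with mutation rate 1.2e-8 and recombination rate 1e-8 per bp
    per generation.
    """

    region_length_bp: int = 20_000_000
    n_haplotypes: int = 2000
    mu_per_bp_gen: float = 1.2e-8
    recomb_per_bp_gen: float = 1e-8
    seed: int = 1

    def __post_init__(self) -> None:
        if self.region_length_bp <= 0:
            raise ValueError("region_length_bp must be positive")
        if self.n_haplotypes < 4 or self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even and >= 4")
        if self.mu_per_bp_gen < 0 or self.recomb_per_bp_gen < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SimulatedRegion:
    """A simulated region: genealogy sequence plus the diploid pairing.

    ``ts`` is the tskit tree sequence carrying the marginal genealogy at
    every position together with the mutations; ``pairing`` maps each
    haplotype index to its diploid individual index.
    """

    ts: tskit.TreeSequence
    pairing: np.ndarray
    config: SimulationConfig
    model: DemographicModel | None = None
    genmap: GeneticMap = field(default=DEFAULT_MAP)

    def __post_init__(self) -> None:
        self.pairing = np.asarray(self.pairing, dtype=np.int64)
        n = self.ts.num_samples
        if len(self.pairing) != n:
            raise ValueError("pairing length must equal the number of haplotypes")
        counts = np.bincount(self.pairing)
        if not np.all(counts == 2):
            raise ValueError("every individual must carry exactly 2 haplotypes")

    @property
    def n_haplotypes(self) -> int:
        return self.ts.num_samples

    @property
    def n_diploids(self) -> int:
        return self.ts.num_samples // 2

    @property
    def region_length_bp(self) -> int:
        return int(self.ts.sequence_length)

    @property
    def num_variants(self) -> int:
        return self.ts.num_sites


def pair_into_diploids(n_haplotypes: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly pair ``n_haplotypes`` haplotypes into ``n/2`` individuals.

    Returns an array mapping haplotype index to individual index; the
    matching is uniform over perfect matchings given the generator state.
    """
    if n_haplotypes < 2 or n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even and >= 2")
    perm = rng.permutation(n_haplotypes)
    pairing = np.empty(n_haplotypes, dtype=np.int64)
    for ind in range(n_haplotypes // 2):
        pairing[perm[2 * ind]] = ind
        pairing[perm[2 * ind + 1]] = ind
    return pairing


def simulate_region(
    model: DemographicModel, config: SimulationConfig
) -> SimulatedRegion:
    """Simulate one region under ``model`` with the parameters of ``config``.

    The coalescent engine is msprime's exact Hudson algorithm; the sample is
    ``n_haplotypes`` haploid genomes, afterwards paired at random into
    diploid individuals.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    anc_seed, mut_seed, pair_seed = (
        int(s) for s in rng.integers(1, 2**31 - 1, size=3)
    )
    ts = msprime.sim_ancestry(
        samples=config.n_haplotypes // 2,
        demography=model.to_msprime(),
        sequence_length=config.region_length_bp,
        recombination_rate=config.recomb_per_bp_gen,
        random_seed=anc_seed,
    )
    if config.mu_per_bp_gen > 0:
        ts = msprime.sim_mutations(
            ts, rate=config.mu_per_bp_gen, random_seed=mut_seed
        )
    pairing = pair_into_diploids(
        config.n_haplotypes, np.random.default_rng(pair_seed)
    )
    return SimulatedRegion(ts=ts, pairing=pairing, config=config, model=model)


@dataclass
class ArrayDataset:
    """Array-like marker panel derived from a simulated region."""

    positions: np.ndarray
    haplotypes: np.ndarray  # shape (n_markers, n_haplotypes), 0/1
    pairing: np.ndarray
    phased: bool = True
    genmap: GeneticMap = field(default=DEFAULT_MAP)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[0] != len(self.positions):
            raise ValueError("positions and haplotypes disagree on marker count")

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    def genotypes(self) -> np.ndarray:
        """Unphased 0/1/2 genotype matrix, shape (n_markers, n_individuals)."""
        n_ind = self.n_haplotypes // 2
        out = np.zeros((self.n_markers, n_ind), dtype=np.int8)
        for hap in range(self.n_haplotypes):
            out[:, self.pairing[hap]] += self.haplotypes[:, hap]
        return out


def downsample_to_array(
    region: SimulatedRegion,
    target_density: int = 5800,
    maf_min: float = 0.05,
    spectrum: Callable[[np.ndarray], np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> ArrayDataset:
    """Down-sample sequence variants to an array-like marker panel.

    Variants with minor allele frequency below ``maf_min`` are dropped; the
    remainder are retained independently with probability proportional to
    ``spectrum(maf)`` (flat by default), scaled so that the expected number
    of retained markers equals ``target_density``.  The realised count
    therefore fluctuates around the target.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    if rng is None:
        rng = np.random.default_rng()
    ts = region.ts
    n = ts.num_samples
    positions = np.zeros(ts.num_sites, dtype=np.int64)
    derived = np.zeros(ts.num_sites, dtype=np.int64)
    for j, var in enumerate(ts.variants()):
        positions[j] = int(var.site.position)
        derived[j] = int(np.count_nonzero(var.genotypes))
    freq = derived / n
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= maf_min
    if not keep.any():
        warnings.warn("no variants survive the MAF filter; empty array dataset")
        return ArrayDataset(
            positions=np.empty(0, dtype=np.int64),
            haplotypes=np.empty((0, n), dtype=np.int8),
            pairing=region.pairing,
            genmap=region.genmap,
        )
    weights = np.ones(keep.sum()) if spectrum is None else np.asarray(
        spectrum(maf[keep]), dtype=float
    )
    if np.any(weights < 0):
        raise ValueError("spectrum weights must be non-negative")
    p_keep = np.minimum(1.0, target_density * weights / weights.sum())
    chosen = np.zeros(ts.num_sites, dtype=bool)
    chosen[np.flatnonzero(keep)] = rng.random(keep.sum()) < p_keep
    idx = np.flatnonzero(chosen)
    hap = np.zeros((len(idx), n), dtype=np.int8)
    want = set(idx.tolist())
    row = 0
    for j, var in enumerate(ts.variants()):
        if j in want:
            hap[row] = (var.genotypes > 0).astype(np.int8)
            row += 1
    return ArrayDataset(
        positions=positions[idx],
        haplotypes=hap,
        pairing=region.pairing,
        phased=True,
        genmap=region.genmap,
    )


def write_vcf(
    path,
    positions: Sequence[int],
    haplotypes: np.ndarray,
    pairing: np.ndarray,
    phased: bool = True,
    contig: str = "1",
    contig_length: int | None = None,
) -> None:
    """Write phased (or unphased) diploid genotypes as a minimal VCF.

    One biallelic record per marker; alleles are written A/T as
    placeholders since downstream analyses only use 0/1 carrier status.
    """
    haplotypes = np.asarray(haplotypes)
    pairing = np.asarray(pairing)
    n_hap = haplotypes.shape[1]
    n_ind = n_hap // 2
    # haplotype columns of each individual, in stable order
    cols = [[] for _ in range(n_ind)]
    for hap in range(n_hap):
        cols[pairing[hap]].append(hap)
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ibdconflate\n")
        if contig_length is not None:
            fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        else:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        names = "\t".join(f"ind{i}" for i in range(n_ind))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        for row, pos in enumerate(positions):
            gts = "\t".join(
                f"{haplotypes[row, a]}{sep}{haplotypes[row, b]}"
                for a, b in cols
            )
            fh.write(f"{contig}\t{int(pos) + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
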