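"""Breed-structured genotype simulation.

Per-breed allele frequencies follow the Balding–Nichols model: around an
ancestral frequency ``p`` each breed draws from
``Beta(p (1-F)/F, (1-p) (1-F)/F)`` with its own divergence parameter ``F``.
Closely related breed pairs share an intermediate ancestor drawn with a
pair-level F, then diverge with a much smaller within-pair F.  Genotypes
are Hardy–Weinberg draws within breeds; loci are independent apart from an
optional correlated-copy mechanism used to exercise LD screening.

All randomness flows from a single master seed through named
``numpy.random.SeedSequence`` children, so every output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EntityLookupError, ValidationError
from .genotype_io import MISSING, GenotypeDataset, LocusInfo

_N_CHROMOSOMES = 18  # autosomes used when laying simulated loci on a map


@dataclass(frozen=True)
class ClosePair:
    """Two breeds diverging from a shared intermediate ancestor.

    ``f_shared`` drives the intermediate's divergence from the ancestral
    frequency; ``f_pair`` (<< breed-level F) drives each member's divergence
    from the intermediate.
    """

    breed_a: str
    breed_b: str
    f_shared: float
    f_pair: float


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulated reference panel."""

    n_breeds: int
    samples_per_breed: tuple[int, ...]
    n_loci: int
    breed_F: tuple[float, ...]
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    close_pairs: tuple[ClosePair, ...] = ()
    missing_rate: float = 0.0
    admix_fraction: float = 0.0
    admix_m: float = 0.5
    n_ld_copies: int = 0
    ld_copy_flip: float = 0.02
    breed_names: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_breeds < 2:
            raise ValidationError("need at least two breeds")
        if len(self.samples_per_breed) != self.n_breeds:
            raise ValidationError("samples_per_breed length != n_breeds")
        if any(n < 1 for n in self.samples_per_breed):
            raise ValidationError("sample sizes must be >= 1")
        if len(self.breed_F) != self.n_breeds:
            raise ValidationError("breed_F length != n_breeds")
        if any(not (0.0 < f < 1.0) for f in self.breed_F):
            raise ValidationError("all breed F must lie in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("ancestral_freq_range must be inside (0, 1)")
        if not (0.0 <= self.missing_rate <= 0.5):
            raise ValidationError("missing_rate must lie in [0, 0.5]")
        if not (0.0 <= self.admix_fraction < 1.0):
            raise ValidationError("admix_fraction must lie in [0, 1)")
        if self.admix_fraction > 0 and not (0.0 < self.admix_m < 1.0):
            raise ValidationError("admix_m must lie in (0, 1)")
        if self.n_ld_copies < 0 or self.n_ld_copies >= self.n_loci:
            if self.n_ld_copies != 0:
                raise ValidationError("n_ld_copies must lie in [0, n_loci)")
        if self.breed_names and len(self.breed_names) != self.n_breeds:
            raise ValidationError("breed_names length != n_breeds")
        names = self.names()
        for cp in self.close_pairs:
            if not (0.0 < cp.f_shared < 1.0 and 0.0 < cp.f_pair < 1.0):
                raise ValidationError("close-pair F values must lie in (0, 1)")
            for b in (cp.breed_a, cp.breed_b):
                if b not in names:
                    raise ValidationError(f"close pair names unknown breed {b!r}")

    def names(self) -> tuple[str, ...]:
        if self.breed_names:
            return self.breed_names
        return tuple(f"BR{i + 1:02d}" for i in range(self.n_breeds))

    def locus_ids(self) -> list[str]:
        width = max(5, len(str(self.n_loci)))
        return [f"L{j + 1:0{width}d}" for j in range(self.n_loci)]


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, f: float
) -> np.ndarray:
    # clip: upstream Beta draws can return exactly 0 or 1, which would give
    # degenerate Beta parameters here
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    return rng.beta(a, b)


def simulate_breed_frequencies(scenario: SimScenario) -> pd.DataFrame:
    """True per-breed alternate-allele frequencies (breeds x loci DataFrame)."""
    rng = _child_rngs(scenario.seed, 4)[0]
    names = scenario.names()
    lo, hi = scenario.ancestral_freq_range
    n_core = scenario.n_loci - scenario.n_ld_copies
    p_anc = rng.uniform(lo, hi, size=n_core)

    paired = {cp.breed_a: cp for cp in scenario.close_pairs}
    paired.update({cp.breed_b: cp for cp in scenario.close_pairs})
    intermediates: dict[ClosePair, np.ndarray] = {}
    for cp in scenario.close_pairs:
        intermediates[cp] = _balding_nichols(rng, p_anc, cp.f_shared)

    freqs = np.empty((scenario.n_breeds, n_core))
    for i, name in enumerate(names):
        cp = paired.get(name)
        if cp is None:
            freqs[i] = _balding_nichols(rng, p_anc, scenario.breed_F[i])
        else:
            freqs[i] = _balding_nichols(rng, intermediates[cp], cp.f_pair)

    if scenario.n_ld_copies:
        # correlated copies mirror their source locus's frequencies
        freqs = np.hstack([freqs, freqs[:, : scenario.n_ld_copies]])
    return pd.DataFrame(freqs, index=list(names), columns=scenario.locus_ids())


def _simulated_loci(scenario: SimScenario) -> list[LocusInfo]:
    ids = scenario.locus_ids()
    n_core = scenario.n_loci - scenario.n_ld_copies
    loci: list[LocusInfo] = []
    for j in range(n_core):
        chrom = str(j % _N_CHROMOSOMES + 1)
        pos = (j // _N_CHROMOSOMES + 1) * 100_000
        loci.append(LocusInfo(ids[j], chromosome=chrom, position_bp=pos))
    for k in range(scenario.n_ld_copies):
        src = loci[k]
        loci.append(
            LocusInfo(
                ids[n_core + k],
                chromosome=src.chromosome,
                position_bp=src.position_bp + 1,
            )
        )
    return loci


def simulate_genotypes(
    freqs: pd.DataFrame, scenario: SimScenario
) -> GenotypeDataset:
    """Draw a genotype dataset from true breed frequencies.

    Non-admixed individuals draw ``Binomial(2, freq)`` per locus; admixed
    individuals draw each allele copy from their own breed with probability
    ``admix_m`` and from a randomly chosen partner breed otherwise.
    Correlated-copy loci duplicate their source column with a small
    per-genotype redraw probability, then missingness is applied uniformly.
    """
    names = scenario.names()
    if list(freqs.index) != list(names):
        raise EntityLookupError("frequency table breeds do not match scenario")
    if freqs.shape[1] != scenario.n_loci:
        raise ValidationError("frequency table loci do not match scenario")
    _, rng_geno, rng_admix, rng_miss = _child_rngs(scenario.seed, 4)

    n_total = int(sum(scenario.samples_per_breed))
    n_core = scenario.n_loci - scenario.n_ld_copies
    fmat = freqs.to_numpy()

    samples: list[str] = []
    breeds: list[str] = []
    blocks: list[np.ndarray] = []
    for i, name in enumerate(names):
        n = scenario.samples_per_breed[i]
        samples += [f"{name}_{k + 1:03d}" for k in range(n)]
        breeds += [name] * n
        blocks.append(
            rng_geno.binomial(2, fmat[i, :n_core], size=(n, n_core)).astype(np.int8)
        )
    calls = np.vstack(blocks)

    if scenario.admix_fraction > 0:
        breed_idx = np.repeat(np.arange(scenario.n_breeds), scenario.samples_per_breed)
        admixed = rng_admix.random(n_total) < scenario.admix_fraction
        for i in np.flatnonzero(admixed):
            own = breed_idx[i]
            partner = rng_admix.integers(scenario.n_breeds - 1)
            if partner >= own:
                partner += 1
            pick_own = rng_admix.random((2, n_core)) < scenario.admix_m
            p = np.where(pick_own, fmat[own, :n_core], fmat[partner, :n_core])
            calls[i, :] = (rng_admix.random((2, n_core)) < p).sum(axis=0).astype(np.int8)

    if scenario.n_ld_copies:
        copies = calls[:, : scenario.n_ld_copies].copy()
        flip = rng_geno.random(copies.shape) < scenario.ld_copy_flip
        if flip.any():
            redraw_p = np.broadcast_to(
                fmat[:, n_core:][
                    np.repeat(np.arange(scenario.n_breeds), scenario.samples_per_breed)
                ],
                copies.shape,
            )
            redraw = rng_geno.binomial(2, redraw_p).astype(np.int8)
            copies = np.where(flip, redraw, copies)
        calls = np.hstack([calls, copies])

    if scenario.missing_rate > 0:
        mask = rng_miss.random(calls.shape) < scenario.missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)

    return GenotypeDataset(samples, breeds, _simulated_loci(scenario), calls)


def simulate_dataset(scenario: SimScenario) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Convenience: simulate frequencies then genotypes."""
    freqs = simulate_breed_frequencies(scenario)
    return simulate_genotypes(freqs, scenario), freqs


# ---------------------------------------------------------------------------
# frozen benchmark scenarios
# ---------------------------------------------------------------------------

# Sample sizes spanning ~21-73 individuals over 14 breeds, mirroring a
# realistic multi-breed reference panel.
_BPL_SAMPLES = (73, 30, 31, 24, 30, 30, 30, 34, 26, 24, 30, 21, 30, 33)

# Breed-level divergence tuned (by simulation during development, then
# frozen) so realized mean pairwise Weir-Cockerham theta falls in ~0.4-0.6,
# the close pair BR06/BR14 realizes theta ~0.1 and the outgroup BR10
# averages ~0.7 against the rest.
_BPL_F = (0.38, 0.30, 0.42, 0.50, 0.52, 0.35, 0.38, 0.36, 0.46, 0.93, 0.48, 0.46, 0.47, 0.35)
_BPL_CLOSE = ClosePair("BR06", "BR14", f_shared=0.33, f_pair=0.085)


def make_benchmark_scenario(name: str, seed: int | None = None) -> SimScenario:
    """Return one of the frozen, documented benchmark scenarios.

    ``two_pop_simple``
        2 breeds, 30 samples each, 200 loci, moderate divergence.
    ``british_pigs_like``
        14 breeds with 21-73 samples each, 5000 loci, one weakly diverged
        close pair (BR06/BR14), one strong outgroup (BR10), 2% missingness.
    ``close_pair_only``
        Just the weakly diverged pair, 500 loci.

    ``seed`` overrides the frozen default master seed.
    """
    if name == "two_pop_simple":
        sc = SimScenario(
            n_breeds=2,
            samples_per_breed=(30, 30),
            n_loci=200,
            breed_F=(0.25, 0.25),
            missing_rate=0.0,
            seed=101,
        )
    elif name == "british_pigs_like":
        sc = SimScenario(
            n_breeds=14,
            samples_per_breed=_BPL_SAMPLES,
            n_loci=5000,
            breed_F=_BPL_F,
            close_pairs=(_BPL_CLOSE,),
            missing_rate=0.02,
            seed=580,
        )
    elif name == "close_pair_only":
        sc = SimScenario(
            n_breeds=2,
            samples_per_breed=(30, 33),
            n_loci=500,
            breed_F=(0.35, 0.35),
            close_pairs=(ClosePair("BR01", "BR02", f_shared=0.33, f_pair=0.065),),
            missing_rate=0.02,
            seed=102,
        )
    else:
        raise EntityLookupError(f"unknown benchmark scenario: {name!r}")
    if seed is not None:
        sc = SimScenario(**{**asdict(sc), "close_pairs": sc.close_pairs, "seed": seed})
    return sc


# -- YAML round-trip ---------------------------------------------------------


def scenario_to_dict(scenario: SimScenario) -> dict:
    d = asdict(scenario)
    d["close_pairs"] = [asdict(cp) for cp in scenario.close_pairs]
    d["samples_per_breed"] = list(scenario.samples_per_breed)
    d["breed_F"] = list(scenario.breed_F)
    d["ancestral_freq_range"] = list(scenario.ancestral_freq_range)
    d["breed_names"] = list(scenario.breed_names)
    return d


def scenario_from_dict(d: dict) -> SimScenario:
    d = dict(d)
    d["close_pairs"] = tuple(ClosePair(**cp) for cp in d.get("close_pairs", ()))
    for key in ("samples_per_breed", "breed_F", "ancestral_freq_range", "breed_names"):
        if key in d:
            d[key] = tuple(d[key])
    return SimScenario(**d)
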