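"""Pairwise breed-contrast power analysis.

For a claimed breed A against an alternative breed B, every reference
individual of either breed contributes one log(LR) value: its log10
likelihood in A minus its log10 likelihood in B (leave-one-out applied to
the individual's own breed's counts only).  Error rates at a threshold t
come, by default, from a normal approximation fitted to the observed
log(LR) means and standard deviations — the only route to the tiny tail
probabilities the posterior formula needs — with an empirical-counting
fallback for diagnostics.  The posterior probability of correct
assignment assumes equal prior odds:

    odds = tp / alpha_fp,   posterior = odds / (odds + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .genotype_io import GenotypeDataset
from .assignment_engine import loglik_matrix

DEFAULT_ALPHA_FLOOR = 1e-12


@dataclass
class ContrastDistributions:
    """Observed log(LR) distributions for one ordered breed contrast."""

    breed_a: str  # claimed origin
    breed_b: str  # alternative origin
    loglr_a: np.ndarray  # values for individuals truly of A
    loglr_b: np.ndarray  # values for individuals truly of B

    def __post_init__(self) -> None:
        self.loglr_a = np.asarray(self.loglr_a, float)
        self.loglr_b = np.asarray(self.loglr_b, float)
        if self.loglr_a.size < 2 or self.loglr_b.size < 2:
            raise ValidationError(
                "each breed needs >= 2 individuals to estimate an SD"
            )

    @property
    def mean_a(self) -> float:
        return float(self.loglr_a.mean())

    @property
    def sd_a(self) -> float:
        return float(self.loglr_a.std(ddof=1))

    @property
    def mean_b(self) -> float:
        return float(self.loglr_b.mean())

    @property
    def sd_b(self) -> float:
        return float(self.loglr_b.std(ddof=1))

    def swapped(self) -> "ContrastDistributions":
        return ContrastDistributions(
            self.breed_b, self.breed_a, -self.loglr_b, -self.loglr_a
        )


@dataclass(frozen=True)
class ContrastErrorRates:
    """False-positive (alpha) and true-positive (1 - beta) rates at one
    log(LR) threshold."""

    threshold: float
    alpha_fp: float
    tp: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_fp <= 1.0 and 0.0 <= self.tp <= 1.0):
            raise ValidationError("rates must lie in [0, 1]")


def pairwise_loglr(
    data: GenotypeDataset,
    panel_loci: Sequence[str] | None = None,
    breed_a: str | None = None,
    breed_b: str | None = None,
    _loglik: pd.DataFrame | None = None,
) -> ContrastDistributions:
    """Observed log(LR) = log10 L(A) - log10 L(B) distributions for the
    individuals of A and of B.

    ``_loglik`` lets callers reuse a precomputed leave-one-out likelihood
    matrix when evaluating many contrasts.
    """
    if breed_a is None or breed_b is None:
        raise ValidationError("both breeds must be named")
    if breed_a == breed_b:
        raise ValidationError("contrast requires two distinct breeds")
    ll = _loglik if _loglik is not None else loglik_matrix(data, panel_loci)
    is_a = np.asarray(data.breeds, dtype=object) == breed_a
    is_b = np.asarray(data.breeds, dtype=object) == breed_b
    lr = ll[breed_a].to_numpy() - ll[breed_b].to_numpy()
    return ContrastDistributions(breed_a, breed_b, lr[is_a], lr[is_b])


def contrast_error_rates(
    dist: ContrastDistributions,
    threshold: float,
    mode: str = "normal",
    alpha_floor: float = DEFAULT_ALPHA_FLOOR,
) -> ContrastErrorRates:
    """Rates of log(LR) > threshold under each true origin.

    ``normal`` fits N(mean, sd) to each observed distribution;
    ``empirical`` counts exceedances directly (diagnostic fallback).
    The false-positive rate is floored at ``alpha_floor``.
    """
    if mode == "normal":
        if dist.sd_a == 0.0 or dist.sd_b == 0.0:
            raise ValidationError(
                "zero log(LR) standard deviation; use mode='empirical'"
            )
        tp = float(norm.sf(threshold, loc=dist.mean_a, scale=dist.sd_a))
        alpha_fp = float(norm.sf(threshold, loc=dist.mean_b, scale=dist.sd_b))
    elif mode == "empirical":
        tp = float((dist.loglr_a > threshold).mean())
        alpha_fp = float((dist.loglr_b > threshold).mean())
    else:
        raise ValidationError(f"unknown mode: {mode!r}")
    return ContrastErrorRates(threshold, max(alpha_fp, alpha_floor), tp)


def posterior_correct_assignment(rates: ContrastErrorRates) -> float:
    """Posterior probability a positive test reflects true claimed origin,
    with equal priors: odds = tp/alpha, posterior = odds / (odds + 1)."""
    if rates.tp == 0.0 and rates.alpha_fp == 0.0:
        raise ValidationError("posterior undefined when both rates are zero")
    if rates.alpha_fp == 0.0:
        raise ValidationError("alpha_fp must be positive (apply the floor)")
    odds = rates.tp / rates.alpha_fp
    return odds / (odds + 1.0)


@dataclass
class PosteriorMatrix:
    """Posterior correct-assignment probabilities for every ordered breed
    pair (claimed rows x contrasted columns) at each threshold, rounded to
    6 decimals; the diagonal is NaN."""

    by_threshold: dict[float, pd.DataFrame]

    def minimum_contrast(self, threshold: float) -> tuple[str, str, float]:
        """(claimed, contrasted, value) of the smallest off-diagonal entry."""
        df = self.by_threshold[threshold]
        arr = df.to_numpy()
        idx = np.unravel_index(np.nanargmin(arr), arr.shape)
        return df.index[idx[0]], df.columns[idx[1]], float(arr[idx])

    def to_csv(self, threshold: float, path: str | Path) -> None:
        self.by_threshold[threshold].to_csv(path, index_label="claimed_breed")


def contrast_matrix(
    data: GenotypeDataset,
    panel_loci: Sequence[str] | None = None,
    thresholds: Sequence[float] = (0.0, 2.0),
    mode: str = "normal",
    alpha_floor: float = DEFAULT_ALPHA_FLOOR,
) -> PosteriorMatrix:
    """Posterior matrix over all ordered breed pairs at each threshold."""
    breeds = data.breed_names()
    if len(breeds) < 2:
        raise ValidationError("need >= 2 breeds")
    ll = loglik_matrix(data, panel_loci)
    out = {
        float(t): pd.DataFrame(np.nan, index=breeds, columns=breeds)
        for t in thresholds
    }
    for a, b in permutations(breeds, 2):
        dist = pairwise_loglr(data, panel_loci, a, b, _loglik=ll)
        for t in thresholds:
            rates = contrast_error_rates(dist, t, mode=mode, alpha_floor=alpha_floor)
            out[float(t)].loc[a, b] = round(posterior_correct_assignment(rates), 6)
    return PosteriorMatrix(out)
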