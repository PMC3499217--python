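"""Partial-Bayesian genotype likelihoods, self-assignment and exclusion tests.

A query genotype is scored against a reference population by the
predictive probability of drawing its two alleles as sequential additional
draws from the Dirichlet posterior over that population's allele
frequencies (uniform prior of 1/k per allele, k = 2).  With ``n_a``
alternate alleles among ``n`` observed:

* homozygote (aa):  ((n_a + 1/2)/(n + 1)) * ((n_a + 3/2)/(n + 2))
* heterozygote:   2 * ((n_a + 1/2)/(n + 1)) * ((n_b + 1/2)/(n + 2))

Likelihoods are log10 throughout.  Missing loci are skipped (the
likelihood is marginalised over them), never penalised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EntityLookupError, ValidationError
from .genotype_io import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeDataset,
    estimate_frequencies,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# core likelihood
# ---------------------------------------------------------------------------


def genotype_logprob_table(
    n_alt: np.ndarray, n_obs: np.ndarray, prior_per_allele: float = 0.5
) -> np.ndarray:
    """(L, 3) log10 predictive probabilities of genotypes 0/1/2 per locus."""
    tau = prior_per_allele
    na = np.asarray(n_alt, dtype=float)
    n = np.asarray(n_obs, dtype=float)
    nb = n - na
    d1 = n + 2 * tau
    d2 = n + 1 + 2 * tau
    p0 = (nb + tau) / d1 * (nb + 1 + tau) / d2
    p1 = 2.0 * (na + tau) / d1 * (nb + tau) / d2
    p2 = (na + tau) / d1 * (na + 1 + tau) / d2
    return np.log10(np.stack([p0, p1, p2], axis=-1))


def genotype_log_likelihood(
    genotype: np.ndarray,
    counts: AlleleFrequencyTable,
    prior_per_allele: float = 0.5,
) -> float:
    """log10 likelihood of a multilocus genotype in one reference breed.

    ``genotype`` holds alt-dosage codes aligned with ``counts``'s loci;
    missing entries are skipped.  Probabilities stay strictly positive for
    any reference counts thanks to the prior, so the result is finite.
    """
    g = np.asarray(genotype)
    if g.shape != (len(counts.locus_ids),):
        raise ValidationError("genotype length does not match reference counts")
    table = genotype_logprob_table(counts.n_alt, counts.n_obs, prior_per_allele)
    obs = g != MISSING
    return float(table[np.flatnonzero(obs), g[obs]].sum())


# ---------------------------------------------------------------------------
# self-assignment
# ---------------------------------------------------------------------------


@dataclass
class AssignmentRecord:
    sample_id: str
    true_breed: str
    log10_likelihoods: dict[str, float]
    assigned_breed: str
    n_loci_used: int
    tied: bool = False

    @property
    def correct(self) -> bool:
        return self.assigned_breed == self.true_breed


def assignment_frame(records: Sequence[AssignmentRecord]) -> pd.DataFrame:
    breeds = sorted(records[0].log10_likelihoods) if records else []
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "true_breed": r.true_breed,
            "assigned_breed": r.assigned_breed,
            "correct": r.correct,
            "n_loci_used": r.n_loci_used,
            "tied": r.tied,
        }
        row.update({f"log10L_{b}": r.log10_likelihoods[b] for b in breeds})
        rows.append(row)
    return pd.DataFrame(rows)


def _breed_counts(
    data: GenotypeDataset, breeds: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (B, L) alt and total allele counts per breed."""
    n_alt = np.empty((len(breeds), data.n_loci), dtype=np.int64)
    n_obs = np.empty_like(n_alt)
    for k, b in enumerate(breeds):
        t = estimate_frequencies(data, b)
        n_alt[k], n_obs[k] = t.n_alt, t.n_obs
    return n_alt, n_obs


def loglik_matrix(
    data: GenotypeDataset,
    panel_loci: Sequence[str] | None = None,
    leave_one_out: bool = True,
    prior_per_allele: float = 0.5,
) -> pd.DataFrame:
    """log10 likelihood of every sample in every breed (samples x breeds).

    With ``leave_one_out`` (default) each sample's own breed's counts are
    re-estimated without that sample; other breeds use full counts.
    """
    if panel_loci is not None:
        data = data.subset_loci(panel_loci)
    breeds = data.breed_names()
    for b in breeds:
        if data.sample_indices(b).size == 1 and leave_one_out:
            logger.warning(
                "breed %r has a single sample; leave-one-out leaves an empty "
                "reference (prior-only predictive)",
                b,
            )
    n_alt, n_obs = _breed_counts(data, breeds)
    tables = genotype_logprob_table(n_alt, n_obs, prior_per_allele)  # (B, L, 3)

    breed_idx = {b: k for k, b in enumerate(breeds)}
    L = data.n_loci
    cols = np.arange(L)
    out = np.empty((data.n_samples, len(breeds)))
    for i in range(data.n_samples):
        g = data.calls[i]
        obs = g != MISSING
        jj, gg = cols[obs], g[obs]
        out[i] = tables[:, jj, gg].sum(axis=1)
        if leave_one_out:
            k = breed_idx[data.breeds[i]]
            na = n_alt[k, jj] - gg
            no = n_obs[k, jj] - 2
            loo = genotype_logprob_table(na, no, prior_per_allele)
            out[i, k] = loo[np.arange(jj.size), gg].sum()
    return pd.DataFrame(out, index=data.samples, columns=breeds)


def self_assign_all(
    data: GenotypeDataset,
    panel_loci: Sequence[str] | None = None,
    prior_per_allele: float = 0.5,
) -> list[AssignmentRecord]:
    """Leave-one-out self-assignment of every sample to its best breed.

    Ties are broken toward the lexicographically first tied breed and
    flagged on the record.
    """
    sub = data.subset_loci(panel_loci) if panel_loci is not None else data
    ll = loglik_matrix(sub, leave_one_out=True, prior_per_allele=prior_per_allele)
    breeds = list(ll.columns)  # sorted
    records = []
    vals = ll.to_numpy()
    n_used = (sub.calls != MISSING).sum(axis=1)
    for i, sample in enumerate(sub.samples):
        row = vals[i]
        best = row.max()
        tied_idx = np.flatnonzero(row == best)
        records.append(
            AssignmentRecord(
                sample_id=sample,
                true_breed=sub.breeds[i],
                log10_likelihoods=dict(zip(breeds, row)),
                assigned_breed=breeds[tied_idx[0]],
                n_loci_used=int(n_used[i]),
                tied=tied_idx.size > 1,
            )
        )
    return records


def score_queries(
    queries: GenotypeDataset,
    reference: GenotypeDataset,
    panel_loci: Sequence[str] | None = None,
    prior_per_allele: float = 0.5,
) -> pd.DataFrame:
    """log10 likelihoods of held-out query samples against a reference panel
    (no leave-one-out; query breed labels are ignored for scoring)."""
    if panel_loci is None:
        panel_loci = reference.locus_ids
    ref = reference.subset_loci(panel_loci)
    q = queries.subset_loci(panel_loci)
    breeds = ref.breed_names()
    n_alt, n_obs = _breed_counts(ref, breeds)
    tables = genotype_logprob_table(n_alt, n_obs, prior_per_allele)
    cols = np.arange(ref.n_loci)
    out = np.empty((q.n_samples, len(breeds)))
    for i in range(q.n_samples):
        g = q.calls[i]
        obs = g != MISSING
        out[i] = tables[:, cols[obs], g[obs]].sum(axis=1)
    return pd.DataFrame(out, index=q.samples, columns=breeds)


# ---------------------------------------------------------------------------
# exclusion-simulation test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExclusionConfig:
    n_sim: int = 10_000
    alpha: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        k = math.ceil(self.alpha * self.n_sim)
        if not (1 <= k <= self.n_sim):
            raise ValidationError("ceil(alpha * n_sim) must lie in [1, n_sim]")


@dataclass
class ExclusionRecord:
    sample_id: str
    true_breed: str | None
    log10_likelihoods: dict[str, float]
    critical_values: dict[str, float]
    excluded: dict[str, bool]
    excluded_from_all: bool


def simulate_null_logliks(
    counts: AlleleFrequencyTable,
    n_sim: int,
    rng: np.random.Generator,
    prior_per_allele: float = 0.5,
) -> np.ndarray:
    """log10 likelihoods of ``n_sim`` HWE genotypes simulated from the
    breed's observed frequencies and scored against its own counts.

    Loci with no observed alleles fall back to the prior predictive
    (frequency 1/2) and a warning is logged.
    """
    freq = counts.freq_alt
    if np.isnan(freq).any():
        logger.warning(
            "breed %r: %d loci without observations use the prior-only "
            "predictive in the null simulation",
            counts.breed,
            int(np.isnan(freq).sum()),
        )
        freq = np.where(np.isnan(freq), 0.5, freq)
    table = genotype_logprob_table(counts.n_alt, counts.n_obs, prior_per_allele)
    sims = rng.binomial(2, freq, size=(n_sim, freq.size))
    return table[np.arange(freq.size), sims].sum(axis=1)


def null_critical_values(
    data: GenotypeDataset,
    panel_loci: Sequence[str] | None = None,
    cfg: ExclusionConfig | None = None,
    prior_per_allele: float = 0.5,
) -> dict[str, float]:
    """Per-breed critical value: the ceil(alpha * n_sim)-th lowest simulated
    log10 likelihood.  Deterministic under ``cfg.seed`` (breeds are
    processed in sorted order with spawned child generators)."""
    cfg = cfg or ExclusionConfig()
    sub = data.subset_loci(panel_loci) if panel_loci is not None else data
    breeds = sub.breed_names()
    k = math.ceil(cfg.alpha * cfg.n_sim)
    children = np.random.SeedSequence(cfg.seed).spawn(len(breeds))
    crit = {}
    for b, ss in zip(breeds, children):
        counts = estimate_frequencies(sub, b)
        sims = simulate_null_logliks(
            counts, cfg.n_sim, np.random.default_rng(ss), prior_per_allele
        )
        crit[b] = float(np.sort(sims)[k - 1])
    return crit


def exclusion_test_all(
    data: GenotypeDataset,
    panel_loci: Sequence[str] | None = None,
    cfg: ExclusionConfig | None = None,
    queries: GenotypeDataset | None = None,
    prior_per_allele: float = 0.5,
) -> list[ExclusionRecord]:
    """Exclusion test of every sample against every reference breed.

    Reference members are scored with leave-one-out against their own
    breed; a sample is excluded from a breed iff its log10 likelihood is
    strictly below that breed's critical value.  With ``queries`` given,
    the held-out queries are tested instead of the reference samples.
    """
    cfg = cfg or ExclusionConfig()
    sub = data.subset_loci(panel_loci) if panel_loci is not None else data
    crit = null_critical_values(sub, None, cfg, prior_per_allele)
    if queries is None:
        ll = loglik_matrix(sub, leave_one_out=True, prior_per_allele=prior_per_allele)
        ids = sub.samples
        true = dict(zip(sub.samples, sub.breeds))
    else:
        ll = score_queries(queries, sub, prior_per_allele=prior_per_allele)
        ids = list(ll.index)
        true = dict(zip(queries.samples, queries.breeds))
    records = []
    for sample in ids:
        lks = ll.loc[sample].to_dict()
        excl = {b: lks[b] < crit[b] for b in crit}
        records.append(
            ExclusionRecord(
                sample_id=sample,
                true_breed=true.get(sample),
                log10_likelihoods=lks,
                critical_values=dict(crit),
                excluded=excl,
                excluded_from_all=all(excl.values()),
            )
        )
    return records


def exclusion_test(
    sample_id: str,
    data: GenotypeDataset,
    panel_loci: Sequence[str] | None = None,
    cfg: ExclusionConfig | None = None,
    prior_per_allele: float = 0.5,
) -> ExclusionRecord:
    """Exclusion test of a single reference sample (see exclusion_test_all)."""
    data.sample_index(sample_id)  # raises for unknown samples
    for rec in exclusion_test_all(data, panel_loci, cfg, None, prior_per_allele):
        if rec.sample_id == sample_id:
            return rec
    raise EntityLookupError(sample_id)  # pragma: no cover


def exclusion_frame(records: Sequence[ExclusionRecord]) -> pd.DataFrame:
    breeds = sorted(records[0].critical_values) if records else []
    rows = []
    for r in records:
        row: dict[str, object] = {
            "sample_id": r.sample_id,
            "true_breed": r.true_breed,
            "excluded_from_all": r.excluded_from_all,
        }
        for b in breeds:
            row[f"log10L_{b}"] = r.log10_likelihoods[b]
            row[f"excluded_{b}"] = r.excluded[b]
        rows.append(row)
    return pd.DataFrame(rows)
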