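"""Genotype data model, PED/MAP and CSV readers/writers, call-rate QC and
allele-frequency estimation.

Genotypes are coded as the count of the designated alternate allele
(0, 1, 2); :data:`MISSING` (-1) is a distinct sentinel and is never imputed.

File dialects
-------------
``ped_map``
    Standard 6-column PED prefix (family, individual, father, mother, sex,
    phenotype) followed by two allele symbols per locus; the family column
    carries the breed label and ``0`` denotes a missing allele.  The MAP
    file holds chromosome, locus id, genetic distance and 1-based bp
    position; chromosome ``0`` / position ``0`` mark unmapped loci.
``csv``
    One header row; samples as rows; columns ``sample_id``, ``breed``, then
    one column per locus id holding ``0``/``1``/``2`` or an empty cell for
    missing.  An optional companion locus-map CSV (columns ``locus_id``,
    ``chromosome``, ``position_bp``, ``ref_allele``, ``alt_allele``)
    preserves map information; round-trips are bit-exact.
"""

from __future__ import annotations

import csv as _csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyPanelError,
    EntityLookupError,
    FormatError,
    ParseError,
    ValidationError,
)

#: Sentinel code for a missing genotype call.
MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})

UNDETERMINED = "Undetermined"


@dataclass(frozen=True)
class LocusInfo:
    """A biallelic locus: identifier, map position and allele symbols.

    ``position_bp`` is 1-based and must be present exactly when the
    chromosome is determined.
    """

    locus_id: str
    chromosome: str = UNDETERMINED
    position_bp: int | None = None
    ref_allele: str = "A"
    alt_allele: str = "B"

    def __post_init__(self) -> None:
        if self.chromosome == UNDETERMINED:
            if self.position_bp is not None:
                raise ValidationError(
                    f"locus {self.locus_id}: position given for undetermined chromosome"
                )
        else:
            if self.position_bp is None or self.position_bp < 0:
                raise ValidationError(
                    f"locus {self.locus_id}: mapped locus requires a non-negative position"
                )


class GenotypeDataset:
    """Diploid biallelic genotypes for breed-labelled individuals.

    Parameters
    ----------
    samples
        Sample identifiers, unique, one per row of ``calls``.
    breeds
        Breed label per sample (parallel to ``samples``).
    loci
        One :class:`LocusInfo` per column of ``calls``; ids unique.
    calls
        ``(n_samples, n_loci)`` integer matrix over ``{0, 1, 2, MISSING}``
        counting alternate-allele copies.
    """

    def __init__(
        self,
        samples: Sequence[str],
        breeds: Sequence[str],
        loci: Sequence[LocusInfo],
        calls: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.breeds = list(breeds)
        self.loci = list(loci)
        calls = np.asarray(calls)
        if calls.dtype.kind not in "iu":
            raise ValidationError("calls matrix must be integer-typed")
        self.calls = calls.astype(np.int8, copy=False)
        self._validate()
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._locus_index = {l.locus_id: j for j, l in enumerate(self.loci)}

    def _validate(self) -> None:
        if len(self.samples) != len(self.breeds):
            raise ValidationError("samples and breeds differ in length")
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValidationError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.loci)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample identifiers")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate locus identifiers")
        bad = set(np.unique(self.calls)) - _VALID_CODES
        if bad:
            raise ValidationError(f"invalid genotype codes present: {sorted(bad)}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def breed_of(self) -> dict[str, str]:
        return dict(zip(self.samples, self.breeds))

    def breed_names(self) -> list[str]:
        """Breed labels, sorted lexicographically (deterministic order)."""
        return sorted(set(self.breeds))

    def sample_indices(self, breed: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.breeds, dtype=object) == breed)
        if idx.size == 0:
            raise EntityLookupError(f"unknown breed: {breed!r}")
        return idx

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise EntityLookupError(f"unknown sample: {sample_id!r}") from None

    def locus_index(self, locus_id: str) -> int:
        try:
            return self._locus_index[locus_id]
        except KeyError:
            raise EntityLookupError(f"unknown locus: {locus_id!r}") from None

    # -- subsetting ------------------------------------------------------

    def subset(
        self,
        sample_idx: Sequence[int] | None = None,
        locus_idx: Sequence[int] | None = None,
    ) -> "GenotypeDataset":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeDataset(
            [self.samples[i] for i in si],
            [self.breeds[i] for i in si],
            [self.loci[j] for j in li],
            self.calls[np.ix_(si, li)],
        )

    def subset_loci(self, locus_ids: Iterable[str]) -> "GenotypeDataset":
        return self.subset(locus_idx=[self.locus_index(l) for l in locus_ids])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.breeds == other.breeds
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeDataset({self.n_samples} samples, {self.n_loci} loci, "
            f"{len(self.breed_names())} breeds)"
        )


@dataclass(frozen=True)
class QcConfig:
    """Call-rate thresholds for locus and sample filtering."""

    min_locus_call_rate: float = 0.80
    call_rate_scope: str = "per_breed"  # or "overall"
    min_sample_call_rate: float = 0.85

    def __post_init__(self) -> None:
        for name in ("min_locus_call_rate", "min_sample_call_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.call_rate_scope not in ("per_breed", "overall"):
            raise ValidationError(
                f"call_rate_scope must be 'per_breed' or 'overall', "
                f"got {self.call_rate_scope!r}"
            )


@dataclass
class QcReport:
    """Dropped loci and samples with the call rates that failed them."""

    dropped_loci: pd.DataFrame  # columns: locus_id, call_rate
    dropped_samples: pd.DataFrame  # columns: sample_id, call_rate
    scope: str
    n_loci_in: int
    n_loci_out: int
    n_samples_in: int
    n_samples_out: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "locus", "id": r.locus_id, "call_rate": r.call_rate}
            for r in self.dropped_loci.itertuples()
        ] + [
            {"kind": "sample", "id": r.sample_id, "call_rate": r.call_rate}
            for r in self.dropped_samples.itertuples()
        ]
        return pd.DataFrame(rows, columns=["kind", "id", "call_rate"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class AlleleFrequencyTable:
    """Per-locus alternate-allele counts for one breed.

    ``n_obs`` counts observed allele copies (2 x non-missing genotypes);
    frequency is undefined (NaN) wherever ``n_obs`` is zero.
    """

    breed: str
    locus_ids: tuple[str, ...]
    n_alt: np.ndarray
    n_obs: np.ndarray

    def __post_init__(self) -> None:
        self.n_alt = np.asarray(self.n_alt, dtype=np.int64)
        self.n_obs = np.asarray(self.n_obs, dtype=np.int64)
        if self.n_alt.shape != self.n_obs.shape or self.n_alt.shape != (
            len(self.locus_ids),
        ):
            raise ValidationError("count arrays must match locus list length")
        if np.any(self.n_alt < 0) or np.any(self.n_alt > self.n_obs):
            raise ValidationError("require 0 <= n_alt <= n_obs")

    @property
    def freq_alt(self) -> np.ndarray:
        """Alternate-allele frequency per locus; NaN where unobserved."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.n_alt / self.n_obs
        return np.where(self.n_obs > 0, f, np.nan)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(
    path: str | Path,
    format: str = "csv",
    map_path: str | Path | None = None,
) -> GenotypeDataset:
    """Read a genotype dataset.

    For ``format='ped_map'``, ``path`` is the PED file (or a prefix shared
    by ``.ped``/``.map``) and ``map_path`` defaults to the sibling ``.map``.
    For ``format='csv'``, ``path`` is the genotype CSV and ``map_path`` an
    optional locus-map CSV.
    """
    path = Path(path)
    if format == "ped_map":
        if path.suffix != ".ped":
            path = path.with_suffix(".ped")
        mp = Path(map_path) if map_path is not None else path.with_suffix(".map")
        return read_ped_map(path, mp)
    if format == "csv":
        return read_csv(path, map_path)
    raise ValidationError(f"unknown format: {format!r}")


def _read_map(map_path: Path) -> list[LocusInfo]:
    loci: list[LocusInfo] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 MAP columns")
            chrom, locus_id, _cm, bp = parts[:4]
            try:
                pos = int(bp)
            except ValueError:
                raise ParseError(f"{map_path}:{lineno}: bad position {bp!r}") from None
            if chrom in ("0", UNDETERMINED) or pos <= 0:
                loci.append(LocusInfo(locus_id))
            else:
                loci.append(LocusInfo(locus_id, chromosome=chrom, position_bp=pos))
    return loci


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Parse PED/MAP files into a dataset.

    Allele symbols are mapped per locus: the lexicographically smaller
    observed symbol becomes the reference allele.  More than two distinct
    symbols at a locus is a format error.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    loci = _read_map(map_path)
    n_loci = len(loci)

    samples: list[str] = []
    breeds: list[str] = []
    rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_loci:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} fields, "
                    f"got {len(parts)}"
                )
            breeds.append(parts[0])
            samples.append(parts[1])
            alleles = parts[6:]
            rows.append([(alleles[2 * j], alleles[2 * j + 1]) for j in range(n_loci)])

    if len(set(samples)) != len(samples):
        raise ValidationError(f"{ped_path}: duplicate sample identifiers")

    calls = np.full((len(samples), n_loci), MISSING, dtype=np.int8)
    out_loci: list[LocusInfo] = []
    for j in range(n_loci):
        observed = sorted(
            {a for row in rows for a in row[j] if a != "0"}
        )
        if len(observed) > 2:
            raise FormatError(
                f"locus {loci[j].locus_id}: more than two alleles {observed}"
            )
        ref = observed[0] if observed else "A"
        alt = observed[1] if len(observed) == 2 else "B"
        out_loci.append(replace(loci[j], ref_allele=ref, alt_allele=alt))
        for i, row in enumerate(rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == alt) + (a2 == alt)
    return GenotypeDataset(samples, breeds, out_loci, calls)


def write_ped_map(data: GenotypeDataset, ped_path: str | Path, map_path: str | Path) -> None:
    ped_path, map_path = Path(ped_path), Path(map_path)
    with open(map_path, "w") as fh:
        for loc in data.loci:
            chrom = "0" if loc.chromosome == UNDETERMINED else loc.chromosome
            pos = 0 if loc.position_bp is None else loc.position_bp
            fh.write(f"{chrom}\t{loc.locus_id}\t0\t{pos}\n")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(data.samples):
            fields = [data.breeds[i], sample, "0", "0", "0", "-9"]
            for j, loc in enumerate(data.loci):
                g = data.calls[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [loc.ref_allele, loc.ref_allele]
                elif g == 1:
                    fields += [loc.ref_allele, loc.alt_allele]
                else:
                    fields += [loc.alt_allele, loc.alt_allele]
            fh.write(" ".join(fields) + "\n")


def read_csv(
    path: str | Path, map_path: str | Path | None = None
) -> GenotypeDataset:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = _csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}:1: empty file") from None
        if header[:2] != ["sample_id", "breed"]:
            raise ParseError(f"{path}:1: header must start 'sample_id,breed'")
        locus_ids = header[2:]
        if len(set(locus_ids)) != len(locus_ids):
            raise ValidationError(f"{path}: duplicate locus identifiers")
        samples, breeds, rows = [], [], []
        for lineno, row in enumerate(reader, 2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            samples.append(row[0])
            breeds.append(row[1])
            parsed = []
            for cell in row[2:]:
                cell = cell.strip()
                if cell in ("", "NA"):
                    parsed.append(MISSING)
                elif cell in ("0", "1", "2"):
                    parsed.append(int(cell))
                else:
                    raise ParseError(f"{path}:{lineno}: bad genotype {cell!r}")
            rows.append(parsed)
    if len(set(samples)) != len(samples):
        raise ValidationError(f"{path}: duplicate sample identifiers")
    calls = np.asarray(rows, dtype=np.int8).reshape(len(samples), len(locus_ids))

    if map_path is not None:
        loci = read_locus_map_csv(map_path)
        by_id = {l.locus_id: l for l in loci}
        missing = [lid for lid in locus_ids if lid not in by_id]
        if missing:
            raise ValidationError(f"locus map lacks entries for {missing[:5]}")
        loci = [by_id[lid] for lid in locus_ids]
    else:
        loci = [LocusInfo(lid) for lid in locus_ids]
    return GenotypeDataset(samples, breeds, loci, calls)


def write_csv(
    data: GenotypeDataset,
    path: str | Path,
    map_path: str | Path | None = None,
) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["sample_id", "breed"] + data.locus_ids)
        for i, sample in enumerate(data.samples):
            row = [sample, data.breeds[i]] + [
                "" if g == MISSING else str(int(g)) for g in data.calls[i]
            ]
            writer.writerow(row)
    if map_path is not None:
        write_locus_map_csv(data.loci, map_path)


def read_locus_map_csv(path: str | Path) -> list[LocusInfo]:
    df = pd.read_csv(path, dtype={"chromosome": str})
    loci = []
    for r in df.itertuples():
        chrom = r.chromosome
        if chrom == UNDETERMINED:
            loci.append(
                LocusInfo(r.locus_id, ref_allele=r.ref_allele, alt_allele=r.alt_allele)
            )
        else:
            loci.append(
                LocusInfo(
                    r.locus_id,
                    chromosome=chrom,
                    position_bp=int(r.position_bp),
                    ref_allele=r.ref_allele,
                    alt_allele=r.alt_allele,
                )
            )
    return loci


def write_locus_map_csv(loci: Sequence[LocusInfo], path: str | Path) -> None:
    pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "chromosome": [l.chromosome for l in loci],
            "position_bp": [l.position_bp if l.position_bp is not None else "" for l in loci],
            "ref_allele": [l.ref_allele for l in loci],
            "alt_allele": [l.alt_allele for l in loci],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def _locus_call_rates(data: GenotypeDataset, scope: str) -> np.ndarray:
    observed = data.calls != MISSING
    if scope == "overall":
        return observed.mean(axis=0)
    rates = np.ones(data.n_loci)
    for breed in data.breed_names():
        idx = data.sample_indices(breed)
        rates = np.minimum(rates, observed[idx].mean(axis=0))
    return rates


def filter_call_rate(
    data: GenotypeDataset, qc: QcConfig | None = None
) -> tuple[GenotypeDataset, QcReport]:
    """Drop loci and samples below the configured call rates.

    Under ``per_breed`` scope a locus passes only if its worst within-breed
    call rate meets the threshold.  Dropping is iterated to a fixed point
    so that both conditions hold simultaneously on the returned dataset
    (which makes the filter idempotent); in practice one round almost
    always suffices.
    """
    if qc is None:
        qc = QcConfig()
    if data.n_samples == 0 or data.n_loci == 0:
        raise ValidationError("cannot QC an empty dataset")

    current = data
    dropped_loci: list[tuple[str, float]] = []
    dropped_samples: list[tuple[str, float]] = []
    while True:
        locus_rates = _locus_call_rates(current, qc.call_rate_scope)
        keep_loci = locus_rates >= qc.min_locus_call_rate
        if not keep_loci.any():
            raise EmptyPanelError("call-rate filter removed every locus")
        dropped_loci += [
            (current.loci[j].locus_id, float(locus_rates[j]))
            for j in np.flatnonzero(~keep_loci)
        ]
        current = current.subset(locus_idx=np.flatnonzero(keep_loci))

        sample_rates = (current.calls != MISSING).mean(axis=1)
        keep_samples = sample_rates >= qc.min_sample_call_rate
        if not keep_samples.any():
            raise ValidationError("call-rate filter removed every sample")
        dropped_samples += [
            (current.samples[i], float(sample_rates[i]))
            for i in np.flatnonzero(~keep_samples)
        ]
        if keep_loci.all() and keep_samples.all():
            break
        current = current.subset(sample_idx=np.flatnonzero(keep_samples))

    report = QcReport(
        dropped_loci=pd.DataFrame(dropped_loci, columns=["locus_id", "call_rate"]),
        dropped_samples=pd.DataFrame(dropped_samples, columns=["sample_id", "call_rate"]),
        scope=qc.call_rate_scope,
        n_loci_in=data.n_loci,
        n_loci_out=current.n_loci,
        n_samples_in=data.n_samples,
        n_samples_out=current.n_samples,
    )
    return current, report


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def estimate_frequencies(
    data: GenotypeDataset, breed: str, leave_out: str | None = None
) -> AlleleFrequencyTable:
    """Alternate-allele counts for one breed, optionally excluding a sample.

    With ``leave_out``, both allele copies of that sample are removed at
    each of its non-missing loci ('leave-one-out' re-estimation).
    """
    idx = data.sample_indices(breed)
    calls = data.calls[idx]
    observed = calls != MISSING
    n_alt = np.where(observed, calls, 0).sum(axis=0).astype(np.int64)
    n_obs = 2 * observed.sum(axis=0).astype(np.int64)

    if leave_out is not None:
        i = data.sample_index(leave_out)
        if data.breeds[i] != breed:
            raise EntityLookupError(
                f"sample {leave_out!r} does not belong to breed {breed!r}"
            )
        row = data.calls[i]
        obs = row != MISSING
        n_alt = n_alt - np.where(obs, row, 0)
        n_obs = n_obs - 2 * obs
    return AlleleFrequencyTable(breed, tuple(data.locus_ids), n_alt, n_obs)


def breed_frequency_tables(data: GenotypeDataset) -> dict[str, AlleleFrequencyTable]:
    """Frequency tables for every breed, keyed by breed name."""
    return {b: estimate_frequencies(data, b) for b in data.breed_names()}


def frequency_matrix(data: GenotypeDataset) -> pd.DataFrame:
    """Breeds x loci matrix of alternate-allele frequencies (NaN where unobserved)."""
    tables = breed_frequency_tables(data)
    return pd.DataFrame(
        {b: t.freq_alt for b, t in tables.items()}, index=data.locus_ids
    ).T
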