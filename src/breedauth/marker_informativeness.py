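"""Delta-based marker informativeness, ranking, panel selection and the
cumulative-panel assignment curve.

The informativeness of a biallelic locus is the absolute allele-frequency
difference |p_A - p_B| averaged over all unordered breed pairs where both
breeds have a defined frequency; pairs lacking data are dropped from the
mean (absence of data is not evidence of similarity) and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genotype_io import GenotypeDataset, LocusInfo, frequency_matrix
from .assignment_engine import self_assign_all
from .popgen_stats import r2_pair


@dataclass(frozen=True)
class DeltaLocusResult:
    """Per-pair deltas at one locus and their mean over defined pairs."""

    delta_mean: float  # NaN sentinel when < 2 breeds have defined frequency
    pairs_used: int
    pair_deltas: dict[tuple[str, str], float]


def delta_locus(freqs: dict[str, float]) -> DeltaLocusResult:
    """Average |p_A - p_B| over all unordered breed pairs at one locus.

    ``freqs`` maps breed -> alternate-allele frequency (NaN = undefined).
    """
    defined = {b: f for b, f in sorted(freqs.items()) if np.isfinite(f)}
    pair_deltas = {
        (a, b): abs(defined[a] - defined[b])
        for a, b in combinations(defined, 2)
    }
    if not pair_deltas:
        return DeltaLocusResult(float("nan"), 0, {})
    return DeltaLocusResult(
        float(np.mean(list(pair_deltas.values()))), len(pair_deltas), pair_deltas
    )


def multiallelic_delta(freq_a: Sequence[float], freq_b: Sequence[float]) -> float:
    """Generalised delta for one pair: sum_a |p_Aa - p_Ba| / 2 over alleles.

    Reduces to |p_A - p_B| in the biallelic case.
    """
    fa, fb = np.asarray(freq_a, float), np.asarray(freq_b, float)
    if fa.shape != fb.shape:
        raise ValidationError("allele frequency vectors differ in length")
    return float(np.abs(fa - fb).sum() / 2.0)


@dataclass
class DeltaRanking:
    """Per-locus mean deltas sorted by informativeness.

    ``table`` has one row per locus with columns ``locus_id``,
    ``delta_mean``, ``pairs_used`` and ``rank`` (1 = most informative);
    rows are ordered by rank.  Ties are broken by ascending locus id, and
    loci without a defined delta sort last.
    """

    table: pd.DataFrame

    def top(self, size: int) -> list[str]:
        if not (1 <= size <= len(self.table)):
            raise ValidationError(
                f"panel size must lie in [1, {len(self.table)}], got {size}"
            )
        return self.table["locus_id"].head(size).tolist()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DeltaRanking":
        return cls(pd.read_csv(path))


def rank_markers(data: GenotypeDataset) -> DeltaRanking:
    """Rank all loci by descending mean pairwise delta (deterministic)."""
    fm = frequency_matrix(data)  # breeds x loci
    f = fm.to_numpy()
    n_breeds = f.shape[0]
    total = np.zeros(data.n_loci)
    pairs = np.zeros(data.n_loci, dtype=np.int64)
    for i, j in combinations(range(n_breeds), 2):
        d = np.abs(f[i] - f[j])
        ok = np.isfinite(d)
        total[ok] += d[ok]
        pairs += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(pairs > 0, total / np.maximum(pairs, 1), np.nan)
    tbl = pd.DataFrame(
        {"locus_id": data.locus_ids, "delta_mean": mean, "pairs_used": pairs}
    )
    tbl = tbl.sort_values(
        by=["delta_mean", "locus_id"],
        ascending=[False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    return DeltaRanking(tbl)


@dataclass(frozen=True)
class PanelSelection:
    """An ordered subset of loci (most informative first)."""

    locus_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValidationError("panel locus ids must be unique")

    @property
    def size(self) -> int:
        return len(self.locus_ids)

    def to_txt(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.locus_ids) + "\n")

    @classmethod
    def from_txt(cls, path: str | Path) -> "PanelSelection":
        return cls(tuple(Path(path).read_text().split()))


def select_panel(ranking: DeltaRanking, size: int) -> PanelSelection:
    """Top-``size`` loci in rank order; prefix-stable in ``size``."""
    return PanelSelection(tuple(ranking.top(size)))


@dataclass
class AssignmentCurve:
    """Self-assignment accuracy versus cumulative panel size."""

    panel_sizes: list[int]
    pct_correct: list[float]
    n_individuals: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"panel_size": self.panel_sizes, "pct_correct": self.pct_correct}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(self.panel_sizes, self.pct_correct, marker="o")
        ax.set_xlabel("Number of top-ranked markers")
        ax.set_ylabel("% individuals correctly self-assigned")
        ax.set_ylim(0, 101)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def assignment_curve(
    data: GenotypeDataset, ranking: DeltaRanking, sizes: Sequence[int]
) -> AssignmentCurve:
    """Leave-one-out self-assignment accuracy for increasing panel sizes."""
    sizes = list(sizes)
    if not sizes or any(s < 1 for s in sizes):
        raise ValidationError("panel sizes must be positive")
    if sorted(sizes) != sizes:
        raise ValidationError("panel sizes must be increasing")
    pct = []
    for s in sizes:
        panel = select_panel(ranking, s)
        records = self_assign_all(data, panel.locus_ids)
        pct.append(100.0 * sum(r.correct for r in records) / len(records))
    return AssignmentCurve(sizes, pct, data.n_samples)


def panel_ld_screen(
    data: GenotypeDataset,
    panel: PanelSelection,
    r2_threshold: float = 0.4,
) -> pd.DataFrame:
    """Within-breed r^2 screen of same-chromosome panel-locus pairs.

    Returns one row per (locus pair, breed) with r^2 above the threshold in
    that breed; unmapped loci are excluded from the screen.
    """
    sub = data.subset_loci(panel.locus_ids)
    by_chrom: dict[str, list[LocusInfo]] = {}
    for loc in sub.loci:
        if loc.position_bp is not None:
            by_chrom.setdefault(loc.chromosome, []).append(loc)
    rows = []
    for chrom, loci in sorted(by_chrom.items()):
        for la, lb in combinations(sorted(l.locus_id for l in loci), 2):
            for breed in sub.breed_names():
                res = r2_pair(sub, breed, la, lb)
                if res.defined and res.r_squared > r2_threshold:
                    rows.append(
                        {
                            "locus_a": la,
                            "locus_b": lb,
                            "chromosome": chrom,
                            "breed": breed,
                            "r_squared": res.r_squared,
                            "em_converged": res.em_converged,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["locus_a", "locus_b", "chromosome", "breed", "r_squared", "em_converged"],
    )
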