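"""Marker/animal quality control and VanRaden genomic relationship matrices.

Filters follow the study protocol: autosomal markers only, minor allele
frequency strictly above 0.01, marker and animal call rates of at least 0.95,
and a heterozygosity-based Hardy-Weinberg screen (|observed - expected
heterozygote frequency| < 0.15). Residual missingness is mean-imputed before
the relationship matrix G = M M' / (2 * sum p(1-p)) is formed, and pairs with
genomic relationship above 0.95 are pruned deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DomainError

DEFAULT_AUTOSOMES = frozenset(range(1, 30))  # Bos taurus autosomes 1..29


@dataclass
class GenotypeMatrix:
    """Animals x markers allele-dose matrix with missingness as NaN.

    ``doses`` holds counts of the first (``a1``) allele in {0, 1, 2, NaN};
    ``markers`` is a frame with columns snp_id, chrom, pos, a1, a2.
    """

    animal_ids: np.ndarray
    markers: pd.DataFrame
    doses: np.ndarray

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids).astype(str)
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.shape != (len(self.animal_ids), len(self.markers)):
            raise DomainError(
                f"dose matrix shape {self.doses.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.markers)} markers"
            )

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_frequencies(self) -> np.ndarray:
        """Observed frequency of the counted allele per marker (ignores NaN)."""
        with np.errstate(invalid="ignore"):
            return np.nansum(self.doses, axis=0) / (
                2.0 * np.sum(~np.isnan(self.doses), axis=0)
            )

    def select(self, animal_idx=None, marker_idx=None) -> "GenotypeMatrix":
        ai = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            animal_ids=self.animal_ids[ai],
            markers=self.markers.iloc[mi].reset_index(drop=True),
            doses=self.doses[np.ix_(ai, mi)],
        )


@dataclass
class Grm:
    """Genomic relationship matrix with its construction denominator."""

    animal_ids: np.ndarray
    values: np.ndarray
    kind: str = "G"  # "G" or "G_hs"
    denominator: float = float("nan")
    _sqrt: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids).astype(str)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise DomainError("GRM must be square and match the id list")

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    def sqrt_factor(self, tol: float = 1e-8) -> np.ndarray:
        """Symmetric square-root factor L with L L' = G (eigenvalues clipped at 0).

        Cached; used to draw GRM-correlated effects in simulation. Raises if G
        is materially non-PSD (most-negative eigenvalue beyond tolerance).
        """
        if self._sqrt is None:
            w, u = np.linalg.eigh(self.values)
            scale = max(abs(w[-1]), 1.0)
            if w[0] < -tol * scale:
                from .errors import SimulationError

                raise SimulationError(
                    f"relationship matrix not PSD: min eigenvalue {w[0]:.3g}"
                )
            self._sqrt = u * np.sqrt(np.clip(w, 0.0, None))
        return self._sqrt


@dataclass
class QcThresholds:
    autosomes: frozenset = DEFAULT_AUTOSOMES
    maf: float = 0.01          # strict: keep MAF > maf
    marker_call_rate: float = 0.95
    animal_call_rate: float = 0.95
    hwe_deviation: float = 0.15  # strict: keep deviation < hwe_deviation


@dataclass
class QcReport:
    """Per-rule removal counts in application order, plus thresholds used."""

    thresholds: QcThresholds
    markers_in: int = 0
    animals_in: int = 0
    removed_non_autosomal: int = 0
    removed_marker_call_rate: int = 0
    removed_animal_call_rate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    markers_out: int = 0
    animals_out: int = 0

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "thresholds"}
        d["thresholds"] = {
            "autosomes": sorted(self.thresholds.autosomes),
            "maf": self.thresholds.maf,
            "marker_call_rate": self.thresholds.marker_call_rate,
            "animal_call_rate": self.thresholds.animal_call_rate,
            "hwe_deviation": self.thresholds.hwe_deviation,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def allele_frequency(doses: Sequence[float]) -> float:
    """Observed counted-allele frequency p = sum(doses) / (2 * n_nonmissing)."""
    arr = np.asarray(doses, dtype=float)
    mask = ~np.isnan(arr)
    if not mask.any():
        raise DegenerateInputError("allele frequency undefined: all doses missing")
    return float(arr[mask].sum() / (2.0 * mask.sum()))


def minor_allele_frequency(doses: Sequence[float]) -> float:
    p = allele_frequency(doses)
    return min(p, 1.0 - p)


def call_rates(genotypes: GenotypeMatrix):
    """(per-marker, per-animal) fractions of non-missing entries."""
    present = ~np.isnan(genotypes.doses)
    return present.mean(axis=0), present.mean(axis=1)


def hwe_het_deviation(doses: Sequence[float]) -> float:
    """|observed het frequency - 2p(1-p)| over non-missing doses."""
    arr = np.asarray(doses, dtype=float)
    mask = ~np.isnan(arr)
    if not mask.any():
        raise DegenerateInputError("HWE deviation undefined: all doses missing")
    obs = arr[mask]
    p = obs.sum() / (2.0 * obs.size)
    h_obs = np.mean(obs == 1.0)
    return float(abs(h_obs - 2.0 * p * (1.0 - p)))


def apply_qc(genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None):
    """Apply the marker/animal filters in a fixed order; return (kept, report).

    Order: autosome filter -> marker call rate -> animal call rate -> MAF ->
    HWE deviation. Allele frequencies are recomputed after the call-rate
    removals, so MAF/HWE see the post-removal animal set.
    """
    th = thresholds or QcThresholds()
    report = QcReport(thresholds=th,
                      markers_in=genotypes.n_markers,
                      animals_in=genotypes.n_animals)

    g = genotypes
    # 1. autosomes only
    chrom = g.markers["chrom"].to_numpy()
    keep_m = np.array([c in th.autosomes for c in chrom])
    report.removed_non_autosomal = int((~keep_m).sum())
    g = g.select(marker_idx=np.flatnonzero(keep_m))

    # 2. marker call rate
    if g.n_markers:
        m_rate, _ = call_rates(g)
        keep_m = m_rate >= th.marker_call_rate
        report.removed_marker_call_rate = int((~keep_m).sum())
        g = g.select(marker_idx=np.flatnonzero(keep_m))

    # 3. animal call rate
    if g.n_markers:
        _, a_rate = call_rates(g)
        keep_a = a_rate >= th.animal_call_rate
        report.removed_animal_call_rate = int((~keep_a).sum())
        g = g.select(animal_idx=np.flatnonzero(keep_a))

    # 4. MAF (strictly larger than threshold), frequencies recomputed post-removal
    if g.n_markers:
        p = g.allele_frequencies()
        maf = np.minimum(p, 1.0 - p)
        keep_m = maf > th.maf
        report.removed_maf = int((~keep_m).sum())
        g = g.select(marker_idx=np.flatnonzero(keep_m))

    # 5. HWE heterozygosity deviation (strictly smaller than threshold)
    if g.n_markers:
        dev = np.array([hwe_het_deviation(g.doses[:, j]) for j in range(g.n_markers)])
        keep_m = dev < th.hwe_deviation
        report.removed_hwe = int((~keep_m).sum())
        g = g.select(marker_idx=np.flatnonzero(keep_m))

    if g.n_markers == 0:
        raise DegenerateInputError("quality control removed every marker")

    report.markers_out = g.n_markers
    report.animals_out = g.n_animals
    return g, report


def mean_impute(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing doses by 2p of their marker (the column mean)."""
    doses = genotypes.doses.copy()
    p = genotypes.allele_frequencies()
    nan_r, nan_c = np.nonzero(np.isnan(doses))
    doses[nan_r, nan_c] = 2.0 * p[nan_c]
    return GenotypeMatrix(genotypes.animal_ids, genotypes.markers, doses)


def vanraden_grm(genotypes: GenotypeMatrix) -> Grm:
    """G = M M' / (2 * sum_j p_j (1 - p_j)) with M the 2p-centered doses."""
    doses = genotypes.doses
    if np.isnan(doses).any():
        raise DomainError("GRM requires complete doses; run mean_impute first")
    p = doses.sum(axis=0) / (2.0 * doses.shape[0])
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise DegenerateInputError("all markers monomorphic: GRM denominator is zero")
    m = doses - 2.0 * p
    values = (m @ m.T) / denom
    return Grm(genotypes.animal_ids, values, kind="G", denominator=denom)


def prune_related(grm: Grm, cutoff: float = 0.95) -> np.ndarray:
    """Greedy removal of over-related animals; returns retained animal ids.

    While any off-diagonal relationship exceeds ``cutoff``, the animal with
    the most super-cutoff partners is removed (ties: the larger animal id).
    """
    n = grm.n
    adj = grm.values > cutoff
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    order = np.argsort(grm.animal_ids)  # lexicographic id order for tie-breaks
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    while True:
        counts = np.where(alive, (adj & alive[None, :]).sum(axis=1), -1)
        if counts.max() <= 0:
            break
        worst = counts.max()
        cand = np.flatnonzero((counts == worst) & alive)
        victim = cand[np.argmax(rank[cand])]  # largest id among the tied
        alive[victim] = False
    return grm.animal_ids[alive]


def subset_grm(grm: Grm, animal_ids: Iterable) -> Grm:
    """Principal submatrix of G for the given animals (kind ``G_hs``)."""
    wanted = [str(a) for a in animal_ids]
    if len(wanted) == 0:
        raise DegenerateInputError("empty animal set for GRM subset")
    index = {a: i for i, a in enumerate(grm.animal_ids)}
    try:
        idx = np.array([index[a] for a in wanted])
    except KeyError as exc:
        raise DomainError(f"animal {exc} not present in GRM") from exc
    return Grm(
        animal_ids=grm.animal_ids[idx],
        values=grm.values[np.ix_(idx, idx)],
        kind="G_hs",
        denominator=grm.denominator,
    )
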