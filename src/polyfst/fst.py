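"""Per-SNP Weir & Cockerham (1984) F_ST estimation from genotype counts.

The estimator decomposes allele-frequency variance at a biallelic SNP
observed in ``r`` population samples into three components:

* ``a`` — among populations,
* ``b`` — among individuals within populations,
* ``c`` — within individuals (heterozygosity),

and estimates F_ST as ``theta = a / (a + b + c)``.  ``theta`` may be
negative (a small-sample property of the estimator) and is deliberately
not clipped, because the lower tail of the genomic distribution is used
downstream for outlier trimming.  A SNP monomorphic for the same allele
in every sample has ``a + b + c = 0`` and ``theta`` undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SNPCounts",
    "WCComponents",
    "SNPPanel",
    "InsufficientSamplesError",
    "wc_components",
    "panel_fst",
    "pool_samples",
    "multilocus_fst",
]


class InsufficientSamplesError(ValueError):
    """Fewer than two population samples carry data for a SNP."""


@dataclass(frozen=True)
class SNPCounts:
    """Genotype counts for one biallelic SNP across population samples.

    Counts are floats so that Hardy-Weinberg-imputed "counts" derived
    from allele frequencies (``n_Aa = 2 p (1-p) n``) are representable.
    """

    snp_id: str
    n: np.ndarray      # diploid individuals genotyped, per population
    n_AA: np.ndarray   # homozygous reference
    n_Aa: np.ndarray   # heterozygous
    n_aa: np.ndarray   # homozygous alternate

    def __post_init__(self):
        for name in ("n", "n_AA", "n_Aa", "n_aa"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.n.shape != self.n_AA.shape or self.n.shape != self.n_Aa.shape or self.n.shape != self.n_aa.shape:
            raise ValueError("genotype count arrays must share one shape")
        if self.n.ndim != 1 or self.n.size < 1:
            raise ValueError("counts must be a 1-D per-population array")
        if np.any(self.n < 0) or np.any(self.n_AA < 0) or np.any(self.n_Aa < 0) or np.any(self.n_aa < 0):
            raise ValueError("negative genotype counts")
        if not np.allclose(self.n_AA + self.n_Aa + self.n_aa, self.n):
            raise ValueError(f"{self.snp_id}: genotype counts do not sum to n")


@dataclass(frozen=True)
class WCComponents:
    """Weir-Cockerham variance components and theta for one SNP."""

    snp_id: str
    a: float
    b: float
    c: float
    theta: float            # NaN when undefined
    defined: bool
    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float


def _wc_from_arrays(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Vectorized W&C components from per-population sample sizes, reference
    allele frequencies and observed heterozygote proportions.

    ``n``, ``p``, ``h`` have shape (n_snps, r); populations without data must
    already be removed (all n > 0).  Returns (a, b, c, n_bar, n_c, p_bar, s2,
    h_bar), each of shape (n_snps,).
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[-1]
    n_tot = n.sum(axis=-1)
    n_bar = n_tot / r
    n_c = (n_tot - (n**2).sum(axis=-1) / n_tot) / (r - 1)
    p_bar = (n * p).sum(axis=-1) / n_tot
    s2 = (n * (p - p_bar[..., None]) ** 2).sum(axis=-1) / ((r - 1) * n_bar)
    h_bar = (n * h).sum(axis=-1) / n_tot

    pq = p_bar * (1.0 - p_bar)
    a = (n_bar / n_c) * (s2 - (pq - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * (pq - (r - 1) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
    c = h_bar / 2.0
    return a, b, c, n_bar, n_c, p_bar, s2, h_bar


def wc_components(snp: SNPCounts) -> WCComponents:
    """Weir-Cockerham variance components for one SNP.

    Populations with no genotyped individuals are dropped before the
    computation; fewer than two remaining samples raises
    :class:`InsufficientSamplesError`.  A mean sample size of one or less
    makes the within-population correction degenerate and is rejected.
    """
    keep = snp.n > 0
    if keep.sum() < 2:
        raise InsufficientSamplesError(f"{snp.snp_id}: fewer than 2 populations with data")
    n = snp.n[keep]
    p = (2.0 * snp.n_AA[keep] + snp.n_Aa[keep]) / (2.0 * n)
    h = snp.n_Aa[keep] / n
    n_bar = n.mean()
    if n_bar <= 1.0:
        raise ValueError(f"{snp.snp_id}: degenerate sample size (n_bar <= 1)")
    a, b, c, n_bar, n_c, p_bar, s2, h_bar = _wc_from_arrays(n[None, :], p[None, :], h[None, :])
    a, b, c = float(a[0]), float(b[0]), float(c[0])
    denom = a + b + c
    defined = denom != 0.0
    theta = a / denom if defined else float("nan")
    return WCComponents(
        snp_id=snp.snp_id, a=a, b=b, c=c, theta=theta, defined=defined,
        n_bar=float(n_bar[0]), n_c=float(n_c[0]), p_bar=float(p_bar[0]),
        s2=float(s2[0]), h_bar=float(h_bar[0]),
    )


@dataclass
class SNPPanel:
    """Ordered collection of per-SNP, per-population genotype counts.

    ``counts`` has shape (n_snps, n_populations, 3) ordered (AA, Aa, aa)
    for a fixed per-SNP reference allele A.  ``mode`` records whether the
    heterozygote column is observed ("genotype") or Hardy-Weinberg imputed
    from allele frequencies ("hwe").
    """

    snp_ids: np.ndarray
    populations: list[str]
    counts: np.ndarray
    mode: str = "genotype"

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.snp_ids), len(self.populations), 3):
            raise ValueError("counts must have shape (n_snps, n_populations, 3)")
        if np.any(self.counts < 0):
            raise ValueError("negative genotype counts")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp_ids")
        if self.mode not in ("genotype", "hwe"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n(self) -> np.ndarray:
        """Diploid individuals genotyped, shape (n_snps, n_populations)."""
        return self.counts.sum(axis=2)

    @property
    def p_ref(self) -> np.ndarray:
        """Reference allele frequency per SNP x population (NaN where n=0)."""
        n = self.n
        with np.errstate(invalid="ignore", divide="ignore"):
            return (2.0 * self.counts[:, :, 0] + self.counts[:, :, 1]) / (2.0 * n)

    @property
    def h_obs(self) -> np.ndarray:
        """Observed heterozygote proportion per SNP x population."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts[:, :, 1] / self.n

    def snp(self, idx: int) -> SNPCounts:
        return SNPCounts(
            snp_id=str(self.snp_ids[idx]),
            n=self.n[idx],
            n_AA=self.counts[idx, :, 0],
            n_Aa=self.counts[idx, :, 1],
            n_aa=self.counts[idx, :, 2],
        )

    def subset(self, mask: np.ndarray) -> "SNPPanel":
        return SNPPanel(self.snp_ids[mask], list(self.populations), self.counts[mask], self.mode)

    @classmethod
    def from_frequencies(cls, snp_ids, populations, n, p_ref) -> "SNPPanel":
        """Build an HWE-imputed panel from sample sizes and allele frequencies."""
        n = np.asarray(n, dtype=float)
        p = np.asarray(p_ref, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("allele frequencies outside [0, 1]")
        counts = np.stack([n * p**2, 2.0 * n * p * (1.0 - p), n * (1.0 - p) ** 2], axis=2)
        return cls(snp_ids, list(populations), counts, mode="hwe")


def panel_fst(panel: SNPPanel) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham components for a whole panel.

    Returns a DataFrame with columns snp_id, a, b, c, theta, defined, mode.
    SNPs with fewer than two sampled populations get defined=False and NaN
    components; SNPs monomorphic for the same allele everywhere get their
    components but defined=False and NaN theta.
    """
    if panel.n_snps == 0:
        return pd.DataFrame(columns=["snp_id", "a", "b", "c", "theta", "defined", "mode"])

    n = panel.n
    p = panel.p_ref
    h = panel.h_obs
    sampled = n > 0
    r_eff = sampled.sum(axis=1)

    a = np.full(panel.n_snps, np.nan)
    b = np.full(panel.n_snps, np.nan)
    c = np.full(panel.n_snps, np.nan)
    theta = np.full(panel.n_snps, np.nan)
    defined = np.zeros(panel.n_snps, dtype=bool)

    # group SNPs by their set of sampled populations so each group is a
    # rectangular array the vectorized kernel can handle
    full = sampled.all(axis=1)
    groups: list[np.ndarray] = []
    if full.any():
        groups.append(np.flatnonzero(full))
    partial = np.flatnonzero(~full & (r_eff >= 2))
    if partial.size:
        patterns = {}
        for i in partial:
            patterns.setdefault(tuple(sampled[i]), []).append(i)
        groups.extend(np.asarray(v) for v in patterns.values())

    for idx in groups:
        keep = sampled[idx[0]]
        ni, pi, hi = n[np.ix_(idx, np.flatnonzero(keep))], p[np.ix_(idx, np.flatnonzero(keep))], h[np.ix_(idx, np.flatnonzero(keep))]
        ai, bi, ci, *_ = _wc_from_arrays(ni, pi, hi)
        a[idx], b[idx], c[idx] = ai, bi, ci
        denom = ai + bi + ci
        ok = denom != 0.0
        defined[idx] = ok
        with np.errstate(invalid="ignore", divide="ignore"):
            th = ai / denom
        th[~ok] = np.nan
        theta[idx] = th

    return pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
            "defined": defined,
            "mode": panel.mode,
        }
    )


def pool_samples(panel: SNPPanel, groups: Mapping[str, str]) -> SNPPanel:
    """Merge population samples by summing genotype counts.

    ``groups`` maps every existing population label to a merged label
    (e.g. ``{"CEU": "CEU", "CHB": "ASN", "JPT": "ASN", "YRI": "YRI"}``).
    """
    unknown = set(groups) - set(panel.populations)
    if unknown:
        raise ValueError(f"group mapping references unknown populations: {sorted(unknown)}")
    missing = set(panel.populations) - set(groups)
    if missing:
        raise ValueError(f"populations not mapped: {sorted(missing)}")

    merged = list(dict.fromkeys(groups[pop] for pop in panel.populations))
    counts = np.zeros((panel.n_snps, len(merged), 3))
    for j, pop in enumerate(panel.populations):
        counts[:, merged.index(groups[pop]), :] += panel.counts[:, j, :]
    return SNPPanel(panel.snp_ids.copy(), merged, counts, panel.mode)


def multilocus_fst(records: pd.DataFrame) -> float:
    """Ratio-of-averages multilocus estimate sum(a) / sum(a+b+c) over defined SNPs."""
    ok = records["defined"].to_numpy(dtype=bool)
    a = records.loc[ok, "a"].to_numpy()
    denom = a + records.loc[ok, "b"].to_numpy() + records.loc[ok, "c"].to_numpy()
    total = denom.sum()
    if total == 0:
        return float("nan")
    return float(a.sum() / total)
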