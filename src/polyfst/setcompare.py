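"""Candidate-set vs genomic-background F_ST comparison battery.

The pipeline, in the order it is run:

1. filter the panel (drop SNPs unsampled everywhere, monomorphic in every
   sample, or with minor allele frequency below the threshold in every
   sample);
2. per-SNP Weir-Cockerham theta on what remains;
3. one-tailed Mann-Whitney test of candidates stochastically greater than
   the background;
4. trim candidates in the extreme tails of the background theta
   distribution ("core set") and re-test;
5. remove candidates in strong linkage disequilibrium (r^2 above the
   threshold in at least one population) with variants associated to other
   traits, and re-test;
6. per-population top-tail enrichment of an externally supplied selection
   score (iHS-like), with an exact binomial test against the tail mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fst import SNPPanel, panel_fst

__all__ = [
    "PipelineConfig",
    "MWResult",
    "EnrichmentResult",
    "ComparisonReport",
    "filter_panel",
    "mann_whitney_one_tailed",
    "trim_outliers",
    "ld_confound_filter",
    "tail_enrichment",
    "run_comparison",
]

# exact Mann-Whitney enumeration is used whenever the number of candidate /
# background labelings is at most C(16, 8); this covers every split with
# m + n <= 12 as well as any split with both sizes <= 8
_EXACT_MAX_LABELINGS = math.comb(16, 8)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the comparison battery.

    maf_min: per-sample minor-allele-frequency floor (a SNP is dropped only
        if below it in *every* sample; set ``maf_any_sample=True`` for the
        stricter any-sample reading).
    tail_fraction: tail mass used both for outlier trimming and for the
        score-enrichment threshold.
    r2_threshold: linkage-disequilibrium cutoff; removal requires r^2
        strictly above it in at least one population.
    alpha: nominal significance level.
    abs_scores: apply the top-tail rule to |score| instead of the signed score.
    """

    maf_min: float = 0.05
    tail_fraction: float = 0.05
    r2_threshold: float = 0.8
    alpha: float = 0.05
    maf_any_sample: bool = False
    abs_scores: bool = False

    def __post_init__(self):
        if not (0.0 < self.tail_fraction < 0.5):
            raise ValueError("tail_fraction must lie in (0, 0.5)")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class MWResult:
    U: float
    p: float
    method: str          # "exact" | "asymptotic"
    n_candidates: int
    n_background: int


@dataclass(frozen=True)
class EnrichmentResult:
    population: str
    n_scored: int
    n_in_tail: int
    proportion: float
    p: float
    threshold: float


@dataclass
class ComparisonReport:
    """All pipeline outputs; serialize with :meth:`to_dict`."""

    n_background: int
    n_candidates_input: int
    n_candidates_used: int
    candidates_missing: list[str]
    median_candidates: float
    median_background: float
    full_test: MWResult
    core_set: list[str]
    n_removed_top: int
    n_removed_bottom: int
    core_test: MWResult
    median_core: float
    ld_removed: list[str]
    post_ld_test: Optional[MWResult]
    median_post_ld: float
    enrichment: list[EnrichmentResult]
    exclusion_log: pd.DataFrame

    def to_dict(self) -> dict:
        d = {
            "n_background": self.n_background,
            "n_candidates_input": self.n_candidates_input,
            "n_candidates_used": self.n_candidates_used,
            "candidates_missing": list(self.candidates_missing),
            "median_candidates": self.median_candidates,
            "median_background": self.median_background,
            "full_test": asdict(self.full_test),
            "core_set": list(self.core_set),
            "n_removed_top": self.n_removed_top,
            "n_removed_bottom": self.n_removed_bottom,
            "core_test": asdict(self.core_test),
            "median_core": self.median_core,
            "ld_removed": list(self.ld_removed),
            "post_ld_test": asdict(self.post_ld_test) if self.post_ld_test else None,
            "median_post_ld": self.median_post_ld,
            "enrichment": [asdict(e) for e in self.enrichment],
            "n_excluded_by_filter": int(len(self.exclusion_log)),
        }
        return d

    def summary(self) -> str:
        lines = [
            f"background SNPs: {self.n_background}",
            f"candidates: {self.n_candidates_input} given, {self.n_candidates_used} analyzed"
            f" ({len(self.candidates_missing)} absent from panel)",
            f"median theta: candidates {self.median_candidates:.4g} vs background {self.median_background:.4g}",
            f"full set: U={self.full_test.U:.1f}, one-tailed p={self.full_test.p:.4g} [{self.full_test.method}]",
            f"core set: {len(self.core_set)} SNPs after trimming"
            f" ({self.n_removed_top} top, {self.n_removed_bottom} bottom); p={self.core_test.p:.4g}",
            f"LD-confounded removed: {len(self.ld_removed)}"
            + (f"; post-LD p={self.post_ld_test.p:.4g}" if self.post_ld_test else ""),
        ]
        for e in self.enrichment:
            lines.append(
                f"score tail [{e.population}]: {e.n_in_tail}/{e.n_scored}"
                f" = {e.proportion:.3f} in top tail, binomial p={e.p:.3g}"
            )
        return "\n".join(lines)


def filter_panel(panel: SNPPanel, cfg: PipelineConfig) -> tuple[SNPPanel, pd.DataFrame]:
    """Apply the SNP exclusion rules; returns (filtered panel, exclusion log).

    A SNP is removed iff it is unsampled in every population, or
    monomorphic in every sampled population, or its MAF is below
    ``cfg.maf_min`` in every sampled population (in at least one, with
    ``maf_any_sample``).  The log records one row (snp_id, rule) per
    removed SNP, with the first matching rule in the order above.
    """
    n = panel.n
    p = panel.p_ref
    sampled = n > 0

    unsampled_all = ~sampled.any(axis=1)
    with np.errstate(invalid="ignore"):
        poly = sampled & (p > 0) & (p < 1)
        maf = np.where(sampled, np.minimum(p, 1.0 - p), np.nan)
    mono_all = ~unsampled_all & ~poly.any(axis=1)
    with np.errstate(invalid="ignore"):
        low = maf < cfg.maf_min
    if cfg.maf_any_sample:
        low_maf = ~unsampled_all & (low & sampled).any(axis=1)
    else:
        low_maf = ~unsampled_all & np.where(sampled, low, True).all(axis=1)

    removed = unsampled_all | mono_all | low_maf
    rule = np.where(unsampled_all, "unsampled", np.where(mono_all, "monomorphic", "low_maf"))
    log = pd.DataFrame({"snp_id": panel.snp_ids[removed], "rule": rule[removed]})
    return panel.subset(~removed), log


def _u_statistic(cand: np.ndarray, back: np.ndarray) -> float:
    """U = #{cand > back pairs} + 0.5 #{ties}, via midranks."""
    m = cand.size
    ranks = stats.rankdata(np.concatenate([cand, back]))
    return float(ranks[:m].sum() - m * (m + 1) / 2.0)


def _exact_p_greater(cand: np.ndarray, back: np.ndarray, u_obs: float) -> float:
    """Permutation-exact one-tailed p by enumerating all labelings."""
    pooled = np.concatenate([cand, back])
    N, m = pooled.size, cand.size
    ranks = stats.rankdata(pooled)
    rank_sum_obs = u_obs + m * (m + 1) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(N), m):
        total += 1
        if ranks[list(idx)].sum() >= rank_sum_obs - 1e-9:
            count += 1
    return count / total


def mann_whitney_one_tailed(candidate_values: Sequence[float], background_values: Sequence[float]) -> MWResult:
    """One-tailed Mann-Whitney test, alternative: candidates greater.

    U counts candidate/background pairs won by the candidate, ties scoring
    half.  The p-value is permutation-exact (enumeration over labelings)
    for small inputs and a tie-corrected normal approximation with
    continuity correction otherwise.
    """
    cand = np.asarray(candidate_values, dtype=float)
    back = np.asarray(background_values, dtype=float)
    if cand.size == 0 or back.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(cand, back)
    if math.comb(cand.size + back.size, cand.size) <= _EXACT_MAX_LABELINGS:
        p = _exact_p_greater(cand, back, u)
        method = "exact"
    else:
        p = float(stats.mannwhitneyu(cand, back, alternative="greater",
                                     use_continuity=True, method="asymptotic").pvalue)
        method = "asymptotic"
    return MWResult(U=u, p=p, method=method, n_candidates=cand.size, n_background=back.size)


def trim_outliers(candidate_theta: pd.DataFrame, background_values: Sequence[float],
                  cfg: PipelineConfig) -> tuple[list[str], int, int]:
    """Drop candidates in the extreme tails of the background distribution.

    ``candidate_theta`` needs columns snp_id and theta.  Thresholds are the
    empirical ``tail_fraction`` and ``1 - tail_fraction`` quantiles of the
    background (linear interpolation); removal is strict (< low or > high).
    Returns (core_set ids, n_removed_top, n_removed_bottom).
    """
    back = np.asarray(background_values, dtype=float)
    if back.size < 20:
        raise ValueError("background too small for tail quantiles (need >= 20 values)")
    q_low, q_high = np.quantile(back, [cfg.tail_fraction, 1.0 - cfg.tail_fraction])
    theta = candidate_theta["theta"].to_numpy(dtype=float)
    top = theta > q_high
    bottom = theta < q_low
    keep = ~(top | bottom)
    core = [str(s) for s in candidate_theta.loc[keep, "snp_id"]]
    return core, int(top.sum()), int(bottom.sum())


def ld_confound_filter(candidate_ids: Iterable[str], ld_table: Optional[pd.DataFrame],
                       cfg: PipelineConfig) -> tuple[list[str], list[str]]:
    """Remove candidates linked (r^2 > threshold in >= 1 population) to other-trait variants.

    ``ld_table`` columns: candidate_snp, other_snp, population, r2, trait.
    Rows whose trait is "height" (case-insensitive) do not confound.
    """
    ids = [str(c) for c in candidate_ids]
    if ld_table is None or len(ld_table) == 0:
        return ids, []
    r2 = ld_table["r2"].to_numpy(dtype=float)
    if np.any((r2 < 0) | (r2 > 1)):
        raise ValueError("r2 values outside [0, 1]")
    other_trait = ld_table["trait"].astype(str).str.lower() != "height"
    hits = ld_table.loc[(r2 > cfg.r2_threshold) & other_trait, "candidate_snp"].astype(str)
    confounded = set(hits)
    kept = [c for c in ids if c not in confounded]
    removed = [c for c in ids if c in confounded]
    return kept, removed


def tail_enrichment(scores: pd.DataFrame, candidate_ids: Iterable[str],
                    cfg: PipelineConfig) -> list[EnrichmentResult]:
    """Per-population candidate enrichment in the top tail of the score distribution.

    ``scores`` columns: snp_id, population, score.  For each population the
    threshold is the (1 - tail_fraction) quantile of the non-candidate
    (background) scores; candidates strictly above it count as hits, and the
    hit proportion is tested two-sided against Binomial(n, tail_fraction).
    Populations where no candidate is scored are omitted.
    """
    cand = set(str(c) for c in candidate_ids)
    results = []
    for pop, grp in scores.groupby("population", sort=True):
        vals = grp["score"].to_numpy(dtype=float)
        if cfg.abs_scores:
            vals = np.abs(vals)
        is_cand = grp["snp_id"].astype(str).isin(cand).to_numpy()
        back = vals[~is_cand]
        cand_vals = vals[is_cand]
        if cand_vals.size == 0 or back.size == 0:
            continue
        thr = float(np.quantile(back, 1.0 - cfg.tail_fraction))
        k = int((cand_vals > thr).sum())
        n = int(cand_vals.size)
        p = float(stats.binomtest(k, n, cfg.tail_fraction, alternative="two-sided").pvalue)
        results.append(EnrichmentResult(population=str(pop), n_scored=n, n_in_tail=k,
                                        proportion=k / n, p=p, threshold=thr))
    return results


def run_comparison(panel: SNPPanel, candidate_ids: Sequence[str],
                   ld_table: Optional[pd.DataFrame] = None,
                   scores: Optional[pd.DataFrame] = None,
                   cfg: Optional[PipelineConfig] = None) -> ComparisonReport:
    """Run the full battery: filter -> theta -> test -> trim -> re-test -> LD -> re-test -> enrichment.

    Candidates absent from the filtered panel are logged and skipped.  The
    background is the set of non-candidate SNPs with defined theta.
    """
    cfg = cfg or PipelineConfig()
    wanted = [str(c) for c in candidate_ids]

    filtered, log = filter_panel(panel, cfg)
    records = panel_fst(filtered)
    records = records[records["defined"]].copy()
    records["snp_id"] = records["snp_id"].astype(str)

    present = set(records["snp_id"])
    used = [c for c in wanted if c in present]
    missing = [c for c in wanted if c not in present]
    if not used:
        raise ValueError(
            "no candidate SNP survives filtering; "
            f"{len(missing)} requested ids absent or filtered (first few: {missing[:5]})"
        )

    is_cand = records["snp_id"].isin(set(used))
    cand_rec = records[is_cand]
    back_theta = records.loc[~is_cand, "theta"].to_numpy()
    cand_theta = cand_rec["theta"].to_numpy()
    if back_theta.size == 0:
        raise ValueError("no background SNP survives filtering")

    full_test = mann_whitney_one_tailed(cand_theta, back_theta)

    core, n_top, n_bottom = trim_outliers(cand_rec, back_theta, cfg)
    core_theta = cand_rec.loc[cand_rec["snp_id"].isin(set(core)), "theta"].to_numpy()
    core_test = mann_whitney_one_tailed(core_theta, back_theta)

    kept, ld_removed = ld_confound_filter(core, ld_table, cfg)
    if ld_removed:
        kept_theta = cand_rec.loc[cand_rec["snp_id"].isin(set(kept)), "theta"].to_numpy()
        post_ld_test = mann_whitney_one_tailed(kept_theta, back_theta)
        median_post_ld = float(np.median(kept_theta))
    else:
        post_ld_test = core_test
        median_post_ld = float(np.median(core_theta))

    enrichment = tail_enrichment(scores, used, cfg) if scores is not None and len(scores) else []

    return ComparisonReport(
        n_background=int(back_theta.size),
        n_candidates_input=len(wanted),
        n_candidates_used=len(used),
        candidates_missing=missing,
        median_candidates=float(np.median(cand_theta)),
        median_background=float(np.median(back_theta)),
        full_test=full_test,
        core_set=core,
        n_removed_top=n_top,
        n_removed_bottom=n_bottom,
        core_test=core_test,
        median_core=float(np.median(core_theta)),
        ld_removed=ld_removed,
        post_ld_test=post_ld_test,
        median_post_ld=median_post_ld,
        enrichment=enrichment,
        exclusion_log=log,
    )
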