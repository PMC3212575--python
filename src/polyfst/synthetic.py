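"""HapMap-like synthetic panels with controlled differentiation.

Background and candidate SNPs are drawn under the Balding-Nichols model:
an ancestral frequency p is drawn per SNP, each population's frequency is
Beta(p(1-F)/F, (1-p)(1-F)/F) around it, and genotypes are sampled at
Hardy-Weinberg proportions.  The Beta's intraclass correlation equals F,
so the generator's F parameter is the ground-truth F_ST the estimator
should recover — which is exactly why this model is the standard fixture
for F_ST estimator validation.  Candidate SNPs are generated identically
but with their own F, giving a controllable "selected set" shift.

Companion generators produce the two auxiliary tables the comparison
battery consumes: a linkage-disequilibrium table with a configurable
fraction of confounded candidates, and a per-population score table
(iHS-like) with a configurable candidate tail enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fst import SNPPanel

__all__ = ["SynthSpec", "balding_nichols_panel", "synth_ld_table", "synth_scores"]

_TRAIT_VOCAB = [
    "type 2 diabetes", "Crohn disease", "LDL cholesterol", "rheumatoid arthritis",
    "bone mineral density", "body mass index", "psoriasis", "prostate cancer",
]


@dataclass(frozen=True)
class SynthSpec:
    """Shape and differentiation of a synthetic panel.

    Sample sizes default to 90 diploids per population (HapMap-era panel
    scale, 60-90), three populations, and a mild background F of 0.1 —
    roughly the human inter-continental range.
    """

    n_background_snps: int = 10_000
    n_candidate_snps: int = 150
    n_populations: int = 3
    n_per_pop: int | Sequence[int] = 90
    F_background: float = 0.1
    F_candidate: float = 0.1
    ancestral_maf_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self):
        for F in (self.F_background, self.F_candidate):
            if not (0.0 <= F < 1.0):
                raise ValueError("F must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_maf_range must be inside (0, 1)")
        if self.n_background_snps < 0 or self.n_candidate_snps < 0:
            raise ValueError("SNP counts must be non-negative")
        if self.n_populations < 2:
            raise ValueError("need at least 2 populations")

    @property
    def sizes(self) -> np.ndarray:
        if np.isscalar(self.n_per_pop):
            return np.full(self.n_populations, int(self.n_per_pop))
        sizes = np.asarray(self.n_per_pop, dtype=int)
        if sizes.size != self.n_populations:
            raise ValueError("n_per_pop length must equal n_populations")
        return sizes


def _pop_freqs(p_anc: np.ndarray, F: float, n_pops: int, rng: np.random.Generator) -> np.ndarray:
    """Per-population frequencies, shape (n_snps, n_pops)."""
    if F == 0.0:
        return np.repeat(p_anc[:, None], n_pops, axis=1)
    k = (1.0 - F) / F
    return rng.beta(p_anc[:, None] * k, (1.0 - p_anc[:, None]) * k, size=(p_anc.size, n_pops))


def _hwe_genotypes(p: np.ndarray, sizes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Trinomial genotype counts (AA, Aa, aa) at HWE, shape (n_snps, n_pops, 3)."""
    n_snps, n_pops = p.shape
    counts = np.empty((n_snps, n_pops, 3))
    for j in range(n_pops):
        pj = p[:, j]
        n = sizes[j]
        n_AA = rng.binomial(n, pj**2)
        rest = n - n_AA
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(pj < 1.0, 2.0 * pj * (1.0 - pj) / (1.0 - pj**2), 0.0)
        n_Aa = rng.binomial(rest, np.clip(cond, 0.0, 1.0))
        counts[:, j, 0] = n_AA
        counts[:, j, 1] = n_Aa
        counts[:, j, 2] = n - n_AA - n_Aa
    return counts


def balding_nichols_panel(spec: SynthSpec, rng: Optional[np.random.Generator] = None
                          ) -> tuple[SNPPanel, list[str]]:
    """Generate a panel of background plus candidate SNPs.

    Returns (panel, candidate_ids); candidate ids are prefixed ``cand_``,
    background ids ``bg_``.  Same spec (and seed) -> identical panel.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sizes = spec.sizes
    lo, hi = spec.ancestral_maf_range

    blocks = []
    ids: list[str] = []
    for label, n_snps, F in (("bg", spec.n_background_snps, spec.F_background),
                             ("cand", spec.n_candidate_snps, spec.F_candidate)):
        if n_snps == 0:
            continue
        p_anc = rng.uniform(lo, hi, size=n_snps)
        p = _pop_freqs(p_anc, F, spec.n_populations, rng)
        blocks.append(_hwe_genotypes(p, sizes, rng))
        ids.extend(f"{label}_{i:06d}" for i in range(n_snps))

    counts = np.concatenate(blocks, axis=0) if blocks else np.zeros((0, spec.n_populations, 3))
    pops = [f"pop{j+1}" for j in range(spec.n_populations)]
    panel = SNPPanel(np.asarray(ids, dtype=object), pops, counts)
    cand_ids = [s for s in ids if s.startswith("cand_")]
    return panel, cand_ids


def synth_ld_table(candidate_ids: Sequence[str], fraction_confounded: float,
                   r2_bounds: tuple[float, float], spec: SynthSpec,
                   rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """LD rows linking a random candidate subset to other-trait variants.

    Each selected candidate gets one row with r^2 ~ Uniform(r2_bounds) in a
    random population; whether the row actually confounds depends on where
    the bounds sit relative to the pipeline's r^2 threshold.
    """
    if not (0.0 <= fraction_confounded <= 1.0):
        raise ValueError("fraction_confounded must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    ids = [str(c) for c in candidate_ids]
    k = int(round(fraction_confounded * len(ids)))
    cols = ["candidate_snp", "other_snp", "population", "r2", "trait"]
    if k == 0:
        return pd.DataFrame(columns=cols)
    chosen = rng.choice(len(ids), size=k, replace=False)
    pops = [f"pop{j+1}" for j in range(spec.n_populations)]
    return pd.DataFrame(
        {
            "candidate_snp": [ids[i] for i in chosen],
            "other_snp": [f"other_{i:05d}" for i in range(k)],
            "population": rng.choice(pops, size=k),
            "r2": rng.uniform(r2_bounds[0], r2_bounds[1], size=k),
            "trait": rng.choice(_TRAIT_VOCAB, size=k),
        },
        columns=cols,
    )


def synth_scores(panel: SNPPanel, candidate_ids: Sequence[str], enrichment_factor: float,
                 spec: SynthSpec, tail_fraction: float = 0.05,
                 rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Per-population iHS-like score table with controlled candidate tail mass.

    Background scores are i.i.d. standard normal per population.  Each
    candidate lands in the top ``tail_fraction`` tail with probability
    ``enrichment_factor * tail_fraction`` (capped at 1): tail scores are
    drawn above the normal quantile z_(1-tail), non-tail scores below it.
    ``enrichment_factor=1`` is the null construction, 0 keeps every
    candidate out of the tail.
    """
    from scipy import stats as _st

    if enrichment_factor < 0:
        raise ValueError("enrichment_factor must be >= 0")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    cand = set(str(c) for c in candidate_ids)
    z_thr = _st.norm.ppf(1.0 - tail_fraction)
    p_tail = min(1.0, enrichment_factor * tail_fraction)

    frames = []
    for j in range(spec.n_populations):
        pop = f"pop{j+1}"
        snp_ids = [str(s) for s in panel.snp_ids]
        is_cand = np.array([s in cand for s in snp_ids])
        vals = rng.standard_normal(len(snp_ids))
        # resample candidates from the two truncated halves of the normal
        n_c = int(is_cand.sum())
        if n_c:
            in_tail = rng.random(n_c) < p_tail
            u = rng.random(n_c)
            hi = _st.norm.ppf((1.0 - tail_fraction) + u * tail_fraction)   # above z_thr
            lo = _st.norm.ppf(u * (1.0 - tail_fraction))                   # below z_thr
            vals[is_cand] = np.where(in_tail, hi, lo)
        frames.append(pd.DataFrame({"snp_id": snp_ids, "population": pop, "score": vals}))
    return pd.concat(frames, ignore_index=True)
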