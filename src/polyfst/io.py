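"""Readers/writers for the pipeline's plain-text table dialects.

All tables are tab-separated with a header row.  Dialects:

* panel (genotype): snp_id, population, n_AA, n_Aa, n_aa
* panel (frequency): snp_id, population, n, p_ref  (heterozygotes imputed
  at Hardy-Weinberg proportions; panel mode set to "hwe")
* candidate list: one snp_id per line
* LD table: candidate_snp, other_snp, population, r2, trait
* scores: snp_id, population, score
* trajectories: population, locus, locus_class, generation, frequency

Config files are flat ``key = value`` lines (# comments allowed).  Every
run writes a JSON manifest carrying the seed and the configuration echo so
runs are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .fst import SNPPanel
from .simulate import SimResult

__all__ = [
    "PanelFormatError",
    "read_panel",
    "write_panel",
    "read_candidates",
    "write_candidates",
    "read_ld_table",
    "read_scores",
    "write_trajectories",
    "read_config",
    "write_manifest",
]

_GENO_COLS = ["snp_id", "population", "n_AA", "n_Aa", "n_aa"]
_FREQ_COLS = ["snp_id", "population", "n", "p_ref"]


class PanelFormatError(ValueError):
    """Malformed panel file; message carries the offending line numbers."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing columns {missing}")


def read_panel(path, dialect: str = "genotype") -> SNPPanel:
    """Read a panel TSV; rows validated with line-number diagnostics.

    Line numbers in error messages count the header as line 1.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str, "population": str})
    if dialect == "genotype":
        _check_columns(df, _GENO_COLS, path)
        num_cols = ["n_AA", "n_Aa", "n_aa"]
    elif dialect == "frequency":
        _check_columns(df, _FREQ_COLS, path)
        num_cols = ["n", "p_ref"]
    else:
        raise PanelFormatError(f"unknown dialect {dialect!r}")

    lines = df.index.to_numpy() + 2  # header is line 1
    bad = df[num_cols].isna().any(axis=1) | (df[num_cols] < 0).any(axis=1)
    if bad.any():
        raise PanelFormatError(f"{path}: negative or missing counts at lines {lines[bad][:5].tolist()}")
    dup = df.duplicated(subset=["snp_id", "population"], keep=False)
    if dup.any():
        raise PanelFormatError(f"{path}: duplicate (snp_id, population) rows at lines {lines[dup][:5].tolist()}")
    if dialect == "frequency" and ((df["p_ref"] < 0) | (df["p_ref"] > 1)).any():
        bad = (df["p_ref"] < 0) | (df["p_ref"] > 1)
        raise PanelFormatError(f"{path}: p_ref outside [0,1] at lines {lines[bad][:5].tolist()}")

    pops = list(dict.fromkeys(df["population"]))
    snps = list(dict.fromkeys(df["snp_id"]))
    pop_ix = {p: j for j, p in enumerate(pops)}
    snp_ix = {s: i for i, s in enumerate(snps)}
    rows = df["snp_id"].map(snp_ix).to_numpy()
    cols = df["population"].map(pop_ix).to_numpy()

    if dialect == "genotype":
        counts = np.zeros((len(snps), len(pops), 3))
        counts[rows, cols, 0] = df["n_AA"].to_numpy(dtype=float)
        counts[rows, cols, 1] = df["n_Aa"].to_numpy(dtype=float)
        counts[rows, cols, 2] = df["n_aa"].to_numpy(dtype=float)
        return SNPPanel(np.asarray(snps, dtype=object), pops, counts, mode="genotype")

    n = np.zeros((len(snps), len(pops)))
    p = np.zeros((len(snps), len(pops)))
    n[rows, cols] = df["n"].to_numpy(dtype=float)
    p[rows, cols] = df["p_ref"].to_numpy(dtype=float)
    return SNPPanel.from_frequencies(np.asarray(snps, dtype=object), pops, n, p)


def write_panel(panel: SNPPanel, path) -> None:
    """Genotype-dialect TSV; inverse of read_panel on valid panels."""
    n_snps, n_pops = panel.n_snps, len(panel.populations)
    df = pd.DataFrame(
        {
            "snp_id": np.repeat(panel.snp_ids, n_pops),
            "population": np.tile(panel.populations, n_snps),
            "n_AA": panel.counts[:, :, 0].ravel(),
            "n_Aa": panel.counts[:, :, 1].ravel(),
            "n_aa": panel.counts[:, :, 2].ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_candidates(path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_candidates(ids, path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in ids))


def read_ld_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"candidate_snp": str, "other_snp": str})
    _check_columns(df, ["candidate_snp", "other_snp", "population", "r2", "trait"], path)
    return df


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str, "population": str})
    _check_columns(df, ["snp_id", "population", "score"], path)
    return df


def write_trajectories(result: SimResult, path) -> None:
    """Long-format TSV: population, locus, locus_class, generation, frequency."""
    n_pops, n_gen1, n_loci = result.trajectories.shape
    cls = np.where(result.locus_selected, "selected", "neutral")
    df = pd.DataFrame(
        {
            "population": np.repeat(np.arange(1, n_pops + 1), n_gen1 * n_loci),
            "locus": np.tile(np.repeat(np.arange(n_loci), 1), n_pops * n_gen1),
            "locus_class": np.tile(cls, n_pops * n_gen1),
            "generation": np.tile(np.repeat(np.arange(n_gen1), n_loci), n_pops),
            "frequency": result.trajectories.reshape(-1),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.5f")


def read_config(path) -> dict[str, str]:
    """Flat ``key = value`` file; values stay strings for the caller to coerce."""
    cfg: dict[str, str] = {}
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {i}: expected 'key = value', got {raw!r}")
        key, val = line.split("=", 1)
        cfg[key.strip()] = val.strip()
    return cfg


def write_manifest(out_dir, seed: int, config: Mapping, inputs: Optional[Mapping[str, Path]] = None) -> Path:
    """JSON manifest with seed, config echo and input checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for name, p in (inputs or {}).items():
        checksums[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    from . import __version__

    manifest = {
        "seed": seed,
        "polyfst_version": __version__,
        "config": {k: str(v) for k, v in dict(config).items()},
        "input_sha256": checksums,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
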