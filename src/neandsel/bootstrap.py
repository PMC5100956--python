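"""Blockwise bootstrap confidence intervals for (p0, s, mu, mu*s).

Genomic data are autocorrelated along the chromosome, so SNP-level
resampling would understate uncertainty.  Instead, each chromosome is tiled
into non-overlapping blocks of fixed genetic length (5 cM by default,
starting from the chromosome's first SNP), and per block the sufficient
statistics of the profile-RSS fit are precomputed on the fine (s, mu) grid:
``sum p_n g`` and ``sum g^2`` (the numerator and denominator of the analytic
p0), plus ``sum p_n^2``.  A bootstrap genome resamples blocks with
replacement within each chromosome (keeping the original per-chromosome
block count), reassembles the RSS surface from the block sums, and
re-optimizes (s, mu, p0).  Confidence intervals are empirical 2.5/97.5
percentiles over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["BlockSums", "BootstrapResult", "make_blocks", "bootstrap_fit", "bootstrap_ci"]


def make_blocks(snp_cm: np.ndarray, snp_chrom: np.ndarray, block_cm: float = 5.0):
    """Assign every SNP to a non-overlapping genetic-distance block.

    Blocks tile each chromosome from its first SNP's cM position in
    right-open intervals ``[start + k*block_cm, start + (k+1)*block_cm)``.
    Returns ``(block_of_snp, block_chrom)`` where ``block_of_snp`` maps SNPs
    to global block indices and ``block_chrom`` labels each block's
    chromosome.  Interior blocks without SNPs are kept (they contribute
    nothing but remain resampling units); partial terminal blocks are kept.
    """
    if block_cm <= 0:
        raise ValueError("block_cm must be positive")
    snp_cm = np.asarray(snp_cm, dtype=float)
    snp_chrom = np.asarray(snp_chrom)
    block_of_snp = np.empty(snp_cm.size, dtype=np.int64)
    block_chrom: list = []
    offset = 0
    for chrom in pd.unique(snp_chrom):
        mask = snp_chrom == chrom
        cm = snp_cm[mask]
        start = cm.min()
        idx = np.floor((cm - start) / block_cm).astype(np.int64)
        n_tiles = int(idx.max()) + 1
        block_of_snp[mask] = offset + idx
        block_chrom.extend([chrom] * n_tiles)
        offset += n_tiles
    return block_of_snp, np.asarray(block_chrom)


@dataclass
class BlockSums:
    """Per-block sufficient statistics of the profile-RSS fit.

    ``num[i, j, b] = sum_{l in b} p_nl g_l(s_i, mu_j)`` and
    ``den[i, j, b] = sum_{l in b} g_l^2``; ``spp[b] = sum p_nl^2``.
    Summing over blocks reproduces the full-data fit exactly.
    """

    s_values: np.ndarray
    mu_values: np.ndarray
    num: np.ndarray  # (S, U, B)
    den: np.ndarray  # (S, U, B)
    spp: np.ndarray  # (B,)
    n_snps: np.ndarray  # (B,)
    chrom: np.ndarray  # (B,) labels

    @property
    def n_blocks(self) -> int:
        return self.chrom.size

    def refit(self, counts: np.ndarray) -> tuple[float, float, float, float]:
        """Fit (s, mu, p0, rss) for a block multiset given by ``counts``."""
        s, mu, p0, r = _fit_from_counts(self, counts[None, :])
        return float(s[0]), float(mu[0]), float(p0[0]), float(r[0])


def _fit_from_counts(bs: BlockSums, counts: np.ndarray):
    """Vectorized re-fit for many block multisets.

    counts: (R, B) block multiplicities.  Returns arrays (R,) of s, mu, p0,
    rss; ties broken toward smaller s then smaller mu (row-major argmin).
    """
    S, U, B = bs.num.shape
    num2 = bs.num.reshape(S * U, B)
    den2 = bs.den.reshape(S * U, B)
    countsT = counts.T.astype(float)  # (B, R)
    num_r = num2 @ countsT  # (S*U, R)
    den_r = den2 @ countsT
    spp_r = bs.spp @ countsT  # (R,)
    with np.errstate(invalid="ignore", divide="ignore"):
        p0_r = np.clip(num_r / den_r, 0.0, 1.0)
    p0_r = np.nan_to_num(p0_r)
    rss_r = spp_r[None, :] - 2.0 * p0_r * num_r + p0_r * p0_r * den_r
    best = np.argmin(rss_r, axis=0)  # first occurrence: smallest s, then mu
    i, j = np.unravel_index(best, (S, U))
    cols = np.arange(counts.shape[0])
    return (
        bs.s_values[i],
        bs.mu_values[j],
        p0_r[best, cols],
        rss_r[best, cols],
    )


def bootstrap_fit(
    block_sums: BlockSums,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Blockwise-bootstrap re-estimates: one row (s, mu, p0, mus) per replicate.

    Each replicate resamples blocks with replacement independently within
    each chromosome, preserving the chromosome's block count, then refits on
    the precomputed grid.  Fully reproducible given ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    B = block_sums.n_blocks
    counts = np.zeros((n_boot, B), dtype=np.int64)
    for chrom in pd.unique(block_sums.chrom):
        idx = np.flatnonzero(block_sums.chrom == chrom)
        k = idx.size
        draws = rng.integers(0, k, size=(n_boot, k))
        local = np.zeros((n_boot, k), dtype=np.int64)
        np.add.at(local, (np.repeat(np.arange(n_boot), k), draws.ravel()), 1)
        counts[:, idx] += local
    s, mu, p0, rss_v = _fit_from_counts(block_sums, counts)
    return pd.DataFrame({"s": s, "mu": mu, "p0": p0, "mus": s * mu, "rss": rss_v})


def _percentile_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    alpha = 100.0 * (1.0 - level) / 2.0
    return float(np.percentile(x, alpha)), float(np.percentile(x, 100.0 - alpha))


@dataclass
class BootstrapResult:
    replicates: pd.DataFrame
    ci: dict  # parameter -> (low, high)
    level: float

    def to_json_dict(self) -> dict:
        return {
            "level": self.level,
            "n_boot": int(len(self.replicates)),
            "ci": {k: [v[0], v[1]] for k, v in self.ci.items()},
        }


def bootstrap_ci(
    block_sums: BlockSums,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> BootstrapResult:
    """Percentile bootstrap confidence intervals for p0, s, mu and mu*s."""
    reps = bootstrap_fit(block_sums, n_boot=n_boot, seed=seed)
    ci = {par: _percentile_ci(reps[par].to_numpy(), level) for par in ("p0", "s", "mu", "mus")}
    return BootstrapResult(replicates=reps, ci=ci, level=level)
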