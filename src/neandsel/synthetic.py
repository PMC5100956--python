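"""Synthetic genomes with the statistical structure the inference assumes.

Generates the three inputs the fitting pipeline reads — a piecewise-linear
genetic map, an exon annotation placed by a renewal process, and a per-SNP
call table whose expected frequencies follow the linked-selection model —
for parameter-recovery studies, bootstrap-coverage checks and demos.

Two call-generation modes exist:

* expectation + noise (default, fast): each SNP's call is drawn around the
  model mean ``p0 * g`` under a chosen noise model (exact, binomial sampling
  of ``n`` haploid genomes, or drift-inflated beta noise);
* mechanistic (slow, used in a handful of tests): selected sites are placed
  with probability ``mu`` per exonic base at exon midpoints, and each SNP's
  frequency is the retention factor to its nearest selected site.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genome import CallTable, ExonAnnotation, GeneticMap
from .inference import GEngine
from .genome import build_windows
from .model import ModelParams, f_autosome, f_xchr

__all__ = [
    "SyntheticGenomeConfig",
    "generate_genome",
    "generate_calls",
    "generate_calls_mechanistic",
    "generate_dataset",
    "write_dataset",
]

_DEFAULT_TRUTH = ModelParams(p0=0.0338, s=4.12e-4, t=2000, mu=8.1e-5)


@dataclass
class SyntheticGenomeConfig:
    """Study conditions for a synthetic genome.

    Defaults emulate a desk-scale genome: 22 autosomes of 50 cM at an
    average 1 cM/Mb with mild recombination-rate heterogeneity, ~2% exonic
    sequence (400 bp exons every ~20 kb), and ~50,000 SNPs, with the true
    model parameters at the magnitudes estimated for European autosomes
    (p0=0.0338, s=4.12e-4, mu=8.1e-5, t=2000) and drift-level noise for a
    recipient population of effective size 10,000.
    """

    n_chromosomes: int = 22
    chrom_cm: float = 50.0
    cm_per_mb: float = 1.0
    map_points: int = 11  # map knots per chromosome
    rate_log_sd: float = 0.3  # lognormal spread of per-interval recomb rates
    mean_exon_length: int = 400
    min_exon_length: int = 50
    mean_exon_gap: int = 20000
    snp_spacing: int = 22000
    snp_jitter: float = 0.25  # uniform jitter as a fraction of the spacing
    truth: ModelParams = field(default_factory=lambda: _DEFAULT_TRUTH)
    noise: str = "drift"  # "none" | "binomial" | "drift"
    noise_n: int = 1006  # haploid sample size for binomial noise
    noise_ne: int = 10000  # recipient effective size for drift noise
    noise_t: int = 2000  # generations of drift
    window_cm: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_cm <= 0 or self.cm_per_mb <= 0:
            raise ValueError("invalid genome dimensions")
        if self.mean_exon_length < self.min_exon_length or self.min_exon_length < 1:
            raise ValueError("invalid exon length parameters")
        if self.mean_exon_gap < 1 or self.snp_spacing < 1:
            raise ValueError("invalid spacing parameters")
        if self.noise not in ("none", "binomial", "drift"):
            raise ValueError("noise must be 'none', 'binomial' or 'drift'")

    @property
    def chrom_bp(self) -> int:
        return int(round(self.chrom_cm / self.cm_per_mb * 1e6))

    @property
    def chrom_names(self) -> list[str]:
        if self.truth.mode == "X":
            return ["X"]
        return [str(i) for i in range(1, self.n_chromosomes + 1)]


def generate_genome(
    config: SyntheticGenomeConfig, rng: Optional[np.random.Generator] = None
) -> tuple[GeneticMap, ExonAnnotation, dict]:
    """Build the map, exon annotation and SNP positions for a config.

    Returns ``(genetic_map, exons, snp_positions)`` with SNP positions as a
    dict ``chrom -> int array``.  Reproducible given ``config.seed``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    length = config.chrom_bp
    map_chroms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    exon_chroms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    snps: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names:
        # piecewise-linear map: lognormal interval rates rescaled to the
        # chromosome's total genetic length
        knots = np.linspace(0, length, config.map_points).astype(np.int64)
        if config.rate_log_sd > 0:
            rates = rng.lognormal(0.0, config.rate_log_sd, size=config.map_points - 1)
        else:
            rates = np.ones(config.map_points - 1)
        seg_cm = rates * np.diff(knots)
        seg_cm *= config.chrom_cm / seg_cm.sum()
        cm = np.concatenate([[0.0], np.cumsum(seg_cm)])
        map_chroms[chrom] = (knots.astype(float), cm)

        # renewal process for exons
        mean_gap = float(config.mean_exon_gap)
        mean_extra = float(config.mean_exon_length - config.min_exon_length)
        n_guess = int(2 * length / (mean_gap + config.mean_exon_length) + 20)
        gaps = rng.exponential(mean_gap, size=n_guess)
        extras = rng.exponential(mean_extra, size=n_guess) if mean_extra > 0 else np.zeros(n_guess)
        lens = (config.min_exon_length + extras).astype(np.int64)
        starts = (np.cumsum(gaps + lens) - lens).astype(np.int64)
        ends = starts + lens
        keep = ends < length
        exon_chroms[chrom] = (starts[keep], ends[keep])

        # jittered SNP grid
        grid = np.arange(config.snp_spacing // 2, length, config.snp_spacing, dtype=np.int64)
        jitter = (
            rng.uniform(-0.5, 0.5, size=grid.size) * config.snp_jitter * config.snp_spacing
        ).astype(np.int64)
        pos = np.unique(np.clip(grid + jitter, 0, length - 1))
        snps[chrom] = pos
    return GeneticMap(map_chroms), ExonAnnotation(exon_chroms), snps


def _expected_means(
    snps: dict,
    gmap: GeneticMap,
    exons: ExonAnnotation,
    truth: ModelParams,
    window_cm: float,
) -> CallTable:
    rows = []
    for chrom, pos in snps.items():
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "p": 0.0}))
    calls = CallTable(pd.concat(rows, ignore_index=True))
    windows = build_windows(calls, exons, gmap, window_cm)
    engine = GEngine(windows, truth.t, truth.mode)
    g = engine.g(truth.s, truth.mu)
    calls.df["p"] = truth.p0 * g
    return calls


def generate_calls(
    genome: tuple,
    truth: ModelParams,
    noise: str = "none",
    seed: Optional[int] = None,
    window_cm: float = 1.0,
    noise_n: int = 1006,
    noise_ne: int = 10000,
    noise_t: int = 2000,
) -> CallTable:
    """Draw a call table around the model means ``p0 * g``.

    noise="none"
        Calls equal the model means exactly.
    noise="binomial"
        ``Binomial(noise_n, mean)/noise_n`` — sampling error of ``noise_n``
        haploid genomes.
    noise="drift"
        Beta-distributed with the mean preserved and variance
        ``mean (1-mean) (1 - (1 - 1/(2*noise_ne))^noise_t)`` — the neutral
        drift variance accumulated over ``noise_t`` generations.
    """
    gmap, exons, snps = genome
    calls = _expected_means(snps, gmap, exons, truth, window_cm)
    mean = calls.df["p"].to_numpy()
    if noise == "none":
        p = mean
    elif noise == "binomial":
        rng = np.random.default_rng(seed)
        p = rng.binomial(int(noise_n), mean) / float(noise_n)
    elif noise == "drift":
        rng = np.random.default_rng(seed)
        factor = -np.expm1(noise_t * math.log1p(-1.0 / (2.0 * noise_ne)))
        var = mean * (1.0 - mean) * factor
        interior = (mean > 0) & (mean < 1)
        p = mean.copy()
        m = mean[interior]
        # beta with matching mean and variance keeps support in [0, 1]
        nu = m * (1.0 - m) / var[interior] - 1.0
        p[interior] = rng.beta(m * nu, (1.0 - m) * nu)
    else:
        raise ValueError("noise must be 'none', 'binomial' or 'drift'")
    calls.df["p"] = np.clip(p, 0.0, 1.0)
    return CallTable(calls.df)


def generate_calls_mechanistic(
    genome: tuple,
    truth: ModelParams,
    seed: Optional[int] = None,
    window_cm: float = 1.0,
) -> CallTable:
    """Place actual selected sites and compute each SNP's frequency from its
    nearest selected site (deterministic retention, no sampling noise).

    Each merged exon receives a selected site at its midpoint with
    probability ``min(mu * length, 1)``.  Averaging over placements
    reproduces the nearest-exon mixture expectation.
    """
    gmap, exons, snps = genome
    rng = np.random.default_rng(seed)
    f_func = f_xchr if truth.mode == "X" else f_autosome
    rows = []
    for chrom, pos in snps.items():
        mids = exons.midpoints(chrom)
        lens = exons.lengths(chrom)
        chosen = rng.random(mids.size) < np.minimum(truth.mu * lens, 1.0)
        sel_cm = np.sort(gmap.interpolate(chrom, mids[chosen]))
        snp_cm = gmap.interpolate(chrom, pos)
        p = np.full(pos.size, truth.p0)
        if sel_cm.size:
            right = np.searchsorted(sel_cm, snp_cm)
            left = np.clip(right - 1, 0, sel_cm.size - 1)
            right = np.clip(right, 0, sel_cm.size - 1)
            dist = np.minimum(
                np.abs(snp_cm - sel_cm[left]), np.abs(sel_cm[right] - snp_cm)
            )
            linked = dist <= window_cm / 2.0
            r = np.minimum(dist[linked] / 100.0, 0.5)
            p[linked] = truth.p0 * np.asarray(f_func(r, truth.s, truth.t))
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "p": p}))
    return CallTable(pd.concat(rows, ignore_index=True))


def generate_dataset(
    config: SyntheticGenomeConfig,
) -> tuple[GeneticMap, ExonAnnotation, CallTable]:
    """One-call convenience: genome plus calls under the config's noise model."""
    rng = np.random.default_rng(config.seed)
    gmap, exons, snps = generate_genome(config, rng)
    calls = generate_calls(
        (gmap, exons, snps),
        config.truth,
        noise=config.noise,
        seed=rng.integers(0, 2**31 - 1),
        window_cm=config.window_cm,
        noise_n=config.noise_n,
        noise_ne=config.noise_ne,
        noise_t=config.noise_t,
    )
    return gmap, exons, calls


def write_dataset(config: SyntheticGenomeConfig, out_dir) -> dict:
    """Generate and write ``map.tsv``, ``exons.bed`` and ``calls.tsv``.

    Returns a manifest dict (also written as ``dataset.json``) recording the
    effective configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gmap, exons, calls = generate_dataset(config)
    rows = []
    for chrom in gmap.chromosomes:
        bp, cm = gmap._chroms[chrom]
        rows.append(pd.DataFrame({"chrom": chrom, "pos": bp.astype(np.int64), "cM": cm}))
    pd.concat(rows, ignore_index=True).to_csv(out / "map.tsv", sep="\t", index=False)
    exons.write(out / "exons.bed")
    calls.write(out / "calls.tsv")
    manifest = dataclasses.asdict(config)
    manifest["truth"] = {
        "p0": config.truth.p0,
        "s": config.truth.s,
        "t": None if config.truth.is_equilibrium else float(config.truth.t),
        "mu": config.truth.mu,
        "mode": config.truth.mode,
    }
    manifest["files"] = {"map": "map.tsv", "exons": "exons.bed", "calls": "calls.tsv"}
    (out / "dataset.json").write_text(json.dumps(manifest, indent=2))
    return manifest
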