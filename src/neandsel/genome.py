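"""Genomic inputs: genetic map, exon annotation, introgressed-call table.

Three plain-text formats are read (gzip-transparently, via pandas):

* genetic map — whitespace/tab-delimited ``chrom  pos_bp  cM`` (cumulative),
  optional header;
* exons — BED, 0-based half-open, 3+ columns; overlapping or book-ended
  records are merged before midpoints are computed;
* calls — tab-delimited ``chrom  pos  p`` with the per-SNP introgressed-allele
  frequency estimate in [0, 1], 1-based positions, optional header.

Physical coordinates are held 0-based internally.  Genetic positions are
interpolated piecewise-linearly from the map, clamped to the boundary cM value
outside the mapped range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .model import LinkedExonContext

__all__ = [
    "GeneticMap",
    "ExonAnnotation",
    "CallTable",
    "WindowSet",
    "read_map",
    "read_exons",
    "read_calls",
    "interpolate_cM",
    "recomb_fraction",
    "build_window",
    "build_windows",
]


class ParseError(ValueError):
    """A malformed line in an input file."""


def _natural_chrom_order(chroms: Iterable[str]) -> list[str]:
    def key(c: str):
        body = c[3:] if c.lower().startswith("chr") else c
        return (0, int(body)) if body.isdigit() else (1, body)

    return sorted(set(chroms), key=key)


@dataclass
class GeneticMap:
    """Per-chromosome monotone mapping physical bp -> cumulative cM."""

    _chroms: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for chrom, (bp, cm) in self._chroms.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size < 2:
                raise ValueError(f"genetic map for {chrom} needs >= 2 points")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"map positions on {chrom} must strictly increase")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"map cM on {chrom} must be non-decreasing")
            self._chroms[chrom] = (bp, cm)

    @property
    def chromosomes(self) -> list[str]:
        return _natural_chrom_order(self._chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def interpolate(self, chrom: str, bp) -> np.ndarray:
        """Genetic position in cM; constant beyond the mapped range."""
        if chrom not in self._chroms:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        pos, cm = self._chroms[chrom]
        out = np.interp(np.asarray(bp, dtype=float), pos, cm)
        return out

    def span_cm(self, chrom: str) -> tuple[float, float]:
        _, cm = self._chroms[chrom]
        return float(cm[0]), float(cm[-1])


def interpolate_cM(gmap: GeneticMap, chrom: str, bp):
    """Functional form of :meth:`GeneticMap.interpolate`."""
    out = gmap.interpolate(chrom, bp)
    return out if np.ndim(bp) else float(out)


def recomb_fraction(d_cm):
    """Genetic distance (cM) -> recombination fraction, ``min(d/100, 0.5)``.

    Linear in Morgans with a cap at 1/2; over the <=10 cM windows used here a
    map function (Haldane/Kosambi) would differ negligibly.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    out = np.minimum(d / 100.0, 0.5)
    return out if out.ndim else float(out)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.lexsort((ends, starts))
    starts, ends = starts[order], ends[order]
    keep_s, keep_e = [], []
    for s, e in zip(starts, ends):
        if keep_e and s <= keep_e[-1]:
            keep_e[-1] = max(keep_e[-1], e)
        else:
            keep_s.append(s)
            keep_e.append(e)
    return np.asarray(keep_s, dtype=np.int64), np.asarray(keep_e, dtype=np.int64)


@dataclass
class ExonAnnotation:
    """Merged exon intervals per chromosome, 0-based half-open.

    Midpoints (the assumed location of a selected site within an exon) are
    ``floor((start + end) / 2)``.
    """

    _chroms: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        merged = {}
        for chrom, (starts, ends) in self._chroms.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            if np.any(ends <= starts):
                raise ValueError(f"exon end must exceed start on {chrom}")
            merged[chrom] = _merge_intervals(starts, ends)
        self._chroms = merged

    @property
    def chromosomes(self) -> list[str]:
        return _natural_chrom_order(self._chroms)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self._chroms:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return self._chroms[chrom]

    def midpoints(self, chrom: str) -> np.ndarray:
        starts, ends = self.intervals(chrom)
        return (starts + ends) // 2

    def lengths(self, chrom: str) -> np.ndarray:
        starts, ends = self.intervals(chrom)
        return ends - starts

    def total_exonic_bases(self) -> int:
        return int(sum(self.lengths(c).sum() for c in self._chroms))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chromosomes:
            starts, ends = self.intervals(chrom)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return pd.concat(rows, ignore_index=True)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


@dataclass
class CallTable:
    """Per-SNP observed introgressed-allele frequencies.

    ``df`` columns: chrom (str), pos (0-based bp, int), p (float in [0, 1]);
    a ``cm`` column with genetic positions is added by :meth:`with_cm`.
    Rows are sorted by (chromosome, position).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = {"chrom", "pos", "p"} - set(df.columns)
        if missing:
            raise ValueError(f"call table is missing columns {sorted(missing)}")
        if np.any((df["p"].to_numpy() < 0) | (df["p"].to_numpy() > 1)):
            bad = int(np.argmax((df["p"].to_numpy() < 0) | (df["p"].to_numpy() > 1)))
            raise ValueError(
                f"call frequency outside [0, 1] at row {bad} "
                f"(chrom={df['chrom'].iat[bad]}, pos={df['pos'].iat[bad]})"
            )
        df = df.copy()
        df["chrom"] = df["chrom"].astype(str)
        order = _natural_chrom_order(df["chrom"])
        rank = {c: i for i, c in enumerate(order)}
        df = df.sort_values(
            by=["chrom", "pos"], key=lambda col: col.map(rank) if col.name == "chrom" else col
        ).reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        return _natural_chrom_order(self.df["chrom"])

    @property
    def p(self) -> np.ndarray:
        return self.df["p"].to_numpy(dtype=float)

    def with_cm(self, gmap: GeneticMap) -> "CallTable":
        df = self.df.copy()
        cm = np.empty(len(df))
        for chrom, sub in df.groupby("chrom", sort=False):
            cm[sub.index.to_numpy()] = gmap.interpolate(chrom, sub["pos"].to_numpy())
        df["cm"] = cm
        return CallTable(df)

    def write(self, path) -> None:
        out = self.df[["chrom", "pos", "p"]].copy()
        out["pos"] = out["pos"] + 1  # back to the 1-based on-disk convention
        out.to_csv(path, sep="\t", index=False)


def _read_table(path, n_min_cols: int, what: str) -> pd.DataFrame:
    try:
        probe = pd.read_csv(path, sep=r"\s+", header=None, comment="#", nrows=1)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{what} file {path} is empty") from exc
    def _is_number(v) -> bool:
        try:
            float(v)
            return True
        except (TypeError, ValueError):
            return False

    has_header = any(not _is_number(v) for v in probe.iloc[0, 1:])
    df = pd.read_csv(path, sep=r"\s+", header=0 if has_header else None, comment="#")
    if df.shape[1] < n_min_cols:
        raise ParseError(f"{what} file {path} needs >= {n_min_cols} columns")
    return df


def _numeric(df: pd.DataFrame, col: int, what: str, path) -> np.ndarray:
    vals = pd.to_numeric(df.iloc[:, col], errors="coerce")
    if vals.isna().any():
        line = int(vals.index[vals.isna()][0]) + 1
        raise ParseError(f"malformed {what} value in {path} at data line {line}")
    return vals.to_numpy()


def read_map(path) -> GeneticMap:
    """Read a ``chrom pos_bp cM`` genetic-map table."""
    df = _read_table(path, 3, "genetic map")
    chroms = df.iloc[:, 0].astype(str).to_numpy()
    bp = _numeric(df, 1, "position", path)
    cm = _numeric(df, 2, "cM", path)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        order = np.argsort(bp[mask], kind="stable")
        out[chrom] = (bp[mask][order], cm[mask][order])
    return GeneticMap(out)


def read_exons(path) -> ExonAnnotation:
    """Read a BED (3+ column) exon annotation; overlapping records merge."""
    df = _read_table(path, 3, "BED")
    chroms = df.iloc[:, 0].astype(str).to_numpy()
    starts = _numeric(df, 1, "start", path).astype(np.int64)
    ends = _numeric(df, 2, "end", path).astype(np.int64)
    out = {str(c): (starts[chroms == c], ends[chroms == c]) for c in pd.unique(chroms)}
    return ExonAnnotation(out)


def read_calls(path) -> CallTable:
    """Read a ``chrom pos p`` call table (1-based positions on disk)."""
    df = _read_table(path, 3, "call table")
    pos = _numeric(df, 1, "position", path).astype(np.int64)
    p = _numeric(df, 2, "frequency", path)
    return CallTable(
        pd.DataFrame({"chrom": df.iloc[:, 0].astype(str).to_numpy(), "pos": pos - 1, "p": p})
    )


@dataclass
class WindowSet:
    """Flattened linked-exon windows for every SNP of a call table.

    Entry arrays are concatenated over SNPs; ``ptr`` delimits each SNP's
    entries (``ptr[i]:ptr[i+1]``), which are sorted by genetic distance from
    the focal SNP (ties broken toward the lower physical coordinate).
    """

    r: np.ndarray  # recombination fraction to each exon midpoint
    length: np.ndarray  # exon length in bp
    ptr: np.ndarray  # int64, len n_snps + 1
    snp_cm: np.ndarray  # genetic position of each SNP
    snp_chrom: np.ndarray  # chromosome label of each SNP
    window_cm: float

    @property
    def n_snps(self) -> int:
        return self.ptr.size - 1

    def context(self, i: int) -> LinkedExonContext:
        sl = slice(self.ptr[i], self.ptr[i + 1])
        return LinkedExonContext(self.r[sl], self.length[sl])


def build_windows(
    calls: CallTable,
    exons: ExonAnnotation,
    gmap: GeneticMap,
    window_cm: float = 1.0,
) -> WindowSet:
    """Construct the linked-exon window for every SNP in one pass.

    An exon belongs to a SNP's window when its midpoint lies within
    ``window_cm / 2`` of the SNP's genetic position (inclusive).
    """
    if window_cm <= 0:
        raise ValueError("window_cm must be positive")
    half = window_cm / 2.0
    df = calls.df
    n = len(df)
    snp_cm = np.empty(n)
    chunks_r, chunks_l = [], []
    counts = np.zeros(n, dtype=np.int64)
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        cm = gmap.interpolate(chrom, pos)
        idx = sub.index.to_numpy()
        snp_cm[idx] = cm
        mids = exons.midpoints(chrom)
        lens = exons.lengths(chrom)
        if mids.size:
            mid_cm = gmap.interpolate(chrom, mids)
            order = np.argsort(mid_cm, kind="stable")
            mid_cm, lens_o, mids_o = mid_cm[order], lens[order], mids[order]
            lo = np.searchsorted(mid_cm, cm - half, side="left")
            hi = np.searchsorted(mid_cm, cm + half, side="right")
            cnt = hi - lo
            counts[idx] = cnt
            total = int(cnt.sum())
            if total:
                # flatten [lo_i, hi_i) ranges
                snp_rep = np.repeat(np.arange(cm.size), cnt)
                offsets = np.concatenate([[0], np.cumsum(cnt)])[:-1]
                within = np.arange(total) - np.repeat(offsets, cnt)
                ex_idx = np.repeat(lo, cnt) + within
                dist = np.abs(mid_cm[ex_idx] - cm[snp_rep])
                # sort each window by (distance, physical midpoint)
                order2 = np.lexsort((mids_o[ex_idx], dist, snp_rep))
                chunks_r.append(recomb_fraction(dist[order2]))
                chunks_l.append(lens_o[ex_idx][order2].astype(float))
    ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    r = np.concatenate(chunks_r) if chunks_r else np.empty(0)
    length = np.concatenate(chunks_l) if chunks_l else np.empty(0)
    return WindowSet(
        r=r,
        length=length,
        ptr=ptr,
        snp_cm=snp_cm,
        snp_chrom=df["chrom"].to_numpy(),
        window_cm=float(window_cm),
    )


def build_window(
    calls: CallTable,
    exons: ExonAnnotation,
    gmap: GeneticMap,
    site: int,
    window_cm: float = 1.0,
) -> LinkedExonContext:
    """Window for a single SNP (row index ``site`` of the call table)."""
    chrom = calls.df["chrom"].iat[site]
    pos = int(calls.df["pos"].iat[site])
    cm = float(gmap.interpolate(chrom, pos))
    mids = exons.midpoints(chrom)
    lens = exons.lengths(chrom)
    if mids.size == 0:
        return LinkedExonContext(np.empty(0), np.empty(0))
    mid_cm = gmap.interpolate(chrom, mids)
    dist = np.abs(mid_cm - cm)
    mask = dist <= window_cm / 2.0
    dist, lens, mids = dist[mask], lens[mask], mids[mask]
    order = np.lexsort((mids, dist))
    return LinkedExonContext(recomb_fraction(dist[order]), lens[order].astype(float))
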