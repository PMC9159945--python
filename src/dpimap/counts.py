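"""Per-replicate base-count ingestion, the filtering cascade, and smoothing.

The pipeline stages mirror the standard deaminase-footprinting workflow:

1. per-replicate depth/alt counts at TC sites (``read_counts`` or the
   alignment adapter in :mod:`dpimap.alignment`);
2. site filters applied jointly across replicates (``site_filters``):
   minimum depth (default 15), a cap on per-replicate transition frequency
   (default 0.95, removing fixed variants and hypervariable positions), and
   an interval mask;
3. the replicate-consensus mean (``replicate_consensus_mean``): a site's mean
   transition frequency is reported only where at least 3 of 4 replicates
   carry at least one mutant read, which suppresses the spatially random
   background of free deaminase activity;
4. a centered 75 bp moving average over surviving sites (``moving_average``)
   for visualization and peak seeding.

Counts TSVs carry 1-based positions; everything in memory is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import MaskSet

__all__ = [
    "SiteCountTable",
    "ReplicateSet",
    "FilterConfig",
    "FrequencyTrack",
    "SmoothedTrack",
    "read_counts",
    "write_counts",
    "site_filters",
    "replicate_consensus_mean",
    "moving_average",
    "window_mean",
]

_COUNT_COLS = ["contig", "pos", "strand", "depth", "alt"]


@dataclass(frozen=True)
class SiteCountTable:
    """Depth and transition counts at TC sites for one sequencing replicate.

    ``df`` columns: contig, pos (0-based), strand, depth, alt with
    0 <= alt <= depth and one row per site.
    """

    replicate_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _COUNT_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"count table missing columns {missing}")
        if (df["alt"] > df["depth"]).any():
            bad = df.index[df["alt"] > df["depth"]][0]
            raise ValueError(f"alt > depth at row {bad}")
        if (df["depth"] < 0).any() or (df["alt"] < 0).any():
            raise ValueError("negative counts")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        keys = df[["contig", "pos", "strand"]]
        if keys.duplicated().any():
            raise ValueError(f"duplicate site rows in replicate {self.replicate_id}")

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class ReplicateSet:
    """The replicate count tables for one condition (default quadruplicate)."""

    tables: tuple[SiteCountTable, ...]
    condition: str = ""

    def __post_init__(self) -> None:
        ids = [t.replicate_id for t in self.tables]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate replicate ids: {ids}")

    @property
    def n_replicates(self) -> int:
        return len(self.tables)

    def site_union(self) -> pd.DataFrame:
        keys = pd.concat(
            [t.df[["contig", "pos", "strand"]] for t in self.tables],
            ignore_index=True,
        ).drop_duplicates()
        return keys.sort_values(["contig", "pos", "strand"], kind="stable").reset_index(
            drop=True
        )

    def wide(self) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
        """Align replicates on the union of sites.

        Returns (site keys, depth matrix, alt matrix), each matrix of shape
        (n_sites, n_replicates).  Sites absent from a replicate get depth 0,
        which the depth filter subsequently removes.
        """
        keys = self.site_union()
        idx = pd.MultiIndex.from_frame(keys)
        S, R = len(keys), self.n_replicates
        depth = np.zeros((S, R), dtype=np.int64)
        alt = np.zeros((S, R), dtype=np.int64)
        for r, tab in enumerate(self.tables):
            sub = tab.df.set_index(["contig", "pos", "strand"])
            loc = idx.get_indexer(sub.index)
            depth[loc, r] = sub["depth"].to_numpy()
            alt[loc, r] = sub["alt"].to_numpy()
        return keys, depth, alt


@dataclass(frozen=True)
class FilterConfig:
    """Filtering-cascade parameters (defaults are the published pipeline's)."""

    min_depth: int = 15
    max_freq: float = 0.95
    consensus_k: int = 3
    consensus_n: int = 4
    window_bp: int = 75
    mask: MaskSet = field(default_factory=MaskSet)

    def __post_init__(self) -> None:
        if not 0 < self.max_freq <= 1:
            raise ValueError("max_freq must be in (0, 1]")
        if not 0 <= self.consensus_k <= self.consensus_n:
            raise ValueError("need 0 <= consensus_k <= consensus_n")
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")


@dataclass(frozen=True)
class FrequencyTrack:
    """Mean transition frequency per surviving site.

    ``df`` columns: contig, pos, strand, mean_freq (mean of alt/depth over all
    replicates, zeros included), n_replicates_with_alt.
    """

    df: pd.DataFrame
    n_replicates: int = 4

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        out = self.df.copy()
        out["pos"] = out["pos"] + 1  # 1-based on disk
        out["mean_freq"] = out["mean_freq"].map(lambda v: f"{v:.6g}")
        _write_tsv(out, path, header_lines)

    def to_bedgraph(self, path: str | Path) -> None:
        bg = pd.DataFrame(
            {
                "chrom": self.df["contig"],
                "start": self.df["pos"],
                "end": self.df["pos"] + 1,
                "value": self.df["mean_freq"].map(lambda v: f"{v:.6g}"),
            }
        )
        bg.to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class SmoothedTrack:
    """Moving-average track defined at every surviving site position."""

    df: pd.DataFrame  # contig, pos, smoothed
    window_bp: int = 75

    def __len__(self) -> int:
        return len(self.df)

    def to_bedgraph(self, path: str | Path) -> None:
        bg = pd.DataFrame(
            {
                "chrom": self.df["contig"],
                "start": self.df["pos"],
                "end": self.df["pos"] + 1,
                "value": self.df["smoothed"].map(lambda v: f"{v:.6g}"),
            }
        )
        bg.to_csv(path, sep="\t", header=False, index=False)


def _write_tsv(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts(path: str | Path) -> list[SiteCountTable]:
    """Read a counts TSV (columns contig, pos, strand, depth, alt, replicate).

    Positions on disk are 1-based and converted to 0-based.  One file may hold
    several replicates; one table per replicate is returned, in order of first
    appearance.  Malformed rows raise with the offending (1-based, post-header)
    line number.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["contig", "pos", "strand", "depth", "alt", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df):
        bad = df.index[df["alt"] > df["depth"]]
        if len(bad):
            raise ValueError(f"{path}: alt > depth at data line {bad[0] + 1}")
        bad = df.index[~df["strand"].isin(["+", "-"])]
        if len(bad):
            raise ValueError(
                f"{path}: unknown strand {df.loc[bad[0], 'strand']!r} "
                f"at data line {bad[0] + 1}"
            )
        if (df["pos"] < 1).any():
            raise ValueError(f"{path}: positions must be 1-based and >= 1")
    df = df.assign(pos=df["pos"] - 1)
    tables = []
    for rid in df["replicate"].drop_duplicates():
        sub = df[df["replicate"] == rid][_COUNT_COLS].reset_index(drop=True)
        tables.append(SiteCountTable(str(rid), sub))
    return tables


def write_counts(reps: ReplicateSet, path: str | Path,
                 header_lines: list[str] | None = None) -> None:
    """Write a :class:`ReplicateSet` as a single 1-based counts TSV."""
    frames = []
    for tab in reps.tables:
        out = tab.df.copy()
        out["pos"] = out["pos"] + 1
        out["replicate"] = tab.replicate_id
        frames.append(out)
    _write_tsv(pd.concat(frames, ignore_index=True), path, header_lines)


def site_filters(reps: ReplicateSet, cfg: FilterConfig) -> ReplicateSet:
    """Apply the depth / frequency-cap / mask filters jointly across replicates.

    A site is dropped from *all* replicates if any replicate has depth below
    ``min_depth``, any replicate's alt/depth exceeds ``max_freq``, or the
    position lies in the mask.  Under these all-or-nothing semantics the
    order of the three rules is irrelevant.
    """
    keys, depth, alt = reps.wide()
    keep = (depth >= cfg.min_depth).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    keep &= (freq <= cfg.max_freq).all(axis=1)
    if len(cfg.mask):
        masked = np.zeros(len(keys), dtype=bool)
        for cid, start, end in cfg.mask.intervals:
            masked |= (
                (keys["contig"] == cid)
                & (keys["pos"] >= start)
                & (keys["pos"] < end)
            ).to_numpy()
        keep &= ~masked
    kept_keys = keys[keep]
    idx = pd.MultiIndex.from_frame(kept_keys)
    tables = []
    for tab in reps.tables:
        sub = tab.df.set_index(["contig", "pos", "strand"])
        sub = sub.loc[sub.index.isin(idx)].reset_index()
        tables.append(SiteCountTable(tab.replicate_id, sub[_COUNT_COLS]))
    return replace(reps, tables=tuple(tables))


def replicate_consensus_mean(reps: ReplicateSet, cfg: FilterConfig) -> FrequencyTrack:
    """Replicate-consensus filter and per-site mean transition frequency.

    Retains sites where at least ``consensus_k`` of ``consensus_n`` replicates
    show >= 1 mutant read (an integer alt-count test, not a frequency test);
    the reported frequency is the mean of alt/depth over *all* replicates,
    zeros included.  With ``consensus_k = 0`` this degenerates to the plain
    per-site mean.
    """
    if reps.n_replicates != cfg.consensus_n:
        raise ValueError(
            f"consensus_n={cfg.consensus_n} but {reps.n_replicates} replicate "
            "tables supplied"
        )
    keys, depth, alt = reps.wide()
    if np.any(depth == 0):
        # mean alt/depth is undefined at zero depth; run site_filters first
        raise ValueError("zero-depth entries present; apply site_filters first")
    n_with_alt = (alt >= 1).sum(axis=1)
    keep = n_with_alt >= cfg.consensus_k
    freq = (alt / depth).mean(axis=1)
    df = keys[keep].reset_index(drop=True)
    df = df.assign(mean_freq=freq[keep], n_replicates_with_alt=n_with_alt[keep])
    return FrequencyTrack(df, n_replicates=reps.n_replicates)


def window_mean(pos: np.ndarray, values: np.ndarray, half_width: int) -> np.ndarray:
    """Centered inclusive window mean over irregularly spaced positions.

    At each position p the result is the unweighted mean of ``values`` at
    positions q with ``|q - p| <= half_width``.  ``pos`` must be sorted.
    """
    pos = np.asarray(pos)
    values = np.asarray(values, dtype=float)
    cs = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.searchsorted(pos, pos - half_width, side="left")
    hi = np.searchsorted(pos, pos + half_width, side="right")
    return (cs[hi] - cs[lo]) / (hi - lo)


def moving_average(track: FrequencyTrack, window_bp: int = 75,
                   denominator: str = "sites") -> SmoothedTrack:
    """Centered moving average of the frequency track over surviving sites.

    The window is inclusive with half-width floor(window_bp/2).  With the
    default ``denominator='sites'`` the value is the mean over retained TC
    sites inside the window, so positions removed by filtering do not
    contribute zeros.  ``denominator='genome'`` divides the window sum by the
    full window width in bp instead, i.e. every genomic position (site or
    not) implicitly contributes zero — the alternative smoothing convention.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if denominator not in ("sites", "genome"):
        raise ValueError(f"unknown denominator {denominator!r}")
    half = window_bp // 2
    pieces = []
    for cid, sub in track.df.groupby("contig", sort=False):
        sub = sub.sort_values("pos", kind="stable")
        pos = sub["pos"].to_numpy()
        vals = sub["mean_freq"].to_numpy()
        if denominator == "sites":
            sm = window_mean(pos, vals, half)
        else:
            cs = np.concatenate([[0.0], np.cumsum(vals)])
            lo = np.searchsorted(pos, pos - half, side="left")
            hi = np.searchsorted(pos, pos + half, side="right")
            sm = (cs[hi] - cs[lo]) / (2 * half + 1)
        pieces.append(pd.DataFrame({"contig": cid, "pos": pos, "smoothed": sm}))
    if pieces:
        df = pd.concat(pieces, ignore_index=True)
    else:
        df = pd.DataFrame({"contig": pd.Series(dtype=str),
                           "pos": pd.Series(dtype=np.int64),
                           "smoothed": pd.Series(dtype=float)})
    return SmoothedTrack(df, window_bp=window_bp)
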