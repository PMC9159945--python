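"""Reference-genome handling and enumeration of deamination-eligible TC sites.

DddA, the double-stranded-DNA cytosine deaminase used for deaminase
footprinting, strongly prefers cytosines preceded by thymidine (5'-TC-3').
Only these positions are scored by the rest of the pipeline.  On the forward
reference a (+) site is the C of a TC dinucleotide; a (-) site is the
forward-strand G of a GA dinucleotide (i.e. the TC context on the reverse
strand).  Coordinates are 0-based internally; BED I/O follows the BED
convention (0-based half-open), while TSV outputs elsewhere are 1-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeIndex",
    "MaskSet",
    "TCSiteSet",
    "load_genome",
    "enumerate_tc_sites",
    "mean_tc_spacing",
]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered collection of contig sequences (uppercase, alphabet ACGTN)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"contig {cid!r} contains invalid characters: {sorted(bad)}"
                )

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def contig_ids(self) -> list[str]:
        return list(self.contigs)


@dataclass(frozen=True)
class MaskSet:
    """Genomic intervals to exclude, 0-based half-open; overlaps are unioned."""

    intervals: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        for cid, start, end in self.intervals:
            if not start < end:
                raise ValueError(f"mask interval on {cid}: start {start} >= end {end}")

    @classmethod
    def from_bed(cls, path: str | Path) -> "MaskSet":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: BED needs >=3 columns")
                rows.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(tuple(rows))

    def bool_mask(self, contig: str, length: int) -> np.ndarray:
        """Boolean array of masked positions for one contig."""
        m = np.zeros(length, dtype=bool)
        for cid, start, end in self.intervals:
            if cid == contig:
                m[max(start, 0) : min(end, length)] = True
        return m

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class TCSiteSet:
    """All unmasked TC-context positions of a genome, both strands.

    ``df`` has columns ``contig`` (str), ``pos`` (0-based int, anchored at the
    deaminated base's forward-strand coordinate) and ``strand`` ('+'/'-'),
    sorted by (contig, pos, strand).
    """

    df: pd.DataFrame
    counts_by_contig: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def for_contig(self, contig: str) -> pd.DataFrame:
        return self.df[self.df["contig"] == contig]

    def key_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.df[["contig", "pos", "strand"]])

    def to_bed(self, path: str | Path) -> None:
        """Write sites as 6-column BED (strand in column 6)."""
        out = pd.DataFrame(
            {
                "chrom": self.df["contig"],
                "start": self.df["pos"],
                "end": self.df["pos"] + 1,
                "name": "TC",
                "score": 0,
                "strand": self.df["strand"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


def load_genome(path: str | Path | io.TextIOBase) -> GenomeIndex:
    """Parse a (multi-record) FASTA into a :class:`GenomeIndex`.

    Lowercase is normalized to uppercase; any character outside {A,C,G,T,N}
    raises a :class:`ValueError` naming the offending record.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    contigs: dict[str, str] = {}
    for rec in records:
        if rec.id in contigs:
            raise ValueError(f"duplicate contig id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"contig {rec.id!r} contains invalid characters: {sorted(bad)}"
            )
        contigs[rec.id] = seq
    return GenomeIndex(contigs)


def _scan_contig(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized dinucleotide scan; returns (+) and (-) site positions."""
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    T, C, G, A = (ord(x) for x in "TCGA")
    # (+): T at p-1, C at p -> anchored at the C
    plus = np.flatnonzero((a[:-1] == T) & (a[1:] == C)) + 1
    # (-): G at p, A at p+1 (reverse-strand TC) -> anchored at the G
    minus = np.flatnonzero((a[:-1] == G) & (a[1:] == A))
    return plus, minus


def enumerate_tc_sites(genome: GenomeIndex, mask: MaskSet | None = None) -> TCSiteSet:
    """Enumerate every 5'-TC-3' site on both strands, excluding masked positions.

    Contexts containing N never match (the scan requires exact T/C or G/A),
    so N-adjacent positions are excluded automatically.
    """
    if mask is not None:
        unknown = {cid for cid, _, _ in mask.intervals} - set(genome.contigs)
        if unknown:
            raise ValueError(f"mask refers to unknown contigs: {sorted(unknown)}")
    frames = []
    counts: dict[str, int] = {}
    for cid, seq in genome.contigs.items():
        if len(seq) < 2:
            counts[cid] = 0
            continue
        plus, minus = _scan_contig(seq)
        if mask is not None and len(mask):
            m = mask.bool_mask(cid, len(seq))
            plus = plus[~m[plus]]
            minus = minus[~m[minus]]
        df = pd.DataFrame(
            {
                "contig": cid,
                "pos": np.concatenate([plus, minus]),
                "strand": ["+"] * len(plus) + ["-"] * len(minus),
            }
        )
        counts[cid] = len(df)
        frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
        out = out.sort_values(["contig", "pos", "strand"], kind="stable").reset_index(
            drop=True
        )
    else:
        out = pd.DataFrame({"contig": pd.Series(dtype=str),
                            "pos": pd.Series(dtype=np.int64),
                            "strand": pd.Series(dtype=str)})
    return TCSiteSet(out, counts)


def mean_tc_spacing(sites: TCSiteSet, genome: GenomeIndex) -> float:
    """Average genomic spacing between scoreable sites: total bp / site count.

    This is the quantity that bounds the method's mapping resolution: a
    binding footprint can only be localized to the nearest scoreable cytosine.
    """
    n = len(sites)
    if n == 0:
        raise ValueError("site set is empty; spacing undefined")
    return genome.total_length / n
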