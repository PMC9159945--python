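"""Single-cell clone analysis: per-clone fixed-SNP tallies and the Poisson
goodness-of-fit test.

After restoring deaminase immunity and outgrowing single clones, each clone's
genome carries a fixed record of the fusion protein's activity in its founder
cell: the number of TC-to-TT SNPs inside the target window.  If activity were
homogeneous across cells, these counts would be approximately Poisson; a
heavy-tailed departure indicates cell-to-cell heterogeneity.  The comparison
uses the Kolmogorov-Smirnov distance between the empirical count distribution
and Poisson(lambda-hat).  Because lambda is estimated from the same data and
the distribution is discrete, the classical K-S p-value is only approximate;
the default is therefore a Lilliefors-style parametric bootstrap in which
lambda is re-estimated within every bootstrap sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CloneSNPTable",
    "PoissonTestResult",
    "tally_clone_snps",
    "clone_calls_from_fasta",
    "clone_calls_from_vcf",
    "poisson_ks_test",
    "poisson_ks_distance",
]


@dataclass(frozen=True)
class CloneSNPTable:
    """Per-clone fixed-SNP counts within a target window.

    ``df`` columns: clone_id, snp_count; optional per-clone position lists in
    ``snp_positions``; ``n_ignored_variants`` counts calls that were discarded
    for not being TC-context transitions.
    """

    df: pd.DataFrame
    window: tuple[str, int, int]
    snp_positions: dict[str, tuple[int, ...]] = field(default_factory=dict)
    n_ignored_variants: int = 0
    excluded_clones: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        cid, start, end = self.window
        if end <= start:
            raise ValueError(f"empty window {cid}:{start}-{end}")
        if (self.df["snp_count"] < 0).any():
            raise ValueError("negative SNP counts")
        for clone, positions in self.snp_positions.items():
            row = self.df.loc[self.df["clone_id"] == clone, "snp_count"]
            if len(row) and int(row.iloc[0]) != len(positions):
                raise ValueError(f"count/position mismatch for clone {clone!r}")

    @property
    def counts(self) -> np.ndarray:
        return self.df["snp_count"].to_numpy()

    @property
    def n_clones(self) -> int:
        return len(self.df)

    def histogram(self) -> pd.DataFrame:
        """SNP-count histogram (one row per count value, as in a clone-summary
        bar chart)."""
        k = self.counts
        vals, n = np.unique(k, return_counts=True)
        return pd.DataFrame({"snp_count": vals, "n_clones": n})

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PoissonTestResult:
    lam: float  # sample-mean estimate of the Poisson rate
    D: float  # K-S sup distance
    p_value: float
    n_clones: int
    method: str  # parametric_bootstrap | plugin

    def __post_init__(self) -> None:
        if not 0 <= self.D <= 1:
            raise ValueError("D must be in [0, 1]")


def _window_tc_index(sites, window):
    cid, start, end = window
    df = sites.df
    sel = (df["contig"] == cid) & (df["pos"] >= start) & (df["pos"] < end)
    sub = df[sel]
    return {(p, s) for p, s in zip(sub["pos"], sub["strand"])}


def tally_clone_snps(
    clone_calls: pd.DataFrame,
    window: tuple[str, int, int],
    sites,
    clone_ids: list[str] | None = None,
    uncovered: set[str] | None = None,
) -> CloneSNPTable:
    """Count qualifying fixed SNPs per clone inside the window.

    ``clone_calls`` columns: clone_id, contig, pos (0-based), ref, alt.  Only
    C->T calls at (+) TC sites and G->A calls at (-) TC sites inside the
    window count; everything else increments the ignored-variant counter.
    ``clone_ids`` fixes the clone universe (clones without calls score 0);
    clones in ``uncovered`` are flagged and excluded from the table.
    """
    cid, start, end = window
    tc = _window_tc_index(sites, window)
    if clone_ids is None:
        clone_ids = list(pd.unique(clone_calls["clone_id"]))
    uncovered = uncovered or set()
    counts: dict[str, int] = {c: 0 for c in clone_ids if c not in uncovered}
    positions: dict[str, list[int]] = {c: [] for c in counts}
    ignored = 0
    for row in clone_calls.itertuples(index=False):
        if row.clone_id in uncovered or row.clone_id not in counts:
            continue
        if row.contig != cid or not (start <= row.pos < end):
            ignored += 1
            continue
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if ref == "C" and alt == "T" and (row.pos, "+") in tc:
            counts[row.clone_id] += 1
            positions[row.clone_id].append(int(row.pos))
        elif ref == "G" and alt == "A" and (row.pos, "-") in tc:
            counts[row.clone_id] += 1
            positions[row.clone_id].append(int(row.pos))
        else:
            ignored += 1
    df = pd.DataFrame(
        {"clone_id": list(counts), "snp_count": [counts[c] for c in counts]}
    )
    return CloneSNPTable(
        df, window=window,
        snp_positions={c: tuple(v) for c, v in positions.items()},
        n_ignored_variants=ignored,
        excluded_clones=tuple(sorted(uncovered & set(clone_ids))),
    )


def clone_calls_from_fasta(path: str | Path, reference_window_seq: str,
                           window: tuple[str, int, int]) -> pd.DataFrame:
    """Derive per-clone variant calls from clone sequences aligned to the
    window (simple column-wise exact comparison; no indels).

    Every record in the FASTA is one clone; each must have exactly the window
    length.  Returns a calls frame suitable for :func:`tally_clone_snps`; the
    full clone universe (including variant-free clones) is recorded in
    ``df.attrs['clone_ids']``.
    """
    from Bio import SeqIO

    cid, start, end = window
    ref = reference_window_seq.upper()
    if len(ref) != end - start:
        raise ValueError("reference_window_seq length does not match window")
    rows = []
    clone_ids = []
    for rec in SeqIO.parse(str(path), "fasta"):
        clone_ids.append(rec.id)
        seq = str(rec.seq).upper()
        if len(seq) != len(ref):
            raise ValueError(
                f"clone {rec.id!r} length {len(seq)} != window length {len(ref)}"
            )
        for i, (a, b) in enumerate(zip(ref, seq)):
            if a != b:
                rows.append(
                    {"clone_id": rec.id, "contig": cid, "pos": start + i,
                     "ref": a, "alt": b}
                )
    df = pd.DataFrame(rows, columns=["clone_id", "contig", "pos", "ref", "alt"])
    df.attrs["clone_ids"] = clone_ids
    return df


def clone_calls_from_vcf(path: str | Path) -> pd.DataFrame:
    """Fixed per-clone SNV calls from a (multi-sample) VCF.

    Each sample column is one clone; a call counts as fixed when every
    called allele of the genotype is the first ALT.  Multi-allelic records
    contribute only that first ALT; non-SNV alleles are skipped.  The clone
    universe (all samples) is recorded in ``df.attrs['clone_ids']``.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        clone_ids = list(vf.header.samples)
        if not clone_ids:
            raise ValueError(f"{path}: VCF has no sample columns")
        for rec in vf:
            if not rec.alts:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            for clone in clone_ids:
                gt = rec.samples[clone].get("GT")
                alleles = [a for a in (gt or ()) if a is not None]
                if alleles and all(a == 1 for a in alleles):
                    rows.append(
                        {"clone_id": clone, "contig": rec.chrom,
                         "pos": rec.pos - 1, "ref": ref, "alt": alt}
                    )
    df = pd.DataFrame(rows, columns=["clone_id", "contig", "pos", "ref", "alt"])
    df.attrs["clone_ids"] = clone_ids
    return df


def poisson_ks_distance(counts: np.ndarray, lam: float) -> float:
    """Sup distance between the empirical CDF of integer counts and the
    Poisson(lam) CDF, evaluated over the support 0..max(count)+1.

    Both CDFs are right-continuous step functions jumping only at integers,
    so the supremum over the real line is attained at an integer.
    """
    counts = np.asarray(counts)
    kmax = int(counts.max()) + 1
    ecdf = np.cumsum(np.bincount(counts, minlength=kmax + 1)) / counts.size
    pcdf = stats.poisson.cdf(np.arange(kmax + 1), lam)
    return float(np.abs(ecdf - pcdf).max())


def poisson_ks_test(
    table: CloneSNPTable | np.ndarray,
    bootstrap_B: int = 999,
    seed: int = 0,
    method: str = "parametric_bootstrap",
) -> PoissonTestResult:
    """Test clone SNP counts against a Poisson distribution via K-S distance.

    ``parametric_bootstrap`` (default) draws ``bootstrap_B`` samples of the
    same size from Poisson(lambda-hat), re-estimates lambda in each, and
    reports the +1-corrected tail probability of the observed distance —
    the appropriate null when the rate is estimated from the data.
    ``plugin`` reports the classical one-sample K-S p-value, which is
    approximate for discrete data and an estimated rate.
    """
    counts = table.counts if isinstance(table, CloneSNPTable) else np.asarray(table)
    n = counts.size
    if n < 2:
        raise ValueError("need at least 2 clones")
    lam = float(counts.mean())
    if lam == 0:
        warnings.warn("all clone counts are zero; Poisson test degenerate")
        return PoissonTestResult(0.0, 0.0, 1.0, n, method)
    D = poisson_ks_distance(counts, lam)
    if method == "plugin":
        p = float(stats.kstest(counts, stats.poisson(lam).cdf).pvalue)
    elif method == "parametric_bootstrap":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(bootstrap_B):
            boot = rng.poisson(lam, size=n)
            lam_b = boot.mean()
            if lam_b == 0:
                d_b = 0.0
            else:
                d_b = poisson_ks_distance(boot, lam_b)
            if d_b >= D:
                hits += 1
        p = (1 + hits) / (bootstrap_B + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PoissonTestResult(lam, D, p, n, method)
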