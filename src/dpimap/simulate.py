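"""Synthetic-data generator: genomes, planted-peak count tables, clones.

This is the fixture source for the rest of the package.  It emulates the
data-generating process of a deaminase-footprinting experiment:

* a random i.i.d. genome with a chosen GC fraction (default 0.66, matching a
  high-GC bacterium such as *P. aeruginosa*);
* at every TC site, per replicate, a sequencing depth drawn from a Poisson
  (optionally negative-binomial) model and a transition count drawn from
  ``Binomial(depth, p_i)``, where p_i is a uniform background rate plus
  Gaussian bumps at planted DNA-protein interaction sites;
* clonal populations for the single-cell mode: each clone receives an
  exposure e (integrated deaminase activity over the outgrowth), and each TC
  site in the target window mutates independently with probability
  ``1 - exp(-e)``, so homogeneous exposure yields approximately Poisson
  per-clone totals — exactly the null the single-cell test assumes.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import ReplicateSet, SiteCountTable
from .genome import GenomeIndex, TCSiteSet, enumerate_tc_sites
from .singlecell import CloneSNPTable

__all__ = [
    "PeakSpec",
    "ExposureModel",
    "SimConfig",
    "SimTruth",
    "simulate_genome",
    "simulate_counts",
    "simulate_clones",
]


@dataclass(frozen=True)
class PeakSpec:
    mu: float
    A: float
    sigma: float


@dataclass(frozen=True)
class ExposureModel:
    """Per-clone exposure distribution.

    kind 'constant': every clone gets ``value`` (the homogeneous-activity
    null).  kind 'mixture': exposure is one of ``values`` with probabilities
    ``weights`` (heterogeneous activity, heavy-tailed totals).
    kind 'gamma': Gamma(shape, scale) exposures (continuous heterogeneity).
    """

    kind: str = "constant"
    value: float = 0.05
    weights: tuple[float, ...] = ()
    values: tuple[float, ...] = ()
    shape: float = 1.0
    scale: float = 1.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, self.value)
        if self.kind == "mixture":
            w = np.asarray(self.weights, dtype=float)
            comp = rng.choice(len(w), size=n, p=w / w.sum())
            return np.asarray(self.values, dtype=float)[comp]
        if self.kind == "gamma":
            return rng.gamma(self.shape, self.scale, size=n)
        raise ValueError(f"unknown exposure kind {self.kind!r}")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults reflect the experimental design the package targets: quadruplicate
    whole-genome sequencing at ~100-fold depth of a high-GC bacterium, with a
    low uniform background deamination rate and, optionally, localized peaks.
    """

    length: int = 10_000
    gc: float = 0.66
    background: float = 0.005
    peaks: tuple[PeakSpec, ...] = ()
    mean_depth: float = 100.0
    nb_dispersion: float | None = None  # None -> Poisson depths
    n_replicates: int = 4
    n_clones: int = 369
    exposure: ExposureModel = field(default_factory=ExposureModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background <= 1:
            raise ValueError("background rate must be in [0, 1]")
        for pk in self.peaks:
            if not 0 <= pk.A <= 1:
                raise ValueError("peak amplitude must be in [0, 1]")


@dataclass(frozen=True)
class SimTruth:
    """Exactly what was generated: the answer key for recovery tests."""

    background: float
    peaks: tuple[PeakSpec, ...]
    site_pos: np.ndarray
    site_p: np.ndarray
    clone_exposure: np.ndarray | None = None

    def to_json_dict(self) -> dict:
        d = {
            "background": self.background,
            "peaks": [{"mu": p.mu, "A": p.A, "sigma": p.sigma} for p in self.peaks],
            "n_sites": int(len(self.site_pos)),
        }
        if self.clone_exposure is not None:
            d["clone_exposure"] = [float(e) for e in self.clone_exposure]
        return d


def simulate_genome(length: int, gc: float,
                    seed: int | np.random.Generator = 0,
                    contig_id: str = "sim") -> GenomeIndex:
    """Random i.i.d. genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
    return GenomeIndex({contig_id: bases.tobytes().decode("ascii")})


def _site_probs(pos: np.ndarray, cfg: SimConfig) -> np.ndarray:
    p = np.full(len(pos), cfg.background, dtype=float)
    for pk in cfg.peaks:
        z = (pos - pk.mu) / pk.sigma
        p += pk.A * np.exp(-0.5 * z * z)
    return np.clip(p, 0.0, 1.0)


def simulate_counts(
    genome: GenomeIndex, cfg: SimConfig,
    sites: TCSiteSet | None = None,
) -> tuple[ReplicateSet, SimTruth]:
    """Replicate count tables over the genome's TC sites with planted peaks.

    Depths are Poisson(mean_depth) (or negative binomial when
    ``nb_dispersion`` is set, parameterized so the variance is
    ``m + m^2/dispersion``); transition counts are Binomial(depth, p_i).
    """
    rng = np.random.default_rng(cfg.seed)
    if sites is None:
        sites = enumerate_tc_sites(genome)
    span = genome.total_length
    for pk in cfg.peaks:
        if not 0 <= pk.mu < span:
            raise ValueError(f"peak center {pk.mu} outside genome span {span}")
    df = sites.df
    pos = df["pos"].to_numpy()
    p = _site_probs(pos, cfg)
    tables = []
    S = len(df)
    for r in range(cfg.n_replicates):
        if cfg.nb_dispersion is None:
            depth = rng.poisson(cfg.mean_depth, size=S)
        else:
            k = cfg.nb_dispersion
            depth = rng.negative_binomial(k, k / (k + cfg.mean_depth), size=S)
        alt = rng.binomial(depth, p)
        tables.append(
            SiteCountTable(
                f"r{r + 1}",
                pd.DataFrame(
                    {"contig": df["contig"].to_numpy(), "pos": pos,
                     "strand": df["strand"].to_numpy(),
                     "depth": depth, "alt": alt}
                ),
            )
        )
    truth = SimTruth(cfg.background, cfg.peaks, pos.copy(), p)
    return ReplicateSet(tuple(tables), condition="simulated"), truth


def simulate_clones(
    n_window_sites: int, cfg: SimConfig,
    window: tuple[str, int, int] | None = None,
) -> tuple[CloneSNPTable, SimTruth]:
    """Per-clone fixed-SNP counts for a target window with ``n_window_sites``
    TC sites, under the configured exposure model."""
    if n_window_sites < 1:
        raise ValueError("window must contain at least one TC site")
    if window is None:
        # nominal window metadata: one site per ~9 bp of amplicon
        window = ("sim", 0, 9 * n_window_sites)
    rng = np.random.default_rng(cfg.seed)
    e = cfg.exposure.draw(cfg.n_clones, rng)
    p_mut = -np.expm1(-e)  # 1 - exp(-e)
    counts = rng.binomial(n_window_sites, p_mut)
    df = pd.DataFrame(
        {"clone_id": [f"clone{i + 1}" for i in range(cfg.n_clones)],
         "snp_count": counts}
    )
    truth = SimTruth(cfg.background, cfg.peaks, np.empty(0, dtype=np.int64),
                     np.empty(0), clone_exposure=e)
    return CloneSNPTable(df, window=window), truth


def write_fixture_bundle(genome: GenomeIndex, reps: ReplicateSet, truth: SimTruth,
                         outdir: str | Path, prefix: str = "sim") -> dict[str, Path]:
    """Emit genome FASTA, counts TSV and truth JSON consumable by the rest of
    the pipeline unchanged."""
    import json

    from .counts import write_counts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{prefix}.fa",
        "counts": outdir / f"{prefix}.counts.tsv",
        "truth": outdir / f"{prefix}.truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    write_counts(reps, paths["counts"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
    return paths
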