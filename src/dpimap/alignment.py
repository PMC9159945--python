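"""Optional adapter: tabulate TC-site base counts from sorted alignments.

Thin wrapper around :func:`pysam.AlignmentFile.count_coverage` (read_callback
``'all'``, base quality threshold 20 by default).  Depth at a site is the
number of quality-passing base calls; the alt count is T calls at (+) sites
and A calls at (-) sites.  Read preprocessing, deduplication and alignment
are upstream of this package.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .counts import SiteCountTable
from .genome import TCSiteSet

__all__ = ["counts_from_alignment"]


def counts_from_alignment(
    path: str | Path,
    sites: TCSiteSet,
    base_quality_min: int = 20,
    replicate_id: str | None = None,
) -> SiteCountTable:
    """Count depth and transition bases at TC sites from a SAM/BAM/CRAM file.

    The alignment must be coordinate-sorted and indexed against the same
    reference the sites were enumerated from; contigs present in the site set
    but absent from the alignment header raise a :class:`ValueError`.
    """
    path = str(path)
    frames = []
    with pysam.AlignmentFile(path) as af:
        have = set(af.references)
        need = set(sites.df["contig"].unique())
        missing = sorted(need - have)
        if missing:
            raise ValueError(f"alignment lacks contigs {missing}")
        for cid in sorted(need):
            sub = sites.for_contig(cid)
            length = af.get_reference_length(cid)
            cov = af.count_coverage(
                cid, 0, length, quality_threshold=base_quality_min,
                read_callback="all",
            )
            acgt = np.asarray(cov, dtype=np.int64)  # rows: A, C, G, T
            pos = sub["pos"].to_numpy()
            depth = acgt[:, pos].sum(axis=0)
            t_calls = acgt[3, pos]
            a_calls = acgt[0, pos]
            alt = np.where(sub["strand"].to_numpy() == "+", t_calls, a_calls)
            frames.append(
                pd.DataFrame(
                    {"contig": cid, "pos": pos, "strand": sub["strand"].to_numpy(),
                     "depth": depth, "alt": alt}
                )
            )
    df = pd.concat(frames, ignore_index=True)
    rid = replicate_id if replicate_id is not None else Path(path).stem
    return SiteCountTable(rid, df)
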