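import numpy as np
import pandas as pd
import pytest

from dpimap.counts import ReplicateSet, SiteCountTable


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
    return path


@pytest.fixture
def fasta_factory(tmp_path):
    def _make(records, name="ref.fa"):
        return write_fasta(tmp_path / name, records)

    return _make


def build_reps(positions, depth, alt, contig="c1", strand="+", rep_prefix="r"):
    """ReplicateSet from per-site position list and (S, R) count matrices."""
    depth = np.atleast_2d(np.asarray(depth))
    alt = np.atleast_2d(np.asarray(alt))
    if depth.shape[0] == 1 and len(positions) > 1:
        depth = depth.T
        alt = alt.T
    strands = [strand] * len(positions) if isinstance(strand, str) else list(strand)
    tables = []
    for r in range(depth.shape[1]):
        tables.append(
            SiteCountTable(
                f"{rep_prefix}{r + 1}",
                pd.DataFrame(
                    {
                        "contig": contig,
                        "pos": list(positions),
                        "strand": strands,
                        "depth": depth[:, r],
                        "alt": alt[:, r],
                    }
                ),
            )
        )
    return ReplicateSet(tuple(tables))


@pytest.fixture
def reps_factory():
    return build_reps
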