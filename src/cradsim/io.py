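"""OTU-table I/O and synthetic fixture tables.

Tables are plain TSV: first column the OTU identifier, one column of
integer counts per sample, with a header row of sample names.  Lines
starting with ``#`` are metadata (parameters, seed, tool version) and are
ignored on read, so every file the package writes can be re-read and
re-run from its own header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import powerlaw_abundance_profile

__all__ = ["OTUTable", "read_otu_table", "write_otu_table", "generate_fixture_table"]


@dataclass
class OTUTable:
    """An OTU count table: ``counts[i, j]`` is the reads of OTU ``j``
    in sample ``i``."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_samples, n_otus) non-negative integers

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        """OTUs as rows, samples as columns (the on-disk layout)."""
        return pd.DataFrame(
            self.counts.T, index=pd.Index(self.otu_ids, name="otu_id"),
            columns=self.sample_ids,
        )


def read_otu_table(path: str | Path) -> OTUTable:
    """Read a TSV OTU table (OTUs as rows, samples as columns).

    Raises on negative or non-integer counts (naming the offending OTU
    and sample) and on duplicate identifiers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an OTU-id column plus >= 1 sample column")
    otu_col = df.columns[0]
    otu_ids = df[otu_col].astype(str).tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    if len(set(otu_ids)) != len(otu_ids):
        dupes = sorted({o for o in otu_ids if otu_ids.count(o) > 1})
        raise ValueError(f"{path}: duplicate OTU ids {dupes}")
    counts = np.zeros((len(sample_ids), len(otu_ids)), dtype=np.int64)
    for j, sample in enumerate(sample_ids):
        col = df[df.columns[j + 1]]
        for i, raw in enumerate(col):
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-integer count {raw!r} at OTU {otu_ids[i]!r}, "
                    f"sample {sample!r}"
                ) from None
            if val < 0:
                raise ValueError(
                    f"{path}: negative count {val} at OTU {otu_ids[i]!r}, "
                    f"sample {sample!r}"
                )
            counts[j, i] = val
    return OTUTable(otu_ids=otu_ids, sample_ids=sample_ids, counts=counts)


def write_otu_table(
    table: OTUTable,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a TSV OTU table, with ``# key=value`` metadata lines first."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("otu_id\t" + "\t".join(table.sample_ids) + "\n")
        for j, otu in enumerate(table.otu_ids):
            row = "\t".join(str(int(c)) for c in table.counts[:, j])
            fh.write(f"{otu}\t{row}\n")


def generate_fixture_table(
    n_samples: int,
    n_species: int,
    beta: float,
    depth: int = 2500,
    seed: int | None = None,
) -> OTUTable:
    """Generate a synthetic OTU table from a power-law community.

    Every sample is an independent ``depth``-read multinomial draw from
    the power-law rank-abundance profile at exponent ``beta`` (see
    :func:`cradsim.diversity.powerlaw_abundance_profile`), emulating a
    rarefied 16S pipeline output for a community whose CRAD follows a
    power law.  Deterministic for a fixed seed.
    """
    if n_samples < 1 or n_species < 1 or depth < 1:
        raise ValueError("n_samples, n_species and depth must be positive")
    rng = np.random.default_rng(seed)
    p = powerlaw_abundance_profile(beta, n_species)
    counts = rng.multinomial(depth, p, size=n_samples).astype(np.int64)
    return OTUTable(
        otu_ids=[f"OTU{i + 1:04d}" for i in range(n_species)],
        sample_ids=[f"S{i + 1:03d}" for i in range(n_samples)],
        counts=counts,
    )
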