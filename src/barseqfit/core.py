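"""Shared data containers and sequence-encoding helpers.

The pipeline passes pandas DataFrames between stages; the dataclasses here
wrap the ones that carry extra structure (a count matrix with its read
ledger, a filter report, a cluster assignment) or fixed configuration (the
amplicon read layout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: byte values of the four bases, indexed by the 2-bit code used internally
BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
    _CODE_LUT[ord(chr(_b).lower())] = _i

LEDGER_COLUMNS = ["assigned", "unassigned_index", "unassigned_tag", "ambiguous_tag"]
#: ledger row that collects reads whose multiplex index matched no sample
UNASSIGNED_ROW = "(unassigned)"

CONDITIONS = ("t0", "basal", "glucose", "sorbitol")


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string as uint8 codes 0..3 (A,C,G,T)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    codes = _CODE_LUT[np.frombuffer(seq, dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError(f"non-ACGT character in sequence {seq!r}")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    """Decode uint8 codes 0..3 back to a DNA string."""
    return BASE_BYTES[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class ReadLayout:
    """Layout of a single-end Bar-seq amplicon read.

    The read starts with the 6-nt multiplex index, followed by the common
    primer flanking either the up-tag or the down-tag, then the 20-mer tag
    itself, then arbitrary filler out to ``read_length``.
    """

    index_offset: int = 0
    index_length: int = 6
    up_common_primer: str = "GATGTCCACGAGGTCTCT"
    down_common_primer: str = "CGGTGTCGGTCTCGTAG"
    tag_length: int = 20
    read_length: int = 50

    def __post_init__(self) -> None:
        if self.read_length < self.min_read_length:
            raise ValueError(
                f"read_length {self.read_length} shorter than required "
                f"{self.min_read_length} for index+primer+tag"
            )

    @property
    def primer_offset(self) -> int:
        return self.index_offset + self.index_length

    @property
    def up_tag_start(self) -> int:
        return self.primer_offset + len(self.up_common_primer)

    @property
    def down_tag_start(self) -> int:
        return self.primer_offset + len(self.down_common_primer)

    @property
    def min_read_length(self) -> int:
        return max(self.up_tag_start, self.down_tag_start) + self.tag_length


DEFAULT_LAYOUT = ReadLayout()


@dataclass
class CountMatrix:
    """Non-negative integer counts (tags or strains × samples) plus a read ledger.

    ``counts`` is indexed by tag_id or strain_id with one column per sample.
    ``ledger`` has one row per sample plus the ``(unassigned)`` row for reads
    whose multiplex index matched no sample; its columns are
    assigned / unassigned_index / unassigned_tag / ambiguous_tag.
    """

    counts: pd.DataFrame
    ledger: pd.DataFrame

    @property
    def library_size(self) -> pd.Series:
        """Total assigned reads per sample (column sums of ``counts``)."""
        return self.counts.sum(axis=0)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def validate(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        for s in self.counts.columns:
            if s in self.ledger.index and self.ledger.loc[s, "assigned"] != self.counts[s].sum():
                raise ValueError(f"ledger/assigned mismatch for sample {s}")

    @property
    def total_reads(self) -> int:
        return int(self.ledger[LEDGER_COLUMNS].values.sum())


@dataclass
class FilterReport:
    """Outcome of the low-abundance and unreliable-gene filters."""

    removed_low_abundance: set[str]
    removed_unreliable: set[str]
    overlap: set[str]
    retained: set[str]

    @property
    def removed(self) -> set[str]:
        return self.removed_low_abundance | self.removed_unreliable

    def summary(self) -> dict:
        return {
            "n_low_abundance": len(self.removed_low_abundance),
            "n_unreliable": len(self.removed_unreliable),
            "n_overlap": len(self.overlap),
            "n_removed": len(self.removed),
            "n_retained": len(self.retained),
        }


@dataclass
class ClusterAssignment:
    """Partition of strains into QT clusters plus the unclustered remainder.

    Clusters are listed in order of discovery (largest first at each QT
    round); ``diameters`` holds the realized max pairwise distance of each.
    """

    clusters: list[list[str]]
    unclustered: list[str]
    diameters: list[float] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> pd.Series:
        """Per-strain cluster id (1-based); 0 marks unclustered strains."""
        out = {}
        for k, members in enumerate(self.clusters, start=1):
            for s in members:
                out[s] = k
        for s in self.unclustered:
            out[s] = 0
        return pd.Series(out, name="cluster")


@dataclass
class DispersionEstimate:
    """Common negative-binomial dispersion and the likelihood at the optimum."""

    phi: float
    log_likelihood_at_max: float


@dataclass
class OverlapResult:
    """Venn overlap of two hit lists and its one-sided Fisher p-value."""

    n_a: int
    n_b: int
    n_intersection: int
    universe_size: int
    fisher_p: float

    @property
    def only_a(self) -> int:
        return self.n_a - self.n_intersection

    @property
    def only_b(self) -> int:
        return self.n_b - self.n_intersection

    @property
    def neither(self) -> int:
        return self.universe_size - self.n_a - self.n_b + self.n_intersection

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_intersection": self.n_intersection,
            "only_a": self.only_a,
            "only_b": self.only_b,
            "neither": self.neither,
            "universe_size": self.universe_size,
            "fisher_p": self.fisher_p,
        }
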