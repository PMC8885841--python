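"""Core domain containers shared across the pipeline stages.

Internal coordinates are 0-based half-open.  Tabular data (methylomes,
kinetic tables, calls, read sets) live in pandas DataFrames with fixed
column contracts documented on each container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MARK_4MC = "4mC"
MARK_6MA = "6mA"

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Gene:
    name: str
    contig: str
    start: int
    end: int
    strand: str
    #: coding exons, oriented by genome coordinate (sorted)
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int]]
    utr5: Optional[tuple[int, int]]
    utr3: Optional[tuple[int, int]]
    promoter: Optional[tuple[int, int]]
    is_te_gene: bool = False
    #: "high"/"low" baseline-expression class assigned by the simulator
    expression_class: str = "high"

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def exonic_length(self) -> int:
        spans = list(self.exons)
        if self.utr5:
            spans.append(self.utr5)
        if self.utr3:
            spans.append(self.utr3)
        return int(sum(e - s for s, e in spans))

    def exonic_spans(self) -> list[tuple[int, int]]:
        spans = list(self.exons)
        if self.utr5:
            spans.append(self.utr5)
        if self.utr3:
            spans.append(self.utr3)
        return sorted(spans)


@dataclass
class TECopy:
    name: str
    family: str
    consensus_length: int
    contig: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def integrity(self) -> float:
        return self.length / self.consensus_length

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class TandemRepeat:
    name: str
    contig: str
    start: int
    end: int
    unit_length: int


@dataclass
class AnnotatedGenome:
    contigs: dict[str, str]
    genes: list[Gene]
    te_copies: list[TECopy]
    tandem_repeats: list[TandemRepeat]

    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def base_at(self, contig: str, pos: int, strand: str = "+") -> str:
        base = self.contigs[contig][pos]
        return base if strand == "+" else base.translate(COMPLEMENT)

    def validate(self) -> None:
        lens = self.contig_lengths()
        for g in self.genes:
            if not (0 <= g.start < g.end <= lens[g.contig]):
                raise ValueError(f"gene {g.name} outside contig bounds")
            for s, e in g.exons + g.introns:
                if not (g.start <= s < e <= g.end):
                    raise ValueError(
                        f"gene {g.name} subfeature outside parent span")
        for t in self.te_copies:
            if not (0 <= t.start < t.end <= lens[t.contig]):
                raise ValueError(f"TE {t.name} outside contig bounds")
        for r in self.tandem_repeats:
            if not (0 <= r.start < r.end <= lens[r.contig]):
                raise ValueError(f"repeat {r.name} outside contig bounds")


#: TrueMethylome columns: contig, pos, strand, mark, fraction
METHYLOME_COLUMNS = ["contig", "pos", "strand", "mark", "fraction"]


def empty_methylome() -> pd.DataFrame:
    return pd.DataFrame({
        "contig": pd.Series(dtype=str),
        "pos": pd.Series(dtype=np.int64),
        "strand": pd.Series(dtype=str),
        "mark": pd.Series(dtype=str),
        "fraction": pd.Series(dtype=float),
    })


@dataclass
class KineticTable:
    """Per-site native kinetic observations plus an in-silico/sampled control.

    ``sites`` columns: contig, pos, strand, coverage, control_log_mu,
    control_sigma.  ``native_ipds[i]`` is the array of per-pass IPDs for row
    i; ``control_ipds[i]`` is None in "model" control mode.
    """

    sites: pd.DataFrame
    native_ipds: list[np.ndarray]
    control_ipds: list[Optional[np.ndarray]]

    def __post_init__(self) -> None:
        n = len(self.sites)
        if len(self.native_ipds) != n or len(self.control_ipds) != n:
            raise ValueError("IPD lists must match the site table length")

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class ReadSet:
    """Simulated alignments for one assay (stand-in for a mapped BAM)."""

    assay: str
    reads: pd.DataFrame  # columns: contig, start, end, strand

    @property
    def total_reads(self) -> int:
        return len(self.reads)

    def validate(self, contig_lengths: dict[str, int]) -> None:
        r = self.reads
        if len(r) == 0:
            return
        if (r["start"] >= r["end"]).any():
            raise ValueError(f"{self.assay}: read with start >= end")
        for contig, grp in r.groupby("contig"):
            L = contig_lengths[str(contig)]
            if (grp["start"] < 0).any() or (grp["end"] > L).any():
                raise ValueError(f"{self.assay}: read outside contig {contig}")


def empty_reads(assay: str) -> ReadSet:
    return ReadSet(assay, pd.DataFrame({
        "contig": pd.Series(dtype=str),
        "start": pd.Series(dtype=np.int64),
        "end": pd.Series(dtype=np.int64),
        "strand": pd.Series(dtype=str),
    }))
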