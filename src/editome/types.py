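"""Shared domain types for the editome pipeline.

Coordinate convention: every in-memory position is 0-based (intervals
half-open); on-disk TSV/VCF positions are 1-based and are converted at the
I/O boundary only (see :mod:`editome.io`).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

BASES = ("A", "C", "G", "T")

#: The 12 ordered substitution types, e.g. "A>G".
SUBSTITUTION_TYPES = tuple(
    f"{r}>{v}" for r in BASES for v in BASES if r != v
)

REGION_CLASSES = (
    "CDS",
    "UTR3",
    "UTR5",
    "ncRNA_exonic",
    "intronic",
    "ncRNA_intronic",
    "intergenic",
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "U": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class ReadBaseObservation:
    """One aligned read base at one genomic position.

    ``base_quality`` is interpreted as a BAQ-recalibrated phred quality
    supplied upstream; ``read_pos`` counts 1-based from the read's 5' end.
    Observations with ``obs_base == 'N'`` are ignored by all callers.
    """

    sample_id: str
    chrom: str
    pos0: int
    ref_base: str
    obs_base: str
    base_quality: int
    map_quality: int
    read_pos: int
    read_id: str

    def __post_init__(self) -> None:
        if self.pos0 < 0:
            raise ValueError(f"pos0 must be >= 0, got {self.pos0}")
        if self.ref_base not in BASES:
            raise ValueError(f"invalid ref_base {self.ref_base!r}")
        if self.obs_base not in BASES and self.obs_base != "N":
            raise ValueError(f"invalid obs_base {self.obs_base!r}")
        if self.base_quality < 0 or self.map_quality < 0:
            raise ValueError("qualities must be >= 0")
        if self.read_pos < 1:
            raise ValueError(f"read_pos must be >= 1, got {self.read_pos}")


@dataclass
class SiteColumn:
    """Aggregated qualified observations at one position."""

    chrom: str
    pos0: int
    ref_base: str
    depth: int
    base_counts: dict[str, int]
    variant_base: str | None = None

    def __post_init__(self) -> None:
        if self.depth != sum(self.base_counts.values()):
            raise ValueError("depth must equal sum of base_counts")


@dataclass
class EditingSite:
    """One called editing position.

    ``level`` is edited_reads / total_reads over qualified observations.
    ``subst_type`` is expressed on the reported strand: a genomic T>C inside
    a minus-strand gene is reported as A>G with strand '-'.
    """

    chrom: str
    pos0: int
    ref_base: str
    var_base: str
    strand: str = "."  # '+', '-' or '.' (unknown)
    subst_type: str = ""
    in_alu: bool = False
    region_class: str = "intergenic"
    gene_ids: list[str] = field(default_factory=list)
    edited_reads: int = 0
    total_reads: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.total_reads < 0 or self.edited_reads < 0:
            raise ValueError("read counts must be >= 0")
        if self.edited_reads > self.total_reads:
            raise ValueError("edited_reads must be <= total_reads")
        if not self.subst_type:
            self.subst_type = f"{self.ref_base}>{self.var_base}"
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")

    @property
    def level(self) -> float:
        return self.edited_reads / self.total_reads if self.total_reads else 0.0

    @property
    def key(self) -> tuple[str, int, str]:
        """Site identity used for joins: (chrom, pos0, var_base on genome)."""
        return (self.chrom, self.pos0, self.var_base)


@dataclass
class GeneModel:
    """Stranded exon/CDS/UTR structure of one gene.

    All interval lists are sorted, disjoint, 0-based half-open. For coding
    genes cds+utr5+utr3 is contained in exons; ncRNAs carry exons only.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        for name in ("exons", "cds", "utr5", "utr3"):
            ivs = getattr(self, name)
            for (s, e) in ivs:
                if s >= e:
                    raise ValueError(f"{self.gene_id}: empty {name} interval {(s, e)}")
            for (a, b), (c, d) in zip(ivs, ivs[1:]):
                if c < b:
                    raise ValueError(f"{self.gene_id}: {name} intervals overlap or unsorted")
        if self.biotype not in ("coding", "ncRNA"):
            raise ValueError(f"invalid biotype {self.biotype!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def in_intervals(self, pos0: int, which: str) -> bool:
        return any(s <= pos0 < e for s, e in getattr(self, which))


class IntervalSet:
    """Per-chromosome sorted disjoint intervals with O(log n) membership.

    Overlapping or adjacent input intervals are merged on construction.
    """

    def __init__(self, intervals: dict[str, list[tuple[int, int]]] | None = None,
                 label: str = "") -> None:
        self.label = label
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in (intervals or {}).items():
            self._add_chrom(chrom, ivs)

    def _add_chrom(self, chrom: str, ivs: list[tuple[int, int]]) -> None:
        merged: list[list[int]] = []
        for s, e in sorted(ivs):
            if s >= e:
                raise ValueError(f"empty interval ({s}, {e}) on {chrom}")
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self._starts[chrom] = [s for s, _ in merged]
        self._ends[chrom] = [e for _, e in merged]

    def __contains__(self, key: tuple[str, int]) -> bool:
        chrom, pos0 = key
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < self._ends[chrom][i]

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        return list(zip(self._starts.get(chrom, []), self._ends.get(chrom, [])))

    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def total_length(self) -> int:
        return sum(e - s for c in self._starts
                   for s, e in zip(self._starts[c], self._ends[c]))


@dataclass
class CallerParams:
    """Thresholds of the variant-calling filter cascade.

    Defaults: >=5 qualified reads with >=2 variant reads, BAQ >= 25,
    MAPQ >= 20; the first 6 read bases are excluded (random-hexamer
    priming artifacts); non-Alu sites additionally require level >= 0.1,
    distance > 4 bp from splice junctions, no homopolymer run >= 5 and
    absence from the genome-similarity mask.
    """

    min_depth: int = 5
    min_variant_reads: int = 2
    min_baq: int = 25
    min_mapq: int = 20
    hexamer_prefix_len: int = 6
    non_alu_min_freq: float = 0.1
    splice_flank_bp: int = 4
    homopolymer_min_run: int = 5
    min_dna_depth: int = 5
    max_dna_variant_reads: int = 0

    def __post_init__(self) -> None:
        for name in ("min_depth", "min_variant_reads", "min_baq", "min_mapq",
                     "hexamer_prefix_len", "splice_flank_bp",
                     "homopolymer_min_run", "min_dna_depth",
                     "max_dna_variant_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.non_alu_min_freq <= 1.0:
            raise ValueError("non_alu_min_freq must be in [0, 1]")


@dataclass
class SampleRecord:
    sample_id: str
    cell_type: str
    replicate_id: str
    path: str


@dataclass
class SampleSheet:
    rows: list[SampleRecord]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values must be unique")

    def by_cell_type(self, cell_type: str) -> list[SampleRecord]:
        return [r for r in self.rows if r.cell_type == cell_type]

    def __iter__(self):
        return iter(self.rows)
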