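"""Readers and writers for every on-disk format the pipeline touches.

This is the only module that converts between on-disk 1-based coordinates
(observation/site TSVs, VCF) and the 0-based half-open convention used in
memory. BED inputs are already 0-based half-open and pass through unchanged.
Every reader rejects malformed rows with a :class:`FormatError` naming the
offending line.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Iterator
from pathlib import Path

import pandas as pd

from .types import (
    BASES,
    EditingSite,
    GeneModel,
    IntervalSet,
    ReadBaseObservation,
    REGION_CLASSES,
    SampleRecord,
    SampleSheet,
)

OBS_COLUMNS = ["sample_id", "chrom", "pos", "ref", "base", "baq", "mapq",
               "read_pos", "read_id"]
SITE_COLUMNS = ["chrom", "pos", "ref", "var", "strand", "subst_type", "in_alu",
                "region_class", "gene_ids", "edited_reads", "total_reads",
                "level"]


class FormatError(ValueError):
    """A malformed row or record in an input file."""


# ---------------------------------------------------------------------------
# read-level observations
# ---------------------------------------------------------------------------

def read_observations(path: str | Path, sample_id: str | None = None
                      ) -> Iterator[ReadBaseObservation]:
    """Stream observations from a long-format TSV, validating each row.

    Rows must be sorted by (chrom, pos); the position column is 1-based on
    disk. If ``sample_id`` is given it overrides the file's column.
    """
    last: tuple[str, int] | None = None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != OBS_COLUMNS:
            raise FormatError(
                f"{path}: bad observation header {header}, expected {OBS_COLUMNS}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(OBS_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected "
                                  f"{len(OBS_COLUMNS)} columns, got {len(fields)}")
            try:
                obs = ReadBaseObservation(
                    sample_id=sample_id or fields[0],
                    chrom=fields[1],
                    pos0=int(fields[2]) - 1,
                    ref_base=fields[3],
                    obs_base=fields[4],
                    base_quality=int(fields[5]),
                    map_quality=int(fields[6]),
                    read_pos=int(fields[7]),
                    read_id=fields[8],
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            key = (obs.chrom, obs.pos0)
            if last is not None and key < last:
                raise FormatError(f"{path}:{lineno}: observations not sorted "
                                  f"by (chrom, pos)")
            last = key
            yield obs


def read_observations_frame(path: str | Path, sample_id: str | None = None
                            ) -> pd.DataFrame:
    """Vectorised observation reader returning the in-memory frame.

    Same validation semantics as :func:`read_observations` but checked
    column-wise; returns columns sample_id, chrom, pos0, ref, base, baq,
    mapq, read_pos, read_id.
    """
    df = pd.read_csv(path, sep="\t", dtype={
        "sample_id": str, "chrom": str, "ref": str, "base": str,
        "read_id": str})
    if list(df.columns) != OBS_COLUMNS:
        raise FormatError(f"{path}: bad observation header {list(df.columns)}")
    for col in ("pos", "baq", "mapq", "read_pos"):
        if not pd.api.types.is_integer_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise FormatError(f"{path}:{line}: non-integer value in '{col}'")
    bad = ~df["base"].isin(list(BASES) + ["N"])
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise FormatError(f"{path}:{line}: invalid base "
                          f"{df.loc[df.index[bad][0], 'base']!r}")
    bad = ~df["ref"].isin(BASES)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise FormatError(f"{path}:{line}: invalid ref base")
    if (df["pos"] < 1).any() or (df["read_pos"] < 1).any():
        raise FormatError(f"{path}: positions must be >= 1")
    if (df[["baq", "mapq"]] < 0).to_numpy().any():
        raise FormatError(f"{path}: negative quality")
    keys = pd.MultiIndex.from_frame(df[["chrom", "pos"]])
    if len(df) > 1 and not keys.is_monotonic_increasing:
        raise FormatError(f"{path}: observations not sorted by (chrom, pos)")
    out = df.rename(columns={"pos": "pos0"}).copy()
    out["pos0"] = out["pos0"] - 1
    if sample_id is not None:
        out["sample_id"] = sample_id
    return out


def write_observations(obs: Iterable[ReadBaseObservation] | pd.DataFrame,
                       path: str | Path) -> None:
    """Write observations as the canonical TSV (1-based positions)."""
    if isinstance(obs, pd.DataFrame):
        out = obs.copy()
        out["pos"] = out["pos0"] + 1
        out[OBS_COLUMNS].to_csv(path, sep="\t", index=False)
        return
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(OBS_COLUMNS)
        for o in obs:
            w.writerow([o.sample_id, o.chrom, o.pos0 + 1, o.ref_base,
                        o.obs_base, o.base_quality, o.map_quality,
                        o.read_pos, o.read_id])


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _derive_utrs(exons: list[tuple[int, int]], thick: tuple[int, int],
                 strand: str) -> tuple[list, list, list]:
    """Split exon blocks at the thick (CDS) range into CDS/UTR5/UTR3."""
    ts, te = thick
    cds, left, right = [], [], []
    for s, e in exons:
        if e <= ts:
            left.append((s, e))
        elif s >= te:
            right.append((s, e))
        else:
            if s < ts:
                left.append((s, ts))
            if e > te:
                right.append((te, e))
            cds.append((max(s, ts), min(e, te)))
    if strand == "+":
        return cds, left, right  # utr5 genomically left of CDS
    return cds, right, left


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 or a minimal GTF.

    The dialect is chosen by extension: ``.bed``/``.bed12`` is BED12,
    anything else is parsed as GTF with feature types gene/exon/CDS.
    BED12 thickStart==thickEnd marks an ncRNA.
    """
    path = Path(path)
    if path.suffix in (".bed", ".bed12"):
        return _read_bed12(path)
    return _read_gtf(path)


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            thick = (int(f[6]), int(f[7]))
            nblocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != nblocks or len(starts) != nblocks:
                raise FormatError(f"{path}:{lineno}: blockCount mismatch")
            exons = [(start + o, start + o + sz)
                     for o, sz in zip(starts, sizes)]
            for (a, b), (c, d) in zip(exons, exons[1:]):
                if c < b:
                    raise FormatError(f"{path}:{lineno}: overlapping blocks")
            if exons[0][0] != start or exons[-1][1] != end:
                raise FormatError(f"{path}:{lineno}: blocks do not span record")
            if thick[0] == thick[1]:
                genes.append(GeneModel(name, chrom, strand, exons,
                                       biotype="ncRNA"))
            else:
                if thick[0] < start or thick[1] > end:
                    raise FormatError(
                        f"{path}:{lineno}: thick range outside record")
                cds, utr5, utr3 = _derive_utrs(exons, thick, strand)
                genes.append(GeneModel(name, chrom, strand, exons, cds=cds,
                                       utr5=utr5, utr3=utr3, biotype="coding"))
    return genes


def _read_gtf(path: Path) -> list[GeneModel]:
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{lineno}: GTF needs 9 columns")
            chrom, _, feat, start, end, _, strand, _, attrs = f
            if feat not in ("gene", "exon", "CDS"):
                continue
            gid = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gid = part.split(None, 1)[1].strip('"')
            if gid is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id")
            iv = (int(start) - 1, int(end))  # GTF is 1-based inclusive
            meta.setdefault(gid, (chrom, strand))
            if feat == "exon":
                exons.setdefault(gid, []).append(iv)
            elif feat == "CDS":
                cds.setdefault(gid, []).append(iv)
    genes = []
    for gid, (chrom, strand) in meta.items():
        ex = sorted(exons.get(gid, []))
        if not ex:
            raise FormatError(f"{path}: gene {gid} has no exons")
        if gid not in cds:
            genes.append(GeneModel(gid, chrom, strand, ex, biotype="ncRNA"))
            continue
        cd = sorted(cds[gid])
        thick = (cd[0][0], cd[-1][1])
        cds_iv, utr5, utr3 = _derive_utrs(ex, thick, strand)
        genes.append(GeneModel(gid, chrom, strand, ex, cds=cds_iv, utr5=utr5,
                               utr3=utr3, biotype="coding"))
    return genes


def write_gene_models_bed12(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.start, g.end
            if g.biotype == "coding" and g.cds:
                thick = (g.cds[0][0], g.cds[-1][1])
            else:
                thick = (start, start)
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offs = ",".join(str(s - start) for s, _ in g.exons)
            fh.write("\t".join(map(str, [
                g.chrom, start, end, g.gene_id, 0, g.strand, thick[0],
                thick[1], 0, len(g.exons), sizes, offs])) + "\n")


# ---------------------------------------------------------------------------
# masks and variants
# ---------------------------------------------------------------------------

def read_interval_mask(path: str | Path, label: str = "") -> IntervalSet:
    """Read a BED3+ mask; overlapping intervals are merged."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                s, e = int(f[1]), int(f[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if s >= e:
                raise FormatError(f"{path}:{lineno}: start >= end")
            by_chrom.setdefault(f[0], []).append((s, e))
    return IntervalSet(by_chrom, label=label)


def write_interval_mask(ivset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in ivset.chroms():
            for s, e in ivset.intervals(chrom):
                fh.write(f"{chrom}\t{s}\t{e}\t{ivset.label}\n")


def read_variant_positions(path: str | Path) -> set[tuple[str, int, str]]:
    """Read known-variant positions from a VCF (CHROM/POS/REF/ALT only).

    Returns a set of (chrom, pos0, alt); multi-allelic rows are expanded.
    Parsing goes through cyvcf2; its htslib-level errors are re-raised as
    :class:`FormatError`.
    """
    from cyvcf2 import VCF

    out: set[tuple[str, int, str]] = set()
    try:
        reader = VCF(str(path))
        for rec in reader:
            for alt in rec.ALT:
                out.add((rec.CHROM, rec.POS - 1, alt))
        reader.close()
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return out


def write_variant_positions(variants: Iterable[tuple[str, int, str, str]],
                            path: str | Path) -> None:
    """Write (chrom, pos0, ref, alt) records as a minimal VCF 4.2."""
    rows = sorted(variants)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({r[0] for r in rows}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, ref, alt in rows:
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

def write_site_table(sites: list[EditingSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SITE_COLUMNS)
        for s in sites:
            w.writerow([s.chrom, s.pos0 + 1, s.ref_base, s.var_base, s.strand,
                        s.subst_type, int(s.in_alu), s.region_class,
                        ",".join(s.gene_ids), s.edited_reads, s.total_reads,
                        f"{s.level:.6f}"])


def read_site_table(path: str | Path) -> list[EditingSite]:
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SITE_COLUMNS:
            raise FormatError(f"{path}: bad site-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(SITE_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            try:
                if f[7] not in REGION_CLASSES:
                    raise ValueError(f"unknown region_class {f[7]!r}")
                site = EditingSite(
                    chrom=f[0], pos0=int(f[1]) - 1, ref_base=f[2],
                    var_base=f[3], strand=f[4], subst_type=f[5],
                    in_alu=bool(int(f[6])), region_class=f[7],
                    gene_ids=f[8].split(",") if f[8] else [],
                    edited_reads=int(f[9]), total_reads=int(f[10]))
                level = float(f[11])
                if not 0.0 <= level <= 1.0:
                    raise ValueError(f"level {level} outside [0, 1]")
                if site.total_reads and abs(site.level - level) > 5e-6:
                    raise ValueError(
                        f"level {level} inconsistent with counts "
                        f"{site.edited_reads}/{site.total_reads}")
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            sites.append(site)
    return sites


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path, check_paths: bool = True) -> SampleSheet:
    rows = []
    base = Path(path).parent
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "cell_type", "replicate_id", "path"]
        if header != expected:
            raise FormatError(f"{path}: bad sample-sheet header {header}")
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != 4:
                raise FormatError(f"{path}:{lineno}: wrong column count")
            p = Path(f[3])
            if not p.is_absolute():
                p = base / p
            if check_paths and not p.exists():
                raise FormatError(f"{path}:{lineno}: missing file {p}")
            rows.append(SampleRecord(f[0], f[1], f[2], str(p)))
    return SampleSheet(rows)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcell_type\treplicate_id\tpath\n")
        for r in sheet:
            fh.write(f"{r.sample_id}\t{r.cell_type}\t{r.replicate_id}\t{r.path}\n")


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA wholesale as {name: sequence} (desk-scale genomes)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a sites x samples level matrix (first column = site key)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="site")
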