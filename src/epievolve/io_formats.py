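"""Readers and writers for the file dialects the pipeline touches.

Dialects
--------
* Bismark-coverage/bedGraph (methylation): ``chrom  start  end  pct  meth
  unmeth`` with 1-based inclusive positions (start == end for a CpG).
* Popoolation2 sync (pooled allele counts): ``chrom  pos(1-based)  ref
  A:T:C:G:N:del`` with one colon-block per pool.
* BED6/BED12 (gene annotation): already 0-based half-open.
* TSV (expression summaries and all result tables).

Internal coordinates are 0-based half-open everywhere; the 1-based dialects
are converted on read and restored on write. Writers emit deterministic
ordering (chrom, pos).
"""
from __future__ import annotations

import logging
from pathlib import Path

from .types import ExpressionRecord, GeneAnnotation, MethylationSite, SnpSite

logger = logging.getLogger(__name__)

_SYNC_ALLELES = "ATCG"  # N and del columns never define the biallelic pair


class ParseError(ValueError):
    """Malformed input line; carries the offending path and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _site_id(chrom: str, pos: int) -> str:
    return f"{chrom}:{pos}"


# ---------------------------------------------------------------------------
# Bismark coverage
# ---------------------------------------------------------------------------

def read_methylation_counts(path, sample_id: str) -> list[MethylationSite]:
    """Read one sample's Bismark-coverage file into per-site count fragments.

    The percent column is ignored and recomputed from the counts; a
    discrepancy greater than 0.5 percentage points is logged as a warning.
    Positions are converted from 1-based inclusive to 0-based.
    """
    sites: list[MethylationSite] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 6:
                raise ParseError(path, lineno, f"expected 6 fields, got {len(fields)}")
            chrom, start_s, _end_s, pct_s, meth_s, unmeth_s = fields
            try:
                start = int(start_s)
                pct = float(pct_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-numeric field: {exc}") from exc
            if meth < 0 or unmeth < 0:
                raise ParseError(path, lineno, f"negative counts meth={meth} unmeth={unmeth}")
            total = meth + unmeth
            if total == 0:
                raise ParseError(path, lineno, "zero total coverage")
            recomputed = 100.0 * meth / total
            if abs(recomputed - pct) > 0.5:
                logger.warning(
                    "%s:%d: percent column %.3f disagrees with counts (%.3f); using counts",
                    path, lineno, pct, recomputed,
                )
            pos = start - 1
            site = MethylationSite(_site_id(chrom, pos), chrom, pos,
                                   {sample_id: (meth, total)})
            site.validate()
            sites.append(site)
    return sites


def write_methylation_counts(sites, sample_id: str, path) -> None:
    """Write one sample's counts back to Bismark-coverage dialect (1-based)."""
    rows = sorted(sites, key=lambda s: (s.chrom, s.pos))
    with open(path, "w") as fh:
        for s in rows:
            m, t = s.counts[sample_id]
            pct = 100.0 * m / t
            p1 = s.pos + 1
            fh.write(f"{s.chrom}\t{p1}\t{p1}\t{pct:.6g}\t{m}\t{t - m}\n")


def merge_methylation_samples(per_sample: dict[str, list[MethylationSite]],
                              require_all: bool = True) -> list[MethylationSite]:
    """Merge single-sample fragments into multi-sample sites keyed by locus.

    With ``require_all`` only loci observed in every sample are kept, which
    is the precondition of the coverage filter (every site has counts for
    every sample in the design).
    """
    merged: dict[str, MethylationSite] = {}
    for sample_id, sites in per_sample.items():
        for s in sites:
            tgt = merged.setdefault(
                s.site_id, MethylationSite(s.site_id, s.chrom, s.pos, {}))
            tgt.counts[sample_id] = s.counts[sample_id]
    out = [s for s in merged.values()
           if not require_all or len(s.counts) == len(per_sample)]
    out.sort(key=lambda s: (s.chrom, s.pos))
    return out


# ---------------------------------------------------------------------------
# Popoolation2 sync
# ---------------------------------------------------------------------------

def read_pool_counts(path, pool_ids: list[str]) -> tuple[list[SnpSite], dict]:
    """Read a sync file into biallelic SnpSites.

    The two alleles with the highest total read count across all pools
    define the site; ``alt`` is the lower-count (overall minor) one, ties
    broken in A<T<C<G column order. Sites where a third allele exceeds 5%
    of total reads are dropped and counted; monoallelic and all-zero sites
    are skipped. Returns (sites, report) where report counts the drops.
    """
    sites: list[SnpSite] = []
    report = {"n_triallelic_dropped": 0, "n_monoallelic_dropped": 0, "n_zero_skipped": 0}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3 + len(pool_ids):
                raise ParseError(
                    path, lineno,
                    f"expected {3 + len(pool_ids)} fields for {len(pool_ids)} pools, "
                    f"got {len(fields)}")
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos1 = int(pos_s)
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-numeric position {pos_s!r}") from exc
            per_pool = []
            for block in fields[3:]:
                parts = block.split(":")
                if len(parts) != 6:
                    raise ParseError(path, lineno, f"bad count block {block!r}")
                try:
                    cnt = [int(x) for x in parts]
                except ValueError as exc:
                    raise ParseError(path, lineno, f"non-numeric count in {block!r}") from exc
                if any(c < 0 for c in cnt):
                    raise ParseError(path, lineno, f"negative count in {block!r}")
                per_pool.append(cnt)
            # totals per A/T/C/G column across pools
            col_tot = [sum(p[i] for p in per_pool) for i in range(4)]
            grand = sum(col_tot)
            if grand == 0:
                logger.warning("%s:%d: all-zero counts, site skipped", path, lineno)
                report["n_zero_skipped"] += 1
                continue
            order = sorted(range(4), key=lambda i: (-col_tot[i], i))
            major_i, minor_i = order[0], order[1]
            if col_tot[minor_i] == 0:
                report["n_monoallelic_dropped"] += 1
                continue
            third = col_tot[order[2]]
            if third > 0.05 * grand:
                report["n_triallelic_dropped"] += 1
                continue
            pos = pos1 - 1
            counts = {}
            for pid, cnt in zip(pool_ids, per_pool):
                alt = cnt[minor_i]
                total = cnt[major_i] + cnt[minor_i]
                counts[pid] = (alt, total)
            sites.append(SnpSite(
                snp_id=_site_id(chrom, pos), chrom=chrom, pos=pos, counts=counts,
                ref_allele=_SYNC_ALLELES[major_i], alt_allele=_SYNC_ALLELES[minor_i]))
    if report["n_triallelic_dropped"]:
        logger.info("%s: dropped %d sites with >5%% third allele",
                    path, report["n_triallelic_dropped"])
    return sites, report


def write_pool_counts(sites, pool_ids: list[str], path) -> None:
    """Write SnpSites back to sync dialect (1-based positions)."""
    rows = sorted(sites, key=lambda s: (s.chrom, s.pos))
    with open(path, "w") as fh:
        for s in rows:
            blocks = []
            for pid in pool_ids:
                a, t = s.counts[pid]
                cnt = [0, 0, 0, 0, 0, 0]
                cnt[_SYNC_ALLELES.index(s.alt_allele)] = a
                cnt[_SYNC_ALLELES.index(s.ref_allele)] = t - a
                blocks.append(":".join(str(c) for c in cnt))
            fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.ref_allele}\t" + "\t".join(blocks) + "\n")


# ---------------------------------------------------------------------------
# BED annotation
# ---------------------------------------------------------------------------

def read_annotation(path) -> list[GeneAnnotation]:
    """Read BED6 (or BED12 with exon blocks) gene annotation."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ParseError(path, lineno, f"expected >=4 BED fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-numeric interval: {exc}") from exc
            if start >= end:
                raise ParseError(path, lineno, f"start {start} >= end {end}")
            gene_id = fields[3]
            strand = fields[5] if len(fields) >= 6 else "+"
            exons = None
            if len(fields) >= 12:
                try:
                    n_blocks = int(fields[9])
                    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                except ValueError as exc:
                    raise ParseError(path, lineno, f"bad BED12 blocks: {exc}") from exc
                if not (len(sizes) == len(starts) == n_blocks):
                    raise ParseError(path, lineno, "blockCount disagrees with block lists")
                exons = [(start + off, start + off + sz)
                         for off, sz in zip(starts, sizes)]
            g = GeneAnnotation(gene_id, chrom, start, end, strand, exons)
            try:
                g.validate()
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            genes.append(g)
    return genes


def write_annotation(genes, path) -> None:
    """Write genes as BED12 when exons are present, BED6 otherwise."""
    rows = sorted(genes, key=lambda g: (g.chrom, g.start))
    with open(path, "w") as fh:
        for g in rows:
            base = f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t.\t{g.strand}"
            if g.exons is None:
                fh.write(base + "\n")
            else:
                ex = sorted(g.exons)
                sizes = ",".join(str(e - s) for s, e in ex) + ","
                starts = ",".join(str(s - g.start) for s, e in ex) + ","
                fh.write(base + f"\t{g.start}\t{g.end}\t0\t{len(ex)}\t{sizes}\t{starts}\n")


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------

_EXPR_COLUMNS = ["gene_id", "contrast", "log2fc", "adj_p", "mean_expression"]


def read_expression(path) -> list[ExpressionRecord]:
    """Read a gene-level expression summary TSV.

    Header must contain gene_id, contrast, log2fc, adj_p, mean_expression;
    "NA" adjusted p-values parse as missing. Duplicate (gene_id, contrast)
    pairs are an error.
    """
    records: list[ExpressionRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        for col in _EXPR_COLUMNS:
            if col not in header:
                raise ParseError(path, 1, f"missing required column {col!r}")
        idx = {c: header.index(c) for c in _EXPR_COLUMNS}
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise ParseError(path, lineno, f"expected {len(header)} fields, got {len(fields)}")
            gene_id = fields[idx["gene_id"]]
            contrast = fields[idx["contrast"]]
            key = (gene_id, contrast)
            if key in seen:
                raise ParseError(path, lineno, f"duplicate (gene_id, contrast) pair {key}")
            seen.add(key)
            adj_raw = fields[idx["adj_p"]]
            try:
                log2fc = float(fields[idx["log2fc"]])
                adj_p = None if adj_raw in ("NA", "", "NaN") else float(adj_raw)
                mean_expression = float(fields[idx["mean_expression"]])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-numeric field: {exc}") from exc
            if adj_p is not None and not (0.0 <= adj_p <= 1.0):
                raise ParseError(path, lineno, f"adj_p {adj_p} outside [0,1]")
            records.append(ExpressionRecord(gene_id, contrast, log2fc, adj_p, mean_expression))
    return records


def write_expression(records, path) -> None:
    rows = sorted(records, key=lambda r: (r.gene_id, r.contrast))
    with open(path, "w") as fh:
        fh.write("\t".join(_EXPR_COLUMNS) + "\n")
        for r in rows:
            # repr() keeps floats byte-exact through a write/read cycle
            adj = "NA" if r.adj_p is None else repr(float(r.adj_p))
            fh.write(f"{r.gene_id}\t{r.contrast}\t{float(r.log2fc)!r}\t{adj}\t"
                     f"{float(r.mean_expression)!r}\n")


def write_tsv(df, path) -> None:
    """Write a result DataFrame as a deterministic TSV (no index)."""
    df.to_csv(path, sep="\t", index=False)


__all__ = [
    "ParseError",
    "read_methylation_counts", "write_methylation_counts", "merge_methylation_samples",
    "read_pool_counts", "write_pool_counts",
    "read_annotation", "write_annotation",
    "read_expression", "write_expression", "write_tsv",
]
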