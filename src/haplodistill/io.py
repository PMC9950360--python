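"""Readers and writers for the pipeline's external formats.

Phased genotypes come in as VCF 4.2 (via cyvcf2/htslib) or PLINK PED/MAP;
population panels, archaic genotype calls, ancient-sample genotypes and
expression values come in as TSV.  Everything lands in the containers of
:mod:`haplodistill.datatypes`.

Filtering is conservative and logged: multi-allelic records, unphased
genotypes and malformed rows are dropped with per-reason counts, never
silently.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .datatypes import (
    MISSING,
    AncientSampleTable,
    ArchaicGenotypeTable,
    DataError,
    ExpressionTable,
    HaplotypeMatrix,
    VariantRecord,
)

logger = logging.getLogger(__name__)

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive)."""
    m = _REGION_RE.match(region)
    if not m:
        raise DataError(f"malformed region string {region!r}; expected chrom:start-end")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start > end:
        raise DataError(f"region start {start} after end {end}")
    return chrom, start, end


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, region: str | None = None) -> HaplotypeMatrix:
    """Read phased diploid genotypes from a VCF into a HaplotypeMatrix.

    Only biallelic records are retained (multi-allelic records are dropped
    and counted).  Genotypes that are unphased or carry any missing allele
    become missing for *both* haplotype columns of that sample at that site.

    Parameters
    ----------
    region :
        Optional ``chrom:start-end`` filter, 1-based inclusive.
    """
    path = str(path)
    want = parse_region(region) if region else None
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises plain OSError on bad files
        raise DataError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_multi = n_unphased_gts = 0
    for rec in vcf:
        if want is not None:
            chrom, start, end = want
            if rec.CHROM != chrom or not (start <= rec.POS <= end):
                continue
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        row = np.empty(2 * len(samples), dtype=np.int8)
        for j, g in enumerate(rec.genotypes):  # [allele_a, allele_b, phased]
            a, b, phased = g[0], g[1], bool(g[2])
            if a < 0 or b < 0 or not phased:
                row[2 * j] = row[2 * j + 1] = MISSING
                if not phased and a >= 0 and b >= 0:
                    n_unphased_gts += 1
            else:
                row[2 * j], row[2 * j + 1] = a, b
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(
            VariantRecord(rec.CHROM, rec.POS, vid, rec.REF, rec.ALT[0])
        )
        rows.append(row)
    if n_multi:
        logger.info("%s: dropped %d multi-allelic record(s)", path, n_multi)
    if n_unphased_gts:
        logger.info("%s: set %d unphased genotype(s) to missing", path, n_unphased_gts)
    if not variants:
        raise DataError(
            f"no biallelic variants retained from {path}"
            + (f" in region {region}" if region else "")
        )
    sample_ids = [s for s in samples for _ in range(2)]
    alleles = np.vstack(rows)
    order = np.argsort([v.pos for v in variants], kind="stable")
    variants = [variants[i] for i in order]
    alleles = alleles[order]
    return HaplotypeMatrix(variants, alleles, sample_ids)


def write_vcf(matrix: HaplotypeMatrix, path: str | Path) -> None:
    """Write a HaplotypeMatrix as a minimal phased VCF 4.2 file.

    ``read_vcf(write_vcf(m)) == m`` for any valid matrix.
    """
    path = Path(path)
    samples = matrix.sample_ids[::2]
    if matrix.sample_ids != [s for s in samples for _ in range(2)]:
        raise DataError("haplotype columns are not paired per diploid sample")
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplodistill\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if matrix.variants:
            chrom = matrix.variants[0].chrom
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i, v in enumerate(matrix.variants):
            row = matrix.alleles[i]
            gts = []
            for j in range(0, len(row), 2):
                a, b = row[j], row[j + 1]
                if a == MISSING or b == MISSING:
                    gts.append(".|.")
                else:
                    gts.append(f"{a}|{b}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------

def read_ped(
    ped_path: str | Path,
    map_path: str | Path,
    reference_alleles: dict[str, tuple[str, str]] | None = None,
) -> HaplotypeMatrix:
    """Read a PLINK PED/MAP pair into a HaplotypeMatrix.

    Allele coding: when ``reference_alleles`` supplies ``vid -> (ref, alt)``
    the bases are mapped accordingly; otherwise the lexicographically
    smaller observed allele at each variant becomes 0 (logged).  ``0``
    alleles are missing; a half-missing genotype blanks both haplotypes.
    Phase is taken as column order, as for phased 1000G PED exports.
    """
    map_rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise DataError(f"{map_path} line {ln}: expected 4 columns")
        map_rows.append((parts[0], parts[1], int(parts[3])))
    n_var = len(map_rows)

    sample_ids: list[str] = []
    hap_a: list[list[str]] = []
    hap_b: list[list[str]] = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_var:
            raise DataError(
                f"{ped_path} line {ln}: {len(parts)} fields, expected "
                f"{6 + 2 * n_var} for {n_var} MAP variants"
            )
        sample_ids.append(parts[1])
        hap_a.append(parts[6::2])
        hap_b.append(parts[7::2])

    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    n_lex = 0
    for k, (chrom, vid, pos) in enumerate(map_rows):
        a_alleles = [h[k] for h in hap_a]
        b_alleles = [h[k] for h in hap_b]
        observed = sorted({x for x in a_alleles + b_alleles if x != "0"})
        if reference_alleles and vid in reference_alleles:
            ref, alt = reference_alleles[vid]
        else:
            if len(observed) == 1:
                ref, alt = observed[0], "?"
            elif len(observed) == 2:
                ref, alt = observed
                n_lex += 1
            else:
                raise DataError(f"variant {vid}: more than two alleles {observed}")
        code = {ref: 0, alt: 1, "0": MISSING}
        row = np.empty(2 * len(sample_ids), dtype=np.int8)
        for j, (a, b) in enumerate(zip(a_alleles, b_alleles)):
            if a not in code or b not in code:
                raise DataError(f"variant {vid}, sample {sample_ids[j]}: allele {a}/{b}")
            va, vb = code[a], code[b]
            if va == MISSING or vb == MISSING:
                va = vb = MISSING
            row[2 * j], row[2 * j + 1] = va, vb
        variants.append(VariantRecord(chrom, pos, vid, ref, alt))
        cols.append(row)
    if n_lex:
        logger.info(
            "%s: %d variant(s) coded by lexicographic allele order", ped_path, n_lex
        )
    order = np.argsort([v.pos for v in variants], kind="stable")
    return HaplotypeMatrix(
        [variants[i] for i in order],
        np.vstack(cols)[order],
        [s for s in sample_ids for _ in range(2)],
    )


# ---------------------------------------------------------------------------
# Archaic, panel, ancient, expression tables
# ---------------------------------------------------------------------------

def read_archaic(path: str | Path, individual_id: str | None = None) -> ArchaicGenotypeTable:
    """Read archaic genotype calls from a two-column TSV (pos, call).

    Heterozygous calls use IUPAC two-base ambiguity codes; ``N`` or ``.``
    means missing and the position is not retained.  Lines starting with
    ``#`` are comments; an optional header line ``pos\\tcall`` is skipped.
    """
    path = Path(path)
    calls: dict[int, str] = {}
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if parts[0].lower() in ("pos", "position"):
            continue
        if len(parts) < 2:
            raise DataError(f"{path} line {ln}: expected (pos, call)")
        try:
            pos = int(parts[0])
        except ValueError as exc:
            raise DataError(f"{path} line {ln}: bad position {parts[0]!r}") from exc
        call = parts[1].upper()
        if call in ("N", "."):
            continue
        calls[pos] = call
    table = ArchaicGenotypeTable(individual_id or path.stem, calls)
    return table


def read_panel(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a sample panel TSV: columns sample, population[, superpopulation].

    Returns (sample -> population, population -> superpopulation).
    """
    pop: dict[str, str] = {}
    superpop: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if parts[0].lower() in ("sample", "sample_id"):
            continue
        if len(parts) < 2:
            raise DataError(f"{path} line {ln}: expected sample<TAB>population")
        pop[parts[0]] = parts[1]
        if len(parts) >= 3:
            superpop[parts[1]] = parts[2]
    return pop, superpop


def read_ancient(path: str | Path) -> AncientSampleTable:
    """Read an ancient-sample TSV: sample, age_years_bp, then one column per
    tag variant holding derived-allele counts in {0,1,2} or ``.`` (missing).
    """
    lines = [
        l for l in Path(path).read_text().splitlines() if l.strip() and not l.startswith("#")
    ]
    if not lines:
        raise DataError(f"{path}: empty ancient table")
    header = lines[0].split("\t")
    if header[0].lower() not in ("sample", "sample_id"):
        raise DataError(f"{path}: first header column must be 'sample'")
    tag_vids = header[2:]
    samples, ages, genos = [], [], []
    for ln, line in enumerate(lines[1:], 2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise DataError(f"{path} line {ln}: {len(parts)} fields, expected {len(header)}")
        samples.append(parts[0])
        ages.append(float(parts[1]))
        g: dict[str, int] = {}
        for vid, cell in zip(tag_vids, parts[2:]):
            if cell in (".", "", "NA"):
                continue
            g[vid] = int(cell)
        genos.append(g)
    return AncientSampleTable(samples, ages, genos)


def write_ancient(table: AncientSampleTable, tag_vids: list[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tage_years_bp\t" + "\t".join(tag_vids) + "\n")
        for s, a, g in zip(table.samples, table.ages_years_bp, table.genotypes):
            cells = [str(g[v]) if v in g else "." for v in tag_vids]
            fh.write(f"{s}\t{a:g}\t" + "\t".join(cells) + "\n")


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a two-column expression TSV (sample, FPKM)."""
    samples, values = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if parts[0].lower() in ("sample", "sample_id"):
            continue
        if len(parts) < 2:
            raise DataError(f"{path} line {ln}: expected sample<TAB>value")
        samples.append(parts[0])
        values.append(float(parts[1]))
    return ExpressionTable(samples, values)


def write_archaic(table: ArchaicGenotypeTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("pos\tcall\n")
        for pos in sorted(table.calls):
            fh.write(f"{pos}\t{table.calls[pos]}\n")


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tfpkm\n")
        for s, v in zip(table.samples, table.values):
            fh.write(f"{s}\t{v:.6g}\n")
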