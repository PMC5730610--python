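"""Readers and writers for the formats the pipeline touches.

Formats
-------
* VCF 4.x (read via cyvcf2, genotype-only: the GT field; DP/GQ ignored;
  phase discarded).  Population assignment always comes from a separate
  two-column popmap, never from sample-name parsing.
* genepop, 2- and 3-digit diploid dialects (microsatellite carrier).
* A plain TSV matrix dialect: header row ``individual  population  <locus ids>``,
  cells ``a/b`` or ``.`` for missing; an optional ``#tags`` line carries the
  RAD-tag label per locus so round trips are lossless.
* popmap TSV: ``individual_id <tab> population``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import numpy as np

from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "read_popmap",
    "read_vcf",
    "write_vcf",
    "read_genepop",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column individual -> population TSV."""
    popmap: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        ind, pop = parts
        if ind in popmap:
            raise ValueError(f"{path}:{lineno}: duplicate individual {ind!r}")
        popmap[ind] = pop
    return popmap


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, popmap: Mapping[str, str] | str | Path) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a GenotypeMatrix.

    One matrix locus per VCF record; allele codes follow the VCF convention
    (REF=0, ALT_i=i).  ``./.`` and half-calls become MISSING.  The CHROM
    field is taken as the RAD-tag label of each record, so single-SNP
    selection can run downstream.  ``popmap`` maps sample name to
    population (a mapping or a path to a popmap TSV).
    """
    from cyvcf2 import VCF

    if not isinstance(popmap, Mapping):
        popmap = read_popmap(popmap)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample names in VCF header")
    absent = [s for s in samples if s not in popmap]
    if absent:
        raise ValueError(f"{path}: samples missing from popmap: {absent[:5]}")

    locus_ids: list[str] = []
    tags: list[str] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        lid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        genos = rec.genotypes  # per sample: [a0, a1, ..., phased]
        calls = np.full((len(samples), 2), MISSING, dtype=np.int16)
        for i, g in enumerate(genos):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"{path}: non-diploid GT for sample {samples[i]!r} at record {lid}"
                )
            a, b = alleles
            if a < 0 or b < 0:  # ./. and half-calls
                continue
            calls[i] = (a, b)
        locus_ids.append(lid)
        tags.append(rec.CHROM)
        rows.append(calls)
    vcf.close()

    n, l = len(samples), len(locus_ids)
    arr = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((n, 0, 2), dtype=np.int16)
    )
    return GenotypeMatrix(
        individual_ids=samples,
        populations=[popmap[s] for s in samples],
        locus_ids=locus_ids,
        calls=arr,
        tags=tags if l else [],
    )


_ALT_BASES = ["C", "G", "T"]


def _alt_symbol(i: int) -> str:
    # synthetic ALT sequences for anonymous loci: C, G, T, CC, CG, ...
    i -= 1
    out = []
    while True:
        out.append(_ALT_BASES[i % 3])
        i = i // 3 - 1
        if i < 0:
            break
    return "".join(reversed(out))


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as a minimal GT-only VCF 4.2 file.

    Loci are anonymous, so REF/ALT are synthetic single-base (or short)
    sequences; CHROM carries the tag label (locus id if tags are absent).
    """
    tags = gm.tags if gm.tags is not None else gm.locus_ids
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        *(f"##contig=<ID={t}>" for t in dict.fromkeys(tags)),
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.individual_ids),
    ]
    for j, lid in enumerate(gm.locus_ids):
        n_alt = max(1, gm.calls[:, j, :].max(initial=0))
        alt = ",".join(_alt_symbol(i) for i in range(1, n_alt + 1))
        gts = []
        for i in range(gm.n_individuals):
            a, b = gm.calls[i, j]
            gts.append("./." if a == MISSING else f"{a}/{b}")
        lines.append(
            f"{tags[j]}\t{j + 1}\t{lid}\tA\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genepop


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Read a genepop file (2- or 3-digit diploid coding).

    Allele code 0 ("00"/"000") marks a missing allele; a call with one
    missing allele is treated as fully MISSING.  POP blocks become
    populations named ``pop1``, ``pop2``, ... in file order.  Genepop
    allele codes are kept verbatim ("003005" -> the pair {3, 5}).
    """
    raw = Path(path).read_text().splitlines()
    if len(raw) < 2:
        raise ValueError(f"{path}: truncated genepop file")
    body = raw[1:]  # first line is a title/comment

    # locus names: either one per line until POP, or comma-separated
    locus_ids: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        chunk = body[i].strip()
        if chunk:
            locus_ids.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(body):
        raise ValueError(f"{path}: no POP line found")

    individual_ids: list[str] = []
    populations: list[str] = []
    genotype_rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    digits: int | None = None
    for lineno, line in enumerate(body[i:], i + 2):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.upper() == "POP":
            pop_idx += 1
            continue
        if pop_idx == 0:
            raise ValueError(f"{path}:{lineno}: genotypes before first POP")
        if "," not in stripped:
            raise ValueError(f"{path}:{lineno}: expected 'name , genotypes'")
        name, _, geno_part = stripped.partition(",")
        name = name.strip()
        entries = geno_part.split()
        if len(entries) != len(locus_ids):
            raise ValueError(
                f"{path}:{lineno}: {len(entries)} genotypes for "
                f"{len(locus_ids)} loci"
            )
        row: list[tuple[int, int]] = []
        for entry in entries:
            if not re.fullmatch(r"\d+", entry) or len(entry) not in (4, 6):
                raise ValueError(f"{path}:{lineno}: malformed entry {entry!r}")
            w = len(entry) // 2
            if digits is None:
                digits = w
            elif w != digits:
                raise ValueError(
                    f"{path}:{lineno}: inconsistent allele digit width "
                    f"({w} vs {digits})"
                )
            a, b = int(entry[:w]), int(entry[w:])
            if a == 0 or b == 0:
                row.append((MISSING, MISSING))
            else:
                row.append((a, b))
        individual_ids.append(name)
        populations.append(f"pop{pop_idx}")
        genotype_rows.append(row)

    calls = (
        np.array(genotype_rows, dtype=np.int16)
        if genotype_rows
        else np.empty((0, len(locus_ids), 2), dtype=np.int16)
    )
    return GenotypeMatrix(
        individual_ids=individual_ids,
        populations=populations,
        locus_ids=locus_ids,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# TSV matrix dialect


def write_matrix_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV matrix dialect (lossless, including tags and MISSING)."""
    lines = ["\t".join(["individual", "population", *gm.locus_ids])]
    if gm.tags is not None:
        lines.append("\t".join(["#tags", "-", *gm.tags]))
    for i, (ind, pop) in enumerate(zip(gm.individual_ids, gm.populations)):
        cells = []
        for j in range(gm.n_loci):
            a, b = gm.calls[i, j]
            cells.append("." if a == MISSING else f"{a}/{b}")
        lines.append("\t".join([ind, pop, *cells]))
    Path(path).write_text("\n".join(lines) + "\n")


_CELL_RE = re.compile(r"^(\d+)/(\d+)$")


def read_matrix_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the TSV matrix dialect written by :func:`write_matrix_tsv`."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[:2] != ["individual", "population"]:
        raise ValueError(f"{path}: bad header (expected individual/population)")
    locus_ids = header[2:]

    tags: list[str] | None = None
    body_start = 1
    if len(lines) > 1 and lines[1].startswith("#tags\t"):
        tag_row = lines[1].split("\t")
        tags = tag_row[2:]
        if len(tags) != len(locus_ids):
            raise ValueError(f"{path}: #tags row length mismatch")
        body_start = 2

    individual_ids: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    for lineno, line in enumerate(lines[body_start:], body_start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 + len(locus_ids):
            raise ValueError(
                f"{path}:{lineno}: {len(parts)} columns, expected {2 + len(locus_ids)}"
            )
        individual_ids.append(parts[0])
        populations.append(parts[1])
        row: list[tuple[int, int]] = []
        for col, cell in enumerate(parts[2:]):
            if cell == ".":
                row.append((MISSING, MISSING))
                continue
            m = _CELL_RE.match(cell)
            if not m:
                raise ValueError(
                    f"{path}:{lineno}: malformed cell {cell!r} in column "
                    f"{locus_ids[col]!r}"
                )
            row.append((int(m.group(1)), int(m.group(2))))
        rows.append(row)

    calls = (
        np.array(rows, dtype=np.int16)
        if rows and locus_ids
        else np.empty((len(rows), len(locus_ids), 2), dtype=np.int16)
    )
    return GenotypeMatrix(
        individual_ids=individual_ids,
        populations=populations,
        locus_ids=locus_ids,
        calls=calls,
        tags=tags,
    )
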