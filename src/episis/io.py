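"""Readers and writers for case-control genotype data.

Two input formats are supported: PLINK binary (``.bed``/``.bim``/``.fam``,
SNP-major, magic bytes ``0x6C 0x1B 0x01``) and a plain whitespace-delimited
table with the phenotype in the first column.  Genotypes are returned as
minor-allele counts per the ``.bim`` allele columns (A1 = minor); missing
genotypes are rejected with a message naming the offending SNP and sample.
"""

from __future__ import annotations

import os

import numpy as np

from .genotypes import GenotypeMatrix, PhenotypeVector

__all__ = ["read_plink_bed", "write_plink_bed", "read_genotype_table"]

_BED_MAGIC = b"\x6c\x1b\x01"

# 2-bit PLINK codes, lowest bits = first sample: 00 hom A1 (2 minor copies),
# 01 missing, 10 het, 11 hom A2.
_DECODE = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _code = (_b >> (2 * _k)) & 0b11
        _DECODE[_b, _k] = {0b00: 2, 0b01: -1, 0b10: 1, 0b11: 0}[_code]
_ENCODE = {2: 0b00, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    pass


def _read_cols(path, ncols_min):
    rows = []
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if len(tok) < ncols_min:
                raise PlinkFormatError(f"{path}: expected >= {ncols_min} columns")
            rows.append(tok)
    return rows


def read_plink_bed(path_prefix: str):
    """Read a PLINK binary fileset; returns ``(GenotypeMatrix, PhenotypeVector)``.

    The genotype value counts copies of the A1 allele from the ``.bim``
    file (PLINK convention: A1 = minor allele); ``.fam`` phenotype 1/2 is
    mapped to 0/1.  Any missing genotype (bed code 01) is a hard error.
    """
    bed_path = path_prefix + ".bed"
    bim = _read_cols(path_prefix + ".bim", 6)
    fam = _read_cols(path_prefix + ".fam", 6)
    n, L = len(fam), len(bim)
    snp_ids = [r[1] for r in bim]
    alleles = [(r[4], r[5]) for r in bim]
    sample_ids = [r[1] for r in fam]
    status = np.empty(n, dtype=np.int8)
    for k, r in enumerate(fam):
        if r[5] == "1":
            status[k] = 0
        elif r[5] == "2":
            status[k] = 1
        else:
            raise PlinkFormatError(
                f"{path_prefix}.fam: phenotype '{r[5]}' for sample {r[1]} "
                "is not 1 (control) / 2 (case)"
            )
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:2]) != _BED_MAGIC[:2]:
        raise PlinkFormatError(f"{bed_path}: not a PLINK .bed file (bad magic bytes)")
    if raw[2] != 0x01:
        raise PlinkFormatError(
            f"{bed_path}: sample-major .bed files are not supported (third byte "
            f"0x{raw[2]:02X}, expected 0x01 for SNP-major)"
        )
    nbytes = (n + 3) // 4
    body = raw[3:]
    if body.size != L * nbytes:
        raise PlinkFormatError(
            f"{bed_path}: size mismatch ({body.size} data bytes, expected {L * nbytes})"
        )
    geno = _DECODE[body.reshape(L, nbytes)].reshape(L, nbytes * 4)[:, :n].T
    miss = np.argwhere(geno == -1)
    if miss.size:
        i, j = miss[0]
        raise PlinkFormatError(
            f"missing genotype at SNP {snp_ids[j]}, sample {sample_ids[i]}; "
            "missing genotypes are not supported"
        )
    g = GenotypeMatrix(geno, snp_ids=snp_ids, alleles=alleles, sample_ids=sample_ids)
    return g, PhenotypeVector(status)


def write_plink_bed(path_prefix: str, g: GenotypeMatrix, y: PhenotypeVector) -> None:
    """Write a PLINK binary fileset (A1 = minor allele, phenotype 0/1 -> 1/2)."""
    n, L = g.n_samples, g.n_snps
    nbytes = (n + 3) // 4
    codes = np.array([_ENCODE[0], _ENCODE[1], _ENCODE[2]], dtype=np.uint8)
    padded = np.zeros((L, nbytes * 4), dtype=np.uint8)
    padded[:, :n] = codes[g.genotypes.T]
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(L, nbytes, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(path_prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    with open(path_prefix + ".bim", "w") as fh:
        for k in range(L):
            a1, a2 = g.alleles[k]
            fh.write(f"1\t{g.snp_ids[k]}\t0\t{k + 1}\t{a1}\t{a2}\n")
    with open(path_prefix + ".fam", "w") as fh:
        for k in range(n):
            sid = g.sample_ids[k]
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t{int(y.status[k]) + 1}\n")


def read_genotype_table(path: str):
    """Read a whitespace-delimited genotype table.

    One row per individual; first column is the phenotype (0 control /
    1 case), remaining columns are 0/1/2 minor-allele counts.  An optional
    header row supplies SNP ids (defaults to ``SNP1..SNPL``).
    """
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = None
    first = lines[0]
    try:
        float(first[0])
    except ValueError:
        header = first
        lines = lines[1:]
    if not lines:
        raise ValueError(f"{path}: no data rows")
    ncol = len(lines[0])
    if ncol < 2:
        raise ValueError(f"{path}: need a phenotype column plus >= 1 genotype column")
    data = np.empty((len(lines), ncol), dtype=np.int8)
    for r, tok in enumerate(lines):
        if len(tok) != ncol:
            raise ValueError(f"{path}: row {r + 1} has {len(tok)} columns, expected {ncol}")
        for c, t in enumerate(tok):
            try:
                v = int(t)
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer entry '{t}' at row {r + 1}, column {c + 1}"
                ) from None
            if c == 0:
                if v not in (0, 1):
                    raise ValueError(
                        f"{path}: phenotype '{t}' at row {r + 1} must be 0 or 1"
                    )
            elif v not in (0, 1, 2):
                raise ValueError(
                    f"{path}: genotype '{t}' at row {r + 1}, column {c + 1} "
                    "must be 0, 1, or 2"
                )
            data[r, c] = v
    snp_ids = None
    if header is not None:
        snp_ids = header[1:] if len(header) == ncol else header
        if len(snp_ids) != ncol - 1:
            raise ValueError(f"{path}: header has {len(snp_ids)} ids for {ncol - 1} SNPs")
    g = GenotypeMatrix(data[:, 1:], snp_ids=snp_ids)
    return g, PhenotypeVector(data[:, 0])
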