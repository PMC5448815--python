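"""Minimal reader for PLINK 1 binary genotype triplets (.bed/.bim/.fam).

Only SNP-major (variant-major) .bed files are supported, which is what PLINK
writes by default. Genotypes are returned as minor-allele counts; the .bim
allele-1 column is taken as the counted allele (PLINK convention: A1 is
usually the minor allele). The 2-bit codes per the PLINK spec are
00=hom A1 (2 copies), 01=missing, 10=het, 11=hom A2 (0 copies).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

MAGIC = b"\x6c\x1b"
SNP_MAJOR = b"\x01"

# code -> A1 count; missing -> NaN
_DECODE = np.array([2.0, np.nan, 1.0, 0.0])

BIM_COLUMNS = ["chromosome", "snp_id", "cm", "position", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


def read_bim(path: str) -> pd.DataFrame:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"malformed bim line {lineno} in {path}: {line!r}")
            records.append(parts)
    bim = pd.DataFrame(records, columns=BIM_COLUMNS)
    try:
        bim["position"] = bim["position"].astype(np.int64)
    except ValueError as exc:
        raise ValueError(f"non-integer position in {path}: {exc}") from exc
    return bim


def read_fam(path: str) -> pd.DataFrame:
    fam = pd.read_csv(path, sep=r"\s+", header=None, names=FAM_COLUMNS, dtype=str)
    return fam


def read_bed(prefix: str) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Read a bed/bim/fam triplet.

    Returns (fam, bim, genotypes) with genotypes shaped (n_samples, n_snps),
    float with NaN for missing calls.
    """
    for ext in (".bed", ".bim", ".fam"):
        if not os.path.exists(prefix + ext):
            raise FileNotFoundError(f"missing {prefix + ext}")
    fam = read_fam(prefix + ".fam")
    bim = read_bim(prefix + ".bim")
    n, s = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        header = fh.read(3)
        if header[:2] != MAGIC:
            raise ValueError(f"{prefix}.bed: bad magic bytes")
        if header[2:3] != SNP_MAJOR:
            raise ValueError(f"{prefix}.bed: only SNP-major layout supported")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if data.size != bytes_per_snp * s:
        raise ValueError(
            f"{prefix}.bed: expected {bytes_per_snp * s} data bytes, got {data.size}"
        )
    data = data.reshape(s, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((s, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (data >> (2 * shift)) & 0b11
    geno = _DECODE[codes[:, :n]].T  # (n, s)
    return fam, bim, geno


def write_bed(prefix: str, genotypes: np.ndarray, fam: pd.DataFrame, bim: pd.DataFrame) -> None:
    """Write a SNP-major bed/bim/fam triplet (used for round-trip tests)."""
    geno = np.asarray(genotypes, dtype=float)
    n, s = geno.shape
    code = np.full((s, n), 1, dtype=np.uint8)  # default missing
    codeT = code  # (s, n)
    g = geno.T
    codeT[g == 2] = 0b00
    codeT[g == 1] = 0b10
    codeT[g == 0] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.ones((s, bytes_per_snp * 4), dtype=np.uint8)  # pad with 'missing'
    padded[:, :n] = codeT
    packed = np.zeros((s, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        packed |= padded[:, shift::4] << (2 * shift)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(MAGIC + SNP_MAJOR)
        fh.write(packed.tobytes())
    fam.to_csv(prefix + ".fam", sep=" ", header=False, index=False)
    bim[BIM_COLUMNS].to_csv(prefix + ".bim", sep="\t", header=False, index=False)
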