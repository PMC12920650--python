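"""Minimal PLINK 1 bed/bim/fam reader and writer for hard-call genotypes.

Genotypes are stored as the dosage of the A1 allele (0, 1, 2 or NaN for
missing), SNP-major, two bits per sample as in the PLINK 1 binary format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# two-bit code -> A1 dosage; 0b01 is missing
_CODE_TO_DOSE = np.array([2.0, np.nan, 1.0, 0.0])


def write_bed(prefix: str, genotypes: np.ndarray, iids, snps: pd.DataFrame | None = None) -> None:
    """Write genotypes (N x M, A1 dosages with NaN missing) as bed/bim/fam.

    ``snps`` may supply columns chrom/snp/cm/pos/a1/a2; defaults are invented
    when absent.
    """
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    if snps is None:
        snps = pd.DataFrame(
            {
                "chrom": np.ones(m, dtype=int),
                "snp": [f"snp{i + 1}" for i in range(m)],
                "cm": np.zeros(m),
                "pos": (np.arange(m) + 1) * 10_000,
                "a1": ["A"] * m,
                "a2": ["G"] * m,
            }
        )
    snps.to_csv(
        f"{prefix}.bim", sep="\t", header=False, index=False,
        columns=["chrom", "snp", "cm", "pos", "a1", "a2"],
    )
    fam = pd.DataFrame(
        {
            "fid": iids,
            "iid": iids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)

    n_bytes = (n + 3) // 4
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_MAGIC)
        codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing
        codes[:, :] = np.where(np.isnan(G.T), 0b01,
                               np.where(G.T == 2, 0b00,
                                        np.where(G.T == 1, 0b10, 0b11)))
        for j in range(m):
            row = np.zeros(n_bytes * 4, dtype=np.uint8)
            row[:n] = codes[j]
            packed = (
                row[0::4] | (row[1::4] << 2) | (row[2::4] << 4) | (row[3::4] << 6)
            )
            fh.write(packed.tobytes())


def read_bed(prefix: str):
    """Read bed/bim/fam; returns (genotypes N x M, iids, snp table)."""
    bim = pd.read_csv(
        f"{prefix}.bim", sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        f"{prefix}.fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    if raw.size != m * n_bytes:
        raise ValueError("bed payload size does not match bim/fam dimensions")
    raw = raw.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = raw & 0b11
    codes[:, 1::4] = (raw >> 2) & 0b11
    codes[:, 2::4] = (raw >> 4) & 0b11
    codes[:, 3::4] = (raw >> 6) & 0b11
    G = _CODE_TO_DOSE[codes[:, :n]].T
    return G, fam["iid"].astype(str).tolist(), bim
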