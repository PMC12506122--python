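"""Structural diversity of compound sets from binary molecular fingerprints.

Tanimoto similarity of two fingerprints is |A∩B| / |A∪B| over their set
bits; the diversity of a compound set is

    d = 1 − mean Tanimoto similarity over all unordered distinct pairs.

Self-pairs are excluded — including the diagonal of 1s would deflate d.
Values near 0 mean the compounds are structurally homogeneous; values near
1 mean high structural diversity.

The metric is fingerprint-agnostic: any fixed-length bit matrix works.  An
optional adapter (:func:`fingerprints_from_smiles`, requires rdkit) builds
Morgan fingerprints (radius 2, 2048 bits) from SMILES strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FingerprintSet",
    "DiversityResult",
    "tanimoto",
    "diversity",
    "diversity_excluding",
    "fingerprints_from_smiles",
]


@dataclass
class FingerprintSet:
    """n compounds × L bits, with one row per compound."""

    ids: list[str]
    bits: np.ndarray  # (n, L) uint8

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.ids):
            raise ValueError("bits must be an (n_ids, L) matrix")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate compound ids")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprints must be binary")
        if self.bits.size and (self.bits.sum(axis=1) == 0).any():
            raise ValueError("every fingerprint needs at least one set bit")

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_bitstrings(cls, ids: Sequence[str], strings: Sequence[str]) -> "FingerprintSet":
        bits = np.array([[int(c) for c in s] for s in strings], dtype=np.uint8)
        return cls(ids=list(ids), bits=bits)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FingerprintSet":
        """Read ``compound_id\tfingerprint`` rows (0/1 bitstrings)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("compound_id", "fingerprint"):
            if col not in df.columns:
                raise ValueError(f"fingerprint table missing column {col!r}")
        return cls.from_bitstrings(list(df["compound_id"]), list(df["fingerprint"]))

    def write_tsv(self, path: str | Path) -> None:
        strings = ["".join(map(str, row)) for row in self.bits]
        pd.DataFrame({"compound_id": self.ids, "fingerprint": strings}).to_csv(
            path, sep="\t", index=False)


@dataclass(frozen=True)
class DiversityResult:
    d: float
    n: int
    n_pairs: int
    mean_similarity: float


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two binary fingerprints."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("fingerprints must be 1-D and of equal length")
    if not a.any() or not b.any():
        raise ValueError("fingerprints must each have at least one set bit")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter) / float(union)


def diversity(fps: FingerprintSet) -> DiversityResult:
    """d = 1 − mean pairwise Tanimoto similarity (vectorised).

    Pairwise intersections come from one integer matrix product; unions via
    |A∪B| = |A| + |B| − |A∩B|.
    """
    n = fps.n
    if n < 2:
        raise ValueError("diversity needs at least two compounds")
    B = fps.bits.astype(np.int64)
    inter = B @ B.T
    counts = B.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    iu = np.triu_indices(n, k=1)
    sims = inter[iu] / union[iu]
    mean_sim = float(sims.mean())
    return DiversityResult(d=1.0 - mean_sim, n=n, n_pairs=len(sims),
                           mean_similarity=mean_sim)


def diversity_excluding(fps: FingerprintSet, exclude_ids: Iterable[str]) -> DiversityResult:
    """Diversity of the set with the named compounds removed."""
    exclude = set(exclude_ids)
    unknown = exclude - set(fps.ids)
    if unknown:
        raise ValueError(f"unknown compound ids: {sorted(unknown)[:5]}")
    keep = [i for i, cid in enumerate(fps.ids) if cid not in exclude]
    if len(keep) < 2:
        raise ValueError("fewer than two compounds remain after exclusion")
    sub = FingerprintSet(ids=[fps.ids[i] for i in keep], bits=fps.bits[keep])
    return diversity(sub)


def fingerprints_from_smiles(
    ids: Sequence[str],
    smiles: Sequence[str],
    radius: int = 2,
    n_bits: int = 2048,
) -> FingerprintSet:
    """Morgan-fingerprint adapter for SMILES input (requires rdkit)."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = []
    for cid, smi in zip(ids, smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for {cid!r}: {smi!r}")
        fp = gen.GetFingerprint(mol)
        rows.append(np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8) - ord("0"))
    return FingerprintSet(ids=list(ids), bits=np.array(rows, dtype=np.uint8))
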