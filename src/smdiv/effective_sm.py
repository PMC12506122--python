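"""Effective number of secondary metabolites per BGC.

A single SM is often linked to several BGCs (the same compound made by
homologous clusters in different species).  Counting it once per BGC would
inflate the per-BGC yield, so shared SMs are down-weighted: an SM linked to
k BGCs contributes 1/k to each of them,

    effective(b) = Σ_{s ∈ SMs(b)} 1 / k_s .

This scheme has a clean bookkeeping identity — the effective counts sum to
the number of distinct SMs, so the mean effective count is exactly
(distinct SMs) / (BGCs).  It is one reasonable interpretation of
"down-weighting shared SMs"; alternative weightings would change the
multiplier and are intentionally not built in.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "BgcSmTable",
    "EffectiveSmResult",
    "read_links",
    "sm_multiplicity",
    "effective_sm_per_bgc",
]


@dataclass(frozen=True)
class BgcSmTable:
    """Bipartite BGC ↔ SM link table as a set of (bgc_id, sm_id) pairs."""

    links: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs) -> "BgcSmTable":
        pairs = list(pairs)
        uniq = frozenset(pairs)
        if len(uniq) != len(pairs):
            raise ValueError("duplicate (bgc_id, sm_id) pairs")
        return cls(links=uniq)

    @property
    def bgc_ids(self) -> set[str]:
        return {b for b, _ in self.links}

    @property
    def sm_ids(self) -> set[str]:
        return {s for _, s in self.links}


def read_links(path: str | Path) -> BgcSmTable:
    """Read a flat BGC–SM link table (TSV with ``bgc_id``/``sm_id`` columns,
    or a JSON list of pair objects); an optional ``smiles`` column is ignored
    here and consumed by the fingerprint adapter instead."""
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
        pairs = [(str(r["bgc_id"]), str(r["sm_id"])) for r in rows]
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("bgc_id", "sm_id"):
            if col not in df.columns:
                raise ValueError(f"link table missing column {col!r}")
        pairs = list(zip(df["bgc_id"], df["sm_id"]))
    return BgcSmTable.from_pairs(pairs)


@dataclass(frozen=True)
class EffectiveSmResult:
    per_bgc: dict[str, float]
    mean_effective: float
    n_bgcs: int
    n_distinct_sms: int


def sm_multiplicity(table: BgcSmTable) -> dict[str, int]:
    """Number of BGCs linked to each SM (k_s ≥ 1)."""
    return dict(Counter(s for _, s in table.links))


def effective_sm_per_bgc(table: BgcSmTable) -> EffectiveSmResult:
    """Down-weighted SM count per BGC and its mean.

    Exact identity: Σ_b effective(b) = number of distinct SMs, hence
    mean_effective = n_distinct_sms / n_bgcs.
    """
    if not table.links:
        raise ValueError("empty BGC-SM table")
    k = sm_multiplicity(table)
    per_bgc: dict[str, float] = defaultdict(float)
    for b, s in table.links:
        per_bgc[b] += 1.0 / k[s]
    n_bgcs = len(per_bgc)
    n_sms = len(k)
    return EffectiveSmResult(
        per_bgc=dict(per_bgc),
        mean_effective=sum(per_bgc.values()) / n_bgcs,
        n_bgcs=n_bgcs,
        n_distinct_sms=n_sms,
    )
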