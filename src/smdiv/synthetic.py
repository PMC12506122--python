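"""Synthetic genome-mining inputs with full ground-truth bookkeeping.

Real inputs to this pipeline are genome-mining summaries: a species × GCF
incidence matrix, a bipartite BGC–SM link table, and molecular
fingerprints.  This module generates all three with the statistical
structure the analysis assumes, so every downstream stage can be tested
end-to-end without external data.

Incidence model
---------------
Each of ``s_true`` GCFs receives an occupancy count Y_i drawn from a Zipf
distribution truncated to {1..T} (pmf ∝ y^−α); the occupied units are
chosen uniformly without replacement, and each presence is expanded into
1 + Poisson(λ) BGC records (within-genome duplicate cluster copies).  The
two knobs are calibrated against the observed Aspergillus summary
statistics: α is solved so that P(Y = 1) matches the 3,607/4,463 (~80.8%)
singleton fraction, and λ so that the expected GCF:BGC count ratio matches
4,463/6,972 (~0.640).  Defaults: T = 135 units and s_true = 4,463 families,
giving ~51.6 BGCs per species.

Under truncated-Zipf occupancy every pool family is observed (Y ≥ 1), so
this model exercises the shape of the data, not detectability.  For
estimator-recovery experiments use :func:`gen_incidence_homogeneous`, a
homogeneous detection model in which each of ``s_true`` families is present
in each unit independently with probability ``p``; families missed by all T
units are genuinely undetected and the Chao2 target S_true is known.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import zipfian

from .chemdiv import FingerprintSet
from .effective_sm import BgcSmTable
from .incidence import BgcRecord, IncidenceMatrix, build_incidence

__all__ = [
    "SINGLETON_TARGET",
    "RATIO_TARGET",
    "IncidenceModel",
    "GroundTruth",
    "calibrate_occupancy",
    "calibrate_duplication",
    "default_incidence_model",
    "gen_incidence",
    "gen_incidence_homogeneous",
    "gen_bgc_sm_table",
    "gen_fingerprints",
    "write_dataset",
]

#: calibration targets from the 135-genome Aspergillus summary counts
SINGLETON_TARGET = 3607 / 4463
RATIO_TARGET = 4463 / 6972


def calibrate_occupancy(T: int, target_singleton_fraction: float = SINGLETON_TARGET,
                        tol: float = 1e-9) -> float:
    """Solve for the truncated-Zipf decay α with P(Y=1) at the target.

    P(Y=1 | α) increases monotonically from 1/T (α → 0, uniform) towards 1,
    so the target must lie strictly inside that range.
    """
    if not 0.0 < target_singleton_fraction < 1.0:
        raise ValueError("target singleton fraction must lie in (0, 1)")
    lo, hi = 1e-8, 80.0
    p_lo, p_hi = zipfian.pmf(1, lo, T), zipfian.pmf(1, hi, T)
    if not p_lo < target_singleton_fraction < p_hi:
        raise ValueError(
            f"target {target_singleton_fraction} unattainable for T={T}: "
            f"feasible range ({p_lo:.6f}, {p_hi:.6f})")
    return brentq(lambda a: zipfian.pmf(1, a, T) - target_singleton_fraction,
                  lo, hi, xtol=tol)


def calibrate_duplication(occupancy_alpha: float, T: int,
                          target_ratio: float = RATIO_TARGET) -> float:
    """Solve for the duplication rate λ hitting a GCF:BGC count ratio.

    Expected BGCs per family is E[Y]·(1+λ), so ratio = 1 / (E[Y]·(1+λ)).
    """
    ey = float(zipfian.mean(occupancy_alpha, T))
    lam = 1.0 / (target_ratio * ey) - 1.0
    if lam < 0:
        raise ValueError(
            f"ratio {target_ratio} unattainable: maximum {1.0 / ey:.4f} at λ=0")
    return lam


@dataclass(frozen=True)
class IncidenceModel:
    """Parameters of the truncated-Zipf incidence generator."""

    T: int = 135
    s_true: int = 4463
    occupancy_alpha: float | None = None  # None -> calibrated to SINGLETON_TARGET
    duplication_rate: float | None = None  # None -> calibrated to RATIO_TARGET
    seed: int = 0
    contig_edge_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.T < 2 or self.s_true < 1:
            raise ValueError("require T >= 2 and s_true >= 1")
        if self.duplication_rate is not None and self.duplication_rate < 0:
            raise ValueError("duplication_rate must be >= 0")
        if not 0.0 <= self.contig_edge_prob <= 1.0:
            raise ValueError("contig_edge_prob must lie in [0, 1]")

    def resolved(self) -> "IncidenceModel":
        """Fill calibrated defaults for any unset knob."""
        alpha = self.occupancy_alpha
        if alpha is None:
            alpha = calibrate_occupancy(self.T)
        lam = self.duplication_rate
        if lam is None:
            lam = calibrate_duplication(alpha, self.T)
        return IncidenceModel(T=self.T, s_true=self.s_true, occupancy_alpha=alpha,
                              duplication_rate=lam, seed=self.seed,
                              contig_edge_prob=self.contig_edge_prob)


def default_incidence_model(seed: int) -> IncidenceModel:
    return IncidenceModel(seed=seed).resolved()


@dataclass
class GroundTruth:
    """Generator bookkeeping; fields are populated by whichever generator ran."""

    s_true: int | None = None
    S_obs: int | None = None
    Q1: int | None = None
    Q2: int | None = None
    n_bgcs: int | None = None
    n_contig_edge: int | None = None
    singleton_fraction: float | None = None
    gcf_bgc_ratio: float | None = None
    sm_multiplicity: dict[str, int] | None = None
    n_distinct_sms: int | None = None
    fingerprint_families: dict[str, list[str]] | None = None
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _records_from_occupancy(Y: np.ndarray, T: int, lam: float, edge_prob: float,
                            rng: np.random.Generator) -> tuple[list[BgcRecord], int]:
    records: list[BgcRecord] = []
    n_edge = 0
    bgc_serial = 0
    width = len(str(T))
    for i, y in enumerate(Y):
        gcf = f"GCF{i + 1:05d}"
        units = rng.choice(T, size=int(y), replace=False)
        for u in np.sort(units):
            sp = f"sp{u + 1:0{width}d}"
            n_copies = 1 + int(rng.poisson(lam))
            for _ in range(n_copies):
                bgc_serial += 1
                edge = bool(rng.random() < edge_prob) if edge_prob > 0 else False
                n_edge += edge
                records.append(BgcRecord(
                    bgc_id=f"BGC{bgc_serial:06d}", gcf_id=gcf,
                    genome_id=f"g_{sp}", species_id=sp,
                    bgc_class=None, contig_edge=edge))
    return records, n_edge


def gen_incidence(model: IncidenceModel) -> tuple[list[BgcRecord], IncidenceMatrix, GroundTruth]:
    """Draw records and their incidence matrix from the truncated-Zipf model.

    Pure function of (parameters, seed): identical models give identical
    output.  The matrix is rebuilt from the records through
    :func:`~smdiv.incidence.build_incidence`, so the two are consistent by
    construction.
    """
    model = model.resolved()
    rng = np.random.default_rng(model.seed)
    Y = np.asarray(zipfian.rvs(model.occupancy_alpha, model.T,
                               size=model.s_true, random_state=rng))
    records, n_edge = _records_from_occupancy(
        Y, model.T, model.duplication_rate, model.contig_edge_prob, rng)
    matrix = build_incidence(records, unit_level="species")
    truth = GroundTruth(
        s_true=model.s_true,
        S_obs=int(Y.size),
        Q1=int((Y == 1).sum()),
        Q2=int((Y == 2).sum()),
        n_bgcs=len(records),
        n_contig_edge=n_edge,
        singleton_fraction=float((Y == 1).mean()),
        gcf_bgc_ratio=Y.size / len(records),
        params={"model": asdict(model)},
    )
    return records, matrix, truth


def gen_incidence_homogeneous(
    T: int, s_true: int, detection_prob: float, seed: int,
) -> tuple[IncidenceMatrix, GroundTruth]:
    """Homogeneous detection model: Y_i ~ Binomial(T, p), zeros undetected.

    Every family has the same per-unit presence probability, so families
    missed by all T units are genuinely undetected and S_true = ``s_true``
    is a meaningful recovery target for Chao2-type estimation.
    """
    if not 0.0 < detection_prob < 1.0:
        raise ValueError("detection_prob must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    Y_all = rng.binomial(T, detection_prob, size=s_true)
    detected = np.flatnonzero(Y_all > 0)
    if detected.size == 0:
        raise ValueError("no family detected; increase T, s_true or detection_prob")
    width = len(str(T))
    unit_ids = [f"sp{u + 1:0{width}d}" for u in range(T)]
    gcf_ids = [f"GCF{i + 1:05d}" for i in detected]
    cells = np.zeros((T, detected.size), dtype=np.uint8)
    for j, i in enumerate(detected):
        units = rng.choice(T, size=int(Y_all[i]), replace=False)
        cells[units, j] = 1
    Y = Y_all[detected]
    matrix = IncidenceMatrix(unit_ids=unit_ids, gcf_ids=gcf_ids, cells=cells)
    truth = GroundTruth(
        s_true=s_true, S_obs=int(detected.size),
        Q1=int((Y == 1).sum()), Q2=int((Y == 2).sum()),
        singleton_fraction=float((Y == 1).mean()),
        params={"T": T, "detection_prob": detection_prob, "seed": seed},
    )
    return matrix, truth


def gen_bgc_sm_table(
    n_bgcs: int,
    mean_sms_per_bgc: float = 1.6,
    sharing_prob: float = 0.2,
    seed: int = 0,
) -> tuple[BgcSmTable, GroundTruth]:
    """Bipartite BGC–SM links with tunable SM sharing.

    Each BGC is linked to 1 + Poisson(mean_sms_per_bgc − 1) SMs.  Each link
    reuses an SM from the existing pool with probability ``sharing_prob``
    (creating shared compounds), otherwise mints a novel SM.  A reuse that
    would duplicate a pair within the same BGC falls back to a novel SM, so
    the pair set stays duplicate-free.
    """
    if n_bgcs < 1 or mean_sms_per_bgc < 1:
        raise ValueError("need n_bgcs >= 1 and mean_sms_per_bgc >= 1")
    if not 0.0 <= sharing_prob <= 1.0:
        raise ValueError("sharing_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    pool: list[str] = []
    serial = 0
    for b in range(n_bgcs):
        bgc = f"BGC{b + 1:06d}"
        mine: set[str] = set()
        n_sms = 1 + int(rng.poisson(mean_sms_per_bgc - 1.0))
        for _ in range(n_sms):
            sm = None
            if pool and rng.random() < sharing_prob:
                cand = pool[int(rng.integers(len(pool)))]
                if cand not in mine:
                    sm = cand
            if sm is None:
                serial += 1
                sm = f"SM{serial:06d}"
                pool.append(sm)
            mine.add(sm)
            pairs.append((bgc, sm))
    table = BgcSmTable.from_pairs(pairs)
    from .effective_sm import sm_multiplicity
    mult = sm_multiplicity(table)
    truth = GroundTruth(
        n_bgcs=n_bgcs, sm_multiplicity=mult, n_distinct_sms=len(mult),
        params={"n_bgcs": n_bgcs, "mean_sms_per_bgc": mean_sms_per_bgc,
                "sharing_prob": sharing_prob, "seed": seed},
    )
    return table, truth


def gen_fingerprints(
    n_families: int,
    per_family: int,
    bits_per_fp: int = 256,
    within_family_overlap: float = 0.8,
    seed: int = 0,
) -> tuple[FingerprintSet, GroundTruth]:
    """Structured fingerprint families: shared cores plus member noise.

    Bit positions are partitioned into disjoint family cores (plus a spare
    noise region).  Every member carries its family's full core; in
    addition it sets ``round((1 − overlap) · core_size)`` random bits
    outside the core.  At overlap = 1 members of a family are identical;
    lower overlap increases within-family variation.  Disjoint cores keep
    between-family similarity below within-family similarity in
    expectation.
    """
    if n_families < 1 or per_family < 1 or bits_per_fp < 2 * n_families:
        raise ValueError("need n_families, per_family >= 1 and bits_per_fp >= 2*n_families")
    if not 0.0 <= within_family_overlap <= 1.0:
        raise ValueError("within_family_overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    core_size = max(1, bits_per_fp // (2 * n_families))
    n_noise = round((1.0 - within_family_overlap) * core_size)
    ids, rows = [], []
    families: dict[str, list[str]] = {}
    for f in range(n_families):
        core = np.arange(f * core_size, (f + 1) * core_size)
        fam = f"fam{f + 1:03d}"
        families[fam] = []
        non_core = np.setdiff1d(np.arange(bits_per_fp), core)
        for m in range(per_family):
            cid = f"{fam}_c{m + 1:03d}"
            row = np.zeros(bits_per_fp, dtype=np.uint8)
            row[core] = 1
            if n_noise:
                row[rng.choice(non_core, size=n_noise, replace=False)] = 1
            ids.append(cid)
            rows.append(row)
            families[fam].append(cid)
    fps = FingerprintSet(ids=ids, bits=np.array(rows, dtype=np.uint8))
    truth = GroundTruth(
        fingerprint_families=families,
        params={"n_families": n_families, "per_family": per_family,
                "bits_per_fp": bits_per_fp,
                "within_family_overlap": within_family_overlap, "seed": seed},
    )
    return fps, truth


def write_dataset(out_dir: str | Path, model: IncidenceModel,
                  sm_kwargs: dict | None = None,
                  fp_kwargs: dict | None = None) -> dict[str, Path]:
    """Emit a full synthetic dataset in the TSV dialects the readers consume.

    Writes a BiG-SCAPE-style clustering table, the BGC metadata sidecar, a
    BGC–SM link table, a fingerprint table, the incidence matrix, and
    ``ground_truth.json``; returns the path of each artefact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, matrix, truth = gen_incidence(model)

    clustering = out / "clustering.tsv"
    pd.DataFrame({"#BGC Name": [r.bgc_id for r in records],
                  "Family Number": [r.gcf_id for r in records]}).to_csv(
        clustering, sep="\t", index=False)
    metadata = out / "bgc_metadata.tsv"
    pd.DataFrame({"bgc_id": [r.bgc_id for r in records],
                  "genome_id": [r.genome_id for r in records],
                  "species_id": [r.species_id for r in records],
                  "contig_edge": [int(bool(r.contig_edge)) for r in records]}).to_csv(
        metadata, sep="\t", index=False)
    incidence_tsv = out / "incidence.tsv"
    matrix.write_tsv(incidence_tsv)

    sm_kwargs = {"n_bgcs": 158, "seed": model.seed, **(sm_kwargs or {})}
    table, sm_truth = gen_bgc_sm_table(**sm_kwargs)
    links = out / "bgc_sm_links.tsv"
    pd.DataFrame(sorted(table.links), columns=["bgc_id", "sm_id"]).to_csv(
        links, sep="\t", index=False)

    fp_kwargs = {"n_families": 8, "per_family": 12, "seed": model.seed,
                 **(fp_kwargs or {})}
    fps, fp_truth = gen_fingerprints(**fp_kwargs)
    fp_tsv = out / "fingerprints.tsv"
    fps.write_tsv(fp_tsv)

    truth.sm_multiplicity = sm_truth.sm_multiplicity
    truth.n_distinct_sms = sm_truth.n_distinct_sms
    truth.fingerprint_families = fp_truth.fingerprint_families
    truth.params.update({"sm": sm_truth.params, "fingerprints": fp_truth.params})
    gt = out / "ground_truth.json"
    truth.to_json(gt)
    return {"clustering": clustering, "metadata": metadata, "incidence": incidence_tsv,
            "links": links, "fingerprints": fp_tsv, "ground_truth": gt}
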