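"""Paired tests, diversity, distance-based multivariate tests, variation
partitioning and carbon-pool bookkeeping.

The permutation tests (PERMANOVA / ANOSIM / MRPP) are written from scratch on
a shared distance-matrix container so their permutation schemes (free or
block-restricted) and p-value convention p = (1 + #{perm >= obs}) / (1 + n)
are identical across statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import (
    CountTable,
    FractionRecord,
    SampleMetadata,
    ValidationError,
    CONTROL,
    WARMING,
    paired_arrays,
)


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    mean_control: float
    mean_warming: float
    flag: str = ""


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValidationError("distance matrix diagonal not zero")


@dataclass
class MultivariateTestResult:
    method: str
    statistic: float
    p: float
    n_perm: int
    seed: int | None
    extras: dict = field(default_factory=dict)


def paired_t(x_control: Sequence[float], x_warming: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test on block-aligned arrays.

    t = mean(d) / (sd(d) / sqrt(n)) with d the within-block differences and
    df = n - 1. A zero-variance difference vector is flagged degenerate.
    """
    x = np.asarray(x_control, float)
    y = np.asarray(x_warming, float)
    if x.shape != y.shape:
        raise ValidationError("paired arrays must have equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("paired t-test needs at least 3 pairs")
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return PairedTResult(0.0, n - 1, 1.0, x.mean(), y.mean(), flag="all differences zero")
        t = np.inf * np.sign(d.mean())
        return PairedTResult(float(t), n - 1, 0.0, x.mean(), y.mean(), flag="zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedTResult(float(t), n - 1, float(p), float(x.mean()), float(y.mean()))


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample richness and Shannon-Wiener H = -sum p ln p (natural log)."""
    sums = table.sample_sums()
    if np.any(sums == 0):
        empty = [s for s, tot in zip(table.sample_ids, sums) if tot == 0]
        raise ValidationError(f"empty samples: {empty}")
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        nz = col[col > 0]
        p = nz / nz.sum()
        rows.append({"sample_id": sid, "richness": int(len(nz)), "shannon": float(-(p * np.log(p)).sum())})
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(i,j) = sum|x-y| / sum(x+y) between samples."""
    x = table.counts.T.astype(float)  # samples x features
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        den = (x[i] + x[i + 1:]).sum(axis=1)
        if np.any(den == 0):
            j = i + 1 + int(np.argmax(den == 0))
            raise ValidationError(
                f"Bray-Curtis undefined for all-zero pair ({table.sample_ids[i]}, {table.sample_ids[j]})"
            )
        d[i, i + 1:] = d[i + 1:, i] = num / den
    return DistanceMatrix(list(table.sample_ids), d)


# ---------------------------------------------------------------------------
# Permutation multivariate tests
# ---------------------------------------------------------------------------


def _group_indices(dm: DistanceMatrix, groups: Mapping[str, str]) -> np.ndarray:
    labels = np.array([groups[s] for s in dm.sample_ids])
    uniq, idx = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    counts = np.bincount(idx)
    if np.any(counts < 2):
        singles = uniq[counts < 2]
        raise ValidationError(f"singleton groups: {list(singles)}")
    return idx


def _permutations(
    n: int, n_perm: int, seed: int | None, strata: Sequence[str] | None, exhaustive_labels=None
):
    """Yield permuted index arrays; free or within-strata shuffles."""
    rng = np.random.default_rng(seed)
    base = np.arange(n)
    if strata is None:
        for _ in range(n_perm):
            yield rng.permutation(n)
    else:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
        for _ in range(n_perm):
            perm = base.copy()
            for g in groups:
                perm[g] = g[rng.permutation(len(g))]
            yield perm


def _permanova_f(d2: np.ndarray, idx: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(idx == g)
        sub = d2[np.ix_(members, members)]
        ssw += sub[np.triu_indices(len(members), 1)].sum() / len(members)
    ssa = sst - ssw
    a = n_groups
    return (ssa / (a - 1)) / (ssw / (n - a))


def permanova(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
    strata: Mapping[str, str] | None = None,
    method: str = "permutation",
) -> MultivariateTestResult:
    """One-factor PERMANOVA (Adonis) pseudo-F with permutation p-value.

    ``method='exact'`` enumerates all distinct label assignments (small n
    only) and reports p as the exact tail fraction including the observed
    assignment.
    """
    idx = _group_indices(dm, groups)
    n_groups = idx.max() + 1
    d2 = dm.d**2
    f_obs = _permanova_f(d2, idx, n_groups)
    if method == "exact":
        stats = [
            _permanova_f(d2, np.array(perm), n_groups)
            for perm in set(itertools.permutations(idx))
        ]
        p = float(np.mean([s >= f_obs - 1e-12 for s in stats]))
        return MultivariateTestResult("permanova", float(f_obs), p, len(stats), seed)
    strata_v = [strata[s] for s in dm.sample_ids] if strata else None
    count = 0
    for perm in _permutations(len(idx), n_perm, seed, strata_v):
        if _permanova_f(d2, idx[perm], n_groups) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MultivariateTestResult("permanova", float(f_obs), float(p), n_perm, seed)


def _anosim_r(rank_d: np.ndarray, idx: np.ndarray) -> float:
    n = rank_d.shape[0]
    iu = np.triu_indices(n, 1)
    same = idx[iu[0]] == idx[iu[1]]
    r_within = rank_d[iu][same].mean()
    r_between = rank_d[iu][~same].mean()
    return (r_between - r_within) / (n * (n - 1) / 4.0)


def anosim(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
    strata: Mapping[str, str] | None = None,
) -> MultivariateTestResult:
    """ANOSIM R = (mean between-group rank - mean within-group rank) / (N(N-1)/4)."""
    idx = _group_indices(dm, groups)
    n = dm.d.shape[0]
    iu = np.triu_indices(n, 1)
    rank_flat = sps.rankdata(dm.d[iu])
    rank_d = np.zeros_like(dm.d)
    rank_d[iu] = rank_flat
    rank_d = rank_d + rank_d.T
    r_obs = _anosim_r(rank_d, idx)
    strata_v = [strata[s] for s in dm.sample_ids] if strata else None
    count = 0
    for perm in _permutations(n, n_perm, seed, strata_v):
        if _anosim_r(rank_d, idx[perm]) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MultivariateTestResult("anosim", float(r_obs), float(p), n_perm, seed)


def _mrpp_delta(d: np.ndarray, idx: np.ndarray, n_groups: int) -> float:
    n = d.shape[0]
    delta = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(idx == g)
        sub = d[np.ix_(members, members)]
        k = len(members)
        delta += (k / n) * sub[np.triu_indices(k, 1)].mean()
    return delta


def mrpp(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
    strata: Mapping[str, str] | None = None,
) -> MultivariateTestResult:
    """MRPP: delta = group-size-weighted mean within-group distance;
    chance-corrected agreement A = 1 - delta/E[delta]; small delta is extreme."""
    idx = _group_indices(dm, groups)
    n_groups = idx.max() + 1
    d_obs = _mrpp_delta(dm.d, idx, n_groups)
    strata_v = [strata[s] for s in dm.sample_ids] if strata else None
    perm_deltas = [
        _mrpp_delta(dm.d, idx[perm], n_groups)
        for perm in _permutations(len(idx), n_perm, seed, strata_v)
    ]
    count = sum(1 for pd_ in perm_deltas if pd_ <= d_obs + 1e-12)
    p = (1 + count) / (1 + n_perm)
    expected = float(np.mean(perm_deltas))
    a = 1.0 - d_obs / expected
    return MultivariateTestResult(
        "mrpp", float(d_obs), float(p), n_perm, seed, extras={"A": a, "expected_delta": expected}
    )


# ---------------------------------------------------------------------------
# RDA variation partitioning
# ---------------------------------------------------------------------------


def _rda_r2(y: np.ndarray, x: np.ndarray) -> float:
    """Unadjusted redundancy statistic: share of total variance of centred Y
    explained by the linear fit on X (with intercept)."""
    yc = y - y.mean(axis=0)
    design = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(design, yc, rcond=None)
    fitted = design @ coef
    return float((fitted**2).sum() / (yc**2).sum())


def _adjust_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rda_varpart(
    response: pd.DataFrame, set_plant: pd.DataFrame, set_soil: pd.DataFrame
) -> dict[str, float]:
    """Partition adjusted explained variance of ``response`` between two
    covariate sets by inclusion-exclusion on marginal and joint RDAs.

    Components may be slightly negative; they are reported as computed.
    """
    n = len(response)
    p1, p2 = set_plant.shape[1], set_soil.shape[1]
    if n <= p1 + p2 + 2:
        raise ValidationError("need n samples > total covariates + 2")
    for name, x in (("plant", set_plant), ("soil", set_soil)):
        arr = np.column_stack([np.ones(n), x.to_numpy(float)])
        if np.linalg.matrix_rank(arr) < arr.shape[1]:
            raise ValidationError(f"collinear covariates in {name} set: {list(x.columns)}")
    joint = np.column_stack([np.ones(n), set_plant.to_numpy(float), set_soil.to_numpy(float)])
    if np.linalg.matrix_rank(joint) < joint.shape[1]:
        raise ValidationError(
            f"collinear covariates across sets: {list(set_plant.columns) + list(set_soil.columns)}"
        )
    y = response.to_numpy(float)
    r2_plant = _adjust_r2(_rda_r2(y, set_plant.to_numpy(float)), n, p1)
    r2_soil = _adjust_r2(_rda_r2(y, set_soil.to_numpy(float)), n, p2)
    x_joint = np.column_stack([set_plant.to_numpy(float), set_soil.to_numpy(float)])
    r2_joint = _adjust_r2(_rda_r2(y, x_joint), n, p1 + p2)
    unique_plant = r2_joint - r2_soil
    unique_soil = r2_joint - r2_plant
    shared = r2_plant + r2_soil - r2_joint
    return {
        "unique_plant": unique_plant,
        "unique_soil": unique_soil,
        "shared": shared,
        "residual": 1.0 - r2_joint,
        "total_adj_r2": r2_joint,
    }


# ---------------------------------------------------------------------------
# Carbon pools
# ---------------------------------------------------------------------------


def carbon_pools(
    fractions: Sequence[FractionRecord],
    rh_series: pd.DataFrame | None,
    metadata: Sequence[SampleMetadata],
) -> dict:
    """Fraction C proportions, recovery diagnostics and the R_h warming effect.

    Per-sample fraction C stock = fraction mass x fraction C concentration;
    proportions are relative to summed recovered C (robust to <100% recovery).
    The warming effect on R_h is (mean_W - mean_C) / mean_C x 100 on
    per-sample seasonal means.
    """
    rows = []
    for rec in fractions:
        stocks = {
            "poc": rec.poc_mass_g / 1000.0 * rec.poc_c_g_kg,
            "heavy_poc": rec.heavy_poc_mass_g / 1000.0 * rec.heavy_poc_c_g_kg,
            "maoc": rec.maom_mass_g / 1000.0 * rec.maoc_c_g_kg,
        }
        recovered_c = sum(stocks.values())
        bulk_c = rec.initial_mass_g / 1000.0 * rec.bulk_soc_g_kg
        c_recovery = recovered_c / bulk_c
        flags = []
        if c_recovery > 1.05:
            flags.append(f"C recovery {c_recovery:.3f} > 1.05")
        rows.append(
            {
                "sample_id": rec.sample_id,
                "prop_poc": stocks["poc"] / recovered_c,
                "prop_heavy_poc": stocks["heavy_poc"] / recovered_c,
                "prop_maoc": stocks["maoc"] / recovered_c,
                "mass_recovery": rec.mass_recovery(),
                "c_recovery": c_recovery,
                "flags": "; ".join(flags),
            }
        )
    frac_df = pd.DataFrame(rows).set_index("sample_id")
    contrasts = {}
    for var in ("prop_maoc", "prop_poc", "prop_heavy_poc"):
        ctrl, warm, _ = paired_arrays(metadata, frac_df[var].to_dict())
        contrasts[var] = paired_t(ctrl, warm)
    out: dict = {"fractions": frac_df, "contrasts": contrasts}
    if rh_series is not None and len(rh_series):
        sample_means = rh_series.groupby("sample_id")["rh"].mean()
        ctrl, warm, _ = paired_arrays(metadata, sample_means.to_dict())
        out["rh_sample_means"] = sample_means
        out["rh_mean_control"] = float(ctrl.mean())
        out["rh_mean_warming"] = float(warm.mean())
        out["rh_warming_effect_pct"] = float((warm.mean() - ctrl.mean()) / ctrl.mean() * 100.0)
        out["rh_contrast"] = paired_t(ctrl, warm)
    return out
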