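"""Gene-centric functional profiling: length-normalised relative abundance,
aggregation to CAZy families/classes or KO sets, and LEfSe-style
differential-abundance scoring.

The per-gene relative abundance divides the read count by the gene length
before normalising, RA_i = (r_i / L_i) / sum_j (r_j / L_j), so long genes do
not dominate simply by recruiting more reads. Family scores follow the LEfSe
recipe for a two-group design without subclasses: a Kruskal-Wallis screen at
p < 0.05, then a bootstrap-averaged linear-discriminant effect size on
parts-per-million-scaled abundances, reported on the log10 scale with the
conventional |LDA| > 2 cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import CountTable, SampleMetadata, ValidationError, paired_arrays
from . import stats as pstats

CAZY_CLASSES = ("GH", "GT", "CBM", "CE", "PL", "AA")
PPM = 1e6


@dataclass
class LDAResult:
    family: str
    kw_p: float
    lda_score: float
    enriched_in: str  # control | warming | none


def _lengths(table: CountTable) -> np.ndarray:
    lens = []
    for fid in table.feature_ids:
        meta = table.feature_meta.get(fid, {})
        L = meta.get("length_bp")
        if L is None:
            raise ValidationError(f"gene {fid!r} missing length_bp annotation")
        lens.append(float(L))
    return np.array(lens)


def relative_abundance(table: CountTable, sample: str) -> pd.Series:
    """Length-normalised relative abundance of every gene in one sample."""
    j = table.sample_ids.index(sample)
    counts = table.counts[:, j].astype(float)
    if counts.sum() == 0:
        raise ValidationError(f"sample {sample!r} has no mapped reads")
    ratios = counts / _lengths(table)
    return pd.Series(ratios / ratios.sum(), index=table.feature_ids, name=sample)


def relative_abundance_matrix(table: CountTable) -> pd.DataFrame:
    """Genes x samples matrix of length-normalised relative abundances."""
    counts = table.counts.astype(float)
    if np.any(counts.sum(axis=0) == 0):
        empty = [s for s, t in zip(table.sample_ids, counts.sum(axis=0)) if t == 0]
        raise ValidationError(f"samples with no mapped reads: {empty}")
    ratios = counts / _lengths(table)[:, None]
    ra = ratios / ratios.sum(axis=0, keepdims=True)
    return pd.DataFrame(ra, index=table.feature_ids, columns=table.sample_ids)


def aggregate(table: CountTable, level: str = "family") -> pd.DataFrame:
    """Sum gene relative abundances per annotation label.

    ``level`` is 'family', 'cazy_class' or 'ko'. Genes without the annotation
    still contribute to the relative-abundance denominator but to no label,
    so label totals are sub-additive (<= 1 per sample).
    """
    if level not in ("family", "cazy_class", "ko"):
        raise ValidationError(f"unknown aggregation level {level!r}")
    ra = relative_abundance_matrix(table)
    labels = [table.feature_meta.get(f, {}).get(level) for f in table.feature_ids]
    ra = ra.assign(_label=labels)
    grouped = ra.dropna(subset=["_label"]).groupby("_label").sum()
    grouped.index.name = level
    return grouped


def lefse(
    family_ra: pd.DataFrame,
    groups: Mapping[str, str],
    n_boot: int = 30,
    subsample_frac: float = 2 / 3,
    seed: int | None = None,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    fdr: bool = False,
) -> list[LDAResult]:
    """Two-group LEfSe-style scoring of a family x sample abundance table.

    Per family: Kruskal-Wallis on the raw abundances; if significant, the
    effect size is the bootstrap average (random ``subsample_frac`` subsets
    per group) of the group-mean difference along the discriminant axis on
    ppm-scaled data, log10-transformed. For a single family the discriminant
    axis coincides with the family axis, so the effect is the ppm group-mean
    difference itself. Positive scores mark warming-enriched families.
    Set ``fdr`` to apply a Benjamini-Hochberg correction to the screen.
    """
    sample_ids = list(family_ra.columns)
    labels = np.array([groups[s] for s in sample_ids])
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValidationError(f"LEfSe here supports exactly 2 groups, got {uniq}")
    g1, g2 = uniq  # alphabetical: control, warming
    idx1 = np.flatnonzero(labels == g1)
    idx2 = np.flatnonzero(labels == g2)
    if len(idx1) < 3 or len(idx2) < 3:
        raise ValidationError("need at least 3 samples per group")
    rng = np.random.default_rng(seed)
    x = family_ra.to_numpy(float) * PPM
    pvals = np.ones(len(family_ra))
    for i, row in enumerate(x):
        if np.ptp(row) == 0:
            continue  # constant feature: p = 1, skipped
        pvals[i] = sps.kruskal(row[idx1], row[idx2]).pvalue
    screen = pvals
    if fdr:
        screen = sps.false_discovery_control(pvals, method="bh")
    n1 = max(3, int(math.ceil(subsample_frac * len(idx1))))
    n2 = max(3, int(math.ceil(subsample_frac * len(idx2))))
    results = []
    for i, fam in enumerate(family_ra.index):
        if screen[i] >= alpha:
            results.append(LDAResult(str(fam), float(pvals[i]), 0.0, "none"))
            continue
        diffs = []
        for _ in range(n_boot):
            s1 = rng.choice(idx1, size=n1, replace=False)
            s2 = rng.choice(idx2, size=n2, replace=False)
            diffs.append(x[i, s2].mean() - x[i, s1].mean())  # warming minus control
        effect = float(np.mean(diffs))
        magnitude = math.log10(max(abs(effect), 1.0))
        score = math.copysign(magnitude, effect)
        if abs(score) > lda_threshold:
            enriched = g2 if score > 0 else g1
        else:
            enriched = "none"
        results.append(LDAResult(str(fam), float(pvals[i]), score, enriched))
    return results


def total_cazy_contrast(
    table: CountTable, metadata: Sequence[SampleMetadata]
) -> pstats.PairedTResult:
    """Paired two-sided t-test on the per-sample summed CAZy relative abundance."""
    ra = relative_abundance_matrix(table)
    annotated = [
        f for f in table.feature_ids if table.feature_meta.get(f, {}).get("cazy_class") in CAZY_CLASSES
    ]
    totals = ra.loc[annotated].sum(axis=0)
    ctrl, warm, _ = paired_arrays(metadata, totals.to_dict())
    return pstats.paired_t(ctrl, warm)
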