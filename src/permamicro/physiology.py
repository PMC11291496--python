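"""Microbial physiology from heavy-oxygen-water incubations.

Growth is measured substrate-independently: soil is incubated with
:sup:`18`O-enriched water, newly synthesised DNA incorporates the label, and
the excess :sup:`18`O of the DNA extract yields the amount of DNA produced.
Combining that with the biomass-C-to-DNA ratio gives gross growth ``G``;
headspace CO2 against empty blank vials gives respiration ``R``; carbon use
efficiency is ``CUE = G / (G + R)`` and turnover ``T_m = G / C_mic x 24``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import IncubationRecord, PairedExperiment, paired_arrays
from . import stats as pstats

#: mass percentage of oxygen in an average DNA molecule
O_PCT_IN_DNA = 31.21
#: chloroform fumigation-extraction efficiency for microbial biomass C
FUMIGATION_KEC = 0.45
#: ideal gas constant, J mol^-1 K^-1
R_GAS = 8.314462618
#: standard atmosphere, Pa
P_ATM = 101325.0
#: molar mass of carbon, g mol^-1
C_MOLAR_G = 12.011


@dataclass
class PhysiologyResult:
    """Per-sample physiology estimates (units in field names/docs)."""

    sample_id: str
    R: float  # ug C g^-1 dry soil h^-1
    G: float  # ug C g^-1 dry soil h^-1
    MBC: float  # ug C g^-1 dry soil
    DNA_produced: float  # ug
    CUE: float
    T_m: float  # day^-1
    G_m: float  # mg C g^-1 Cmic h^-1
    R_m: float  # mg C g^-1 Cmic h^-1
    flags: str = ""


def headspace_mol(vial_volume_ml: float, temp_C: float) -> float:
    """Total mol of gas in the vial headspace by the ideal gas law.

    The soil plug volume (~0.3 g in a 50 ml vial) is neglected.
    """
    volume_m3 = vial_volume_ml * 1e-6
    return P_ATM * volume_m3 / (R_GAS * (temp_C + 273.15))


def respiration_rate(rec: IncubationRecord) -> float:
    """Respiration R (ug C g^-1 dry soil h^-1) from the headspace CO2 buildup
    relative to the empty blank vial. A sample below the blank is floored at
    zero with a warning (small-signal noise, not an error)."""
    delta_ppm = rec.co2_sample_ppm - rec.co2_blank_ppm
    if delta_ppm < 0:
        warnings.warn(
            f"{rec.sample_id}: headspace CO2 below blank ({delta_ppm:.1f} ppm); R floored at 0"
        )
        return 0.0
    mol_co2 = delta_ppm * 1e-6 * headspace_mol(rec.vial_volume_ml, rec.temp_C)
    ug_c = mol_co2 * C_MOLAR_G * 1e6
    return ug_c / (rec.soil_dry_mass_g * rec.duration_h)


def o_excess(rec: IncubationRecord, natural_mean_pct: float | None = None) -> float:
    """Surplus at% 18O of the labelled DNA over the natural-abundance mean.

    ``natural_mean_pct`` should be the mean across the run's natural-abundance
    replicates; the record's own value is used when not supplied. Negative
    excess is floored at zero (no label incorporated)."""
    nat = rec.at18O_natural_pct if natural_mean_pct is None else natural_mean_pct
    ex = rec.at18O_labelled_pct - nat
    if ex < 0:
        warnings.warn(f"{rec.sample_id}: negative 18O excess ({ex:.4f} at%); floored at 0")
        return 0.0
    return ex


def dna_produced(rec: IncubationRecord, natural_mean_pct: float | None = None) -> float:
    """DNA newly produced over the incubation (ug).

    DNA_produced = O_total * (O_excess/100) * (100/O_label) * (100/31.21),
    where 31.21 is the mass % of O in DNA.
    """
    if rec.o_label_pct <= 0:
        raise ValueError(f"{rec.sample_id}: o_label_pct must be > 0")
    ex = o_excess(rec, natural_mean_pct)
    return rec.o_total_ug * (ex / 100.0) * (100.0 / rec.o_label_pct) * (100.0 / O_PCT_IN_DNA)


def mbc(rec: IncubationRecord) -> float:
    """Microbial biomass C (ug C g^-1) from the fumigation-extraction flush
    divided by the extraction efficiency 0.45."""
    flush = rec.c_fumigated_ug_per_g - rec.c_unfumigated_ug_per_g
    if flush < 0:
        raise ValueError(f"{rec.sample_id}: fumigated C below unfumigated C (flush {flush:.2f})")
    return flush / FUMIGATION_KEC


def growth_rate(rec: IncubationRecord, dna_prod: float, mbc_val: float) -> float:
    """Growth G (ug C g^-1 h^-1) = ((C_mic / DNA_mic) * DNA_produced) / (w * t)."""
    if rec.dna_mic_ug_per_g <= 0:
        raise ValueError(f"{rec.sample_id}: dna_mic_ug_per_g must be > 0")
    return (mbc_val / rec.dna_mic_ug_per_g) * dna_prod / (rec.soil_dry_mass_g * rec.duration_h)


def cue(G: float, R: float) -> float:
    """Carbon use efficiency G / (G + R)."""
    if G + R <= 0:
        raise ValueError("CUE undefined for G + R <= 0")
    return G / (G + R)


def turnover(G: float, c_mic: float) -> float:
    """Turnover rate T_m (day^-1) = G / C_mic * 24."""
    if c_mic <= 0:
        raise ValueError("turnover undefined for C_mic <= 0")
    return G / c_mic * 24.0


def mass_specific(G: float, R: float, c_mic: float) -> tuple[float, float]:
    """Biomass-specific growth and respiration (mg C g^-1 Cmic h^-1)."""
    if c_mic <= 0:
        raise ValueError("mass-specific rates undefined for C_mic <= 0")
    return 1000.0 * G / c_mic, 1000.0 * R / c_mic


def physiology_results(records: Sequence[IncubationRecord]) -> list[PhysiologyResult]:
    """Evaluate the full physiology chain for a run of incubation records.

    The natural-abundance baseline is the mean at% 18O over all records in the
    run, mirroring how natural-abundance replicates are pooled.
    """
    if not records:
        return []
    nat_mean = float(np.mean([r.at18O_natural_pct for r in records]))
    out = []
    for rec in records:
        flags = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            R = respiration_rate(rec)
            dna = dna_produced(rec, nat_mean)
        flags.extend(str(w.message) for w in caught)
        c_mic = mbc(rec)
        G = growth_rate(rec, dna, c_mic)
        g_m, r_m = mass_specific(G, R, c_mic)
        out.append(
            PhysiologyResult(
                sample_id=rec.sample_id,
                R=R,
                G=G,
                MBC=c_mic,
                DNA_produced=dna,
                CUE=cue(G, R),
                T_m=turnover(G, c_mic),
                G_m=g_m,
                R_m=r_m,
                flags="; ".join(flags),
            )
        )
    return out


def physiology_table(
    experiment: PairedExperiment,
) -> tuple[pd.DataFrame, dict[str, pstats.PairedTResult]]:
    """Per-sample physiology table plus paired warming-vs-control contrasts
    (two-sided paired t) for G_m, R_m, CUE and T_m."""
    results = physiology_results(experiment.incubations)
    df = pd.DataFrame([vars(r) for r in results]).set_index("sample_id")
    contrasts: dict[str, pstats.PairedTResult] = {}
    for var in ("G_m", "R_m", "CUE", "T_m"):
        ctrl, warm, _ = paired_arrays(experiment.metadata, df[var].to_dict())
        contrasts[var] = pstats.paired_t(ctrl, warm)
    return df, contrasts
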