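"""Microbial necromass carbon from amino-sugar biomarkers.

Muramic acid (MurA) occurs only in bacterial cell walls, so bacterial
necromass C is a fixed stoichiometric multiple of MurA. Glucosamine (GluN)
is shared between fungi and bacteria; the fungal share is GluN minus two
moles of GluN per mole of bacterial MurA, converted to C:

    bacterial C = 45 * m
    fungal C    = (n/179.17 - 2 * m/251.23) * 179.17 * 9

with m, n the MurA and GluN contents (ug g^-1 dry soil), 179.17 and 251.23
the molecular weights of GluN and MurA, and 45 / 9 the residue-to-C
conversion factors. Total necromass C is their sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core_io import AminoSugarProfile, SampleMetadata, ValidationError, paired_arrays
from . import stats as pstats

MURA_TO_BACTERIAL_C = 45.0
GLUN_TO_FUNGAL_C = 9.0
MW_GLUN = 179.17
MW_MURA = 251.23

#: 1 g kg^-1 = 1000 ug g^-1 (SOC is reported in g C kg^-1 dry soil)
UG_PER_G_PER_G_KG = 1000.0


@dataclass
class NecromassResult:
    sample_id: str
    bacterial_c: float  # ug C g^-1 dry soil
    fungal_c: float
    total_c: float
    total_amino_sugars: float  # ug g^-1, GluN + GalN + MurA
    prop_of_soc: float
    flags: str = ""


def amino_sugar_content(
    peak_area: float,
    is_area: float,
    is_mass_ug: float,
    response_factor: float,
    soil_mass_g: float,
) -> float:
    """Quantify one analyte against the internal standard:
    content = (peak_area / is_area) * is_mass * response_factor / soil_mass."""
    if is_area <= 0:
        raise ValidationError("internal-standard peak area must be > 0")
    if soil_mass_g <= 0:
        raise ValidationError("soil mass must be > 0")
    return (peak_area / is_area) * is_mass_ug * response_factor / soil_mass_g


def bacterial_necromass(m: float) -> float:
    """Bacterial necromass C (ug C g^-1) = 45 * MurA content."""
    if m < 0:
        raise ValidationError(f"MurA content must be >= 0, got {m}")
    return MURA_TO_BACTERIAL_C * m


def fungal_necromass(n: float, m: float) -> float:
    """Fungal necromass C (ug C g^-1) from GluN after subtracting the
    bacterial GluN share (2 mol GluN per mol MurA). A negative result
    (bacterial GluN exceeding total GluN) is floored at 0 with a warning."""
    if n < 0 or m < 0:
        raise ValidationError("amino-sugar contents must be >= 0")
    # algebraically (n/MW_GLUN - 2 m/MW_MURA) * MW_GLUN * GLUN_TO_FUNGAL_C
    value = (n - 2.0 * m * (MW_GLUN / MW_MURA)) * GLUN_TO_FUNGAL_C
    if value < 0:
        warnings.warn(f"fungal necromass negative ({value:.3f}); floored at 0")
        return 0.0
    return value


def necromass_result(
    profile: AminoSugarProfile, soc_g_kg: float | None
) -> NecromassResult:
    flags = []
    bact = bacterial_necromass(profile.mura_ug_per_g)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fung = fungal_necromass(profile.glun_ug_per_g, profile.mura_ug_per_g)
    flags.extend(str(w.message) for w in caught)
    total = bact + fung
    if soc_g_kg is None:
        raise ValidationError(f"sample {profile.sample_id!r}: SOC missing from metadata")
    prop = total / (soc_g_kg * UG_PER_G_PER_G_KG)
    if prop > 1:
        flags.append(f"necromass exceeds SOC (proportion {prop:.2f})")
    return NecromassResult(
        sample_id=profile.sample_id,
        bacterial_c=bact,
        fungal_c=fung,
        total_c=total,
        total_amino_sugars=profile.glun_ug_per_g + profile.galn_ug_per_g + profile.mura_ug_per_g,
        prop_of_soc=prop,
        flags="; ".join(flags),
    )


def necromass_table(
    profiles: Sequence[AminoSugarProfile], metadata: Sequence[SampleMetadata]
) -> tuple[pd.DataFrame, dict[str, pstats.PairedTResult]]:
    """Per-sample necromass table plus paired contrasts for bacterial, fungal
    and total necromass C and the necromass/SOC proportion."""
    soc = {m.sample_id: m.env.get("SOC") for m in metadata}
    results = [necromass_result(p, soc.get(p.sample_id)) for p in profiles]
    df = pd.DataFrame([vars(r) for r in results]).set_index("sample_id")
    contrasts = {}
    for var in ("bacterial_c", "fungal_c", "total_c", "prop_of_soc"):
        ctrl, warm, _ = paired_arrays(metadata, df[var].to_dict())
        contrasts[var] = pstats.paired_t(ctrl, warm)
    return df, contrasts
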