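"""Synthetic paired warming/control experiment with known ground truth.

Every observable table is generated by inverting the downstream estimators:
true physiology, necromass, fraction and enrichment quantities are drawn
first, then the raw observables (headspace CO2, DNA isotope excess,
fumigation flushes, amino-sugar contents, gene read counts, fraction masses
and C concentrations) are back-calculated so that the forward pipeline on
noiseless data recovers every truth exactly. Multiplicative log-normal
noise with coefficient of variation ``cv_noise`` is then applied to the
observables only — the stored truths stay exact.

Community tables use a latent log-normal factor model: members of a planted
module share a latent factor (within-module latent correlation >= 0.8 at the
default loadings), warming multiplies the planted-factor variance by
``warming_module_boost`` so warming networks are denser, and the first
prokaryotic module tracks the soil-temperature covariate so module
eigengenes have a recoverable environmental driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    AminoSugarProfile,
    CountTable,
    FractionRecord,
    IncubationRecord,
    PairedExperiment,
    SampleMetadata,
    ValidationError,
    CONTROL,
    WARMING,
    write_count_table,
    write_metadata,
    write_records,
)
from .physiology import FUMIGATION_KEC, O_PCT_IN_DNA, headspace_mol, C_MOLAR_G
from .necromass import (
    GLUN_TO_FUNGAL_C,
    MURA_TO_BACTERIAL_C,
    MW_GLUN,
    MW_MURA,
    UG_PER_G_PER_G_KG,
)

#: natural 18O abundance of unlabelled DNA, at%
AT18O_NATURAL = 0.2047
#: C_mic : DNA_mic mass ratio used for the inverse physiology model
MBC_TO_DNA_RATIO = 25.0
#: baseline microbial biomass C, ug C per g dry soil
MBC_BASE = 600.0
#: total O content of the dried DNA extract, ug
O_TOTAL_UG = 25.0
#: extractable C of unfumigated soil, ug C per g
C_UNFUMIGATED = 150.0
#: CO2 of the flushed blank vial after 24 h, ppm
CO2_BLANK_PPM = 5.0

_CAZY_CLASS_CYCLE = ("GH", "GH", "GT", "CBM", "GH", "CE", "PL", "GT", "AA", "CBM")
_PLANT_SUBSTRATES = ("starch", "hemicellulose", "cellulose", "pectin")


@dataclass
class GeneratorConfig:
    """Study conditions of the emulated paired warming experiment.

    Defaults mirror the reported field contrasts: CUE 0.41 vs 0.34,
    necromass/SOC 0.28 vs 0.31, MAOC/SOC 0.65 vs 0.71, heterotrophic
    respiration +41%, topsoil warming within 0.8-2.2 degC, and 30 vs 13
    differentially enriched CAZy families, at 10 paired blocks.
    """

    n_blocks: int = 10
    year: int = 2019
    seq_depth: int = 5000
    n_asv_prok: int = 150
    n_asv_fungi: int = 80
    n_planted_modules: int = 3
    module_size: int = 12
    warming_module_boost: float = 2.0
    n_gene_families: int = 60
    genes_per_family: int = 3
    n_background_genes: int = 300
    background_to_cazy_ratio: float = 90.0
    gene_depth: int = 1_000_000
    n_enriched_warming: int = 30
    n_enriched_control: int = 13
    fold_change: float = 3.0
    true_cue_control: float = 0.41
    true_cue_warming: float = 0.34
    true_growth_control: float = 0.12  # ug C g^-1 h^-1
    cv_noise: float = 0.1
    true_necromass_prop_control: float = 0.28
    true_necromass_prop_warming: float = 0.31
    true_maoc_prop_control: float = 0.65
    true_maoc_prop_warming: float = 0.71
    rh_warming_effect: float = 0.41
    warming_dT: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        props = (
            self.true_cue_control,
            self.true_cue_warming,
            self.true_necromass_prop_control,
            self.true_necromass_prop_warming,
            self.true_maoc_prop_control,
            self.true_maoc_prop_warming,
        )
        if not all(0 < p < 1 for p in props):
            raise ValidationError("all proportions must lie in (0, 1)")
        if self.fold_change < 1:
            raise ValidationError("fold_change must be >= 1")
        max_planted = self.n_planted_modules * self.module_size
        if max_planted > min(self.n_asv_prok, self.n_asv_fungi):
            raise ValidationError(
                f"planted modules need {max_planted} ASVs, tables have "
                f"{self.n_asv_prok}/{self.n_asv_fungi}"
            )
        if self.n_enriched_warming + self.n_enriched_control > self.n_gene_families:
            raise ValidationError("more enriched families than families")
        if not 0.8 <= self.warming_dT <= 2.2:
            raise ValidationError("warming_dT outside the observed 0.8-2.2 degC range")
        if self.n_blocks < 2:
            raise ValidationError("need at least 2 blocks")
        if self.cv_noise < 0:
            raise ValidationError("cv_noise must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to verify downstream estimates against the truth."""

    per_sample: pd.DataFrame  # indexed by sample_id
    module_membership: dict[str, str]  # feature id -> module label
    enriched_warming: list[str]
    enriched_control: list[str]
    family_ra: pd.DataFrame  # family x sample, realized length-normalised RA
    seq_depths: dict[str, dict[str, int]]  # table name -> sample -> depth drawn
    block_effects: dict[str, float]
    config: GeneratorConfig = field(repr=False, default=None)


def _noise(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative log-normal noise; exactly 1 when cv = 0."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return np.exp(rng.normal(0.0, sigma, size=size) - sigma**2 / 2.0)


def _sample_id(block: int, treatment: str, year: int) -> str:
    tag = "C" if treatment == CONTROL else "W"
    return f"block{block:02d}_{tag}_{year}"


def generate_metadata(cfg: GeneratorConfig, rng: np.random.Generator) -> list[SampleMetadata]:
    """Paired sample roster with environmental covariates.

    Soil temperature carries the configured warming offset; NH4/NO3, NDVI
    and root biomass carry modest warming responses; SOC and moisture do not
    differ by treatment (matching the field observation).
    """
    out = []
    for b in range(1, cfg.n_blocks + 1):
        base_temp = 8.0 + rng.normal(0, 0.5)
        soc = 60.0 * np.exp(rng.normal(0, 0.1))
        moisture = 32.0 + rng.normal(0, 2.0)
        ph = 6.6 + rng.normal(0, 0.15)
        doc = 300.0 * np.exp(rng.normal(0, 0.1))
        for treatment in (CONTROL, WARMING):
            warm = treatment == WARMING
            env = {
                "soil_temperature": base_temp + (cfg.warming_dT if warm else 0.0) + rng.normal(0, 0.15),
                "moisture": moisture + rng.normal(0, 0.5),
                "pH": ph + rng.normal(0, 0.05),
                "NH4_N": 5.0 * (1.2 if warm else 1.0) * np.exp(rng.normal(0, 0.1)),
                "NO3_N": 3.0 * (1.3 if warm else 1.0) * np.exp(rng.normal(0, 0.1)),
                "DOC": doc * np.exp(rng.normal(0, 0.05)),
                "SOC": soc * np.exp(rng.normal(0, 0.03)),
                "NDVI": min(0.95, 0.60 + (0.05 if warm else 0.0) + rng.normal(0, 0.02)),
                "root_biomass": 400.0 * (1.15 if warm else 1.0) * np.exp(rng.normal(0, 0.1)),
            }
            out.append(
                SampleMetadata(
                    sample_id=_sample_id(b, treatment, cfg.year),
                    block_id=f"block{b:02d}",
                    treatment=treatment,
                    year=cfg.year,
                    env=env,
                )
            )
    return out


# module latent-factor loadings: corr = L^2 / (L^2 + S^2) = 0.935 at baseline,
# high enough that planted edges survive correlation estimation at n = 10
_MODULE_LOADING = 0.95
_MODULE_NOISE_SD = 0.25
_INDEPENDENT_SD = 0.5
_N_CORE = 40  # high-baseline ASVs guaranteed present everywhere


def simulate_latent(
    cfg: GeneratorConfig,
    n_asv: int,
    metadata: Sequence[SampleMetadata],
    rng: np.random.Generator,
    prefix: str,
    temperature_module: bool = False,
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Latent log-abundance matrix (features x samples) plus module labels.

    Planted-module members load on a shared per-sample factor whose variance
    is multiplied by ``warming_module_boost`` under warming. When
    ``temperature_module`` is set, module 0's factor is the standardized
    soil temperature so that its eigengene tracks the covariate.
    """
    n_samples = len(metadata)
    ids = [f"{prefix}{i:04d}" for i in range(n_asv)]
    membership: dict[str, str] = {}
    mu = rng.normal(0.0, 1.5, size=n_asv)
    planted = cfg.n_planted_modules * cfg.module_size
    mu[: max(planted, min(_N_CORE, n_asv))] += 3.0  # core set kept prevalent
    temps = np.array([m.env["soil_temperature"] for m in metadata])
    temp_std = (temps - temps.mean()) / temps.std()
    warm_mask = np.array([m.treatment == WARMING for m in metadata])
    boost = np.where(warm_mask, np.sqrt(cfg.warming_module_boost), 1.0)
    z = np.empty((n_asv, n_samples))
    for mod in range(cfg.n_planted_modules):
        lo, hi = mod * cfg.module_size, (mod + 1) * cfg.module_size
        if temperature_module and mod == 0:
            factor = temp_std + rng.normal(0, 0.1, size=n_samples)
        else:
            factor = rng.normal(0, 1, size=n_samples) * boost
        for i in range(lo, hi):
            membership[ids[i]] = f"{prefix}mod{mod}"
            z[i] = mu[i] + _MODULE_LOADING * factor + rng.normal(0, _MODULE_NOISE_SD, n_samples)
    for i in range(planted, n_asv):
        z[i] = mu[i] + rng.normal(0, _INDEPENDENT_SD, n_samples)
    return z, ids, membership


def generate_asv_tables(
    cfg: GeneratorConfig, metadata: Sequence[SampleMetadata], rng: np.random.Generator
) -> tuple[CountTable, CountTable, dict[str, str], dict[str, dict[str, int]]]:
    """Prokaryotic and fungal ASV tables with planted co-occurrence modules.

    Counts are multinomial draws at a per-sample depth (the configured depth
    minus a random per-sample loss) from the exponentiated latent matrix.
    """
    sample_ids = [m.sample_id for m in metadata]
    membership: dict[str, str] = {}
    depths: dict[str, dict[str, int]] = {}
    tables = []
    phyla = ("Acidobacteriota", "Proteobacteria", "Actinobacteriota", "Verrucomicrobiota")
    fungal_phyla = ("Ascomycota", "Basidiomycota", "Mortierellomycota")
    for prefix, n_asv, taxa, temp_mod in (
        ("pASV_", cfg.n_asv_prok, phyla, True),
        ("fASV_", cfg.n_asv_fungi, fungal_phyla, False),
    ):
        z, ids, member = simulate_latent(cfg, n_asv, metadata, rng, prefix, temp_mod)
        membership.update(member)
        abun = np.exp(z)
        p = abun / abun.sum(axis=0, keepdims=True)
        max_loss = cfg.seq_depth // 10
        counts = np.empty((n_asv, len(sample_ids)), dtype=np.int64)
        depth_map = {}
        for j, sid in enumerate(sample_ids):
            depth = cfg.seq_depth - int(rng.integers(0, max_loss + 1))
            depth_map[sid] = depth
            counts[:, j] = rng.multinomial(depth, p[:, j])
        meta = {
            fid: {"taxonomy": f"{taxa[i % len(taxa)]};genus{i % 17}"} for i, fid in enumerate(ids)
        }
        tables.append(CountTable(ids, list(sample_ids), counts, meta))
        depths[prefix.rstrip("_")] = depth_map
    return tables[0], tables[1], membership, depths


def generate_incubation(
    cfg: GeneratorConfig,
    metadata: Sequence[SampleMetadata],
    block_effects: dict[str, float],
    rng: np.random.Generator,
) -> tuple[list[IncubationRecord], pd.DataFrame]:
    """Incubation observables back-calculated from drawn true physiology.

    Per sample the true growth G is drawn (block effect x log-normal sample
    variation, same distribution in both arms), the true CUE equals the
    configured treatment value exactly, and R follows. Observables are then
    the exact inverses of the estimator chain, times noise. ``cv_noise`` is
    the end-to-end relative error of each measurement chain: it enters once
    through the primary observable of the respiration chain (the headspace
    CO2 difference) and once through that of the growth chain (the heavy-
    oxygen excess); the auxiliary quantities (DNA yield, fumigation flush)
    are treated as precisely measured so the derived G and R carry
    coefficient of variation ~cv_noise each, not a compounded multiple.
    """
    records = []
    truths = []
    ugc_per_ppm = headspace_mol(50.0, 15.0) * 1e-6 * C_MOLAR_G * 1e6
    w, t = 0.3, 24.0
    for m in metadata:
        be = block_effects[m.block_id]
        g_true = cfg.true_growth_control * be * np.exp(rng.normal(0, 0.1))
        cue_true = cfg.true_cue_warming if m.treatment == WARMING else cfg.true_cue_control
        r_true = g_true * (1.0 - cue_true) / cue_true
        mbc_true = MBC_BASE * be * np.exp(rng.normal(0, 0.08))
        dna_mic = mbc_true / MBC_TO_DNA_RATIO
        dna_prod = g_true * w * t * dna_mic / mbc_true
        o_excess = dna_prod * 20.0 * O_PCT_IN_DNA / (100.0 * O_TOTAL_UG)
        delta_ppm = r_true * w * t / ugc_per_ppm
        flush = mbc_true * FUMIGATION_KEC
        f = _noise(rng, cfg.cv_noise, 2)
        records.append(
            IncubationRecord(
                sample_id=m.sample_id,
                co2_sample_ppm=CO2_BLANK_PPM + delta_ppm * f[0],
                co2_blank_ppm=CO2_BLANK_PPM,
                o_total_ug=O_TOTAL_UG,
                at18O_labelled_pct=AT18O_NATURAL + o_excess * f[1],
                at18O_natural_pct=AT18O_NATURAL,
                dna_mic_ug_per_g=dna_mic,
                c_fumigated_ug_per_g=C_UNFUMIGATED + flush,
                c_unfumigated_ug_per_g=C_UNFUMIGATED,
                o_label_pct=20.0,
                vial_volume_ml=50.0,
                soil_dry_mass_g=w,
                duration_h=t,
                temp_C=15.0,
            )
        )
        truths.append(
            {
                "sample_id": m.sample_id,
                "true_G": g_true,
                "true_R": r_true,
                "true_CUE": cue_true,
                "true_MBC": mbc_true,
            }
        )
    return records, pd.DataFrame(truths).set_index("sample_id")


def generate_amino_sugars(
    cfg: GeneratorConfig, metadata: Sequence[SampleMetadata], rng: np.random.Generator
) -> tuple[list[AminoSugarProfile], pd.DataFrame]:
    """Amino-sugar contents inverted from the configured necromass/SOC share.

    Total necromass C is split 1:2 bacterial:fungal (fungal residues dominate
    in soil), MurA follows from the bacterial share and GluN from the fungal
    share plus the bacterial GluN correction term.
    """
    profiles = []
    truths = []
    for m in metadata:
        soc = m.env["SOC"]
        prop = (
            cfg.true_necromass_prop_warming
            if m.treatment == WARMING
            else cfg.true_necromass_prop_control
        )
        total_c = prop * soc * UG_PER_G_PER_G_KG
        bact_c = total_c / 3.0
        fung_c = total_c * 2.0 / 3.0
        mura = bact_c / MURA_TO_BACTERIAL_C
        glun = fung_c / GLUN_TO_FUNGAL_C + 2.0 * mura * (MW_GLUN / MW_MURA)
        galn = 0.6 * glun
        f = _noise(rng, cfg.cv_noise, 3)
        profiles.append(
            AminoSugarProfile(
                sample_id=m.sample_id,
                glun_ug_per_g=glun * f[0],
                galn_ug_per_g=galn * f[1],
                mura_ug_per_g=mura * f[2],
            )
        )
        truths.append(
            {
                "sample_id": m.sample_id,
                "true_necromass_bacterial": bact_c,
                "true_necromass_fungal": fung_c,
                "true_necromass_total": total_c,
                "true_necromass_prop": prop,
                "soc": soc,
            }
        )
    return profiles, pd.DataFrame(truths).set_index("sample_id")


def generate_gene_table(
    cfg: GeneratorConfig, metadata: Sequence[SampleMetadata], rng: np.random.Generator
) -> tuple[CountTable, list[str], list[str], pd.DataFrame]:
    """CAZy gene catalog counts with planted family-level enrichment.

    Expected reads are proportional to latent family intensity x gene weight
    x gene length (so the length normalisation is non-trivial); enriched
    families carry the configured fold change in their favoured arm. Counts
    are Poisson around the expectation (exact expectation at cv_noise = 0).
    An unannotated background pool emulates the non-CAZy bulk of a gene
    catalog: it dominates the relative-abundance denominator (by
    ``background_to_cazy_ratio``), so boosting a few dozen families barely
    perturbs the abundances of the untouched ones — as in a real metagenome.
    Returns the table, the warming- and control-enriched family names, and
    the realized per-family relative-abundance bookkeeping.
    """
    families = [f"{_CAZY_CLASS_CYCLE[i % len(_CAZY_CLASS_CYCLE)]}{i + 1}" for i in range(cfg.n_gene_families)]
    order = rng.permutation(cfg.n_gene_families)
    enriched_w = [families[i] for i in order[: cfg.n_enriched_warming]]
    enriched_c = [
        families[i]
        for i in order[cfg.n_enriched_warming : cfg.n_enriched_warming + cfg.n_enriched_control]
    ]
    sample_ids = [m.sample_id for m in metadata]
    n_cazy = cfg.n_gene_families * cfg.genes_per_family
    n_genes = n_cazy + cfg.n_background_genes
    lengths = rng.integers(600, 3001, size=n_genes)
    weights = np.exp(rng.normal(0, 0.6, size=n_genes))
    fam_of_gene = np.full(n_genes, -1)
    fam_of_gene[:n_cazy] = np.repeat(np.arange(cfg.n_gene_families), cfg.genes_per_family)
    # scale the background pool to carry the configured share of the catalog
    if cfg.n_background_genes:
        fg_total = weights[:n_cazy].sum()
        bg_total = weights[n_cazy:].sum()
        weights[n_cazy:] *= cfg.background_to_cazy_ratio * fg_total / bg_total
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    meta = {}
    for i, gid in enumerate(gene_ids):
        if fam_of_gene[i] < 0:
            meta[gid] = {"length_bp": int(lengths[i])}
            continue
        fam = families[fam_of_gene[i]]
        cls = "".join(ch for ch in fam if ch.isalpha())
        meta[gid] = {
            "length_bp": int(lengths[i]),
            "family": fam,
            "cazy_class": cls,
            "ko": f"K{10000 + fam_of_gene[i]}",
            "substrate": _PLANT_SUBSTRATES[fam_of_gene[i] % len(_PLANT_SUBSTRATES)]
            if fam in enriched_w
            else "",
        }
    counts = np.empty((n_genes, len(sample_ids)), dtype=np.int64)
    fam_mult_base = np.ones(cfg.n_gene_families + 1)  # last slot = background
    for j, m in enumerate(metadata):
        fam_mult = fam_mult_base.copy()
        if m.treatment == WARMING:
            fam_mult[[families.index(f) for f in enriched_w]] = cfg.fold_change
        else:
            fam_mult[[families.index(f) for f in enriched_c]] = cfg.fold_change
        intensity = fam_mult[fam_of_gene] * weights
        expected = intensity * lengths
        expected = expected / expected.sum() * cfg.gene_depth
        if cfg.cv_noise == 0:
            counts[:, j] = np.rint(expected).astype(np.int64)
        else:
            counts[:, j] = rng.poisson(expected * _noise(rng, cfg.cv_noise, n_genes))
    table = CountTable(gene_ids, list(sample_ids), counts, meta)
    # independent bookkeeping of realized family relative abundance (length-
    # normalised) for recovery tests against the enrichment module
    ratios = counts / lengths[:, None]
    ra = ratios / ratios.sum(axis=0, keepdims=True)
    fam_ra = pd.DataFrame(ra, index=gene_ids, columns=sample_ids)
    fam_ra["family"] = [meta[g].get("family") for g in gene_ids]
    family_ra = fam_ra.dropna(subset=["family"]).groupby("family").sum()
    return table, enriched_w, enriched_c, family_ra


def generate_fractions(
    cfg: GeneratorConfig, metadata: Sequence[SampleMetadata], rng: np.random.Generator
) -> tuple[list[FractionRecord], pd.DataFrame]:
    """Fraction masses and C concentrations from the configured MAOC share.

    Mass recovery is drawn in [0.94, 0.99] and C recovery in [0.97, 0.995];
    noisy per-fraction stocks are rescaled to preserve the drawn C recovery,
    keeping the >97% C recovery property of the fractionation protocol.
    """
    records = []
    truths = []
    for m in metadata:
        soc = m.env["SOC"]
        maoc_prop = (
            cfg.true_maoc_prop_warming if m.treatment == WARMING else cfg.true_maoc_prop_control
        )
        heavy_share = 0.4 if m.treatment == WARMING else 0.5  # heavy POC declines under warming
        initial_mass = 10.0
        mass_rec = rng.uniform(0.94, 0.99)
        c_rec = rng.uniform(0.97, 0.995)
        bulk_c_g = initial_mass / 1000.0 * soc
        recovered_c = c_rec * bulk_c_g
        stocks = np.array(
            [
                (1.0 - maoc_prop) * (1.0 - heavy_share),  # light POC
                (1.0 - maoc_prop) * heavy_share,  # heavy POC
                maoc_prop,  # MAOC
            ]
        ) * recovered_c
        noisy = stocks * _noise(rng, cfg.cv_noise, 3)
        noisy *= recovered_c / noisy.sum()
        poc_mass = 0.8 * mass_rec / 0.96
        heavy_mass = 2.2 * mass_rec / 0.96
        maom_mass = mass_rec * initial_mass - poc_mass - heavy_mass
        masses = np.array([poc_mass, heavy_mass, maom_mass])
        concs = noisy / (masses / 1000.0)
        records.append(
            FractionRecord(
                sample_id=m.sample_id,
                initial_mass_g=initial_mass,
                poc_mass_g=masses[0],
                heavy_poc_mass_g=masses[1],
                maom_mass_g=masses[2],
                poc_c_g_kg=concs[0],
                heavy_poc_c_g_kg=concs[1],
                maoc_c_g_kg=concs[2],
                bulk_soc_g_kg=soc,
            )
        )
        truths.append({"sample_id": m.sample_id, "true_maoc_prop": maoc_prop})
    return records, pd.DataFrame(truths).set_index("sample_id")


def generate_rh(
    cfg: GeneratorConfig,
    metadata: Sequence[SampleMetadata],
    block_effects: dict[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Growing-season heterotrophic respiration series (umol CO2 m^-2 s^-1).

    Twice-monthly observations May-October with a mid-summer peak; warming
    multiplies every observation by 1 + rh_warming_effect, so the ratio of
    treatment seasonal means is exact at zero noise.
    """
    dates = [f"2020-{month:02d}-{day:02d}" for month in range(5, 11) for day in (5, 20)]
    season = 1.0 + 0.6 * np.sin(np.linspace(0, np.pi, len(dates)))
    rows = []
    for m in metadata:
        base = 2.0 * block_effects[m.block_id]
        mult = (1.0 + cfg.rh_warming_effect) if m.treatment == WARMING else 1.0
        f = _noise(rng, cfg.cv_noise, len(dates))
        for d, s, fi in zip(dates, season, f):
            rows.append({"sample_id": m.sample_id, "date": d, "rh": base * s * mult * fi})
    return pd.DataFrame(rows)


def generate_experiment(cfg: GeneratorConfig) -> tuple[PairedExperiment, GroundTruth]:
    """Generate the full paired experiment and its ground truth, deterministically."""
    cfg.validate()
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(8)]
    meta_rng, asv_rng, inc_rng, amino_rng, gene_rng, frac_rng, rh_rng, block_rng = streams
    metadata = generate_metadata(cfg, meta_rng)
    block_ids = sorted({m.block_id for m in metadata})
    block_effects = {b: float(np.exp(block_rng.normal(0, 0.15))) for b in block_ids}
    asv_prok, asv_fungi, membership, depths = generate_asv_tables(cfg, metadata, asv_rng)
    incubations, phys_truth = generate_incubation(cfg, metadata, block_effects, inc_rng)
    profiles, necro_truth = generate_amino_sugars(cfg, metadata, amino_rng)
    genes, enriched_w, enriched_c, family_ra = generate_gene_table(cfg, metadata, gene_rng)
    fractions, frac_truth = generate_fractions(cfg, metadata, frac_rng)
    rh = generate_rh(cfg, metadata, block_effects, rh_rng)
    experiment = PairedExperiment(
        metadata=metadata,
        asv_prok=asv_prok,
        asv_fungi=asv_fungi,
        genes=genes,
        incubations=incubations,
        amino_sugars=profiles,
        fractions=fractions,
        rh_series=rh,
    )
    per_sample = phys_truth.join(necro_truth).join(frac_truth)
    per_sample["treatment"] = [m.treatment for m in metadata]
    per_sample["block_id"] = [m.block_id for m in metadata]
    truth = GroundTruth(
        per_sample=per_sample,
        module_membership=membership,
        enriched_warming=enriched_w,
        enriched_control=enriched_c,
        family_ra=family_ra,
        seq_depths=depths,
        block_effects=block_effects,
        config=cfg,
    )
    return experiment, truth


def write_experiment(experiment: PairedExperiment, truth: GroundTruth, out_dir: str | Path) -> None:
    """Write every table of a generated experiment (plus ground truth) as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_metadata(experiment.metadata, out / "metadata.tsv")
    write_count_table(experiment.asv_prok, out / "asv_prok.tsv")
    write_count_table(experiment.asv_fungi, out / "asv_fungi.tsv")
    write_count_table(experiment.genes, out / "genes.tsv")
    write_records(experiment.incubations, out / "incubations.tsv")
    write_records(experiment.amino_sugars, out / "amino_sugars.tsv")
    write_records(experiment.fractions, out / "fractions.tsv")
    experiment.rh_series.to_csv(out / "rh_series.tsv", sep="\t", index=False)
    truth.per_sample.to_csv(out / "ground_truth.tsv", sep="\t")
    pd.Series(truth.module_membership, name="module").rename_axis("feature_id").to_csv(
        out / "ground_truth_modules.tsv", sep="\t"
    )
    pd.DataFrame(
        {
            "family": truth.enriched_warming + truth.enriched_control,
            "enriched_in": [WARMING] * len(truth.enriched_warming)
            + [CONTROL] * len(truth.enriched_control),
        }
    ).to_csv(out / "ground_truth_enriched.tsv", sep="\t", index=False)
    truth.family_ra.to_csv(out / "ground_truth_family_ra.tsv", sep="\t")
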