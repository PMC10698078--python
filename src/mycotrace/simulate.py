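"""Synthetic dual-isotope labelling studies with known ground truth.

The generator emulates a pulse-labelling experiment on young beech colonized
by a natural ectomycorrhizal (EM) assemblage: ~16 fungal species of which 7
dominant ones cover ~80% of root tips, per-species carbon 380-440 mg g-1 and
C/N ratios spanning 7-30, 13C enrichment linear in C/N (slope -2.49,
intercept 57.1 mg g-1) and 15N likewise (-0.57, 15.1 ug g-1), EM enrichment
coupled to the attached lateral rootlet with slopes 1.23 (13C) and 0.53
(15N), ~29215 EM tips per plant, and two sampling dates with no community
shift. Enrichments are rectified at zero (allocation cannot be negative);
the untruncated values are retained in the ground truth so downstream tests
can quantify the attenuation this rectification induces in fitted slopes.

Everything is drawn from one seeded ``numpy.random.default_rng``; identical
seed and config give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import isotope as iso

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "DOMINANT_SPECIES",
    "generate_community",
    "generate_isotope_measurements",
    "generate_study",
    "ground_truth_report",
]

#: The seven dominant, isotope-analysed taxa of the emulated assemblage.
DOMINANT_SPECIES = [
    "Pachyphlodes_conglomerata",
    "UEM1",
    "UEM2",
    "UEM3",
    "Tomentella_punicea",
    "Cenococcum_geophilum",
    "Tomentella_sp1",
]

MEASUREMENT_COLUMNS = [
    "plant_id", "time_point", "compartment", "species", "dry_mass_g",
    "element", "element_mass_g", "isotope_value", "value_kind", "is_control",
]

# Table-level element concentrations (mg g-1 dry mass) for non-EM
# compartments: (N, C) per compartment code.
COMPARTMENT_ELEMENT_CONC = {
    "BA": (8.75, 448.1),
    "CR": (6.41, 452.7),
    "FR": (12.34, 344.3),
    "LR": (15.69, 471.0),
    "RS": (2.64, 36.6),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of a synthetic study (defaults = stated world)."""

    n_plants: int = 20          # 10 per sampling date
    n_controls: int = 10
    n_species: int = 16
    n_dominant: int = 7
    dirichlet_concentration: float = 40.0
    dominant_mass: float = 0.8  # expected abundance share of dominant taxa
    total_tips_mean: float = 29215.0
    total_tips_sd: float = 4361.0
    tips_counted_mean: float = 400.0
    tips_counted_sd: float = 30.0
    colonization_mean: float = 92.6   # %
    colonization_sd: float = 2.2
    vitality_mean: float = 89.6       # %
    vitality_sd: float = 2.1
    cn_range: tuple[float, float] = (7.0, 30.0)
    cn_jitter_sd: float = 0.5         # per-plant jitter around species C/N
    carbon_conc_range: tuple[float, float] = (380.0, 440.0)   # mg g-1
    nitrogen_conc_range: tuple[float, float] = (20.0, 40.0)   # mg g-1 (display)
    slope_13c: float = -2.49
    intercept_13c: float = 57.1
    noise_sd_13c: float = 5.0
    slope_15n: float = -0.57
    intercept_15n: float = 15.1
    noise_sd_15n: float = 2.0
    lateral_coupling_slope_13c: float = 1.23
    lateral_coupling_slope_15n: float = 0.53
    lateral_noise_sd_13c: float = 1.5
    lateral_noise_sd_15n: float = 1.0
    control_delta_13c: float = -28.0  # natural-abundance permil
    control_delta_15n: float = 0.0
    control_delta_sd: float = 0.5
    tip_biomass_range: tuple[float, float] = (1e-4, 4e-4)     # g per tip
    sample_dry_mass_range: tuple[float, float] = (5e-4, 1.5e-3)  # weighed aliquot, g
    fine_root_biomass_g: float = 3.9
    coarse_root_biomass_g: float = 12.5
    soil_dry_mass_g: float = 54.0
    # compartment enrichment means back-solved from the printed pool sizes
    # over the printed biomasses (mg g-1 for 13C, ug g-1 for 15N)
    compartment_enrichment_13c: dict = field(default_factory=lambda: {
        "BA": 7.0, "CR": 10.16, "FR": 6.95, "RS": 0.0352,
    })
    compartment_enrichment_15n: dict = field(default_factory=lambda: {
        "BA": 6.0, "CR": 9.51, "FR": 5.97, "RS": 0.0,
    })
    compartment_noise_frac: float = 0.2
    fungal_tissue_range: tuple[float, float] = (25.3, 50.0)   # % of cross section
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dominant > self.n_species:
            raise ValueError("n_dominant cannot exceed n_species")
        for rng_field in ("cn_range", "carbon_conc_range", "nitrogen_conc_range",
                          "tip_biomass_range", "sample_dry_mass_range",
                          "fungal_tissue_range"):
            lo, hi = getattr(self, rng_field)
            if not lo <= hi:
                raise ValueError(f"{rng_field} must be well-ordered")
        for sd_field in ("total_tips_sd", "noise_sd_13c", "noise_sd_15n",
                         "control_delta_sd", "cn_jitter_sd",
                         "lateral_noise_sd_13c", "lateral_noise_sd_15n"):
            if getattr(self, sd_field) < 0:
                raise ValueError(f"{sd_field} must be >= 0")

    def species_names(self) -> list[str]:
        rare = [f"EM{i:02d}" for i in range(self.n_dominant + 1, self.n_species + 1)]
        return DOMINANT_SPECIES[: self.n_dominant] + rare

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class SyntheticStudy:
    """All generated input tables plus the generating ground truth."""

    config: SimulationConfig
    measurements: pd.DataFrame
    census: pd.DataFrame
    morphotypes: pd.DataFrame
    areas: pd.DataFrame
    tip_biomass: pd.DataFrame
    species_truth: pd.DataFrame          # per-species generating values
    observation_truth: pd.DataFrame      # per plant x species x isotope values
    plant_truth: pd.DataFrame            # total tips etc. per plant

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("measurements", self.measurements), ("census", self.census),
            ("morphotypes", self.morphotypes), ("areas", self.areas),
            ("tip_biomass", self.tip_biomass),
            ("ground_truth_species", self.species_truth),
            ("ground_truth_observations", self.observation_truth),
            ("ground_truth_plants", self.plant_truth),
        ]:
            p = out / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths[name] = p
        self.config.to_yaml(out / "config.yaml")
        return paths


def generate_community(config: SimulationConfig, rng: np.random.Generator):
    """Draw per-plant abundances, tip censuses and morphotype counts.

    Abundances follow a Dirichlet whose mass splits ``dominant_mass`` /
    (1 - dominant_mass) between the dominant and rare taxa; realized tip
    counts are multinomial over the ~400 tips inspected per plant.
    """
    species = config.species_names()
    n_rare = config.n_species - config.n_dominant
    alpha = np.array(
        [config.dominant_mass / config.n_dominant] * config.n_dominant
        + ([(1 - config.dominant_mass) / n_rare] * n_rare if n_rare else [])
    ) * config.dirichlet_concentration

    census_rows, morpho_rows, abundance_rows = [], [], []
    for i in range(config.n_plants):
        plant = f"P{i + 1:02d}"
        tp = 5 if i < config.n_plants // 2 else 20
        counted = max(50, int(round(rng.normal(config.tips_counted_mean,
                                               config.tips_counted_sd))))
        vitality = np.clip(rng.normal(config.vitality_mean, config.vitality_sd), 0, 100)
        colonization = np.clip(rng.normal(config.colonization_mean,
                                          config.colonization_sd), 0, 100)
        n_vital = int(round(counted * vitality / 100))
        n_myco = int(round(n_vital * colonization / 100))
        census_rows.append({
            "plant_id": plant, "time_point": tp, "n_vital_myco": n_myco,
            "n_vital_nonmyco": n_vital - n_myco, "n_dry": counted - n_vital,
        })
        abund = rng.dirichlet(alpha)
        counts = rng.multinomial(n_myco, abund)
        abundance_rows.append(counts / n_myco)
        for sp, c in zip(species, counts):
            if c > 0:
                morpho_rows.append({"plant_id": plant, "time_point": tp,
                                    "species": sp, "n_tips": int(c)})
    census = pd.DataFrame(census_rows)
    morphotypes = pd.DataFrame(morpho_rows)
    abundances = pd.DataFrame(
        abundance_rows, index=census["plant_id"], columns=species
    )
    return abundances, census, morphotypes


def _emit_rows(rows, plant, tp, comp, species, dry_mass, conc_c, conc_n,
               enr_13c, enr_15n, af_ctl_c, af_ctl_n, is_control, rng,
               control_cfg=None):
    """Append one C row and one N row carrying the given enrichments as delta."""
    frac_c, frac_n = conc_c / 1000.0, conc_n / 1000.0
    if is_control:
        mu_c, mu_n, sd = control_cfg
        delta_c = rng.normal(mu_c, sd)
        delta_n = rng.normal(mu_n, sd)
    else:
        ape_c = enr_13c / (iso.UNIT_FACTOR["13C"] / 100.0 * frac_c)
        ape_n = enr_15n / (iso.UNIT_FACTOR["15N"] / 100.0 * frac_n)
        delta_c = iso.atom_fraction_to_delta(af_ctl_c + ape_c / 100.0, iso.CARBON_13)
        delta_n = iso.atom_fraction_to_delta(af_ctl_n + ape_n / 100.0, iso.NITROGEN_15)
    for element, conc, delta in (("C", conc_c, delta_c), ("N", conc_n, delta_n)):
        rows.append({
            "plant_id": plant, "time_point": tp, "compartment": comp,
            "species": species, "dry_mass_g": dry_mass, "element": element,
            "element_mass_g": conc / 1000.0 * dry_mass,
            "isotope_value": delta, "value_kind": "delta_permil",
            "is_control": is_control,
        })


def generate_isotope_measurements(
    abundances: pd.DataFrame,
    census: pd.DataFrame,
    morphotypes: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Emit the measurement table (delta notation) plus ground-truth tables.

    The generator inverts the analysis: per-species C/N is drawn from
    ``cn_range``, EM enrichment is linear in C/N plus Gaussian noise and
    rectified at zero, the attached lateral rootlet receives the EM
    enrichment divided by the coupling slope plus noise, and every
    enrichment is converted back through APE and atom fraction to the delta
    value an isotope-ratio mass spectrometer would report.
    """
    species = config.species_names()
    dominant = species[: config.n_dominant]
    cn = rng.uniform(*config.cn_range, size=len(species))
    conc_c = rng.uniform(*config.carbon_conc_range, size=len(species))
    conc_n = conc_c / cn  # C/N is the generative quantity
    tip_biomass = rng.uniform(*config.tip_biomass_range, size=len(species))
    species_truth = pd.DataFrame({
        "species": species, "cn_ratio": cn, "carbon_conc_mg_g": conc_c,
        "nitrogen_conc_mg_g": conc_n, "tip_biomass_g": tip_biomass,
        "is_dominant": [s in dominant for s in species],
    })
    af_ctl_c = iso.delta_to_atom_fraction(config.control_delta_13c, iso.CARBON_13)
    af_ctl_n = iso.delta_to_atom_fraction(config.control_delta_15n, iso.NITROGEN_15)

    rows: list[dict] = []
    obs_rows: list[dict] = []
    plant_rows: list[dict] = []
    morpho_key = set(zip(morphotypes["plant_id"], morphotypes["species"]))
    time_of = dict(zip(census["plant_id"], census["time_point"]))

    for plant in abundances.index:
        tp = int(time_of[plant])
        total_tips = max(1000.0, rng.normal(config.total_tips_mean,
                                            config.total_tips_sd))
        plant_rows.append({"plant_id": plant, "time_point": tp,
                           "total_tips": total_tips})
        # EM tips of the dominant taxa plus their attached lateral rootlets
        for si, sp in enumerate(species):
            if sp not in dominant or (plant, sp) not in morpho_key:
                continue
            cn_obs = cn[si] + rng.normal(0.0, config.cn_jitter_sd)
            em13_raw = (config.intercept_13c + config.slope_13c * cn_obs
                        + rng.normal(0.0, config.noise_sd_13c))
            em15_raw = (config.intercept_15n + config.slope_15n * cn_obs
                        + rng.normal(0.0, config.noise_sd_15n))
            em13, em15 = max(0.0, em13_raw), max(0.0, em15_raw)
            lr13 = max(0.0, em13 / config.lateral_coupling_slope_13c
                       + rng.normal(0.0, config.lateral_noise_sd_13c))
            lr15 = max(0.0, em15 / config.lateral_coupling_slope_15n
                       + rng.normal(0.0, config.lateral_noise_sd_15n))
            sp_conc_c = conc_c[si]
            sp_conc_n = sp_conc_c / cn_obs  # measured C/N reproduces cn_obs
            dm_em = rng.uniform(*config.sample_dry_mass_range)
            dm_lr = rng.uniform(*config.sample_dry_mass_range)
            _emit_rows(rows, plant, tp, "EM", sp, dm_em, sp_conc_c, sp_conc_n,
                       em13, em15, af_ctl_c, af_ctl_n, False, rng)
            n_lr, c_lr = COMPARTMENT_ELEMENT_CONC["LR"]
            _emit_rows(rows, plant, tp, "LR", sp, dm_lr, c_lr, n_lr,
                       lr13, lr15, af_ctl_c, af_ctl_n, False, rng)
            obs_rows.append({
                "plant_id": plant, "time_point": tp, "species": sp,
                "cn_obs": cn_obs, "em_13c_untruncated": em13_raw,
                "em_13c": em13, "em_15n_untruncated": em15_raw,
                "em_15n": em15, "lr_13c": lr13, "lr_15n": lr15,
            })
        # bulk compartments
        for comp in ("BA", "CR", "FR", "RS"):
            n_conc, c_conc = COMPARTMENT_ELEMENT_CONC[comp]
            mu13 = config.compartment_enrichment_13c[comp]
            mu15 = config.compartment_enrichment_15n[comp]
            e13 = max(0.0, rng.normal(mu13, config.compartment_noise_frac * mu13))
            e15 = max(0.0, rng.normal(mu15, config.compartment_noise_frac * mu15))
            dm = rng.uniform(*config.sample_dry_mass_range)
            _emit_rows(rows, plant, tp, comp, "", dm, c_conc, n_conc,
                       e13, e15, af_ctl_c, af_ctl_n, False, rng)

    # non-labelled control plants: natural-abundance delta in every compartment
    ctl = (config.control_delta_13c, config.control_delta_15n,
           config.control_delta_sd)
    em_n, em_c = 26.23, 419.7  # EM element concentrations, mg g-1
    for i in range(config.n_controls):
        plant = f"C{i + 1:02d}"
        for comp in ("BA", "CR", "FR", "LR", "EM", "RS"):
            if comp == "EM":
                n_conc, c_conc = em_n, em_c
            else:
                n_conc, c_conc = COMPARTMENT_ELEMENT_CONC[comp]
            dm = rng.uniform(*config.sample_dry_mass_range)
            _emit_rows(rows, plant, 0, comp, "", dm, c_conc, n_conc,
                       0.0, 0.0, af_ctl_c, af_ctl_n, True, rng,
                       control_cfg=ctl)

    measurements = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    observation_truth = pd.DataFrame(obs_rows)
    plant_truth = pd.DataFrame(plant_rows)
    return measurements, species_truth, observation_truth, plant_truth


def generate_study(config: SimulationConfig | None = None,
                   seed: int | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study (all input tables + ground truth)."""
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    abundances, census, morphotypes = generate_community(config, rng)
    measurements, species_truth, observation_truth, plant_truth = (
        generate_isotope_measurements(abundances, census, morphotypes, config, rng)
    )
    areas = pd.DataFrame({
        "species": config.species_names()[: config.n_dominant],
        "area_total_um2": 1e5,
    })
    frac = rng.uniform(*config.fungal_tissue_range, size=config.n_dominant)
    areas["area_fungal_um2"] = areas["area_total_um2"] * frac / 100.0
    tip_biomass = species_truth[["species", "tip_biomass_g"]].copy()
    return SyntheticStudy(
        config=config, measurements=measurements, census=census,
        morphotypes=morphotypes, areas=areas, tip_biomass=tip_biomass,
        species_truth=species_truth, observation_truth=observation_truth,
        plant_truth=plant_truth,
    )


def ground_truth_report(study: SyntheticStudy) -> pd.DataFrame:
    """Tidy parameter/value table: config echo plus realized species values."""
    rows = []
    cfg = asdict(study.config)
    for k, v in cfg.items():
        if isinstance(v, dict):
            for kk, vv in v.items():
                rows.append({"scope": "config", "name": f"{k}.{kk}", "value": vv})
        elif isinstance(v, tuple):
            rows.append({"scope": "config", "name": f"{k}.low", "value": v[0]})
            rows.append({"scope": "config", "name": f"{k}.high", "value": v[1]})
        else:
            rows.append({"scope": "config", "name": k, "value": v})
    for r in study.species_truth.itertuples():
        for col in ("cn_ratio", "carbon_conc_mg_g", "nitrogen_conc_mg_g",
                    "tip_biomass_g"):
            rows.append({"scope": f"species:{r.species}", "name": col,
                         "value": getattr(r, col)})
    for r in study.plant_truth.itertuples():
        rows.append({"scope": f"plant:{r.plant_id}", "name": "total_tips",
                     "value": r.total_tips})
    return pd.DataFrame(rows)
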