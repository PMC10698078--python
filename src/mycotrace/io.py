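"""Study readers, the end-to-end analysis runner and the report writer.

A study consists of tab-separated UTF-8 tables: a long-format measurement
table (one row per sample x element, delta or atom-fraction dialect declared
per file), a root-tip census, a morphotype count table, and optional
cross-section-area and per-species tip-biomass tables. ``read_study``
validates schemas and referential integrity; ``run_full_analysis`` executes
the whole tracer-accounting sequence (control means -> APE -> enrichment ->
community -> per-species statistics -> coupling and C/N regressions with
threshold -> pool accounting) deterministically given dataset, config and
seed; ``write_report`` serializes the result as a TSV bundle plus a plain
text summary.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allocation as alloc
from . import community as comm
from . import isotope as iso
from . import stats as st
from .errors import MissingControlsError, SchemaError
from .simulate import MEASUREMENT_COLUMNS, SyntheticStudy

__all__ = [
    "StudyDataset",
    "AnalysisConfig",
    "AnalysisReport",
    "read_study",
    "dataset_from_study",
    "run_full_analysis",
    "write_report",
]

CENSUS_COLUMNS = ["plant_id", "time_point", "n_vital_myco", "n_vital_nonmyco", "n_dry"]
MORPHOTYPE_COLUMNS = ["plant_id", "time_point", "species", "n_tips"]
ELEMENT_SYSTEM = {"C": iso.CARBON_13, "N": iso.NITROGEN_15}
ISOTOPE_OF = {"C": "13C", "N": "15N"}


@dataclass
class StudyDataset:
    measurements: pd.DataFrame
    census: pd.DataFrame
    morphotypes: pd.DataFrame
    areas: pd.DataFrame | None = None
    tip_biomass: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the end-to-end run (biomasses default to the studied trees)."""

    seed: int = 0
    alpha: float = 0.05
    n_permutations: int = 999
    n_bootstrap: int = 2000
    fine_root_biomass_g: float = 3.9
    coarse_root_biomass_g: float = 12.5
    soil_dry_mass_g: float = 54.0
    total_tips_per_plant: float = 29215.0
    auto_log: bool = True
    anosim_on_relative_abundance: bool = True


@dataclass
class AnalysisReport:
    enrichment: pd.DataFrame
    compartment_summary: pd.DataFrame
    control_tests: pd.DataFrame
    community: pd.DataFrame
    anosim: pd.DataFrame
    census_rates: pd.DataFrame
    species_summary: pd.DataFrame
    regressions: pd.DataFrame
    thresholds: pd.DataFrame
    correlations: pd.DataFrame
    pools_per_plant: pd.DataFrame
    pools_summary: pd.DataFrame
    shares: pd.DataFrame
    log: list = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "enrichment": self.enrichment,
            "compartment_summary": self.compartment_summary,
            "control_tests": self.control_tests,
            "community_matrix": self.community,
            "anosim": self.anosim,
            "census_rates": self.census_rates,
            "species_summary": self.species_summary,
            "regressions": self.regressions,
            "thresholds": self.thresholds,
            "correlations": self.correlations,
            "pools_per_plant": self.pools_per_plant,
            "pools_summary": self.pools_summary,
            "shares": self.shares,
        }


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t", encoding="utf-8")


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Schema, dialect and physical-range validation with row numbers."""
    _require_columns(df, MEASUREMENT_COLUMNS, "measurements")
    df = df.copy()
    df["species"] = df["species"].fillna("")
    errors = []
    kinds = set(df["value_kind"].unique())
    if not kinds <= {"delta_permil", "atom_fraction"}:
        raise SchemaError(f"measurements: unknown value_kind {kinds}")
    if len(kinds) > 1:
        raise SchemaError(
            "measurements: mixed delta_permil/atom_fraction dialects in one "
            "file; the value_kind flag is per-file"
        )
    for idx, row in df.iterrows():
        line = idx + 2  # header + 1-based
        if row.dry_mass_g <= 0:
            errors.append(f"line {line}: dry_mass_g must be > 0")
        elif not 0 <= row.element_mass_g <= row.dry_mass_g:
            errors.append(f"line {line}: element_mass_g outside [0, dry_mass_g]")
        if row.element not in ELEMENT_SYSTEM:
            errors.append(f"line {line}: element must be C or N")
        if row.value_kind == "delta_permil" and row.isotope_value <= -1000:
            errors.append(f"line {line}: delta must exceed -1000 permil")
        if row.value_kind == "atom_fraction" and not 0 <= row.isotope_value <= 1:
            errors.append(f"line {line}: atom fraction outside [0, 1]")
    if errors:
        raise SchemaError("measurements:\n" + "\n".join(errors))
    return df


def read_study(
    measurements: str | Path,
    census: str | Path,
    morphotypes: str | Path,
    areas: str | Path | None = None,
    tip_biomass: str | Path | None = None,
) -> StudyDataset:
    """Read and validate all study tables from TSV files."""
    paths = {"measurements": Path(measurements), "census": Path(census),
             "morphotypes": Path(morphotypes)}
    if areas:
        paths["areas"] = Path(areas)
    if tip_biomass:
        paths["tip_biomass"] = Path(tip_biomass)

    meas = validate_measurements(_read_tsv(paths["measurements"]))
    cen = _read_tsv(paths["census"])
    _require_columns(cen, CENSUS_COLUMNS, "census")
    bad = cen[(cen[["n_vital_myco", "n_vital_nonmyco", "n_dry"]] < 0).any(axis=1)]
    if len(bad):
        raise SchemaError(f"census: negative counts in rows {list(bad.index)}")
    novital = cen[cen.n_vital_myco + cen.n_vital_nonmyco == 0]
    if len(novital):
        raise SchemaError(
            f"census: plants without vital tips: {list(novital.plant_id)}"
        )
    mor = _read_tsv(paths["morphotypes"])
    _require_columns(mor, MORPHOTYPE_COLUMNS, "morphotypes")
    merged = mor.groupby("plant_id")["n_tips"].sum().rename("assigned")
    chk = cen.set_index("plant_id").join(merged)
    over = chk[chk["assigned"].fillna(0) > chk["n_vital_myco"]]
    if len(over):
        raise SchemaError(
            "morphotypes: assigned tips exceed vital mycorrhizal tips for "
            f"plants {list(over.index)}"
        )
    # referential integrity: labelled EM measurements name a morphotyped species
    em = meas[(meas.compartment == "EM") & ~meas.is_control & (meas.species != "")]
    known = set(zip(mor.plant_id, mor.species))
    orphan = [
        (r.plant_id, r.species) for r in em.itertuples()
        if (r.plant_id, r.species) not in known
    ]
    if orphan:
        raise SchemaError(
            f"measurements: EM species not in morphotype table: {sorted(set(orphan))}"
        )
    ds = StudyDataset(
        measurements=meas, census=cen, morphotypes=mor,
        areas=_read_tsv(paths["areas"]) if areas else None,
        tip_biomass=_read_tsv(paths["tip_biomass"]) if tip_biomass else None,
        provenance={k: _hash(p) for k, p in paths.items()},
    )
    return ds


def dataset_from_study(study: SyntheticStudy) -> StudyDataset:
    """Wrap an in-memory synthetic study as a validated dataset."""
    return StudyDataset(
        measurements=validate_measurements(study.measurements),
        census=study.census.copy(),
        morphotypes=study.morphotypes.copy(),
        areas=study.areas.copy(),
        tip_biomass=study.tip_biomass.copy(),
        provenance={"source": "synthetic", "seed": study.config.seed},
    )


def compute_enrichment(meas: pd.DataFrame) -> pd.DataFrame:
    """Per-sample APE and enrichment concentration against control means.

    Control atom fractions are averaged per compartment x element over the
    non-labelled plants (the least-assumption mapping of controls to
    samples); 13C results are in mg g-1, 15N in ug g-1, and negative APE is
    retained but flagged.
    """
    meas = meas.copy()
    kind = meas["value_kind"].iloc[0]
    afs = np.empty(len(meas))
    for elem, system in ELEMENT_SYSTEM.items():
        m = (meas["element"] == elem).to_numpy()
        vals = meas.loc[m, "isotope_value"].to_numpy(dtype=float)
        afs[m] = (vals if kind == "atom_fraction"
                  else iso.delta_to_atom_fraction(vals, system))
    meas["atom_fraction"] = afs

    controls = meas[meas.is_control]
    labelled = meas[~meas.is_control].copy()
    ctl_mean = controls.groupby(["compartment", "element"])["atom_fraction"].mean()
    need = set(zip(labelled.compartment, labelled.element))
    have = set(ctl_mean.index)
    if not need <= have:
        raise MissingControlsError(
            f"no controls for compartment x element: {sorted(need - have)}"
        )

    out = []
    for df, is_ctl in ((labelled, False), (controls.copy(), True)):
        key = pd.MultiIndex.from_arrays([df.compartment, df.element])
        af_ctl = ctl_mean.loc[key].to_numpy()
        ape = iso.atom_percent_excess(df["atom_fraction"].to_numpy(), af_ctl)
        isotope = df["element"].map(ISOTOPE_OF)
        unit_factor = isotope.map(iso.UNIT_FACTOR).to_numpy(dtype=float)
        enr = iso.enrichment_concentration(
            ape, df["element_mass_g"].to_numpy(), df["dry_mass_g"].to_numpy(),
            unit_factor=1.0,
        ) * unit_factor
        df = df.assign(
            isotope=isotope,
            ape_percent=ape,
            enrichment_conc=enr,
            element_conc_mg_g=1000.0 * df["element_mass_g"] / df["dry_mass_g"],
            unit=isotope.map(iso.UNIT_NAME) + "/g",
            negative_ape=ape < 0,
        )
        out.append(df)
    return pd.concat(out, ignore_index=True)


def _mean_se(g: pd.Series) -> pd.Series:
    return pd.Series({
        "n": g.size, "mean": g.mean(),
        "se": g.std(ddof=1) / np.sqrt(g.size) if g.size > 1 else np.nan,
    })


def _community_matrix(census: pd.DataFrame, morphotypes: pd.DataFrame) -> comm.CommunityMatrix:
    species = sorted(morphotypes["species"].unique())
    rows, groups = [], []
    for r in census.itertuples():
        c = comm.RootTipCensus(r.plant_id, r.time_point, r.n_vital_myco,
                               r.n_vital_nonmyco, r.n_dry)
        sub = morphotypes[morphotypes.plant_id == r.plant_id]
        t = comm.MorphotypeTable(r.plant_id, r.time_point,
                                 dict(zip(sub.species, sub.n_tips)))
        ra = comm.relative_abundance(t, c)
        rows.append([ra.get(sp, 0.0) for sp in species] + [ra[comm.UNCLASSIFIED]])
        groups.append(r.time_point)
    df = pd.DataFrame(rows, index=census["plant_id"],
                      columns=species + [comm.UNCLASSIFIED])
    return comm.CommunityMatrix(df, groups=pd.Series(groups, index=census["plant_id"]))


def _species_em_table(enr: pd.DataFrame) -> pd.DataFrame:
    """Per plant x species EM observations: C/N ratio and both enrichments."""
    em = enr[(enr.compartment == "EM") & ~enr.is_control & (enr.species != "")]
    pivot = em.pivot_table(
        index=["plant_id", "time_point", "species"],
        columns="element",
        values=["enrichment_conc", "element_conc_mg_g"],
    )
    out = pd.DataFrame({
        "enr_13c": pivot[("enrichment_conc", "C")],
        "enr_15n": pivot[("enrichment_conc", "N")],
        "carbon_conc": pivot[("element_conc_mg_g", "C")],
        "nitrogen_conc": pivot[("element_conc_mg_g", "N")],
    }).reset_index()
    out["cn_ratio"] = out["carbon_conc"] / out["nitrogen_conc"]
    return out


def _lateral_coupling_table(enr: pd.DataFrame) -> pd.DataFrame:
    keys = ["plant_id", "time_point", "species", "element"]
    lab = enr[~enr.is_control & (enr.species != "")]
    em = lab[lab.compartment == "EM"].set_index(keys)["enrichment_conc"]
    lr = lab[lab.compartment == "LR"].set_index(keys)["enrichment_conc"]
    joined = pd.concat({"em": em, "lr": lr}, axis=1).dropna().reset_index()
    return joined


def run_full_analysis(dataset: StudyDataset,
                      config: AnalysisConfig | None = None) -> AnalysisReport:
    """Execute the full tracer-accounting and statistics sequence."""
    config = config or AnalysisConfig()
    log: list[dict] = [{"step": "config", **config.__dict__}]

    enr = compute_enrichment(dataset.measurements)
    log.append({"step": "enrichment", "rows": len(enr)})
    lab = enr[~enr.is_control]

    # compartment-level summary and labelled-vs-control Welch tests
    comp_sum = (
        lab.groupby(["compartment", "isotope", "time_point"])["enrichment_conc"]
        .apply(_mean_se).unstack().reset_index()
    )
    ctl_rows = []
    for (compn, isot), g in lab.groupby(["compartment", "isotope"]):
        ctl = enr[enr.is_control & (enr.compartment == compn)
                  & (enr.isotope == isot)]["enrichment_conc"]
        if g["enrichment_conc"].size >= 2 and ctl.size >= 2:
            p = st.enrichment_above_control_test(g["enrichment_conc"], ctl)
            ctl_rows.append({"compartment": compn, "isotope": isot,
                             "n_labelled": g["enrichment_conc"].size,
                             "n_control": ctl.size, "p_value": p})
    control_tests = pd.DataFrame(ctl_rows)

    # census rates and community composition between sampling dates
    rates = []
    for r in dataset.census.itertuples():
        c = comm.RootTipCensus(r.plant_id, r.time_point, r.n_vital_myco,
                               r.n_vital_nonmyco, r.n_dry)
        rates.append({"plant_id": r.plant_id, "time_point": r.time_point,
                      "colonization_pct": comm.colonization_rate(c),
                      "vitality_pct": comm.vitality_rate(c)})
    census_rates = pd.DataFrame(rates)
    matrix = _community_matrix(dataset.census, dataset.morphotypes)
    anores = comm.anosim(
        matrix, matrix.groups.to_numpy(), n_permutations=config.n_permutations,
        seed=config.seed, use_relative_abundance=config.anosim_on_relative_abundance,
    )
    anosim_df = pd.DataFrame([{
        "groups": "time_point", "r_statistic": anores.r_statistic,
        "p_value": anores.p_value, "n_permutations": anores.n_permutations,
        "seed": anores.seed,
    }])
    log.append({"step": "anosim", "r": anores.r_statistic, "p": anores.p_value})

    # per-species observations, ANOVA + Tukey letters per isotope
    sp_table = _species_em_table(enr)
    species_rows = []
    for col, isot in (("enr_13c", "13C"), ("enr_15n", "15N")):
        groups = {
            sp: g[col].to_numpy() for sp, g in sp_table.groupby("species")
            if g[col].size >= 2
        }
        if len(groups) >= 2:
            res = st.anova_tukey(groups, alpha=config.alpha, auto_log=config.auto_log)
            gm = res.group_means.assign(isotope=isot, f_statistic=res.f_statistic,
                                        p_anova=res.p_value,
                                        log_transformed=res.log_transformed)
            species_rows.append(gm)
    species_summary = (pd.concat(species_rows, ignore_index=True)
                       if species_rows else pd.DataFrame())

    # regressions: lateral-root coupling and C/N stoichiometry
    reg_rows, thr_rows = [], []
    coupling = _lateral_coupling_table(enr)
    for elem, isot, ref in (("C", "13C", 1.0), ("N", "15N", 1.0)):
        sub = coupling[coupling.element == elem]
        if len(sub) >= 3 and np.ptp(sub["lr"].to_numpy()) > 0:
            fit = st.fit_linear(sub["lr"], sub["em"])
            tst = st.test_slope_against_value(sub["lr"], sub["em"], ref)
            reg_rows.append({
                "analysis": f"coupling_{isot.lower()}", "x": "lateral_root",
                "y": "ectomycorrhiza", "isotope": isot, "slope": fit.slope,
                "intercept": fit.intercept, "se_slope": fit.se_slope,
                "r": fit.r, "p_slope": fit.p_slope, "n": fit.n,
                "reference_slope": ref, "t_vs_reference": tst.t_statistic,
                "p_vs_reference": tst.p_value,
            })
    for col, isot in (("enr_13c", "13C"), ("enr_15n", "15N")):
        x = sp_table["cn_ratio"].to_numpy()
        y = sp_table[col].to_numpy()
        if len(sp_table) >= 3 and np.ptp(x) > 0:
            fit = st.fit_linear(x, y)
            reg_rows.append({
                "analysis": f"cn_{isot.lower()}", "x": "cn_ratio",
                "y": "enrichment", "isotope": isot, "slope": fit.slope,
                "intercept": fit.intercept, "se_slope": fit.se_slope,
                "r": fit.r, "p_slope": fit.p_slope, "n": fit.n,
                "reference_slope": np.nan, "t_vs_reference": np.nan,
                "p_vs_reference": np.nan,
            })
            if fit.p_slope <= config.alpha:
                thr = st.x_intercept_threshold(
                    x, y, n_bootstrap=config.n_bootstrap, seed=config.seed,
                    alpha_slope=config.alpha,
                )
                thr_rows.append({
                    "isotope": isot, "cn_threshold": thr.x_intercept,
                    "ci_low": thr.ci_low, "ci_high": thr.ci_high,
                    "n_bootstrap": thr.n_bootstrap, "seed": thr.seed,
                    "method": thr.method,
                })
    regressions = pd.DataFrame(reg_rows)
    thresholds = pd.DataFrame(thr_rows)

    # abundance and fungal-tissue correlations
    corr_rows = []
    ra = matrix.abundances.reset_index().melt(
        id_vars="plant_id", var_name="species", value_name="relative_abundance"
    )
    sp_ra = sp_table.merge(ra, on=["plant_id", "species"], how="left")
    for col, isot in (("enr_13c", "13C"), ("enr_15n", "15N")):
        sub = sp_ra.dropna(subset=[col, "relative_abundance"])
        if len(sub) >= 3:
            r, p = st.pearson_correlation_test(sub["relative_abundance"], sub[col])
            corr_rows.append({"analysis": f"abundance_vs_{isot.lower()}",
                              "r": r, "p_value": p, "n": len(sub)})
    if dataset.areas is not None and len(dataset.areas) >= 3:
        ft = dataset.areas.copy()
        ft["fungal_tissue_pct"] = [
            comm.fungal_tissue_fraction(
                comm.CrossSectionAreas(r.species, r.area_fungal_um2, r.area_total_um2)
            ) for r in ft.itertuples()
        ]
        sp_means = sp_table.groupby("species")[
            ["enr_13c", "enr_15n", "carbon_conc", "nitrogen_conc"]
        ].mean()
        joined = ft.set_index("species").join(sp_means, how="inner")
        for col, label in (("enr_13c", "13C"), ("carbon_conc", "C"),
                           ("enr_15n", "15N"), ("nitrogen_conc", "N")):
            sub = joined.dropna(subset=[col])
            if len(sub) >= 3 and np.ptp(sub[col].to_numpy()) > 0:
                r, p = st.pearson_correlation_test(sub["fungal_tissue_pct"], sub[col])
                corr_rows.append({"analysis": f"fungal_tissue_vs_{label}",
                                  "r": r, "p_value": p, "n": len(sub)})
    correlations = pd.DataFrame(corr_rows)

    # pool accounting per plant and isotope
    tb = (dataset.tip_biomass.set_index("species")["tip_biomass_g"]
          if dataset.tip_biomass is not None else pd.Series(dtype=float))
    abund = matrix.abundances
    pool_rows = []
    bulk = lab[lab.species == ""].pivot_table(
        index=["plant_id", "isotope"], columns="compartment",
        values="enrichment_conc",
    )
    for plant in dataset.census["plant_id"]:
        sp_obs = sp_table[sp_table.plant_id == plant]
        for col, isot in (("enr_13c", "13C"), ("enr_15n", "15N")):
            entries = [
                alloc.SpeciesPoolEntry(
                    species=r.species,
                    enrichment_conc=getattr(r, col),
                    tip_biomass=float(tb.get(r.species, 0.0)),
                    relative_abundance=float(abund.loc[plant, r.species]),
                )
                for r in sp_obs.itertuples()
            ]
            em_pool = (alloc.em_pool_amount(entries, config.total_tips_per_plant)
                       if entries else np.nan)
            if (plant, isot) in bulk.index:
                row = bulk.loc[(plant, isot)]
                fine = alloc.rhizosphere_amount(row.get("FR", np.nan),
                                                config.fine_root_biomass_g)
                coarse = alloc.rhizosphere_amount(row.get("CR", np.nan),
                                                  config.coarse_root_biomass_g)
                rhizo = alloc.rhizosphere_amount(row.get("RS", np.nan),
                                                 config.soil_dry_mass_g)
            else:
                fine = coarse = rhizo = np.nan
            pool_rows.append({
                "plant_id": plant, "isotope": isot, "unit": iso.UNIT_NAME[isot],
                "em_pool": em_pool, "fine_root": fine, "coarse_root": coarse,
                "total_root": fine + coarse, "rhizosphere": rhizo,
            })
    pools = pd.DataFrame(pool_rows)
    pool_cols = ["em_pool", "fine_root", "coarse_root", "total_root", "rhizosphere"]
    pools_summary = (
        pools.groupby("isotope")[pool_cols]
        .agg(["mean", "sem"]).stack(level=0, future_stack=True).reset_index()
        .rename(columns={"level_1": "pool"})
    )

    share_rows = []
    for isot, g in pools.groupby("isotope"):
        m = g[pool_cols].mean()
        if m["fine_root"] > 0:
            share_rows.extend([
                {"isotope": isot, "quantity": "em_share_of_fine_root_pct",
                 "value": alloc.pool_share(m["em_pool"], m["fine_root"])},
                {"isotope": isot,
                 "quantity": "em_plus_rhizosphere_share_of_fine_root_pct",
                 "value": alloc.pool_share(m["em_pool"] + m["rhizosphere"],
                                           m["fine_root"])},
                {"isotope": isot, "quantity": "coarse_to_fine_ratio",
                 "value": alloc.coarse_to_fine_ratio(m["total_root"], m["fine_root"])},
            ])
    m13 = pools[pools.isotope == "13C"][pool_cols].mean()
    m15 = pools[pools.isotope == "15N"][pool_cols].mean()
    for pool in ("total_root", "em_pool"):
        if m15[pool] > 0:
            share_rows.append({
                "isotope": "13C/15N", "quantity": f"transfer_ratio_{pool}",
                "value": alloc.transfer_ratio(m13[pool], m15[pool]),
            })
    shares = pd.DataFrame(share_rows)
    log.append({"step": "pools", "plants": pools["plant_id"].nunique()})

    return AnalysisReport(
        enrichment=enr, compartment_summary=comp_sum, control_tests=control_tests,
        community=matrix.abundances.reset_index(), anosim=anosim_df,
        census_rates=census_rates, species_summary=species_summary,
        regressions=regressions, thresholds=thresholds, correlations=correlations,
        pools_per_plant=pools, pools_summary=pools_summary, shares=shares, log=log,
    )


def write_report(report: AnalysisReport, out_dir: str | Path) -> dict[str, Path]:
    """Write every report table as TSV plus a human-readable summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in report.tables().items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    lines = ["mycotrace analysis summary", "=" * 28, ""]
    if len(report.regressions):
        for r in report.regressions.itertuples():
            lines.append(
                f"{r.analysis}: y = {r.slope:+.3f} x {r.intercept:+.2f} "
                f"(R = {r.r:.3f}, p = {r.p_slope:.3g}, n = {r.n})"
            )
    for t in report.thresholds.itertuples():
        lines.append(
            f"C/N threshold ({t.isotope}): {t.cn_threshold:.2f} "
            f"[{t.ci_low:.2f}, {t.ci_high:.2f}] ({t.method}, B = {t.n_bootstrap})"
        )
    for a in report.anosim.itertuples():
        lines.append(f"ANOSIM ({a.groups}): R = {a.r_statistic:.3f}, "
                     f"p = {a.p_value:.3f} ({a.n_permutations} permutations)")
    for s in report.shares.itertuples():
        lines.append(f"{s.isotope} {s.quantity}: {s.value:.2f}")
    for entry in report.log:
        lines.append("log: " + ", ".join(f"{k}={v}" for k, v in entry.items()))
    p = out / "summary.txt"
    p.write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths["summary"] = p
    return paths
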