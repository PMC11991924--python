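"""Synthetic reservoir scenarios with known ground truth.

Emulates a monsoon-climate drinking-water reservoir surveyed on repeated
cruises: 12 stations sampled at the surface, four key stations profiled over
depth, summer thermal stratification, and seasonally varying nutrients.  Each
phytoplankton group responds to every environmental variable through a
Gaussian (bell-shaped) niche with known optimum ``mu*`` and breadth
``sigma*``; group biomasses are mapped to pigment concentrations through a
known group x pigment ratio matrix and to microscopy counts through a Poisson
counting model.  Because every downstream stage of the pipeline (chemotaxonomy,
abundance computation, niche estimation, ordination) has a known answer here,
the whole analysis is testable by parameter recovery without any field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EnvVariable",
    "ScenarioConfig",
    "default_scenario",
    "default_ratio_matrix",
    "generate_environment",
    "generate_true_biomass",
    "generate_pigments",
    "generate_counts",
    "write_scenario",
    "season_of_month",
]

#: Months -> hydrological season (Dec-Feb winter, Mar-May spring,
#: Jun-Aug summer, Sep-Nov autumn).
_SEASON_BY_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

#: Position of each season on the seasonal (winter -1 ... summer +1) axis.
SEASON_FACTOR = {"winter": -1.0, "spring": 0.0, "summer": 1.0, "autumn": 0.0}

#: Strength of vertical stratification by season: full thermocline in summer,
#: weak stratification in spring, mixed water column in autumn/winter.
STRATIFICATION = {"winter": 0.0, "spring": 0.3, "summer": 1.0, "autumn": 0.0}

PIGMENTS = (
    "peridinin", "fucoxanthin", "violaxanthin", "alloxanthin", "lutein",
    "neoxanthin", "zeaxanthin", "chlorophyll_b", "diadinoxanthin",
    "echinenone", "tchla",
)

GROUPS = ("Bacillariophyta", "Chlorophyta", "Cryptophyta", "Cyanophyta",
          "Pyrrophyta")

NICHE_VARIABLES = ("temperature", "pH", "DO", "NOx", "DRP", "DSi")


def season_of_month(month: int) -> str:
    return _SEASON_BY_MONTH[int(month)]


@dataclass(frozen=True)
class EnvVariable:
    """Seasonal/vertical model for one environmental variable.

    value = mean + amplitude * season_factor
            + gradient * depth * stratification(season)
            + Normal(0, noise_sd)

    with ``season_factor`` +1 in summer, -1 in winter, 0 in the transition
    seasons, and the vertical gradient active only when the water column is
    stratified.  Values falling below ``detection_limit`` are stored as half
    the limit and flagged (the usual non-detect convention).
    """

    mean: float
    amplitude: float = 0.0
    gradient: float = 0.0  # units per metre while stratified
    noise_sd: float = 0.0
    detection_limit: float | None = None


@dataclass
class ScenarioConfig:
    """Full description of a synthetic reservoir survey."""

    n_stations: int = 12
    profile_stations: tuple[str, ...] = ("X2", "X5", "X9", "X12")
    depths: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 30.0)
    #: (cruise label, ISO date); the season is derived from the month.
    cruises: tuple[tuple[str, str], ...] = (
        ("C1", "2022-08-15"), ("C2", "2022-11-15"), ("C3", "2023-02-15"),
        ("C4", "2023-04-15"), ("C5", "2023-08-15"), ("C6", "2023-11-15"),
        ("C7", "2024-01-15"),
    )
    env_params: dict[str, EnvVariable] = field(default_factory=dict)
    groups: tuple[str, ...] = GROUPS
    niche_variables: tuple[str, ...] = NICHE_VARIABLES
    #: group -> variable -> (mu*, sigma*)
    true_niches: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict)
    #: peak chlorophyll-a biomass of each group at its joint optimum (ng/L)
    biomass_scale: dict[str, float] = field(default_factory=dict)
    ratio_matrix_true: pd.DataFrame | None = None
    noise_cv: float = 0.3
    #: cells per ng chlorophyll a, used by the counting model
    cells_per_chla: dict[str, float] = field(default_factory=dict)
    count_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")
        if len(self.depths) == 0:
            raise ValueError("depth list must not be empty")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not self.env_params:
            raise ValueError("env_params must not be empty")
        for g in self.groups:
            niches = self.true_niches.get(g)
            if niches is None:
                raise ValueError(f"group {g!r} has no niche entry")
            for v in self.niche_variables:
                if v not in niches:
                    raise ValueError(f"group {g!r} lacks a niche for {v!r}")
                _, sigma = niches[v]
                if sigma <= 0:
                    raise ValueError(
                        f"sigma_true for ({g!r}, {v!r}) must be > 0")
        for g, f in self.cells_per_chla.items():
            if f < 0:
                raise ValueError(f"cells_per_chla[{g!r}] must be >= 0")

    @property
    def stations(self) -> tuple[str, ...]:
        return tuple(f"X{i + 1}" for i in range(self.n_stations))


def default_ratio_matrix() -> pd.DataFrame:
    """Group x pigment mass ratios normalised to chlorophyll a.

    Entries follow the usual diagnostic-pigment assignments: fucoxanthin and
    diadinoxanthin for diatoms, chlorophyll b / lutein / neoxanthin /
    violaxanthin for green algae, alloxanthin for cryptophytes, zeaxanthin and
    echinenone for cyanobacteria, peridinin for dinoflagellates.  The tchla
    column is identically 1 by construction.
    """
    R = pd.DataFrame(0.0, index=list(GROUPS), columns=list(PIGMENTS))
    R.loc["Bacillariophyta", ["fucoxanthin", "diadinoxanthin"]] = [0.75, 0.14]
    R.loc["Chlorophyta", ["violaxanthin", "lutein", "neoxanthin",
                          "zeaxanthin", "chlorophyll_b"]] = \
        [0.06, 0.20, 0.05, 0.02, 0.35]
    R.loc["Cryptophyta", "alloxanthin"] = 0.35
    R.loc["Cyanophyta", ["zeaxanthin", "echinenone"]] = [0.35, 0.10]
    R.loc["Pyrrophyta", ["peridinin", "diadinoxanthin"]] = [0.60, 0.24]
    R["tchla"] = 1.0
    return R


def _default_env_params() -> dict[str, EnvVariable]:
    # Ranges bracket a warm monomictic reservoir: ~18 C winter / ~30 C summer
    # surface water, alkaline pH, a P-deficient nutrient pool.  Temperature
    # carries the seasonal cycle and the summer thermocline; the remaining
    # niche axes vary mostly independently (weak seasonality, no vertical
    # gradient) so that each group's niche is identifiable from a univariate
    # response curve — strongly collinear gradients would confound the
    # marginal estimates for any method.
    return {
        "temperature": EnvVariable(24.0, 6.0, -0.35, 2.0),
        "pH": EnvVariable(8.2, 0.1, 0.0, 1.0),
        "DO": EnvVariable(9.0, 0.2, 0.0, 1.9),
        "conductivity": EnvVariable(140.0, 15.0, 0.0, 8.0),
        "NOx": EnvVariable(90.0, -3.0, 0.0, 28.0, detection_limit=0.007),
        "DRP": EnvVariable(0.13, -0.003, 0.0, 0.055, detection_limit=0.019),
        "DSi": EnvVariable(140.0, -5.0, 0.0, 43.0, detection_limit=0.03),
    }


def _default_niches() -> dict[str, dict[str, tuple[float, float]]]:
    # Encodes the qualitative community structure of a warm stratified
    # reservoir: green algae and cyanobacteria share warm, alkaline,
    # nutrient-rich optima; diatoms and cryptophytes prefer cool silicate-rich
    # water; dinoflagellates sit apart with low pH/DO optima and the widest
    # pH and phosphorus tolerance.  Optima sit within ~0.6 sd of each
    # variable's centre and breadths are comparable to the variable's spread:
    # optima near the edge of the sampled range, or breadths far wider than
    # it, are not identifiable from field-style occupancy data.
    return {
        "Bacillariophyta": {
            "temperature": (21.5, 4.75), "pH": (7.85, 1.0), "DO": (10.0, 2.1),
            "NOx": (76.0, 31.0), "DRP": (0.10, 0.0625), "DSi": (163.0, 47.5),
        },
        "Chlorophyta": {
            "temperature": (26.6, 5.0), "pH": (8.6, 1.06), "DO": (9.6, 2.25),
            "NOx": (104.0, 32.5), "DRP": (0.158, 0.0625), "DSi": (122.0, 47.5),
        },
        "Cryptophyta": {
            "temperature": (21.8, 4.75), "pH": (7.9, 1.0), "DO": (9.9, 2.1),
            "NOx": (74.0, 31.0), "DRP": (0.10, 0.0625), "DSi": (158.0, 47.5),
        },
        "Cyanophyta": {
            "temperature": (27.0, 5.0), "pH": (8.75, 1.06), "DO": (9.8, 2.25),
            "NOx": (107.0, 32.5), "DRP": (0.162, 0.0625), "DSi": (116.0, 45.0),
        },
        "Pyrrophyta": {
            "temperature": (24.5, 3.75), "pH": (7.6, 1.15), "DO": (7.8, 1.875),
            "NOx": (86.0, 25.0), "DRP": (0.125, 0.0775), "DSi": (138.0, 45.0),
        },
    }


def default_scenario(seed: int = 0, *, noise_cv: float = 0.3,
                     n_cruises: int | None = None) -> ScenarioConfig:
    """The default reservoir scenario: 12 stations, 7 cruises spanning four
    seasons, 4 vertical-profile stations at depths 0-30 m, 5 groups and 11
    pigment columns.

    ``n_cruises`` extends the survey by cycling through the default cruise
    calendar (one extra year per 7 cruises) when a larger sample is wanted.
    """
    cfg = ScenarioConfig(
        env_params=_default_env_params(),
        true_niches=_default_niches(),
        biomass_scale={
            "Bacillariophyta": 2500.0, "Chlorophyta": 5000.0,
            "Cryptophyta": 2000.0, "Cyanophyta": 6000.0, "Pyrrophyta": 800.0,
        },
        ratio_matrix_true=default_ratio_matrix(),
        noise_cv=noise_cv,
        cells_per_chla={
            "Bacillariophyta": 50.0, "Chlorophyta": 100.0,
            "Cryptophyta": 80.0, "Cyanophyta": 500.0, "Pyrrophyta": 20.0,
        },
        seed=seed,
    )
    if n_cruises is not None and n_cruises != len(cfg.cruises):
        base = cfg.cruises
        cruises = []
        for i in range(n_cruises):
            label, date = base[i % len(base)]
            year = int(date[:4]) + i // len(base)
            cruises.append((f"C{i + 1}", f"{year}{date[4:]}"))
        cfg = replace(cfg, cruises=tuple(cruises))
    return cfg


def _lognormal_factor(rng: np.random.Generator, cv: float,
                      size) -> np.ndarray:
    """Mean-preserving multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    s = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * s ** 2, sigma=s, size=size)


def generate_environment(config: ScenarioConfig) -> pd.DataFrame:
    """One row per station x depth x cruise with every environmental variable.

    Surface (0 m) samples are generated at all stations; the remaining depths
    only at the profile stations.  Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    rows = []
    profile = set(config.profile_stations) & set(config.stations)
    for cruise, date in config.cruises:
        season = season_of_month(int(date[5:7]))
        for station in config.stations:
            depths = config.depths if station in profile \
                else config.depths[:1]
            for depth in depths:
                rows.append((cruise, date, season, station, float(depth)))
    env = pd.DataFrame(rows, columns=["cruise", "date", "season", "station",
                                      "depth"])
    env.insert(0, "sample_id", [
        f"{c}-{s}-{d:g}m" for c, s, d in
        zip(env["cruise"], env["station"], env["depth"])])
    sf = env["season"].map(SEASON_FACTOR).to_numpy()
    strat = env["season"].map(STRATIFICATION).to_numpy()
    depth = env["depth"].to_numpy()
    n = len(env)
    for var, p in config.env_params.items():
        x = p.mean + p.amplitude * sf + p.gradient * depth * strat
        if p.noise_sd > 0:
            x = x + rng.normal(0.0, p.noise_sd, n)
        if p.detection_limit is not None:
            censored = x < p.detection_limit
            x = np.where(censored, p.detection_limit / 2.0, x)
            env[var] = x
            env[f"{var}_censored"] = censored
        else:
            env[var] = x
    return env


def generate_true_biomass(env: pd.DataFrame,
                          config: ScenarioConfig) -> pd.DataFrame:
    """Ground-truth chlorophyll-a biomass of each group in each sample.

    biomass(g, i) = K_g * prod_v exp(-(x_iv - mu*_gv)^2 / (2 sigma*_gv^2))
                    * lognormal(cv = noise_cv)
    """
    config.validate()
    missing = [v for v in config.niche_variables if v not in env.columns]
    if missing:
        raise KeyError(f"environment table lacks variable(s): {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    out = pd.DataFrame({"sample_id": env["sample_id"].to_numpy()})
    for g in config.groups:
        logb = np.full(len(env), np.log(config.biomass_scale.get(g, 1000.0)))
        for v in config.niche_variables:
            mu, sigma = config.true_niches[g][v]
            x = env[v].to_numpy(dtype=float)
            logb -= (x - mu) ** 2 / (2.0 * sigma ** 2)
        out[g] = np.exp(logb) * _lognormal_factor(rng, config.noise_cv,
                                                  len(env))
    return out


def generate_pigments(truth: pd.DataFrame,
                      config: ScenarioConfig) -> pd.DataFrame:
    """Pigment table implied by the true biomasses and the true ratio matrix.

    pigments = biomass @ ratio_matrix, then cell-wise multiplicative
    lognormal noise.  The tchla column of the product is the row sum of group
    chlorophyll a because the ratio matrix's tchla column is 1.
    """
    R = config.ratio_matrix_true
    if R is None:
        raise ValueError("config.ratio_matrix_true is not set")
    groups = [g for g in truth.columns if g != "sample_id"]
    if list(R.index) != groups:
        if set(R.index) != set(groups):
            raise ValueError(
                "ratio matrix rows do not match biomass groups: "
                f"{list(R.index)} vs {groups}")
        R = R.loc[groups]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    B = truth[groups].to_numpy(dtype=float)
    P = B @ R.to_numpy(dtype=float)
    P *= _lognormal_factor(rng, config.noise_cv, P.shape)
    out = pd.DataFrame(P, columns=list(R.columns))
    out.insert(0, "sample_id", truth["sample_id"].to_numpy())
    return out


def generate_counts(truth: pd.DataFrame, config: ScenarioConfig, *,
                    A: float = 400.0, Ac: float = 400.0, V0: float = 500.0,
                    V1: float = 30.0, V: float = 0.1) -> pd.DataFrame:
    """Microscopy count records for each sample x group x replicate.

    A 500 mL sample is settled and concentrated to 30 mL; a 0.1 mL aliquot is
    counted over an area ``Ac`` of the ``A`` = 400 mm^2 chamber.  The expected
    count in the aliquot is

        E[n] = cells_per_litre * (V0/1000) * (V/V1) * (Ac/A)

    and the observed count is Poisson with that mean, in triplicate.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    groups = [g for g in truth.columns if g != "sample_id"]
    recs = []
    for g in groups:
        factor = config.cells_per_chla.get(g, 0.0)
        cells_per_l = truth[g].to_numpy(dtype=float) * factor
        mean_n = cells_per_l * (V0 / 1000.0) * (V / V1) * (Ac / A)
        for rep in range(config.count_replicates):
            n = rng.poisson(mean_n)
            for sid, ni in zip(truth["sample_id"], n):
                recs.append((sid, g, rep + 1, int(ni), A, Ac, V0, V1, V))
    return pd.DataFrame(recs, columns=["sample_id", "group", "replicate",
                                       "n", "A", "Ac", "V0", "V1", "V"])


def write_scenario(config: ScenarioConfig, outdir) -> dict[str, str]:
    """Generate a full scenario and write the pipeline input files.

    Writes pigments.csv, environment.csv, counts.csv plus the ground truth
    (truth.csv with per-sample biomass, true_niches.csv with mu*/sigma*, and
    true_ratios.csv) as comma-separated UTF-8 text.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    env = generate_environment(config)
    truth = generate_true_biomass(env, config)
    pig = generate_pigments(truth, config)
    counts = generate_counts(truth, config)
    niche_rows = [
        (g, v, *config.true_niches[g][v])
        for g in config.groups for v in config.niche_variables]
    true_niches = pd.DataFrame(niche_rows,
                               columns=["group", "variable", "mu", "sigma"])
    paths = {}
    for name, df in [("environment", env), ("pigments", pig),
                     ("counts", counts), ("truth", truth),
                     ("true_niches", true_niches)]:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = str(path)
    rpath = outdir / "true_ratios.csv"
    config.ratio_matrix_true.to_csv(rpath, index_label="group")
    paths["true_ratios"] = str(rpath)
    return paths
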