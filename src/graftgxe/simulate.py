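"""Synthetic study generator with known planted truth.

Emulates a replicated grafted-vineyard expression study: a 2-tissue x 3-year
x 3-phenology x 4-rootstock factorial sampled in replicated blocks, with the
reproductive x harvest cell of the final year missing (fruit lost to powdery
mildew in the source design). Counts are negative-binomial with a 1/mu + a0
dispersion trend, lognormal library-size heterogeneity, planted rootstock /
tissue / year / phenology effects, and rootstock-specific responses to a
weather-derived environment index. An hourly weather record is simulated with
diurnal and seasonal structure and an anomalous middle year (warmer, higher
evapotranspiration, more variable humidity).

Everything is deterministic given the config seed, so every downstream stage
has a parameter-recovery test surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AnnotationMap, CountMatrix, FactorDomains, HourlyWeather, SampleTable

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "ARCHETYPES",
    "GXE_PATTERN",
    "simulate_design",
    "simulate_weather",
    "simulate_counts",
    "simulate_annotation",
    "simulate_study",
]

#: Rootstock-pattern archetypes planted on rootstock-responsive genes, as
#: log2-fold multipliers over (ungrafted, 1103P, 3309C, SO4). These are the
#: recoverable cluster shapes the SOM stage is expected to find.
ARCHETYPES = {
    "grafted_up": (0.0, 1.0, 1.0, 1.0),
    "grafted_down": (0.0, -1.0, -1.0, -1.0),
    "single_up": (0.0, 1.0, 0.0, 0.0),
    "split": (1.0, -1.0, 1.0, -1.0),
}

#: Environment-slope pattern over (ungrafted, 1103P, 3309C, SO4): ungrafted
#: and 3309C respond positively to the environment index, 1103P and SO4
#: negatively — the cross pattern the interaction screen must flag.
GXE_PATTERN = (1.0, -1.0, 1.0, -1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults give 2,000 genes x 204 samples (3 blocks, 1 vine per block) so
    full-pipeline runs finish in minutes; the deposited study's physical
    layout (9 blocks x 2 vines, 1,224 samples) is obtained by overriding
    ``n_blocks`` and ``n_vines``.
    """

    n_genes: int = 2000
    n_blocks: int = 3
    n_vines: int = 1
    domains: FactorDomains = field(default_factory=FactorDomains)
    years: tuple = (2017, 2018, 2019)

    # negative-binomial model: Var = mu + alpha(mu) mu^2, alpha = a1/mu + a0
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    disp_a0: float = 0.1
    disp_a1: float = 1.0
    libsize_sd: float = 0.3

    # planted effects: fraction of genes carrying the effect, log2-fold size
    frac_rootstock: float = 0.05
    lfc_rootstock: float = 1.5
    frac_tissue: float = 0.30
    lfc_tissue: float = 2.0
    frac_year: float = 0.20
    lfc_year: float = 1.0
    frac_phenology: float = 0.20
    lfc_phenology: float = 1.0
    frac_gxe: float = 0.05
    slope_gxe: float = 1.0  # log2-fold per SD of the environment index

    # weather generator
    season_start_month: int = 4
    season_start_day: int = 1
    season_days: int = 214
    temp_base: float = 20.0
    seasonal_amplitude: float = 8.0
    diurnal_amplitude: float = 5.0
    weather_noise_sd: float = 1.5
    temp_offset_year2: float = 3.0
    et_offset_year2: float = 0.05
    humidity_var_factor_year2: float = 1.5

    # annotation generator
    n_terms: int = 50
    term_size_mean: float = 40.0
    enrich_odds: float = 20.0
    frac_fail_evalue: float = 0.2

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_rootstock", "frac_tissue", "frac_year", "frac_phenology",
                     "frac_gxe", "frac_fail_evalue"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.disp_a0 < 0 or self.disp_a1 < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class PlantedTruth:
    """Per-gene record of every planted effect: flags, magnitudes, the
    rootstock archetype id (for SOM recovery), and per-rootstock environment
    slopes (for interaction-screen recovery)."""

    data: pd.DataFrame
    rootstocks: tuple

    def genes_with(self, effect: str) -> list:
        return self.data.loc[self.data[f"{effect}_flag"], "gene"].tolist()


# ---------------------------------------------------------------------------
# design


def simulate_design(config: SimulationConfig) -> SampleTable:
    """Full factorial over declared levels x blocks x vines, minus the
    reproductive x harvest cell of the final year. Deterministic.

    Sampling datetimes follow the field protocol: each (year, phenology) has
    one sampling day, with samples collected in block order between 10:00 and
    14:00 local time.
    """
    d = config.domains
    for name, levels in (("tissue", d.tissue), ("phenology", d.phenology),
                         ("rootstock", d.rootstock), ("years", config.years)):
        if not levels:
            raise ValueError(f"empty factor level list: {name}")

    phen_base_doy = {p: doy for p, doy in zip(d.phenology, (156, 220, 268))}
    rows = []
    last_year = max(config.years)
    for year in config.years:
        for pi, phen in enumerate(d.phenology):
            doy = phen_base_doy.get(phen, 150 + 50 * pi) + (year - min(config.years))
            date = pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=doy - 1)
            cell = []
            for tissue in d.tissue:
                if tissue == "reproductive" and phen == "harvest" and year == last_year:
                    continue  # fruit not collected in the final harvest
                for ri, rootstock in enumerate(d.rootstock):
                    for block in range(1, config.n_blocks + 1):
                        for vine in range(1, config.n_vines + 1):
                            cell.append((tissue, rootstock, ri, block, vine))
            times = np.linspace(10.0, 14.0, num=max(len(cell), 2))
            for k, (tissue, rootstock, ri, block, vine) in enumerate(cell):
                when = date + pd.Timedelta(hours=float(times[k]))
                irrigation = d.irrigation[(block - 1) % len(d.irrigation)]
                rows.append({
                    "sample": f"{year}_{phen}_{tissue}_{rootstock}_b{block}_v{vine}",
                    "tissue": tissue,
                    "year": year,
                    "phenology": phen,
                    "rootstock": rootstock,
                    "irrigation": irrigation,
                    "block": f"b{block}",
                    "datetime": when,
                })
    return SampleTable(pd.DataFrame(rows), domains=d)


# ---------------------------------------------------------------------------
# weather


def simulate_weather(config: SimulationConfig) -> HourlyWeather:
    """Hourly record over the growing seasons of all study years.

    The middle year receives the configured positive offsets on temperature
    and reference evapotranspiration and inflated humidity noise, emulating
    the study's anomalous season.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    frames = []
    year2 = config.years[1] if len(config.years) > 1 else None
    for year in config.years:
        start = pd.Timestamp(
            year=year, month=config.season_start_month, day=config.season_start_day
        )
        n_hours = config.season_days * 24
        ts = pd.date_range(start, periods=n_hours, freq="h")
        hours = np.arange(n_hours)
        day_frac = (hours % 24) / 24.0
        season_frac = hours / n_hours

        is_anom = year == year2
        t_offset = config.temp_offset_year2 if is_anom else 0.0
        # all stochastic components scale with the configured noise sd so the
        # zero-noise limit is fully deterministic and year means compare exactly
        noise_scale = config.weather_noise_sd / 1.5
        hum_sd = 4.0 * noise_scale * (
            config.humidity_var_factor_year2 if is_anom else 1.0
        )

        seasonal = config.temp_base + config.seasonal_amplitude * np.sin(
            np.pi * season_frac
        )
        diurnal = config.diurnal_amplitude * np.sin(2 * np.pi * (day_frac - 0.25))
        temp = seasonal + diurnal + t_offset + rng.normal(0, config.weather_noise_sd, n_hours)

        sun = np.clip(np.sin(2 * np.pi * (day_frac - 0.25)), 0, None)
        clear_sky = 900.0 * sun * (0.75 + 0.25 * np.sin(np.pi * season_frac))
        cloud = 0.7 + noise_scale * (rng.beta(5, 2, n_hours) - 5.0 / 7.0)
        radiance = clear_sky * np.clip(cloud, 0, 1)
        rad_density = radiance * 0.0036  # hourly MJ/m^2 from W/m^2

        humidity = np.clip(
            85.0 - 1.2 * (temp - config.temp_base) + rng.normal(0, 1, n_hours) * hum_sd,
            5,
            100,
        )
        precip = np.where(
            rng.random(n_hours) < 0.04, rng.exponential(1.5, n_hours) * noise_scale, 0.0
        )
        wind = np.abs(3.0 + rng.normal(0, 1.5, n_hours) * noise_scale)
        pressure = (
            1013.0
            - 0.1 * (temp - config.temp_base)
            + rng.normal(0, 2.0, n_hours) * noise_scale
        )
        dew = temp - (100.0 - humidity) / 5.0
        et = np.clip(
            0.008 * np.clip(temp - 5.0, 0, None)
            + 0.00025 * radiance
            + rng.normal(0, 0.01, n_hours) * noise_scale,
            0,
            None,
        ) + (config.et_offset_year2 if is_anom else 0.0)

        frames.append(pd.DataFrame({
            "timestamp": ts,
            "temperature": temp,
            "precipitation": precip,
            "wind_speed": wind,
            "relative_humidity": humidity,
            "solar_radiance": radiance,
            "radiation_density": rad_density,
            "pressure": pressure,
            "dew_point": dew,
            "ref_evapotranspiration": et,
            "clear_sky_radiation": clear_sky,
        }))
    return HourlyWeather(pd.concat(frames, ignore_index=True))


def environment_index(weather: HourlyWeather) -> pd.Series:
    """Standardized day-mean temperature: the planted environment axis.

    The generator couples expression to this index (a stand-in for the first
    environmental PC); recovery tests know it exactly.
    """
    df = weather.data
    day_mean = df.groupby(df["timestamp"].dt.normalize())["temperature"].mean()
    z = (day_mean - day_mean.mean()) / day_mean.std(ddof=0)
    return z


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    design: SampleTable, weather: HourlyWeather, config: SimulationConfig
) -> tuple:
    """Negative-binomial counts with planted design effects.

    log2 mu(g, s) = baseline_g + tissue + year + phenology + rootstock
    archetype + rootstock-specific slope x environment index of the sampling
    day + library factor. Var(K) = mu + alpha(mu) mu^2 with
    alpha(mu) = a1/mu + a0.

    Returns ``(CountMatrix, PlantedTruth)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    meta = design.data
    n_s = len(meta)
    n_g = config.n_genes
    d = config.domains
    rootstocks = tuple(d.rootstock)
    if len(rootstocks) != len(GXE_PATTERN):
        raise ValueError("generator archetypes assume four rootstock levels")

    env = environment_index(weather)
    dates = meta["datetime"].dt.normalize()
    missing = sorted(set(dates) - set(env.index))
    if missing:
        raise ValueError(f"design dates not covered by weather: {missing[:3]}")
    env_s = dates.map(env).to_numpy()

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_g)
    lib = np.exp(rng.normal(0.0, config.libsize_sd, n_s))

    def pick(frac):
        flags = np.zeros(n_g, bool)
        k = int(round(frac * n_g))
        if k:
            flags[rng.choice(n_g, size=k, replace=False)] = True
        return flags

    rs_flag = pick(config.frac_rootstock)
    ti_flag = pick(config.frac_tissue)
    yr_flag = pick(config.frac_year)
    ph_flag = pick(config.frac_phenology)
    gxe_flag = pick(config.frac_gxe)

    arch_names = list(ARCHETYPES)
    arch_id = np.where(rs_flag, rng.integers(0, len(arch_names), n_g), -1)
    arch_mat = np.array([ARCHETYPES[a] for a in arch_names])  # archetype x rootstock

    ti_sign = rng.choice([-1.0, 1.0], n_g)
    yr_level = rng.integers(0, len(config.years), n_g)
    yr_sign = rng.choice([-1.0, 1.0], n_g)
    ph_level = rng.integers(0, len(d.phenology), n_g)
    ph_sign = rng.choice([-1.0, 1.0], n_g)

    slopes = np.zeros((n_g, len(rootstocks)))
    slopes[gxe_flag] = config.slope_gxe * np.asarray(GXE_PATTERN)

    rs_idx = meta["rootstock"].map({r: i for i, r in enumerate(rootstocks)}).to_numpy()
    ti_is_second = (meta["tissue"] == d.tissue[-1]).to_numpy().astype(float)
    yr_idx = meta["year"].map({y: i for i, y in enumerate(config.years)}).to_numpy()
    ph_idx = meta["phenology"].map({p: i for i, p in enumerate(d.phenology)}).to_numpy()

    log2mu = np.tile(baseline[:, None], (1, n_s))
    rs_rows = np.where(rs_flag)[0]
    if rs_rows.size:
        log2mu[rs_rows] += (
            config.lfc_rootstock * arch_mat[arch_id[rs_rows]][:, rs_idx]
        )
    log2mu[ti_flag] += (
        config.lfc_tissue * ti_sign[ti_flag, None] * ti_is_second[None, :]
    )
    yr_rows = np.where(yr_flag)[0]
    if yr_rows.size:
        hit = (yr_idx[None, :] == yr_level[yr_rows, None]).astype(float)
        log2mu[yr_rows] += config.lfc_year * yr_sign[yr_rows, None] * hit
    ph_rows = np.where(ph_flag)[0]
    if ph_rows.size:
        hit = (ph_idx[None, :] == ph_level[ph_rows, None]).astype(float)
        log2mu[ph_rows] += config.lfc_phenology * ph_sign[ph_rows, None] * hit
    gxe_rows = np.where(gxe_flag)[0]
    if gxe_rows.size:
        log2mu[gxe_rows] += slopes[gxe_rows][:, rs_idx] * env_s[None, :]

    mu = np.exp2(log2mu) * lib[None, :]
    counts = _nb_sample(rng, mu, config.disp_a0, config.disp_a1)

    genes = [f"g{i:05d}" for i in range(n_g)]
    truth = pd.DataFrame({
        "gene": genes,
        "baseline_log2": baseline,
        "rootstock_flag": rs_flag,
        "rootstock_lfc": np.where(rs_flag, config.lfc_rootstock, 0.0),
        "archetype": [arch_names[a] if a >= 0 else "" for a in arch_id],
        "tissue_flag": ti_flag,
        "tissue_lfc": np.where(ti_flag, config.lfc_tissue * ti_sign, 0.0),
        "year_flag": yr_flag,
        "phenology_flag": ph_flag,
        "gxe_flag": gxe_flag,
    })
    for i, r in enumerate(rootstocks):
        truth[f"slope_{r}"] = slopes[:, i]

    matrix = CountMatrix(genes, design.samples, counts)
    return matrix, PlantedTruth(truth, rootstocks)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """Draw NB counts with Var = mu + (a1/mu + a0) mu^2 = (1+a1) mu + a0 mu^2.

    With alpha = a1/mu + a0 the NB size is 1/alpha; the a0 = a1 = 0 limit is
    Poisson.
    """
    mu = np.clip(mu, 1e-12, None)
    alpha = a1 / mu + a0
    if a0 == 0.0 and a1 == 0.0:
        return rng.poisson(mu).astype(np.int64)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p).astype(np.int64)


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimulationConfig, truth: PlantedTruth) -> AnnotationMap:
    """Assign functional terms so the first term is enriched (with the
    configured odds) among rootstock-responsive genes, remaining terms
    uniform. A configurable fraction of records receive E-values above the
    conventional 1e-10 cutoff so the filter has work to do."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    genes = truth.data["gene"].to_numpy()
    flagged = truth.data["rootstock_flag"].to_numpy()
    n_g = len(genes)
    records = []
    for t in range(config.n_terms):
        term = "TERM_ENRICHED" if t == 0 else f"TERM{t:03d}"
        size = max(1, int(rng.poisson(config.term_size_mean)))
        size = min(size, n_g)
        if t == 0 and config.enrich_odds != 1.0:
            w = np.where(flagged, config.enrich_odds, 1.0)
            w = w / w.sum()
            members = rng.choice(n_g, size=size, replace=False, p=w)
        else:
            members = rng.choice(n_g, size=size, replace=False)
        for gi in members:
            fails = rng.random() < config.frac_fail_evalue
            expo = rng.uniform(1.0, 9.9) if fails else rng.uniform(10.5, 30.0)
            records.append({
                "gene": genes[gi],
                "term": term,
                "source": "pfam",
                "evalue": 10.0 ** (-expo),
            })
    cols = ["gene", "term", "source", "evalue"]
    return AnnotationMap(pd.DataFrame(records, columns=cols))


# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig) -> dict:
    """Generate the complete synthetic study: design, weather, counts, truth,
    annotation. Deterministic given ``config.seed``."""
    design = simulate_design(config)
    weather = simulate_weather(config)
    counts, truth = simulate_counts(design, weather, config)
    annotation = simulate_annotation(config, truth)
    return {
        "design": design,
        "weather": weather,
        "counts": counts,
        "truth": truth,
        "annotation": annotation,
    }
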