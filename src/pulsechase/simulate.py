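"""Synthetic-data generator with known ground truth.

Every input the pipeline consumes can be generated here:

* a first-order compartment model of the pulse-chase — the source
  (leaf) excess-13C pool drains into each sink organ at a per-hour
  transfer rate and into an explicit respired pool at a respiration
  rate, integrated by forward Euler with conservation accounting;
* colorimetric and HPLC assay signals obtained by inverting the
  calibration formulas around planted "true" sugar contents;
* FPKM expression tables with genes planted at a chosen population
  correlation to the sucrose trajectory, among independent background
  genes;
* enzyme activity panels as noisy replicates around stage profiles.

All randomness descends from one integer seed; the same
:class:`SimConfig` reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from pulsechase.assays import (
    SOLUBLE_SUGAR_OFFSET,
    SOLUBLE_SUGAR_SLOPE,
    STANDARD_GRADIENT_MG_ML,
    STARCH_OFFSET,
    STARCH_SLOPE,
)
from pulsechase.isotope import (
    VPDB_RATIO,
    IsotopeConstants,
    atom_percent,
    delta_from_atom_percent,
)

__all__ = [
    "OrganSpec",
    "MonthSpec",
    "SimConfig",
    "SimTruth",
    "default_config",
    "load_config",
    "transfer_rates_for_allocation",
    "simulate_pulse_chase",
    "simulate_assays",
    "simulate_expression",
    "simulate_enzyme_panels",
    "simulate_deg_table",
    "DEFAULT_SUGAR_TRUTH",
    "DEFAULT_ENZYME_PROFILES",
    "DEFAULT_HPLC_DETECTOR",
]


@dataclass(frozen=True)
class OrganSpec:
    """Static properties of one organ's carbon pool."""

    biomass_g: float
    carbon_fraction: float
    respiration_rate_per_h: float = 0.0

    def __post_init__(self) -> None:
        if self.biomass_g <= 0:
            raise ValueError("biomass_g must be > 0")
        if not 0 <= self.carbon_fraction <= 1:
            raise ValueError("carbon_fraction must be in [0, 1]")
        if self.respiration_rate_per_h < 0:
            raise ValueError("respiration_rate_per_h must be >= 0")


@dataclass(frozen=True)
class MonthSpec:
    """Per-month kinetics: either explicit rates or an allocation target.

    Give either ``transfer_rates_per_h`` (sink organ -> per-hour rate
    out of the source pool) together with ``source_respiration_per_h``,
    or ``target_allocation_percent`` — the per-organ allocation
    percentages the noiseless model should show at the end of the chase,
    from which the rates are solved in closed form.
    """

    transfer_rates_per_h: Mapping[str, float] | None = None
    source_respiration_per_h: float | None = None
    target_allocation_percent: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        has_rates = self.transfer_rates_per_h is not None
        has_target = self.target_allocation_percent is not None
        if has_rates == has_target:
            raise ValueError(
                "give exactly one of transfer_rates_per_h and "
                "target_allocation_percent"
            )
        if has_rates and any(v < 0 for v in self.transfer_rates_per_h.values()):
            raise ValueError("transfer rates must be >= 0")


def transfer_rates_for_allocation(
    targets_percent: Mapping[str, float],
    source_organ: str,
    horizon_h: float = 72.0,
    respired_export_fraction: float = 0.2,
) -> tuple[dict[str, float], float]:
    """Solve first-order rates that hit an allocation target.

    For the linear model (source pool draining to sinks and a respired
    pool, sinks not respiring), the end-of-chase allocation over organs
    depends only on the total source outflow ``K`` and the split of that
    outflow.  Given the target per-organ percentages and the fraction
    ``rho`` of exported carbon lost to respiration, the retained source
    fraction is ``f = P_src (1 - rho) / (1 - P_src rho)``, ``K = -ln(f)
    / T``, the source respiration rate ``rho K``, and each sink rate
    ``(1 - rho) K P_j / (1 - P_src)``.

    Returns ``(sink_rates, source_respiration_rate)``.
    """
    if source_organ not in targets_percent:
        raise ValueError(f"targets must include the source organ {source_organ!r}")
    if not 0 <= respired_export_fraction < 1:
        raise ValueError("respired_export_fraction must be in [0, 1)")
    total = float(sum(targets_percent.values()))
    if total <= 0:
        raise ValueError("targets must sum to a positive value")
    P = {k: v / total for k, v in targets_percent.items()}
    P_src = P[source_organ]
    if not 0 < P_src < 1:
        raise ValueError("source allocation target must be in (0, 100) percent")
    rho = respired_export_fraction
    f = P_src * (1 - rho) / (1 - P_src * rho)
    K = -math.log(f) / horizon_h
    sink_rates = {
        organ: (1 - rho) * K * p / (1 - P_src)
        for organ, p in P.items()
        if organ != source_organ
    }
    return sink_rates, rho * K


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of the synthetic labeling study.

    Defaults emulate the field protocol: a two-hour 99 atom-percent
    13CO2 feeding treated as an instantaneous pulse that raises the leaf
    pool 0.2 atom-percent points above a natural background of
    delta-13C = -27 per mil, a 72 h chase sampled at 0/6/24/48/72 h, and
    quadruplicate assays with 2 % coefficient of variation.
    """

    organs: Mapping[str, OrganSpec]
    months: Mapping[str, MonthSpec]
    seed: int = 20210722
    rc: float = VPDB_RATIO
    source_organ: str = "leaves"
    background_delta13c: float = -27.0
    pulse_excess_atom_percent: float = 0.2
    respired_export_fraction: float = 0.2
    timepoints_h: Sequence[float] = (0.0, 6.0, 24.0, 48.0, 72.0)
    dt_h: float = 0.01
    noise_sd_delta: float = 1.0
    assay_noise_cv: float = 0.02
    n_replicates: int = 4
    n_expr_replicates: int = 3
    expression_log_sigma: float = 0.25

    def __post_init__(self) -> None:
        if self.source_organ not in self.organs:
            raise ValueError(f"source organ {self.source_organ!r} not in organs")
        tp = list(self.timepoints_h)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints_h must be strictly increasing")
        if self.dt_h <= 0:
            raise ValueError("dt_h must be > 0")
        if self.noise_sd_delta < 0 or self.assay_noise_cv < 0:
            raise ValueError("noise levels must be >= 0")

    @property
    def constants(self) -> IsotopeConstants:
        return IsotopeConstants(Rc=self.rc)

    @property
    def background_atom_percent(self) -> float:
        """Natural-abundance F_n implied by the background delta-13C."""
        return atom_percent(self.background_delta13c, self.constants)

    def resolved_rates(self, month: str) -> tuple[dict[str, float], float]:
        """Sink transfer rates and source respiration rate for a month."""
        spec = self.months[month]
        if spec.transfer_rates_per_h is not None:
            resp = spec.source_respiration_per_h
            if resp is None:
                resp = self.organs[self.source_organ].respiration_rate_per_h
            return dict(spec.transfer_rates_per_h), float(resp)
        return transfer_rates_for_allocation(
            spec.target_allocation_percent,
            self.source_organ,
            horizon_h=float(list(self.timepoints_h)[-1]),
            respired_export_fraction=self.respired_export_fraction,
        )

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the one seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


# stream ids for per-stage RNGs
_STREAM_ISOTOPE = 0
_STREAM_ASSAYS = 1
_STREAM_EXPRESSION = 2
_STREAM_ENZYMES = 3
_STREAM_DEG = 4


@dataclass
class SimTruth:
    """Ground truth recorded alongside synthetic outputs."""

    pulse_mg: dict[str, float] = field(default_factory=dict)
    isotope: pd.DataFrame | None = None  # month, organ, time_h, excess13c_mg, allocation_percent
    respired: pd.DataFrame | None = None  # month, time_h, respired_mg
    sugars: pd.DataFrame | None = None  # organ, month, contents (mg/g FW)
    enzymes: pd.DataFrame | None = None  # organ, month, enzyme means
    planted_genes: list[str] = field(default_factory=list)
    target_r: float | None = None


# ---------------------------------------------------------------------------
# pulse-chase compartment model
# ---------------------------------------------------------------------------

def simulate_pulse_chase(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate the labeling experiment for every configured month.

    The source organ starts with the pulse's excess-13C mass (its carbon
    pool times the pulse enrichment); sinks start at background.  The
    linear system is advanced by forward Euler with step ``dt_h``:
    at each step the source loses ``(sum of transfer rates +
    respiration) * E_src * dt``, each sink gains its share, and every
    organ's own respiration drains to the cumulative respired pool, so
    organs + respired equals the pulse at all times by construction.

    Returns ``(readings, pools, truth)`` in the pipeline's input
    schemas: readings have one delta-13C value (with Gaussian
    measurement noise ``noise_sd_delta``) per organ x month x timepoint;
    pools give biomass, carbon fraction and the background atom percent.
    """
    organs = list(config.organs)
    fn = config.background_atom_percent
    rng = config.rng(_STREAM_ISOTOPE)
    dt = config.dt_h
    timepoints = [float(t) for t in config.timepoints_h]
    n_steps = int(round(timepoints[-1] / dt))
    record_steps = {int(round(t / dt)): t for t in timepoints}

    reading_rows, pool_rows, truth_rows, respired_rows = [], [], [], []
    pulse_mg: dict[str, float] = {}

    ci_g = {
        o: config.organs[o].biomass_g * config.organs[o].carbon_fraction
        for o in organs
    }

    for month in config.months:
        rates, src_resp = config.resolved_rates(month)
        unknown = set(rates) - set(organs)
        if unknown:
            raise ValueError(f"month {month!r}: unknown sink organs {sorted(unknown)}")
        resp = {o: config.organs[o].respiration_rate_per_h for o in organs}
        resp[config.source_organ] = src_resp
        outflow = {o: resp[o] for o in organs}
        outflow[config.source_organ] += sum(rates.values())
        worst = max(outflow.values())
        if worst * dt > 0.1:
            raise ValueError(
                f"month {month!r}: dt_h={dt} too large for stability "
                f"(max rate {worst:.4g}/h gives rate*dt={worst * dt:.3g} > 0.1)"
            )

        src = config.source_organ
        pulse = ci_g[src] * config.pulse_excess_atom_percent / 100.0 * 1000.0  # mg
        pulse_mg[month] = pulse
        excess = {o: 0.0 for o in organs}
        excess[src] = pulse
        respired = 0.0

        def record(t: float) -> None:
            total_organs = sum(excess.values())
            for o in organs:
                truth_rows.append(
                    dict(
                        month=month,
                        organ=o,
                        time_h=t,
                        excess13c_mg=excess[o],
                        allocation_percent=(
                            excess[o] / total_organs * 100.0 if total_organs > 0 else np.nan
                        ),
                    )
                )
                ap = fn + excess[o] / (10.0 * ci_g[o])  # inverse of excess mass
                delta = delta_from_atom_percent(ap, config.constants)
                if config.noise_sd_delta > 0:
                    delta += rng.normal(0.0, config.noise_sd_delta)
                reading_rows.append(
                    dict(organ=o, month=month, time_h=t, rs=np.nan, delta13c=delta)
                )
            respired_rows.append(dict(month=month, time_h=t, respired_mg=respired))

        record(0.0)
        for step in range(1, n_steps + 1):
            exported = {sink: k * excess[src] * dt for sink, k in rates.items()}
            breathed = {o: resp[o] * excess[o] * dt for o in organs}
            excess[src] -= sum(exported.values()) + breathed[src]
            for sink, amt in exported.items():
                excess[sink] += amt
            for o in organs:
                if o != src and breathed[o]:
                    excess[o] -= breathed[o]
            respired += sum(breathed.values())
            if step in record_steps:
                record(record_steps[step])

        for o in organs:
            pool_rows.append(
                dict(
                    organ=o,
                    month=month,
                    biomass_g=config.organs[o].biomass_g,
                    carbon_fraction=config.organs[o].carbon_fraction,
                    fn_atom_percent=fn,
                )
            )

    truth = SimTruth(
        pulse_mg=pulse_mg,
        isotope=pd.DataFrame(truth_rows),
        respired=pd.DataFrame(respired_rows),
    )
    return pd.DataFrame(reading_rows), pd.DataFrame(pool_rows), truth


# ---------------------------------------------------------------------------
# assay signal generation
# ---------------------------------------------------------------------------

#: Planted "true" sugar contents (mg per g fresh weight) per organ and
#: month, emulating the seasonal pattern of an oil-fruit tree: fructose
#: dominates early, seed sucrose peaks in September during the switch to
#: oil conversion, and soluble sugars stay above starch everywhere.
DEFAULT_SUGAR_TRUTH = pd.DataFrame(
    [
        # organ, month, sucrose, glucose, fructose, soluble_sugar, starch
        ("leaves", "Jul", 6.5, 9.0, 12.5, 30.0, 14.0),
        ("leaves", "Aug", 7.2, 8.2, 11.8, 29.0, 13.0),
        ("leaves", "Sep", 8.4, 6.5, 7.2, 24.0, 11.0),
        ("leaves", "Oct", 7.0, 5.1, 5.6, 19.5, 10.0),
        ("peels", "Jul", 3.1, 7.5, 10.2, 22.8, 12.0),
        ("peels", "Aug", 4.0, 8.8, 11.5, 26.3, 13.0),
        ("peels", "Sep", 6.2, 6.0, 7.4, 21.6, 10.0),
        ("peels", "Oct", 7.8, 4.2, 5.0, 19.0, 9.0),
        ("seed_kernels", "Jul", 4.2, 6.8, 11.0, 24.0, 15.0),
        ("seed_kernels", "Aug", 9.8, 7.5, 12.4, 31.7, 20.0),
        ("seed_kernels", "Sep", 25.93, 5.2, 8.1, 41.0, 26.0),
        ("seed_kernels", "Oct", 22.5, 3.9, 5.3, 33.7, 28.0),
    ],
    columns=["organ", "month", "sucrose", "glucose", "fructose", "soluble_sugar", "starch"],
)

#: True HPLC detector response per analyte: (area per mg/ml, area offset).
DEFAULT_HPLC_DETECTOR = {
    "sucrose": (118000.0, 1500.0),
    "glucose": (131000.0, 1200.0),
    "fructose": (126000.0, 1800.0),
}

_COLORIMETRIC_FW_G = 0.1  # fresh weight per colorimetric assay
_HPLC_SAMPLE_MASS_G = 1.0
_HPLC_EXTRACT_VOLUME_ML = 10.0


def simulate_assays(
    sugar_truth: pd.DataFrame | None,
    config: SimConfig,
    detector: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate colorimetric and HPLC signals around true contents.

    Absorbances invert the kit calibrations (``A = content * W / 2.34 -
    0.07`` for soluble sugar and the starch analogue), HPLC areas invert
    the detector line around the extract concentration implied by the
    default bookkeeping (1 g tissue brought to 10 ml).  Noise is
    multiplicative with coefficient of variation ``assay_noise_cv`` on
    the signal part of every reading.

    Returns ``(colorimetric, standards, hplc_samples)`` DataFrames in
    the pipeline's input schemas.
    """
    if sugar_truth is None:
        sugar_truth = DEFAULT_SUGAR_TRUTH
    detector = dict(detector or DEFAULT_HPLC_DETECTOR)
    rng = config.rng(_STREAM_ASSAYS)
    cv = config.assay_noise_cv

    def jitter(x):
        if cv == 0:
            return np.asarray(x, dtype=float)
        x = np.asarray(x, dtype=float)
        return x * (1.0 + cv * rng.standard_normal(x.shape))

    colorimetric_rows = []
    hplc_rows = []
    for row in sugar_truth.itertuples(index=False):
        for rep in range(1, config.n_replicates + 1):
            sid = f"{row.organ}_{row.month}_r{rep}"
            a_sugar = jitter(row.soluble_sugar * _COLORIMETRIC_FW_G / SOLUBLE_SUGAR_SLOPE)
            a_starch = jitter(row.starch * _COLORIMETRIC_FW_G / STARCH_SLOPE)
            colorimetric_rows.append(
                dict(
                    sample_id=sid,
                    organ=row.organ,
                    month=row.month,
                    replicate=rep,
                    assay="soluble_sugar",
                    absorbance_620=float(a_sugar) - SOLUBLE_SUGAR_OFFSET,
                    fresh_weight_g=_COLORIMETRIC_FW_G,
                )
            )
            colorimetric_rows.append(
                dict(
                    sample_id=sid,
                    organ=row.organ,
                    month=row.month,
                    replicate=rep,
                    assay="starch",
                    absorbance_620=float(a_starch) - STARCH_OFFSET,
                    fresh_weight_g=_COLORIMETRIC_FW_G,
                )
            )
            for analyte in ("sucrose", "glucose", "fructose"):
                slope, intercept = detector[analyte]
                conc = (
                    getattr(row, analyte)
                    * _HPLC_SAMPLE_MASS_G
                    / _HPLC_EXTRACT_VOLUME_ML
                )
                area = intercept + float(jitter(slope * conc))
                hplc_rows.append(
                    dict(
                        sample_id=sid,
                        organ=row.organ,
                        month=row.month,
                        replicate=rep,
                        analyte=analyte,
                        peak_area=area,
                        extract_volume_ml=_HPLC_EXTRACT_VOLUME_ML,
                        sample_mass_g=_HPLC_SAMPLE_MASS_G,
                    )
                )

    standard_rows = []
    for analyte, (slope, intercept) in detector.items():
        for conc in STANDARD_GRADIENT_MG_ML:
            standard_rows.append(
                dict(
                    analyte=analyte,
                    concentration_mg_ml=conc,
                    peak_area=intercept + float(jitter(slope * conc)),
                )
            )

    return (
        pd.DataFrame(colorimetric_rows),
        pd.DataFrame(standard_rows),
        pd.DataFrame(hplc_rows),
    )


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimConfig,
    sucrose_series: Mapping[str, float],
    n_genes: int = 1000,
    n_planted: int = 10,
    target_r: float = 0.9,
) -> tuple[pd.DataFrame, list[str]]:
    """Expression table with genes planted to track sucrose.

    Planted genes mix the standardized sucrose trajectory with
    independent Gaussian noise at weight ``target_r`` (so the latent
    population correlation is ``target_r``); background genes are pure
    noise.  FPKM values are made non-negative with a log-normal
    transform ``exp(mu + sigma * z)`` whose small ``sigma``
    (``expression_log_sigma``) keeps the transform near-linear, so the
    observable FPKM-vs-sucrose correlation is only mildly attenuated
    below the latent target.

    Returns a long-format table ``gene_id, stage, replicate, fpkm`` and
    the list of planted gene ids.
    """
    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")
    if n_planted > n_genes:
        raise ValueError("n_planted cannot exceed n_genes")
    rng = config.rng(_STREAM_EXPRESSION)

    stages = list(sucrose_series)
    reps = config.n_expr_replicates
    s = np.repeat([float(sucrose_series[st]) for st in stages], reps)
    if np.ptp(s) == 0:
        raise ValueError("sucrose series must vary across stages")
    s_std = (s - s.mean()) / s.std()
    n_obs = s.size

    width = len(str(n_genes))
    gene_ids = [f"g{idx:0{width}d}" for idx in range(1, n_genes + 1)]
    planted = gene_ids[:n_planted]

    z = rng.standard_normal((n_genes, n_obs))
    lam = target_r
    z[:n_planted] = lam * s_std + math.sqrt(1.0 - lam**2) * z[:n_planted]
    log_mu = math.log(50.0)
    fpkm = np.exp(log_mu + config.expression_log_sigma * z)

    stage_col = np.repeat(stages, reps)
    rep_col = np.tile(np.arange(1, reps + 1), len(stages))
    frames = []
    for i, gid in enumerate(gene_ids):
        frames.append(
            pd.DataFrame(
                dict(gene_id=gid, stage=stage_col, replicate=rep_col, fpkm=fpkm[i])
            )
        )
    return pd.concat(frames, ignore_index=True), planted


# ---------------------------------------------------------------------------
# enzyme panels
# ---------------------------------------------------------------------------

#: Stage profiles of the five sucrose-metabolism enzymes (U per g) per
#: organ over Jul-Oct, emulating the seasonal shapes of the assayed
#: kits: SuSy-II peaking in September, SPS dipping then recovering,
#: invertases low and organ-specific; the neutral invertase assay is
#: absent for peels.
DEFAULT_ENZYME_PROFILES = pd.DataFrame(
    [
        ("leaves", "Jul", 1200.0, 210.0, 8.0, 5.0, 45.0),
        ("leaves", "Aug", 1500.0, 150.0, 9.0, 2.11, 50.0),
        ("leaves", "Sep", 1677.62, 71.44, 11.0, 3.0, 62.80),
        ("leaves", "Oct", 900.0, 260.0, 12.0, 6.0, 58.0),
        ("peels", "Jul", 1100.0, 200.0, 75.2, 3.0, np.nan),
        ("peels", "Aug", 1600.0, 140.0, 60.0, 4.5, np.nan),
        ("peels", "Sep", 2535.58, 74.43, 45.0, 6.0, np.nan),
        ("peels", "Oct", 1500.0, 230.0, 29.48, 7.99, np.nan),
        ("seed_kernels", "Jul", 800.0, 150.0, 20.0, 6.0, 12.0),
        ("seed_kernels", "Aug", 1400.0, 240.0, 28.0, 9.0, 8.0),
        ("seed_kernels", "Sep", 2071.62, 180.0, 34.06, 7.0, 4.81),
        ("seed_kernels", "Oct", 1900.0, 263.96, 25.0, 12.25, 39.61),
    ],
    columns=["organ", "month", "SuSy_II", "SPS", "S_AI", "B_AI", "NI"],
)


def simulate_enzyme_panels(
    config: SimConfig,
    stage_profiles: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Replicate enzyme activities around stage profile means.

    Each replicate value is ``mean * (1 + cv * eps)`` truncated at zero;
    missing assays (NaN in the profile) stay missing in every replicate.
    """
    profiles = stage_profiles if stage_profiles is not None else DEFAULT_ENZYME_PROFILES
    rng = config.rng(_STREAM_ENZYMES)
    cv = config.assay_noise_cv
    enzyme_cols = [c for c in profiles.columns if c not in ("organ", "month")]

    rows = []
    for prof in profiles.itertuples(index=False):
        for rep in range(1, config.n_replicates + 1):
            row = dict(organ=prof.organ, month=prof.month, replicate=rep)
            for enz in enzyme_cols:
                mean = getattr(prof, enz)
                if pd.isna(mean):
                    row[enz] = np.nan
                    continue
                val = mean * (1.0 + cv * rng.standard_normal()) if cv > 0 else mean
                row[enz] = max(val, 0.0)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# differential-expression tables (plumbing for the end-to-end run)
# ---------------------------------------------------------------------------

def simulate_deg_table(
    config: SimConfig,
    gene_ids: Sequence[str],
    comparisons: Sequence[str] = ("Jul_vs_Aug", "Jul_vs_Sep", "Jul_vs_Oct"),
    de_fraction: float = 0.3,
) -> pd.DataFrame:
    """Toy differential-expression table for pipeline smoke runs.

    A fraction of genes per comparison is drawn as differentially
    expressed (|log2FC| >= 1 with a small FDR); the rest get small fold
    changes and uniform FDRs.  This emulates the *shape* of an upstream
    DE table, not any DE model.
    """
    rng = config.rng(_STREAM_DEG)
    rows = []
    for comparison in comparisons:
        de_mask = rng.random(len(gene_ids)) < de_fraction
        for gid, is_de in zip(gene_ids, de_mask):
            if is_de:
                log2fc = float(rng.choice([-1.0, 1.0]) * (1.0 + rng.exponential(1.0)))
                fdr = float(rng.uniform(0.0, 0.05))
            else:
                log2fc = float(rng.normal(0.0, 0.4))
                fdr = float(rng.uniform(0.05, 1.0))
            rows.append(dict(gene_id=gid, comparison=comparison, log2fc=log2fc, fdr=fdr))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

def _config_from_dict(raw: dict) -> SimConfig:
    organs = {
        name: OrganSpec(**spec) for name, spec in raw["organs"].items()
    }
    months = {}
    for name, spec in raw["months"].items():
        months[name] = MonthSpec(
            transfer_rates_per_h=spec.get("transfer_rates_per_h"),
            source_respiration_per_h=spec.get("source_respiration_per_h"),
            target_allocation_percent=spec.get("target_allocation_percent"),
        )
    kwargs = {
        k: raw[k]
        for k in (
            "seed",
            "rc",
            "source_organ",
            "background_delta13c",
            "pulse_excess_atom_percent",
            "respired_export_fraction",
            "timepoints_h",
            "dt_h",
            "noise_sd_delta",
            "assay_noise_cv",
            "n_replicates",
            "n_expr_replicates",
            "expression_log_sigma",
        )
        if k in raw
    }
    return SimConfig(organs=organs, months=months, **kwargs)


def load_config(path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _config_from_dict(raw)


def default_config(seed: int | None = None) -> SimConfig:
    """The committed default study configuration.

    Emulates a four-month campaign whose noiseless 72 h allocation
    matches the four canonical monthly partition vectors; pass ``seed``
    to override the committed seed.
    """
    raw = yaml.safe_load(
        resources.files("pulsechase.data").joinpath("default.yaml").read_text()
    )
    cfg = _config_from_dict(raw)
    if seed is not None:
        cfg = cfg.with_(seed=int(seed))
    return cfg
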