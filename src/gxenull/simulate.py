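"""Synthetic cohort generation.

Generates cohorts with the statistical structure that GRS-by-exposure
interaction analyses assume: a polygenic score built from Hardy-Weinberg
variants, a continuous outcome (BMI, kg/m^2) linked to the score, a binary
exposure whose cases have a higher outcome mean *and* SD than controls
(sampled conditional on the outcome, as real case selection operates), an
integer severity score correlated with the outcome among cases, a treated
flag within cases, and a standard covariate block (age, sex, centre, a
deprivation index, five principal components, genotyping array).

Two noise models are provided.  ``additive_normal`` produces a homoscedastic
outcome: no interaction exists unless one is planted.  With
``multiplicative_lognormal`` the log-outcome is linear in the score, so the
raw-scale variance grows with the mean; combined with case selection on the
outcome this reproduces the heteroscedasticity artefact that motivates
negative-control experiments.

Determinism: a single integer seed; each sub-step draws from its own
deterministically derived substream, so adding or reordering downstream
draws cannot perturb upstream ones.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize
from scipy.special import expit, logit

from .errors import InvalidConfigError

__all__ = [
    "SimConfig",
    "CohortBundle",
    "simulate_variants",
    "simulate_bmi",
    "assign_exposures",
    "generate_cohort",
    "write_bundle",
    "read_weights",
    "read_dosages",
    "read_phenotypes",
]

_NOISE_MODELS = ("additive_normal", "multiplicative_lognormal")

# substream labels: (seed, code) -> independent generator
_S_VARIANTS, _S_NOISE, _S_EXPOSURE, _S_SEVERITY, _S_TREATED, _S_COVARIATES = range(6)


def _rng(config: "SimConfig", code: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), code])


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults emulate a large population study's major-depression subset:
    case prevalence ~0.24, cases 0.6 kg/m^2 heavier with an SD ratio of
    ~1.16 (27.2 (5.1) vs 26.6 (4.4) kg/m^2), ~15.5% of cases on treatment,
    and a 73-variant score with per-allele effects of ~0.02 SD.
    """

    n_individuals: int = 10_000
    n_variants: int = 73
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    weight_scale: float = 0.02       # per-allele effect, inverse-normal BMI units
    bmi_mean: float = 26.7           # kg/m^2
    bmi_sd: float = 4.6              # kg/m^2
    noise_model: str = "additive_normal"
    exposure_prevalence: float = 0.24
    exposure_bmi_shift: float = 0.6  # case minus control mean, kg/m^2
    exposure_bmi_scale: float = 1.16  # case SD / control SD
    true_interaction: float = 0.0    # per-allele x exposure coefficient, INT scale
    treated_fraction_in_cases: float = 0.155
    severity_max: int = 10
    confound_covariates: bool = False
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise InvalidConfigError(
                f"allele_freq_range must satisfy 0 < lo <= hi < 1, got ({lo}, {hi})"
            )
        if self.n_variants < 1:
            raise InvalidConfigError("n_variants must be >= 1")
        if self.n_individuals < 1:
            raise InvalidConfigError("n_individuals must be >= 1")
        for name in ("exposure_prevalence", "treated_fraction_in_cases"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.exposure_bmi_scale < 0:
            raise InvalidConfigError("exposure_bmi_scale must be >= 0")
        if self.noise_model not in _NOISE_MODELS:
            raise InvalidConfigError(
                f"unknown noise_model {self.noise_model!r}; expected one of {_NOISE_MODELS}"
            )
        if self.bmi_mean <= 0 or self.bmi_sd <= 0:
            raise InvalidConfigError("bmi_mean and bmi_sd must be positive")
        if self.severity_max < 1:
            raise InvalidConfigError("severity_max must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "allele_freq_range" in raw:
            raw["allele_freq_range"] = tuple(raw["allele_freq_range"])
        return cls(**raw)


@dataclass
class CohortBundle:
    """Weights + dosages + phenotypes for one synthetic cohort."""

    weights: pd.DataFrame
    dosages: pd.DataFrame
    phenotypes: pd.DataFrame
    config: SimConfig | None = None

    def validate(self) -> None:
        if not self.dosages.index.equals(self.phenotypes.index):
            raise InvalidConfigError("dosage and phenotype row ids differ")
        if list(self.dosages.columns) != list(self.weights["variant_id"]):
            raise InvalidConfigError("dosage columns do not match weight table")
        vals = self.dosages.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise InvalidConfigError("dosages outside [0, 2]")


def simulate_variants(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a variant weight table and a Hardy-Weinberg dosage matrix.

    Each variant gets an effect-allele frequency uniform on
    ``allele_freq_range`` and a positive per-allele weight (the weight is on
    the trait-increasing allele by construction, as published discovery
    weights are after orientation).  Dosages count effect alleles:
    Binomial(2, f) per individual.
    """
    rng = _rng(config, _S_VARIANTS)
    m, n = config.n_variants, config.n_individuals
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, size=m)
    weights = config.weight_scale * rng.uniform(0.5, 1.5, size=m)
    alleles = np.array(list("ACGT"))
    eff = rng.integers(0, 4, size=m)
    oth = (eff + rng.integers(1, 4, size=m)) % 4
    ids = [f"rs{100001 + i}" for i in range(m)]
    wtab = pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": alleles[eff],
            "other_allele": alleles[oth],
            "weight": weights,
            "eaf": freqs,
        }
    )
    dosages = pd.DataFrame(
        rng.binomial(2, freqs, size=(n, m)).astype(float),
        index=pd.Index([f"id{i + 1:06d}" for i in range(n)], name="iid"),
        columns=ids,
    )
    return wtab, dosages


def _latent_genetic(dosages: pd.DataFrame, weights: pd.DataFrame) -> np.ndarray:
    """Centred weighted allele burden on the inverse-normal (unit) scale."""
    w = weights.set_index("variant_id")["weight"].reindex(dosages.columns).to_numpy()
    g = dosages.to_numpy(float) @ w
    return g - g.mean()


def simulate_bmi(
    dosages: pd.DataFrame, weights: pd.DataFrame, config: SimConfig
) -> pd.Series:
    """Draw raw BMI (kg/m^2) from the genetic burden plus noise.

    additive_normal:
        BMI = bmi_mean + bmi_sd * (g + e),  e ~ N(0, 1 - Var(g)) so the
        marginal SD is bmi_sd and the noise is homoscedastic.
    multiplicative_lognormal:
        log BMI = mu + s * (g + e) with (mu, s) solved so the *raw* mean and
        SD match bmi_mean/bmi_sd; raw-scale variance then increases with the
        mean (the heteroscedasticity artefact generator).
    """
    if config.noise_model not in _NOISE_MODELS:  # defensive for hand-built configs
        raise InvalidConfigError(f"unknown noise_model {config.noise_model!r}")
    g = _latent_genetic(dosages, weights)
    var_g = float(np.var(g))
    if var_g >= 1.0:
        raise InvalidConfigError(
            f"genetic variance {var_g:.3f} >= 1 on the standardized scale; "
            "reduce weight_scale or n_variants"
        )
    rng = _rng(config, _S_NOISE)
    z = g + rng.normal(0.0, np.sqrt(1.0 - var_g), size=len(g))
    if config.noise_model == "additive_normal":
        bmi = config.bmi_mean + config.bmi_sd * z
    else:
        cv2 = (config.bmi_sd / config.bmi_mean) ** 2
        s = np.sqrt(np.log1p(cv2))
        mu = np.log(config.bmi_mean) - 0.5 * s**2
        bmi = np.exp(mu + s * z)
    return pd.Series(bmi, index=dosages.index, name="bmi_raw")


def _calibrate_case_probability(
    z: np.ndarray, prevalence: float, shift_z: float, sd_ratio: float
) -> np.ndarray:
    """Per-individual case probability, logistic in standardized BMI.

    p(case | z) = expit(a + b1*z + b2*(z^2 - 1)); (a, b1, b2) are solved so
    the expected prevalence, case-minus-control mean and case/control SD
    ratio hit their targets.  The quadratic term lets case selection favour
    the tails, which is what raises the case SD above the control SD.
    """
    if shift_z == 0.0 and sd_ratio == 1.0:
        return np.full(z.shape, prevalence)

    def _moments(params):
        a, b1, b2 = params
        p = expit(a + b1 * z + b2 * (z * z - 1.0))
        pv = p.mean()
        w1 = p / p.sum()
        w0 = (1.0 - p) / (1.0 - p).sum()
        m1, m0 = w1 @ z, w0 @ z
        v1 = w1 @ (z - m1) ** 2
        v0 = w0 @ (z - m0) ** 2
        return pv, m1 - m0, np.sqrt(v1 / v0)

    def _loss(params):
        pv, d, r = _moments(params)
        return (
            ((pv - prevalence) / max(prevalence, 1e-3)) ** 2
            + 4.0 * (d - shift_z) ** 2
            + 4.0 * (r - sd_ratio) ** 2
        )

    x0 = np.array([logit(np.clip(prevalence, 1e-6, 1 - 1e-6)), shift_z, 0.2 * (sd_ratio - 1.0)])
    res = minimize(_loss, x0, method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 600})
    a, b1, b2 = res.x
    return expit(a + b1 * z + b2 * (z * z - 1.0))


def assign_exposures(bmi: pd.Series, config: SimConfig) -> pd.DataFrame:
    """Sample case status, severity and treatment conditional on BMI.

    Case status is Bernoulli with a probability logistic in standardized
    BMI, calibrated so the realized case/control moments approximate
    ``exposure_bmi_shift`` and ``exposure_bmi_scale``.  Severity (cases
    only) is Binomial(severity_max, expit(0.6 z)), giving a BMI-correlated
    severity gradient.  The treated flag is Bernoulli within cases.
    """
    vals = bmi.to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise InvalidConfigError("BMI must be finite for exposure assignment")
    z = (vals - vals.mean()) / vals.std()
    shift_z = config.exposure_bmi_shift / vals.std()
    p = _calibrate_case_probability(
        z, config.exposure_prevalence, shift_z, config.exposure_bmi_scale
    )
    rng = _rng(config, _S_EXPOSURE)
    case = (rng.random(len(vals)) < p).astype(np.int8)

    sev_rng = _rng(config, _S_SEVERITY)
    severity = pd.array([pd.NA] * len(vals), dtype="Int64")
    idx_case = np.flatnonzero(case == 1)
    if idx_case.size:
        sev = sev_rng.binomial(config.severity_max, expit(0.6 * z[idx_case]))
        severity[idx_case] = sev

    trt_rng = _rng(config, _S_TREATED)
    treated = np.zeros(len(vals), dtype=np.int8)
    if idx_case.size and config.treated_fraction_in_cases > 0:
        treated[idx_case] = (
            trt_rng.random(idx_case.size) < config.treated_fraction_in_cases
        ).astype(np.int8)

    return pd.DataFrame(
        {"case": case, "severity": severity, "treated": treated}, index=bmi.index
    )


def _covariates(config: SimConfig, index: pd.Index, z_bmi: np.ndarray) -> pd.DataFrame:
    rng = _rng(config, _S_COVARIATES)
    n = len(index)
    cov = pd.DataFrame(index=index)
    cov["age"] = rng.uniform(40.0, 70.0, n)
    cov["sex"] = rng.integers(0, 2, n).astype(np.int8)
    cov["centre"] = pd.Categorical.from_codes(
        rng.integers(0, 6, n), categories=[f"C{k}" for k in range(1, 7)]
    ).astype(str)
    if config.confound_covariates:
        # deprivation correlated with BMI (r ~ 0.4) to exercise the Keller adjustment
        cov["tdi"] = 3.0 * (0.4 * z_bmi + np.sqrt(1 - 0.16) * rng.normal(size=n))
    else:
        cov["tdi"] = rng.normal(0.0, 3.0, n)
    for k in range(1, 6):
        cov[f"pc{k}"] = rng.normal(0.0, 1.0, n)
    cov["array"] = rng.integers(0, 2, n).astype(np.int8)
    return cov


def generate_cohort(config: SimConfig) -> CohortBundle:
    """Full generator: variants -> BMI -> exposures -> covariates.

    If ``true_interaction`` is non-zero, after exposures are assigned the
    outcome of cases is perturbed by gamma * (allele-count GRS, centred) on
    the latent scale, planting a genuine per-allele x exposure interaction
    while leaving group means unchanged.
    """
    weights, dosages = simulate_variants(config)
    bmi = simulate_bmi(dosages, weights, config)
    exposures = assign_exposures(bmi, config)

    if config.true_interaction != 0.0:
        from .grs import compute_weighted_grs

        grs = compute_weighted_grs(dosages, weights).scores.to_numpy()
        bump = config.true_interaction * (grs - grs.mean()) * exposures["case"].to_numpy()
        if config.noise_model == "additive_normal":
            bmi = bmi + config.bmi_sd * bump
        else:
            s = np.sqrt(np.log1p((config.bmi_sd / config.bmi_mean) ** 2))
            bmi = bmi * np.exp(s * bump)
        bmi.name = "bmi_raw"

    vals = bmi.to_numpy(float)
    z = (vals - vals.mean()) / vals.std()
    phen = pd.concat([bmi, exposures, _covariates(config, bmi.index, z)], axis=1)
    bundle = CohortBundle(weights=weights, dosages=dosages, phenotypes=phen, config=config)
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# TSV round trip


def write_bundle(bundle: CohortBundle, outdir) -> dict:
    """Write weights/dosages/phenotypes TSVs (and config YAML); returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "weights": os.path.join(outdir, "weights.tsv"),
        "dosages": os.path.join(outdir, "dosages.tsv"),
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
    }
    bundle.weights.to_csv(paths["weights"], sep="\t", index=False, float_format="%.10g")
    bundle.dosages.to_csv(paths["dosages"], sep="\t", float_format="%.10g")
    bundle.phenotypes.to_csv(paths["phenotypes"], sep="\t", float_format="%.10g")
    if bundle.config is not None:
        paths["config"] = os.path.join(outdir, "sim_config.yaml")
        bundle.config.to_yaml(paths["config"])
    return paths


def read_weights(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    required = {"variant_id", "effect_allele", "other_allele", "weight", "eaf"}
    missing = required - set(tab.columns)
    if missing:
        raise InvalidConfigError(f"weights TSV missing column(s): {sorted(missing)}")
    if tab["variant_id"].duplicated().any():
        raise InvalidConfigError("duplicate variant_id in weights TSV")
    return tab


def read_dosages(path) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    vals = mat.to_numpy(float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise InvalidConfigError("dosages outside [0, 2]")
    return mat


def read_phenotypes(path) -> pd.DataFrame:
    phen = pd.read_csv(path, sep="\t", index_col=0)
    if "bmi_raw" not in phen.columns:
        raise InvalidConfigError("phenotype TSV must contain a bmi_raw column")
    if (phen["bmi_raw"] <= 0).any():
        warnings.warn("non-positive bmi_raw values present", stacklevel=2)
    if "severity" in phen.columns:
        phen["severity"] = phen["severity"].astype("Int64")
    return phen
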