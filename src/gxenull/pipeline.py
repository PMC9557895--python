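"""End-to-end orchestration: simulate/load -> GRS -> transform -> models ->
negative controls -> report.

``run_pipeline`` produces, per exposure definition and stratum, a
stratified-association table shaped like a published interaction table
(decile contrasts in kg/m^2, per-allele beta/SE/P on the inverse-normal
scale, interaction P against the reference group, and the negative-test
count when negative controls are run), plus a per-variant interaction scan,
replicate-level negative-control TSVs with -log10(P) histogram data, and a
JSON manifest (config hash, seed, versions) from which every output is
byte-identically reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InvalidConfigError
from .grs import assign_deciles, compute_weighted_grs, recode_to_increasing_allele
from .models import ModelSpec, decile_contrast, fit_interaction_model, per_snp_interaction_scan
from .negcontrol import GroupTargets, run_negative_experiments
from .phenotypes import prepare_cohort
from .simulate import CohortBundle, SimConfig, generate_cohort, read_dosages, read_phenotypes, read_weights

__all__ = [
    "PipelineConfig",
    "ExposureDef",
    "PipelineResult",
    "run_pipeline",
    "build_analysis_cohort",
]


def build_analysis_cohort(sim: SimConfig, rescale: str = "allele_count") -> pd.DataFrame:
    """Simulate a cohort and return the analysis-ready frame.

    Convenience wrapper: generate -> recode -> GRS + deciles -> INT/severity
    preparation, yielding one DataFrame with ``grs`` and ``grs_decile``
    attached — the input shape every model fit expects.
    """
    bundle = generate_cohort(sim)
    weights, dosages = recode_to_increasing_allele(bundle.weights, bundle.dosages)
    grsvec = compute_weighted_grs(dosages, weights, rescale=rescale)
    cohort = prepare_cohort(bundle.phenotypes)
    cohort["grs"] = grsvec.scores
    cohort["grs_decile"] = assign_deciles(grsvec.scores)
    return cohort

DEFAULT_COVARIATES = (
    "age", "sex", "centre", "tdi", "pc1", "pc2", "pc3", "pc4", "pc5", "array",
)


@dataclass(frozen=True)
class ExposureDef:
    """One exposure contrast: name, binary column, optional sample restriction."""

    name: str
    column: str
    stratum: dict | None = None  # e.g. {"case": 1} for within-case contrasts


@dataclass
class PipelineConfig:
    sim: SimConfig | None = None
    weights_path: str | None = None
    dosages_path: str | None = None
    phenotypes_path: str | None = None
    exposures: tuple[ExposureDef, ...] = (
        ExposureDef("depression", "case"),
        ExposureDef("treatment_within_cases", "treated", {"case": 1}),
        ExposureDef("severity_within_cases", "severity_high", {"case": 1}),
    )
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    sex_stratified: bool = False
    keller: bool = False
    rescale: str = "allele_count"
    adjust_decile_contrasts: bool = True
    per_snp_scan: bool = True
    run_negative_controls: bool = True
    negcontrol_R: int = 1000
    negcontrol_tolerance: float = 0.05
    negcontrol_strict_R: bool = True
    negcontrol_covariates: bool = True
    seed: int = 0
    outdir: str = "gxenull_output"

    def validate(self) -> None:
        if self.sim is None and not (
            self.weights_path and self.dosages_path and self.phenotypes_path
        ):
            raise InvalidConfigError(
                "provide either a SimConfig or all three input paths"
            )
        if not self.exposures:
            raise InvalidConfigError("at least one exposure is required")

    # -- YAML round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("sim") is not None:
            sim = dict(raw["sim"])
            if "allele_freq_range" in sim:
                sim["allele_freq_range"] = tuple(sim["allele_freq_range"])
            raw["sim"] = SimConfig(**sim)
        if "exposures" in raw:
            raw["exposures"] = tuple(ExposureDef(**e) for e in raw["exposures"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)


@dataclass
class PipelineResult:
    tables: dict = field(default_factory=dict)       # name -> DataFrame
    negcontrols: dict = field(default_factory=dict)  # name -> NegativeControlSummary
    paths: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    cohort: pd.DataFrame | None = None


def _fmt_p(p: float) -> str:
    return f"{p:.3e}" if np.isfinite(p) else "NA"


def _manifest_config(config: PipelineConfig) -> dict:
    # outdir is where the manifest lives, not part of what it reproduces
    d = config.to_dict()
    d.pop("outdir", None)
    return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_manifest_config(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_bundle(config: PipelineConfig) -> CohortBundle:
    if config.sim is not None:
        return generate_cohort(config.sim)
    return CohortBundle(
        weights=read_weights(config.weights_path),
        dosages=read_dosages(config.dosages_path),
        phenotypes=read_phenotypes(config.phenotypes_path),
    )


def _strata_filters(config: PipelineConfig):
    yield "all", None
    if config.sex_stratified:
        yield "female", {"sex": 0}
        yield "male", {"sex": 1}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle to ``config.outdir``."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    bundle = _load_bundle(config)
    weights, dosages = recode_to_increasing_allele(bundle.weights, bundle.dosages)
    grsvec = compute_weighted_grs(dosages, weights, rescale=config.rescale)
    deciles = assign_deciles(grsvec.scores)

    cohort = prepare_cohort(bundle.phenotypes)
    cohort["grs"] = grsvec.scores
    cohort["grs_decile"] = deciles

    result = PipelineResult(cohort=cohort)
    log = {
        "per_variant_missingness": grsvec.missingness,
        "n_all_missing_scores": grsvec.n_all_missing,
        "decile_occupancy": {
            int(k): int(v) for k, v in deciles.value_counts().sort_index().items()
        },
        "negative_control_convergence": {},
    }

    rows = []
    for stratum_name, sex_filter in _strata_filters(config):
        for exp in config.exposures:
            if exp.column not in cohort.columns:
                continue
            stratum = dict(exp.stratum or {})
            if sex_filter:
                stratum.update(sex_filter)
            covs = tuple(c for c in config.covariates
                         if c != "sex" or not sex_filter)
            spec = ModelSpec(
                outcome="bmi_int",
                genetic="grs",
                exposure=exp.column,
                covariates=covs,
                keller=config.keller,
                stratum=stratum or None,
            )
            fit = fit_interaction_model(cohort, spec)
            contrasts = decile_contrast(
                cohort, cohort["grs_decile"].astype("float"), spec,
                adjust=config.adjust_decile_contrasts,
            )
            neg_note = "NA"
            if config.run_negative_controls:
                sub = cohort if not stratum else cohort.loc[
                    np.logical_and.reduce(
                        [cohort[c] == v for c, v in stratum.items()]
                    )
                ]
                targets = GroupTargets.from_groups(
                    sub["bmi_raw"], sub[exp.column],
                    tolerance=config.negcontrol_tolerance,
                )
                summary = run_negative_experiments(
                    cohort,
                    spec,
                    targets,
                    R=config.negcontrol_R,
                    seed=int(
                        np.random.SeedSequence(
                            [config.seed, len(result.negcontrols)]
                        ).generate_state(1)[0] % (2**31)
                    ),
                    observed_p=fit.p_int,
                    include_covariates=config.negcontrol_covariates,
                    strict_R=config.negcontrol_strict_R,
                )
                key = f"{stratum_name}_{exp.name}"
                result.negcontrols[key] = summary
                neg_note = f"{summary.count_below}/{summary.R}"
                log["negative_control_convergence"][key] = {
                    "converged": summary.R,
                    "failures": summary.failure_count,
                }
                rep_path = os.path.join(config.outdir, f"negcontrol_{key}.tsv")
                summary.to_frame().to_csv(
                    rep_path, sep="\t", index=False, float_format="%.10g"
                )
                hist = summary.histogram()
                hist_path = os.path.join(config.outdir, f"negcontrol_{key}_hist.tsv")
                pd.DataFrame(
                    {
                        "bin_left": hist["bin_edges"][:-1],
                        "bin_right": hist["bin_edges"][1:],
                        "count": hist["counts"],
                    }
                ).to_csv(hist_path, sep="\t", index=False, float_format="%.10g")
                result.paths[f"negcontrol_{key}"] = rep_path

            for level, label in ((0, "reference"), (1, "exposed")):
                s = fit.strata[level]
                rows.append(
                    {
                        "stratum": stratum_name,
                        "exposure": exp.name,
                        "group": label,
                        "n": s.n,
                        "bmi_diff_bottom_decile": (
                            "Reference" if level == 0
                            else f"{contrasts['bottom'][0]:+.2f}"
                        ),
                        "bmi_diff_top_decile": (
                            "Reference" if level == 0
                            else f"{contrasts['top'][0]:+.2f}"
                        ),
                        "per_allele_beta": f"{s.beta:.4f}",
                        "se": f"{s.se:.4f}",
                        "p_association": _fmt_p(s.p),
                        "p_interaction": "Reference" if level == 0 else _fmt_p(fit.p_int),
                        "p_interaction_raw": "" if level == 0 else repr(fit.p_int),
                        "n_negative_below_observed": "NA" if level == 0 else neg_note,
                    }
                )

    table2 = pd.DataFrame(rows)
    t2_path = os.path.join(config.outdir, "interaction_table.tsv")
    table2.to_csv(t2_path, sep="\t", index=False)
    result.tables["interaction_table"] = table2
    result.paths["interaction_table"] = t2_path

    if config.per_snp_scan:
        exp = config.exposures[0]
        spec = ModelSpec(
            outcome="bmi_int",
            genetic="_snp",
            exposure=exp.column,
            covariates=config.covariates,
            keller=config.keller,
            stratum=exp.stratum,
        )
        scan = per_snp_interaction_scan(dosages, cohort, spec)
        scan_path = os.path.join(config.outdir, "per_snp_scan.tsv")
        scan.to_csv(scan_path, sep="\t", index=False, float_format="%.6g")
        result.tables["per_snp_scan"] = scan
        result.paths["per_snp_scan"] = scan_path

    manifest = {
        "package": "gxenull",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": _manifest_config(config),
        "log": log,
    }
    man_path = os.path.join(config.outdir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    result.manifest = manifest
    result.paths["manifest"] = man_path
    return result
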