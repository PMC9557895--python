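"""Weighted genetic risk score construction.

A GRS is a weighted sum of effect-allele dosages, GRS_i = sum_n beta_n * SNP_in,
rescaled so it reads as a count of trait-increasing alleles: multiplying the
weighted sum by M / sum(beta) puts the score on [0, 2M] for M variants, with
every unit one "average-weight" allele.  Variants are first recoded so all
weights are positive (a negative discovery weight means the listed effect
allele is trait-decreasing; the orientation is flipped instead).

Deciles of the score (1 = lowest 10% genetic risk, 10 = highest) support the
decile-contrast presentation of interaction effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidConfigError, MissingWeightError

__all__ = [
    "GrsVector",
    "recode_to_increasing_allele",
    "compute_weighted_grs",
    "assign_deciles",
    "read_vcf_dosages",
]


@dataclass
class GrsVector:
    """Per-individual score (allele-count scale by default) and deciles."""

    scores: pd.Series
    deciles: pd.Series | None = None
    missingness: dict = field(default_factory=dict)
    n_all_missing: int = 0
    rescale: str = "allele_count"


def recode_to_increasing_allele(
    weights: pd.DataFrame, dosages: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flip negatively-weighted variants to their trait-increasing allele.

    For every weight row with weight < 0: negate the weight, swap the
    effect/other allele labels, complement the frequency, and replace the
    dosage column by ``2 - dosage``.  Positive rows pass through unchanged,
    so the operation is idempotent.
    """
    missing = set(dosages.columns) - set(weights["variant_id"])
    if missing:
        raise MissingWeightError(missing)
    w = weights.copy()
    d = dosages.copy()
    neg = w["weight"] < 0
    if neg.any():
        w.loc[neg, ["effect_allele", "other_allele"]] = w.loc[
            neg, ["other_allele", "effect_allele"]
        ].to_numpy()
        w.loc[neg, "eaf"] = 1.0 - w.loc[neg, "eaf"]
        w.loc[neg, "weight"] = -w.loc[neg, "weight"]
        flipped = [v for v in w.loc[neg, "variant_id"] if v in d.columns]
        d[flipped] = 2.0 - d[flipped]
    return w, d


def compute_weighted_grs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    rescale: str = "allele_count",
) -> GrsVector:
    """Weighted score per individual, rescaled to the allele-count scale.

    ``rescale="allele_count"`` (default) returns weighted_score * M / sum(beta),
    range [0, 2M]; ``"sum_beta"`` returns weighted_score / sum(beta).  The two
    differ by the constant M only, so regression P-values are identical.

    Missing dosages are mean-imputed per variant with 2*eaf (frequency from
    the weight table); per-variant missing counts are reported on the result.
    Individuals missing *every* dosage get a NaN score and are counted.
    """
    if rescale not in ("allele_count", "sum_beta"):
        raise InvalidConfigError(f"unknown rescale {rescale!r}")
    wtab = weights.set_index("variant_id")
    missing_w = set(dosages.columns) - set(wtab.index)
    if missing_w:
        raise MissingWeightError(missing_w)
    w = wtab["weight"].reindex(dosages.columns)
    if (w < 0).any():
        bad = list(w.index[w < 0])
        raise InvalidConfigError(
            f"negative weight(s) for {bad}; run recode_to_increasing_allele first"
        )
    mat = dosages.to_numpy(float)
    miss = ~np.isfinite(mat)
    missingness = {
        col: int(c) for col, c in zip(dosages.columns, miss.sum(axis=0)) if c
    }
    all_missing = miss.all(axis=1)
    n_all_missing = int(all_missing.sum())
    if n_all_missing:
        warnings.warn(
            f"{n_all_missing} individual(s) missing all dosages; score set to NaN",
            stacklevel=2,
        )
    if miss.any():
        fill = (2.0 * wtab["eaf"].reindex(dosages.columns)).to_numpy()
        mat = np.where(miss, fill[np.newaxis, :], mat)
    wv = w.to_numpy()
    weighted = mat @ wv
    if wv.sum() == 0:
        # all-zero weights: the equal-weight limit of the rescaled score is
        # the plain count of trait-increasing alleles
        if rescale != "allele_count":
            raise InvalidConfigError("sum of weights is zero; cannot divide by sum(beta)")
        warnings.warn("all weights zero; returning unweighted allele count", stacklevel=2)
        scores = mat.sum(axis=1)
    elif rescale == "allele_count":
        scores = weighted * (len(wv) / wv.sum())
    else:
        scores = weighted / wv.sum()
    scores = np.where(all_missing, np.nan, scores)
    return GrsVector(
        scores=pd.Series(scores, index=dosages.index, name="grs"),
        missingness=missingness,
        n_all_missing=n_all_missing,
        rescale=rescale,
    )


def assign_deciles(scores: pd.Series) -> pd.Series:
    """Split scores into 10 near-equal rank groups, 1 = lowest risk.

    Ties are resolved by stable rank: equal scores keep their input (id)
    order, so the assignment is deterministic across runs.  Group sizes
    differ by at most one.  NaN scores get missing deciles.
    """
    s = scores.dropna()
    n = len(s)
    if n < 10:
        raise InsufficientDataError(f"need >= 10 non-missing scores, got {n}")
    order = np.argsort(s.to_numpy(), kind="stable")
    dec = np.empty(n, dtype=np.int64)
    dec[order] = np.arange(n, dtype=np.int64) * 10 // n + 1
    out = pd.Series(pd.array([pd.NA] * len(scores), dtype="Int64"),
                    index=scores.index, name="grs_decile")
    out[s.index] = dec
    return out


def read_vcf_dosages(path, weights: pd.DataFrame) -> pd.DataFrame:
    """Read effect-allele dosages for the weight table's variants from a VCF.

    Uses the DS FORMAT field when present, otherwise counts ALT alleles from
    GT.  Orientation is checked against the weight table: if the effect
    allele is the VCF REF the dosage is flipped to 2 - ALT count; variants
    whose alleles match neither orientation are skipped with a warning.
    Requires cyvcf2 (optional dependency).
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("VCF ingestion requires the optional cyvcf2 dependency") from exc

    wtab = weights.set_index("variant_id")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for record in vcf:
        vid = record.ID
        if vid is None or vid not in wtab.index:
            continue
        if len(record.ALT) != 1:
            warnings.warn(f"{vid}: multi-allelic record skipped", stacklevel=2)
            continue
        eff = wtab.at[vid, "effect_allele"]
        oth = wtab.at[vid, "other_allele"]
        try:
            ds = np.asarray(record.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            gts = np.asarray(record.gt_types)
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            ds = np.where(gts == 2, np.nan, np.where(gts == 3, 2.0, gts.astype(float)))
        if (record.REF, record.ALT[0]) == (oth, eff):
            dosage = ds
        elif (record.REF, record.ALT[0]) == (eff, oth):
            dosage = 2.0 - ds
        else:
            warnings.warn(
                f"{vid}: VCF alleles {record.REF}/{record.ALT[0]} do not match "
                f"weight table {eff}/{oth}; skipped",
                stacklevel=2,
            )
            continue
        columns[vid] = dosage
    if not columns:
        raise InvalidConfigError("no weight-table variants found in VCF")
    return pd.DataFrame(columns, index=pd.Index(samples, name="iid"))
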