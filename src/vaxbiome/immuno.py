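"""ELISA-derived IgA quantification and association screening.

The positivity cutoff is mean(negative controls) + 3.365 x sample SD; the
multiplier is the one-sided 99% Student-t quantile at 5 degrees of freedom
(six negative controls per group), rounded to three decimals.  Endpoint
titers follow the monotone-prefix rule: the largest dilution factor whose OD
exceeds the cutoff with every smaller dilution also exceeding it.  Total IgA
is quantified against a monotone piecewise-linear standard curve in log10
concentration fitted to duplicate-averaged 1:10 serial standards.

Association screening computes Spearman's rank correlation per treatment
between features (taxa abundances, alpha diversity) and IgA variables, with
missing-IgA samples dropped first and no multiple-testing correction;
significance is flagged at p < 0.1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

__all__ = [
    "CUTOFF_MULTIPLIER",
    "positivity_cutoff",
    "endpoint_titer",
    "fit_standard_curve",
    "StandardCurve",
    "quantify_total_iga",
    "log_transform_specific",
    "spearman",
    "correlation_screen",
    "titer_table",
]

#: one-sided 99% Student-t quantile at 5 df, rounded to 3 decimals
CUTOFF_MULTIPLIER = 3.365


def positivity_cutoff(neg_ods, multiplier: float = CUTOFF_MULTIPLIER) -> float:
    """OD cutoff = mean(negatives) + multiplier x sample SD (n-1)."""
    v = np.asarray(neg_ods, dtype=float)
    if v.size < 2:
        raise DataError("need at least two negative-control ODs")
    return float(v.mean() + multiplier * v.std(ddof=1))


def endpoint_titer(series, cutoff: float) -> int:
    """Endpoint titer from a (dilution, OD) series sorted by dilution.

    Returns the largest dilution factor whose OD exceeds the cutoff with all
    smaller dilutions also exceeding it (monotone-prefix rule); 0 if the
    first dilution already fails.
    """
    pairs = list(series)
    if not pairs:
        raise DataError("empty dilution series")
    dilutions = [d for d, _ in pairs]
    if dilutions != sorted(dilutions):
        raise DataError("dilution series must be sorted ascending")
    titer = 0
    for d, od in pairs:
        if od > cutoff:
            titer = int(d)
        else:
            break
    return titer


@dataclass
class StandardCurve:
    """Monotone piecewise-linear OD vs log10(concentration) interpolant."""

    log_conc: np.ndarray  # ascending
    od: np.ndarray  # strictly increasing with concentration

    @property
    def od_range(self) -> tuple[float, float]:
        return float(self.od.min()), float(self.od.max())

    def concentration(self, od: float) -> float | None:
        """Inverse evaluation; None (flagged) outside the standards' range."""
        lo, hi = self.od_range
        if od < lo or od > hi:
            return None
        return float(10 ** np.interp(od, self.od, self.log_conc))


def fit_standard_curve(standards: pd.DataFrame) -> StandardCurve:
    """Fit the standard curve from (concentration, od) duplicate rows.

    Duplicates are averaged per concentration before fitting; the averaged
    ODs must increase strictly with concentration.
    """
    if not {"concentration", "od"} <= set(standards.columns):
        raise DataError("standards need 'concentration' and 'od' columns")
    means = standards.groupby("concentration")["od"].mean().sort_index()
    if len(means) < 3:
        raise DataError("need at least three distinct standard concentrations")
    ods = means.to_numpy()
    if not (np.diff(ods) > 0).all():
        bad = means.index[np.flatnonzero(np.diff(ods) <= 0)[0]]
        raise DataError(
            f"averaged standards are not monotone: OD does not increase above {bad} ng/mL"
        )
    return StandardCurve(log_conc=np.log10(means.index.to_numpy(dtype=float)), od=ods)


def quantify_total_iga(curve: StandardCurve, series) -> tuple[float | None, dict]:
    """Dilution-corrected concentration from a (dilution, OD) series.

    Each in-range dilution contributes curve-inverse(OD) x dilution; the
    reported value is their mean.  If every OD is out of range the value is
    None and flagged.
    """
    estimates = []
    flags = {"out_of_range": []}
    for d, od in series:
        conc = curve.concentration(od)
        if conc is None:
            flags["out_of_range"].append(int(d))
        else:
            estimates.append(conc * d)
    if not estimates:
        flags["missing"] = True
        return None, flags
    return float(np.mean(estimates)), flags


def log_transform_specific(values):
    """Zero-replacement log transform: x -> ln(max(x, 1))."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise DataError("antigen-specific IgA values must be non-negative")
    return np.log(np.maximum(v, 1.0))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with the two-sided t-approximation p-value.

    rho is the Pearson correlation of average-ranked values; p comes from
    t = rho sqrt((n-2)/(1-rho^2)) on n-2 df; |rho| = 1 gives p = 0.
    A constant input leaves rho undefined (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("need equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("inputs must be finite")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) > 1.0 - 1e-12:  # snap exact monotone orderings past rounding
        rho = math.copysign(1.0, rho)
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def correlation_screen(
    features: pd.DataFrame,
    iga: pd.DataFrame,
    samples: pd.DataFrame,
    alpha_level: float = 0.1,
) -> pd.DataFrame:
    """Per-treatment Spearman screen of features against IgA variables.

    ``features`` (samples x features) is joined to ``iga`` (samples x IgA
    variables) on sample id; each IgA variable is screened separately so
    missingness in one does not drop samples from another.  Treatments with
    fewer than three complete pairs are skipped with a warning.  Flags are
    uncorrected, at p < ``alpha_level``.
    """
    if not (0 < alpha_level < 1):
        raise ConfigError("alpha_level must lie in (0, 1)")
    if "treatment" not in samples.columns:
        raise DataError("sample table lacks a 'treatment' column")
    rows = []
    for var in iga.columns:
        values = iga[var]
        for treatment, group in samples.groupby("treatment"):
            shared = group.index.intersection(features.index).intersection(values.index)
            v = values.loc[shared].dropna()
            if len(v) < 3:
                warnings.warn(
                    f"treatment {treatment!r} has < 3 complete pairs for {var!r}; skipped"
                )
                continue
            sub = features.loc[v.index]
            for feat in features.columns:
                rho, p = spearman(sub[feat].to_numpy(), v.to_numpy())
                rows.append(
                    (feat, var, treatment, rho, p, len(v),
                     bool(p < alpha_level) if np.isfinite(p) else False)
                )
    return pd.DataFrame(
        rows,
        columns=["feature", "iga_variable", "treatment", "rho", "p", "n", "significant"],
    )


def titer_table(plate, samples_by_group: dict | None = None,
                multiplier: float = CUTOFF_MULTIPLIER) -> pd.DataFrame:
    """Quantify a whole plate: per-sample total IgA and endpoint titer.

    ``plate`` is a PlateData-like object (standards / negatives / samples).
    ``samples_by_group`` maps sample id -> negative-control group; absent
    samples use the pooled negatives.  Returns a table with the cutoff used
    and out-of-range flags.
    """
    curve = fit_standard_curve(plate.standards)
    pooled = np.concatenate([np.asarray(v) for v in plate.negatives.values()])
    rows = []
    for sid, sub in plate.samples.groupby("sample_id"):
        sub = sub.sort_values("dilution")
        series = list(zip(sub["dilution"].tolist(), sub["od"].tolist()))
        group = (samples_by_group or {}).get(sid)
        negs = plate.negatives[group] if group in (plate.negatives or {}) else pooled
        cutoff = positivity_cutoff(negs, multiplier)
        conc, flags = quantify_total_iga(curve, series)
        titer = endpoint_titer(series, cutoff)
        rows.append((sid, conc, titer, cutoff, len(flags.get("out_of_range", []))))
    return pd.DataFrame(
        rows, columns=["sample_id", "total_iga", "titer", "cutoff", "n_out_of_range"]
    ).set_index("sample_id")
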