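"""Study-shaped synthetic data with recorded ground truth.

The generator emulates the post-OTU-calling structure of a longitudinal
mouse-gut vaccine experiment: six treatment groups (negative control NG,
wild-type vector WT, and the vaccine strains MPER, IL1b, FliC, plus MPER with
a rice-bran diet, RB), six mice per group (five for RB), fecal samples at
weeks 0, 2, 4, 6, 8 and 10 (RB additionally at -1 and 12), one cecal sample
per mouse at necropsy, an average sequencing depth of 4e4 reads per sample,
mock-community control samples with ten expected members plus spurious
low-count OTUs, and IgA trajectories with treatment-specific cubic trends.

Counts are drawn from a Dirichlet-multinomial whose latent log-composition
follows a per-treatment polynomial trend plus a per-mouse intercept; group
differences in richness are induced by treatment- and week-specific presence
masks so that observed richness and Chao1 respond directly.  Every stochastic
choice is recorded in a :class:`GroundTruth` object so downstream estimators
can be scored against what was actually simulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import ConfigError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PlateData",
    "simulate_study",
    "simulate_mock_samples",
    "simulate_iga",
    "simulate_elisa_plate",
    "DEFAULT_TREATMENTS",
    "RANKS",
]

DEFAULT_TREATMENTS = ("NG", "WT", "MPER", "IL1b", "FliC", "RB")
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

# Fixed lineage vocabulary, dominated by Firmicutes and Bacteroidetes as in
# the mouse gut; sampling weights in the last field.  No claim of taxonomic
# realism beyond exercising phylum aggregation and importance tables.
_LINEAGES: tuple[tuple[str, str, str, str, str, float], ...] = (
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "unclassified", 0.16),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Lachnospiraceae_NK4A136_group", 0.07),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Tyzzerella", 0.04),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Acetatifactor", 0.03),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Marvinbryantia", 0.03),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Lachnoclostridium", 0.04),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Ruminiclostridium", 0.06),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Anaerotruncus", 0.04),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Oscillibacter", 0.05),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Ruminococcaceae_UCG-014", 0.04),
    ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiales_vadinBB60_group", "Clostridiales_vadinBB60_ge", 0.05),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", 0.04),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Lactococcus", 0.02),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidales_S24-7_group", "Bacteroidales_S24-7_group_ge", 0.18),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Alloprevotella", 0.05),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae", "Alistipes", 0.04),
    ("Actinobacteria", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium", 0.02),
    ("Tenericutes", "Mollicutes", "Anaeroplasmatales", "Anaeroplasmataceae", "Anaeroplasma", 0.02),
    ("Proteobacteria", "Deltaproteobacteria", "Desulfovibrionales", "Desulfovibrionaceae", "Desulfovibrio", 0.02),
)


def _poly(coeffs: Sequence[float], x: float) -> float:
    """Evaluate sum_k coeffs[k] * x**k (ascending order)."""
    return float(sum(c * x**k for k, c in enumerate(coeffs)))


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Week is centered and scaled to x = (week - 5) / 5 before polynomial
    trends are evaluated, so coefficient vectors are on the same scale the
    trend-fitting module uses.  Coefficients are ascending-order
    (intercept, linear, quadratic, cubic).
    """

    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    mice_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"NG": 6, "WT": 6, "MPER": 6, "IL1b": 6, "FliC": 6, "RB": 5}
    )
    weeks: tuple[int, ...] = (0, 2, 4, 6, 8, 10)
    rb_extra_weeks: tuple[int, ...] = (-1, 12)
    include_cecal: bool = True
    n_otus: int = 300
    mean_depth: float = 4e4
    depth_dispersion: float = 0.25
    baseline_sd: float = 1.2
    responder_fraction: float = 0.2
    #: per-treatment polynomial trend on latent log-abundance
    trend_coefficients: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "NG": (0.0, 0.0, 0.0, 0.0),
            "WT": (0.0, 0.6, 0.0, 0.0),
            "MPER": (0.0, 0.8, 0.4, 0.0),
            "IL1b": (0.0, 0.9, 0.4, 0.0),
            "FliC": (0.0, 0.15, 0.0, 0.0),
            "RB": (0.4, 1.2, 0.5, 0.3),
        }
    )
    #: per-treatment polynomial on the fraction of OTUs masked absent
    richness_mask_coefficients: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "NG": (0.0, 0.0, 0.0, 0.0),
            "WT": (0.05, 0.02, 0.0, 0.0),
            "MPER": (0.10, 0.05, 0.0, 0.0),
            "IL1b": (0.16, 0.05, 0.0, 0.0),
            "FliC": (0.03, 0.0, 0.0, 0.0),
            "RB": (0.30, 0.08, 0.0, 0.0),
        }
    )
    mouse_sd: float = 0.4
    overdispersion: float = 150.0
    # mock community
    n_mock_samples: int = 5
    mock_members: int = 10
    spurious_max_count: int = 25
    spurious_fraction: float = 0.15
    # IgA (no measurements for RB or cecal samples)
    iga_trend_coefficients: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "NG": (900.0, 80.0, 0.0, 0.0),
            "WT": (700.0, 250.0, -250.0, -200.0),
            "MPER": (1000.0, 150.0, 0.0, 0.0),
            "IL1b": (1100.0, 200.0, 100.0, 0.0),
            "FliC": (1150.0, 100.0, 350.0, -250.0),
        }
    )
    iga_mouse_sd: float = 120.0
    iga_noise_sd: float = 80.0
    mper_positive_treatments: tuple[str, ...] = ("MPER", "IL1b", "FliC")
    #: cubic trend of log MPER-specific IgA among positive animals
    mper_log_trend: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "MPER": (3.2, 1.2, 0.0, 0.0),
            "IL1b": (3.8, 1.5, 0.0, 0.0),
            "FliC": (3.4, 1.3, 0.0, 0.0),
        }
    )
    mper_log_sd: float = 0.5
    # ELISA plate
    n_elisa_samples: int = 16
    elisa_noise_sd: float = 0.02
    elisa_neg_mean: float = 0.06  # background slightly above the curve floor
    elisa_neg_sd: float = 0.008
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_otus <= 0 or self.mean_depth <= 0 or self.n_mock_samples <= 0:
            raise ConfigError("counts and depths must be strictly positive")
        if not self.weeks:
            raise ConfigError("weeks list must be non-empty")
        if list(self.weeks) != sorted(self.weeks):
            raise ConfigError("weeks must be sorted ascending")
        if self.depth_dispersion < 0 or self.mouse_sd < 0:
            raise ConfigError("dispersion parameters must be non-negative")
        if self.spurious_max_count < 0:
            raise ConfigError("spurious_max_count must be >= 0")
        if self.mock_members < 1 or self.mock_members > self.n_otus:
            raise ConfigError("mock_members must be in [1, n_otus]")
        lengths = {len(self.trend_coefficients[t]) for t in self.treatments}
        lengths |= {len(self.richness_mask_coefficients[t]) for t in self.treatments}
        if len(lengths) != 1:
            raise ConfigError("every treatment needs coefficient vectors of identical length")
        if next(iter(lengths)) > 4:
            raise ConfigError("trend polynomials are limited to degree 3")
        for t in self.treatments:
            if t not in self.mice_per_group or self.mice_per_group[t] <= 0:
                raise ConfigError(f"missing or non-positive mouse count for treatment {t!r}")

    def scaled_week(self, week: float) -> float:
        lo, hi = min(self.weeks), max(self.weeks)
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        return (week - mid) / half

    def otu_ids(self) -> list[str]:
        return [f"OTU{i + 1:04d}" for i in range(self.n_otus)]

    def mouse_ids(self, treatment: str) -> list[str]:
        return [f"{treatment}.M{j + 1}" for j in range(self.mice_per_group[treatment])]


@dataclass
class GroundTruth:
    """What was actually simulated, for scoring downstream estimators."""

    trend_coefficients: dict
    richness_mask_coefficients: dict
    baseline_log_abundance: pd.Series
    mouse_intercepts: dict
    expected_composition: pd.DataFrame  # samples x OTUs, rows sum to 1
    expected_richness: pd.Series  # unmasked OTUs per sample
    iga_coefficients: dict = field(default_factory=dict)
    iga_mouse_intercepts: dict = field(default_factory=dict)
    mock_spurious_otus: list = field(default_factory=list)

    def validate(self) -> None:
        sums = self.expected_composition.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("expected compositions must sum to 1")
        if self.expected_composition.index.duplicated().any():
            raise ValueError("every generated sample must appear exactly once")

    def to_json(self, path) -> None:
        doc = {
            "trend_coefficients": {k: list(v) for k, v in self.trend_coefficients.items()},
            "richness_mask_coefficients": {
                k: list(v) for k, v in self.richness_mask_coefficients.items()
            },
            "baseline_log_abundance": self.baseline_log_abundance.to_dict(),
            "mouse_intercepts": self.mouse_intercepts,
            "expected_richness": self.expected_richness.to_dict(),
            "expected_composition": {
                "samples": list(self.expected_composition.index),
                "otus": list(self.expected_composition.columns),
                "values": self.expected_composition.to_numpy().tolist(),
            },
            "iga_coefficients": {k: list(v) for k, v in self.iga_coefficients.items()},
            "iga_mouse_intercepts": self.iga_mouse_intercepts,
            "mock_spurious_otus": list(self.mock_spurious_otus),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


# ----------------------------------------------------------------------
def _sample_frame(config: SimConfig) -> pd.DataFrame:
    """Enumerate all (sample, mouse, treatment, week, type) rows."""
    rows = []
    for t in config.treatments:
        weeks = list(config.weeks)
        if t == "RB":
            weeks = sorted(set(weeks) | set(config.rb_extra_weeks))
        for mouse in config.mouse_ids(t):
            for w in weeks:
                rows.append((f"{mouse}.wk{w}", mouse, t, w, "fecal"))
            if config.include_cecal:
                w = max(weeks)
                rows.append((f"{mouse}.cecal", mouse, t, w, "cecal"))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "mouse", "treatment", "week", "sample_type"]
    ).set_index("sample_id")
    return frame


def simulate_study(config: SimConfig):
    """Simulate the full study.

    Returns ``(counts, samples, taxonomy, truth)`` where ``counts`` is an
    integer DataFrame (samples x OTUs), ``samples`` the per-sample metadata,
    ``taxonomy`` the OTU -> 6-rank lineage table and ``truth`` the recorded
    :class:`GroundTruth`.  The same seed yields byte-identical output.
    """
    config.validate()
    rng = substream(config.seed, "counts")
    otus = config.otu_ids()
    n = config.n_otus

    baseline = rng.normal(0.0, config.baseline_sd, n)
    mouse_direction = rng.normal(0.0, 1.0, n)
    loadings = {}
    mask_order = {}
    for t in config.treatments:
        rf = config.responder_fraction
        loadings[t] = rng.choice([-1.0, 0.0, 1.0], size=n, p=[rf / 2, 1 - rf, rf / 2])
        mask_order[t] = rng.permutation(n)
    mouse_intercepts = {
        m: float(rng.normal(0.0, config.mouse_sd))
        for t in config.treatments
        for m in config.mouse_ids(t)
    }

    samples = _sample_frame(config)
    expected = np.zeros((len(samples), n))
    richness = np.zeros(len(samples), dtype=int)
    counts = np.zeros((len(samples), n), dtype=np.int64)

    for i, (sid, row) in enumerate(samples.iterrows()):
        t, week = row["treatment"], row["week"]
        x = config.scaled_week(week)
        lam = (
            baseline
            + _poly(config.trend_coefficients[t], x) * loadings[t]
            + mouse_intercepts[row["mouse"]] * mouse_direction
        )
        frac = min(max(_poly(config.richness_mask_coefficients[t], x), 0.0), 0.9)
        n_masked = int(round(frac * n))
        masked = mask_order[t][:n_masked]
        p = np.exp(lam - lam.max())
        p[masked] = 0.0
        p /= p.sum()
        expected[i] = p
        richness[i] = int((p > 0).sum())

        mu = math.log(config.mean_depth) - config.depth_dispersion**2 / 2
        depth = max(1, int(round(rng.lognormal(mu, config.depth_dispersion))))
        support = np.flatnonzero(p)
        if np.isfinite(config.overdispersion):
            alpha = p[support] * config.overdispersion
            probs = rng.dirichlet(alpha)
        else:
            probs = p[support]
        counts[i, support] = rng.multinomial(depth, probs)

    count_table = pd.DataFrame(counts, index=samples.index, columns=otus)

    tax_rng = substream(config.seed, "taxonomy")
    weights = np.array([rec[5] for rec in _LINEAGES])
    weights = weights / weights.sum()
    picks = tax_rng.choice(len(_LINEAGES), size=n, p=weights)
    taxonomy = pd.DataFrame(
        [("Bacteria",) + _LINEAGES[k][:5] for k in picks],
        index=pd.Index(otus, name="otu_id"),
        columns=list(RANKS),
    )

    truth = GroundTruth(
        trend_coefficients={t: tuple(v) for t, v in config.trend_coefficients.items()},
        richness_mask_coefficients={
            t: tuple(v) for t, v in config.richness_mask_coefficients.items()
        },
        baseline_log_abundance=pd.Series(baseline, index=otus),
        mouse_intercepts=mouse_intercepts,
        expected_composition=pd.DataFrame(expected, index=samples.index, columns=otus),
        expected_richness=pd.Series(richness, index=samples.index),
        iga_coefficients={t: tuple(v) for t, v in config.iga_trend_coefficients.items()},
    )
    truth.validate()
    return count_table, samples, taxonomy, truth


def simulate_mock_samples(config: SimConfig, truth: GroundTruth | None = None):
    """Mock-community control samples.

    Expected members receive high counts; a random subset of non-member OTUs
    receives spurious counts uniform on [1, spurious_max_count].  Returns
    ``(counts, expected_member_ids)``; if ``truth`` is given the spurious OTU
    identifiers are recorded there.
    """
    config.validate()
    rng = substream(config.seed, "mock")
    otus = config.otu_ids()
    members = sorted(rng.choice(config.n_otus, size=config.mock_members, replace=False))
    member_ids = [otus[i] for i in members]
    non_members = [i for i in range(config.n_otus) if i not in set(members)]

    counts = np.zeros((config.n_mock_samples, config.n_otus), dtype=np.int64)
    spurious: set[str] = set()
    for s in range(config.n_mock_samples):
        depth = max(1, int(rng.normal(config.mean_depth, config.mean_depth * 0.05)))
        probs = rng.dirichlet(np.full(config.mock_members, 50.0))
        counts[s, members] = rng.multinomial(depth, probs)
        if config.spurious_max_count > 0 and non_members:
            k = max(1, int(round(config.spurious_fraction * len(non_members))))
            hit = rng.choice(len(non_members), size=k, replace=False)
            for j in hit:
                counts[s, non_members[j]] = rng.integers(1, config.spurious_max_count + 1)
                spurious.add(otus[non_members[j]])
    table = pd.DataFrame(
        counts,
        index=[f"mock{s + 1}" for s in range(config.n_mock_samples)],
        columns=otus,
    )
    if truth is not None:
        truth.mock_spurious_otus = sorted(spurious)
    return table, member_ids


def simulate_iga(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Per-sample total and MPER-specific IgA.

    Total IgA follows a per-treatment cubic polynomial in scaled week plus a
    per-mouse intercept and Gaussian noise, floored at zero.  MPER-specific
    IgA is identically zero for groups without the MPER epitope (NG, WT) and
    zero-inflated log-normal for MPER-bearing groups.  Cecal samples and the
    RB group carry no IgA values and are absent from the returned table.
    """
    config.validate()
    rng = substream(config.seed, "iga")
    frame = _sample_frame(config)
    frame = frame[(frame["sample_type"] == "fecal") & (frame["treatment"] != "RB")]

    mouse_iga = {}
    for t in config.treatments:
        if t == "RB":
            continue
        for m in config.mouse_ids(t):
            mouse_iga[m] = float(rng.normal(0.0, config.iga_mouse_sd))
    truth.iga_mouse_intercepts = mouse_iga
    truth.iga_coefficients = {t: tuple(v) for t, v in config.iga_trend_coefficients.items()}

    rows = []
    for sid, row in frame.iterrows():
        t, week, mouse = row["treatment"], row["week"], row["mouse"]
        x = config.scaled_week(week)
        total = _poly(config.iga_trend_coefficients[t], x) + mouse_iga[mouse]
        if config.iga_noise_sd > 0:
            total += rng.normal(0.0, config.iga_noise_sd)
        total = max(total, 0.0)
        if t in config.mper_positive_treatments:
            p_pos = min(0.95, 0.15 + 0.6 * max(week, 0) / max(config.weeks))
            if rng.random() < p_pos:
                mper = float(
                    np.exp(_poly(config.mper_log_trend[t], x) + rng.normal(0.0, config.mper_log_sd))
                )
            else:
                mper = 0.0
        else:
            mper = 0.0
        rows.append((sid, mouse, t, week, total, mper))
    return pd.DataFrame(
        rows, columns=["sample_id", "mouse", "treatment", "week", "total_iga", "mper_iga"]
    ).set_index("sample_id")


# ----------------------------------------------------------------------
@dataclass
class PlateData:
    """One synthetic ELISA plate with known truth.

    Standards are 1:10 serial dilutions from 1000 ng/mL in duplicate; sample
    series run over the two-fold dilutions 1:10 .. 1:640.  The OD response is
    linear in log10 concentration between ``od_range`` over the standards'
    concentration span (clamped outside it), which keeps the true inverse
    exactly recoverable by a monotone piecewise-linear standard curve.
    """

    standards: pd.DataFrame  # columns: concentration, od (two rows per level)
    negatives: dict  # group -> array of 6 ODs
    samples: pd.DataFrame  # columns: sample_id, dilution, od
    true_concentration: dict
    true_titer: dict
    od_range: tuple[float, float] = (0.05, 2.0)
    conc_range: tuple[float, float] = (0.1, 1000.0)

    def curve_od(self, conc: float) -> float:
        lo, hi = self.conc_range
        c = min(max(conc, lo), hi)
        f = (math.log10(c) - math.log10(lo)) / (math.log10(hi) - math.log10(lo))
        return self.od_range[0] + f * (self.od_range[1] - self.od_range[0])


DILUTIONS = (10, 20, 40, 80, 160, 320, 640)
TITER_LEVELS = (0, 10, 20, 40, 80, 160, 320, 640)


def simulate_elisa_plate(config: SimConfig) -> PlateData:
    """Simulate one ELISA plate (standards, negatives, sample series)."""
    config.validate()
    rng = substream(config.seed, "elisa")
    plate = PlateData(
        standards=pd.DataFrame(),
        negatives={},
        samples=pd.DataFrame(),
        true_concentration={},
        true_titer={},
    )
    noise = config.elisa_noise_sd

    std_rows = []
    for k in range(5):  # 1000, 100, 10, 1, 0.1 ng/mL
        conc = 1000.0 / 10**k
        for _ in range(2):
            od = plate.curve_od(conc) + (rng.normal(0.0, noise) if noise > 0 else 0.0)
            std_rows.append((conc, max(od, 0.0)))
    plate.standards = pd.DataFrame(std_rows, columns=["concentration", "od"])

    for t in config.treatments:
        base = np.full(6, config.elisa_neg_mean)
        if noise > 0:
            base = base + rng.normal(0.0, config.elisa_neg_sd, 6)
        plate.negatives[t] = np.clip(base, 0.0, None)

    sample_rows = []
    half = config.n_elisa_samples // 2
    for s in range(config.n_elisa_samples):
        sid = f"es{s + 1:02d}"
        if s < half:  # quantification sample with known total concentration
            # kept within the standard curve's span across the 1:10..1:640 series
            conc = float(10 ** rng.uniform(2.5, 3.95))  # ng/mL before dilution
            plate.true_concentration[sid] = conc
            plate.true_titer[sid] = None
            for d in DILUTIONS:
                od = plate.curve_od(conc / d) + (rng.normal(0.0, noise) if noise > 0 else 0.0)
                sample_rows.append((sid, d, max(od, 0.0)))
        else:  # titer sample constructed to a known endpoint
            titer = int(rng.choice(TITER_LEVELS))
            plate.true_titer[sid] = titer
            if titer == 0:
                conc = plate.conc_range[0] * DILUTIONS[0] / 4.0
            else:
                # midway in log2 between passing at `titer` and failing at 2x
                conc = plate.conc_range[0] * titer * math.sqrt(2.0)
            plate.true_concentration[sid] = conc
            for d in DILUTIONS:
                od = plate.curve_od(conc / d) + (rng.normal(0.0, noise) if noise > 0 else 0.0)
                sample_rows.append((sid, d, max(od, 0.0)))
    plate.samples = pd.DataFrame(sample_rows, columns=["sample_id", "dilution", "od"])
    return plate
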