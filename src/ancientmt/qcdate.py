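"""Preservation QC and simple molecular dating.

qPCR standard-curve quantification (is there enough endogenous template
for a reliable consensus?), amino-acid racemization screening, radiocarbon
date averaging, clock-rate calibration against an assumed divergence time,
the pairwise rho TMRCA estimator, and theta -> Ne conversion for a
maternally inherited, effectively haploid locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

RACEMIZATION_CAVEAT = (
    "Amino-acid racemization is an indirect proxy for biomolecular "
    "preservation; its utility as a DNA-survival predictor is debated, so "
    "treat this screen as supporting evidence, not proof."
)

DEFAULT_DL_THRESHOLDS = {"aspartic_acid": 0.10, "alanine": 0.10, "glutamine": 0.10}


@dataclass
class StandardCurve:
    slope: float  # Ct per log10(copies); negative for a valid series
    y_intercept: float  # Ct at 1 copy
    r_squared: float
    efficiency: float  # 10^(-1/slope) - 1
    warning: Optional[str] = None


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Ct on log10(copies) over a dilution series."""
    if len(points) < 3:
        raise ValueError("need at least 3 dilution points")
    x = np.log10([c for c, _ in points])
    y = np.array([ct for _, ct in points])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10(copies)")
    fit = stats.linregress(x, y)
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    warning = None
    if fit.slope >= 0:
        warning = "non-negative slope: not a valid dilution series"
    elif not 0.0 < efficiency <= 1.2:
        warning = f"amplification efficiency {efficiency:.2f} outside (0, 1.2]"
    return StandardCurve(
        slope=float(fit.slope),
        y_intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=float(efficiency),
        warning=warning,
    )


def quantify(ct: float, curve: StandardCurve) -> float:
    """Copies per reaction from a Ct value: 10^((ct - intercept)/slope)."""
    if curve.slope >= 0:
        raise ValueError("standard curve slope must be negative")
    return 10.0 ** ((ct - curve.y_intercept) / curve.slope)


def quantify_replicates(cts: Sequence[float], curve: StandardCurve) -> tuple[float, float]:
    """Mean and sd of copy number across replicate Ct measurements."""
    if not cts:
        raise ValueError("no replicate Ct values")
    copies = [quantify(ct, curve) for ct in cts]
    mean = float(np.mean(copies))
    sd = float(np.std(copies, ddof=1)) if len(copies) > 1 else 0.0
    return mean, sd


@dataclass
class PreservationReport:
    dl_ratios: dict[str, float]
    thresholds: dict[str, float]
    acid_pass: dict[str, bool]
    racemization_pass: bool
    copies_per_reaction: Optional[float] = None
    copies_sd: Optional[float] = None
    copy_threshold: float = 5000.0
    caveat: str = RACEMIZATION_CAVEAT

    @property
    def overall_pass(self) -> bool:
        copies_ok = (self.copies_per_reaction is None
                     or self.copies_per_reaction > self.copy_threshold)
        return self.racemization_pass and copies_ok


def racemization_check(
    dl: dict[str, float],
    thresholds: Optional[dict[str, float]] = None,
) -> PreservationReport:
    """Per-amino-acid D/L screen against preservation thresholds."""
    thr = dict(DEFAULT_DL_THRESHOLDS if thresholds is None else thresholds)
    unknown = set(dl) - set(thr)
    if unknown:
        raise ValueError(f"unknown amino acid keys: {sorted(unknown)}")
    for acid, v in dl.items():
        if not 0.0 <= v <= 1.5:
            raise ValueError(f"D/L value for {acid} outside [0, 1.5]: {v}")
    acid_pass = {acid: dl[acid] < thr[acid] for acid in dl}
    return PreservationReport(
        dl_ratios=dict(dl),
        thresholds=thr,
        acid_pass=acid_pass,
        racemization_pass=all(acid_pass.values()) if acid_pass else False,
    )


@dataclass
class DatedSample:
    label: str
    age: float  # years BP
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be > 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def average_dates(samples: Sequence[DatedSample], weighted: bool = False) -> DatedSample:
    """Combine replicate radiocarbon dates.

    Unweighted arithmetic mean by default; inverse-variance weighting
    optional. The combined sd assumes independent determinations.
    """
    if not samples:
        raise ValueError("no dates to average")
    if len(samples) == 1:
        return samples[0]
    ages = np.array([s.age for s in samples], dtype=float)
    sds = np.array([s.sd for s in samples], dtype=float)
    if weighted:
        if np.any(sds <= 0):
            raise ValueError("weighted average needs positive sds")
        w = 1.0 / sds**2
        age = float(np.sum(w * ages) / np.sum(w))
        sd = float(math.sqrt(1.0 / np.sum(w)))
    else:
        age = float(ages.mean())
        sd = float(math.sqrt(np.sum(sds**2)) / len(samples))
    label = "+".join(s.label for s in samples)
    return DatedSample(label=label, age=age, sd=sd)


@dataclass
class CalibratedRates:
    calibration_time: float  # years of assumed divergence
    rate: float  # substitutions / site / year

    def __post_init__(self) -> None:
        if self.calibration_time <= 0 or self.rate <= 0:
            raise ValueError("calibration time and rate must be > 0")


def calibrate_rate(base: CalibratedRates, new_time: float) -> CalibratedRates:
    """Rescale a clock rate to a different assumed divergence time.

    The substitution count along the calibration branch is fixed, so
    rate x time is conserved: halving the assumed age doubles the rate.
    """
    if new_time <= 0:
        raise ValueError("new_time must be > 0")
    return CalibratedRates(
        calibration_time=new_time,
        rate=base.rate * base.calibration_time / new_time,
    )


@dataclass
class RhoEstimate:
    rho: float  # mean substitutions from the ancestral haplotype
    sigma: float  # sd of rho (per-branch count variance / n^2)
    age: float  # years (or generations, in the units of the rate)
    age_lower: float
    age_upper: float
    n_sequences: int


def rho_tmrca(
    seqs: dict[str, str],
    ancestral: str,
    rate: CalibratedRates,
    seq_len: Optional[int] = None,
) -> RhoEstimate:
    """Pairwise rho estimator of the age of a sequence cluster.

    rho is the mean number of substitutions separating each sequence from
    the (assumed) ancestral haplotype; dividing by rate x sequence length
    converts it to an age. The variance is the standard star-genealogy
    form sum(counts) / n^2, giving a +/-1.96 sigma interval. Sites with N
    or gaps in either sequence are skipped.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    counts = []
    for name, s in seqs.items():
        if len(s) != len(ancestral):
            raise ValueError(f"sequence {name} not aligned to ancestral")
        counts.append(sum(
            1 for a, b in zip(ancestral, s)
            if a in "ACGT" and b in "ACGT" and a != b
        ))
    n = len(counts)
    rho = float(np.mean(counts))
    sigma = float(math.sqrt(sum(counts)) / n)
    L = seq_len if seq_len is not None else len(ancestral)
    denom = rate.rate * L
    return RhoEstimate(
        rho=rho,
        sigma=sigma,
        age=rho / denom,
        age_lower=max(0.0, (rho - 1.96 * sigma) / denom),
        age_upper=(rho + 1.96 * sigma) / denom,
        n_sequences=n,
    )


def theta_to_ne(
    theta_per_site: float,
    rate: CalibratedRates,
    generation_time: float = 7.0,
) -> float:
    """Female effective population size from per-site diversity.

    For a haploid, maternally inherited locus theta = 2 Ne mu per
    generation, so Ne = theta / (2 x rate_per_year x generation_time).
    """
    if theta_per_site <= 0 or generation_time <= 0:
        raise ValueError("theta and generation time must be > 0")
    return theta_per_site / (2.0 * rate.rate * generation_time)
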