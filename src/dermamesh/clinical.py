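"""PASI scoring and treatment-efficacy statistics for psoriasis trials.

The Psoriasis Area and Severity Index (PASI) combines, for each of four
body regions (head ``h``, upper limbs ``u``, trunk ``t``, lower limbs
``l``), three 0-4 severity sub-scores — erythema E, infiltration I,
desquamation D — with a 0-6 lesion-area score P and the regional surface
weights 0.1 / 0.2 / 0.3 / 0.4:

    PASI = sum_r (E_r + I_r + D_r) * P_r * w_r,   range 0..72.

Treatment response is measured by the absolute reduction
``dPASI = PASI_before - PASI_after`` and the relative reduction
``dPASI% = 100 * dPASI / PASI_before``, which maps onto four efficacy
categories (cured / markedly effective / effective / ineffective) at the
conventional 90 / 60 / 30 percent regression cut-offs.  The total
effective rate of a treatment arm is the share of patients in the top
three categories.  Group comparisons use a Welch t test on summary
statistics and a Pearson chi-square test on category counts.

Itching is scored on the four-level 0 / 2 / 4 / 6 scale (none / mild /
paroxysmal medication-requiring / severe).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

REGIONS = ("h", "u", "t", "l")
REGION_NAMES = {"h": "head", "u": "upper limbs", "t": "trunk", "l": "lower limbs"}
REGION_WEIGHTS = {"h": 0.1, "u": 0.2, "t": 0.3, "l": 0.4}

CATEGORIES = ("cured", "markedly_effective", "effective", "ineffective")

#: four-level itching scale
ITCHING_SCALE = {
    0: "no itching",
    2: "mild, does not affect normal life",
    4: "paroxysmal, requires medication, some impact on life",
    6: "severe, life seriously affected",
}


class ClinicalError(ValueError):
    """Invalid clinical score or table."""


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching printed clinical reporting."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# scores


@dataclass(frozen=True)
class RegionAssessment:
    """One region's severity sub-scores (0-4 each) and area score (0-6)."""

    region: str
    erythema: int
    infiltration: int
    desquamation: int
    area: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ClinicalError(f"region must be one of {REGIONS}, got {self.region!r}")
        for name in ("erythema", "infiltration", "desquamation"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 4):
                raise ClinicalError(f"{name} must be an integer in [0, 4], got {v!r}")
        if not (isinstance(self.area, (int, np.integer)) and 0 <= self.area <= 6):
            raise ClinicalError(f"area score must be an integer in [0, 6], got {self.area!r}")

    @property
    def severity_sum(self) -> int:
        return self.erythema + self.infiltration + self.desquamation


#: lesion-area percentage bins -> area score P (upper bounds, score)
AREA_BINS = ((0.0, 0), (10.0, 1), (30.0, 2), (50.0, 3), (70.0, 4), (90.0, 5), (100.0, 6))


def area_score(lesion_area_percent: float, bins=AREA_BINS) -> int:
    """Map percent body-region area involved to the 0-6 area score.

    0% scores 0; (0, 10)% scores 1; then [10,30) -> 2, [30,50) -> 3,
    [50,70) -> 4, [70,90) -> 5, [90,100] -> 6.
    """
    p = float(lesion_area_percent)
    if not 0.0 <= p <= 100.0:
        raise ClinicalError(f"lesion area percent must be in [0, 100], got {p}")
    if p == 0.0:
        return bins[0][1]
    for upper, score in bins[1:-1]:
        if p < upper:
            return score
    return bins[-1][1]


def pasi_score(assessments) -> float:
    """Weighted PASI over exactly the four body regions.

    ``assessments`` is an iterable of :class:`RegionAssessment`, one per
    region (or a mapping region -> assessment).
    """
    if isinstance(assessments, dict):
        assessments = assessments.values()
    by_region: dict[str, RegionAssessment] = {}
    for a in assessments:
        if a.region in by_region:
            raise ClinicalError(f"duplicate assessment for region {a.region!r}")
        by_region[a.region] = a
    missing = [r for r in REGIONS if r not in by_region]
    if missing:
        raise ClinicalError(f"missing assessments for regions {missing}")
    return float(sum(
        by_region[r].severity_sum * by_region[r].area * REGION_WEIGHTS[r] for r in REGIONS
    ))


@dataclass(frozen=True)
class PasiPair:
    """PASI before and after treatment, each in [0, 72]."""

    before: float
    after: float

    def __post_init__(self) -> None:
        for name, v in (("before", self.before), ("after", self.after)):
            if not 0.0 <= v <= 72.0:
                raise ClinicalError(f"PASI {name} must lie in [0, 72], got {v}")


def delta_pasi(pair: PasiPair) -> float:
    """Absolute PASI reduction, before minus after (negative on worsening)."""
    return pair.before - pair.after


def delta_pasi_percent(pair: PasiPair) -> float:
    """Relative PASI reduction as a percentage of the pre-treatment score."""
    if pair.before == 0:
        raise ClinicalError("dPASI% undefined: PASI before treatment is 0")
    return 100.0 * (pair.before - pair.after) / pair.before


def itching_score(value: int) -> int:
    """Validate membership in the 0/2/4/6 itching scale."""
    if value not in ITCHING_SCALE:
        raise ClinicalError(f"itching score must be one of {sorted(ITCHING_SCALE)}, got {value!r}")
    return int(value)


# ---------------------------------------------------------------------------
# efficacy


@dataclass(frozen=True)
class EfficacyThresholds:
    """Percent-regression cut-offs, strictly decreasing; closed below.

    pct >= cured is "cured"; markedly <= pct < cured is "markedly
    effective"; effective <= pct < markedly is "effective"; below is
    "ineffective".
    """

    cured: float = 90.0
    markedly_effective: float = 60.0
    effective: float = 30.0

    def __post_init__(self) -> None:
        if not self.cured > self.markedly_effective > self.effective:
            raise ClinicalError(
                f"thresholds must be strictly decreasing, got "
                f"{(self.cured, self.markedly_effective, self.effective)}"
            )


def efficacy_category(delta_pasi_pct: float, thresholds: EfficacyThresholds = EfficacyThresholds()) -> str:
    """Classify a relative PASI reduction into the four efficacy categories."""
    if delta_pasi_pct >= thresholds.cured:
        return "cured"
    if delta_pasi_pct >= thresholds.markedly_effective:
        return "markedly_effective"
    if delta_pasi_pct >= thresholds.effective:
        return "effective"
    return "ineffective"


@dataclass(frozen=True)
class GroupOutcome:
    """Per-arm counts of the four efficacy categories."""

    cured: int
    markedly_effective: int
    effective: int
    ineffective: int

    def __post_init__(self) -> None:
        for name in CATEGORIES:
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ClinicalError(f"count {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ClinicalError("group outcome must contain at least one patient")

    @property
    def n(self) -> int:
        return self.cured + self.markedly_effective + self.effective + self.ineffective

    def counts(self) -> tuple[int, int, int, int]:
        return (self.cured, self.markedly_effective, self.effective, self.ineffective)


def total_effective_rate(outcome: GroupOutcome) -> float:
    """Percent of the arm in the top three categories (cured + markedly + effective)."""
    return 100.0 * (outcome.cured + outcome.markedly_effective + outcome.effective) / outcome.n


def proportion_percent(part: int, whole: int) -> float:
    """Plain share of a subgroup, as a percentage."""
    if whole <= 0:
        raise ClinicalError("whole must be positive")
    if not 0 <= part <= whole:
        raise ClinicalError(f"part {part} out of range for whole {whole}")
    return 100.0 * part / whole


# ---------------------------------------------------------------------------
# group statistics


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    equal_var: bool = False,
) -> TTestResult:
    """Two-sample t test from summary statistics.

    Default is the Welch unequal-variance test with Welch-Satterthwaite
    degrees of freedom; ``equal_var=True`` gives the pooled-variance
    Student test.  Two-sided p-value.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ClinicalError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ClinicalError("each group needs n >= 2")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if equal_var:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    else:
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(statistic=float(t), df=float(df), pvalue=float(p))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float


def chi_square_2xk(table) -> ChiSquareResult:
    """Pearson chi-square on a 2 x k contingency table, no continuity correction.

    df = k - 1 for two rows.  Raises when a marginal is zero (an expected
    count would be zero).
    """
    counts = np.asarray(table, dtype=np.float64)
    if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
        raise ClinicalError(f"expected a 2 x k table with k >= 2, got shape {counts.shape}")
    if (counts < 0).any():
        raise ClinicalError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ClinicalError("zero marginal: chi-square expected counts undefined")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(statistic=float(chi2), df=int(df), pvalue=float(p))


# ---------------------------------------------------------------------------
# delimited-text input

ASSESSMENT_COLUMNS = ["patient_id", "region", "E", "I", "D", "P", "timepoint"]
OUTCOME_COLUMNS = ["arm", "cured", "markedly_effective", "effective", "ineffective"]


def load_assessments(path: str | Path) -> pd.DataFrame:
    """Read the per-patient assessment CSV (columns: patient_id, region,
    E, I, D, P, timepoint)."""
    df = pd.read_csv(path)
    missing = [c for c in ASSESSMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ClinicalError(f"assessment CSV missing columns {missing}")
    return df


def pasi_table(assessments: pd.DataFrame) -> pd.DataFrame:
    """Per patient and timepoint, the PASI score computed from region rows."""
    rows = []
    for (patient, timepoint), group in assessments.groupby(["patient_id", "timepoint"]):
        regional = [
            RegionAssessment(
                region=str(r.region),
                erythema=int(r.E),
                infiltration=int(r.I),
                desquamation=int(r.D),
                area=int(r.P),
            )
            for r in group.itertuples()
        ]
        rows.append({"patient_id": patient, "timepoint": timepoint, "pasi": pasi_score(regional)})
    return pd.DataFrame(rows)


def pasi_outcomes(
    assessments: pd.DataFrame,
    before: str = "before",
    after: str = "after",
    thresholds: EfficacyThresholds = EfficacyThresholds(),
) -> pd.DataFrame:
    """Per patient: PASI before/after, dPASI, dPASI% and efficacy category."""
    table = pasi_table(assessments).pivot(index="patient_id", columns="timepoint", values="pasi")
    for tp in (before, after):
        if tp not in table.columns:
            raise ClinicalError(f"timepoint {tp!r} absent from assessments")
    out = pd.DataFrame(index=table.index)
    out["pasi_before"] = table[before]
    out["pasi_after"] = table[after]
    pairs = [PasiPair(b, a) for b, a in zip(out.pasi_before, out.pasi_after)]
    out["delta_pasi"] = [delta_pasi(p) for p in pairs]
    out["delta_pasi_percent"] = [delta_pasi_percent(p) for p in pairs]
    out["category"] = [efficacy_category(pct, thresholds) for pct in out.delta_pasi_percent]
    return out.reset_index()


def load_outcomes(path: str | Path) -> dict[str, GroupOutcome]:
    """Read the per-arm outcome CSV (columns: arm, cured, markedly_effective,
    effective, ineffective)."""
    df = pd.read_csv(path)
    missing = [c for c in OUTCOME_COLUMNS if c not in df.columns]
    if missing:
        raise ClinicalError(f"outcome CSV missing columns {missing}")
    return {
        str(r.arm): GroupOutcome(
            cured=int(r.cured),
            markedly_effective=int(r.markedly_effective),
            effective=int(r.effective),
            ineffective=int(r.ineffective),
        )
        for r in df.itertuples()
    }
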