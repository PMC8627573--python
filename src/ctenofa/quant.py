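"""GC-MS relative quantitation from external standards.

Calibration: each standard compound is injected at several inlet split
ratios; the slope of integrated signal against the on-column fraction
(regression through the origin) is its mass ionization coefficient, and
dividing by molar mass gives the molar ionization coefficient.  Sample peak
integrals divided by molar coefficients give relative mole amounts, closed
to mole fractions.

Quantitation-ion selection: integration uses a compound's base peak unless
it coelutes with another compound, in which case the most intense ion that
is at least tenfold more abundant in the target spectrum than in every
coeluting spectrum is used instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .lipids import CompositionProfile
from .stats import holm_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "StandardSeries",
    "IonizationCoefficients",
    "MassSpectrum",
    "PeakObservation",
    "UnresolvableCoelutionError",
    "on_column_fraction",
    "fit_standard_curve",
    "select_quant_ion",
    "integrate_peak",
    "compute_mole_fractions",
    "detect_significant_species",
]


class UnresolvableCoelutionError(ValueError):
    """No quantitation ion separates a compound from its coeluters."""


@dataclass(frozen=True)
class StandardSeries:
    """Calibration series for one compound: (split setting, integral) pairs."""

    compound: str
    molar_mass: float
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar mass must be positive for {self.compound}")
        splits = {s for s, _ in self.points}
        if len(splits) < 2:
            raise ValueError(
                f"standard series for {self.compound} needs >=2 distinct "
                "split settings to define a slope"
            )
        if any(s <= 0 for s in splits):
            raise ValueError("split settings must be positive")


@dataclass(frozen=True)
class IonizationCoefficients:
    """Instrument response per unit (split-normalized) mass and per mole."""

    compound: str
    mass_coefficient: float
    molar_coefficient: float
    valid: bool = True


@dataclass(frozen=True)
class MassSpectrum:
    """Reference spectrum: integer m/z -> relative intensity in [0, 1]."""

    compound: str
    intensities: Mapping[int, float]

    def __post_init__(self) -> None:
        if not self.intensities:
            raise ValueError(f"empty spectrum for {self.compound}")
        peak = max(self.intensities.values())
        if not math.isclose(peak, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"spectrum for {self.compound} must be normalized to its "
                f"base peak (max intensity {peak})"
            )
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError("negative spectral intensity")

    @property
    def base_peak(self) -> int:
        """Most intense ion; ties broken toward lower m/z."""
        best = max(self.intensities.values())
        return min(m for m, v in self.intensities.items() if v == best)

    def intensity(self, mz: int) -> float:
        return self.intensities.get(mz, 0.0)


@dataclass(frozen=True)
class PeakObservation:
    """One integrated single-ion peak in one sample."""

    sample_id: str
    compound: str
    quant_mz: int
    integral: float

    def __post_init__(self) -> None:
        if self.integral < 0:
            raise ValueError("peak integral must be >= 0")


def on_column_fraction(split_ratio: float) -> float:
    """Fraction of the injected sample reaching the column at a split ratio.

    A split ratio r vents r parts per 1 part on-column, so the fraction is
    1/(1 + r); it tends to 0 as the split opens and signal must vanish with
    it, which is why the calibration line is forced through the origin.
    """
    if split_ratio <= 0:
        raise ValueError("split ratio must be positive")
    return 1.0 / (1.0 + split_ratio)


def fit_standard_curve(series: StandardSeries) -> IonizationCoefficients:
    """Least-squares slope of integral vs on-column fraction through 0.

    The slope is the mass ionization coefficient; dividing by molar mass
    gives the molar ionization coefficient.  A series that is all zeros
    fits slope 0 and is flagged invalid.
    """
    x = np.array([on_column_fraction(s) for s, _ in series.points])
    y = np.array([a for _, a in series.points])
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError(f"degenerate split settings for {series.compound}")
    mass_coef = float(x @ y) / sxx
    return IonizationCoefficients(
        compound=series.compound,
        mass_coefficient=mass_coef,
        molar_coefficient=mass_coef / series.molar_mass,
        valid=mass_coef > 0,
    )


def select_quant_ion(
    target: MassSpectrum,
    coeluters: Sequence[MassSpectrum] = (),
    thres_ortho: float = 0.9,
    rule: str = "tenfold",
) -> int:
    """Choose the quantitation ion for a (possibly coeluting) compound.

    With no coeluters, the base peak is used.  Otherwise the most intense
    target ion orthogonal to every coeluting spectrum is chosen; ties break
    toward lower m/z.  Two orthogonality rules are supported:

    - ``"tenfold"`` (default): target intensity at m/z >= 10 x the coeluter's.
    - ``"share"``: target's share of the summed intensity at m/z >=
      ``thres_ortho`` (0.9 corresponds to a ninefold margin).

    Raises
    ------
    UnresolvableCoelutionError
        If no ion satisfies the rule against every coeluter.
    """
    if not coeluters:
        return target.base_peak

    def ok(mz: int, mine: float) -> bool:
        for other in coeluters:
            theirs = other.intensity(mz)
            if rule == "tenfold":
                if mine < 10.0 * theirs:
                    return False
            elif rule == "share":
                if mine <= 0 or mine / (mine + theirs) < thres_ortho:
                    return False
            else:
                raise ValueError(f"unknown orthogonality rule {rule!r}")
        return mine > 0

    candidates = [
        (mz, inten) for mz, inten in target.intensities.items() if ok(mz, inten)
    ]
    if not candidates:
        pair = ", ".join(sorted(c.compound for c in coeluters))
        raise UnresolvableCoelutionError(
            f"no quantitation ion separates {target.compound} from "
            f"coeluting {pair}"
        )
    # most intense first, then lowest m/z
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return candidates[0][0]


def integrate_peak(
    trace: Sequence[tuple[float, float]], bounds: tuple[float, float]
) -> float:
    """Trapezoidal area of a single-ion trace between retention-time bounds.

    Endpoints are linearly interpolated; empty bounds integrate to zero.
    """
    lo, hi = bounds
    if hi < lo:
        raise ValueError(f"unordered integration bounds ({lo}, {hi})")
    if hi == lo or not trace:
        return 0.0
    t = np.array([p[0] for p in trace])
    y = np.array([p[1] for p in trace])
    if np.any(y < 0):
        raise ValueError("negative intensity in ion trace")
    if lo < t[0] or hi > t[-1]:
        raise ValueError("integration bounds fall outside the trace")
    inner = (t > lo) & (t < hi)
    tt = np.concatenate([[lo], t[inner], [hi]])
    yy = np.concatenate([[np.interp(lo, t, y)], y[inner], [np.interp(hi, t, y)]])
    return float(np.trapezoid(yy, tt))


def compute_mole_fractions(
    peaks: Iterable[PeakObservation],
    coefficients: Mapping[str, IonizationCoefficients],
) -> CompositionProfile:
    """Close a sample's coefficient-scaled integrals to mole fractions.

    x_i = (A_i / k_i) / sum_j (A_j / k_j) with k the molar ionization
    coefficient.  Compounds without a valid coefficient are excluded from
    the closure and logged (only known compounds are quantified).
    """
    peaks = list(peaks)
    if not peaks:
        raise ValueError("no peaks to quantify")
    sample_ids = {p.sample_id for p in peaks}
    if len(sample_ids) != 1:
        raise ValueError(f"peaks span multiple samples: {sorted(sample_ids)}")
    sample_id = peaks[0].sample_id

    moles: dict[str, float] = {}
    for p in peaks:
        coef = coefficients.get(p.compound)
        if coef is None or not coef.valid or coef.molar_coefficient <= 0:
            logger.warning(
                "sample %s: compound %s has no valid ionization coefficient; "
                "excluded from closure",
                sample_id,
                p.compound,
            )
            continue
        moles[p.compound] = moles.get(p.compound, 0.0) + p.integral / coef.molar_coefficient
    total = sum(moles.values())
    if total <= 0:
        raise ValueError(f"sample {sample_id}: all quantifiable integrals are zero")
    return CompositionProfile(sample_id, {c: m / total for c, m in moles.items()})


def detect_significant_species(
    profiles: Sequence[CompositionProfile],
    alpha: float = 0.05,
    min_n: int = 3,
) -> "pd.DataFrame":
    """Test which compounds are detected at statistically significant levels.

    Per compound: observations farther than 6 sample standard deviations
    from the sample mean are removed (single pass), then a one-tailed
    one-sample t-test of mean > 0 is run; p-values are Holm-adjusted across
    compounds and those below ``alpha`` are flagged detected.

    Returns a report DataFrame (compound, n_used, n_outliers_removed, t, p,
    p_holm, detected).  Compounds with fewer than ``min_n`` surviving
    observations are excluded with a warning.
    """
    import pandas as pd

    if len(profiles) < min_n:
        raise ValueError(f"need at least {min_n} profiles")

    compounds = sorted({sp.label for prof in profiles for sp in prof})
    rows = []
    for label in compounds:
        x = np.array([prof[label] for prof in profiles], dtype=float)
        mu, sd = x.mean(), x.std(ddof=1)
        if sd > 0:
            keep = np.abs(x - mu) <= 6.0 * sd
        else:
            keep = np.ones_like(x, dtype=bool)
        n_removed = int((~keep).sum())
        x = x[keep]
        if len(x) < min_n:
            logger.warning(
                "compound %s: only %d observations survive outlier removal; "
                "excluded from detection test",
                label,
                len(x),
            )
            continue
        sd_kept = x.std(ddof=1)
        if sd_kept == 0.0:
            # degenerate: constant observations carry no sampling variance
            t_stat = math.inf if x.mean() > 0 else 0.0
            p = 0.0 if x.mean() > 0 else 1.0
        else:
            t_stat, p = stats.ttest_1samp(x, 0.0, alternative="greater")
            t_stat, p = float(t_stat), float(p)
        rows.append(
            {
                "compound": label,
                "n_used": len(x),
                "n_outliers_removed": n_removed,
                "t": t_stat,
                "p": p,
            }
        )
    report = pd.DataFrame(rows)
    report["p_holm"] = holm_adjust(report["p"].to_numpy())
    report["detected"] = report["p_holm"] < alpha
    return report
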