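"""Transcript competition and decay kinetics from qPCR data.

Fold enrichment follows the delta-Ct convention: one qPCR cycle is one
doubling, so a construct whose Ct sits 14.61 cycles below the reference
target is 2^14.61 ~ 2.5e4-fold more abundant.  Decay is modeled as
one-phase exponential decay Y(t) = (Y0 - plateau) * exp(-k t) + plateau
with half-life ln(2)/k, fit by nonlinear least squares on the abundance
scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import NonDecayWarning, PairingError, ValidationError

LN2 = math.log(2.0)

CT_TABLE_COLUMNS = ("sample_id", "target", "time_h", "replicate", "ct")


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR well: a Ct value for one target at one chase time."""

    sample_id: str
    target: str
    time_h: float
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct):
            raise ValidationError(f"{self.sample_id}: non-finite Ct")
        if self.time_h < 0:
            raise ValidationError(f"{self.sample_id}: negative time")


@dataclass(frozen=True)
class DecayTimeCourse:
    """Replicate relative abundances per time, normalized to mean 1 at t0."""

    times_h: Tuple[float, ...]
    abundance: Tuple[Tuple[float, ...], ...]  # per time, per replicate

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times_h)
        object.__setattr__(self, "times_h", times)
        object.__setattr__(
            self, "abundance", tuple(tuple(map(float, a)) for a in self.abundance)
        )
        if len(set(times)) < 3:
            raise ValidationError("need >= 3 distinct time points")
        if list(times) != sorted(times):
            raise ValidationError("times must be sorted ascending")
        if len(self.abundance) != len(times):
            raise ValidationError("abundance rows must match times")
        for a in self.abundance:
            if not a or any(v <= 0 for v in a):
                raise ValidationError("abundances must be positive and nonempty")
        if abs(float(np.mean(self.abundance[0])) - 1.0) > 1e-9:
            raise ValidationError("mean abundance at earliest time must be 1")

    def flatten(self) -> Tuple[np.ndarray, np.ndarray]:
        t = np.concatenate(
            [np.full(len(a), tt) for tt, a in zip(self.times_h, self.abundance)]
        )
        y = np.concatenate([np.asarray(a) for a in self.abundance])
        return t, y


@dataclass(frozen=True)
class DecayFit:
    """One-phase decay parameter estimates."""

    y0: float
    plateau: float
    k: float
    half_life_h: float
    rss: float
    converged: bool
    ci_half_life: Optional[Tuple[float, float]] = None


def fold_enrichment(ct_reference_target: float, ct_construct: float) -> float:
    """Fold abundance of the construct relative to the reference target.

    Returns ``2 ** (ct_reference_target - ct_construct)``, i.e.
    ``0.5 ** (ct_construct - ct_reference_target)``; > 1 iff the construct
    is more abundant.
    """
    if not (math.isfinite(ct_reference_target) and math.isfinite(ct_construct)):
        raise ValidationError("Ct values must be finite")
    return 2.0 ** (ct_reference_target - ct_construct)


def read_ct_table(path: Union[str, Path]) -> List[QpcrMeasurement]:
    """Read a TSV Ct table with columns sample_id, target, time_h, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        QpcrMeasurement(
            sample_id=str(row.sample_id),
            target=str(row.target),
            time_h=float(row.time_h),
            replicate=int(row.replicate),
            ct=float(row.ct),
        )
        for row in df.itertuples()
    ]


def write_ct_table(
    measurements: Sequence[QpcrMeasurement], path: Union[str, Path]
) -> None:
    df = pd.DataFrame(
        [
            (m.sample_id, m.target, m.time_h, m.replicate, m.ct)
            for m in measurements
        ],
        columns=list(CT_TABLE_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def normalize_timecourse(
    measurements: Sequence[QpcrMeasurement], target: str, reference: str
) -> DecayTimeCourse:
    """Compute per-replicate relative abundances 2^(Ct_ref - Ct_target).

    Every (time, replicate) pair must have both a target and a reference Ct;
    all abundances are then divided by the mean at the earliest time.
    """
    by_key = {}
    for m in measurements:
        if m.target not in (target, reference):
            continue
        key = (m.time_h, m.replicate)
        by_key.setdefault(key, {})[m.target] = m.ct
    if not by_key:
        raise PairingError(
            f"no measurements for target {target!r} / reference {reference!r}"
        )
    rel = {}
    for (t, r), cts in sorted(by_key.items()):
        if target not in cts or reference not in cts:
            missing = reference if target in cts else target
            raise PairingError(
                f"time {t} replicate {r}: missing Ct for {missing!r}"
            )
        rel.setdefault(t, []).append(2.0 ** (cts[reference] - cts[target]))
    times = sorted(rel)
    scale = float(np.mean(rel[times[0]]))
    return DecayTimeCourse(
        times_h=tuple(times),
        abundance=tuple(tuple(v / scale for v in rel[t]) for t in times),
    )


def _initial_rate(tc: DecayTimeCourse) -> float:
    """OLS slope of ln(mean abundance) over the first four time points."""
    n = min(4, len(tc.times_h))
    t = np.asarray(tc.times_h[:n])
    ly = np.log([np.mean(a) for a in tc.abundance[:n]])
    slope = np.polyfit(t, ly, 1)[0]
    return -float(slope)


def fit_one_phase_decay(
    tc: DecayTimeCourse,
    fix_plateau_zero: bool = True,
    weighting: Optional[str] = None,
) -> DecayFit:
    """Least-squares fit of Y(t) = (Y0 - P) exp(-k t) + P, half-life ln2/k.

    Plateau P is fixed to 0 by default (labeled-RNA chases decay to
    background); pass ``fix_plateau_zero=False`` to free it with bound
    P >= 0.  ``weighting="1/y2"`` applies relative (1/Y^2) weights for
    heteroscedastic data.  Data whose initial log-slope is not negative get
    a :class:`NonDecayWarning` and ``converged=False``.
    """
    if weighting not in (None, "1/y2"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    t, y = tc.flatten()
    y0_init = float(np.mean(tc.abundance[0]))
    k_init = _initial_rate(tc)
    if k_init <= 0:
        warnings.warn(
            "initial slope is not negative; data do not look like decay",
            NonDecayWarning,
        )
        return DecayFit(
            y0=y0_init,
            plateau=0.0,
            k=math.nan,
            half_life_h=math.nan,
            rss=math.nan,
            converged=False,
        )
    w = 1.0 / y if weighting == "1/y2" else np.ones_like(y)

    if fix_plateau_zero:
        def resid(p):
            return w * (p[0] * np.exp(-p[1] * t) - y)

        x0 = [y0_init, k_init]
        lb, ub = [0.0, 1e-12], [np.inf, np.inf]
    else:
        def resid(p):
            return w * ((p[0] - p[2]) * np.exp(-p[1] * t) + p[2] - y)

        p_init = max(float(np.min(y)), 0.0)
        x0 = [y0_init, k_init, p_init]
        lb, ub = [0.0, 1e-12, 0.0], [np.inf, np.inf, np.inf]

    result = least_squares(
        resid,
        x0,
        bounds=(lb, ub),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=500 * len(x0),
    )
    y0_fit = float(result.x[0])
    k_fit = float(result.x[1])
    plateau = float(result.x[2]) if not fix_plateau_zero else 0.0
    model = (y0_fit - plateau) * np.exp(-k_fit * t) + plateau
    rss = float(np.sum((model - y) ** 2))
    return DecayFit(
        y0=y0_fit,
        plateau=plateau,
        k=k_fit,
        half_life_h=LN2 / k_fit,
        rss=rss,
        converged=bool(result.success) and k_fit > 0,
    )


def bootstrap_half_life(
    tc: DecayTimeCourse,
    n_boot: int = 1000,
    seed: int = 0,
    fix_plateau_zero: bool = True,
) -> Tuple[float, float]:
    """Bootstrap 95% interval for the half-life.

    Replicates are resampled with replacement within each time point, the
    resampled course is renormalized and refit, and the 2.5/97.5 percentiles
    of the fitted half-lives are reported.  Deterministic given `seed`.
    """
    if any(len(a) < 2 for a in tc.abundance):
        raise ValidationError(
            "bootstrap needs >= 2 replicates per time point; with single "
            "replicates, report the point estimate without a bootstrap interval"
        )
    rng = np.random.default_rng(seed)
    halves = []
    for _ in range(n_boot):
        rows = [
            tuple(rng.choice(a, size=len(a), replace=True)) for a in tc.abundance
        ]
        scale = float(np.mean(rows[0]))
        boot = DecayTimeCourse(
            times_h=tc.times_h,
            abundance=tuple(tuple(v / scale for v in row) for row in rows),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonDecayWarning)
            fit = fit_one_phase_decay(boot, fix_plateau_zero=fix_plateau_zero)
        if fit.converged and math.isfinite(fit.half_life_h):
            halves.append(fit.half_life_h)
    if not halves:
        raise ValidationError("no bootstrap replicate produced a converged fit")
    lo, hi = np.percentile(halves, [2.5, 97.5])
    return float(lo), float(hi)
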