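"""Method-validation statistics: recovery, RSD, confidence intervals and
selectivity summaries.

Conventions follow routine analytical method validation:

    recovery [%]  = 100 · measured / nominal
    RSD [%]       = 100 · sd / mean            (sd with n−1 denominator)
    CI95          = mean ± Z · sd / √n          (Z = 1.96, α = 0.05)

Reports round to one decimal; full precision is retained internally.
Dispersions are always labelled explicitly as sd or sem — never a bare
"±".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import DesignError, ParameterError

Z_95 = 1.96


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    rsd_percent: float
    sem: float


@dataclass(frozen=True)
class RecoveryResult:
    measured_mean: float
    nominal: float
    recovery_percent: float


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    z: float = Z_95
    alpha: float = 0.05


def recovery(measured: float, nominal: float) -> RecoveryResult:
    """Recovery rate of a measured mean against the nominal concentration."""
    if nominal <= 0:
        raise ParameterError(f"nominal concentration must be positive, got {nominal}")
    return RecoveryResult(
        measured_mean=float(measured),
        nominal=float(nominal),
        recovery_percent=100.0 * measured / nominal,
    )


def summarize(values) -> SummaryStats:
    """n, mean, sd (n−1), RSD% and sem of a replicate series."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise DesignError(f"need at least two replicates for sd, got {v.size}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    rsd = 100.0 * sd / mean if mean != 0 else float("nan")
    return SummaryStats(
        n=int(v.size), mean=mean, sd=sd, rsd_percent=rsd, sem=sd / np.sqrt(v.size)
    )


def confidence_interval(stats: SummaryStats, z: float = Z_95) -> ConfidenceInterval:
    """mean ± z·sd/√n."""
    if stats.n < 2:
        raise DesignError("confidence interval needs at least two replicates")
    half = z * stats.sd / np.sqrt(stats.n)
    return ConfidenceInterval(stats.mean - half, stats.mean + half, z=z)


def selectivity_report(
    control, spiked: Mapping[str, np.ndarray], nominal: float
) -> pd.DataFrame:
    """Selectivity table: per condition the measured mean ± sd and the
    recovery rate against the shared nominal concentration.

    ``control`` is the interferent-free replicate series; ``spiked`` maps
    interferent name → replicate series measured in its presence. Rows
    mirror the two-row (concentration / recovery) layout of a
    validation report, flattened into columns.
    """
    ctrl = np.asarray(control, dtype=float).ravel()
    if ctrl.size < 2:
        raise DesignError("selectivity needs a control series with >= 2 replicates")
    rows = []
    for name, series in [("control", ctrl)] + list(spiked.items()):
        st = summarize(series)
        rec = recovery(st.mean, nominal)
        rows.append(
            {
                "condition": name,
                "n": st.n,
                "mean_mg_l": st.mean,
                "sd_mg_l": st.sd,
                "sem_mg_l": st.sem,
                "recovery_percent": rec.recovery_percent,
                "recovery_sd_percent": 100.0 * st.sd / nominal,
            }
        )
    return pd.DataFrame(rows)


def repeatability_report(values, nominal: float, z: float = Z_95) -> dict:
    """Repeatability/accuracy block: RSD, recovery and CI95 for one
    replicate series at a known nominal concentration."""
    st = summarize(values)
    rec = recovery(st.mean, nominal)
    ci = confidence_interval(st, z=z)
    return {
        "n": st.n,
        "mean_mg_l": st.mean,
        "sd_mg_l": st.sd,
        "sem_mg_l": st.sem,
        "rsd_percent": st.rsd_percent,
        "recovery_percent": rec.recovery_percent,
        "ci95_lower": ci.lower,
        "ci95_upper": ci.upper,
    }
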