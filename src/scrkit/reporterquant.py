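"""Reporter-based readthrough quantification and small closed-form assay helpers.

The dual-reporter readthrough design places firefly luciferase (FLuc)
downstream of a stop codon + ISR cassette, with Renilla luciferase (RLuc)
as the co-transfection control: FLuc is produced only upon readthrough, and
per-replicate FLuc/RLuc ratios are anchored to a stop-less construct taken
as 100%.  The same logic applies to GFP/DsRed fluorescence pairs.

Also provided: the GFP/DsRed stability ratio, 2^-ddCt expression, MTT fold
proliferation, calliper tumour volume, actin-normalised densitometry, and
two-sample t statistics (Student / Welch / paired).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

#: Construct labels understood by :func:`scr_efficiency`.
TEST, NO_STOP, NO_ISR, NONSPECIFIC = "test_isr", "no_stop", "no_isr", "nonspecific"


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Readthrough efficiency in percent, with its normalization provenance.

    ``dispersion`` is the standard deviation of the per-replicate test
    ratios expressed on the percent scale.
    """

    pct: float
    n_test: int
    n_ref: int
    normalization: str  # "no_stop_100" | "background_subtracted"
    dispersion: float
    estimator: str = "mean_of_ratios"


@dataclass(frozen=True)
class StabilityRatio:
    ratio: float
    condition: str = ""


def _require_columns(table: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise DataError(f"luciferase table missing columns {missing}")


def relative_activity(table: pd.DataFrame, construct: str) -> np.ndarray:
    """Per-replicate FLuc/RLuc ratios for one construct."""
    _require_columns(table, ["construct", "fluc", "rluc"])
    sub = table[table["construct"] == construct]
    if sub.empty:
        raise ConfigError(f"construct {construct!r} absent from table")
    rluc = sub["rluc"].to_numpy(dtype=float)
    if np.any(rluc <= 0):
        raise DataError(f"non-positive RLuc reading for construct {construct!r}")
    return sub["fluc"].to_numpy(dtype=float) / rluc


def scr_efficiency(
    table: pd.DataFrame,
    mode: str = "no_stop_100",
    background_construct: Optional[str] = None,
    estimator: str = "mean_of_ratios",
) -> EfficiencyEstimate:
    """Readthrough efficiency as a percentage of the no-stop construct.

    ``no_stop_100``: pct = 100 * mean(test ratios) / mean(no-stop ratios).
    ``background_subtracted``: the mean ratio of a background construct
    (``nonspecific`` if present, else ``no_isr``) is subtracted from both
    numerator and denominator first; a negative corrected numerator clips
    to 0 with a warning.

    ``estimator="ratio_of_means"`` divides channel means instead of averaging
    per-replicate ratios.
    """
    if mode not in {"no_stop_100", "background_subtracted"}:
        raise ConfigError(f"unknown efficiency mode {mode!r}")
    if estimator not in {"mean_of_ratios", "ratio_of_means"}:
        raise ConfigError(f"unknown estimator {estimator!r}")

    def level(construct: str) -> tuple[float, np.ndarray]:
        ratios = relative_activity(table, construct)
        if estimator == "mean_of_ratios":
            return float(np.mean(ratios)), ratios
        sub = table[table["construct"] == construct]
        return float(sub["fluc"].mean() / sub["rluc"].mean()), ratios

    test_level, test_ratios = level(TEST)
    ref_level, ref_ratios = level(NO_STOP)
    bg = 0.0
    if mode == "background_subtracted":
        if background_construct is None:
            present = set(table["construct"])
            background_construct = NONSPECIFIC if NONSPECIFIC in present else NO_ISR
        bg, _ = level(background_construct)
    num, den = test_level - bg, ref_level - bg
    if den <= 0:
        raise DataError("background exceeds the no-stop reference level")
    if num < 0:
        warnings.warn("background-corrected test signal negative; clipping to 0")
        num = 0.0
    scale = 100.0 / den
    return EfficiencyEstimate(
        pct=scale * num,
        n_test=len(test_ratios),
        n_ref=len(ref_ratios),
        normalization=mode,
        dispersion=float(np.std(test_ratios, ddof=1) * scale) if len(test_ratios) > 1 else 0.0,
        estimator=estimator,
    )


def stability_ratio(gfp_mfi: float, dsred_mfi: float, condition: str = "") -> StabilityRatio:
    """GFP/DsRed mean-fluorescence-intensity ratio (reporter stability proxy)."""
    if dsred_mfi <= 0:
        raise DataError("DsRed MFI must be positive")
    return StabilityRatio(ratio=gfp_mfi / dsred_mfi, condition=condition)


def fold_proliferation(abs_t: float, abs_day0: float) -> float:
    """MTT fold proliferation: absorbance at time t over day-zero absorbance."""
    if abs_day0 <= 0:
        raise DataError("day-zero absorbance must be positive")
    return abs_t / abs_day0


def tumour_volume(shortest_mm: float, longest_mm: float) -> float:
    """Calliper tumour volume in mm^3: shortest^2 * longest * 0.5."""
    if shortest_mm <= 0 or longest_mm <= 0:
        raise DataError("diameters must be positive")
    if shortest_mm > longest_mm:
        raise DataError("shortest diameter exceeds longest (argument order)")
    return shortest_mm**2 * longest_mm * 0.5


def ddct_expression(
    ct_target_s: float, ct_ref_s: float, ct_target_c: float, ct_ref_c: float
) -> float:
    """Relative expression by the 2^-ddCt method (sample vs control)."""
    ddct = (ct_target_s - ct_ref_s) - (ct_target_c - ct_ref_c)
    return float(2.0 ** (-ddct))


def relative_density(
    band: float, background: float, actin_band: float, actin_background: float
) -> float:
    """Background-deducted band density normalised to the actin band."""
    actin_net = actin_band - actin_background
    if actin_net <= 0:
        raise DataError("actin net density must be positive")
    return (band - background) / actin_net


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-tailed two-sample t-test: returns (t, df, p).

    Student's pooled test by default; ``welch`` applies the
    Welch-Satterthwaite correction (unpaired only); ``paired`` compares
    replicate-matched differences.  Identical paired samples return
    (0, n-1, 1) rather than 0/0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataError("each group needs at least 2 observations")
    if paired:
        if welch:
            raise ConfigError("Welch correction applies to unpaired tests only")
        if len(x) != len(y):
            raise DataError("paired test requires equal group sizes")
        if np.ptp(x - y) == 0 and np.allclose(x, y):
            return 0.0, float(len(x) - 1), 1.0
        res = stats.ttest_rel(x, y)
        return float(res.statistic), float(len(x) - 1), float(res.pvalue)
    res = stats.ttest_ind(x, y, equal_var=not welch)
    if welch:
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        nx, ny = len(x), len(y)
        num = (vx / nx + vy / ny) ** 2
        den = (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        df = num / den if den > 0 else float(nx + ny - 2)
    else:
        df = float(len(x) + len(y) - 2)
    return float(res.statistic), float(df), float(res.pvalue)
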