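"""Plate-reader and cultivation analytics for inducible knockdown strains.

Bulk quantification of CRISPRi knockdown works on two kinds of series:

* :class:`WellSeries` -- OD600 + fluorescence trajectories of microplate
  wells, in biological replicate, for a knockdown strain, a fluorescent
  non-targeting control, and a non-fluorescent background strain.  From
  these the *GFP fraction* (background-subtracted reporter concentration
  of the knockdown strain relative to the control) is computed at a fixed
  OD600 threshold, with a percentile-bootstrap confidence interval, and
  the post-induction *quiescent phase* (the delay before the reporter
  concentration starts to fall) is located.
* :class:`CultureSeries` -- OD600 plus substrate / intermediate / product
  concentrations of a batch cultivation converting p-coumarate (p-CA) to
  beta-ketoadipate (betaKA), from which final titer (g/L) and molar yield
  on *initial* substrate are computed.

The statsmodels-style front door is :class:`KnockdownAssay`, whose
``fit()`` returns a :class:`KnockdownAssayResults` carrying the estimates,
their uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WellSeries",
    "CultureSeries",
    "AssayParams",
    "OnsetResult",
    "GfpFractionResult",
    "conc_at_threshold",
    "gfp_fraction",
    "growth_rate_at",
    "detect_onset",
    "yield_and_titer",
    "KnockdownAssay",
    "KnockdownAssayResults",
    "molecular_weight",
    "MW_TABLE",
    "OVERALL_REACTION",
    "theoretical_yield",
]

LN2 = float(np.log(2.0))

STRAIN_ROLES = ("knockdown", "gfp_control", "nonfluorescent")
MEDIA_CLASSES = ("rich", "minimal")

# ---------------------------------------------------------------------------
# stoichiometry and molecular weights
# ---------------------------------------------------------------------------

ATOMIC_WEIGHTS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "P": 30.974}

#: Elemental compositions of the metabolites handled by the yield arithmetic.
COMPOSITIONS = {
    "beta_ketoadipate": {"C": 6, "H": 8, "O": 5},
    "p_coumarate": {"C": 9, "H": 8, "O": 3},
    "4_hydroxybenzoate": {"C": 7, "H": 6, "O": 3},
    "protocatechuate": {"C": 7, "H": 6, "O": 4},
}


def molecular_weight(formula: dict) -> float:
    """Molecular weight (g/mol) from an elemental composition mapping."""
    return float(sum(ATOMIC_WEIGHTS[el] * n for el, n in formula.items()))


#: Default molecular-weight table (g/mol), derived from the formulas above.
MW_TABLE = {name: molecular_weight(f) for name, f in COMPOSITIONS.items()}

#: Overall conversion catabolising p-CA down to betaKA (signed stoichiometric
#: coefficients; negative = consumed).  One mole of betaKA and one of
#: acetyl-CoA per mole of p-CA, so the theoretical molar product yield is 1.
OVERALL_REACTION = {
    "p_coumarate": -1,
    "ATP": -1,
    "CoA": -1,
    "O2": -2,
    "H2O": -1,
    "beta_ketoadipate": 1,
    "acetyl_coa": 1,
    "AMP": 1,
    "diphosphate": 1,
    "CO2": 1,
}


def theoretical_yield(
    reaction: dict | None = None,
    product: str = "beta_ketoadipate",
    substrate: str = "p_coumarate",
) -> float:
    """Stoichiometric molar yield of *product* on *substrate* (mol/mol)."""
    rxn = OVERALL_REACTION if reaction is None else reaction
    return rxn[product] / float(-rxn[substrate])


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class WellSeries:
    """Time series of one microplate well: OD600 and bulk fluorescence."""

    well_id: str
    strain_role: str
    media_class: str
    time_h: np.ndarray
    od600: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        if self.strain_role not in STRAIN_ROLES:
            raise ValueError(
                f"well {self.well_id!r}: unknown strain_role {self.strain_role!r}"
            )
        if self.media_class not in MEDIA_CLASSES:
            raise ValueError(
                f"well {self.well_id!r}: unknown media_class {self.media_class!r}"
            )
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        n = self.time_h.size
        if self.od600.size != n or self.fluorescence.size != n:
            raise ValueError(f"well {self.well_id!r}: column lengths differ")
        if n >= 2 and not np.all(np.diff(self.time_h) > 0):
            raise ValueError(f"well {self.well_id!r}: time not strictly increasing")

    def __len__(self) -> int:
        return self.time_h.size


@dataclass
class CultureSeries:
    """Batch-cultivation time series: biomass and supernatant chemistry (mM)."""

    time_h: np.ndarray
    od600: np.ndarray
    p_ca_mm: np.ndarray
    hba_mm: np.ndarray
    pca_mm: np.ndarray
    bka_mm: np.ndarray

    def __post_init__(self):
        for name in ("time_h", "od600", "p_ca_mm", "hba_mm", "pca_mm", "bka_mm"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.time_h.size
        for name in ("od600", "p_ca_mm", "hba_mm", "pca_mm", "bka_mm"):
            if getattr(self, name).size != n:
                raise ValueError("culture series column lengths differ")
        if n >= 2 and not np.all(np.diff(self.time_h) > 0):
            raise ValueError("culture series time not strictly increasing")


@dataclass
class AssayParams:
    """Tunables of the bulk assay.

    ``od_threshold_rich``/``od_threshold_minimal`` set the OD600 at which
    cellular reporter concentration is read out (0.1 for rich media, 0.05
    for minimal).  ``onset_drop_fraction`` is the sustained fractional drop
    of the knockdown/control concentration ratio that defines knockdown
    onset; ``smoothing_window`` is the centred moving-average width (odd,
    in samples) applied to the ratio before thresholding.
    """

    od_threshold_rich: float = 0.1
    od_threshold_minimal: float = 0.05
    n_bootstrap: int = 10_000
    ci_level: float = 0.95
    slope_points: int = 3
    onset_drop_fraction: float = 0.05
    smoothing_window: int = 3
    bootstrap_seed: int = 0

    def __post_init__(self):
        if self.od_threshold_rich <= 0 or self.od_threshold_minimal <= 0:
            raise ValueError("OD thresholds must be positive")
        if self.n_bootstrap < 1000:
            raise ValueError("n_bootstrap must be >= 1000")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if not 0 < self.onset_drop_fraction < 0.5:
            raise ValueError("onset_drop_fraction must be in (0, 0.5)")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.slope_points < 2:
            raise ValueError("slope_points must be >= 2")

    def od_threshold(self, media_class: str) -> float:
        return (
            self.od_threshold_rich
            if media_class == "rich"
            else self.od_threshold_minimal
        )


@dataclass
class GfpFractionResult:
    fraction: float
    ci_low: float
    ci_high: float
    kd_concs: np.ndarray
    ctrl_concs: np.ndarray
    background: float


@dataclass
class OnsetResult:
    quiescent_h: float
    quiescent_doublings: float
    onset_time_h: float
    growth_rate: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _threshold_crossing(well: WellSeries, threshold: float) -> float:
    """Time (h) at which OD600 first crosses *threshold*, by linear interpolation."""
    od = well.od600
    t = well.time_h
    if od[0] > threshold:
        raise ValueError(
            f"well {well.well_id!r}: OD600 already above threshold "
            f"{threshold} at the first sample"
        )
    idx = np.nonzero(od >= threshold)[0]
    if idx.size == 0:
        raise ValueError(
            f"well {well.well_id!r}: OD600 never reaches threshold {threshold}"
        )
    i = int(idx[0])
    if od[i] == threshold or i == 0:
        return float(t[i])
    frac = (threshold - od[i - 1]) / (od[i] - od[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def conc_at_threshold(well: WellSeries, params: AssayParams | None = None) -> float:
    """Cellular reporter concentration (AU per OD) at the media OD threshold.

    The threshold crossing is located by linear interpolation of the OD
    trace; fluorescence is interpolated to the same instant and divided by
    the threshold OD.
    """
    params = params or AssayParams()
    threshold = params.od_threshold(well.media_class)
    t_star = _threshold_crossing(well, threshold)
    f_star = float(np.interp(t_star, well.time_h, well.fluorescence))
    return f_star / threshold


def gfp_fraction(
    kd_wells: list,
    ctrl_wells: list,
    nonfluor_wells: list,
    params: AssayParams | None = None,
) -> GfpFractionResult:
    """Knockdown reporter fraction with a percentile-bootstrap 95% CI.

    fraction = (mean kd conc - bg) / (mean control conc - bg), where bg is
    the mean threshold concentration of the non-fluorescent strain.  The
    CI resamples the replicate-level knockdown and control concentrations
    independently with replacement (``n_bootstrap`` draws) and takes the
    2.5/97.5 percentiles of the resampled ratio; a negative lower limit is
    clamped to zero, as negative concentrations are not physical.
    """
    params = params or AssayParams()
    for role, wells in (
        ("knockdown", kd_wells),
        ("gfp_control", ctrl_wells),
        ("nonfluorescent", nonfluor_wells),
    ):
        if len(wells) < 2:
            raise ValueError(f"need >= 2 replicate wells for role {role!r}")
    kd = np.array([conc_at_threshold(w, params) for w in kd_wells])
    ctrl = np.array([conc_at_threshold(w, params) for w in ctrl_wells])
    bg = float(np.mean([conc_at_threshold(w, params) for w in nonfluor_wells]))

    ctrl_net = ctrl.mean() - bg
    if ctrl_net <= 0:
        raise ValueError("control not above background")
    point = float((kd.mean() - bg) / ctrl_net)

    rng = np.random.default_rng(params.bootstrap_seed)
    b = params.n_bootstrap
    kd_means = kd[rng.integers(0, kd.size, size=(b, kd.size))].mean(axis=1)
    ctrl_means = ctrl[rng.integers(0, ctrl.size, size=(b, ctrl.size))].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = (kd_means - bg) / (ctrl_means - bg)
    ratios = ratios[np.isfinite(ratios)]
    alpha = (1.0 - params.ci_level) / 2.0
    lo, hi = np.percentile(ratios, [100 * alpha, 100 * (1 - alpha)])
    lo = max(0.0, float(lo))  # negative concentrations are not possible
    return GfpFractionResult(point, lo, float(hi), kd, ctrl, bg)


def growth_rate_at(
    well: WellSeries,
    anchor,
    params: AssayParams | None = None,
) -> float:
    """Specific growth rate (1/h): 3-point ln-OD slope centred at *anchor*.

    *anchor* is either the string ``"threshold"`` (the media OD threshold
    crossing) or a time in hours.  The slope is a least-squares fit of
    ln(OD600) over ``slope_points`` consecutive samples centred on the
    sample nearest the anchor.  Returns NaN (with a warning) if fewer than
    ``slope_points`` usable samples exist.
    """
    params = params or AssayParams()
    if isinstance(anchor, str):
        if anchor != "threshold":
            raise ValueError(f"unknown anchor {anchor!r}")
        t_anchor = _threshold_crossing(well, params.od_threshold(well.media_class))
    else:
        t_anchor = float(anchor)
    n = len(well)
    k = params.slope_points
    if n < k:
        warnings.warn(
            f"well {well.well_id!r}: fewer than {k} samples; growth rate undefined"
        )
        return float("nan")
    center = int(np.argmin(np.abs(well.time_h - t_anchor)))
    start = min(max(center - k // 2, 0), n - k)
    sl = slice(start, start + k)
    od = well.od600[sl]
    if np.any(od <= 0):
        warnings.warn(f"well {well.well_id!r}: non-positive OD in slope window")
        return float("nan")
    return float(np.polyfit(well.time_h[sl], np.log(od), 1)[0])


def _mean_ratio_series(kd_wells: list, ctrl_wells: list):
    """Common time grid and knockdown/control mean F/OD ratio."""
    t = kd_wells[0].time_h
    for w in list(kd_wells) + list(ctrl_wells):
        if w.time_h.size != t.size or not np.allclose(w.time_h, t):
            raise ValueError("wells are not time-aligned")
    kd_conc = np.mean([w.fluorescence / w.od600 for w in kd_wells], axis=0)
    ctrl_conc = np.mean([w.fluorescence / w.od600 for w in ctrl_wells], axis=0)
    return t, kd_conc / ctrl_conc


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(x, dtype=float)
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def detect_onset(
    kd_wells: list,
    ctrl_wells: list,
    t_ind: float,
    params: AssayParams | None = None,
) -> OnsetResult | None:
    """Locate the post-induction quiescent phase of a knockdown response.

    The knockdown/control-normalised F/OD ratio is smoothed with a centred
    moving average; onset is the first time after ``t_ind`` at which the
    smoothed ratio drops below ``(1 - onset_drop_fraction)`` times its
    value at induction and stays below for at least two samples.  The
    crossing instant is linearly interpolated between samples.  The
    quiescent phase is ``onset - t_ind`` in hours, and in doublings it is
    ``quiescent_h * mu / ln 2`` with ``mu`` the realised ln-OD slope of the
    knockdown wells over the quiescent window.

    Returns ``None`` (with a warning) if no sustained drop is found.
    """
    params = params or AssayParams()
    t, ratio = _mean_ratio_series(kd_wells, ctrl_wells)
    if not (t[0] <= t_ind <= t[-1]):
        raise ValueError("induction time lies outside the series")
    sm = _smooth(ratio, params.smoothing_window)
    i_ind = int(np.argmin(np.abs(t - t_ind)))
    baseline = sm[i_ind]
    thresh = (1.0 - params.onset_drop_fraction) * baseline

    below = sm < thresh
    onset_time = None
    for i in range(i_ind + 1, t.size - 1):
        if t[i] <= t_ind:
            continue
        if below[i] and below[i + 1]:
            if i > 0 and sm[i - 1] >= thresh and sm[i] < sm[i - 1]:
                frac = (sm[i - 1] - thresh) / (sm[i - 1] - sm[i])
                onset_time = float(t[i - 1] + frac * (t[i] - t[i - 1]))
            else:
                onset_time = float(t[i])
            break
    if onset_time is None:
        warnings.warn("no sustained reporter decline detected before series end")
        return None
    onset_time = max(onset_time, float(t_ind))

    quiescent_h = onset_time - float(t_ind)
    kd_od = np.mean([w.od600 for w in kd_wells], axis=0)
    window = (t >= t_ind) & (t <= onset_time)
    if window.sum() < 2:  # degenerate: fall back to slope_points around t_ind
        c = int(np.argmin(np.abs(t - t_ind)))
        start = min(max(c - 1, 0), t.size - params.slope_points)
        window = np.zeros(t.size, dtype=bool)
        window[start : start + params.slope_points] = True
    mu = float(np.polyfit(t[window], np.log(kd_od[window]), 1)[0])
    doublings = quiescent_h * mu / LN2
    return OnsetResult(quiescent_h, doublings, onset_time, mu)


def yield_and_titer(
    culture: CultureSeries,
    mw_table: dict | None = None,
    substrate_tol_mm: float = 0.5,
):
    """Final product titer (g/L), molar yield on initial substrate, exhaustion time.

    Exhaustion is the first sample at which p-CA falls to ``substrate_tol_mm``
    or below (series end, with a warning, if it never does).  The titer is
    the betaKA concentration there converted to g/L via the molecular-weight
    table; Y_P/S divides moles of product at exhaustion by moles of substrate
    at time zero.
    """
    mw = MW_TABLE if mw_table is None else mw_table
    if "beta_ketoadipate" not in mw:
        raise ValueError("molecular weight table lacks 'beta_ketoadipate'")
    s = culture.p_ca_mm
    s0 = float(s[0])
    if s0 <= 0:
        raise ValueError("initial substrate concentration must be positive")
    idx = np.nonzero(s <= substrate_tol_mm)[0]
    if idx.size:
        i_exh = int(idx[0])
    else:
        warnings.warn("substrate never exhausted; using final sample")
        i_exh = len(s) - 1
    p_mm = float(culture.bka_mm[i_exh])
    titer_gl = p_mm * mw["beta_ketoadipate"] / 1000.0
    yield_molmol = p_mm / s0
    return titer_gl, yield_molmol, float(culture.time_h[i_exh])


# ---------------------------------------------------------------------------
# model / results front door
# ---------------------------------------------------------------------------


class KnockdownAssay:
    """Knockdown quantification model over a collection of plate wells.

    Parameters
    ----------
    wells : sequence of WellSeries
        Must contain at least two replicate wells for each of the roles
        ``knockdown``, ``gfp_control`` and ``nonfluorescent``.
    params : AssayParams, optional
    induction_time : float, optional
        Inducer addition time (h).  If given, ``fit()`` also runs onset
        detection and reports the quiescent phase.
    """

    def __init__(self, wells, params: AssayParams | None = None, induction_time=None):
        self.params = params or AssayParams()
        self.induction_time = induction_time
        self.wells = {role: [] for role in STRAIN_ROLES}
        for w in wells:
            self.wells[w.strain_role].append(w)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "KnockdownAssay":
        """Build from a long-format table (columns: well, strain_role,
        media_class, time_h, od600, fluor)."""
        from .io import wells_from_dataframe

        return cls(wells_from_dataframe(df), **kwargs)

    def fit(self) -> "KnockdownAssayResults":
        p = self.params
        frac = gfp_fraction(
            self.wells["knockdown"],
            self.wells["gfp_control"],
            self.wells["nonfluorescent"],
            p,
        )
        rates = {
            role: float(
                np.mean([growth_rate_at(w, "threshold", p) for w in ws])
            )
            for role, ws in self.wells.items()
            if ws
        }
        onset = None
        if self.induction_time is not None:
            onset = detect_onset(
                self.wells["knockdown"],
                self.wells["gfp_control"],
                self.induction_time,
                p,
            )
        return KnockdownAssayResults(self, frac, rates, onset)


class KnockdownAssayResults:
    """Estimates produced by :meth:`KnockdownAssay.fit`."""

    def __init__(self, model, fraction_result, growth_rates, onset):
        self.model = model
        self.fraction_result = fraction_result
        self.growth_rates = growth_rates
        self.onset = onset

    @property
    def gfp_fraction(self) -> float:
        return self.fraction_result.fraction

    @property
    def conf_int(self):
        return (self.fraction_result.ci_low, self.fraction_result.ci_high)

    @property
    def quiescent_h(self):
        return None if self.onset is None else self.onset.quiescent_h

    @property
    def quiescent_doublings(self):
        return None if self.onset is None else self.onset.quiescent_doublings

    def to_dict(self) -> dict:
        out = {
            "gfp_fraction": self.gfp_fraction,
            "ci_low": self.fraction_result.ci_low,
            "ci_high": self.fraction_result.ci_high,
            "background_au_per_od": self.fraction_result.background,
            "growth_rates_per_h": self.growth_rates,
        }
        if self.onset is not None:
            out.update(
                quiescent_h=self.onset.quiescent_h,
                quiescent_doublings=self.onset.quiescent_doublings,
                onset_time_h=self.onset.onset_time_h,
            )
        return out

    def summary(self) -> str:
        lines = [
            "Knockdown assay results",
            "=" * 47,
            f"{'GFP fraction':<30}{self.gfp_fraction:>12.4f}",
            f"{'95% CI low':<30}{self.fraction_result.ci_low:>12.4f}",
            f"{'95% CI high':<30}{self.fraction_result.ci_high:>12.4f}",
            f"{'background (AU/OD)':<30}{self.fraction_result.background:>12.2f}",
        ]
        for role, mu in sorted(self.growth_rates.items()):
            lines.append(f"{'growth rate ' + role + ' (1/h)':<30}{mu:>12.4f}")
        if self.onset is not None:
            lines += [
                f"{'quiescent phase (h)':<30}{self.onset.quiescent_h:>12.3f}",
                f"{'quiescent doublings':<30}{self.onset.quiescent_doublings:>12.3f}",
            ]
        lines.append("=" * 47)
        return "\n".join(lines)

    def plot(self, ax=None):
        """OD and F/OD trajectories of the fitted wells (one panel each)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.5))
        colors = {"knockdown": "C0", "gfp_control": "C2", "nonfluorescent": "C7"}
        for role, ws in self.model.wells.items():
            for w in ws:
                ax[0].semilogy(w.time_h, w.od600, color=colors[role], alpha=0.6)
                ax[1].plot(
                    w.time_h,
                    w.fluorescence / w.od600,
                    color=colors[role],
                    alpha=0.6,
                )
        if self.onset is not None:
            ax[1].axvline(self.onset.onset_time_h, ls="--", color="k", lw=0.8)
        ax[0].set(xlabel="time (h)", ylabel="OD600")
        ax[1].set(xlabel="time (h)", ylabel="F / OD (AU per OD)")
        return ax
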