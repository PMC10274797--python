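"""Regime segmentation and spectroscopic fingerprint extraction.

From a wideband spectrum and its alpha(omega) curve this module locates
fluid/solid transitions (alpha = 0.5 crossings), elastic plateaus (alpha
local minima, coinciding with G'' minima), per-regime power-law exponents of
G'' and |G*|, and the inflection frequency at which the G'' scaling law
changes; it then partitions the valid band into labelled regimes
(I, II, IIIa, ...).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger("shears")

PLATEAU_PROMINENCE = 0.05  # alpha units below the lower neighbouring maximum

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass
class Transition:
    """An alpha = 0.5 crossing."""

    omega: float  # rad/s
    direction: str  # "fluid->solid" (alpha decreasing) or "solid->fluid"


@dataclass
class Plateau:
    omega: float  # plateau frequency (alpha local minimum)
    modulus: float  # G'(omega) there, Pa
    alpha_min: float
    label: str = ""


@dataclass
class PowerLawFit:
    exponent: float
    stderr: float
    omega_range: Tuple[float, float]
    label: str = ""


@dataclass
class ScalingTransition:
    omega: Optional[float]  # None when absent
    multiplicity: int  # number of inflections found


@dataclass
class Regime:
    label: str
    omega_lo: float
    omega_hi: float
    kind: str  # "transition" | "plateau" | "scaling" | "initial"


@dataclass
class SpectroParams:
    """Extracted fingerprint parameters with regime labels."""

    transitions: List[Transition] = field(default_factory=list)
    plateaus: List[Plateau] = field(default_factory=list)
    loss_exponents: List[PowerLawFit] = field(default_factory=list)  # gamma_k
    magnitude_exponents: List[PowerLawFit] = field(default_factory=list)  # alpha_k
    scaling_transitions: List[ScalingTransition] = field(default_factory=list)
    regimes: List[Regime] = field(default_factory=list)
    spread_method: str = "none"

    def to_rows(self) -> list:
        """Supplementary-table layout: one row per parameter."""
        rows = []
        for tr in self.transitions:
            rows.append(
                ("omega_T", tr.direction, tr.omega, float("nan"), self.spread_method,
                 "rad/s", float("nan"), float("nan"))
            )
        for pl in self.plateaus:
            rows.append(
                (f"omega0_{pl.label}", pl.label, pl.omega, float("nan"),
                 self.spread_method, "rad/s", float("nan"), float("nan"))
            )
            rows.append(
                (f"G0_{pl.label}", pl.label, pl.modulus, float("nan"),
                 self.spread_method, "Pa", float("nan"), float("nan"))
            )
        for pf in self.loss_exponents:
            rows.append(
                (f"gamma_{pf.label}", pf.label, pf.exponent, pf.stderr,
                 "fit stderr", "dimensionless", pf.omega_range[0], pf.omega_range[1])
            )
        for pf in self.magnitude_exponents:
            rows.append(
                (f"alpha_{pf.label}", pf.label, pf.exponent, pf.stderr,
                 "fit stderr", "dimensionless", pf.omega_range[0], pf.omega_range[1])
            )
        for st in self.scaling_transitions:
            if st.omega is not None:
                rows.append(
                    ("omega_gamma", "", st.omega, float("nan"), self.spread_method,
                     "rad/s", float("nan"), float("nan"))
                )
        return rows


# ---------------------------------------------------------------------------
# feature finders
# ---------------------------------------------------------------------------


def find_transitions(alpha_curve) -> List[Transition]:
    """All crossings of alpha through 0.5, interpolated linearly in log
    omega, each tagged with its crossing direction."""
    omega = alpha_curve.omega
    a = alpha_curve.alpha
    out: List[Transition] = []
    d = a - 0.5
    for i in range(len(a) - 1):
        lo, hi = d[i], d[i + 1]
        if lo == 0.0:
            continue  # handled when the previous interval ended exactly at 0
        if lo * hi < 0 or (hi == 0.0 and lo != 0.0):
            span = hi - lo
            frac = -lo / span if span != 0 else 0.0
            lw = math.log10(omega[i]) + frac * (
                math.log10(omega[i + 1]) - math.log10(omega[i])
            )
            direction = "fluid->solid" if lo > 0 else "solid->fluid"
            out.append(Transition(omega=10 ** lw, direction=direction))
    return out


def find_plateaus(
    spectrum, alpha_curve, prominence: float = PLATEAU_PROMINENCE
) -> List[Plateau]:
    """Interior local minima of alpha with sufficient prominence.

    A minimum qualifies when it sits at least ``prominence`` below the lower
    of its two neighbouring maxima (band edges count as maxima).  The plateau
    modulus G0 is G' evaluated at the minimum.  Ties break toward lower
    omega.
    """
    omega = alpha_curve.omega
    a = np.asarray(alpha_curve.alpha, dtype=float)
    valid = np.asarray(spectrum.valid, dtype=bool)
    idx = np.nonzero(valid)[0]
    if len(idx) < 3:
        return []
    lo_i, hi_i = idx[0], idx[-1]
    a_band = a[lo_i : hi_i + 1]
    n = len(a_band)

    minima = []
    for i in range(1, n - 1):
        if a_band[i] < a_band[i - 1] and a_band[i] <= a_band[i + 1]:
            minima.append(i)
    out: List[Plateau] = []
    for i in minima:
        left_max = a_band[:i].max()
        right_max = a_band[i + 1 :].max()
        if min(left_max, right_max) - a_band[i] >= prominence:
            gi = lo_i + i
            out.append(
                Plateau(
                    omega=float(omega[gi]),
                    modulus=float(spectrum.g_storage[gi]),
                    alpha_min=float(a_band[i]),
                )
            )
    # suppress shoulder minima of the same basin: keep the deeper of any two
    # plateaus not separated by an intervening rise of >= prominence
    pruned: List[Plateau] = []
    for pl in out:
        if pruned:
            prev = pruned[-1]
            i0 = np.searchsorted(omega, prev.omega)
            i1 = np.searchsorted(omega, pl.omega)
            ridge = a[i0 : i1 + 1].max()
            if ridge - max(prev.alpha_min, pl.alpha_min) < prominence:
                if pl.alpha_min < prev.alpha_min:
                    pruned[-1] = pl
                continue
        pruned.append(pl)
    return pruned


def fit_power_laws(
    spectrum, regime_intervals: Sequence[Tuple[float, float]]
) -> Tuple[List[PowerLawFit], List[PowerLawFit]]:
    """Per-interval log-log slopes of G'' (gamma_k) and |G*| (alpha_k).

    Each fit is an ordinary least-squares line of log10(modulus) against
    log10(omega) over the grid points inside the interval, with the standard
    error of the slope.
    """
    gamma_fits: List[PowerLawFit] = []
    alpha_fits: List[PowerLawFit] = []
    omega = np.asarray(spectrum.omega, dtype=float)
    for lo, hi in regime_intervals:
        sel = (omega >= lo) & (omega <= hi) & spectrum.valid
        if sel.sum() < 5:
            raise ValueError(
                f"interval ({lo:.3g}, {hi:.3g}) rad/s holds fewer than 5 grid points"
            )
        for name, vals, acc in (
            ("G_loss", spectrum.g_loss[sel], gamma_fits),
            ("G_mag", spectrum.g_mag[sel], alpha_fits),
        ):
            if np.any(vals <= 0):
                raise ValueError(f"{name} has non-positive values inside the interval")
            x = np.log10(omega[sel])
            y = np.log10(vals)
            slope, intercept, se = _linfit_with_stderr(x, y)
            acc.append(PowerLawFit(exponent=slope, stderr=se, omega_range=(lo, hi)))
    return gamma_fits, alpha_fits


def _linfit_with_stderr(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    n = len(x)
    xm = x - x.mean()
    sxx = np.dot(xm, xm)
    slope = np.dot(xm, y) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    dof = max(n - 2, 1)
    se = math.sqrt(np.dot(resid, resid) / dof / sxx)
    return float(slope), float(intercept), float(se)


def _hinge_fit(x: np.ndarray, y: np.ndarray, knots: Sequence[int]):
    """Least-squares continuous piecewise-linear fit with hinges at the
    given indices; returns (rss, slopes per segment)."""
    cols = [np.ones_like(x), x]
    for i in knots:
        cols.append(np.maximum(x - x[i], 0.0))
    A = np.column_stack(cols)
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    slopes = np.cumsum(coef[1:])
    return float(resid @ resid), slopes


def find_scaling_transition(
    spectrum,
    regime_interval: Tuple[float, float],
    min_slope_change: float = 0.1,
    settle_margin_decades: float = 0.0,
    min_segment_points: int = 8,
) -> ScalingTransition:
    """Locate the frequency where the G'' scaling law changes exponent.

    This is the inflection of the log-log derivative of G''.  Numerically
    differentiating a noisy 30-point/decade curve twice is hopeless, so the
    feature is located by fitting continuous broken power laws (0, 1 or 2
    breaks) to log G'' over the interval and selecting among them by BIC;
    the single-break model's hinge is the inflection.  A slope change below
    ``min_slope_change`` does not count as a break.  Returns omega_gamma
    when exactly one significant break wins; otherwise absent, with the
    number of significant breaks as the multiplicity.
    ``settle_margin_decades`` skips the leading part of the interval where
    G'' is still settling out of a plateau minimum.
    """
    omega = np.asarray(spectrum.omega, dtype=float)
    lo, hi = regime_interval
    lo_scan = lo * 10.0 ** settle_margin_decades
    sel = (omega >= lo_scan) & (omega <= hi) & spectrum.valid & (spectrum.g_loss > 0)
    n = int(sel.sum())
    if n < 3 * min_segment_points:
        return ScalingTransition(omega=None, multiplicity=0)
    x = np.log10(omega[sel])
    y = np.log10(spectrum.g_loss[sel])

    def bic(rss, n_params):
        return n * math.log(max(rss, 1e-30) / n) + n_params * math.log(n)

    rss0, _ = _hinge_fit(x, y, [])
    best = {"bic": bic(rss0, 2), "breaks": [], "slopes": None}

    cand = range(min_segment_points, n - min_segment_points)
    best1 = None
    for i in cand:
        rss, slopes = _hinge_fit(x, y, [i])
        if best1 is None or rss < best1[0]:
            best1 = (rss, [i], slopes)
    if best1 is not None:
        b = bic(best1[0], 4)
        if b < best["bic"]:
            best = {"bic": b, "breaks": best1[1], "slopes": best1[2]}

    best2 = None
    for i in cand:
        for j in range(i + min_segment_points, n - min_segment_points):
            rss, slopes = _hinge_fit(x, y, [i, j])
            if best2 is None or rss < best2[0]:
                best2 = (rss, [i, j], slopes)
    if best2 is not None:
        b = bic(best2[0], 6)
        if b < best["bic"]:
            best = {"bic": b, "breaks": best2[1], "slopes": best2[2]}

    if not best["breaks"]:
        return ScalingTransition(omega=None, multiplicity=0)
    slopes = best["slopes"]
    changes = [
        (x[idx], slopes[k + 1] - slopes[k])
        for k, idx in enumerate(best["breaks"])
        if abs(slopes[k + 1] - slopes[k]) >= min_slope_change
    ]
    # two nearby same-signed hinges are the piecewise-linear rendering of a
    # single smooth slope transition: merge them (position weighted by the
    # slope change carried by each hinge)
    merge_decades = 0.6
    merged: List[Tuple[float, float]] = []
    for pos, dslope in changes:
        if (
            merged
            and pos - merged[-1][0] <= merge_decades
            and merged[-1][1] * dslope > 0
        ):
            p0, d0 = merged[-1]
            tot = d0 + dslope
            merged[-1] = ((p0 * d0 + pos * dslope) / tot, tot)
        else:
            merged.append((pos, dslope))
    if len(merged) != 1:
        return ScalingTransition(omega=None, multiplicity=len(merged))
    return ScalingTransition(omega=float(10.0 ** merged[0][0]), multiplicity=1)


# ---------------------------------------------------------------------------
# regime segmentation
# ---------------------------------------------------------------------------


def _logmid(a: float, b: float) -> float:
    return 10.0 ** ((math.log10(a) + math.log10(b)) / 2.0)


def segment_regimes(
    alpha_curve,
    transitions: Sequence[Transition],
    plateaus: Sequence[Plateau],
    scaling_transitions: Sequence[ScalingTransition] = (),
    band: Optional[Tuple[float, float]] = None,
) -> List[Regime]:
    """Partition the valid band into labelled regimes.

    Plateaus anchor the even-numbered regimes (II, IV, ...); each is
    followed by an odd-numbered scaling regime and the band below the first
    plateau regime is regime I (which holds any fluid/solid transition).
    Boundaries fall at log-omega midpoints between adjacent features; where
    no transition separates consecutive plateaus (or a plateau from the band
    edge), the gap is split at one-third/two-thirds in log omega so a
    scaling regime always follows the plateau.  An omega_gamma inside a
    scaling regime splits it into sub-labels a/b.
    """
    omega = alpha_curve.omega
    lo_band = band[0] if band else float(omega[0])
    hi_band = band[1] if band else float(omega[-1])
    tr_freqs = sorted(t.omega for t in transitions if lo_band < t.omega < hi_band)
    pl_freqs = sorted(p.omega for p in plateaus if lo_band < p.omega < hi_band)
    splits = sorted(st.omega for st in scaling_transitions if st.omega is not None)

    if not pl_freqs:
        return [Regime(label="I", omega_lo=lo_band, omega_hi=hi_band, kind="initial")]

    def boundary(w_lo: float, w_hi: float, frac: float, side: str) -> float:
        """Boundary inside (w_lo, w_hi): log-midpoint to the nearest
        intervening transition when one exists, else the log-``frac`` point
        of the gap.  ``side`` names which end is the plateau."""
        between = [t for t in tr_freqs if w_lo < t < w_hi]
        if between:
            if side == "hi_of_plateau":  # plateau sits at w_lo
                return _logmid(w_lo, min(between))
            return _logmid(max(between), w_hi)  # plateau sits at w_hi
        return 10.0 ** (
            math.log10(w_lo) + frac * (math.log10(w_hi) - math.log10(w_lo))
        )

    # plateau regime edges
    edges: List[Tuple[float, float]] = []
    for i, w0 in enumerate(pl_freqs):
        prev = pl_freqs[i - 1] if i else lo_band
        nxt = pl_freqs[i + 1] if i + 1 < len(pl_freqs) else hi_band
        lo_frac = 2.0 / 3.0 if i else 0.5
        lo_edge = boundary(prev, w0, lo_frac, "lo_of_plateau")
        hi_edge = boundary(w0, nxt, 1.0 / 3.0, "hi_of_plateau")
        edges.append((lo_edge, hi_edge))

    regimes: List[Regime] = []
    counter = 1
    if edges[0][0] > lo_band * (1 + 1e-12):
        regimes.append(Regime("I", lo_band, edges[0][0], "initial"))
    counter = 2

    def add(label_num: int, lo: float, hi: float, kind: str) -> None:
        label = _ROMAN[label_num - 1] if label_num <= len(_ROMAN) else str(label_num)
        if kind == "scaling":
            inner = [w for w in splits if lo < w < hi]
            if len(inner) == 1:
                regimes.append(Regime(label + "a", lo, inner[0], "scaling"))
                regimes.append(Regime(label + "b", inner[0], hi, "scaling"))
                return
        regimes.append(Regime(label, lo, hi, kind))

    for i, (lo_edge, hi_edge) in enumerate(edges):
        add(counter, lo_edge, hi_edge, "plateau")
        counter += 1
        next_lo = edges[i + 1][0] if i + 1 < len(edges) else hi_band
        if next_lo > hi_edge * (1 + 1e-12):
            add(counter, hi_edge, next_lo, "scaling")
        counter += 1

    # plateau labels propagate onto the plateau records
    pl_regs = [r for r in regimes if r.kind == "plateau"]
    for pl, reg in zip(sorted(plateaus, key=lambda p: p.omega), pl_regs):
        pl.label = reg.label
    return regimes


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def extract_spectro_params(
    spectrum,
    alpha_curve,
    prominence: float = PLATEAU_PROMINENCE,
    band: Optional[Tuple[float, float]] = None,
) -> SpectroParams:
    """Full fingerprint extraction: features, regimes and per-regime fits.

    Loss-modulus power laws are fitted between each plateau and the next
    feature (or band edge), shrunk by one grid step at each side to avoid
    curvature contamination.
    """
    omega = np.asarray(spectrum.omega, dtype=float)
    valid = np.asarray(spectrum.valid, dtype=bool)
    if band is None:
        vi = np.nonzero(valid)[0]
        if len(vi) == 0:
            raise ValueError("spectrum has no valid points")
        band = (float(omega[vi[0]]), float(omega[vi[-1]]))

    transitions = find_transitions(alpha_curve)
    plateaus = find_plateaus(spectrum, alpha_curve, prominence)

    step = omega[1] / omega[0]  # log-uniform grid ratio

    # search the stretch above each plateau (up to the next feature) for a
    # change of the G'' scaling exponent; anchoring at the plateau keeps the
    # settle margin meaningful
    main_feats = sorted(
        [t.omega for t in transitions] + [p.omega for p in plateaus] + [band[1]]
    )
    scaling_transitions: List[ScalingTransition] = []
    for pl in sorted(plateaus, key=lambda p: p.omega):
        hi = min(f for f in main_feats if f > pl.omega)
        st = find_scaling_transition(
            spectrum, (pl.omega, hi), settle_margin_decades=0.5
        )
        scaling_transitions.append(st)
    regimes = segment_regimes(
        alpha_curve, transitions, plateaus, scaling_transitions, band=band
    )

    # power-law fits: anchored at each plateau (G'' rises from its minimum
    # at omega0), running to the next feature, split at omega_gamma.  The
    # ends adjoining omega0 / omega_gamma get a settle margin so blending
    # curvature does not contaminate the slopes.
    settle = 10.0 ** 0.3
    features = sorted(
        [t.omega for t in transitions] + [p.omega for p in plateaus] + [band[1]]
    )
    scaling_regs = [r for r in regimes if r.kind == "scaling"]
    loss_fits: List[PowerLawFit] = []
    mag_fits: List[PowerLawFit] = []
    reg_idx = 0
    for pl in sorted(plateaus, key=lambda p: p.omega):
        hi = min(f for f in features if f > pl.omega)
        inner = [
            st.omega for st in scaling_transitions
            if st.omega is not None and pl.omega < st.omega < hi
        ]
        cuts = [pl.omega] + inner + [hi]
        for j in range(len(cuts) - 1):
            lo_fit = cuts[j] * (settle if j == 0 or inner else step)
            hi_fit = cuts[j + 1] / (settle if j + 1 <= len(inner) else step)
            sel = (omega >= lo_fit) & (omega <= hi_fit) & valid
            if sel.sum() < 5:  # margin too aggressive for a short segment
                lo_fit, hi_fit = cuts[j] * step, cuts[j + 1] / step
                sel = (omega >= lo_fit) & (omega <= hi_fit) & valid
                if sel.sum() < 5:
                    continue
            label = (
                scaling_regs[reg_idx].label if reg_idx < len(scaling_regs) else ""
            )
            reg_idx += 1
            gfits, afits = fit_power_laws(spectrum, [(lo_fit, hi_fit)])
            gfits[0].label = label
            afits[0].label = label
            loss_fits.append(gfits[0])
            mag_fits.append(afits[0])

    return SpectroParams(
        transitions=transitions,
        plateaus=plateaus,
        loss_exponents=loss_fits,
        magnitude_exponents=mag_fits,
        scaling_transitions=scaling_transitions,
        regimes=regimes,
        spread_method="single measurement",
    )
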