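"""Statistics for orientation distributions, division-angle weighting,
daughter-separation dynamics, and diffusion coefficients.

Conventions:

* Long-axis orientation distributions are histogrammed on [0, pi/2], mirrored
  about pi/2 to cover [0, pi], normalized to unit integral, and divided by the
  isotropic 3D reference P_iso(theta) = sin(theta)/2 so that an isotropic
  sample gives P/P_iso = 1 everywhere.
* Division angles are grouped as planar [0, pi/6], oblique (pi/6, pi/3],
  perpendicular (pi/3, pi/2]; stage weights are the normalized fractions.
* The daughter-separation statistic follows the division-event ensemble: for
  each event, s(t) = r_d1(t) - r_d2(t) (minimal image, unwrapped in time),
  Delta_s(t) = s(t) - s(t0), and Dd2(t) = <|Delta_s|^2> averaged over events
  at fixed time-since-division (no time-window averaging).
* The effective diffusion coefficient D is the raw slope of Dd2 vs t on the
  late-time window (no dimensional prefactor), with uncertainties from
  independent subgroup estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLANAR, OBLIQUE, PERPENDICULAR = "planar", "oblique", "perpendicular"
BIN_LABELS = (PLANAR, OBLIQUE, PERPENDICULAR)

#: observed division-orientation fractions per developmental stage
#: (planar, oblique, perpendicular)
STAGE_FRACTIONS = {
    "E14": (0.20, 0.25, 0.55),
    "E16": (0.60, 0.25, 0.15),
}


@dataclass
class AngleDistribution:
    edges: np.ndarray          # on [0, pi]
    density: np.ndarray        # normalized P(theta)
    iso: np.ndarray            # P_iso(theta) per bin
    ratio: np.ndarray          # P / P_iso
    peak: float
    anisotropy_ratio: float
    fwhm: float                # radians, of the ratio curve

    @property
    def centers(self):
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class DivisionAngleWeights:
    fractions: np.ndarray
    weights: np.ndarray        # normalized, sums to 1

    def __getitem__(self, label: str) -> float:
        return float(self.weights[BIN_LABELS.index(label)])

    @classmethod
    def for_stage(cls, stage: str) -> "DivisionAngleWeights":
        return division_angle_weights(STAGE_FRACTIONS[stage.upper()])


def division_angle_weights(fractions) -> DivisionAngleWeights:
    """Normalize observed orientation-bin fractions into weights W_i = f_i / sum f."""
    f = np.asarray(fractions, dtype=float)
    if (f < 0).any() or f.sum() <= 0:
        raise ValueError("fractions must be nonnegative and not all zero")
    return DivisionAngleWeights(fractions=f, weights=f / f.sum())


def classify_division_angle(theta: float) -> str:
    """Bin a division angle: planar [0, pi/6], oblique (pi/6, pi/3],
    perpendicular (pi/3, pi/2]."""
    if not 0.0 <= theta <= np.pi / 2 + 1e-12:
        raise ValueError("theta outside [0, pi/2]")
    if theta <= np.pi / 6:
        return PLANAR
    if theta <= np.pi / 3:
        return OBLIQUE
    return PERPENDICULAR


def long_axis_distribution(theta_samples, n_bins: int = 18) -> AngleDistribution:
    """Mirrored, isotropic-normalized distribution of long-axis angles.

    Input samples lie in [0, pi/2]; the histogram is mirrored about pi/2,
    normalized to unit integral over [0, pi], and divided by
    P_iso = sin(theta)/2.  Metrics: peak of the ratio curve, max/min
    anisotropy ratio, and FWHM about the global peak (linear interpolation).
    """
    th = np.asarray(theta_samples, dtype=float)
    if len(th) == 0:
        raise ValueError("no samples")
    if (th < -1e-9).any() or (th > np.pi / 2 + 1e-9).any():
        raise ValueError("samples must lie in [0, pi/2]")
    full = np.concatenate([th, np.pi - th])
    edges = np.linspace(0.0, np.pi, 2 * n_bins + 1)
    counts, _ = np.histogram(full, bins=edges)
    width = edges[1] - edges[0]
    density = counts / counts.sum() / width
    centers = 0.5 * (edges[:-1] + edges[1:])
    iso = 0.5 * np.sin(centers)
    ratio = np.where(iso > 0, density / iso, 0.0)
    peak = float(ratio.max())
    rmin = float(ratio.min())
    aniso = np.inf if rmin == 0 else peak / rmin
    fwhm = _fwhm(centers, ratio)
    return AngleDistribution(edges=edges, density=density, iso=iso, ratio=ratio,
                             peak=peak, anisotropy_ratio=float(aniso), fwhm=fwhm)


def _fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum about the global peak, linearly interpolated.

    When the curve never falls below half maximum on one side, the distance
    to the domain edge is used for that side.
    """
    k = int(np.argmax(y))
    half = 0.5 * y[k]
    left = x[0]
    for i in range(k, 0, -1):
        if y[i - 1] <= half:
            frac = (y[i] - half) / max(y[i] - y[i - 1], 1e-30)
            left = x[i] - frac * (x[i] - x[i - 1])
            break
    right = x[-1]
    for i in range(k, len(y) - 1):
        if y[i + 1] <= half:
            frac = (y[i] - half) / max(y[i] - y[i + 1], 1e-30)
            right = x[i] + frac * (x[i + 1] - x[i])
            break
    return float(right - left)


# ---------------------------------------------------------------------------
# Daughter separation and diffusion
# ---------------------------------------------------------------------------

@dataclass
class SeparationTrace:
    """Ensemble of per-event squared separation changes vs time since division."""

    times: np.ndarray          # common time-since-division grid
    dd2: np.ndarray            # (n_events, n_times), NaN once censored
    event_ids: np.ndarray

    def mean(self):
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dd2, axis=0)

    def n_alive(self):
        return np.isfinite(self.dd2).sum(axis=0)


def daughter_separation(events: pd.DataFrame, trajectories: pd.DataFrame,
                        box, basal_code: int = 1,
                        max_lag: float | None = None) -> SeparationTrace:
    """Daughter-daughter squared separation Dd2(t) per division event.

    ``events`` needs columns (t0, d1, d2); ``trajectories`` needs
    (time, cell, x, y, z, type) sampled on a regular grid.  Separation
    vectors use the minimal image and are unwrapped continuously in time;
    an event is censored from the first sample where either daughter is no
    longer basal (or disappears).
    """
    tgrid = np.unique(trajectories["time"].values)
    if len(tgrid) < 2:
        raise ValueError("need at least two trajectory frames")
    dt_frame = np.min(np.diff(tgrid))
    by_cell = {c: g.sort_values("time") for c, g in trajectories.groupby("cell")}
    rows = []
    ev_ids = []
    n_lag = len(tgrid)
    if max_lag is not None:
        n_lag = min(n_lag, int(round(max_lag / dt_frame)) + 1)
    lag_times = np.arange(n_lag) * dt_frame
    for ev_i, ev in events.iterrows():
        g1 = by_cell.get(ev["d1"])
        g2 = by_cell.get(ev["d2"])
        if g1 is None or g2 is None:
            continue
        m = pd.merge(g1, g2, on="time", suffixes=("_1", "_2"))
        m = m[m["time"] >= ev["t0"] - 1e-9]
        if len(m) == 0:
            continue
        alive = (m["type_1"].values == basal_code) & (m["type_2"].values == basal_code)
        ncensor = int(np.argmin(alive)) if not alive.all() else len(alive)
        if ncensor == 0:
            continue
        p1 = m[["x_1", "y_1", "z_1"]].values[:ncensor]
        p2 = m[["x_2", "y_2", "z_2"]].values[:ncensor]
        s_raw = p1 - p2
        # unwrap in time: s(0) by minimal image, then continuity
        s = np.empty_like(s_raw)
        s[0] = box.minimal_image(s_raw[0])
        for k in range(1, len(s_raw)):
            s[k] = s[k - 1] + box.minimal_image(s_raw[k] - s_raw[k - 1])
        ds = s - s[0]
        dd2 = (ds ** 2).sum(axis=1)
        row = np.full(n_lag, np.nan)
        n = min(len(dd2), n_lag)
        row[:n] = dd2[:n]
        rows.append(row)
        ev_ids.append(ev_i)
    if not rows:
        raise ValueError("no usable division events")
    return SeparationTrace(times=lag_times, dd2=np.array(rows),
                           event_ids=np.array(ev_ids))


def bin_with_bootstrap(trace: SeparationTrace, bin_width: float,
                       n_subgroups: int = 5, rng=None):
    """Bin Dd2 into time intervals; subgroup-based standard errors.

    Events are partitioned into ``n_subgroups`` equal subgroups (the ensemble
    size must divide evenly); the per-bin error is the standard deviation of
    the subgroup means divided by sqrt(n_subgroups).
    Returns DataFrame (t, mean, err, n).
    """
    n_ev = trace.dd2.shape[0]
    if n_ev % n_subgroups:
        raise ValueError(f"{n_ev} events do not divide into {n_subgroups} subgroups")
    perm = (np.random.default_rng(0) if rng is None else rng).permutation(n_ev)
    groups = perm.reshape(n_subgroups, -1)
    edges = np.arange(0.0, trace.times[-1] + bin_width, bin_width)
    idx = np.digitize(trace.times, edges) - 1
    out = []
    for b in range(len(edges) - 1):
        cols = idx == b
        if not cols.any():
            continue
        vals = trace.dd2[:, cols]
        finite = np.isfinite(vals)
        if not finite.any():
            out.append({"t": 0.5 * (edges[b] + edges[b + 1]), "mean": np.nan,
                        "err": np.nan, "n": 0})
            continue
        mean = float(np.nanmean(vals))
        with np.errstate(invalid="ignore"):
            sub_means = np.array([np.nanmean(vals[g]) for g in groups])
        ok = np.isfinite(sub_means)
        err = float(np.std(sub_means[ok]) / np.sqrt(n_subgroups)) if ok.sum() > 1 else np.nan
        out.append({"t": 0.5 * (edges[b] + edges[b + 1]), "mean": mean,
                    "err": err, "n": int(finite.sum())})
    return pd.DataFrame(out), groups


def fit_diffusion(binned: pd.DataFrame, window: tuple[float, float],
                  trace: SeparationTrace | None = None,
                  groups: np.ndarray | None = None,
                  bin_width: float | None = None,
                  fallback_all: bool = False):
    """Effective diffusion coefficient: slope of the unweighted linear fit of
    Dd2 vs t on the window.  With subgroup info, the uncertainty is the
    standard deviation of per-subgroup slopes.

    With ``fallback_all`` the fit falls back to every finite bin when the
    requested window is fully censored (heavily stratifying ensembles).
    """
    sel = binned[(binned["t"] >= window[0]) & (binned["t"] <= window[1])
                 & np.isfinite(binned["mean"])]
    if len(sel) < 3 and fallback_all:
        sel = binned[np.isfinite(binned["mean"])]
        window = (float(binned["t"].min()), float(binned["t"].max()))
    if len(sel) < 3:
        raise ValueError("fewer than 3 bins in the fit window")
    D = float(np.polyfit(sel["t"], sel["mean"], 1)[0])
    D_err = np.nan
    if trace is not None and groups is not None:
        slopes = []
        for g in groups:
            sub = SeparationTrace(times=trace.times, dd2=trace.dd2[g],
                                  event_ids=trace.event_ids[g])
            t = sub.times
            m = sub.mean()
            ok = np.isfinite(m) & (t >= window[0]) & (t <= window[1])
            if ok.sum() >= 3:
                slopes.append(np.polyfit(t[ok], m[ok], 1)[0])
        if len(slopes) > 1:
            D_err = float(np.std(slopes))
    return D, D_err


def msd_exponent(binned: pd.DataFrame, window: tuple[float, float],
                 subdiffusive_below: float = 0.8,
                 diffusive_band: tuple[float, float] = (0.8, 1.2),
                 fallback_all: bool = False):
    """Log-log slope of Dd2 vs t on the window; classifies the dynamics."""
    sel = binned[(binned["t"] >= window[0]) & (binned["t"] <= window[1])
                 & np.isfinite(binned["mean"])]
    if len(sel) < 3 and fallback_all:
        sel = binned[np.isfinite(binned["mean"]) & (binned["mean"] > 0)
                     & (binned["t"] > 0)]
    if (sel["mean"] <= 0).any() or (sel["t"] <= 0).any():
        raise ValueError("nonpositive values in log-log window")
    if len(sel) < 3:
        raise ValueError("fewer than 3 bins in the fit window")
    expo = float(np.polyfit(np.log(sel["t"]), np.log(sel["mean"]), 1)[0])
    if expo < subdiffusive_below:
        label = "subdiffusive"
    elif diffusive_band[0] <= expo <= diffusive_band[1]:
        label = "diffusive"
    else:
        label = "superdiffusive"
    return expo, label


def default_fit_window(times: np.ndarray, late_fraction: float = 0.4):
    """Late-time window covering the last `late_fraction` of available lags."""
    t_max = float(times[-1])
    return ((1.0 - late_fraction) * t_max, t_max)


def orientation_weighted_average(values_by_angle: dict,
                                 weights: DivisionAngleWeights):
    """<X> = sum_theta W(theta) X(theta); spread is the (unweighted) standard
    deviation of the mean over the orientation angles."""
    vals = []
    for label in BIN_LABELS:
        if label not in values_by_angle or values_by_angle[label] is None:
            raise ValueError(f"missing value for bin {label!r}")
        vals.append(float(values_by_angle[label]))
    vals = np.array(vals)
    mean = float((weights.weights * vals).sum())
    spread = float(np.std(vals) / np.sqrt(len(vals)))
    return mean, spread
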