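"""Tabular post-processing of segmented FLS records and trajectories.

Records arrive as a tidy DataFrame, one row per structure per frame, with
columns ``fov``, ``structure_id``, ``frame``, ``x_um``, ``y_um``,
``base_area_um2``, ``length_um``, ``straightness`` and one
``intensity_<channel>`` column per imaged channel (background-corrected;
negative values are preserved, ranks are unaffected).  All grouping
statistics (Spearman matrices, enrichment thresholds, cohort percentiles)
are computed per field of view and then averaged, so uneven illumination
between fields never enters a pooled statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.base import BaseEstimator

__all__ = [
    "effective_diameter",
    "filter_snapshots",
    "background_correct",
    "repair_tracks",
    "smooth_velocity",
    "spearman_matrix",
    "CorrelationMatrix",
    "enrichment_length_change",
    "cohort_ecdf",
    "cross_correlate",
    "ShaftProfileFit",
    "shaft_profile_fit",
]

MERGE_DISTANCE_UM = 1.0
MERGE_MAX_GAP_FRAMES = 6
MIN_EFFECTIVE_DIAMETER_UM = 0.5
LENGTH_TRUNCATION_UM = (5.0, 20.0)


def effective_diameter(base_area_um2) -> np.ndarray:
    """Diameter of the circle with the given area: 2*sqrt(A/pi)."""
    return 2.0 * np.sqrt(np.asarray(base_area_um2, dtype=float) / np.pi)


def filter_snapshots(
    records: pd.DataFrame,
    min_diameter: float = MIN_EFFECTIVE_DIAMETER_UM,
    length_bounds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Drop unreliable segmented structures.

    Structures with effective base diameter < ``min_diameter`` (strict) are
    always removed — base morphology and intensity are unreliable at or
    below the resolution limit.  ``length_bounds`` additionally truncates to
    a closed length window; pass ``LENGTH_TRUNCATION_UM`` for
    length-distribution analyses, leave ``None`` otherwise.
    """
    required = {"base_area_um2", "length_um"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing required columns: {sorted(missing)}")
    diam = effective_diameter(records["base_area_um2"])
    keep = diam >= min_diameter
    if length_bounds is not None:
        lo, hi = length_bounds
        keep &= (records["length_um"] >= lo) & (records["length_um"] <= hi)
    return records.loc[keep].copy()


def background_correct(raw_intensity, ring_mean) -> np.ndarray:
    """Local-background correction: base mean minus surrounding ring mean.

    The ring mean comes from an annulus two to three times the base size
    with neighbouring bases excluded (see ``imaging.measure_fls``).  A NaN
    ring mean (ring fully occluded) propagates to a NaN corrected value.
    """
    return np.asarray(raw_intensity, dtype=float) - np.asarray(ring_mean, dtype=float)


def _track_summary(df: pd.DataFrame) -> pd.DataFrame:
    g = df.groupby("track_id")
    out = pd.DataFrame(
        {
            "start": g["frame"].min(),
            "end": g["frame"].max(),
            "x": g["x_um"].mean(),
            "y": g["y_um"].mean(),
        }
    )
    return out


def repair_tracks(
    tracks: pd.DataFrame,
    max_distance_um: float = MERGE_DISTANCE_UM,
    max_gap_frames: int = MERGE_MAX_GAP_FRAMES,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Merge track fragments produced by segmentation dropouts.

    Fragment pairs whose lifetime-average base positions are closer than
    ``max_distance_um``, whose frame ranges do not overlap and are separated
    by at most ``max_gap_frames``, are merged greedily in ascending distance
    order; a merged track keeps the earlier fragment's id.  Returns the
    repaired table and the {old_id: new_id} mapping.
    """
    df = tracks.copy()
    parent = {tid: tid for tid in df["track_id"].unique()}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    summ = _track_summary(df)
    ids = summ.index.to_numpy()
    cands = []
    for a, b in itertools.combinations(ids, 2):
        ra, rb = summ.loc[a], summ.loc[b]
        d = float(np.hypot(ra.x - rb.x, ra.y - rb.y))
        if d >= max_distance_um:
            continue
        cands.append((d, a, b))
    cands.sort()

    spans = {t: (summ.loc[t, "start"], summ.loc[t, "end"]) for t in ids}
    members: dict[int, list] = {t: [t] for t in ids}

    def gates_ok(ta, tb):
        sa, ea = spans[ta]
        sb, eb = spans[tb]
        if sa > sb:
            (sa, ea), (sb, eb) = (sb, eb), (sa, ea)
        missing = sb - ea - 1  # frames with neither fragment present
        return 0 <= missing <= max_gap_frames

    for d, a, b in cands:
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        if not gates_ok(ra, rb):
            continue
        keep, drop = (ra, rb) if ra <= rb else (rb, ra)
        parent[drop] = keep
        spans[keep] = (
            min(spans[keep][0], spans[drop][0]),
            max(spans[keep][1], spans[drop][1]),
        )
        members[keep].extend(members.pop(drop))

    mapping = {t: find(t) for t in ids}
    df["track_id"] = df["track_id"].map(mapping)
    return df, mapping


def smooth_velocity(
    lengths,
    frame_interval_min: float = 1.0,
    window: int = 11,
    order: int = 3,
) -> dict:
    """Savitzky–Golay smoothing of a length series plus its derivative.

    Returns smoothed lengths and velocities in µm/min.  Series shorter than
    the window are returned unsmoothed with ``flagged=True`` (velocity by
    plain finite differences).
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < window:
        return {
            "smoothed": x.copy(),
            "velocity": np.gradient(x, frame_interval_min) if x.size > 1 else np.zeros_like(x),
            "flagged": True,
        }
    sm = signal.savgol_filter(x, window, order)
    vel = signal.savgol_filter(x, window, order, deriv=1, delta=frame_interval_min)
    return {"smoothed": sm, "velocity": vel, "flagged": False}


@dataclass
class CorrelationMatrix:
    labels: list[str]
    mean: pd.DataFrame  # mean Spearman across fovs
    per_fov: dict  # (var_a, var_b) -> list of per-fov values
    n_fov: pd.DataFrame  # contributing fov count per cell


def spearman_matrix(
    records: pd.DataFrame, variables: list[str], fov_col: str = "fov", min_records: int = 3
) -> CorrelationMatrix:
    """Spearman correlations computed per field of view, then averaged.

    A fov contributes to a cell only if it holds >= ``min_records`` rows and
    neither variable is constant within it (rank correlation undefined).
    """
    k = len(variables)
    per_fov: dict = {}
    mean = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    groups = [g for _, g in records.groupby(fov_col) if len(g) >= min_records]
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if j < i:
                continue
            vals = []
            for g in groups:
                xa, xb = g[a].to_numpy(float), g[b].to_numpy(float)
                if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                    continue
                if i == j:
                    vals.append(1.0)
                else:
                    vals.append(float(stats.spearmanr(xa, xb).statistic))
            per_fov[(a, b)] = vals
            if vals:
                mean[i, j] = mean[j, i] = float(np.mean(vals))
                nmat[i, j] = nmat[j, i] = len(vals)
    return CorrelationMatrix(
        labels=list(variables),
        mean=pd.DataFrame(mean, index=variables, columns=variables),
        per_fov=per_fov,
        n_fov=pd.DataFrame(nmat, index=variables, columns=variables),
    )


def _enriched_mask(g: pd.DataFrame, channels: list[str]) -> pd.DataFrame:
    """Per-record top-half membership for each channel within one fov."""
    out = {}
    for ch in channels:
        x = g[ch].to_numpy(float)
        med = np.median(x)
        out[ch] = x > med
    return pd.DataFrame(out, index=g.index)


def enrichment_length_change(
    records: pd.DataFrame,
    channels: list[str],
    fov_col: str = "fov",
    scope: str = "per-fov",
) -> pd.DataFrame:
    """Relative length change by number of simultaneously enriched channels.

    A channel is "enriched" in a record when its background-corrected
    intensity lies in the top half of that channel's values (within the
    record's field of view by default; ``scope="global"`` uses pooled
    thresholds).  Within each fov, records are bucketed by enriched-channel
    count and each bucket's relative change is its mean length over the fov
    mean length, minus 1.  Buckets are then averaged across fovs with a 95%
    t-interval of the mean.

    Returns a DataFrame indexed by enriched-channel count with columns
    ``rel_change``, ``ci_low``, ``ci_high``, ``n_fov``, ``n_records``.
    """
    if len(channels) < 2:
        raise ValueError("need >= 2 channels")
    if scope not in {"per-fov", "global"}:
        raise ValueError("scope must be 'per-fov' or 'global'")
    max_k = len(channels)
    per_bucket: dict[int, list[float]] = {k: [] for k in range(max_k + 1)}
    counts = {k: 0 for k in range(max_k + 1)}
    if scope == "global":
        global_mask = _enriched_mask(records, channels)
    for _, g in records.groupby(fov_col):
        if scope == "per-fov":
            mask = _enriched_mask(g, channels)
        else:
            mask = global_mask.loc[g.index]
        n_enriched = mask.sum(axis=1)
        fov_mean = g["length_um"].mean()
        for k in range(max_k + 1):
            sel = g.loc[n_enriched == k, "length_um"]
            counts[k] += len(sel)
            if len(sel) == 0:
                continue  # empty bucket excluded from this fov's average
            per_bucket[k].append(float(sel.mean() / fov_mean - 1.0))
    rows = []
    for k in range(max_k + 1):
        vals = np.asarray(per_bucket[k])
        if vals.size == 0:
            rows.append((k, np.nan, np.nan, np.nan, 0, counts[k]))
            continue
        m = vals.mean()
        if vals.size > 1:
            half = stats.t.ppf(0.975, vals.size - 1) * vals.std(ddof=1) / np.sqrt(vals.size)
        else:
            half = np.nan
        rows.append((k, m, m - half, m + half, vals.size, counts[k]))
    return pd.DataFrame(
        rows, columns=["n_enriched", "rel_change", "ci_low", "ci_high", "n_fov", "n_records"]
    ).set_index("n_enriched")


def two_plus_enrichment_effect(
    records: pd.DataFrame, channels: list[str], fov_col: str = "fov"
) -> float:
    """Mean length of >=2-enriched records over <=1-enriched records, minus 1.

    Computed per fov and averaged, matching the headline comparison of
    multiply enriched structures against those with none or one enriched
    regulator.
    """
    vals = []
    for _, g in records.groupby(fov_col):
        mask = _enriched_mask(g, channels)
        n_enriched = mask.sum(axis=1)
        hi = g.loc[n_enriched >= 2, "length_um"]
        lo = g.loc[n_enriched <= 1, "length_um"]
        if len(hi) == 0 or len(lo) == 0:
            continue
        vals.append(float(hi.mean() / lo.mean() - 1.0))
    if not vals:
        raise ValueError("no fov with both cohorts populated")
    return float(np.mean(vals))


def _ecdf(x: np.ndarray):
    xs = np.sort(x)
    return xs, np.arange(1, xs.size + 1) / xs.size


def cohort_ecdf(
    records: pd.DataFrame,
    channel_a: str,
    channel_b: str,
    hi_pct: float = 70.0,
    lo_pct: float = 30.0,
    fov_col: str = "fov",
) -> dict:
    """Length ECDFs for all records vs both-high vs both-low cohorts.

    Percentile thresholds (linear interpolation between order statistics)
    are computed per field of view.  A cohort below 10 records is still
    returned, flagged ``low_n``.
    """
    for c in (channel_a, channel_b):
        if c not in records.columns:
            raise ValueError(f"missing channel column {c!r}")
    hi_rows, lo_rows = [], []
    for _, g in records.groupby(fov_col):
        ta_hi, tb_hi = (np.percentile(g[c], hi_pct) for c in (channel_a, channel_b))
        ta_lo, tb_lo = (np.percentile(g[c], lo_pct) for c in (channel_a, channel_b))
        hi_rows.append(g[(g[channel_a] > ta_hi) & (g[channel_b] > tb_hi)])
        lo_rows.append(g[(g[channel_a] < ta_lo) & (g[channel_b] < tb_lo)])
    both_hi = pd.concat(hi_rows) if hi_rows else records.iloc[0:0]
    both_lo = pd.concat(lo_rows) if lo_rows else records.iloc[0:0]
    out = {}
    for name, df in (("all", records), ("both_high", both_hi), ("both_low", both_lo)):
        lengths = df["length_um"].to_numpy(float)
        x, f = _ecdf(lengths) if lengths.size else (np.array([]), np.array([]))
        out[name] = {"x": x, "ecdf": f, "n": int(lengths.size), "low_n": lengths.size < 10}
    return out


def cross_correlate(
    velocity_series: list,
    intensity_series: list,
    max_shift: int = 10,
) -> pd.DataFrame:
    """Mean cross-correlation of |velocity| with shifted intensity.

    For every trajectory, the Pearson correlation of |v(t)| with I(t + s) is
    computed at integer-frame shifts s in [-max_shift, max_shift]; negative
    shifts mean intensity changes precede velocity changes.  Trajectories
    are averaged unweighted with a 95% t-interval; a trajectory contributes
    only at shifts it fully covers (and is skipped if shorter than
    2*max_shift + 2).
    """
    shifts = np.arange(-max_shift, max_shift + 1)
    per_shift: list[list[float]] = [[] for _ in shifts]
    for v, inten in zip(velocity_series, intensity_series, strict=True):
        v = np.abs(np.asarray(v, dtype=float))
        inten = np.asarray(inten, dtype=float)
        if v.shape != inten.shape:
            raise ValueError("velocity and intensity series must be paired and equal length")
        if v.size < 2 * max_shift + 2:
            continue
        for k, s in enumerate(shifts):
            if s >= 0:
                a, b = v[: v.size - s], inten[s:]
            else:
                a, b = v[-s:], inten[: inten.size + s]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            per_shift[k].append(float(stats.pearsonr(a, b).statistic))
    rows = []
    for k, s in enumerate(shifts):
        vals = np.asarray(per_shift[k])
        if vals.size == 0:
            rows.append((s, np.nan, np.nan, np.nan, 0))
            continue
        m = vals.mean()
        half = (
            stats.t.ppf(0.975, vals.size - 1) * vals.std(ddof=1) / np.sqrt(vals.size)
            if vals.size > 1
            else np.nan
        )
        rows.append((s, m, m - half, m + half, vals.size))
    return pd.DataFrame(
        rows, columns=["shift", "correlation", "ci_low", "ci_high", "n"]
    ).set_index("shift")


class ShaftProfileFit(BaseEstimator):
    """Exponential or linear fit of an intensity/width profile along a shaft.

    ``kind="exponential"`` fits I(z) = I0 * exp(-z / decay_length) by
    log-linear least squares on the positive values; ``kind="linear"`` fits
    a straight line.  Confidence intervals (66% by default, matching how
    shaft decay lengths are reported) come from a resampled-residuals
    bootstrap.
    """

    def __init__(
        self,
        kind: str = "exponential",
        n_bootstrap: int = 200,
        ci_level: float = 0.66,
        seed: int = 0,
    ):
        self.kind = kind
        self.n_bootstrap = n_bootstrap
        self.ci_level = ci_level
        self.seed = seed

    def _fit_once(self, z, y):
        if self.kind == "exponential":
            slope, intercept = np.polyfit(z, np.log(y), 1)
            if slope >= 0:
                return np.inf, float(np.exp(intercept))
            return -1.0 / slope, float(np.exp(intercept))
        slope, intercept = np.polyfit(z, y, 1)
        return float(slope), float(intercept)

    def fit(self, X, y):
        if self.kind not in {"exponential", "linear"}:
            raise ValueError("kind must be 'exponential' or 'linear'")
        z = np.asarray(X, dtype=float).ravel()
        yv = np.asarray(y, dtype=float).ravel()
        if z.size != yv.size or z.size < 4:
            raise ValueError("need >= 4 paired samples")
        self.n_excluded_ = 0
        if self.kind == "exponential":
            pos = yv > 0
            self.n_excluded_ = int((~pos).sum())
            z, yv = z[pos], yv[pos]
            if z.size < 4:
                raise ValueError("fewer than 4 positive values for log-linear fit")
        param, intercept = self._fit_once(z, yv)
        # resampled-residuals bootstrap in the fitting space
        work = np.log(yv) if self.kind == "exponential" else yv
        coeffs = np.polyfit(z, work, 1)
        fitted = np.polyval(coeffs, z)
        resid = work - fitted
        rng = np.random.default_rng(self.seed)
        boot = []
        for _ in range(self.n_bootstrap):
            w = fitted + rng.choice(resid, size=resid.size, replace=True)
            s, _b = np.polyfit(z, w, 1)
            if self.kind == "exponential":
                boot.append(-1.0 / s if s < 0 else np.nan)
            else:
                boot.append(s)
        boot = np.asarray(boot)
        alpha = (1.0 - self.ci_level) / 2.0
        self.param_ = param  # decay length, or slope
        self.intercept_ = intercept
        self.ci_ = (
            float(np.nanquantile(boot, alpha)),
            float(np.nanquantile(boot, 1 - alpha)),
        )
        return self


def shaft_profile_fit(heights, values, kind: str = "exponential", **kw) -> dict:
    """Fit a shaft profile; returns param (decay length or slope) and CI."""
    est = ShaftProfileFit(kind=kind, **kw).fit(heights, values)
    return {
        "param": est.param_,
        "intercept": est.intercept_,
        "ci": est.ci_,
        "n_excluded": est.n_excluded_,
        "kind": kind,
    }
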