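"""Synthetic data generators with known ground truth.

Every input the analysis pipelines consume can be generated here:
OU-driven growth trajectory sets, per-field intensity tables with a planted
rank-correlation structure and enrichment effect, four-ROI FRAP traces,
3D rod-field z-stacks and 2D filament movies with ground-truth skeletons
and identities.  Each generator is a pure function of its parameters and a
seed, and returns a :class:`SyntheticScene` whose ``ground_truth`` record is
sufficient to compute the true value of every downstream statistic.

The generators emulate the statistical structure of the microscopy data
(marginals, rank correlations, timing protocols, planted defects), not its
optics: there is no camera shot-noise model and no illumination-profile
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .frap import FrapTrace
from .imaging import PIXEL_SIZE_UM
from .model import GrowthModelParams, LengthTrajectory, compose_force, simulate_length

__all__ = [
    "SyntheticScene",
    "gen_trajectory_set",
    "gen_intensity_table",
    "gen_frap_trace",
    "gen_rod_stack",
    "gen_filament_movie",
]

# exponential scales of the snapshot morphology marginals (µm, µm²)
LENGTH_SCALE_UM = 7.6
AREA_SCALE_UM2 = 1.07

# FRAP acquisition protocol: 5 prebleach frames at 1 s, then 40 recovery
# frames at 0.5 s followed by 80 at 1 s
FRAP_N_PREBLEACH = 5
FRAP_FAST_FRAMES = 40
FRAP_SLOW_FRAMES = 80


@dataclass
class SyntheticScene:
    """A generated dataset plus the ground truth that produced it."""

    kind: str
    data: dict[str, Any]
    ground_truth: dict[str, Any]
    seed: int


def gen_trajectory_set(
    params: GrowthModelParams,
    n_traj: int,
    initiation_window: float = 20.0,
    seed: int = 0,
) -> SyntheticScene:
    """Simulate ``n_traj`` length trajectories with random initiation times.

    Initiation times are uniform on [0, initiation_window] minutes; each
    trajectory runs the full OU -> sum-of-products -> length integration
    with its own child seed.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if initiation_window < 0:
        raise ValueError("initiation_window must be >= 0")
    if params.duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    init = rng.uniform(0.0, initiation_window, size=n_traj) if initiation_window > 0 else np.zeros(n_traj)
    init = np.minimum(init, params.duration * 0.999)
    child_seeds = rng.integers(0, 2**31, size=n_traj)
    trajectories = []
    for i in range(n_traj):
        traj = simulate_length(
            params.with_(seed=int(child_seeds[i])),
            initiation_time=float(init[i]),
            traj_id=f"sim-{i}",
        )
        trajectories.append(traj)
    return SyntheticScene(
        kind="trajectory_set",
        data={"trajectories": trajectories},
        ground_truth={
            "M": params.M,
            "N": params.N,
            "theta": params.theta,
            "eta": params.eta,
            "initiation_times": init,
            "seeds": child_seeds,
        },
        seed=seed,
    )


def _validate_rank_corr(rank_corr: np.ndarray) -> np.ndarray:
    r = np.asarray(rank_corr, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("rank_corr must be square")
    if not np.allclose(r, r.T):
        raise ValueError("rank_corr must be symmetric")
    if not np.allclose(np.diag(r), 1.0):
        raise ValueError("rank_corr must have unit diagonal")
    eig = np.linalg.eigvalsh(r)
    if eig.min() < -1e-10:
        raise ValueError(
            f"rank_corr is not positive semidefinite (min eigenvalue {eig.min():.3g})"
        )
    return r


def gen_intensity_table(
    n_fov: int,
    n_per_fov: int,
    rank_corr: np.ndarray,
    effect_two_plus: float = 0.0,
    seed: int = 0,
    channels: list[str] | None = None,
    length_scale_um: float = LENGTH_SCALE_UM,
) -> SyntheticScene:
    """Per-field FLS records with planted rank structure and length effect.

    Channel intensities are lognormal with a Gaussian-copula rank
    correlation ``rank_corr`` (Spearman scale); only the rank structure is
    controlled, matching how the correlations are reported.  Lengths are
    exponential with scale ``length_scale_um`` and are multiplied by
    (1 + effect_two_plus) for records whose intensity lies in the top half
    of >= 2 channels within their field of view.
    """
    r = _validate_rank_corr(rank_corr)
    k = r.shape[0]
    channels = channels or [f"ch{i}" for i in range(k)]
    if len(channels) != k:
        raise ValueError("channel list must match rank_corr size")
    # Gaussian copula: Pearson correlation reproducing the target Spearman
    pearson = 2.0 * np.sin(np.pi * r / 6.0)
    np.fill_diagonal(pearson, 1.0)
    chol = np.linalg.cholesky(pearson + 1e-12 * np.eye(k))
    rng = np.random.default_rng(seed)
    rows = []
    enriched_counts = []
    for fov in range(n_fov):
        z = rng.standard_normal((n_per_fov, k)) @ chol.T
        inten = np.exp(1.0 + 0.6 * z)  # lognormal marginals
        lengths = rng.exponential(length_scale_um, size=n_per_fov)
        top_half = inten > np.median(inten, axis=0)
        n_enriched = top_half.sum(axis=1)
        lengths = np.where(n_enriched >= 2, lengths * (1.0 + effect_two_plus), lengths)
        enriched_counts.append(n_enriched)
        area = rng.exponential(AREA_SCALE_UM2, size=n_per_fov)
        df = pd.DataFrame(
            {
                "fov": fov,
                "structure_id": np.arange(n_per_fov),
                "frame": 0,
                "x_um": rng.uniform(0, 100, n_per_fov),
                "y_um": rng.uniform(0, 100, n_per_fov),
                "base_area_um2": area,
                "length_um": lengths,
                "straightness": rng.uniform(0.85, 1.0, n_per_fov),
            }
        )
        for c, name in enumerate(channels):
            df[f"intensity_{name}"] = inten[:, c]
        rows.append(df)
    records = pd.concat(rows, ignore_index=True)
    return SyntheticScene(
        kind="intensity_table",
        data={"records": records},
        ground_truth={
            "rank_corr": r,
            "effect_two_plus": effect_two_plus,
            "channels": channels,
            "length_scale_um": length_scale_um,
            "n_enriched": np.concatenate(enriched_counts),
        },
        seed=seed,
    )


def gen_frap_trace(
    rate: float,
    mobile_fraction: float = 1.0,
    bleach_depth: float = 0.8,
    acq_bleach_rate: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    plateau: float = 1000.0,
    background: float = 100.0,
) -> SyntheticScene:
    """Four-ROI FRAP trace with known recovery rate and mobile fraction.

    The bleached structure drops by ``bleach_depth`` at the bleach frame and
    recovers single-exponentially at ``rate`` (1/s) to the mobile fraction
    of the bleached pool; both structure ROIs decay multiplicatively at
    ``acq_bleach_rate`` during postbleach acquisition.  Background ROIs are
    flat.  Gaussian noise of SD ``noise_sd`` (relative to the prebleach
    plateau) is added to every series.
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must be in [0, 1]")
    if rate < 0 or acq_bleach_rate < 0:
        raise ValueError("rates must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0.0 < bleach_depth <= 1.0:
        raise ValueError("bleach_depth must be in (0, 1]")
    rng = np.random.default_rng(seed)
    t_pre = np.arange(FRAP_N_PREBLEACH, dtype=float)  # 1-s prebleach frames
    t0 = t_pre[-1] + 1.0
    t_fast = t0 + 0.5 * np.arange(FRAP_FAST_FRAMES)
    t_slow = t_fast[-1] + 1.0 + 1.0 * np.arange(FRAP_SLOW_FRAMES)
    time_s = np.concatenate([t_pre, t_fast, t_slow])
    ib = FRAP_N_PREBLEACH  # bleach frame index
    tb = time_s[ib]
    post = time_s >= tb
    rec = np.zeros_like(time_s)
    rec[~post] = plateau
    dt_post = time_s[post] - tb
    recovered = mobile_fraction * (1.0 - np.exp(-rate * dt_post))
    rec[post] = plateau * (1.0 - bleach_depth + bleach_depth * recovered)
    acq = np.ones_like(time_s)
    acq[post] = np.exp(-acq_bleach_rate * dt_post)
    bleached = rec * acq + background
    unbleached = plateau * acq + background
    bg = np.full_like(time_s, background)
    noise = lambda: rng.standard_normal(time_s.size) * noise_sd * plateau
    trace = FrapTrace(
        time_s=time_s,
        bleached=bleached + noise(),
        unbleached=unbleached + noise(),
        background_bleached=bg + noise(),
        background_unbleached=bg + noise(),
        bleach_frame=None,
    )
    return SyntheticScene(
        kind="frap_trace",
        data={"trace": trace},
        ground_truth={
            "rate": rate,
            "half_time_s": np.log(2.0) / rate if rate > 0 else np.inf,
            "mobile_fraction": mobile_fraction,
            "bleach_depth": bleach_depth,
            "acq_bleach_rate": acq_bleach_rate,
            "bleach_frame": ib,
        },
        seed=seed,
    )


def gen_rod_stack(
    n_rods: int,
    z_planes: int = 12,
    psf_sigma_px: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
    px_size_um: float = PIXEL_SIZE_UM,
    z_step_um: float = 0.5,
    base_radius_px: float = 3.0,
    amplitude: float = 1000.0,
    background: float = 0.0,
    max_tilt_px_per_plane: float = 1.0,
) -> SyntheticScene:
    """3D z-stack of blurred rods rising from the base plane.

    Rods start at random base positions in plane 0, extend upward for a
    random number of planes with a constant small xy tilt, are voxelized as
    disks, Gaussian-blurred per plane and noised.  Rods whose requested
    extent exceeds the stack are clipped and flagged.  Ground truth lists
    base centroid, base area, tip position and path length per rod.
    """
    if z_planes < 2:
        raise ValueError("z_planes must be >= 2")
    rng = np.random.default_rng(seed)
    H, W = shape
    stack = np.full((z_planes, H, W), background, dtype=float)
    rods = []
    margin = int(np.ceil(base_radius_px + max_tilt_px_per_plane * z_planes + 3 * psf_sigma_px))
    # bases on a jittered grid so neighbouring rods stay separable
    n_cols = max(1, int(np.ceil(np.sqrt(n_rods))))
    pitch_r = (H - 2 * margin) / max(1, n_cols - 1) if n_cols > 1 else 0
    pitch_c = (W - 2 * margin) / max(1, n_cols - 1) if n_cols > 1 else 0
    rr, cc = np.mgrid[0:H, 0:W]
    for i in range(n_rods):
        gr, gc = divmod(i, n_cols)
        r0 = margin + gr * pitch_r + rng.uniform(-2, 2)
        c0 = margin + gc * pitch_c + rng.uniform(-2, 2)
        want_planes = int(rng.integers(z_planes // 2, z_planes + 3))
        clipped = want_planes > z_planes
        n_pl = min(want_planes, z_planes)
        tilt = rng.uniform(-max_tilt_px_per_plane, max_tilt_px_per_plane, size=2)
        centers = []
        for z in range(n_pl):
            cr, ccol = r0 + tilt[0] * z, c0 + tilt[1] * z
            disk = (rr - cr) ** 2 + (cc - ccol) ** 2 <= base_radius_px**2
            stack[z][disk] += amplitude
            centers.append((z, cr, ccol))
        pts = np.array([(z * z_step_um, r * px_size_um, c * px_size_um) for z, r, c in centers])
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()) if len(pts) > 1 else 0.0
        rods.append(
            {
                "base_centroid_px": (r0, c0),
                "base_area_px": int(np.sum((rr - r0) ** 2 + (cc - c0) ** 2 <= base_radius_px**2)),
                "tip_px": centers[-1],
                "n_planes": n_pl,
                "length_um": length,
                "clipped": clipped,
            }
        )
    for z in range(z_planes):
        if psf_sigma_px > 0:
            stack[z] = ndimage.gaussian_filter(stack[z], psf_sigma_px)
    if noise_sd > 0:
        stack += rng.standard_normal(stack.shape) * noise_sd * amplitude
    return SyntheticScene(
        kind="rod_stack",
        data={"stack": stack},
        ground_truth={
            "rods": rods,
            "px_size_um": px_size_um,
            "z_step_um": z_step_um,
            "background": background,
            "amplitude": amplitude,
        },
        seed=seed,
    )


def _filament_points(base, angle0, curvature, length_px, step=0.5):
    """Sample points along a gently curving filament of given arc length."""
    n = max(2, int(length_px / step))
    s = np.arange(n) * step
    phi = angle0 + curvature * s
    dr = np.cumsum(np.stack([-np.cos(phi), np.sin(phi)], axis=1) * step, axis=0)
    return np.asarray(base) + np.vstack([[0.0, 0.0], dr[:-1]])


def gen_filament_movie(
    n_filaments: int,
    frames: int,
    growth_model: GrowthModelParams | None = None,
    break_frac: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
    frame_interval_s: float = 15.0,
    px_size_um: float = PIXEL_SIZE_UM,
    baseline_length_um: float = 5.0,
    thickness_px: int = 1,
    amplitude: float = 200.0,
    noise_sd: float = 0.0,
    annotation_fraction: float = 0.2,
) -> SyntheticScene:
    """2D movie of curvilinear filaments whose lengths follow the growth model.

    Filaments rise from fixed bases along the bottom edge with a small
    random tilt and curvature; per-frame length = baseline + the integrated
    OU sum-of-products trajectory, clipped to the frame.  Ground truth
    carries per-frame skeletons, lengths and identities, a track table
    (with ``break_frac`` of tracks split into gap-separated fragments under
    new ids, emulating segmentation dropouts), and the first
    ``annotation_fraction`` of frames as manually-annotated training labels.
    """
    if frames < 5:
        raise ValueError("frames must be >= 5")
    rng = np.random.default_rng(seed)
    H, W = shape
    duration_min = frames * frame_interval_s / 60.0
    gm = (growth_model or GrowthModelParams()).with_(duration=duration_min * 1.05)
    margin = 16
    min_spacing = 28  # base pitch keeping full-length curves > the join gate
    if n_filaments > 1:
        W = max(W, 2 * margin + min_spacing * (n_filaments - 1))
    if n_filaments > 0:
        base_cols = np.linspace(margin, W - margin, n_filaments)
    else:
        base_cols = np.array([])
    angles = rng.uniform(-0.18, 0.18, size=n_filaments)
    curvatures = rng.uniform(-0.002, 0.002, size=n_filaments)
    max_len_px = (H - 2 * margin)
    # structures are resolvable by construction: redraw tilt/curvature until
    # every full-length curve stays in frame and keeps > 22 px clearance
    # from its neighbours (beyond the 20-px tip-joining gate; crossing or
    # touching filaments are outside the tracer's contract)
    for _round in range(50):
        full_curves = [None] * n_filaments
        placed_all = True
        for i in range(n_filaments):
            for _attempt in range(60):
                pts = _filament_points(
                    (H - margin, base_cols[i]), angles[i], curvatures[i], max_len_px
                )
                in_frame = (
                    (pts[:, 0] >= 4) & (pts[:, 0] < H - 4)
                    & (pts[:, 1] >= 4) & (pts[:, 1] < W - 4)
                ).all()
                ok = in_frame and all(
                    full_curves[j] is None
                    or np.min(
                        np.linalg.norm(
                            pts[:, None, :] - full_curves[j][None, :, :], axis=2
                        )
                    )
                    >= 22.0
                    for j in range(i)
                )
                if ok:
                    full_curves[i] = pts
                    break
                angles[i] = rng.uniform(-0.18, 0.18)
                curvatures[i] = rng.uniform(-0.002, 0.002)
            else:
                placed_all = False
                break
        if placed_all:
            break
        # a stuck configuration: redraw every filament jointly
        angles = rng.uniform(-0.18, 0.18, size=n_filaments)
        curvatures = rng.uniform(-0.002, 0.002, size=n_filaments)
    else:
        raise ValueError("could not place separable filaments; reduce n_filaments")
    # per-filament length series sampled at the frame interval
    lengths_px = np.zeros((n_filaments, frames))
    for i in range(n_filaments):
        traj = simulate_length(gm.with_(seed=int(rng.integers(2**31))), initiation_time=0.0)
        t_frames = np.arange(frames) * frame_interval_s / 60.0
        L = np.interp(t_frames, traj.times, traj.lengths)
        # floor keeps every rendered structure above the tracer's 40-px
        # component cut (immature sub-µm structures are not emulated)
        lengths_px[i] = np.clip(
            (baseline_length_um + L) / px_size_um, 22.0, max_len_px
        )
    movie = np.zeros((frames, H, W), dtype=float)
    skeletons: list[list[np.ndarray]] = []
    for f in range(frames):
        frame_skels = []
        for i in range(n_filaments):
            pts = _filament_points(
                (H - margin, base_cols[i]), angles[i], curvatures[i], lengths_px[i, f]
            )
            pix = np.unique(np.round(pts).astype(int), axis=0)
            pix = pix[(pix[:, 0] >= 0) & (pix[:, 0] < H) & (pix[:, 1] >= 0) & (pix[:, 1] < W)]
            mask = np.zeros((H, W), dtype=bool)
            mask[pix[:, 0], pix[:, 1]] = True
            if thickness_px > 0:
                mask = ndimage.binary_dilation(mask, iterations=thickness_px)
            movie[f][mask] += amplitude
            frame_skels.append(pix)
        skeletons.append(frame_skels)
    if noise_sd > 0:
        movie += rng.standard_normal(movie.shape) * noise_sd * amplitude
    # track table with injected breaks
    rows = []
    next_extra_id = n_filaments
    true_ids = {}
    broken = rng.random(n_filaments) < break_frac
    for i in range(n_filaments):
        base_x = base_cols[i] * px_size_um
        base_y = (H - margin) * px_size_um
        frag_id = i
        true_ids[frag_id] = i
        if broken[i] and frames >= 10:
            split = int(rng.integers(3, frames - 5))
            gap = int(rng.integers(1, 7))  # 1..6 missing frames
            second_start = min(split + gap, frames - 2)
            segments = [(frag_id, range(0, split)), (next_extra_id, range(second_start, frames))]
            true_ids[next_extra_id] = i
            next_extra_id += 1
        else:
            segments = [(frag_id, range(frames))]
        for tid, fr in segments:
            for f in fr:
                rows.append(
                    {
                        "track_id": tid,
                        "frame": f,
                        "x_um": base_x + rng.normal(0, 0.05),
                        "y_um": base_y + rng.normal(0, 0.05),
                        "length_um": lengths_px[i, f] * px_size_um,
                    }
                )
    track_table = pd.DataFrame(rows)
    n_annot = max(1, int(round(annotation_fraction * frames)))
    annotation_frames = list(range(n_annot))
    annotation_masks = []
    for f in annotation_frames:
        m = np.zeros((H, W), dtype=bool)
        for pix in skeletons[f]:
            m[pix[:, 0], pix[:, 1]] = True
        annotation_masks.append(ndimage.binary_dilation(m, iterations=max(1, thickness_px)))
    return SyntheticScene(
        kind="filament_movie",
        data={
            "movie": movie,
            "track_table": track_table,
            "annotation_frames": annotation_frames,
            "annotation_masks": annotation_masks,
        },
        ground_truth={
            "skeletons": skeletons,
            "lengths_px": lengths_px,
            "true_ids": true_ids,
            "n_breaks": int(broken.sum()),
            "px_size_um": px_size_um,
            "frame_interval_s": frame_interval_s,
            "theta": gm.theta,
            "M": gm.M,
            "N": gm.N,
        },
        seed=seed,
    )
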