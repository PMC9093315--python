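"""Scripted studies on synthetic head data.

Three study families mirror how the instrument is used:

* the sphere-inclusion localization study: a 20 mm blood-conductivity sphere
  is embedded at four intracranial locations in a forward phantom, frames are
  simulated at several SNR levels, and both reconstruction methods are scored
  by centre-of-gravity localization error on a (deliberately different)
  inverse mesh;

* REG mode: a cardiac-synchronous, zero-mean-over-the-cycle conductivity
  modulation (~1 % peak) of grey/white-matter territories, forward-solved
  frame by frame at the instrument frame rate;

* THR mode: a lateralized slow conductivity change emulating a brief carotid
  artery occlusion (default -20 % on the occluded side, +5 % contralateral,
  on top of the REG modulation), with cycle-averaged difference imaging.

All studies are driven by explicit seeds; per-repeat sub-seeds are derived by
fixed offsets, so reports regenerate bit-identically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import protocol as proto_mod
from .forward import jacobian, solve_frame
from .imaging import (center_of_gravity, localization_error, remove_scalp,
                      voxelize)
from .mesh import (DEFAULT_TISSUE_TABLE, HeadMesh, assign_conductivities,
                   build_layered_head, embed_sphere, place_electrodes,
                   simulation_tissue_table)
from .protocol import MeasurementProtocol, VoltageFrame, add_noise
from .reconstruction import (ReconOptions, nonlinear_difference,
                             traditional_difference)

#: Default inclusion locations (metres) on the desk-scale phantom, all inside
#: the grey/white compartment.  Left is +y in the head frame (+x nose, +z up).
DEFAULT_LOCATIONS: dict[str, tuple[float, float, float]] = {
    "middle": (0.000, 0.000, 0.030),
    "front": (0.035, 0.000, 0.030),
    "left": (0.000, 0.035, 0.030),
    "right": (0.000, -0.035, 0.030),
}


@dataclass
class StudyConfig:
    """Sphere-inclusion localization study configuration."""

    locations: dict[str, tuple[float, float, float]] = \
        field(default_factory=lambda: dict(DEFAULT_LOCATIONS))
    sphere_diameter: float = 0.020
    sphere_conductivity: float = 0.65
    snr_levels: tuple[float, ...] = (math.inf, 70.0, 50.0)
    repeats: int = 10
    seed: int = 1
    radii: tuple[float, ...] = (0.060, 0.065, 0.070, 0.075, 0.080)
    forward_elements: int = 12000
    inverse_elements: int = 5000
    forward_seed: int = 11
    inverse_seed: int = 23
    voxel_resolution: float = 0.003
    # at desk scale the Gauss-Newton residual plateaus after ~4 iterations,
    # so the study default stops at 6 (ReconOptions itself defaults to 15)
    recon: ReconOptions = field(
        default_factory=lambda: ReconOptions(iterations=6))


def build_study_meshes(cfg: StudyConfig) -> tuple[HeadMesh, HeadMesh]:
    """Forward and inverse phantoms: same geometry, different meshes."""
    fwd = place_electrodes(build_layered_head(cfg.radii, cfg.forward_elements,
                                              seed=cfg.forward_seed))
    inv = place_electrodes(build_layered_head(cfg.radii, cfg.inverse_elements,
                                              seed=cfg.inverse_seed))
    return fwd, inv


def run_inclusion_study(cfg: StudyConfig,
                        protocol: MeasurementProtocol | None = None,
                        methods: tuple[str, ...] = ("nonlinear",
                                                    "traditional")
                        ) -> pd.DataFrame:
    """Full localization study; one row per method x location x SNR x repeat.

    The forward truth uses the reduced simulation tissue table (grey and CSF
    at the white-matter value) plus the sphere; the reconstruction operates
    on the inverse mesh at the nominal (five-value) conductivities, so the
    study includes deliberate modelling error from both the tissue tables
    and the mesh mismatch.  Noise is added independently to the inclusion
    and reference frames.  Scalp change is removed before voxelization and
    CoG scoring.
    """
    if protocol is None:
        protocol = proto_mod.default_protocol()
    fwd_mesh, inv_mesh = build_study_meshes(cfg)
    sim_table = simulation_tissue_table()
    sigma_ref = assign_conductivities(fwd_mesh, sim_table)
    v_ref = solve_frame(fwd_mesh, sigma_ref, protocol)
    sigma_n = assign_conductivities(inv_mesh, DEFAULT_TISSUE_TABLE)
    J_n = jacobian(inv_mesh, sigma_n, protocol) \
        if "traditional" in methods else None

    rows = []
    for loc_idx, (loc_name, center) in enumerate(cfg.locations.items()):
        sigma_inc = embed_sphere(sigma_ref, fwd_mesh, center,
                                 cfg.sphere_diameter,
                                 cfg.sphere_conductivity)
        v_inc = solve_frame(fwd_mesh, sigma_inc, protocol)
        for snr in cfg.snr_levels:
            n_rep = 1 if math.isinf(snr) else cfg.repeats
            for rep in range(n_rep):
                sub = (cfg.seed + 100_000 * loc_idx
                       + 1_000 * int(snr if math.isfinite(snr) else 0)
                       + rep)
                dv = (add_noise(v_inc, snr, 2 * sub).values
                      - add_noise(v_ref, snr, 2 * sub + 1).values)
                for method in methods:
                    if method == "nonlinear":
                        res = nonlinear_difference(dv, sigma_n, inv_mesh,
                                                   protocol, cfg.recon)
                    elif method == "traditional":
                        res = traditional_difference(dv, sigma_n, J_n,
                                                     inv_mesh, cfg.recon)
                    else:
                        raise ValueError(f"unknown method {method!r}")
                    cranial = remove_scalp(res.dsigma, inv_mesh)
                    img = voxelize(inv_mesh, cranial, cfg.voxel_resolution)
                    cog = center_of_gravity(img)
                    rows.append({
                        "method": method, "location": loc_name,
                        "snr_db": snr, "repeat": rep,
                        "error_mm": localization_error(cog, center),
                        "cog_x": cog[0], "cog_y": cog[1], "cog_z": cog[2],
                    })
    return pd.DataFrame(rows)


def summarize_localization(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +- std localization-error table (no std in the no-noise rows)."""
    rows = []
    for (method, snr), grp in df.groupby(["method", "snr_db"]):
        row = {"method": method, "snr_db": snr}
        for loc, g in grp.groupby("location"):
            mean = g["error_mm"].mean()
            if math.isinf(snr) or len(g) < 2:
                row[loc] = f"{mean:.1f}"
            else:
                row[loc] = f"{mean:.1f} +- {g['error_mm'].std(ddof=1):.1f}"
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_cog_separations(df: pd.DataFrame, method: str,
                             snr: float = math.inf) -> np.ndarray:
    """Pairwise distances (mm) between the per-location mean CoGs."""
    sel = df[(df["method"] == method) & (df["snr_db"] == snr)]
    cogs = sel.groupby("location")[["cog_x", "cog_y", "cog_z"]].mean().values
    out = []
    for i in range(len(cogs)):
        for j in range(i + 1, len(cogs)):
            out.append(np.linalg.norm(cogs[i] - cogs[j]) * 1e3)
    return np.array(out)


# ---------------------------------------------------------------------------
# Synthetic hemodynamic time series


@dataclass
class FrameSeries:
    """Uniformly spaced voltage frames with event annotations.

    ``truth`` stores, when available, the ground-truth conductivity fields
    at annotated instants (a dict name -> per-element array).
    """

    frames: np.ndarray
    fps: float
    annotations: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> VoltageFrame:
        return VoltageFrame(self.frames[i], index=i)

    def times(self) -> np.ndarray:
        return np.arange(len(self.frames)) / self.fps


#: Systolic pulse centre and width as fractions of the cardiac cycle.  The
#: pulse is narrow enough that late diastole (the reference window) is quiet.
_PULSE_CENTER = 0.32
_PULSE_WIDTH = 0.08
#: Onset of the rapid voltage fall: two pulse widths before the peak.
_FALL_ONSET = _PULSE_CENTER - 2.0 * _PULSE_WIDTH

_PHASE_GRID = np.linspace(0.0, 1.0, 2048, endpoint=False)
_PULSE_MEAN = float(np.exp(
    -0.5 * ((_PHASE_GRID - _PULSE_CENTER) / _PULSE_WIDTH) ** 2).mean())
_PULSE_PEAK = 1.0 - _PULSE_MEAN


def cardiac_waveform(phase) -> np.ndarray:
    """Zero-mean, unit-peak cardiac modulation waveform.

    A Gaussian systolic pulse (conductivity rise = EIT voltage fall) with a
    quiescent diastole; the zero-mean normalization makes the modulation
    integrate to zero over a complete cycle, so cycle averages recover the
    baseline.
    """
    w = np.exp(-0.5 * ((np.asarray(phase) % 1.0 - _PULSE_CENTER)
                       / _PULSE_WIDTH) ** 2)
    return (w - _PULSE_MEAN) / _PULSE_PEAK


def _territory_mask(mesh: HeadMesh, center, radius: float) -> np.ndarray:
    c = mesh.element_centroids()
    brain = mesh.tissue_mask("grey") | mesh.tissue_mask("white")
    return brain & (np.linalg.norm(c - np.asarray(center), axis=1) <= radius)


#: Default REG territories: three anterior grey/white blobs.
DEFAULT_REG_TERRITORIES = (
    ((0.030, 0.018, 0.035), 0.018),
    ((0.030, -0.018, 0.035), 0.018),
    ((0.042, 0.000, 0.018), 0.018),
)


def synth_timeseries(mesh: HeadMesh, sigma_N: np.ndarray, mode: str,
                     params: dict | None = None, seed: int = 0
                     ) -> FrameSeries:
    """Generate a synthetic measurement time series by frame-wise forward
    solving of a modulated conductivity field.

    ``mode="reg"``: periodic modulation (default 1 % peak) of the REG
    territories with a cardiac-like waveform.  ``mode="thr"``: additionally a
    lateralized slow change over the occlusion window (default -20 % on the
    occluded side of the grey/white matter, +5 % contralateral).  Channel
    noise at ``params["snr_db"]`` (default none) is added per frame.
    """
    p = {
        "fps": 100.0, "duration": 3.0, "cycle_period": 1.0,
        "amplitude": 0.01, "territories": DEFAULT_REG_TERRITORIES,
        "protocol": None, "snr_db": math.inf,
        # thr-specific
        "occlusion": (3.0, 8.0), "ramp": 0.5,
        "occluded_drop": 0.20, "contralateral_rise": 0.05, "side": "left",
    }
    p.update(params or {})
    protocol = p["protocol"] or proto_mod.default_protocol()
    fps, T = float(p["fps"]), float(p["cycle_period"])
    n_frames = int(round(p["duration"] * fps))
    times = np.arange(n_frames) / fps

    terr = np.zeros(mesh.n_elements)
    for center, radius in p["territories"]:
        terr[_territory_mask(mesh, center, radius)] = 1.0

    brain = mesh.tissue_mask("grey") | mesh.tissue_mask("white")
    cy = mesh.element_centroids()[:, 1]
    side_sign = 1.0 if p["side"] == "left" else -1.0
    occluded = brain & (side_sign * cy > 0)
    contra = brain & (side_sign * cy < 0)

    def waveform(t):
        return float(cardiac_waveform(t / T))

    def occlusion_level(t):
        t0, t1 = p["occlusion"]
        r = p["ramp"]
        if t < t0 or t > t1 + r:
            return 0.0
        if t < t0 + r:
            return (t - t0) / r
        if t <= t1:
            return 1.0
        return 1.0 - (t - t1) / r

    frames = np.empty((n_frames, len(protocol)))
    truth = {}
    troughs = []
    falls = []
    for i, t in enumerate(times):
        mod = np.ones(mesh.n_elements)
        mod += p["amplitude"] * waveform(t) * terr
        if mode == "thr":
            s = occlusion_level(t)
            mod -= p["occluded_drop"] * s * occluded
            mod += p["contralateral_rise"] * s * contra
        elif mode != "reg":
            raise ValueError(f"unknown mode {mode!r}")
        sigma_t = sigma_N * mod
        if np.any(sigma_t <= 0):
            raise ValueError("modulation drives conductivity non-positive")
        frame = solve_frame(mesh, sigma_t, protocol, index=i)
        frame = add_noise(frame, p["snr_db"], seed + 7919 * i)
        frames[i] = frame.values
        phase = (t / T) % 1.0
        if abs(phase - _PULSE_CENTER) < 0.5 / fps / T:
            troughs.append(i)
            truth.setdefault("peak_sigma", sigma_t.copy())
        if abs(phase - _FALL_ONSET) < 0.5 / fps / T:
            falls.append(i)
    if mode == "thr":
        t0, t1 = p["occlusion"]
        mid = (t0 + t1) / 2.0
        i_mid = int(round(mid * fps))
        if 0 <= i_mid < n_frames:
            s = occlusion_level(times[i_mid])
            truth["occlusion_sigma"] = sigma_N * (
                1.0 - p["occluded_drop"] * s * occluded
                + p["contralateral_rise"] * s * contra)
    annotations = {
        "cycle_period": T, "troughs": troughs, "falls": falls, "mode": mode,
        "amplitude": p["amplitude"],
    }
    if mode == "thr":
        annotations["occlusion"] = p["occlusion"]
        annotations["side"] = p["side"]
    return FrameSeries(frames, fps, annotations, truth)


def reg_reference(series: FrameSeries, trough_index: int) -> VoltageFrame:
    """Reference frame: mean of the two frames ending 60 ms before the given
    instant.

    The convention follows the measurement rule "two frames at 60 ms before
    the rapid fall of the EIT voltage": pass the frame index of the onset of
    the rapid fall (annotated as ``"falls"`` in synthetic series), which
    lands the reference window in quiet diastole.
    """
    k = int(round(0.06 * series.fps))
    first = trough_index - k - 1
    if first < 0:
        raise ValueError("insufficient history before the trough for a "
                         "60 ms-early two-frame reference")
    return VoltageFrame(series.frames[first:first + 2].mean(axis=0),
                        index=first)


def pair_average(series: FrameSeries) -> FrameSeries:
    """Average non-overlapping consecutive frame pairs (halves the rate)."""
    n = len(series)
    if n % 2:
        warnings.warn("odd frame count: dropping the trailing frame")
        n -= 1
    avg = series.frames[:n].reshape(n // 2, 2, -1).mean(axis=1)
    return FrameSeries(avg, series.fps / 2.0, dict(series.annotations),
                       dict(series.truth))


def cycle_average(series: FrameSeries, bounds: tuple[int, int]
                  ) -> VoltageFrame:
    """Mean frame over ``bounds = (start, stop)`` (Python slice semantics)."""
    start, stop = bounds
    window = series.frames[start:stop]
    if len(window) == 0:
        raise ValueError("empty averaging window")
    return VoltageFrame(window.mean(axis=0), index=start)


def difference_series(series: FrameSeries,
                      reference: VoltageFrame | np.ndarray) -> FrameSeries:
    """Per-frame voltage difference dV_t = V_t - V_ref."""
    ref = reference.values if isinstance(reference, VoltageFrame) \
        else np.asarray(reference, float)
    if series.frames.shape[1] != len(ref):
        raise ValueError("reference length does not match the series")
    return FrameSeries(series.frames - ref[None, :], series.fps,
                       dict(series.annotations), dict(series.truth))


# ---------------------------------------------------------------------------
# End-to-end difference-imaging pipelines (matched forward/inverse mesh)


def reg_pipeline(mesh: HeadMesh, sigma_N: np.ndarray,
                 protocol: MeasurementProtocol | None = None,
                 params: dict | None = None, seed: int = 0,
                 opts: ReconOptions | None = None) -> dict:
    """Simulate a REG series and reconstruct the image at modulation peak.

    Returns the reconstruction, the injected and recovered peak relative
    conductivity change in the grey/white matter, and the series itself.
    """
    protocol = protocol or proto_mod.default_protocol()
    params = dict(params or {})
    params.setdefault("protocol", protocol)
    series = synth_timeseries(mesh, sigma_N, "reg", params, seed=seed)
    k = int(round(0.06 * series.fps)) + 1
    falls = [f for f in series.annotations["falls"] if f - k >= 0]
    fall = falls[0]
    ref = reg_reference(series, fall)
    trough = min(t for t in series.annotations["troughs"] if t > fall)
    halved = pair_average(difference_series(series, ref))
    peak_idx = trough // 2
    dv = halved.frames[peak_idx]
    res = nonlinear_difference(dv, sigma_N, mesh, protocol, opts)
    brain = mesh.tissue_mask("grey") | mesh.tissue_mask("white")
    rel = np.abs(res.dsigma[brain]) / sigma_N[brain]
    injected = series.annotations["amplitude"]
    return {"series": series, "reconstruction": res,
            "injected_peak": injected,
            "recovered_peak": float(rel.max()),
            "reference": ref}


def thr_pipeline(mesh: HeadMesh, sigma_N: np.ndarray,
                 protocol: MeasurementProtocol | None = None,
                 params: dict | None = None, seed: int = 0,
                 opts: ReconOptions | None = None) -> dict:
    """Simulate a THR occlusion and reconstruct cycle-averaged images.

    The reference is the average over the complete cardiac cycle immediately
    preceding the occlusion; images are reconstructed for a cycle during the
    occlusion plateau and a late post-release cycle.  Returns per-hemisphere
    mean conductivity change (grey/white matter) for both instants.
    """
    protocol = protocol or proto_mod.default_protocol()
    params = dict(params or {})
    params.setdefault("protocol", protocol)
    params.setdefault("duration", 14.0)
    series = synth_timeseries(mesh, sigma_N, "thr", params, seed=seed)
    fps, T = series.fps, series.annotations["cycle_period"]
    t0, t1 = series.annotations["occlusion"]
    cyc = int(round(T * fps))

    pre_stop = int(round(t0 * fps))
    ref = cycle_average(series, (pre_stop - cyc, pre_stop))
    mid = int(round((t0 + t1) / 2.0 * fps))
    occ = cycle_average(series, (mid, mid + cyc))
    post_start = int(round((t1 + 2.5 * T) * fps))
    post = cycle_average(series, (post_start, post_start + cyc))

    out = {"series": series, "reference": ref}
    brain = mesh.tissue_mask("grey") | mesh.tissue_mask("white")
    cy = mesh.element_centroids()[:, 1]
    left = brain & (cy > 0)
    right = brain & (cy < 0)
    for name, frame in (("occlusion", occ), ("release", post)):
        dv = frame.values - ref.values
        res = nonlinear_difference(dv, sigma_N, mesh, protocol, opts)
        out[f"{name}_reconstruction"] = res
        out[f"{name}_left_mean"] = float(res.dsigma[left].mean())
        out[f"{name}_right_mean"] = float(res.dsigma[right].mean())
        out[f"{name}_contrast"] = abs(out[f"{name}_left_mean"]
                                      - out[f"{name}_right_mean"])
    return out
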