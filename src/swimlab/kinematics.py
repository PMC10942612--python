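"""3-D schooling and swimming kinematics from landmark trajectories.

Inputs are already-reconstructed 3-D coordinates (m) of three anatomical
landmarks per fish per frame — nose tip, caudal peduncle, and the right-angle
"crosshair" point between them — sampled at high speed (default 125 Hz) in a
flume-fixed frame: +X downstream along the flow, +Y lateral, +Z vertical
(right-handed).  From these the module computes the collective metrics used to
characterise schooling: pairwise nose–nose distances, school length along the
flow axis, body angles to the frontal plane and to the flow, tail-beat
frequency and amplitude, 90-degree-turn frequency, and the Strouhal and
Reynolds numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial.distance import pdist

from .water import water_density, water_viscosity

__all__ = [
    "Track3D",
    "SchoolMetrics",
    "KinematicsSummary",
    "LANDMARKS",
    "dist3d",
    "body_angle_3d",
    "angle_to_flow",
    "school_metrics",
    "lateral_excursion",
    "steady_frames",
    "tail_beat_frequency",
    "tail_beat_amplitude",
    "headings_from_track",
    "turning_frequency",
    "strouhal",
    "reynolds",
    "summarize_kinematics",
]

LANDMARKS = ("nose", "peduncle", "crosshair")


class Track3D:
    """Landmark coordinates per fish per frame.

    ``coords`` has shape ``(n_frames, n_fish, 3 landmarks, 3)`` in metres,
    landmark order ``nose, peduncle, crosshair``.  ``flow_axis`` is the unit
    vector of the downstream direction (default +X).
    """

    def __init__(self, coords: np.ndarray, fps: float = 125.0,
                 flow_axis: np.ndarray | None = None):
        coords = np.asarray(coords, float)
        if coords.ndim != 4 or coords.shape[2] != 3 or coords.shape[3] != 3:
            raise ValueError("coords must have shape (frames, fish, 3 landmarks, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if fps <= 0:
            raise ValueError("fps must be positive")
        self.coords = coords
        self.fps = float(fps)
        axis = np.asarray([1.0, 0.0, 0.0] if flow_axis is None else flow_axis, float)
        self.flow_axis = axis / np.linalg.norm(axis)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_fish(self) -> int:
        return self.coords.shape[1]

    def landmark(self, name: str) -> np.ndarray:
        """(n_frames, n_fish, 3) array for one landmark."""
        return self.coords[:, :, LANDMARKS.index(name), :]

    def to_dataframe(self) -> pd.DataFrame:
        f, n, _, _ = self.coords.shape
        frames = np.repeat(np.arange(f), n * 3)
        fish = np.tile(np.repeat(np.arange(n), 3), f)
        lm = np.tile(np.array(LANDMARKS), f * n)
        xyz = self.coords.reshape(-1, 3)
        return pd.DataFrame(
            {"frame": frames, "fish_id": fish, "landmark": lm,
             "x_m": xyz[:, 0], "y_m": xyz[:, 1], "z_m": xyz[:, 2]}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.7f")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fps: float = 125.0,
                       flow_axis: np.ndarray | None = None) -> "Track3D":
        frames = np.sort(df["frame"].unique())
        fish = np.sort(df["fish_id"].unique())
        coords = np.empty((len(frames), len(fish), 3, 3))
        lm_order = {lm: i for i, lm in enumerate(LANDMARKS)}
        d = df.set_index(["frame", "fish_id", "landmark"]).sort_index()
        for fi, fr in enumerate(frames):
            for ni, fid in enumerate(fish):
                for lm, li in lm_order.items():
                    row = d.loc[(fr, fid, lm)]
                    coords[fi, ni, li] = (row["x_m"], row["y_m"], row["z_m"])
        return cls(coords, fps=fps, flow_axis=flow_axis)

    @classmethod
    def from_csv(cls, path, fps: float = 125.0,
                 flow_axis: np.ndarray | None = None) -> "Track3D":
        return cls.from_dataframe(pd.read_csv(path), fps=fps, flow_axis=flow_axis)


def dist3d(p, q) -> float:
    """Euclidean distance between two 3-D points."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    return float(np.linalg.norm(p - q))


def body_angle_3d(nose, peduncle, crosshair) -> float:
    """3-D body angle to the frontal plane, degrees.

    The angle at the caudal peduncle between the vectors to the crosshair
    point and to the nose: ``arccos`` of the normalised dot product.  With the
    crosshair constructed as the right-angle projection of the nose onto the
    peduncle's horizontal plane, this is the pitch of the body axis.
    """
    v1 = np.asarray(crosshair, float) - np.asarray(peduncle, float)
    v2 = np.asarray(nose, float) - np.asarray(peduncle, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate (zero-length) landmark vector")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def angle_to_flow(nose, peduncle, flow_axis=(1.0, 0.0, 0.0),
                  projection: str = "3d") -> float:
    """Angle of the body axis (peduncle -> nose) off the upstream direction.

    Returns degrees in (-180, 180]; 0 = heading straight into the flow.  The
    sign follows the lateral (Y) component of the body axis.  ``projection``
    selects the full 3-D angle (default) or the ventral-plane (``"ventral"``,
    X–Y) projection.
    """
    body = np.asarray(nose, float) - np.asarray(peduncle, float)
    axis = np.asarray(flow_axis, float)
    axis = axis / np.linalg.norm(axis)
    upstream = -axis
    if projection == "ventral":
        # Components in the horizontal plane: along upstream, and lateral.
        lat_axis = np.array([-axis[1], axis[0], 0.0])
        if np.linalg.norm(lat_axis) == 0:
            raise ValueError("flow axis is vertical; ventral projection undefined")
        lat_axis /= np.linalg.norm(lat_axis)
        x = float(np.dot(body, upstream))
        y = float(np.dot(body, lat_axis))
        if x == 0 and y == 0:
            raise ValueError("degenerate body vector in the ventral plane")
        return float(np.degrees(np.arctan2(y, x)))
    if projection != "3d":
        raise ValueError(f"unknown projection {projection!r}")
    n = np.linalg.norm(body)
    if n == 0:
        raise ValueError("degenerate (zero-length) body vector")
    c = np.clip(np.dot(body, upstream) / n, -1.0, 1.0)
    ang = float(np.degrees(np.arccos(c)))
    lat = float(np.dot(body, np.array([-axis[1], axis[0], 0.0])))
    return -ang if lat < 0 else ang


@dataclass(frozen=True)
class SchoolMetrics:
    """Pairwise spacing and school length, in body lengths."""

    mean_pairwise_bl: float
    sd_pairwise_bl: float
    school_length_bl: float


def school_metrics(track: Track3D, body_length_m: float,
                   frames: np.ndarray | None = None) -> SchoolMetrics:
    """Mean/SD nose–nose distance and school length along the flow axis.

    Per frame, all unordered nose pairs are measured and the school length is
    the 3-D distance from the nose of the most-upstream fish (leading the
    school, smallest downstream coordinate) to the caudal peduncle of the
    most-downstream fish; per-frame values are then averaged over ``frames``
    (default: all).  A single fish has no pairwise statistics; its school
    length is its own nose–peduncle extent.
    """
    if body_length_m <= 0:
        raise ValueError("body length must be positive")
    idx = np.arange(track.n_frames) if frames is None else np.asarray(frames, int)
    noses = track.landmark("nose")[idx]
    peds = track.landmark("peduncle")[idx]
    axis = track.flow_axis

    if track.n_fish >= 2:
        means, sds = [], []
        for f in range(len(idx)):
            d = pdist(noses[f])
            means.append(d.mean())
            sds.append(d.std(ddof=0))
        mean_pair = float(np.mean(means)) / body_length_m
        sd_pair = float(np.mean(sds)) / body_length_m
    else:
        mean_pair, sd_pair = float("nan"), float("nan")

    lengths = []
    for f in range(len(idx)):
        downstream = noses[f] @ axis
        lead = int(np.argmin(downstream))   # most upstream = first fish
        trail = int(np.argmax(downstream))  # most downstream = last fish
        lengths.append(dist3d(noses[f, lead], peds[f, trail]))
    return SchoolMetrics(mean_pair, sd_pair, float(np.mean(lengths)) / body_length_m)


def lateral_excursion(track: Track3D, fish: int = 0,
                      landmark: str = "peduncle",
                      frames: np.ndarray | None = None) -> np.ndarray:
    """Detrended lateral (perpendicular to the body axis, horizontal) signal.

    The landmark's position is projected onto the horizontal axis
    perpendicular to the fish's median body heading over ``frames`` (all by
    default) and mean-centred — the tail-beat excursion signal for
    frequency/amplitude estimation.  For a fish heading into the flow this is
    simply the detrended lateral (Y) coordinate; after a turn the projection
    follows the body frame.  Measure on a steady-swimming segment (see
    :func:`steady_frames`) when the recording contains turns.
    """
    idx = np.arange(track.n_frames) if frames is None else np.asarray(frames, int)
    axis = track.flow_axis
    lat_axis = np.array([-axis[1], axis[0], 0.0])
    lat_axis /= np.linalg.norm(lat_axis)
    body = (track.landmark("nose") - track.landmark("peduncle"))[idx, fish, :]
    x = body @ (-axis)
    y = body @ lat_axis
    theta = np.median(np.arctan2(y, x))
    # Horizontal unit vector perpendicular to the median body axis.
    perp = np.sin(theta) * (-axis) + np.cos(theta) * lat_axis
    sig = track.landmark(landmark)[idx, fish, :] @ perp
    return sig - sig.mean()


def steady_frames(heading_deg: np.ndarray, fps: float,
                  max_rate_deg_s: float = 150.0,
                  min_duration_s: float = 1.5) -> np.ndarray:
    """Longest contiguous frame run where the heading rate stays moderate.

    Frames whose |d heading/dt| exceeds ``max_rate_deg_s`` (turning
    manoeuvres) are excluded; the longest remaining run is returned, or all
    frames if no run reaches ``min_duration_s`` (steady recording).
    """
    h = np.asarray(heading_deg, float)
    rate = np.abs(np.gradient(h)) * fps
    ok = rate <= max_rate_deg_s
    best_i, best_j, i, n = 0, 0, 0, len(ok)
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            if j - i > best_j - best_i:
                best_i, best_j = i, j
            i = j
        else:
            i += 1
    if best_j - best_i < min_duration_s * fps:
        return np.arange(n)
    return np.arange(best_i, best_j)


def _peaks(signal: np.ndarray, prominence_frac: float) -> np.ndarray:
    iqr = float(np.subtract(*np.percentile(signal, [75, 25])))
    prominence = prominence_frac * iqr if iqr > 0 else None
    if prominence is None or prominence <= 0:
        raise ValueError("flat signal: no tail-beat oscillation detected")
    peaks, _ = find_peaks(signal, prominence=prominence)
    return peaks


def tail_beat_frequency(signal: np.ndarray, fps: float,
                        n_beats: int = 10,
                        prominence_frac: float = 0.2) -> float:
    """Tail-beat frequency (Hz) by peak detection on the excursion signal.

    Peaks with prominence above ``prominence_frac`` of the signal's
    inter-quartile range mark successive beats; the frequency is the number of
    beat intervals over their time span, using the first ``n_beats`` beats
    (the 10-beat sampling rule) or as many as the signal contains.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    signal = np.asarray(signal, float)
    peaks = _peaks(signal, prominence_frac)
    if len(peaks) < 2:
        raise ValueError("fewer than two tail-beat peaks detected")
    use = peaks[: n_beats + 1]
    span_s = (use[-1] - use[0]) / fps
    return float((len(use) - 1) / span_s)


def tail_beat_amplitude(signal: np.ndarray, n_cycles: int = 5,
                        prominence_frac: float = 0.2) -> float:
    """Mean of ``n_cycles`` consecutive peak-to-peak excursions (same units).

    Peak-to-peak is measured between each detected crest and the deepest
    trough before the next crest.
    """
    signal = np.asarray(signal, float)
    crests = _peaks(signal, prominence_frac)
    troughs = _peaks(-signal, prominence_frac)
    if len(crests) < 2 or len(troughs) < 1:
        raise ValueError("not enough oscillation cycles for an amplitude estimate")
    p2p = []
    for a, b in zip(crests[:-1], crests[1:]):
        mid = troughs[(troughs > a) & (troughs < b)]
        if len(mid):
            p2p.append(signal[a] - signal[mid].min())
        if len(p2p) >= n_cycles:
            break
    if not p2p:
        raise ValueError("no crest-trough cycle found")
    return float(np.mean(p2p))


def headings_from_track(track: Track3D, smooth_s: float = 0.0) -> np.ndarray:
    """Ventral-plane heading (deg off upstream) per frame per fish.

    Optionally smoothed with a moving average of ``smooth_s`` seconds to damp
    tail-beat wobble before turn detection.
    """
    noses = track.landmark("nose")
    peds = track.landmark("peduncle")
    axis = track.flow_axis
    lat_axis = np.array([-axis[1], axis[0], 0.0])
    lat_axis /= np.linalg.norm(lat_axis)
    body = noses - peds
    x = body @ (-axis)
    y = body @ lat_axis
    headings = np.degrees(np.unwrap(np.arctan2(y, x), axis=0))
    if smooth_s > 0:
        w = max(int(round(smooth_s * track.fps)), 1)
        kernel = np.ones(w) / w
        headings = np.apply_along_axis(
            lambda h: np.convolve(h, kernel, mode="same"), 0, headings
        )
    return headings


def turning_frequency(headings: np.ndarray, fps: float, n_fish: int | None = None,
                      threshold_deg: float = 90.0, span_s: float = 1.0,
                      refractory_s: float = 0.5) -> float:
    """Count >= ``threshold_deg`` turns per fish over the recording.

    A turn event fires when the net heading change across a rolling
    ``span_s``-second span reaches the threshold; after an event the detector
    re-arms only once the rolling change falls back below *half* the
    threshold (hysteresis, so jitter around the threshold cannot double-count
    a single turn) and the refractory period has elapsed.  Tail-beat wobble
    (tens of degrees) never triggers.  Returns total events divided by the
    number of fish.
    """
    headings = np.atleast_2d(np.asarray(headings, float))
    if headings.shape[0] < headings.shape[1]:
        pass  # (frames, fish) expected; caller responsibility for tiny inputs
    n_frames, n_cols = headings.shape
    if n_fish is None:
        n_fish = n_cols
    span = int(round(span_s * fps))
    refractory = int(round(refractory_s * fps))
    if n_frames <= span:
        raise ValueError("recording shorter than the turn-detection span")
    total = 0
    for j in range(n_cols):
        h = headings[:, j]
        armed = True
        last_event = -10 * n_frames
        for i in range(span, n_frames):
            d = abs(h[i] - h[i - span])
            if armed and d >= threshold_deg and i - last_event >= refractory:
                total += 1
                last_event = i
                armed = False
            elif not armed and d < 0.5 * threshold_deg:
                armed = True
    return total / n_fish


def strouhal(ftb_hz: float, amplitude_m: float, speed_m_s: float) -> float:
    """Strouhal number f*A/U (A = peak-to-peak tail-beat amplitude)."""
    if speed_m_s <= 0:
        raise ValueError("speed must be positive")
    return ftb_hz * amplitude_m / speed_m_s


def reynolds(speed_m_s: float, fork_length_m: float,
             density_kg_m3: float | None = None,
             viscosity_pa_s: float | None = None,
             temp_c: float = 28.0) -> float:
    """Reynolds number rho*U*L/mu; water properties default to ``temp_c``."""
    rho = water_density(temp_c) if density_kg_m3 is None else density_kg_m3
    mu = water_viscosity(temp_c) if viscosity_pa_s is None else viscosity_pa_s
    if min(speed_m_s, fork_length_m, rho, mu) <= 0:
        raise ValueError("all Reynolds inputs must be positive")
    return rho * speed_m_s * fork_length_m / mu


@dataclass(frozen=True)
class KinematicsSummary:
    """Schooling/swimming kinematics for one speed."""

    mean_pairwise_bl: float
    sd_pairwise_bl: float
    school_length_bl: float
    mean_angle_to_flow_deg: float
    sd_angle_to_flow_deg: float
    mean_body_angle_deg: float
    ftb_hz: float
    turning_freq_per_fish: float
    amplitude_m: float
    strouhal: float
    reynolds: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def summarize_kinematics(
    track: Track3D,
    body_length_m: float,
    speed_bls: float,
    temp_c: float = 28.0,
    frames: np.ndarray | None = None,
) -> KinematicsSummary:
    """Compute the full kinematics panel for a track at one swimming speed."""
    sm = school_metrics(track, body_length_m, frames=frames)
    noses = track.landmark("nose")
    peds = track.landmark("peduncle")
    cross = track.landmark("crosshair")
    idx = np.arange(track.n_frames) if frames is None else np.asarray(frames, int)
    a2f, ba = [], []
    for f in idx:
        for n in range(track.n_fish):
            a2f.append(angle_to_flow(noses[f, n], peds[f, n], track.flow_axis))
            ba.append(body_angle_3d(noses[f, n], peds[f, n], cross[f, n]))
    headings = headings_from_track(track)
    ftbs, amps = [], []
    for n in range(track.n_fish):
        steady = steady_frames(headings[:, n], track.fps)
        sig = lateral_excursion(track, fish=n, frames=steady)
        ftbs.append(tail_beat_frequency(sig, track.fps))
        amps.append(tail_beat_amplitude(sig))
    turns = turning_frequency(headings, track.fps)
    speed_m_s = speed_bls * body_length_m
    ftb = float(np.mean(ftbs))
    amp = float(np.mean(amps))
    return KinematicsSummary(
        mean_pairwise_bl=sm.mean_pairwise_bl,
        sd_pairwise_bl=sm.sd_pairwise_bl,
        school_length_bl=sm.school_length_bl,
        mean_angle_to_flow_deg=float(np.mean(a2f)),
        sd_angle_to_flow_deg=float(np.std(a2f)),
        mean_body_angle_deg=float(np.mean(ba)),
        ftb_hz=ftb,
        turning_freq_per_fish=turns,
        amplitude_m=amp,
        strouhal=strouhal(ftb, amp, speed_m_s) if speed_m_s > 0 else float("nan"),
        reynolds=reynolds(speed_m_s, body_length_m, temp_c=temp_c)
        if speed_m_s > 0 else float("nan"),
    )
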