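"""Synthetic generators for every input the pipeline consumes.

The generators emulate the statistical structure of filopodium tip-tracking
data: a fluorescence signal with AR(1) temporal correlation, a tip-movement
signal that (in "responder" filopodia) follows the fluorescence at a fixed
lag, two-channel punctum images with a controlled fraction of shared centres,
event-triggered overlap/velocity traces, and SMLM localisation tables that
straddle the filter bounds. All generators are deterministic for a fixed
(parameters, seed) pair.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import FilopodiumTrack

__all__ = [
    "CouplingParams",
    "ImageSimParams",
    "simulate_coupled_track",
    "simulate_dataset",
    "simulate_two_channel_stack",
    "simulate_event_traces",
    "simulate_localizations",
]


@dataclasses.dataclass(frozen=True)
class CouplingParams:
    """Generative parameters for one coupled fluorescence/movement series.

    The latent tip-fluorescence state Z_t is a standardised AR(1) process with
    coefficient ``fluor_ar`` and innovation sd ``fluor_sd``. Responder
    movement is M_t = beta * Z_{t - lag} + N_t with N_t an AR(1) noise
    (coefficient ``movement_ar``, innovation sd ``movement_sd``, units
    um/frame); non-responder movement is N_t alone. Recorded tip fluorescence
    is an affine, strictly positive rescaling of Z_t.
    """

    beta: float = 0.15               # um/frame per sd of fluorescence
    lag: int = 1                     # frames by which fluorescence leads
    fluor_ar: float = 0.7
    fluor_sd: float = 1.0
    movement_ar: float = 0.3
    movement_sd: float = 0.12        # um/frame
    responder_fraction: float = 35 / 88
    n_frames: int = 150
    frame_interval: float = 2.0      # seconds
    missing_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0 < self.fluor_sd and 0 < self.movement_sd):
            raise ValueError("noise sds must be positive")
        if not (-1 < self.fluor_ar < 1 and -1 < self.movement_ar < 1):
            raise ValueError("AR coefficients must lie in (-1, 1)")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.lag >= self.n_frames:
            raise ValueError("lag must be smaller than n_frames")


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) sample path of length n."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
    eps = rng.normal(0.0, sd, size=n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


# affine map from latent state to recorded fluorescence units; boundary and
# body channels bracket it so normalisation recovers an affine image of Z
_FLUOR_OFFSET = 120.0
_FLUOR_SCALE = 25.0
_BOUNDARY_LEVEL = 20.0
_BODY_LEVEL = 140.0


def simulate_coupled_track(
    p: CouplingParams, responder: bool, seed: int
) -> tuple[FilopodiumTrack, dict]:
    """Generate one filopodium track plus its ground truth.

    Returns the track and a dict with keys ``responder``, ``latent_fluor``
    (the standardised latent state Z), ``movement`` (pre-masking M in
    um/frame), ``beta`` and ``lag``.
    """
    rng = np.random.default_rng(seed)
    n = p.n_frames
    z_raw = _ar1(rng, n, p.fluor_ar, p.fluor_sd)
    z = z_raw * np.sqrt(1.0 - p.fluor_ar**2) / p.fluor_sd  # unit-variance scale
    noise = _ar1(rng, n, p.movement_ar, p.movement_sd)
    m = noise.copy()
    if responder:
        m[p.lag:] += p.beta * z[: n - p.lag]
    tip_fluor = _FLUOR_OFFSET + _FLUOR_SCALE * z
    boundary = _BOUNDARY_LEVEL + rng.normal(0.0, 1.0, n)
    body = _BODY_LEVEL + rng.normal(0.0, 1.0, n)
    base_fluor = _FLUOR_OFFSET + _FLUOR_SCALE * _ar1(rng, n, p.fluor_ar, 1.0)
    length = np.maximum(0.0, 1.0 + np.cumsum(m))
    base_movement = rng.normal(0.0, 0.03, n)
    waviness = np.clip(rng.normal(0.15, 0.05, n), 0.0, 1.0)
    data = pd.DataFrame(
        {
            "frame": np.arange(1, n + 1),
            "tip_fluor": tip_fluor,
            "base_fluor": base_fluor,
            "body_fluor": body,
            "boundary_fluor": boundary,
            "length": length,
            "tip_movement": m,
            "base_movement": base_movement,
            "waviness": waviness,
        }
    )
    if p.missing_fraction > 0:
        for col in ("tip_fluor", "tip_movement", "base_fluor"):
            mask = rng.random(n) < p.missing_fraction
            data.loc[mask, col] = np.nan
    track = FilopodiumTrack(track_id=f"synt{seed}", frame_interval=p.frame_interval, data=data)
    truth = {
        "responder": bool(responder),
        "latent_fluor": z,
        "movement": m,
        "beta": p.beta if responder else 0.0,
        "lag": p.lag,
    }
    return track, truth


def simulate_dataset(
    p: CouplingParams, n_filopodia: int, seed: int | None = None
) -> tuple[list[FilopodiumTrack], list[dict]]:
    """Generate a pooled dataset of ``n_filopodia`` tracks.

    The first floor(responder_fraction * n) tracks are responders (the
    fractional remainder is dropped deterministically); per-track seeds are
    derived from the master seed so any subset is reproducible.
    """
    if n_filopodia < 1:
        raise ValueError("n_filopodia must be >= 1")
    master = p.seed if seed is None else seed
    n_resp = int(np.floor(p.responder_fraction * n_filopodia))
    ss = np.random.SeedSequence(master)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_filopodia)]
    tracks, truths = [], []
    for i in range(n_filopodia):
        tr, truth = simulate_coupled_track(p, responder=i < n_resp, seed=child_seeds[i])
        tr.track_id = f"filo{i:03d}"
        tracks.append(tr)
        truths.append(truth)
    return tracks, truths


@dataclasses.dataclass(frozen=True)
class ImageSimParams:
    """Parameters for a two-channel punctum image stack."""

    shape: tuple[int, int] = (128, 128)      # pixels (rows, cols)
    pixel_size: float = 0.065                # micrometres
    n_frames: int = 1
    amplitude: float = 100.0
    radius: float = 0.13                     # Gaussian sd, micrometres
    n_puncta_a: int = 10
    n_puncta_b: int = 10
    overlap_fraction: float = 0.5
    gauss_noise_sd: float = 0.0
    poisson_scale: float = 0.0
    drift_per_frame: float = 0.0             # micrometres per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.n_puncta_a < 0 or self.n_puncta_b < 0:
            raise ValueError("punctum counts must be >= 0")


def _draw_centres(
    rng: np.random.Generator, n: int, shape: tuple[int, int], min_sep_px: float
) -> list[tuple[float, float]]:
    """Rejection-sample punctum centres with a minimum pairwise separation."""
    margin = min_sep_px / 2.0
    centres: list[tuple[float, float]] = []
    attempts = 0
    while len(centres) < n:
        attempts += 1
        if attempts > 10000 * max(n, 1):
            raise RuntimeError("cannot place puncta with requested separation")
        r = rng.uniform(margin, shape[0] - 1 - margin)
        c = rng.uniform(margin, shape[1] - 1 - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep_px**2 for r0, c0 in centres):
            centres.append((r, c))
    return centres


def simulate_two_channel_stack(
    p: ImageSimParams,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a (2, n_frames, H, W) stack of Gaussian puncta plus ground truth.

    ``round(overlap_fraction * min(n_a, n_b))`` centres are shared between the
    channels; all remaining centres are unique to one channel. Centres are
    kept at least 8 Gaussian sds apart so rendered puncta never merge. The
    ground-truth table lists every punctum once (frame, channel, centre in
    pixels, shared flag); noise is added after rendering.
    """
    rng = np.random.default_rng(p.seed)
    sigma_px = p.radius / p.pixel_size
    n_shared = int(round(p.overlap_fraction * min(p.n_puncta_a, p.n_puncta_b)))
    stack = np.zeros((2, p.n_frames, *p.shape))
    rows = []
    yy, xx = np.mgrid[0 : p.shape[0], 0 : p.shape[1]]
    drift_px = p.drift_per_frame / p.pixel_size
    n_total = p.n_puncta_a + p.n_puncta_b - n_shared
    centres = _draw_centres(rng, n_total, p.shape, min_sep_px=8.0 * sigma_px)
    shared = centres[:n_shared]
    only_a = centres[n_shared : n_shared + (p.n_puncta_a - n_shared)]
    only_b = centres[n_shared + (p.n_puncta_a - n_shared) :]
    for f in range(p.n_frames):
        off = f * drift_px
        for ch, cents, flags in ((0, shared + only_a, None), (1, shared + only_b, None)):
            for i, (r, c) in enumerate(cents):
                rr, cc = r + off, c + off
                stack[ch, f] += p.amplitude * np.exp(
                    -((yy - rr) ** 2 + (xx - cc) ** 2) / (2.0 * sigma_px**2)
                )
                rows.append(
                    {
                        "frame": f,
                        "channel": "A" if ch == 0 else "B",
                        "row": rr,
                        "col": cc,
                        "shared": (r, c) in shared,
                    }
                )
    if p.gauss_noise_sd > 0:
        stack += rng.normal(0.0, p.gauss_noise_sd, stack.shape)
    if p.poisson_scale > 0:
        stack = rng.poisson(np.maximum(stack, 0.0) * p.poisson_scale) / p.poisson_scale
    truth = pd.DataFrame(rows, columns=["frame", "channel", "row", "col", "shared"])
    return stack, truth


def simulate_event_traces(
    n_events: int,
    pre_overlap_prob: float,
    post_overlap_prob: float,
    velocity_burst: float,
    window: int,
    frame_interval: float = 1.5,
    seed: int = 0,
    event_type: str = "re_extension",
) -> tuple[list[dict], list[dict]]:
    """Generate event-centred traces for the event-alignment pipeline.

    Each trace spans ``2*window + 1`` frames centred on its event frame.
    The per-frame overlap flag is Bernoulli(pre_overlap_prob) before the
    event and Bernoulli(post_overlap_prob) from the event frame on; tip
    velocity is zero except for a one-frame pulse of ``velocity_burst``
    (um/s) at the event. Returns (traces, events) ready for
    :func:`filocausal.puncta_overlap.align_to_events`.
    """
    if window < 1:
        raise ValueError("window must be >= 1 frame")
    if not (0 <= pre_overlap_prob <= 1 and 0 <= post_overlap_prob <= 1):
        raise ValueError("overlap probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = 2 * window + 1
    traces, events = [], []
    for i in range(n_events):
        vel = np.zeros(n)
        vel[window] = velocity_burst
        position = np.concatenate([[0.0], np.cumsum(vel[1:] * frame_interval)])
        overlap = np.empty(n, dtype=bool)
        overlap[:window] = rng.random(window) < pre_overlap_prob
        overlap[window:] = rng.random(window + 1) < post_overlap_prob
        fluor_a = 1.0 + 0.5 * overlap + rng.normal(0.0, 0.05, n)
        fluor_b = 1.0 + 0.3 * overlap + rng.normal(0.0, 0.05, n)
        traces.append(
            {
                "position": position,
                "fluor_a": fluor_a,
                "fluor_b": fluor_b,
                "overlap": overlap,
            }
        )
        events.append({"event_id": f"ev{i:03d}", "type": event_type, "frame": window})
    return traces, events


_SMLM_BOUNDS = {
    "photons": (50.0, 5000.0),
    "precision": (0.5, 50.0),
    "sigma": (50.0, 150.0),
}
_LLR_MAX = 150.0


def simulate_localizations(
    n: int, scenario: str = "straddle", seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a localisation table with known keep/drop labels.

    ``scenario='in_bounds'`` draws every attribute inside the filter bounds
    (all labels keep). ``scenario='straddle'`` makes each row violate exactly
    one bound, cycling through photons-low/high, precision-low/high, llr-high,
    sigma-low/high, then an in-bounds row.
    """
    rng = np.random.default_rng(seed)
    rows = []
    labels = np.ones(n, dtype=bool)

    def in_bounds_row() -> dict:
        return {
            "x": rng.uniform(0, 5000),
            "y": rng.uniform(0, 5000),
            "photons": rng.uniform(100, 4000),
            "precision": rng.uniform(5, 30),
            "llr": rng.uniform(10, 100),
            "sigma": rng.uniform(80, 140),
        }

    violations = [
        ("photons", 10.0), ("photons", 6000.0),
        ("precision", 0.1), ("precision", 80.0),
        ("llr", 200.0),
        ("sigma", 20.0), ("sigma", 200.0),
        (None, None),
    ]
    for i in range(n):
        row = in_bounds_row()
        if scenario == "straddle":
            field, value = violations[i % len(violations)]
            if field is not None:
                row[field] = value
                labels[i] = False
        elif scenario != "in_bounds":
            raise ValueError(f"unknown scenario {scenario!r}")
        rows.append(row)
    cols = ["x", "y", "photons", "precision", "llr", "sigma"]
    table = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    return table, labels
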