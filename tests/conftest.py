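import numpy as np
import pytest

from wormtrace.synthetic import (NeuronSpec, SceneConfig, KINETICS_PRESETS,
                                 simulate_movie)


def small_scene(seed=0, **overrides):
    """Compact two-neuron scene for fast unit tests (not the full
    acquisition geometry)."""
    defaults = dict(
        height_px=64, width_px=64, n_frames=80, n_z=3,
        stimulus_onset_frame=20, stimulus_duration_frames=30,
        drift_step_sd_px=0.0, twitch_prob=0.0, twitch_max_px=0,
        background_level=100.0, background_gradient=0.2,
        read_noise_sd=3.0, shot_noise=True, seed=seed,
    )
    defaults.update(overrides)
    cfg = SceneConfig(**defaults)
    if not cfg.neurons:
        cfg.neurons = [
            NeuronSpec("left", (30.0, 20.0), radius_px=4.0, baseline_B=400.0,
                       amplitude_A=1.6, true_class="high",
                       **KINETICS_PRESETS["fast"]),
            NeuronSpec("right", (34.0, 44.0), radius_px=4.0, baseline_B=180.0,
                       amplitude_A=1.6, true_class="high",
                       **KINETICS_PRESETS["slow"]),
        ]
    cfg.validate()
    return cfg


def noiseless_scene(seed=0, **overrides):
    base = dict(read_noise_sd=0.0, shot_noise=False)
    base.update(overrides)
    return small_scene(seed=seed, **base)


@pytest.fixture(scope="session")
def noiseless_movie():
    """Drift-free, noise-free small movie plus ground truth."""
    return simulate_movie(noiseless_scene())


@pytest.fixture(scope="session")
def noisy_movie():
    """Small movie with default noise, still drift-free."""
    return simulate_movie(small_scene(seed=5))


@pytest.fixture(scope="session")
def drifting_movie():
    """Small movie with integer drift and twitches, plus noise."""
    cfg = small_scene(seed=9, drift_step_sd_px=0.4, twitch_prob=0.05,
                      twitch_max_px=3)
    return simulate_movie(cfg)


def zncc_direct(ref, mov, gate):
    """Exhaustive-search overlap ZNCC oracle (plain slicing, no FFT)."""
    H, W = ref.shape
    out = np.full((2 * gate + 1, 2 * gate + 1), -np.inf)
    for dy in range(-gate, gate + 1):
        for dx in range(-gate, gate + 1):
            ys = slice(max(dy, 0), min(H + dy, H))
            xs = slice(max(dx, 0), min(W + dx, W))
            ysr = slice(max(-dy, 0), min(H - dy, H))
            xsr = slice(max(-dx, 0), min(W - dx, W))
            a = ref[ysr, xsr].astype(float).ravel()
            b = mov[ys, xs].astype(float).ravel()
            if a.size < 2:
                continue
            a = a - a.mean()
            b = b - b.mean()
            denom = np.sqrt((a * a).sum() * (b * b).sum())
            if denom <= 1e-9 * a.size:
                continue
            out[dy + gate, dx + gate] = (a * b).sum() / denom
    return out


def best_gated_assignment(heads, dets, gate):
    """Brute-force oracle: over all one-to-one matchings within the gate,
    maximize the number of matched pairs, then minimize total distance."""
    from itertools import permutations

    heads = np.asarray(heads, float).reshape(-1, 2)
    dets = np.asarray(dets, float).reshape(-1, 2)
    n, m = len(heads), len(dets)
    best = (-1, np.inf, [])
    # enumerate all injective maps from the smaller side into the larger
    if n <= m:
        for perm in permutations(range(m), n):
            pairs, dist = [], 0.0
            for h, d in enumerate(perm):
                dd = float(np.linalg.norm(heads[h] - dets[d]))
                if dd <= gate:
                    pairs.append((h, d))
                    dist += dd
            cand = (len(pairs), -dist)
            if cand > (best[0], -best[1]):
                best = (len(pairs), dist, pairs)
    else:
        for perm in permutations(range(n), m):
            pairs, dist = [], 0.0
            for d, h in enumerate(perm):
                dd = float(np.linalg.norm(heads[h] - dets[d]))
                if dd <= gate:
                    pairs.append((h, d))
                    dist += dd
            cand = (len(pairs), -dist)
            if cand > (best[0], -best[1]):
                best = (len(pairs), dist, pairs)
    return best  # (n_matched, total_distance, pairs)
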