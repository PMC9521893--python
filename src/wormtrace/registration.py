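"""Whole-field motion correction by integer-shift cross-correlation.

Every projected frame is aligned to the first frame of the series by
maximizing the zero-mean normalized cross-correlation (ZNCC) over all
integer shifts within a gate.  The ZNCC at each candidate shift is computed
exactly over the overlap region (the running sums needed for per-shift
normalization are obtained with FFT correlations), so the returned shift is
the true gated optimum, with deterministic tie-breaking.  Shifts are integer
only; aligned frames are produced by translation with zero fill.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import fft as sfft

from .io import ProjectedMovie
from .synthetic import shift_image

__all__ = ["Shift", "ShiftSeries", "estimate_shift", "register_movie", "validity_mask"]

DEFAULT_MAX_SHIFT = 20
DEFAULT_SCORE_FLOOR = 0.3
_TIE_DECIMALS = 9  # scores equal to this precision are tie-broken geometrically


@dataclass
class Shift:
    """One frame's estimated displacement relative to the reference."""

    dy: int
    dx: int
    score: float  # ZNCC at the chosen shift, in [-1, 1]
    low_confidence: bool = False
    degenerate: bool = False


@dataclass
class ShiftSeries:
    shifts: list[Shift] = field(default_factory=list)
    reference_frame: int = 0
    max_shift: int = DEFAULT_MAX_SHIFT

    def as_array(self) -> np.ndarray:
        return np.array([[s.dy, s.dx] for s in self.shifts], dtype=int)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "reference_frame": self.reference_frame,
                "max_shift": self.max_shift,
                "shifts": [asdict(s) for s in self.shifts],
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ShiftSeries":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            shifts=[Shift(**s) for s in d["shifts"]],
            reference_frame=d["reference_frame"],
            max_shift=d["max_shift"],
        )


class ReferenceCorrelator:
    """Exact gated overlap-ZNCC against a fixed reference image.

    For displacement d = (dy, dx) the overlap correlation is
    C_ab(d) = sum_x a(x) * b(x + d); the five running sums entering the
    per-shift ZNCC normalization are cross-correlations of the images (or
    their squares) with a ones mask.  They are evaluated with FFTs padded
    far enough that the gated window is free of circular wraparound, and
    everything that depends only on the reference is precomputed once so a
    whole movie can be scored against frame 0 cheaply.
    """

    def __init__(self, reference: np.ndarray, max_shift: int):
        if max_shift < 0:
            raise ValueError("max_shift must be nonnegative")
        ref = reference.astype(float)
        H, W = ref.shape
        g = min(max_shift, H - 1, W - 1)
        self.shape = (H, W)
        self.max_shift = max_shift
        self.gate = g
        self._Ly = sfft.next_fast_len(H + g)
        self._Lx = sfft.next_fast_len(W + g)
        ones = np.ones_like(ref)
        self._ONES_c = np.conj(self._fft(ones))
        self._REF_c = np.conj(self._fft(ref))
        # reference-only sums over the overlap, one value per gated shift
        self.n = self._corr_from_spec(self._ONES_c, ones)
        self.s_r = self._gated(sfft.irfft2(self._REF_c * self._fft(ones),
                                           s=(self._Ly, self._Lx)))
        self.s_rr = self._gated(sfft.irfft2(np.conj(self._fft(ref * ref))
                                            * self._fft(ones),
                                            s=(self._Ly, self._Lx)))

    def _fft(self, a):
        return sfft.rfft2(a, s=(self._Ly, self._Lx))

    def _gated(self, full):
        """Extract the (2g+1)^2 window of displacements, dy/dx in [-g, g],
        embedded centrally in a (2*max_shift+1)^2 array (out-of-range
        shifts, possible on tiny images, read as -inf later)."""
        g, G = self.gate, self.max_shift
        idx_y = np.arange(-g, g + 1) % self._Ly
        idx_x = np.arange(-g, g + 1) % self._Lx
        win = full[np.ix_(idx_y, idx_x)]
        if g == G:
            return win
        out = np.zeros((2 * G + 1, 2 * G + 1))
        out[G - g:G + g + 1, G - g:G + g + 1] = win
        return out

    def _corr_from_spec(self, a_conj_spec, b):
        return self._gated(sfft.irfft2(a_conj_spec * self._fft(b),
                                       s=(self._Ly, self._Lx)))

    def surface(self, moving: np.ndarray) -> np.ndarray:
        """ZNCC of `moving` against the reference for every gated shift.

        Entry [i, j] corresponds to dy = i - max_shift, dx = j - max_shift.
        Shifts whose overlap has (near) zero variance get -inf.
        """
        if moving.shape != self.shape:
            raise ValueError("moving image shape must match the reference")
        mov = moving.astype(float)
        MOV = self._fft(mov)
        MOV2 = self._fft(mov * mov)
        s_rm = self._gated(sfft.irfft2(self._REF_c * MOV, s=(self._Ly, self._Lx)))
        s_m = self._gated(sfft.irfft2(self._ONES_c * MOV, s=(self._Ly, self._Lx)))
        s_mm = self._gated(sfft.irfft2(self._ONES_c * MOV2, s=(self._Ly, self._Lx)))
        return _zncc_from_sums(self.n, s_rm, self.s_r, s_m, self.s_rr, s_mm)


def _zncc_from_sums(n, s_rm, s_r, s_m, s_rr, s_mm) -> np.ndarray:
    n = np.where(n > 0.5, n, np.nan)  # out-of-range shifts on tiny images
    with np.errstate(invalid="ignore", divide="ignore"):
        var_r = np.clip(s_rr - s_r * s_r / n, 0.0, None)
        var_m = np.clip(s_mm - s_m * s_m / n, 0.0, None)
        num = s_rm - s_r * s_m / n
        denom = np.sqrt(var_r * var_m)
        score = num / denom
    score[~np.isfinite(score)] = -np.inf
    with np.errstate(invalid="ignore"):
        score[denom <= 1e-9 * np.maximum(n, 1)] = -np.inf
    return np.clip(score, -1.0, 1.0, out=score)


def zncc_surface(reference: np.ndarray, moving: np.ndarray,
                 max_shift: int) -> np.ndarray:
    """Gated overlap-ZNCC surface for a single image pair."""
    return ReferenceCorrelator(reference, max_shift).surface(moving)


def _pick_shift(surf: np.ndarray, max_shift: int,
                score_floor: float) -> Shift:
    if not np.isfinite(surf).any():
        return Shift(0, 0, 0.0, low_confidence=True, degenerate=True)

    g = max_shift
    dys, dxs = np.meshgrid(np.arange(-g, g + 1), np.arange(-g, g + 1), indexing="ij")
    rounded = np.round(surf, _TIE_DECIMALS)
    best = rounded.max()
    cand = np.argwhere(rounded == best)
    # deterministic tie-break: closest to zero shift, then dy, then dx
    order = sorted(
        (abs(dys[i, j]) + abs(dxs[i, j]), dys[i, j], dxs[i, j], i, j)
        for i, j in cand
    )
    _, dy, dx, i, j = order[0]
    score = float(surf[i, j])
    return Shift(int(dy), int(dx), score, low_confidence=score < score_floor)


def estimate_shift(reference: np.ndarray, moving: np.ndarray,
                   max_shift: int = DEFAULT_MAX_SHIFT,
                   score_floor: float = DEFAULT_SCORE_FLOOR) -> Shift:
    """Best integer shift of `moving` relative to `reference`.

    Returns the gated shift maximizing the overlap ZNCC; ties (to 1e-9) are
    broken by smallest |dy|+|dx|, then smallest dy, then dx.  A constant
    image yields a degenerate (0, 0) result rather than an error.
    """
    if reference.shape != moving.shape:
        raise ValueError("reference and moving images must share a shape")
    if max_shift < 0:
        raise ValueError("max_shift must be nonnegative")
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        return Shift(0, 0, 0.0, low_confidence=True, degenerate=True)
    surf = zncc_surface(reference, moving, max_shift)
    return _pick_shift(surf, max_shift, score_floor)


def validity_mask(shape: tuple[int, int], shift: Shift) -> np.ndarray:
    """Pixels of a registered frame that carry real data (not zero padding)."""
    return shift_image(np.ones(shape, dtype=bool), -shift.dy, -shift.dx)


def register_movie(movie: ProjectedMovie,
                   max_shift: int = DEFAULT_MAX_SHIFT,
                   score_floor: float = DEFAULT_SCORE_FLOOR,
                   ) -> tuple[ProjectedMovie, ShiftSeries]:
    """Align every frame to frame 0 by its estimated gated shift.

    Frame t is translated by the negated estimated shift with zero fill; the
    reference frame's shift is (0, 0) with score 1 by construction.
    """
    data = movie.data
    ref = data[0].astype(float)
    out = np.empty_like(data)
    out[0] = data[0]
    series = ShiftSeries(max_shift=max_shift)
    series.shifts.append(Shift(0, 0, 1.0))
    ref_degenerate = np.ptp(ref) == 0
    correlator = None if ref_degenerate else ReferenceCorrelator(ref, max_shift)
    for t in range(1, data.shape[0]):
        mov = data[t].astype(float)
        if ref_degenerate or np.ptp(mov) == 0:
            s = Shift(0, 0, 0.0, low_confidence=True, degenerate=True)
        else:
            s = _pick_shift(correlator.surface(mov), max_shift, score_floor)
        series.shifts.append(s)
        out[t] = shift_image(data[t], -s.dy, -s.dx)
    return movie.with_data(out), series
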