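"""Coincidence-image estimation from left/right frame stacks.

The estimator is the temporal covariance of inversely registered pixel
pairs.  With the total intensities I^L = I_coin + I_noise^L and
I^R = I_coin + I_noise^R at a mirrored pixel pair, and detector noise that
is uncorrelated between the two regions,

    cov(I^L, I^R) = var(I_coin) = mean(I_coin),

the last equality because the coincidence count is Poisson (variance equals
mean).  The covariance image therefore estimates the mean coincidence
intensity directly, while any left/right-uncorrelated contribution — read
noise, dark counts, stray-light speckle — drops out in expectation whatever
its magnitude.  Covariances use the population normalization 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .biphoton_sim import FrameStack

__all__ = [
    "RegisteredPairMap",
    "CoincidenceImage",
    "CovarianceAccumulator",
    "CenterNotFoundError",
    "estimate_center",
    "covariance_coincidence",
    "classical_from_stack",
    "bin2",
]


class CenterNotFoundError(RuntimeError):
    """No symmetric correlation peak above the landscape noise floor."""


def _frames_of(stack) -> "FrameStack | np.ndarray":
    return stack


def _iter_chunks(stack, chunk_size: int):
    if isinstance(stack, FrameStack):
        yield from stack.iter_chunks(chunk_size)
    else:
        arr = np.asarray(stack)
        if arr.ndim != 3:
            raise ValueError("expected a (n, rows, cols) stack")
        for start in range(0, arr.shape[0], chunk_size):
            yield arr[start : start + chunk_size]


def _stack_info(stack) -> tuple[int, tuple[int, int]]:
    if isinstance(stack, FrameStack):
        return stack.n_frames, stack.shape
    arr = np.asarray(stack)
    return arr.shape[0], arr.shape[1:]


@dataclass
class RegisteredPairMap:
    """Mirror registration p -> p' = S - p between left and right regions.

    ``center_sum`` S is an integer pair; the map is an involution.  Left
    pixels whose mirror falls outside the right region are flagged invalid
    and excluded from estimates.
    """

    center_sum: tuple[int, int]
    left_shape: tuple[int, int]
    right_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.center_sum = (int(self.center_sum[0]), int(self.center_sum[1]))
        self.left_shape = tuple(self.left_shape)
        if self.right_shape is None:
            self.right_shape = self.left_shape
        self.right_shape = tuple(self.right_shape)

    @classmethod
    def full_flip(cls, shape: tuple[int, int]) -> "RegisteredPairMap":
        return cls((shape[0] - 1, shape[1] - 1), shape, shape)

    def mirror(self, p: tuple[int, int]) -> tuple[int, int]:
        return (self.center_sum[0] - p[0], self.center_sum[1] - p[1])

    @property
    def valid_mask(self) -> np.ndarray:
        """Left-region pixels whose mirror lies inside the right region."""
        rows, cols = self.left_shape
        rr, cr = self.right_shape
        s0, s1 = self.center_sum
        p0 = np.arange(rows)[:, None]
        p1 = np.arange(cols)[None, :]
        return ((s0 - p0 >= 0) & (s0 - p0 < rr) & (s1 - p1 >= 0) & (s1 - p1 < cr))

    def align_right(self, chunk: np.ndarray) -> np.ndarray:
        """Reindex a right-region chunk so aligned[..., p] = chunk[..., S-p].

        Positions without a valid mirror are zero-filled (and masked out of
        the final estimate).
        """
        rows, cols = self.left_shape
        rr, cr = self.right_shape
        s0, s1 = self.center_sum
        out = np.zeros(chunk.shape[:-2] + (rows, cols), dtype=chunk.dtype)
        p0a, p0b = max(0, s0 - rr + 1), min(rows - 1, s0)
        p1a, p1b = max(0, s1 - cr + 1), min(cols - 1, s1)
        if p0a > p0b or p1a > p1b:
            return out
        block = chunk[..., s0 - p0b : s0 - p0a + 1, s1 - p1b : s1 - p1a + 1]
        out[..., p0a : p0b + 1, p1a : p1b + 1] = block[..., ::-1, ::-1]
        return out


@dataclass
class CoincidenceImage:
    """Reconstructed mean coincidence intensity with provenance.

    ``values`` may contain small negatives (noise around zero rate); they
    are retained — clipping, if any, belongs to display-time normalization.
    ``std_error`` is the per-pixel standard error of the covariance
    estimate, sqrt((var_L * var_R + cov^2) / N).
    """

    values: np.ndarray
    n_frames: int
    center_sum: tuple[int, int]
    std_error: np.ndarray
    var_left: np.ndarray
    var_right: np.ndarray
    mean_left: np.ndarray
    mean_right: np.ndarray

    def to_fits(self, path, extra_header: dict | None = None):
        from ._fits import write_image

        header = {
            "NFRAMES": int(self.n_frames),
            "CTRSUM0": int(self.center_sum[0]),
            "CTRSUM1": int(self.center_sum[1]),
        }
        header.update(extra_header or {})
        return write_image(path, self.values.astype(np.float64), header)


class CovarianceAccumulator:
    """Single-pass, chunk-merged first/second-moment accumulator.

    Each chunk's mean and (co)moment are computed exactly, then merged with
    the running totals by the pairwise-update formulas, so the result is
    numerically stable and independent of chunking.
    """

    def __init__(self, shape: tuple[int, int]) -> None:
        self.n = 0
        self.mean_l = np.zeros(shape)
        self.mean_r = np.zeros(shape)
        self.comoment = np.zeros(shape)
        self.m2_l = np.zeros(shape)
        self.m2_r = np.zeros(shape)
        # shift constants + shifted power sums for the (2,2) mixed moment,
        # which sets the standard error of the covariance estimate
        self._shift_l = None
        self._shift_r = None
        self._s = {key: np.zeros(shape) for key in ("10", "01", "11", "20", "02", "21", "12", "22")}

    def update(self, left_chunk: np.ndarray, right_chunk: np.ndarray) -> None:
        l = np.asarray(left_chunk, dtype=np.float64)
        r = np.asarray(right_chunk, dtype=np.float64)
        nb = l.shape[0]
        ml, mr = l.mean(axis=0), r.mean(axis=0)
        dl, dr = l - ml, r - mr
        cb = np.einsum("ijk,ijk->jk", dl, dr)
        m2lb = np.einsum("ijk,ijk->jk", dl, dl)
        m2rb = np.einsum("ijk,ijk->jk", dr, dr)
        if self._shift_l is None:
            self._shift_l, self._shift_r = ml.copy(), mr.copy()
        u, v = l - self._shift_l, r - self._shift_r
        s = self._s
        s["10"] += u.sum(axis=0)
        s["01"] += v.sum(axis=0)
        s["11"] += np.einsum("ijk,ijk->jk", u, v)
        u2, v2 = u * u, v * v
        s["20"] += u2.sum(axis=0)
        s["02"] += v2.sum(axis=0)
        s["21"] += np.einsum("ijk,ijk->jk", u2, v)
        s["12"] += np.einsum("ijk,ijk->jk", u, v2)
        s["22"] += np.einsum("ijk,ijk->jk", u2, v2)
        if self.n == 0:
            self.n, self.mean_l, self.mean_r = nb, ml, mr
            self.comoment, self.m2_l, self.m2_r = cb, m2lb, m2rb
            return
        na, n = self.n, self.n + nb
        delta_l, delta_r = ml - self.mean_l, mr - self.mean_r
        w = na * nb / n
        self.comoment += cb + delta_l * delta_r * w
        self.m2_l += m2lb + delta_l**2 * w
        self.m2_r += m2rb + delta_r**2 * w
        self.mean_l += delta_l * nb / n
        self.mean_r += delta_r * nb / n
        self.n = n

    def result(self, center_sum: tuple[int, int]) -> CoincidenceImage:
        if self.n < 2:
            raise ValueError("need at least 2 frames to estimate a covariance")
        n = self.n
        cov = self.comoment / n
        var_l = self.m2_l / n
        var_r = self.m2_r / n
        # central mixed moment E[dL^2 dR^2] from shifted raw sums; the
        # large-sample variance of the sample covariance is (m22 - cov^2)/N
        s = self._s
        a, b = s["10"] / n, s["01"] / n
        m22 = (
            s["22"] / n
            - 2.0 * b * s["21"] / n
            - 2.0 * a * s["12"] / n
            + b**2 * s["20"] / n
            + a**2 * s["02"] / n
            + 4.0 * a * b * s["11"] / n
            - 3.0 * a**2 * b**2
        )
        se = np.sqrt(np.maximum(m22 - cov**2, 0.0) / n)
        return CoincidenceImage(
            values=cov,
            n_frames=self.n,
            center_sum=tuple(center_sum),
            std_error=se,
            var_left=var_l,
            var_right=var_r,
            mean_left=self.mean_l,
            mean_right=self.mean_r,
        )


def covariance_coincidence(
    left,
    right,
    pairs: RegisteredPairMap | None = None,
    *,
    chunk_size: int = 1000,
    binning: int = 1,
) -> CoincidenceImage:
    """Estimate the coincidence image as cov(I^L(p), I^R(S - p)).

    Streams both stacks chunk by chunk (memory bounded at one chunk) and
    matches a naive two-pass covariance to floating-point accuracy.  Pixels
    without a valid mirror are NaN in the output.  ``binning`` > 1 sums
    counts in ``binning x binning`` blocks before the covariance; the center
    is then interpreted on the binned grid.
    """
    n_l, shape_l = _stack_info(left)
    n_r, shape_r = _stack_info(right)
    if n_l != n_r:
        raise ValueError(f"frame counts differ: {n_l} vs {n_r}")
    if n_l < 2:
        raise ValueError("need at least 2 frames to estimate a covariance")
    if binning > 1:
        shape_l = tuple(s // binning for s in shape_l)
        shape_r = tuple(s // binning for s in shape_r)
    if pairs is None:
        pairs = RegisteredPairMap.full_flip(shape_l)
    if pairs.left_shape != tuple(shape_l) or pairs.right_shape != tuple(shape_r):
        raise ValueError(
            f"pair map shapes {pairs.left_shape}/{pairs.right_shape} do not "
            f"match stacks {shape_l}/{shape_r}"
        )

    acc = CovarianceAccumulator(tuple(shape_l))
    for lc, rc in zip(_iter_chunks(left, chunk_size), _iter_chunks(right, chunk_size)):
        if lc.shape[0] != rc.shape[0]:
            raise ValueError("left/right chunking out of step")
        lc = lc.astype(np.float64)
        rc = rc.astype(np.float64)
        if binning > 1:
            lc, rc = bin2(lc, binning), bin2(rc, binning)
        acc.update(lc, pairs.align_right(rc))
    img = acc.result(pairs.center_sum)
    invalid = ~pairs.valid_mask
    if invalid.any():
        img.values = img.values.copy()
        img.values[invalid] = np.nan
        img.std_error[invalid] = np.nan
    return img


def classical_from_stack(stack, *, chunk_size: int = 1000, binning: int = 1) -> np.ndarray:
    """Per-pixel temporal mean of the signal-arm stack (the classical image)."""
    n, shape = _stack_info(stack)
    if n < 1:
        raise ValueError("empty stack")
    if binning > 1:
        shape = tuple(s // binning for s in shape)
    total = np.zeros(shape)
    for chunk in _iter_chunks(stack, chunk_size):
        c = chunk.astype(np.float64)
        if binning > 1:
            c = bin2(c, binning)
        total += c.sum(axis=0)
    return total / n


def bin2(frames: np.ndarray, factor: int = 2) -> np.ndarray:
    """Sum counts in ``factor x factor`` blocks over the last two axes.

    Trailing rows/columns that do not fill a block are dropped (a typical
    acquisition keeps a 100 x 50 pixel area *after* binning of 2).
    """
    frames = np.asarray(frames)
    r, c = frames.shape[-2] // factor, frames.shape[-1] // factor
    trimmed = frames[..., : r * factor, : c * factor]
    shape = trimmed.shape[:-2] + (r, factor, c, factor)
    return trimmed.reshape(shape).sum(axis=(-3, -1))


def estimate_center(
    left,
    right,
    search_window: int | None = None,
    *,
    chunk_size: int = 1000,
    min_peak_snr: float = 6.0,
    return_landscape: bool = False,
):
    """Find the integer center sum S maximizing the total pair covariance.

    The objective sum_p cov(I^L(p), I^R(S - p)) for *all* candidate S is the
    frame-summed full convolution of the temporally demeaned stacks, so the
    whole covariance landscape is computed in one FFT pass; landscape index
    (a, b) is the candidate center sum itself.  ``search_window`` (half-width
    in pixels) restricts candidates around the full-flip center.

    Raises :class:`CenterNotFoundError` when the landscape peak does not
    stand ``min_peak_snr`` robust standard deviations (1.4826 * MAD) above
    the landscape median — i.e. no coincidence signal is present.
    """
    n_l, shape_l = _stack_info(left)
    n_r, shape_r = _stack_info(right)
    if n_l != n_r:
        raise ValueError(f"frame counts differ: {n_l} vs {n_r}")
    if n_l < 2:
        raise ValueError("need at least 2 frames")

    # pass 1: temporal means
    sum_l = np.zeros(shape_l)
    sum_r = np.zeros(shape_r)
    for lc, rc in zip(_iter_chunks(left, chunk_size), _iter_chunks(right, chunk_size)):
        sum_l += lc.astype(np.float64).sum(axis=0)
        sum_r += rc.astype(np.float64).sum(axis=0)
    mean_l, mean_r = sum_l / n_l, sum_r / n_r

    # pass 2: landscape(S) = (1/N) sum_i conv(dL_i, dR_i)(S)
    landscape = np.zeros(
        (shape_l[0] + shape_r[0] - 1, shape_l[1] + shape_r[1] - 1)
    )
    for lc, rc in zip(_iter_chunks(left, chunk_size), _iter_chunks(right, chunk_size)):
        dl = lc.astype(np.float64) - mean_l
        dr = rc.astype(np.float64) - mean_r
        landscape += fftconvolve(dl, dr, mode="full", axes=(1, 2)).sum(axis=0)
    landscape /= n_l

    # cells of the full landscape sum different numbers of pixel pairs;
    # normalize by sqrt(pair count) so the noise floor is uniform before
    # testing the peak against it
    counts = fftconvolve(np.ones(shape_l), np.ones(shape_r), mode="full")
    counts = np.maximum(np.rint(counts), 1.0)
    normalized = landscape / np.sqrt(counts)

    if search_window is not None:
        s0c, s1c = shape_l[0] - 1, shape_l[1] - 1
        w = int(search_window)
        window = np.full(landscape.shape, False)
        window[
            max(0, s0c - w) : s0c + w + 1, max(0, s1c - w) : s1c + w + 1
        ] = True
        candidates = np.where(window, landscape, -np.inf)
        stat_region = normalized[window]
    else:
        candidates = landscape
        stat_region = normalized.ravel()

    med = np.median(stat_region)
    mad = np.median(np.abs(stat_region - med))
    robust_sigma = 1.4826 * mad
    peak_idx = np.unravel_index(np.argmax(candidates), candidates.shape)
    peak = normalized[peak_idx]
    if robust_sigma == 0.0 or (peak - med) < min_peak_snr * robust_sigma:
        raise CenterNotFoundError(
            "no symmetric correlation found: landscape peak "
            f"{peak:.3g} is within the noise floor (median {med:.3g}, "
            f"robust sigma {robust_sigma:.3g})"
        )
    center = (int(peak_idx[0]), int(peak_idx[1]))
    if return_landscape:
        return center, landscape
    return center
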