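"""Sample entropy and multiscale entropy (MSE).

Sample entropy SampEn(m, r, N) = -log(A / B), where B counts unordered
pairs of length-m templates whose Chebyshev distance is <= r and A counts
the same for templates extended to length m + 1.  Match counting follows
the Richman-Moorman convention: templates of both lengths are drawn from
the first N - m starting positions, self-matches are excluded, and the
distance test is inclusive.  Under this convention a constant input gives
A == B and SampEn exactly 0.

The multiscale profile applies SampEn to coarse-grained copies of the
series: at scale tau, non-overlapping blocks of tau consecutive samples
are replaced by their mean, shortening the series to floor(N / tau)
points.  The tolerance r is fixed once from the scale-1 series (by
default 0.15 x its standard deviation) and reused at every scale, so the
profile reflects changing temporal structure rather than the variance
reduction that coarse-graining itself causes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "SampEnParams",
    "MSEProfile",
    "coarse_grain",
    "match_counts",
    "sample_entropy",
    "mse_profile",
]


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters.

    m : template length (default 2).
    r_factor : tolerance multiplier (default 0.15); interpreted relative
        to the epoch standard deviation unless ``r_mode="absolute"``, in
        which case it is the tolerance in amplitude units.
    The match metric is always the Chebyshev (max-coordinate) distance.
    """

    m: int = 2
    r_factor: float = 0.15
    r_mode: str = "relative_to_epoch_sd"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError(f"template length m must be >= 1, got {self.m}")
        if self.r_factor <= 0:
            raise ParameterError(f"r_factor must be > 0, got {self.r_factor}")
        if self.r_mode not in ("relative_to_epoch_sd", "absolute"):
            raise ParameterError(f"unknown r_mode {self.r_mode!r}")


@dataclass
class MSEProfile:
    """SampEn values over scales 1..tau_max for one epoch.

    ``values[tau - 1]`` is the sample entropy (nats) of the series
    coarse-grained at scale tau; undefined entries (no m+1 matches) are
    NaN.  ``n_points[tau - 1]`` is the coarse-grained length floor(N/tau)
    and ``r_abs`` is the tolerance, fixed from the scale-1 series.
    """

    values: np.ndarray
    tau_max: int
    n_points: np.ndarray
    r_abs: float
    params: SampEnParams = field(default_factory=SampEnParams)

    def __len__(self) -> int:
        return self.tau_max

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.values).sum())


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Block-average ``x`` at scale ``tau``.

    Returns y with y[j] = mean(x[j*tau : (j+1)*tau]) for
    j = 0..floor(N/tau)-1; trailing remainder samples are dropped.
    """
    x = np.asarray(x, dtype=float).ravel()
    if tau < 1:
        raise ParameterError(f"scale tau must be >= 1, got {tau}")
    if tau > x.size:
        raise ParameterError(f"scale tau={tau} exceeds series length {x.size}")
    if tau == 1:
        return x.copy()
    k = x.size // tau
    return x[: k * tau].reshape(k, tau).mean(axis=1)


def match_counts(
    x: np.ndarray, m: int, r_abs: float, *, chunk: int = 512
) -> tuple[int, int]:
    """Count template matches (A, B) for SampEn.

    B counts unordered template pairs of length ``m`` within Chebyshev
    distance ``r_abs`` (inclusive); A counts the same pairs whose
    length-(m+1) extensions also match.  Both template sets start at the
    first N - m positions, so the two counts range over identical pairs
    and a constant input yields A == B.

    Vectorised in row blocks of ``chunk`` templates; O(N^2) time,
    O(chunk * N) memory.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < m + 2:
        raise ParameterError(f"need at least m + 2 = {m + 2} samples, got {n}")
    if r_abs <= 0:
        raise ParameterError(f"tolerance r_abs must be > 0, got {r_abs}")
    nt = n - m
    # rows are the length-m templates; tail[i] extends row i to length m+1
    templates = x[np.arange(nt)[:, None] + np.arange(m)[None, :]]
    tail = x[m:]
    a = 0
    b = 0
    for i0 in range(0, nt, chunk):
        i1 = min(i0 + chunk, nt)
        d = np.abs(templates[i0:i1, None, :] - templates[None, :, :]).max(axis=2)
        within_m = d <= r_abs
        # unordered pairs: keep j > i only
        upper = np.arange(nt)[None, :] > np.arange(i0, i1)[:, None]
        within_m &= upper
        b += int(within_m.sum())
        within_m &= np.abs(tail[i0:i1, None] - tail[None, :]) <= r_abs
        a += int(within_m.sum())
    return a, b


def sample_entropy(x: np.ndarray, params: SampEnParams, r_abs: float) -> float:
    """SampEn(m, r_abs) of ``x`` in nats; NaN when undefined.

    Returns -log(A/B).  A == B returns exactly 0.0 (no loss of
    complexity information at the longer template).  A == 0 (or B == 0)
    means no matches to form the ratio; the value is undefined and NaN is
    returned so downstream feature assembly can drop it explicitly.
    """
    a, b = match_counts(x, params.m, r_abs)
    if a == 0 or b == 0:
        return float("nan")
    if a == b:
        return 0.0
    return -math.log(a / b)


def mse_profile(
    x: "np.ndarray | object",
    params: SampEnParams | None = None,
    tau_max: int = 20,
    *,
    r_abs: float | None = None,
) -> MSEProfile:
    """Multiscale entropy profile over scales 1..tau_max.

    ``x`` may be a raw sample array or any object with a ``samples``
    attribute (an epoch).  The tolerance is fixed once: ``r_abs`` if
    given, else ``params.r_factor`` times the population standard
    deviation of the scale-1 series (or ``params.r_factor`` itself in
    absolute mode), and reused at every scale.
    """
    params = params or SampEnParams()
    samples = np.asarray(getattr(x, "samples", x), dtype=float).ravel()
    n = samples.size
    if tau_max < 1:
        raise ParameterError(f"tau_max must be >= 1, got {tau_max}")
    min_len = params.m + 2
    if n // tau_max < min_len:
        feasible = n // min_len
        raise ParameterError(
            f"epoch of {n} samples too short for tau_max={tau_max} "
            f"(largest feasible scale is {feasible})"
        )
    if r_abs is None:
        if params.r_mode == "absolute":
            r_abs = params.r_factor
        else:
            # population SD (ddof=0): deterministic and bit-stable
            r_abs = params.r_factor * float(samples.std())
    if r_abs <= 0:
        raise ParameterError(
            "tolerance r_abs must be > 0 (constant epoch with relative r? "
            "pass an absolute r_abs)"
        )
    values = np.empty(tau_max)
    n_points = np.empty(tau_max, dtype=int)
    for tau in range(1, tau_max + 1):
        y = coarse_grain(samples, tau)
        n_points[tau - 1] = y.size
        values[tau - 1] = sample_entropy(y, params, r_abs)
    n_undef = int(np.isnan(values).sum())
    if n_undef:
        logger.info("mse_profile: %d of %d scales undefined (A=0)", n_undef, tau_max)
    return MSEProfile(values=values, tau_max=tau_max, n_points=n_points,
                      r_abs=float(r_abs), params=params)
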