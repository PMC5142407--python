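"""Bennett acceptance ratio (BAR) free-energy estimation with bisection.

A segment between adjacent coupling states lambda_i -> lambda_j is estimated
from two sets of potential-energy differences: ``forward`` samples
U(lambda_j) - U(lambda_i) drawn in state i, and ``reverse`` samples
U(lambda_i) - U(lambda_j) drawn in state j. The estimator solves the
self-consistency condition

    sum_{reverse} f(w_R - M + dG/kT) = sum_{forward} f(w_F + M - dG/kT),
    M = ln(N_i / N_j),  f(x) = 1 / (1 + exp(x)),

by bisection (the left side decreases and the right side increases in dG, so
the root is unique), and reports the shift constant C = dG - kT ln(N_j/N_i)
so the free energy obeys dG = kT ln(N_j/N_i) + C exactly. A full
alchemical path is the sum of its segment estimates, and a histogram
intersection score between the two sample clouds diagnoses whether adjacent
states overlap enough for the estimate to be trustworthy.

Note on the Fermi function: the estimator uses f(x) = 1/(1 + exp(x/kBT)) on
energies; dividing the argument by kBT is the only dimensionally consistent
reading (multiplying energy by kBT would leave the exponent with units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit, logsumexp

from .errors import ConvergenceError, DomainError, EmptyDatasetError, PepGCMError
from .parameters import KB


@dataclass(frozen=True)
class WorkSamples:
    """Energy-difference samples (kJ/mol) for one lambda segment."""

    forward: np.ndarray  # U(lambda_j) - U(lambda_i) on state-i configurations
    reverse: np.ndarray  # U(lambda_i) - U(lambda_j) on state-j configurations
    temperature: float = 300.0  # K

    def __post_init__(self):
        object.__setattr__(self, "forward", np.atleast_1d(np.asarray(self.forward, dtype=float)))
        object.__setattr__(self, "reverse", np.atleast_1d(np.asarray(self.reverse, dtype=float)))
        if self.forward.size == 0 or self.reverse.size == 0:
            raise EmptyDatasetError("both forward and reverse sample sets must be non-empty")
        if not self.temperature > 0:
            raise DomainError(f"temperature must be positive, got {self.temperature}")

    @property
    def kT(self) -> float:
        return KB * self.temperature


@dataclass(frozen=True)
class BARResult:
    delta_g: float  # kJ/mol
    c_constant: float  # kJ/mol; delta_g == kT ln(Nj/Ni) + c_constant
    n_bisections: int
    converged: bool
    overlap_score: float  # histogram intersection in [0, 1]
    std_error: float  # kJ/mol, analytic BAR variance estimate


@dataclass(frozen=True)
class LambdaPath:
    lambdas: tuple[float, ...]
    segments: tuple[BARResult, ...]

    def __post_init__(self):
        if len(self.segments) != len(self.lambdas) - 1:
            raise PepGCMError(
                f"{len(self.lambdas)} lambda states require {len(self.lambdas) - 1} "
                f"segments, got {len(self.segments)}"
            )

    @property
    def delta_g(self) -> float:
        """Total free-energy change, kJ/mol: sum over segments."""
        return float(sum(s.delta_g for s in self.segments))


def fermi(x: float | np.ndarray, kT: float):
    """Fermi function 1 / (1 + exp(x / kT)); kT in the same units as x."""
    if not kT > 0:
        raise DomainError(f"kT must be positive, got {kT}")
    return expit(-np.asarray(x, dtype=float) / kT) if np.ndim(x) else float(expit(-x / kT))


def _imbalance(samples: WorkSamples, x: float) -> float:
    """log sum_F f(w + M - x) - log sum_R f(r - M + x), reduced units.

    Strictly increasing in x; its root is the BAR estimate of dG/kT.
    """
    w = samples.forward / samples.kT
    r = samples.reverse / samples.kT
    m = math.log(w.size / r.size)
    lhs = logsumexp(log_expit(-(w + m - x)))
    rhs = logsumexp(log_expit(-(r - m + x)))
    return lhs - rhs


def bar_segment(samples: WorkSamples, tol: float = 1e-8, max_iter: int = 200,
                n_bins: int = 50) -> BARResult:
    """BAR estimate for one segment, solved by bisection on the shift constant.

    ``tol`` is the bracket half-width target in units of kT; the initial
    bracket spans +/-(max|dU|/kT + 10) and doubles until it encloses a sign
    change. Raises :class:`ConvergenceError` (carrying the final bracket in
    kJ/mol) if ``max_iter`` iterations are exhausted.
    """
    kT = samples.kT
    w, r = samples.forward, samples.reverse
    span = max(np.max(np.abs(w)), np.max(np.abs(r))) / kT + 10.0
    lo, hi = -span, span
    n_iter = 0
    while _imbalance(samples, lo) > 0 or _imbalance(samples, hi) < 0:
        lo, hi = 2 * lo, 2 * hi
        n_iter += 1
        if n_iter > max_iter:
            raise ConvergenceError(
                "could not bracket the BAR root", bracket=(lo * kT, hi * kT)
            )
    converged = False
    while n_iter < max_iter:
        mid = 0.5 * (lo + hi)
        n_iter += 1
        if _imbalance(samples, mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"BAR bisection did not reach tolerance {tol} kT in {max_iter} iterations",
            bracket=(lo * kT, hi * kT),
        )
    x = 0.5 * (lo + hi)  # dG / kT
    ln_term = kT * math.log(r.size / w.size)
    c_constant = x * kT - ln_term
    delta_g = ln_term + c_constant  # dG = kT ln(Nj/Ni) + C, exact by construction
    return BARResult(
        delta_g=float(delta_g),
        c_constant=float(c_constant),
        n_bisections=n_iter,
        converged=converged,
        overlap_score=overlap(w, -r, n_bins=n_bins),
        std_error=float(_bar_std_error(samples, x)),
    )


def _bar_std_error(samples: WorkSamples, x: float) -> float:
    """First-order error propagation through the two Fermi averages, kJ/mol."""
    kT = samples.kT
    w = samples.forward / kT
    r = samples.reverse / kT
    m = math.log(w.size / r.size)
    ff = expit(-(w + m - x))
    fr = expit(-(r - m + x))
    var = 0.0
    for f in (ff, fr):
        mean = f.mean()
        if mean > 0:
            var += f.var() / (f.size * mean**2)
    return math.sqrt(var) * kT


def bar_at(samples: WorkSamples, c: float) -> float:
    """Single-pass BAR estimate (no iteration) at a fixed shift constant ``c``
    (kJ/mol): kT * [log mean_R f(r + c) - log mean_F f(w - c)] + c.

    Valid for any c in expectation; the self-consistent root merely minimises
    the variance. As c falls far below the forward samples this reduces to
    exponential (Zwanzig) averaging of the forward work.
    """
    kT = samples.kT
    w = samples.forward / kT
    r = samples.reverse / kT
    x = c / kT
    num = logsumexp(log_expit(-(r + x))) - math.log(r.size)
    den = logsumexp(log_expit(-(w - x))) - math.log(w.size)
    return float(kT * (num - den) + c)


def zwanzig(work: np.ndarray, temperature: float = 300.0) -> float:
    """One-sided exponential-averaging estimate -kT ln<exp(-w/kT)>, kJ/mol."""
    w = np.atleast_1d(np.asarray(work, dtype=float))
    if w.size == 0:
        raise EmptyDatasetError("zwanzig() needs at least one work value")
    kT = KB * temperature
    return float(-kT * (logsumexp(-w / kT) - math.log(w.size)))


def bar_total(segments: list[WorkSamples], lambdas: list[float] | None = None,
              **kwargs) -> LambdaPath:
    """Estimate every segment of a lambda path and sum them.

    ``lambdas`` defaults to ``len(segments) + 1`` equidistant states on
    [0, 1]. Segment count must equal state count minus one.
    """
    if lambdas is None:
        lambdas = list(np.linspace(0.0, 1.0, len(segments) + 1))
    lambdas = [float(v) for v in lambdas]
    if len(segments) != len(lambdas) - 1:
        raise PepGCMError(
            f"path with {len(lambdas)} lambda states needs {len(lambdas) - 1} "
            f"segments, got {len(segments)}"
        )
    if lambdas != sorted(lambdas) or lambdas[0] != 0.0 or lambdas[-1] != 1.0:
        raise PepGCMError("lambdas must ascend from 0 to 1")
    results = tuple(bar_segment(s, **kwargs) for s in segments)
    return LambdaPath(lambdas=tuple(lambdas), segments=results)


def overlap(samples_i, samples_j, n_bins: int = 50) -> float:
    """Histogram-intersection score of two sample sets on a shared binning.

    Bins span the pooled range; the score is sum_b min(p_i, p_j) over
    normalised bin masses: 1 for identical distributions, 0 for disjoint
    supports.
    """
    a = np.atleast_1d(np.asarray(samples_i, dtype=float))
    b = np.atleast_1d(np.asarray(samples_j, dtype=float))
    if a.size == 0 or b.size == 0:
        raise EmptyDatasetError("overlap() needs non-empty sample sets")
    if n_bins < 2:
        raise DomainError(f"n_bins must be >= 2, got {n_bins}")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:  # all samples identical across both sets
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(np.minimum(pa / a.size, pb / b.size).sum())


def synth_work(
    delta_f: float,
    sigma: float,
    n_forward: int,
    n_reverse: int,
    temperature: float = 300.0,
    seed: int = 0,
) -> WorkSamples:
    """Gaussian work samples satisfying the Crooks relation exactly.

    Forward work is N(delta_f + sigma^2/2, sigma^2) and reverse work
    N(-delta_f + sigma^2/2, sigma^2), all in kT units, converted to kJ/mol;
    the construction has true free-energy difference ``delta_f`` kT, giving
    an analytic ground truth for estimator tests. Reproducible per ``seed``.
    """
    if not sigma > 0:
        raise DomainError(f"sigma must be positive, got {sigma}")
    if n_forward < 1 or n_reverse < 1:
        raise DomainError("sample counts must be >= 1")
    if not temperature > 0:
        raise DomainError(f"temperature must be positive, got {temperature}")
    rng = np.random.default_rng(seed)
    kT = KB * temperature
    fwd = rng.normal(delta_f + sigma**2 / 2.0, sigma, size=n_forward) * kT
    rev = rng.normal(-delta_f + sigma**2 / 2.0, sigma, size=n_reverse) * kT
    return WorkSamples(forward=fwd, reverse=rev, temperature=temperature)
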