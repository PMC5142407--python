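"""Calibration of the per-(residue, class) alpha scale factors.

The forty alphas are re-derived from a reference set of peptides with known
interface free energies by bounded nonlinear least squares, started from the
packaged values. The model is linear in 1/alpha (``as_printed`` mode) or in
alpha (``reciprocal`` mode), so the problem is well behaved; bounds keep
every alpha strictly positive, and an optional ridge penalty pulls fitted
values toward the prior, which also regularises parameters the reference set
barely observes. A parameter with *no* observations is unconstrained: with
zero regularization that is an error naming the offending entries, with
``on_unidentifiable='keep_prior'`` (or any positive ridge weight) such
entries stay at their prior values and are reported on the result.

A synthetic generator draws random peptides and model-exact energies (plus
Gaussian noise) from known alphas, giving an analytic ground truth for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .classification import classify_residues
from .errors import DomainError, EmptyDatasetError, PepGCMError, UnidentifiableParameterError
from .gcm import MODES, gcm_energy
from .parameters import CLASSES, STANDARD_CODES, AlphaParameter, ParameterSet

#: Column order of the design matrix: (code, cls) sorted by code then class.
ALPHA_KEYS: tuple[tuple[str, str], ...] = tuple(
    (code, cls) for code in sorted(STANDARD_CODES) for cls in CLASSES
)


@dataclass(frozen=True)
class ReferencePeptide:
    id: str
    sequence: str
    dg_reference: float  # kJ/mol


@dataclass(frozen=True)
class FitResult:
    alphas: tuple[AlphaParameter, ...]  # all 40, fitted where observed
    residual_sse: float  # (kJ/mol)^2, data term only
    n_iterations: int
    converged: bool
    unconstrained: tuple[tuple[str, str], ...] = ()

    def as_parameter_set(self, params: ParameterSet) -> ParameterSet:
        return params.with_alphas(self.alphas)


def design_counts(params: ParameterSet, peptides: list[ReferencePeptide]) -> pd.DataFrame:
    """Count matrix n_(i,j): one row per peptide, one column per (code, cls).

    Row sums equal sequence lengths by construction.
    """
    rows = np.zeros((len(peptides), len(ALPHA_KEYS)), dtype=float)
    index = {key: k for k, key in enumerate(ALPHA_KEYS)}
    ids = []
    for p, pep in enumerate(peptides):
        cls = classify_residues(params, pep.sequence)
        for key, n in cls.counts.items():
            rows[p, index[key]] = n
        ids.append(pep.id)
    cols = pd.MultiIndex.from_tuples(ALPHA_KEYS, names=["code", "cls"])
    return pd.DataFrame(rows, index=ids, columns=cols)


def _model_matrix(counts: np.ndarray, dg: np.ndarray, alphas: np.ndarray, mode: str) -> np.ndarray:
    if mode == "as_printed":
        return counts @ (dg / alphas)
    return counts @ (dg * alphas / 100.0)


def fit_alpha(
    params: ParameterSet,
    peptides: list[ReferencePeptide],
    mode: str = "as_printed",
    regularization: float = 0.0,
    on_unidentifiable: str = "raise",
) -> FitResult:
    """Least-squares calibration of the alpha table against reference energies.

    Minimises sum_p (dg_reference_p - model_p(alpha))^2 (+ ridge toward the
    prior when ``regularization`` > 0) over the observed alphas, with all
    parameters bounded positive and the packaged table as the start point.
    Deterministic given inputs; the solver is derivative-based with an
    analytic Jacobian.
    """
    if mode not in MODES:
        raise DomainError(f"mode must be one of {MODES}, got {mode!r}")
    if regularization < 0:
        raise DomainError("regularization weight must be non-negative")
    if on_unidentifiable not in ("raise", "keep_prior"):
        raise PepGCMError(f"on_unidentifiable must be 'raise' or 'keep_prior', got {on_unidentifiable!r}")
    if not peptides:
        raise EmptyDatasetError("fit_alpha() needs at least one reference peptide")

    counts = design_counts(params, peptides).to_numpy()
    y = np.array([p.dg_reference for p in peptides], dtype=float)
    dg = np.array([params.dg(code) for code, _ in ALPHA_KEYS])
    prior = np.array([params.alpha(code, cls) for code, cls in ALPHA_KEYS])

    observed = counts.sum(axis=0) > 0
    unconstrained = tuple(key for key, obs in zip(ALPHA_KEYS, observed) if not obs)
    if unconstrained and regularization == 0.0 and on_unidentifiable == "raise":
        raise UnidentifiableParameterError(unconstrained)

    sqrt_reg = np.sqrt(regularization)
    free = np.flatnonzero(observed)
    x_full = prior.copy()

    def assemble(x_free: np.ndarray) -> np.ndarray:
        a = x_full.copy()
        a[free] = x_free
        return a

    def residuals(x_free: np.ndarray) -> np.ndarray:
        a = assemble(x_free)
        res = y - _model_matrix(counts, dg, a, mode)
        if sqrt_reg > 0:
            res = np.concatenate([res, sqrt_reg * (x_free - prior[free])])
        return res

    def jacobian(x_free: np.ndarray) -> np.ndarray:
        a = assemble(x_free)
        if mode == "as_printed":
            # d/d alpha of -(counts @ dg/alpha) = counts * dg / alpha^2
            jac = counts[:, free] * (dg[free] / a[free] ** 2)
        else:
            jac = -counts[:, free] * (dg[free] / 100.0)
        if sqrt_reg > 0:
            jac = np.vstack([jac, sqrt_reg * np.eye(free.size)])
        return jac

    sol = least_squares(
        residuals,
        x0=prior[free],
        jac=jacobian,
        bounds=(1e-6, np.inf),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    fitted = assemble(sol.x)
    data_res = y - _model_matrix(counts, dg, fitted, mode)
    alphas = tuple(
        AlphaParameter(code=code, cls=cls, alpha=float(a))
        for (code, cls), a in zip(ALPHA_KEYS, fitted)
    )
    return FitResult(
        alphas=alphas,
        residual_sse=float(data_res @ data_res),
        n_iterations=int(sol.nfev),
        converged=bool(sol.success),
        unconstrained=unconstrained,
    )


def generate_reference_set(
    params: ParameterSet,
    n_peptides: int,
    length_range: tuple[int, int],
    true_alphas: list[AlphaParameter] | None = None,
    noise_sd: float = 0.0,
    mode: str = "as_printed",
    seed: int = 0,
    composition: dict[str, float] | None = None,
) -> list[ReferencePeptide]:
    """Synthetic reference peptides with model-exact (noisy) energies.

    Sequences are drawn uniformly over the twenty residues (or with
    ``composition`` weights), lengths uniformly over ``length_range``.
    Reference energies are the group-contribution value under ``true_alphas``
    (the packaged table when None) plus Gaussian noise of SD ``noise_sd``
    kJ/mol. Fully reproducible for a fixed ``seed``.
    """
    if n_peptides < 1:
        raise DomainError("n_peptides must be >= 1")
    lo, hi = length_range
    if lo < 2 or hi < lo:
        raise DomainError(f"invalid length range {length_range}; need 2 <= min <= max")
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")

    truth = params if true_alphas is None else params.with_alphas(true_alphas)
    rng = np.random.default_rng(seed)
    codes = np.array(sorted(STANDARD_CODES))
    if composition is None:
        weights = None
    else:
        weights = np.array([composition.get(c, 0.0) for c in codes], dtype=float)
        if weights.sum() <= 0:
            raise DomainError("composition weights must have positive total mass")
        weights = weights / weights.sum()

    peptides = []
    for k in range(n_peptides):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(codes, size=length, p=weights))
        energy = gcm_energy(truth, classify_residues(truth, seq), mode=mode)
        if noise_sd > 0:
            energy += rng.normal(0.0, noise_sd)
        peptides.append(ReferencePeptide(id=f"syn{k + 1}", sequence=seq, dg_reference=float(energy)))
    return peptides
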