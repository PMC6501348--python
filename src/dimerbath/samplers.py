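"""Random-variate machinery for the collisional heat bath.

The open boundary of the co-moving frame needs three non-trivial samplers:

* the *depth* of a particle entering a face within one step, whose density
  is proportional to ``erfc(z + beta)`` on ``z >= 0`` (``beta`` encodes the
  frame velocity along the face normal) — sampled exactly by an
  acceptance-rejection scheme with an exponential proposal;
* the entering particle's velocity: Maxwell-Boltzmann with the component
  along the inward normal conditioned to exceed a threshold (a one-sided
  truncated Gaussian, sampled by Robert's translated-exponential method);
* bulk Maxwell-Boltzmann velocities and spatial Poisson placement for
  initialising the frame.

All samplers take an explicit :class:`numpy.random.Generator`; there is no
global random state.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Tuple

import numpy as np
from scipy import special

from . import _kernels
from .errors import EnvelopeViolationError, IntegrityError

__all__ = [
    "ErfcTailParams",
    "ShortRangeBathParams",
    "ar_constants",
    "ar_log_constants",
    "erfc_tail_normalizer",
    "erfc_tail_density",
    "erfc_tail_sample",
    "acceptance_probability",
    "maxwell_boltzmann_sample",
    "truncated_gaussian_velocity_sample",
    "bath_density",
]

_SQRT_PI = math.sqrt(math.pi)

# beyond this the plain a2 = 1/erfc(beta) overflows a float64; the sampler
# itself keeps working through ar_log_constants
_BETA_MAX = 26.0


@dataclasses.dataclass(frozen=True)
class ErfcTailParams:
    """Shift parameter of the erfc-tail density p(z) = C3(beta) erfc(z+beta)."""

    beta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")

    @property
    def C3(self) -> float:
        return erfc_tail_normalizer(self.beta)

    @property
    def a1(self) -> float:
        return ar_constants(self.beta)[0]

    @property
    def a2(self) -> float:
        return ar_constants(self.beta)[1]


def ar_constants(beta: float) -> Tuple[float, float]:
    """Envelope constants (a1, a2) of the acceptance-rejection sampler.

    a1 is the mean of the exponential proposal, a2 scales the acceptance
    test. a1 = (sqrt(pi)/2) erfc(beta) e^{beta^2} for beta >= 0 (computed via
    the scaled complementary error function for stability) and sqrt(pi)/2
    otherwise; a2 = 1/erfc(beta) for beta >= 0 and e^{2 beta/sqrt(pi)}
    otherwise. Both branches agree at beta = 0.
    """
    if not math.isfinite(beta):
        raise ValueError("beta must be finite")
    if abs(beta) > _BETA_MAX:
        raise OverflowError(
            f"|beta| > {_BETA_MAX}: a2 is not representable as a float; "
            "use ar_log_constants")
    if beta >= 0.0:
        a1 = 0.5 * _SQRT_PI * special.erfcx(beta)
        a2 = 1.0 / special.erfc(beta)
    else:
        a1 = 0.5 * _SQRT_PI
        a2 = math.exp(2.0 * beta / _SQRT_PI)
    return a1, a2


def ar_log_constants(beta: float) -> Tuple[float, float]:
    """(a1, log a2) — overflow-safe variant used by the compiled sampler."""
    if beta >= 0.0:
        return (0.5 * _SQRT_PI * special.erfcx(beta),
                beta * beta - math.log(special.erfcx(beta)))
    return 0.5 * _SQRT_PI, 2.0 * beta / _SQRT_PI


def erfc_tail_normalizer(beta: float) -> float:
    """C3(beta) with 1/C3 = int_0^inf erfc(z+beta) dz
    = e^{-beta^2}/sqrt(pi) - beta*erfc(beta)."""
    inv = math.exp(-beta * beta) / _SQRT_PI - beta * special.erfc(beta)
    return 1.0 / inv


def erfc_tail_density(z, beta: float):
    """Density C3(beta) * erfc(z + beta) on z >= 0 (zero for z < 0)."""
    z = np.asarray(z, dtype=float)
    out = erfc_tail_normalizer(beta) * special.erfc(z + beta)
    out = np.where(z < 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def erfc_tail_sample(beta: float, rng: np.random.Generator,
                     size: Optional[int] = None,
                     a1: Optional[float] = None, a2: Optional[float] = None,
                     return_stats: bool = False):
    """Exact draws from the erfc-tail density by acceptance-rejection.

    Proposals are z = -a1*log(eta1) (exponential of mean a1); z is accepted
    when eta1*eta2 < a2*erfc(z+beta). With ``return_stats`` the number of
    proposals used is returned alongside, so empirical acceptance rates can
    be tracked.
    """
    if a1 is None or a2 is None:
        a1k, log_a2 = ar_log_constants(beta)
        a1 = a1k if a1 is None else a1
        if a2 is not None:
            log_a2 = math.log(a2)
    else:
        log_a2 = math.log(a2)
    n = 1 if size is None else int(size)
    seed = int(rng.integers(1 << 31))
    out, proposals = _kernels._erfc_tail_batch(beta, a1, log_a2, n, seed)
    if np.any(np.isnan(out)):
        raise IntegrityError(
            "erfc-tail sampler exceeded 10^6 consecutive rejections; "
            "the envelope constants are inconsistent")
    if size is None:
        out = float(out[0])
    if return_stats:
        return out, int(proposals)
    return out


def acceptance_probability(beta: float, a1: Optional[float] = None,
                           a2: Optional[float] = None) -> float:
    """Closed-form acceptance probability a2 / (a1 * C3(beta)) of the
    erfc-tail sampler; defaults to the piecewise envelope constants."""
    if a1 is None and a2 is None:
        a1, a2 = ar_constants(beta)
    if a1 is None or a2 is None:
        raise ValueError("provide both a1 and a2, or neither")
    if not (a1 > 0 and a2 > 0):
        raise ValueError("a1 and a2 must be positive")
    p = (a2 / a1) * (math.exp(-beta * beta) / _SQRT_PI
                     - beta * special.erfc(beta))
    if p > 1.0 + 1e-12:
        raise EnvelopeViolationError(
            f"acceptance probability {p:.4f} > 1: (a1, a2) do not bound the "
            "target density")
    return min(p, 1.0)


def maxwell_boltzmann_sample(sigma_mu: float, n: int,
                             rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. Maxwell-Boltzmann velocity 3-vectors with per-component
    standard deviation sigma_mu."""
    if not sigma_mu > 0:
        raise ValueError("sigma_mu must be positive")
    return rng.normal(0.0, sigma_mu, size=(n, 3))


def truncated_gaussian_velocity_sample(threshold: float, sigma_mu: float,
                                       rng: np.random.Generator,
                                       size: Optional[int] = None):
    """Velocity 3-vector(s) whose first component is Gaussian(0, sigma_mu^2)
    conditioned on exceeding ``threshold``; the other two components are
    unconditioned. threshold = -inf reduces to a plain Maxwell-Boltzmann
    draw."""
    if not sigma_mu > 0:
        raise ValueError("sigma_mu must be positive")
    n = 1 if size is None else int(size)
    a = threshold / sigma_mu if math.isfinite(threshold) else -np.inf
    seed = int(rng.integers(1 << 31))
    v1 = sigma_mu * _kernels._truncnorm_tail_batch(a, n, seed)
    out = np.empty((n, 3))
    out[:, 0] = v1
    out[:, 1:] = rng.normal(0.0, sigma_mu, size=(n, 2))
    return out[0] if size is None else out


@dataclasses.dataclass(frozen=True)
class ShortRangeBathParams:
    """Point-particle heat bath colliding elastically with the monomers.

    The bath is characterised by the monomer radius r0 and the mass ratio
    mu = M/m, plus the macroscopic (gamma, D) it is meant to reproduce. The
    number density lambda_mu and velocity scale sigma_mu are *derived*:

        sigma_mu^2 = (mu + 1) * D * gamma
        lambda_mu  = 3/(8 r0^2) * sqrt((mu + 1) gamma / (2 pi D))

    With these, elastic collisions realise friction gamma*(mu+1)/mu on a
    single monomer (exactly gamma as mu -> inf); this pair inverts the
    specular-reflection (Epstein) drag law and is verified operationally by
    the friction-recovery tests.
    """

    r0: float
    mu: float
    gamma: float
    D: float

    def __post_init__(self) -> None:
        if not (self.r0 > 0 and self.mu > 0 and self.gamma > 0 and self.D > 0):
            raise ValueError("r0, mu, gamma and D must all be positive")

    @property
    def sigma_mu(self) -> float:
        return math.sqrt((self.mu + 1.0) * self.D * self.gamma)

    @property
    def lambda_mu(self) -> float:
        return bath_density(self)

    @property
    def m(self) -> float:
        """Bath particle mass for monomer mass M = mu * m = 1 by default;
        only the ratio mu enters the dynamics."""
        return 1.0 / self.mu


def bath_density(params: ShortRangeBathParams) -> float:
    """Spatial Poisson intensity lambda_mu of the bath."""
    return 3.0 / (8.0 * params.r0 ** 2) * math.sqrt(
        (params.mu + 1.0) * params.gamma / (2.0 * math.pi * params.D))
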