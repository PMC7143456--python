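"""Synthetic site-level and taxa data generation.

Everything downstream of data collection is testable without any download:
``simulate_standardized`` draws sites from a fully specified recursive
linear-Gaussian path model, ``to_raw_scale`` maps standardized columns onto
target raw-scale marginals (affine or method-of-moments lognormal), and
``simulate_taxa`` builds a taxa table whose BMI score hits a requested
target exactly.

All randomness comes from ``numpy.random.default_rng(seed)`` (PCG64), so a
fixed seed reproduces tables bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .path_model import PathModel

logger = logging.getLogger(__name__)

__all__ = [
    "MarginalTarget",
    "simulate_standardized",
    "to_raw_scale",
    "simulate_taxa",
]


@dataclasses.dataclass(frozen=True)
class MarginalTarget:
    """Target raw-scale marginal summary for one variable."""

    variable: str
    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"{self.variable}: target sd must be positive")
        if not self.min <= self.mean <= self.max:
            raise ValueError(f"{self.variable}: need min <= mean <= max")


def simulate_standardized(model: PathModel, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` sites from a fully fixed standardized path model.

    Exogenous variables are sampled jointly Gaussian with the model's
    exogenous covariance; each endogenous variable follows in topological
    order as the linear combination of its parents plus an independent
    Gaussian error with the model's residual variance.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    free = model.free_parameters()
    if free:
        raise ValueError(f"model has unset (free) parameters: {free}")
    for t, v in model.residual_variances.items():
        if v is not None and v <= 0:
            raise ValueError(f"residual variance of {t!r} must be positive")
    _, psi = model.matrices()
    idx = {v: i for i, v in enumerate(model.variables)}
    exog = model.exogenous
    exog_idx = [idx[v] for v in exog]
    exog_cov = psi[np.ix_(exog_idx, exog_idx)]
    try:
        L = np.linalg.cholesky(exog_cov)
    except np.linalg.LinAlgError:
        raise ValueError("exogenous covariance matrix is not positive definite") from None

    rng = np.random.default_rng(seed)
    data = np.zeros((n, model.p))
    z = rng.standard_normal((n, len(exog)))
    data[:, exog_idx] = z @ L.T

    B, _ = model.matrices()
    for var in model.topological_order():
        if var in exog:
            continue
        t = idx[var]
        mean = data @ B[t, :]
        resid_sd = float(np.sqrt(psi[t, t]))
        data[:, t] = mean + resid_sd * rng.standard_normal(n)

    out = pd.DataFrame(data, columns=model.variables)
    out.insert(0, "site_id", [f"S{i + 1:04d}" for i in range(n)])
    return out


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # method of moments: match the raw mean and SD exactly in expectation
    if mean <= 0:
        raise ValueError("lognormal back-transform needs a positive target mean")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def to_raw_scale(
    table: pd.DataFrame,
    targets: Mapping[str, MarginalTarget] | Iterable[MarginalTarget],
    lognormal_vars: Iterable[str] = (),
    clamp: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Map standardized columns onto raw-scale marginals.

    Variables in ``lognormal_vars`` go through ``exp(mu + sigma*z)`` with
    ``mu, sigma`` solved so the raw mean/SD match the target; the rest are
    mapped affinely ``mean + sd*z``. ``clamp`` bounds (default: ``bmi`` to
    [0, 100]) are applied after mapping — clamping rather than resampling
    preserves seed determinism.
    """
    if not isinstance(targets, Mapping):
        targets = {t.variable: t for t in targets}
    lognormal_vars = set(lognormal_vars)
    clamp = dict(clamp) if clamp is not None else {"bmi": (0.0, 100.0)}

    out = table.copy()
    columns = [c for c in table.columns if c != "site_id"]
    for col in columns:
        if col not in targets:
            raise ValueError(f"no marginal target supplied for variable {col!r}")
        tgt = targets[col]
        if tgt.sd <= 0:
            raise ValueError(f"{col}: target sd must be positive")
        z = out[col].to_numpy(dtype=float)
        if col in lognormal_vars:
            mu, sigma = _lognormal_params(tgt.mean, tgt.sd)
            raw = np.exp(mu + sigma * z)
        else:
            raw = tgt.mean + tgt.sd * z
        if col in clamp:
            lo, hi = clamp[col]
            n_out = int(np.sum((raw < lo) | (raw > hi)))
            if n_out:
                logger.info("clamping %d %s value(s) into [%g, %g]", n_out, col, lo, hi)
            raw = np.clip(raw, lo, hi)
        out[col] = raw
    return out


def simulate_taxa(target_bmi: float, richness: int = 10, seed: int = 0) -> pd.DataFrame:
    """Build a taxa table (``taxon,s,h,q``) whose BMI equals ``target_bmi``.

    Draws random saprobic values and weights (with one clean-water ``s=0``
    and one tolerant ``s=4`` taxon always present), then rescales the
    frequencies of the low-``s`` stratum so the ``h*q``-weighted mean of
    ``s`` equals ``4 * (1 - target/100)``.
    """
    if not 0.0 <= target_bmi <= 100.0:
        raise ValueError(f"target BMI {target_bmi} outside [0, 100]")
    if richness < 2:
        raise ValueError("richness must be at least 2")

    rng = np.random.default_rng(seed)
    s = rng.uniform(0.0, 4.0, size=richness)
    s[0] = 0.0
    s[1] = 4.0
    q = rng.uniform(0.5, 5.0, size=richness)
    h = rng.uniform(0.5, 5.0, size=richness)
    m = 4.0 * (1.0 - target_bmi / 100.0)

    w = h * q
    if m <= 0.0 or m >= 4.0:
        # boundary target: concentrate effective weight on the extreme taxa
        extreme = s == (0.0 if m <= 0.0 else 4.0)
        h[~extreme] *= 1e-14 * np.sum(w[extreme]) / np.sum(w[~extreme])
    else:
        low = s < m
        high = s > m
        num = float(np.sum(w[high] * (s[high] - m)))
        den = float(np.sum(w[low] * (m - s[low])))
        h[low] *= num / den

    table = pd.DataFrame(
        {"taxon": [f"T{i + 1:03d}" for i in range(richness)], "s": s, "h": h, "q": q}
    )
    return table
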