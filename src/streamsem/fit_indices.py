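"""Goodness-of-fit indices for covariance-structure models.

Computes NFI, TLI, CFI (relative to an independence baseline with free
variances) and GFI, AGFI, RMSEA (absolute), plus pass/fail evaluation
against the conventional thresholds (>= 0.90 for the first five,
<= 0.05 for RMSEA). Indices that require df > 0 (TLI, AGFI, RMSEA) are
reported as ``None`` ("n/a") for saturated models, never as 0 or 1.

GFI uses the ML-weighted form ``1 - tr[(Sigma^-1 S - I)^2] / tr[(Sigma^-1 S)^2]``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .path_model import SampleMoments

__all__ = [
    "FitIndexReport",
    "baseline_chi_square",
    "compute_fit_indices",
    "evaluate_criteria",
    "THRESHOLDS",
]

# inclusive acceptance thresholds
THRESHOLDS = {
    "nfi": (">=", 0.90),
    "tli": (">=", 0.90),
    "cfi": (">=", 0.90),
    "gfi": (">=", 0.90),
    "agfi": (">=", 0.90),
    "rmsea": ("<=", 0.05),
}


@dataclasses.dataclass
class FitIndexReport:
    chi_square: float
    df: int
    chi_square_baseline: float
    df_baseline: int
    nfi: float | None
    tli: float | None
    cfi: float | None
    gfi: float | None
    agfi: float | None
    rmsea: float | None
    criteria: dict[str, bool | None] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def render(self) -> str:
        lines = ["Index    Criterion   Value"]
        for name, (op, thr) in THRESHOLDS.items():
            val = getattr(self, name)
            shown = "n/a" if val is None else f"{val:.3f}"
            ok = self.criteria.get(name)
            flag = "" if ok is None else ("  pass" if ok else "  FAIL")
            lines.append(f"{name.upper():<8} {op}{thr:<9.2f} {shown}{flag}")
        return "\n".join(lines)


def baseline_chi_square(
    moments: SampleMoments, chi_square_convention: str = "n-1"
) -> tuple[float, int]:
    """Independence-baseline fit: ``F_b = -ln|R|``, ``df_b = p(p-1)/2``.

    The baseline model frees every variance and fixes all covariances at
    zero, so its ML discrepancy reduces to minus the log-determinant of the
    sample correlation matrix.
    """
    S = moments.S
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("sample matrix must be positive definite")
    f_b = -float(logdet)
    scale = moments.n - 1 if chi_square_convention == "n-1" else moments.n
    p = moments.p
    return scale * f_b, p * (p - 1) // 2


def compute_fit_indices(
    chi_square: float,
    df: int,
    chi_square_baseline: float,
    df_baseline: int,
    n: int,
    S: np.ndarray | None = None,
    sigma_hat: np.ndarray | None = None,
    chi_square_convention: str = "n-1",
) -> FitIndexReport:
    """Compute the six indices from chi-square statistics (and S, Sigma-hat for GFI)."""
    if df_baseline <= 0:
        raise ValueError("degenerate baseline: df_baseline must be > 0")
    if n <= 1:
        raise ValueError("n must exceed 1")

    nfi = (chi_square_baseline - chi_square) / chi_square_baseline if chi_square_baseline > 0 else None

    excess = chi_square - df
    excess_b = chi_square_baseline - df_baseline
    denom = max(excess_b, excess, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - max(excess, 0.0) / denom

    tli = rmsea = agfi = None
    if df > 0:
        ratio_b = chi_square_baseline / df_baseline
        if ratio_b != 1.0:
            tli = (ratio_b - chi_square / df) / (ratio_b - 1.0)
        scale = n - 1 if chi_square_convention == "n-1" else n
        rmsea = math.sqrt(max(excess, 0.0) / (df * scale))

    gfi = None
    if S is not None and sigma_hat is not None:
        S = np.asarray(S, dtype=float)
        sigma_hat = np.asarray(sigma_hat, dtype=float)
        M = np.linalg.solve(sigma_hat, S)
        resid = M - np.eye(M.shape[0])
        gfi = 1.0 - float(np.trace(resid @ resid)) / float(np.trace(M @ M))
        if df > 0:
            p = S.shape[0]
            agfi = 1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi)

    report = FitIndexReport(
        chi_square=float(chi_square),
        df=int(df),
        chi_square_baseline=float(chi_square_baseline),
        df_baseline=int(df_baseline),
        nfi=None if nfi is None else float(nfi),
        tli=None if tli is None else float(tli),
        cfi=float(cfi),
        gfi=None if gfi is None else float(gfi),
        agfi=None if agfi is None else float(agfi),
        rmsea=None if rmsea is None else float(rmsea),
    )
    report.criteria = evaluate_criteria(report)
    return report


def evaluate_criteria(report: FitIndexReport) -> dict[str, bool | None]:
    """Inclusive pass/fail per index; ``suitable`` = all applicable pass."""
    out: dict[str, bool | None] = {}
    for name, (op, thr) in THRESHOLDS.items():
        val = getattr(report, name)
        if val is None:
            out[name] = None
        elif op == ">=":
            out[name] = bool(val >= thr)
        else:
            out[name] = bool(val <= thr)
    applicable = [v for v in out.values() if v is not None]
    out["suitable"] = bool(applicable) and all(applicable)
    return out
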