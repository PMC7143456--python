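"""Recursive path-model (all-observed SEM) estimation.

Implements the covariance-structure machinery for directed acyclic path
models among observed variables: model parsing and validation, the implied
covariance matrix ``Sigma = (I-B)^-1 Psi (I-B)^-T``, maximum-likelihood
fitting of free parameters to a sample covariance/correlation matrix,
standard errors and critical ratios from the numerical Hessian, and the
direct / indirect / total effect decomposition.

Conventions
-----------
* ``B[t, s]`` holds the coefficient of the path ``s -> t``.
* Parameter labels are ``"s->t"`` for paths and ``"a~~b"`` for (co)variance
  entries of ``Psi`` (``"a~~a"`` is an exogenous variance or, for an
  endogenous variable, its residual/structural-error variance).
* The model chi-square uses ``(n - 1) * F_ML`` by default; pass
  ``chi_square_convention="n"`` for ``n * F_ML``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import re
import warnings
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "Edge",
    "PathModel",
    "SampleMoments",
    "FittedModel",
    "EffectTable",
    "ValidationReport",
    "ModelSpecError",
    "FitError",
    "parse_model",
    "validate_model",
    "implied_covariance",
    "solve_unit_variance_residuals",
    "fit_ml",
    "decompose_effects",
]


class ModelSpecError(ValueError):
    """Raised for an invalid or unparseable model specification."""


class FitError(RuntimeError):
    """Raised when estimation cannot proceed (bad inputs, hard failure)."""


# ---------------------------------------------------------------------------
# model structure
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Edge:
    """A directed structural path ``source -> target``.

    ``value is None`` marks the coefficient as a free parameter; a float
    fixes it.
    """

    source: str
    target: str
    value: float | None = None

    @property
    def free(self) -> bool:
        return self.value is None

    @property
    def label(self) -> str:
        return f"{self.source}->{self.target}"


def _cov_label(a: str, b: str, order: Sequence[str]) -> str:
    ia, ib = order.index(a), order.index(b)
    if ia > ib:
        a, b = b, a
    return f"{a}~~{b}"


def _cov_lookup(values: Mapping[str, float], a: str, b: str, order: Sequence[str]):
    """Fetch a Psi-entry value accepting either orientation of the label."""
    val = values.get(_cov_label(a, b, order))
    if val is None and a != b:
        val = values.get(f"{b}~~{a}", values.get(f"{a}~~{b}"))
    return val


@dataclasses.dataclass
class PathModel:
    """A recursive (acyclic) path model over observed variables.

    Parameters
    ----------
    variables
        Ordered variable names (defines matrix order everywhere).
    edges
        Structural paths with free or fixed coefficients.
    exog_cov
        ``(a, b) -> value-or-None`` entries among exogenous variables
        (``(a, a)`` is a variance). Undeclared exogenous variances are
        added as free; undeclared exogenous covariances are fixed at 0.
    residual_variances
        ``target -> value-or-None`` structural-error variances, one per
        endogenous variable (free by default).
    """

    variables: list[str]
    edges: list[Edge]
    exog_cov: dict[tuple[str, str], float | None] = dataclasses.field(default_factory=dict)
    residual_variances: dict[str, float | None] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for v in self.variables:
            if v in seen:
                raise ModelSpecError(f"duplicate variable {v!r}")
            seen.add(v)
        pairs: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source == e.target:
                raise ModelSpecError(f"self-loop {e.label!r}")
            for v in (e.source, e.target):
                if v not in seen:
                    raise ModelSpecError(f"edge {e.label!r} uses unknown variable {v!r}")
            if (e.source, e.target) in pairs:
                raise ModelSpecError(f"duplicate edge {e.label!r}")
            pairs.add((e.source, e.target))
        exog = set(self.exogenous)
        cleaned: dict[tuple[str, str], float | None] = {}
        for (a, b), val in self.exog_cov.items():
            if a not in seen or b not in seen:
                raise ModelSpecError(f"covariance {a}~~{b} uses an unknown variable")
            if a == b:
                if a not in exog:
                    # self-(co)variance on an endogenous variable fixes/frees
                    # its residual variance instead
                    self.residual_variances[a] = val
                    continue
            else:
                if a not in exog or b not in exog:
                    raise ModelSpecError(
                        f"covariance {a}~~{b} allowed between exogenous variables only"
                    )
                a, b = sorted((a, b), key=self.variables.index)
            cleaned[(a, b)] = val
        for v in self.exogenous:
            cleaned.setdefault((v, v), None)
        self.exog_cov = cleaned
        for v in self.endogenous:
            self.residual_variances.setdefault(v, None)
        for v in list(self.residual_variances):
            if v not in self.endogenous:
                raise ModelSpecError(f"residual variance for non-endogenous {v!r}")

    # -- structure -----------------------------------------------------

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def endogenous(self) -> list[str]:
        targets = {e.target for e in self.edges}
        return [v for v in self.variables if v in targets]

    @property
    def exogenous(self) -> list[str]:
        targets = {e.target for e in self.edges}
        return [v for v in self.variables if v not in targets]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        return g

    def topological_order(self) -> list[str]:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = [u for u, _ in nx.find_cycle(g)]
            raise ModelSpecError(f"model contains a cycle: {' -> '.join(cycle + cycle[:1])}")
        return list(nx.topological_sort(g))

    def parents(self, target: str) -> list[str]:
        return [e.source for e in self.edges if e.target == target]

    # -- parameters ----------------------------------------------------

    def free_parameters(self) -> list[str]:
        """Free-parameter labels in canonical order: paths, Psi entries."""
        labels = [e.label for e in self.edges if e.free]
        for (a, b), val in sorted(
            self.exog_cov.items(),
            key=lambda kv: (self.variables.index(kv[0][0]), self.variables.index(kv[0][1])),
        ):
            if val is None:
                labels.append(_cov_label(a, b, self.variables))
        for v in self.variables:
            if v in self.residual_variances and self.residual_variances[v] is None:
                labels.append(f"{v}~~{v}")
        return labels

    def df(self) -> int:
        moments = self.p * (self.p + 1) // 2
        return moments - len(self.free_parameters())

    def matrices(self, values: Mapping[str, float] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Build ``(B, Psi)`` from fixed values plus ``values`` for the free ones."""
        values = dict(values or {})
        idx = {v: i for i, v in enumerate(self.variables)}
        B = np.zeros((self.p, self.p))
        Psi = np.zeros((self.p, self.p))
        for e in self.edges:
            val = e.value if not e.free else values.get(e.label)
            if val is None:
                raise ModelSpecError(f"no value supplied for free path {e.label!r}")
            B[idx[e.target], idx[e.source]] = val
        for (a, b), fixed in self.exog_cov.items():
            val = fixed if fixed is not None else _cov_lookup(values, a, b, self.variables)
            if val is None:
                raise ModelSpecError(f"no value supplied for {a}~~{b}")
            Psi[idx[a], idx[b]] = Psi[idx[b], idx[a]] = val
        for t, fixed in self.residual_variances.items():
            val = fixed if fixed is not None else values.get(f"{t}~~{t}")
            if val is None:
                raise ModelSpecError(f"no value supplied for residual variance of {t!r}")
            Psi[idx[t], idx[t]] = val
        return B, Psi

    def implied(self, values: Mapping[str, float] | None = None) -> np.ndarray:
        B, Psi = self.matrices(values)
        return implied_covariance(B, Psi)

    # -- editing -------------------------------------------------------

    def without_edges(self, labels: Iterable[str]) -> "PathModel":
        """Return a copy with the given ``"s->t"`` paths removed.

        A variable left with no incident paths (or no remaining parents)
        stays in the model with a free variance.
        """
        drop = set(labels)
        kept = [e for e in self.edges if e.label not in drop]
        if len(kept) != len(self.edges) - len(drop):
            missing = drop - {e.label for e in self.edges}
            raise ModelSpecError(f"cannot remove unknown path(s): {sorted(missing)}")
        new_targets = {e.target for e in kept}
        exog_cov = {
            (a, b): v
            for (a, b), v in self.exog_cov.items()
            if a not in new_targets and b not in new_targets
        }
        resid = {t: v for t, v in self.residual_variances.items() if t in new_targets}
        return PathModel(list(self.variables), kept, exog_cov, resid)

    def with_values(self, values: Mapping[str, float]) -> "PathModel":
        """Return a copy with every free parameter fixed at ``values``."""
        edges = [
            Edge(e.source, e.target, e.value if not e.free else float(values[e.label]))
            for e in self.edges
        ]
        exog_cov = {}
        for (a, b), v in self.exog_cov.items():
            if v is None:
                v = _cov_lookup(values, a, b, self.variables)
                if v is None:
                    raise ModelSpecError(f"no value supplied for {a}~~{b}")
            exog_cov[(a, b)] = float(v)
        resid = {
            t: (v if v is not None else float(values[f"{t}~~{t}"]))
            for t, v in self.residual_variances.items()
        }
        return PathModel(list(self.variables), edges, exog_cov, resid)


# ---------------------------------------------------------------------------
# parsing / validation
# ---------------------------------------------------------------------------

_PATH_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*->\s*([A-Za-z_]\w*)\s*(?:=\s*([-+0-9.eE]+))?\s*$")
_COV_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*~~\s*([A-Za-z_]\w*)\s*(?:=\s*([-+0-9.eE]+))?\s*$")


def parse_model(spec_text: str) -> PathModel:
    """Parse the line-oriented model grammar.

    Grammar: ``A -> B [= value]`` declares a path, ``A ~~ B [= value]`` an
    exogenous (co)variance (``A ~~ A`` on an endogenous variable addresses
    its residual variance), ``#`` starts a comment. Variable order is
    first-appearance order.
    """
    variables: list[str] = []
    edges: list[Edge] = []
    covs: dict[tuple[str, str], float | None] = {}

    def note(v: str) -> None:
        if v not in variables:
            variables.append(v)

    for lineno, raw in enumerate(spec_text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _PATH_RE.match(line)
        if m:
            src, tgt, val = m.group(1), m.group(2), m.group(3)
            if src == tgt:
                raise ModelSpecError(f"line {lineno}: self-loop {src}->{tgt}")
            note(src)
            note(tgt)
            if any(e.source == src and e.target == tgt for e in edges):
                raise ModelSpecError(f"line {lineno}: duplicate edge {src}->{tgt}")
            edges.append(Edge(src, tgt, float(val) if val is not None else None))
            continue
        m = _COV_RE.match(line)
        if m:
            a, b, val = m.group(1), m.group(2), m.group(3)
            note(a)
            note(b)
            key = (a, b)
            if key in covs or (b, a) in covs:
                raise ModelSpecError(f"line {lineno}: duplicate covariance {a}~~{b}")
            covs[key] = float(val) if val is not None else None
            continue
        raise ModelSpecError(f"line {lineno}: cannot parse {raw.strip()!r}")

    if not edges:
        raise ModelSpecError("model declares no paths")
    try:
        return PathModel(variables, edges, covs)
    except ModelSpecError as exc:
        raise ModelSpecError(str(exc)) from None


@dataclasses.dataclass
class ValidationReport:
    ok: bool
    df: int
    n_free: int
    messages: list[str]


def validate_model(model: PathModel) -> ValidationReport:
    """Check acyclicity and the counting rule; report degrees of freedom."""
    messages: list[str] = []
    ok = True
    g = model.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = [u for u, _ in nx.find_cycle(g)]
        messages.append("cycle: " + " -> ".join(cycle + cycle[:1]))
        ok = False
    df = model.df()
    if df < 0:
        messages.append("under-identified by counting rule")
        ok = False
    for v in model.endogenous:
        if not model.parents(v):  # pragma: no cover - impossible by construction
            messages.append(f"endogenous variable {v!r} has no parents")
            ok = False
    return ValidationReport(ok=ok, df=df, n_free=len(model.free_parameters()), messages=messages)


# ---------------------------------------------------------------------------
# covariance algebra
# ---------------------------------------------------------------------------


def implied_covariance(B: np.ndarray, Psi: np.ndarray) -> np.ndarray:
    """Model-implied covariance ``(I-B)^-1 Psi (I-B)^-T``."""
    B = np.asarray(B, dtype=float)
    Psi = np.asarray(Psi, dtype=float)
    if not np.allclose(Psi, Psi.T, atol=1e-10):
        raise ValueError("Psi must be symmetric")
    p = B.shape[0]
    A = np.linalg.solve(np.eye(p) - B, np.eye(p))
    sigma = A @ Psi @ A.T
    return (sigma + sigma.T) / 2.0


def solve_unit_variance_residuals(
    B: np.ndarray, exog_indices: Sequence[int], exog_corr: np.ndarray
) -> np.ndarray:
    """Residual variances making every variable have unit implied variance.

    Treats the entries of ``B`` as standardized coefficients: with exogenous
    variables at unit variance and correlation ``exog_corr``, each endogenous
    residual variance is set (in topological order) to one minus the variance
    its parents explain. Raises ``ValueError`` when a residual would be
    non-positive, i.e. the coefficients are inconsistent with a standardized
    population model.
    """
    B = np.asarray(B, dtype=float)
    p = B.shape[0]
    exog_indices = list(exog_indices)
    exog_corr = np.atleast_2d(np.asarray(exog_corr, dtype=float))
    if exog_corr.shape != (len(exog_indices), len(exog_indices)):
        raise ValueError("exog_corr shape does not match exogenous index count")
    if not np.allclose(np.diag(exog_corr), 1.0, atol=1e-10):
        raise ValueError("exogenous correlation matrix must have unit diagonal")
    off = exog_corr - np.eye(len(exog_indices))
    if np.any(np.abs(off) >= 1.0):
        raise ValueError("exogenous correlations must satisfy |r| < 1")

    g = nx.DiGraph()
    g.add_nodes_from(range(p))
    g.add_edges_from((s, t) for t in range(p) for s in range(p) if B[t, s] != 0.0)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("coefficient matrix is not acyclic")

    Psi = np.zeros((p, p))
    Psi[np.ix_(exog_indices, exog_indices)] = exog_corr
    exog = set(exog_indices)
    for node in nx.topological_sort(g):
        if node in exog:
            continue
        sigma = implied_covariance(B, Psi)
        resid = 1.0 - sigma[node, node]
        if resid <= 0.0:
            raise ValueError(
                "standardized coefficients inconsistent with unit variance "
                f"(variable index {node}: explained variance {sigma[node, node]:.4f})"
            )
        Psi[node, node] = resid
    return Psi


# ---------------------------------------------------------------------------
# sample moments
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SampleMoments:
    """A sample covariance or correlation matrix with its sample size."""

    S: np.ndarray
    n: int
    names: list[str]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        p = self.S.shape[0]
        if self.S.shape != (p, p):
            raise ValueError("S must be square")
        if len(self.names) != p:
            raise ValueError("names length does not match S")
        if not np.allclose(self.S, self.S.T, atol=1e-8):
            raise ValueError("S must be symmetric")
        self.S = (self.S + self.S.T) / 2.0
        try:
            np.linalg.cholesky(self.S)
        except np.linalg.LinAlgError:
            raise ValueError("S must be positive definite") from None
        if self.n <= p:
            raise ValueError(f"sample size n={self.n} must exceed p={p}")
        cond = np.linalg.cond(self.S)
        if cond > 1e10:
            warnings.warn(f"sample matrix is near-singular (condition {cond:.3g})")

    @property
    def p(self) -> int:
        return self.S.shape[0]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str = "covariance") -> "SampleMoments":
        names = list(df.columns)
        if kind == "covariance":
            S = df.cov(ddof=1).to_numpy()
        elif kind == "correlation":
            S = df.corr().to_numpy()
        else:
            raise ValueError("kind must be 'covariance' or 'correlation'")
        return cls(S=S, n=len(df), names=names)

    def reordered(self, names: Sequence[str]) -> "SampleMoments":
        missing = [v for v in names if v not in self.names]
        if missing:
            raise ValueError(f"moments are missing variables: {missing}")
        idx = [self.names.index(v) for v in names]
        return SampleMoments(S=self.S[np.ix_(idx, idx)], n=self.n, names=list(names))

    def correlation(self) -> "SampleMoments":
        d = np.sqrt(np.diag(self.S))
        R = self.S / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        return SampleMoments(S=R, n=self.n, names=list(self.names))


# ---------------------------------------------------------------------------
# maximum-likelihood fit
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FittedModel:
    """Result of :func:`fit_ml`."""

    model: PathModel
    estimates: dict[str, float]
    se: dict[str, float]
    cr: dict[str, float]
    p_value: dict[str, float]
    standardized_estimates: dict[str, float]
    chi_square: float
    df: int
    implied: np.ndarray
    converged: bool
    iterations: int
    n: int
    fmin: float
    moments: SampleMoments

    def path_labels(self) -> list[str]:
        return [e.label for e in self.model.edges]

    def free_path_labels(self) -> list[str]:
        return [e.label for e in self.model.edges if e.free]

    def effects(self) -> "EffectTable":
        """Standardized direct/indirect/total effect decomposition."""
        idx = {v: i for i, v in enumerate(self.model.variables)}
        B = np.zeros((self.model.p, self.model.p))
        for e in self.model.edges:
            B[idx[e.target], idx[e.source]] = self.standardized_estimates[e.label]
        return decompose_effects(B, names=self.model.variables)

    def summary_rows(self) -> list[dict[str, float | str]]:
        rows = []
        for e in self.model.edges:
            label = e.label
            rows.append(
                {
                    "path": f"{e.source} -> {e.target}",
                    "standardized": self.standardized_estimates[label],
                    "estimate": self.estimates.get(label, e.value),
                    "se": self.se.get(label, float("nan")),
                    "cr": self.cr.get(label, float("nan")),
                    "p": self.p_value.get(label, float("nan")),
                }
            )
        return rows


def _ols_start_values(model: PathModel, S: np.ndarray) -> dict[str, float]:
    """Equation-wise least-squares starting values (plus sample Psi entries)."""
    idx = {v: i for i, v in enumerate(model.variables)}
    values: dict[str, float] = {}
    for t in model.endogenous:
        parents = model.parents(t)
        pi = [idx[v] for v in parents]
        ti = idx[t]
        try:
            b = np.linalg.solve(S[np.ix_(pi, pi)], S[pi, ti])
        except np.linalg.LinAlgError:  # pragma: no cover - S is PD upstream
            b = np.linalg.lstsq(S[np.ix_(pi, pi)], S[pi, ti], rcond=None)[0]
        resid = float(S[ti, ti] - b @ S[pi, ti])
        for v, coef in zip(parents, b):
            lab = f"{v}->{t}"
            values[lab] = float(coef)
        if model.residual_variances.get(t) is None:
            values[f"{t}~~{t}"] = max(resid, 1e-3 * S[ti, ti])
    for (a, b_), fixed in model.exog_cov.items():
        if fixed is None:
            values[_cov_label(a, b_, model.variables)] = float(S[idx[a], idx[b_]])
    return {k: values[k] for k in model.free_parameters() if k in values}


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 0.1)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_ml(
    model: PathModel,
    moments: SampleMoments,
    *,
    chi_square_convention: str = "n-1",
    max_iter: int = 500,
    gtol: float = 1e-7,
    ftol: float = 1e-12,
) -> FittedModel:
    """Fit ``model`` to ``moments`` by minimizing the ML discrepancy.

    Minimizes ``F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p`` over the
    free parameters, starting from equation-wise least-squares values.
    Standard errors come from the inverse numerical Hessian of ``F`` scaled
    by ``2/(n-1)`` (or ``2/n`` under the ``"n"`` convention); critical
    ratios are estimate/SE with two-sided normal p-values.
    """
    report = validate_model(model)
    if not report.ok:
        raise FitError("invalid model: " + "; ".join(report.messages))
    if chi_square_convention not in ("n-1", "n"):
        raise ValueError("chi_square_convention must be 'n-1' or 'n'")
    mom = moments.reordered(model.variables)
    S = mom.S
    p = mom.p
    n = mom.n
    scale = float(n - 1 if chi_square_convention == "n-1" else n)

    free = model.free_parameters()
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:  # pragma: no cover - SampleMoments guarantees PD
        raise FitError("sample matrix is not positive definite")

    n_retreats = 0

    def objective(theta: np.ndarray) -> float:
        nonlocal n_retreats
        B, Psi = model.matrices(dict(zip(free, theta)))
        sigma = implied_covariance(B, Psi)
        try:
            c = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            n_retreats += 1
            eigmin = float(np.linalg.eigvalsh(sigma)[0])
            return 1e6 * (1.0 + abs(eigmin))
        logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(c))))
        inv_sigma_S = np.linalg.solve(sigma, S)
        return logdet_sigma + float(np.trace(inv_sigma_S)) - logdet_S - p

    if not free:
        theta_hat = np.empty(0)
        fmin = objective(theta_hat)
        res_nit = 0
        converged = True
    else:
        x0 = np.array([_ols_start_values(model, S).get(lab, 0.0) for lab in free])
        bounds = [
            (1e-10, None) if lab.split("~~")[0] == lab.split("~~")[-1] and "~~" in lab else (None, None)
            for lab in free
        ]
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": ftol, "gtol": gtol, "maxfun": 50 * max_iter},
        )
        theta_hat = res.x
        fmin = float(res.fun)
        res_nit = int(res.nit)
        converged = bool(res.success)
        if not converged:
            # the line search can fail when the start is already (numerically)
            # at the minimum; decide on the gradient itself
            grad = np.array(
                [
                    (objective(theta_hat + h * e) - objective(theta_hat - h * e)) / (2.0 * h)
                    for i in range(len(theta_hat))
                    for h, e in [(1e-6 * max(abs(theta_hat[i]), 1.0), np.eye(len(theta_hat))[i])]
                ]
            )
            converged = bool(np.max(np.abs(grad)) < 1e-5)
            if not converged:
                logger.warning("optimizer did not converge: %s", res.message)
    if n_retreats:
        logger.info("objective penalized a non-PD implied matrix %d time(s)", n_retreats)

    fmin = max(fmin, 0.0)
    chi_square = scale * fmin
    df = model.df()

    estimates = dict(zip(free, (float(v) for v in theta_hat)))
    B_hat, Psi_hat = model.matrices(estimates)
    sigma_hat = implied_covariance(B_hat, Psi_hat)

    se: dict[str, float] = {}
    cr: dict[str, float] = {}
    pvals: dict[str, float] = {}
    if free:
        H = _numeric_hessian(objective, theta_hat)
        try:
            cov_theta = (2.0 / scale) * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            warnings.warn("Hessian singular; using pseudo-inverse for standard errors")
            cov_theta = (2.0 / scale) * np.linalg.pinv(H)
        var_theta = np.clip(np.diag(cov_theta), 0.0, None)
        for lab, v, est in zip(free, var_theta, theta_hat):
            se_v = math.sqrt(v)
            se[lab] = se_v
            cr[lab] = float(est / se_v) if se_v > 0 else float("inf") * np.sign(est or 1.0)
            pvals[lab] = float(2.0 * stats.norm.sf(abs(cr[lab]))) if math.isfinite(cr[lab]) else 0.0

    sd = np.sqrt(np.diag(sigma_hat))
    idx = {v: i for i, v in enumerate(model.variables)}
    standardized: dict[str, float] = {}
    for e in model.edges:
        b = estimates.get(e.label, e.value)
        standardized[e.label] = float(b * sd[idx[e.source]] / sd[idx[e.target]])
    for (a, b_), fixed in model.exog_cov.items():
        if a != b_:
            lab = _cov_label(a, b_, model.variables)
            val = estimates.get(lab, fixed)
            standardized[lab] = float(val / (sd[idx[a]] * sd[idx[b_]]))

    return FittedModel(
        model=model,
        estimates=estimates,
        se=se,
        cr=cr,
        p_value=pvals,
        standardized_estimates=standardized,
        chi_square=float(chi_square),
        df=df,
        implied=sigma_hat,
        converged=converged,
        iterations=res_nit,
        n=n,
        fmin=fmin,
        moments=mom,
    )


# ---------------------------------------------------------------------------
# effect decomposition
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EffectTable:
    """Direct/indirect/total effects; entry ``[t, s]`` = effect of s on t."""

    direct: np.ndarray
    indirect: np.ndarray
    total: np.ndarray
    names: list[str]

    def of(self, source: str, target: str) -> dict[str, float]:
        s = self.names.index(source)
        t = self.names.index(target)
        return {
            "direct": float(self.direct[t, s]),
            "indirect": float(self.indirect[t, s]),
            "total": float(self.total[t, s]),
        }

    def to_frame(self, which: str = "total") -> pd.DataFrame:
        mat = getattr(self, which)
        return pd.DataFrame(mat, index=self.names, columns=self.names)


def decompose_effects(B: np.ndarray, names: Sequence[str] | None = None) -> EffectTable:
    """Decompose effects of an acyclic coefficient matrix.

    ``direct = B``, ``total = (I-B)^-1 - I``, ``indirect = total - direct``.
    """
    B = np.asarray(B, dtype=float)
    p = B.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(p))
    g.add_edges_from((s, t) for t in range(p) for s in range(p) if B[t, s] != 0.0)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("effect decomposition requires an acyclic coefficient matrix")
    total = np.linalg.solve(np.eye(p) - B, np.eye(p)) - np.eye(p)
    direct = B.copy()
    indirect = total - direct
    names = list(names) if names is not None else [f"v{i}" for i in range(p)]
    return EffectTable(direct=direct, indirect=indirect, total=total, names=names)
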