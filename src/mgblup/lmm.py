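"""Linear mixed model machinery: design matrices, REML, and BLUP.

The model is y = X b + sum_r Z_r u_r + e with u_r ~ N(0, K_r sigma2_r) and
e ~ N(0, I sigma2_e).  Covariance structures: identity, G (line x line genomic
relationships), env-block-G (block-diagonal G over environments, for additive
G x E effects), and Q (plot x plot metabolomic similarity).

Variance components are estimated by average-information REML with
step-halving and an EM fallback whenever the AI step is non-ascending or the
AI matrix is not positive definite; proposals are floored at 1e-10 * var(y)
and re-enter estimation each iteration.  All solvers are dense and target
designs of up to a few thousand plots.

BLUP solutions are computed in the marginal-covariance form
b_hat = (X'V^-1 X)^-1 X'V^-1 y and u_hat_r = sigma2_r K_r Z_r' V^-1 (y - X b_hat),
which is algebraically equivalent to Henderson's mixed model equations but
needs no inverse of K_r; levels without records are predicted through their
covariance with observed levels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .errors import ConfigurationError, DataFormatError, NumericalError
from .relationships import GMatrix, QMatrix

logger = logging.getLogger(__name__)

STRUCTURES = ("identity", "G", "envblockG", "Q")


@dataclass(frozen=True)
class RandomTerm:
    """One random term: a name, the design factor(s), and a covariance structure."""

    name: str
    factor: str | tuple
    structure: str = "identity"

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ConfigurationError(
                f"unknown covariance structure {self.structure!r}"
            )


GBLUP_TERMS = (
    RandomTerm("g", "line", "G"),
    RandomTerm("l", "line", "identity"),
    RandomTerm("ig", ("env", "line"), "envblockG"),
    RandomTerm("il", ("env", "line"), "identity"),
    RandomTerm("t", "batch", "identity"),
)


@dataclass(frozen=True)
class ModelSpec:
    response: str
    fixed: tuple = ("location", "year", "trial")
    random_terms: tuple = GBLUP_TERMS

    def __post_init__(self):
        names = [t.name for t in self.random_terms]
        if len(set(names)) != len(names):
            raise ConfigurationError("random term names must be unique")
        if "e" in names:
            raise ConfigurationError("'e' is reserved for the residual")


def gblup_spec(trait: str) -> ModelSpec:
    """The six-term GBLUP structure: g(G) + l + ig(blockG) + il + t + e."""
    return ModelSpec(response=trait)


def mgblup1_spec(trait: str) -> ModelSpec:
    """GBLUP structure plus the per-plot metabolomic term u with covariance Q."""
    return ModelSpec(
        response=trait,
        random_terms=(RandomTerm("u", "plot", "Q"),) + GBLUP_TERMS,
    )


@dataclass
class TermDesign:
    name: str
    Z: np.ndarray                 # (n, q) incidence
    K: np.ndarray | None          # (q, q) covariance, None = identity
    levels: np.ndarray
    structure: str

    @property
    def n_levels(self) -> int:
        return self.Z.shape[1]


@dataclass
class DesignMatrices:
    y: np.ndarray
    X: np.ndarray
    fixed_levels: np.ndarray
    terms: list
    plot_ids: np.ndarray

    @property
    def n(self) -> int:
        return self.y.size

    def vr_stack(self) -> tuple[np.ndarray, list, list]:
        """Marginal covariance contributions V_r = Z_r K_r Z_r' plus residual I."""
        mats, names, qs = [], [], []
        for t in self.terms:
            ZK = t.Z if t.K is None else t.Z @ t.K
            mats.append(ZK @ t.Z.T)
            names.append(t.name)
            qs.append(t.n_levels)
        mats.append(np.eye(self.n))
        names.append("e")
        qs.append(self.n)
        return np.stack(mats), names, qs


def _onehot(idx: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((idx.size, n_levels))
    Z[np.arange(idx.size), idx] = 1.0
    return Z


def _combined(df: pd.DataFrame, factor) -> pd.Series:
    if isinstance(factor, str):
        return df[factor].astype(str)
    out = df[factor[0]].astype(str)
    for c in factor[1:]:
        out = out + "|" + df[c].astype(str)
    return out


def build_design(
    plots: pd.DataFrame,
    spec: ModelSpec,
    G: GMatrix | None = None,
    Q: QMatrix | None = None,
) -> DesignMatrices:
    """Assemble y, X and the random-term incidence/covariance matrices.

    Rows with a missing response are dropped.  The fixed design has one
    column per observed fixed-factor cell (cell-means coding); empty cells
    are simply absent.  G-structured terms index all lines of G and
    Q-structured terms all plots of Q, so unphenotyped levels are carried and
    predicted through covariance.
    """
    if spec.response not in plots.columns:
        raise DataFormatError(f"response column {spec.response!r} missing")
    df = plots[plots[spec.response].notna()]
    if df.empty:
        raise DataFormatError("no observed phenotypes after masking")
    y = df[spec.response].to_numpy(dtype=float)

    if spec.fixed:
        cells = _combined(df, tuple(spec.fixed))
        codes, uniques = pd.factorize(cells, sort=True)
        X = _onehot(codes, uniques.size)
        fixed_levels = np.asarray(uniques, dtype=str)
    else:
        X = np.empty((len(df), 0))
        fixed_levels = np.array([], dtype=str)

    terms = []
    for term in spec.random_terms:
        if term.structure in ("G", "envblockG") and G is None:
            raise ConfigurationError(f"term {term.name!r} requires a G matrix")
        if term.structure == "Q" and Q is None:
            raise ConfigurationError(f"term {term.name!r} requires a Q matrix")
        if term.structure == "G":
            idx = pd.Index(G.line_ids).get_indexer(df[term.factor].astype(str))
            if (idx < 0).any():
                plot = df.loc[idx < 0, "plot"].iloc[0]
                raise DataFormatError(
                    f"plot {plot!r}: line not present in the G matrix"
                )
            terms.append(TermDesign(term.name, _onehot(idx, G.line_ids.size),
                                    G.values, G.line_ids.copy(), "G"))
        elif term.structure == "envblockG":
            env_col, line_col = term.factor
            envs = np.sort(df[env_col].astype(str).unique())
            eidx = pd.Index(envs).get_indexer(df[env_col].astype(str))
            lidx = pd.Index(G.line_ids).get_indexer(df[line_col].astype(str))
            if (lidx < 0).any():
                plot = df.loc[lidx < 0, "plot"].iloc[0]
                raise DataFormatError(
                    f"plot {plot!r}: line not present in the G matrix"
                )
            nl = G.line_ids.size
            levels = np.array([f"{e}|{l}" for e in envs for l in G.line_ids])
            Z = _onehot(eidx * nl + lidx, envs.size * nl)
            K = np.kron(np.eye(envs.size), G.values)
            terms.append(TermDesign(term.name, Z, K, levels, "envblockG"))
        elif term.structure == "Q":
            idx = pd.Index(Q.plot_ids).get_indexer(df[term.factor].astype(str))
            if (idx < 0).any():
                plot = df.loc[idx < 0, term.factor].iloc[0]
                raise DataFormatError(
                    f"plot {plot!r} not present in the Q matrix"
                )
            terms.append(TermDesign(term.name, _onehot(idx, Q.plot_ids.size),
                                    Q.values, Q.plot_ids.copy(), "Q"))
        else:
            vals = _combined(df, term.factor)
            codes, uniques = pd.factorize(vals, sort=True)
            terms.append(TermDesign(term.name, _onehot(codes, uniques.size),
                                    None, np.asarray(uniques, dtype=str),
                                    "identity"))
    return DesignMatrices(y, X, fixed_levels, terms,
                          df["plot"].to_numpy(dtype=str))


@dataclass
class VCEstimates:
    """REML variance components (per random term plus residual)."""

    components: dict
    residual: float
    converged: bool = True
    n_iterations: int = 0
    loglik: float = float("nan")

    def as_dict(self) -> dict:
        d = dict(self.components)
        d["e"] = self.residual
        return d

    @classmethod
    def from_dict(cls, d: dict, **kw) -> "VCEstimates":
        d = dict(d)
        resid = d.pop("e")
        return cls(components=d, residual=resid, **kw)


@dataclass
class BLUPSolution:
    fixed: pd.Series
    random: dict            # term name -> pd.Series over term levels
    residuals: pd.Series    # per observed plot
    fitted: pd.Series


def _reml_core(theta, Vrs, X, y):
    """Restricted log-likelihood plus the P-projected quantities."""
    n = y.size
    V = np.tensordot(theta, Vrs, axes=1)
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by floors
        raise NumericalError(f"covariance matrix not positive definite: {exc}")
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Vinv = cho_solve(cf, np.eye(n))
    if X.shape[1]:
        W = Vinv @ X
        XtViX = X.T @ W
        sign, logdet_c = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise NumericalError("singular fixed-effect design in REML")
        P = Vinv - W @ np.linalg.solve(XtViX, W.T)
    else:
        logdet_c = 0.0
        P = Vinv
    Py = P @ y
    ll = -0.5 * (logdet_v + logdet_c + float(y @ Py))
    return ll, P, Py


def reml_estimate(
    design: DesignMatrices,
    start: VCEstimates | None = None,
    max_iter: int = 500,
    rtol: float = 1e-8,
    lltol: float = 1e-9,
) -> VCEstimates:
    """Average-information REML with EM fallback and variance floors.

    The restricted log-likelihood is non-decreasing across accepted
    iterations.  Non-convergence within ``max_iter`` is flagged, not raised.
    """
    y, X = design.y, design.X
    n = y.size
    if n <= X.shape[1]:
        raise DataFormatError(
            f"need more observations ({n}) than fixed-effect columns "
            f"({X.shape[1]})"
        )
    Vrs, names, qs = design.vr_stack()
    vary = float(np.var(y)) or 1.0
    floor = 1e-10 * vary
    if start is not None:
        d = start.as_dict()
        theta = np.array([max(d[nm], floor) for nm in names])
    else:
        theta = np.full(len(names), vary / (len(names) + 1.0))
        theta[-1] = vary / 2.0
    qs = np.asarray(qs, dtype=float)

    ll, P, Py = _reml_core(theta, Vrs, X, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        T = Vrs @ Py                                   # (t, n)
        ypvpy = T @ Py                                 # y'P V_i P y
        trpv = np.einsum("ij,tij->t", P, Vrs)          # tr(P V_i)
        score = 0.5 * (ypvpy - trpv)
        AI = 0.5 * (T @ P @ T.T)
        AI = 0.5 * (AI + AI.T)

        # components at the floor that want to decrease are held there for
        # this iteration; they re-enter whenever their score turns positive
        free = ~((theta <= floor * (1.0 + 1e-6)) & (score < 0.0))
        new_theta = None
        try:
            if not free.any():
                raise np.linalg.LinAlgError
            delta = np.zeros_like(theta)
            delta[free] = np.linalg.solve(AI[np.ix_(free, free)], score[free])
            step = 1.0
            for _ in range(8):
                cand = np.maximum(theta + step * delta, floor)
                try:
                    cand_ll, cand_P, cand_Py = _reml_core(cand, Vrs, X, y)
                except NumericalError:
                    step *= 0.5
                    continue
                if cand_ll >= ll - 1e-10:
                    new_theta, new_ll = cand, cand_ll
                    P, Py = cand_P, cand_Py
                    break
                step *= 0.5
        except np.linalg.LinAlgError:
            pass
        if new_theta is None:
            # EM step: guaranteed ascent of the restricted likelihood
            cand = np.maximum(theta + theta**2 * (ypvpy - trpv) / qs, floor)
            new_ll, P, Py = _reml_core(cand, Vrs, X, y)
            new_theta = cand

        rel_change = float(np.max(np.abs(new_theta - theta)
                                  / np.maximum(np.abs(theta), floor)))
        ll_change = new_ll - ll
        theta, ll = new_theta, new_ll
        if rel_change < rtol or abs(ll_change) < lltol:
            converged = True
            break
    if not converged:
        logger.warning("REML did not converge in %d iterations", max_iter)
    comps = {nm: float(v) for nm, v in zip(names[:-1], theta[:-1])}
    return VCEstimates(components=comps, residual=float(theta[-1]),
                       converged=converged, n_iterations=it, loglik=float(ll))


def blup_solve(design: DesignMatrices, vc: VCEstimates) -> BLUPSolution:
    """Solve for fixed-effect estimates and random-effect predictions.

    Predictions are returned for every level of each term, including levels
    with no records (shrunk toward zero through their covariance with
    observed levels).
    """
    y, X = design.y, design.X
    n = y.size
    d = vc.as_dict()
    theta = np.array([max(d[t.name], 0.0) for t in design.terms]
                     + [max(d["e"], 1e-12 * (float(np.var(y)) or 1.0))])
    Vrs, names, _ = design.vr_stack()
    V = np.tensordot(theta, Vrs, axes=1)
    cf = cho_factor(V, lower=True)
    if X.shape[1]:
        W = cho_solve(cf, X)
        XtViX = X.T @ W
        try:
            beta = np.linalg.solve(XtViX, W.T @ y)
        except np.linalg.LinAlgError:
            warnings.warn("singular fixed-effect system: using pseudo-inverse")
            beta = np.linalg.pinv(XtViX) @ (W.T @ y)
        resid = y - X @ beta
    else:
        beta = np.empty(0)
        resid = y
    Vinv_r = cho_solve(cf, resid)
    random = {}
    fitted = X @ beta if X.shape[1] else np.zeros(n)
    for t, th in zip(design.terms, theta[:-1]):
        proj = t.Z.T @ Vinv_r
        u = th * (proj if t.K is None else t.K @ proj)
        random[t.name] = pd.Series(u, index=t.levels, name=t.name)
        fitted = fitted + t.Z @ u
    residuals = y - fitted
    return BLUPSolution(
        fixed=pd.Series(beta, index=design.fixed_levels, name="fixed"),
        random=random,
        residuals=pd.Series(residuals, index=design.plot_ids),
        fitted=pd.Series(fitted, index=design.plot_ids),
    )


def correct_phenotypes(
    design: DesignMatrices,
    solution: BLUPSolution,
    batch_term: str = "t",
) -> pd.Series:
    """Phenotypes corrected for fixed effects and the batch effect.

    corrected y = y - X b_hat - Z_t t_hat, using a full-data GBLUP fit.
    """
    if batch_term not in solution.random:
        raise DataFormatError(
            f"fit has no batch term {batch_term!r}; cannot correct phenotypes"
        )
    y = design.y
    corrected = y - (design.X @ solution.fixed.to_numpy()
                     if design.X.shape[1] else 0.0)
    t = next(td for td in design.terms if td.name == batch_term)
    corrected = corrected - t.Z @ solution.random[batch_term].to_numpy()
    return pd.Series(corrected, index=design.plot_ids, name="corrected")
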