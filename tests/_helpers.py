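"""Independent oracle solvers used by the tests.

These deliberately take a different computational route from the package:
Henderson's mixed model equations in effect space (requiring explicit
covariance inverses) instead of the marginal-covariance form, and a
per-feature ridge-regression decomposition of the metabolomic model instead
of the two-step Q-matrix procedure.
"""

import numpy as np
import scipy.linalg

from mgblup.lmm import build_design, gblup_spec


def henderson_mme(design, vc):
    """Solve Henderson's MME directly; returns (beta, {term: u}, C, rhs).

    Requires every covariance structure to be invertible.
    """
    d = vc.as_dict()
    se = d["e"]
    blocks = [design.X] + [t.Z for t in design.terms]
    W = np.hstack(blocks)
    C = W.T @ W / se
    rhs = W.T @ design.y / se
    off = design.X.shape[1]
    for t in design.terms:
        q = t.n_levels
        Kinv = np.eye(q) if t.K is None else np.linalg.inv(t.K)
        C[off:off + q, off:off + q] += Kinv / d[t.name]
        off += q
    sol = np.linalg.solve(C, rhs)
    beta = sol[: design.X.shape[1]]
    out = {}
    off = design.X.shape[1]
    for t in design.terms:
        out[t.name] = sol[off:off + t.n_levels]
        off += t.n_levels
    return beta, out, C, rhs


def joint_posterior_breeding_values(plots, G, M, sigma2_alpha, vc_pheno,
                                    vc_feat, trait="y"):
    """Exact posterior mean of a = sum_j g_j2 alpha_j + g1 given (y, M).

    Conditional on the observed feature matrix the posterior factorises:
    alpha and g1 come from a ridge regression of y on [X, M, genetic and
    environmental incidences], and each g_j2 from a per-feature mixed model
    of m_j; the breeding value is g1_hat + sum_j alphahat_j * ghat_j2.
    ``vc_pheno`` holds (g1, l1, ig1, il1, t1, e1); ``vc_feat`` the common
    per-feature components (g2, l2, ig2, il2, t2, e2).
    """
    design = build_design(plots, gblup_spec(trait), G=G)
    X = design.X
    Zs = {t.name: t.Z for t in design.terms}
    Ks = {t.name: t.K for t in design.terms}
    nl = G.line_ids.size
    Ginv = np.linalg.inv(G.values)
    n_env = Ks["ig"].shape[0] // nl
    BGinv = np.kron(np.eye(n_env), Ginv)

    # align feature rows to the design rows
    pos = {p: i for i, p in enumerate(M.plot_ids)}
    Ms = M.intensities[[pos[p] for p in design.plot_ids]]
    k = Ms.shape[1]

    # ridge system for (b1, alpha, g1, l1, ig1, il1, t1)
    g1v, l1v, ig1v, il1v, t1v, e1v = vc_pheno
    W1 = np.hstack([X, Ms, Zs["g"], Zs["l"], Zs["ig"], Zs["il"], Zs["t"]])
    D = scipy.linalg.block_diag(
        np.zeros((X.shape[1], X.shape[1])),
        np.eye(k) / sigma2_alpha,
        Ginv / g1v,
        np.eye(nl) / l1v,
        BGinv / ig1v,
        np.eye(Zs["il"].shape[1]) / il1v,
        np.eye(Zs["t"].shape[1]) / t1v,
    )
    sol = np.linalg.solve(W1.T @ W1 / e1v + D, W1.T @ design.y / e1v)
    off = X.shape[1]
    alpha_hat = sol[off:off + k]
    g1_hat = sol[off + k:off + k + nl]

    # per-feature mixed models, one factorization, k right-hand sides
    g2v, l2v, ig2v, il2v, t2v, e2v = vc_feat
    W2 = np.hstack([X, Zs["g"], Zs["l"], Zs["ig"], Zs["il"], Zs["t"]])
    D2 = scipy.linalg.block_diag(
        np.zeros((X.shape[1], X.shape[1])),
        Ginv / g2v,
        np.eye(nl) / l2v,
        BGinv / ig2v,
        np.eye(Zs["il"].shape[1]) / il2v,
        np.eye(Zs["t"].shape[1]) / t2v,
    )
    sols = np.linalg.solve(W2.T @ W2 / e2v + D2, W2.T @ Ms / e2v)
    g_j2_hat = sols[X.shape[1]:X.shape[1] + nl, :]   # (nl, k)

    a_hat = g1_hat + g_j2_hat @ alpha_hat
    return a_hat, G.line_ids
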