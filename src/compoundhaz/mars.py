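"""Multivariate adaptive regression splines with a Poisson lack-of-fit.

Fits county outcome counts with an adaptively chosen hinge-function basis:
a forward pass greedily adds the reflected hinge pair
``max(0, x_v - t), max(0, t - x_v)`` (knots restricted to observed predictor
values) that most reduces the Poisson deviance, and a backward pass deletes
terms one at a time, keeping the subset minimizing the generalized
cross-validation score::

    GCV = deviance / (n * (1 - M_eff / n)^2),   M_eff = M + penalty*(M - 1)/2

with M the number of basis functions including the intercept.  The default
penalty is 3: with knots searched exhaustively over all observed values the
selection pressure is high, and a charge of 3 per knot is what keeps
pure-noise responses near the intercept-only model (2 admits noticeably more
spurious hinges).  Variable importance is the GCV
increase when all of a variable's basis functions are dropped and the
coefficients refit, normalized so the top variable scores 100.

Models are fit by iteratively reweighted least squares on the log link; the
deviance is the Poisson deviance 2*sum(y log(y/mu) - (y - mu)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

logger = logging.getLogger(__name__)

#: hinge: (var_index, knot, sign); term: tuple of hinges; () is the intercept
Hinge = tuple[int, float, int]
Term = tuple[Hinge, ...]

DEFAULT_PENALTY = 3.0
_ETA_CLIP = 30.0


def design_matrix(X: np.ndarray, terms: list[Term]) -> np.ndarray:
    n = X.shape[0]
    B = np.empty((n, len(terms)))
    for j, term in enumerate(terms):
        col = np.ones(n)
        for (v, t, s) in term:
            col = col * np.maximum(0.0, s * (X[:, v] - t))
        B[:, j] = col
    return B


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum(xlogy(y, y) - xlogy(y, mu) - (y - mu)))


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(xlogy(y, mu) - mu - gammaln(y + 1.0)))


def fit_poisson(B: np.ndarray, y: np.ndarray, beta0: np.ndarray | None = None,
                max_iter: int = 50, tol: float = 1e-10):
    """Poisson IRLS on the log link.  Returns (beta, deviance).

    Rank-deficient designs (duplicate hinge columns) are handled by a tiny
    ridge on the normal equations with an lstsq fallback.
    """
    n, m = B.shape
    y = np.asarray(y, dtype=float)
    if beta0 is not None and beta0.shape == (m,):
        beta = beta0.copy()
    else:
        beta = np.zeros(m)
        beta[0] = np.log(max(y.mean(), 1e-8))
    eta = np.clip(B @ beta, -_ETA_CLIP, _ETA_CLIP)
    dev_old = np.inf
    for _ in range(max_iter):
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        w = mu
        Bw = B * w[:, None]
        G = Bw.T @ B
        b = Bw.T @ z
        ridge = 1e-10 * (np.trace(G) / m + 1.0)
        try:
            beta = np.linalg.solve(G + ridge * np.eye(m), b)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(B * np.sqrt(w)[:, None],
                                   z * np.sqrt(w), rcond=None)[0]
        eta = np.clip(B @ beta, -_ETA_CLIP, _ETA_CLIP)
        dev = poisson_deviance(y, np.exp(eta))
        if abs(dev_old - dev) <= tol * (abs(dev) + 0.1):
            break
        dev_old = dev
    return beta, dev


def gcv_score(dev: float, n: int, n_terms: int,
              penalty: float = DEFAULT_PENALTY) -> float:
    m_eff = n_terms + penalty * (n_terms - 1) / 2.0
    if m_eff >= n:
        return np.inf
    return dev / (n * (1.0 - m_eff / n) ** 2)


def term_variables(term: Term) -> set[int]:
    return {v for (v, _, _) in term}


def forward_pass(X: np.ndarray, y: np.ndarray, max_terms: int = 21,
                 max_degree: int = 1, tol: float = 1e-4) -> list[Term]:
    """Greedy growth of the hinge basis.

    Each step evaluates, for every parent term below the degree cap, every
    eligible variable and every observed knot, the reflected hinge pair
    (degenerate all-zero columns at extreme knots are dropped, leaving a
    single hinge); the pair giving the largest Poisson-deviance reduction is
    added.  Stops at ``max_terms`` or when the relative improvement falls
    below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    terms: list[Term] = [()]
    B = design_matrix(X, terms)
    beta, dev = fit_poisson(B, y)
    skipped_constant: set[int] = set()
    while len(terms) < max_terms:
        best = None  # (dev, new_cols, new_terms)
        for parent_idx, parent in enumerate(terms):
            if len(parent) >= max_degree:
                continue
            parent_col = B[:, parent_idx]
            active = parent_col > 0
            if not active.any():
                continue
            for v in range(p):
                if v in term_variables(parent):
                    continue
                xv = X[:, v]
                knots = np.unique(xv[active])
                if knots.size <= 1:
                    if v not in skipped_constant:
                        logger.info("predictor %d constant; skipped", v)
                        skipped_constant.add(v)
                    continue
                for t in knots:
                    cols = []
                    new_terms = []
                    for s in (1, -1):
                        col = parent_col * np.maximum(0.0, s * (xv - t))
                        if np.any(col != 0.0):
                            cols.append(col)
                            new_terms.append(parent + ((v, float(t), s),))
                    if not cols or len(terms) + len(cols) > max_terms:
                        continue
                    Bc = np.column_stack([B] + cols)
                    beta0 = np.concatenate([beta, np.zeros(len(cols))])
                    _, dev_c = fit_poisson(Bc, y, beta0=beta0, max_iter=25)
                    if best is None or dev_c < best[0]:
                        best = (dev_c, cols, new_terms)
        if best is None or (dev - best[0]) < tol * max(dev, 1.0):
            break
        terms = terms + best[2]
        B = np.column_stack([B] + best[1])
        beta, dev = fit_poisson(B, y)
    return terms


@dataclass
class MarsModel:
    """A pruned hinge-basis Poisson model with fit statistics."""

    terms: list[Term]
    coefficients: np.ndarray
    gcv: float
    gcv_null: float
    gcv_r2: float
    effective_df: float
    deviance: float
    log_likelihood: float
    n: int
    penalty: float
    importance: pd.DataFrame | None = field(default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = design_matrix(np.asarray(X, dtype=float),
                            self.terms) @ self.coefficients
        return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


def backward_prune(terms: list[Term], X: np.ndarray, y: np.ndarray,
                   penalty: float = DEFAULT_PENALTY) -> MarsModel:
    """Delete terms one at a time, keeping the GCV-minimal subset.

    The intercept-only model closes the deletion sequence, so the returned
    GCV never exceeds the null GCV; ``gcv_r2 = 1 - gcv/gcv_null``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)

    def fit_subset(subset: list[Term]):
        B = design_matrix(X, subset)
        beta, dev = fit_poisson(B, y)
        return beta, dev, gcv_score(dev, n, len(subset), penalty)

    _, dev_null, gcv_null = fit_subset([()])
    current = list(terms)
    beta, dev, gcv = fit_subset(current)
    best = (gcv, list(current), beta, dev)
    while len(current) > 1:
        step_best = None  # (gcv, subset, beta, dev)
        for j in range(1, len(current)):
            subset = current[:j] + current[j + 1:]
            beta_j, dev_j, gcv_j = fit_subset(subset)
            if step_best is None or gcv_j < step_best[0]:
                step_best = (gcv_j, subset, beta_j, dev_j)
        current = step_best[1]
        if step_best[0] < best[0]:
            best = step_best
    gcv, best_terms, beta, dev = best
    n_terms = len(best_terms)
    mu = np.exp(np.clip(design_matrix(X, best_terms) @ beta,
                        -_ETA_CLIP, _ETA_CLIP))
    return MarsModel(
        terms=best_terms, coefficients=beta, gcv=gcv, gcv_null=gcv_null,
        gcv_r2=1.0 - gcv / gcv_null if gcv_null > 0 else 0.0,
        effective_df=n_terms + penalty * (n_terms - 1) / 2.0,
        deviance=dev, log_likelihood=poisson_loglik(y, mu), n=n,
        penalty=penalty)


def variable_importance(model: MarsModel, X: np.ndarray, y: np.ndarray,
                        feature_names: list[str] | None = None,
                        ) -> pd.DataFrame:
    """Per-variable GCV-increase importance, normalized to a top score of 100.

    For each variable, all basis functions involving it are dropped, the
    coefficients refit, and the GCV increase recorded; negative increases
    clip to 0.  ``bases`` counts the basis functions using the variable.
    With ``feature_names`` given, predictors absent from the basis appear
    with bases 0 and importance 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    variables = sorted({v for t in model.terms for v in term_variables(t)})
    if not variables:
        return pd.DataFrame(columns=["variable", "bases", "importance"])
    rows = []
    for v in variables:
        reduced = [t for t in model.terms if v not in term_variables(t)]
        B = design_matrix(X, reduced)
        _, dev = fit_poisson(B, y)
        gcv_v = gcv_score(dev, n, len(reduced), model.penalty)
        delta = max(gcv_v - model.gcv, 0.0)
        bases = sum(1 for t in model.terms if v in term_variables(t))
        rows.append((v, bases, delta))
    max_delta = max(r[2] for r in rows)
    if feature_names is not None:
        rows += [(v, 0, 0.0) for v in range(len(feature_names))
                 if v not in variables]
    out = pd.DataFrame(rows, columns=["variable", "bases", "delta_gcv"])
    if max_delta > 0:
        out["importance"] = 100.0 * out["delta_gcv"] / max_delta
    else:
        logger.warning("all variables have zero GCV increase; importance"
                       " not normalizable")
        out["importance"] = 0.0
    if feature_names is not None:
        out["variable"] = [feature_names[v] for v in out["variable"]]
    return (out.sort_values("importance", ascending=False, kind="stable")
            .reset_index(drop=True)[["variable", "bases", "importance"]])


def partition_data(n_rows: int, seed: int | None = None) -> np.ndarray:
    """Random train/test/validation thirds (sizes differ by at most 1)."""
    if n_rows < 9:
        raise ValueError("need at least 9 rows to partition into thirds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_rows)
    base, rem = divmod(n_rows, 3)
    sizes = [base + (1 if k < rem else 0) for k in range(3)]
    labels = np.empty(n_rows, dtype=object)
    start = 0
    for size, name in zip(sizes, ("train", "test", "validation")):
        labels[order[start:start + size]] = name
        start += size
    return labels


def fit_mars(X, y, feature_names: list[str] | None = None,
             max_terms: int = 21, max_degree: int = 1,
             penalty: float = DEFAULT_PENALTY, tol: float = 1e-4,
             ) -> MarsModel:
    """Forward growth, GCV pruning and variable importance in one call."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    terms = forward_pass(X, y, max_terms=max_terms, max_degree=max_degree,
                         tol=tol)
    model = backward_prune(terms, X, y, penalty=penalty)
    model.importance = variable_importance(model, X, y,
                                           feature_names=feature_names)
    return model


def fit_cluster_model(covariate_table: pd.DataFrame,
                      cluster_counties, outcome_counts: pd.Series,
                      include_all_counties: bool = False,
                      partition: bool = True, seed: int | None = None,
                      max_terms: int = 21, max_degree: int = 1,
                      penalty: float = DEFAULT_PENALTY,
                      ) -> tuple[MarsModel, dict] | None:
    """MARS fit of per-county outcome counts in high-risk cluster counties.

    The response is the county's outcome visit count; predictors are the
    covariate roster columns.  By default only cluster counties enter
    (matching the high-risk-cluster framing); ``include_all_counties`` keeps
    every county and adds a cluster-membership indicator predictor.  With
    ``partition`` and at least 30 rows, selection uses the training third
    and the held-out thirds are reported as out-of-sample deviance only
    (with fewer counties the thirds are too small to mean anything and the
    model fits all rows).

    Returns (model, report) or None when fewer than 2 cluster counties exist.
    """
    cluster_counties = list(cluster_counties)
    if len(cluster_counties) < 2:
        logger.warning("fewer than 2 cluster counties; MARS model skipped")
        return None
    tab = covariate_table.set_index("county_id")
    feature_names = [c for c in tab.columns
                     if not c.startswith("ice_")]
    if include_all_counties:
        rows = tab.index.to_list()
        tab = tab.copy()
        tab["in_cluster"] = [1.0 if c in set(cluster_counties) else 0.0
                             for c in rows]
        feature_names = feature_names + ["in_cluster"]
    else:
        rows = cluster_counties
    X = tab.loc[rows, feature_names].to_numpy(dtype=float)
    y = np.array([outcome_counts.get(c, 0) for c in rows], dtype=float)

    report: dict = {"n_rows": len(rows), "partitioned": False}
    if partition and len(rows) >= 30:
        labels = partition_data(len(rows), seed=seed)
        train = labels == "train"
        model = fit_mars(X[train], y[train], feature_names=feature_names,
                         max_terms=max_terms, max_degree=max_degree,
                         penalty=penalty)
        report["partitioned"] = True
        for part in ("test", "validation"):
            mask = labels == part
            mu = model.predict(X[mask])
            report[f"{part}_deviance"] = poisson_deviance(y[mask], mu)
    else:
        model = fit_mars(X, y, feature_names=feature_names,
                         max_terms=max_terms, max_degree=max_degree,
                         penalty=penalty)
    report.update({
        "gcv": model.gcv, "gcv_r2": model.gcv_r2,
        "effective_df": model.effective_df,
        "log_likelihood": model.log_likelihood,
        "deviance": model.deviance,
    })
    return model, report
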