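"""Procrustes ANOVA with randomised residual permutation (RRPP),
allometry adjustment, repeatability (ICC) and nested variance
partitioning.

Procrustes ANOVA treats the (N, 2k) matrix of superimposed coordinates
as a multivariate response and measures effects as summed squared
Procrustes distances: sequential (type-I) sums of squares are the
traces of the usual univariate decomposition summed over coordinates.
Significance comes from RRPP: for each term, residuals of the reduced
model (all preceding terms) are permuted across specimens, pseudo-data
are refitted, and the observed F statistic is ranked within the
permutation distribution.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-9


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable model design."""


def _term_columns(term: str, data: pd.DataFrame) -> np.ndarray:
    """Design columns for one term. Categorical factors expand to full
    indicator blocks (rank handled downstream); ``a:b`` builds the
    element-wise products of the two blocks (interaction / nesting)."""
    parts = term.split(":")
    blocks = []
    for p in parts:
        if p not in data.columns:
            raise DesignError(f"model term {term!r}: column {p!r} not in data")
        col = data[p]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2 and not isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            blocks.append(col.to_numpy(float)[:, None])
        else:
            blocks.append(pd.get_dummies(col.astype(str)).to_numpy(float))
    out = blocks[0]
    for b in blocks[1:]:
        out = (out[:, :, None] * b[:, None, :]).reshape(len(data), -1)
    return out


def _orthonormal_increment(Q: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the part of span(T) not already in span(Q)."""
    resid = T - Q @ (Q.T @ T)
    U, s, _ = np.linalg.svd(resid, full_matrices=False)
    scale = max(np.linalg.norm(T, ord=2), 1.0)
    return U[:, s > _RANK_TOL * scale]


@dataclasses.dataclass
class ProcrustesANOVAResults:
    """Sequential SS table with RRPP p-values.

    ``table`` columns follow the conventional layout: Df, SS, Rsq, F,
    Z, P. Z is the effect size: the standardised position of log F in
    its permutation distribution.
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int | None
    terms: list
    total_ss: float

    def summary(self) -> str:
        with pd.option_context("display.float_format", lambda v: f"{v:.6g}"):
            body = self.table.to_string()
        return (
            f"Procrustes ANOVA (RRPP, {self.n_permutations} permutations, "
            f"seed={self.seed})\n{body}"
        )

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


class ProcrustesANOVA:
    """Linear model on a shape matrix with sequential SS and RRPP.

    Parameters
    ----------
    shape
        (N, d) response matrix (superimposed coordinates or residuals).
    data
        DataFrame holding the model columns.
    terms
        Ordered term names; each is a column of ``data`` or an ``a:b``
        interaction. Order matters: sums of squares are sequential.
    """

    def __init__(self, shape: np.ndarray, data: pd.DataFrame, terms):
        shape = np.asarray(shape, float)
        if shape.ndim != 2:
            raise ValueError("shape must be (N, d)")
        if len(data) != shape.shape[0]:
            raise ValueError("data rows must align with shape rows")
        self.shape = shape
        self.data = data.reset_index(drop=True)
        self.terms = list(terms)
        if not self.terms:
            raise DesignError("at least one model term is required")

    @classmethod
    def from_gpa(cls, gpa_result, terms, extra: pd.DataFrame | None = None):
        """Build from a GPA fit; ``log_cs`` (log centroid size) and the
        factor columns are available as model terms."""
        data = gpa_result.factors.copy()
        data["log_cs"] = gpa_result.log_centroid_sizes
        if extra is not None:
            data = pd.concat([data, extra.reset_index(drop=True)], axis=1)
        return cls(gpa_result.flat, data, terms)

    def fit(self, n_permutations: int = 999, seed: int | None = None) -> ProcrustesANOVAResults:
        if n_permutations < 99:
            warnings.warn(
                f"n_permutations={n_permutations} is very low; p-values will be coarse",
                stacklevel=2,
            )
        Y = self.shape
        N = Y.shape[0]
        grand = Y.mean(axis=0)
        total_ss = float(((Y - grand) ** 2).sum())

        # sequential orthonormal bases: intercept, then one increment per term
        Q_cum = np.full((N, 1), 1.0 / np.sqrt(N))
        bases = []
        for term in self.terms:
            T = _term_columns(term, self.data)
            U = _orthonormal_increment(Q_cum, T)
            if U.shape[1] == 0:
                raise DesignError(
                    f"term {term!r} is aliased with preceding terms (adds no rank)"
                )
            bases.append(U)
            Q_cum = np.hstack([Q_cum, U])
        rank_full = Q_cum.shape[1]
        df_resid = N - rank_full
        if df_resid <= 0:
            raise DesignError("saturated design: no residual degrees of freedom")

        ss_terms = np.array([float(((U.T @ Y) ** 2).sum()) for U in bases])
        rss = total_ss - ss_terms.sum()
        rss = max(rss, 0.0)
        df_terms = np.array([U.shape[1] for U in bases])
        f_obs = (ss_terms / df_terms) / (rss / df_resid)

        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(N) for _ in range(n_permutations)])

        p_values = np.empty(len(self.terms))
        z_values = np.empty(len(self.terms))
        Q_full = Q_cum
        for j, term in enumerate(self.terms):
            Q_red = np.hstack([np.full((N, 1), 1.0 / np.sqrt(N))] + bases[:j])
            R = Y - Q_red @ (Q_red.T @ Y)
            r_norm2 = float((R ** 2).sum())
            U = bases[j]
            f_perm = np.empty(n_permutations)
            for start in range(0, n_permutations, 256):
                idx = perms[start:start + 256]
                Rp = R[idx]                                   # (c, N, d)
                ss_j = np.einsum("nu,cnd->cud", U, Rp)
                ss_j = (ss_j ** 2).sum(axis=(1, 2))
                fitted = np.einsum("nr,cnd->crd", Q_full, Rp)
                rss_p = r_norm2 - (fitted ** 2).sum(axis=(1, 2))
                rss_p = np.maximum(rss_p, 1e-300)
                f_perm[start:start + 256] = (ss_j / df_terms[j]) / (rss_p / df_resid)
            p_values[j] = (1.0 + np.sum(f_perm >= f_obs[j])) / (n_permutations + 1.0)
            log_f = np.log(np.maximum(f_perm, 1e-300))
            sd = log_f.std(ddof=1)
            z_values[j] = (np.log(max(f_obs[j], 1e-300)) - log_f.mean()) / sd if sd > 0 else np.nan

        rows = []
        for j, term in enumerate(self.terms):
            rows.append(
                dict(term=term, Df=int(df_terms[j]), SS=ss_terms[j],
                     Rsq=ss_terms[j] / total_ss, F=f_obs[j], Z=z_values[j],
                     P=p_values[j])
            )
        rows.append(dict(term="Residuals", Df=int(df_resid), SS=rss,
                         Rsq=rss / total_ss, F=np.nan, Z=np.nan, P=np.nan))
        rows.append(dict(term="Total", Df=N - 1, SS=total_ss, Rsq=1.0,
                         F=np.nan, Z=np.nan, P=np.nan))
        table = pd.DataFrame(rows).set_index("term")
        return ProcrustesANOVAResults(
            table=table, n_permutations=n_permutations, seed=seed,
            terms=self.terms, total_ss=total_ss,
        )


def procrustes_anova(shape, data, terms, n_permutations: int = 999,
                     seed: int | None = None) -> ProcrustesANOVAResults:
    """Convenience wrapper: ``ProcrustesANOVA(shape, data, terms).fit(...)``."""
    return ProcrustesANOVA(shape, data, terms).fit(n_permutations=n_permutations, seed=seed)


# ----------------------------------------------------------------------
# allometry

def allometry_adjust(shape: np.ndarray, log_cs: np.ndarray, group) -> np.ndarray:
    """Remove the size effect on shape while retaining group differences.

    Fits ``shape ~ log_cs + group`` by least squares and returns
    residuals plus the model prediction at the grand-mean size for each
    row's group. Per-group means of the adjusted shapes equal the model
    prediction at mean size; with zero allometric slope the data are
    returned unchanged.
    """
    Y = np.asarray(shape, float)
    log_cs = np.asarray(log_cs, float)
    if not np.all(np.isfinite(log_cs)):
        raise ValueError("log centroid sizes must be finite")
    group = np.asarray(group)
    dummies = pd.get_dummies(pd.Series(group).astype(str), drop_first=True).to_numpy(float)
    if np.ptp(log_cs) < 1e-12:
        warnings.warn("log centroid size is constant; size term dropped", stacklevel=2)
        return Y.copy()
    X = np.column_stack([np.ones_like(log_cs), log_cs, dummies])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    X_at_mean = X.copy()
    X_at_mean[:, 1] = log_cs.mean()
    return resid + X_at_mean @ beta


# ----------------------------------------------------------------------
# measurement-error variance decompositions

@dataclasses.dataclass
class RepeatabilityResult:
    """Intraclass-correlation repeatability from one-way Procrustes ANOVA.

    ``R = s2_among / (s2_among + MS_within)`` with
    ``s2_among = (MS_among - MS_within) / m``; R is 1 exactly when
    replicates are identical within individuals and near 0 when
    among-individual variance vanishes.
    """

    R: float
    ms_among: float
    ms_within: float
    m: int
    n_individuals: int
    anova_r2: float

    def summary(self) -> str:
        return (
            f"Repeatability (ICC): R={self.R:.4f} from n={self.n_individuals} "
            f"individuals x m={self.m} replicates "
            f"(MS among={self.ms_among:.3e}, within={self.ms_within:.3e}, "
            f"ANOVA r2={self.anova_r2:.4f})"
        )


def repeatability(shape: np.ndarray, individual, m: int | None = None) -> RepeatabilityResult:
    """Digitisation repeatability across replicate trials.

    A one-way Procrustes ANOVA with individual as the factor provides
    mean squares (summed over all coordinates); the design must be
    balanced with exactly ``m`` replicates per individual.
    """
    Y = np.asarray(shape, float)
    individual = np.asarray(individual)
    labels, counts = np.unique(individual, return_counts=True)
    if m is None:
        m = int(counts[0])
    if np.any(counts != m):
        raise ValueError(
            f"unbalanced replicates: expected {m} per individual, found counts "
            f"{dict(zip(labels[counts != m], counts[counts != m]))}"
        )
    if m < 2:
        raise ValueError("repeatability needs at least two replicates per individual")
    n = labels.size
    grand = Y.mean(axis=0)
    ss_among = 0.0
    ss_within = 0.0
    for g in labels:
        block = Y[individual == g]
        mu = block.mean(axis=0)
        ss_among += m * float(((mu - grand) ** 2).sum())
        ss_within += float(((block - mu) ** 2).sum())
    ms_among = ss_among / (n - 1)
    ms_within = ss_within / (n * (m - 1))
    if ms_within <= 1e-13 * ms_among:
        # replicates identical within individuals (up to rounding)
        ms_within = 0.0
        R = 1.0
    else:
        s2a = (ms_among - ms_within) / m
        R = s2a / (s2a + ms_within)
    total = ss_among + ss_within
    return RepeatabilityResult(
        R=float(R), ms_among=float(ms_among), ms_within=float(ms_within),
        m=m, n_individuals=int(n), anova_r2=float(ss_among / total) if total > 0 else np.nan,
    )


def nested_variance_partition(shape: np.ndarray, individual, operator) -> pd.DataFrame:
    """Partition shape variation into individual ('ID'), operator nested
    in individual ('ID:operator'), and residual (within-trial) parts.

    Requires a complete balanced crossing: every individual digitised by
    every operator the same number of times. Returns a table of
    (term, df, SS, fraction); fractions sum to one.
    """
    Y = np.asarray(shape, float)
    individual = np.asarray(individual)
    operator = np.asarray(operator)
    ids = np.unique(individual)
    ops = np.unique(operator)
    n, o = ids.size, ops.size
    cells = pd.crosstab(pd.Series(individual), pd.Series(operator))
    if cells.shape != (n, o) or cells.to_numpy().min() == 0:
        raise ValueError("incomplete crossing: every individual needs every operator")
    m_vals = np.unique(cells.to_numpy())
    if m_vals.size != 1:
        raise ValueError("unbalanced cells: replicate counts differ across (ID, operator)")
    m = int(m_vals[0])

    grand = Y.mean(axis=0)
    ss_id = 0.0
    ss_id_op = 0.0
    ss_resid = 0.0
    for i in ids:
        block_i = Y[individual == i]
        mu_i = block_i.mean(axis=0)
        ss_id += o * m * float(((mu_i - grand) ** 2).sum())
        for op in ops:
            cell = Y[(individual == i) & (operator == op)]
            mu_io = cell.mean(axis=0)
            ss_id_op += m * float(((mu_io - mu_i) ** 2).sum())
            ss_resid += float(((cell - mu_io) ** 2).sum())
    total = ss_id + ss_id_op + ss_resid
    table = pd.DataFrame(
        {
            "term": ["ID", "ID:operator", "Residuals"],
            "df": [n - 1, n * (o - 1), n * o * (m - 1)],
            "SS": [ss_id, ss_id_op, ss_resid],
        }
    )
    table["fraction"] = table["SS"] / total if total > 0 else np.nan
    return table
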