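"""Network principal component analysis (NetPCA).

NetPCA extracts global components from a network of data matrices
``X(g, b)`` indexed by observation set ``g`` (row-class) and variable block
``b`` (col-class).  The network links act as constraints: all matrices in a
row-class share one score vector per component, and all matrices in a
col-class share one loading vector.  Component ``a`` minimizes the summed
reconstruction error

    sum_{(g,b)} || X(g,b) - t(g,a) p(b,a)^T ||^2

subject to unit Euclidean norm of the concatenated loading vector
``(p(b1,a), ..., p(bB,a))``, fitted by alternating least squares with
deflation between components.  On a single-matrix network this reduces
exactly to ordinary PCA (the leading singular triplets).

Besides the fit, the module provides the two decompositions used to read
such a model: per-matrix *block influences* (share of a component's
explained variance contributed by each matrix) and per-variable explained
variance with marker selection by threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_network import DataNetwork, StructuralError

__all__ = [
    "NetPCAModel",
    "BlockInfluenceTable",
    "VariableVarianceTable",
    "ConvergenceWarning",
    "fit_netpca",
    "block_influence",
    "variable_explained_variance",
    "select_markers",
]


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class NetPCAModel:
    """Fitted NetPCA model.

    ``scores[g]`` is ``n_obs(g) x A``; ``loadings[b]`` is ``n_vars(b) x A``.
    For every component the concatenated loading vector has unit norm, so
    score magnitudes carry the variance.  ``component_variance`` is the
    percent of the total network sum of squares explained per component.
    """

    n_components: int
    scores: dict[str, np.ndarray]
    loadings: dict[str, np.ndarray]
    component_variance: np.ndarray
    total_variance: float
    obs_ids: dict[str, list[str]]
    var_ids: dict[str, list[str]]
    pairs: list[tuple[str, str]]
    n_iter: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)

    def score_frame(self, row_class: str) -> pd.DataFrame:
        cols = [f"comp{a + 1}" for a in range(self.n_components)]
        return pd.DataFrame(self.scores[row_class], index=self.obs_ids[row_class], columns=cols)

    def loading_frame(self, col_class: str) -> pd.DataFrame:
        cols = [f"comp{a + 1}" for a in range(self.n_components)]
        return pd.DataFrame(self.loadings[col_class], index=self.var_ids[col_class], columns=cols)

    def export(self, directory: str | Path) -> None:
        """Write scores (per row-class), loadings (per col-class) and component variance."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)

        def safe(label: str) -> str:
            return label.replace("+", "pos").replace("-", "neg").replace("/", "_")

        for g in self.scores:
            self.score_frame(g).to_csv(directory / f"scores_{safe(g)}.tsv", sep="\t", index_label="obs_id")
        for b in self.loadings:
            self.loading_frame(b).to_csv(directory / f"loadings_{safe(b)}.tsv", sep="\t", index_label="var_id")
        pd.DataFrame(
            {"percent_variance": self.component_variance},
            index=[f"comp{a + 1}" for a in range(self.n_components)],
        ).to_csv(directory / "component_variance.tsv", sep="\t", index_label="component")


@dataclass
class BlockInfluenceTable:
    """Percent of each component's explained variance per (row_class, col_class) matrix."""

    table: pd.DataFrame  # MultiIndex (row_class, col_class) x columns comp1..compA

    def influence(self, row_class: str, col_class: str, component: int) -> float:
        if not 1 <= component <= self.table.shape[1]:
            raise IndexError(f"component {component} out of range 1..{self.table.shape[1]}")
        return float(self.table.loc[(row_class, col_class), f"comp{component}"])

    def by_row_class(self, component: int) -> pd.Series:
        """Summed influence per row-class, descending."""
        if not 1 <= component <= self.table.shape[1]:
            raise IndexError(f"component {component} out of range 1..{self.table.shape[1]}")
        return (
            self.table[f"comp{component}"].groupby(level=0).sum().sort_values(ascending=False)
        )

    def export(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


@dataclass
class VariableVarianceTable:
    """Per-variable percent of total variance explained, per component and cumulative."""

    percent: pd.DataFrame  # index var_id, columns comp1..compA
    cumulative: pd.DataFrame
    col_class: pd.Series  # var_id -> block label

    def export(self, path: str | Path) -> None:
        out = self.percent.copy()
        out.columns = [f"{c}_pct" for c in out.columns]
        cum = self.cumulative.copy()
        cum.columns = [f"{c}_cum_pct" for c in cum.columns]
        pd.concat([self.col_class.rename("block"), out, cum], axis=1).to_csv(
            path, sep="\t", index_label="var_id"
        )


def _init_loadings(
    X: dict[tuple[str, str], np.ndarray],
    col_classes: list[str],
    rng: np.random.Generator | None,
) -> dict[str, np.ndarray]:
    p = {}
    for b in col_classes:
        stack = np.vstack([X[k] for k in X if k[1] == b])
        if rng is not None:
            p[b] = rng.standard_normal(stack.shape[1])
        else:
            # leading right singular vector of the block's row-wise concatenation
            _, _, vt = np.linalg.svd(stack, full_matrices=False)
            p[b] = vt[0]
    norm = np.sqrt(sum(float(v @ v) for v in p.values()))
    return {b: v / norm for b, v in p.items()}


def fit_netpca(
    network: DataNetwork,
    n_components: int,
    tol: float = 1e-9,
    max_iter: int = 500,
    seed: int | None = None,
    init: str = "svd",
) -> NetPCAModel:
    """Fit a NetPCA model on a validated, scaled data network.

    Components are extracted sequentially.  Within a component, alternating
    least squares updates

        t(g) <- [sum_b X(g,b) p(b)] / [sum_b ||p(b)||^2]
        p(b) <- [sum_g X(g,b)^T t(g)] / [sum_g ||t(g)||^2]

    (sums over the matrices present for that g or b) followed by global
    renormalization of the concatenated loading; iteration stops when the
    relative change of the reconstruction objective drops below ``tol``.
    The fitted rank-1 terms are deflated before the next component.  Each
    component is sign-fixed so its largest-magnitude loading entry is
    positive.

    Parameters
    ----------
    init
        ``"svd"`` (deterministic, per-block leading right singular vector)
        or ``"random"`` (Gaussian, controlled by ``seed``).
    """
    if not network.matrices:
        raise StructuralError("empty network")
    min_obs = min(m.shape[0] for m in network.matrices)
    total_vars = sum(len(network.var_ids(b)) for b in network.col_classes)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min_obs or n_components > total_vars:
        raise ValueError(
            f"n_components={n_components} exceeds the smallest observation "
            f"count ({min_obs}) or the total variable count ({total_vars})"
        )

    rng = np.random.default_rng(seed) if init == "random" else None
    row_classes = network.row_classes
    col_classes = network.col_classes
    pairs = [(m.row_class, m.col_class) for m in network.matrices]
    X = {(m.row_class, m.col_class): m.values.copy() for m in network.matrices}
    blocks_of = {g: [b for (g2, b) in pairs if g2 == g] for g in row_classes}
    groups_of = {b: [g for (g, b2) in pairs if b2 == b] for b in col_classes}

    total_variance = float(sum(np.sum(v**2) for v in X.values()))
    A = n_components
    scores = {g: np.zeros((len(network.obs_ids(g)), A)) for g in row_classes}
    loadings = {b: np.zeros((len(network.var_ids(b)), A)) for b in col_classes}
    component_variance = np.zeros(A)
    n_iter_list: list[int] = []
    converged_list: list[bool] = []

    current_ss = total_variance
    for a in range(A):
        p = _init_loadings(X, col_classes, rng)
        prev_obj = None
        converged = False
        t: dict[str, np.ndarray] = {}
        for it in range(1, max_iter + 1):
            # score update: least squares given the current loadings
            explained = 0.0
            for g in row_classes:
                s_g = sum(float(p[b] @ p[b]) for b in blocks_of[g])
                t[g] = sum(X[(g, b)] @ p[b] for b in blocks_of[g]) / s_g
                explained += float(t[g] @ t[g]) * s_g
            obj = current_ss - explained  # residual SS with LS scores
            if obj <= 1e-12 * max(total_variance, 1.0):  # exact fit
                converged = True
                break
            if prev_obj is not None:
                denom = max(abs(prev_obj), np.finfo(float).tiny)
                if abs(prev_obj - obj) / denom < tol:
                    converged = True
                    break
            prev_obj = obj
            # loading update + global renormalization
            for b in col_classes:
                s_b = sum(float(t[g] @ t[g]) for g in groups_of[b])
                p[b] = sum(X[(g, b)].T @ t[g] for g in groups_of[b]) / s_b
            norm = np.sqrt(sum(float(v @ v) for v in p.values()))
            p = {b: v / norm for b, v in p.items()}
        if not converged:
            warnings.warn(
                f"component {a + 1}: ALS did not converge in {max_iter} iterations "
                f"(last objective {obj:.6g}); returning the partial model",
                ConvergenceWarning,
                stacklevel=2,
            )
        n_iter_list.append(it)
        converged_list.append(converged)

        # sign convention: largest-magnitude concatenated loading entry positive
        concat = np.concatenate([p[b] for b in col_classes])
        if concat[np.argmax(np.abs(concat))] < 0:
            p = {b: -v for b, v in p.items()}
            t = {g: -v for g, v in t.items()}

        explained = 0.0
        for g in row_classes:
            s_g = sum(float(p[b] @ p[b]) for b in blocks_of[g])
            explained += float(t[g] @ t[g]) * s_g
        component_variance[a] = explained / total_variance * 100.0
        for g in row_classes:
            scores[g][:, a] = t[g]
        for b in col_classes:
            loadings[b][:, a] = p[b]
        for g, b in pairs:
            X[(g, b)] -= np.outer(t[g], p[b])
        current_ss = float(sum(np.sum(v**2) for v in X.values()))

    return NetPCAModel(
        n_components=A,
        scores=scores,
        loadings=loadings,
        component_variance=component_variance,
        total_variance=total_variance,
        obs_ids={g: network.obs_ids(g) for g in row_classes},
        var_ids={b: network.var_ids(b) for b in col_classes},
        pairs=pairs,
        n_iter=n_iter_list,
        converged=converged_list,
    )


def block_influence(model: NetPCAModel, network: DataNetwork) -> BlockInfluenceTable:
    """Percent of each component's variance attributable to each matrix.

    influence(g, b, a) = ||t(g,a) p(b,a)^T||^2 normalized over all matrices,
    times 100; the fitted rank-1 norm factorizes as ||t||^2 ||p||^2.
    """
    rows = []
    raw = np.zeros((len(model.pairs), model.n_components))
    for i, (g, b) in enumerate(model.pairs):
        rows.append((g, b))
        for a in range(model.n_components):
            raw[i, a] = float(model.scores[g][:, a] @ model.scores[g][:, a]) * float(
                model.loadings[b][:, a] @ model.loadings[b][:, a]
            )
    totals = raw.sum(axis=0)
    totals[totals == 0] = 1.0
    pct = raw / totals * 100.0
    table = pd.DataFrame(
        pct,
        index=pd.MultiIndex.from_tuples(rows, names=["row_class", "col_class"]),
        columns=[f"comp{a + 1}" for a in range(model.n_components)],
    )
    return BlockInfluenceTable(table)


def variable_explained_variance(
    model: NetPCAModel, network: DataNetwork
) -> VariableVarianceTable:
    """Percent of each variable's total variance explained per component.

    For variable ``v`` of block ``b`` on component ``a``:

        100 * [sum_g ||t(g,a)||^2 * p(b,a,v)^2] / [sum_g sum_rows X(g,b)[., v]^2]

    with sums over the observation sets present for block ``b`` and the
    denominator taken on the scaled network the model was fitted on.
    """
    pair_set = set(model.pairs)
    records: dict[str, np.ndarray] = {}
    classes: dict[str, str] = {}
    by_pair = network.by_pair()
    for b in network.col_classes:
        groups = [g for (g, b2) in model.pairs if b2 == b]
        score_ss = np.array(
            [sum(float(model.scores[g][:, a] @ model.scores[g][:, a]) for g in groups)
             for a in range(model.n_components)]
        )
        denom = np.zeros(len(network.var_ids(b)))
        for g in groups:
            if (g, b) in pair_set:
                denom += np.sum(by_pair[(g, b)].values ** 2, axis=0)
        denom[denom == 0] = np.inf  # all-zero column explains nothing
        P = model.loadings[b]  # n_vars x A
        pct = (P**2) * score_ss[np.newaxis, :] / denom[:, np.newaxis] * 100.0
        for i, v in enumerate(network.var_ids(b)):
            if v in records:
                raise StructuralError(f"variable id {v!r} occurs in more than one block")
            records[v] = pct[i]
            classes[v] = b
    cols = [f"comp{a + 1}" for a in range(model.n_components)]
    percent = pd.DataFrame.from_dict(records, orient="index", columns=cols)
    return VariableVarianceTable(
        percent=percent,
        cumulative=percent.cumsum(axis=1),
        col_class=pd.Series(classes, name="col_class"),
    )


def select_markers(
    table: VariableVarianceTable, component: int, threshold_percent: float = 20.0
) -> list[str]:
    """Variables whose explained-variance percent on ``component`` is >= threshold.

    Sorted by descending percent, ties broken by variable id.  The threshold
    is inclusive: a variable accounting for exactly the threshold proportion
    of its total variability is selected.
    """
    if not 0 <= threshold_percent <= 100:
        raise ValueError("threshold_percent must be in [0, 100]")
    col = f"comp{component}"
    if col not in table.percent.columns:
        raise IndexError(f"component {component} out of range")
    s = table.percent[col]
    hits = s[s >= threshold_percent]
    order = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))
    return [v for v, _ in order]
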