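"""Multigroup/multiblock data structure for network PCA.

A study that measures several cohorts (possibly at several timepoints) on
several analytical blocks of variables naturally unfolds into a *network of
data matrices*: one matrix per (observation set, variable block) pair.
Matrices that share their observation set are linked row-wise; matrices that
share their variable block are linked column-wise.  This module provides the
container types, structural validation, unit-variance scaling, and delimited
text I/O for that structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class StructuralError(ValueError):
    """Raised when the matrix network violates its structural invariants."""


class DisconnectedNetworkWarning(UserWarning):
    """The matrix network is not a single connected component."""


@dataclass
class DataMatrix:
    """One observations x variables intensity matrix.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_obs, n_vars)``; no missing values.
    obs_ids, var_ids
        Unique ordered identifiers for rows and columns.
    row_class
        Label of the observation set (e.g. a cohort-timepoint like ``"preHD"``).
    col_class
        Label of the variable block (e.g. an LC-MS setup like ``"RPLC+"``).
    """

    values: np.ndarray
    obs_ids: list[str]
    var_ids: list[str]
    row_class: str
    col_class: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.obs_ids = [str(o) for o in self.obs_ids]
        self.var_ids = [str(v) for v in self.var_ids]
        if self.values.ndim != 2:
            raise StructuralError("values must be a 2-D matrix")
        n_obs, n_vars = self.values.shape
        if n_obs < 1 or n_vars < 1:
            raise StructuralError("matrix must have at least one row and one column")
        if len(self.obs_ids) != n_obs:
            raise StructuralError(
                f"{len(self.obs_ids)} obs_ids for {n_obs} rows "
                f"({self.row_class}/{self.col_class})"
            )
        if len(self.var_ids) != n_vars:
            raise StructuralError(
                f"{len(self.var_ids)} var_ids for {n_vars} columns "
                f"({self.row_class}/{self.col_class})"
            )
        if len(set(self.obs_ids)) != n_obs:
            raise StructuralError("duplicate obs_ids")
        if len(set(self.var_ids)) != n_vars:
            raise StructuralError("duplicate var_ids")
        if not np.all(np.isfinite(self.values)):
            raise StructuralError(
                f"non-finite values in matrix {self.row_class}/{self.col_class}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.obs_ids, columns=self.var_ids)


@dataclass
class DataNetwork:
    """A validated collection of :class:`DataMatrix` linked by shared rows/columns."""

    matrices: list[DataMatrix]
    row_classes: list[str] = field(default_factory=list)
    col_classes: list[str] = field(default_factory=list)
    # edges: (i, j, kind) with i < j and kind in {"shared-rows", "shared-columns"}
    edges: list[tuple[int, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def incidence(self) -> np.ndarray:
        """Symmetric binary matrix-by-matrix incidence."""
        n = len(self.matrices)
        inc = np.zeros((n, n), dtype=int)
        for i, j, _ in self.edges:
            inc[i, j] = inc[j, i] = 1
        return inc

    def by_pair(self) -> dict[tuple[str, str], DataMatrix]:
        return {(m.row_class, m.col_class): m for m in self.matrices}

    def obs_ids(self, row_class: str) -> list[str]:
        for m in self.matrices:
            if m.row_class == row_class:
                return m.obs_ids
        raise KeyError(row_class)

    def var_ids(self, col_class: str) -> list[str]:
        for m in self.matrices:
            if m.col_class == col_class:
                return m.var_ids
        raise KeyError(col_class)

    def total_sum_of_squares(self) -> float:
        return float(sum(np.sum(m.values**2) for m in self.matrices))


@dataclass
class ScalingState:
    """Per-variable centering/scaling statistics, one table per variable block.

    Statistics are computed over the vertical concatenation of every matrix
    in the block (all observation sets pooled), with the sample (n-1)
    standard deviation.
    """

    stats: dict[str, pd.DataFrame]  # col_class -> DataFrame(index=var_id, cols=[mean, sd])
    dropped: dict[str, list[str]] = field(default_factory=dict)


def build_data_network(matrices: Sequence[DataMatrix]) -> DataNetwork:
    """Assemble and validate a :class:`DataNetwork`.

    Links every pair of matrices with equal ``row_class`` (shared-rows edge)
    or equal ``col_class`` (shared-columns edge), checking that shared
    identifier lists agree element-wise and that each (row_class, col_class)
    pair occurs at most once.  A network that is not one connected component
    is legal but triggers :class:`DisconnectedNetworkWarning`.
    """
    matrices = list(matrices)
    if not matrices:
        raise StructuralError("at least one matrix is required")
    seen_pairs: set[tuple[str, str]] = set()
    for m in matrices:
        if not m.row_class or not m.col_class:
            raise StructuralError("row_class and col_class labels must be populated")
        pair = (m.row_class, m.col_class)
        if pair in seen_pairs:
            raise StructuralError(f"duplicate (row_class, col_class) pair {pair}")
        seen_pairs.add(pair)

    edges: list[tuple[int, int, str]] = []
    for i in range(len(matrices)):
        for j in range(i + 1, len(matrices)):
            a, b = matrices[i], matrices[j]
            if a.row_class == b.row_class:
                if a.obs_ids != b.obs_ids:
                    raise StructuralError(
                        f"matrices ({a.row_class}/{a.col_class}) and "
                        f"({b.row_class}/{b.col_class}) share row_class "
                        f"{a.row_class!r} but their obs_ids differ"
                    )
                edges.append((i, j, "shared-rows"))
            if a.col_class == b.col_class:
                if a.var_ids != b.var_ids:
                    raise StructuralError(
                        f"matrices ({a.row_class}/{a.col_class}) and "
                        f"({b.row_class}/{b.col_class}) share col_class "
                        f"{a.col_class!r} but their var_ids differ"
                    )
                edges.append((i, j, "shared-columns"))

    row_classes = list(dict.fromkeys(m.row_class for m in matrices))
    col_classes = list(dict.fromkeys(m.col_class for m in matrices))
    net = DataNetwork(matrices, row_classes, col_classes, edges)
    if len(matrices) > 1 and _n_components(len(matrices), edges) > 1:
        warnings.warn(
            "data network is not a single connected component",
            DisconnectedNetworkWarning,
            stacklevel=2,
        )
    return net


def _n_components(n: int, edges: Iterable[tuple[int, int, str]]) -> int:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, _ in edges:
        parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def uv_scale(
    network: DataNetwork, drop_zero_variance: bool = False
) -> tuple[DataNetwork, ScalingState]:
    """Unit-variance scale every variable over its pooled block concatenation.

    Each variable is centered and divided by its sample standard deviation,
    both computed over the vertical concatenation of all matrices sharing the
    variable's block.  Pooling across observation sets (rather than per
    matrix) preserves between-group mean offsets, which is what lets the
    leading component separate groups.

    Parameters
    ----------
    drop_zero_variance
        If true, constant variables are removed from every matrix of their
        block instead of raising.
    """
    stats: dict[str, pd.DataFrame] = {}
    dropped: dict[str, list[str]] = {}
    keep_idx: dict[str, np.ndarray] = {}
    for b in network.col_classes:
        block = [m for m in network.matrices if m.col_class == b]
        concat = np.vstack([m.values for m in block])
        mean = concat.mean(axis=0)
        sd = concat.std(axis=0, ddof=1) if concat.shape[0] > 1 else np.zeros(concat.shape[1])
        var_ids = block[0].var_ids
        zero = sd <= 0
        if np.any(zero):
            bad = [v for v, z in zip(var_ids, zero) if z]
            if not drop_zero_variance:
                raise StructuralError(
                    f"zero-variance variables in block {b!r}: {', '.join(bad)}"
                )
            dropped[b] = bad
        keep = ~zero
        if not np.any(keep):
            raise StructuralError(f"block {b!r} has no variable with nonzero variance")
        keep_idx[b] = keep
        stats[b] = pd.DataFrame(
            {"mean": mean[keep], "sd": sd[keep]},
            index=[v for v, k in zip(var_ids, keep) if k],
        )

    scaled = []
    for m in network.matrices:
        keep = keep_idx[m.col_class]
        st = stats[m.col_class]
        vals = (m.values[:, keep] - st["mean"].to_numpy()) / st["sd"].to_numpy()
        scaled.append(
            DataMatrix(vals, m.obs_ids, list(st.index), m.row_class, m.col_class)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DisconnectedNetworkWarning)
        out = build_data_network(scaled)
    return out, ScalingState(stats=stats, dropped=dropped)


# ---------------------------------------------------------------------------
# Delimited text I/O


def read_matrix(path: str | Path, row_class: str, col_class: str, sep: str | None = None) -> DataMatrix:
    """Read one matrix: first column observation ids, header row variable ids."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return DataMatrix(
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        row_class,
        col_class,
    )


def write_matrix(matrix: DataMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, index_label="obs_id")


def read_manifest(path: str | Path) -> DataNetwork:
    """Read a matrix manifest: delimited table with path, row_class, col_class.

    Relative matrix paths are resolved against the manifest's directory.
    """
    path = Path(path)
    man = pd.read_csv(path, sep="\t")
    required = {"path", "row_class", "col_class"}
    if not required.issubset(man.columns):
        raise StructuralError(f"manifest must have columns {sorted(required)}")
    matrices = []
    for _, row in man.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = path.parent / p
        matrices.append(read_matrix(p, str(row["row_class"]), str(row["col_class"])))
    return build_data_network(matrices)


def write_manifest(network: DataNetwork, directory: str | Path) -> Path:
    """Write every matrix plus a manifest TSV into ``directory``; return manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in network.matrices:
        safe = f"{m.row_class}__{m.col_class}".replace("+", "pos").replace("-", "neg")
        fname = f"matrix_{safe}.tsv"
        write_matrix(m, directory / fname)
        rows.append({"path": fname, "row_class": m.row_class, "col_class": m.col_class})
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
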