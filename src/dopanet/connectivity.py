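"""Condition-wise Fisher-z functional connectivity and load regression.

Edges are Fisher z-transformed Pearson correlations between parcellated
BOLD node time courses. For each edge the load-dependent connectivity
change is the slope w1 of the linear model zFC = w0 + w1 * load with load
coded 0/1/2; network summaries are arithmetic means of w1 over the edges
within the DMN, within the TPN, and between them.

Block sample windows are shifted forward by `lag_volumes` (default 2
volumes = 4 s at TR 2 s) to account for haemodynamic delay before samples
are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REST = -1
Z_CLAMP = 1.0 - 1e-12

__all__ = [
    "REST", "ParcelTimeSeries", "EdgeMatrix", "LoadRegressionResult",
    "condition_connectivity", "blockwise_network_strength",
    "edge_load_regression", "whole_session_connectivity", "edge_masks",
]


class ConnectivityError(ValueError):
    pass


@dataclass
class ParcelTimeSeries:
    """Node x volume BOLD matrix with volume-wise condition labels.

    Labels are integers: -1 for rest, 0/1/2 for the n-back load of the
    task block covering that volume (acquisition-aligned, unshifted).
    """

    data: np.ndarray
    node_ids: list[str]
    labels: np.ndarray
    tr: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 2:
            raise ConnectivityError("data must be a nodes x volumes matrix")
        if self.data.shape[0] != len(self.node_ids):
            raise ConnectivityError("node_ids do not match the data rows")
        if self.data.shape[1] != len(self.labels):
            raise ConnectivityError("label vector must match the volume count")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data.T, columns=self.node_ids)


@dataclass
class EdgeMatrix:
    """Symmetric Fisher-z connectivity for one condition (diagonal NaN)."""

    condition: int
    z: np.ndarray
    n_samples: int

    def to_long(self, node_ids: list[str]) -> pd.DataFrame:
        iu = np.triu_indices(self.z.shape[0], k=1)
        return pd.DataFrame({
            "node_i": [node_ids[i] for i in iu[0]],
            "node_j": [node_ids[j] for j in iu[1]],
            "z": self.z[iu],
        })


@dataclass
class LoadRegressionResult:
    """Per-edge intercept/slope of zFC on load, plus network means."""

    w0: np.ndarray
    w1: np.ndarray
    dmn_w1: float = np.nan
    tpn_w1: float = np.nan
    between_w1: float = np.nan


def _condition_runs(labels: np.ndarray, condition: int) -> list[np.ndarray]:
    """Contiguous volume-index runs where labels == condition."""
    mask = np.asarray(labels) == condition
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    return np.split(idx, breaks + 1)


def _shifted_samples(ts: ParcelTimeSeries, runs: list[np.ndarray],
                     lag_volumes: int) -> np.ndarray:
    cols = []
    for run in runs:
        shifted = run + lag_volumes
        shifted = shifted[shifted < ts.n_volumes]
        cols.append(shifted)
    if not cols:
        raise ConnectivityError("no usable samples after lag shift")
    return np.concatenate(cols)


def _block_demeaned(ts: ParcelTimeSeries, runs: list[np.ndarray],
                    lag_volumes: int) -> tuple[np.ndarray, int]:
    """Concatenate lag-shifted block windows, demeaning each block per node.

    Without per-block demeaning, block-to-block variation of the sample
    means is shared across all nodes and spuriously inflates every
    correlation.
    """
    segs = []
    for run in runs:
        idx = run + lag_volumes
        idx = idx[idx < ts.n_volumes]
        if len(idx) == 0:
            continue
        seg = ts.data[:, idx]
        segs.append(seg - seg.mean(axis=1, keepdims=True))
    if not segs:
        raise ConnectivityError("no usable samples after lag shift")
    samples = np.concatenate(segs, axis=1)
    return samples, samples.shape[1]


def _fisher_z(samples: np.ndarray, node_ids: list[str]) -> np.ndarray:
    sd = samples.std(axis=1)
    if np.any(sd == 0):
        bad = [node_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ConnectivityError(f"constant signal in node(s): {bad}")
    r = np.corrcoef(samples)
    r = np.clip(r, -Z_CLAMP, Z_CLAMP)
    z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    return z


def condition_connectivity(ts: ParcelTimeSeries, condition: int,
                           lag_volumes: int = 2) -> EdgeMatrix:
    """Fisher-z connectivity over all lag-shifted blocks of one condition."""
    runs = _condition_runs(ts.labels, condition)
    if not runs:
        raise ConnectivityError(f"condition {condition} absent from labels")
    samples, n = _block_demeaned(ts, runs, lag_volumes)
    if n < 10:
        raise ConnectivityError(
            f"condition {condition}: only {n} samples after lag shift")
    z = _fisher_z(samples, ts.node_ids)
    return EdgeMatrix(condition=condition, z=z, n_samples=n)


def blockwise_network_strength(ts: ParcelTimeSeries, dmn_mask: np.ndarray,
                               lag_volumes: int = 2,
                               min_samples: int = 8) -> np.ndarray:
    """Mean within-DMN Fisher z per task block, in temporal order."""
    dmn_mask = np.asarray(dmn_mask, dtype=bool)
    task_runs = [run for cond in (0, 1, 2)
                 for run in _condition_runs(ts.labels, cond)]
    task_runs.sort(key=lambda run: run[0])
    if not task_runs:
        raise ConnectivityError("no task blocks in the label vector")
    iu = np.triu_indices(int(dmn_mask.sum()), k=1)
    strengths = np.empty(len(task_runs))
    for b, run in enumerate(task_runs):
        idx = _shifted_samples(ts, [run], lag_volumes)
        if len(idx) < min_samples:
            raise ConnectivityError(
                f"block {b}: only {len(idx)} samples (need >= {min_samples})")
        z = _fisher_z(ts.data[np.ix_(dmn_mask, idx)],
                      [n for n, m in zip(ts.node_ids, dmn_mask) if m])
        strengths[b] = z[iu].mean()
    return strengths


def edge_masks(dmn_mask: np.ndarray) -> dict[str, np.ndarray]:
    """Upper-triangular boolean edge masks for the three edge sets."""
    dmn_mask = np.asarray(dmn_mask, dtype=bool)
    n = len(dmn_mask)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    both_dmn = dmn_mask[:, None] & dmn_mask[None, :]
    both_tpn = ~dmn_mask[:, None] & ~dmn_mask[None, :]
    return {
        "dmn": upper & both_dmn,
        "tpn": upper & both_tpn,
        "between": upper & ~both_dmn & ~both_tpn,
    }


def edge_load_regression(z_by_condition: dict[int, EdgeMatrix],
                         dmn_mask: np.ndarray | None = None,
                         ) -> LoadRegressionResult:
    """Per-edge OLS of Fisher z on load in {0, 1, 2}, plus network means."""
    for load in (0, 1, 2):
        if load not in z_by_condition:
            raise ConnectivityError(f"missing condition {load}")
    z = np.stack([z_by_condition[load].z for load in (0, 1, 2)])
    loads = np.array([0.0, 1.0, 2.0])
    lc = loads - loads.mean()
    w1 = np.tensordot(lc, z, axes=(0, 0)) / (lc @ lc)
    w0 = z.mean(axis=0) - w1 * loads.mean()
    result = LoadRegressionResult(w0=w0, w1=w1)
    if dmn_mask is not None:
        masks = edge_masks(dmn_mask)
        result.dmn_w1 = float(w1[masks["dmn"]].mean())
        result.tpn_w1 = float(w1[masks["tpn"]].mean())
        result.between_w1 = float(w1[masks["between"]].mean())
    return result


def whole_session_connectivity(ts: ParcelTimeSeries, dmn_mask: np.ndarray,
                               lag_volumes: int = 2) -> dict[str, float]:
    """Mean Fisher z per network, pooling all task (non-rest) blocks."""
    task_runs = [run for cond in (0, 1, 2)
                 for run in _condition_runs(ts.labels, cond)]
    if not task_runs:
        raise ConnectivityError("no task volumes in the label vector")
    samples, _ = _block_demeaned(ts, task_runs, lag_volumes)
    z = _fisher_z(samples, ts.node_ids)
    masks = edge_masks(dmn_mask)
    return {name: float(z[m].mean()) for name, m in masks.items()}
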