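"""Connectome construction and per-subject network features.

Turns parcel time series into Fisher-z functional-connectivity matrices
and summarises them per subject as

* mean within-network connectivity for each of the seven networks,
* network segregation ``(Z̄n - Z̄a) / Z̄n``, the relative excess of mean
  within-network over mean network-to-rest connectivity, and
* optionally the canonical upper-triangle edge vector.

Also houses the subject-level quality-control filter (head motion and
adult age range) applied before any statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import NETWORKS, NetworkAtlas, ParcelTimeSeries, SubjectRecord

#: below this the Pearson correlation of two columns is treated as degenerate
_EPS = 1e-7

FD_MAX_DEFAULT = 0.55  # mm; subjects strictly above are excluded
AGE_MIN_DEFAULT = 18.0
AGE_MAX_DEFAULT = 65.0


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric P x P Fisher-z matrix; the diagonal is undefined (NaN)."""

    values: np.ndarray
    parcel_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if v.shape[0] != len(self.parcel_ids):
            raise ValueError("matrix size does not match parcel_ids")
        off = ~np.eye(v.shape[0], dtype=bool)
        if not np.allclose(v[off], v.T[off], atol=1e-10, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(v[off])):
            raise ValueError("off-diagonal entries must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Exclusion:
    subject_id: str
    reason: str  # "high_motion" | "age_range" | "missing_covariate"
    detail: str = ""


def filter_subjects(
    records: Sequence[SubjectRecord],
    fd_max: float = FD_MAX_DEFAULT,
    age_min: float = AGE_MIN_DEFAULT,
    age_max: float = AGE_MAX_DEFAULT,
) -> tuple[list[SubjectRecord], list[Exclusion]]:
    """Subject-level QC: keep adults with acceptable head motion.

    A subject is kept when ``mean_fd <= fd_max`` (the threshold itself
    passes; exclusion is strict) and ``age_min <= age <= age_max``.
    Missing age or motion never drops a subject silently — it is recorded
    with reason ``missing_covariate``.
    """
    kept: list[SubjectRecord] = []
    excluded: list[Exclusion] = []
    for rec in records:
        age, fd = rec.age, rec.mean_fd
        if age is None or fd is None or not np.isfinite(age) or not np.isfinite(fd):
            excluded.append(Exclusion(rec.subject_id, "missing_covariate",
                                      "age or mean_fd unavailable"))
        elif fd > fd_max:
            excluded.append(Exclusion(rec.subject_id, "high_motion",
                                      f"mean_fd={fd:.3f} > {fd_max}"))
        elif not age_min <= age <= age_max:
            excluded.append(Exclusion(rec.subject_id, "age_range",
                                      f"age={age:.1f} outside [{age_min}, {age_max}]"))
        else:
            kept.append(rec)
    return kept, excluded


def fisher_z(r):
    """Variance-stabilising Fisher transform z = arctanh(r).

    Correlations are clipped to ``|r| <= 1 - 1e-7`` first so that perfect
    (anti-)correlations map to large finite values instead of infinities.
    Inputs with ``|r| > 1`` are rejected.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise ValueError("correlations must satisfy |r| <= 1")
    out = np.arctanh(np.clip(arr, -1.0 + _EPS, 1.0 - _EPS))
    return out if arr.ndim else float(out)


def compute_fc(ts: ParcelTimeSeries) -> ConnectivityMatrix:
    """Fisher-z Pearson connectivity matrix of one subject's time series."""
    x = ts.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for a correlation matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"time series for {ts.subject_id} contains non-finite values")
    sd = x.std(axis=0)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        names = [ts.parcel_ids[i] for i in flat]
        raise ValueError(f"zero-variance parcels for {ts.subject_id}: {names}")
    if x.shape[0] < x.shape[1]:
        warnings.warn(
            f"{ts.subject_id}: fewer timepoints ({x.shape[0]}) than parcels "
            f"({x.shape[1]}); correlations will be noisy", stacklevel=2)
    r = np.corrcoef(x, rowvar=False)
    # numerical excursions beyond +/-1 from corrcoef are rounding only
    np.clip(r, -1.0, 1.0, out=r)
    z = np.arctanh(np.clip(r, -1.0 + _EPS, 1.0 - _EPS))
    z = 0.5 * (z + z.T)
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z, tuple(ts.parcel_ids))


def within_network_mean(fc: ConnectivityMatrix, atlas: NetworkAtlas, network: str) -> float:
    """Mean Fisher z over all unordered within-network parcel pairs (signed)."""
    idx = atlas.indices(network)
    if idx.size < 2:
        raise ValueError(f"network {network} has fewer than 2 parcels")
    sub = fc.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(np.mean(sub[iu]))


def edge_vector(fc: ConnectivityMatrix) -> np.ndarray:
    """Canonical edge vector: row-major upper triangle, length P(P-1)/2."""
    iu = np.triu_indices(fc.n_parcels, k=1)
    return fc.values[iu].copy()


def matrix_from_edges(edges: np.ndarray, parcel_ids: Sequence[str]) -> ConnectivityMatrix:
    """Inverse of :func:`edge_vector` (diagonal restored as undefined)."""
    p = len(parcel_ids)
    expected = p * (p - 1) // 2
    edges = np.asarray(edges, dtype=float)
    if edges.shape != (expected,):
        raise ValueError(f"expected {expected} edges for {p} parcels, got {edges.shape}")
    m = np.full((p, p), np.nan)
    iu = np.triu_indices(p, k=1)
    m[iu] = edges
    m[(iu[1], iu[0])] = edges
    return ConnectivityMatrix(m, tuple(parcel_ids))


def network_segregation(
    fc: ConnectivityMatrix,
    atlas: NetworkAtlas,
    network: str,
    between_policy: str = "positive",
) -> float:
    """Segregation s = (Z̄n - Z̄a) / Z̄n of one network.

    Z̄n averages the positive within-network z values; Z̄a averages the z
    values on edges from this network's parcels to all parcels of other
    networks. ``between_policy`` selects whether Z̄a is restricted to
    positive edges (``"positive"``, default, mirroring the within-network
    treatment) or uses all edges (``"signed"``). With no positive
    between-network edge under the positive policy Z̄a is 0 (s = 1); with
    no positive within-network edge the metric is undefined and NaN is
    returned so the subject/network can be reported as missing.
    """
    if between_policy not in ("positive", "signed"):
        raise ValueError("between_policy must be 'positive' or 'signed'")
    idx = atlas.indices(network)
    if idx.size < 2:
        raise ValueError(f"network {network} has fewer than 2 parcels")
    inside = np.zeros(fc.n_parcels, dtype=bool)
    inside[idx] = True

    sub = fc.values[np.ix_(idx, idx)]
    within = sub[np.triu_indices(idx.size, k=1)]
    within_pos = within[within > 0]
    if within_pos.size == 0:
        return float("nan")
    z_n = float(np.mean(within_pos))

    between = fc.values[np.ix_(idx, np.nonzero(~inside)[0])].ravel()
    if between_policy == "positive":
        between_sel = between[between > 0]
        z_a = float(np.mean(between_sel)) if between_sel.size else 0.0
    else:
        z_a = float(np.mean(between)) if between.size else 0.0
    return (z_n - z_a) / z_n


def subject_features(
    series: Iterable[ParcelTimeSeries],
    atlas: NetworkAtlas,
    between_policy: str = "positive",
    include_edges: bool = False,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Feature table: per subject, within-network mean z and segregation.

    Columns are ``fc_<NET>`` and ``seg_<NET>`` for the seven networks.
    When ``include_edges`` is set the full edge vectors are returned as a
    second (n_subjects x P(P-1)/2) array in the canonical edge order.
    """
    if between_policy not in ("positive", "signed"):
        raise ValueError("between_policy must be 'positive' or 'signed'")
    # flat index sets per network, shared across subjects
    p = atlas.n_parcels
    labels = np.asarray(atlas.labels)
    plan = {}
    for net in NETWORKS:
        inside = labels == net
        within = np.nonzero(np.triu(np.outer(inside, inside), 1).ravel())[0]
        between = np.nonzero(np.outer(inside, ~inside).ravel())[0]
        plan[net] = (within, between)

    rows = []
    edge_rows = [] if include_edges else None
    iu_flat = None
    for ts in series:
        if tuple(ts.parcel_ids) != tuple(atlas.parcel_ids):
            raise ValueError(
                f"parcels of {ts.subject_id} do not match the atlas ordering")
        fc = compute_fc(ts)
        flat = fc.values.ravel()
        row: dict = {"subject_id": ts.subject_id}
        for net, (within, between) in plan.items():
            w = flat[within]
            row[f"fc_{net}"] = float(w.mean())
            wpos = w[w > 0]
            if wpos.size == 0:
                row[f"seg_{net}"] = float("nan")
            else:
                z_n = wpos.mean()
                b = flat[between]
                if between_policy == "positive":
                    bpos = b[b > 0]
                    z_a = bpos.mean() if bpos.size else 0.0
                else:
                    z_a = b.mean() if b.size else 0.0
                row[f"seg_{net}"] = float((z_n - z_a) / z_n)
        rows.append(row)
        if edge_rows is not None:
            if iu_flat is None:
                iu = np.triu_indices(p, k=1)
                iu_flat = iu[0] * p + iu[1]
            edge_rows.append(flat[iu_flat])
    feats = pd.DataFrame(rows)
    edges = np.vstack(edge_rows) if edge_rows else None
    return feats, edges


def feature_names(kind: str = "both") -> list[str]:
    """Names of the network feature columns (``fc``, ``seg`` or ``both``)."""
    fc = [f"fc_{n}" for n in NETWORKS]
    seg = [f"seg_{n}" for n in NETWORKS]
    if kind == "fc":
        return fc
    if kind == "seg":
        return seg
    if kind == "both":
        return fc + seg
    raise ValueError("kind must be 'fc', 'seg' or 'both'")
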