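"""Sliding-window dynamic functional connectivity and k-means brain states.

Pipeline: windowed Pearson correlation per region pair (window length L = 50
volumes, step s = 1 by default), Fisher z transform, per-edge temporal-
variability (SD) maps, k-means decomposition of the pooled window vectors into
recurring connectivity states with SSE-elbow / silhouette / Calinski-Harabasz
model selection, and per-subject state dynamics (fractional occupancy, mean
dwell time, transition counts and frequency).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import get_window
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from ._utils import derive_seed, fisher_z
from .signal_prep import SubjectTimeSeries

logger = logging.getLogger("gradstates.dfc_states")


def edge_index(P: int) -> tuple[np.ndarray, np.ndarray]:
    """Strict upper triangle, row-major — the canonical edge vectorisation."""
    return np.triu_indices(P, k=1)


def edge_names(region_ids: Sequence[str]) -> list[str]:
    iu = edge_index(len(region_ids))
    return [f"{region_ids[i]}--{region_ids[j]}" for i, j in zip(*iu)]


@dataclass(frozen=True)
class WindowedFCStack:
    """Per-subject stack of Fisher-z window connectivity vectors.

    ``z`` has shape (W, E) with E = P(P-1)/2 upper-triangle edges.
    """

    subject_id: str
    group: str
    z: np.ndarray
    window_length: int
    step: int
    n_regions: int
    window_starts: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.z.shape[0]


def n_windows(T: int, L: int, s: int) -> int:
    """floor((T - L)/s) + 1 — the governing window-count formula."""
    if T < L:
        raise ValueError(f"T={T} shorter than window length L={L}")
    return (T - L) // s + 1


def sliding_window_fc(ts: SubjectTimeSeries, window_length: int = 50,
                      step: int = 1, taper: str | None = None) -> WindowedFCStack:
    """Windowed Pearson correlations, clipped and Fisher-z transformed.

    Window w covers volumes [w*s, w*s + L).  A region that is constant within
    a window gets zero correlations there (logged).  ``taper`` optionally names
    a scipy window (e.g. "hamming") used as observation weights; the default is
    rectangular.
    """
    L, s = window_length, step
    if L < 3:
        raise ValueError("window length must be at least 3")
    T, P = ts.data.shape
    W = n_windows(T, L, s)
    starts = np.arange(W) * s
    iu = edge_index(P)
    if taper:
        w = get_window(taper, L)
        w = w / w.sum()
    else:
        w = np.full(L, 1.0 / L)
    Z = np.empty((W, len(iu[0])))
    n_const = 0
    for idx, w0 in enumerate(starts):
        seg = ts.data[w0:w0 + L]
        mean = w @ seg
        centered = seg - mean
        cov = (centered * w[:, None]).T @ centered
        sd = np.sqrt(np.diag(cov))
        const = (seg.max(axis=0) - seg.min(axis=0)) <= 0
        if const.any():
            n_const += int(const.sum())
            sd = np.where(const, 1.0, sd)
        corr = cov / np.outer(sd, sd)
        if const.any():
            corr[const, :] = 0.0
            corr[:, const] = 0.0
        Z[idx] = fisher_z(corr[iu])
    if n_const:
        logger.warning("subject %s: %d constant region-windows, correlations set to 0",
                       ts.subject_id, n_const)
    return WindowedFCStack(ts.subject_id, ts.group, Z, L, s, P, starts)


def window_majority_labels(states: np.ndarray, window_length: int = 50,
                           step: int = 1) -> np.ndarray:
    """Volume-level state path -> per-window majority state (ties -> lower id).

    Used to compare recovered window labels against a simulation's truth.
    """
    states = np.asarray(states)
    W = n_windows(len(states), window_length, step)
    out = np.empty(W, dtype=np.int64)
    for w in range(W):
        seg = states[w * step:w * step + window_length]
        out[w] = np.bincount(seg).argmax()
    return out


def dfc_variability(stack: WindowedFCStack) -> np.ndarray:
    """Per-edge sample SD (denominator W-1) of z across windows."""
    if stack.n_windows < 2:
        raise ValueError("need at least 2 windows to compute variability")
    return stack.z.std(axis=0, ddof=1)


def mean_dfc(stack: WindowedFCStack) -> np.ndarray:
    """Per-edge mean z across windows (the static-connectivity analogue)."""
    return stack.z.mean(axis=0)


# ---------------------------------------------------------------------------
# State decomposition
# ---------------------------------------------------------------------------

@dataclass
class StateModel:
    """k-means decomposition of pooled window vectors into brain states."""

    k: int
    centroids: np.ndarray  # (k, E)
    labels: dict[str, np.ndarray]  # subject -> per-window state in 0..k-1
    sse: float
    seed: int
    selection: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.labels)


def _pool(stacks: Sequence[WindowedFCStack]) -> tuple[np.ndarray, list[tuple[str, int]]]:
    sizes = [(st.subject_id, st.n_windows) for st in stacks]
    return np.vstack([st.z for st in stacks]).astype(np.float32), sizes


def _split(labels: np.ndarray, sizes: list[tuple[str, int]]) -> dict[str, np.ndarray]:
    out, pos = {}, 0
    for sid, w in sizes:
        out[sid] = labels[pos:pos + w].copy()
        pos += w
    return out


def fit_states(stacks: Sequence[WindowedFCStack], k: int, n_init: int = 20,
               seed: int = 0, max_iter: int = 300) -> StateModel:
    """k-means (k-means++ init, best of ``n_init`` restarts by SSE) on the
    pooled upper-triangle window vectors of all subjects."""
    X, sizes = _pool(stacks)
    if len(X) < k:
        raise ValueError(f"pooled window count {len(X)} < k={k}")
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter,
                random_state=seed % (2**31)).fit(X)
    return StateModel(k, km.cluster_centers_.astype(float), _split(km.labels_, sizes),
                      float(km.inertia_), seed)


@dataclass
class KSelection:
    table: pd.DataFrame  # columns k, sse, silhouette, calinski_harabasz
    chosen_k: int
    elbow_k: int | None
    silhouette_k: int
    ch_k: int
    models: dict[int, StateModel]


def _elbow(ks: np.ndarray, sse: np.ndarray) -> int | None:
    """k maximising perpendicular distance of the (normalized) SSE curve to
    the chord joining its endpoints; None when the curve is effectively linear."""
    span = sse[0] - sse[-1]
    if span <= 0:
        return None
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    y = (sse - sse[-1]) / span
    chord = y[0] + (y[-1] - y[0]) * x
    d = np.abs(y - chord) / np.hypot(1.0, y[-1] - y[0])
    if d.max() < 1e-3:  # indistinguishable from a straight line
        return None
    return int(ks[int(np.argmax(d))])


def select_k(stacks: Sequence[WindowedFCStack], k_range: Iterable[int] = range(2, 9),
             n_init: int = 20, seed: int = 0,
             silhouette_subsample: int = 2000) -> KSelection:
    """Fit every candidate k and choose the SSE-elbow.

    Silhouette and Calinski-Harabasz maxima are reported alongside; when the
    indices disagree with the elbow this is logged and the elbow wins.  An
    SSE curve that is non-monotone (restart noise) is re-fit with three times
    the restarts; a curve with no elbow falls back to the silhouette argmax.
    """
    ks = np.array(sorted(k_range))
    X, sizes = _pool(stacks)
    if len(X) < ks[-1]:
        raise ValueError("pooled window count smaller than the largest candidate k")
    rng = np.random.default_rng(derive_seed(seed, 0x51))
    sub = (rng.choice(len(X), size=silhouette_subsample, replace=False)
           if len(X) > silhouette_subsample else np.arange(len(X)))

    def _fit_all(n_restarts: int) -> tuple[list[KMeans], np.ndarray]:
        models = [KMeans(n_clusters=int(k), n_init=n_restarts,
                         random_state=seed % (2**31)).fit(X) for k in ks]
        return models, np.array([m.inertia_ for m in models])

    models, sse = _fit_all(n_init)
    if np.any(np.diff(sse) > 0):
        logger.warning("non-monotone SSE across k; re-fitting with %d restarts",
                       3 * n_init)
        models, sse = _fit_all(3 * n_init)

    sil = np.array([silhouette_score(X[sub], m.labels_[sub]) for m in models])
    ch = np.array([calinski_harabasz_score(X, m.labels_) for m in models])
    table = pd.DataFrame({"k": ks, "sse": sse, "silhouette": sil,
                          "calinski_harabasz": ch})
    elbow_k = _elbow(ks.astype(float), sse)
    sil_k = int(ks[int(np.argmax(sil))])
    ch_k = int(ks[int(np.argmax(ch))])
    if elbow_k is None:
        logger.warning("SSE curve has no elbow; falling back to silhouette argmax %d",
                       sil_k)
        chosen = sil_k
    else:
        chosen = elbow_k
        if sil_k != elbow_k or ch_k != elbow_k:
            logger.info("model-selection indices disagree (elbow=%d, silhouette=%d, "
                        "CH=%d); elbow wins", elbow_k, sil_k, ch_k)
    state_models = {
        int(k): StateModel(int(k), m.cluster_centers_.astype(float),
                           _split(m.labels_, sizes), float(m.inertia_), seed)
        for k, m in zip(ks, models)
    }
    sel = KSelection(table, chosen, elbow_k, sil_k, ch_k, state_models)
    for m in state_models.values():
        m.selection = table
    return sel


# ---------------------------------------------------------------------------
# State dynamics
# ---------------------------------------------------------------------------

def run_lengths(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of a label sequence as (label, length) pairs."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return [(int(labels[a]), int(b - a)) for a, b in zip(starts, ends)]


def state_dynamics(model: StateModel) -> pd.DataFrame:
    """Occupancy, mean dwell time, transition count/frequency per subject.

    Mean dwell of an unvisited state is NaN (flagged, to be excluded listwise
    from group tests).  Transition frequency = transitions / (W - 1).
    """
    rows = []
    for sid, lab in model.labels.items():
        W = len(lab)
        if W < 2:
            raise ValueError(f"subject {sid}: need at least 2 windows for dynamics")
        runs = run_lengths(lab)
        transitions = len(runs) - 1
        row: dict[str, float | str] = {
            "subject_id": sid,
            "n_transitions": transitions,
            "transition_frequency": transitions / (W - 1),
        }
        counts = np.bincount(lab, minlength=model.k)
        for j in range(model.k):
            row[f"occupancy_state{j + 1}"] = counts[j] / W
            lens = [l for s, l in runs if s == j]
            row[f"dwell_state{j + 1}"] = float(np.mean(lens)) if lens else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def statewise_connectivity(model: StateModel,
                           stacks: Sequence[WindowedFCStack]) -> dict[str, dict[int, np.ndarray]]:
    """Per subject and state, the mean z-vector of the windows assigned to it.

    States a subject never visits are absent from that subject's dict.
    """
    by_id = {st.subject_id: st for st in stacks}
    missing = [sid for sid in model.labels if sid not in by_id]
    if missing:
        raise ValueError(f"stacks missing for subjects: {missing[:5]}")
    out: dict[str, dict[int, np.ndarray]] = {}
    for sid, lab in model.labels.items():
        st = by_id[sid]
        if len(lab) != st.n_windows:
            raise ValueError(f"subject {sid}: label/window count mismatch")
        per_state = {}
        for j in range(model.k):
            mask = lab == j
            if mask.any():
                per_state[j] = st.z[mask].mean(axis=0)
        out[sid] = per_state
    return out
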