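"""Synthetic two-group cohorts with known dynamic-connectivity and gradient structure.

The generator emulates the structure of a paediatric focal-epilepsy resting-state
study: 34 patients and 32 controls, ~200 retained volumes at TR = 2 s, band-limited
(0.01-0.08 Hz) signals.  Three ground-truth layers are planted so that every
downstream stage of the pipeline is falsifiable:

* **Connectivity states** — a Markov chain over ``n_states`` covariance regimes.
  Each state is a random bipartition pattern ``corr(I + g * u u^T)`` with
  ``u in {-1,+1}^P``: regions within the same block are positively correlated,
  regions across blocks anticorrelated, and the block pattern differs between
  states, which is what sliding-window k-means is meant to recover.
* **Group connectivity effects** — Fisher-z shifts on designated default-mode /
  sensorimotor edges, applied to the patient group's state covariances only
  (three positive shifts and one negative by default, mirroring the sign
  pattern typically reported for this contrast).
* **A smooth connectivity manifold** — per-network voxels carry a 1-D latent
  coordinate; their 400-parcel connectivity profiles vary smoothly along it,
  with a latent offset added for patients in designated voxel sets.  Diffusion
  embedding should recover the coordinate as gradient 1.

Clinical covariates (ages, one-group Wechsler scores, disease duration) are drawn
with configurable means/SDs, and requested gradient-score/clinical correlations
are planted by mixing the standardized gradient score into the clinical score.

All randomness flows from a single master seed through per-subject derived
seeds, so any subset of a cohort is reproducible.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import derive_seed, rng_for
from .signal_prep import (
    SUBCORTICAL,
    YEO7,
    NetworkMap,
    SubjectTimeSeries,
    bandpass,
    write_manifest,
    write_network_map,
    write_timeseries,
)

logger = logging.getLogger("gradstates.synthetic_cohort")

PATIENT = "patient"
CONTROL = "control"


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study-level parameters of the simulated cohort.

    ``stickiness`` is the Markov self-transition probability per volume
    (0.9 -> geometric mean dwell of 10 volumes = 20 s at TR 2 s).
    ``state_strength`` g sets the planted correlation magnitude g/(1+g)
    (g = 1 -> off-diagonal correlations of +/-0.5).
    ``effect_edges`` is a list of (region_i, region_j, z_shift) applied to the
    patient group only; ``None`` selects default DMN-SMN edges, ``()`` disables
    group effects.
    """

    n_patients: int = 34
    n_controls: int = 32
    T: int = 200
    TR: float = 2.0
    P: int = 90
    n_states: int = 4
    stickiness: float = 0.9
    ar_coef: float = 0.1
    state_strength: float = 1.0
    separation_floor: float | None = None  # Frobenius floor; None -> auto
    effect_edges: tuple[tuple[int, int, float], ...] | None = None
    low_hz: float = 0.01
    high_hz: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.n_patients + self.n_controls < 4:
            raise ValueError("need at least 4 subjects in total")
        if not (0.0 <= self.stickiness < 1.0):
            raise ValueError("stickiness must lie in [0, 1)")
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        if self.P < 4:
            raise ValueError("need at least 4 regions")
        if not (0.0 <= self.ar_coef < 1.0):
            raise ValueError("ar_coef must lie in [0, 1)")
        if self.effect_edges is not None:
            for (i, j, _) in self.effect_edges:
                if not (0 <= i < self.P and 0 <= j < self.P and i != j):
                    raise ValueError(f"effect edge ({i},{j}) references invalid regions")

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    def auto_separation_floor(self) -> float:
        # a random bipartition pair differs on ~half the edges by 2g/(1+g);
        # 25% of the expected distance catches only degenerate draws
        g = self.state_strength
        expected = np.sqrt(self.P * (self.P - 1)) * g / (1.0 + g)
        return 0.25 * expected


@dataclass(frozen=True)
class GradientManifoldSpec:
    """Parameters of the smooth 1-D connectivity manifold per network.

    Voxels sit on an ascending latent coordinate grid in [0, 1]; the profile of
    voxel i over the 400 parcels is a Gaussian bump centred at its coordinate
    (width ``smoothness``) plus i.i.d. noise, so profiles of nearby voxels
    correlate more strongly.  ``group_shift_regions`` lists (voxel index set,
    latent offset) perturbations applied to patients only.
    """

    n_voxels: int = 150
    n_parcels: int = 400
    smoothness: float = 0.08
    noise_sd: float = 0.25
    amplitude: float = 1.0
    n_regions: int = 6
    group_shift_regions: tuple[tuple[tuple[int, ...], float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_voxels < 50:
            raise ValueError("need at least 50 voxels")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive (0 is degenerate)")
        seen: set[int] = set()
        for idx, _ in self.group_shift_regions:
            s = set(idx)
            if s & seen:
                raise ValueError("group_shift_regions voxel sets must be disjoint")
            if not s <= set(range(self.n_voxels)):
                raise ValueError("group_shift_regions reference invalid voxels")
            seen |= s

    def latent_coords(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_voxels)

    def region_labels(self) -> np.ndarray:
        """Contiguous voxel regions along the latent coordinate."""
        return np.minimum(
            (np.arange(self.n_voxels) * self.n_regions) // self.n_voxels,
            self.n_regions - 1,
        )


#: (mean, SD) per Wechsler index for the patient group; medians/IQRs in the
#: motivating cohort were converted to normal parameters where needed
DEFAULT_SCORE_PARAMS: dict[str, tuple[float, float]] = {
    "verbal_comprehension": (31.41, 11.293),
    "perceptual_processing": (29.0, 11.0),
    "working_memory": (19.56, 4.825),
    "processing_speed": (17.7, 4.4),
    "full_scale": (97.68, 23.708),
}


@dataclass(frozen=True)
class ClinicalSpec:
    """Demographics and cognitive-score distributions.

    Ages follow the two observed group distributions; Wechsler indices and
    disease duration are generated for patients only.  ``planted_correlations``
    entries (score name, gradient region name, target r) mix the standardized
    gradient score into the clinical score at weight r.
    """

    age_patients: tuple[float, float] = (10.41, 1.376)
    age_controls: tuple[float, float] = (11.28, 2.439)
    sex_counts_patients: tuple[int, int] = (15, 19)  # (male, female)
    sex_counts_controls: tuple[int, int] = (19, 14)
    duration_lognorm: tuple[float, float] = (0.0, 0.9)  # (mu, sigma) of log-years
    score_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_PARAMS)
    )
    planted_correlations: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self):
        for name, (_, sd) in self.score_params.items():
            if sd <= 0:
                raise ValueError(f"score {name!r}: SD must be positive")
        for score, _, r in self.planted_correlations:
            if score not in self.score_params:
                raise ValueError(f"unknown score name {score!r}")
            if not abs(r) < 1:
                raise ValueError(f"target correlation for {score!r} must satisfy |r| < 1")


# ---------------------------------------------------------------------------
# State model
# ---------------------------------------------------------------------------

def default_network_map(P: int) -> NetworkMap:
    """Contiguous region blocks over the 7 Yeo networks plus a subcortical rest."""
    labels = {}
    n_cortical = (P * 7) // 8 if P >= 16 else P
    per = n_cortical // 7
    for i in range(P):
        rid = f"r{i:03d}"
        labels[rid] = YEO7[min(i // per, 6)] if i < n_cortical else SUBCORTICAL
    return NetworkMap(labels)


def default_effect_edges(spec: CohortSpec, nmap: NetworkMap | None = None,
                         z_shift: float = 0.5) -> tuple[tuple[int, int, float], ...]:
    """Default DMN-SMN group effects: three positive shifts, one negative."""
    nmap = nmap or default_network_map(spec.P)
    ids = [f"r{i:03d}" for i in range(spec.P)]
    dmn = [ids.index(r) for r in nmap.regions_of("default_mode")]
    smn = [ids.index(r) for r in nmap.regions_of("somatomotor")]
    if not dmn or not smn:
        raise ValueError("network map has no DMN or SMN regions for effect edges")
    n_pairs = min(4, len(dmn), len(smn))
    signs = [+1.0, +1.0, +1.0, -1.0][:n_pairs]
    if n_pairs == 4:
        pass
    elif n_pairs > 1:
        signs[-1] = -1.0  # keep the mixed sign pattern whenever possible
    return tuple((dmn[i], smn[i], signs[i] * z_shift) for i in range(n_pairs))


def _nearest_correlation(C: np.ndarray, min_eig: float = 1e-6,
                         max_retries: int = 50) -> np.ndarray:
    """Repair a symmetric matrix into a positive-definite correlation matrix."""
    C = (C + C.T) / 2.0
    for _ in range(max_retries):
        w, V = np.linalg.eigh(C)
        if w[0] > min_eig:
            return C
        w = np.clip(w, min_eig, None)
        C = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        C = (C + C.T) / 2.0
    raise RuntimeError("failed to repair covariance to positive definite")


def generate_state_model(
    spec: CohortSpec, max_retries: int = 50
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Transition matrix and per-state covariance (correlation) matrices.

    The transition matrix has ``stickiness`` on the diagonal and the remaining
    mass spread uniformly.  State covariances are bipartition sign patterns
    (see module docstring); draws whose pairwise Frobenius separation falls
    below the floor are rejected and re-drawn.
    """
    k, P, g = spec.n_states, spec.P, spec.state_strength
    trans = np.full((k, k), (1.0 - spec.stickiness) / (k - 1))
    np.fill_diagonal(trans, spec.stickiness)

    floor = (spec.separation_floor if spec.separation_floor is not None
             else spec.auto_separation_floor())
    rng = rng_for(spec.seed, 0xC0)
    for attempt in range(max_retries):
        covs = []
        for _ in range(k):
            u = rng.choice([-1.0, 1.0], size=P)
            C = np.eye(P) * (1.0 + g) + g * (np.outer(u, u) - np.eye(P))
            d = np.sqrt(np.diag(C))
            covs.append(_nearest_correlation(C / np.outer(d, d)))
        dists = [np.linalg.norm(covs[a] - covs[b])
                 for a in range(k) for b in range(a + 1, k)]
        if min(dists) >= floor:
            if attempt:
                logger.info("state model accepted after %d redraws", attempt)
            return trans, covs
    raise RuntimeError(
        f"could not draw {k} states separated by {floor:.3g} in {max_retries} tries"
    )


def apply_effect_edges(covs: Sequence[np.ndarray],
                       effect_edges: Sequence[tuple[int, int, float]]) -> list[np.ndarray]:
    """Shift state correlations at the given edges on the Fisher-z scale."""
    out = []
    for C in covs:
        C = C.copy()
        for i, j, dz in effect_edges:
            r_new = np.tanh(np.arctanh(np.clip(C[i, j], -0.999999, 0.999999)) + dz)
            C[i, j] = C[j, i] = r_new
        out.append(_nearest_correlation(C))
    return out


# ---------------------------------------------------------------------------
# Subject simulation
# ---------------------------------------------------------------------------

def _sample_markov_chain(trans: np.ndarray, T: int,
                         rng: np.random.Generator) -> np.ndarray:
    k = trans.shape[0]
    states = np.empty(T, dtype=np.int64)
    states[0] = rng.integers(k)
    u = rng.random(T - 1)
    cum = np.cumsum(trans, axis=1)
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")
    return states


def simulate_subject(
    spec: CohortSpec,
    group: str,
    model: tuple[np.ndarray, Sequence[np.ndarray]],
    seed: int,
    region_ids: Sequence[str] | None = None,
) -> tuple[SubjectTimeSeries, np.ndarray]:
    """One subject: Markov state path, AR(1)-coloured state-covariance draws,
    band-pass filter.  Returns the series and the true volume-level state path.
    """
    if group not in (PATIENT, CONTROL):
        raise ValueError(f"group must be {PATIENT!r} or {CONTROL!r}")
    trans, covs = model
    if group == PATIENT and spec.effect_edges is not None and len(spec.effect_edges):
        covs = apply_effect_edges(covs, spec.effect_edges)
    rng = np.random.default_rng(seed)
    states = _sample_markov_chain(trans, spec.T, rng)
    chols = [np.linalg.cholesky(C) for C in covs]
    innov = rng.standard_normal((spec.T, spec.P))
    X = np.empty((spec.T, spec.P))
    phi = spec.ar_coef
    c = np.sqrt(1.0 - phi**2)
    x = chols[states[0]] @ innov[0]
    X[0] = x
    for t in range(1, spec.T):
        x = phi * x + c * (chols[states[t]] @ innov[t])
        X[t] = x
    ts = SubjectTimeSeries(
        subject_id="tmp", group=group, data=X, tr=spec.TR,
        region_ids=tuple(region_ids) if region_ids else (),
    )
    ts = bandpass(ts, spec.low_hz, spec.high_hz)  # raises if T < filter transient
    return ts, states


@dataclass
class Cohort:
    """A generated cohort plus every piece of planted ground truth."""

    spec: CohortSpec
    subjects: list[SubjectTimeSeries]
    clinical: pd.DataFrame
    network_map: NetworkMap
    transition_matrix: np.ndarray
    state_covs: list[np.ndarray]
    true_states: dict[str, np.ndarray]
    effect_edges: tuple[tuple[int, int, float], ...]

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])


def generate_cohort(spec: CohortSpec,
                    clinical_spec: ClinicalSpec | None = None,
                    gradient_scores: pd.DataFrame | None = None) -> Cohort:
    """Generate the full two-group cohort from a single master seed."""
    nmap = default_network_map(spec.P)
    if spec.effect_edges is None:
        spec = CohortSpec(**{**spec.__dict__, "effect_edges":
                             default_effect_edges(spec, nmap)})
    model = generate_state_model(spec)
    region_ids = [f"r{i:03d}" for i in range(spec.P)]
    subjects, true_states = [], {}
    groups = [PATIENT] * spec.n_patients + [CONTROL] * spec.n_controls
    for i, group in enumerate(groups):
        sid = f"sub{i:03d}"
        ts, states = simulate_subject(
            spec, group, model, derive_seed(spec.seed, 1, i), region_ids
        )
        ts = SubjectTimeSeries(sid, group, ts.data, ts.tr, ts.region_ids)
        subjects.append(ts)
        true_states[sid] = states
    clinical = generate_clinical(
        clinical_spec or ClinicalSpec(),
        [(s.subject_id, s.group) for s in subjects],
        gradient_scores,
        derive_seed(spec.seed, 2),
    )
    return Cohort(spec, subjects, clinical, nmap, model[0], model[1],
                  true_states, spec.effect_edges or ())


# ---------------------------------------------------------------------------
# Gradient manifold
# ---------------------------------------------------------------------------

def simulate_network_voxels(
    spec: GradientManifoldSpec, group: str, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-by-parcel Fisher-z connectivity with a smooth 1-D latent structure.

    Returns (n_voxels x n_parcels matrix, true latent coordinates).  For
    patients, voxels in ``group_shift_regions`` have their latent coordinate
    offset before profile construction — an additive profile perturbation that
    translates into a gradient-score shift downstream.
    """
    if group not in (PATIENT, CONTROL):
        raise ValueError(f"group must be {PATIENT!r} or {CONTROL!r}")
    rng = np.random.default_rng(seed)
    lat = spec.latent_coords()
    eff = lat.copy()
    if group == PATIENT:
        for idx, delta in spec.group_shift_regions:
            eff[list(idx)] += delta
    centers = np.linspace(0.0, 1.0, spec.n_parcels)
    prof = spec.amplitude * np.exp(
        -((eff[:, None] - centers[None, :]) ** 2) / (2.0 * spec.smoothness**2)
    )
    prof = prof + spec.noise_sd * rng.standard_normal(prof.shape)
    return prof, lat


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------

def generate_clinical(
    spec: ClinicalSpec,
    cohort: Sequence[tuple[str, str]],
    gradient_scores: pd.DataFrame | None,
    seed: int,
) -> pd.DataFrame:
    """Manifest table: demographics for everyone, scores/duration for patients.

    ``gradient_scores`` (patients x named regions) supplies the signal mixed
    into clinical scores for ``planted_correlations``; required whenever any
    correlation is planted.
    """
    rng = np.random.default_rng(seed)
    sids = [s for s, _ in cohort]
    groups = [g for _, g in cohort]
    pat = [i for i, g in enumerate(groups) if g == PATIENT]
    con = [i for i, g in enumerate(groups) if g == CONTROL]
    n = len(cohort)

    age = np.empty(n)
    age[pat] = spec.age_patients[0] + spec.age_patients[1] * rng.standard_normal(len(pat))
    age[con] = spec.age_controls[0] + spec.age_controls[1] * rng.standard_normal(len(con))

    sex = np.empty(n, dtype=object)
    for idx, (m, f) in ((pat, spec.sex_counts_patients), (con, spec.sex_counts_controls)):
        labels = np.array(["M"] * m + ["F"] * f, dtype=object)
        if len(labels) < len(idx):
            labels = np.concatenate([
                labels, rng.choice(["M", "F"], size=len(idx) - len(labels))])
        sex[idx] = rng.permutation(labels)[: len(idx)]

    duration = np.full(n, np.nan)
    mu, sigma = spec.duration_lognorm
    duration[pat] = np.exp(mu + sigma * rng.standard_normal(len(pat)))

    planted = {score: (region, r) for score, region, r in spec.planted_correlations}
    if planted:
        if gradient_scores is None:
            raise ValueError("planted correlations require gradient scores for patients")
        missing = [s for s, _ in cohort if s in {sids[i] for i in pat}
                   and s not in gradient_scores.index]
        if missing:
            raise ValueError(f"gradient scores missing for patients: {missing[:5]}")
        unknown = [reg for reg, _ in planted.values()
                   if reg not in gradient_scores.columns]
        if unknown:
            raise ValueError(f"unknown gradient region names: {unknown}")

    table: dict[str, np.ndarray] = {
        "subject_id": np.array(sids, dtype=object),
        "group": np.array(groups, dtype=object),
        "age": age,
        "sex": sex,
        "duration_years": duration,
    }
    for score, (mean, sd) in spec.score_params.items():
        vals = np.full(n, np.nan)
        eps = rng.standard_normal(len(pat))
        if score in planted:
            region, r = planted[score]
            g = gradient_scores.loc[[sids[i] for i in pat], region].to_numpy(float)
            gstd = np.std(g, ddof=1)
            if gstd == 0:
                raise ValueError(f"gradient region {region!r} has zero variance")
            z = (g - g.mean()) / gstd
            mix = r * z + np.sqrt(1.0 - r**2) * eps
        else:
            mix = eps
        vals[pat] = mean + sd * mix
        table[score] = vals
    return pd.DataFrame(table)


# ---------------------------------------------------------------------------
# External interface: on-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(outdir: str | Path, cohort: Cohort) -> dict[str, str]:
    """Write the delimited-text cohort contract plus the ground-truth JSON."""
    outdir = Path(outdir)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    for ts in cohort.subjects:
        write_timeseries(ts_dir / f"{ts.subject_id}.tsv", ts)
    write_manifest(outdir / "manifest.csv", cohort.clinical)
    write_network_map(outdir / "network_map.tsv", cohort.network_map)
    truth = {
        "true_states": {sid: st.tolist() for sid, st in cohort.true_states.items()},
        "effect_edges": [list(e) for e in cohort.effect_edges],
        "transition_matrix": cohort.transition_matrix.tolist(),
        "seed": cohort.spec.seed,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh)
    return {
        "manifest": str(outdir / "manifest.csv"),
        "timeseries_dir": str(ts_dir),
        "network_map": str(outdir / "network_map.tsv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
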